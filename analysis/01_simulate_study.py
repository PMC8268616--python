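"""Generate the reference synthetic study and export it in standard formats.

Writes the single-cell matrix as a 10x-style MTX triplet plus metadata TSV
and the bulk cohorts as expression/clinical TSV pairs under scratch/study/
(large, regenerable), and a small composition summary under results/.
"""
import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "config", Path(__file__).parent / "00_config.py")
config = importlib.util.module_from_spec(spec)
spec.loader.exec_module(config)

from phenosig.sc_io import write_10x_matrix, write_bulk_cohort


def main():
    matrix, cohorts, truth = config.make_study()
    out = config.SCRATCH / "study"
    write_10x_matrix(matrix, out / "single_cell")
    for cohort in cohorts:
        write_bulk_cohort(cohort, out / f"{cohort.cohort_id}_expr.tsv",
                          out / f"{cohort.cohort_id}_clinical.tsv")
    truth.mixture_fractions.to_csv(out / "true_fractions.tsv", sep="\t")

    config.RESULTS.mkdir(exist_ok=True)
    summary = pd.DataFrame({
        "n_cells": matrix.subclusters.value_counts(),
        "n_planted_markers": {s: len(g)
                              for s, g in truth.planted_markers.items()},
    })
    summary.to_csv(config.RESULTS / "01_study_summary.tsv", sep="\t")
    print(f"Simulated {matrix.n_genes} genes x {matrix.n_cells} cells across "
          f"{summary.shape[0]} subclusters and {len(cohorts)} bulk cohorts "
          f"({len(cohorts[0].samples)} samples each).")
    print(f"Data written to {out}; summary to results/01_study_summary.tsv")


if __name__ == "__main__":
    main()
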