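"""Synthetic single-cell, bulk-cohort, survival and copy-number generators.

Every downstream stage of the pipeline (marker cascade, SSZ scoring,
signature deconvolution, survival meta-analysis, CNA concordance) can be
exercised against a known ground truth:

* single-cell UMI counts are negative-binomial with planted subcluster
  markers whose in-subcluster detection rate is controlled exactly through
  the NB zero-probability;
* bulk samples are convex (Dirichlet) mixtures of the subcluster mean
  expression profiles plus Gaussian noise on the log scale;
* overall-survival times follow an exponential proportional-hazards model
  whose log-hazard is linear in standardized mixture fractions plus
  age/stage/debulking effects, with independent exponential censoring;
* copy-number cells scale tumour-cell gene means by (copy_number/2)^effect.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .sc_io import BulkCohort, CNProfile, SingleCellMatrix, normalize

SITES = ["ovary", "omentum", "peritoneum"]


@dataclass
class SimTruth:
    """Ground truth recorded by the generators."""

    planted_markers: dict[str, list[str]] = field(default_factory=dict)
    subcluster_profiles: pd.DataFrame | None = None   # genes x subclusters
    mixture_fractions: pd.DataFrame | None = None     # samples x subclusters
    beta_true: dict[str, float] = field(default_factory=dict)
    seed: int | None = None


def nb_mean_for_detection(detection: float, dispersion: float) -> float:
    """Mean of a NB(mean, dispersion) with P(count >= 1) = detection.

    ``dispersion`` is the gamma shape r (variance = mu + mu^2/r), so
    P(0) = (r / (r + mu))^r and mu = r * ((1 - d)^(-1/r) - 1).
    """
    if not 0 <= detection < 1:
        raise ConfigError("detection rate must be in [0, 1)")
    r = dispersion
    return r * ((1.0 - detection) ** (-1.0 / r) - 1.0)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
               n_cols: int) -> np.ndarray:
    """Draw a genes x n_cols NB count matrix with per-gene means."""
    r = dispersion
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p[:, None], size=(len(p), n_cols))


def simulate_single_cell(n_subclusters: int = 6, cells_per_subcluster: int = 500,
                         n_genes: int = 1000, markers_per_subcluster: int = 20,
                         marker_detection_target: float | None = 0.8,
                         background_detection: float = 0.02,
                         fold_change: float = 4.0, dispersion: float = 0.5,
                         n_patients: int = 7, seed: int = 0
                         ) -> tuple[SingleCellMatrix, SimTruth]:
    """Negative-binomial scRNA-seq counts with planted subcluster markers.

    Each subcluster owns ``markers_per_subcluster`` disjoint marker genes.
    Background genes have per-gene means drawn around the level implied by
    ``background_detection`` (log-normal spread, shared across subclusters).
    In its own subcluster a marker's mean is solved from
    ``marker_detection_target`` so the realized detection rate matches the
    target; when the target is ``None`` the mean is ``fold_change`` times the
    gene's background mean instead (``fold_change=1`` is a global null).
    Patients/samples are assigned round-robin within each subcluster.
    """
    if markers_per_subcluster * n_subclusters > n_genes:
        raise ConfigError("more planted markers than genes")
    if marker_detection_target is not None and not 0 < marker_detection_target <= 1:
        raise ConfigError("marker_detection_target must be in (0, 1]")
    if not 0 <= background_detection < 1:
        raise ConfigError("background_detection must be in [0, 1)")
    rng = np.random.default_rng(seed)

    subclusters = [f"SC{k + 1}" for k in range(n_subclusters)]
    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)], dtype=object)
    mu_bg_level = nb_mean_for_detection(background_detection, dispersion)
    # per-gene baseline spread mimics the long-tailed mean-expression
    # distribution of droplet data without moving the detection regime
    gene_base = mu_bg_level * rng.lognormal(0.0, 0.5, size=n_genes)

    planted: dict[str, list[str]] = {}
    mean_matrix = np.tile(gene_base[:, None], (1, n_subclusters))
    for k, sub in enumerate(subclusters):
        idx = np.arange(k * markers_per_subcluster, (k + 1) * markers_per_subcluster)
        planted[sub] = list(genes[idx])
        if marker_detection_target is None:
            mean_matrix[idx, k] = gene_base[idx] * fold_change
        else:
            mean_matrix[idx, k] = nb_mean_for_detection(
                min(marker_detection_target, 1 - 1e-12), dispersion)

    blocks, cell_ids, meta_rows = [], [], []
    for k, sub in enumerate(subclusters):
        blocks.append(_nb_sample(rng, mean_matrix[:, k], dispersion,
                                 cells_per_subcluster))
        for j in range(cells_per_subcluster):
            pat = f"P{j % n_patients + 1}"
            cell_ids.append(f"{sub}_CELL{j + 1:05d}")
            meta_rows.append({"patient_id": pat, "sample_id": f"{pat}T",
                              "tissue_type": "tumour",
                              "site": SITES[j % len(SITES)],
                              "major_cell_type": "synthetic",
                              "subcluster": sub})
    counts = sp.csr_matrix(np.concatenate(blocks, axis=1))
    meta = pd.DataFrame(meta_rows, index=cell_ids)
    matrix = SingleCellMatrix(counts, genes, np.array(cell_ids, dtype=object), meta)

    norm = normalize(matrix).toarray()
    profiles = pd.DataFrame(
        {sub: norm[:, (matrix.subclusters == sub).values].mean(axis=1)
         for sub in subclusters}, index=genes)
    truth = SimTruth(planted_markers=planted, subcluster_profiles=profiles,
                     seed=seed)
    return matrix, truth


def simulate_bulk_cohorts(profiles: pd.DataFrame, n_cohorts: int = 6,
                          samples_per_cohort: int = 250,
                          fraction_concentration: float = 1.0,
                          noise_sd: float = 0.1, seed: int = 0
                          ) -> tuple[list[BulkCohort], SimTruth]:
    """Bulk cohorts as Dirichlet mixtures of subcluster profiles plus noise.

    ``profiles`` is genes x subclusters (log-scale mean expression).  Each
    sample's expression is sum_k fraction_k * profile_k with N(0, noise_sd)
    noise added on the log scale.  Clinical tables are not attached here; use
    :func:`simulate_survival` on the recorded fractions.
    """
    if fraction_concentration <= 0:
        raise ConfigError("fraction_concentration must be positive")
    rng = np.random.default_rng(seed)
    subclusters = list(profiles.columns)
    P = profiles.values
    cohorts, frac_frames = [], []
    for c in range(n_cohorts):
        cid = f"cohort_{c + 1}"
        frac = rng.dirichlet([fraction_concentration] * len(subclusters),
                             size=samples_per_cohort)
        expr = frac @ P.T + rng.normal(0.0, noise_sd,
                                       size=(samples_per_cohort, P.shape[0]))
        samples = [f"{cid}_S{i + 1:04d}" for i in range(samples_per_cohort)]
        cohorts.append(BulkCohort(cid, pd.DataFrame(expr, index=samples,
                                                    columns=profiles.index)))
        frac_frames.append(pd.DataFrame(frac, index=samples, columns=subclusters))
    truth = SimTruth(mixture_fractions=pd.concat(frac_frames), seed=seed)
    return cohorts, truth


def simulate_survival(fractions: pd.DataFrame,
                      beta_per_subcluster: dict[str, float] | None = None,
                      covariate_effects: dict | None = None,
                      baseline_hazard: float = 1.0 / 1000,
                      censor_rate: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Exponential proportional-hazards survival for mixture samples.

    The linear predictor is sum_k beta_k * standardized(fraction_k) plus
    age/stage/debulking terms; event times are exponential with rate
    baseline_hazard * exp(lp), censoring times independent exponential with
    rate chosen so that a baseline subject is censored with probability
    ``censor_rate``.  Returns a clinical table indexed like ``fractions``.
    """
    if not 0 <= censor_rate < 1:
        raise ConfigError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(fractions)
    beta = beta_per_subcluster or {}
    eff = {"age": 0.02, "stage": 0.15, "debulking": 0.3}
    eff.update(covariate_effects or {})

    age = rng.normal(60.0, 10.0, size=n)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.05, 0.1, 0.55, 0.3])
    debulking = rng.choice(["optimal", "suboptimal"], size=n, p=[0.6, 0.4])
    stage_num = pd.Series(stage).map({"I": 0, "II": 1, "III": 2, "IV": 3}).values

    lp = (eff["age"] * (age - 60.0) + eff["stage"] * stage_num
          + eff["debulking"] * (debulking == "suboptimal"))
    for sub, b in beta.items():
        f = fractions[sub].values
        sd = f.std(ddof=1)
        lp = lp + b * (f - f.mean()) / (sd if sd > 0 else 1.0)

    t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(lp)))
    if censor_rate > 0:
        rate_c = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_days = np.minimum(t_event, t_cens)
    os_days = np.maximum(os_days, 1e-6)
    return pd.DataFrame({"os_days": os_days,
                         "os_event": (t_event <= t_cens).astype(int),
                         "age": age, "stage": stage, "debulking": debulking},
                        index=fractions.index)


def simulate_study(n_subclusters: int = 6, cells_per_subcluster: int = 500,
                   n_genes: int = 1000, markers_per_subcluster: int = 20,
                   n_cohorts: int = 6, samples_per_cohort: int = 250,
                   noise_sd: float = 0.1,
                   beta_per_subcluster: dict[str, float] | None = None,
                   censor_rate: float = 0.3, seed: int = 0, **sc_kwargs
                   ) -> tuple[SingleCellMatrix, list[BulkCohort], SimTruth]:
    """Wire single-cell, bulk and survival generators into one study.

    Seeds for the three stages are derived from ``seed``; ground truth from
    all stages is merged into one :class:`SimTruth`.
    """
    ss = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    matrix, truth = simulate_single_cell(
        n_subclusters=n_subclusters, cells_per_subcluster=cells_per_subcluster,
        n_genes=n_genes, markers_per_subcluster=markers_per_subcluster,
        seed=int(ss[0]), **sc_kwargs)
    cohorts, bulk_truth = simulate_bulk_cohorts(
        truth.subcluster_profiles, n_cohorts=n_cohorts,
        samples_per_cohort=samples_per_cohort, noise_sd=noise_sd,
        seed=int(ss[1]))
    truth.mixture_fractions = bulk_truth.mixture_fractions
    truth.beta_true = dict(beta_per_subcluster or {})
    for i, cohort in enumerate(cohorts):
        frac = truth.mixture_fractions.loc[cohort.samples]
        cohort.clinical = simulate_survival(
            frac, beta_per_subcluster=beta_per_subcluster,
            censor_rate=censor_rate, seed=int(ss[2]) + i)
        cohort.__post_init__()
    truth.seed = seed
    return matrix, cohorts, truth


def simulate_cn_cells(cn_profile: CNProfile, n_tumour_cells: int = 300,
                      n_stromal_cells: int = 300,
                      genes_with_positions: pd.DataFrame | None = None,
                      n_genes: int = 500, effect_size: float = 1.0,
                      base_detection: float = 0.3, dispersion: float = 0.5,
                      seed: int = 0) -> tuple[SingleCellMatrix, pd.DataFrame]:
    """Tumour vs stromal cells whose expression tracks a copy-number profile.

    Tumour cells' per-gene NB mean is scaled by (copy_number/2)**effect_size
    for the segment containing the gene start; stromal cells are unscaled.
    When ``genes_with_positions`` (gene, chrom, start) is None, ``n_genes``
    genes are placed uniformly across the profile's segments.  Returns the
    matrix and the gene-position table used.
    """
    rng = np.random.default_rng(seed)
    seg = cn_profile.segments
    if genes_with_positions is None:
        rows = []
        for i in range(n_genes):
            s = seg.iloc[i % len(seg)]
            start = int(s["start"] + (i // len(seg) + 1) *
                        (s["end"] - s["start"]) / (n_genes // len(seg) + 2))
            rows.append({"gene": f"GENE{i + 1:05d}", "chrom": s["chrom"],
                         "start": min(start, int(s["end"]) - 1)})
        genes_with_positions = pd.DataFrame(rows)
    gp = genes_with_positions
    cn = np.full(len(gp), 2.0)
    for i, row in gp.iterrows():
        hit = seg[(seg["chrom"] == row["chrom"]) & (seg["start"] <= row["start"])
                  & (row["start"] < seg["end"])]
        if len(hit):
            cn[i] = float(hit["copy_number"].iloc[0])

    base = nb_mean_for_detection(base_detection, dispersion) * \
        rng.lognormal(0.0, 0.3, size=len(gp))
    tum = _nb_sample(rng, base * (cn / 2.0) ** effect_size, dispersion,
                     n_tumour_cells)
    stro = _nb_sample(rng, base, dispersion, n_stromal_cells)
    counts = sp.csr_matrix(np.concatenate([tum, stro], axis=1))
    cells = ([f"TUM_CELL{i + 1:05d}" for i in range(n_tumour_cells)] +
             [f"STR_CELL{i + 1:05d}" for i in range(n_stromal_cells)])
    labels = ["tumour"] * n_tumour_cells + ["stromal"] * n_stromal_cells
    meta = pd.DataFrame({"patient_id": "P1", "sample_id": "P1T",
                         "tissue_type": "tumour", "site": "ovary",
                         "major_cell_type": labels, "subcluster": labels},
                        index=cells)
    return (SingleCellMatrix(counts, gp["gene"].values,
                             np.array(cells, dtype=object), meta),
            gp)
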