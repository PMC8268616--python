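"""Subcluster-specific z-scores (SSZ) of bulk samples.

Within a cohort, each marker gene's expression is z-scored over samples
(sample SD, ddof=1); a sample's SSZ score for a subcluster is the mean of
those z-scores over the subcluster's transcriptomic markers.  Scores are
deliberately within-cohort quantities and have mean zero per cohort.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .marker_selection import MarkerSet
from .sc_io import BulkCohort

log = logging.getLogger(__name__)


def zscore_genes(cohort: BulkCohort, genes) -> pd.DataFrame:
    """Genes x samples z-scores within the cohort.

    Genes absent from the platform, and zero-variance genes, are dropped
    with a logged warning.
    """
    if len(cohort.samples) < 3:
        raise ValidationError(
            f"{cohort.cohort_id}: need >= 3 samples to z-score")
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in cohort.expr.columns]
    absent = len(genes) - len(present)
    if absent:
        log.warning("%s: %d/%d genes absent from platform",
                    cohort.cohort_id, absent, len(genes))
    x = cohort.expr[present].T  # genes x samples
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("%s: dropping %d zero-variance genes",
                    cohort.cohort_id, int(constant.sum()))
        x, sd = x[~constant], sd[~constant]
    return x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)


def ssz_scores(z: pd.DataFrame, marker_set: MarkerSet | dict) -> pd.DataFrame:
    """Samples x subclusters SSZ matrix from a genes x samples z matrix.

    Subclusters with no marker gene on the platform get NaN scores.
    """
    markers = marker_set.markers if isinstance(marker_set, MarkerSet) else marker_set
    if not markers or all(len(g) == 0 for g in markers.values()):
        raise ValidationError("empty marker set")
    out = {}
    for sub, genes in markers.items():
        present = [g for g in dict.fromkeys(genes) if g in z.index]
        out[sub] = (z.loc[present].mean(axis=0) if present
                    else pd.Series(np.nan, index=z.columns))
    scores = pd.DataFrame(out)
    scores.attrs["method"] = "SSZ"
    return scores


def score_cohort(cohort: BulkCohort, marker_set: MarkerSet | dict) -> pd.DataFrame:
    """Convenience: z-score all marker genes, then average per subcluster."""
    markers = marker_set.markers if isinstance(marker_set, MarkerSet) else marker_set
    all_genes = [g for genes in markers.values() for g in genes]
    return ssz_scores(zscore_genes(cohort, all_genes), markers)
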