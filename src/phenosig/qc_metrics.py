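"""Composition, robustness and tumour-cell identification statistics.

Shannon indices flag patient- or sample-dominated subclusters; NMI and ARI
quantify clustering agreement across parameter scans; the CNA-concordance
score correlates per-cell expression z-scores with an external copy-number
segment profile to mark malignant cells.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .errors import ValidationError
from .sc_io import CNProfile, SingleCellMatrix, normalize

log = logging.getLogger(__name__)


def shannon_index(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i of a composition vector."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any() or c.sum() <= 0:
        raise ValidationError("composition counts must be >= 0 with sum > 0")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def subcluster_shannon(matrix: SingleCellMatrix, by: str = "patient_id"
                       ) -> pd.Series:
    """Shannon index of each subcluster's patient (or sample) composition."""
    meta = matrix.cell_meta
    return meta.groupby("subcluster")[by].apply(
        lambda s: shannon_index(s.value_counts().values)).rename("shannon")


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information, I(A;B) / mean(H(A), H(B))."""
    if len(labels_a) != len(labels_b):
        raise ValidationError("label vectors differ in length")
    return float(normalized_mutual_info_score(labels_a, labels_b,
                                              average_method="arithmetic"))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index under the permutation model."""
    if len(labels_a) != len(labels_b):
        raise ValidationError("label vectors differ in length")
    return float(adjusted_rand_score(labels_a, labels_b))


def cna_concordance(matrix: SingleCellMatrix, profile: CNProfile,
                    gene_positions: pd.DataFrame,
                    low_expr_quantile: float = 0.05) -> pd.Series:
    """Per-cell Spearman correlation of gene z-scores with segment copy number.

    Genes are assigned to the segment containing their start coordinate;
    genes below the ``low_expr_quantile`` of mean normalized expression are
    excluded; each remaining gene is z-scored across cells, and per cell the
    Spearman rank correlation between its z-scores and the genes' segment
    copy numbers is returned.  NaN when the mapped copy numbers are constant.
    """
    norm = normalize(matrix).toarray()
    gp = gene_positions.set_index("gene")
    seg = profile.segments
    gene_cn, gene_rows = [], []
    for i, g in enumerate(matrix.gene_ids):
        if g not in gp.index:
            continue
        chrom, start = gp.at[g, "chrom"], gp.at[g, "start"]
        hit = seg[(seg["chrom"] == chrom) & (seg["start"] <= start)
                  & (start < seg["end"])]
        if len(hit):
            gene_rows.append(i)
            gene_cn.append(float(hit["copy_number"].iloc[0]))
    if not gene_rows:
        raise ValidationError("no genes map to the copy-number profile")
    gene_rows = np.array(gene_rows)
    gene_cn = np.array(gene_cn)

    mean_expr = norm.mean(axis=1)
    cutoff = np.quantile(mean_expr, low_expr_quantile)
    keep = mean_expr[gene_rows] >= cutoff
    gene_rows, gene_cn = gene_rows[keep], gene_cn[keep]
    if len(gene_rows) == 0:
        raise ValidationError("no mappable genes after expression filter")
    if len(gene_rows) < 50:
        log.warning("only %d mappable genes; concordance scores unstable",
                    len(gene_rows))

    X = norm[gene_rows]
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if np.unique(gene_cn).size < 2:
        log.warning("copy-number profile is flat; concordance undefined")
        return pd.Series(np.nan, index=matrix.cell_ids, name="cna_concordance")
    rho = np.array([spearmanr(Z[:, j], gene_cn).statistic
                    for j in range(Z.shape[1])])
    return pd.Series(rho, index=matrix.cell_ids, name="cna_concordance")
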