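"""Transcriptomic-marker (TM) selection cascade.

A gene becomes a TM for a subcluster when it survives six filters:

1. one-vs-rest Wilcoxon within the subcluster's major cell type with
   natural-log fold change >= 0.25 and p <= 0.01;
2. Wilcoxon against the subcluster with the second-highest mean expression
   of the gene (across all cell types) with p <= 0.01, BH-adjusted p <= 0.05
   and log fold change >= 0.25;
3. three detection-rate criteria: detected in > 40% of the subcluster's
   cells, in < 50% of the cells of the second-highest subcluster, and a
   median detection rate over all subclusters < 10% (strict inequalities).

Per-criterion elimination counts are reported in that order so the cascade
is auditable.  Fold changes use de-logged means with pseudocount 1:
ln(mean(expm1 x) + 1) - ln(mean(expm1 rest) + 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .sc_io import SingleCellMatrix, normalize

log = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """TMs per subcluster plus the thresholds and cascade bookkeeping."""

    table: pd.DataFrame                 # one row per passing candidate
    thresholds: dict = field(default_factory=dict)
    eliminations: dict = field(default_factory=dict)

    @property
    def markers(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sub, grp in self.table.groupby("subcluster", sort=True):
            out[sub] = list(grp["gene"])
        return out

    def sizes(self) -> dict[str, int]:
        return {sub: len(g) for sub, g in self.markers.items()}

    def __len__(self) -> int:
        return len(self.table)


def _dense(norm) -> np.ndarray:
    return norm.toarray() if sp.issparse(norm) else np.asarray(norm)


def detection_rates(matrix: SingleCellMatrix,
                    labels: pd.Series | None = None) -> pd.DataFrame:
    """Fraction of each subcluster's cells with count >= 1, per gene."""
    labels = matrix.subclusters if labels is None else labels
    detected = (matrix.counts > 0).astype(np.int8)
    if isinstance(labels.dtype, pd.CategoricalDtype):
        groups = list(labels.cat.categories)
    else:
        groups = sorted(labels.unique())
    out = {}
    for sub in groups:
        mask = np.asarray(labels == sub)
        if mask.sum() == 0:
            raise ValidationError(f"empty subcluster {sub}")
        out[sub] = np.asarray(detected[:, mask].sum(axis=1)).ravel() / mask.sum()
    return pd.DataFrame(out, index=matrix.gene_ids)


def _log_fc(expm1_a_mean: np.ndarray, expm1_b_mean: np.ndarray) -> np.ndarray:
    return np.log(expm1_a_mean + 1.0) - np.log(expm1_b_mean + 1.0)


def within_type_markers(matrix: SingleCellMatrix, norm=None,
                        logfc_min: float = 0.25, p_max: float = 0.01,
                        min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon DE of each subcluster within its major cell type.

    Returns candidates (gene, subcluster, log_fc, p_within) with
    log_fc >= ``logfc_min`` and p <= ``p_max``.  Subclusters with fewer than
    ``min_cells`` cells are skipped with a warning.
    """
    norm = _dense(normalize(matrix) if norm is None else norm)
    meta = matrix.cell_meta
    rows = []
    for ct in sorted(meta["major_cell_type"].unique()):
        ct_mask = (meta["major_cell_type"] == ct).values
        X = norm[:, ct_mask]
        expm1 = np.expm1(X)
        subs = meta.loc[ct_mask, "subcluster"]
        for sub in sorted(subs.unique()):
            in_mask = (subs == sub).values
            if in_mask.sum() < min_cells:
                log.warning("subcluster %s has < %d cells; skipped", sub, min_cells)
                continue
            if (~in_mask).sum() == 0:
                log.warning("subcluster %s is its whole cell type; skipped", sub)
                continue
            lfc = _log_fc(expm1[:, in_mask].mean(axis=1),
                          expm1[:, ~in_mask].mean(axis=1))
            sel = np.flatnonzero(lfc >= logfc_min)
            if len(sel) == 0:
                continue
            res = mannwhitneyu(X[np.ix_(sel, in_mask)], X[np.ix_(sel, ~in_mask)],
                               axis=-1, alternative="two-sided",
                               method="asymptotic")
            keep = res.pvalue <= p_max
            for g_idx, p in zip(sel[keep], res.pvalue[keep]):
                rows.append({"gene": matrix.gene_ids[g_idx], "subcluster": sub,
                             "log_fc": lfc[g_idx], "p_within": p})
    return pd.DataFrame(rows, columns=["gene", "subcluster", "log_fc", "p_within"])


def second_highest_filter(candidates: pd.DataFrame, matrix: SingleCellMatrix,
                          norm=None, logfc_min: float = 0.25,
                          p_max: float = 0.01, adj_p_max: float = 0.05
                          ) -> pd.DataFrame:
    """Compare each candidate against the top other subcluster for its gene.

    Subclusters (across all cell types) are ranked by mean normalized
    expression of the gene; the candidate's cells are tested against the
    highest-ranked OTHER subcluster by two-sided Wilcoxon.  BH is applied
    over all tests of this stage.  Candidates pass with p <= ``p_max``,
    BH-adjusted p <= ``adj_p_max`` and log fold change >= ``logfc_min``.
    """
    if candidates.empty:
        return candidates.assign(p_second=[], p_second_adj=[], log_fc_second=[])
    norm = _dense(normalize(matrix) if norm is None else norm)
    labels = matrix.subclusters
    subs = sorted(labels.unique())
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    masks = {s: (labels == s).values for s in subs}
    means = np.column_stack([norm[:, masks[s]].mean(axis=1) for s in subs])
    mean_df = pd.DataFrame(means, index=matrix.gene_ids, columns=subs)

    cand = candidates.copy().reset_index(drop=True)
    missing = [g for g in cand["gene"] if g not in gene_pos]
    if missing:
        raise ValidationError(f"candidate genes missing from matrix: {missing[:5]}")
    # pick the competitor (highest other subcluster) per candidate
    competitors = []
    for g, t in zip(cand["gene"], cand["subcluster"]):
        row = mean_df.loc[g].drop(t)
        competitors.append(row.idxmax())
    cand["competitor"] = competitors

    p2 = np.ones(len(cand))
    lfc2 = np.zeros(len(cand))
    for (t, comp), grp in cand.groupby(["subcluster", "competitor"], sort=False):
        gi = np.array([gene_pos[g] for g in grp["gene"]])
        a = norm[np.ix_(gi, masks[t])]
        b = norm[np.ix_(gi, masks[comp])]
        lfc2[grp.index] = _log_fc(np.expm1(a).mean(axis=1),
                                  np.expm1(b).mean(axis=1))
        p2[grp.index] = mannwhitneyu(a, b, axis=-1, alternative="two-sided",
                                     method="asymptotic").pvalue
    cand["log_fc_second"] = lfc2
    cand["p_second"] = p2
    cand["p_second_adj"] = multipletests(p2, method="fdr_bh")[1]
    keep = ((cand["p_second"] <= p_max) & (cand["p_second_adj"] <= adj_p_max)
            & (cand["log_fc_second"] >= logfc_min))
    return cand[keep].reset_index(drop=True)


def apply_detection_criteria(candidates: pd.DataFrame, det: pd.DataFrame,
                             mean_expr: pd.DataFrame, min_target: float = 0.40,
                             max_second: float = 0.50, max_median: float = 0.10
                             ) -> MarkerSet:
    """Apply the three detection-rate criteria with strict inequalities.

    ``det`` and ``mean_expr`` are genes x subclusters.  Criteria, in order:
    detection in the target subcluster > ``min_target``; detection in the
    subcluster with the second-highest mean expression < ``max_second``;
    median detection over all subclusters < ``max_median``.  Eliminations are
    counted sequentially in that order.
    """
    cand = candidates.copy().reset_index(drop=True)
    det_target = np.empty(len(cand))
    det_second = np.empty(len(cand))
    det_median = np.empty(len(cand))
    for i, (g, t) in enumerate(zip(cand["gene"], cand["subcluster"])):
        det_target[i] = det.at[g, t]
        second = mean_expr.loc[g].drop(t).idxmax()
        det_second[i] = det.at[g, second]
        det_median[i] = float(np.median(det.loc[g].values))
    cand["det_target"] = det_target
    cand["det_second"] = det_second
    cand["det_median"] = det_median

    pass1 = cand["det_target"] > min_target
    pass2 = cand["det_second"] < max_second
    pass3 = cand["det_median"] < max_median
    eliminations = {
        "det_target": int((~pass1).sum()),
        "det_second": int((pass1 & ~pass2).sum()),
        "det_median": int((pass1 & pass2 & ~pass3).sum()),
    }
    passed = cand[pass1 & pass2 & pass3].reset_index(drop=True)
    return MarkerSet(table=passed,
                     thresholds={"min_target": min_target,
                                 "max_second": max_second,
                                 "max_median": max_median},
                     eliminations=eliminations)


def select_markers(matrix: SingleCellMatrix, logfc_min: float = 0.25,
                   p_max: float = 0.01, adj_p_max: float = 0.05,
                   min_target: float = 0.40, max_second: float = 0.50,
                   max_median: float = 0.10) -> MarkerSet:
    """Run the full six-filter TM cascade on an annotated matrix."""
    norm = _dense(normalize(matrix))
    stage1 = within_type_markers(matrix, norm, logfc_min=logfc_min, p_max=p_max)
    stage2 = second_highest_filter(stage1, matrix, norm, logfc_min=logfc_min,
                                   p_max=p_max, adj_p_max=adj_p_max)
    det = detection_rates(matrix)
    labels = matrix.subclusters
    subs = sorted(labels.unique())
    mean_expr = pd.DataFrame(
        {s: norm[:, (labels == s).values].mean(axis=1) for s in subs},
        index=matrix.gene_ids)
    marker_set = apply_detection_criteria(stage2, det, mean_expr,
                                          min_target=min_target,
                                          max_second=max_second,
                                          max_median=max_median)
    marker_set.eliminations = {"n_stage1": len(stage1), "n_stage2": len(stage2),
                               **marker_set.eliminations}
    return marker_set
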