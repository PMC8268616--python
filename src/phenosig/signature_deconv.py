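"""Calibrated signature-enrichment deconvolution of bulk expression.

The training side mirrors the xCell recipe, but uses annotated single-cell
subclusters instead of purified cell lines:

1. per-gene expression percentiles {10, 25, 33, 50, 67, 75, 90} within each
   subcluster;
2. candidate signatures from percentile-gap comparisons: gene g belongs to
   the candidate for (subcluster, pair, rank, threshold) when its low
   percentile in the target exceeds the rank-th largest high percentile over
   the other subclusters by more than the threshold (pairs (10,90), (25,75),
   (33,67), (50,50); ranks 1-3; thresholds 0, 0.10, 0.50, 0.80); candidates
   with fewer than 8 or more than 200 genes are discarded;
3. each candidate scored per cell with a rank-weighted single-sample
   enrichment statistic (ssGSEA-style, weight exponent alpha=0.25); the
   top-3 candidates per subcluster by Welch t-statistic (target cells vs all
   others) become the final signatures, whose mean score is the subcluster's
   raw score;
4. in-silico dilution series (11 concentrations 0.8-25%, 3 replicates,
   10,000 cells per mixture) calibrate raw scores: 0.01/0.99-quantile
   rescaling to [0, 1] followed by a power-law fit c = a * s'^b in log-log
   space;
5. a spillover matrix K from 25%-pure mixtures captures cross-contamination
   between related subclusters; prediction solves min ||K x - c||, x >= 0.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls
from scipy.stats import rankdata

from .errors import CalibrationError, ConfigError, ValidationError
from .sc_io import SingleCellMatrix, normalize

log = logging.getLogger(__name__)

PERCENTILES = (10, 25, 33, 50, 67, 75, 90)
PERCENTILE_PAIRS = ((10, 90), (25, 75), (33, 67), (50, 50))
THRESHOLDS = (0.0, 0.10, 0.50, 0.80)
RANKS = (1, 2, 3)
DEFAULT_CONCENTRATIONS = tuple(np.geomspace(0.008, 0.25, 11))


@dataclass(frozen=True)
class CandidateSignature:
    subcluster: str
    genes: tuple
    pair: tuple
    rank: int
    threshold: float

    def sort_key(self):
        # tie-break after the t-statistic: larger set first, then params
        return (-len(self.genes), self.pair, self.rank, self.threshold)


@dataclass
class Calibration:
    """Rescale bounds and power-law parameters for one subcluster."""

    q01: float
    q99: float
    a: float
    b: float

    def rescale(self, s):
        if self.q99 <= self.q01:
            raise CalibrationError("degenerate rescale bounds")
        return np.clip((np.asarray(s, float) - self.q01)
                       / (self.q99 - self.q01), 0.0, 1.0)

    def concentration(self, s):
        return self.a * self.rescale(s) ** self.b


@dataclass
class SignatureModel:
    """Per-subcluster top-3 signatures, calibration, and spillover matrix."""

    subclusters: list
    signatures: dict                     # subcluster -> list of gene tuples
    calibration: dict                    # subcluster -> Calibration
    spillover: pd.DataFrame              # signature x mixture, unit diagonal
    alpha: float = 0.25

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "subclusters": list(self.subclusters),
            "signatures": {s: [list(g) for g in sigs]
                           for s, sigs in self.signatures.items()},
            "calibration": {s: vars(c) for s, c in self.calibration.items()},
            "spillover": self.spillover.to_dict(orient="split"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        spill = pd.DataFrame(d["spillover"]["data"],
                             index=d["spillover"]["index"],
                             columns=d["spillover"]["columns"])
        return cls(subclusters=d["subclusters"],
                   signatures={s: [tuple(g) for g in sigs]
                               for s, sigs in d["signatures"].items()},
                   calibration={s: Calibration(**c)
                                for s, c in d["calibration"].items()},
                   spillover=spill, alpha=d["alpha"])


# ---------------------------------------------------------------------------
# Percentile profiles and candidate signatures

def percentile_profiles(norm, gene_ids, labels: pd.Series,
                        percentiles=PERCENTILES) -> dict[int, pd.DataFrame]:
    """Empirical percentiles (linear interpolation) per gene and subcluster."""
    X = norm.toarray() if sp.issparse(norm) else np.asarray(norm)
    out = {p: {} for p in percentiles}
    for sub in sorted(labels.unique()):
        mask = (labels == sub).values
        if mask.sum() < 10:
            log.warning("subcluster %s has < 10 cells; percentiles unstable", sub)
        q = np.percentile(X[:, mask], percentiles, axis=1)
        for p, row in zip(percentiles, q):
            out[p][sub] = row
    return {p: pd.DataFrame(cols, index=gene_ids) for p, cols in out.items()}


def candidate_signatures(profiles: dict[int, pd.DataFrame],
                         min_genes: int = 8, max_genes: int = 200
                         ) -> list[CandidateSignature]:
    """Percentile-gap candidate gene sets for every (pair, rank, threshold)."""
    subs = list(profiles[PERCENTILES[0]].columns)
    genes = profiles[PERCENTILES[0]].index
    n_other = len(subs) - 1
    usable_ranks = [r for r in RANKS if r <= n_other]
    if len(usable_ranks) < len(RANKS):
        log.warning("only %d other subclusters; ranks beyond that skipped", n_other)
    out = []
    for low, high in PERCENTILE_PAIRS:
        lo = profiles[low]
        hi = profiles[high]
        for target in subs:
            lo_t = lo[target].values
            others = hi.drop(columns=[target]).values  # genes x (K-1)
            # rank-th largest high percentile among the other subclusters
            order = np.sort(others, axis=1)[:, ::-1]
            for rank in usable_ranks:
                gap = lo_t - order[:, rank - 1]
                for thr in THRESHOLDS:
                    members = genes[gap > thr]
                    if min_genes <= len(members) <= max_genes:
                        out.append(CandidateSignature(
                            target, tuple(members), (low, high), rank, thr))
    return out


# ---------------------------------------------------------------------------
# Single-sample enrichment scoring

def _ssgsea(values: np.ndarray, in_set: np.ndarray, alpha: float) -> np.ndarray:
    """Rank-weighted running-sum enrichment, vectorized over columns.

    ``values`` is genes x samples; ``in_set`` a boolean gene mask.  Genes are
    walked in descending expression order; the weighted in-set ECDF (weights
    = mid-rank^alpha) is compared with the uniform out-of-set ECDF and the
    difference summed, normalized by (G - 1).  Rank-based, hence invariant
    under strictly monotone transforms of the expression values.
    """
    G, S = values.shape
    n_in = int(in_set.sum())
    if n_in == 0:
        return np.full(S, np.nan)
    if n_in == G:
        return np.zeros(S)
    ranks = rankdata(values, axis=0)           # ascending mid-ranks
    order = np.argsort(-values, axis=0, kind="stable")
    in_sorted = np.take_along_axis(np.broadcast_to(in_set[:, None], (G, S)),
                                   order, axis=0)
    w = np.take_along_axis(ranks, order, axis=0) ** alpha
    w_in = np.where(in_sorted, w, 0.0)
    p_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0, keepdims=True)
    p_out = np.cumsum(~in_sorted, axis=0) / float(G - n_in)
    return (p_in - p_out).sum(axis=0) / (G - 1)


def ss_enrichment(expr, gene_set, alpha: float = 0.25):
    """Enrichment score(s) of a gene set in one or more expression profiles.

    ``expr`` is a pandas Series (one sample, indexed by gene) or a genes x
    samples DataFrame.  Returns a float or a per-sample Series.  NaN when no
    gene of the set is measured.
    """
    single = isinstance(expr, pd.Series)
    df = expr.to_frame() if single else expr
    in_set = df.index.isin(set(gene_set))
    scores = _ssgsea(df.values.astype(float), np.asarray(in_set), alpha)
    return float(scores[0]) if single else pd.Series(scores, index=df.columns)


# ---------------------------------------------------------------------------
# Top-3 selection

def select_top3(candidates: list[CandidateSignature], norm, gene_ids,
                labels: pd.Series, alpha: float = 0.25, n_top: int = 3
                ) -> dict[str, list[CandidateSignature]]:
    """Rank candidates per subcluster by the Welch t-statistic of their
    per-cell enrichment scores (target cells vs all others)."""
    X = norm.toarray() if sp.issparse(norm) else np.asarray(norm)
    gene_index = pd.Index(gene_ids)
    lab = np.asarray(labels)
    scored: dict[str, list] = {}
    for cand in candidates:
        in_set = gene_index.isin(set(cand.genes))
        s = _ssgsea(X, np.asarray(in_set), alpha)
        m = lab == cand.subcluster
        a, b = s[m], s[~m]
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        denom = np.sqrt(va + vb)
        t = (a.mean() - b.mean()) / denom if denom > 0 else 0.0
        scored.setdefault(cand.subcluster, []).append((t, cand))
    out = {}
    for sub, lst in scored.items():
        if len(lst) < n_top:
            log.warning("subcluster %s has only %d candidate signatures",
                        sub, len(lst))
        lst.sort(key=lambda tc: (-tc[0], tc[1].sort_key()))
        out[sub] = [c for _, c in lst[:n_top]]
    return out


# ---------------------------------------------------------------------------
# Dilutions, calibration, spillover

def simulate_dilutions(norm, labels: pd.Series, target: str,
                       concentrations=DEFAULT_CONCENTRATIONS,
                       n_cells: int = 10000, reps: int = 3, seed: int = 0,
                       gene_ids=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Pseudo-bulk mixtures of the target subcluster at known concentrations.

    Each mixture is the mean normalized expression of ``n_cells`` cells with
    the target at the stated fraction and the remainder drawn uniformly from
    the other subclusters.  Sampling is without replacement when the pool
    suffices, otherwise with replacement (logged).  Returns a genes x
    (len(concentrations) * reps) profile frame and the matching
    concentration vector.
    """
    X = norm.toarray() if sp.issparse(norm) else np.asarray(norm)
    lab = np.asarray(labels)
    tgt_pool = np.flatnonzero(lab == target)
    oth_pool = np.flatnonzero(lab != target)
    if len(tgt_pool) == 0:
        raise ValidationError(f"subcluster {target} has no cells")
    rng = np.random.default_rng(seed)
    cols, conc_out = [], []
    profiles = np.empty((X.shape[0], len(concentrations) * reps))
    j = 0
    for c in concentrations:
        n_tgt = int(round(c * n_cells))
        n_oth = n_cells - n_tgt
        for rep in range(reps):
            parts = []
            for pool, n_draw in ((tgt_pool, n_tgt), (oth_pool, n_oth)):
                if n_draw == 0:
                    continue
                replace = n_draw > len(pool)
                if replace:
                    log.debug("sampling %d cells with replacement from pool "
                              "of %d", n_draw, len(pool))
                parts.append(rng.choice(pool, size=n_draw, replace=replace))
            idx = np.concatenate(parts)
            profiles[:, j] = X[:, idx].mean(axis=1)
            cols.append(f"{target}_c{c:.4f}_r{rep + 1}")
            conc_out.append(c)
            j += 1
    index = gene_ids if gene_ids is not None else np.arange(X.shape[0])
    return pd.DataFrame(profiles, index=index, columns=cols), np.array(conc_out)


def fit_power(s_rescaled, concentrations) -> tuple[float, float]:
    """Least-squares power law c = a * s^b on log-transformed pairs (s > 0)."""
    s = np.asarray(s_rescaled, float)
    c = np.asarray(concentrations, float)
    ok = (s > 0) & (c > 0)
    if len(set(np.round(s[ok], 12))) < 3:
        raise CalibrationError("need >= 3 distinct positive score points")
    b, log_a = np.polyfit(np.log(s[ok]), np.log(c[ok]), 1)
    return float(np.exp(log_a)), float(b)


def calibrate(scores, concentrations, reps: int | None = None) -> Calibration:
    """Rescale raw dilution scores to [0, 1] and fit the power law.

    ``scores`` are raw mixture scores aligned with ``concentrations``;
    replicate scores at the same concentration are averaged first.
    """
    s = np.asarray(scores, float)
    c = np.asarray(concentrations, float)
    df = pd.DataFrame({"s": s, "c": c}).groupby("c", sort=True)["s"].mean()
    c_u, s_u = df.index.values, df.values
    q01, q99 = np.quantile(s_u, [0.01, 0.99])
    if q99 <= q01:
        raise CalibrationError("constant scores across dilutions")
    cal = Calibration(q01=float(q01), q99=float(q99), a=1.0, b=1.0)
    a, b = fit_power(cal.rescale(s_u), c_u)
    cal.a, cal.b = a, b
    return cal


def _raw_scores(expr: pd.DataFrame, signatures: dict, alpha: float
                ) -> pd.DataFrame:
    """Samples x subclusters mean top-3 enrichment of a genes x samples frame."""
    out = {}
    for sub, sigs in signatures.items():
        per_sig = []
        for genes in sigs:
            present = expr.index.isin(set(genes)).sum()
            if present == 0:
                log.warning("signature for %s has no genes on platform", sub)
            elif present < 0.5 * len(genes):
                log.warning("signature for %s: only %d/%d genes on platform",
                            sub, present, len(genes))
            per_sig.append(ss_enrichment(expr, genes, alpha=alpha))
        out[sub] = pd.concat(per_sig, axis=1).mean(axis=1)
    return pd.DataFrame(out)


def spillover_fit(norm, labels: pd.Series, signatures: dict,
                  calibration: dict, gene_ids, alpha: float = 0.25,
                  n_cells: int = 10000, reps: int = 3,
                  purity: float = 0.25, seed: int = 0) -> pd.DataFrame:
    """Spillover matrix from 25%-pure artificial mixtures.

    K[j, k] is signature j's calibrated score on the mixture of subcluster k,
    divided by k's score on its own mixture; the diagonal is 1 and negatives
    are clipped to 0.
    """
    subs = list(signatures)
    lab = np.asarray(labels)
    for sub in subs:
        if (lab == sub).sum() == 0:
            raise ValidationError(f"subcluster {sub} absent from matrix")
    mixes = {}
    for i, sub in enumerate(subs):
        prof, _ = simulate_dilutions(norm, labels, sub,
                                     concentrations=[purity], n_cells=n_cells,
                                     reps=reps, seed=seed + i, gene_ids=gene_ids)
        mixes[sub] = prof.mean(axis=1)
    mix_expr = pd.DataFrame(mixes)          # genes x subclusters
    raw = _raw_scores(mix_expr, signatures, alpha)   # mixtures x signatures
    K = np.zeros((len(subs), len(subs)))
    for j, sig_sub in enumerate(subs):
        cal = calibration[sig_sub]
        K[j, :] = cal.concentration(raw[sig_sub].loc[subs].values)
    diag = np.diag(K).copy()
    diag[diag == 0] = 1.0
    K = np.clip(K / diag[np.newaxis, :], 0.0, None)
    np.fill_diagonal(K, 1.0)
    return pd.DataFrame(K, index=subs, columns=subs)


def build_signature_model(matrix: SingleCellMatrix, alpha: float = 0.25,
                          concentrations=DEFAULT_CONCENTRATIONS,
                          n_mix_cells: int = 10000, reps: int = 3,
                          seed: int = 0) -> SignatureModel:
    """Train the full deconvolution model from an annotated single-cell matrix."""
    norm = normalize(matrix).toarray()
    labels = matrix.subclusters
    profiles = percentile_profiles(norm, matrix.gene_ids, labels)
    candidates = candidate_signatures(profiles)
    if not candidates:
        raise ConfigError("no candidate signatures survived the size filter")
    top3 = select_top3(candidates, norm, matrix.gene_ids, labels, alpha=alpha)
    signatures = {sub: [c.genes for c in lst] for sub, lst in top3.items()}

    calibration = {}
    for i, sub in enumerate(signatures):
        prof, conc = simulate_dilutions(norm, labels, sub,
                                        concentrations=concentrations,
                                        n_cells=n_mix_cells, reps=reps,
                                        seed=seed * 1000 + i,
                                        gene_ids=matrix.gene_ids)
        raw = _raw_scores(prof, {sub: signatures[sub]}, alpha)[sub].values
        calibration[sub] = calibrate(raw, conc)

    K = spillover_fit(norm, labels, signatures, calibration, matrix.gene_ids,
                      alpha=alpha, n_cells=n_mix_cells, reps=reps,
                      seed=seed * 1000 + 500)
    return SignatureModel(subclusters=list(signatures), signatures=signatures,
                          calibration=calibration, spillover=K, alpha=alpha)


def deconvolve(bulk_expr: pd.DataFrame, model: SignatureModel,
               spill_damping: float = 0.5) -> pd.DataFrame:
    """Spillover-corrected abundance estimates for bulk samples.

    ``bulk_expr`` is samples x genes.  Raw top-3 scores are rescaled and
    power-calibrated per subcluster, then corrected by solving
    min ||K x - c||, x >= 0 per sample.  Off-diagonal spillover is damped by
    ``spill_damping`` before solving (the xCell compensation constant):
    with few cell phenotypes the 75% complement of a spillover mixture
    contains every other phenotype at a substantial genuine fraction, so the
    raw ratio K over-states contamination and full compensation
    over-corrects.  Subclusters whose signatures share no gene with the
    platform yield NaN estimates.
    """
    expr = bulk_expr.T  # genes x samples
    raw = _raw_scores(expr, model.signatures, model.alpha)
    conc = pd.DataFrame({sub: model.calibration[sub].concentration(raw[sub].values)
                         for sub in model.subclusters}, index=raw.index)
    K = model.spillover.loc[model.subclusters, model.subclusters].values.copy()
    K = K * spill_damping
    np.fill_diagonal(K, 1.0)
    est = np.full(conc.shape, np.nan)
    valid = ~conc.isna().any(axis=1).values
    for i in np.flatnonzero(valid):
        est[i], _ = nnls(K, conc.values[i])
    out = pd.DataFrame(est, index=conc.index, columns=model.subclusters)
    out.attrs["method"] = "xcell"
    return out
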