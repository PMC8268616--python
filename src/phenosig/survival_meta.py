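"""Per-cohort Cox models pooled by REML random-effects meta-analysis.

For every bulk cohort and subcluster score, overall survival is modelled
with Cox proportional hazards (Efron tie handling) adjusting for age, FIGO
stage and debulking; the score coefficient and its standard error are then
pooled across cohorts under a random-effects model beta_i ~ N(mu, tau^2 +
se_i^2) with tau^2 estimated by REML (Fisher scoring).  Benjamini-Hochberg
controls the FDR across subclusters.  Kaplan-Meier tertile curves and a
size-matched random-gene-set permutation null complete the module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import norm as normal
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, FitError, ValidationError
from .sc_io import BulkCohort
from .ssz_scoring import score_cohort

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "stage", "debulking")


@dataclass
class CohortFit:
    cohort_id: str
    subcluster: str
    beta: float
    se: float
    n: int
    events: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError("standard error must be positive")
        if self.events > self.n:
            raise ValidationError("more events than samples")


@dataclass
class MetaResult:
    subcluster: str
    mu: float                       # pooled log hazard ratio
    se: float
    tau2: float
    p: float
    p_bh: float | None = None
    fits: list = field(default_factory=list)
    degenerate: bool = False

    @property
    def hr(self) -> float:
        return float(np.exp(self.mu))

    @property
    def ci95(self) -> tuple[float, float]:
        return (float(np.exp(self.mu - 1.959963984540054 * self.se)),
                float(np.exp(self.mu + 1.959963984540054 * self.se)))


def _design_frame(cohort: BulkCohort, score: pd.Series,
                  covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    clin = cohort.clinical
    df = pd.DataFrame({"os_days": clin["os_days"].astype(float),
                       "os_event": clin["os_event"].astype(int),
                       "score": score.loc[clin.index].astype(float)})
    if "age" in covariates:
        df["age"] = clin["age"].astype(float)
    if "stage" in covariates:
        stage = clin["stage"].astype(str).copy()
        # merge early stages when sparse to avoid separation
        if ((stage == "I").sum() < 5) or ((stage == "II").sum() < 5):
            stage = stage.replace({"I": "I-II", "II": "I-II"})
        dummies = pd.get_dummies(stage, prefix="stage", drop_first=True,
                                 dtype=float)
        df = pd.concat([df, dummies], axis=1)
    if "debulking" in covariates:
        df["debulking_suboptimal"] = (clin["debulking"] == "suboptimal"
                                      ).astype(float)
    return df


def fit_cox(cohort: BulkCohort, score: pd.Series, subcluster: str = "score",
            covariates=DEFAULT_COVARIATES, min_events: int = 10) -> CohortFit:
    """Cox PH coefficient of a continuous subcluster score, with covariates.

    Ties are handled by the Efron approximation; the model-based SE of the
    score coefficient is returned.
    """
    if score.loc[cohort.clinical.index].isna().any():
        raise ValidationError(
            f"{cohort.cohort_id}/{subcluster}: score missing for some samples")
    df = _design_frame(cohort, score, covariates)
    if df["os_event"].sum() < min_events:
        raise ValidationError(
            f"{cohort.cohort_id}/{subcluster}: fewer than {min_events} events")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_days", event_col="os_event")
    except Exception as exc:
        raise FitError(f"Cox fit failed for {cohort.cohort_id}/{subcluster}: "
                       f"{exc}") from exc
    beta = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        raise FitError(f"separation suspected for {cohort.cohort_id}/"
                       f"{subcluster} (|beta|={abs(beta):.2g}, se={se:.2g})")
    return CohortFit(cohort.cohort_id, subcluster, beta, se,
                     n=len(df), events=int(df["os_event"].sum()))


def reml_meta(fits: list[CohortFit], max_iter: int = 100,
              tol: float = 1e-8) -> MetaResult:
    """Random-effects pooling with REML between-study variance.

    Fisher scoring on the restricted likelihood; tau^2 floored at zero.
    With a single cohort the fixed effect is returned and flagged degenerate.
    """
    if not fits:
        raise ValidationError("no cohort fits to pool")
    sub = fits[0].subcluster
    y = np.array([f.beta for f in fits])
    v = np.array([f.se ** 2 for f in fits])
    k = len(fits)
    if k == 1:
        mu, se = y[0], np.sqrt(v[0])
        p = 2 * normal.sf(abs(mu / se))
        return MetaResult(sub, float(mu), float(se), 0.0, float(p),
                          fits=list(fits), degenerate=True)

    tau2 = max(0.0, np.var(y, ddof=1) - v.mean())  # moment start
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        resid2 = (y - mu) ** 2
        score = (-0.5 * np.sum(w) + 0.5 * np.sum(w ** 2) / np.sum(w)
                 + 0.5 * np.sum(w ** 2 * resid2))
        info = (0.5 * np.sum(w ** 2) - np.sum(w ** 3) / np.sum(w)
                + 0.5 * (np.sum(w ** 2) / np.sum(w)) ** 2)
        if info <= 0:
            break
        step = score / info
        new = max(0.0, tau2 + step)
        if abs(new - tau2) < tol:
            tau2 = new
            break
        tau2 = new
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    p = float(2 * normal.sf(abs(mu / se)))
    return MetaResult(sub, mu, se, float(tau2), p, fits=list(fits))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def meta_analyse(cohorts: list[BulkCohort], scores: dict[str, pd.DataFrame],
                 covariates=DEFAULT_COVARIATES,
                 skip_failures: bool = False) -> pd.DataFrame:
    """Cox + REML for every subcluster; returns a Table-3-style frame.

    ``scores`` maps cohort_id -> samples x subclusters score matrix.
    Columns: subcluster, hr, ci_low, ci_high, tau2, p, p_bh, n_cohorts.
    """
    subclusters = list(scores[cohorts[0].cohort_id].columns)
    results: list[MetaResult] = []
    for sub in subclusters:
        fits = []
        for cohort in cohorts:
            s = scores[cohort.cohort_id][sub]
            if s.isna().all():
                continue
            try:
                fits.append(fit_cox(cohort, s, sub, covariates))
            except (FitError, ValidationError):
                if not skip_failures:
                    raise
                log.warning("skipping %s/%s", cohort.cohort_id, sub)
        if fits:
            results.append(reml_meta(fits))
    p_bh = bh_adjust([r.p for r in results])
    rows = []
    for r, adj in zip(results, p_bh):
        r.p_bh = float(adj)
        lo, hi = r.ci95
        rows.append({"subcluster": r.subcluster, "hr": r.hr, "ci_low": lo,
                     "ci_high": hi, "tau2": r.tau2, "p": r.p, "p_bh": r.p_bh,
                     "n_cohorts": len(r.fits)})
    return pd.DataFrame(rows).set_index("subcluster")


# ---------------------------------------------------------------------------
# Kaplan-Meier tertiles

def km_tertiles(scores: pd.Series, clinical: pd.DataFrame) -> dict:
    """KM curves of pooled samples split at the score tertiles.

    Returns the three fitted curves, the T3 - T1 median-survival difference
    in days (NaN when a median is undefined) and the unadjusted two-group
    log-rank p between T3 and T1.  Boundary ties go to the lower stratum.
    """
    s = scores.loc[clinical.index]
    q1, q2 = s.quantile([1 / 3, 2 / 3])
    stratum = pd.Series(np.where(s <= q1, "T1", np.where(s <= q2, "T2", "T3")),
                        index=s.index)
    curves, medians = {}, {}
    for t in ("T1", "T2", "T3"):
        m = stratum == t
        km = KaplanMeierFitter(label=t)
        km.fit(clinical.loc[m, "os_days"], clinical.loc[m, "os_event"])
        curves[t] = km
        medians[t] = float(km.median_survival_time_)
    lr = logrank_test(clinical.loc[stratum == "T3", "os_days"],
                      clinical.loc[stratum == "T1", "os_days"],
                      clinical.loc[stratum == "T3", "os_event"],
                      clinical.loc[stratum == "T1", "os_event"])
    diff = medians["T3"] - medians["T1"]
    if not np.isfinite(diff):
        log.warning("median survival undefined in a tertile")
        diff = float("nan")
    return {"curves": curves, "medians": medians,
            "median_diff_days": diff, "logrank_p": float(lr.p_value),
            "strata": stratum}


# ---------------------------------------------------------------------------
# Size-matched random-gene-set null

def random_geneset_null(cohorts: list[BulkCohort], marker_sizes: dict[str, int],
                        observed_count: int, n_iter: int = 500,
                        alpha: float = 0.05, covariates=DEFAULT_COVARIATES,
                        seed: int = 0) -> dict:
    """Fraction of random-gene-set iterations matching the observed signal.

    Each iteration draws, for every subcluster, a uniform random gene set of
    the same size from the genes present in all cohorts, recomputes SSZ
    scores, per-cohort Cox fits, REML meta-analysis and BH correction, and
    counts the BH-significant subclusters.  Returns the fraction of
    iterations with count >= ``observed_count`` plus the null counts.
    """
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    frame = set(cohorts[0].genes)
    for cohort in cohorts[1:]:
        frame &= set(cohort.genes)
    frame = np.array(sorted(frame), dtype=object)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        random_sets = {
            sub: list(rng.choice(frame, size=size, replace=False))
            for sub, size in marker_sizes.items()}
        scores = {c.cohort_id: score_cohort(c, random_sets) for c in cohorts}
        table = meta_analyse(cohorts, scores, covariates, skip_failures=True)
        counts[it] = int((table["p_bh"] <= alpha).sum())
    fraction = float(np.mean(counts >= observed_count))
    return {"fraction": fraction, "null_counts": counts,
            "observed_count": observed_count}
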