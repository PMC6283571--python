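"""Clinical statistics: paired and stage-wise comparisons, PD-L1 association,
quadrant stratification, Kaplan–Meier / log-rank and Cox regression.

Survival machinery is delegated to ``lifelines`` (Breslow tie handling,
Newton–Raphson partial-likelihood maximization); rank tests to ``scipy``;
OLS to ``statsmodels``. The quadrant rule and the Dunn post-hoc with a
Tukey-style familywise adjustment are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats as sps
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "paired_signed_rank",
    "rank_sum",
    "kruskal_wallis_stages",
    "ols_pdl1_association",
    "stratify_quadrants",
    "km_logrank",
    "cox_regression",
    "SurvivalComparison",
    "CoxFit",
]


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def paired_signed_rank(tumor_scores, normal_scores) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped; the null is exact for n <= 25 pairs and a
    normal approximation with continuity correction above.
    """
    tumor = np.asarray(tumor_scores, dtype=float)
    normal = np.asarray(normal_scores, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("paired vectors must have equal length")
    if len(tumor) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = tumor - normal
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        raise ValueError("degenerate pairing: all differences zero")
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = sps.wilcoxon(
        nonzero, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)


def rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test for unpaired groups."""
    res = sps.mannwhitneyu(np.asarray(x, float), np.asarray(y, float), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_stages(scores, stages) -> tuple[float, float, pd.DataFrame]:
    """Tie-corrected Kruskal–Wallis H across stages plus Dunn post-hoc pairs.

    Stages with fewer than 2 samples are excluded with a warning. The
    post-hoc comparisons are Dunn rank tests with a Tukey-style familywise
    adjustment (the pairwise z statistics, scaled by sqrt(2), referred to the
    studentized-range distribution over the k groups).
    """
    scores = np.asarray(scores, dtype=float)
    stages = np.asarray(stages, dtype=object)
    keep_levels = []
    for level in pd.unique(stages):
        if level is None or (isinstance(level, float) and np.isnan(level)):
            continue
        if (stages == level).sum() < 2:
            logger.warning("stage %r has < 2 samples; excluded", level)
            continue
        keep_levels.append(level)
    if len(keep_levels) < 2:
        raise ValueError("need >= 2 stages with >= 2 samples each")
    mask = np.isin(stages, keep_levels)
    scores, stages = scores[mask], stages[mask]

    groups = [scores[stages == lv] for lv in keep_levels]
    h_stat, p = sps.kruskal(*groups)

    # Dunn z statistics on the pooled average ranks, tie-corrected.
    n = len(scores)
    ranks = sps.rankdata(scores)
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks = {lv: ranks[stages == lv].mean() for lv in keep_levels}
    sizes = {lv: int((stages == lv).sum()) for lv in keep_levels}
    k = len(keep_levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = keep_levels[i], keep_levels[j]
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            # Tukey-style familywise adjustment: |z|*sqrt(2) vs the
            # studentized range with k groups (infinite df).
            q = abs(z) * np.sqrt(2.0)
            p_adj = float(np.clip(sps.studentized_range.sf(q, k, np.inf), 0.0, 1.0))
            rows.append({"stage_a": a, "stage_b": b, "z": float(z), "p_adjusted": p_adj})
    return float(h_stat), float(p), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PD-L1 ~ infiltration association
# ---------------------------------------------------------------------------


def ols_pdl1_association(pdl1, bscore, tscore=None) -> pd.DataFrame:
    """OLS of PD-L1 expression on the B-cell score (and optionally the CD8+
    T-cell score as a covariate); returns coefficient, SE and t-based p per
    term."""
    pdl1 = np.asarray(pdl1, dtype=float)
    cols = {"bscore": np.asarray(bscore, dtype=float)}
    if tscore is not None:
        cols["tscore"] = np.asarray(tscore, dtype=float)
    X = pd.DataFrame(cols)
    if len(pdl1) <= len(cols) + 2:
        raise ValueError("too few samples for the regression")
    if not (np.all(np.isfinite(pdl1)) and np.all(np.isfinite(X.to_numpy()))):
        raise ValueError("non-finite values in regression inputs")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("collinear predictors: design matrix is rank-deficient")
    fit = sm.OLS(pdl1, design).fit()
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "coefficient": fit.params.to_numpy(),
            "std_error": fit.bse.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# Quadrant stratification
# ---------------------------------------------------------------------------


def stratify_quadrants(pdl1: pd.Series, bscore: pd.Series) -> pd.DataFrame:
    """Assign each sample to a PD-L1 × B-score quadrant at the medians.

    high = value > median, low = value <= median (both medians over all
    supplied samples). Labels: A = low PD-L1/low B, B = high PD-L1/low B,
    C = high PD-L1/high B, D = low PD-L1/high B.
    """
    pdl1 = pd.Series(pdl1, dtype=float)
    bscore = pd.Series(bscore, dtype=float).reindex(pdl1.index)
    if bscore.isna().any():
        raise ValueError("bscore missing for some samples")
    if len(pdl1) < 4:
        raise ValueError("need >= 4 samples to stratify")
    for name, v in (("PD-L1", pdl1), ("B score", bscore)):
        if v.min() == v.max():
            raise ValueError(f"degenerate stratification: {name} is constant")
    pdl1_high = pdl1 > pdl1.median()
    b_high = bscore > bscore.median()
    label = np.where(
        pdl1_high & b_high, "C", np.where(pdl1_high, "B", np.where(b_high, "D", "A"))
    )
    return pd.DataFrame(
        {
            "sample_id": pdl1.index,
            "group": label,
            "pdl1_value": pdl1.to_numpy(),
            "bscore": bscore.to_numpy(),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalComparison:
    groups: list[str]
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    mean_survival: dict[str, float]
    mean_survival_difference_days: float
    restriction_time: float


@dataclass
class CoxFit:
    model: str  # "univariate" | "multivariate"
    table: pd.DataFrame  # covariate, coefficient, hazard_ratio, std_error, p_value
    n: int = 0
    n_events: int = 0
    warnings: list[str] = field(default_factory=list)


def km_logrank(times, events, group_labels) -> SurvivalComparison:
    """Kaplan–Meier curves per group plus the log-rank test over all groups.

    Mean survival is the restricted mean (area under each KM curve up to the
    largest observed time across groups); for two groups the difference is
    reported, for more the max−min spread.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group_labels = np.asarray(group_labels, dtype=object)
    levels = [lv for lv in pd.unique(group_labels)]
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    for lv in levels:
        if events[group_labels == lv].sum() == 0:
            logger.warning("group %r has zero events", lv)

    tau = float(times.max())
    curves: dict[str, pd.DataFrame] = {}
    means: dict[str, float] = {}
    for lv in levels:
        mask = group_labels == lv
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(lv))
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        curves[str(lv)] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(),
                "at_risk": at_risk.to_numpy(),
            }
        )
        means[str(lv)] = float(restricted_mean_survival_time(kmf, t=tau))

    res = multivariate_logrank_test(times, group_labels, events)
    vals = sorted(means.values())
    diff = vals[-1] - vals[0]
    return SurvivalComparison(
        groups=[str(lv) for lv in levels],
        km_curves=curves,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        mean_survival=means,
        mean_survival_difference_days=float(diff),
        restriction_time=tau,
    )


_REFERENCE_LEVELS = {
    "stage": "I",
    "sex": "male",
    "egfr_status": "non-mutation",
    "kras_status": "non-mutation",
}


def _expand_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical covariates against their stated reference levels.

    Binary high/low factors use "low" as reference; "unknown" mutation
    status becomes its own indicator so unknowns are retained.
    """
    out = {}
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype):
            out[name] = col.astype(float)
            continue
        col = col.astype(object)
        levels = [lv for lv in pd.unique(col.dropna())]
        ref = _REFERENCE_LEVELS.get(name)
        if ref is None:
            ref = "low" if "low" in levels else sorted(map(str, levels))[0]
        for lv in sorted(map(str, levels)):
            if lv == ref:
                continue
            out[f"{name}[{lv}]"] = (col.astype(str) == lv).astype(float)
    return pd.DataFrame(out, index=covariates.index)


def cox_regression(times, events, covariates: pd.DataFrame, mode: str = "multivariate") -> CoxFit:
    """Cox proportional-hazards regression via lifelines (Breslow ties).

    ``mode="multivariate"`` fits all covariates jointly; ``"univariate"``
    fits each covariate alone and stacks the per-covariate rows. Categorical
    covariates are expanded against reference levels (stage I, male,
    non-mutation, low).
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    warnings_: list[str] = []

    def _fit_block(block: pd.DataFrame) -> pd.DataFrame:
        X = _expand_covariates(block)
        arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            raise ValueError("rank-deficient design: collinear or constant covariates")
        if events.sum() < 5 * X.shape[1]:
            msg = f"only {int(events.sum())} events for {X.shape[1]} coefficients"
            warnings_.append(msg)
            logger.warning(msg)
        df = X.copy()
        df["_time"] = times
        df["_event"] = events.astype(int)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # lifelines ConvergenceError and friends
            raise ValueError(f"Cox fit failed: {exc}") from exc
        summ = cph.summary
        return pd.DataFrame(
            {
                "covariate": summ.index,
                "coefficient": summ["coef"].to_numpy(),
                "hazard_ratio": summ["exp(coef)"].to_numpy(),
                "std_error": summ["se(coef)"].to_numpy(),
                "p_value": summ["p"].to_numpy(),
            }
        )

    if mode == "multivariate":
        table = _fit_block(covariates)
    else:
        parts = [_fit_block(covariates[[name]]) for name in covariates.columns]
        table = pd.concat(parts, ignore_index=True)
    return CoxFit(
        model=mode,
        table=table.reset_index(drop=True),
        n=len(times),
        n_events=int(events.sum()),
        warnings=warnings_,
    )
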