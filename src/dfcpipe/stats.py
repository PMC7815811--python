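"""Clinical scoring and the statistical analysis stage.

Implements CIS-20r fatigue scoring, normality-gated two-sample and paired
comparisons, a three-block hierarchical forward regression for fatigue,
post-hoc Spearman correlation profiles, and the cutoff-based three-group
(control / non-fatigued / fatigued) comparison. Following the exploratory
design this stage emulates, p-values are reported uncorrected for multiple
testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Cis20rScore",
    "RegressionBlocks",
    "RegressionResult",
    "TestResult",
    "DEFAULT_CIS20R_MAP",
    "score_cis20r",
    "classify_severe_fatigue",
    "assess_normality",
    "two_group_compare",
    "paired_compare",
    "hierarchical_forward_regression",
    "spearman_profile",
    "three_group_compare",
]

# Item -> subscale assignment (0-based item indices). The instrument's exact
# keying is not public in the emulated protocol; this default groups the 20
# items in order by the published subscale sizes (8/4/3/5) with no
# reverse-scored items, and is configurable.
DEFAULT_CIS20R_MAP: dict[str, tuple[int, ...]] = {
    "subjective_complaints": tuple(range(0, 8)),
    "motivation": tuple(range(8, 12)),
    "physical_activity": tuple(range(12, 15)),
    "concentration": tuple(range(15, 20)),
}


@dataclass
class Cis20rScore:
    subjective_complaints: int
    motivation: int
    physical_activity: int
    concentration: int

    @property
    def total(self) -> int:
        return (
            self.subjective_complaints
            + self.motivation
            + self.physical_activity
            + self.concentration
        )


def score_cis20r(
    items,
    item_map: dict[str, tuple[int, ...]] | None = None,
    reverse_items: tuple[int, ...] = (),
) -> Cis20rScore:
    """Score the 20-item fatigue questionnaire into four subscales.

    Items are responses on a 1-7 agreement scale; subscales are item sums
    and the total is the sum of the four subscales (range 20-140).
    ``reverse_items`` lists 0-based indices to reverse-key (x -> 8 - x);
    none are reversed by default. Missing or out-of-range items raise.
    """
    item_map = item_map or DEFAULT_CIS20R_MAP
    arr = np.asarray(items, dtype=float)
    if arr.shape != (20,):
        raise ValueError("exactly 20 item responses are required")
    if np.any(~np.isfinite(arr)) or np.any((arr < 1) | (arr > 7)):
        raise ValueError("item responses must be in [1, 7] with no missing values")
    if np.any(arr != np.round(arr)):
        raise ValueError("item responses must be integers")
    arr = arr.astype(int)
    for idx in reverse_items:
        arr[idx] = 8 - arr[idx]
    used = sorted(i for idxs in item_map.values() for i in idxs)
    if used != list(range(20)):
        raise ValueError("item map must partition items 0..19")
    sums = {name: int(arr[list(idxs)].sum()) for name, idxs in item_map.items()}
    return Cis20rScore(**sums)


def classify_severe_fatigue(total: float, cutoff: float = 76.0) -> str:
    """Severe fatigue iff the total reaches the clinical cutoff (default 76)."""
    if not 20 <= total <= 140:
        raise ValueError("CIS-20r total must be in [20, 140]")
    return "severe" if total >= cutoff else "non-severe"


def assess_normality(sample, alpha: float = 0.05) -> str:
    """Kolmogorov-Smirnov normality gate with sample mean/sd plug-in.

    Returns ``"normal"`` or ``"non-normal"``. Degenerate (constant)
    samples are non-normal. This mirrors the common statistics-package
    behaviour of testing against a normal with estimated parameters.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("normality assessment requires at least 4 values")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("constant sample: flagged non-normal")
        return "non-normal"
    _, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    decision = "normal" if p >= alpha else "non-normal"
    logger.info("KS normality p=%.4f -> %s", p, decision)
    return decision


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    df: float | None = None

    def label(self) -> str:
        if self.name == "t-test" and self.df is not None:
            return f"t({self.df:g}) = {self.statistic:.3f}"
        if self.name == "mann-whitney":
            return f"U = {self.statistic:g}"
        if self.name == "wilcoxon":
            return f"Z/W = {self.statistic:g}"
        if self.name == "kruskal-wallis" and self.df is not None:
            return f"H({self.df:g}) = {self.statistic:.3f}"
        return f"{self.name}: {self.statistic:.3f}"


def _drop_nan(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def two_group_compare(
    x, y, variance_ratio_limit: float = 4.0, force: str | None = None
) -> TestResult:
    """Normality-gated cross-sectional comparison of two independent samples.

    If both samples pass the KS normality gate, a two-sample t-test is used
    (pooled variance, switching to Welch when the variance ratio exceeds
    ``variance_ratio_limit``); otherwise a Mann-Whitney U test. ``force``
    overrides the gate with ``"t"``, ``"welch"`` or ``"mannwhitney"``.
    """
    x, y = _drop_nan(x), _drop_nan(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if force is None:
        use_t = (
            x.size >= 4
            and y.size >= 4
            and assess_normality(x) == "normal"
            and assess_normality(y) == "normal"
        )
        kind = "t" if use_t else "mannwhitney"
    else:
        kind = force
    if kind in ("t", "welch"):
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        ratio = max(vx, vy) / max(min(vx, vy), 1e-300)
        welch = kind == "welch" or ratio > variance_ratio_limit
        res = sps.ttest_ind(x, y, equal_var=not welch)
        df = float(res.df)
        return TestResult("t-test", float(res.statistic), float(res.pvalue), df)
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: no evidence of a shift
        return TestResult("mann-whitney", float(x.size * y.size / 2.0), 1.0)
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult("mann-whitney", float(u), float(p))


def paired_compare(before, after, force: str | None = None) -> TestResult:
    """Longitudinal paired comparison gated on normality of the differences.

    Paired t-test when the within-subject differences pass the KS gate,
    otherwise Wilcoxon signed-rank. Identical sequences return p = 1.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired sequences must have equal length")
    keep = np.isfinite(before) & np.isfinite(after)
    before, after = before[keep], after[keep]
    if before.size < 2:
        raise ValueError("paired comparison needs at least 2 complete pairs")
    diff = after - before
    if np.allclose(diff, 0.0):
        return TestResult("paired-t" if force != "wilcoxon" else "wilcoxon", 0.0, 1.0)
    if force is None:
        use_t = diff.size >= 4 and assess_normality(diff) == "normal"
        kind = "paired-t" if use_t else "wilcoxon"
    else:
        kind = force
    if kind == "paired-t":
        res = sps.ttest_rel(after, before)
        return TestResult("paired-t", float(res.statistic), float(res.pvalue),
                          float(diff.size - 1))
    w, p = sps.wilcoxon(after, before)
    return TestResult("wilcoxon", float(w), float(p))


@dataclass
class RegressionBlocks:
    """Ordered predictor blocks for the hierarchical forward regression.

    Block 1: demographic/clinical covariates; block 2: brain volumetrics;
    block 3: dynamic-connectivity predictors. Blocks must name disjoint
    columns of the analysis table.
    """

    block1: tuple[str, ...]
    block2: tuple[str, ...] = ()
    block3: tuple[str, ...] = ()
    outcome: str = "cis20r_total"

    def __post_init__(self) -> None:
        all_cols = list(self.block1) + list(self.block2) + list(self.block3)
        if len(set(all_cols)) != len(all_cols):
            raise ValueError("regression blocks must be disjoint")
        if self.outcome in all_cols:
            raise ValueError("outcome cannot appear among predictors")

    @property
    def blocks(self) -> list[tuple[str, ...]]:
        return [tuple(b) for b in (self.block1, self.block2, self.block3) if b]


@dataclass
class RegressionResult:
    selected: list[str]
    r2_steps: list[float]
    delta_r2: list[float]
    entry_p: list[float]
    r2: float
    adjusted_r2: float
    standardized_beta: dict[str, float] = field(default_factory=dict)
    t_values: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    f_statistic: float = float("nan")
    f_df: tuple[int, int] = (0, 0)
    f_p: float = float("nan")
    n: int = 0

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": name,
                "standardized_beta": self.standardized_beta[name],
                "t": self.t_values[name],
                "p": self.p_values[name],
                "delta_r2": self.delta_r2[i],
            }
            for i, name in enumerate(self.selected)
        ]
        return pd.DataFrame(rows)


def _fit_z(y: np.ndarray, x: np.ndarray):
    design = sm.add_constant(x) if x.size else np.ones((y.size, 1))
    return sm.OLS(y, design).fit()


def hierarchical_forward_regression(
    data: pd.DataFrame,
    blocks: RegressionBlocks,
    p_enter: float = 0.05,
    collinearity_r: float = 0.9,
) -> RegressionResult:
    """Three-block hierarchical forward selection for a continuous outcome.

    Blocks are offered in order; within each block, the candidate whose
    partial t-test has the smallest p enters if p < ``p_enter``, repeatedly,
    with previously entered predictors always retained. Variables are
    z-scored before fitting, so coefficients are standardized betas.
    Incomplete rows are dropped listwise (logged); pairwise correlations
    above ``collinearity_r`` among candidates are logged as warnings. If no
    predictor ever enters, an intercept-only result is returned with a
    warning.
    """
    cols = [c for b in blocks.blocks for c in b] + [blocks.outcome]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in analysis table: {missing}")
    frame = data[cols].apply(pd.to_numeric, errors="coerce")
    n_before = len(frame)
    frame = frame.dropna()
    if len(frame) < n_before:
        logger.info(
            "listwise deletion: %d of %d rows dropped", n_before - len(frame), n_before
        )
    n = len(frame)
    candidates = [c for b in blocks.blocks for c in b]
    if n < 4:
        raise ValueError("too few complete cases for regression")
    if n <= len(candidates) + 1:
        logger.warning(
            "complete cases (%d) do not cover the %d candidates; forward "
            "selection will stop when residual df is exhausted", n, len(candidates)
        )
    # screen collinearity among candidates
    corr = frame[candidates].corr().abs()
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if corr.loc[a, b] > collinearity_r:
                logger.warning("collinearity screen: |r(%s, %s)| = %.3f", a, b,
                               corr.loc[a, b])
    z = (frame - frame.mean()) / frame.std(ddof=1)
    dropped = [c for c in candidates if not np.isfinite(z[c]).all()]
    if dropped:
        logger.warning("zero-variance candidates dropped: %s", dropped)
    y = z[blocks.outcome].to_numpy()

    selected: list[str] = []
    r2_steps: list[float] = []
    delta_r2: list[float] = []
    entry_p: list[float] = []
    current_r2 = 0.0
    for block in blocks.blocks:
        remaining = [c for c in block if c not in dropped]
        while remaining:
            if n - len(selected) - 2 < 1:  # residual df exhausted
                remaining = []
                break
            best = None
            for cand in remaining:
                trial = selected + [cand]
                fit = _fit_z(y, z[trial].to_numpy())
                p_cand = float(fit.pvalues[-1])
                if best is None or p_cand < best[1]:
                    best = (cand, p_cand, fit)
            cand, p_cand, fit = best
            if p_cand >= p_enter:
                break
            selected.append(cand)
            remaining.remove(cand)
            r2_steps.append(float(fit.rsquared))
            delta_r2.append(float(fit.rsquared) - current_r2)
            entry_p.append(p_cand)
            current_r2 = float(fit.rsquared)
    if not selected:
        warnings.warn("forward selection admitted no predictor", stacklevel=2)
        return RegressionResult(
            selected=[], r2_steps=[], delta_r2=[], entry_p=[],
            r2=0.0, adjusted_r2=0.0, n=n,
        )
    final = _fit_z(y, z[selected].to_numpy())
    return RegressionResult(
        selected=selected,
        r2_steps=r2_steps,
        delta_r2=delta_r2,
        entry_p=entry_p,
        r2=float(final.rsquared),
        adjusted_r2=float(final.rsquared_adj),
        standardized_beta={c: float(final.params[i + 1]) for i, c in enumerate(selected)},
        t_values={c: float(final.tvalues[i + 1]) for i, c in enumerate(selected)},
        p_values={c: float(final.pvalues[i + 1]) for i, c in enumerate(selected)},
        f_statistic=float(final.fvalue),
        f_df=(int(final.df_model), int(final.df_resid)),
        f_p=float(final.f_pvalue),
        n=n,
    )


def spearman_profile(
    predictors: pd.DataFrame, fatigue_scores: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho and p for every predictor x fatigue-score pair.

    Rows are (predictor, score) pairs; p-values are uncorrected. Pairs with
    fewer than 5 complete observations raise.
    """
    rows = []
    for pred in predictors.columns:
        for score in fatigue_scores.columns:
            x = pd.to_numeric(predictors[pred], errors="coerce")
            y = pd.to_numeric(fatigue_scores[score], errors="coerce")
            keep = x.notna() & y.notna()
            if keep.sum() < 5:
                raise ValueError(
                    f"fewer than 5 complete pairs for ({pred}, {score})"
                )
            rho, p = sps.spearmanr(x[keep], y[keep])
            rows.append({"predictor": pred, "score": score, "rho": float(rho),
                         "p": float(p), "n": int(keep.sum())})
    return pd.DataFrame(rows)


def three_group_compare(groups: dict[str, np.ndarray]) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis omnibus plus uncorrected pairwise Mann-Whitney tests.

    ``groups`` maps group name (e.g. control / non-fatigued / fatigued) to
    the per-subject values of the predictor under test.
    """
    names = list(groups)
    arrays = [_drop_nan(groups[g]) for g in names]
    if len(names) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        omnibus = TestResult("kruskal-wallis", 0.0, 1.0, float(len(names) - 1))
    else:
        h, p = sps.kruskal(*arrays)
        omnibus = TestResult("kruskal-wallis", float(h), float(p), float(len(names) - 1))
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = two_group_compare(groups[a], groups[b], force="mannwhitney")
            rows.append({"group_a": a, "group_b": b, "U": res.statistic, "p": res.p})
    return omnibus, pd.DataFrame(rows)
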