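"""Univariate screening, interobserver agreement and rank correlation.

Group comparison follows the common clinical-imaging recipe: each group
is first checked for normality (Lilliefors-corrected Kolmogorov–Smirnov
by default, since the group mean and SD are estimated from the data);
when both groups pass, an independent-samples t-test is used and groups
are summarized as mean +/- SD, otherwise a two-sided Mann–Whitney U test
with median +/- IQR summaries.  Categorical tables use Pearson chi-square
or, for sparse 2x2 tables, Fisher's exact test.  Interobserver agreement
is the two-way random-effects absolute-agreement single-measures
intraclass correlation, ICC(2,1).

No multiple-testing correction is applied across features; callers
screening many features should treat the per-feature significance flags
accordingly (the pipeline report carries an explicit warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: ICC agreement bands: upper bound (inclusive) -> label.
ICC_BANDS = ((0.4, "poor"), (0.6, "moderate"), (0.8, "good"), (np.inf, "excellent"))


@dataclass
class UnivariateResult:
    """Outcome of one feature's two-group comparison."""

    feature_name: str
    test_used: str  # "t-test" or "mann-whitney"
    p_value: float
    #: per-class (center, spread): (mean, SD) for the t-test path,
    #: (median, IQR) for the Mann-Whitney path.
    group_summaries: dict[int, tuple[float, float]]
    significant: bool
    alpha: float


@dataclass
class AgreementResult:
    """Two-reader agreement for one feature."""

    feature_name: str
    icc: float
    band: str
    degenerate: bool = False  # zero total variance -> trivial agreement


@dataclass
class CategoricalResult:
    test_used: str  # "chi-square" or "fisher"
    p_value: float


def _is_normal(x: np.ndarray, alpha: float, method: str) -> bool:
    """Normality gate for one group; small or constant groups fail it."""
    x = np.asarray(x, dtype=np.float64)
    if x.std(ddof=1) == 0.0:
        return False
    if method == "lilliefors":
        if x.size < 4:
            return False
        from statsmodels.stats.diagnostic import lilliefors

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = lilliefors(x, dist="norm", pvalmethod="table")
    elif method == "ks":
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown normality method {method!r}")
    return p > alpha


def compare_groups(
    values,
    labels,
    alpha: float = 0.05,
    feature_name: str = "",
    normality: str = "lilliefors",
    pooled_normality: bool = False,
    welch: bool = False,
) -> UnivariateResult:
    """Two-group comparison with a per-group normality gate.

    Parameters
    ----------
    values, labels : array-like
        Per-subject feature values and binary group labels (0/1).
    alpha : float
        Significance level for both the normality gate and the final test.
    normality : {"lilliefors", "ks"}
        Normality test; ``"lilliefors"`` corrects for the estimated mean
        and SD, ``"ks"`` is the plain fully-specified KS test.
    pooled_normality : bool
        Assess normality on the pooled (group-centered) values rather
        than per group.
    welch : bool
        Use the unequal-variance t statistic on the parametric path.

    Mann-Whitney p-values are exact (permutation-distribution) when both
    groups have <= 8 untied observations, else use the normal
    approximation with tie correction.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    g0, g1 = values[labels == 0], values[labels == 1]
    if g0.size < 3 or g1.size < 3:
        raise ValueError("each group needs >= 3 subjects")

    if pooled_normality:
        centered = np.concatenate([g0 - g0.mean(), g1 - g1.mean()])
        normal = _is_normal(centered, alpha, normality)
    else:
        normal = _is_normal(g0, alpha, normality) and _is_normal(g1, alpha, normality)

    if normal:
        stat, p = sps.ttest_ind(g0, g1, equal_var=not welch)
        test_used = "t-test"
        summaries = {
            0: (float(g0.mean()), float(g0.std(ddof=1))),
            1: (float(g1.mean()), float(g1.std(ddof=1))),
        }
    else:
        n0, n1 = g0.size, g1.size
        has_ties = np.unique(values).size < values.size
        method = "exact" if (max(n0, n1) <= 8 and not has_ties) else "asymptotic"
        stat, p = sps.mannwhitneyu(g0, g1, alternative="two-sided", method=method)
        test_used = "mann-whitney"

        def _iqr(x):
            q1, q3 = np.percentile(x, [25, 75])
            return float(q3 - q1)

        summaries = {
            0: (float(np.median(g0)), _iqr(g0)),
            1: (float(np.median(g1)), _iqr(g1)),
        }
    p = float(min(p, 1.0))
    return UnivariateResult(
        feature_name=feature_name,
        test_used=test_used,
        p_value=p,
        group_summaries=summaries,
        significant=p < alpha,
        alpha=alpha,
    )


def categorical_test(table) -> CategoricalResult:
    """Chi-square or Fisher's exact test on a 2 x k contingency table.

    Fisher's exact test is used when any expected cell count is below 5
    and the table is 2x2; larger sparse tables fall back to the
    chi-square test with a warning.  The chi-square statistic carries no
    continuity correction.
    """
    table = np.asarray(table)
    if table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k contingency table with k >= 2")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("contingency counts must be integers")
        table = np.round(table).astype(int)
    if (table < 0).any():
        raise ValueError("contingency counts must be non-negative")

    expected = sps.contingency.expected_freq(table)
    if (expected < 5).any():
        if table.shape == (2, 2):
            _, p = sps.fisher_exact(table)
            return CategoricalResult(test_used="fisher", p_value=float(p))
        warnings.warn(
            "expected cell count < 5 in a 2xk (k>2) table; using chi-square anyway",
            stacklevel=2,
        )
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return CategoricalResult(test_used="chi-square", p_value=float(p))


def icc_two_readers(reader1, reader2, feature_name: str = "") -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA decomposition over n subjects and
    k = 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the subject, rater and residual mean squares.  Zero
    total variance (all measurements identical) is reported as ICC = 1
    with ``degenerate=True``.
    """
    x = np.column_stack(
        [np.asarray(reader1, dtype=np.float64), np.asarray(reader2, dtype=np.float64)]
    )
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs >= 3 subjects")
    grand = x.mean()
    if np.allclose(x, grand):
        return AgreementResult(feature_name, 1.0, "excellent", degenerate=True)
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return AgreementResult(feature_name, float(icc), icc_band(float(icc)))


def icc_band(icc: float) -> str:
    """Agreement band: <=0.4 poor, <=0.6 moderate, <=0.8 good, else excellent."""
    for upper, label in ICC_BANDS:
        if icc <= upper:
            return label
    raise AssertionError("unreachable")


def spearman_with_class(values, labels) -> float:
    """Spearman rank correlation between a feature and the binary class.

    Uses midranks for ties (the 0/1 class labels are heavily tied by
    construction).  Raises when only one class is present or the feature
    is constant (rank variance zero).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if values.size < 3:
        raise ValueError("need >= 3 subjects")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    if np.unique(values).size < 2:
        raise ValueError("constant feature: Spearman correlation undefined")
    r, _ = sps.spearmanr(values, labels)
    return float(r)
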