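"""Forward-stepwise logistic modelling, calibration and ROC evaluation.

The selection procedure mirrors the classic "Forward: LR" convention: at
each step the candidate with the smallest likelihood-ratio entry p-value
joins the model when that p-value is below ``entry_p`` (default 0.05);
after every entry, included variables whose likelihood-ratio removal
p-value exceeds ``removal_p`` (default 0.10) are dropped, and the
procedure iterates to a fixed point.  Evaluation is in-sample: the ROC
is computed on the fitted probabilities of the same cohort the model was
fit on (no train/test split), which the report flags as a caveat.

AUC uses the Mann-Whitney identity (ties count 1/2) with a DeLong
variance for the 95% CI; the operating point maximizes the Youden index
J = sensitivity + specificity - 1 over observed thresholds, ties broken
toward higher sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from texturestager.stats import UnivariateResult


# --------------------------------------------------------------------------
# logistic fitting


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist (coefficients diverge)."""


class _LogitFit:
    """Minimal logistic-fit result in the predictors' original units."""

    def __init__(self, params, bse, pvalues, llf, fitted):
        self.params = params
        self.bse = bse
        self.pvalues = pvalues
        self.llf = llf
        self._fitted = fitted

    def predict(self) -> np.ndarray:
        return self._fitted


def _fit_logit(X: np.ndarray, y: np.ndarray) -> _LogitFit:
    """Maximum-likelihood logistic fit with an intercept.

    Predictors are standardized internally (Newton is unstable on badly
    scaled designs) and the coefficients mapped back to original units.
    Raises :class:`SeparationError` when the likelihood surface has no
    interior maximum (perfect separation) and ``RuntimeError`` on
    non-convergence.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    if k:
        center, scale = X.mean(axis=0), X.std(axis=0)
        scale[scale == 0] = 1.0
        Z = (X - center) / scale
    else:
        center = scale = np.empty(0)
        Z = X
    design = sm.add_constant(Z, has_constant="add")
    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    # On the standardized scale a slope beyond ~15 (odds ratio > e^15 per
    # SD) only arises when the MLE is escaping to infinity: the candidate
    # (quasi-)separates the classes.
    if k and np.any(np.abs(np.asarray(res.params)[1:]) > 15.0):
        raise SeparationError("perfect or quasi-perfect separation")
    if not res.mle_retvals.get("converged", False):
        # statsmodels' flag tracks the parameter step, which can stall at
        # machine precision; a vanished gradient still certifies the
        # fixed point.
        grad_norm = float(np.linalg.norm(res.mle_retvals.get("score", np.inf)))
        if grad_norm >= 1e-6:
            if not np.isfinite(res.llf) or res.llf / n > -0.05:
                raise SeparationError("perfect or quasi-perfect separation")
            raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")

    params_z = np.asarray(res.params)
    bse_z = np.asarray(res.bse)
    beta = params_z[1:] / scale if k else params_z[1:]
    intercept = params_z[0] - float(np.sum(params_z[1:] * center / scale)) if k else params_z[0]
    return _LogitFit(
        params=np.concatenate([[intercept], beta]),
        # the intercept SE is not propagated through the de-scaling
        bse=np.concatenate([[np.nan], bse_z[1:] / scale if k else bse_z[1:]]),
        pvalues=np.asarray(res.pvalues),
        llf=float(res.llf),
        fitted=np.asarray(res.predict()),
    )


@dataclass
class StepwiseModel:
    """A forward-stepwise selected logistic model."""

    selected_features: list[str]
    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    odds_ratios: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]  # Wald p per selected feature
    entry_p: float
    removal_p: float
    hl_p: float | None = None
    fitted_probabilities: np.ndarray | None = field(default=None, repr=False)
    separation_flags: list[str] = field(default_factory=list)
    log_likelihood: float = np.nan

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        z = np.full(len(X), self.intercept)
        for name in self.selected_features:
            z = z + self.coefficients[name] * np.asarray(X[name], dtype=np.float64)
        return 1.0 / (1.0 + np.exp(-z))


def _lr_pvalue(llf_full: float, llf_reduced: float) -> float:
    stat = max(2.0 * (llf_full - llf_reduced), 0.0)
    return float(sps.chi2.sf(stat, df=1))


def forward_stepwise_logistic(
    features: pd.DataFrame,
    labels,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> StepwiseModel:
    """Forward-stepwise logistic regression with likelihood-ratio tests.

    Parameters
    ----------
    features : DataFrame
        Candidate predictor columns (no missing values).
    labels : array-like
        Binary outcome, 0/1.
    entry_p, removal_p : float
        Likelihood-ratio entry and removal thresholds.

    Candidates whose fit diverges (perfect separation) are flagged in
    ``separation_flags`` and excluded from entry.  An empty model (no
    candidate reaches ``entry_p``) is returned with an intercept only.
    """
    y = np.asarray(labels).astype(int)
    if features.isna().any().any():
        raise ValueError("candidate features contain missing values")
    if min((y == 0).sum(), (y == 1).sum()) < 10:
        raise ValueError("need >= 10 subjects per class for stepwise modelling")
    candidates = list(features.columns)

    included: list[str] = []
    flags: list[str] = []
    llf_current = float(_fit_logit(np.empty((len(y), 0)), y).llf)

    for _ in range(2 * len(candidates) + 2):  # fixed point reached earlier
        changed = False
        # --- entry step
        best_name, best_p, best_llf = None, np.inf, None
        for name in candidates:
            if name in included or name in flags:
                continue
            try:
                res = _fit_logit(features[included + [name]].to_numpy(), y)
            except SeparationError:
                flags.append(name)
                continue
            p = _lr_pvalue(res.llf, llf_current)
            if p < best_p:
                best_name, best_p, best_llf = name, p, float(res.llf)
        if best_name is not None and best_p < entry_p:
            included.append(best_name)
            llf_current = best_llf
            changed = True
        # --- removal step
        while len(included) > 1:
            worst_name, worst_p = None, -1.0
            llf_full = llf_current
            for name in included:
                reduced = [c for c in included if c != name]
                res = _fit_logit(features[reduced].to_numpy(), y)
                p = _lr_pvalue(llf_full, float(res.llf))
                if p > worst_p:
                    worst_name, worst_p = name, p
            if worst_p > removal_p:
                included.remove(worst_name)
                llf_current = float(_fit_logit(features[included].to_numpy(), y).llf)
                changed = True
            else:
                break
        if not changed:
            break

    res = _fit_logit(features[included].to_numpy(), y)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    wald_p = np.asarray(res.pvalues)
    coefs = dict(zip(included, params[1:]))
    ses = dict(zip(included, bse[1:]))
    z = sps.norm.ppf(0.975)
    model = StepwiseModel(
        selected_features=included,
        intercept=float(params[0]),
        coefficients={k: float(v) for k, v in coefs.items()},
        std_errors={k: float(v) for k, v in ses.items()},
        odds_ratios={k: float(np.exp(v)) for k, v in coefs.items()},
        ci_low={k: float(np.exp(coefs[k] - z * ses[k])) for k in included},
        ci_high={k: float(np.exp(coefs[k] + z * ses[k])) for k in included},
        p_values=dict(zip(included, (float(v) for v in wald_p[1:]))),
        entry_p=entry_p,
        removal_p=removal_p,
        fitted_probabilities=np.asarray(res.predict()),
        separation_flags=flags,
        log_likelihood=float(res.llf),
    )
    if included:
        hl = hosmer_lemeshow(model.fitted_probabilities, y)
        model.hl_p = hl.p_value
    return model


# --------------------------------------------------------------------------
# Hosmer-Lemeshow calibration


@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    n_groups: int
    merged: bool = False


def hosmer_lemeshow(probabilities, labels, n_groups: int = 10) -> HosmerLemeshowResult:
    """Hosmer–Lemeshow goodness-of-fit over deciles of fitted risk.

    Subjects are sorted by fitted probability and split into ``n_groups``
    near-equal groups with tied probabilities kept together; the
    chi-square statistic compares observed and expected events in each
    group with ``df = groups - 2``.  Groups whose expected count is zero
    are merged into a neighbor (reducing df).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if p.size != y.size:
        raise ValueError("probabilities and labels must have the same length")
    if p.size < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} subjects for {n_groups} groups")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")

    # quantile bins on the probabilities; ties fall into one bin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bins = pd.qcut(p, q=n_groups, duplicates="drop", labels=False)
    groups = []
    for g in np.unique(bins):
        sel = bins == g
        groups.append((float(p[sel].sum()), int(y[sel].sum()), int(sel.sum())))

    merged = False
    # merge groups with zero expected events or non-events into a neighbor
    def _degenerate(grp):
        e1, _, n = grp
        return e1 <= 0.0 or (n - e1) <= 0.0

    i = 0
    while len(groups) > 1 and i < len(groups):
        if _degenerate(groups[i]):
            j = i + 1 if i + 1 < len(groups) else i - 1
            e1a, o1a, na = groups[i]
            e1b, o1b, nb = groups[j]
            groups[j] = (e1a + e1b, o1a + o1b, na + nb)
            del groups[i]
            merged = True
            warnings.warn("merged a risk group with zero expected count", stacklevel=2)
        else:
            i += 1

    stat = 0.0
    for e1, o1, n in groups:
        e0, o0 = n - e1, n - o1
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
    df = len(groups) - 2
    p_value = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return HosmerLemeshowResult(
        statistic=float(stat), df=max(df, 0), p_value=p_value,
        n_groups=len(groups), merged=merged,
    )


# --------------------------------------------------------------------------
# ROC analysis


@dataclass
class ROCSummary:
    """Empirical ROC summary at the Youden-optimal operating point."""

    auc: float
    ci_low: float
    ci_high: float
    direction: str  # ">" positive-if-greater, "<" positive-if-smaller
    cutoff: float | None
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    youden: float
    degenerate: bool = False  # constant scores: no usable cutoff

    @property
    def cutoff_label(self) -> str:
        if self.cutoff is None:
            return "undefined"
        return f"{self.direction} {self.cutoff:.6g}"


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the concordant-pair fraction (ties count 1/2), via ranks."""
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    n1, n0 = pos.size, neg.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_se(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong standard error of the empirical AUC from placement values."""
    n1, n0 = pos.size, neg.size
    # V10_i: fraction of negatives each positive beats (ties 1/2)
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return float(np.sqrt(s10 / n1 + s01 / n0))


def roc_analysis(scores, labels) -> ROCSummary:
    """Empirical ROC with DeLong 95% CI and Youden-optimal cutoff.

    The decision direction (positive if score above vs below the cutoff)
    is chosen so the AUC is >= 0.5.  Cutoffs are reported in the style
    "> c" / "< c": a subject is called positive when its score is
    strictly beyond ``c``, with ``c`` an observed score.  Among cutoffs
    tied on the Youden index the one with higher sensitivity wins.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    pos, neg = s[y == 1], s[y == 0]

    if np.unique(s).size == 1:
        return ROCSummary(
            auc=0.5, ci_low=0.5, ci_high=0.5, direction=">", cutoff=None,
            sensitivity=np.nan, specificity=np.nan, accuracy=np.nan,
            youden=np.nan, degenerate=True,
        )

    auc_raw = _auc_mann_whitney(pos, neg)
    if auc_raw >= 0.5:
        direction, sp, sn, flip = ">", pos, neg, 1.0
    else:
        direction, sp, sn, flip = "<", -pos, -neg, -1.0
    auc = _auc_mann_whitney(sp, sn)
    se = _delong_se(sp, sn, auc)
    ci_low = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
    ci_high = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))

    # candidate cutoffs: every observed score plus one below the minimum
    all_scores = np.concatenate([sp, sn])
    cand = np.concatenate([[all_scores.min() - 1.0], np.unique(all_scores)])
    best = None
    for c in cand:
        sens = float(np.mean(sp > c))
        spec = float(np.mean(sn <= c))
        j = sens + spec - 1.0
        key = (round(j, 12), sens)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, c, sens, spec = best
    n1, n0 = sp.size, sn.size
    accuracy = (sens * n1 + spec * n0) / (n1 + n0)
    return ROCSummary(
        auc=auc, ci_low=ci_low, ci_high=ci_high, direction=direction,
        cutoff=float(flip * c), sensitivity=100.0 * sens,
        specificity=100.0 * spec, accuracy=100.0 * accuracy,
        youden=float(sens + spec - 1.0),
    )


# --------------------------------------------------------------------------
# model suite over sequence scopes


@dataclass
class ScopeReport:
    scope: str
    candidates: list[str]
    model: StepwiseModel | None
    roc: ROCSummary | None
    skipped: bool = False
    reason: str = ""


def run_model_suite(
    features: pd.DataFrame,
    labels,
    univariate: list[UnivariateResult],
    scopes: tuple[str, ...] = ("sagittal", "axial", "combined"),
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> dict[str, ScopeReport]:
    """Stepwise model + in-sample ROC per sequence scope.

    A scope's candidate list contains the features flagged significant in
    the univariate screen whose column name carries that sequence prefix;
    the "combined" scope takes the union.  Scopes with no candidate are
    reported as skipped.
    """
    y = np.asarray(labels).astype(int)
    significant = [r.feature_name for r in univariate if r.significant]
    reports: dict[str, ScopeReport] = {}
    for scope in scopes:
        if scope == "combined":
            cands = [f for f in significant if f in features.columns]
        else:
            cands = [
                f for f in significant
                if f in features.columns and f.startswith(f"{scope}_")
            ]
        if not cands:
            warnings.warn(f"scope {scope!r}: no significant candidate features; skipped",
                          stacklevel=2)
            reports[scope] = ScopeReport(scope, [], None, None, skipped=True,
                                         reason="no significant candidates")
            continue
        model = forward_stepwise_logistic(features[cands], y,
                                          entry_p=entry_p, removal_p=removal_p)
        if model.selected_features:
            roc = roc_analysis(model.fitted_probabilities, y)
        else:
            roc = None
        reports[scope] = ScopeReport(scope, cands, model, roc)
    return reports
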