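"""Statistical layer for field biomechanics experiments.

Covers the analyses the pipeline reports on extracted slopes and
contribution ratios: Pearson correlation, one-way and additive two-way
ANOVA with Tukey HSD post-hoc pairs, agreement repeatability (intraclass
correlation from one-way variance components, parametric-bootstrap
uncertainty, permutation p-value), a normality-gated Tukey
ladder-of-powers transform, and the two-predictor OLS used to relate
stalk stiffness to flowering time and plant height at the line-mean
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegenerateFitError, DomainError, InsufficientDataError, SingularDesignError

__all__ = [
    "pearson",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "RepeatabilityResult",
    "repeatability",
    "repeatability_point",
    "TransformResult",
    "tukey_ladder",
    "normalize_if_needed",
    "TukeyLadderTransformer",
    "two_predictor_regression",
]


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise InsufficientDataError(f"need >= 2 groups, got {len(out)}")
    for k, v in out.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {k!r} has {v.size} values, need >= 2")
    return out


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("pearson needs equal-length sequences of >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Between/within mean-square F and its p-value.

    All-constant input (zero within- and between-group variance) is
    degenerate and raises rather than returning NaN silently.
    """
    g = _as_groups(groups)
    vals = list(g.values())
    if all(np.ptp(v) == 0 for v in vals) and np.ptp(np.concatenate(vals)) == 0:
        raise DegenerateFitError("all groups identical constant: F undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = sps.f_oneway(*vals)
    if np.isinf(f):  # zero within-group variance, distinct means
        return float("inf"), 0.0
    return float(f), float(p)


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Additive two-factor ANOVA (main effects only, no interaction).

    Returns the type-II ANOVA table with F and PR(>F) per factor.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "a": list(factor_a), "b": list(factor_b)})
    model = smf.ols("y ~ C(a) + C(b)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All-pairs Tukey HSD: mean differences and studentized-range adjusted p.

    Rows are unordered pairs in label order; columns ``group1, group2,
    mean_diff, p_adj``.
    """
    g = _as_groups(groups)
    labels = list(g)
    res = sps.tukey_hsd(*g.values())
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({
                "group1": labels[i],
                "group2": labels[j],
                "mean_diff": float(g[labels[i]].mean() - g[labels[j]].mean()),
                "p_adj": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RepeatabilityResult:
    """Agreement repeatability (ICC) with bootstrap uncertainty.

    ``R`` is the fraction of total variance attributable to between-group
    (between-plant) variance under the one-way random-effects model;
    ``SE``/``ci_low``/``ci_high`` come from a parametric bootstrap and
    ``p_value`` from a permutation test of group labels.
    """

    R: float
    SE: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int


def _anova_variance_components(values: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA estimators of (sigma^2_group, sigma^2_residual).

    Negative between-group component is truncated at zero.
    """
    n_total = values.size
    group_ids, counts = np.unique(codes, return_counts=True)
    k = group_ids.size
    grand = values.mean()
    means = np.array([values[codes == gid].mean() for gid in group_ids])
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[np.searchsorted(group_ids, codes)]) ** 2))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    # unbalanced-design effective group size
    n0 = (n_total - np.sum(counts**2) / n_total) / (k - 1)
    sigma2_group = max((ms_between - ms_within) / n0, 0.0)
    return sigma2_group, ms_within


def _icc(values: np.ndarray, codes: np.ndarray) -> float:
    s2g, s2r = _anova_variance_components(values, codes)
    total = s2g + s2r
    return 0.0 if total == 0 else s2g / total


def repeatability_point(values: Sequence[float], group_ids: Sequence) -> float:
    """Point estimate of repeatability R (no bootstrap, no p-value)."""
    values = np.asarray(values, dtype=float)
    codes = pd.factorize(np.asarray(group_ids))[0]
    uniq, counts = np.unique(codes, return_counts=True)
    if uniq.size < 2 or np.any(counts < 2):
        raise InsufficientDataError("repeatability needs >= 2 groups with >= 2 values each")
    return _icc(values, codes)


def repeatability(
    values: Sequence[float],
    group_ids: Sequence,
    n_boot: int = 1000,
    n_permute: int = 1000,
    seed: int | None = None,
) -> RepeatabilityResult:
    """Repeatability R of repeated measurements grouped by individual.

    R = sigma^2_group / (sigma^2_group + sigma^2_residual) from the
    one-way ANOVA variance-components estimator (negative between
    component truncated at 0). SE and the 95% interval come from a
    parametric bootstrap: Gaussian group effects and residuals are
    resampled from the fitted components on the observed design and R is
    re-estimated ``n_boot`` times. The p-value against R = 0 is a
    permutation test (group labels shuffled ``n_permute`` times).
    """
    values = np.asarray(values, dtype=float)
    codes = pd.factorize(np.asarray(group_ids))[0]
    uniq, counts = np.unique(codes, return_counts=True)
    if uniq.size < 2 or np.any(counts < 2):
        raise InsufficientDataError("repeatability needs >= 2 groups with >= 2 values each")
    if values.size != codes.size:
        raise InsufficientDataError("values and group_ids must have equal length")

    rng = np.random.default_rng(seed)
    s2g, s2r = _anova_variance_components(values, codes)
    total = s2g + s2r
    r_hat = 0.0 if total == 0 else s2g / total

    group_means_design = codes  # bootstrap keeps the observed grouping design
    boot = np.empty(n_boot)
    for b in range(n_boot):
        effects = rng.normal(0.0, np.sqrt(s2g), size=uniq.size)
        sim = effects[group_means_design] + rng.normal(0.0, np.sqrt(s2r), size=values.size)
        boot[b] = _icc(sim, codes)
    se = float(boot.std(ddof=1)) if n_boot > 1 else float("nan")
    ci_low, ci_high = (float(q) for q in np.quantile(boot, [0.025, 0.975]))

    if n_permute > 0:
        perm_r = np.empty(n_permute)
        for p in range(n_permute):
            perm_r[p] = _icc(values, rng.permutation(codes))
        p_value = float((1 + np.sum(perm_r >= r_hat)) / (1 + n_permute))
    else:
        p_value = float("nan")

    return RepeatabilityResult(float(r_hat), se, ci_low, ci_high, p_value, n_boot)


@dataclass(frozen=True)
class TransformResult:
    """Outcome of the Tukey ladder-of-powers search."""

    lam: float
    transformed: np.ndarray
    W: float


def _ladder_transform(x: np.ndarray, lam: float) -> np.ndarray:
    """Order-preserving power transform: x^lam (lam>0), log x (lam=0), -(x^lam) (lam<0)."""
    if lam > 0:
        return x**lam
    if lam == 0:
        return np.log(x)
    return -(x**lam)


def tukey_ladder(
    x: Sequence[float],
    grid: np.ndarray | None = None,
) -> TransformResult:
    """Tukey's ladder of powers: pick the power maximising Shapiro-Wilk W.

    The default grid runs from -2 to 2 in steps of 0.025 (which contains
    the identity lam = 1, so the selected transform never has lower W
    than the raw data). Values must be strictly positive because the
    grid contains non-integer and negative powers; shift the data first
    if needed.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("tukey_ladder needs n >= 3")
    if np.any(x <= 0):
        raise DomainError(
            "tukey_ladder requires strictly positive values "
            "(non-integer powers and log in the grid); shift the data first"
        )
    if grid is None:
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.025), 6)
    best: tuple[float, float, np.ndarray] | None = None
    for lam in grid:
        t = _ladder_transform(x, float(lam))
        if np.ptp(t) == 0:
            continue
        w = float(sps.shapiro(t).statistic)
        if best is None or w > best[0]:
            best = (w, float(lam), t)
    if best is None:
        raise DegenerateFitError("no ladder power produced a non-constant sample")
    w, lam, t = best
    return TransformResult(lam, t, w)


def normalize_if_needed(
    x: Sequence[float],
    alpha: float = 0.05,
    normalize_when: str = "p_lt",
) -> tuple[np.ndarray, TransformResult | None]:
    """Shapiro-Wilk gate in front of the ladder transform.

    With ``normalize_when="p_lt"`` (default) the transform is applied
    when normality is *rejected* (Shapiro p < alpha) — the conventional
    gate. ``"p_ge"`` applies it when p >= alpha instead, for exact
    reproduction of workflows written with the opposite gate.
    """
    if normalize_when not in ("p_lt", "p_ge"):
        raise ValueError("normalize_when must be 'p_lt' or 'p_ge'")
    x = np.asarray(x, dtype=float)
    p = float(sps.shapiro(x).pvalue)
    trigger = p < alpha if normalize_when == "p_lt" else p >= alpha
    if not trigger:
        return x, None
    res = tukey_ladder(x)
    return res.transformed, res


class TukeyLadderTransformer:
    """sklearn-style transformer wrapping the ladder-of-powers search.

    ``fit`` selects the power on the training column; ``transform``
    applies the same power to new data (single-column input).
    """

    def __init__(self, alpha: float = 0.05, normalize_when: str = "p_lt"):
        self.alpha = alpha
        self.normalize_when = normalize_when

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "normalize_when": self.normalize_when}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        _, res = normalize_if_needed(x, self.alpha, self.normalize_when)
        self.lambda_ = 1.0 if res is None else res.lam
        self.W_ = float(sps.shapiro(_ladder_transform(x, self.lambda_)).statistic)
        return self

    def transform(self, X):
        if not hasattr(self, "lambda_"):
            raise RuntimeError("TukeyLadderTransformer is not fitted")
        x = np.asarray(X, dtype=float)
        return _ladder_transform(x.ravel(), self.lambda_).reshape(x.shape)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def two_predictor_regression(y, x1, x2) -> dict:
    """OLS of y on two predictors with intercept.

    Returns coefficients (b0, b1, b2), per-coefficient two-sided t-test
    p-values and the model R^2. Rank-deficient designs (e.g. collinear
    predictors) raise.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (y.size == x1.size == x2.size) or y.size < 4:
        raise InsufficientDataError("need equal-length sequences of >= 4")
    X = sm.add_constant(np.column_stack([x1, x2]))
    if np.linalg.matrix_rank(X) < 3:
        raise SingularDesignError("design matrix is rank deficient (collinear predictors?)")
    fit = sm.OLS(y, X).fit()
    return {
        "b0": float(fit.params[0]),
        "b1": float(fit.params[1]),
        "b2": float(fit.params[2]),
        "p_values": tuple(float(p) for p in fit.pvalues),
        "r_squared": float(fit.rsquared),
    }
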