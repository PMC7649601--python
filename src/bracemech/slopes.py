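"""Force-deflection slope extraction.

The device records force versus *rotation*; the mechanical quantity of
interest is the slope of force versus horizontal *deflection* at the load
point (N/m), a proxy for whole-plant stiffness including anchorage. The
conversion chain is

    theta = deg * pi / 180,        delta = h * sin(theta)

with ``h`` the load height (m). Three extraction methods are provided,
each an sklearn-style regressor over (deflection, force) pairs:

``FullSlopeRegressor``
    Ordinary least squares over the complete trace, loading and unloading
    legs of all cycles pooled. Robust to cycle-parser failures (wind);
    the pipeline default.
``LoadingSlopeRegressor``
    OLS pooled over the loading cycles only, where a loading cycle is a
    maximal run of >= ``min_run`` strictly increasing deflection samples
    spanning >= ``min_span_m``.
``RansacSlopeRegressor``
    RANSAC line per cycle; the cycle whose consensus set has the longest
    run of consecutive-index inliers wins (ties -> earliest cycle).

All fits include an intercept: field traces carry load-cell offsets at
zero deflection, and only the slope is interpreted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression, RANSACRegressor
from sklearn.utils.validation import check_is_fitted

from .errors import (
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
    NoCycleError,
    ParameterError,
)
from .trace_io import ForceRotationTrace

__all__ = [
    "degrees_to_radians",
    "rotation_to_deflection",
    "trace_deflections",
    "parse_loading_cycles",
    "LoadingCycle",
    "SlopeEstimate",
    "FullSlopeRegressor",
    "LoadingSlopeRegressor",
    "RansacSlopeRegressor",
    "fit_slope_full",
    "fit_slope_loading",
    "fit_slope_ransac",
    "extract_slope",
    "compare_methods",
]


def degrees_to_radians(deg):
    """Convert degrees to radians, ``theta = deg * pi / 180``.

    Full machine-precision pi is used throughout; the relative slope error
    versus a 5-digit pi is below 3e-5 and irrelevant to the analysis.
    """
    deg = np.asarray(deg, dtype=float)
    if not np.all(np.isfinite(deg)):
        raise DomainError("rotation must be finite")
    out = deg * (math.pi / 180.0)
    return out if out.ndim else float(out)


def rotation_to_deflection(theta_rad, load_height_m: float):
    """Horizontal deflection at the load point, ``delta = h * sin(theta)``."""
    if not load_height_m > 0:
        raise DomainError(f"load_height_m must be > 0, got {load_height_m}")
    theta = np.asarray(theta_rad, dtype=float)
    out = load_height_m * np.sin(theta)
    return out if out.ndim else float(out)


def trace_deflections(trace: ForceRotationTrace) -> np.ndarray:
    """Deflection sequence (m) for a trace, elementwise over its samples."""
    return rotation_to_deflection(degrees_to_radians(trace.rotation_deg), trace.load_height_m)


@dataclass(frozen=True)
class LoadingCycle:
    """Inclusive positional bounds of one accepted loading cycle."""

    start_index: int
    end_index: int
    span_m: float

    def slice(self) -> slice:
        return slice(self.start_index, self.end_index + 1)

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1


def parse_loading_cycles(
    deflection_m: np.ndarray,
    min_run: int = 10,
    min_span_m: float = 0.02,
) -> list[LoadingCycle]:
    """Segment a deflection sequence into accepted loading cycles.

    A cycle starts at the first sample of a maximal run of strictly
    increasing deflection of length >= ``min_run`` and extends to the end
    of that run; runs spanning less than ``min_span_m`` (max - min
    deflection) are discarded. Returned cycles are disjoint and ordered.

    Strict increase is deliberate: noise makes exact ties rare, and a
    strict rule is crisp. An empty sequence yields an empty list.
    """
    if min_run < 2:
        raise ParameterError(f"min_run must be >= 2, got {min_run}")
    d = np.asarray(deflection_m, dtype=float)
    cycles: list[LoadingCycle] = []
    if d.size < 2:
        return cycles
    increasing = np.diff(d) > 0
    i = 0
    n = d.size
    while i < n - 1:
        if increasing[i]:
            j = i
            while j < n - 1 and increasing[j]:
                j += 1
            # maximal strictly-increasing run d[i..j]
            run_len = j - i + 1
            span = float(d[i : j + 1].max() - d[i : j + 1].min())
            if run_len >= min_run and span >= min_span_m:
                cycles.append(LoadingCycle(i, j, span))
            i = j
        else:
            i += 1
    return cycles


@dataclass(frozen=True)
class SlopeEstimate:
    """A fitted force-deflection slope with provenance.

    ``method`` is one of ``full``, ``loading``, ``ransac``; ``fallback``
    is set when a loading/ransac request fell back to the full-trace fit
    because no cycle passed the filters.
    """

    slope_N_per_m: float
    intercept_N: float
    method: str
    n_points: int
    r_squared: float
    cycles_used: int
    fallback: bool = False

    def __post_init__(self):
        if self.method not in ("full", "loading", "ransac"):
            raise ParameterError(f"unknown method {self.method!r}")
        if self.n_points < 2:
            raise InsufficientDataError("slope estimate needs >= 2 points")
        if not np.isfinite(self.slope_N_per_m):
            raise DegenerateFitError("non-finite slope")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of an OLS line with intercept."""
    if x.size < 2:
        raise InsufficientDataError("need >= 2 points for a line fit")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero deflection variance: line fit undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), r2


class _SlopeRegressorBase(BaseEstimator, RegressorMixin):
    """Shared fit/predict plumbing for the three slope extractors."""

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single deflection column")
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be 1-d and match X")
        if X.shape[0] < 2:
            raise InsufficientDataError("need >= 2 samples")
        return X, y

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.slope_ * X[:, 0] + self.intercept_

    def _finish(self, slope, intercept, r2, n_points, cycles_used, method, fallback=False):
        self.slope_ = slope
        self.intercept_ = intercept
        self.r_squared_ = r2
        self.n_points_ = n_points
        self.cycles_used_ = cycles_used
        self.estimate_ = SlopeEstimate(slope, intercept, method, n_points, r2, cycles_used, fallback)
        return self

    def fit_trace(self, trace: ForceRotationTrace):
        """Fit directly from a force-rotation trace."""
        return self.fit(trace_deflections(trace)[:, None], trace.force_N)


class FullSlopeRegressor(_SlopeRegressorBase):
    """OLS of force on deflection over the complete trace (all legs, all cycles)."""

    _method = "full"

    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        slope, intercept, r2 = _ols(X[:, 0], y)
        return self._finish(slope, intercept, r2, X.shape[0], 0, "full")


class LoadingSlopeRegressor(_SlopeRegressorBase):
    """OLS pooled over samples inside accepted loading cycles only.

    Parameters
    ----------
    min_run : int
        Consecutive strictly-increasing deflection samples required to
        declare a loading cycle (default 10).
    min_span_m : float
        Minimum deflection span of an accepted cycle in metres
        (default 0.02).
    """

    _method = "loading"

    def __init__(self, min_run: int = 10, min_span_m: float = 0.02):
        self.min_run = min_run
        self.min_span_m = min_span_m

    def fit(self, X, y, cycles: list[LoadingCycle] | None = None):
        X, y = self._validate_xy(X, y)
        d = X[:, 0]
        if cycles is None:
            cycles = parse_loading_cycles(d, self.min_run, self.min_span_m)
        if not cycles:
            raise NoCycleError("no loading cycle passed the run/span filters")
        keep = np.concatenate([np.arange(c.start_index, c.end_index + 1) for c in cycles])
        slope, intercept, r2 = _ols(d[keep], y[keep])
        return self._finish(slope, intercept, r2, keep.size, len(cycles), "loading")


def _longest_consecutive_inlier_run(indices: np.ndarray) -> int:
    """Length of the longest run of consecutive sample indices."""
    if indices.size == 0:
        return 0
    breaks = np.flatnonzero(np.diff(indices) != 1)
    run_edges = np.concatenate([[-1], breaks, [indices.size - 1]])
    return int(np.max(np.diff(run_edges)))


class RansacSlopeRegressor(_SlopeRegressorBase):
    """Per-cycle RANSAC line fit with longest-continuous-consensus selection.

    Each accepted loading cycle gets its own RANSAC line; the reported
    slope comes from the cycle whose inlier set contains the longest run
    of consecutive sample indices (mid-cycle disturbances break runs and
    demote a cycle). Ties go to the earliest cycle. The residual
    threshold adapts to trace noise: ``threshold_scale`` times the median
    absolute residual of a preliminary full-trace OLS.
    """

    _method = "ransac"

    def __init__(
        self,
        min_run: int = 10,
        min_span_m: float = 0.02,
        n_iter: int = 200,
        min_samples: int = 2,
        threshold_scale: float = 1.5,
        seed: int | None = 0,
    ):
        self.min_run = min_run
        self.min_span_m = min_span_m
        self.n_iter = n_iter
        self.min_samples = min_samples
        self.threshold_scale = threshold_scale
        self.seed = seed

    def fit(self, X, y, cycles: list[LoadingCycle] | None = None):
        X, y = self._validate_xy(X, y)
        d = X[:, 0]
        if cycles is None:
            cycles = parse_loading_cycles(d, self.min_run, self.min_span_m)
        if not cycles:
            raise NoCycleError("no loading cycle passed the run/span filters")
        full_slope, full_intercept, _ = _ols(d, y)
        mad = float(np.median(np.abs(y - (full_slope * d + full_intercept))))
        threshold = self.threshold_scale * mad
        if threshold == 0:  # noise-free trace: any positive tolerance accepts all
            threshold = 1e-9
        rng = np.random.RandomState(self.seed)

        best = None  # (run_len, -cycle_order) maximised
        for order, cyc in enumerate(cycles):
            sl = cyc.slice()
            xc, yc = d[sl], y[sl]
            if np.ptp(xc) == 0:
                continue
            ransac = RANSACRegressor(
                estimator=LinearRegression(),
                min_samples=self.min_samples,
                residual_threshold=threshold,
                max_trials=self.n_iter,
                random_state=rng.randint(0, 2**31 - 1),
            )
            try:
                ransac.fit(xc[:, None], yc)
            except ValueError:
                continue  # no consensus in this cycle
            inliers = np.flatnonzero(ransac.inlier_mask_)
            run = _longest_consecutive_inlier_run(inliers)
            if best is None or run > best[0]:
                slope = float(ransac.estimator_.coef_[0])
                intercept = float(ransac.estimator_.intercept_)
                resid = yc[inliers] - (slope * xc[inliers] + intercept)
                ss_tot = float(np.sum((yc[inliers] - yc[inliers].mean()) ** 2))
                r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
                best = (run, order, slope, intercept, r2, int(inliers.size))
        if best is None:
            raise DegenerateFitError("RANSAC found no consensus in any cycle")
        _, _, slope, intercept, r2, n_in = best
        return self._finish(slope, intercept, r2, n_in, len(cycles), "ransac")


# ---------------------------------------------------------------------------
# functional wrappers

def fit_slope_full(trace: ForceRotationTrace) -> SlopeEstimate:
    """Complete-dataset OLS slope (loading + unloading, all cycles)."""
    return FullSlopeRegressor().fit_trace(trace).estimate_


def fit_slope_loading(
    trace: ForceRotationTrace,
    cycles: list[LoadingCycle] | None = None,
    min_run: int = 10,
    min_span_m: float = 0.02,
) -> SlopeEstimate:
    """Loading-cycles-only OLS slope."""
    reg = LoadingSlopeRegressor(min_run, min_span_m)
    d = trace_deflections(trace)
    return reg.fit(d[:, None], trace.force_N, cycles=cycles).estimate_


def fit_slope_ransac(
    trace: ForceRotationTrace,
    cycles: list[LoadingCycle] | None = None,
    seed: int | None = 0,
    **params,
) -> SlopeEstimate:
    """Per-cycle RANSAC slope with longest-consensus cycle selection."""
    reg = RansacSlopeRegressor(seed=seed, **params)
    d = trace_deflections(trace)
    return reg.fit(d[:, None], trace.force_N, cycles=cycles).estimate_


def extract_slope(
    trace: ForceRotationTrace,
    method: str = "full",
    fallback_to_full: bool = True,
    seed: int | None = 0,
    min_run: int = 10,
    min_span_m: float = 0.02,
) -> SlopeEstimate:
    """Extract a slope by the named method with the standard fallback.

    When the cycle parser finds nothing (e.g. wind-corrupted traces) the
    loading and ransac methods cannot run; with ``fallback_to_full`` the
    complete-dataset fit is returned instead, flagged via ``fallback``.
    """
    if method == "full":
        return fit_slope_full(trace)
    try:
        if method == "loading":
            return fit_slope_loading(trace, min_run=min_run, min_span_m=min_span_m)
        if method == "ransac":
            return fit_slope_ransac(trace, seed=seed, min_run=min_run, min_span_m=min_span_m)
    except NoCycleError:
        if fallback_to_full:
            est = fit_slope_full(trace)
            return SlopeEstimate(
                est.slope_N_per_m, est.intercept_N, est.method,
                est.n_points, est.r_squared, 0, fallback=True,
            )
        raise
    raise ParameterError(f"unknown method {method!r}")


METHODS = ("full", "loading", "ransac")


def compare_methods(traces, seed: int | None = 0) -> np.ndarray:
    """Pairwise Pearson correlation matrix of the three methods' slopes.

    Rows/columns are ordered (full, loading, ransac). Only traces for
    which all three methods succeed (no fallback) are used; fewer than
    three such traces is an error.
    """
    from scipy.stats import pearsonr

    slopes = {m: [] for m in METHODS}
    for tr in traces:
        try:
            ests = {m: extract_slope(tr, m, fallback_to_full=False, seed=seed) for m in METHODS}
        except (NoCycleError, DegenerateFitError):
            continue
        for m in METHODS:
            slopes[m].append(ests[m].slope_N_per_m)
    n = len(slopes["full"])
    if n < 3:
        raise InsufficientDataError(f"need >= 3 traces where all methods succeed, got {n}")
    mat = np.eye(3)
    vecs = [np.array(slopes[m]) for m in METHODS]
    for i in range(3):
        for j in range(i + 1, 3):
            r = pearsonr(vecs[i], vecs[j]).statistic
            mat[i, j] = mat[j, i] = r
    return mat
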