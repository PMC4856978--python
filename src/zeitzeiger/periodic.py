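"""Periodic smoothing splines and per-feature time-dependent Gaussian densities.

Each feature's time-dependent mean f_j(t) is a cyclic cubic P-spline: a
penalized regression on an evenly spaced periodic cubic B-spline basis with
``n_knots`` basis functions, a cyclic second-difference roughness penalty,
and the smoothing parameter chosen by generalized cross-validation (GCV).
The variance about the mean is assumed constant over time and estimated as
RSS/n from the spline residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .data import TimeStampedMatrix

SPLINE_DEGREE = 3
# log-spaced smoothing-parameter grid searched by GCV; wide enough to cover
# near-interpolation through near-constant fits for unit-scale data
LAMBDA_GRID = np.logspace(-8.0, 4.0, 25)
VARIANCE_FLOOR_REL = 1e-8
VARIANCE_FLOOR_ABS = 1e-12


def _periodic_knots(n_knots: int, degree: int = SPLINE_DEGREE) -> np.ndarray:
    h = 1.0 / n_knots
    return np.arange(-degree, n_knots + degree + 1) * h


def _design_matrix(times: np.ndarray, n_knots: int) -> np.ndarray:
    """Periodic B-spline design matrix of shape (n, n_knots).

    Standard B-spline basis columns on the extended knot vector are folded
    modulo ``n_knots`` so the resulting basis is periodic with period 1.
    """
    t = np.mod(np.asarray(times, dtype=float), 1.0)
    knots = _periodic_knots(n_knots)
    dm = BSpline.design_matrix(t, knots, SPLINE_DEGREE).toarray()
    n_std = dm.shape[1]  # n_knots + degree standard basis functions
    folded = np.zeros((t.shape[0], n_knots))
    for j in range(n_std):
        folded[:, j % n_knots] += dm[:, j]
    return folded


def _cyclic_penalty(n_knots: int) -> np.ndarray:
    """D'D for the cyclic second-difference operator on the coefficients."""
    d = np.zeros((n_knots, n_knots))
    for i in range(n_knots):
        d[i, (i - 1) % n_knots] += 1.0
        d[i, i] += -2.0
        d[i, (i + 1) % n_knots] += 1.0
    return d.T @ d


@dataclass
class PeriodicCurve:
    """A smooth periodic function of time on [0, 1) with f(0) = f(1).

    Wraps a cyclic B-spline: ``coef`` holds the ``n_knots`` periodic basis
    coefficients; evaluation folds time into [0, 1) so periodicity is exact.
    """

    coef: np.ndarray
    n_knots: int

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if self.n_knots < 2:
            raise ValueError("n_knots must be >= 2")
        if self.coef.shape != (self.n_knots,):
            raise ValueError("coef must have length n_knots")
        knots = _periodic_knots(self.n_knots)
        ext = self.coef[np.arange(self.n_knots + SPLINE_DEGREE) % self.n_knots]
        self._spline = BSpline(knots, ext, SPLINE_DEGREE)

    def evaluate(self, t) -> np.ndarray:
        t = np.mod(np.asarray(t, dtype=float), 1.0)
        return self._spline(t)

    __call__ = evaluate


@dataclass
class TimeDensity:
    """Gaussian conditional density of one feature given time.

    The mean is a :class:`PeriodicCurve`; the variance is constant over time.
    """

    mean_curve: PeriodicCurve
    variance: float
    n_used: int

    def __post_init__(self):
        if not np.isfinite(self.variance) or self.variance <= 0:
            raise ValueError("variance must be finite and > 0")


def _drop_missing(times, values):
    times = np.asarray(times, dtype=float).ravel()
    values = np.asarray(values, dtype=float).ravel()
    if times.shape != values.shape:
        raise ValueError("times and values must have the same length")
    keep = ~np.isnan(values) & ~np.isnan(times)
    return times[keep], values[keep]


def _solve_penalized(bt_b, bt_y, penalty, lam):
    a = bt_b + lam * penalty
    try:
        c, low = cho_factor(a, check_finite=False)
    except np.linalg.LinAlgError:
        a = a + 1e-10 * np.trace(bt_b) / bt_b.shape[0] * np.eye(bt_b.shape[0])
        c, low = cho_factor(a, check_finite=False)
    return (c, low)


def _fit_penalized_multi(basis, y, penalty, lam_grid=LAMBDA_GRID):
    """GCV-selected penalized fit, vectorized over the columns of ``y``.

    Returns (coef, rss) where coef is (n_knots, n_targets) and rss the
    per-target residual sum of squares at each target's selected lambda.
    """
    y = np.atleast_2d(y.T).T  # ensure 2-D, columns = targets
    n = basis.shape[0]
    bt_b = basis.T @ basis
    bt_y = basis.T @ y
    best_gcv = np.full(y.shape[1], np.inf)
    best_coef = np.zeros((basis.shape[1], y.shape[1]))
    best_rss = np.zeros(y.shape[1])
    for lam in lam_grid:
        fac = _solve_penalized(bt_b, bt_y, penalty, lam)
        coef = cho_solve(fac, bt_y, check_finite=False)
        df = np.trace(cho_solve(fac, bt_b, check_finite=False))
        fitted = basis @ coef
        rss = np.sum((y - fitted) ** 2, axis=0)
        denom = max(n - df, 1e-8) ** 2
        gcv = n * rss / denom
        better = gcv < best_gcv - 1e-15
        best_gcv[better] = gcv[better]
        best_coef[:, better] = coef[:, better]
        best_rss[better] = rss[better]
    return best_coef, best_rss


def fit_periodic_curve(times, values, n_knots: int = 3) -> PeriodicCurve:
    """Fit the time-dependent mean of one feature as a periodic smoothing spline.

    Parameters
    ----------
    times : array-like in [0, 1)
    values : array-like, may contain NaN (dropped pairwise)
    n_knots : int
        Number of periodic B-spline basis functions (>= 2).

    Returns
    -------
    PeriodicCurve
    """
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    t, v = _drop_missing(times, values)
    if v.size == 0:
        raise ValueError("all values are missing")
    if np.unique(t).size < 3:
        raise ValueError(
            f"need >= 3 distinct time values after dropping missing entries, got {np.unique(t).size}"
        )
    basis = _design_matrix(t, n_knots)
    penalty = _cyclic_penalty(n_knots)
    coef, _ = _fit_penalized_multi(basis, v[:, None], penalty)
    return PeriodicCurve(coef=coef[:, 0], n_knots=n_knots)


def estimate_variance(curve: PeriodicCurve, times, values) -> float:
    """Variance about the mean curve: mean squared residual RSS/n.

    A small floor (1e-8 x squared value range, or 1e-12 for constant input)
    keeps degenerate noiseless features from producing a zero variance.
    """
    t, v = _drop_missing(times, values)
    if v.size == 0:
        raise ValueError("no non-missing (time, value) pairs")
    resid = v - curve.evaluate(t)
    var = float(np.mean(resid**2))
    rng = float(np.ptp(v))
    floor = VARIANCE_FLOOR_REL * rng**2 if rng > 0 else VARIANCE_FLOOR_ABS
    return max(var, floor)


def fit_time_densities(data: TimeStampedMatrix, n_knots: int = 3) -> list[TimeDensity]:
    """Fit a :class:`TimeDensity` for every feature of a time-stamped matrix.

    Missing entries are dropped pairwise per feature. Features sharing a
    complete set of observations are fitted in one vectorized pass.
    """
    x, times = data.values, data.times
    n, p = x.shape
    missing = np.isnan(x)
    penalty = _cyclic_penalty(n_knots)
    densities: list[TimeDensity | None] = [None] * p

    complete = ~missing.any(axis=0)
    if complete.any():
        if np.unique(times).size < 3:
            raise ValueError("need >= 3 distinct time values to fit densities")
        basis = _design_matrix(times, n_knots)
        cols = np.flatnonzero(complete)
        coef, rss = _fit_penalized_multi(basis, x[:, cols], penalty)
        for i, j in enumerate(cols):
            v = x[:, j]
            var = float(rss[i] / n)
            rng = float(np.ptp(v))
            floor = VARIANCE_FLOOR_REL * rng**2 if rng > 0 else VARIANCE_FLOOR_ABS
            densities[j] = TimeDensity(
                mean_curve=PeriodicCurve(coef=coef[:, i], n_knots=n_knots),
                variance=max(var, floor),
                n_used=n,
            )

    for j in np.flatnonzero(~complete):
        try:
            curve = fit_periodic_curve(times, x[:, j], n_knots=n_knots)
            var = estimate_variance(curve, times, x[:, j])
        except ValueError as exc:
            raise ValueError(f"feature '{data.feature_ids[j]}': {exc}") from exc
        densities[j] = TimeDensity(
            mean_curve=curve, variance=var, n_used=int((~missing[:, j]).sum())
        )
    return densities
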