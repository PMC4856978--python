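"""Supervised prediction of a periodic variable by sparse components.

The :class:`ZeitZeiger` estimator learns, from an observations x features
matrix and a time per observation:

1. a periodic-spline Gaussian density per feature,
2. a centered, noise-scaled pattern matrix of discretized mean curves,
3. sparse principal components (SPCs) of that matrix,
4. periodic-spline Gaussian densities of the training data projected onto
   the SPCs.

Prediction for a new observation projects it into SPC-space and maximizes
the summed Gaussian log-likelihood over the circle, treating the leading
``n_spc`` components as independent.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .data import Prediction, TimeStampedMatrix
from .decomposition import build_pattern_matrix, pmd
from .evaluate import mean_absolute_error
from .periodic import fit_time_densities

_LOG_2PI = np.log(2.0 * np.pi)


class ZeitZeiger(RegressorMixin, BaseEstimator):
    """Predict a periodic variable from high-dimensional observations.

    Parameters
    ----------
    sumabsv : float, default=2.0
        L1 budget on each sparse component's loadings; must lie in
        [1, sqrt(p)], or ``inf`` for standard (unpenalized) principal
        components. Larger values admit more features per component.
    n_spc : int, default=2
        Number of leading components whose Gaussian log-likelihoods are
        summed at prediction time (n_spc <= m).
    m : int, default=12
        Number of evenly spaced time-points at which each feature's mean
        curve is discretized; also the number of components extracted.
    n_knots : int, default=3
        Periodic B-spline basis size for the mean curves.
    period : float, default=1.0
        Period of the time variable in its native units (e.g. 24 for hours).
        ``fit`` rescales times to [0, 1); ``predict`` reports native units.
    n_grid : int, default=100
        Coarse grid size for the likelihood maximization; the best grid
        point is refined by bounded local search.

    Attributes
    ----------
    loadings_ : ndarray of shape (p, m)
        Sparse component loadings V, one component per column.
    feature_densities_ : list of TimeDensity, length p
    spc_densities_ : list of TimeDensity, length m
        Time-dependent mean and variance of each component score.
    predictor_features_ : ndarray of int
        Indices of features with a nonzero loading in any of the first
        ``n_spc`` components; the only features a test observation needs.
    feature_ids_ : list of str
    """

    def __init__(self, sumabsv=2.0, n_spc=2, m=12, n_knots=3, period=1.0, n_grid=100):
        self.sumabsv = sumabsv
        self.n_spc = n_spc
        self.m = m
        self.n_knots = n_knots
        self.period = period
        self.n_grid = n_grid

    # ------------------------------------------------------------------ fit

    def fit(self, X, t, feature_ids=None, observation_ids=None):
        if self.n_spc > self.m:
            raise ValueError(f"n_spc ({self.n_spc}) cannot exceed m ({self.m})")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        t = np.mod(np.asarray(t, dtype=float).ravel() / self.period, 1.0)
        data = TimeStampedMatrix(
            values=X, times=t, feature_ids=feature_ids, observation_ids=observation_ids
        )

        try:
            self.feature_densities_ = fit_time_densities(data, n_knots=self.n_knots)
        except ValueError as exc:
            raise ValueError(f"feature density estimation: {exc}") from exc
        pattern = build_pattern_matrix(self.feature_densities_, self.m)
        pattern.feature_ids = list(data.feature_ids)
        self.pattern_ = pattern
        self.decomposition_ = pmd(pattern.z, self.sumabsv, n_components=self.m)
        self.loadings_ = self.decomposition_.loadings_matrix

        x_tilde = self._project_training(X)
        try:
            self.spc_densities_ = fit_time_densities(
                TimeStampedMatrix(values=x_tilde, times=t), n_knots=self.n_knots
            )
        except ValueError as exc:
            raise ValueError(f"component density estimation: {exc}") from exc

        nz = np.any(self.loadings_[:, : self.n_spc] != 0, axis=1)
        self.predictor_features_ = np.flatnonzero(nz)
        if self.predictor_features_.size == 0:
            raise ValueError("no feature received a nonzero loading; model is empty")
        self.feature_ids_ = list(data.feature_ids)
        self.n_features_in_ = X.shape[1]
        self.x_tilde_ = x_tilde
        return self

    def _project_training(self, X):
        """Project training rows onto the loadings, tolerating missing entries.

        A missing entry contributes nothing to the inner product; the score
        is rescaled by 1/||v_obs||^2 (the least-squares projection
        coefficient on the observed loadings), so partially observed rows
        stay on the scale of fully observed ones.
        """
        if not np.isnan(X).any():
            return X @ self.loadings_
        scores = np.empty((X.shape[0], self.loadings_.shape[1]))
        for i, row in enumerate(X):
            obs = ~np.isnan(row)
            for k in range(self.loadings_.shape[1]):
                v = self.loadings_[:, k]
                denom = float(v[obs] @ v[obs])
                scores[i, k] = (row[obs] @ v[obs]) / denom if denom > 0 else 0.0
        return scores

    # -------------------------------------------------------------- predict

    def project(self, X, observation_ids=None):
        """Project test observations into SPC-space: returns (n, m) scores.

        Test observations must not have missing values among the predictor
        features; missing values elsewhere contribute zero.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if observation_ids is None:
            observation_ids = [f"obs_{i}" for i in range(X.shape[0])]
        bad = np.argwhere(np.isnan(X[:, self.predictor_features_]))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                "Test data cannot have missing measurements for the features used "
                f"in the predictor: observation '{observation_ids[i]}', feature "
                f"'{self.feature_ids_[self.predictor_features_[j]]}'"
            )
        return np.nan_to_num(X, nan=0.0) @ self.loadings_

    def log_likelihood(self, w_tilde, t):
        """Summed Gaussian log-likelihood of time(s) ``t`` on [0, 1) given
        component scores ``w_tilde`` (length >= n_spc)."""
        w_tilde = np.asarray(w_tilde, dtype=float).ravel()
        t = np.asarray(t, dtype=float)
        ll = np.zeros(t.shape) if t.ndim else 0.0
        for k in range(self.n_spc):
            dens = self.spc_densities_[k]
            mu = dens.mean_curve.evaluate(t)
            ll = ll - 0.5 * (_LOG_2PI + np.log(dens.variance)) - (
                w_tilde[k] - mu
            ) ** 2 / (2.0 * dens.variance)
        return ll

    def _argmax_likelihood(self, w_tilde, keep_curve=False):
        grid = np.arange(self.n_grid) / self.n_grid
        ll = self.log_likelihood(w_tilde, grid)
        i = int(np.argmax(ll))  # ties resolve to the smallest t
        t_best, ll_best = float(grid[i]), float(ll[i])
        h = 1.0 / self.n_grid
        res = minimize_scalar(
            lambda t: -self.log_likelihood(w_tilde, np.mod(t, 1.0)),
            bounds=(t_best - h, t_best + h),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if -res.fun > ll_best:
            t_best, ll_best = float(np.mod(res.x, 1.0)), float(-res.fun)
        curve = np.column_stack([grid, ll]) if keep_curve else None
        return Prediction(time_hat=t_best, log_likelihood=ll_best, curve=curve)

    def predict_one(self, w, keep_curve=False) -> Prediction:
        """Predict the time of a single observation; time_hat is on [0, 1)."""
        w_tilde = self.project(np.atleast_2d(w))[0]
        return self._argmax_likelihood(w_tilde, keep_curve=keep_curve)

    def predict_batch(self, X, observation_ids=None, keep_curve=False) -> list[Prediction]:
        """Predict each row of ``X``; order preserved. Validation errors name
        the offending observation and feature before any prediction is made."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0 or X.size == 0:
            return []
        scores = self.project(X, observation_ids=observation_ids)
        return [self._argmax_likelihood(w, keep_curve=keep_curve) for w in scores]

    def predict(self, X):
        """Predicted times in the native units of ``period``, shape (n,)."""
        preds = self.predict_batch(X)
        return np.array([p.time_hat for p in preds]) * self.period

    def score(self, X, y):
        """Negative mean absolute circular error, in native period units."""
        t_true = np.mod(np.asarray(y, dtype=float) / self.period, 1.0)
        t_hat = self.predict(X) / self.period
        return -mean_absolute_error(list(zip(t_true, t_hat))) * self.period


# --------------------------------------------------------- function surface


def train(
    data: TimeStampedMatrix, sumabsv=2.0, n_spc=2, m=12, n_knots=3
) -> ZeitZeiger:
    """Train a predictor on a :class:`TimeStampedMatrix` (times on [0, 1))."""
    model = ZeitZeiger(sumabsv=sumabsv, n_spc=n_spc, m=m, n_knots=n_knots)
    return model.fit(
        data.values,
        data.times,
        feature_ids=data.feature_ids,
        observation_ids=data.observation_ids,
    )


def project(model: ZeitZeiger, observations) -> np.ndarray:
    return model.project(observations)


def log_likelihood(model: ZeitZeiger, w_tilde, t) -> float:
    return model.log_likelihood(w_tilde, t)


def predict(model: ZeitZeiger, w, keep_curve=False) -> Prediction:
    return model.predict_one(w, keep_curve=keep_curve)


def predict_batch(model: ZeitZeiger, observations, observation_ids=None) -> list[Prediction]:
    return model.predict_batch(observations, observation_ids=observation_ids)
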