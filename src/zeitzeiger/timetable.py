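"""Molecular-timetable comparator: cosine-template time prediction.

Features are selected for high periodicity (maximum Pearson correlation,
over phase, with a cosine of the system's period) and high variability
(standard deviation across training observations — the coefficient of
variation is meaningless for data containing negative values). A test
observation's time is predicted by matching its standardized values against
the selected features' cosine templates evaluated at candidate times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .data import Prediction, TimeStampedMatrix

N_PHASE_GRID = 200


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


class MolecularTimetable(BaseEstimator):
    """Time-indicating-feature predictor of a periodic variable.

    Parameters
    ----------
    min_periodicity : float, default=0.8
        Minimum peak correlation with a period-1 cosine (over phase).
    min_sd : float or None, default=None
        Minimum standard deviation across training observations. When None,
        the ``sd_quantile`` quantile of all feature SDs is used.
    sd_quantile : float, default=0.9
    period : float, default=1.0
        Period of the time variable in native units.

    Attributes
    ----------
    features_ : DataFrame with columns (feature_id, index, peak_time,
        periodicity, mean, sd), one row per retained feature, sorted by
        original feature index.
    thresholds_ : dict with the resolved min_periodicity and min_sd.
    """

    def __init__(self, min_periodicity=0.8, min_sd=None, sd_quantile=0.9, period=1.0):
        self.min_periodicity = min_periodicity
        self.min_sd = min_sd
        self.sd_quantile = sd_quantile
        self.period = period

    def fit(self, X, t, feature_ids=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.isnan(X).any():
            raise ValueError("molecular-timetable training data cannot contain missing values")
        tt = np.mod(np.asarray(t, dtype=float).ravel() / self.period, 1.0)
        n, p = X.shape
        if feature_ids is None:
            feature_ids = [f"feature_{j}" for j in range(p)]

        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)

        phases = np.arange(N_PHASE_GRID) / N_PHASE_GRID
        templates = np.cos(2.0 * np.pi * (tt[:, None] - phases[None, :]))  # n x G
        tc = templates - templates.mean(axis=0)
        tn = np.linalg.norm(tc, axis=0)
        xc = X - means
        xn = np.linalg.norm(xc, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (xc.T @ tc) / np.outer(xn, tn)  # p x G
        corr = np.nan_to_num(corr, nan=0.0)

        periodicity = np.empty(p)
        peak_time = np.empty(p)
        h = 1.0 / N_PHASE_GRID
        for j in range(p):
            if xn[j] == 0:  # constant feature: periodicity undefined, excluded
                periodicity[j] = 0.0
                peak_time[j] = 0.0
                continue
            g = int(np.argmax(corr[j]))
            xj = xc[:, j]

            def neg_corr(phi):
                return -_pearson(xj, np.cos(2.0 * np.pi * (tt - phi)))

            res = minimize_scalar(
                neg_corr,
                bounds=(phases[g] - h, phases[g] + h),
                method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun >= corr[j, g]:
                periodicity[j] = float(-res.fun)
                peak_time[j] = float(np.mod(res.x, 1.0))
            else:
                periodicity[j] = float(corr[j, g])
                peak_time[j] = float(phases[g])

        min_sd = (
            float(np.quantile(sds, self.sd_quantile))
            if self.min_sd is None
            else float(self.min_sd)
        )
        keep = (periodicity >= self.min_periodicity) & (sds >= min_sd)
        if not keep.any():
            raise ValueError(
                f"no feature passed both thresholds (min_periodicity="
                f"{self.min_periodicity}, min_sd={min_sd:.4g})"
            )
        idx = np.flatnonzero(keep)
        self.features_ = pd.DataFrame(
            {
                "feature_id": [feature_ids[j] for j in idx],
                "index": idx,
                "peak_time": peak_time[idx],
                "periodicity": periodicity[idx],
                "mean": means[idx],
                "sd": sds[idx],
            }
        )
        self.thresholds_ = {"min_periodicity": self.min_periodicity, "min_sd": min_sd}
        self.n_features_in_ = p
        return self

    # -------------------------------------------------------------- predict

    def _objective_values(self, w_std, times):
        """Correlation (across features) between the standardized observation
        and the cosine templates at each candidate time."""
        peaks = self.features_["peak_time"].to_numpy()
        templ = np.cos(2.0 * np.pi * (np.asarray(times)[:, None] - peaks[None, :]))
        if w_std.size < 2:  # correlation undefined for one feature: use the product
            return (templ * w_std).sum(axis=1)
        return np.array([_pearson(w_std, row) for row in templ])

    def predict_one(self, w) -> Prediction:
        """Predict the time of one observation; the stored objective is the
        achieved template correlation, not a log-likelihood."""
        w = np.asarray(w, dtype=float).ravel()
        if w.shape[0] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {w.shape[0]}")
        idx = self.features_["index"].to_numpy()
        if np.isnan(w[idx]).any():
            j = idx[int(np.argmax(np.isnan(w[idx])))]
            raise ValueError(f"missing value for model feature index {j}")
        w_std = (w[idx] - self.features_["mean"].to_numpy()) / self.features_[
            "sd"
        ].to_numpy()

        grid = np.arange(N_PHASE_GRID) / N_PHASE_GRID
        vals = self._objective_values(w_std, grid)
        g = int(np.argmax(vals))
        h = 1.0 / N_PHASE_GRID
        res = minimize_scalar(
            lambda t: -self._objective_values(w_std, np.mod(np.atleast_1d(t), 1.0))[0],
            bounds=(grid[g] - h, grid[g] + h),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if -res.fun > vals[g]:
            return Prediction(time_hat=float(np.mod(res.x, 1.0)), log_likelihood=float(-res.fun))
        return Prediction(time_hat=float(grid[g]), log_likelihood=float(vals[g]))

    def predict(self, X):
        """Predicted times in native period units, one per row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.predict_one(row).time_hat for row in X]) * self.period

    def random_subset(self, k: int, seed: int) -> "MolecularTimetable":
        """A copy of the fitted model retaining a uniform random subset of
        ``k`` features (seeded, reproducible)."""
        n_feat = len(self.features_)
        if not 1 <= k <= n_feat:
            raise ValueError(f"k must be in [1, {n_feat}], got {k}")
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(n_feat, size=k, replace=False))
        sub = MolecularTimetable(**self.get_params())
        sub.features_ = self.features_.iloc[pick].reset_index(drop=True)
        sub.thresholds_ = dict(self.thresholds_)
        sub.n_features_in_ = self.n_features_in_
        return sub


# --------------------------------------------------------- function surface


def mt_train(
    data: TimeStampedMatrix, min_periodicity=0.8, min_sd=None, sd_quantile=0.9
) -> MolecularTimetable:
    model = MolecularTimetable(
        min_periodicity=min_periodicity, min_sd=min_sd, sd_quantile=sd_quantile
    )
    return model.fit(data.values, data.times, feature_ids=data.feature_ids)


def mt_predict(model: MolecularTimetable, w) -> Prediction:
    return model.predict_one(w)


def mt_random_subset(model: MolecularTimetable, k: int, seed: int) -> MolecularTimetable:
    return model.random_subset(k, seed)
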