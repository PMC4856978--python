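"""Core containers for time-stamped high-dimensional data and predictions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TimeStampedMatrix:
    """A matrix of observations x features with a periodic time per observation.

    Parameters
    ----------
    values : ndarray of shape (n_observations, n_features)
        Measurements (e.g. normalized log expression). May contain NaN
        (missing entries).
    times : ndarray of shape (n_observations,)
        Periodic-variable values scaled to [0, 1).
    feature_ids : sequence of str, optional
        Unique identifiers, one per feature column.
    observation_ids : sequence of str, optional
        Identifiers, one per row.
    """

    values: np.ndarray
    times: np.ndarray
    feature_ids: list[str] = field(default=None)
    observation_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times = np.asarray(self.times, dtype=float).ravel()
        n, p = self.values.shape
        if self.times.shape[0] != n:
            raise ValueError(
                f"times has length {self.times.shape[0]} but values has {n} rows"
            )
        if np.any((self.times < 0) | (self.times >= 1)):
            raise ValueError("all times must lie in [0, 1); rescale by the period first")
        if self.feature_ids is None:
            self.feature_ids = [f"feature_{j}" for j in range(p)]
        else:
            self.feature_ids = [str(f) for f in self.feature_ids]
            if len(self.feature_ids) != p:
                raise ValueError("feature_ids length does not match number of columns")
            if len(set(self.feature_ids)) != p:
                raise ValueError("feature_ids must be unique")
        if self.observation_ids is None:
            self.observation_ids = [f"obs_{i}" for i in range(n)]
        else:
            self.observation_ids = [str(o) for o in self.observation_ids]
            if len(self.observation_ids) != n:
                raise ValueError("observation_ids length does not match number of rows")

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, times: np.ndarray) -> "TimeStampedMatrix":
        """Build from an observations x features DataFrame."""
        return cls(
            values=frame.to_numpy(dtype=float),
            times=times,
            feature_ids=list(frame.columns),
            observation_ids=list(frame.index),
        )


@dataclass
class Prediction:
    """A single predicted time on [0, 1) with its objective value.

    ``log_likelihood`` is the maximized Gaussian log-likelihood for the
    sparse-component predictor; the molecular-timetable comparator stores
    its maximized template correlation in the same slot (a documented
    difference in semantics).
    """

    time_hat: float
    log_likelihood: float
    curve: np.ndarray | None = None  # optional (t, value) samples, shape (g, 2)
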