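"""Circular error metrics and leave-one-group-out cross-validation.

The signed error between a true and predicted periodic value (both on
[0, 1)) is the shortest signed arc: t_hat - t wrapped into [-0.5, 0.5].
A predictor that guesses uniformly at random therefore has absolute errors
uniform on [0, 0.5] with mean 0.25 (6 h on a 24 h scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneGroupOut

from .data import TimeStampedMatrix


@dataclass
class CircularError:
    signed_error: float
    absolute_error: float


def _check_unit(x, name):
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x >= 1)):
        raise ValueError(f"{name} must lie in [0, 1)")
    return x


def signed_circular_error(t, t_hat):
    """Vectorized shortest signed arc t_hat - t, wrapped into [-0.5, 0.5].

    At exactly |t_hat - t| = 0.5 the unwrapped branch wins, so the signed
    error keeps the raw sign (+0.5 or -0.5).
    """
    t = _check_unit(t, "t")
    t_hat = _check_unit(t_hat, "t_hat")
    d = t_hat - t
    d = np.where(d < -0.5, d + 1.0, d)
    d = np.where(d > 0.5, d - 1.0, d)
    return d


def circular_error(t: float, t_hat: float) -> CircularError:
    """Signed and absolute circular error between two values on [0, 1)."""
    d = float(signed_circular_error(t, t_hat))
    return CircularError(signed_error=d, absolute_error=abs(d))


def mean_absolute_error(pairs: Iterable[tuple[float, float]]) -> float:
    """Mean absolute circular error over (t, t_hat) pairs; in [0, 0.5]."""
    pairs = np.asarray(list(pairs), dtype=float)
    if pairs.size == 0:
        raise ValueError("mean_absolute_error requires at least one pair")
    return float(np.mean(np.abs(signed_circular_error(pairs[:, 0], pairs[:, 1]))))


@dataclass
class CVResult:
    """Pooled leave-one-group-out results for one (sumabsv, n_spc) grid point."""

    per_observation: pd.DataFrame  # obs id, group, true time, predicted, error, ll
    per_group_mae: dict
    overall_mae: float
    parameters: dict
    models: dict | None = None  # held-out group -> fitted model, if requested


def leave_one_group_out_cv(
    data: TimeStampedMatrix,
    groups: Sequence,
    param_grid: Sequence[tuple[float, int]],
    m: int = 12,
    n_knots: int = 3,
    return_models: bool = False,
) -> list[CVResult]:
    """For each (sumabsv, n_spc) grid point, hold out each group in turn,
    train on the remaining groups and predict the held-out rows.

    The held-out group contributes nothing to training; fold order does not
    affect the result. Returns one :class:`CVResult` per grid point.
    """
    from .predictor import ZeitZeiger  # local import to avoid a cycle

    groups = np.asarray(groups)
    if groups.shape[0] != data.n_observations:
        raise ValueError("groups must have one label per observation")
    if np.unique(groups).size < 2:
        raise ValueError("leave-one-group-out needs >= 2 distinct groups")

    splits = list(
        LeaveOneGroupOut().split(np.zeros(data.n_observations), groups=groups)
    )
    results = []
    for sumabsv, n_spc in param_grid:
        rows = []
        fold_models = {}
        for train_idx, test_idx in splits:
            held = groups[test_idx[0]]
            model = ZeitZeiger(sumabsv=sumabsv, n_spc=n_spc, m=m, n_knots=n_knots)
            try:
                model.fit(
                    data.values[train_idx],
                    data.times[train_idx],
                    feature_ids=data.feature_ids,
                )
            except ValueError as exc:
                raise ValueError(f"training failed with group '{held}' held out: {exc}")
            if return_models:
                fold_models[held] = model
            preds = model.predict_batch(
                data.values[test_idx],
                observation_ids=[data.observation_ids[i] for i in test_idx],
            )
            for i, pred in zip(test_idx, preds):
                err = float(signed_circular_error(data.times[i], pred.time_hat))
                rows.append(
                    {
                        "observation_id": data.observation_ids[i],
                        "group": groups[i],
                        "time_true": data.times[i],
                        "time_pred": pred.time_hat,
                        "signed_error": err,
                        "log_likelihood": pred.log_likelihood,
                    }
                )
        frame = pd.DataFrame(rows)
        per_group = (
            frame.assign(abs_error=frame["signed_error"].abs())
            .groupby("group", sort=True)["abs_error"]
            .mean()
            .to_dict()
        )
        overall = float(frame["signed_error"].abs().mean())
        results.append(
            CVResult(
                per_observation=frame,
                per_group_mae=per_group,
                overall_mae=overall,
                parameters={"sumabsv": sumabsv, "n_spc": n_spc},
                models=fold_models if return_models else None,
            )
        )
    return results
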