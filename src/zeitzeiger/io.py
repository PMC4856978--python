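"""Delimited-text readers/writers and JSON model serialization."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .periodic import PeriodicCurve, TimeDensity
from .decomposition import Decomposition, SparseComponent
from .predictor import ZeitZeiger
from .timetable import MolecularTimetable

logger = logging.getLogger("zeitzeiger")

SCHEMA_VERSION = 1


def read_expression(path, delimiter="\t", transpose=False) -> pd.DataFrame:
    """Read an observations x features matrix from delimited text.

    First column = observation id (feature id if ``transpose``). Non-numeric
    cells become missing; the count is logged. Duplicate ids are an error.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate id '{dup}' in {path}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicate column id '{dup}' in {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    n_coerced = int((numeric.isna() & frame.notna()).sum().sum())
    if n_coerced:
        logger.info("read_expression: %d non-numeric cells treated as missing", n_coerced)
    if transpose:
        numeric = numeric.T
    return numeric


def write_expression(frame: pd.DataFrame, path, delimiter="\t") -> None:
    frame.to_csv(path, sep=delimiter)


def read_times(path, observation_ids, period=1.0, delimiter="\t") -> np.ndarray:
    """Read a two-column (observation id, time) file and return times aligned
    to ``observation_ids``, reduced modulo ``period`` and rescaled to [0, 1)."""
    meta = pd.read_csv(path, sep=delimiter, index_col=0)
    series = meta.iloc[:, 0]
    if series.index.duplicated().any():
        dup = series.index[series.index.duplicated()][0]
        raise ValueError(f"duplicate observation id '{dup}' in {path}")
    missing = [o for o in observation_ids if o not in series.index]
    if missing:
        raise ValueError(f"observation id '{missing[0]}' not found in {path}")
    t = series.loc[list(observation_ids)].to_numpy(dtype=float)
    return np.mod(t, period) / period


# ------------------------------------------------------------ model <-> JSON


def _density_to_dict(d: TimeDensity) -> dict:
    return {
        "coef": d.mean_curve.coef.tolist(),
        "n_knots": d.mean_curve.n_knots,
        "variance": d.variance,
        "n_used": d.n_used,
    }


def _density_from_dict(obj: dict) -> TimeDensity:
    return TimeDensity(
        mean_curve=PeriodicCurve(coef=np.array(obj["coef"]), n_knots=obj["n_knots"]),
        variance=obj["variance"],
        n_used=obj["n_used"],
    )


def model_to_dict(model) -> dict:
    if isinstance(model, ZeitZeiger):
        components = []
        for comp in model.decomposition_.components:
            nz = np.flatnonzero(comp.loadings)
            components.append(
                {
                    "loadings": {int(j): float(comp.loadings[j]) for j in nz},
                    "left_vector": comp.left_vector.tolist(),
                    "singular_value": comp.singular_value,
                }
            )
        return {
            "schema_version": SCHEMA_VERSION,
            "class": "ZeitZeiger",
            "params": model.get_params(),
            "feature_ids": model.feature_ids_,
            "components": components,
            "spc_densities": [_density_to_dict(d) for d in model.spc_densities_],
        }
    if isinstance(model, MolecularTimetable):
        return {
            "schema_version": SCHEMA_VERSION,
            "class": "MolecularTimetable",
            "params": model.get_params(),
            "n_features_in": model.n_features_in_,
            "thresholds": model.thresholds_,
            "features": model.features_.to_dict(orient="list"),
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(obj: dict):
    if not isinstance(obj, dict) or "schema_version" not in obj or "class" not in obj:
        raise ValueError("not a recognized model document")
    if obj["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {obj['schema_version']} (expected {SCHEMA_VERSION})"
        )
    if obj["class"] == "ZeitZeiger":
        model = ZeitZeiger(**obj["params"])
        feature_ids = list(obj["feature_ids"])
        p = len(feature_ids)
        components = []
        for cd in obj["components"]:
            v = np.zeros(p)
            for j, val in cd["loadings"].items():
                v[int(j)] = val
            components.append(
                SparseComponent(
                    loadings=v,
                    left_vector=np.array(cd["left_vector"]),
                    singular_value=cd["singular_value"],
                    n_nonzero=int(np.count_nonzero(v)),
                )
            )
        model.decomposition_ = Decomposition(
            components=components, sumabsv=model.sumabsv
        )
        model.loadings_ = model.decomposition_.loadings_matrix
        model.spc_densities_ = [_density_from_dict(d) for d in obj["spc_densities"]]
        model.feature_ids_ = feature_ids
        model.n_features_in_ = p
        nz = np.any(model.loadings_[:, : model.n_spc] != 0, axis=1)
        model.predictor_features_ = np.flatnonzero(nz)
        return model
    if obj["class"] == "MolecularTimetable":
        model = MolecularTimetable(**obj["params"])
        model.features_ = pd.DataFrame(obj["features"])
        model.thresholds_ = dict(obj["thresholds"])
        model.n_features_in_ = int(obj["n_features_in"])
        return model
    raise ValueError(f"unknown model class '{obj['class']}'")


def save_model(model, path) -> None:
    """Write a fitted model to a versioned JSON document."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path):
    """Load a model saved by :func:`save_model`; predictions from the
    reloaded model are bit-identical to the original's."""
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model JSON in {path}: {exc}") from exc
    try:
        return model_from_dict(obj)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed model document in {path}: {exc}") from exc
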