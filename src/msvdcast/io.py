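"""CSV and plain-text serialization for series, components, models and tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forecasting import MimoArModel, MlpModel

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_components_csv",
    "write_components_csv",
    "write_predictions_csv",
    "save_model",
    "load_model",
    "write_manifest",
]

MODEL_FORMAT_VERSION = 1


def read_series_csv(path) -> np.ndarray:
    """Read a univariate series from CSV.

    Accepts a single numeric column, optionally preceded by an ISO-8601 date
    column; the last numeric column is taken as the series.
    """
    df = pd.read_csv(path)
    numeric = df.select_dtypes(include="number")
    if numeric.shape[1] == 0:
        raise ValueError(f"no numeric column found in {path}")
    values = numeric.iloc[:, -1].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError(f"non-finite values in series column of {path}")
    return values


def write_series_csv(path, values, dates=None) -> None:
    data = {"value": np.asarray(values, dtype=float)}
    if dates is not None:
        data = {"date": dates, **data}
    pd.DataFrame(data).to_csv(path, index=False)


def write_components_csv(path, c_L, c_H) -> None:
    """Three-column component file: index, c_L, c_H (shared by MSVD and SWT)."""
    pd.DataFrame(
        {"index": np.arange(1, len(c_L) + 1), "c_L": c_L, "c_H": c_H}
    ).to_csv(path, index=False)


def read_components_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    missing = {"c_L", "c_H"} - set(df.columns)
    if missing:
        raise ValueError(f"components file {path} is missing columns: {sorted(missing)}")
    return df["c_L"].to_numpy(dtype=float), df["c_H"].to_numpy(dtype=float)


def write_predictions_csv(path, time_index, observed, predicted) -> None:
    """Long-format forecasts: one row per (time index, horizon)."""
    rows, tau = np.asarray(observed).shape
    t = np.repeat(np.asarray(time_index), tau)
    h = np.tile(np.arange(1, tau + 1), rows)
    pd.DataFrame(
        {
            "time_index": t,
            "horizon": h,
            "observed": np.asarray(observed, dtype=float).ravel(),
            "predicted": np.asarray(predicted, dtype=float).ravel(),
        }
    ).to_csv(path, index=False)


def _write_matrix(fh, name: str, m: np.ndarray) -> None:
    fh.write(f"{name}: {m.shape[0]} {m.shape[1]}\n")
    for row in m:
        fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_matrix(lines, i: int, name: str) -> tuple[np.ndarray, int]:
    head = lines[i].split(":")
    if head[0].strip() != name:
        raise ValueError(f"expected matrix {name!r}, found {lines[i]!r}")
    r, c = map(int, head[1].split())
    rows = [list(map(float, lines[i + 1 + k].split())) for k in range(r)]
    return np.array(rows).reshape(r, c), i + 1 + r


def save_model(path, model: MimoArModel | MlpModel) -> None:
    """Versioned plain-text model file (key-value header + row-major matrices)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# msvdcast-model v{MODEL_FORMAT_VERSION}\n")
        if isinstance(model, MimoArModel):
            fh.write("kind: mimo_ar\n")
            fh.write(f"P: {model.P}\ntau: {model.tau}\nbias: {int(model.bias)}\n")
            _write_matrix(fh, "beta", model.beta)
        elif isinstance(model, MlpModel):
            fh.write("kind: mimo_ann\n")
            fh.write(f"Q: {model.Q}\n")
            fh.write(f"standardized_inputs: {int(model.input_mean is not None)}\n")
            fh.write(f"standardized_targets: {int(model.target_mean is not None)}\n")
            _write_matrix(fh, "input_weights", model.input_weights)
            _write_matrix(fh, "output_weights", model.output_weights)
            if model.input_mean is not None:
                _write_matrix(fh, "input_mean", model.input_mean[None, :])
                _write_matrix(fh, "input_scale", model.input_scale[None, :])
            if model.target_mean is not None:
                _write_matrix(fh, "target_mean", model.target_mean[None, :])
                _write_matrix(fh, "target_scale", np.array([[model.target_scale]]))
        else:
            raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def load_model(path) -> MimoArModel | MlpModel:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# msvdcast-model v"):
        raise ValueError(f"{path} is not a model file")
    version = int(lines[0].rsplit("v", 1)[1])
    if version > MODEL_FORMAT_VERSION:
        raise ValueError(f"model format v{version} is newer than supported")
    matrix_names = {"beta", "input_weights", "output_weights", "input_mean", "input_scale"}
    fields = {}
    i = 1
    while i < len(lines) and ":" in lines[i]:
        key = lines[i].split(":", 1)[0].strip()
        if key in matrix_names:
            break
        fields[key] = lines[i].split(":", 1)[1].strip()
        i += 1
    kind = fields["kind"]
    if kind == "mimo_ar":
        beta, i = _read_matrix(lines, i, "beta")
        return MimoArModel(
            beta=beta, P=int(fields["P"]), tau=int(fields["tau"]),
            bias=bool(int(fields.get("bias", "0"))),
        )
    if kind == "mimo_ann":
        w, i = _read_matrix(lines, i, "input_weights")
        b, i = _read_matrix(lines, i, "output_weights")
        mean = scale = t_mean = t_scale = None
        if bool(int(fields.get("standardized_inputs", "0"))):
            mean, i = _read_matrix(lines, i, "input_mean")
            scale, i = _read_matrix(lines, i, "input_scale")
            mean, scale = mean[0], scale[0]
        if bool(int(fields.get("standardized_targets", "0"))):
            t_mean, i = _read_matrix(lines, i, "target_mean")
            t_scale_m, i = _read_matrix(lines, i, "target_scale")
            t_mean, t_scale = t_mean[0], float(t_scale_m[0, 0])
        return MlpModel(
            input_weights=w, output_weights=b, Q=int(fields["Q"]),
            input_mean=mean, input_scale=scale,
            target_mean=t_mean, target_scale=t_scale,
        )
    raise ValueError(f"unknown model kind {kind!r}")


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
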