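"""Serialization: stimulus/spike HDF5 (with CSV fallback), model JSON,
mosaic CSV, and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model_core import (
    ConeStimulus,
    ConeWeights,
    SpikeCounts,
    SubunitAssignment,
    SubunitModel,
    SubunitWeights,
)
from .nonlinearity import Spline
from .synthetic import ConeMosaic

__all__ = [
    "FORMAT_VERSION",
    "save_stimulus_spikes",
    "load_stimulus_spikes",
    "model_to_dict",
    "model_from_dict",
    "save_model_json",
    "load_model_json",
    "save_mosaic_csv",
    "load_mosaic_csv",
    "write_manifest",
]

FORMAT_VERSION = 1


class SchemaError(ValueError):
    """A serialized document is missing or corrupting a required field."""


# ---------------------------------------------------------------------------
# stimulus + spikes
# ---------------------------------------------------------------------------

def save_stimulus_spikes(path, stim: ConeStimulus, counts: SpikeCounts) -> None:
    """Write paired stimulus/counts; HDF5 for .h5/.hdf5, CSV otherwise."""
    path = Path(path)
    if counts.n_frames != stim.n_frames:
        raise ValueError("stimulus and counts frame counts differ")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("stimulus", data=stim.values.astype(np.float64))
            fh.create_dataset("counts", data=counts.counts.astype(np.int32))
            fh.attrs["frame_rate_hz"] = float(stim.frame_rate_hz)
            fh.attrs["cone_ids"] = [str(c) for c in stim.cone_ids]
            fh.attrs["version"] = FORMAT_VERSION
    else:
        rows = {f"cone_{c}": stim.values[i] for i, c in enumerate(stim.cone_ids)}
        rows["counts"] = counts.counts
        df = pd.DataFrame(rows).T
        df.insert(0, "frame_rate_hz", float(stim.frame_rate_hz))
        df.to_csv(path, index_label="series")


def load_stimulus_spikes(path):
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            for key in ("stimulus", "counts"):
                if key not in fh:
                    raise SchemaError(f"missing dataset {key!r} in {path.name}")
            if "frame_rate_hz" not in fh.attrs:
                raise SchemaError(f"missing attribute 'frame_rate_hz' in {path.name}")
            values = fh["stimulus"][()]
            counts = fh["counts"][()]
            ids = tuple(fh.attrs.get("cone_ids", ()))
            stim = ConeStimulus(
                values,
                frame_rate_hz=float(fh.attrs["frame_rate_hz"]),
                cone_ids=ids if len(ids) else None,
            )
    else:
        df = pd.read_csv(path, index_col="series")
        if "counts" not in df.index or "frame_rate_hz" not in df.columns:
            raise SchemaError(f"malformed stimulus CSV {path.name}")
        frame_rate = float(df["frame_rate_hz"].iloc[0])
        frames = df.drop(columns="frame_rate_hz")
        counts = frames.loc["counts"].to_numpy()
        cone_rows = frames.drop(index="counts")
        ids = tuple(s.removeprefix("cone_") for s in cone_rows.index)
        stim = ConeStimulus(cone_rows.to_numpy(), frame_rate_hz=frame_rate, cone_ids=ids)
    return stim, SpikeCounts(np.asarray(counts).astype(np.int64))


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

def _spline_to_dict(sp: Spline) -> dict:
    return {
        "node_x": sp.node_x.tolist(),
        "node_y": sp.node_y.tolist(),
        "coefficients": sp.coefficients.tolist(),
        "extrapolation_slopes": [sp.slope_low, sp.slope_high],
    }


def _spline_from_dict(d: dict, where: str) -> Spline:
    for key in ("node_x", "node_y"):
        if key not in d:
            raise SchemaError(f"spline {where!r} missing field {key!r}")
    return Spline(np.asarray(d["node_x"]), np.asarray(d["node_y"]))


def model_to_dict(model: SubunitModel, metadata: dict | None = None) -> dict:
    """JSON-ready document: assignment as cone-index lists per subunit."""
    I = model.assignment.indicator
    A = model.cone_weights.weights
    subunits = []
    for s in range(model.n_subunits):
        cones = np.flatnonzero(I[s])
        subunits.append(
            {"cones": cones.tolist(), "weights": A[s, cones].tolist()}
        )
    return {
        "version": FORMAT_VERSION,
        "n_cones": model.n_cones,
        "subunits": subunits,
        "subunit_weights": model.subunit_weights.weights.tolist(),
        "f": _spline_to_dict(model.f),
        "g": _spline_to_dict(model.g),
        "metadata": dict(metadata or {}),
    }


def model_from_dict(doc: dict) -> SubunitModel:
    for key in ("n_cones", "subunits", "subunit_weights", "f", "g"):
        if key not in doc:
            raise SchemaError(f"model document missing field {key!r}")
    C = int(doc["n_cones"])
    subunits = doc["subunits"]
    S = len(subunits)
    I = np.zeros((S, C), dtype=np.int8)
    A = np.zeros((S, C))
    for s, entry in enumerate(subunits):
        for key in ("cones", "weights"):
            if key not in entry:
                raise SchemaError(f"subunit {s} missing field {key!r}")
        cones = np.asarray(entry["cones"], dtype=int)
        I[s, cones] = 1
        A[s, cones] = entry["weights"]
    return SubunitModel(
        SubunitAssignment(I),
        ConeWeights(A),
        SubunitWeights(np.asarray(doc["subunit_weights"], dtype=float)),
        _spline_from_dict(doc["f"], "f"),
        _spline_from_dict(doc["g"], "g"),
    )


def save_model_json(path, model: SubunitModel, metadata: dict | None = None) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model, metadata), indent=2, sort_keys=True) + "\n"
    )


def load_model_json(path) -> SubunitModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"model file {Path(path).name} is not valid JSON: {exc}")
    return model_from_dict(doc)


# ---------------------------------------------------------------------------
# mosaic CSV
# ---------------------------------------------------------------------------

def save_mosaic_csv(path, mosaic: ConeMosaic) -> None:
    pd.DataFrame(
        {
            "id": mosaic.cone_ids,
            "x": mosaic.x,
            "y": mosaic.y,
            "sigma": mosaic.sigma,
            "gain": mosaic.gain,
        }
    ).to_csv(path, index=False)


def load_mosaic_csv(path) -> ConeMosaic:
    df = pd.read_csv(path)
    for col in ("id", "x", "y", "sigma", "gain"):
        if col not in df.columns:
            raise SchemaError(f"mosaic CSV missing column {col!r}")
    return ConeMosaic(
        cone_ids=tuple(df["id"]),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float),
        gain=df["gain"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path, config: dict, seed: int, outputs: list[str]) -> dict:
    """Record what produced a set of outputs: config hash, seed, versions."""
    import numpy
    import scipy

    from . import __version__

    canonical = json.dumps(config, sort_keys=True)
    manifest = {
        "version": FORMAT_VERSION,
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": int(seed),
        "outputs": list(outputs),
        "package_versions": {
            "conesubunits": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
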