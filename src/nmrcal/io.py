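"""Readers and writers: two-column text spectra, JSON peak models, HDF5 dataset
bundles, and trained-model directories.

Spectra are stored as plain two-column text (ppm, intensity) with ``#``-prefixed
header lines carrying the spectrometer frequency and provenance. Files with a
descending ppm axis (the conventional display order) are accepted and flipped
to the ascending internal representation. Dataset bundles are HDF5 with groups
``/spectra`` (float32 by default), ``/labels``, ``/params`` and grid/seed/
config-hash attributes, so a bundle is self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .augment import LabeledDataset
from .network import AnnConfig, TrainedModel, TrainingHistory
from .spectral import (
    PseudoVoigtPeak,
    PureComponentModel,
    SpectralGrid,
    Spectrum,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "save_component_model",
    "load_component_model",
    "write_bundle",
    "read_bundle",
    "save_model",
    "load_model",
    "config_hash",
]


def config_hash(obj: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# two-column text spectra


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write ppm/intensity columns with grid metadata in ``#`` headers."""
    path = Path(path)
    g = spectrum.grid
    with open(path, "w") as fh:
        fh.write(f"# spectrometer_freq_mhz: {g.spectrometer_freq}\n")
        for key, val in spectrum.meta.items():
            fh.write(f"# {key}: {val}\n")
        for p, y in zip(g.ppm, spectrum.intensity):
            fh.write(f"{p:.8f}\t{y:.10e}\n")


def read_spectrum(path: str | Path, spectrometer_freq: float | None = None) -> Spectrum:
    """Read a two-column text spectrum; a descending ppm axis is flipped.

    Raises a ``ValueError`` naming the offending line on malformed input; a
    truncated file yields no partial object.
    """
    path = Path(path)
    meta: dict = {}
    ppm: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
    if len(ppm) < 2:
        raise ValueError(f"{path}: fewer than two data rows")
    p = np.asarray(ppm)
    y = np.asarray(inten)
    d = np.diff(p)
    if np.all(d < 0):
        logger.info("%s: descending ppm axis, flipping to ascending", path)
        p, y = p[::-1], y[::-1]
        d = -d[::-1]
    elif not np.all(d > 0):
        raise ValueError(f"{path}: ppm axis is not monotonic")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: ppm axis is not uniformly spaced")
    freq = spectrometer_freq or float(meta.pop("spectrometer_freq_mhz", 43.3))
    grid = SpectralGrid(float(p[0]), float(p[-1]), len(p), freq)
    return Spectrum(grid, y, meta)


# ---------------------------------------------------------------------------
# JSON peak models


def save_component_model(
    model: PureComponentModel, path: str | Path, delta_nu: float | None = None
) -> None:
    doc = {
        "name": model.name,
        "peaks": [
            {"omega": p.omega, "alpha": p.alpha, "gamma": p.gamma, "beta": p.beta,
             "group": p.group_id}
            for p in model.peaks
        ],
    }
    if delta_nu is not None:
        doc["delta_nu"] = delta_nu
    Path(path).write_text(json.dumps(doc, indent=2))


def load_component_model(path: str | Path) -> PureComponentModel:
    doc = json.loads(Path(path).read_text())
    peaks = tuple(
        PseudoVoigtPeak(
            omega=p["omega"], alpha=p["alpha"], gamma=p["gamma"],
            beta=p.get("beta", 1.0), group_id=p.get("group", 0),
        )
        for p in doc["peaks"]
    )
    return PureComponentModel(doc["name"], peaks)


# ---------------------------------------------------------------------------
# HDF5 dataset bundles


def write_bundle(dataset: LabeledDataset, path: str | Path, dtype: str = "float32") -> None:
    """Write a LabeledDataset to an HDF5 bundle (spectra stored ``float32`` by
    default; computation stays float64)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=dataset.spectra.astype(dtype))
        f.create_dataset("labels", data=dataset.labels)
        params = f.create_group("params")
        for col in dataset.params_log.columns:
            params.create_dataset(col, data=dataset.params_log[col].to_numpy())
        g = dataset.grid
        f.attrs["ppm_start"] = g.ppm_start
        f.attrs["ppm_end"] = g.ppm_end
        f.attrs["n_points"] = g.n_points
        f.attrs["spectrometer_freq"] = g.spectrometer_freq
        f.attrs["seed"] = dataset.seed
        f.attrs["component_names"] = json.dumps(dataset.component_names)
        f.attrs["config_hash"] = config_hash(dataset.meta.get("config", {}))
        f.attrs["generator"] = dataset.meta.get("generator", "")


def read_bundle(path: str | Path) -> LabeledDataset:
    with h5py.File(path, "r") as f:
        grid = SpectralGrid(
            float(f.attrs["ppm_start"]), float(f.attrs["ppm_end"]),
            int(f.attrs["n_points"]), float(f.attrs["spectrometer_freq"]),
        )
        params = pd.DataFrame({k: v[()] for k, v in f["params"].items()})
        return LabeledDataset(
            spectra=f["spectra"][()].astype(float),
            labels=f["labels"][()].astype(float),
            params_log=params,
            grid=grid,
            component_names=list(json.loads(f.attrs["component_names"])),
            seed=int(f.attrs["seed"]),
            meta={"generator": str(f.attrs.get("generator", "")),
                  "config_hash": str(f.attrs.get("config_hash", ""))},
        )


# ---------------------------------------------------------------------------
# trained models


def save_model(model: TrainedModel, directory: str | Path,
               history: TrainingHistory | None = None) -> None:
    """Persist a trained model: config + scales as JSON, weights as ``.npz``,
    history as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dict(model.config.__dict__)
    cfg["lr_schedule"] = [list(x) for x in cfg["lr_schedule"]]
    (directory / "config.json").write_text(json.dumps(cfg, indent=2))
    (directory / "scales.json").write_text(
        json.dumps({"x_scale": model.x_scale, "y_scale": model.y_scale})
    )
    np.savez(directory / "weights.npz", **model.weights)
    if history is not None:
        pd.DataFrame(
            {k: v for k, v in history.__dict__.items() if v}
        ).to_csv(directory / "history.csv", index=False)


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    cfg["lr_schedule"] = tuple(tuple(x) for x in cfg["lr_schedule"])
    config = AnnConfig(**cfg)
    scales = json.loads((directory / "scales.json").read_text())
    with np.load(directory / "weights.npz") as npz:
        weights = {k: npz[k] for k in npz.files}
    return TrainedModel(config=config, weights=weights,
                        x_scale=scales["x_scale"], y_scale=scales["y_scale"])
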