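"""Persistence and configuration for the command-line pipeline.

HDF5 is the primary container (NPZ is used when a path ends in ``.npz``);
reflection tables are CSV.  Every artefact carries the detector-geometry
fingerprint so cross-artefact operations (e.g. integrating a stack against
a model built for a different geometry) are refused early.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from icebg.geometry import DetectorGeometry
from icebg.global_model import BackgroundModel, ImageStack, PixelStatistics
from icebg.simulate import GroundTruth, SimulatedData, build_spot_shoeboxes

__all__ = [
    "ConfigError",
    "DataError",
    "load_config",
    "geometry_from_config",
    "save_model",
    "load_model",
    "save_stack",
    "load_stack",
    "save_reflection_table",
    "load_reflection_table",
]


class ConfigError(ValueError):
    """A configuration file is missing keys or has invalid values."""


class DataError(ValueError):
    """A data artefact is unreadable or inconsistent with the run."""


_GEOMETRY_KEYS = (
    "n_slow",
    "n_fast",
    "pixel_size_mm",
    "distance_mm",
    "beam_centre_px",
    "wavelength_A",
)


def load_config(path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping at the top level")
    return cfg


def geometry_from_config(cfg: dict) -> DetectorGeometry:
    block = cfg.get("geometry")
    if not isinstance(block, dict):
        raise ConfigError("config is missing the 'geometry' block")
    for key in _GEOMETRY_KEYS:
        if key not in block:
            raise ConfigError(f"geometry block is missing key: {key!r}")
    try:
        return DetectorGeometry.from_dict(block)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid geometry: {exc}") from exc


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------

def save_model(
    path,
    model: BackgroundModel,
    geom: DetectorGeometry,
    stats: PixelStatistics | None = None,
) -> None:
    """Persist a background model (+ optional statistics images)."""
    path = Path(path)
    params = {k: v for k, v in model.provenance.items() if not isinstance(v, dict)}
    if path.suffix == ".npz":
        payload = {
            "background": model.b,
            "mask": model.off_grid,
            "geometry_json": np.bytes_(json.dumps(geom.to_dict())),
            "params_json": np.bytes_(json.dumps(params, default=str)),
            "fingerprint": np.bytes_(geom.fingerprint()),
        }
        if stats is not None:
            payload |= {
                "mean": stats.mean,
                "variance": stats.variance,
                "dispersion": stats.dispersion,
            }
        np.savez_compressed(path, **payload)
        return
    with h5py.File(path, "w") as fh:
        fh.create_dataset("background", data=model.b)
        fh.create_dataset("mask", data=model.off_grid)
        if stats is not None:
            fh.create_dataset("mean", data=stats.mean)
            fh.create_dataset("variance", data=stats.variance)
            fh.create_dataset("dispersion", data=stats.dispersion)
        fh.attrs["geometry"] = json.dumps(geom.to_dict())
        fh.attrs["params"] = json.dumps(params, default=str)
        fh.attrs["fingerprint"] = geom.fingerprint()


def load_model(path) -> tuple[BackgroundModel, DetectorGeometry]:
    path = Path(path)
    try:
        if path.suffix == ".npz":
            with np.load(path) as fh:
                geom = DetectorGeometry.from_dict(json.loads(bytes(fh["geometry_json"]).decode()))
                model = BackgroundModel(
                    b=fh["background"],
                    off_grid=fh["mask"].astype(bool),
                    provenance=json.loads(bytes(fh["params_json"]).decode()),
                )
        else:
            with h5py.File(path, "r") as fh:
                geom = DetectorGeometry.from_dict(json.loads(fh.attrs["geometry"]))
                model = BackgroundModel(
                    b=fh["background"][()],
                    off_grid=fh["mask"][()].astype(bool),
                    provenance=json.loads(fh.attrs["params"]),
                )
    except (OSError, KeyError) as exc:
        raise DataError(f"cannot load model from {path}: {exc}") from exc
    return model, geom


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def save_stack(path, data: SimulatedData, geom: DetectorGeometry, sim_params: dict | None = None) -> None:
    """Persist a simulated stack with ground truth and the spot table."""
    sim_params = sim_params or {}
    with h5py.File(path, "w") as fh:
        fh.create_dataset("images", data=data.stack.images, compression="gzip", compression_opts=1)
        fh.create_dataset("masks", data=data.stack.masks, compression="gzip", compression_opts=1)
        truth = fh.create_group("truth")
        truth.create_dataset("base_map", data=data.truth.base_map)
        truth.create_dataset("ring_map", data=data.truth.ring_map)
        truth.create_dataset("drift", data=data.truth.drift)
        truth.create_dataset("bg_sums", data=data.truth.bg_sums)
        spots = fh.create_group("spots")
        for col in data.truth.spot_table.columns:
            spots.create_dataset(col, data=np.asarray(data.truth.spot_table[col]))
        fh.attrs["geometry"] = json.dumps(geom.to_dict())
        fh.attrs["fingerprint"] = geom.fingerprint()
        fh.attrs["fg_radius_sigma"] = float(sim_params.get("fg_radius_sigma", 3.0))
        fh.attrs["shoebox_margin"] = int(sim_params.get("shoebox_margin", 4))


def load_stack(path) -> tuple[SimulatedData, DetectorGeometry]:
    """Reload a stack; shoeboxes are re-cut from the stored spot table."""
    try:
        with h5py.File(path, "r") as fh:
            geom = DetectorGeometry.from_dict(json.loads(fh.attrs["geometry"]))
            images = fh["images"][()]
            masks = fh["masks"][()].astype(bool)
            truth = GroundTruth(
                base_map=fh["truth/base_map"][()],
                ring_map=fh["truth/ring_map"][()],
                drift=fh["truth/drift"][()],
                spot_table=pd.DataFrame(
                    {col: fh[f"spots/{col}"][()] for col in fh["spots"]}
                ),
                bg_sums=fh["truth/bg_sums"][()],
            )
            fg_sigma = float(fh.attrs.get("fg_radius_sigma", 3.0))
            margin = int(fh.attrs.get("shoebox_margin", 4))
    except (OSError, KeyError) as exc:
        raise DataError(f"cannot load stack from {path}: {exc}") from exc
    # gap mask: pixels masked in every image were never usable (detector gaps)
    gap_mask = masks.any(axis=0)
    shoeboxes = build_spot_shoeboxes(images, gap_mask, geom, truth.spot_table, fg_sigma, margin)
    table = pd.DataFrame(
        [
            {"id": sb.id, "image": sb.image, "s0": sb.bbox[0], "s1": sb.bbox[1],
             "f0": sb.bbox[2], "f1": sb.bbox[3], "d": sb.d}
            for sb in shoeboxes
        ]
    )
    data = SimulatedData(
        stack=ImageStack(images=images, masks=masks), truth=truth, shoeboxes=shoeboxes, table=table
    )
    return data, geom


def stack_fingerprint(path) -> str:
    with h5py.File(path, "r") as fh:
        return str(fh.attrs["fingerprint"])


# ---------------------------------------------------------------------------
# reflection tables
# ---------------------------------------------------------------------------

def save_reflection_table(path, table: pd.DataFrame, geom: DetectorGeometry) -> None:
    path = Path(path)
    table = table.copy()
    table.attrs["fingerprint"] = geom.fingerprint()
    with open(path, "w") as fh:
        fh.write(f"# geometry_fingerprint: {geom.fingerprint()}\n")
        table.to_csv(fh, index=False)


def load_reflection_table(path) -> tuple[pd.DataFrame, str | None]:
    path = Path(path)
    fingerprint = None
    try:
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# geometry_fingerprint:"):
                fingerprint = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            table = pd.read_csv(fh)
    except OSError as exc:
        raise DataError(f"cannot read reflection table {path}: {exc}") from exc
    return table, fingerprint
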