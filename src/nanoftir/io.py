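"""HDF5 container layout, CSV and PNG export.

One HDF5 file per run with groups ``/truth``, ``/band_<id>``, ``/hyper``
and ``/analysis``.  Phase is stored in degrees (float32), frequencies in
cm^-1, lengths in nm; every group carries a ``schema_version`` attribute.
"""

from __future__ import annotations

import contextlib
from typing import Dict, Optional, Union

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .acquisition import AcquisitionMeta, BandCube
from .errors import SchemaError
from .grids import FrequencyGrid
from .scene import SyntheticScene
from .stitching import HyperCube

__all__ = [
    "SCHEMA_VERSION",
    "write_band_cube",
    "read_band_cube",
    "write_hypercube",
    "read_hypercube",
    "write_scene_truth",
    "read_scene_truth",
    "write_raw",
    "read_raw",
    "export_spectrum_csv",
    "read_spectrum_csv",
    "write_drift_log_csv",
    "export_png",
]

SCHEMA_VERSION = "1.0"


@contextlib.contextmanager
def _open(path_or_group, mode: str):
    if isinstance(path_or_group, (h5py.File, h5py.Group)):
        yield path_or_group
    else:
        with h5py.File(path_or_group, mode) as handle:
            yield handle


def _stamp(group: h5py.Group) -> None:
    group.attrs["schema_version"] = SCHEMA_VERSION
    group.attrs["phase_units"] = "degree"
    group.attrs["frequency_units"] = "cm^-1"
    group.attrs["length_units"] = "nm"


def _check_schema(group: h5py.Group, required: tuple) -> None:
    version = group.attrs.get("schema_version")
    if version is None:
        raise SchemaError(f"group '{group.name}' has no schema_version attribute")
    if str(version).split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(f"unsupported schema version {version!r} in '{group.name}'")
    for name in required:
        if name not in group:
            raise SchemaError(f"file is missing dataset '{group.name}/{name}'")


def write_band_cube(path_or_group, cube: BandCube, name: Optional[str] = None) -> None:
    with _open(path_or_group, "a") as root:
        gname = name or f"band_{cube.band_id}"
        if gname in root:
            del root[gname]
        g = root.create_group(gname)
        _stamp(g)
        g.create_dataset("phase", data=cube.phase.astype(np.float32))
        g.create_dataset("amplitude", data=cube.amplitude.astype(np.float32))
        g.create_dataset("frequency", data=cube.grid.values)
        g.create_dataset("support", data=cube.support.astype(np.uint8))
        if cube.topo_blocks:
            g.create_dataset("topo_blocks", data=np.stack(cube.topo_blocks).astype(np.float32))
        if cube.sampled_labels is not None:
            g.create_dataset("sampled_labels", data=cube.sampled_labels)
        if cube.drift_log:
            g.create_dataset("drift_log", data=np.asarray(cube.drift_log, dtype=float))
        g.attrs["band_id"] = cube.band_id
        g.attrs["center_cm-1"] = cube.center
        g.attrs["bandwidth_cm-1"] = cube.bandwidth
        g.attrs["n"] = cube.meta.demodulation_order
        g.attrs["t_spectrum_s"] = cube.meta.t_spectrum
        g.attrs["tip_frequency_hz"] = cube.meta.tip_frequency


def read_band_cube(path_or_group, band_id: str) -> BandCube:
    with _open(path_or_group, "r") as root:
        gname = f"band_{band_id}"
        if gname not in root:
            raise SchemaError(f"file has no group '{gname}'")
        g = root[gname]
        _check_schema(g, ("phase", "amplitude", "frequency", "support"))
        meta = AcquisitionMeta(
            tip_frequency=float(g.attrs.get("tip_frequency_hz", 250e3)),
            demodulation_order=int(g.attrs.get("n", 3)),
            t_spectrum=float(g.attrs.get("t_spectrum_s", 1.66)),
            band_id=str(g.attrs["band_id"]),
        )
        return BandCube(
            band_id=str(g.attrs["band_id"]),
            grid=FrequencyGrid(g["frequency"][()]),
            amplitude=g["amplitude"][()].astype(float),
            phase=g["phase"][()].astype(float),
            support=g["support"][()].astype(bool),
            center=float(g.attrs["center_cm-1"]),
            bandwidth=float(g.attrs["bandwidth_cm-1"]),
            meta=meta,
            topo_blocks=list(g["topo_blocks"][()]) if "topo_blocks" in g else [],
            drift_log=[tuple(row) for row in g["drift_log"][()]] if "drift_log" in g else [],
            sampled_labels=g["sampled_labels"][()] if "sampled_labels" in g else None,
        )


def write_hypercube(path_or_group, cube: HyperCube, name: str = "hyper") -> None:
    with _open(path_or_group, "a") as root:
        if name in root:
            del root[name]
        g = root.create_group(name)
        _stamp(g)
        ny, nx = cube.shape
        g.create_dataset("phase", data=cube.phase.astype(np.float32))
        g.create_dataset("frequency", data=cube.grid.values)
        g.create_dataset("x", data=np.arange(nx) * cube.pixel_size)
        g.create_dataset("y", data=np.arange(ny) * cube.pixel_size)
        prov = g.create_group("provenance")
        for key, value in cube.provenance.items():
            prov.create_dataset(key, data=np.asarray(value))
        g.attrs["resolution_cm-1"] = cube.grid.resolution
        g.attrs["pixel_size_nm"] = cube.pixel_size


def read_hypercube(path_or_group, name: str = "hyper") -> HyperCube:
    with _open(path_or_group, "r") as root:
        if name not in root:
            raise SchemaError(f"file has no group '{name}'")
        g = root[name]
        _check_schema(g, ("phase", "frequency"))
        provenance: Dict = {}
        if "provenance" in g:
            provenance = {k: g["provenance"][k][()] for k in g["provenance"]}
        return HyperCube(
            grid=FrequencyGrid(g["frequency"][()]),
            phase=g["phase"][()].astype(float),
            pixel_size=float(g.attrs.get("pixel_size_nm", 30.0)),
            provenance=provenance,
        )


def write_scene_truth(path_or_group, scene: SyntheticScene, name: str = "truth") -> None:
    with _open(path_or_group, "a") as root:
        if name in root:
            del root[name]
        g = root.create_group(name)
        _stamp(g)
        g.create_dataset("labels", data=scene.labels)
        g.create_dataset("phase", data=scene.truth_phase.astype(np.float32))
        g.create_dataset("frequency", data=scene.grid.values)
        g.attrs["pixel_size_nm"] = scene.pixel_size
        names = g.create_group("label_names")
        for lab, nm in scene.label_names.items():
            names.attrs[str(lab)] = nm


def read_scene_truth(path_or_group, name: str = "truth") -> dict:
    with _open(path_or_group, "r") as root:
        if name not in root:
            raise SchemaError(f"file has no group '{name}'")
        g = root[name]
        _check_schema(g, ("labels", "phase", "frequency"))
        label_names = {}
        if "label_names" in g:
            label_names = {int(k): str(v) for k, v in g["label_names"].attrs.items()}
        return {
            "labels": g["labels"][()],
            "phase": g["phase"][()].astype(float),
            "grid": FrequencyGrid(g["frequency"][()]),
            "pixel_size": float(g.attrs.get("pixel_size_nm", 30.0)),
            "label_names": label_names,
        }


def write_raw(path_or_group, band_id: str, records: np.ndarray, positions: np.ndarray) -> None:
    with _open(path_or_group, "a") as root:
        g = root.require_group("raw").require_group(f"band_{band_id}")
        _stamp(g)
        for dset in ("interferograms", "positions"):
            if dset in g:
                del g[dset]
        g.create_dataset("interferograms", data=np.asarray(records, dtype=np.float32))
        g.create_dataset("positions", data=np.asarray(positions, dtype=float))


def read_raw(path_or_group, band_id: str) -> tuple:
    with _open(path_or_group, "r") as root:
        gname = f"raw/band_{band_id}"
        if gname not in root:
            raise SchemaError(f"file has no group '{gname}'")
        g = root[gname]
        _check_schema(g, ("interferograms", "positions"))
        return g["interferograms"][()].astype(float), g["positions"][()]


def export_spectrum_csv(path, grid: FrequencyGrid, phase: np.ndarray) -> None:
    """Two-column CSV: wavenumber_cm-1, phase_deg."""
    pd.DataFrame({"wavenumber_cm-1": grid.values, "phase_deg": np.asarray(phase)}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path) -> tuple:
    frame = pd.read_csv(path)
    return (
        FrequencyGrid(frame["wavenumber_cm-1"].to_numpy()),
        frame["phase_deg"].to_numpy(),
    )


def write_drift_log_csv(path, drift_log) -> None:
    pd.DataFrame(drift_log, columns=["block", "dx_px", "dy_px"]).to_csv(path, index=False)


def export_png(path, image: np.ndarray) -> None:
    """8-bit PNG; greyscale for 2-D input, RGB for (ny, nx, 3) in [0, 1]."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        lo, hi = arr.min(), arr.max()
        scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
        Image.fromarray(np.round(scaled * 255).astype(np.uint8), mode="L").save(path)
    elif arr.ndim == 3 and arr.shape[2] == 3:
        Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8), mode="RGB").save(path)
    else:
        raise SchemaError("export_png expects a 2-D map or an (ny, nx, 3) RGB image")
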