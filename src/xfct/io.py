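"""Serialization: sinogram containers, TIFF images, run manifests.

Sinogram sets and transmission scans are stored as compressed ``.npz``
arrays with a JSON sidecar (same stem, ``.json``) carrying geometry,
protocol and seed metadata; images are 32-bit TIFF with a JSON sidecar
(grid, units, iterations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import tifffile

from .forward import AcquisitionProtocol, SinogramSet, TransmissionSinogram
from .geometry import SystemGeometry, VoxelGrid
from .physics import EnergyBin

__all__ = [
    "save_sinograms",
    "load_sinograms",
    "save_transmission",
    "load_transmission",
    "save_image",
    "load_image",
    "sha256_file",
    "RunManifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_sinograms(path: str | Path, s: SinogramSet) -> Path:
    path = Path(path)
    arrays = {"counts": s.counts}
    if s.fluorescence_expectation is not None:
        arrays["fluorescence_expectation"] = s.fluorescence_expectation
    if s.scatter_expectation is not None:
        arrays["scatter_expectation"] = s.scatter_expectation
    np.savez_compressed(path, **arrays)
    meta = {
        "geometry": dataclasses.asdict(s.geometry),
        "protocol": {
            **{k: v for k, v in dataclasses.asdict(s.protocol).items() if k != "bins"},
            "bins": [[b.e_min, b.e_max, b.label] for b in s.protocol.bins],
        },
        "seed": s.seed,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_sinograms(path: str | Path) -> SinogramSet:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    bins = tuple(EnergyBin(*b) for b in meta["protocol"].pop("bins"))
    protocol = AcquisitionProtocol(bins=bins, **meta["protocol"])
    geom = SystemGeometry(**{
        k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["geometry"].items()
    })
    with np.load(path) as z:
        return SinogramSet(
            counts=z["counts"],
            protocol=protocol,
            geometry=geom,
            fluorescence_expectation=z.get("fluorescence_expectation"),
            scatter_expectation=z.get("scatter_expectation"),
            seed=meta.get("seed"),
        )


def save_transmission(path: str | Path, t: TransmissionSinogram) -> Path:
    path = Path(path)
    arrays = {"optical_depths": t.optical_depths, "angles_deg": t.angles_deg}
    if t.starved_rays is not None:
        arrays["starved_rays"] = t.starved_rays
    np.savez_compressed(path, **arrays)
    meta = {
        "grid": dataclasses.asdict(t.grid),
        "energy_keV": t.energy_keV,
        "photons_per_ray": t.photons_per_ray,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_transmission(path: str | Path) -> TransmissionSinogram:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    g = meta["grid"]
    grid = VoxelGrid(g["n_x"], g["n_y"], g["pixel_size"], tuple(g["origin"]))
    with np.load(path) as z:
        return TransmissionSinogram(
            optical_depths=z["optical_depths"],
            angles_deg=z["angles_deg"],
            grid=grid,
            energy_keV=meta["energy_keV"],
            photons_per_ray=meta.get("photons_per_ray"),
            starved_rays=z.get("starved_rays"),
        )


def save_image(path: str | Path, image: np.ndarray, grid: VoxelGrid, **meta) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    sidecar = {"grid": dataclasses.asdict(grid), **meta}
    _sidecar(path).write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def load_image(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    path = Path(path)
    img = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    g = meta["grid"]
    return img, VoxelGrid(g["n_x"], g["n_y"], g["pixel_size"], tuple(g["origin"]))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Per-run provenance: config, seed, output digests, timing.

    Written atomically (temp file + rename) at the end of a run; identical
    config and seed reproduce identical digests for deterministic stages.
    """

    def __init__(self, config_dump: dict, seed: int, version: str):
        self.data = {
            "package_version": version,
            "seed": seed,
            "config": config_dump,
            "outputs": {},
            "timing_s": {},
            "created": None,
        }
        self._t0 = time.time()
        self._stage_start: float | None = None
        self._stage_name: str | None = None

    def start_stage(self, name: str) -> None:
        self._stage_name = name
        self._stage_start = time.time()

    def end_stage(self) -> None:
        if self._stage_name is not None:
            self.data["timing_s"][self._stage_name] = round(time.time() - self._stage_start, 3)
            self._stage_name = None

    def record(self, label: str, path: str | Path) -> None:
        self.data["outputs"][label] = {"path": str(path), "sha256": sha256_file(path)}

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.data["created"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.data, indent=1, default=str))
        tmp.replace(path)
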