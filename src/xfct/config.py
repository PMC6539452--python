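"""Validated run configuration for the command-line pipeline.

A run is described by one YAML file with blocks for the system geometry,
the reconstruction grid, the acquisition protocol, the incident spectra
(XFCT and transmission CT), the phantom, reconstruction parameters and
metric ROIs.  Unknown keys are rejected so typos fail loudly before any
computation starts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import physics
from .forward import AcquisitionProtocol
from .geometry import SystemGeometry, VoxelGrid
from .phantom import PhantomSpec, calibration_phantom, mouse_slice_phantom

__all__ = ["RunConfig", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Block):
    pinhole_to_center: float = 75.0
    pinhole_to_detector: float = 63.5
    detector_pixels: int = 256
    pixel_width: float = 0.5
    pixel_height: float = 2.0
    aperture_width: float = 0.5
    aperture_height: float = 2.0
    detector_side_angle: float = 90.0

    def build(self) -> SystemGeometry:
        return SystemGeometry(**self.model_dump())


class GridConfig(_Block):
    n_x: int = 128
    n_y: int = 128
    pixel_size: float = 0.5

    def build(self) -> VoxelGrid:
        return VoxelGrid(**self.model_dump())


class TubeSpectrumConfig(_Block):
    kvp: float
    filter_mm_cu: float = 0.0


class SpectrumConfig(_Block):
    """Either {"mono": keV} or {"tube": {"kvp": ..., "filter_mm_cu": ...}}."""

    mono: Optional[float] = None
    tube: Optional[TubeSpectrumConfig] = None

    @model_validator(mode="after")
    def _one_of(self) -> "SpectrumConfig":
        if (self.mono is None) == (self.tube is None):
            raise ValueError("specify exactly one of 'mono' or 'tube'")
        return self

    def build(self) -> physics.IncidentSpectrum:
        if self.mono is not None:
            return physics.IncidentSpectrum.monochromatic(self.mono)
        return physics.IncidentSpectrum.filtered_tube(self.tube.kvp, self.tube.filter_mm_cu)


class ProtocolConfig(_Block):
    n_views: int = 45
    angular_range: float = 360.0
    exposure_per_view: float = 10.0
    source_fluence: float = 2.0e8

    def build(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(**self.model_dump())


class CtConfig(_Block):
    spectrum: SpectrumConfig = Field(
        default_factory=lambda: SpectrumConfig(tube=TubeSpectrumConfig(kvp=65, filter_mm_cu=0.1))
    )
    n_views: int = 180
    photons_per_ray: float = 5.0e4


class InsertionConfig(_Block):
    center: tuple[float, float]
    radius: float
    concentration: float
    profile: Literal["flat", "parabolic"] = "flat"


class PhantomConfig(_Block):
    kind: Literal["calibration", "mouse", "custom"] = "calibration"
    # calibration options
    concentrations: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0)
    background_radius: float = 25.0
    insertion_radius: float = 4.0
    ring_radius: float = 15.0
    # mouse options
    preset: Literal["liver", "kidney", "leg_tumor"] = "liver"
    hotspot_concentration: Optional[float] = None
    # custom options
    background_material: str = "water"
    background_density: float = 1.0
    background_semi_axes: tuple[float, float] = (20.0, 20.0)
    insertions: Sequence[InsertionConfig] = ()

    def build(self, seed: int | None = None) -> PhantomSpec:
        if self.kind == "calibration":
            return calibration_phantom(
                concentrations=tuple(self.concentrations),
                background_radius=self.background_radius,
                insertion_radius=self.insertion_radius,
                ring_radius=self.ring_radius,
            )
        if self.kind == "mouse":
            return mouse_slice_phantom(self.preset, self.hotspot_concentration, seed)
        from .phantom import Insertion

        return PhantomSpec(
            background_material=self.background_material,
            background_density=self.background_density,
            background_semi_axes=tuple(self.background_semi_axes),
            insertions=tuple(
                Insertion(tuple(i.center), i.radius, i.concentration, i.profile)
                for i in self.insertions
            ),
        )


class ReconstructionConfig(_Block):
    n_iter: int = 100
    n_outer: int = 1
    stop_rel_change: Optional[float] = 1e-4
    max_concentration: float = 20.0
    bone_threshold: Optional[float] = None


class MetricsConfig(_Block):
    #: target ROI radius as a fraction of the insertion radius
    roi_radius_fraction: float = 0.7
    #: background sampling ring (radius mm, number of discs, disc radius mm)
    background_ring_radius: float = 7.0
    background_n_rois: int = 6
    background_roi_radius: float = 2.8


class RunConfig(_Block):
    seed: int = 0
    noise: bool = True
    output_dir: str = "runs/demo"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    spectrum: SpectrumConfig = Field(
        default_factory=lambda: SpectrumConfig(tube=TubeSpectrumConfig(kvp=140, filter_mm_cu=0.4))
    )
    ct: CtConfig = Field(default_factory=CtConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    reconstruction: ReconstructionConfig = Field(default_factory=ReconstructionConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)

    def sub_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        stage_ids = {"xfct": 0, "ct": 1}
        ss = np.random.SeedSequence([self.seed, stage_ids[stage]])
        return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
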