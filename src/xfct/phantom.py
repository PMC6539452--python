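"""Synthetic objects for the XFCT phantom study.

Two families of digital phantoms are provided: a PMMA concentration
calibration phantom (a cylinder with six Gd-solution insertions spanning
0-20 mg/mL) and simplified mouse axial slices (a water body with bone and
one or two inhomogeneous Gd hotspots whose peak concentrations follow the
organ uptake levels of the animal study: liver ~7.94, kidney ~2.51, leg
tumor ~7.13 mg/mL).

Rasterization is antialiased (area-weighted edge voxels via supersampling)
and produces a :class:`GroundTruth` holding the Gd concentration map, the
per-material partial-density maps, and attenuation maps at any energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import VoxelGrid
from .physics import GD_MASS_FRACTION_NAGDF4, material_table

__all__ = [
    "Insertion",
    "PhantomSpec",
    "GroundTruth",
    "rasterize",
    "calibration_phantom",
    "mouse_slice_phantom",
    "BONE_DENSITY",
]

#: nominal cortical-bone density used for bone regions [g/cm^3]
BONE_DENSITY = 1.92


@dataclass(frozen=True)
class Insertion:
    """A disc of Gd solution: center (mm), radius (mm), Gd concentration (mg/mL).

    ``profile`` is "flat" (uniform) or "parabolic" (concentration tapers as
    1 - (r/R)^2, peaking at ``concentration`` in the center), the latter used
    for inhomogeneous organ uptake.
    """

    center: tuple[float, float]
    radius: float
    concentration: float
    profile: str = "flat"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("insertion radius must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")
        if self.profile not in ("flat", "parabolic"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of a slice phantom.

    ``background`` is (material name, density g/cm^3, semi-axes (rx, ry) mm);
    a circular background uses rx == ry.  Insertions hold Gd solutions in
    water and must lie inside the background and not overlap each other.
    """

    background_material: str
    background_density: float
    background_semi_axes: tuple[float, float]
    center: tuple[float, float] = (0.0, 0.0)
    insertions: tuple[Insertion, ...] = ()
    bone_regions: tuple[tuple[tuple[float, float], float], ...] = ()  # (center, radius)

    def __post_init__(self) -> None:
        rx, ry = self.background_semi_axes
        if rx <= 0 or ry <= 0 or self.background_density <= 0:
            raise ValueError("invalid background")
        cx, cy = self.center
        for ins in self.insertions:
            dx, dy = ins.center[0] - cx, ins.center[1] - cy
            if (dx / (rx - ins.radius)) ** 2 + (dy / (ry - ins.radius)) ** 2 > 1.0 + 1e-9:
                raise ValueError("insertion extends outside the background")
        for a in range(len(self.insertions)):
            for b in range(a + 1, len(self.insertions)):
                ia, ib = self.insertions[a], self.insertions[b]
                gap = np.hypot(ia.center[0] - ib.center[0], ia.center[1] - ib.center[1])
                if gap < ia.radius + ib.radius:
                    raise ValueError("insertions overlap")


class GroundTruth:
    """Rasterized phantom: concentration, partial densities, attenuation maps."""

    def __init__(self, grid: VoxelGrid, concentration_map: np.ndarray,
                 partial_densities: dict[str, np.ndarray]):
        self.grid = grid
        self.concentration_map = concentration_map
        #: g/cm^3 of each material per voxel; keys are material-table names
        self.partial_densities = partial_densities

    @property
    def density_map(self) -> np.ndarray:
        """Total mass density per voxel (g/cm^3)."""
        return sum(self.partial_densities.values())

    def mass_fractions(self) -> dict[str, np.ndarray]:
        """Per-material mass fractions; zero outside the object."""
        total = self.density_map
        safe = np.where(total > 0, total, 1.0)
        return {m: rho / safe for m, rho in self.partial_densities.items()}

    def mu_map(self, energy_keV: float) -> np.ndarray:
        """Linear attenuation map [1/cm] at one energy."""
        mu = np.zeros(self.grid.shape)
        for name, rho in self.partial_densities.items():
            mu += rho * material_table(name).mu_over_rho(float(energy_keV))
        return mu

    def electron_density_map(self) -> np.ndarray:
        """Water-relative electron-density proxy (mass density in g/cm^3).

        At the 1-2% level the Z/A ratios of water, PMMA and soft tissue
        coincide, so mass density is an adequate Compton-scatter weight.
        """
        return self.density_map


def _supersampled_disc(grid: VoxelGrid, center, radius, profile, n_sub=4):
    """Coverage fraction and mean profile weight per voxel for one disc."""
    ps = grid.pixel_size
    off = (np.arange(n_sub) + 0.5) / n_sub
    xs = grid.origin[0] + np.arange(grid.n_x)[:, None] * ps + off[None, :] * ps
    ys = grid.origin[1] + np.arange(grid.n_y)[:, None] * ps + off[None, :] * ps
    dx = (xs - center[0]).reshape(1, 1, grid.n_x, n_sub)
    dy = (ys - center[1]).reshape(grid.n_y, n_sub, 1, 1)
    r2 = (dx * dx + dy * dy) / radius**2
    inside = r2 <= 1.0
    frac = inside.mean(axis=(1, 3))
    if profile == "flat":
        weight = frac
    else:  # parabolic taper 1 - (r/R)^2
        weight = np.where(inside, 1.0 - r2, 0.0).mean(axis=(1, 3))
    return frac, weight


def _supersampled_ellipse(grid: VoxelGrid, center, semi_axes, n_sub=4):
    ps = grid.pixel_size
    off = (np.arange(n_sub) + 0.5) / n_sub
    xs = grid.origin[0] + np.arange(grid.n_x)[:, None] * ps + off[None, :] * ps
    ys = grid.origin[1] + np.arange(grid.n_y)[:, None] * ps + off[None, :] * ps
    dx = ((xs - center[0]) / semi_axes[0]).reshape(1, 1, grid.n_x, n_sub)
    dy = ((ys - center[1]) / semi_axes[1]).reshape(grid.n_y, n_sub, 1, 1)
    return ((dx * dx + dy * dy) <= 1.0).mean(axis=(1, 3))


def rasterize(spec: PhantomSpec, grid: VoxelGrid, n_sub: int = 4) -> GroundTruth:
    """Rasterize a phantom onto a voxel grid with area-weighted antialiasing.

    Insertions displace the background material and consist of water plus
    dissolved NaGdF4 at the stated Gd concentration (the Gd mass is mapped
    to NaGdF4 through the stoichiometric mass fraction 157.25/257.2).
    """
    rx, ry = spec.background_semi_axes
    half_x = grid.n_x * grid.pixel_size / 2.0
    half_y = grid.n_y * grid.pixel_size / 2.0
    if (abs(spec.center[0]) + rx > half_x + 1e-9) or (abs(spec.center[1]) + ry > half_y + 1e-9):
        raise ValueError("phantom extends outside the voxel grid")

    bg_frac = _supersampled_ellipse(grid, spec.center, spec.background_semi_axes, n_sub)
    conc = np.zeros(grid.shape)
    ins_frac_total = np.zeros(grid.shape)
    for ins in spec.insertions:
        frac, weight = _supersampled_disc(grid, ins.center, ins.radius, ins.profile, n_sub)
        ins_frac_total += frac
        conc += ins.concentration * weight
    bone_frac_total = np.zeros(grid.shape)
    for b_center, b_radius in spec.bone_regions:
        frac, _ = _supersampled_disc(grid, b_center, b_radius, "flat", n_sub)
        bone_frac_total += frac

    carved = np.clip(bg_frac - ins_frac_total - bone_frac_total, 0.0, 1.0)
    nagdf4_rho = conc / 1000.0 / GD_MASS_FRACTION_NAGDF4  # mg/mL Gd -> g/cm^3 NaGdF4
    water_rho = ins_frac_total * 1.0  # insertion solvent
    if spec.background_material == "water":
        water_rho = water_rho + carved * spec.background_density
        partial = {"water": water_rho}
    else:
        partial = {
            spec.background_material: carved * spec.background_density,
            "water": water_rho,
        }
    partial["bone_cortical"] = bone_frac_total * BONE_DENSITY
    partial["nagdf4"] = nagdf4_rho
    partial = {k: v for k, v in partial.items() if np.any(v > 0)}
    return GroundTruth(grid, conc, partial)


def calibration_phantom(
    concentrations: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0),
    background_radius: float = 25.0,
    insertion_radius: float = 4.0,
    ring_radius: float = 15.0,
) -> PhantomSpec:
    """Six-insertion PMMA concentration-calibration phantom.

    The default concentrations span 0-20 mg/mL, bracketing the ~20 mg/mL
    stock solution of the imaging study, with insertions evenly spaced on a
    ring.
    """
    ins = tuple(
        Insertion(
            center=(
                ring_radius * np.cos(2 * np.pi * k / len(concentrations)),
                ring_radius * np.sin(2 * np.pi * k / len(concentrations)),
            ),
            radius=insertion_radius,
            concentration=float(c),
        )
        for k, c in enumerate(concentrations)
    )
    return PhantomSpec(
        background_material="pmma",
        background_density=material_table("pmma").density,
        background_semi_axes=(background_radius, background_radius),
        insertions=ins,
    )


_MOUSE_PRESETS = {
    # body semi-axes, hotspot list (center, radius, default peak), bone list
    "liver": {
        "body": (14.0, 11.0),
        "hotspots": [((3.0, 2.0), 6.0, 7.94)],
        "bones": [((0.0, -8.0), 1.5)],
    },
    "kidney": {
        "body": (14.0, 11.0),
        "hotspots": [((-6.5, -1.0), 3.2, 2.51), ((6.5, -1.0), 3.2, 2.51)],
        "bones": [((0.0, -7.5), 1.5)],
    },
    "leg_tumor": {
        "body": (9.0, 9.0),
        "hotspots": [((2.0, 1.0), 4.0, 7.13)],
        "bones": [((-3.5, -3.5), 1.4)],
    },
}


def mouse_slice_phantom(
    preset: str,
    hotspot_concentration: float | None = None,
    seed: int | None = None,
) -> PhantomSpec:
    """Simplified mouse axial slice: water body, bone, tapered Gd hotspots.

    ``preset`` is one of liver, kidney, leg_tumor; the default hotspot peak
    concentrations follow the organ uptake of the animal study.  A seed adds
    sub-millimetre jitter to hotspot and bone placement so repeated slices
    differ slightly.
    """
    if preset not in _MOUSE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_MOUSE_PRESETS)}")
    if hotspot_concentration is not None and hotspot_concentration < 0:
        raise ValueError("hotspot concentration must be nonnegative")
    cfg = _MOUSE_PRESETS[preset]
    rng = np.random.default_rng(seed)
    jitter = (lambda: rng.uniform(-0.8, 0.8, 2)) if seed is not None else (lambda: np.zeros(2))
    hotspots = []
    for (cx, cy), radius, peak in cfg["hotspots"]:
        dx, dy = jitter()
        c = peak if hotspot_concentration is None else hotspot_concentration
        hotspots.append(Insertion((cx + dx, cy + dy), radius, c, profile="parabolic"))
    bones = []
    for (cx, cy), radius in cfg["bones"]:
        dx, dy = jitter()
        bones.append(((cx + dx, cy + dy), radius))
    return PhantomSpec(
        background_material="water",
        background_density=1.0,
        background_semi_axes=cfg["body"],
        insertions=tuple(hotspots),
        bone_regions=tuple(bones),
    )
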