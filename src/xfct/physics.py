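"""Photon-physics primitives for pinhole XFCT imaging.

This module collects the small amount of radiation physics the rest of the
package relies on:

* the Klein-Nishina differential cross-section for Compton scattering,
* photon-counting detector energy bins and relative per-bin scatter weights,
* incident X-ray tube spectra (monoenergetic or analytic filtered
  bremsstrahlung),
* mass-attenuation tables for the materials of the phantom study (water,
  PMMA, cortical bone, gadolinium / NaGdF4) with K-edge aware log-log
  interpolation, and
* the Gd K-fluorescence emission model (K alpha lines, fluorescence yield).

All energies are in keV, lengths in cm unless stated otherwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "R0_CM",
    "ELECTRON_REST_KEV",
    "GD_K_EDGE_KEV",
    "GD_KALPHA1_KEV",
    "GD_KALPHA2_KEV",
    "GD_FLUORESCENCE_YIELD",
    "ScatterConstants",
    "EnergyBin",
    "default_energy_bins",
    "FluorescenceLineSet",
    "gd_fluorescence_lines",
    "IncidentSpectrum",
    "MaterialTable",
    "material_table",
    "klein_nishina",
    "bin_scatter_weight",
    "attenuation_coefficient",
    "xrf_yield_factor",
]

#: classical electron radius [cm]
R0_CM = 2.8179403262e-13
#: electron rest energy m0 c^2 [keV]
ELECTRON_REST_KEV = 511.0

#: Gd K absorption edge [keV]
GD_K_EDGE_KEV = 50.2
#: Gd K alpha emission lines [keV]
GD_KALPHA1_KEV = 42.98
GD_KALPHA2_KEV = 42.28
#: K-shell fluorescence yield of Gd (literature value; the absolute emission
#: scale is removed by concentration calibration downstream, so moderate
#: uncertainty here does not propagate to calibrated images).
GD_FLUORESCENCE_YIELD = 0.93

#: Ka1:Ka2 relative intensities (statistical 2:1 weighting of the doublet).
_GD_KALPHA_REL = (0.667, 0.333)


@dataclass(frozen=True)
class ScatterConstants:
    """Physical constants entering the Klein-Nishina cross-section."""

    r0_cm: float = R0_CM
    m0c2_keV: float = ELECTRON_REST_KEV

    def __post_init__(self) -> None:
        if self.r0_cm <= 0 or self.m0c2_keV <= 0:
            raise ValueError("physical constants must be positive")


@dataclass(frozen=True)
class EnergyBin:
    """A counting window [e_min, e_max) of a photon-counting detector, keV."""

    e_min: float
    e_max: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.e_min < self.e_max):
            raise ValueError(f"empty energy bin: [{self.e_min}, {self.e_max}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.e_min + self.e_max)

    def contains(self, energy: float) -> bool:
        return self.e_min <= energy < self.e_max


def default_energy_bins() -> tuple[EnergyBin, EnergyBin, EnergyBin]:
    """The three contiguous acquisition bins; Gd K alpha falls in the middle one."""
    return (
        EnergyBin(33.0, 39.0, "33-39 keV"),
        EnergyBin(39.0, 45.0, "39-45 keV"),
        EnergyBin(45.0, 51.0, "45-51 keV"),
    )


@dataclass(frozen=True)
class FluorescenceLineSet:
    """K-fluorescence emission model of a high-Z element.

    ``lines`` holds (energy keV, relative intensity) pairs; intensities sum
    to 1 and every line lies below the K edge.
    """

    k_edge_keV: float
    lines: tuple[tuple[float, float], ...]
    fluorescence_yield: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fluorescence_yield <= 1.0):
            raise ValueError("fluorescence yield must be in (0, 1]")
        total = sum(w for _, w in self.lines)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("relative line intensities must sum to 1")
        for e, _ in self.lines:
            if e >= self.k_edge_keV:
                raise ValueError("fluorescence line above the K edge")


def gd_fluorescence_lines(fluorescence_yield: float = GD_FLUORESCENCE_YIELD) -> FluorescenceLineSet:
    """Gd K alpha doublet (42.98 / 42.28 keV) below the 50.2 keV K edge."""
    return FluorescenceLineSet(
        k_edge_keV=GD_K_EDGE_KEV,
        lines=(
            (GD_KALPHA1_KEV, _GD_KALPHA_REL[0]),
            (GD_KALPHA2_KEV, _GD_KALPHA_REL[1]),
        ),
        fluorescence_yield=fluorescence_yield,
    )


# ---------------------------------------------------------------------------
# incident spectra
# ---------------------------------------------------------------------------


class IncidentSpectrum:
    """Relative photon fluence per keV on an increasing energy grid.

    A single-point grid is interpreted as a monoenergetic (delta) line with
    the given integrated fluence.
    """

    def __init__(self, energies: np.ndarray, fluence: np.ndarray, description: str = ""):
        energies = np.asarray(energies, dtype=float)
        fluence = np.asarray(fluence, dtype=float)
        if energies.ndim != 1 or energies.size == 0:
            raise ValueError("spectrum requires a non-empty 1-D energy grid")
        if energies.size != fluence.size:
            raise ValueError("energies and fluence must have equal length")
        if energies.size > 1 and np.any(np.diff(energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(fluence < 0) or not np.all(np.isfinite(fluence)):
            raise ValueError("fluence must be finite and nonnegative")
        if np.all(fluence == 0):
            raise ValueError("spectrum has no photons")
        self.energies = energies
        self.fluence = fluence
        self.description = description

    @property
    def is_delta(self) -> bool:
        return self.energies.size == 1

    @classmethod
    def monochromatic(cls, energy_keV: float, fluence: float = 1.0) -> "IncidentSpectrum":
        if energy_keV <= 0:
            raise ValueError("photon energy must be positive")
        return cls(np.array([energy_keV]), np.array([fluence]), f"mono {energy_keV} keV")

    @classmethod
    def filtered_tube(
        cls,
        kvp: float,
        filter_mm_cu: float = 0.0,
        e_min_keV: float = 20.0,
        de_keV: float = 0.5,
    ) -> "IncidentSpectrum":
        """Analytic tube spectrum: Kramers bremsstrahlung times Cu filtration.

        The unfiltered shape is I(E) proportional to (kVp - E)/E; a copper
        filter of the given thickness applies Beer-Lambert transmission using
        the embedded Cu attenuation table.  Characteristic tungsten lines are
        not modelled.
        """
        if kvp <= e_min_keV:
            raise ValueError("tube voltage below the spectrum floor")
        energies = np.arange(e_min_keV, kvp, de_keV)
        fluence = (kvp - energies) / energies
        if filter_mm_cu > 0:
            cu = material_table("copper")
            mu = cu.mu_over_rho(energies) * cu.density  # 1/cm
            fluence = fluence * np.exp(-mu * filter_mm_cu / 10.0)
        return cls(energies, fluence, f"tube {kvp:g} kVp + {filter_mm_cu:g} mm Cu")

    # -- summaries ----------------------------------------------------------

    def total_fluence(self, e_min: float = -np.inf, e_max: float = np.inf) -> float:
        """Integrated fluence over [e_min, e_max] (sum for delta spectra)."""
        if self.is_delta:
            e = self.energies[0]
            return float(self.fluence[0]) if e_min <= e <= e_max else 0.0
        m = (self.energies >= e_min) & (self.energies <= e_max)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.fluence[m], self.energies[m]))

    def mean_energy(self, e_min: float = -np.inf, e_max: float = np.inf) -> float:
        """Fluence-weighted mean energy over [e_min, e_max]."""
        if self.is_delta:
            return float(self.energies[0])
        m = (self.energies >= e_min) & (self.energies <= e_max)
        if m.sum() < 2:
            raise ValueError("no spectral support in the requested window")
        e, f = self.energies[m], self.fluence[m]
        return float(np.trapezoid(e * f, e) / np.trapezoid(f, e))

    def fraction_above(self, energy: float) -> float:
        total = self.total_fluence()
        return self.total_fluence(e_min=energy) / total if total > 0 else 0.0


# ---------------------------------------------------------------------------
# mass-attenuation tables
# ---------------------------------------------------------------------------


class MaterialTable:
    """Tabulated mass attenuation mu/rho [cm^2/g] with K-edge handling.

    Interpolation is linear in log-log coordinates within each smooth
    segment.  An absorption edge (an upward jump between two nearly equal
    energies) splits the table into segments that are never interpolated
    across.
    """

    def __init__(
        self,
        material: str,
        energies: np.ndarray,
        mass_attenuation: np.ndarray,
        density: float,
        photoelectric: np.ndarray | None = None,
    ):
        energies = np.asarray(energies, dtype=float)
        mass_attenuation = np.asarray(mass_attenuation, dtype=float)
        if np.any(np.diff(energies) <= 0):
            raise ValueError("table energies must be strictly increasing")
        if np.any(mass_attenuation <= 0) or density <= 0:
            raise ValueError("attenuation coefficients and density must be positive")
        self.material = material
        self.energies = energies
        self.mass_attenuation = mass_attenuation
        self.density = density
        self.photoelectric = None if photoelectric is None else np.asarray(photoelectric, float)
        # an upward jump marks an absorption edge; split segments there
        self._breaks = [0, *np.nonzero(np.diff(mass_attenuation) > 0)[0] + 1, energies.size]

    @property
    def e_min(self) -> float:
        return float(self.energies[0])

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])

    def _interp_column(self, column: np.ndarray, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.e_min - 1e-9) or np.any(e > self.e_max + 1e-9):
            raise ValueError(
                f"energy outside the {self.material} table range "
                f"[{self.e_min}, {self.e_max}] keV"
            )
        out = np.empty(e.shape, dtype=float)
        loge = np.log(e)
        for lo, hi in zip(self._breaks[:-1], self._breaks[1:]):
            seg_lo = self.energies[lo] if lo > 0 else -np.inf
            seg_hi = self.energies[hi] if hi < self.energies.size else np.inf
            m = (e >= seg_lo) & (e < seg_hi)
            if not np.any(m):
                continue
            out[m] = np.exp(
                np.interp(loge[m], np.log(self.energies[lo:hi]), np.log(column[lo:hi]))
            )
        return out

    def mu_over_rho(self, energy) -> np.ndarray:
        """Mass attenuation mu/rho [cm^2/g] at the given energy/energies."""
        out = self._interp_column(self.mass_attenuation, energy)
        return out if np.ndim(energy) else float(out)

    def photoelectric_mu_over_rho(self, energy) -> np.ndarray:
        if self.photoelectric is None:
            raise ValueError(f"no photoelectric column for {self.material}")
        out = self._interp_column(self.photoelectric, energy)
        return out if np.ndim(energy) else float(out)


_DENSITIES = {
    "water": 1.000,
    "pmma": 1.190,
    "bone_cortical": 1.920,
    "gadolinium": 7.900,
    "copper": 8.960,
}

_ALIASES = {"bone": "bone_cortical", "gd": "gadolinium"}

#: mass fraction of Gd in NaGdF4 (molar masses 257.2 and 157.25 g/mol)
GD_MASS_FRACTION_NAGDF4 = 157.25 / 257.2
#: crystal density of NaGdF4 [g/cm^3]
NAGDF4_DENSITY = 5.6


def _load_csv(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = resources.files("xfct.data").joinpath(f"{name}.csv")
    rows = []
    with path.open("r") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#") or row[0] == "energy_keV":
                continue
            rows.append([float(x) for x in row])
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2]


@lru_cache(maxsize=None)
def material_table(name: str) -> MaterialTable:
    """Load an embedded material table by name.

    Known names: water, pmma, bone (cortical), gadolinium (elemental),
    copper, nagdf4.  The NaGdF4 table is synthesized as the mass-weighted
    mixture of elemental Gd and a light-element matrix approximated by the
    water table (the Na/F contribution differs from water by far less than
    the Gd term dominates at 20-150 keV).
    """
    key = _ALIASES.get(name.lower(), name.lower())
    if key == "nagdf4":
        gd = material_table("gadolinium")
        water = material_table("water")
        e = gd.energies
        w = GD_MASS_FRACTION_NAGDF4
        mu = w * gd.mass_attenuation + (1 - w) * water.mu_over_rho(e)
        pe = w * gd.photoelectric + (1 - w) * water.photoelectric_mu_over_rho(e)
        return MaterialTable("nagdf4", e, mu, NAGDF4_DENSITY, pe)
    energies, mu, pe = _load_csv(key)
    return MaterialTable(key, energies, mu, _DENSITIES[key], pe)


# ---------------------------------------------------------------------------
# Compton scattering
# ---------------------------------------------------------------------------


def klein_nishina(energy_keV, theta, constants: ScatterConstants = ScatterConstants()):
    """Klein-Nishina cross-section differential in polar angle, d(sigma)/d(theta).

    Parameters
    ----------
    energy_keV
        Incident photon energy E > 0 [keV]; scalar or array.
    theta
        Polar scattering angle in [0, pi] radians; scalar or array
        (broadcast against ``energy_keV``).

    Returns
    -------
    Cross-section per unit polar angle [cm^2/rad], azimuthally integrated
    (hence the 2 pi sin(theta) factor); vanishes at theta = 0 and pi.
    """
    E = np.asarray(energy_keV, dtype=float)
    th = np.asarray(theta, dtype=float)
    if np.any(E <= 0) or not np.all(np.isfinite(E)):
        raise ValueError("photon energy must be positive and finite")
    if np.any(th < 0) or np.any(th > np.pi + 1e-12):
        raise ValueError("scatter angle must lie in [0, pi]")
    alpha = E / constants.m0c2_keV
    ct = np.cos(th)
    one_m_ct = 1.0 - ct
    p = 1.0 / (1.0 + alpha * one_m_ct)  # ratio of scattered to incident energy
    base = (1.0 + ct * ct) / 2.0
    corr = 1.0 + (alpha * alpha * one_m_ct * one_m_ct) / ((1.0 + ct * ct) * (1.0 + alpha * one_m_ct))
    out = 2.0 * np.pi * constants.r0_cm**2 * np.sin(th) * p * p * base * corr
    return out if (np.ndim(energy_keV) or np.ndim(theta)) else float(out)


def bin_scatter_weight(spectrum: IncidentSpectrum, bin: EnergyBin, theta):
    """Relative number of Compton-scattered photons landing in an energy bin.

    Integrates the incident spectrum times the Klein-Nishina angular
    cross-section over the bin, r = integral over [e_min, e_max] of
    I0(E) f_KN(E, theta) dE, by trapezoidal quadrature on the spectrum grid
    (with the bin edges inserted).  Only the per-bin ratios of these weights
    matter to the scatter correction, so the absolute normalization of
    ``spectrum`` is irrelevant there.

    ``theta`` may be an array; the result then has the same shape.
    """
    th = np.asarray(theta, dtype=float)
    if spectrum.is_delta:
        e0 = float(spectrum.energies[0])
        if bin.contains(e0):
            out = spectrum.fluence[0] * klein_nishina(e0, th)
        else:
            out = np.zeros_like(th)
        return out if np.ndim(theta) else float(out)

    e, f = spectrum.energies, spectrum.fluence
    lo = max(bin.e_min, e[0])
    hi = min(bin.e_max, e[-1])
    if lo >= hi:
        return np.zeros_like(th) if np.ndim(theta) else 0.0
    inside = (e > lo) & (e < hi)
    grid = np.concatenate(([lo], e[inside], [hi]))
    flu = np.interp(grid, e, f)
    kn = klein_nishina(grid, th[..., None] if th.ndim else th)  # (..., n_grid)
    out = np.trapezoid(flu * kn, grid, axis=-1)
    return out if np.ndim(theta) else float(out)


# ---------------------------------------------------------------------------
# attenuation and fluorescence emission
# ---------------------------------------------------------------------------


def attenuation_coefficient(
    materials: Sequence[tuple[MaterialTable, float]],
    density: float,
    energy_keV,
    require_normalized: bool = True,
):
    """Linear attenuation mu [1/cm] of a mixture at the given energy.

    mu = density * sum_k w_k (mu/rho)_k(E) over (table, mass fraction)
    pairs.  Interpolation happens inside each table (log-log, never across
    an absorption edge).
    """
    if density < 0:
        raise ValueError("density must be nonnegative")
    weights = np.array([w for _, w in materials], dtype=float)
    if np.any(weights < 0):
        raise ValueError("mass fractions must be nonnegative")
    if require_normalized and abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("mass fractions must sum to 1")
    acc = 0.0
    for table, w in materials:
        if w > 0:
            acc = acc + w * table.mu_over_rho(energy_keV)
    return density * acc


def xrf_yield_factor(
    lines: FluorescenceLineSet,
    bin: EnergyBin,
    photoelectric_mu: float = 1.0,
) -> float:
    """Emission weight of the fluorescence lines captured by one energy bin.

    weight = fluorescence_yield * (sum of relative intensities of lines
    inside the bin) * photoelectric_mu.  With the default Gd lines and the
    39-45 keV bin both K alpha lines are captured, so the weight is the
    fluorescence yield itself (times the optional photoelectric factor that
    carries the per-atom excitation cross-section when an absolute scale is
    wanted).
    """
    frac = sum(w for e, w in lines.lines if bin.contains(e))
    return lines.fluorescence_yield * frac * photoelectric_mu
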