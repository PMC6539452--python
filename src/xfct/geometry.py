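"""System geometry for the pinhole-collimated XFCT scanner.

The scanner is modelled in-plane (2D): the incident beam is a parallel fan
travelling along +x in laboratory coordinates, the rotation stage spins the
object about the world origin, and a linear photon-counting detector sits
behind a rectangular pinhole on one side of the beam (90 degrees by
default).  The detector's 2 mm pixel height and the matching 2 mm aperture
height are collapsed into the per-pixel solid angle; no collimator
penetration is modelled (ideal, infinitely thin pinhole).

Distances are millimetres in world coordinates; attenuation maps are 1/cm,
so optical depths convert lengths mm -> cm internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates

__all__ = [
    "SystemGeometry",
    "VoxelGrid",
    "RayPath",
    "pinhole_response",
    "prf_matrix",
    "scatter_angle",
    "trace_ray",
    "trace_line_integral",
    "sampled_path_integrals",
    "rotate_map_to_lab",
    "fov_diameter",
]


@dataclass(frozen=True)
class SystemGeometry:
    """Distances and detector layout of the pinhole XFCT bench (mm)."""

    pinhole_to_center: float = 75.0
    pinhole_to_detector: float = 63.5
    detector_pixels: int = 256
    pixel_width: float = 0.5
    pixel_height: float = 2.0
    aperture_width: float = 0.5
    aperture_height: float = 2.0
    #: angle of the pinhole axis from the beam (+x) direction, degrees
    detector_side_angle: float = 90.0

    def __post_init__(self) -> None:
        for name in ("pinhole_to_center", "pinhole_to_detector", "pixel_width",
                     "pixel_height", "aperture_width", "aperture_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detector_pixels < 1:
            raise ValueError("detector needs at least one pixel")

    # -- derived vectors ----------------------------------------------------

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from the rotation center towards the pinhole."""
        a = np.deg2rad(self.detector_side_angle)
        return np.array([np.cos(a), np.sin(a)])

    @property
    def lateral(self) -> np.ndarray:
        """Unit vector along the detector line (pixel index direction)."""
        a = np.deg2rad(self.detector_side_angle)
        return np.array([-np.sin(a), np.cos(a)])

    @property
    def pinhole_position(self) -> np.ndarray:
        return self.pinhole_to_center * self.axis

    @property
    def detector_length(self) -> float:
        return self.detector_pixels * self.pixel_width

    def pixel_lateral_centers(self) -> np.ndarray:
        """Signed lateral coordinate of each pixel center on the detector (mm)."""
        return (np.arange(self.detector_pixels) + 0.5 - self.detector_pixels / 2.0) * self.pixel_width

    @property
    def beam_direction(self) -> np.ndarray:
        return np.array([1.0, 0.0])


def fov_diameter(geom: SystemGeometry) -> float:
    """Diameter of the object-plane disk imaged onto the full detector (mm)."""
    return geom.detector_length * geom.pinhole_to_center / geom.pinhole_to_detector


@dataclass(frozen=True)
class VoxelGrid:
    """Square-pixel 2D image grid in world mm.

    Arrays indexed ``[iy, ix]``; the center of voxel (ix, iy) sits at
    ``origin + (index + 0.5) * pixel_size``.  By default the grid is centred
    on the rotation axis.
    """

    n_x: int = 128
    n_y: int = 128
    pixel_size: float = 0.5
    origin: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.n_x < 1 or self.n_y < 1:
            raise ValueError("invalid grid")
        if self.origin is None:
            object.__setattr__(
                self,
                "origin",
                (-self.n_x * self.pixel_size / 2.0, -self.n_y * self.pixel_size / 2.0),
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    @property
    def n_voxels(self) -> int:
        return self.n_x * self.n_y

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (n_y*n_x, 2), row-major."""
        xs = self.origin[0] + (np.arange(self.n_x) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(self.n_y) + 0.5) * self.pixel_size
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def world_to_fractional_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (n, 2) to fractional array indices (iy, ix), (2, n)."""
        p = np.atleast_2d(points)
        ix = (p[:, 0] - self.origin[0]) / self.pixel_size - 0.5
        iy = (p[:, 1] - self.origin[1]) / self.pixel_size - 0.5
        return np.vstack([iy, ix])


@dataclass(frozen=True)
class RayPath:
    """Voxels traversed by a straight segment, with intersection lengths (mm)."""

    start: tuple[float, float]
    end: tuple[float, float]
    indices: np.ndarray  # (n, 2) int, (iy, ix)
    lengths: np.ndarray  # (n,) mm


# ---------------------------------------------------------------------------
# pinhole response
# ---------------------------------------------------------------------------


def _prf_geometry(points: np.ndarray, geom: SystemGeometry):
    """Per-point image position, spot width and total aperture solid angle."""
    p = np.atleast_2d(points)
    s = p @ geom.axis          # axial coordinate towards the pinhole
    x_l = p @ geom.lateral     # lateral coordinate
    L1 = geom.pinhole_to_center - s
    L2 = geom.pinhole_to_detector
    valid = L1 > 1e-9
    L1 = np.where(valid, L1, np.nan)
    mag = L2 / L1
    u_img = -x_l * mag
    spot_width = geom.aperture_width * (1.0 + mag)
    d2 = x_l * x_l + L1 * L1
    # Omega = A cos(chi) / (4 pi d^2), cos(chi) = L1/d -> A L1 / (4 pi d^3)
    omega = geom.aperture_width * geom.aperture_height * L1 / (4.0 * np.pi * d2 ** 1.5)
    omega = np.where(valid, omega, 0.0)
    return u_img, spot_width, omega, valid


def pinhole_response(voxel_center, pixel_index: int, geom: SystemGeometry) -> float:
    """Solid-angle fraction coupling one voxel to one detector pixel.

    Fraction of the unit sphere around the voxel subtended by rays that pass
    through the rectangular aperture and strike pixel ``pixel_index``.  The
    aperture projects the voxel to a uniform spot of width
    ``aperture_width * (1 + L2/L1)`` on the detector; the pixel receives the
    total aperture solid angle times its fractional overlap with that spot.
    """
    u_img, width, omega, valid = _prf_geometry(np.asarray(voxel_center, float), geom)
    if not valid[0]:
        return 0.0
    centers = geom.pixel_lateral_centers()
    lo = max(u_img[0] - width[0] / 2.0, centers[pixel_index] - geom.pixel_width / 2.0)
    hi = min(u_img[0] + width[0] / 2.0, centers[pixel_index] + geom.pixel_width / 2.0)
    frac = max(hi - lo, 0.0) / width[0]
    return float(omega[0] * frac)


def prf_matrix(points: np.ndarray, geom: SystemGeometry) -> sparse.csr_matrix:
    """Sparse pinhole-response matrix, shape (n_points, detector_pixels).

    Vectorized equivalent of :func:`pinhole_response` over many emission
    points; the row sum equals the total aperture solid-angle fraction for
    every point whose spot lies fully on the detector.
    """
    p = np.atleast_2d(points)
    u_img, width, omega, valid = _prf_geometry(p, geom)
    n = p.shape[0]
    pw = geom.pixel_width
    half_n = geom.detector_pixels / 2.0
    lo = u_img - width / 2.0
    hi = u_img + width / 2.0
    with np.errstate(invalid="ignore"):
        k_lo = np.floor(lo / pw + half_n).astype(int)
        k_hi = np.floor((hi - 1e-12) / pw + half_n).astype(int)
    k_lo = np.where(valid, k_lo, 0)
    k_hi = np.where(valid, k_hi, -1)
    max_span = int(np.max(k_hi - k_lo, initial=-1)) + 1
    rows, cols, vals = [], [], []
    for off in range(max_span):
        k = k_lo + off
        m = valid & (k <= k_hi) & (k >= 0) & (k < geom.detector_pixels)
        if not np.any(m):
            continue
        e_lo = (k[m] - half_n) * pw
        overlap = np.minimum(hi[m], e_lo + pw) - np.maximum(lo[m], e_lo)
        rows.append(np.nonzero(m)[0])
        cols.append(k[m])
        vals.append(omega[m] * np.clip(overlap, 0.0, None) / width[m])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, geom.detector_pixels))


def scatter_angle(voxel_center, beam_direction, geom: SystemGeometry):
    """Compton scatter angle: beam direction vs. voxel-to-pinhole direction.

    Accepts a single point or an (n, 2) array; returns radians in [0, pi].
    """
    p = np.atleast_2d(np.asarray(voxel_center, float))
    b = np.asarray(beam_direction, float)
    b = b / np.linalg.norm(b)
    v = geom.pinhole_position - p
    norm = np.linalg.norm(v, axis=1)
    cosang = (v @ b) / np.where(norm > 0, norm, 1.0)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    return ang if np.asarray(voxel_center).ndim == 2 else float(ang[0])


# ---------------------------------------------------------------------------
# ray tracing
# ---------------------------------------------------------------------------


def trace_ray(start, end, grid: VoxelGrid) -> RayPath:
    """Exact incremental (Siddon-style) traversal of a segment through a grid.

    Returns the traversed voxels and intersection lengths; the lengths sum
    to the Euclidean chord length of the segment inside the grid to
    floating-point accuracy.
    """
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    empty = RayPath(tuple(p0), tuple(p1), np.empty((0, 2), int), np.empty(0))
    if length == 0.0:
        return empty

    ox, oy = grid.origin
    ps = grid.pixel_size
    x_max = ox + grid.n_x * ps
    y_max = oy + grid.n_y * ps

    # clip parametric range to the grid box
    a_min, a_max = 0.0, 1.0
    for p, dd, lo, hi in ((p0[0], d[0], ox, x_max), (p0[1], d[1], oy, y_max)):
        if dd == 0.0:
            if not (lo <= p <= hi):
                return empty
        else:
            a0, a1 = (lo - p) / dd, (hi - p) / dd
            a_min = max(a_min, min(a0, a1))
            a_max = min(a_max, max(a0, a1))
    if a_min >= a_max:
        return empty

    # crossing parameters with x- and y-grid lines
    alphas = [np.array([a_min, a_max])]
    for p, dd, o, n in ((p0[0], d[0], ox, grid.n_x), (p0[1], d[1], oy, grid.n_y)):
        if dd != 0.0:
            i = np.arange(n + 1)
            a = (o + i * ps - p) / dd
            alphas.append(a[(a > a_min) & (a < a_max)])
    alpha = np.unique(np.concatenate(alphas))
    mid = 0.5 * (alpha[:-1] + alpha[1:])
    seg_len = np.diff(alpha) * length
    mx = p0[0] + mid * d[0]
    my = p0[1] + mid * d[1]
    ix = np.clip(((mx - ox) / ps).astype(int), 0, grid.n_x - 1)
    iy = np.clip(((my - oy) / ps).astype(int), 0, grid.n_y - 1)
    keep = seg_len > 1e-12 * max(length, 1.0)
    return RayPath(tuple(p0), tuple(p1), np.column_stack([iy, ix])[keep], seg_len[keep])


def trace_line_integral(start, end, mu_map: np.ndarray, grid: VoxelGrid) -> float:
    """Optical depth of a segment through a per-voxel attenuation map.

    ``mu_map`` is in 1/cm on ``grid`` (mm); the result is dimensionless.
    Portions of the segment outside the grid contribute nothing.
    """
    path = trace_ray(start, end, grid)
    if path.indices.size == 0:
        return 0.0
    mu = mu_map[path.indices[:, 0], path.indices[:, 1]]
    return float(np.sum(mu * path.lengths) / 10.0)


def sampled_path_integrals(
    mu_map: np.ndarray,
    grid: VoxelGrid,
    points: np.ndarray,
    target,
    n_samples: int = 224,
) -> np.ndarray:
    """Optical depths from many points to a common target, by midpoint sampling.

    Vectorized companion to :func:`trace_line_integral` used on the emission
    (voxel -> pinhole) legs of the forward model, where one line integral per
    image voxel is needed.  Each segment is sampled at ``n_samples`` midpoints
    with bilinear interpolation; points outside the grid read as zero.
    """
    p = np.atleast_2d(points)
    t = np.asarray(target, float)
    seg = t[None, :] - p
    lengths = np.linalg.norm(seg, axis=1)
    frac = (np.arange(n_samples) + 0.5) / n_samples
    # sample positions: (n_samples, n_points, 2)
    pos = p[None, :, :] + frac[:, None, None] * seg[None, :, :]
    coords = grid.world_to_fractional_index(pos.reshape(-1, 2))
    vals = map_coordinates(mu_map, coords, order=1, mode="constant", cval=0.0)
    vals = vals.reshape(n_samples, p.shape[0])
    return vals.mean(axis=0) * lengths / 10.0


def rotate_map_to_lab(obj_map: np.ndarray, grid: VoxelGrid, angle_deg: float) -> np.ndarray:
    """Resample an object-frame map onto the laboratory grid at one view.

    The rotation stage turns the object by ``angle_deg`` (counterclockwise in
    world coordinates); the value at lab point x is the object map at
    R(-angle) x.  Bilinear interpolation, zero outside the object grid.
    """
    if angle_deg % 360.0 == 0.0:
        return obj_map.copy()
    c = grid.voxel_centers()
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])  # R(-a)
    coords = grid.world_to_fractional_index(c @ rot.T)
    vals = map_coordinates(obj_map, coords, order=1, mode="constant", cval=0.0)
    return vals.reshape(grid.shape)
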