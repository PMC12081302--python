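"""Volumetric data model: grids, rotations, poses, Fourier filters and I/O.

Conventions used throughout the package
---------------------------------------
* ``Volume.data`` is indexed ``[z, y, x]`` (the tomography / TIFF stack order).
* All positions, shifts and vectors handed to functions are in ``(x, y, z)``
  order, in voxel units unless a name says ``_nm``.
* Rotations are intrinsic ZXZ Euler angles in degrees (the de-facto
  subtomogram-averaging convention): ``R = Rz(phi) @ Rx(theta) @ Rz(psi)``,
  acting on ``(x, y, z)`` column vectors.
* The rotation/interpolation center of a volume is ``floor(dim / 2)`` on each
  axis.  Physical lengths are nanometres; the MRC boundary converts to/from Å.
* The electron beam of the (virtual) microscope runs along ``z``; the tilt
  axis of the missing wedge is one of the grid axes (default ``y``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation as _SciRotation

from .errors import ParameterError

__all__ = [
    "Volume",
    "Rotation",
    "Pose",
    "WedgeSpec",
    "make_rotation_grid",
    "make_inplane_grid",
    "apply_missing_wedge",
    "lowpass",
    "transform",
    "bin_volume",
    "read_mrc",
    "write_mrc",
    "read_particle_table",
    "write_particle_table",
    "PARTICLE_TABLE_COLUMNS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3D scalar density grid with a physical voxel size.

    Parameters
    ----------
    data:
        3D array indexed ``[z, y, x]``; values must be finite.
    voxel_size_nm:
        Edge length of one voxel in nanometres (> 0).
    origin_voxel:
        Location of grid index (0, 0, 0) in a parent frame, in voxels,
        ``(x, y, z)`` order.  Purely bookkeeping; defaults to the origin.
    """

    data: np.ndarray
    voxel_size_nm: float = 1.0
    origin_voxel: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError("Volume.data must be 3-dimensional")
        if min(self.data.shape) < 8:
            raise ParameterError("all Volume dimensions must be >= 8")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("Volume.data must be finite")
        if not (np.isfinite(self.voxel_size_nm) and self.voxel_size_nm > 0):
            raise ParameterError("voxel_size_nm must be positive and finite")
        self.origin_voxel = np.asarray(self.origin_voxel, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def center_xyz(self) -> np.ndarray:
        """Grid center ``floor(dim/2)`` in (x, y, z) voxel coordinates."""
        nz, ny, nx = self.data.shape
        return np.array([nx // 2, ny // 2, nz // 2], dtype=float)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size_nm, self.origin_voxel.copy())

    def value_at_xyz(self, pos: Sequence[float]) -> float:
        x, y, z = (int(round(p)) for p in pos)
        return float(self.data[z, y, x])


def _norm_angles(phi: float, theta: float, psi: float) -> tuple[float, float, float]:
    import warnings

    # canonicalise via the matrix so that theta lands in [0, 180]; scipy warns
    # about the (intentional, documented) gimbal degeneracy at theta in {0, 180}
    mat = _SciRotation.from_euler("ZXZ", [phi, theta, psi], degrees=True)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        p, t, s = mat.as_euler("ZXZ", degrees=True)
    return p % 360.0, abs(t) if abs(t) < 1e-12 else t, s % 360.0


@dataclass(frozen=True)
class Rotation:
    """Intrinsic ZXZ Euler rotation in degrees.

    Angles are normalised so that ``phi, psi`` lie in [0, 360) and ``theta``
    in [0, 180].  The rotation matrix acts on (x, y, z) column vectors.
    """

    phi: float
    theta: float
    psi: float

    def __post_init__(self) -> None:
        for a in (self.phi, self.theta, self.psi):
            if not np.isfinite(a):
                raise ParameterError("Euler angles must be finite")
        p, t, s = _norm_angles(self.phi, self.theta, self.psi)
        object.__setattr__(self, "phi", float(p))
        object.__setattr__(self, "theta", float(t))
        object.__setattr__(self, "psi", float(s))

    @classmethod
    def identity(cls) -> "Rotation":
        return cls(0.0, 0.0, 0.0)

    @classmethod
    def about_z(cls, angle_deg: float) -> "Rotation":
        return cls(angle_deg % 360.0, 0.0, 0.0)

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "Rotation":
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Gimbal lock")
            p, t, s = _SciRotation.from_matrix(np.asarray(mat)).as_euler("ZXZ", degrees=True)
        return cls(p, t, s)

    def as_matrix(self) -> np.ndarray:
        return _SciRotation.from_euler(
            "ZXZ", [self.phi, self.theta, self.psi], degrees=True
        ).as_matrix()

    def inverse(self) -> "Rotation":
        return Rotation.from_matrix(self.as_matrix().T)

    def compose(self, other: "Rotation") -> "Rotation":
        """Return the rotation ``self @ other`` (apply ``other`` first)."""
        return Rotation.from_matrix(self.as_matrix() @ other.as_matrix())

    def apply(self, vec: Sequence[float]) -> np.ndarray:
        return self.as_matrix() @ np.asarray(vec, dtype=float)

    def geodesic_deg(self, other: "Rotation") -> float:
        """Geodesic distance on SO(3) in degrees."""
        tr = np.trace(self.as_matrix().T @ other.as_matrix())
        c = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))


@dataclass(frozen=True)
class Pose:
    """Rigid transform: rotate about the grid center, then shift (voxels)."""

    shift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: Rotation = field(default_factory=Rotation.identity)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", np.asarray(self.shift, dtype=float).reshape(3))

    def inverse(self) -> "Pose":
        rinv = self.rotation.inverse()
        return Pose(shift=-rinv.apply(self.shift), rotation=rinv)

    def compose(self, other: "Pose") -> "Pose":
        """Pose equivalent to applying ``other`` first, then ``self``."""
        r = self.rotation.compose(other.rotation)
        s = self.rotation.apply(other.shift) + self.shift
        return Pose(shift=s, rotation=r)

    def apply_point(self, point: Sequence[float], center: Sequence[float] | None = None) -> np.ndarray:
        """Map a point (x, y, z): rotate about ``center`` (default origin), shift."""
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        p = np.asarray(point, dtype=float)
        return self.rotation.apply(p - c) + c + self.shift


@dataclass(frozen=True)
class WedgeSpec:
    """Single-axis tilt range of the acquisition, defining the missing wedge.

    ``tilt_axis`` names the grid axis the stage rotates about: "y" (default)
    or "x".  The beam runs along z; Fourier directions in the plane
    orthogonal to the tilt axis outside [tilt_min_deg, tilt_max_deg] are
    unsampled.
    """

    tilt_min_deg: float = -52.0
    tilt_max_deg: float = 64.0
    tilt_axis: str = "y"

    def __post_init__(self) -> None:
        if not (-90.0 <= self.tilt_min_deg < self.tilt_max_deg <= 90.0):
            raise ParameterError("require -90 <= tilt_min < tilt_max <= 90")
        if self.tilt_axis not in ("x", "y"):
            raise ParameterError("tilt_axis must be 'x' or 'y'")

    @property
    def span_deg(self) -> float:
        return self.tilt_max_deg - self.tilt_min_deg


FULL_WEDGE = WedgeSpec(-90.0 + 1e-9, 90.0)


# ---------------------------------------------------------------------------
# rotation grids
# ---------------------------------------------------------------------------


def make_rotation_grid(increment_deg: float) -> list[Rotation]:
    """Deterministic ZXZ Euler grid: phi, psi over [0, 360), theta over [0, 180].

    The grid has ``ceil(360/inc)**2 * (floor(180/inc) + 1)`` nodes, returned in
    lexicographic (phi, theta, psi) order.  Orientations duplicated at
    theta in {0, 180} (where phi and psi degenerate) are intentionally kept so
    the node count is predictable.
    """
    if not (np.isfinite(increment_deg) and 0 < increment_deg <= 360):
        raise ParameterError("increment_deg must be in (0, 360]")
    phis = np.arange(0.0, 360.0 - 1e-9, increment_deg)
    thetas = np.arange(0.0, 180.0 + 1e-9, increment_deg)
    psis = phis
    grid = []
    for p in phis:
        for t in thetas:
            for s in psis:
                grid.append(Rotation(p, t, s))
    return grid


def make_inplane_grid(increment_deg: float) -> list[Rotation]:
    """Rotations about the z (pore) axis only, stepped by ``increment_deg``."""
    if not (np.isfinite(increment_deg) and 0 < increment_deg <= 360):
        raise ParameterError("increment_deg must be in (0, 360]")
    return [Rotation.about_z(a) for a in np.arange(0.0, 360.0 - 1e-9, increment_deg)]


# ---------------------------------------------------------------------------
# Fourier filters
# ---------------------------------------------------------------------------


def _wedge_mask_rfft(shape: tuple[int, int, int], wedge: WedgeSpec, soft_edge_deg: float) -> np.ndarray:
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.rfftfreq(nx)[None, None, :]
    # in-plane component orthogonal to the tilt axis; beam along z
    kp = kx if wedge.tilt_axis == "y" else ky
    kb = kz
    ang = np.degrees(np.arctan2(kb, kp + np.zeros_like(kb)))
    # fold line directions into (-90, 90]
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    if soft_edge_deg <= 0:
        mask = ((ang >= wedge.tilt_min_deg) & (ang <= wedge.tilt_max_deg)).astype(np.float32)
    else:
        lo = np.clip((ang - (wedge.tilt_min_deg - soft_edge_deg)) / soft_edge_deg, 0.0, 1.0)
        hi = np.clip(((wedge.tilt_max_deg + soft_edge_deg) - ang) / soft_edge_deg, 0.0, 1.0)
        mask = (0.5 - 0.5 * np.cos(np.pi * lo)) * (0.5 - 0.5 * np.cos(np.pi * hi))
        mask = mask.astype(np.float32)
    mask = np.broadcast_to(mask, (nz, ny, nx // 2 + 1)).copy()
    mask[0, 0, 0] = 1.0  # DC is always measured
    return mask


def apply_missing_wedge(vol: Volume, wedge: WedgeSpec, soft_edge_deg: float = 0.0) -> Volume:
    """Zero Fourier directions outside the sampled tilt range.

    A hard binary mask by default (idempotent and test-deterministic);
    ``soft_edge_deg`` > 0 applies a cosine taper of that angular width.
    """
    f = sfft.rfftn(vol.data)
    f *= _wedge_mask_rfft(vol.shape, wedge, soft_edge_deg)
    out = sfft.irfftn(f, s=vol.shape).astype(vol.data.dtype, copy=False)
    return Volume(out, vol.voxel_size_nm, vol.origin_voxel.copy())


def wedge_zero_fraction(shape: tuple[int, int, int], wedge: WedgeSpec,
                        bin_deg: float = 1.0) -> float:
    """Fraction of in-plane Fourier *directions* zeroed by the wedge mask.

    Coefficients in the plane orthogonal to the tilt axis are binned by their
    direction angle (1° bins by default); a direction counts as zeroed when
    every coefficient in its bin is zeroed.  For a hard mask this equals
    ``(180 - tilt span) / 180`` up to bin quantisation.
    """
    mask = _wedge_mask_rfft(shape, wedge, 0.0)
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.rfftfreq(nx)[None, None, :]
    kp = kx if wedge.tilt_axis == "y" else ky
    kb = kz
    ang = np.degrees(np.arctan2(kb, kp + np.zeros_like(kb)))
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    ang = np.broadcast_to(ang, mask.shape).ravel()
    radial = np.broadcast_to(np.sqrt(kb**2 + kp**2), mask.shape).ravel()
    keep = radial > 1e-9  # direction undefined on the tilt-axis line
    bins = np.floor((ang[keep] + 90.0) / bin_deg).astype(int)
    nbins = int(np.ceil(180.0 / bin_deg))
    bins = np.clip(bins, 0, nbins - 1)
    kept_count = np.bincount(bins, weights=(mask.ravel()[keep] > 0), minlength=nbins)
    tot_count = np.bincount(bins, minlength=nbins)
    present = tot_count > 0
    # majority rule so that bins straddling the wedge edge split evenly
    zeroed = present & (kept_count < 0.5 * tot_count)
    return float(zeroed.sum() / present.sum())


def lowpass(vol: Volume, resolution_nm: float, soft_width: float = 0.0) -> Volume:
    """Radial low-pass at the given resolution.

    With ``soft_width == 0`` (default) the filter is a binary cutoff at
    spatial frequency ``1/resolution_nm`` and hence an exact projection
    (applying it twice equals once).  ``soft_width`` > 0 replaces the edge by
    a raised-cosine roll-off spanning ``cutoff * (1 ± soft_width)``; the soft
    variant trades idempotence for reduced ringing.  The DC term is always
    preserved, so the volume mean is exact.
    """
    if not np.isfinite(resolution_nm) or resolution_nm < 2.0 * vol.voxel_size_nm:
        raise ParameterError("resolution_nm must be >= 2 * voxel_size_nm (Nyquist)")
    nz, ny, nx = vol.shape
    kz = np.fft.fftfreq(nz, d=vol.voxel_size_nm)[:, None, None]
    ky = np.fft.fftfreq(ny, d=vol.voxel_size_nm)[None, :, None]
    kx = np.fft.rfftfreq(nx, d=vol.voxel_size_nm)[None, None, :]
    k = np.sqrt(kz**2 + ky**2 + kx**2)
    kc = 1.0 / resolution_nm
    if soft_width <= 0:
        h = (k <= kc).astype(np.float32)
    else:
        k1 = kc * (1.0 - soft_width)
        k2 = kc * (1.0 + soft_width)
        ramp = np.clip((k2 - k) / (k2 - k1), 0.0, 1.0)
        h = (0.5 - 0.5 * np.cos(np.pi * ramp)).astype(np.float32)
    h.reshape(-1)[0] = 1.0
    f = sfft.rfftn(vol.data)
    f *= h
    out = sfft.irfftn(f, s=vol.shape).astype(vol.data.dtype, copy=False)
    return Volume(out, vol.voxel_size_nm, vol.origin_voxel.copy())


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def transform(vol: Volume, pose: Pose, order: int = 1, fill: float | None = None) -> Volume:
    """Resample a volume under a pose: rotate about the grid center, then shift.

    Trilinear interpolation by default; samples falling outside the grid are
    filled with the volume mean (so matching scores do not reward empty
    borders) unless ``fill`` is given.
    """
    if pose.rotation == Rotation.identity() and np.allclose(pose.shift, 0.0):
        return vol.copy()
    rinv = pose.rotation.inverse().as_matrix()
    c = vol.center_xyz
    # index space (z,y,x) <-> world space (x,y,z): reverse both axes of R
    m_idx = rinv[::-1, ::-1]
    offset = (c - rinv @ (c + pose.shift))[::-1]
    cval = float(vol.data.mean()) if fill is None else float(fill)
    out = affine_transform(
        vol.data, m_idx, offset=offset, order=order, mode="constant", cval=cval,
        prefilter=(order > 1),
    )
    return Volume(out.astype(vol.data.dtype, copy=False), vol.voxel_size_nm, vol.origin_voxel.copy())


def bin_volume(vol: Volume, factor: int) -> Volume:
    """Block-average binning by an integer factor (dimensions must divide)."""
    if factor < 1 or any(s % factor for s in vol.shape):
        raise ParameterError("binning factor must divide every dimension")
    nz, ny, nx = (s // factor for s in vol.shape)
    d = vol.data.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    return Volume(d.astype(vol.data.dtype, copy=False), vol.voxel_size_nm * factor,
                  vol.origin_voxel / factor)


# ---------------------------------------------------------------------------
# I/O: MRC2014 volumes and particle tables
# ---------------------------------------------------------------------------


def write_mrc(vol: Volume, path: str | Path) -> None:
    """Write a volume as MRC2014 (voxel size recorded in the header, in Å)."""
    import gemmi

    data = np.ascontiguousarray(vol.data.astype(np.float32))
    grid = gemmi.FloatGrid(data)
    a = vol.voxel_size_nm * 10.0  # nm -> Å
    nz, ny, nx = data.shape
    grid.unit_cell = gemmi.UnitCell(nz * a, ny * a, nx * a, 90, 90, 90)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> Volume:
    """Read an MRC/CCP4 map; voxel size is taken from the header (Å -> nm)."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    voxel_nm = float(np.mean(m.grid.spacing)) / 10.0
    return Volume(data, voxel_nm)


PARTICLE_TABLE_COLUMNS = ["id", "x", "y", "z", "phi", "theta", "psi", "score", "class"]


def write_particle_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a particle/pose table as CSV with the canonical column set."""
    missing = [c for c in PARTICLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"particle table missing columns: {missing}")
    extra = [c for c in df.columns if c not in PARTICLE_TABLE_COLUMNS]
    df[PARTICLE_TABLE_COLUMNS + extra].to_csv(path, index=False)


def read_particle_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARTICLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"particle table missing columns: {missing}")
    return df


def poses_from_table(df: pd.DataFrame) -> list[Pose]:
    return [
        Pose(shift=np.array([r.x, r.y, r.z]), rotation=Rotation(r.phi, r.theta, r.psi))
        for r in df.itertuples()
    ]
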