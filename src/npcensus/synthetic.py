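"""Ground-truth simulators: NPC phantoms, rendered subvolumes and nucleus stacks.

The generator emulates the inputs of the tomography pipeline: each nuclear
pore complex (NPC) is three coaxial rings — cytoplasmic (CR), inner (IR) and
nuclear (NR) — of protomer densities with n-fold symmetry (n in {7, 8, 9} by
default), embedded in a double-membrane sheet with a circular opening, imaged
with a single-axis missing wedge and additive Gaussian noise at a requested
SNR.  Every stochastic choice derives from a single integer seed, and every
rendered subvolume is paired with a ground-truth manifest row.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import GeometryError, ParameterError
from .volumes import Pose, Rotation, Volume, WedgeSpec, apply_missing_wedge, write_mrc

RING_IDS = ("CR", "IR", "NR")

__all__ = [
    "RingSpec",
    "MembraneSpec",
    "NPCPhantom",
    "DesignGroup",
    "RenderResult",
    "build_protomer_template",
    "build_phantom",
    "render_npc",
    "render_npc_volume",
    "simulate_dataset",
    "NucleusSpec",
    "NucleusScene",
    "make_nucleus_scene",
    "render_nucleus_stack",
]


# ---------------------------------------------------------------------------
# phantom parameterisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingSpec:
    """One NPC ring: radius at protomer centers and axial offset from the
    pore midplane (CR positive/cytoplasmic, NR negative/nuclear, IR ~ 0)."""

    ring_id: str
    radius_nm: float
    z_offset_nm: float

    def __post_init__(self) -> None:
        if self.ring_id not in RING_IDS:
            raise ParameterError(f"ring_id must be one of {RING_IDS}")
        if not self.radius_nm > 0:
            raise ParameterError("radius_nm must be positive")
        if not abs(self.z_offset_nm) < 60:
            raise ParameterError("|z_offset_nm| must be < 60")


@dataclass(frozen=True)
class MembraneSpec:
    """Nuclear-envelope model: two parallel Gaussian-profile sheets separated
    by ``separation_nm`` (luminal spacing, center-to-center), fused at the
    pore rim into a half-toroid with apex at ``opening_radius_nm``."""

    separation_nm: float = 40.0
    sheet_sigma_nm: float = 3.0
    opening_radius_nm: float = 50.0
    # protomer blobs peak near 1; the lower membrane amplitude keeps the
    # sheets clearly visible while letting individual protomers dominate the
    # local matching statistics (the membrane-adjacent CR/NR protomers
    # overlap the sheets)
    amplitude: float = 0.15


@dataclass
class NPCPhantom:
    """Parametric truth for one NPC."""

    symmetry_n: int
    rings: dict[str, RingSpec]
    presence: dict[str, np.ndarray]
    pose: Pose
    diameter_nm: float
    cr_detach_nm: float
    membrane: MembraneSpec

    def __post_init__(self) -> None:
        for ring in RING_IDS:
            if ring not in self.rings or ring not in self.presence:
                raise ParameterError(f"phantom must define ring {ring}")
            self.presence[ring] = np.asarray(self.presence[ring], dtype=bool)
            if self.presence[ring].shape != (self.symmetry_n,):
                raise ParameterError("presence vector length must equal symmetry_n")
        if abs(self.diameter_nm - 2.0 * self.rings["IR"].radius_nm) > 1e-9:
            raise ParameterError("diameter_nm must equal 2 * IR radius")

    def present_counts(self) -> dict[str, int]:
        return {r: int(self.presence[r].sum()) for r in RING_IDS}

    def slot_angles_deg(self) -> np.ndarray:
        return np.arange(self.symmetry_n) * (360.0 / self.symmetry_n)

    def slot_position_xyz_nm(self, ring: str, slot: int) -> np.ndarray:
        """Slot center in the pore frame (x, y, z), nm."""
        spec = self.rings[ring]
        a = np.radians(self.slot_angles_deg()[slot])
        z = spec.z_offset_nm + (self.cr_detach_nm if ring == "CR" else 0.0)
        return np.array([spec.radius_nm * np.cos(a), spec.radius_nm * np.sin(a), z])


def build_phantom(
    symmetry_n: int,
    diameter_nm: float,
    missing: Mapping[str, Sequence[int]] | None = None,
    cr_detach_nm: float = 0.0,
    pose: Pose | None = None,
    membrane: MembraneSpec | None = None,
    cr_radius_offset_nm: float = -4.0,
    cr_z_nm: float = 16.0,
    nr_radius_offset_nm: float = -2.0,
    nr_z_nm: float = -16.0,
) -> NPCPhantom:
    """Assemble an NPC phantom.

    Ring radii scale with the IR diameter: by default the CR sits 4 nm inside
    the IR radius at z = +16 nm and the NR 2 nm inside at z = −16 nm.
    ``missing`` maps ring ids to slot index sets left unoccupied.
    """
    if symmetry_n < 3:
        raise ParameterError("symmetry_n must be >= 3")
    if not diameter_nm > 0:
        raise ParameterError("diameter_nm must be positive")
    r_ir = diameter_nm / 2.0
    rings = {
        "CR": RingSpec("CR", r_ir + cr_radius_offset_nm, cr_z_nm),
        "IR": RingSpec("IR", r_ir, 0.0),
        "NR": RingSpec("NR", r_ir + nr_radius_offset_nm, nr_z_nm),
    }
    presence = {r: np.ones(symmetry_n, dtype=bool) for r in RING_IDS}
    missing = missing or {}
    for ring, slots in missing.items():
        if ring not in RING_IDS:
            raise ParameterError(f"unknown ring id {ring!r}")
        for s in slots:
            if not (0 <= int(s) < symmetry_n):
                raise ParameterError(f"missing slot {s} out of range for n={symmetry_n}")
            presence[ring][int(s)] = False
    if membrane is None:
        membrane = MembraneSpec(opening_radius_nm=diameter_nm / 2.0)
    return NPCPhantom(
        symmetry_n=symmetry_n,
        rings=rings,
        presence=presence,
        pose=pose if pose is not None else Pose(),
        diameter_nm=diameter_nm,
        cr_detach_nm=cr_detach_nm,
        membrane=membrane,
    )


# ---------------------------------------------------------------------------
# protomer templates
# ---------------------------------------------------------------------------

# Per-ring multi-blob layouts in the template local frame (x radial outward,
# z along the pore axis): (dx, dy, dz, sigma, amplitude) in nm.  Blobs sit
# 8-9.5 nm off-center in well-spread directions with ~1.3-1.5 nm widths: a
# 10° rotation about ANY axis measurably decorrelates the density
# (orientation identifiability margin >= 0.1 on the 10° search grid), the
# three arrangements are mutually distinct (best-alignment cross-correlation
# <= ~0.45), and the density stays smooth at the voxel scale so matched
# peaks span several voxels.
_BLOBS: dict[str, tuple[tuple[float, float, float, float, float], ...]] = {
    "CR": (
        (-1.78, -1.71, 8.84, 1.30, 0.85),
        (-5.96, 5.52, -4.63, 1.44, 0.88),
        (6.68, -4.12, -4.79, 1.31, 0.75),
        (-6.12, -6.54, 0.35, 1.34, 0.78),
        (7.69, 1.78, 4.08, 1.32, 0.70),
        (4.24, 4.60, -6.14, 1.39, 0.70),
    ),
    "IR": (
        (0.85, 4.64, -7.92, 1.32, 0.79),
        (1.75, -8.29, -0.38, 1.33, 0.68),
        (-1.76, 3.17, 7.63, 1.46, 0.76),
        (-6.13, -4.43, -5.66, 1.36, 1.00),
        (4.19, 7.78, 0.58, 1.36, 0.68),
        (6.57, -3.65, 4.21, 1.35, 0.99),
    ),
    "NR": (
        (4.78, 7.46, -0.06, 1.32, 0.86),
        (-7.48, 0.66, 5.04, 1.32, 0.99),
        (4.71, -7.87, -2.30, 1.38, 0.77),
        (3.54, 1.97, 8.00, 1.37, 0.83),
        (3.66, -0.65, -8.69, 1.46, 0.87),
        (-7.30, -3.38, -2.46, 1.31, 0.87),
    ),
}


@functools.lru_cache(maxsize=32)
def build_protomer_template(ring_id: str, voxel_size_nm: float = 2.0) -> tuple[Volume, Volume]:
    """Deterministic multi-blob protomer density plus its ellipsoidal mask.

    Returns ``(template, mask)`` volumes of identical shape.  The mask is a
    binary ellipsoid sized to contain at least 99% of the template mass.
    """
    if ring_id not in RING_IDS:
        raise ParameterError(f"ring_id must be one of {RING_IDS}")
    if not 0 < voxel_size_nm <= 4.0:
        raise ParameterError("voxel size too coarse to resolve protomer blobs (need <= 4 nm)")
    blobs = _BLOBS[ring_id]
    side = max(8, int(np.ceil(40.0 / voxel_size_nm)))
    c = side // 2
    zz, yy, xx = np.indices((side, side, side), dtype=np.float32)
    x = (xx - c) * voxel_size_nm
    y = (yy - c) * voxel_size_nm
    z = (zz - c) * voxel_size_nm
    t = np.zeros((side, side, side), dtype=np.float32)
    for dx, dy, dz, sig, amp in blobs:
        t += amp * np.exp(-(((x - dx) ** 2 + (y - dy) ** 2 + (z - dz) ** 2) / (2.0 * sig**2)))
    semi = np.array([
        max(abs(b[0]) + 2.6 * b[3] for b in blobs),
        max(abs(b[1]) + 2.6 * b[3] for b in blobs),
        max(abs(b[2]) + 2.6 * b[3] for b in blobs),
    ])
    cap = (c - 0.5) * voxel_size_nm
    # inflate until the ellipsoid holds >= 99.5% of the template mass
    total = float(t.sum())
    for _ in range(20):
        s = np.minimum(semi, cap)
        m = ((x / s[0]) ** 2 + (y / s[1]) ** 2 + (z / s[2]) ** 2 <= 1.0).astype(np.float32)
        if float(t[m > 0].sum()) >= 0.995 * total or np.all(semi >= cap):
            break
        semi = semi * 1.06
    vol = Volume(t, voxel_size_nm)
    mask = Volume(m, voxel_size_nm)
    return vol, mask


def analytic_protomer_rotator(ring_id: str, voxel_size_nm: float = 2.0):
    """Return ``rot -> (template, mask)`` arrays with the blob model evaluated
    analytically at the rotated offsets (no interpolation loss).

    The mask is the matching rotated ellipsoid.  Used by the template
    matcher so that rotated search templates are exact at every node of the
    angular grid.
    """
    if ring_id not in RING_IDS:
        raise ParameterError(f"ring_id must be one of {RING_IDS}")
    if not 0 < voxel_size_nm <= 4.0:
        raise ParameterError("voxel size too coarse to resolve protomer blobs (need <= 4 nm)")
    blobs = _BLOBS[ring_id]
    tpl, mask = build_protomer_template(ring_id, voxel_size_nm)
    side = tpl.shape[0]
    c = side // 2
    zz, yy, xx = np.indices((side, side, side), dtype=np.float32)
    gx = (xx - c) * voxel_size_nm
    gy = (yy - c) * voxel_size_nm
    gz = (zz - c) * voxel_size_nm
    # semi-axes of the unrotated mask, recovered from its extents
    on = mask.data > 0
    semi = np.array([
        (np.flatnonzero(on.any(axis=(0, 1)))[-1] - np.flatnonzero(on.any(axis=(0, 1)))[0] + 1),
        (np.flatnonzero(on.any(axis=(0, 2)))[-1] - np.flatnonzero(on.any(axis=(0, 2)))[0] + 1),
        (np.flatnonzero(on.any(axis=(1, 2)))[-1] - np.flatnonzero(on.any(axis=(1, 2)))[0] + 1),
    ]) / 2.0 * voxel_size_nm

    def rotate(rot: Rotation) -> tuple[np.ndarray, np.ndarray]:
        rmat = rot.as_matrix().astype(np.float32)
        t = np.zeros((side, side, side), dtype=np.float32)
        for dx, dy, dz, sig, amp in blobs:
            o = rmat @ np.array([dx, dy, dz], dtype=np.float32)
            t += amp * np.exp(-(((gx - o[0]) ** 2 + (gy - o[1]) ** 2 + (gz - o[2]) ** 2)
                                / (2.0 * sig**2)))
        rinv = rmat.T
        qx = rinv[0, 0] * gx + rinv[0, 1] * gy + rinv[0, 2] * gz
        qy = rinv[1, 0] * gx + rinv[1, 1] * gy + rinv[1, 2] * gz
        qz = rinv[2, 0] * gx + rinv[2, 1] * gy + rinv[2, 2] * gz
        m = ((qx / semi[0]) ** 2 + (qy / semi[1]) ** 2 + (qz / semi[2]) ** 2
             <= 1.0).astype(np.float32)
        return t, m

    return rotate


def template_extent_nm(ring_id: str, voxel_size_nm: float = 2.0) -> float:
    """Conservative half-extent of the protomer template, nm."""
    blobs = _BLOBS[ring_id]
    return max(max(abs(b[0]), abs(b[1]), abs(b[2])) + 2.6 * b[3] for b in blobs)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _paste_rotated(target: np.ndarray, template: Volume, rot: Rotation,
                   pos_xyz: np.ndarray) -> None:
    """Add ``template`` rotated by ``rot`` with its center at ``pos_xyz``
    (continuous voxel coordinates) into ``target`` (indexed z, y, x)."""
    side = max(template.shape)
    half = int(np.ceil(side * 0.75)) + 1
    nz, ny, nx = target.shape
    lo = np.maximum(np.round(pos_xyz).astype(int) - half, 0)
    hi = np.minimum(np.round(pos_xyz).astype(int) + half + 1, [nx, ny, nz])
    if np.any(lo >= hi):
        return
    xs = np.arange(lo[0], hi[0])
    ys = np.arange(lo[1], hi[1])
    zs = np.arange(lo[2], hi[2])
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    rel = np.stack([gx.ravel() - pos_xyz[0], gy.ravel() - pos_xyz[1], gz.ravel() - pos_xyz[2]])
    rinv = rot.inverse().as_matrix()
    tc = template.center_xyz
    tcoords = rinv @ rel + tc[:, None]  # (x, y, z) template voxel coords
    vals = map_coordinates(
        template.data, np.stack([tcoords[2], tcoords[1], tcoords[0]]),
        order=1, mode="constant", cval=0.0,
    )
    target[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += vals.reshape(gz.shape).astype(target.dtype)


def _paint_protomer(target: np.ndarray, ring_id: str, rot: Rotation,
                    pos_xyz: np.ndarray, voxel_size_nm: float) -> None:
    """Add one protomer at ``pos_xyz`` (voxels) with orientation ``rot`` by
    evaluating the blob Gaussians analytically on the grid (no interpolation
    loss, exact across voxel sizes)."""
    nz, ny, nx = target.shape
    rmat = rot.as_matrix()
    for dx, dy, dz, sig, amp in _BLOBS[ring_id]:
        c = pos_xyz + rmat @ np.array([dx, dy, dz]) / voxel_size_nm
        half = int(np.ceil(3.2 * sig / voxel_size_nm)) + 1
        lo = np.maximum(np.round(c).astype(int) - half, 0)
        hi = np.minimum(np.round(c).astype(int) + half + 1, [nx, ny, nz])
        if np.any(lo >= hi):
            continue
        xs = (np.arange(lo[0], hi[0]) - c[0]) * voxel_size_nm
        ys = (np.arange(lo[1], hi[1]) - c[1]) * voxel_size_nm
        zs = (np.arange(lo[2], hi[2]) - c[2]) * voxel_size_nm
        g = amp * np.exp(-(zs[:, None, None] ** 2 + ys[None, :, None] ** 2
                           + xs[None, None, :] ** 2) / (2.0 * sig**2))
        target[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += g.astype(target.dtype)


def _membrane_density(shape: tuple[int, int, int], voxel_size_nm: float,
                      phantom: NPCPhantom) -> np.ndarray:
    """Analytic double-sheet nuclear envelope with a toroidal pore rim."""
    mem = phantom.membrane
    h = mem.separation_nm / 2.0
    r_apex = mem.opening_radius_nm
    nz, ny, nx = shape
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    zz, yy, xx = np.indices(shape, dtype=np.float32)
    pts = np.stack([(xx - cx).ravel(), (yy - cy).ravel(), (zz - cz).ravel()]) * voxel_size_nm
    rinv = phantom.pose.rotation.inverse().as_matrix().astype(np.float32)
    shift = (phantom.pose.shift * voxel_size_nm).astype(np.float32)
    q = rinv @ (pts - shift[:, None])
    r = np.hypot(q[0], q[1])
    z = q[2]
    r_c = r_apex + h  # center of the rim semicircle in the (r, z) half-plane
    d_plane = np.abs(np.abs(z) - h)
    d_torus = np.abs(np.hypot(r - r_c, z) - h)
    d = np.where(r >= r_c, d_plane, d_torus)
    dens = mem.amplitude * np.exp(-(d**2) / (2.0 * mem.sheet_sigma_nm**2))
    return dens.reshape(shape).astype(np.float32)


@dataclass
class RenderResult:
    """A rendered subvolume with its separable components and truth."""

    volume: Volume          # signal (wedge applied) + noise
    signal: Volume          # wedge-filtered noise-free signal
    noise: Volume           # the additive noise realisation
    signal_mask: np.ndarray  # bool voxels considered "inside the phantom"
    phantom: NPCPhantom
    requested_snr: float

    def realized_snr(self) -> float:
        m = self.signal_mask
        nv = float(self.noise.data[m].var())
        return float(self.signal.data[m].var() / nv) if nv > 0 else np.inf


def render_npc(
    phantom: NPCPhantom,
    box_voxels: int = 64,
    voxel_size_nm: float = 2.0,
    snr: float = np.inf,
    wedge: WedgeSpec | None = None,
    seed: int = 0,
    templates: Mapping[str, tuple[Volume, Volume]] | None = None,
) -> RenderResult:
    """Render one phantom into a cubic subvolume.

    Protomer templates are placed at the ring slot positions with the
    tangential orientation convention (template z along the pore axis, x
    pointing radially outward); the membrane is added analytically; the
    missing wedge (if any) filters the noise-free signal; Gaussian noise is
    scaled so that ``var(signal | mask) / var(noise)`` equals ``snr``.
    """
    half_nm = (box_voxels // 2) * voxel_size_nm
    ext = max(template_extent_nm(r, voxel_size_nm) for r in RING_IDS)
    r_max = max(phantom.rings[r].radius_nm for r in RING_IDS)
    shift_nm = float(np.max(np.abs(phantom.pose.shift))) * voxel_size_nm
    if r_max + ext + shift_nm + voxel_size_nm > half_nm:
        raise GeometryError(
            f"phantom (radius {r_max:.0f} nm + protomer {ext:.0f} nm) exceeds the "
            f"{box_voxels}-voxel box at {voxel_size_nm} nm/voxel"
        )
    zmax = max(abs(phantom.rings[r].z_offset_nm) for r in RING_IDS) + abs(phantom.cr_detach_nm)
    if zmax + ext + shift_nm + voxel_size_nm > half_nm:
        raise GeometryError("phantom axial extent exceeds the box")

    shape = (box_voxels,) * 3
    clean = np.zeros(shape, dtype=np.float32)
    center = np.array([box_voxels // 2] * 3, dtype=float)
    for ring in RING_IDS:
        for slot in np.flatnonzero(phantom.presence[ring]):
            p_nm = phantom.slot_position_xyz_nm(ring, int(slot))
            angle = phantom.slot_angles_deg()[int(slot)]
            rot = phantom.pose.rotation.compose(Rotation.about_z(angle))
            pos = phantom.pose.rotation.apply(p_nm / voxel_size_nm) + center + phantom.pose.shift
            _paint_protomer(clean, ring, rot, pos, voxel_size_nm)
    clean += _membrane_density(shape, voxel_size_nm, phantom)
    mask = clean > 0.05

    sig = Volume(clean, voxel_size_nm)
    if wedge is not None:
        sig = apply_missing_wedge(sig, wedge)
    if np.isfinite(snr):
        if not snr > 0:
            raise ParameterError("snr must be positive (or infinite)")
        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(sig.data[mask].var() / snr))
        noise = rng.normal(0.0, sigma, size=shape).astype(np.float32)
    else:
        noise = np.zeros(shape, dtype=np.float32)
    final = Volume(sig.data + noise, voxel_size_nm)
    return RenderResult(final, sig, Volume(noise, voxel_size_nm), mask, phantom, snr)


def render_npc_volume(phantom: NPCPhantom, box_voxels: int = 64, voxel_size_nm: float = 2.0,
                      snr: float = np.inf, wedge: WedgeSpec | None = None,
                      seed: int = 0) -> Volume:
    return render_npc(phantom, box_voxels, voxel_size_nm, snr, wedge, seed).volume


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignGroup:
    """One homogeneous group of simulated pores."""

    n_pores: int
    symmetry_n: int = 8
    diameter_nm: tuple[float, float] = (95.0, 95.0)
    dropout: Mapping[str, float] | None = None          # ring -> Bernoulli miss prob
    fixed_missing: Mapping[str, Sequence[int]] | None = None
    detach_fraction: float = 0.0
    detach_nm: tuple[float, float] = (20.0, 40.0)
    contiguous_dropout: bool = False

    def __post_init__(self) -> None:
        if self.n_pores < 1:
            raise ParameterError("n_pores must be >= 1")


def _draw_missing(rng: np.random.Generator, n: int, p: float, contiguous: bool) -> list[int]:
    if p <= 0:
        return []
    if contiguous:
        k = int(rng.binomial(n, p))
        if k == 0:
            return []
        start = int(rng.integers(n))
        return [(start + i) % n for i in range(k)]
    return [i for i in range(n) if rng.random() < p]


def simulate_dataset(
    design: Sequence[DesignGroup],
    box_voxels: int = 72,
    voxel_size_nm: float = 2.0,
    snr: float = np.inf,
    wedge: WedgeSpec | None = None,
    seed: int = 0,
    shift_jitter_voxels: float = 2.0,
    out_dir: str | Path | None = None,
) -> tuple[list[RenderResult], pd.DataFrame]:
    """Render a designed mixture of phantoms and return (renders, manifest).

    Every pore gets its own child seed derived from ``(seed, group, index)``,
    so identical arguments reproduce the dataset bit-for-bit.  The manifest
    has one row per rendered subvolume with the full phantom truth and the
    over-stretch class assigned from the true diameter.
    """
    from .census import classify_opening

    if len(design) == 0:
        raise ParameterError("design must contain at least one group")
    results: list[RenderResult] = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    idx = 0
    for gi, grp in enumerate(design):
        for pi in range(grp.n_pores):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), gi, pi]))
            d = float(rng.uniform(*grp.diameter_nm))
            missing: dict[str, list[int]] = {}
            if grp.fixed_missing:
                missing = {r: list(map(int, s)) for r, s in grp.fixed_missing.items()}
            elif grp.dropout:
                for ring, p in grp.dropout.items():
                    missing[ring] = _draw_missing(rng, grp.symmetry_n, float(p),
                                                  grp.contiguous_dropout)
            detach = 0.0
            if grp.detach_fraction > 0 and rng.random() < grp.detach_fraction:
                detach = float(rng.uniform(*grp.detach_nm))
            phase = float(rng.uniform(0.0, 360.0 / grp.symmetry_n))
            shift = rng.uniform(-shift_jitter_voxels, shift_jitter_voxels, size=3)
            pose = Pose(shift=shift, rotation=Rotation.about_z(phase))
            phantom = build_phantom(grp.symmetry_n, d, missing=missing,
                                    cr_detach_nm=detach, pose=pose)
            render_seed = int(rng.integers(0, 2**31 - 1))
            res = render_npc(phantom, box_voxels, voxel_size_nm, snr, wedge, render_seed)
            counts = phantom.present_counts()
            row = {
                "id": idx, "group": gi, "symmetry_n": grp.symmetry_n,
                "diameter_nm": d, "cr_detach_nm": detach,
                "cr_count": counts["CR"], "ir_count": counts["IR"], "nr_count": counts["NR"],
                "cr_missing": ",".join(map(str, sorted(missing.get("CR", [])))),
                "ir_missing": ",".join(map(str, sorted(missing.get("IR", [])))),
                "nr_missing": ",".join(map(str, sorted(missing.get("NR", [])))),
                "phase_deg": phase,
                "shift_x": shift[0], "shift_y": shift[1], "shift_z": shift[2],
                "stretch_class": classify_opening(d),
                "snr": snr, "seed": render_seed,
            }
            if out_dir is not None:
                fname = f"pore_{idx:04d}.mrc"
                write_mrc(res.volume, out_dir / fname)
                row["file"] = fname
            rows.append(row)
            results.append(res)
            idx += 1
    manifest = pd.DataFrame(rows)
    manifest.attrs.update({"voxel_size_nm": voxel_size_nm, "box_voxels": box_voxels,
                           "snr": snr, "seed": seed,
                           "wedge": (wedge.tilt_min_deg, wedge.tilt_max_deg) if wedge else None})
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return results, manifest


# ---------------------------------------------------------------------------
# fluorescence nucleus scenes
# ---------------------------------------------------------------------------


@dataclass
class NucleusSpec:
    center: np.ndarray            # (x, y, z) voxels
    semi_axes: np.ndarray         # (a, b, c) voxels along x, y, z
    rotation_deg: float = 0.0     # in-plane (about z) only
    intensity: dict[str, float] = field(default_factory=dict)   # channel -> interior mean
    foci: dict[str, int] = field(default_factory=dict)          # channel -> planted count
    focus_amplitude: float = 500.0
    focus_sigma: float = 1.5

    def bbox_extents(self) -> np.ndarray:
        """Analytic axis-aligned bounding-box extents (x, y, z) in voxels."""
        a, b, c = self.semi_axes
        th = np.radians(self.rotation_deg)
        ex = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
        ey = np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2)
        return 2.0 * np.array([ex, ey, c])

    def flatness(self) -> float:
        ex, ey, ez = self.bbox_extents()
        return float(ez / min(ex, ey))


@dataclass
class NucleusScene:
    shape: tuple[int, int, int]                 # (z, y, x)
    nuclei: list[NucleusSpec]
    channels: tuple[str, ...] = ("dna", "damage", "yap")
    background: float = 100.0
    noise_sigma: float = 20.0
    seed: int = 0


def make_nucleus_scene(
    n_nuclei: int,
    seed: int = 0,
    plane_voxels: int | None = None,
    n_z: int = 112,
    semi_axes_range: tuple[tuple[float, float], ...] = ((15.0, 18.0), (12.0, 15.0), (7.0, 9.0)),
    foci_range: tuple[int, int] = (0, 10),
    dna_intensity: float = 900.0,
    yap_intensity_range: tuple[float, float] = (1500.0, 4500.0),
    focus_amplitude: float = 500.0,
    focus_sigma: float = 1.5,
    noise_sigma: float = 20.0,
) -> NucleusScene:
    """Place ``n_nuclei`` non-overlapping ellipsoidal nuclei on a jittered grid."""
    rng = np.random.default_rng(seed)
    cols = int(np.ceil(np.sqrt(n_nuclei)))
    rows = int(np.ceil(n_nuclei / cols))
    # cell spacing sized so that planted foci occupy well under the
    # top-percentile threshold fraction of the field of view
    cell = 56
    ny = rows * cell
    nx = cols * cell if plane_voxels is None else plane_voxels
    nuclei = []
    for k in range(n_nuclei):
        r, c = divmod(k, cols)
        a = rng.uniform(*semi_axes_range[0])
        b = rng.uniform(*semi_axes_range[1])
        cc = rng.uniform(*semi_axes_range[2])
        cx = c * cell + cell / 2 + rng.uniform(-1.5, 1.5)
        cy = r * cell + cell / 2 + rng.uniform(-1.5, 1.5)
        cz = n_z / 2 + rng.uniform(-3, 3)
        nuclei.append(NucleusSpec(
            center=np.array([cx, cy, cz]),
            semi_axes=np.array([a, b, cc]),
            rotation_deg=0.0,
            intensity={"dna": dna_intensity,
                       "damage": 150.0,
                       "yap": float(rng.uniform(*yap_intensity_range))},
            foci={"damage": int(rng.integers(foci_range[0], foci_range[1] + 1))},
            focus_amplitude=focus_amplitude,
            focus_sigma=focus_sigma,
        ))
    return NucleusScene(shape=(n_z, ny, nx), nuclei=nuclei,
                        noise_sigma=noise_sigma, seed=seed)


def _check_disjoint(scene: NucleusScene) -> None:
    boxes = []
    for n in scene.nuclei:
        e = n.bbox_extents() / 2.0
        boxes.append((n.center - e, n.center + e))
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            lo = np.maximum(boxes[i][0], boxes[j][0])
            hi = np.minimum(boxes[i][1], boxes[j][1])
            if np.all(lo < hi):
                raise GeometryError(f"nuclei {i} and {j} overlap")


def render_nucleus_stack(scene: NucleusScene) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a multichannel 3D stack (channel, z, y, x) plus its truth table.

    Nuclei are uniform-interior ellipsoids per channel; DNA-damage foci are
    Gaussian spots planted at mutually separated interior points; Gaussian
    read noise and a constant background are added everywhere.
    """
    _check_disjoint(scene)
    rng = np.random.default_rng(scene.seed)
    nz, ny, nx = scene.shape
    stack = np.zeros((len(scene.channels), nz, ny, nx), dtype=np.float32)
    chan_idx = {c: i for i, c in enumerate(scene.channels)}
    rows = []

    def window(center, half):
        lo = np.maximum(np.floor(center - half).astype(int), 0)
        hi = np.minimum(np.ceil(center + half).astype(int) + 1, [nx, ny, nz])
        zs, ys, xs = (np.arange(lo[2], hi[2]), np.arange(lo[1], hi[1]),
                      np.arange(lo[0], hi[0]))
        gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
        return (slice(lo[2], hi[2]), slice(lo[1], hi[1]), slice(lo[0], hi[0])), gx, gy, gz

    for nid, nuc in enumerate(scene.nuclei):
        th = np.radians(nuc.rotation_deg)
        a, b, c = nuc.semi_axes
        sl, gx, gy, gz = window(nuc.center, np.array([max(a, b) + 2, max(a, b) + 2, c + 2]))
        dx = gx - nuc.center[0]
        dy = gy - nuc.center[1]
        dz = gz - nuc.center[2]
        xr = dx * np.cos(th) + dy * np.sin(th)
        yr = -dx * np.sin(th) + dy * np.cos(th)
        inside = (xr / a) ** 2 + (yr / b) ** 2 + (dz / c) ** 2 <= 1.0
        for ch, mean in nuc.intensity.items():
            stack[chan_idx[ch]][sl][inside] += mean
        # plant foci at mutually separated interior points
        for ch, count in nuc.foci.items():
            centers: list[np.ndarray] = []
            tries = 0
            while len(centers) < count and tries < 5000:
                tries += 1
                u = rng.uniform(-1, 1, size=3)
                if np.sum(u**2) > 1.0:
                    continue
                p = nuc.center + 0.85 * u * nuc.semi_axes
                if centers and min(np.linalg.norm(p - q) for q in centers) < 3.5 * nuc.focus_sigma:
                    continue
                centers.append(p)
            if len(centers) < count:
                raise GeometryError(f"could not place {count} separated foci in nucleus {nid}")
            for p in centers:
                fsl, fx, fy, fz = window(p, np.full(3, 4.0 * nuc.focus_sigma))
                d2 = (fx - p[0]) ** 2 + (fy - p[1]) ** 2 + (fz - p[2]) ** 2
                stack[chan_idx[ch]][fsl] += (nuc.focus_amplitude
                                             * np.exp(-d2 / (2.0 * nuc.focus_sigma**2))
                                             ).astype(np.float32)
        row = {"nucleus_id": nid,
               "center_x": nuc.center[0], "center_y": nuc.center[1], "center_z": nuc.center[2],
               "extent_x": nuc.bbox_extents()[0], "extent_y": nuc.bbox_extents()[1],
               "extent_z": nuc.bbox_extents()[2], "flatness": nuc.flatness()}
        for ch in scene.channels:
            row[f"mean_{ch}"] = nuc.intensity.get(ch, 0.0)
            row[f"foci_{ch}"] = nuc.foci.get(ch, 0)
        rows.append(row)
    stack += scene.background
    stack += rng.normal(0.0, scene.noise_sigma, size=stack.shape).astype(np.float32)
    return stack, pd.DataFrame(rows)


def write_nucleus_tiff(stack: np.ndarray, path: str | Path) -> None:
    """Write a (channel, z, y, x) stack as a channel-major multi-page TIFF."""
    import tifffile

    tifffile.imwrite(str(path), stack.astype(np.float32))


def read_nucleus_tiff(path: str | Path, n_channels: int) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 3:  # pages flattened
        arr = arr.reshape(n_channels, -1, *arr.shape[-2:])
    return arr.astype(np.float32)
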