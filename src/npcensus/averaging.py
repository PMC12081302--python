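"""Subtomogram alignment, symmetrised averaging and particle quality filters.

Alignment scores are global correlation coefficients computed with periodic
(circular) translation via FFT cross-correlation; the best pose maps the
particle onto the reference (rotate about the grid center, then shift).
Averages can be Cn-symmetrised by averaging the n axial rotations of the
mean, mirroring whole-pore averaging with imposed rotational symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.fft as sfft

from .errors import EmptySetError, ParameterError
from .volumes import Pose, Rotation, Volume, transform

__all__ = [
    "ParticleSet",
    "align_particle",
    "align_to_references",
    "average_particles",
    "symmetrize",
    "extract_asymmetric_units",
    "filter_particles",
    "fsc",
    "fsc_resolution_nm",
]


@dataclass
class ParticleSet:
    """Subvolumes with 1:1 poses, reference correlations and keep/discard flags."""

    subvolumes: list[Volume]
    poses: list[Pose]
    cc: np.ndarray | None = None
    kept: np.ndarray | None = None
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.subvolumes)
        if len(self.poses) != n:
            raise ParameterError("poses and subvolumes must align 1:1")
        if self.cc is None:
            self.cc = np.full(n, np.nan)
        self.cc = np.asarray(self.cc, dtype=float)
        if self.kept is None:
            self.kept = np.ones(n, dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if not self.reasons:
            self.reasons = [""] * n

    def __len__(self) -> int:
        return len(self.subvolumes)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for i, (pose, c, k, r) in enumerate(zip(self.poses, self.cc, self.kept, self.reasons)):
            rows.append({"id": i, "x": pose.shift[0], "y": pose.shift[1], "z": pose.shift[2],
                         "phi": pose.rotation.phi, "theta": pose.rotation.theta,
                         "psi": pose.rotation.psi, "score": c,
                         "class": "kept" if k else "discarded", "reason": r})
        return pd.DataFrame(rows)


def _shift_window_scores(cc_map: np.ndarray, shift_range: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores and integer shifts within +/- shift_range, zero shift first so
    exact ties resolve to the smallest movement."""
    rng = range(-shift_range, shift_range + 1)
    shifts = np.array([(sx, sy, sz) for sx in rng for sy in rng for sz in rng])
    order = np.argsort(np.linalg.norm(shifts, axis=1), kind="stable")
    shifts = shifts[order]
    vals = cc_map[shifts[:, 2] % cc_map.shape[0],
                  shifts[:, 1] % cc_map.shape[1],
                  shifts[:, 0] % cc_map.shape[2]]
    return vals, shifts


def align_particle(subvol: Volume, reference: Volume, shift_range_voxels: int,
                   rotations: Sequence[Rotation]) -> tuple[Pose, float]:
    """Exhaustive rigid alignment of a particle onto a reference.

    For every rotation in the set, the particle is resampled and the
    translation is found as the circular cross-correlation argmax within
    ``+/- shift_range_voxels`` per axis; the returned correlation is the
    global (zero-mean, norm-normalised) coefficient.  The search is purely
    exhaustive — no local refinement — so it is reproducible and directly
    comparable to a brute-force enumeration.
    """
    if len(rotations) == 0:
        raise ParameterError("rotation set is empty")
    if shift_range_voxels < 0 or 2 * shift_range_voxels >= min(subvol.shape):
        raise ParameterError("shift range must be within subvolume margins")
    ref0 = reference.data.astype(np.float64) - float(reference.data.mean())
    nref = float(np.linalg.norm(ref0))
    f_ref = sfft.rfftn(ref0)
    best = (-np.inf, None, None)
    for rot in rotations:
        a = transform(subvol, Pose(rotation=rot)).data.astype(np.float64)
        a0 = a - a.mean()
        na = float(np.linalg.norm(a0))
        if na <= 0 or nref <= 0:
            continue
        # cc_map[s] = <roll(a0, s), ref0>
        cc_map = sfft.irfftn(np.conj(sfft.rfftn(a0)) * f_ref, s=a0.shape) / (na * nref)
        vals, shifts = _shift_window_scores(cc_map, shift_range_voxels)
        j = int(np.argmax(vals))
        if vals[j] > best[0]:
            best = (float(vals[j]), shifts[j].astype(float), rot)
    cc, shift, rot = best
    return Pose(shift=shift, rotation=rot), cc


def align_to_references(subvol: Volume, references: Mapping[object, Volume],
                        shift_range_voxels: int, rotations: Sequence[Rotation]
                        ) -> dict[object, tuple[Pose, float]]:
    """Align one particle against several references, sharing the per-rotation
    resampling of the particle (the expensive step) across references."""
    if len(rotations) == 0:
        raise ParameterError("rotation set is empty")
    refs = {}
    for key, ref in references.items():
        r0 = ref.data.astype(np.float64) - float(ref.data.mean())
        refs[key] = (sfft.rfftn(r0), float(np.linalg.norm(r0)))
    best: dict[object, tuple[float, np.ndarray, Rotation]] = {
        k: (-np.inf, None, None) for k in references}
    for rot in rotations:
        a = transform(subvol, Pose(rotation=rot)).data.astype(np.float64)
        a0 = a - a.mean()
        na = float(np.linalg.norm(a0))
        f_a = np.conj(sfft.rfftn(a0))
        for key, (f_ref, nref) in refs.items():
            cc_map = sfft.irfftn(f_a * f_ref, s=a0.shape) / (na * nref)
            vals, shifts = _shift_window_scores(cc_map, shift_range_voxels)
            j = int(np.argmax(vals))
            if vals[j] > best[key][0]:
                best[key] = (float(vals[j]), shifts[j].astype(float), rot)
    return {k: (Pose(shift=s, rotation=r), c) for k, (c, s, r) in best.items()}


def symmetrize(vol: Volume, symmetry_n: int, phase_deg: float = 0.0) -> Volume:
    """Average the n axial (z) rotations of a volume — imposed Cn symmetry.

    ``phase_deg`` offsets every rotation angle.  Because the angle set
    ``{phase + 360 k / n}`` is invariant (mod 360) under adding ``360/n``,
    the symmetrised density rotated by one symmetry step — evaluated from
    the source volume, i.e. ``symmetrize(v, n, 360/n)`` — is numerically
    identical to ``symmetrize(v, n)``: the output is Cn-invariant exactly.
    (Resampling the *output grid* by 360/n instead incurs ordinary trilinear
    interpolation error, as for any lattice-sampled density.)
    """
    if symmetry_n < 1:
        raise ParameterError("symmetry_n must be >= 1")
    if symmetry_n == 1 and phase_deg == 0.0:
        return vol.copy()
    acc = np.zeros_like(vol.data, dtype=np.float64)
    for k in range(symmetry_n):
        ang = (phase_deg + 360.0 * k / symmetry_n) % 360.0
        acc += transform(vol, Pose(rotation=Rotation.about_z(ang))).data
    return Volume((acc / symmetry_n).astype(vol.data.dtype, copy=False), vol.voxel_size_nm)


def average_particles(particles: ParticleSet, symmetry_n: int = 1) -> Volume:
    """Equal-weight average of kept particles in the reference frame, then
    Cn-symmetrised."""
    idx = np.flatnonzero(particles.kept)
    if len(idx) == 0:
        raise EmptySetError("no kept particles to average")
    acc = None
    for i in idx:
        v = transform(particles.subvolumes[i], particles.poses[i])
        acc = v.data.astype(np.float64) if acc is None else acc + v.data
    mean = Volume((acc / len(idx)).astype(np.float32), particles.subvolumes[idx[0]].voxel_size_nm)
    return symmetrize(mean, symmetry_n)


def extract_asymmetric_units(pore_pose: Pose, symmetry_n: int, ring_radius_nm: float,
                             voxel_size_nm: float, center_xyz: Sequence[float],
                             z_offset_nm: float = 0.0) -> list[tuple[np.ndarray, Rotation]]:
    """Positions and tangential orientations of the n (or oversampled m)
    asymmetric units on the ring circumference, transformed by the pore pose.

    With ``symmetry_n=60`` this is the circumferential oversampling mode used
    to seed symmetry assessment.
    """
    if symmetry_n < 1:
        raise ParameterError("symmetry_n must be >= 1")
    if not ring_radius_nm > 0:
        raise ParameterError("ring radius must be positive")
    center = np.asarray(center_xyz, dtype=float)
    out = []
    for i in range(symmetry_n):
        ang = 360.0 * i / symmetry_n
        a = np.radians(ang)
        p_vox = np.array([ring_radius_nm * np.cos(a), ring_radius_nm * np.sin(a),
                          z_offset_nm]) / voxel_size_nm
        pos = pore_pose.rotation.apply(p_vox) + center + pore_pose.shift
        rot = pore_pose.rotation.compose(Rotation.about_z(ang))
        out.append((pos, rot))
    return out


def filter_particles(ps: ParticleSet, cc_min: float = 0.1,
                     top_view_max_tilt_deg: float = 20.0,
                     bounds: tuple[Sequence[float], Sequence[float]] | None = None,
                     beam_axis: Sequence[float] = (0.0, 0.0, 1.0)) -> ParticleSet:
    """Quality filters: low reference correlation, top views, out-of-bounds.

    Discards (with reason codes) particles whose cc to the reference is below
    ``cc_min``; whose pore axis lies within ``top_view_max_tilt_deg`` of the
    beam axis (top views, which carry no usable side information under the
    missing wedge); and whose center falls outside ``bounds`` (inclusive on
    both ends).
    """
    kept = ps.kept.copy()
    reasons = list(ps.reasons)
    beam = np.asarray(beam_axis, dtype=float)
    beam = beam / np.linalg.norm(beam)
    for i in range(len(ps)):
        if not kept[i]:
            continue
        if np.isfinite(ps.cc[i]) and ps.cc[i] < cc_min:
            kept[i] = False
            reasons[i] = "low_cc"
            continue
        axis = ps.poses[i].rotation.apply([0.0, 0.0, 1.0])
        tilt = np.degrees(np.arccos(np.clip(abs(np.dot(axis, beam)), -1.0, 1.0)))
        if tilt < top_view_max_tilt_deg:
            kept[i] = False
            reasons[i] = "top_view"
            continue
        if bounds is not None:
            lo = np.asarray(bounds[0], dtype=float)
            hi = np.asarray(bounds[1], dtype=float)
            c = ps.poses[i].shift
            if np.any(c < lo) or np.any(c > hi):
                kept[i] = False
                reasons[i] = "out_of_bounds"
    return ParticleSet(ps.subvolumes, ps.poses, ps.cc.copy(), kept, reasons)


def fsc(vol_a: Volume, vol_b: Volume, n_shells: int | None = None
        ) -> tuple[np.ndarray, np.ndarray]:
    """Fourier shell correlation between two volumes of identical shape.

    Returns (spatial frequency in 1/nm at shell centers, FSC values).
    """
    if vol_a.shape != vol_b.shape:
        raise ParameterError("volumes must share a shape")
    n = min(vol_a.shape)
    n_shells = n_shells or (n // 2)
    fa = np.fft.fftn(vol_a.data)
    fb = np.fft.fftn(vol_b.data)
    freqs = [np.fft.fftfreq(s, d=vol_a.voxel_size_nm) for s in vol_a.shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    k = np.sqrt(kz**2 + ky**2 + kx**2)
    k_ny = 0.5 / vol_a.voxel_size_nm
    edges = np.linspace(0.0, k_ny, n_shells + 1)
    which = np.clip(np.digitize(k.ravel(), edges) - 1, 0, n_shells - 1)
    num = np.bincount(which, weights=(fa * np.conj(fb)).real.ravel(), minlength=n_shells)
    da = np.bincount(which, weights=(np.abs(fa) ** 2).ravel(), minlength=n_shells)
    db = np.bincount(which, weights=(np.abs(fb) ** 2).ravel(), minlength=n_shells)
    denom = np.sqrt(da * db)
    curve = np.where(denom > 0, num / np.maximum(denom, 1e-30), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, curve


def fsc_resolution_nm(vol_a: Volume, vol_b: Volume, threshold: float = 0.5) -> float:
    """Resolution (nm) at the first crossing of the FSC below ``threshold``.

    Linear interpolation between shells; returns the Nyquist resolution when
    the curve never drops below the threshold.
    """
    freq, curve = fsc(vol_a, vol_b)
    below = np.nonzero(curve < threshold)[0]
    below = below[below > 0]
    if len(below) == 0:
        return float(1.0 / freq[-1])
    i = int(below[0])
    f0, f1 = freq[i - 1], freq[i]
    c0, c1 = curve[i - 1], curve[i]
    f_cross = f0 + (threshold - c0) * (f1 - f0) / (c1 - c0) if c1 != c0 else f1
    return float(1.0 / f_cross)
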