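"""Rotational-symmetry determination for individual NPCs.

Two routes are provided, mirroring the two stages of the classification
workflow:

* ``collapse_oversampled`` seeds m (default 60) positions on the pore
  circumference and iteratively re-aligns a small crop at each seed to a
  protomer reference; seeds drift onto the true protomer slots, and
  ``count_position_clusters`` turns the converged positions into a symmetry
  estimate (the algorithmic replacement for visual assessment).
* ``classify_by_reference`` aligns the whole pore against C7/C8/C9
  references under a seeded stochastic pose perturbation, repeats the
  classification and accepts a label only when the votes satisfy the
  consistency rule (all-of-4 by default; k-of-n supported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .averaging import ParticleSet, align_to_references, average_particles
from .errors import EmptySetError, ParameterError
from .volumes import Pose, Rotation, Volume, make_inplane_grid

__all__ = [
    "SymmetryCall",
    "azimuthal_profile",
    "collapse_oversampled",
    "count_position_clusters",
    "classify_by_reference",
    "build_class_references",
]


@dataclass
class SymmetryCall:
    """Outcome of symmetry determination for one particle."""

    label: int | str                 # 7 / 8 / 9 / "ambiguous" / "discarded"
    votes: list[int]
    method: str                      # "collapse" or "reference"
    reason: str = ""


def _crop_centered(data: np.ndarray, pos_xyz: np.ndarray, side: int) -> np.ndarray | None:
    half = side // 2
    c = np.round(pos_xyz).astype(int)
    lo = c - half
    hi = lo + side
    nz, ny, nx = data.shape
    if lo[0] < 0 or lo[1] < 0 or lo[2] < 0 or hi[0] > nx or hi[1] > ny or hi[2] > nz:
        return None
    return data[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]]


def collapse_oversampled(
    subvolume: Volume,
    protomer_reference: Volume,
    ring_radius_voxels: float,
    pore_center_xyz: Sequence[float] | None = None,
    m: int = 60,
    iterations: int = 16,
    shift_range_voxels: int = 5,
    symmetry_upper_bound: int = 9,
) -> np.ndarray:
    """Iterative circumferential collapse of m oversampled seeds.

    The pore must be center/axis aligned beforehand (axis along z).  Each
    cycle crops a reference-sized box at every seed, orients the reference
    tangentially for the seed's current azimuth, and moves the seed by the
    in-plane cross-correlation argmax within ``+/- shift_range_voxels``.
    Returns the (m, 2) final in-plane positions (x, y) in voxels.
    """
    import warnings

    if m < 2 * symmetry_upper_bound:
        warnings.warn("oversampling m below twice the symmetry upper bound; "
                      "cluster counting may under-resolve", stacklevel=2)
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    center = (np.asarray(pore_center_xyz, dtype=float) if pore_center_xyz is not None
              else subvolume.center_xyz)
    data = subvolume.data.astype(np.float32)
    side = min(protomer_reference.shape)
    angles = np.radians(np.arange(m) * 360.0 / m)
    pos = np.stack([center[0] + ring_radius_voxels * np.cos(angles),
                    center[1] + ring_radius_voxels * np.sin(angles)], axis=1)
    if iterations == 0:
        return pos
    # reference crops, tangentially oriented, cached per azimuth bin (3° bins)
    from .volumes import transform

    ref_cache: dict[int, np.ndarray] = {}

    def oriented_ref(azimuth_deg: float) -> np.ndarray:
        key = int(round(azimuth_deg / 3.0)) % 120
        if key not in ref_cache:
            r = transform(protomer_reference,
                          Pose(rotation=Rotation.about_z(key * 3.0)), fill=0.0)
            d = r.data - r.data.mean()
            ref_cache[key] = d.astype(np.float32)
        return ref_cache[key]

    rng_shifts = [(dx, dy) for dx in range(-shift_range_voxels, shift_range_voxels + 1)
                  for dy in range(-shift_range_voxels, shift_range_voxels + 1)]
    rng_shifts.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2))
    z0 = center[2]
    for _ in range(iterations):
        for i in range(m):
            az = np.degrees(np.arctan2(pos[i, 1] - center[1], pos[i, 0] - center[0]))
            ref = oriented_ref(az % 360.0)
            best_val, best_shift = -np.inf, (0, 0)
            for dx, dy in rng_shifts:
                crop = _crop_centered(data, np.array([pos[i, 0] + dx, pos[i, 1] + dy, z0]),
                                      side)
                if crop is None:
                    continue
                val = float(np.sum((crop - crop.mean()) * ref))
                if val > best_val:
                    best_val, best_shift = val, (dx, dy)
            pos[i, 0] += best_shift[0]
            pos[i, 1] += best_shift[1]
    return pos


def count_position_clusters(positions: np.ndarray, merge_radius_voxels: float) -> int:
    """Single-linkage cluster count of collapsed positions at a merge radius."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or len(positions) == 0:
        raise ParameterError("positions must be a non-empty (m, d) array")
    if len(positions) == 1:
        return 1
    d = squareform(pdist(positions))
    adj = csr_matrix(d <= merge_radius_voxels)
    n, _ = connected_components(adj, directed=False)
    return int(n)


def default_merge_radius(ring_radius_voxels: float, smallest_symmetry: int = 7,
                         fraction: float = 0.4) -> float:
    """Default cluster merge radius: a fraction of the inter-slot arc distance
    for the smallest plausible symmetry."""
    arc = 2.0 * np.pi * ring_radius_voxels / smallest_symmetry
    return fraction * arc


def azimuthal_profile(vol: Volume, r_range_voxels: tuple[float, float],
                      z_range_voxels: tuple[float, float] = (-10.0, 10.0),
                      n_theta: int = 360, z_step: float = 2.0) -> np.ndarray:
    """(theta, z) intensity profile of the ring annulus, radially averaged
    and with the rotationally symmetric component (the per-z azimuthal mean)
    removed — what remains is the n-fold protomer comb, the symmetry
    fingerprint of the pore."""
    from scipy.ndimage import map_coordinates

    c = vol.center_xyz
    th = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rs = np.arange(r_range_voxels[0], r_range_voxels[1] + 1e-9, 1.0)
    zs = np.arange(z_range_voxels[0], z_range_voxels[1] + 1e-9, z_step)
    T, R, Z = np.meshgrid(th, rs, zs, indexing="ij")
    x = c[0] + R * np.cos(T)
    y = c[1] + R * np.sin(T)
    z = c[2] + Z
    vals = map_coordinates(vol.data, np.stack([z.ravel(), y.ravel(), x.ravel()]),
                           order=1, mode="nearest")
    prof = vals.reshape(T.shape).mean(axis=1)
    return prof - prof.mean(axis=0, keepdims=True)


def _comb_correlation(p_particle: np.ndarray, p_ref: np.ndarray) -> float:
    """Max over azimuthal shift of the normalised profile correlation."""
    import scipy.fft as sfft

    fp = sfft.rfft(p_particle, axis=0)
    fr = sfft.rfft(p_ref, axis=0)
    cc = sfft.irfft((fp * np.conj(fr)).sum(axis=1), n=p_particle.shape[0])
    denom = np.linalg.norm(p_particle) * np.linalg.norm(p_ref)
    return float(cc.max() / denom) if denom > 0 else 0.0


def ring_radius_from_reference(ref: Volume, r_max_frac: float = 0.45) -> float:
    """Radius (voxels) of the strongest azimuthal-harmonic annulus — used to
    center the profile band automatically on the protomer rings."""
    c = ref.center_xyz
    r_max = int(min(ref.shape[1], ref.shape[2]) * r_max_frac)
    best_r, best_e = 1.0, -np.inf
    for r in range(4, r_max):
        prof = azimuthal_profile(ref, (r - 1, r + 1))
        e = float((prof**2).sum())
        if e > best_e:
            best_r, best_e = float(r), e
    return best_r


def classify_by_reference(
    subvolume: Volume,
    references: Mapping[int, Volume],
    repeats: int = 4,
    required_consistency: int | str = "all",
    seed: int = 0,
    rotations: Sequence[Rotation] | None = None,
    shift_range_voxels: int = 2,
    perturb_rot_deg: float = 8.0,
    perturb_shift_voxels: float = 1.5,
    method: str = "azimuthal",
    ring_radius_voxels: float | None = None,
    reference_profiles: Mapping[int, np.ndarray] | None = None,
) -> SymmetryCall:
    """Repeated reference-based classification with consistency voting.

    Each repeat perturbs the particle pose with a seeded random in-plane
    rotation and shift (the deterministic stand-in for a stochastic
    alignment), re-aligns it against every reference, and votes for the
    highest-correlating one.  The label is set only when the votes satisfy
    the consistency rule: ``"all"`` requires unanimity (the default, 4-run
    protocol); an integer k accepts the majority label when it holds at
    least k votes (e.g. 5-of-8).

    Two alignment/score routes:

    * ``method="azimuthal"`` (default): the particle and references are
      compared through their ring-annulus comb profiles
      (:func:`azimuthal_profile`), with a dense (1°) azimuthal alignment
      scan.  Removing the rotational average makes the score an (almost)
      orthogonal decomposition over symmetry harmonics, so cross-symmetry
      scores are near zero.
    * ``method="volume"``: full exhaustive 3D alignment of the particle
      against each reference volume over ``rotations``.
    """
    if not references:
        raise ParameterError("at least one reference is required")
    for n, ref in references.items():
        if ref.shape != subvolume.shape:
            raise ParameterError("references must match the particle shape")
    if rotations is None:
        rotations = make_inplane_grid(15.0)
    from .volumes import transform

    if method == "azimuthal":
        first = next(iter(references.values()))
        if ring_radius_voxels is None:
            ring_radius_voxels = ring_radius_from_reference(first)
        band = (max(ring_radius_voxels - 4.0, 1.0), ring_radius_voxels + 4.0)
        if reference_profiles is None:
            reference_profiles = {n: azimuthal_profile(r, band)
                                  for n, r in references.items()}
    votes: list[int] = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        pert = Pose(
            shift=rng.uniform(-perturb_shift_voxels, perturb_shift_voxels, size=3),
            rotation=Rotation.about_z(rng.uniform(-perturb_rot_deg, perturb_rot_deg)),
        )
        particle = transform(subvolume, pert)
        if method == "azimuthal":
            prof = azimuthal_profile(particle, band)
            scores = {n: _comb_correlation(prof, reference_profiles[n])
                      for n in references}
            votes.append(max(scores, key=scores.get))
        else:
            aligned = align_to_references(particle, references, shift_range_voxels,
                                          rotations)
            votes.append(max(aligned, key=lambda k: aligned[k][1]))
    label = resolve_votes(votes, required_consistency)
    ok = label != "ambiguous"
    return SymmetryCall(label=label, votes=votes, method="reference",
                        reason="" if ok else "inconsistent votes")


def resolve_votes(votes: Sequence[int], required_consistency: int | str = "all") -> int | str:
    """Consistency rule over repeated class votes.

    ``"all"`` labels a particle only when every repeat agrees (the 4-run
    unanimous protocol); an integer k accepts the plurality label when it
    holds at least k votes (the 5-of-8 protocol).  Anything else is
    ``"ambiguous"``.
    """
    votes = list(votes)
    if not votes:
        raise ParameterError("no votes to resolve")
    counts = {v: votes.count(v) for v in set(votes)}
    top = max(counts, key=counts.get)
    if required_consistency == "all":
        ok = counts[top] == len(votes)
    else:
        ok = counts[top] >= int(required_consistency)
    return top if ok else "ambiguous"


def build_class_references(
    particles: ParticleSet,
    labels: Sequence[int],
    symmetries: Sequence[int] = (7, 8, 9),
) -> dict[int, Volume]:
    """Per-class Cn-symmetrised averages used as classification references.

    ``labels`` assigns each particle a symmetry class (the synthetic-truth
    stand-in for the manual pre-sort of clearly symmetric particles).
    """
    labels = np.asarray(labels)
    if len(labels) != len(particles):
        raise ParameterError("labels must align with particles")
    refs: dict[int, Volume] = {}
    for n in symmetries:
        idx = np.flatnonzero((labels == n) & particles.kept)
        if len(idx) == 0:
            raise EmptySetError(f"no particles labelled {n}")
        sub = ParticleSet([particles.subvolumes[i] for i in idx],
                          [particles.poses[i] for i in idx])
        refs[n] = average_particles(sub, symmetry_n=n)
    return refs
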