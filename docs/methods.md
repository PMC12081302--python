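# Methods

This note documents the models, algorithms and numerical choices behind
npcensus, and what its synthetic validation does and does not demonstrate.

## Coordinate and orientation conventions

Volumes are stored `[z, y, x]`; all positions and vectors in code interfaces
are `(x, y, z)` in voxels, physical lengths in nanometres (the MRC boundary
converts to/from Å). Rotations are intrinsic ZXZ Euler angles in degrees,
normalised to φ, ψ ∈ [0, 360), θ ∈ [0, 180]; matrices act on (x, y, z)
column vectors. The rotation center of a grid is `floor(dim/2)` per axis.
The electron beam runs along z; the tilt axis is y by default. Protomers use
the tangential convention: template local z along the pore axis, local x
pointing radially outward.

## Phantom generator

Each NPC phantom is parameterised by its symmetry n (7/8/9 by default, any
n ≥ 3), IR diameter (the pore diameter, 2 × IR protomer radius), per-ring
per-slot presence, whole-pore pose (in-plane phase plus a small residual
shift — the state after whole-pore alignment), and CR detachment (an axial
displacement of the entire CR away from the membrane). Ring geometry
defaults: CR radius = IR radius − 4 nm at z = +16 nm; NR radius = IR radius
− 2 nm at z = −16 nm (all overridable).

**Protomer density.** Each protomer is six Gaussian blobs at 8–9.5 nm from
the protomer center in well-spread directions, widths σ ≈ 1.3–1.5 nm,
amplitudes 0.68–1.0 (frozen constants; the three ring layouts are distinct).
The layout was chosen, once, by a seeded random search with three explicit
design targets, all verified by tests:

* orientation identifiability — the autocorrelation margin against the
  nearest non-identity rotations of a 10° ZXZ grid (the minimal-net-rotation
  family `(φ, 10°, −φ±10°)` plus ±10° spins) is ≥ 0.1 for every ring, so the
  best-matching orientation is unique at the search-grid resolution;
* ring distinguishability — best-alignment cross-correlation between any
  two ring templates ≤ ~0.45;
* translational smoothness — the 1-voxel translation autocorrelation is
  ≈ 0.57 at 2 nm voxels, so a genuine matched-filter maximum spans several
  voxels.

Renders paint the blobs analytically (each Gaussian evaluated at its rotated
offset), so phantoms are exact at any voxel size; the matcher rotates the
same parametric model analytically (see below). At 2 nm voxels a protomer
spans ~25 nm — the scale of the Y-complex assemblies that build the rings.

**Membrane.** The nuclear envelope is two parallel Gaussian-profile sheets
(center-to-center separation 40 nm, sheet σ 3 nm) fused at the pore rim into
a half-toroid whose apex radius equals the pore radius — the apex circle is
the outer–inner membrane fusion line where opening diameters are measured.
The membrane amplitude is 0.15 against protomer blob peaks near 1: the
sheets are clearly visible, but the protomers dominate the local matching
statistics, as they must for a per-protomer census to be meaningful. This
contrast is a phantom design constant, not a fitted value.

**Imaging model.** The missing wedge is applied as a hard binary Fourier
mask over the unsampled in-plane directions (default −52°…+64°, the
FIB-lamella tilt range; a cosine soft edge is optional). Noise is white
Gaussian scaled so that `var(signal inside the phantom mask) / var(noise)`
equals the requested SNR; the wedge filters the signal, the noise models
detector/reconstruction noise. Defaults for desk-scale work: 2 nm voxels,
72-voxel boxes (240–300-voxel boxes at ~1 nm voxels, the acquisition-scale
geometry, are supported but not default).

**Dataset simulation** draws diameters uniformly from a range (intact pores:
90–95 nm by default, within the observed 90–135 nm intact span), protomer
dropout as independent Bernoulli per slot (a contiguous-gap mode exists),
in-plane phase uniform, residual shifts uniform ±1.5 voxels, and assigns the
over-stretch class from the true diameter. All stage seeds derive from one
integer seed; identical seeds reproduce datasets bit for bit. The
over-stretch classes follow strict ">" semantics: ≤ 135 nm normal,
135–150 nm over-stretched, > 150 nm disintegrated.

**Nucleus scenes** place non-overlapping ellipsoidal nuclei (semi-axes
~11–16 × 9–13 × 6–8 voxels) on a jittered grid, with uniform interior
intensity per channel, 0–10 planted Gaussian foci (σ 1.5 voxels, amplitude
500 over noise σ 20 — spot SNR 25) at mutually separated interior points,
constant background and Gaussian read noise. The field of view is sparse by
design so that the planted foci occupy well under the top-0.02-percentile
voxel fraction used by the focus threshold; scenes with far denser foci
would need the more inclusive percentile, exactly as dense real datasets do.

## Template matching

For every rotation of the search grid the matcher computes the fast local
(masked) cross-correlation: the numerator correlates the mask-windowed,
zero-mean, unit-norm rotated template; local mean and variance of the volume
under the rotated mask footprint are obtained by FFT; scores are true
correlation coefficients clipped to [−1, 1]. Regions whose local s.d. falls
below 5% of the global s.d. score 0 (flat regions would otherwise divide by
~0). Rotated-template FFTs are cached, so matching a whole dataset costs
three inverse FFTs per rotation per volume. Ring templates are rotated
analytically from the blob model — exact at every grid node; arbitrary
templates fall back to trilinear resampling. Pores are whole-pore aligned
upstream, so the default census searches in-plane rotations only (10°
steps); the full ZXZ grid is available.

**Peak threshold.** Peaks must exceed `mean + k·s.d.` (k = 5 by default,
6 in the macrophage profile). The statistics are the stricter of (a) the
best-score field's own mean/s.d. and (b) the pooled mean/s.d. over all
rotations' score fields. The pooled variant keeps the Gaussian-tail meaning
of the k-s.d. rule independent of how many rotations were maximised over;
the field variant guards against structured backgrounds whose best-score
field is broad. For a single-rotation search both coincide. A candidate
also needs ≥ 2 voxels above the `(k−1)·s.d.` support level in its 3×3×3
neighborhood — a genuine matched-filter maximum carries near-threshold
neighbors over the template correlation length, a bare statistical
exceedance is a single voxel.

**Architecture-consistency filters** (the algorithmic replacement for the
visual inspection step of interactive workflows; every rule is a fixed
geometric statement about the pore architecture, none is fitted to data):

1. orientation: the peak's rotation must map the template axis to within
   30° of the pore axis and the radial axis to within 17° of the outward
   direction at the peak (with analytically rotated templates the recovered
   spin is accurate to about one grid step; measured true-peak tangential
   errors stay below ~14° down to SNR 0.3, while membrane matches spread
   much wider);
2. position: per-ring axial windows (CR +10…+26 nm, IR ±7 nm, NR −26…−10 nm
   about the pore midplane) and radius annuli (bracketing the ring radii of
   intact 90–105 nm pores; widened for dilation-series analyses);
3. competition: a peak is discarded if a membrane-decoy template (a Gaussian
   sheet swept over tilts 0–45° and azimuths) explains its voxel at least as
   well, or if another ring's template scores at least as high at the same
   voxel (winner-take-all across the three rings);
4. non-maximum suppression last (radius 0.6 × the inter-protomer arc of the
   smallest plausible symmetry at the smallest intact diameter ≈ 9 voxels),
   after the consistency filters, so that geometrically implausible high
   scorers cannot shadow true protomers.

**Census.** Counts are capped at n keeping the highest-cc peaks; slot angles
and the largest angular gap are measured about the axis fitted to the IR
peaks; particles with fewer than five IR peaks are discarded (symmetry
unjudgeable). An optional second-pass refinement re-filters peaks against
the pore's own fitted geometry (pooled-ring circle center, median IR radius);
it is off by default because partial-arc fits on heavy-dropout pores are
less reliable than the fixed architecture windows.

## Alignment, averaging, symmetry

`align_particle` is a purely exhaustive search: for each rotation the
particle is resampled and the translation found as the circular FFT
cross-correlation argmax within the allowed range; scores are global
zero-mean correlation coefficients; ties resolve to the smallest shift.
Exhaustiveness makes the search exactly equivalent to brute-force
enumeration — asserted, pose-for-pose, in the validation battery.

Averages are equal-weight sums of pose-resampled particles; imposed Cn
symmetry averages the n axial rotations of the mean. On a voxel lattice no
nontrivial density can be exactly invariant under resampled 45° rotation, so
the invariance contract is stated through the operator: the angle set
{phase + 360k/n} is invariant (mod 360) under adding 360/n, hence
`symmetrize(v, n, phase=360/n)` is numerically identical to
`symmetrize(v, n)` — rotating the symmetrised density by one symmetry step,
evaluated from the source, changes nothing. Resampling the output grid
instead incurs ordinary interpolation error, as for any lattice density.
Resolution is measured by Fourier shell correlation against the clean
phantom with the 0.5 threshold (linear interpolation between shells). No
per-particle wedge compensation is applied beyond the common wedge (a
documented limitation; all phantoms share one wedge).

Symmetry determination has two routes. The oversampled collapse seeds 60
positions on the pore circumference and, for 16 cycles, re-aligns a
reference-sized crop at each seed (reference oriented tangentially for the
seed's azimuth, ±5-voxel shift search, ties stay put); seeds drift onto the
true protomer slots and single-linkage clustering at 0.4 × the smallest-
symmetry arc spacing counts them. Reference-based classification aligns the
whole pore against C7/C8/C9 references under a seeded random pose
perturbation per repeat and votes; the default comparison is the azimuthal
comb profile — a cylindrical (θ, z) resampling of the ring annulus with the
per-z azimuthal mean removed. Subtracting the rotational average leaves the
n-fold protomer comb, and combs of different order are (nearly) orthogonal
over the circle, so cross-symmetry scores sit close to zero while the dense
1° azimuthal alignment avoids the phase-quantisation loss of a coarse
rotation grid. A full 3D volume-alignment route is retained as an option.
References are built as per-class Cn-symmetrised averages; ground-truth
labels and poses stand in for the manual pre-sort and upstream whole-pore
alignment of the original workflow.

## Geometry

Circle fits use total-least-squares plane fitting followed by the algebraic
Kåsa circle fit; opposing-pair diameters average the n/2 opposite-protomer
distances of a complete even-n ring (odd or incomplete rings fall back to
the circle fit with a warning). Membrane openings are traced at the fusion
crest: per azimuth, the radial density profile of the midplane slab is
scanned for its maximum with parabolic sub-voxel refinement, and the opening
diameter is the maximum Feret chord of the rim polygon (a binary opening
mask is also accepted). Envelope thickness is the distance between the two
sheet apexes of the axial intensity profile far from the pore, again with
parabolic refinement. The buffer model is closed-form: area ratio (d1/d0)²,
surface increase f0·(ratio − 1), with the non-pore membrane area held fixed.

## Nucleus imaging

Segmentation: global Otsu threshold, 26-connected components, minimum-volume
filter. Focus detection: 3D median filter (3×3×3), one intensity threshold
per dataset at the top 0.02 percentile of the pooled voxel histogram
(0.1 for high-signal datasets; "top 0.02 percentile" means the brightest
0.02% of voxels — on 10⁶ voxels, the value of the 200th-brightest voxel),
26-connected components, components larger than three voxels counted for the
nucleus containing their centroid. The flatness index is the bounding-box
height divided by the shorter horizontal extent; values above 3 are flagged
segmentation outliers and excluded from summaries. Cohort percentages use
≥ 5 foci (inclusive), mean YAP intensity > 3,000 (strict) and flatness
< 0.8 (strict), with per-replicate means when replicate ids are present.

## Validation battery and problem sizes

The standing experiments (in `npcensus.benchmarks`, asserted by
`tests/test_acceptance.py` and recomputed by `scripts/acceptance.py`):

* surface buffer: closed form at f0 = 0.10, 90 → 130 nm;
* symmetry recovery: 60 phantoms (20 each C7/C8/C9, 95 nm, 96³ boxes,
  SNR 0.3, −52…+64° wedge), references from the same particles via truth
  labels, 4-repeat unanimous voting;
* census exactness: 100 noise-free phantoms (7/8/9-fold mixed, 90–95 nm,
  72³ boxes) with Bernoulli dropout (CR/NR 0.25, IR 0.1); plus 100 matched
  noise-only volumes through the identical pipeline, which must yield no
  peaks at the 5-s.d. threshold;
* diameter recovery: 90–160 nm in 5 nm steps, 5 phantoms each, SNR 0.5,
  100³ boxes, IR-ring matching at 15° with a widened radius annulus;
  circle-fit error against truth and the exactness of the 135/150 nm class
  boundaries;
* alignment oracle: 20 random 32³ instances, 90° grid, ±2-voxel shifts —
  exact pose agreement between the FFT search and direct enumeration;
* averaging: 32 copies at SNR 0.25, C8-symmetrised average vs clean truth
  (FSC at 0.5) against every single particle, plus the exact phase-shift
  invariance;
* imaging: 3 replicates × 50 nuclei, planted foci 0–10; ≥ 5-foci
  classification accuracy, worst flatness error, percentile rank exactness.

These sizes keep the full battery within desk-scale runtimes while matching
the study-like conditions above; they are the package's chosen benchmark
conditions, stated here so results are interpretable.

**What passing shows — and does not.** The phantoms share the generator's
idealisations: protomers are identical rigid blob clusters, the membrane is
an analytic surface, noise is white and Gaussian, the wedge is common to all
particles, and pores are pre-aligned to the axis with only small residual
poses. Real tomograms add CTF modulation, structured (non-white) noise,
neighbouring densities, segmentation errors and alignment failures. Passing
the battery therefore demonstrates that the *procedures* are implemented
correctly and are statistically well-calibrated under controlled conditions,
not that their sensitivity/specificity transfers unchanged to any real
dataset; on real data the thresholds (k-s.d., tolerances, windows) are the
tunable surface, and all of them live in `PipelineConfig`.

## Known limitations

* Tomographic reconstruction, CTF modelling and dose weighting are out of
  scope; inputs are assumed reconstructed, aligned subvolumes.
* The census assumes whole-pore alignment upstream (axis ≈ z); strongly
  tilted pores require the full rotation grid and looser windows.
* The membrane decoy models sheets up to 45° tilt; near-vertical membrane
  at the fusion crest is handled by the position windows instead.
* FSC uses a single common mask-free comparison; no per-shell noise
  weighting.
* The nucleus segmentation is a deliberately simple Otsu + components
  chain; crowded or touching nuclei need a dedicated instance segmenter.
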