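"""Ground-truth benchmark battery.

Each function simulates a study-like condition with the phantom generator,
runs the corresponding analysis end to end, and returns the measured
figures of merit as a plain dict.  All randomness derives from the ``seed``
argument, so a run is reproducible bit for bit.

These are the package's standing validation experiments:

* the analytic surface-area buffer of pore dilation;
* symmetry recovery on a 7/8/9-fold mixture at SNR 0.3 under the missing
  wedge;
* census exactness on noise-free dropout phantoms plus the false-positive
  control on matched noise-only volumes;
* diameter recovery and over-stretch classification across a 90-160 nm
  dilation series at SNR 0.5;
* equivalence of the FFT alignment search with a brute-force enumeration;
* resolution gain of symmetrised multi-particle averaging (FSC at 0.5);
* focus counting / flatness recovery on synthetic nucleus stacks.
"""

from __future__ import annotations

import numpy as np

from .averaging import ParticleSet, align_particle, average_particles, fsc_resolution_nm, symmetrize
from .census import census_from_peaks, classify_opening, fit_ring_circle, surface_buffer
from .config import paper_defaults
from .matching import ThreeRingConfig, TemplateMatcher, build_membrane_decoy, run_three_ring_tm
from .pipeline import build_matchers
from .synthetic import (DesignGroup, build_phantom, build_protomer_template, render_npc,
                        make_nucleus_scene, render_nucleus_stack, simulate_dataset)
from .volumes import Pose, Rotation, Volume, WedgeSpec, make_inplane_grid, transform

STUDY_WEDGE = WedgeSpec(-52.0, 64.0)


def surface_buffer_values(f0: float = 0.10, d0_nm: float = 90.0, d1_nm: float = 130.0) -> dict:
    """The dilation buffer arithmetic: per-pore area ratio and fractional
    nuclear-surface increase for a 90 -> 130 nm dilation at 10% NPC area."""
    ratio, increase = surface_buffer(f0, d0_nm, d1_nm)
    return {"area_ratio": ratio, "surface_increase_pct": 100.0 * increase, "n": 1}


def symmetry_recovery(seed: int = 0, n_per_class: int = 20, snr: float = 0.3,
                      box_voxels: int = 96, voxel_size_nm: float = 2.0,
                      diameter_nm: float = 95.0) -> dict:
    """Classify a seeded 7/8/9-fold mixture rendered under the study wedge.

    References are built from the same particles using the ground-truth
    class labels and poses (the synthetic stand-in for whole-pore alignment
    and the manual pre-sort); classification is 4-repeat unanimous voting.
    """
    rng = np.random.default_rng(seed)
    parts, labels, align = [], [], []
    k = 0
    for n in (7, 8, 9):
        for _ in range(n_per_class):
            sh = rng.uniform(-1.5, 1.5, 3)
            phase = float(rng.uniform(0.0, 360.0))
            ph = build_phantom(n, diameter_nm,
                               pose=Pose(shift=sh, rotation=Rotation.about_z(phase)))
            res = render_npc(ph, box_voxels, voxel_size_nm, snr=snr, wedge=STUDY_WEDGE,
                             seed=int(rng.integers(2**31 - 1)))
            parts.append(res.volume)
            labels.append(n)
            align.append(Pose(shift=-sh, rotation=Rotation.about_z(-phase)))
            k += 1
    ps = ParticleSet(parts, align)
    from .symmetry import build_class_references, classify_by_reference

    refs = build_class_references(ps, labels, (7, 8, 9))
    correct = ambiguous = confusions = 0
    for i, (v, lab) in enumerate(zip(parts, labels)):
        call = classify_by_reference(v, refs, repeats=4, seed=seed * 100003 + i)
        if call.label == "ambiguous":
            ambiguous += 1
        elif call.label == lab:
            correct += 1
        else:
            confusions += 1
    n_calls = correct + confusions
    return {
        "accuracy_pct": 100.0 * correct / n_calls if n_calls else 0.0,
        "cross_confusions": confusions,
        "n_ambiguous": ambiguous,
        "n": len(parts),
    }


def _study_matchers(config=None, box_voxels: int = 72):
    cfg = config or paper_defaults()
    matchers = build_matchers(cfg, box_voxels=box_voxels)
    decoy = build_membrane_decoy(cfg.voxel_size_nm, (box_voxels,) * 3)
    return cfg, matchers, decoy


def census_exactness(seed: int = 0, n_phantoms: int = 100, n_noise: int = 100,
                     box_voxels: int = 72) -> dict:
    """Noise-free census exactness plus the noise-only false-positive control.

    Phantoms mix 7/8/9-fold symmetries with random per-ring protomer dropout;
    the detected (CR, IR, NR) counts are compared with the planted truth.
    Matched noise-only volumes run through the identical three-ring pipeline
    at the 5-s.d. threshold and should yield no peaks at all.
    """
    cfg, matchers, decoy = _study_matchers(box_voxels=box_voxels)
    tm_cfg = ThreeRingConfig()
    per = [n_phantoms - 2 * (n_phantoms // 3), n_phantoms // 3, n_phantoms // 3]
    design = [DesignGroup(n_pores=p, symmetry_n=n, diameter_nm=(90.0, 95.0),
                          dropout={"CR": 0.25, "NR": 0.25, "IR": 0.1})
              for p, n in zip(per, (7, 8, 9))]
    results, manifest = simulate_dataset(design, box_voxels=box_voxels,
                                         voxel_size_nm=cfg.voxel_size_nm,
                                         seed=seed, shift_jitter_voxels=1.5)
    exact = 0
    for res, row in zip(results, manifest.itertuples()):
        peaks = run_three_ring_tm(res.volume, {}, {}, tm_cfg, matchers=matchers,
                                  decoy_matcher=decoy)
        c = census_from_peaks(peaks, row.symmetry_n)
        exact += (c.counts["CR"] == row.cr_count and c.counts["IR"] == row.ir_count
                  and c.counts["NR"] == row.nr_count)
    zero = 0
    total_peaks = 0
    for i in range(n_noise):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, i]))
        nv = Volume(rng.normal(size=(box_voxels,) * 3).astype(np.float32),
                    cfg.voxel_size_nm)
        peaks = run_three_ring_tm(nv, {}, {}, tm_cfg, matchers=matchers,
                                  decoy_matcher=decoy)
        count = sum(len(p) for p in peaks.values())
        total_peaks += count
        zero += count == 0
    return {
        "exact_pct": 100.0 * exact / n_phantoms,
        "noise_zero_pct": 100.0 * zero / n_noise,
        "noise_mean_peaks": total_peaks / n_noise,
        "n": n_phantoms,
    }


def diameter_recovery(seed: int = 0, n_per_diameter: int = 5, snr: float = 0.5,
                      box_voxels: int = 100, voxel_size_nm: float = 2.0) -> dict:
    """Dilation series 90 -> 160 nm in 5 nm steps at SNR 0.5.

    Per phantom the IR protomers are detected by template matching and a
    least-squares circle is fitted; the figure of merit is the worst absolute
    diameter error.  Over-stretch classes must change exactly at the >135 nm
    and >150 nm boundaries of the series.
    """
    from .synthetic import analytic_protomer_rotator

    cfg = paper_defaults()
    tpl, mask = build_protomer_template("IR", voxel_size_nm)
    rots = make_inplane_grid(15.0)
    matchers = {"IR": TemplateMatcher(tpl, mask, rots, (box_voxels,) * 3,
                                      rotator=analytic_protomer_rotator("IR", voxel_size_nm))}
    decoy = build_membrane_decoy(voxel_size_nm, (box_voxels,) * 3,
                                 azimuth_step_deg=45.0)
    tm_cfg = ThreeRingConfig(angular_increment_deg=15.0,
                             ring_r_windows_nm={"CR": (35.0, 86.0), "IR": (39.0, 88.0),
                                                "NR": (37.0, 86.0)})
    rng = np.random.default_rng(seed)
    errors = []
    n_fit = 0
    classes_ok = True
    diameters = np.arange(90.0, 160.0 + 1e-9, 5.0)
    for d in diameters:
        for _ in range(n_per_diameter):
            sh = rng.uniform(-1.0, 1.0, 3)
            phase = float(rng.uniform(0.0, 360.0))
            ph = build_phantom(8, float(d),
                               pose=Pose(shift=sh, rotation=Rotation.about_z(phase)))
            res = render_npc(ph, box_voxels, voxel_size_nm, snr=snr,
                             wedge=STUDY_WEDGE, seed=int(rng.integers(2**31 - 1)))
            peaks = run_three_ring_tm(res.volume, {}, {}, tm_cfg, matchers=matchers,
                                      decoy_matcher=decoy)["IR"]
            peaks = sorted(peaks, key=lambda p: -p.cc)[:8]
            if len(peaks) >= 3:
                pos = np.stack([p.position for p in peaks])
                _, radius_nm, _ = fit_ring_circle(pos, voxel_size_nm)
                errors.append(abs(2.0 * radius_nm - d))
                n_fit += 1
        expected = ("normal" if d <= 135 else
                    "over_stretched" if d <= 150 else "disintegrated")
        classes_ok &= classify_opening(float(d)) == expected
    errors = np.asarray(errors)
    return {
        "max_abs_error_nm": float(errors.max()),
        "mean_abs_error_nm": float(errors.mean()),
        "fit_fraction_pct": 100.0 * n_fit / (len(diameters) * n_per_diameter),
        "class_boundaries_exact": int(classes_ok),
        "n": int(len(diameters) * n_per_diameter),
    }


def _brute_force_align(subvol: Volume, reference: Volume, shift_range: int,
                       rotations) -> tuple[Pose, float]:
    """Independent enumeration over every (rotation, circular shift) pair."""
    ref0 = reference.data.astype(np.float64) - float(reference.data.mean())
    nref = float(np.linalg.norm(ref0))
    shifts = [(sx, sy, sz)
              for sx in range(-shift_range, shift_range + 1)
              for sy in range(-shift_range, shift_range + 1)
              for sz in range(-shift_range, shift_range + 1)]
    shifts.sort(key=lambda s: s[0] ** 2 + s[1] ** 2 + s[2] ** 2)
    best = (-np.inf, None, None)
    for rot in rotations:
        a = transform(subvol, Pose(rotation=rot)).data.astype(np.float64)
        a0 = a - a.mean()
        na = float(np.linalg.norm(a0))
        for sx, sy, sz in shifts:
            b = np.roll(a0, (sz, sy, sx), axis=(0, 1, 2))
            cc = float(np.dot(b.ravel(), ref0.ravel()) / (na * nref))
            if cc > best[0]:
                best = (cc, (sx, sy, sz), rot)
    cc, s, rot = best
    return Pose(shift=np.array(s, dtype=float), rotation=rot), cc


def alignment_oracle(seed: int = 0, n_instances: int = 20, box_voxels: int = 32,
                     shift_range: int = 2) -> dict:
    """Exact agreement of the FFT alignment with brute-force enumeration.

    Random smooth references are displaced by a random 90°-grid rotation and
    integer shift; both search routes must return the identical pose, and
    their correlations must agree to floating-point accuracy.
    """
    from scipy.ndimage import gaussian_filter

    from .volumes import make_rotation_grid

    grid = make_rotation_grid(90.0)
    agree = 0
    max_cc_diff = 0.0
    for i in range(n_instances):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31337, i]))
        ref = Volume(gaussian_filter(
            rng.normal(size=(box_voxels,) * 3), 1.5).astype(np.float32), 2.0)
        true_rot = grid[int(rng.integers(len(grid)))]
        true_shift = rng.integers(-shift_range, shift_range + 1, size=3).astype(float)
        subvol = transform(transform(ref, Pose(rotation=true_rot.inverse())),
                           Pose(shift=-true_shift))
        pose_a, cc_a = align_particle(subvol, ref, shift_range, grid)
        pose_b, cc_b = _brute_force_align(subvol, ref, shift_range, grid)
        same = (np.array_equal(pose_a.shift, pose_b.shift)
                and np.abs(pose_a.rotation.as_matrix()
                           - pose_b.rotation.as_matrix()).max() < 1e-9)
        agree += same
        max_cc_diff = max(max_cc_diff, abs(cc_a - cc_b))
    return {"agreement_pct": 100.0 * agree / n_instances,
            "max_cc_difference": max_cc_diff, "n": n_instances}


def averaging_resolution(seed: int = 0, n_particles: int = 32, snr: float = 0.25,
                         box_voxels: int = 72, voxel_size_nm: float = 2.0) -> dict:
    """Symmetrised averaging of noisy copies sharpens the FSC-0.5 resolution.

    Thirty-two wedge-filtered SNR-0.25 copies at known random poses are
    averaged with imposed C8 symmetry; the average's FSC-at-0.5 resolution
    against the clean phantom must be finer than that of every single
    particle, and the symmetrised density must be exactly C8-invariant under
    a symmetry-step phase shift of the averaging operator.
    """
    clean = render_npc(build_phantom(8, 95.0), box_voxels, voxel_size_nm).volume
    rng = np.random.default_rng(seed)
    parts, poses = [], []
    for i in range(n_particles):
        sh = rng.uniform(-1.5, 1.5, 3)
        phase = float(rng.uniform(0.0, 360.0))
        ph = build_phantom(8, 95.0, pose=Pose(shift=sh, rotation=Rotation.about_z(phase)))
        res = render_npc(ph, box_voxels, voxel_size_nm, snr=snr, wedge=STUDY_WEDGE,
                         seed=int(rng.integers(2**31 - 1)))
        parts.append(res.volume)
        poses.append(Pose(shift=-sh, rotation=Rotation.about_z(-phase)))
    ps = ParticleSet(parts, poses)
    avg = average_particles(ps, symmetry_n=8)
    res_avg = fsc_resolution_nm(avg, clean)
    res_singles = [fsc_resolution_nm(transform(parts[i], poses[i]), clean)
                   for i in range(n_particles)]
    shifted = symmetrize(average_particles(ps, symmetry_n=1), 8, phase_deg=45.0)
    base = symmetrize(average_particles(ps, symmetry_n=1), 8)
    inv = float(np.abs(shifted.data - base.data).max() / np.abs(base.data).max())
    return {
        "fsc_avg_nm": res_avg,
        "fsc_best_single_nm": float(min(res_singles)),
        "resolution_gain_nm": float(min(res_singles)) - res_avg,
        "symmetry_invariance_residual": inv,
        "n": n_particles,
    }


def imaging_recovery(seed: int = 0, n_replicates: int = 3, n_nuclei: int = 50) -> dict:
    """Focus-count and flatness recovery on synthetic nucleus stacks.

    Three replicates of 50 nuclei with 0-10 planted foci each are segmented
    and quantified with the standard chain (Otsu 3D segmentation, dataset
    top-0.02-percentile focus threshold on median-filtered stacks, foci
    larger than three voxels).  Reports the >= 5-foci classification
    accuracy, the worst flatness error against the analytic truth, and the
    exactness of the percentile rank rule (the 200th-brightest voxel of a
    million at the 0.02 top percentile).
    """
    from skimage.measure import regionprops

    from .imaging import (dataset_focus_threshold, detect_foci, measure_nuclei,
                          segment_nuclei_3d)

    ok = tot = 0
    flat_err = []
    for rep in range(n_replicates):
        scene = make_nucleus_scene(n_nuclei, seed=seed * 1009 + rep)
        stack, truth = render_nucleus_stack(scene)
        labels = segment_nuclei_3d(stack[0])
        thr = dataset_focus_threshold([stack[1]], 0.02)
        foci = detect_foci(stack[1], labels, threshold=thr)
        rec = measure_nuclei(labels, {"damage": stack[1], "yap": stack[2]},
                             {"damage": foci}, replicate=rep)
        centroids = {p.label: np.array([p.centroid[2], p.centroid[1], p.centroid[0]])
                     for p in regionprops(labels)}
        for _, trow in truth.iterrows():
            tc = np.array([trow.center_x, trow.center_y, trow.center_z])
            lab = min(centroids, key=lambda l: np.linalg.norm(centroids[l] - tc))
            r = rec[rec.label == lab].iloc[0]
            tot += 1
            ok += (r.foci_damage >= 5) == (trow.foci_damage >= 5)
            flat_err.append(abs(r.flatness - trow.flatness))
    vals = np.random.default_rng(seed).permutation(10**6).astype(np.float64)
    thr = dataset_focus_threshold([vals.reshape(100, 100, 100)], 0.02, median_radius=0)
    rank_exact = int(thr == np.sort(vals)[-200])
    return {
        "foci_class_accuracy_pct": 100.0 * ok / tot,
        "flatness_max_abs_error": float(max(flat_err)),
        "percentile_rank_exact": rank_exact,
        "n": tot,
    }
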