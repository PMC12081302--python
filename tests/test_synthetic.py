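"""Phantom generator: templates, renders, dataset simulation, nucleus scenes."""

import numpy as np
import pytest

from npcensus.errors import GeometryError, ParameterError
from npcensus.synthetic import (DesignGroup, MembraneSpec, NucleusScene, NucleusSpec,
                                _draw_missing, build_phantom, build_protomer_template,
                                make_nucleus_scene, render_npc, render_nucleus_stack,
                                simulate_dataset)
from npcensus.volumes import FULL_WEDGE, Pose, Rotation, Volume, WedgeSpec, bin_volume, transform


def masked_cc(a, b, mask=None):
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if mask is not None:
        m = mask.ravel() > 0
        a, b = a[m], b[m]
    a -= a.mean()
    b -= b.mean()
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def rotated_cc(tpl, rot):
    r = transform(tpl, Pose(rotation=rot), fill=0.0)
    return masked_cc(tpl.data, r.data)


class TestProtomerTemplates:
    def test_deterministic(self):
        a, _ = build_protomer_template("IR", 2.0)
        b, _ = build_protomer_template("IR", 2.0)
        assert np.array_equal(a.data, b.data)

    def test_voxel_size_precondition(self):
        with pytest.raises(ParameterError):
            build_protomer_template("IR", 5.0)

    @pytest.mark.parametrize("ring", ["CR", "IR", "NR"])
    def test_mask_contains_mass(self, ring):
        tpl, mask = build_protomer_template(ring, 2.0)
        inside = float(tpl.data[mask.data > 0].sum())
        assert inside >= 0.99 * float(tpl.data.sum())

    def test_rings_distinguishable(self):
        """Best-alignment cross-correlation between ring templates stays < 0.8."""
        tpls = {r: build_protomer_template(r, 2.0)[0] for r in ("CR", "IR", "NR")}
        for a, b in (("CR", "NR"), ("CR", "IR"), ("IR", "NR")):
            best = -1.0
            for phi in range(0, 360, 20):
                for theta in (0, 45, 90, 135, 180):
                    r = transform(tpls[a], Pose(rotation=Rotation(phi, theta, 0)), fill=0.0)
                    best = max(best, masked_cc(r.data, tpls[b].data))
            assert best < 0.8, f"{a} vs {b}: {best:.3f}"

    @pytest.mark.parametrize("ring", ["CR", "IR", "NR"])
    def test_orientation_identifiability_margin(self, ring):
        """Autocorrelation margin >= 0.1 against the nearest 10°-grid rotations
        (the global non-identity maximum of a decaying autocorrelation)."""
        tpl, _ = build_protomer_template(ring, 2.0)
        neighbors = [Rotation.about_z(10), Rotation.about_z(350), Rotation(0, 10, 0),
                     Rotation(10, 10, 0), Rotation(350, 10, 10), Rotation(10, 10, 350),
                     Rotation(0, 10, 350), Rotation(0, 10, 10), Rotation(350, 10, 0)]
        worst = max(rotated_cc(tpl, r) for r in neighbors)
        assert 1.0 - worst >= 0.1

    def test_identifiability_sweep_ir(self):
        """Coarse sweep of the full grid never beats the near-identity nodes."""
        tpl, _ = build_protomer_template("IR", 2.0)
        best = -1.0
        for phi in range(0, 360, 30):
            for theta in (10, 30, 60, 90, 120, 150, 170):
                for psi in range(0, 360, 30):
                    best = max(best, rotated_cc(tpl, Rotation(phi, theta, psi)))
        assert best <= 0.9


class TestPhantom:
    def test_complete_counts(self):
        ph = build_phantom(8, 95.0)
        assert ph.present_counts() == {"CR": 8, "IR": 8, "NR": 8}
        assert all(ph.presence[r].all() for r in ("CR", "IR", "NR"))

    def test_ir_radius_definition(self):
        assert build_phantom(8, 95.0).rings["IR"].radius_nm == pytest.approx(47.5)

    def test_all_cr_missing(self):
        ph = build_phantom(7, 92.0, missing={"CR": range(7)})
        assert ph.present_counts()["CR"] == 0

    def test_bad_missing_slot(self):
        with pytest.raises(ParameterError):
            build_phantom(8, 95.0, missing={"CR": [8]})

    def test_min_symmetry(self):
        with pytest.raises(ParameterError):
            build_phantom(2, 95.0)


class TestRender:
    def test_deterministic(self):
        ph = build_phantom(8, 95.0)
        a = render_npc(ph, 72, 2.0, snr=0.5, wedge=WedgeSpec(-52, 64), seed=3)
        b = render_npc(ph, 72, 2.0, snr=0.5, wedge=WedgeSpec(-52, 64), seed=3)
        assert np.array_equal(a.volume.data, b.volume.data)

    def test_box_too_small(self):
        with pytest.raises(GeometryError):
            render_npc(build_phantom(8, 160.0), 72, 2.0)

    def test_matched_filter_finds_planted_slots(self, clean_c8_render):
        """Noise-free, full-wedge render: masked-CC argmax of the protomer
        template lies within 1 voxel of every planted IR slot center."""
        from npcensus.matching import match_template
        from npcensus.volumes import make_inplane_grid

        res = clean_c8_render
        tpl, mask = build_protomer_template("IR", 2.0)
        sv = match_template(res.volume, tpl, mask, make_inplane_grid(45.0))
        ph = res.phantom
        c = res.volume.center_xyz
        peak = float(sv.cc.max())
        for s in range(8):
            p = ph.slot_position_xyz_nm("IR", s) / 2.0 + c
            local = sv.cc[int(p[2]) - 1:int(p[2]) + 2,
                          int(p[1]) - 1:int(p[1]) + 2,
                          int(p[0]) - 1:int(p[0]) + 2]
            assert local.max() >= 0.95 * peak

    def test_realized_snr(self):
        ph = build_phantom(8, 95.0)
        res = render_npc(ph, 72, 2.0, snr=0.5, wedge=WedgeSpec(-52, 64), seed=1)
        assert res.realized_snr() == pytest.approx(0.5, rel=0.10)

    def test_protomer_conservation(self):
        """Total protomer mass scales with the number of planted slots."""
        full = render_npc(build_phantom(8, 95.0,
                                        membrane=MembraneSpec(amplitude=0.0,
                                                              opening_radius_nm=47.5)),
                          64, 2.0).volume.data.sum()
        half = render_npc(build_phantom(8, 95.0, missing={"CR": [0, 1], "IR": [2], "NR": [3]},
                                        membrane=MembraneSpec(amplitude=0.0,
                                                              opening_radius_nm=47.5)),
                          64, 2.0).volume.data.sum()
        assert half / full == pytest.approx(20 / 24, rel=0.02)

    def test_scale_consistency(self):
        """Rendering at half voxel size and binning by 2 matches the coarse render."""
        ph = build_phantom(8, 95.0)
        coarse = render_npc(ph, 72, 2.0).volume
        fine = render_npc(ph, 144, 1.0).volume
        assert masked_cc(bin_volume(fine, 2).data, coarse.data) >= 0.95


class TestSimulateDataset:
    def test_manifest_counts_no_dropout(self):
        results, man = simulate_dataset([DesignGroup(n_pores=4, symmetry_n=8)],
                                        box_voxels=72, seed=0)
        assert len(man) == 4
        assert (man[["cr_count", "ir_count", "nr_count"]] == 8).all().all()

    def test_empty_design_rejected(self):
        with pytest.raises(ParameterError):
            simulate_dataset([], box_voxels=72)

    def test_determinism(self):
        _, a = simulate_dataset([DesignGroup(n_pores=3, dropout={"CR": 0.3})], seed=5)
        _, b = simulate_dataset([DesignGroup(n_pores=3, dropout={"CR": 0.3})], seed=5)
        assert a.drop(columns=["stretch_class"]).equals(b.drop(columns=["stretch_class"]))

    def test_dropout_binomial_fraction(self):
        """Bernoulli(0.5) dropout over 1,000 slots lands in the 3-sigma CI."""
        rngs = [np.random.default_rng(i) for i in range(125)]
        present = sum(8 - len(_draw_missing(r, 8, 0.5, False)) for r in rngs)
        frac = present / 1000.0
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 1000)

    def test_stretch_classes_from_diameters(self):
        design = [DesignGroup(n_pores=1, symmetry_n=8, diameter_nm=(d, d))
                  for d in (120.0, 140.0, 160.0)]
        _, man = simulate_dataset(design, box_voxels=96, seed=1, shift_jitter_voxels=0.5)
        assert man.stretch_class.tolist() == ["normal", "over_stretched", "disintegrated"]


class TestNucleusScenes:
    def test_zero_foci_truth(self):
        scene = make_nucleus_scene(4, seed=0, foci_range=(0, 0))
        _, truth = render_nucleus_stack(scene)
        assert (truth.foci_damage == 0).all()

    def test_flatness_truth_axis_aligned(self):
        nuc = NucleusSpec(center=np.zeros(3), semi_axes=np.array([10.0, 8.0, 4.0]))
        assert nuc.flatness() == pytest.approx(0.5)

    def test_overlapping_nuclei_rejected(self):
        a = NucleusSpec(center=np.array([20.0, 20, 20]), semi_axes=np.array([8.0, 8, 4]))
        b = NucleusSpec(center=np.array([24.0, 20, 20]), semi_axes=np.array([8.0, 8, 4]))
        scene = NucleusScene(shape=(40, 48, 48), nuclei=[a, b])
        with pytest.raises(GeometryError):
            render_nucleus_stack(scene)

    def test_planted_marker_intensity_recovered(self):
        scene = make_nucleus_scene(4, seed=2, noise_sigma=25.0)
        for n in scene.nuclei:
            n.intensity["yap"] = 3500.0
        stack, truth = render_nucleus_stack(scene)
        nuc = scene.nuclei[0]
        zz, yy, xx = np.indices(scene.shape, dtype=float)
        a, b, c = nuc.semi_axes
        inside = (((xx - nuc.center[0]) / a) ** 2 + ((yy - nuc.center[1]) / b) ** 2
                  + ((zz - nuc.center[2]) / c) ** 2) <= 1.0
        measured = stack[2][inside].mean() - scene.background
        assert measured == pytest.approx(3500.0, rel=0.05)

    def test_determinism(self):
        a, _ = render_nucleus_stack(make_nucleus_scene(4, seed=7))
        b, _ = render_nucleus_stack(make_nucleus_scene(4, seed=7))
        assert np.array_equal(a, b)
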