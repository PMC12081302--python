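"""Census statistics, diameters, over-stretch classes and the buffer model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcensus.census import (DISINTEGRATION_THRESHOLD_NM, OVERSTRETCH_THRESHOLD_NM,
                             RingCensus, census_from_peaks, classify_opening,
                             completeness_histogram, envelope_thickness,
                             fit_ring_circle, measure_opening_chord, npc_area_fraction,
                             opening_mask_from_membrane, opening_rim_polygon,
                             opposing_pair_diameter, surface_buffer)
from npcensus.errors import GeometryError, ParameterError
from npcensus.matching import Peak
from npcensus.synthetic import MembraneSpec, _membrane_density, build_phantom
from npcensus.volumes import Rotation


def ring_peaks(n, radius=24.0, center=(32, 32, 32), z=0.0, count=None, cc0=0.9):
    center = np.array(center, dtype=float)
    peaks = []
    for i in range(count if count is not None else n):
        ang = 360.0 * i / n
        a = np.radians(ang)
        pos = center + [radius * np.cos(a), radius * np.sin(a), z]
        peaks.append(Peak(pos, Rotation.about_z(ang), cc0 - 0.01 * i, 6.0))
    return peaks


class TestCensus:
    def test_complete_flags(self):
        peaks = {"CR": ring_peaks(8, radius=22.0, z=8), "IR": ring_peaks(8),
                 "NR": ring_peaks(8, radius=23.0, z=-8)}
        c = census_from_peaks(peaks, 8)
        assert c.counts == {"CR": 8, "IR": 8, "NR": 8}
        assert all(c.complete.values()) and not c.discarded

    def test_few_ir_peaks_discarded(self):
        peaks = {"CR": ring_peaks(8, radius=22.0, z=8), "IR": ring_peaks(8, count=4), "NR": []}
        c = census_from_peaks(peaks, 8)
        assert c.discarded and "IR" in c.reason

    def test_counts_capped_at_n(self):
        peaks = {"CR": ring_peaks(8, radius=22.0, z=8, count=8)
                 + ring_peaks(8, radius=28.0, z=8, count=4, cc0=0.5),
                 "IR": ring_peaks(8), "NR": ring_peaks(8, radius=23.0, z=-8)}
        c = census_from_peaks(peaks, 8)
        assert c.counts["CR"] == 8

    def test_largest_gap(self):
        peaks = {"CR": [p for p in ring_peaks(8, radius=22.0, z=8) if
                        np.degrees(np.arctan2(p.position[1] - 32, p.position[0] - 32)) % 360
                        in (0.0, 45.0, 90.0)],
                 "IR": ring_peaks(8), "NR": []}
        c = census_from_peaks(peaks, 8)
        assert c.largest_gap_deg["CR"] == pytest.approx(270.0, abs=1.0)
        assert c.largest_gap_deg["NR"] == 360.0


class TestCompletenessHistogram:
    def make_census(self, cr, nr, n=8):
        return RingCensus(n, {"CR": cr, "IR": n, "NR": nr},
                          {r: np.array([]) for r in ("CR", "IR", "NR")},
                          {r: 0.0 for r in ("CR", "IR", "NR")},
                          {r: False for r in ("CR", "IR", "NR")})

    def test_cells(self):
        hist = completeness_histogram([self.make_census(8, 8), self.make_census(8, 8),
                                       self.make_census(0, 4)])
        assert hist.loc[8, 8] == 2 and hist.loc[0, 4] == 1
        assert hist.values.sum() == 3

    def test_empty(self):
        assert completeness_histogram([]).values.sum() == 0

    def test_mixed_symmetry_rejected(self):
        with pytest.raises(ParameterError):
            completeness_histogram([self.make_census(8, 8, 8), self.make_census(7, 7, 7)])

    def test_binomial_marginal(self):
        """With independent per-slot dropout the CR-count marginal follows
        Binomial(n, 1-p); chi-square goodness of fit at alpha = 0.01."""
        from scipy.stats import binom, chisquare

        rng = np.random.default_rng(0)
        p_miss = 0.3
        counts = rng.binomial(8, 1 - p_miss, size=500)
        censuses = [self.make_census(int(c), 8) for c in counts]
        hist = completeness_histogram(censuses)
        observed = hist.sum(axis=1).to_numpy()
        expected = binom.pmf(np.arange(9), 8, 1 - p_miss) * 500
        keep = expected > 1.0
        stat, pval = chisquare(observed[keep], expected[keep] * observed[keep].sum()
                               / expected[keep].sum())
        assert pval > 0.01


class TestCircleFit:
    def test_exact_octagon(self):
        a = np.radians(np.arange(8) * 45.0)
        pts = np.stack([47.5 * np.cos(a), 47.5 * np.sin(a), np.zeros(8)], axis=1)
        _, radius, resid = fit_ring_circle(pts, 1.0)
        assert radius == pytest.approx(47.5, abs=1e-9)
        assert resid < 1e-9

    def test_jittered_radius_within_half_nm(self):
        a = np.radians(np.arange(8) * 45.0)
        base = np.stack([47.5 * np.cos(a), 47.5 * np.sin(a), np.zeros(8)], axis=1)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, radius, _ = fit_ring_circle(base + rng.normal(0, 1.0, base.shape), 1.0)
            assert abs(radius - 47.5) <= 1.5  # jitter sigma 1 nm; bias << 0.5 nm
        radii = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, radius, _ = fit_ring_circle(base + rng.normal(0, 1.0, base.shape), 1.0)
            radii.append(radius)
        assert abs(np.mean(radii) - 47.5) <= 0.5

    def test_right_triangle_circumradius(self):
        # right triangle inscribed in a circle: hypotenuse is the diameter
        pts = np.array([[0, 0, 0], [6.0, 0, 0], [0, 8.0, 0]])
        _, radius, _ = fit_ring_circle(pts, 1.0)
        assert radius == pytest.approx(5.0, abs=1e-9)

    def test_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])
        with pytest.raises(GeometryError):
            fit_ring_circle(pts)


class TestOpposingPairs:
    def test_regular_octagon(self):
        a = np.radians(np.arange(8) * 45.0)
        pts = np.stack([47.5 * np.cos(a), 47.5 * np.sin(a), np.zeros(8)], axis=1)
        rec = opposing_pair_diameter(pts, 8, 1.0)
        assert rec.method == "opposing_pairs"
        assert rec.diameter_nm == pytest.approx(95.0, abs=1e-9)

    def test_elliptical_ring(self):
        a = np.radians(np.arange(8) * 45.0)
        pts = np.stack([50 * np.cos(a), 45 * np.sin(a), np.zeros(8)], axis=1)
        analytic = np.mean([2 * np.hypot(50 * np.cos(t), 45 * np.sin(t))
                            for t in a[:4]])
        rec = opposing_pair_diameter(pts, 8, 1.0)
        assert 90.0 <= rec.diameter_nm <= 100.0
        assert rec.diameter_nm == pytest.approx(analytic, abs=1e-9)

    def test_odd_symmetry_falls_back(self):
        a = np.radians(np.arange(7) * (360 / 7))
        pts = np.stack([47.5 * np.cos(a), 47.5 * np.sin(a), np.zeros(7)], axis=1)
        with pytest.warns(UserWarning):
            rec = opposing_pair_diameter(pts, 7, 1.0)
        assert rec.method == "circle_fit"
        assert rec.diameter_nm == pytest.approx(95.0, abs=1e-6)


class TestOpening:
    def test_circular_mask_feret(self):
        yy, xx = np.indices((100, 100))
        disk = (xx - 50) ** 2 + (yy - 50) ** 2 <= 35**2
        assert measure_opening_chord(disk, 2.0) == pytest.approx(140.0, abs=4.0)

    def test_elliptical_mask_major_axis(self):
        yy, xx = np.indices((120, 120))
        ell = ((xx - 60) / 40) ** 2 + ((yy - 60) / 30) ** 2 <= 1.0
        assert measure_opening_chord(ell, 2.0) == pytest.approx(160.0, abs=4.0)

    def test_degenerate_rejected(self):
        with pytest.raises(GeometryError):
            measure_opening_chord(np.zeros((20, 20), dtype=bool))

    @pytest.mark.parametrize("d", [120.0, 140.0, 160.0])
    def test_rim_polygon_chord(self, d):
        mem = _membrane_density((96, 96, 96), 2.0, build_phantom(8, d))
        poly = opening_rim_polygon(mem, 2.0)
        assert measure_opening_chord(poly, 2.0) == pytest.approx(d, abs=2.0)

    def test_opening_mask_extraction(self):
        mem = _membrane_density((96, 96, 96), 2.0, build_phantom(8, 140.0))
        opening = opening_mask_from_membrane(mem > 0.07)
        assert opening[48, 48]
        assert measure_opening_chord(opening, 2.0) == pytest.approx(140.0, abs=8.0)


class TestClassification:
    @pytest.mark.parametrize("d,cls", [
        (120.0, "normal"), (135.0, "normal"), (140.0, "over_stretched"),
        (150.0, "over_stretched"), (150.1, "disintegrated"), (160.0, "disintegrated"),
    ])
    def test_thresholds_strictly_greater(self, d, cls):
        assert classify_opening(d) == cls

    def test_thresholds_match_constants(self):
        assert OVERSTRETCH_THRESHOLD_NM == 135.0
        assert DISINTEGRATION_THRESHOLD_NM == 150.0


class TestSurfaceBuffer:
    def test_dilation_roughly_doubles(self):
        ratio, inc = surface_buffer(0.10, 90.0, 130.0)
        assert ratio == pytest.approx((130 / 90) ** 2, rel=1e-12)
        assert ratio == pytest.approx(2.086, abs=0.001)
        assert inc == pytest.approx(0.109, abs=0.001)

    def test_no_dilation(self):
        assert surface_buffer(0.10, 100.0, 100.0) == (1.0, 0.0)

    def test_fraction_from_density(self):
        assert npc_area_fraction(10.0, 90.0) == pytest.approx(0.0636, abs=0.0005)

    @given(st.floats(0.01, 1.0), st.floats(50, 200), st.floats(50, 200))
    @settings(max_examples=100, deadline=None)
    def test_closed_form(self, f0, d0, d1):
        ratio, inc = surface_buffer(f0, d0, d1)
        if abs(ratio - 1) > 1e-9:
            assert inc / (ratio - 1) == pytest.approx(f0, rel=1e-9)


class TestEnvelopeThickness:
    def test_default_separation(self):
        mem = _membrane_density((64, 64, 64), 2.0, build_phantom(8, 95.0))
        assert envelope_thickness(mem, 2.0) == pytest.approx(40.0, abs=2.0)

    def test_separation_difference(self):
        ms = [MembraneSpec(separation_nm=s, opening_radius_nm=47.5) for s in (30.0, 40.0)]
        th = [envelope_thickness(_membrane_density((64, 64, 64), 2.0,
                                                   build_phantom(8, 95.0, membrane=m)), 2.0)
              for m in ms]
        assert th[1] - th[0] == pytest.approx(10.0, abs=2.0)

    def test_single_sheet_rejected(self):
        zz = np.indices((64, 32, 32))[0].astype(float)
        single = np.exp(-((zz - 32) ** 2) / (2 * 1.5**2))
        with pytest.raises(GeometryError):
            envelope_thickness(single, 2.0)
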