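"""Region grid construction, stain quantification, fold-change maps, nuclei density."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from valvescale import histo, synthetic
from valvescale.histo import StainQuant, StainedSection
from valvescale.morphometry import SectionGeometry


def _rect_section(L=30.0, th=1.0, n=40):
    x = np.linspace(0, L, n)
    return SectionGeometry(
        atrialis_mm=np.column_stack([x, np.zeros(n)]),
        ventricularis_mm=np.column_stack([x, np.full(n, th)]),
    )


class TestBuildRegionGrid:
    def test_rectangle_band_gives_congruent_cells(self):
        grid = histo.build_region_grid(_rect_section(30.0, 1.0))
        areas = np.array([[p.area for p in row] for row in grid.polygons])
        assert areas.shape == (3, 10)
        assert np.allclose(areas, 1.0, rtol=1e-6)  # 10 mm x 0.1 mm

    def test_partition_conserves_band_area(self):
        grid = histo.build_region_grid(_rect_section())
        total = sum(p.area for row in grid.polygons for p in row)
        assert total == pytest.approx(grid.band.area, rel=1e-3)

    def test_wedge_band_areas_match_trapezoids(self):
        t = synthetic.default_truth(seed=1, thickness_mm_annulus=2.0,
                                    thickness_mm_free_edge=0.5)
        sec = synthetic.gen_section_geometry(t, base="line", length_mm=30.0)
        grid = histo.build_region_grid(sec)
        areas = np.array([[p.area for p in row] for row in grid.polygons])
        # analytic: thickness falls linearly 2.0 -> 0.5 over arc length 30 mm;
        # segment i spans thickness integral 10 * mean thickness / 10 layers
        for i in range(3):
            s0, s1 = i / 3, (i + 1) / 3
            mean_th = 2.0 + (s0 + s1) / 2 * (0.5 - 2.0)
            expect = 10.0 * mean_th / 10.0
            assert np.allclose(areas[i], expect, rtol=0.01)

    def test_crossing_contours_rejected(self):
        x = np.linspace(0, 30, 40)
        sec = SectionGeometry(
            atrialis_mm=np.column_stack([x, np.zeros(40)]),
            ventricularis_mm=np.column_stack([x, np.linspace(-1, 1, 40)]),
        )
        with pytest.raises(ValueError, match="cross"):
            histo.build_region_grid(sec)


class TestQuantifyStain:
    def test_planted_fraction_in_single_region(self, truth):
        f = np.zeros((3, 10))
        f[1, 4] = 0.25
        t = synthetic.default_truth(seed=3, region_positive_fractions=f)
        image, sec, attained = synthetic.gen_ihc_image(t)
        q = histo.quantify_stain(image, histo.build_region_grid(sec))
        assert q.positive_pct[1, 4] == pytest.approx(25.0, abs=1e-9)
        others = q.positive_pct.copy()
        others[1, 4] = 0.0
        assert np.nanmax(others) == 0.0

    def test_all_zero_and_all_positive(self):
        t = synthetic.default_truth(seed=3, region_positive_fractions=np.zeros((3, 10)))
        image, sec, _ = synthetic.gen_ihc_image(t)
        q = histo.quantify_stain(image, histo.build_region_grid(sec))
        assert np.nanmax(q.positive_pct) == 0.0
        t1 = synthetic.default_truth(seed=3, region_positive_fractions=np.ones((3, 10)))
        image1, sec1, _ = synthetic.gen_ihc_image(t1)
        q1 = histo.quantify_stain(image1, histo.build_region_grid(sec1))
        assert np.nanmin(q1.positive_pct) == pytest.approx(100.0)

    def test_random_grid_recovered_exactly(self):
        t = synthetic.default_truth(seed=9)
        image, sec, attained = synthetic.gen_ihc_image(t)
        q = histo.quantify_stain(image, histo.build_region_grid(sec))
        assert np.allclose(q.positive_pct / 100.0, attained, atol=1e-12)

    def test_partition_conservation_exact(self):
        t = synthetic.default_truth(seed=9)
        image, sec, _ = synthetic.gen_ihc_image(t)
        q = histo.quantify_stain(image, histo.build_region_grid(sec))
        assert q.total_counts.sum() == image.tissue.sum()

    def test_exclusion_removes_pixels_from_totals(self):
        t = synthetic.default_truth(seed=9)
        image, sec, _ = synthetic.gen_ihc_image(t)
        band_mm = (
            image.tissue.shape[1] * image.calibration_mm,
            image.tissue.shape[0] * image.calibration_mm,
        )
        ex = Polygon([(0, 0), (band_mm[0] / 6, 0), (band_mm[0] / 6, band_mm[1]), (0, band_mm[1])])
        grid = histo.build_region_grid(sec, exclusions=[ex])
        q = histo.quantify_stain(image, grid)
        grid0 = histo.build_region_grid(sec)
        q0 = histo.quantify_stain(image, grid0)
        assert q.total_counts.sum() < q0.total_counts.sum()
        # untouched segments keep their counts
        assert np.array_equal(q.total_counts[2], q0.total_counts[2])


class TestDabPositivity:
    def test_threshold_monotonicity(self, rng):
        rgb = rng.uniform(0, 1, (64, 64, 3))
        lo = histo.dab_positivity(rgb, threshold=-0.1)
        hi = histo.dab_positivity(rgb, threshold=0.1)
        assert np.all(hi <= lo)


def _quant_from(pct: np.ndarray) -> StainQuant:
    return StainQuant(
        positive_pct=pct.astype(float),
        positive_counts=(pct * 10).astype(int),
        total_counts=np.full_like(pct, 1000, dtype=int),
    )


class TestFoldChangeMap:
    def test_identical_groups_give_zero_log2fc(self, rng):
        q = [_quant_from(rng.uniform(5, 50, (3, 10))) for _ in range(6)]
        fm = histo.fold_change_map(q, q)
        assert np.allclose(fm.fc, 1.0)
        assert np.allclose(fm.log2fc, 0.0)
        assert not fm.undefined.any()

    def test_double_expression_gives_log2fc_one(self):
        base = np.full((3, 10), 10.0)
        fm = histo.fold_change_map([_quant_from(2 * base)], [_quant_from(base)])
        assert np.allclose(fm.fc, 2.0)
        assert np.allclose(fm.log2fc, 1.0)

    def test_zero_control_flagged_not_zeroed(self):
        tic = _quant_from(np.full((3, 10), 10.0))
        ctl = _quant_from(np.zeros((3, 10)))
        fm = histo.fold_change_map([tic], [ctl])
        assert fm.undefined.all()
        assert np.isnan(fm.log2fc).all()

    def test_permutation_safety(self, rng):
        qs = [_quant_from(rng.uniform(5, 50, (3, 10))) for _ in range(6)]
        ctl = [_quant_from(rng.uniform(5, 50, (3, 10))) for _ in range(6)]
        fm1 = histo.fold_change_map(qs, ctl)
        order = rng.permutation(6)
        fm2 = histo.fold_change_map([qs[i] for i in order], [ctl[i] for i in order[::-1]])
        assert np.allclose(fm1.fc, fm2.fc)

    def test_planted_cohort_ratio_recovery(self, rng):
        # cell-wise planted ratios recovered within mean |log2fc| error 0.1
        base = rng.uniform(10, 40, (3, 10))
        ratio = rng.uniform(0.5, 2.0, (3, 10))
        ctl = [_quant_from(base * rng.normal(1, 0.1, (3, 10))) for _ in range(6)]
        tic = [_quant_from(base * ratio * rng.normal(1, 0.1, (3, 10))) for _ in range(6)]
        fm = histo.fold_change_map(tic, ctl)
        err = np.abs(fm.log2fc - np.log2(ratio))
        assert err.mean() < 0.1


class TestNucleiDensity:
    def test_counts_match_planted_density(self):
        # 10 nuclei scattered in one known cell of a 30 x 1 mm band at 0.02 mm/px
        sec = _rect_section(30.0, 1.0)
        grid = histo.build_region_grid(sec)
        cal = 0.02
        H, W = 50, 1500  # 1 mm x 30 mm
        mask = np.zeros((H, W), bool)
        rng = np.random.default_rng(0)
        # all nuclei inside length segment 0, depth layer 0 (top-left cell)
        for _ in range(10):
            r = rng.integers(1, 4)
            c = rng.integers(5, 495)
            mask[r, c] = True
        dens = histo.nuclei_density(mask, grid, calibration_mm=cal,
                                    origin_mm=(cal / 2, cal / 2))
        assert dens[0, 0] == pytest.approx(10.0 / (10.0 * 0.1), rel=1e-6)
        assert dens.sum() == pytest.approx(dens[0, 0])

    def test_empty_region_is_zero(self):
        sec = _rect_section(30.0, 1.0)
        grid = histo.build_region_grid(sec)
        dens = histo.nuclei_density(np.zeros((50, 1500), bool), grid, 0.02)
        assert np.all(dens == 0.0)
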