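"""Synthetic slide simulator: physics, determinism, geometry, cohorts."""

import warnings

import numpy as np
import pytest

from aicyto import (
    ConditionDesign,
    NucleusROI,
    PopulationSpec,
    SceneSpec,
    StudyDesign,
    analyze_sample,
    generate_cohort,
    integrated_optical_density,
    load_image,
    load_layout,
    load_rois,
    mask_to_polygon,
    measure_sample,
    rasterize_polygon,
    render_scene,
    to_optical_density,
)


def _measure_quiet(plane, rois, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return measure_sample(plane, rois, **kw)


SMALL_SCENE = dict(shape=(320, 320), n_controls=10, n_epithelial=25)


class TestSpecValidation:
    def test_population_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SceneSpec(populations=(PopulationSpec("2N", 0.5, 1.0),))

    def test_bad_population(self):
        with pytest.raises(ValueError):
            PopulationSpec("x", 1.2, 1.0)
        with pytest.raises(ValueError):
            PopulationSpec("x", 1.0, -1.0)


class TestRenderScene:
    def test_same_seed_is_bit_identical(self):
        spec = SceneSpec(**SMALL_SCENE, seed=7)
        p1, r1, t1 = render_scene(spec)
        p2, r2, t2 = render_scene(spec)
        np.testing.assert_array_equal(p1.pixels, p2.pixels)
        assert [n.true_absorbance for n in t1.nuclei] == [
            n.true_absorbance for n in t2.nuclei
        ]

    def test_different_seeds_differ(self):
        p1 = render_scene(SceneSpec(**SMALL_SCENE, seed=1))[0]
        p2 = render_scene(SceneSpec(**SMALL_SCENE, seed=2))[0]
        assert (p1.pixels != p2.pixels).any()

    def test_zero_noise_2n_iod_within_one_percent_of_truth(self, clean_measurements):
        ms, truth = clean_measurements
        for m in ms:
            ratio = m.iod / (10.0 * truth.by_id(m.roi_id).true_absorbance)
            assert 0.99 <= ratio <= 1.01

    def test_4n_to_2n_iod_ratio_within_two_percent_of_two(self, clean_measurements):
        ms, truth = clean_measurements
        by_pop = {"2N": [], "4N": []}
        for m in ms:
            nt = truth.by_id(m.roi_id)
            if nt.population in by_pop:
                by_pop[nt.population].append(m.iod)
        mean2 = np.mean(by_pop["2N"])
        mean4 = np.mean(by_pop["4N"])
        assert abs(mean4 / mean2 - 2.0) <= 0.04

    def test_ploidy_multiple_monotone_in_measured_iod(self):
        """Raising a population's DNA content raises its nuclei's IOD."""
        iods = {}
        for mult in (1.0, 1.5, 2.0):
            spec = SceneSpec(
                **SMALL_SCENE, noise_sd=0.0, texture_cv=0.0, control_cv=0.0,
                populations=(PopulationSpec("p", 1.0, mult, cv=0.0),), seed=9,
            )
            plane, rois, truth = render_scene(spec)
            ms = _measure_quiet(plane, rois)
            iods[mult] = np.mean(
                [m.iod for m in ms if m.cell_class == "epithelial"]
            )
        assert iods[1.0] < iods[1.5] < iods[2.0]

    def test_truth_masks_and_exported_polygons_measure_identically(self):
        spec = SceneSpec(**SMALL_SCENE, seed=13)
        plane, rois, truth = render_scene(spec)
        od = to_optical_density(plane)
        for roi in rois[:8]:
            via_poly = integrated_optical_density(od, roi).iod
            via_mask = integrated_optical_density(
                od,
                NucleusROI(id=roi.id, cell_class=roi.cell_class,
                           mask=truth.masks[roi.id]),
            ).iod
            assert via_poly == via_mask

    def test_nuclei_do_not_overlap(self):
        spec = SceneSpec(**SMALL_SCENE, seed=21)
        _, rois, _ = render_scene(spec)
        from aicyto import check_nonoverlap

        assert check_nonoverlap(rois, spec.shape).ok

    def test_infeasible_placement_raises(self):
        spec = SceneSpec(shape=(48, 48), n_controls=30, n_epithelial=30, seed=0)
        with pytest.raises(RuntimeError, match="crowded"):
            render_scene(spec)


class TestMaskToPolygon:
    def test_round_trip_on_random_ellipse_masks(self, rng):
        for _ in range(15):
            cy, cx = rng.uniform(10, 20, size=2)
            ry, rx = rng.uniform(2.5, 7, size=2)
            rr, cc = np.mgrid[0:32, 0:32]
            mask = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
            if not mask.any():
                continue
            poly = mask_to_polygon(mask)
            np.testing.assert_array_equal(rasterize_polygon(poly, (32, 32)), mask)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        poly = mask_to_polygon(mask)
        got = rasterize_polygon(poly, (5, 5))
        np.testing.assert_array_equal(got, mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_to_polygon(np.zeros((4, 4), dtype=bool))


class TestGenerateCohort:
    def _tiny_design(self, conditions):
        return StudyDesign(
            conditions=conditions,
            scene=SceneSpec(shape=(256, 256), n_controls=10, n_epithelial=20),
        )

    def test_files_and_layout_on_disk(self, tmp_path):
        design = self._tiny_design(
            (
                ConditionDesign("NCT", 2, 0.95, 0.08, (0.81, 1.05)),
                ConditionDesign("AC", 2, 1.46, 0.27, (1.20, 2.04)),
            )
        )
        # tiny samples: pin epithelial count below the protocol's 150-200
        import aicyto.synth as synth

        layout = generate_cohort(tmp_path, design, seed=3)
        assert len(layout.samples) == 4
        assert layout.conditions == ("NCT", "AC")
        back = load_layout(tmp_path / "layout.csv")
        assert back.conditions == layout.conditions
        for entry in layout.samples:
            plane = load_image(entry.image_path)
            rois = load_rois(entry.roi_path)
            assert plane.bit_depth == 16
            assert len(rois) >= 30
        assert (tmp_path / "truth.csv").exists()
        assert (tmp_path / "targets.csv").exists()

    def test_all_diploid_design_yields_zero_aneuploid_fraction(self, tmp_path):
        design = self._tiny_design(
            (ConditionDesign("NCT", 3, 0.95, 0.04, (0.85, 1.05), g2_fraction=0.0),)
        )
        layout = generate_cohort(tmp_path, design, seed=11)
        n_aneuploid = 0
        for entry in layout.samples:
            plane = load_image(entry.image_path)
            rois = load_rois(entry.roi_path)
            res = analyze_sample(_measure_quiet(plane, rois),
                                 sample_id=entry.sample_id)
            n_aneuploid += res.aneuploid
        assert n_aneuploid == 0

    def test_same_seed_reproduces_cohort_bytes(self, tmp_path):
        design = self._tiny_design(
            (ConditionDesign("NCT", 1, 0.95, 0.08, (0.81, 1.05)),)
        )
        generate_cohort(tmp_path / "a", design, seed=5)
        generate_cohort(tmp_path / "b", design, seed=5)
        img_a = (tmp_path / "a" / "NCT-01.tif").read_bytes()
        img_b = (tmp_path / "b" / "NCT-01.tif").read_bytes()
        assert img_a == img_b

    def test_target_distribution_is_respected(self, tmp_path):
        """Drawn per-sample targets track the requested truncated normal."""
        import pandas as pd

        design = self._tiny_design(
            (ConditionDesign("AC", 12, 1.46, 0.27, (1.20, 2.04)),)
        )
        generate_cohort(tmp_path, design, seed=17)
        targets = pd.read_csv(tmp_path / "targets.csv")["target_peak_di"]
        assert ((targets >= 1.20) & (targets <= 2.04)).all()
        from scipy import stats

        a = (1.20 - 1.46) / 0.27
        b = (2.04 - 1.46) / 0.27
        mu = stats.truncnorm.mean(a, b, loc=1.46, scale=0.27)
        se = stats.truncnorm.std(a, b, loc=1.46, scale=0.27) / np.sqrt(len(targets))
        assert abs(targets.mean() - mu) <= 3 * se


class TestPopulationCounts:
    def test_counts_sum_and_respect_overrides(self, rng):
        from aicyto.synth import _population_counts

        pops = [
            PopulationSpec("a", 0.5, 1.0),
            PopulationSpec("b", 0.3, 2.0),
            PopulationSpec("c", 0.2, 3.0, count=7),
        ]
        counts = _population_counts(rng, pops, 50)
        assert sum(counts) == 50
        assert counts[2] == 7
        # free slots split ~ 5:3
        assert counts[0] > counts[1]
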