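"""Exposure histograms, ratio tables, threshold curves, dose-response fit."""

import numpy as np
import pytest

from pemfdose import analysis as an
from pemfdose import coil as cm
from pemfdose.errors import ConfigurationError


def random_fixture(seed, shape=(16, 16, 16)):
    """Random masks + field on a small grid for brute-force comparisons."""
    rng = np.random.default_rng(seed)
    pre = rng.random(shape) > 0.6
    pre[2, 2, 2] = True  # never empty
    post = rng.random(shape) > 0.7
    field = rng.uniform(0.5, 2.5, size=shape)
    return pre, post, field


class TestExposureSummary:
    def test_uniform_field_collapses_extremes(self):
        field = np.full((8, 8, 8), 1.5)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        s = an.exposure_summary(field, mask, bin_width=0.05)
        assert s.min_value == s.max_value == 1.5
        assert s.mode_value == pytest.approx(1.5, abs=0.025)
        assert int(s.counts.sum()) == int(mask.sum())

    def test_gradient_slab_mode_matches_brute_force(self):
        # Linear-gradient field over a slab with varying cross-section:
        # the mode must equal the bin holding the most voxels, found by
        # exhaustive counting.
        shape = (20, 12, 12)
        field = np.broadcast_to(
            np.linspace(0.5, 2.4, shape[0])[:, None, None], shape
        ).copy()
        mask = np.zeros(shape, bool)
        for i in range(shape[0]):
            w = 2 + (i % 5)
            mask[i, :w, :w] = True
        bw = 0.1
        s = an.exposure_summary(field, mask, bin_width=bw)
        values = field[mask]
        edges = s.bin_edges
        counts = [np.sum((values >= lo) & (values < hi))
                  for lo, hi in zip(edges[:-1], edges[1:])]
        # np.histogram closes the last bin; mirror that.
        counts[-1] += np.sum(values == edges[-1])
        best = int(np.argmax(s.counts))
        assert counts[best] == max(counts)
        assert s.mode_value == pytest.approx(
            0.5 * (edges[best] + edges[best + 1])
        )

    def test_extreme_voxel_indices(self):
        field = np.zeros((6, 6, 6))
        field[1, 2, 3] = -5.0
        field[4, 4, 1] = 7.0
        mask = np.ones((6, 6, 6), bool)
        s = an.exposure_summary(field, mask, bin_width=0.5)
        assert s.min_voxel_index == (1, 2, 3)
        assert s.max_voxel_index == (4, 4, 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            an.exposure_summary(np.ones((4, 4, 4)), np.zeros((4, 4, 4), bool))


class TestRatioByRange:
    def test_identical_masks_give_unit_ratios(self):
        pre, _, field = random_fixture(0)
        table = an.ratio_by_range(pre, pre, field, (0.5, 1.0, 1.5, 2.0, 2.5))
        for (lo, hi), r in zip(table.ranges, table.ratios):
            if r is not None:
                assert r == pytest.approx(1.0)

    def test_hand_counted_toy_table(self):
        # 100 pre voxels and 47 post voxels inside [1.7, 2.0) mT.
        shape = (10, 10, 10)
        field = np.full(shape, 1.8)
        pre = np.zeros(shape, bool)
        pre.reshape(-1)[:100] = True
        post = np.zeros(shape, bool)
        post.reshape(-1)[:47] = True
        table = an.ratio_by_range(pre, post, field,
                                  (1.0, 1.3, 1.7, 2.0, np.inf),
                                  voxel_volume_mm3=8.0)
        assert table.ratios[2] == pytest.approx(0.47)
        assert table.v_pre_mm3[2] == pytest.approx(800.0)
        # Ranges not occupied by either lesion carry the "slash".
        assert table.ratios[0] is None
        assert table.ratios[3] is None

    def test_range_volume_conservation(self):
        # Sum of per-range pre volumes equals the pre volume inside
        # [first edge, last edge) - an exact voxel-count identity.
        for seed in range(5):
            pre, post, field = random_fixture(seed)
            edges = (0.5, 1.0, 1.5, 2.0, 2.5)
            table = an.ratio_by_range(pre, post, field, edges)
            total = np.sum(table.v_pre_mm3)
            expected = np.sum(pre & (field >= edges[0]) & (field < edges[-1]))
            assert total == expected

    def test_brute_force_equality(self):
        for seed in range(5):
            pre, post, field = random_fixture(seed)
            edges = np.array([0.5, 0.9, 1.4, 2.0, np.inf])
            table = an.ratio_by_range(pre, post, field, edges,
                                      voxel_volume_mm3=2.0)
            for k, (lo, hi) in enumerate(table.ranges):
                n_pre = sum(
                    1 for v in zip(*np.nonzero(pre))
                    if lo <= field[v] < hi
                )
                n_post = sum(
                    1 for v in zip(*np.nonzero(post))
                    if lo <= field[v] < hi
                )
                assert table.v_pre_mm3[k] == pytest.approx(2.0 * n_pre)
                assert table.v_post_mm3[k] == pytest.approx(2.0 * n_post)

    def test_empty_pre_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            an.ratio_by_range(np.zeros((4, 4, 4), bool),
                              np.zeros((4, 4, 4), bool),
                              np.ones((4, 4, 4)), (0.0, 1.0))


class TestRatioByThreshold:
    def test_lowest_threshold_gives_total_volume_ratio(self):
        pre, post, field = random_fixture(1)
        data = an.ratio_by_threshold(pre, post, field, [field.min()])
        expected = 100.0 * post.sum() / pre.sum()
        assert data.ratios_percent[0] == pytest.approx(expected)

    def test_threshold_semantics_greater_or_equal(self):
        shape = (6, 6, 6)
        field = np.full(shape, 1.7)
        pre = np.zeros(shape, bool)
        pre[0] = True
        post = np.zeros(shape, bool)
        post[1, :3] = True
        data = an.ratio_by_threshold(pre, post, field, [1.7])
        # Voxels at exactly the threshold count ("equal or greater").
        assert data.ratios_percent[0] == pytest.approx(100.0 * 18 / 36)

    def test_brute_force_equality_on_random_grids(self):
        for seed in range(5):
            pre, post, field = random_fixture(seed)
            thresholds = np.linspace(0.6, 2.2, 9)
            data = an.ratio_by_threshold(pre, post, field, thresholds)
            kept = 0
            for t in thresholds:
                n_pre = sum(1 for v in zip(*np.nonzero(pre)) if field[v] >= t)
                n_post = sum(1 for v in zip(*np.nonzero(post)) if field[v] >= t)
                if n_pre == 0:
                    continue
                assert data.ratios_percent[kept] == pytest.approx(
                    100.0 * n_post / n_pre
                )
                kept += 1
            assert kept == len(data.thresholds)

    def test_tail_sum_identity_with_range_table(self):
        # At aligned edges, the threshold ratio equals the tail sums of
        # the range-table numerators/denominators - exactly.
        for seed in range(3):
            pre, post, field = random_fixture(seed)
            edges = np.array([0.6, 1.0, 1.5, 2.0, np.inf])
            table = an.ratio_by_range(pre, post, field, edges)
            data = an.ratio_by_threshold(pre, post, field, edges[:-1])
            for k, t in enumerate(edges[:-1]):
                v_pre_tail = np.sum(table.v_pre_mm3[k:])
                v_post_tail = np.sum(table.v_post_mm3[k:])
                if v_pre_tail == 0:
                    continue
                expected = 100.0 * v_post_tail / v_pre_tail
                idx = np.nonzero(np.isclose(data.thresholds, t))[0][0]
                assert data.ratios_percent[idx] == pytest.approx(expected)


class TestPoolCases:
    def test_single_case_is_identity(self):
        d = an.DoseResponseData([1.0, 1.5], [80.0, 70.0], ["X", "X"])
        pooled = an.pool_cases([d])
        np.testing.assert_array_equal(pooled.thresholds, d.thresholds)
        np.testing.assert_array_equal(pooled.case_ids, d.case_ids)

    def test_case_ids_preserved(self):
        a = an.DoseResponseData([1.0], [80.0], ["A"])
        b = an.DoseResponseData([2.0], [60.0], ["B"])
        pooled = an.pool_cases([a, b])
        assert list(pooled.case_ids) == ["A", "B"]

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            an.pool_cases([])

    def test_three_replicates_tighten_covariance(self):
        # Pooling three noisy cases generated from the same truth gives
        # a smaller parameter variance than any single case.
        rng = np.random.default_rng(0)
        x = np.linspace(1.0, 2.0, 8)

        def noisy_case(cid):
            y = 80.0 * np.exp(-0.3 * x) + rng.normal(0, 1.5, len(x))
            return an.DoseResponseData(x, y, [cid] * len(x))

        cases = [noisy_case(c) for c in "ABC"]
        single_vars = [np.diag(an.fit_dose_response(c).cov_params)
                       for c in cases]
        pooled_var = np.diag(an.fit_dose_response(an.pool_cases(cases)).cov_params)
        for sv_ in single_vars:
            assert np.all(pooled_var < sv_)


class TestDoseResponseFit:
    def test_exact_recovery_of_noiseless_exponential(self):
        x = np.linspace(1.0, 2.2, 10)
        y = 79.38 * np.exp(-0.1 * x)
        res = an.DoseResponseModel(x, y).fit()
        assert abs(res.M - 79.38) < 1e-6
        assert abs(res.a - (-0.1)) < 1e-9
        assert res.nobs == 10

    def test_flat_data_fits_zero_slope(self):
        rng = np.random.default_rng(4)
        x = np.linspace(1.0, 2.0, 12)
        y = 70.0 + rng.normal(0, 0.5, len(x))
        res = an.DoseResponseModel(x, y).fit()
        assert abs(res.a) <= 2.0 * res.bse[1]

    def test_insufficient_points_rejected(self):
        with pytest.raises(ConfigurationError):
            an.DoseResponseModel([1.0, 2.0], [80.0, 60.0])

    def test_degenerate_identical_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            an.DoseResponseModel([1.5, 1.5, 1.5], [80.0, 75.0, 70.0])

    def test_summary_reports_estimates(self):
        x = np.linspace(1.0, 2.0, 6)
        res = an.DoseResponseModel(x, 90.0 * np.exp(-0.2 * x)).fit()
        text = res.summary()
        assert "M" in text and "a" in text
        assert f"{res.M:.4f}" in text

    def test_threshold_for_ratio_inverts_fit(self):
        x = np.linspace(1.0, 2.0, 6)
        res = an.DoseResponseModel(x, 90.0 * np.exp(-0.2 * x)).fit()
        x50 = res.threshold_for_ratio(50.0)
        assert res.predict([x50])[0] == pytest.approx(50.0)


@pytest.fixture(scope="module")
def sphere_setup():
    from pemfdose import phantom as ph

    head = ph.build_layered_head(radius_mm=60.0,
                                 layers=(("skin", 4), ("skull", 7),
                                         ("csf", 3), ("grey", 10)),
                                 voxel_size_mm=2.5)
    mask = ph.generate_lesion(head, (15.0, 0.0, 0.0), (14.0, 14.0, 14.0),
                              irregularity=0.0, seed=0)
    frame = cm.CoilFrame([70.0, 0.0, 0.0], [0.0, 0.0, 1.0],
                         [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0])
    return head, mask, frame


class TestCoilFrameSlices:

    def test_spherical_mask_central_slice_largest_and_symmetric(self, sphere_setup):
        head, mask, frame = sphere_setup
        slices = an.coil_frame_slices(mask, mask, head, frame, plane="d",
                                      spacing_mm=5.0, with_contours=False)
        areas = slices.pre_areas_mm2
        center = int(np.argmax(areas))
        # Analytic circle areas: slab at distance x from the sphere
        # center has mean cross-section ~ pi (r^2 - x^2).
        offsets = slices.offsets_mm - (70.0 - 15.0 - slices.offsets_mm * 0) * 0
        d_center = 70.0 - 15.0  # coil plane to lesion center
        for off, area in zip(slices.offsets_mm, areas):
            x = off - d_center
            if abs(x) <= 9.0:
                analytic = np.pi * (14.0 ** 2 - x ** 2)
                assert area == pytest.approx(analytic, rel=0.25)
        # Symmetric decay around the maximum.
        left = areas[:center][::-1]
        right = areas[center + 1:]
        n = min(len(left), len(right))
        np.testing.assert_allclose(left[:n], right[:n], rtol=0.35)

    def test_identical_masks_identical_areas(self, sphere_setup):
        head, mask, frame = sphere_setup
        slices = an.coil_frame_slices(mask, mask, head, frame, plane="f",
                                      spacing_mm=5.0, with_contours=False)
        np.testing.assert_array_equal(slices.pre_areas_mm2,
                                      slices.post_areas_mm2)

    def test_default_spacing_and_contours(self, sphere_setup):
        head, mask, frame = sphere_setup
        slices = an.coil_frame_slices(mask, mask, head, frame, plane="d")
        assert slices.spacing_mm == 5.0
        populated = [off for off, cs in slices.contours_pre.items() if cs]
        assert populated  # central slabs produce contour polylines

    def test_invalid_plane_rejected(self, sphere_setup):
        head, mask, frame = sphere_setup
        with pytest.raises(ConfigurationError):
            an.coil_frame_slices(mask, mask, head, frame, plane="x")
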