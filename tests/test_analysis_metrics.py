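import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import mannwhitneyu

from agesal.analysis_metrics import (
    AgreementConfig,
    agreement_auc,
    agreement_matrix,
    center_map_prediction_auc,
    compute_center_map,
    explorativeness_entropy,
    threshold_saliency_map,
)
from agesal.gaze_data import (
    FixationMap,
    FixationRecord,
    FixationTable,
    SaliencyMap,
    build_fixation_map,
    build_human_saliency_map,
)
from conftest import make_table


class TestEntropy:
    def test_constant_map_zero_entropy_degenerate(self):
        smap = SaliencyMap(grid=np.full((8, 8), 0.5))
        res = explorativeness_entropy(smap)
        assert res.H == 0
        assert res.degenerate

    def test_four_pixel_uniform_histogram_hand_value(self):
        smap = SaliencyMap(grid=np.array([[0, 1 / 3], [2 / 3, 1.0]]),
                           normalization="minmax01")
        res = explorativeness_entropy(smap, bins=4)
        assert res.H == pytest.approx(4 * np.log(4))
        assert res.L == 4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identity_with_L_times_shannon(self, seed, random_map):
        smap = random_map(seed)
        res = explorativeness_entropy(smap)
        p = res.histogram[res.histogram > 0] / res.L
        shannon = float(-(p * np.log(p)).sum())
        assert res.H == pytest.approx(res.L * shannon, rel=1e-9)

    def test_upper_bound_and_histogram_total(self, random_map):
        smap = random_map(5)
        res = explorativeness_entropy(smap, bins=16)
        assert res.histogram.sum() == res.L
        assert 0 <= res.H <= res.L * np.log(16)


class TestThreshold:
    def test_full_coverage_selects_everything(self, random_map):
        mask = threshold_saliency_map(random_map(1), 1.0)
        assert mask.all()

    def test_top_k_without_ties(self):
        grid = np.arange(10, dtype=float).reshape(2, 5) / 9
        mask = threshold_saliency_map(
            SaliencyMap(grid=grid, normalization="minmax01"), 0.3)
        assert mask.sum() == 3
        assert mask[1, 2] and mask[1, 3] and mask[1, 4]

    def test_constant_map_ties_break_in_raster_order(self):
        grid = np.full((4, 5), 0.7)
        mask = threshold_saliency_map(SaliencyMap(grid=grid), 0.5)
        k = int(np.ceil(0.5 * 20))
        expected = np.zeros(20, dtype=bool)
        expected[:k] = True  # raster-first pixels win ties
        np.testing.assert_array_equal(mask.ravel(), expected)

    def test_invalid_coverage_rejected(self, random_map):
        with pytest.raises(ValueError):
            threshold_saliency_map(random_map(0), 0.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        grid=arrays(float, (6, 7),
                    elements=st.floats(0, 1, allow_nan=False)),
        cov_a=st.floats(0.01, 1.0),
        cov_b=st.floats(0.01, 1.0),
    )
    def test_mask_size_exact_and_masks_nested(self, grid, cov_a, cov_b):
        lo, hi = sorted((cov_a, cov_b))
        smap = SaliencyMap(grid=grid)
        m_lo = threshold_saliency_map(smap, lo)
        m_hi = threshold_saliency_map(smap, hi)
        assert m_lo.sum() == int(np.ceil(lo * grid.size))
        assert m_hi.sum() == int(np.ceil(hi * grid.size))
        assert np.all(m_hi[m_lo])  # lower coverage is a subset


def _random_fixmap(rng, shape, n):
    grid = np.zeros(shape, dtype=np.uint8)
    idx = rng.choice(shape[0] * shape[1], size=n, replace=False)
    grid.ravel()[idx] = 1
    return FixationMap(grid=grid, image_id="im", group="g")


class TestAgreementAuc:
    def test_self_prediction_is_high(self):
        rng = np.random.default_rng(11)
        fmap = _random_fixmap(rng, (64, 64), 30)
        smap = build_human_saliency_map(fmap, sigma=2)
        assert agreement_auc(smap, fmap).auc >= 0.95

    def test_matches_rank_auc_with_per_pixel_levels(self):
        shape = (64, 64)
        L = shape[0] * shape[1]
        cfg = AgreementConfig(
            coverage_levels=tuple((k + 1) / L for k in range(L)))
        for seed in range(5):
            rng = np.random.default_rng(seed)
            smap = SaliencyMap(grid=rng.random(shape))
            fmap = _random_fixmap(rng, shape, 30)
            roc = agreement_auc(smap, fmap, cfg)
            vals, fix = smap.grid.ravel(), fmap.grid.ravel().astype(bool)
            u = mannwhitneyu(vals[fix], vals[~fix], alternative="greater")
            rank_auc = u.statistic / (fix.sum() * (~fix).sum())
            assert roc.auc == pytest.approx(rank_auc, abs=0.02)

    def test_constant_map_near_chance(self):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fmap = _random_fixmap(rng, (32, 32), 20)
            smap = SaliencyMap(grid=np.full((32, 32), 0.5))
            aucs.append(agreement_auc(smap, fmap).auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_invariant_under_monotone_transform(self, random_map):
        rng = np.random.default_rng(4)
        fmap = _random_fixmap(rng, (32, 32), 15)
        smap = random_map(4)
        base = agreement_auc(smap, fmap).auc
        for f in (np.sqrt, lambda g: g ** 3, lambda g: np.exp(2 * g)):
            t = SaliencyMap(grid=f(smap.grid))
            assert agreement_auc(t, fmap).auc == pytest.approx(base,
                                                               abs=1e-12)

    def test_curve_properties(self, random_map):
        rng = np.random.default_rng(9)
        fmap = _random_fixmap(rng, (32, 32), 10)
        roc = agreement_auc(random_map(9), fmap)
        fprs = [p[0] for p in roc.points]
        tprs = [p[1] for p in roc.points]
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)
        assert fprs == sorted(fprs)
        assert all(b >= a - 1e-12 for a, b in zip(tprs, tprs[1:]))
        assert 0.0 <= roc.auc <= 1.0

    def test_empty_target_rejected(self, random_map):
        empty = FixationMap(grid=np.zeros((32, 32), dtype=np.uint8),
                            image_id="im", group="g")
        with pytest.raises(ValueError):
            agreement_auc(random_map(0), empty)


def _two_group_table(seed=0, dims=(48, 48), same=False):
    rng = np.random.default_rng(seed)
    recs = []
    for g, corner in (("a", (8, 8)), ("b", (8, 8) if same else (34, 34))):
        for ob in range(4):
            for _ in range(8):
                x = np.clip(corner[0] + rng.normal(0, 3), 0, dims[0] - 1)
                y = np.clip(corner[1] + rng.normal(0, 3), 0, dims[1] - 1)
                recs.append(FixationRecord(f"{g}{ob}", g, "im",
                                           float(x), float(y)))
    return FixationTable(records=recs, image_dims={"im": dims})


class TestAgreementMatrix:
    def test_single_group_single_image_equals_direct_auc(self):
        table = _two_group_table(seed=1)
        m = agreement_matrix(table, ["a"], ["im"], sigma=2)
        fmap = build_fixation_map(table, "a", "im")
        smap = build_human_saliency_map(fmap, sigma=2)
        assert m.shape == (1, 1)
        assert m.loc["a", "a"] == pytest.approx(
            agreement_auc(smap, fmap).auc)

    def test_disjoint_groups_diagonal_dominates(self):
        m = agreement_matrix(_two_group_table(seed=2), ["a", "b"], ["im"],
                             sigma=2)
        assert m.loc["a", "a"] > m.loc["a", "b"]
        assert m.loc["b", "b"] > m.loc["b", "a"]

    def test_invariant_under_observer_relabeling(self):
        table = _two_group_table(seed=3)
        m1 = agreement_matrix(table, ["a", "b"], ["im"], sigma=2)
        relabeled = FixationTable(
            records=[FixationRecord("x" + r.observer_id[::-1], r.group,
                                    r.image_id, r.x, r.y)
                     for r in table.records],
            image_dims=table.image_dims)
        m2 = agreement_matrix(relabeled, ["a", "b"], ["im"], sigma=2)
        np.testing.assert_allclose(m1.values, m2.values)


class TestCenterMap:
    def test_point_mass_at_origin_closed_form_distance(self):
        grid = np.zeros((101, 101))
        grid[0, 0] = 1.0
        res = compute_center_map([SaliencyMap(grid=grid)])
        assert res.distance_px == pytest.approx(50 * np.sqrt(2))

    def test_mirrored_point_masses_cancel(self):
        a = np.zeros((101, 101))
        b = np.zeros((101, 101))
        a[10, 30] = 1.0
        b[90, 70] = 1.0
        res = compute_center_map([SaliencyMap(grid=a), SaliencyMap(grid=b)])
        assert res.distance_px == pytest.approx(0.0, abs=1e-9)

    def test_central_gaussian_centroid_at_center(self):
        yy, xx = np.mgrid[0:65, 0:65].astype(float)
        g = np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / 50)
        res = compute_center_map([SaliencyMap(grid=g)])
        assert res.distance_px == pytest.approx(0.0, abs=1e-6)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compute_center_map([])

    def test_most_central_pixel_fixations_score_near_one(self):
        yy, xx = np.mgrid[0:33, 0:33].astype(float)
        g = np.exp(-((xx - 16) ** 2 + (yy - 16) ** 2) / 30)
        res = compute_center_map([SaliencyMap(grid=g)])
        fix = np.zeros((33, 33), dtype=np.uint8)
        fix[16, 16] = 1
        fmap = FixationMap(grid=fix, image_id="im", group="g")
        L = 33 * 33
        fine = AgreementConfig(
            coverage_levels=tuple((k + 1) / L for k in range(L)))
        assert center_map_prediction_auc(res, fmap, fine) >= 0.99


def test_agreement_config_validation():
    with pytest.raises(ValueError):
        AgreementConfig(coverage_levels=(0.5, 0.4, 1.0))
    with pytest.raises(ValueError):
        AgreementConfig(coverage_levels=(0.5, 0.9))
    cfg = AgreementConfig()
    assert cfg.T == 20
    assert cfg.coverage_levels[-1] == 1.0
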