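import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import myoseg as m
from myoseg.config import ValidationError
from myoseg.evaluation import KL_BIN_SIZES, ContingencyTable


class TestSensitivity:
    def test_size6_worked_example(self):
        t = ContingencyTable(n=6, a=4)
        assert t.d == 2
        assert round(m.sensitivity(t), 2) == 0.67

    def test_size5_worked_example(self):
        assert m.sensitivity(ContingencyTable(n=5, a=2)) == pytest.approx(0.4)

    def test_perfect_separation(self):
        assert m.sensitivity(ContingencyTable(n=3, a=3)) == 1.0

    @given(n=st.integers(1, 30), a_frac=st.floats(0, 1))
    def test_bounds_and_conservation(self, n, a_frac):
        a = int(round(a_frac * n))
        t = ContingencyTable(n=n, a=a)
        s = m.sensitivity(t)
        assert 0.0 <= s <= 1.0
        assert t.a + t.d == t.n
        assert (s == 1.0) == (t.d == 0)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(n=0, a=0)
        with pytest.raises(ValidationError):
            ContingencyTable(n=2, a=3)


class TestDice:
    def test_identical_masks(self):
        x = np.zeros((5, 5), bool)
        x[1:3, 1:3] = True
        assert m.dice(x, x) == 1.0

    def test_disjoint_masks(self):
        x = np.zeros((5, 5), bool)
        y = np.zeros((5, 5), bool)
        x[0, 0] = y[4, 4] = True
        assert m.dice(x, y) == 0.0

    def test_half_overlap(self):
        x = np.zeros((4, 4), bool)
        y = np.zeros((4, 4), bool)
        x[0, :4] = True
        y[0, 2:] = y[1, :2] = True
        assert m.dice(x, y) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            m.dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool))

    @given(seed=st.integers(0, 50))
    def test_symmetric_bounded_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((8, 8)) > 0.5
        y = rng.random((8, 8)) > 0.5
        if not (x.any() or y.any()):
            x[0, 0] = True
        d = m.dice(x, y)
        assert d == m.dice(y, x)
        assert 0.0 <= d <= 1.0
        assert (d == 1.0) == bool(np.array_equal(x, y))


class TestBootstrap:
    def test_identical_values_p_one(self):
        v = [0.5, 0.7, 0.9]
        assert m.bootstrap_compare(v, v, B=1000, seed=0).p_value == 1.0

    def test_constant_shift_endpoints(self):
        x = np.array([0.4, 0.6, 0.5, 0.8])
        assert m.bootstrap_compare(x, x + 0.1, B=1000, seed=0).p_value == 1.0
        assert m.bootstrap_compare(x + 0.1, x, B=1000, seed=0).p_value == 0.0

    def test_all_ones_vs_all_zeros(self):
        assert m.bootstrap_compare([1.0] * 5, [0.0] * 5, B=500, seed=1).p_value == 0.0

    def test_matches_exhaustive_enumeration_at_n3(self):
        pl1 = np.array([0.2, 0.9, 0.6])
        pl2 = np.array([0.7, 0.3, 0.5])
        hits = total = 0
        for idx in itertools.product(range(3), repeat=3):
            total += 1
            hits += pl2[list(idx)].mean() >= pl1[list(idx)].mean()
        exact = hits / total
        B = 100_000
        res = m.bootstrap_compare(pl1, pl2, B=B, seed=0)
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(res.p_value - exact) <= 3 * se

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(20), rng.random(20)
        r1 = m.bootstrap_compare(a, b, B=5000, seed=42)
        r2 = m.bootstrap_compare(a, b, B=5000, seed=42)
        assert r1.p_value == r2.p_value

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            m.bootstrap_compare([], [], B=10, seed=0)


class TestKLDivergence:
    def test_identical_sequences_zero_all_bin_sizes(self):
        areas = [120.0, 800.0, 1500.0, 5200.0, 900.0]
        for h in KL_BIN_SIZES:
            assert m.kl_area_divergence(areas, areas, h) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_value(self):
        # P counts (2,2), Q counts (3,1) over two bins of width 10
        p = [5.0, 5.0, 15.0, 15.0]
        q = [5.0, 5.0, 5.0, 15.0]
        expected = 0.5 * np.log(0.5 / 0.75) + 0.5 * np.log(0.5 / 0.25)
        assert m.kl_area_divergence(p, q, 10.0) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.1438, abs=5e-4)

    @given(seed=st.integers(0, 99))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 5000, 30)
        q = rng.uniform(0, 5000, 30)
        assert m.kl_area_divergence(p, q, 500.0) >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            m.kl_area_divergence([], [1.0], 10.0)


class TestAreaDensity:
    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        areas = rng.gamma(5, 400, 300)
        grid, dens = m.area_density(areas)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_bimodal_curve(self):
        areas = np.concatenate([np.full(50, 2000.0), np.full(50, 6000.0)])
        grid, dens = m.area_density(areas, bin_size=800.0)
        mid = 4000.0
        left = np.interp(mid - np.linspace(0, 1500, 40), grid, dens)
        right = np.interp(mid + np.linspace(0, 1500, 40), grid, dens)
        assert np.abs(left - right).max() < 1e-6

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValidationError):
            m.area_density([500.0, 500.0, 500.0])


class TestMatching:
    def test_perfect_detection(self):
        gt = np.zeros((10, 10), np.int32)
        gt[1:4, 1:4] = 1
        gt[6:9, 6:9] = 2
        match = m.match_detections(gt.copy(), gt)
        assert {(d, g) for d, g, _ in match.pairs} == {(1, 1), (2, 2)}
        assert all(s == 1.0 for _, _, s in match.pairs)

    def test_empty_detection(self):
        gt = np.zeros((6, 6), np.int32)
        gt[2:4, 2:4] = 1
        match = m.match_detections(np.zeros_like(gt), gt)
        assert match.pairs == [] and match.unmatched_groundtruth == [1]

    def test_merged_detection_counts_once(self):
        gt = np.zeros((4, 8), np.int32)
        gt[:, :4] = 1
        gt[:, 4:] = 2
        det = np.ones_like(gt)  # one detection covering both cells entirely
        match = m.match_detections(det, gt)
        assert len(match.pairs) == 1
        d, g, s = match.pairs[0]
        assert s == pytest.approx(2 / 3)
        assert g == 1  # tie broken towards the first groundtruth id


class TestContingency:
    @staticmethod
    def _cluster(gt, members):
        mask = np.isin(gt, list(members))
        return m.ReferenceCluster(
            cluster_id=1, member_cell_ids=frozenset(members), mask=mask
        )

    def test_partial_match_a4_of_6(self):
        gt = np.zeros((6, 36), np.int32)
        for i in range(6):
            gt[1:5, 6 * i + 1: 6 * i + 5] = i + 1
        det = np.where(gt <= 4, gt, 0)  # cells 5, 6 missed
        rc = self._cluster(gt, range(1, 7))
        match = m.match_detections(det, gt)
        t = m.contingency(rc, match, det, gt)
        assert (t.n, t.a, t.d) == (6, 4, 2)
        assert round(m.sensitivity(t), 2) == 0.67

    def test_perfect_separation_n3(self):
        gt = np.zeros((6, 18), np.int32)
        for i in range(3):
            gt[1:5, 6 * i + 1: 6 * i + 5] = i + 1
        rc = self._cluster(gt, {1, 2, 3})
        match = m.match_detections(gt.copy(), gt)
        t = m.contingency(rc, match, gt, gt)
        assert (t.a, t.b, t.d) == (3, 0, 0)

    def test_merged_detection_b1(self):
        gt = np.zeros((4, 8), np.int32)
        gt[:, :4] = 1
        gt[:, 4:] = 2
        det = np.ones_like(gt)
        rc = self._cluster(gt, {1, 2})
        match = m.match_detections(det, gt)
        # the single spanning detection is matched to cell 1 (dice 2/3) but
        # contains both member cells: counts as a false positive, and cell 2
        # stays unseparated
        t = m.contingency(rc, match, det, gt)
        assert t.b == 1 and t.a == 1 and t.d == 1


class TestReferenceClusters:
    def test_clean_sample_no_multi_clusters(self, clean_sample):
        assert m.reference_clusters(clean_sample.image, clean_sample.groundtruth) == []

    def test_single_hole_gives_n2(self):
        sample = m.generate_cross_section(
            m.SyntheticConfig(
                height=128, width=128, n_fibres=4, border_hole_rate=1.0,
                border_intensity=255, fibre_intensity_range=(60, 110),
                gap_fraction=0.0, seed=5,
            )
        )
        holes = [(a, b) for a, b, h in sample.wall_registry if h]
        refs = m.reference_clusters(sample.image, sample.groundtruth)
        if holes:  # geometry-dependent: at least one interior wall got a hole
            assert any(rc.n >= 2 for rc in refs)
            holed = set(np.concatenate([list(p) for p in holes]))
            for rc in refs:
                assert rc.member_cell_ids <= holed

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            m.reference_clusters(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.int32))


class TestGroupAndFilter:
    class _Sized:
        def __init__(self, n):
            self.n = n

    def test_below_min_samples_dropped(self):
        out = m.group_and_filter([self._Sized(2)] * 4)
        assert out == {}

    def test_mixed_groups(self):
        clusters = [self._Sized(2)] * 5 + [self._Sized(3)] * 3
        out = m.group_and_filter(clusters)
        assert list(out) == [2] and len(out[2]) == 5

    def test_reported_size_spectrum_all_retained(self):
        counts = {2: 150, 3: 58, 4: 31, 5: 8, 6: 15}
        clusters = [self._Sized(n) for n, k in counts.items() for _ in range(k)]
        out = m.group_and_filter(clusters)
        assert {n: len(g) for n, g in out.items()} == counts


def test_evaluate_single_method_vs_itself(clean_sample):
    det = clean_sample.groundtruth.copy()
    report = m.evaluate_pipelines(
        [clean_sample.image], [clean_sample.groundtruth],
        {"a": [det], "b": [det]}, B=200, seed=0,
    )
    for entry in report["sensitivity_by_size"].values():
        for key, p in entry["p_values"].items():
            assert p == 1.0
    assert report["dice"]["a"]["mean"] == report["dice"]["b"]["mean"]
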