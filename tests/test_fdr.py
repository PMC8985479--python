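import numpy as np
import pandas as pd
import pytest

from conjfdr.errors import InputError
from conjfdr.fdr import (
    CondFdrGrid,
    GridSpec,
    build_condfdr_grid,
    compute_conjfdr,
    conditional_qq,
    lookup_condfdr,
    qq_deflection,
    weighted_ecdf,
)
from conjfdr.simulate import WORKED_FIXTURE_EXPECTED


def make_pair(p1, p2, chrom="1"):
    n = len(p1)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * 1000,
            "a1": "A",
            "a2": "G",
            "z1": 0.0,
            "p1": np.asarray(p1, dtype=float),
            "z2": 0.0,
            "p2": np.asarray(p2, dtype=float),
        }
    )


class TestWeightedECDF:
    def test_equal_weights_reduce_to_ordinary_ecdf(self):
        f = weighted_ecdf([0.3, 0.1, 0.2])
        assert f(0.1) == pytest.approx(1 / 3)
        assert f(0.25) == pytest.approx(2 / 3)
        assert f(0.3) == pytest.approx(1.0)

    def test_weighted_value(self):
        f = weighted_ecdf([0.1, 0.2], weights=[1.0, 0.5])
        assert f(0.1) == pytest.approx(1 / 1.5)

    def test_below_minimum_is_zero(self):
        f = weighted_ecdf([0.1, 0.2])
        assert f(0.05) == 0.0

    def test_zero_total_weight_rejected(self):
        with pytest.raises(InputError):
            weighted_ecdf([0.1], weights=[0.0])

    def test_right_continuity_and_bounds(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=50)
        w = rng.uniform(0.1, 1.0, size=50)
        f = weighted_ecdf(v, w)
        xs = np.sort(v)
        vals = f(xs)
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] == pytest.approx(1.0)


class TestConditionalQQ:
    def test_threshold_one_equals_all_snp_curve(self):
        rng = np.random.default_rng(1)
        pair = make_pair(rng.uniform(size=500), rng.uniform(size=500))
        curves = conditional_qq(pair, thresholds=(1.0,), min_stratum_weight=10)
        assert len(curves) == 1
        c = curves[0]
        assert len(c.expected) == 500
        # observed sorted ascending along expected; curve endpoints sane
        assert np.all(np.diff(c.observed) >= 0)
        assert c.effective_n == pytest.approx(500)

    def test_null_deflection_near_zero(self):
        rng = np.random.default_rng(2)
        pair = make_pair(rng.uniform(size=5000), rng.uniform(size=5000))
        curves = conditional_qq(pair, min_stratum_weight=10)
        for c in curves:
            assert abs(qq_deflection(c)) < 0.1

    def test_enriched_stratum_deflects_upward(self):
        rng = np.random.default_rng(3)
        n = 4000
        p1 = rng.uniform(size=n)
        p2 = rng.uniform(size=n)
        shared = rng.choice(n, 150, replace=False)
        p1[shared] = 10.0 ** rng.uniform(-8, -2, size=150)
        p2[shared] = 10.0 ** rng.uniform(-8, -2, size=150)
        curves = conditional_qq(make_pair(p1, p2), min_stratum_weight=10)
        d = {c.stratum_threshold: qq_deflection(c) for c in curves}
        assert d[0.001] > d[0.1] > d[1.0]

    def test_small_stratum_omitted(self):
        rng = np.random.default_rng(4)
        pair = make_pair(rng.uniform(size=200), rng.uniform(0.5, 1.0, size=200))
        curves = conditional_qq(pair, min_stratum_weight=50)
        assert [c.stratum_threshold for c in curves] == [1.0]

    def test_empty_pair_rejected(self):
        with pytest.raises(InputError):
            conditional_qq(make_pair([], []))


class TestCondFdrGrid:
    def test_worked_fixture_counting(self, worked_pair):
        grid = build_condfdr_grid(worked_pair)
        cut = WORKED_FIXTURE_EXPECTED["stratum_p2"]
        for p1, expected in WORKED_FIXTURE_EXPECTED["cfdr_at"].items():
            assert lookup_condfdr(grid, p1, cut) == pytest.approx(expected, abs=1e-12)

    def test_five_snp_stratum_by_hand(self):
        # stratum of 5 equally weighted SNPs; ecdf(0.02) = 2/5 -> cFDR = 0.05
        p1 = [0.001, 0.02, 0.3, 0.5, 0.9]
        pair = make_pair(p1, [0.05] * 5)
        grid = build_condfdr_grid(pair)
        assert lookup_condfdr(grid, 0.02, 0.05) == pytest.approx(0.05, abs=1e-12)

    def test_single_extreme_snp(self):
        # smallest p1 = 1e-6 alone below it, stratum weight 5 -> ecdf 0.2 -> 5e-6
        p1 = [1e-6, 0.3, 0.5, 0.7, 0.9]
        pair = make_pair(p1, [0.01] * 5)
        grid = build_condfdr_grid(pair)
        assert lookup_condfdr(grid, 1e-6, 0.01) == pytest.approx(5e-6, rel=1e-9)

    def test_null_grid_values_near_one(self):
        rng = np.random.default_rng(5)
        n = 5000
        pair = make_pair(rng.uniform(size=n), rng.uniform(size=n))
        grid = build_condfdr_grid(pair)
        # at p1 = 0.5 in the all-SNP column the estimate is ~0.5/0.5 = 1
        assert lookup_condfdr(grid, 0.5, 1.0) == pytest.approx(1.0, abs=0.1)
        assert lookup_condfdr(grid, 0.1, 1.0) == pytest.approx(1.0, abs=0.15)

    def test_monotone_in_p1_and_cut(self, worked_pair):
        grid = build_condfdr_grid(worked_pair)
        assert np.all(np.diff(grid.values, axis=0) >= -1e-15)  # along p1
        assert np.all(np.diff(grid.values, axis=1) >= -1e-15)  # looser cut >= stricter

    def test_p1_equal_one_gives_one(self, worked_pair):
        grid = build_condfdr_grid(worked_pair)
        assert lookup_condfdr(grid, 1.0, 0.5) == pytest.approx(1.0)

    def test_oracle_equivalence_on_random_fixture(self):
        """Grid + interpolation at the data points equals an independent
        brute-force evaluation of the stated construction (counting ecdf,
        running max along p1 at data points, running min over cuts)."""
        rng = np.random.default_rng(6)
        n = 15
        p1 = np.round(10.0 ** rng.uniform(-5, 0, n), 8)
        p2 = np.round(10.0 ** rng.uniform(-5, 0, n), 8)
        pair = make_pair(p1, p2)
        grid = build_condfdr_grid(pair)

        def oracle(q1, cut):
            cuts = sorted(c for c in np.unique(p2) if c >= cut)
            best = 1.0
            for c in cuts:
                ps = np.sort(p1[p2 <= c])
                m = len(ps)
                cd = np.minimum(1.0, ps * m / np.arange(1, m + 1))
                cstar = np.maximum.accumulate(cd)
                k = np.searchsorted(ps, q1, side="left")
                val = cstar[k] if k < m else max(cstar[-1], min(1.0, q1))
                if k == 0 and q1 < ps[0]:
                    val = min(cstar[0], q1 * m)
                best = min(best, val)
            return best

        for i in range(n):
            got = lookup_condfdr(grid, p1[i], p2[i])
            assert got == pytest.approx(oracle(p1[i], p2[i]), abs=1e-12)

    def test_condfdr_at_least_p1(self, worked_pair):
        grid = build_condfdr_grid(worked_pair)
        nodes = 10.0 ** grid.log10_p1
        assert np.all(grid.values >= nodes[:, None] - 1e-12)


class TestLookup:
    def grid(self):
        return CondFdrGrid(
            log10_p1=np.array([-4.0, -2.0]),
            log10_p2=np.array([-2.0, 0.0]),
            values=np.array([[0.01, 0.01], [0.04, 0.04]]),
            orientation="1|2",
        )

    def test_node_identity(self):
        assert lookup_condfdr(self.grid(), 1e-4, 1e-2) == pytest.approx(0.01)
        assert lookup_condfdr(self.grid(), 1e-2, 1.0) == pytest.approx(0.04)

    def test_log_midpoint_is_geometric_mean(self):
        assert lookup_condfdr(self.grid(), 1e-3, 1e-2) == pytest.approx(0.02)

    def test_clamping_outside_grid(self):
        assert lookup_condfdr(self.grid(), 1e-8, 1e-8) == pytest.approx(0.01)
        assert lookup_condfdr(self.grid(), 1.0, 1.0) == pytest.approx(0.04)


class TestConjFdr:
    def test_max_rule_and_role_swap(self):
        rng = np.random.default_rng(7)
        n = 300
        pair = make_pair(rng.uniform(size=n), rng.uniform(size=n))
        tab = compute_conjfdr(pair)
        assert np.allclose(tab["conjfdr"], np.maximum(tab["cfdr_1given2"], tab["cfdr_2given1"]))
        # swapping trait roles leaves the conjunction unchanged
        swapped = pair.rename(columns={"p1": "p2", "p2": "p1", "z1": "z2", "z2": "z1"})
        tab2 = compute_conjfdr(swapped)
        assert np.allclose(tab["conjfdr"], tab2["conjfdr"])
        assert np.allclose(tab["cfdr_1given2"], tab2["cfdr_2given1"])

    def test_conjfdr_bounds_both_condfdrs(self, worked_pair):
        tab = compute_conjfdr(worked_pair)
        assert (tab["conjfdr"] >= tab["cfdr_1given2"] - 1e-15).all()
        assert (tab["conjfdr"] >= tab["cfdr_2given1"] - 1e-15).all()
        assert ((tab["conjfdr"] > 0) & (tab["conjfdr"] <= 1)).all()

    def test_deterministic(self, worked_pair):
        t1 = compute_conjfdr(worked_pair)
        t2 = compute_conjfdr(worked_pair)
        pd.testing.assert_frame_equal(t1, t2)
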