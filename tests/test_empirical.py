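import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from cutroc import (
    BiomarkerSample,
    bootstrap_interval,
    bootstrap_intervals,
    empirical_auc,
    empirical_cutoffs,
    nonpar_fit,
    silverman_bandwidth,
)
from cutroc.criteria import auc_from_roc
from cutroc.empirical import (
    EmpiricalCDF,
    UnsupportedModelError,
    _empirical_candidates,
    empirical_fit,
)


def brute_force_auc(y0, y1):
    gt = (y1[:, None] > y0[None, :]).mean()
    eq = (y1[:, None] == y0[None, :]).mean()
    return gt + 0.5 * eq


class TestEmpiricalAUC:
    @pytest.mark.parametrize(
        "y0,y1,expected",
        [
            ([1, 2], [3, 4], 1.0),
            ([1, 3], [2, 4], 0.75),
            ([1, 2], [2, 3], 0.875),
        ],
    )
    def test_small_examples(self, y0, y1, expected):
        assert empirical_auc(np.array(y0, float), np.array(y1, float)) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        y0 = rng.integers(0, 8, rng.integers(2, 12)).astype(float)
        y1 = rng.integers(0, 8, rng.integers(2, 12)).astype(float)
        assert empirical_auc(y0, y1) == pytest.approx(
            brute_force_auc(y0, y1), abs=1e-12
        )

    def test_equals_trapezoid_area_under_step_roc(self):
        rng = np.random.default_rng(5)
        s = BiomarkerSample(rng.normal(0, 1, 60), rng.normal(0.8, 1.2, 60))
        roc = empirical_fit(s)
        # evaluate the step ROC densely enough to resolve every jump
        assert auc_from_roc(roc.roc, n_grid=50_001) == pytest.approx(
            roc.auc, abs=2e-4
        )


class TestEmpiricalCutoffs:
    def test_perfect_separation(self):
        s = BiomarkerSample(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        cuts = empirical_cutoffs(s)
        res = cuts["J"]
        assert res.cutoff == 2.5
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.criterion_value == pytest.approx(1.0)

    def test_identical_groups_degenerate_youden(self):
        y = np.arange(10, dtype=float)
        cuts = empirical_cutoffs(BiomarkerSample(y, y.copy()))
        assert cuts["J"].degenerate_flag

    def test_matches_exhaustive_candidate_scan(self):
        rng = np.random.default_rng(30)
        s = BiomarkerSample(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        cand = _empirical_candidates(s.y0, s.y1)
        auc = empirical_auc(s.y0, s.y1)
        cuts = empirical_cutoffs(s)
        for crit, sign in (("J", -1), ("ER", 1), ("CZ", -1), ("IU", 1)):
            vals = []
            for c in cand:
                sp = (s.y0 <= c).mean()
                se = (s.y1 > c).mean()
                if crit == "J":
                    v = se + sp - 1
                elif crit == "ER":
                    v = np.sqrt((1 - se) ** 2 + (1 - sp) ** 2)
                elif crit == "CZ":
                    v = se * sp
                else:
                    v = abs(se - auc) + abs(sp - auc)
                vals.append(sign * v)
            best = cand[np.flatnonzero(np.array(vals) <= min(vals) + 1e-12)[0]]
            if crit != "IU":  # IU applies a secondary |se-sp| tie-break
                assert cuts[crit].cutoff == best
            assert sign * cuts[crit].criterion_value == pytest.approx(
                min(vals), abs=1e-12
            )

    def test_covariates_rejected(self):
        s = BiomarkerSample(
            np.array([1.0, 2.0]), np.array([3.0, 4.0]),
            x0=np.array([[0.0], [1.0]]), x1=np.array([[0.0], [1.0]]),
        )
        with pytest.raises(UnsupportedModelError):
            empirical_cutoffs(s)

    def test_lower_is_diseased_cutoff_back_transformed(self):
        from cutroc import Direction

        # original scale: healthy at (3, 4), diseased at (1, 2); internal
        # representation is negated, cutoffs map back through negation
        s = BiomarkerSample(
            np.array([-3.0, -4.0]), np.array([-1.0, -2.0]),
            direction=Direction.lower_is_diseased,
        )
        assert empirical_cutoffs(s)["J"].cutoff == 2.5


class TestSilvermanBandwidth:
    def test_plug_in_arithmetic(self):
        # sd = 1 and IQR = 1.349 give h = 0.9 * 100^(-1/5)
        rng = np.random.default_rng(0)
        v = rng.normal(size=100)
        v = (v - v.mean()) / v.std(ddof=1)
        q1, q3 = np.percentile(v, [25, 75])
        v = v * (1.349 / (q3 - q1))
        v = v / v.std(ddof=1)  # renormalize sd to 1; IQR now ~< 1.34*sd
        h = silverman_bandwidth(v)
        spread = min(1.0, (np.percentile(v, 75) - np.percentile(v, 25)) / 1.34)
        assert h == pytest.approx(0.9 * spread * 100 ** (-0.2), rel=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=50)
        assert silverman_bandwidth(3.7 * v) == pytest.approx(
            3.7 * silverman_bandwidth(v), rel=1e-12
        )

    def test_shrinks_with_sample_size(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=4000)
        assert silverman_bandwidth(v) < silverman_bandwidth(v[:100])

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            silverman_bandwidth(np.ones(10))


class TestNonParFit:
    def test_perfect_separation(self):
        s = BiomarkerSample(
            np.array([0.0, 0.1, 0.2, 0.3]), np.array([10.0, 10.1, 10.2, 10.3])
        )
        roc, cuts = nonpar_fit(s)
        assert roc.auc >= 0.999
        for res in cuts.values():
            assert 0.3 < res.cutoff < 10.0

    def test_consistency_toward_binormal_truth(self):
        rng = np.random.default_rng(12)
        s = BiomarkerSample(rng.normal(0, 1, 500), rng.normal(1, 1, 500))
        roc, _ = nonpar_fit(s)
        assert roc.auc == pytest.approx(float(ndtr(1 / np.sqrt(2))), abs=0.05)

    def test_small_bandwidth_limit_recovers_empirical_auc(self):
        rng = np.random.default_rng(42)
        s = BiomarkerSample(rng.normal(0, 1, 200), rng.normal(1, 1, 200))
        roc, _ = nonpar_fit(s, bandwidth0=1e-4, bandwidth1=1e-4)
        assert roc.auc == pytest.approx(empirical_auc(s.y0, s.y1), abs=1e-3)

    def test_covariates_rejected(self):
        s = BiomarkerSample(
            np.array([1.0, 2.0]), np.array([3.0, 4.0]),
            x0=np.array([[0.0], [1.0]]), x1=np.array([[0.0], [1.0]]),
        )
        with pytest.raises(UnsupportedModelError):
            nonpar_fit(s)


class TestBootstrap:
    def test_constant_statistic_collapses_interval(self, binormal_sample):
        b = bootstrap_interval(lambda s: 3.14, binormal_sample, n_boot=100, seed=0)
        assert b.lower == b.upper == b.point == 3.14

    def test_same_seed_reproduces_interval(self, binormal_sample):
        stat = lambda s: empirical_auc(s.y0, s.y1)
        b1 = bootstrap_interval(stat, binormal_sample, n_boot=200, seed=9)
        b2 = bootstrap_interval(stat, binormal_sample, n_boot=200, seed=9)
        assert (b1.lower, b1.upper) == (b2.lower, b2.upper)

    def test_small_n_boot_rejected(self, binormal_sample):
        with pytest.raises(ValueError):
            bootstrap_interval(lambda s: 1.0, binormal_sample, n_boot=10, seed=0)

    def test_interval_brackets_point_for_smooth_statistic(self, binormal_sample):
        stat = lambda s: empirical_auc(s.y0, s.y1)
        b = bootstrap_interval(stat, binormal_sample, n_boot=300, seed=1)
        assert b.lower <= b.point <= b.upper

    def test_auc_interval_coverage(self):
        # percentile bootstrap interval should cover the true AUC at a rate
        # close to its nominal 95% level
        truth = float(ndtr(1 / np.sqrt(2)))
        stat = lambda s: empirical_auc(s.y0, s.y1)
        covered = 0
        n_outer = 120
        for r in range(n_outer):
            rng = np.random.default_rng(20_000 + r)
            s = BiomarkerSample(rng.normal(0, 1, 60), rng.normal(1, 1, 60))
            b = bootstrap_interval(stat, s, n_boot=250, seed=r)
            covered += b.lower <= truth <= b.upper
        assert 0.88 <= covered / n_outer <= 1.0


def test_empirical_roc_hits_corners():
    rng = np.random.default_rng(8)
    s = BiomarkerSample(rng.normal(0, 1, 40), rng.normal(1, 1, 40))
    roc = empirical_fit(s).roc
    assert float(roc(0.0)) == pytest.approx(0.0, abs=0.05)
    assert float(roc(1.0)) == pytest.approx(1.0, abs=1e-12)
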