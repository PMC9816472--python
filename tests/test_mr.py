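import numpy as np
import pytest
from scipy import stats

from dtmr.mr import (
    MrEstimate,
    QResult,
    cochran_q,
    ivw_fixed,
    mr_egger,
    wald_ratio,
    wald_ratios,
    weighted_median,
    weighted_median_point,
    write_estimates_tsv,
)

from conftest import make_hset, make_pair, random_hset


class TestWaldRatio:
    def test_forced_arithmetic(self):
        e = wald_ratio(beta_x=0.1, se_x=0.01, beta_y=0.02, se_y=0.005)
        assert e.theta == pytest.approx(0.2)
        assert e.se == pytest.approx(0.05)
        assert e.n_snps == 1

    def test_null_outcome(self):
        e = wald_ratio(beta_x=0.1, se_x=0.01, beta_y=0.0, se_y=0.005)
        assert e.theta == 0.0
        assert e.pval == 1.0

    def test_sign_symmetry(self):
        e = wald_ratio(beta_x=-0.1, se_x=0.01, beta_y=0.02, se_y=0.005)
        assert e.theta == pytest.approx(-0.2)
        assert e.se == pytest.approx(0.05)

    def test_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(beta_x=0.0, se_x=0.01, beta_y=0.02, se_y=0.005)

    def test_second_order_se_exceeds_first_order(self):
        first = wald_ratio(0.1, 0.02, 0.05, 0.01, se_order="first")
        second = wald_ratio(0.1, 0.02, 0.05, 0.01, se_order="second")
        assert second.se > first.se
        # oracle: direct delta-method formula
        expected = np.sqrt(0.01**2 / 0.1**2 + 0.05**2 * 0.02**2 / 0.1**4)
        assert second.se == pytest.approx(expected, rel=1e-12)

    def test_ci_brackets_theta(self):
        e = wald_ratio(0.1, 0.01, 0.02, 0.005)
        assert e.ci_low <= e.theta <= e.ci_high


class TestIvwFixed:
    def test_single_estimate_is_wald(self):
        w = wald_ratio(0.1, 0.01, 0.02, 0.005)
        combined = ivw_fixed([w])
        assert combined.method == "ivw_fe"
        assert combined.theta == w.theta
        assert combined.se == w.se
        assert combined.pval == w.pval

    def test_forced_arithmetic(self):
        ests = [
            MrEstimate("wald", 0.2, 0.05, 0.1, 0.3, 0.5, 1),
            MrEstimate("wald", 0.4, 0.1, 0.2, 0.6, 0.5, 1),
        ]
        combined = ivw_fixed(ests)
        assert combined.theta == pytest.approx(0.24)   # w = {400, 100}
        assert combined.se == pytest.approx(np.sqrt(1 / 500))

    def test_equal_thetas_invariant_to_weights(self, rng):
        ses = rng.uniform(0.01, 0.5, size=6)
        ests = [MrEstimate("wald", 0.37, float(s), 0.37 - s, 0.37 + s, 0.5, 1) for s in ses]
        assert ivw_fixed(ests).theta == pytest.approx(0.37)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ivw_fixed([])


class TestCochranQ:
    def test_no_heterogeneity(self):
        ests = [MrEstimate("wald", 0.2, 0.05, 0.1, 0.3, 0.5, 1)] * 3
        q = cochran_q(ests)
        assert q.q == pytest.approx(0.0, abs=1e-12)
        assert q.pval == pytest.approx(1.0)

    def test_worked_example(self):
        # Q = 400*(0.2-0.24)^2 + 100*(0.4-0.24)^2 = 3.2, df = 1
        ests = [
            MrEstimate("wald", 0.2, 0.05, 0.1, 0.3, 0.5, 1),
            MrEstimate("wald", 0.4, 0.1, 0.2, 0.6, 0.5, 1),
        ]
        q = cochran_q(ests)
        assert q.q == pytest.approx(3.2)
        assert q.df == 1
        # oracle: chi-square upper tail at (3.2, 1); frozen value 0.07363827...
        assert q.pval == pytest.approx(float(stats.chi2.sf(3.2, 1)), rel=1e-12)
        assert q.pval == pytest.approx(0.0736383, abs=1e-6)

    def test_doubling_ses_quarters_q(self):
        ests = [
            MrEstimate("wald", 0.2, 0.05, 0.1, 0.3, 0.5, 1),
            MrEstimate("wald", 0.4, 0.1, 0.2, 0.6, 0.5, 1),
        ]
        doubled = [MrEstimate("wald", e.theta, 2 * e.se, e.ci_low, e.ci_high, e.pval, 1) for e in ests]
        assert cochran_q(doubled).q == pytest.approx(cochran_q(ests).q / 4)

    def test_single_estimate_raises(self):
        with pytest.raises(ValueError):
            cochran_q([MrEstimate("wald", 0.2, 0.05, 0.1, 0.3, 0.5, 1)])

    def test_qresult_invariants(self):
        with pytest.raises(ValueError):
            QResult(q=-1.0, df=1, pval=0.5)
        with pytest.raises(ValueError):
            QResult(q=1.0, df=0, pval=0.5)


def oracle_weighted_median(theta, weights):
    """Direct evaluation of the interpolation formula, independent of numpy interp."""
    order = sorted(range(len(theta)), key=lambda i: theta[i])
    t = [theta[i] for i in order]
    w = [weights[i] for i in order]
    total = sum(w)
    s = []
    acc = 0.0
    for wi in w:
        acc += wi
        s.append((acc - wi / 2) / total)
    if 0.5 <= s[0]:
        return t[0]
    if 0.5 >= s[-1]:
        return t[-1]
    for i in range(len(s) - 1):
        if s[i] <= 0.5 <= s[i + 1]:
            frac = (0.5 - s[i]) / (s[i + 1] - s[i])
            return t[i] + frac * (t[i + 1] - t[i])
    raise AssertionError("unreachable")


class TestWeightedMedian:
    def test_equal_weights_reduce_to_plain_median(self):
        assert weighted_median_point([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]) == pytest.approx(2.0)

    def test_worked_interpolation_example(self):
        # s = {0.0833, 0.25, 0.6667}; interpolate to 0.5 -> 2.6
        assert weighted_median_point([1.0, 2.0, 3.0], [1.0, 1.0, 4.0]) == pytest.approx(2.6)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            j = int(rng.integers(3, 9))
            theta = rng.normal(0, 1, size=j)
            weights = rng.uniform(0.1, 5.0, size=j)
            assert weighted_median_point(theta, weights) == pytest.approx(
                oracle_weighted_median(list(theta), list(weights)), rel=1e-12
            )

    def test_estimator_point_and_determinism(self, rng):
        hset = random_hset(rng, j=6, theta=0.3)
        e1 = weighted_median(hset, n_boot=200, seed=7)
        e2 = weighted_median(hset, n_boot=200, seed=7)
        assert e1.se == e2.se  # bit-identical under the same seed
        ests = wald_ratios(hset)
        expected_point = oracle_weighted_median(
            [e.theta for e in ests], [1 / e.se**2 for e in ests]
        )
        assert e1.theta == pytest.approx(expected_point, rel=1e-12)

    def test_requires_three_pairs_and_seed(self, rng):
        hset = random_hset(rng, j=2)
        with pytest.raises(ValueError):
            weighted_median(hset, n_boot=10, seed=1)
        hset3 = random_hset(rng, j=3)
        with pytest.raises(ValueError):
            weighted_median(hset3, n_boot=10, seed=None)


def oracle_egger_normal_equations(bx, by, sy):
    """Explicit 2x2 weighted normal equations for intercept + slope."""
    w = 1.0 / np.asarray(sy) ** 2
    x = np.asarray(bx)
    y = np.asarray(by)
    s_w, s_wx, s_wxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    s_wy, s_wxy = (w * y).sum(), (w * x * y).sum()
    a = np.array([[s_w, s_wx], [s_wx, s_wxx]])
    b = np.array([s_wy, s_wxy])
    intercept, slope = np.linalg.solve(a, b)
    return slope, intercept


class TestMrEgger:
    def test_exact_line_through_collinear_points(self):
        pairs = [make_pair(f"rs{i}", beta_x=float(i + 1), beta_y=2.0 * (i + 1) + 0.1, se_y=0.01)
                 for i in range(3)]
        slope, intercept = mr_egger(make_hset(pairs))
        assert slope.theta == pytest.approx(2.0, abs=1e-10)
        assert intercept.theta == pytest.approx(0.1, abs=1e-10)

    def test_no_pleiotropy_gives_zero_intercept(self, rng):
        c = -0.7
        pairs = [make_pair(f"rs{i}", beta_x=bx, beta_y=c * bx, se_y=float(rng.uniform(0.005, 0.02)))
                 for i, bx in enumerate(rng.uniform(-0.3, -0.05, size=8))]
        slope, intercept = mr_egger(make_hset(pairs))
        assert slope.theta == pytest.approx(c, abs=1e-10)
        assert intercept.theta == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        hset = random_hset(rng, j=10, theta=0.4, intercept=0.002)
        slope, intercept = mr_egger(hset)
        bx = [p.beta_x for p in hset.pairs]
        by = [p.beta_y for p in hset.pairs]
        sy = [p.se_y for p in hset.pairs]
        o_slope, o_intercept = oracle_egger_normal_equations(bx, by, sy)
        assert slope.theta == pytest.approx(o_slope, abs=1e-10)
        assert intercept.theta == pytest.approx(o_intercept, abs=1e-10)

    def test_too_few_pairs_raises(self, rng):
        with pytest.raises(ValueError):
            mr_egger(random_hset(rng, j=2))

    def test_identical_exposure_effects_singular(self):
        pairs = [make_pair(f"rs{i}", beta_x=-0.1, beta_y=0.01 * i) for i in range(4)]
        with pytest.raises(np.linalg.LinAlgError):
            mr_egger(make_hset(pairs))

    def test_dispersion_floor_never_shrinks_se(self, rng):
        # near-perfect fit would give scale << 1; the floor keeps the unscaled SE
        pairs = [make_pair(f"rs{i}", beta_x=bx, beta_y=0.3 * bx + 1e-9, se_y=0.01)
                 for i, bx in enumerate(rng.uniform(-0.3, -0.05, size=6))]
        slope, _ = mr_egger(make_hset(pairs))
        bx = np.array([p.beta_x for p in pairs])
        w = np.full(len(pairs), 1 / 0.01**2)
        xbar = (w * bx).sum() / w.sum()
        unscaled_se = np.sqrt(1.0 / (w * (bx - xbar) ** 2).sum())
        assert slope.se == pytest.approx(unscaled_se, rel=1e-9)


class TestEstimatorIdentities:
    def test_ivw_on_one_snp_equals_wald(self):
        w = wald_ratio(-0.12, 0.01, 0.003, 0.001)
        combined = ivw_fixed([w])
        assert (combined.theta, combined.se) == (w.theta, w.se)

    def test_egger_through_origin_equals_ivw(self, rng):
        # algebraic identity under first-order Wald SEs
        for _ in range(50):
            hset = random_hset(rng, j=int(rng.integers(3, 12)), theta=float(rng.normal()))
            ivw = ivw_fixed(wald_ratios(hset, se_order="first"))
            slope = mr_egger(hset, fit_intercept=False)
            assert slope.theta == pytest.approx(ivw.theta, abs=1e-10)

    def test_joint_sign_flip_equivariance(self, rng):
        hset = random_hset(rng, j=8, theta=0.25, intercept=0.003)
        flipped = make_hset([
            make_pair(p.rsid, beta_x=-p.beta_x, se_x=p.se_x, beta_y=-p.beta_y, se_y=p.se_y)
            for p in hset.pairs
        ])
        ivw_a = ivw_fixed(wald_ratios(hset))
        ivw_b = ivw_fixed(wald_ratios(flipped))
        assert ivw_b.theta == pytest.approx(ivw_a.theta, rel=1e-12)
        wm_a = weighted_median(hset, n_boot=50, seed=3)
        wm_b = weighted_median(flipped, n_boot=50, seed=3)
        assert wm_b.theta == pytest.approx(wm_a.theta, rel=1e-12)
        slope_a, int_a = mr_egger(hset)
        slope_b, int_b = mr_egger(flipped)
        assert slope_b.theta == pytest.approx(slope_a.theta, rel=1e-10)
        assert int_b.theta == pytest.approx(-int_a.theta, rel=1e-10)


class TestStochasticCalibration:
    def test_q_rejection_and_ivw_coverage_under_null_heterogeneity(self, rng):
        # scaled-down sibling of the acceptance criterion (200 reps here)
        theta_true = 0.1
        j = 10
        hits, rejects = 0, 0
        reps = 200
        for _ in range(reps):
            bx = rng.uniform(-0.4, -0.2, size=j)
            sy = np.full(j, 0.01)
            by = theta_true * bx + rng.normal(0, sy)
            pairs = [make_pair(f"rs{i}", beta_x=float(bx[i]), se_x=1e-6,
                               beta_y=float(by[i]), se_y=float(sy[i])) for i in range(j)]
            ests = wald_ratios(make_hset(pairs))
            ivw = ivw_fixed(ests)
            if ivw.ci_low <= theta_true <= ivw.ci_high:
                hits += 1
            if cochran_q(ests).pval < 0.05:
                rejects += 1
        assert 0.90 <= hits / reps <= 0.99
        assert rejects / reps <= 0.12


class TestEstimatesExport:
    def test_tsv_round_trips_numbers(self, tmp_path, rng):
        hset = random_hset(rng, j=5, theta=0.2)
        ests = [ivw_fixed(wald_ratios(hset))]
        p = tmp_path / "estimates.tsv"
        write_estimates_tsv(ests, p)
        lines = p.read_text().strip().split("\n")
        assert lines[0] == "method\ttheta\tse\tci_low\tci_high\tpval\tn_snps"
        fields = lines[1].split("\t")
        assert fields[0] == "ivw_fe"
        assert float(fields[1]) == ests[0].theta
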