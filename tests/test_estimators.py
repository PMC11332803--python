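import numpy as np
import pytest

from mrmediate import (
    DegenerateExposureError,
    HarmonizedSet,
    InsufficientInstrumentsError,
    MrResult,
    classify_direction,
    generate_chain,
    harmonize,
    ivw,
    mode_estimator,
    mr_egger,
    run_all_estimators,
    wald_ratio,
    weighted_median,
)


def h_from_ratios(ratios, weights=None, sy=0.05):
    """Harmonized set whose per-SNP ratios (and IV weights) are exactly as given."""
    ratios = np.asarray(ratios, float)
    if weights is None:
        bx = np.ones_like(ratios)
    else:
        bx = sy * np.sqrt(np.asarray(weights, float))
    return HarmonizedSet.from_arrays(bx, np.full_like(bx, 1e-6), ratios * bx, np.full_like(bx, sy))


class TestWaldRatio:
    def test_direct_division(self):
        res = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)
        assert res.or_ == pytest.approx(np.exp(0.5), rel=1e-12)

    def test_null_outcome(self):
        res = wald_ratio(0.1, 0.02, 0.0, 0.01)
        assert res.beta == 0.0
        assert res.or_ == 1.0

    def test_zero_exposure_rejected(self):
        with pytest.raises(DegenerateExposureError):
            wald_ratio(0.0, 0.02, 0.05, 0.01)

    def test_second_order_se_matches_monte_carlo(self):
        bx, sx, by, sy = 0.1, 0.005, 0.05, 0.01
        res = wald_ratio(bx, sx, by, sy, se_method="second")
        rng = np.random.default_rng(42)
        n = 1_000_000
        draws = (by + sy * rng.standard_normal(n)) / (bx + sx * rng.standard_normal(n))
        assert res.se == pytest.approx(np.std(draws), rel=0.02)


class TestIvw:
    def test_weighted_ls_through_origin_oracle(self, three_snp_h):
        res = ivw(three_snp_h, model="fixed")
        assert res.beta == pytest.approx(820 / 1400, rel=1e-12)
        # independently coded weighted LS through the origin
        bx, by, sy = three_snp_h.beta_exp, three_snp_h.beta_out, three_snp_h.se_out
        w = 1 / sy**2
        oracle = np.sum(bx * by * w) / np.sum(bx**2 * w)
        assert res.beta == pytest.approx(oracle, rel=1e-14)
        assert res.se == pytest.approx(np.sqrt(1 / np.sum(bx**2 * w)), rel=1e-12)

    def test_consensus_ratios(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2, 0.4], [0.01] * 3,
                                      [0.05, 0.10, 0.20], [0.01, 0.02, 0.03])
        res = ivw(h)
        assert res.beta == pytest.approx(0.5, rel=1e-12)
        assert res.extras["q_statistic"] == pytest.approx(0.0, abs=1e-20)
        assert res.extras["q_pvalue"] == pytest.approx(1.0)

    def test_single_snp_equals_wald_ratio(self):
        h = HarmonizedSet.from_arrays([0.1], [0.02], [0.05], [0.01])
        res = ivw(h)
        ref = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert res.beta == pytest.approx(ref.beta) and res.se == pytest.approx(ref.se)

    def test_degenerate_exposure(self):
        h = HarmonizedSet.from_arrays([0.0, 0.0], [0.01] * 2, [0.1, 0.2], [0.01] * 2)
        with pytest.raises(DegenerateExposureError):
            ivw(h)

    def test_random_effects_never_below_fixed(self, three_snp_h):
        assert ivw(three_snp_h, "multiplicative_random").se >= ivw(three_snp_h, "fixed").se


class TestMrEgger:
    def test_exact_collinear_fit(self, collinear_h):
        res = mr_egger(collinear_h)
        assert res.beta == pytest.approx(0.5, rel=1e-9)
        assert res.extras["egger_intercept"] == pytest.approx(0.02, rel=1e-9)

    def test_requires_three_snps(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)

    def test_orientation_invariance(self, collinear_h):
        flipped = HarmonizedSet.from_arrays(
            -collinear_h.beta_exp, collinear_h.se_exp, -collinear_h.beta_out, collinear_h.se_out
        )
        a, b = mr_egger(collinear_h), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.extras["egger_intercept"] == pytest.approx(b.extras["egger_intercept"], rel=1e-12)

    def test_directional_pleiotropy_recovered(self):
        """Constant per-SNP pleiotropy equals the Egger intercept (InSIDE holds).

        Instruments are selected first: with unselected weak SNPs the
        exposure-allele orientation is random, which would wash out the
        planted directional effect.
        """
        from mrmediate import filter_weak, select_by_pvalue

        alpha = 0.03
        intercepts = []
        for rep in range(500):
            bundle = generate_chain(
                j_snps=50, j_mediator_snps=0, seed=50_000 + rep,
                pleiotropy_mode="directional", pleiotropy_magnitude=alpha, pleiotropy_fraction=1.0,
            )
            inst = filter_weak(select_by_pvalue(bundle.exposure, 1e-5), 10).as_summary()
            h = harmonize(inst, bundle.outcome)
            intercepts.append(mr_egger(h).extras["egger_intercept"])
        intercepts = np.asarray(intercepts)
        mc_se = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean() - alpha) < 2 * mc_se + 1e-4


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        res = weighted_median(h_from_ratios([0.4, 0.5, 0.6]), n_boot=100, seed=1)
        assert res.beta == pytest.approx(0.5, rel=1e-9)

    def test_majority_weight_dominates(self):
        res = weighted_median(h_from_ratios([0.3, 0.9, 1.5], weights=[30, 1, 1]),
                              n_boot=100, seed=1)
        assert abs(res.beta - 0.3) < 0.1

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2,
                                                      [0.05, 0.1], [0.01] * 2),
                            n_boot=10, seed=1)

    def test_bootstrap_reproducible(self):
        h = h_from_ratios([0.4, 0.45, 0.5, 0.55, 0.6])
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        assert a.se == b.se and a.pvalue == b.pvalue


class TestModeEstimator:
    def test_point_mass(self):
        res = mode_estimator(h_from_ratios([0.7, 0.7, 0.7]), n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.7)

    def test_dominant_cluster(self):
        res = mode_estimator(h_from_ratios([0.5, 0.5, 0.5, 0.9]), weighted=False,
                             phi=0.3, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.5, abs=0.05)

    def test_bimodal_majority_mode_beats_ivw(self):
        """With a 60/40 bimodal ratio mixture the mode tracks the majority
        cluster while the inverse-variance mean lands between the modes."""
        wins = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(7_000 + rep)
            ratios = np.concatenate([
                0.5 + 0.02 * rng.standard_normal(12),
                1.2 + 0.02 * rng.standard_normal(8),
            ])
            h = h_from_ratios(ratios)
            mode_b = mode_estimator(h, weighted=False, n_boot=10, seed=rep).beta
            ivw_b = ivw(h).beta
            wins += abs(mode_b - 0.5) < abs(ivw_b - 0.5)
        assert wins / reps >= 0.95


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "beta,p,expected",
        [
            (0.147, 0.04, "risk"),
            (-0.120, 0.03, "protective"),
            (0.5, 0.5, "no_causal_evidence"),
            (0.0, 0.01, "no_causal_evidence"),
        ],
    )
    def test_decision_rule(self, beta, p, expected):
        res = MrResult("ivw", beta, 0.1, p, 10)
        assert classify_direction(res) == expected

    def test_or_side_matches_beta_sign(self):
        assert MrResult("ivw", 0.147, 0.07, 0.04, 10).or_ > 1
        assert MrResult("ivw", -0.120, 0.05, 0.03, 10).or_ < 1


class TestEquivariance:
    @pytest.fixture
    def base_h(self):
        rng = np.random.default_rng(3)
        bx = 0.1 + 0.05 * rng.random(8)
        return HarmonizedSet.from_arrays(bx, np.full(8, 0.01),
                                         0.4 * bx + 0.01 * rng.standard_normal(8),
                                         np.full(8, 0.012))

    def test_outcome_scale_equivariance(self, base_h):
        k = 2.5
        scaled = HarmonizedSet.from_arrays(base_h.beta_exp, base_h.se_exp,
                                           k * base_h.beta_out, k * base_h.se_out)
        for fn in (
            lambda h: ivw(h),
            lambda h: mr_egger(h),
            lambda h: weighted_median(h, n_boot=100, seed=5),
            lambda h: mode_estimator(h, weighted=True, n_boot=100, seed=5),
        ):
            a, b = fn(base_h), fn(scaled)
            assert b.beta == pytest.approx(k * a.beta, rel=1e-9)
            assert b.se == pytest.approx(k * a.se, rel=1e-6)
            assert b.pvalue == pytest.approx(a.pvalue, rel=1e-6)

    def test_outcome_sign_equivariance(self, base_h):
        negated = HarmonizedSet.from_arrays(base_h.beta_exp, base_h.se_exp,
                                            -base_h.beta_out, base_h.se_out)
        for fn, exact_se in (
            (lambda h: ivw(h), True),
            (lambda h: mr_egger(h), True),
            (lambda h: weighted_median(h, n_boot=100, seed=5), False),
            (lambda h: mode_estimator(h, weighted=True, n_boot=100, seed=5), False),
        ):
            a, b = fn(base_h), fn(negated)
            assert b.beta == pytest.approx(-a.beta, rel=1e-9)
            if exact_se:
                assert b.se == pytest.approx(a.se, rel=1e-12)
                assert b.pvalue == pytest.approx(a.pvalue, rel=1e-12)


def test_estimators_converge_with_sample_size():
    """With all instruments valid, the five estimators agree as n grows."""

    def spread(n, seed):
        bundle = generate_chain(j_snps=50, j_mediator_snps=0, n_exp=n, n_med=n, n_out=n,
                                seed=seed)
        h = harmonize(bundle.exposure, bundle.mediator)
        results = run_all_estimators(h, seed=seed, n_boot=100)
        betas = [r.beta for r in results.values()]
        return max(betas) - min(betas)

    small = np.mean([spread(2_000, s) for s in (11, 12, 13)])
    large = np.mean([spread(200_000, s) for s in (11, 12, 13)])
    assert large < small
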