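import numpy as np
import pytest
from scipy import stats

from genolrt.genotypic_lrt import (
    calibrated_statistic,
    expected_case_freqs,
    genotype_class_groups,
    group_counts,
    lrt_statistic,
    multinomial_covariance,
    simulated_variance,
)
from genolrt.panel_io import joint_genotype_freq
from genolrt.virtual_variant import collapse

from conftest import make_panel


def reweighting_oracle(g, d, d_case):
    """Exhaustive per-individual importance weighting P(D'_j)/P(D_j)."""
    d_ctrl = np.bincount(d, minlength=3) / d.size
    weights = np.array([d_case[j] / d_ctrl[j] if d_ctrl[j] > 0 else 0.0 for j in d])
    pi = np.zeros(3)
    for a in range(3):
        pi[a] = weights[g == a].sum() / d.size
    return pi


class TestExpectedCaseFreqs:
    def test_candidate_equal_to_disease_variant_returns_case_triple(self):
        d = np.array([0, 0, 1, 2, 1, 0, 0, 1, 0, 2])
        joint = joint_genotype_freq(d, d)
        d_case = np.array([0.2, 0.5, 0.3])
        out = expected_case_freqs(joint, d_case)
        assert np.allclose(out.pi, d_case)

    def test_independent_joint_returns_control_margins(self):
        rng = np.random.default_rng(11)
        g = rng.integers(0, 3, 3000)
        d = rng.integers(0, 3, 3000)
        # force exact independence: build the table as the outer product
        from genolrt.panel_io import JointGenotypeFreq

        pg = np.bincount(g, minlength=3) / g.size
        pd_ = np.bincount(d, minlength=3) / d.size
        joint = JointGenotypeFreq(table=np.outer(pg, pd_))
        out = expected_case_freqs(joint, [0.1, 0.3, 0.6])
        assert np.allclose(out.pi, pg, atol=1e-12)

    @pytest.mark.parametrize("n", [10, 20, 30])
    def test_matches_exhaustive_reweighting_oracle(self, n):
        rng = np.random.default_rng(n)
        g = rng.integers(0, 3, n)
        d = rng.integers(0, 3, n)
        d_case = rng.dirichlet([2, 2, 2])
        d_case[np.bincount(d, minlength=3) == 0] = 0.0
        d_case = d_case / d_case.sum()
        joint = joint_genotype_freq(g, d)
        out = expected_case_freqs(joint, d_case)
        assert np.allclose(out.pi, reweighting_oracle(g, d, d_case), atol=1e-12)
        assert out.pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unreachable_case_genotype_is_an_error(self):
        d = np.array([0, 0, 1, 1, 0, 0])  # no homozygote in controls
        joint = joint_genotype_freq(d, d)
        with pytest.raises(ValueError, match="unreachable"):
            expected_case_freqs(joint, [0.5, 0.3, 0.2])


class TestMultinomialCovariance:
    def test_two_category_case_is_the_binomial_variance(self):
        cov = multinomial_covariance([0.3, 0.7, 0.0], 100)
        assert cov.shape == (1, 1)
        assert cov[0, 0] == pytest.approx(21.0)

    def test_determinant_matches_monte_carlo_oracle(self):
        pi = np.array([0.25, 0.5, 0.25])
        cov = multinomial_covariance(pi, 100)
        rng = np.random.default_rng(0)
        draws = rng.multinomial(100, pi, size=100_000)[:, :2]
        mc = np.cov(draws, rowvar=False)
        assert np.linalg.det(cov) == pytest.approx(np.linalg.det(mc), rel=0.03)

    def test_zero_category_reduces_dimension(self):
        cov = multinomial_covariance([0.5, 0.0, 0.5], 50)
        assert cov.shape == (1, 1)
        assert cov[0, 0] == pytest.approx(50 * 0.25)


class TestGenotypeClassGroups:
    def test_rare_homozygote_class_is_pooled_with_carriers(self):
        groups = genotype_class_groups([0.9, 0.095, 0.005], n=500)
        assert [list(g) for g in groups] == [[0], [1, 2]]

    def test_well_filled_classes_stay_separate(self):
        groups = genotype_class_groups([0.25, 0.5, 0.25], n=500)
        assert [list(g) for g in groups] == [[0], [1], [2]]

    def test_group_counts_assigns_stray_mass_to_nearest_group(self):
        groups = [np.array([0]), np.array([1])]
        out = group_counts(np.array([10.0, 5.0, 2.0]), groups)
        assert list(out) == [10.0, 7.0]


class TestSimulatedVariance:
    def make_setup(self, seed=0, n_ctrl=2000):
        rng = np.random.default_rng(seed)
        # two independent common variants; candidate 1 has no LD with the
        # "disease" variant 0
        hap = rng.integers(0, 2, size=(2 * n_ctrl, 2)).astype(np.int8)
        hap[: n_ctrl // 4] = [1, 0]
        panel = make_panel(hap)
        virt = collapse(panel, [0])
        return panel, virt

    def test_identical_seed_gives_identical_determinant(self):
        panel, virt = self.make_setup()
        d_case = np.array([0.3, 0.5, 0.2])
        s1 = simulated_variance(panel.haplotypes, virt, d_case, 1, 200, reps=100, seed=5)
        s2 = simulated_variance(panel.haplotypes, virt, d_case, 1, 200, reps=100, seed=5)
        assert s1.det == s2.det
        assert np.array_equal(s1.statistics, s2.statistics)

    def test_no_ld_determinant_near_model_multinomial(self):
        panel, virt = self.make_setup(seed=1)
        d_ctrl = np.bincount(virt.genotypes, minlength=3) / panel.n_individuals
        n_cases = 100  # small against the control pool: sampling noise dominates
        sim = simulated_variance(
            panel.haplotypes, virt, d_ctrl, 1, n_cases, reps=1000, enrich=0.0, seed=2
        )
        g = panel.genotypes()[:, 1]
        pi = np.bincount(g, minlength=3) / g.size
        det_model = np.linalg.det(multinomial_covariance(pi, n_cases))
        assert sim.det == pytest.approx(det_model, rel=0.25)

    def test_low_rep_runs_are_flagged(self):
        panel, virt = self.make_setup()
        s = simulated_variance(
            panel.haplotypes, virt, [0.3, 0.5, 0.2], 1, 50, reps=2, seed=0
        )
        assert s.low_precision

    def test_rep_floor_enforced(self):
        panel, virt = self.make_setup()
        with pytest.raises(ValueError):
            simulated_variance(panel.haplotypes, virt, [0.3, 0.5, 0.2], 1, 50, reps=1)


class TestLrtStatistic:
    def test_exact_fit_with_unit_correction_is_zero(self):
        res = lrt_statistic([25, 50, 25], [0.25, 0.5, 0.25], 1.0, 1.0)
        assert res.statistic == 0.0
        assert res.p_lower == 0.0
        assert res.df == 2

    def test_plain_g_statistic_closed_form(self):
        o = np.array([30, 50, 20])
        pi = np.array([0.25, 0.5, 0.25])
        res = lrt_statistic(o, pi, 1.0, 1.0)
        expected = 2 * sum(x * np.log(x / (100 * p)) for x, p in zip(o, pi))
        assert res.statistic == pytest.approx(expected)
        assert res.raw_statistic == pytest.approx(expected)

    def test_determinant_ratio_rescales_the_statistic(self):
        o, pi = [30, 50, 20], [0.25, 0.5, 0.25]
        base = lrt_statistic(o, pi, 1.0, 1.0).statistic
        halved = lrt_statistic(o, pi, 1.0, 4.0).statistic
        assert halved == pytest.approx(base / 2.0)  # (1/4)^(1/2)

    def test_zero_expected_with_observed_rejects_outright(self):
        res = lrt_statistic([5, 90, 5], [0.5, 0.5, 0.0], 1.0, 1.0)
        assert np.isinf(res.statistic)
        assert res.p_lower == 1.0

    def test_statistic_invariant_to_category_order(self):
        o = np.array([12, 55, 33])
        pi = np.array([0.1, 0.55, 0.35])
        perm = [2, 0, 1]
        a = lrt_statistic(o, pi, 1.0, 1.0).statistic
        b = lrt_statistic(o[perm], pi[perm], 1.0, 1.0).statistic
        assert a == pytest.approx(b)


class TestCalibratedStatistic:
    def test_chi_square_null_returns_statistic_nearly_unchanged(self):
        rng = np.random.default_rng(3)
        null = rng.chisquare(2, size=20_000)
        for g in (0.5, 2.0, 5.0):
            t, p = calibrated_statistic(g, null, df=2)
            assert t == pytest.approx(g, rel=0.1)
            assert p == pytest.approx(stats.chi2.cdf(g, 2), abs=0.02)

    def test_observed_beyond_all_resamples_maps_to_the_top_rank(self):
        t, p = calibrated_statistic(1000.0, np.arange(199.0), df=1)
        assert p == pytest.approx((199 + 0.5) / 200)
        assert t == pytest.approx(stats.chi2.ppf(p, 1))
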