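import numpy as np
import pytest
from scipy.stats import geom, pearsonr
from scipy.stats import zipf as scipy_zipf

from cdszipf.rankfreq import RankedDistribution, assign_ranks, build_table
from cdszipf.synthetic import SyntheticSpec, sample_zm
from cdszipf.zipf_model import (
    ZipfParams,
    evaluate_fit,
    expected_frequencies,
    fit_clauset,
    fit_mle,
    is_degenerate,
    log_likelihood,
    split_half_fit,
    zm_pmf,
)

from conftest import grid_argmax


def _ranked(counts):
    words = tuple(f"w{i}" for i in range(len(counts)))
    return RankedDistribution(words, np.asarray(counts, dtype=float))


class TestPmf:
    @pytest.mark.parametrize(
        "alpha,beta,n,expected",
        [
            (2.0, 0.0, 3, [0.7347, 0.1837, 0.0816]),
            (1.0, 1.0, 2, [0.6, 0.4]),
            (1.7, 3.0, 1, [1.0]),
        ],
    )
    def test_examples(self, alpha, beta, n, expected):
        np.testing.assert_allclose(zm_pmf(ZipfParams(alpha, beta), n), expected,
                                   atol=5e-5)

    @pytest.mark.parametrize("n", [10, 1_000, 1_000_000])
    @pytest.mark.parametrize("alpha,beta", [(1.16, 0.0), (1.57, 19.48), (115.0, 476.0)])
    def test_normalization(self, n, alpha, beta):
        p = zm_pmf(ZipfParams(alpha, beta), n)
        assert abs(p.sum() - 1.0) < 1e-12
        # strictly decreasing in rank (checked in log space, where extreme
        # exponents cannot underflow)
        from cdszipf.zipf_model import zm_log_pmf
        assert np.all(np.diff(zm_log_pmf(ZipfParams(alpha, beta), n)) < 0) or n == 1

    def test_alpha_steepens_distribution(self):
        lo = zm_pmf(ZipfParams(1.1, 5.0), 500)
        hi = zm_pmf(ZipfParams(1.8, 5.0), 500)
        assert hi[0] > lo[0]
        assert hi[100:].sum() < lo[100:].sum()

    def test_matches_scipy_zipf_at_beta_zero(self):
        """Truncated ZM with beta=0 tracks the infinite-support zeta law."""
        a = 2.5
        n = 200_000
        ours = zm_pmf(ZipfParams(a, 0.0), n)
        theirs = scipy_zipf.pmf(np.arange(1, 51), a)
        np.testing.assert_allclose(ours[:50], theirs, rtol=1e-3)

    def test_invalid_params_error(self):
        with pytest.raises(ValueError):
            ZipfParams(-1.0, 0.0)
        with pytest.raises(ValueError):
            ZipfParams(1.0, -0.5)


class TestLogLikelihood:
    def test_closed_form(self):
        ll = log_likelihood(ZipfParams(1.0, 0.0), _ranked([3, 1]))
        assert ll == pytest.approx(3 * np.log(2 / 3) + np.log(1 / 3), abs=1e-10)

    def test_single_rank_is_zero(self):
        assert log_likelihood(ZipfParams(4.2, 7.0), _ranked([1])) == pytest.approx(0.0)

    def test_optimum_dominates_grid(self):
        counts = [120, 60, 31, 14, 9, 5, 3, 2, 1, 1]
        fit = fit_mle(_ranked(counts))
        best_ll, _, _ = grid_argmax(counts, np.arange(0.5, 3.0, 0.01),
                                    np.arange(0.0, 5.0, 0.05))
        assert fit.log_likelihood >= best_ll - 1e-9


class TestFitMle:
    def test_matches_grid_oracle_within_one_step(self):
        counts = [100, 50, 25, 12, 6]
        fit = fit_mle(_ranked(counts), alpha_bounds=(0.5, 3.0), beta_bounds=(0.0, 5.0))
        _, a_grid, b_grid = grid_argmax(counts, np.arange(0.5, 3.001, 0.01),
                                        np.arange(0.0, 5.001, 0.05))
        assert abs(fit.params.alpha - a_grid) <= 0.01 + 1e-9
        assert abs(fit.params.beta - b_grid) <= 0.05 + 1e-9

    def test_exact_zm_counts_recovered(self):
        """Counts exactly proportional to a ZM PMF return the generating params."""
        p = zm_pmf(ZipfParams(1.4, 10.0), 1_000)
        counts = np.round(p * 5e6)
        fit = fit_mle(_ranked(counts))
        assert fit.params.alpha == pytest.approx(1.4, abs=0.02)
        assert fit.params.beta == pytest.approx(10.0, abs=0.5)

    def test_tie_seed_invariance(self, small_zm_ranked):
        spec, ranked = small_zm_ranked
        table = build_table(sample_zm(spec))
        fits = [fit_mle(assign_ranks(table, tie_seed=s)) for s in (0, 1, 12345)]
        assert len({f.params.alpha for f in fits}) == 1
        assert len({f.params.beta for f in fits}) == 1

    def test_too_few_ranks_errors(self):
        with pytest.raises(ValueError):
            fit_mle(_ranked([5]))


class TestExpectedFrequencies:
    def test_example(self):
        np.testing.assert_allclose(
            expected_frequencies(ZipfParams(1.0, 0.0), 2, 10),
            [20 / 3, 10 / 3], atol=1e-3)

    def test_sums_to_token_total(self):
        e = expected_frequencies(ZipfParams(1.3, 4.0), 5_000, 123_456.7)
        assert e.sum() == pytest.approx(123_456.7, rel=1e-12)

    def test_nonpositive_total_errors(self):
        with pytest.raises(ValueError):
            expected_frequencies(ZipfParams(1.0, 0.0), 3, 0)


class TestDegeneracy:
    @pytest.mark.parametrize(
        "alpha,beta,n,expected",
        [
            (115.07, 476.04, 46, True),    # French preposition scale
            (129.8, 235.1, 17, True),      # Spanish preposition scale
            (49.77, 265.13, 38, False),    # German prepositions fit fine
            (8.59, 33.97, 74, False),      # English prepositions fit fine
            (2.0, 5.0, 100, False),
            (1.16, 0.0, 1_000, False),
        ],
    )
    def test_trigger_pattern(self, alpha, beta, n, expected):
        assert is_degenerate(ZipfParams(alpha, beta), n) is expected

    def test_degenerate_fit_reports_no_correlations(self):
        gof = evaluate_fit(_ranked([1000, 3, 2, 1]), ZipfParams(115.07, 476.04))
        assert gof["degenerate"] is True
        assert gof["pearson_linear"] is None and gof["pearson_loglog"] is None


class TestEvaluateFit:
    def test_perfect_agreement(self):
        params = ZipfParams(1.5, 2.0)
        obs = expected_frequencies(params, 50, 10_000)
        gof = evaluate_fit(_ranked(obs), params)
        assert gof["pearson_linear"] == pytest.approx(1.0)
        assert gof["pearson_loglog"] == pytest.approx(1.0)

    def test_increasing_input_rejected_by_ranking(self):
        with pytest.raises(ValueError):
            _ranked([1, 2, 3])

    def test_agrees_with_scipy_pearson(self, small_zm_ranked):
        _, ranked = small_zm_ranked
        fit = fit_mle(ranked)
        exp = expected_frequencies(fit.params, ranked.n_types, ranked.n_tokens)
        r_ref = pearsonr(ranked.frequencies, exp).statistic
        assert fit.pearson_linear == pytest.approx(r_ref, abs=1e-12)


class TestSplitHalf:
    def test_interleaved_duplicate_matches_full_fit(self, small_zm_ranked):
        spec, ranked = small_zm_ranked
        tokens = sample_zm(spec)
        doubled = np.repeat(tokens, 2)
        full = fit_mle(ranked)
        sh = split_half_fit(doubled, seed=5)
        assert sh.method == "split_half"
        assert sh.params.alpha == pytest.approx(full.params.alpha, abs=0.05)

    def test_seed_changes_within_sampling_noise(self, small_zm_ranked):
        spec, _ = small_zm_ranked
        tokens = sample_zm(spec)
        alphas = [split_half_fit(tokens, seed=s).params.alpha for s in range(4)]
        assert np.ptp(alphas) < 0.1

    def test_zero_fill_mode_runs(self, small_zm_ranked):
        spec, _ = small_zm_ranked
        tokens = sample_zm(spec)
        fit = split_half_fit(tokens, seed=0, missing="zero")
        assert fit.params.alpha > 0

    def test_tiny_stream_errors(self):
        with pytest.raises(ValueError):
            split_half_fit(np.array(["a"], dtype=object), seed=0)


def test_parameter_recovery_grid():
    """Median |alpha_hat - alpha| <= 0.05 per cell over the (alpha, beta) grid
    {1.1, 1.4, 1.7} x {0, 5, 20}, vocabulary 10,000, one million tokens,
    five seeds; beta = 0 cells also return beta_hat near zero (classic
    Zipf limit)."""
    from cdszipf.synthetic import recovery_experiment

    grid = [(a, b) for a in (1.1, 1.4, 1.7) for b in (0.0, 5.0, 20.0)]
    report = recovery_experiment(grid, sizes=[1_000_000], replicates=5, seed=2024,
                                 vocab_size=10_000)
    med = (report.assign(err=lambda d: (d["alpha_hat"] - d["alpha"]).abs())
           .groupby(["alpha", "beta"])[["err", "beta_hat"]].median())
    assert (med["err"] <= 0.05).all()
    zipf_limit = med.xs(0.0, level="beta")
    assert (zipf_limit["beta_hat"] <= 1.0).all()


class TestClauset:
    def test_recovers_discrete_power_law_exponent(self):
        values = scipy_zipf.rvs(1.95, size=50_000, random_state=42)
        fit = fit_clauset(values)
        assert fit.exponent == pytest.approx(1.95, abs=0.1)
        assert 0 <= fit.ks_distance <= 1

    def test_exact_power_law_small_ks_at_low_xmin(self):
        values = scipy_zipf.rvs(2.3, size=20_000, random_state=7)
        fit = fit_clauset(values)
        assert fit.ks_distance < 0.02

    def test_exponential_tail_fits_worse_than_power_law(self):
        pl = fit_clauset(scipy_zipf.rvs(1.9, size=20_000, random_state=0))
        ex = fit_clauset(geom.rvs(0.05, size=20_000, random_state=0))
        assert ex.ks_distance > pl.ks_distance

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError):
            fit_clauset([3] * 100)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            fit_clauset([1, 2, 3])
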