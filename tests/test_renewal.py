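import numpy as np
import pytest
from scipy import integrate, stats

import vesiflux as vf


class TestSummaryStats:
    def test_constant_values(self):
        s = vf.summary_stats(np.array([1.0, 1.0, 1.0]))
        assert s.mean == 1.0 and s.std == 0.0 and s.cv == 0.0

    def test_unbiased_variance(self):
        s = vf.summary_stats(np.array([2.0, 4.0]))
        assert s.mean == 3.0
        assert s.variance == pytest.approx(2.0)

    def test_exponential_cv_is_one(self, rng):
        s = vf.summary_stats(rng.exponential(0.5, 100000))
        assert s.cv == pytest.approx(1.0, abs=0.02)

    def test_counts_report_dispersion(self):
        cs = vf.CountSeries(window=1.0, counts=np.array([2, 4, 3, 1]))
        s = vf.summary_stats(cs)
        assert s.dispersion == pytest.approx(s.variance / s.mean)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            vf.summary_stats(np.array([1.0]))


class TestBinWidth:
    def test_small_sample_rule(self):
        # (0.68 + 2.85*0.56)/sqrt(914)
        assert vf.interspike_bin_width(0.68, 0.56, 914) == pytest.approx(0.0753, abs=2e-4)

    def test_large_sample_scaled_scott(self):
        assert vf.interspike_bin_width(0.68, 0.67, 15504) == pytest.approx(0.0623, abs=2e-4)

    def test_zero_sigma(self):
        assert vf.interspike_bin_width(1.0, 0.0, 4) == pytest.approx(0.5)


class TestHistogram:
    def test_direct_binning(self):
        h = vf.make_histogram(np.array([0.1, 0.2, 0.3]), 0.2)
        assert np.allclose(h.bin_edges, [0.0, 0.2, 0.4])
        assert list(h.counts) == [2, 1]

    def test_density_normalization(self, rng):
        h = vf.make_histogram(rng.gamma(2.0, 1.0, 500), 0.3)
        assert np.sum(h.density * h.widths) == pytest.approx(1.0)

    def test_histogram_cdf_tracks_true_cdf(self, rng):
        x = rng.exponential(1.0, 10000)
        h = vf.make_histogram(x, 0.1)
        emp_cdf = np.cumsum(h.density * h.widths)
        true_cdf = 1.0 - np.exp(-h.bin_edges[1:])
        assert np.max(np.abs(emp_cdf - true_cdf)) < 0.05


class TestDistributions:
    def test_exponential_values(self):
        assert vf.exponential_pdf(0.0, 1.14) == pytest.approx(1.14)
        lam = 2.3
        assert vf.exponential_pdf(1 / lam, lam) == pytest.approx(lam / np.e)
        total, _ = integrate.quad(lambda x: vf.exponential_pdf(x, 1.5), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_poisson_values(self):
        assert vf.poisson_pmf(0, 1.0) == pytest.approx(np.exp(-1))
        k = np.arange(0, 200)
        pmf = vf.poisson_pmf(k, 7.3)
        assert np.sum(k * pmf) == pytest.approx(7.3, rel=1e-9)

    def test_poisson_log_space_large_k(self):
        # independent oracle: scipy's pmf evaluation
        ours = vf.poisson_pmf(100, 100.0)
        ref = stats.poisson.pmf(100, 100.0)
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_gamma_reduces_to_exponential(self):
        x = np.linspace(0.01, 5.0, 200)
        theta = 0.7
        assert np.allclose(vf.gamma_pdf(x, 1.0, theta),
                           vf.exponential_pdf(x, 1.0 / theta), rtol=1e-12)

    def test_gamma_mean_from_printed_fit(self):
        # mean = p*theta for the shape/scale pair of a single-cell fit
        p, theta = 1.58, 0.36
        x = np.linspace(0, 30, 30001)
        mean = np.trapezoid(x * vf.gamma_pdf(x, p, theta), x)
        assert mean == pytest.approx(p * theta, rel=1e-4)
        assert p * theta == pytest.approx(0.5688)

    def test_gamma_mode(self):
        p, theta = 2.5, 0.4
        x = np.linspace(0.01, 5, 5000)
        assert x[np.argmax(vf.gamma_pdf(x, p, theta))] == pytest.approx(
            theta * (p - 1), abs=2e-3)

    def test_gamma_count_reduces_to_poisson(self):
        k = np.arange(0, 21)
        for lam_t in (0.5, 2.0, 9.0):
            assert np.allclose(vf.gamma_count_pmf(k, 1.0, lam_t, 1.0),
                               vf.poisson_pmf(k, lam_t), atol=1e-12)

    def test_gamma_count_closed_form(self):
        # p=2, beta*T=2, k=0: 1 - G(2,2) = 3 e^-2
        assert vf.gamma_count_pmf(0, 2.0, 1.0, 2.0) == pytest.approx(3 * np.exp(-2), rel=1e-12)

    def test_gamma_count_sums_to_one(self):
        for p, beta, T in [(0.7, 2.0, 3.0), (1.6, 2.8, 2.4), (4.0, 1.0, 10.0)]:
            k = np.arange(0, 400)
            assert np.sum(vf.gamma_count_pmf(k, p, beta, T)) == pytest.approx(1.0, abs=1e-10)

    def test_gamma_count_mean_matches_simulation(self, rng):
        """Monte-Carlo counts of a fresh-start gamma renewal match the pmf mean.

        The gamma-count pmf counts renewals of an ordinary process (first
        interval drawn from the same gamma), so the oracle restarts the
        train for every window.
        """
        p, theta, T = 1.6, 0.4, 3.0
        n_rep = 40000
        draws = rng.gamma(p, theta, size=(n_rep, 40))
        arrival = np.cumsum(draws, axis=1)
        emp_mean = (arrival <= T).sum(axis=1).mean()
        k = np.arange(0, 200)
        pmf_mean = np.sum(k * vf.gamma_count_pmf(k, p, 1.0 / theta, T))
        assert emp_mean == pytest.approx(pmf_mean, rel=0.02)

    def test_lognormal(self, rng):
        log_mean, log_sd = -0.5, 0.6
        x = np.linspace(1e-4, 20, 200001)
        pdf = vf.lognormal_pdf(x, log_mean, log_sd)
        assert np.trapezoid(pdf, x) == pytest.approx(1.0, abs=1e-4)
        cdf = np.cumsum(pdf) * (x[1] - x[0])
        median = x[np.searchsorted(cdf, 0.5)]
        assert median == pytest.approx(np.exp(log_mean), rel=1e-2)
        pts = rng.uniform(0.05, 5.0, 10)
        assert np.allclose(vf.lognormal_pdf(pts, log_mean, log_sd),
                           stats.lognorm.pdf(pts, log_sd, scale=np.exp(log_mean)),
                           rtol=1e-10)


class TestFitHistogram:
    def test_exponential_recovery(self, rng):
        x = rng.exponential(1 / 1.5, 100000)
        st = vf.summary_stats(x)
        h = vf.interspike_bin_width(st.mean, st.std, x.size)
        fit = vf.fit_histogram(vf.make_histogram(x, h), "exponential")
        assert 1.45 <= fit.params["lam"] <= 1.55
        assert fit.r_squared > 0.99

    def test_gamma_recovery(self, rng):
        x = rng.gamma(1.6, 0.4, 100000)
        st = vf.summary_stats(x)
        h = vf.interspike_bin_width(st.mean, st.std, x.size)
        fit = vf.fit_histogram(vf.make_histogram(x, h), "gamma")
        assert 1.5 <= fit.params["p"] <= 1.7
        assert 0.37 <= fit.params["theta"] <= 0.43

    def test_gamma_lsq_matches_mle_oracle(self, rng):
        """Histogram LSQ and the independent MLE route agree on clean data."""
        x = rng.gamma(2.2, 0.5, 200000)
        st = vf.summary_stats(x)
        h = vf.interspike_bin_width(st.mean, st.std, x.size)
        fit = vf.fit_histogram(vf.make_histogram(x, h), "gamma")
        p_mle, _, theta_mle = stats.gamma.fit(x, floc=0)
        assert fit.params["p"] == pytest.approx(p_mle, rel=0.05)
        assert fit.params["theta"] == pytest.approx(theta_mle, rel=0.05)

    def test_self_fit_perfect(self):
        edges = np.arange(0, 6.001, 0.1)
        centers = 0.5 * (edges[1:] + edges[:-1])
        lam = 1.2
        density = vf.exponential_pdf(centers, lam)
        counts = density  # proportional is enough: fit uses density normalization
        h = vf.HistogramData(bin_edges=edges, counts=counts * 1000)
        fit = vf.fit_histogram(h, "exponential")
        assert fit.r_squared > 0.9999

    def test_count_fit_poisson(self, rng):
        counts = rng.poisson(4.0, 20000)
        ch = vf.count_frequencies(vf.CountSeries(window=2.0, counts=counts))
        fit = vf.fit_histogram(ch, "poisson")
        assert fit.params["lam_t"] == pytest.approx(4.0, rel=0.03)

    def test_count_fit_gamma_count(self, rng):
        p, theta, T = 1.6, 0.4, 2.56
        times = np.cumsum(rng.gamma(p, theta, 80000))
        seq = vf.SpikeSequence(times, float(times[-1]))
        ch = vf.count_frequencies(vf.spike_counts(seq, T))
        fit = vf.fit_histogram(ch, "gamma_count")
        assert fit.params["p"] == pytest.approx(p, abs=0.2)

    def test_normalization_invariance(self, rng):
        """Scaling the raw counts leaves the fitted parameters unchanged."""
        x = rng.gamma(1.8, 0.5, 20000)
        h1 = vf.make_histogram(x, 0.1)
        h2 = vf.HistogramData(bin_edges=h1.bin_edges, counts=h1.counts * 17)
        f1 = vf.fit_histogram(h1, "gamma")
        f2 = vf.fit_histogram(h2, "gamma")
        assert f1.params["p"] == pytest.approx(f2.params["p"], rel=1e-8)


class TestCombinedFit:
    def test_gamma_pair_recovery(self, rng):
        p, theta = 1.6, 0.4
        times = np.cumsum(rng.gamma(p, theta, 30000))
        seq = vf.SpikeSequence(times, float(times[-1]))
        isi = vf.interspike_times(seq)
        st = vf.summary_stats(isi)
        h = vf.interspike_bin_width(st.mean, st.std, isi.size)
        ch = vf.count_frequencies(vf.spike_counts(seq, 4 * st.mean))
        fit = vf.combined_fit(vf.make_histogram(isi, h), ch, "gamma_pair")
        assert fit.params["p"] == pytest.approx(p, abs=0.15)

    def test_poisson_data_gives_shape_one(self, rng):
        times = np.cumsum(rng.exponential(0.5, 30000))
        seq = vf.SpikeSequence(times, float(times[-1]))
        isi = vf.interspike_times(seq)
        st = vf.summary_stats(isi)
        h = vf.interspike_bin_width(st.mean, st.std, isi.size)
        ch = vf.count_frequencies(vf.spike_counts(seq, 4 * st.mean))
        fit = vf.combined_fit(vf.make_histogram(isi, h), ch, "gamma_pair")
        assert 0.9 <= fit.params["p"] <= 1.15

    def test_gamma_pair_nests_poisson_pair(self, rng):
        times = np.cumsum(rng.gamma(2.5, 0.3, 5000))
        seq = vf.SpikeSequence(times, float(times[-1]))
        isi = vf.interspike_times(seq)
        st = vf.summary_stats(isi)
        h = vf.interspike_bin_width(st.mean, st.std, isi.size)
        ih = vf.make_histogram(isi, h)
        ch = vf.count_frequencies(vf.spike_counts(seq, 4 * st.mean))
        sse_g = vf.combined_fit(ih, ch, "gamma_pair").sse
        sse_p = vf.combined_fit(ih, ch, "poisson_pair").sse
        assert sse_g <= sse_p + 1e-12


class TestDispersion:
    @pytest.mark.parametrize("p,expected", [(0.5, "over"), (1.0, "unit"), (2.0, "under")])
    def test_gamma_renewal_dispersion_regimes(self, p, expected, rng):
        theta = 0.5 / p  # unit-ish mean intervals
        times = np.cumsum(rng.gamma(p, theta, 100000))
        seq = vf.SpikeSequence(times, float(times[-1]))
        d = vf.summary_stats(vf.spike_counts(seq, 4 * 0.5)).dispersion
        if expected == "over":
            assert d > 1.1
        elif expected == "under":
            assert d < 0.9
        else:
            assert d == pytest.approx(1.0, abs=0.1)


class TestModelReport:
    def test_poisson_train_report(self, rng):
        times = np.cumsum(rng.exponential(0.6, 4000))
        seq = vf.SpikeSequence(times, float(times[-1]))
        rep = vf.model_report(seq)
        assert rep["fits"]["gamma"]["params"]["p"] == pytest.approx(1.0, abs=0.15)
        assert rep["dispersion"] == pytest.approx(1.0, abs=0.1)

    def test_gamma_train_report_matches_poisson_at_p1(self, rng):
        times = np.cumsum(rng.gamma(1.0, 0.6, 4000))
        seq = vf.SpikeSequence(times, float(times[-1]))
        rep = vf.model_report(seq)
        lam_exp = rep["fits"]["exponential"]["params"]["lam"]
        theta = rep["fits"]["gamma"]["params"]["theta"]
        assert 1.0 / theta == pytest.approx(lam_exp, rel=0.2)

    def test_needs_enough_spikes(self):
        seq = vf.SpikeSequence(np.linspace(0.1, 5, 50), 5.0)
        with pytest.raises(ValueError):
            vf.model_report(seq)
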