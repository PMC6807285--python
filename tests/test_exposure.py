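import numpy as np
import pytest
import scipy.integrate
import scipy.stats as st

from aacsim.config import ExposurePolicy, TaskConfig
from aacsim.events import Event, EventLog
from aacsim.exposure import (ExposureMixtureModel, NullDistribution,
                             build_null_distribution, compare_models,
                             exgauss_cdf, exgauss_pdf, exposure_latencies,
                             group_comparison, ks_one_sample, lbf_from_bic,
                             merge_latency_sets, permutation_null_from_epochs,
                             uniform_null_from_epochs)
from aacsim.simulate import sample_exgauss, simulate_task2_block


def exgauss_pdf_by_convolution(t, mu, sigma, lam):
    """Brute-force Gaussian (*) exponential convolution by quadrature."""
    def integrand(x):   # x: value of the Gaussian component
        return st.norm.pdf(x, loc=mu, scale=sigma) * lam * np.exp(
            -lam * (t - x))
    lo, hi = mu - 12 * sigma, min(t, mu + 12 * sigma)
    if hi <= lo:
        return 0.0
    val, _ = scipy.integrate.quad(integrand, lo, hi, limit=400,
                                  epsabs=1e-13, epsrel=1e-11)
    return val


class TestExGauss:
    def test_matches_convolution_oracle(self):
        mu, sigma, lam = 300.0, 80.0, 1 / 200.0
        grid = np.linspace(0.0, 2500.0, 100)
        ours = exgauss_pdf(grid, mu, sigma, lam)
        oracle = [exgauss_pdf_by_convolution(t, mu, sigma, lam)
                  for t in grid]
        assert np.allclose(ours, oracle, atol=1e-8)

    def test_sigma_zero_limit_is_shifted_exponential(self):
        lam = 1 / 150.0
        t = np.array([50.0, 200.0, 201.0, 1000.0])
        out = exgauss_pdf(t, 200.0, 0.0, lam)
        expected = np.where(t >= 200.0, lam * np.exp(-lam * (t - 200.0)), 0.0)
        assert np.allclose(out, expected)

    def test_normalization(self):
        mu, sigma, lam = 250.0, 60.0, 1 / 300.0
        total, err = scipy.integrate.quad(
            lambda t: exgauss_pdf(t, mu, sigma, lam), -2000, 20000,
            limit=200)
        assert abs(total - 1.0) < 1e-6

    def test_cdf_consistent_with_pdf(self):
        mu, sigma, lam = 250.0, 60.0, 1 / 300.0
        for t in (0.0, 300.0, 900.0):
            num, _ = scipy.integrate.quad(
                lambda s: exgauss_pdf(s, mu, sigma, lam), -2000, t,
                limit=200)
            assert exgauss_cdf(t, mu, sigma, lam) == pytest.approx(
                num, abs=1e-8)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            exgauss_pdf(1.0, 0.0, -1.0, 0.1)
        with pytest.raises(ValueError):
            exgauss_pdf(1.0, 0.0, 1.0, 0.0)


def _manual_task2_log(token_ts, press_ts, duration=10_000.0):
    events = [Event(0.0, "epoch_start", 0, "med")]
    for i, t in enumerate(token_ts, 1):
        events.append(Event(t, "token_on", 0, "med", {"token_index": i}))
    for j, t in enumerate(press_ts, 1):
        events.append(Event(t, "key_up", 0, "med", {"attempt": j}))
    events.append(Event(duration, "epoch_end", 0, "med",
                        {"exposed": False, "duration": duration}))
    events.sort(key=lambda e: e.t)
    return EventLog(subject_id="s", block_id=0, task="task2",
                    config_hash="x", events=events)


class TestExposureLatencies:
    def test_latency_relative_to_only_token(self):
        ls = exposure_latencies(_manual_task2_log([1000.0], [1400.0]))
        assert ls.latencies.tolist() == [400.0]
        assert ls.n_pre_token == 0

    def test_press_before_first_token_counted_but_excluded(self):
        ls = exposure_latencies(_manual_task2_log([1000.0], [500.0, 1300.0]))
        assert ls.latencies.tolist() == [300.0]
        assert ls.n_pre_token == 1
        assert ls.n_total == 2
        assert ls.fraction_included == pytest.approx(0.5)

    def test_latency_relative_to_most_recent_token(self):
        ls = exposure_latencies(_manual_task2_log([1000.0, 3000.0],
                                                  [3700.0]))
        assert ls.latencies.tolist() == [700.0]

    def test_task1_log_rejected(self):
        log = EventLog(subject_id="s", block_id=0, task="task1",
                       config_hash="x")
        with pytest.raises(ValueError):
            exposure_latencies(log)


class TestNullDistributions:
    def test_single_token_uniform_null_is_uniform(self):
        """One token at t=0 in an epoch of duration D: T2 under uniform
        pressing is Uniform(0, D)."""
        D = 4000.0
        null = uniform_null_from_epochs([(D, np.array([0.0]))],
                                        n_sim=4000, seed=0)
        ks = st.kstest(null.samples, st.uniform(loc=0, scale=D).cdf)
        assert ks.pvalue > 0.01

    def test_cdf_monotone_and_normalized(self, config):
        null = build_null_distribution(config, n_sim=2000, seed=1)
        grid = np.linspace(0, null.samples.max(), 200)
        cdf = null.cdf(grid)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == pytest.approx(1.0)
        widths = np.diff(null.grid)
        assert np.sum(null.pdf_vals * widths) == pytest.approx(1.0)

    def test_uniform_data_consistent_with_uniform_null(self, config):
        """Presses that genuinely ignore tokens pass the one-sample KS
        test against the uniform-time null."""
        rng = np.random.default_rng(5)
        null = build_null_distribution(config, n_sim=4000, seed=2)
        probe = uniform_null_from_epochs(
            [( d, o) for d, o in _epochs_from_config(config, 300, rng)],
            n_sim=300, seed=3)
        res = ks_one_sample(probe.samples, null)
        assert res.pvalue > 0.01

    def test_exgauss_data_rejected_against_null(self, config):
        rng = np.random.default_rng(6)
        null = build_null_distribution(config, n_sim=4000, seed=4)
        data = sample_exgauss(300.0, 80.0, 1 / 200.0, rng, size=500)
        res = ks_one_sample(data[data >= 0], null)
        assert res.pvalue < 1e-3

    def test_permutation_null_destroys_coupling(self):
        rng = np.random.default_rng(7)
        epochs = []
        for _ in range(40):
            onsets = np.sort(rng.uniform(0, 8000, size=4))
            presses = onsets + rng.normal(300, 50, size=4)  # tightly coupled
            epochs.append((10_000.0, onsets, presses.tolist()))
        with pytest.warns(UserWarning):
            null = permutation_null_from_epochs(epochs, n_sim=20, seed=8)
        coupled = np.concatenate(
            [np.asarray(p) - o[np.searchsorted(o, p, side="right") - 1]
             for _, o, p in epochs])
        assert np.median(null.samples) > np.median(coupled)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="null T2 samples"):
            NullDistribution(method="uniform_time",
                             samples=np.linspace(0, 100, 50), n_sim=1,
                             seed=0)


def _epochs_from_config(config, n, rng):
    from aacsim.simulate import _task2_token_schedule
    out = []
    for _ in range(n):
        onsets, _, dur = _task2_token_schedule(config, rng)
        out.append((dur, onsets))
    return out


def simulate_mixture_data(null, n, w, mu, sigma, lam, rng):
    n_null = rng.binomial(n, w)
    from_null = rng.choice(null.samples, size=n_null)
    from_exg = sample_exgauss(mu, sigma, lam, rng, size=n - n_null)
    data = np.concatenate([from_null, np.abs(from_exg)])
    return data


@pytest.fixture(scope="module")
def null_dist(config):
    return build_null_distribution(config, n_sim=4000, seed=10)


class TestMixtureModel:
    TRUE = dict(w=0.4, mu=300.0, sigma=80.0, lam=1 / 200.0)

    def test_parameter_recovery_single_fit(self, null_dist):
        rng = np.random.default_rng(11)
        data = simulate_mixture_data(null_dist, 2000, rng=rng, **self.TRUE)
        fit = ExposureMixtureModel({"all": data}, null_dist).fit(
            "combined", n_starts=6, seed=0)
        assert fit.converged
        for name, true in self.TRUE.items():
            est = fit.params["all"][name]
            assert abs(est - true) / true < 0.25, (name, est)

    def test_pure_null_data_pushes_w_to_boundary(self, null_dist):
        rng = np.random.default_rng(12)
        data = rng.choice(null_dist.samples, size=1500)
        fit = ExposureMixtureModel({"all": data}, null_dist).fit(
            "combined", n_starts=6, seed=1)
        assert fit.params["all"]["w"] > 0.95
        if fit.params["all"]["w"] > 0.995:
            assert any("unidentifiable" in f for f in fit.flags)

    def test_split_lambda_nested_likelihood_ordering(self, null_dist):
        rng = np.random.default_rng(13)
        a = simulate_mixture_data(null_dist, 1200, rng=rng, **self.TRUE)
        b = simulate_mixture_data(null_dist, 1200, w=0.4, mu=300.0,
                                  sigma=80.0, lam=1 / 500.0, rng=rng)
        model = ExposureMixtureModel({"ctrl": a, "pat": b}, null_dist)
        fits = model.fit_all(n_starts=4, seed=2)
        combined_ll = fits["combined"].log_likelihood
        for name, fit in fits.items():
            assert fit.log_likelihood >= combined_ll - 1e-6, name
        # the lambda split is the generating difference: it must win
        table = compare_models(fits)
        assert table.variant.iloc[0] == "split_lambda"
        lam_ctrl = fits["split_lambda"].params["ctrl"]["lam"]
        lam_pat = fits["split_lambda"].params["pat"]["lam"]
        assert lam_ctrl > lam_pat   # patient process decays more slowly

    def test_group_comparison_detects_distribution_shift(self, null_dist):
        rng = np.random.default_rng(14)
        a = simulate_mixture_data(null_dist, 800, rng=rng, **self.TRUE)
        b = simulate_mixture_data(null_dist, 800, w=0.4, mu=600.0,
                                  sigma=80.0, lam=1 / 200.0, rng=rng)
        out = group_comparison(a, b, means_a=[a.mean()], means_b=[b.mean()])
        assert out["ks_p"] < 1e-4

    def test_too_few_observations_rejected(self, null_dist):
        with pytest.raises(ValueError):
            ExposureMixtureModel({"all": np.array([1.0, 2.0])}, null_dist)


class TestModelComparison:
    def test_lbf_arithmetic_from_printed_formula(self):
        """LBF = 0.5 * (BIC_ref - BIC): 210 vs 200 -> 5."""
        assert lbf_from_bic(210.0, 200.0) == pytest.approx(5.0)
        assert lbf_from_bic(200.0, 200.0) == 0.0

    def test_reference_has_zero_lbf_and_table_sorted(self, config, null_dist):
        rng = np.random.default_rng(15)
        a = simulate_mixture_data(null_dist, 600, 0.4, 300, 80, 1 / 200, rng)
        b = simulate_mixture_data(null_dist, 600, 0.4, 300, 80, 1 / 450, rng)
        model = ExposureMixtureModel({"c": a, "p": b}, null_dist)
        fits = model.fit_all(["combined", "split_lambda", "split_w"],
                             n_starts=3, seed=4)
        table = compare_models(fits)
        ref = table[table.variant == "combined"]
        assert ref.lbf.iloc[0] == 0.0
        assert (table.lbf.diff().dropna() <= 1e-9).all()
        # BIC definition: k ln n - 2 logL
        for _, row in table.iterrows():
            k, n, ll = row.n_params, fits[row.variant].n_obs, \
                row.log_likelihood
            assert row.bic == pytest.approx(k * np.log(n) - 2 * ll)

    def test_mismatched_data_rejected(self, null_dist):
        rng = np.random.default_rng(16)
        a = simulate_mixture_data(null_dist, 600, 0.4, 300, 80, 1 / 200, rng)
        f1 = ExposureMixtureModel({"x": a}, null_dist).fit(
            "combined", n_starts=2)
        f2 = ExposureMixtureModel({"x": a[:300]}, null_dist).fit(
            "combined", n_starts=2)
        with pytest.raises(ValueError):
            compare_models({"combined": f1, "split_w": f2})


class TestEndToEndTask2:
    def test_simulated_block_latencies_prefer_exgauss_component(self, config):
        """Latencies from the generative Task-2 agent (w=0.35) are
        detected as token-coupled against the uniform null."""
        logs = [simulate_task2_block(config, ExposurePolicy(), s,
                                     subject_id=f"s{s}")
                for s in range(6)]
        pooled = merge_latency_sets([exposure_latencies(lg) for lg in logs])
        null = build_null_distribution(config, n_sim=4000, seed=20)
        res = ks_one_sample(pooled.latencies, null)
        assert res.pvalue < 1e-3
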