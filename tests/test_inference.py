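import numpy as np
import pytest
from scipy import stats

from sanmodel import schedule_from_theta, simulate_ensemble, solve_deterministic
from sanmodel.inference import (
    THETA_NAMES,
    ObservationSet,
    SANRateModel,
    SANRateResults,
    gelman_rubin,
    mean_shift_mode,
    sensitivity_analysis,
)

THETA_STAR = np.array([0.94, 1.14, 1.68, 1.69, 0.71, 0.07])


def totals_only_obs(theta, days=(0, 3, 6, 11, 20, 40), sd=0.2):
    """Deterministic observation set whose likelihood peaks exactly at theta."""
    days = np.asarray(days, dtype=float)
    tot = np.array(
        [st.total for st in solve_deterministic(schedule_from_theta(theta), 30_000, days)]
    )
    z = np.empty(0)
    return ObservationSet(
        days, np.log(tot), np.full(days.size, sd),
        z, np.empty(0, dtype=int), z.reshape(0, 0), z.reshape(0, 0),
    )


def synthetic_obs(theta, n_lineages, ranks, eps, n_reps=3, seed=555):
    """Observations generated from the model itself at known rates."""
    base = totals_only_obs(theta)
    sch = schedule_from_theta(theta)
    ranks = np.asarray(ranks, dtype=int)
    rank_days = np.array([11.0, 40.0])
    reps = []
    for r in range(n_reps):
        ens = simulate_ensemble(n_lineages, sch, rank_days, rng=seed + r, eps=eps)
        row = np.full((2, ranks.size), np.nan)
        for i, d in enumerate(rank_days):
            sz = ens.sizes_at(d).astype(float)
            sz = np.sort(sz[sz > 0])[::-1]
            ok = ranks <= sz.size
            row[i, ok] = sz[ranks[ok] - 1]
        reps.append(np.log(row))
    reps = np.array(reps)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(reps, axis=0)
        sd = np.maximum(np.nanstd(reps, axis=0, ddof=1), 0.1)
    sd[np.isnan(mu)] = np.nan
    return ObservationSet(
        base.total_days, base.total_mu, base.total_sd, rank_days, ranks, mu, sd
    )


class TestLogLikelihood:
    def test_exact_match_gives_zero(self, rng):
        obs = totals_only_obs(THETA_STAR)
        model = SANRateModel(obs)
        assert model.loglike(THETA_STAR, rng) == pytest.approx(0.0, abs=1e-9)

    def test_one_sigma_miss_costs_half(self, rng):
        obs = totals_only_obs(THETA_STAR)
        # shift one day's observed log-mean by exactly its sd
        mu = obs.total_mu.copy()
        mu[2] += obs.total_sd[2]
        shifted = ObservationSet(
            obs.total_days, mu, obs.total_sd, obs.rank_days, obs.ranks,
            obs.rank_mu, obs.rank_sd,
        )
        assert SANRateModel(shifted).loglike(THETA_STAR, rng) == pytest.approx(-0.5)

    def test_out_of_bounds_rejected(self, rng):
        model = SANRateModel(totals_only_obs(THETA_STAR))
        assert model.loglike(np.array([5.0, 1, 1, 1, 1, 1]), rng) == -np.inf
        assert model.loglike(np.array([-0.1, 1, 1, 1, 1, 1]), rng) == -np.inf

    def test_truth_beats_perturbation_on_synthetic_obs(self):
        obs = synthetic_obs(THETA_STAR, n_lineages=600, ranks=[1, 5, 25, 100], eps=1e-2)
        model = SANRateModel(obs, n_lineages=600, eps=1e-2)
        rng = np.random.default_rng(3)
        theta_off = THETA_STAR + np.array([0.3, -0.3, 0.4, -0.4, 0.5, 0.3])
        ll_true = np.mean([model.loglike(THETA_STAR, rng) for _ in range(25)])
        ll_off = np.mean([model.loglike(theta_off, rng) for _ in range(25)])
        assert ll_true > ll_off


class TestPriorRecovery:
    def test_flat_likelihood_returns_uniform_box(self):
        model = SANRateModel(ObservationSet.empty(), n_lineages=10)
        res = model.fit(n_chains=200, n_accept=25, seed=99)
        draws = res.samples
        assert draws.shape == (200, 6)
        for j in range(6):
            p = stats.kstest(draws[:, j], stats.uniform(0, 4).cdf).pvalue
            assert p > 1e-3, j


class TestGelmanRubin:
    def test_identical_constant_chains(self):
        tr = np.ones((4, 50))
        assert gelman_rubin(tr) == (1.0, 1.0)

    def test_distinct_constant_chains_diverge(self):
        tr = np.outer(np.arange(4.0), np.ones(50))
        point, upper = gelman_rubin(tr)
        assert point == np.inf and upper == np.inf

    def test_matches_textbook_formula_on_ar1_chains(self, rng):
        m, n = 6, 400
        chains = np.empty((m, n))
        for c in range(m):
            x = rng.normal()
            for i in range(n):
                x = 0.6 * x + rng.normal()
                chains[c, i] = x

        # independently coded textbook construction (second halves)
        half = chains[:, n // 2:]
        mm, nn = half.shape
        means = half.mean(axis=1)
        W = np.mean([np.var(half[c], ddof=1) for c in range(mm)])
        B = nn * np.var(means, ddof=1)
        sigma2 = (nn - 1) / nn * W + B / nn
        expected = np.sqrt((sigma2 + B / (mm * nn)) / W)

        point, upper = gelman_rubin(chains)
        assert point == pytest.approx(expected, abs=1e-10)
        assert upper >= point

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))


class TestMeanShift:
    def test_single_gaussian_mode_near_mean(self, rng):
        X = rng.normal(loc=[2.0, -1.0], scale=1.0, size=(2_000, 2))
        mode = mean_shift_mode(X)
        assert np.allclose(mode, [2.0, -1.0], atol=0.2)

    def test_mixture_picks_heavier_component(self, rng):
        X = np.vstack(
            [
                rng.normal(0.0, 0.5, size=(2_000, 2)),
                rng.normal(5.0, 0.5, size=(1_000, 2)),
            ]
        )
        mode = mean_shift_mode(X)
        assert np.allclose(mode, [0.0, 0.0], atol=0.3)

    def test_deterministic_and_idempotent(self, rng):
        X = rng.normal(size=(500, 3))
        m1 = mean_shift_mode(X)
        m2 = mean_shift_mode(X)
        assert np.array_equal(m1, m2)


def make_degenerate_results(theta, n_chains=60, jitter=None, seed=0):
    """Results object whose retained draws concentrate at (or around) theta."""
    rng = np.random.default_rng(seed)
    model = SANRateModel(ObservationSet.empty(), n_lineages=10)
    n_accept = 4
    traces = np.tile(theta, (n_chains, n_accept, 1)).astype(float)
    if jitter is not None:
        traces += rng.normal(0.0, jitter, size=traces.shape)
    return SANRateResults(
        model=model,
        traces=traces,
        logliks=np.zeros((n_chains, n_accept)),
        n_accepted=np.full(n_chains, n_accept),
        n_proposed=np.full(n_chains, n_accept),
        flagged=np.zeros(n_chains, dtype=bool),
    )


class TestPosteriorPredictions:
    def test_degenerate_posterior_day11_scells(self):
        res = make_degenerate_results(THETA_STAR)
        s = res.posterior_predict_scells([11.0])
        assert np.allclose(s, 9499.1, atol=5)

    def test_day40_more_dispersed_than_day11(self):
        jit = np.array([0.0, 0.0, 0.05, 0.0, 0.0, 0.0])  # uncertainty after day 11
        res = make_degenerate_results(THETA_STAR, jitter=jit, seed=4)
        s = res.posterior_predict_scells([11.0, 40.0])
        iqr = lambda v: np.quantile(v, 0.9) / np.quantile(v, 0.1)
        assert iqr(s[:, 1]) > iqr(s[:, 0])

    def test_map_estimate_of_degenerate_cloud(self):
        res = make_degenerate_results(THETA_STAR, jitter=0.02, seed=5)
        assert np.allclose(res.map_estimate(), THETA_STAR, atol=0.05)

    def test_summary_mentions_all_parameters(self):
        res = make_degenerate_results(THETA_STAR, jitter=0.02, seed=6)
        text = res.summary()
        for name in THETA_NAMES:
            assert name in text
        assert "net_s" in text


class TestSensitivity:
    def test_zero_sd_matches_map(self):
        out = sensitivity_analysis(
            THETA_STAR, np.zeros(6), days=[11.0, 40.0], n_lineages=200, rng=1
        )
        ref = [st.total for st in out["map"]["deterministic"]]
        for label, block in out.items():
            got = [st.total for st in block["deterministic"]]
            assert np.allclose(got, ref)

    def test_raising_division_rate_raises_day40_size(self):
        sds = np.array([0.0, 0.0, 0.52, 0.0, 0.0, 0.0])
        out = sensitivity_analysis(
            THETA_STAR, sds, days=[40.0], n_lineages=200, rng=1
        )
        up = out["s_ss[11-40]+2sd"]["deterministic"][0].total
        down = out["s_ss[11-40]-2sd"]["deterministic"][0].total
        ref = out["map"]["deterministic"][0].total
        assert down < ref < up

    def test_early_rates_shape_day40_rank_curve(self):
        # perturbing the day 6-11 rates must measurably move the
        # sub-threshold part of the day-40 rank-size curve
        sds = np.array([0.14, 0.175, 0.0, 0.0, 0.0, 0.0])
        out = sensitivity_analysis(
            THETA_STAR, sds, days=[40.0], n_lineages=4_000, rng=7
        )
        hi = out["s_ss[6-11]+2sd"]["rank_sizes"]
        lo = out["s_ss[6-11]-2sd"]["rank_sizes"]
        seg = slice(100, 800)
        m_hi = np.median(hi[seg])
        m_lo = np.median(lo[seg])
        assert m_hi > 1.2 * m_lo

    def test_negative_rates_clipped_with_warning(self):
        sds = np.full(6, 10.0)
        with pytest.warns(UserWarning):
            out = sensitivity_analysis(
                THETA_STAR, sds, days=[11.0], n_lineages=50, rng=0
            )
        assert np.all(out["a_n[11-40]-2sd"]["theta"] >= 0)


@pytest.fixture(scope="module")
def recovery_fit():
    # totals-only observations keep the likelihood noise-free, so the chains
    # mix well at small scale while the totals still pin down the net rates
    obs = totals_only_obs(THETA_STAR, days=(0, 3, 6, 9, 11, 14, 17, 21, 25, 31, 38))
    model = SANRateModel(obs)
    return model.fit(n_chains=16, n_accept=150, seed=1_234, proposal_scale=0.12)


class TestParameterRecovery:
    def test_net_s_rate_recovered(self, recovery_fit):
        draws = recovery_fit.samples
        net = draws[:, 2] - draws[:, 3]
        true_net = THETA_STAR[2] - THETA_STAR[3]
        lo, hi = np.quantile(net, [0.025, 0.975])
        assert lo <= true_net <= hi
        # the net rate is pinned down far more tightly than the box prior
        assert net.std(ddof=1) < 0.5

    def test_stationarity_of_accepted_trajectory(self, recovery_fit):
        # medians across chains midway vs at the end agree within posterior SE
        tr = recovery_fit.traces
        mid = np.median(tr[:, 74, :], axis=0)
        end = np.median(tr[:, 149, :], axis=0)
        se = tr[:, 149, :].std(axis=0, ddof=1)
        assert np.all(np.abs(mid - end) < 4 * se + 1e-12)

    def test_diagnostics_available(self, recovery_fit):
        gr = recovery_fit.gelman_rubin()
        assert set(gr["parameter"]) == set(THETA_NAMES) | {"net_s[11-40]"}
        assert np.all(gr["psrf_upper_95"] >= gr["psrf"] - 1e-12)


class TestPseudoMarginal:
    """Small-scale checks of the noisy-likelihood sampling path."""

    RANKS = [1, 2, 5, 10, 25, 60]

    def fit_at(self, n_lineages, seed):
        obs = synthetic_obs(THETA_STAR, n_lineages=300, ranks=self.RANKS, eps=1e-2)
        # widen degenerate replicate SDs to the generative spread of a small
        # ensemble; three replicates badly underestimate it
        rank_sd = np.maximum(obs.rank_sd, 0.5)
        obs = ObservationSet(
            obs.total_days, obs.total_mu, obs.total_sd,
            obs.rank_days, obs.ranks, obs.rank_mu, rank_sd,
        )
        model = SANRateModel(obs, n_lineages=n_lineages, eps=1e-2)
        return model.fit(
            n_chains=5, n_accept=12, seed=seed, proposal_scale=0.15,
            max_proposals=400,
        )

    def test_chains_run_and_concentrate(self):
        res = self.fit_at(300, seed=11)
        draws = res.samples
        ok = ~np.isnan(draws).any(axis=1)
        assert ok.sum() >= 3
        net = draws[ok, 2] - draws[ok, 3]
        # far tighter than the prior box (whose sd would be ~1.6)
        assert np.abs(net).max() < 1.0

    def test_ensemble_size_invariance(self):
        # tripling the simulator's ensemble size must not shift the posterior
        # beyond Monte-Carlo error
        small = self.fit_at(300, seed=11).samples
        big = self.fit_at(900, seed=12).samples
        small = small[~np.isnan(small).any(axis=1)]
        big = big[~np.isnan(big).any(axis=1)]
        net_s = small[:, 2] - small[:, 3]
        net_b = big[:, 2] - big[:, 3]
        se = np.sqrt(net_s.var(ddof=1) / net_s.size + net_b.var(ddof=1) / net_b.size)
        assert abs(net_s.mean() - net_b.mean()) < 4 * se
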