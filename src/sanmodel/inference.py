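"""Bayesian inference of the six estimable SAN rates.

The estimable parameter vector is theta = (r_S->SS, r_S->N for days 6-11;
r_S->SS, r_S->A, r_A->AN, r_A->N for days 11-40); the embryoid-body rates
(days 0-6) are fixed calibration inputs.  Observations are log-scale,
replicate-aggregated: total organoid sizes on a set of days and ranked
lineage sizes on days 11 and 40.  Assuming log-normal measurement error the
log-likelihood is a sum of standardized Gaussian quadratic terms (additive
constants dropped):

    l(theta) = -1/2 sum_t ((mu_t - log c_t)/sd_t)^2
               -1/2 sum_{t in rank days} sum_r ((mu_{t,r} - log l_(r),t)/sd_{t,r})^2

Total sizes come from the deterministic model; ranked sizes require a
stochastic ensemble plus the sequencing readout, making the likelihood an
unbiased *noisy* estimate — hence pseudo-marginal Metropolis-Hastings: each
proposal gets one fresh simulation, and the current state's likelihood
estimate is never refreshed (the condition under which the chain still
targets the exact posterior).  Following the study's protocol, many chains
are run and each chain's final accepted state is the retained posterior
draw; full traces are kept for the Gelman-Rubin diagnostic.

The module is organised statsmodels-style: build a :class:`SANRateModel`
from an :class:`ObservationSet`, call :meth:`~SANRateModel.fit`, and read
estimates, diagnostics and ``summary()`` off the returned
:class:`SANRateResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .deterministic import solve_deterministic
from .rates import RateSchedule, map_rate_schedule, schedule_from_theta
from .readout import SeqReadoutParams, reads_to_cells, simulate_readcounts
from .simulate import simulate_ensemble

#: days on which total organoid sizes enter the likelihood
DEFAULT_TOTAL_DAYS = (0, 3, 6, 9, 10, 13, 14, 16, 17, 19, 21, 22, 25, 28, 31, 32, 35, 37, 38)
#: ranks at which the rank-size curves (days 11 and 40) enter the likelihood
DEFAULT_RANKS = (1, 2, 5, 10, 15, 25, 40, 60, 100, 150, 250, 400, 600,
                 1000, 1500, 2500, 4000, 6000, 10000, 15000, 25000)

THETA_NAMES = (
    "s_ss[6-11]", "s_n[6-11]", "s_ss[11-40]", "s_a[11-40]", "a_an[11-40]", "a_n[11-40]",
)


@dataclass(frozen=True)
class ObservationSet:
    """Replicate-aggregated log-scale observations.

    ``total_mu``/``total_sd``: mean/SD of log total organoid cells per day in
    ``total_days``.  ``rank_mu``/``rank_sd``: arrays of shape
    (n_rank_days, n_ranks) of mean/SD of log ranked lineage size; NaN cells
    are missing and excluded from the likelihood.
    """

    total_days: np.ndarray
    total_mu: np.ndarray
    total_sd: np.ndarray
    rank_days: np.ndarray
    ranks: np.ndarray
    rank_mu: np.ndarray
    rank_sd: np.ndarray

    def __post_init__(self) -> None:
        for name in ("total_days", "total_mu", "total_sd", "rank_days", "ranks",
                     "rank_mu", "rank_sd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(self.total_sd <= 0) or np.any(self.rank_sd[~np.isnan(self.rank_sd)] <= 0):
            raise ValueError("replicate SDs must be positive (floor degenerate SDs)")
        if not (np.all(np.diff(self.total_days) > 0) and np.all(np.diff(self.ranks) > 0)):
            raise ValueError("days and ranks must be sorted strictly increasing")

    @classmethod
    def empty(cls) -> "ObservationSet":
        """No observations: the likelihood is flat (prior recovery tests)."""
        z = np.empty(0)
        return cls(z, z, z, z, np.empty(0, dtype=int), z.reshape(0, 0), z.reshape(0, 0))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "total", "day": d, "rank": np.nan, "mean_log": m, "sd_log": s}
            for d, m, s in zip(self.total_days, self.total_mu, self.total_sd)
        ]
        for i, d in enumerate(self.rank_days):
            for j, r in enumerate(self.ranks):
                if not np.isnan(self.rank_mu[i, j]):
                    rows.append({"kind": "rank", "day": d, "rank": int(r),
                                 "mean_log": self.rank_mu[i, j], "sd_log": self.rank_sd[i, j]})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservationSet":
        tot = df[df["kind"] == "total"].sort_values("day")
        rk = df[df["kind"] == "rank"]
        rank_days = np.sort(rk["day"].unique()) if len(rk) else np.empty(0)
        ranks = np.sort(rk["rank"].unique().astype(int)) if len(rk) else np.empty(0, int)
        mu = np.full((rank_days.size, ranks.size), np.nan)
        sd = np.full((rank_days.size, ranks.size), np.nan)
        for _, row in rk.iterrows():
            i = np.searchsorted(rank_days, row["day"])
            j = np.searchsorted(ranks, int(row["rank"]))
            mu[i, j], sd[i, j] = row["mean_log"], row["sd_log"]
        return cls(tot["day"].to_numpy(), tot["mean_log"].to_numpy(),
                   tot["sd_log"].to_numpy(), rank_days, ranks, mu, sd)


class SANRateModel:
    """Pseudo-marginal posterior model for the six estimable SAN rates.

    Parameters
    ----------
    obs : ObservationSet
        Log-scale observations (total sizes and ranked lineage sizes).
    n_lineages : int
        Lineages per stochastic ensemble inside the likelihood (the study's
        organoids carry 30,000; tests scale this down).
    readout : SeqReadoutParams or None
        If given, simulated lineage sizes pass through the PCR/sequencing
        observation model before ranking.
    bounds : (float, float)
        Uniform prior box for every rate component.
    """

    def __init__(
        self,
        obs: ObservationSet,
        n_lineages: int = 30_000,
        s0_total: float = 30_000.0,
        readout: SeqReadoutParams | None = None,
        bounds: tuple[float, float] = (0.0, 4.0),
        eps: float = 1e-3,
    ) -> None:
        self.obs = obs
        self.n_lineages = int(n_lineages)
        self.s0_total = float(s0_total)
        self.readout = readout
        self.bounds = bounds
        self.eps = eps
        self.k_params = 6

    # -- predictions ------------------------------------------------------

    def predict_totals(self, theta) -> np.ndarray:
        """Deterministic total organoid size at each observation day."""
        schedule = schedule_from_theta(theta)
        states = solve_deterministic(schedule, self.s0_total, self.obs.total_days)
        return np.array([st.total for st in states])

    def simulate_ranked(self, theta, rng) -> np.ndarray:
        """One stochastic realization of the ranked sizes at each rank day.

        Lineage sizes are scaled from the simulated ensemble to the nominal
        30,000-lineage organoid; if a readout model is attached, sizes are
        passed through PCR + sequencing and back-normalized to cells first.
        Ranks beyond the number of non-empty lineages come back NaN.
        """
        if self.obs.rank_days.size == 0:
            return np.empty((0, 0))
        schedule = schedule_from_theta(theta)
        ens = simulate_ensemble(
            self.n_lineages, schedule, self.obs.rank_days, rng=rng, eps=self.eps
        )
        out = np.full((self.obs.rank_days.size, self.obs.ranks.size), np.nan)
        for i, day in enumerate(self.obs.rank_days):
            sizes = ens.sizes_at(day).astype(float)
            if self.readout is not None and sizes.sum() > 0:
                reads = simulate_readcounts(sizes, self.readout, rng)
                sizes = reads_to_cells(reads, self.readout.library_size, sizes.sum())
            sizes = sizes[sizes > 0]
            ranked = np.sort(sizes)[::-1]
            ok = self.obs.ranks <= ranked.size
            out[i, ok] = ranked[self.obs.ranks[ok] - 1]
        return out

    def loglike(self, theta, rng) -> float:
        """Unbiased noisy log-likelihood estimate (pseudo-marginal)."""
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.bounds
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        ll = 0.0
        if self.obs.total_days.size:
            pred = self.predict_totals(theta)
            if np.any(pred <= 0):
                return -np.inf
            z = (self.obs.total_mu - np.log(pred)) / self.obs.total_sd
            ll -= 0.5 * float(z @ z)
        if self.obs.rank_days.size:
            ranked = self.simulate_ranked(theta, rng)
            with np.errstate(divide="ignore"):
                log_pred = np.log(ranked)
            z = (self.obs.rank_mu - log_pred) / self.obs.rank_sd
            valid = ~np.isnan(self.obs.rank_mu) & np.isfinite(log_pred)
            # a predicted rank that is missing while observed counts as a hard miss
            if np.any(~np.isfinite(log_pred) & ~np.isnan(self.obs.rank_mu)):
                return -np.inf
            ll -= 0.5 * float(np.sum(z[valid] ** 2))
        return ll

    # -- sampling ---------------------------------------------------------

    def fit(
        self,
        n_chains: int = 16,
        n_accept: int = 200,
        seed: int | None = None,
        proposal_scale: float = 0.1,
        max_proposals: int | None = None,
    ) -> "SANRateResults":
        """Run independent pseudo-marginal MH chains.

        Each chain starts uniform in the prior box and runs until it has
        accepted ``n_accept`` moves (or hits ``max_proposals``, in which case
        it is flagged and its partial trace kept).  The retained posterior
        sample is each chain's final accepted state.
        """
        if n_chains < 1:
            raise ValueError("need at least one chain")
        if max_proposals is None:
            max_proposals = 2000 * n_accept
        root = np.random.SeedSequence(seed)
        lo, hi = self.bounds
        traces = np.full((n_chains, n_accept, self.k_params), np.nan)
        logliks = np.full((n_chains, n_accept), np.nan)
        n_accepted = np.zeros(n_chains, dtype=int)
        n_proposed = np.zeros(n_chains, dtype=int)
        flagged = np.zeros(n_chains, dtype=bool)

        for c, ss in enumerate(root.spawn(n_chains)):
            rng = np.random.default_rng(ss)
            theta = rng.uniform(lo, hi, size=self.k_params)
            ll = self.loglike(theta, rng)
            acc = 0
            while acc < n_accept and n_proposed[c] < max_proposals:
                prop = theta + rng.normal(0.0, proposal_scale, size=self.k_params)
                n_proposed[c] += 1
                ll_prop = self.loglike(prop, rng)
                if np.log(rng.uniform()) < ll_prop - ll:
                    theta, ll = prop, ll_prop
                    traces[c, acc] = theta
                    logliks[c, acc] = ll
                    acc += 1
            n_accepted[c] = acc
            if acc < n_accept:
                flagged[c] = True
                warnings.warn(
                    f"chain {c}: only {acc}/{n_accept} accepts within "
                    f"{max_proposals} proposals; partial trace kept"
                )
        return SANRateResults(
            model=self,
            traces=traces,
            logliks=logliks,
            n_accepted=n_accepted,
            n_proposed=n_proposed,
            flagged=flagged,
            seed=seed,
        )


def gelman_rubin(traces: np.ndarray, use_second_half: bool = True) -> tuple[float, float]:
    """Potential scale reduction factor for one scalar parameter.

    ``traces`` has shape (n_chains, n_samples).  Returns (point estimate,
    upper 95% bound).  Uses the classical between/within variance
    construction on the second halves of the chains; the upper bound scales
    the between-chain term by an F quantile.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    if use_second_half:
        traces = traces[:, traces.shape[1] // 2:]
    m, n = traces.shape
    if n < 2:
        raise ValueError("chains too short")
    chain_means = traces.mean(axis=1)
    chain_vars = traces.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0.0:
        return (1.0, 1.0) if B == 0.0 else (np.inf, np.inf)
    var_hat = (n - 1) / n * W + B / n
    psrf2 = var_hat / W + B / (m * n * W)
    # upper bound: inflate the B/W ratio by the 97.5% F quantile
    var_w = chain_vars.var(ddof=1) / m if m > 1 else 0.0
    df_w = 2 * W**2 / var_w if var_w > 0 else np.inf
    fq = f_dist.ppf(0.975, m - 1, df_w) if np.isfinite(df_w) else 1.0
    psrf2_upper = (n - 1) / n + (1 + 1 / m) * (B / (n * W)) * fq
    return float(np.sqrt(psrf2)), float(np.sqrt(max(psrf2_upper, psrf2)))


def mean_shift_mode(
    samples: np.ndarray,
    bandwidth: np.ndarray | float | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_starts: int = 64,
) -> np.ndarray:
    """Highest-density mode of a sample cloud by Gaussian mean-shift.

    Bandwidth defaults to Silverman's per-dimension rule.  Mean-shift is run
    from the ``n_starts`` highest-density sample points; converged points are
    deduplicated and the mode with the highest kernel density is returned.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d sample array with >= 2 rows")
    n, d = X.shape
    if bandwidth is None:
        sig = X.std(axis=0, ddof=1)
        sig = np.where(sig > 0, sig, 1e-12)
        h = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0)) * sig
    else:
        h = np.broadcast_to(np.asarray(bandwidth, dtype=float), (d,)).copy()
    Z = X / h  # work in bandwidth-scaled coordinates (unit kernel)

    def density(points: np.ndarray) -> np.ndarray:
        d2 = ((points[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-0.5 * d2).sum(axis=1)

    dens_all = density(Z)
    starts = Z[np.argsort(dens_all)[::-1][: min(n_starts, n)]]

    modes = []
    for z in starts:
        for _ in range(max_iter):
            w = np.exp(-0.5 * ((Z - z) ** 2).sum(axis=1))
            z_new = (w[:, None] * Z).sum(axis=0) / w.sum()
            if np.linalg.norm(z_new - z) < tol:
                z = z_new
                break
            z = z_new
        else:
            raise RuntimeError("mean-shift did not converge within max_iter")
        modes.append(z)
    modes = np.array(modes)
    best = modes[np.argmax(density(modes))]
    return best * h


@dataclass
class SANRateResults:
    """Posterior sample, diagnostics and summaries from :meth:`SANRateModel.fit`."""

    model: SANRateModel
    traces: np.ndarray      # (n_chains, n_accept, 6) accepted states
    logliks: np.ndarray     # (n_chains, n_accept)
    n_accepted: np.ndarray
    n_proposed: np.ndarray
    flagged: np.ndarray
    seed: int | None = None
    _map_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.traces.shape[0]

    @property
    def samples(self) -> np.ndarray:
        """Retained posterior draws: each chain's final accepted state."""
        out = np.empty((self.n_chains, self.model.k_params))
        for c in range(self.n_chains):
            last = self.n_accepted[c] - 1
            if last < 0:
                out[c] = np.nan
            else:
                out[c] = self.traces[c, last]
        return out

    def samples_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(THETA_NAMES))
        df.insert(0, "chain", np.arange(self.n_chains))
        df["net_s[11-40]"] = df["s_ss[11-40]"] - df["s_a[11-40]"]
        ll = [self.logliks[c, self.n_accepted[c] - 1] if self.n_accepted[c] else np.nan
              for c in range(self.n_chains)]
        df["loglik"] = ll
        return df

    def gelman_rubin(self) -> pd.DataFrame:
        """PSRF per parameter plus the derived net S rate (days 11-40)."""
        full = self.n_accepted == self.traces.shape[1]
        tr = self.traces[full]
        if tr.shape[0] < 2:
            raise ValueError("need >= 2 complete chains for the diagnostic")
        rows = []
        series = {name: tr[:, :, i] for i, name in enumerate(THETA_NAMES)}
        series["net_s[11-40]"] = tr[:, :, 2] - tr[:, :, 3]
        for name, s in series.items():
            point, upper = gelman_rubin(s)
            rows.append({"parameter": name, "psrf": point, "psrf_upper_95": upper})
        return pd.DataFrame(rows)

    def map_estimate(self, bandwidth=None) -> np.ndarray:
        """Joint posterior mode of the retained draws via mean-shift."""
        if self._map_cache is None or bandwidth is not None:
            samples = self.samples
            samples = samples[~np.isnan(samples).any(axis=1)]
            if samples.shape[0] < 50:
                warnings.warn("fewer than 50 retained draws; MAP estimate is rough")
            mode = mean_shift_mode(samples, bandwidth=bandwidth)
            if bandwidth is not None:
                return mode
            self._map_cache = mode
        return self._map_cache

    def map_schedule(self) -> RateSchedule:
        return schedule_from_theta(self.map_estimate())

    def posterior_predict_scells(self, days) -> np.ndarray:
        """Per-draw deterministic total S-cell counts, shape (n_draws, n_days)."""
        days = np.atleast_1d(np.asarray(days, dtype=float))
        draws = self.samples
        draws = draws[~np.isnan(draws).any(axis=1)]
        out = np.empty((draws.shape[0], days.size))
        for i, theta in enumerate(draws):
            states = solve_deterministic(
                schedule_from_theta(theta), self.model.s0_total, days
            )
            out[i] = [st.s for st in states]
        return out

    def summary(self) -> str:
        df = self.samples_frame()
        lines = ["SAN rate posterior summary",
                 f"chains: {self.n_chains}  accepts/chain: {self.traces.shape[1]}"
                 f"  flagged: {int(self.flagged.sum())}", ""]
        lines.append(f"{'parameter':>14} {'mean':>8} {'sd':>8} {'2.5%':>8} {'97.5%':>8}")
        for name in list(THETA_NAMES) + ["net_s[11-40]"]:
            v = df[name].to_numpy()
            v = v[~np.isnan(v)]
            lines.append(
                f"{name:>14} {v.mean():8.3f} {v.std(ddof=1):8.3f} "
                f"{np.quantile(v, 0.025):8.3f} {np.quantile(v, 0.975):8.3f}"
            )
        return "\n".join(lines)

    def plot_traces(self, ax=None):
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
        for i, name in enumerate(THETA_NAMES):
            a = axes.ravel()[i]
            for c in range(self.n_chains):
                a.plot(self.traces[c, :, i], lw=0.5, alpha=0.6)
            a.set_title(name)
        fig.tight_layout()
        return fig


def sensitivity_analysis(
    map_theta,
    posterior_sds,
    days,
    n_lineages: int = 30_000,
    rank_day: float = 40.0,
    s0_total: float = 30_000.0,
    rng: np.random.Generator | int | None = None,
    n_sd: float = 2.0,
) -> dict:
    """Model response to perturbing each rate by +/- n_sd posterior SDs.

    For every rate component (plus a coupled variant shifting r_S->SS and
    r_S->A together, which holds the net S rate fixed) the deterministic
    size curves at ``days`` and one simulated day-``rank_day`` rank-size
    curve are computed.  Perturbed rates falling below 0 are clipped with a
    warning.
    """
    theta = np.asarray(map_theta, dtype=float)
    sds = np.asarray(posterior_sds, dtype=float)
    if np.any(sds < 0):
        raise ValueError("posterior SDs must be >= 0")
    days = np.asarray(days, dtype=float)
    gen = np.random.default_rng(rng)

    variants: dict[str, np.ndarray] = {"map": theta.copy()}
    for i, name in enumerate(THETA_NAMES):
        for sign in (+1, -1):
            v = theta.copy()
            v[i] += sign * n_sd * sds[i]
            variants[f"{name}{'+' if sign > 0 else '-'}{n_sd:g}sd"] = v
    for sign in (+1, -1):
        v = theta.copy()
        v[2] += sign * n_sd * sds[2]
        v[3] += sign * n_sd * sds[2]
        variants[f"net_fixed{'+' if sign > 0 else '-'}{n_sd:g}sd"] = v

    out = {}
    for label, v in variants.items():
        if np.any(v < 0):
            warnings.warn(f"variant {label}: negative rate clipped at 0")
            v = np.clip(v, 0.0, None)
        schedule = schedule_from_theta(v)
        det = solve_deterministic(schedule, s0_total, days)
        ens = simulate_ensemble(n_lineages, schedule, [rank_day], rng=gen)
        sizes = ens.sizes_at(rank_day)
        out[label] = {
            "theta": v,
            "deterministic": det,
            "rank_sizes": np.sort(sizes[sizes > 0])[::-1],
        }
    return out
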