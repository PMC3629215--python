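"""Bayesian admixture inference from haplogroup counts under pure drift.

The model: an admixed population H is founded at some time in the past as a
mixture of two parental populations, with Palaeolithic contribution ``p1``
(Neolithic contribution ``1 - p1``).  After founding, the three populations
evolve independently under pure genetic drift for scaled times
``t_i = T / N_i`` (time since admixture in generations over haploid
effective size).  The data are haplogroup counts sampled today from each
population.

Drift of a sample is handled exactly through the coalescent: a sample of
``n`` lineages observed after scaled drift time ``t`` descends from
``m <= n`` founder lineages, with ``m`` distributed as the
ancestral-lineage-count (pure-death) process, founder types drawn iid from
the ancestral frequency vector, and family sizes uniform over ordered
compositions of ``n`` into ``m`` positive parts.  Summing over founder
configurations gives a closed-form marginal likelihood, so the MCMC needs no
latent genealogy variables: it samples ``(p1, t1, t2, th, x1, x2)`` only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.linalg import expm
from scipy.special import gammaln, logsumexp
from scipy.stats import gaussian_kde

from neodemic.io import HaplogroupCounts, RunConfig

__all__ = [
    "drift_lineage_pmf",
    "drifted_sample_loglik",
    "run_admixture_mcmc",
    "posterior_mode_hpd",
    "PosteriorSample",
]

_LOG_TINY = -745.0


# ---------------------------------------------------------------------------
# Ancestral lineage count distribution
# ---------------------------------------------------------------------------

def _pmf_series(n: int, t: float) -> np.ndarray | None:
    """Eigen-expansion of the lineage-death semigroup.

    Returns P(A_n(t) = m) for m = 1..n, or None when catastrophic
    cancellation in the alternating series would leave fewer than ~4
    reliable digits (small t, large n), in which case the caller switches
    to the matrix route.
    """
    m = np.arange(1, n + 1)
    k = np.arange(1, n + 1)
    mm, kk = np.meshgrid(m, k, indexing="ij")
    valid = kk >= mm
    with np.errstate(invalid="ignore"):
        logcoef = (
            np.log(2 * kk - 1.0)
            + gammaln(mm + kk - 1) - gammaln(mm)          # rising m_(k-1)
            - gammaln(mm + 1.0) - gammaln(kk - mm + 1.0)
            + gammaln(n + 1.0) - gammaln(n - kk + 1.0)     # falling n_[k]
            - (gammaln(n + kk + 0.0) - gammaln(n + 0.0))   # rising n_(k)
        )
    sign = np.where((kk - mm) % 2 == 0, 1.0, -1.0)
    logterm = np.where(valid, logcoef - kk * (kk - 1) * t / 2.0, -np.inf)
    log_abs, _ = logsumexp(logterm, axis=1, return_sign=True)
    log_signed, res_sign = logsumexp(logterm, b=sign, axis=1, return_sign=True)
    # absolute error after float64 summation ~ exp(log_abs) * n * eps
    err = np.exp(np.clip(log_abs, _LOG_TINY, 700) + math.log(n) - 36.0)
    if np.any(err > 1e-12):
        return None
    p = np.where(res_sign > 0, np.exp(np.clip(log_signed, _LOG_TINY, 0.0)), 0.0)
    s = p.sum()
    if not (0.999 < s < 1.001):
        return None
    return p / s


def _pmf_matrix(n: int, t: float) -> np.ndarray:
    """Scaling-and-squaring of the (non-negative) transition matrix.

    Free of cancellation, so it remains accurate where the eigen-series
    is not; cost is O(J n^3) with J ~ log2(n^2 t).
    """
    rates = np.arange(1, n + 1) * np.arange(0, n) / 2.0  # m(m-1)/2, m=1..n
    total = rates[-1] * t
    J = max(0, int(np.ceil(np.log2(max(total, 1e-12) / 0.5))))
    tau = t / 2.0**J
    Q = np.diag(-rates) + np.diag(rates[1:], k=-1)
    P = expm(Q * tau)
    for _ in range(J):
        P = P @ P
    row = np.clip(P[n - 1], 0.0, None)
    return row / row.sum()


def drift_lineage_pmf(n: int, t: float) -> np.ndarray:
    """Distribution of the number of founder lineages of a sample.

    Parameters
    ----------
    n : sample size (>= 1).
    t : scaled drift time; a pair of lineages coalesces at rate 1 per unit t.

    Returns
    -------
    Array of length ``n``; entry ``m - 1`` is P(m founders), m = 1..n.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if t < 0:
        raise ValueError("drift time must be >= 0")
    if n == 1 or t == 0.0:
        p = np.zeros(n)
        p[n - 1] = 1.0
        return p
    if n == 2:
        return np.array([1.0 - math.exp(-t), math.exp(-t)])
    p = _pmf_series(n, t)
    if p is None:
        p = _pmf_matrix(n, t)
    return p


class LineagePmfCache:
    """log-pmf of the founder count on a geometric drift-time grid.

    Built once per sample size for the MCMC: transition matrices are
    obtained by repeated squaring along interleaved doubling chains and
    the log-probabilities are interpolated monotonically (PCHIP) in log t.
    """

    def __init__(self, n: int, t_min: float = 5e-4, t_max: float = 20.0,
                 per_octave: int = 12):
        self.n = n
        octaves = int(np.ceil(np.log2(t_max / t_min)))
        rates = np.arange(1, n + 1) * np.arange(0, n) / 2.0
        Q = np.diag(-rates) + np.diag(rates[1:], k=-1)
        ts, rows = [], []
        for i in range(per_octave):
            tau = t_min * 2.0 ** (i / per_octave)
            P = expm(Q * tau)
            t = tau
            for _ in range(octaves + 1):
                ts.append(t)
                rows.append(np.clip(P[n - 1], 0.0, None))
                P = P @ P
                t *= 2.0
        order = np.argsort(ts)
        self.grid = np.asarray(ts)[order]
        mat = np.asarray(rows)[order]
        mat /= mat.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            logmat = np.clip(np.log(mat), _LOG_TINY, 0.0)
        self._interp = PchipInterpolator(np.log(self.grid), logmat, axis=0,
                                         extrapolate=True)

    def logpmf(self, t: float) -> np.ndarray:
        if t <= self.grid[0]:
            t = self.grid[0]
        elif t >= self.grid[-1]:
            t = self.grid[-1]
        lp = self._interp(np.log(t))
        return lp - _fast_lse(lp)


@lru_cache(maxsize=32)
def _cached_pmf(n: int) -> LineagePmfCache:
    return LineagePmfCache(n)


# ---------------------------------------------------------------------------
# Drifted sample likelihood
# ---------------------------------------------------------------------------

def _fast_lse(a: np.ndarray) -> float:
    m = a.max()
    if m == -np.inf:
        return -np.inf
    return float(m + np.log(np.exp(a - m).sum()))


class _GKernel:
    """Precomputed pieces of the founder-configuration sum for fixed counts.

    Founder types iid from x; within each haplogroup the founder family
    sizes form a uniform ordered composition, giving per-type generating
    polynomials whose product, coefficient by coefficient, is the sum over
    founder configurations.  All terms are non-negative, so the
    convolution is done in linear space with running rescaling.
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=int)
        self.counts = counts
        self.n = int(counts.sum())
        # per-type log [C(ck-1, j-1) / j!] for j = 1..ck
        self.base = []
        for ck in counts:
            if ck == 0:
                self.base.append(None)
                continue
            j = np.arange(1, ck + 1)
            self.base.append(gammaln(ck) - gammaln(j) - gammaln(ck - j + 1.0)
                             - gammaln(j + 1.0))
        mvals = np.arange(1, self.n + 1)
        # m! / C(n-1, m-1)
        self.tail = (gammaln(mvals + 1.0)
                     - (gammaln(self.n + 0.0) - gammaln(mvals)
                        - gammaln(self.n - mvals + 1.0)))

    def loggvec(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            logx = np.log(np.asarray(x, dtype=float))
        poly = np.array([1.0])
        log_scale = 0.0
        for ck, lx, base in zip(self.counts, logx, self.base):
            if base is None:
                continue
            logp = np.arange(1, ck + 1) * lx + base
            top = logp.max()
            if top == -np.inf:
                return np.full(self.n, -np.inf)
            pk = np.zeros(ck + 1)
            pk[1:] = np.exp(logp - top)
            poly = np.convolve(poly, pk)
            log_scale += top
            m = poly.max()
            poly /= m
            log_scale += np.log(m)
        with np.errstate(divide="ignore"):
            logA = np.log(poly[1:self.n + 1])
        return logA + log_scale + self.tail


def _log_g_vector(counts: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log P(counts | m founders, ancestral frequencies x), m = 1..n."""
    return _GKernel(counts).loggvec(x)


def drifted_sample_loglik(counts: np.ndarray, x: np.ndarray, t: float) -> float:
    """Log-probability of haplogroup counts drifted from frequencies x.

    Marginalises over the founder lineage count and founder configuration
    exactly.  ``t = 0`` reduces to the multinomial; ``t`` large reduces to
    a single founder drawn from x.
    """
    counts = np.asarray(counts, dtype=int)
    if (counts < 0).any():
        raise ValueError("negative count")
    n = int(counts.sum())
    if n < 1:
        raise ValueError("empty sample")
    with np.errstate(divide="ignore"):
        logpmf = np.clip(np.log(drift_lineage_pmf(n, t)), _LOG_TINY, 0.0)
    logg = _log_g_vector(counts, np.asarray(x, dtype=float))
    return _fast_lse(logpmf + logg)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    """Retained MCMC draws plus chain diagnostics."""

    draws: pd.DataFrame
    burn_in: int
    thin: int
    acceptance: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for lag in range(1, min(n // 2, 1000)):
        if acf[lag] < 0.0:
            break
        tau += 2.0 * acf[lag]
    return float(n / max(tau, 1.0))


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum()
                 + ((alpha - 1.0) * np.log(x)).sum())


class _AdmixtureModel:
    """Posterior evaluation helpers shared by the Gibbs blocks."""

    def __init__(self, data: HaplogroupCounts, t_bounds: tuple[float, float],
                 likelihood_on: bool = True):
        if data.counts.shape[0] != 3:
            raise ValueError("expected exactly three populations: P1, P2, H")
        if data.n_haplogroups < 2:
            raise ValueError("model unidentifiable with K < 2 haplogroups")
        self.c1, self.c2, self.ch = data.counts
        self.n = data.sample_sizes
        self.t_bounds = t_bounds
        self.likelihood_on = likelihood_on
        if likelihood_on:
            self.caches = [_cached_pmf(int(m)) for m in self.n]
            self.kernels = [_GKernel(c) for c in data.counts]

    def loglik_pop(self, which: int, x: np.ndarray | None,
                   t: float, logg: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        if not self.likelihood_on:
            return 0.0, np.zeros(1)
        if logg is None:
            logg = self.kernels[which].loggvec(x)
        lp = self.caches[which].logpmf(t)
        return _fast_lse(lp + logg), logg


def run_admixture_mcmc(
    data: HaplogroupCounts,
    config: RunConfig | None = None,
    seed: int | None = None,
    n_iter: int = 20000,
    burn_in: int = 5000,
    thin: int = 10,
    t_bounds: tuple[float, float] = (1e-3, 10.0),
    likelihood_on: bool = True,
) -> PosteriorSample:
    """Metropolis-within-Gibbs sampler for ``(p1, t1, t2, th, x1, x2)``.

    Priors: ``p1 ~ U(0,1)``; drift times log-uniform on ``t_bounds``;
    ancestral frequencies flat Dirichlet.  Proposals are a logit random
    walk for ``p1``, log random walks for the ``t_i`` and Dirichlet
    neighbourhood moves for ``x1, x2``; step sizes adapt during burn-in
    only.  With ``likelihood_on=False`` the chain targets the prior
    (used for prior-recovery checks).

    The default chain lengths here are reduced test-scale settings; pass
    larger values (or a RunConfig ``mcmc`` block) for production runs.
    """
    if config is not None:
        blk = config.stage("mcmc")
        n_iter = int(blk.get("n_iter", n_iter))
        burn_in = int(blk.get("burn_in", burn_in))
        thin = int(blk.get("thin", thin))
        t_bounds = tuple(blk.get("t_bounds", t_bounds))
        if seed is None:
            seed = config.seed
    rng = np.random.default_rng(seed)
    model = _AdmixtureModel(data, t_bounds, likelihood_on)
    K = data.n_haplogroups
    log_lo, log_hi = np.log(t_bounds[0]), np.log(t_bounds[1])

    # state
    x1 = (model.c1 + 1.0) / (model.c1.sum() + K)
    x2 = (model.c2 + 1.0) / (model.c2.sum() + K)
    p1 = 0.5
    logt = np.full(3, np.log(0.1))

    def xh(p, a, b):
        return p * a + (1.0 - p) * b

    ll1, logg1 = model.loglik_pop(0, x1, np.exp(logt[0]))
    ll2, logg2 = model.loglik_pop(1, x2, np.exp(logt[1]))
    llh, loggh = model.loglik_pop(2, xh(p1, x1, x2), np.exp(logt[2]))

    step_u = 0.8           # logit(p1) RW sd
    step_v = np.full(3, 0.8)  # log t RW sd
    conc = np.array([300.0, 300.0])  # Dirichlet proposal concentrations
    acc = {k: [0, 0] for k in ("p1", "t1", "t2", "th", "x1", "x2")}
    eps = 1.0  # Dirichlet proposal floor, keeps moves off the boundary

    kept = []
    n_total = n_iter + burn_in
    for it in range(n_total):
        adapt = it < burn_in
        # --- p1 via logit random walk ------------------------------------
        u = math.log(p1 / (1.0 - p1))
        u_new = u + step_u * rng.standard_normal()
        p_new = 1.0 / (1.0 + math.exp(-u_new))
        ll_new, logg_new = model.loglik_pop(2, xh(p_new, x1, x2),
                                            math.exp(logt[2]))
        # flat prior on p1; Jacobian of the logit transform
        log_r = (ll_new - llh
                 + math.log(p_new * (1 - p_new)) - math.log(p1 * (1 - p1)))
        acc["p1"][1] += 1
        if math.log(rng.random()) < log_r:
            p1, llh, loggh = p_new, ll_new, logg_new
            acc["p1"][0] += 1
        if adapt:
            step_u *= math.exp(0.01 * ((min(1.0, math.exp(min(log_r, 0.0)))) - 0.44))

        # --- drift times via log random walk -----------------------------
        for j, key in enumerate(("t1", "t2", "th")):
            v_new = logt[j] + step_v[j] * rng.standard_normal()
            if not (log_lo <= v_new <= log_hi):
                acc[key][1] += 1
                continue  # log-uniform prior: reject outside support
            logg = (logg1, logg2, loggh)[j]
            ll_old = (ll1, ll2, llh)[j]
            ll_new, _ = model.loglik_pop(j, None, math.exp(v_new), logg=logg)
            log_r = ll_new - ll_old  # prior flat in log t, symmetric proposal
            acc[key][1] += 1
            if math.log(rng.random()) < log_r:
                logt[j] = v_new
                if j == 0:
                    ll1 = ll_new
                elif j == 1:
                    ll2 = ll_new
                else:
                    llh = ll_new
                acc[key][0] += 1
            if adapt:
                step_v[j] *= math.exp(0.01 * (min(1.0, math.exp(min(log_r, 0.0))) - 0.44))

        # --- parental frequencies via Dirichlet neighbourhood moves ------
        for j, key in enumerate(("x1", "x2")):
            x_cur = x1 if j == 0 else x2
            alpha_fwd = conc[j] * x_cur + eps
            x_new = rng.dirichlet(alpha_fwd)
            x_new = np.clip(x_new, 1e-12, None)
            x_new /= x_new.sum()
            alpha_rev = conc[j] * x_new + eps
            own_ll = ll1 if j == 0 else ll2
            ll_own_new, logg_own_new = model.loglik_pop(
                j, x_new, math.exp(logt[j]))
            xh_new = xh(p1, x_new, x2) if j == 0 else xh(p1, x1, x_new)
            ll_h_new, logg_h_new = model.loglik_pop(2, xh_new,
                                                    math.exp(logt[2]))
            log_r = (ll_own_new - own_ll + ll_h_new - llh
                     + _dirichlet_logpdf(x_cur, alpha_rev)
                     - _dirichlet_logpdf(x_new, alpha_fwd))
            acc[key][1] += 1
            if math.log(rng.random()) < log_r:
                if j == 0:
                    x1, ll1, logg1 = x_new, ll_own_new, logg_own_new
                else:
                    x2, ll2, logg2 = x_new, ll_own_new, logg_own_new
                llh, loggh = ll_h_new, logg_h_new
                acc[key][0] += 1
            if adapt:
                # higher concentration = smaller moves
                conc[j] *= math.exp(-0.01 * (min(1.0, math.exp(min(log_r, 0.0))) - 0.25))
                conc[j] = min(max(conc[j], 5.0), 1e6)

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept.append((p1, *np.exp(logt)))

    draws = pd.DataFrame(kept, columns=["p1", "t1", "t2", "th"])
    rates = {k: (a / max(b, 1)) for k, (a, b) in acc.items()}
    ess = {c: effective_sample_size(draws[c].to_numpy()) for c in draws.columns}
    return PosteriorSample(draws=draws, burn_in=burn_in, thin=thin,
                           acceptance=rates, ess=ess)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def posterior_mode_hpd(
    draws: np.ndarray, level: float = 0.9,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> tuple[float, tuple[float, float]]:
    """Mode (boundary-reflected KDE) and shortest ``level``-mass interval."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws")
    lo, hi = bounds
    if np.ptp(draws) == 0.0:
        v = float(draws[0])
        return v, (v, v)
    kde = gaussian_kde(draws)
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid) + kde(2 * lo - grid) + kde(2 * hi - grid)
    mode = float(grid[int(np.argmax(dens))])
    srt = np.sort(draws)
    k = max(1, int(math.ceil(level * len(srt))))
    if k >= len(srt):
        interval = (float(srt[0]), float(srt[-1]))
    else:
        widths = srt[k:] - srt[:-k]
        i = int(np.argmin(widths))
        interval = (float(srt[i]), float(srt[i + k]))
    return mode, interval
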