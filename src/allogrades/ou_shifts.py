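"""Bayesian reversible-jump multiregime Ornstein-Uhlenbeck regression.

Detects shifts in a bivariate allometry (slope and intercept of log10
response on log10 predictor) on a time-calibrated phylogeny without
specifying shift locations a priori. Each branch may carry at most one
shift; a shift opens a new regime with its own optimum-intercept theta and
slope beta, inherited by descendants. Tip expectations are the OU
regime-weight mixture

    E[y_i] = sum_k W[i,k] (theta_k + beta_k x_i),

with W the exponentially discounted regime occupancy of tip i's history
(see phylo.ou_weight_matrix) and residual covariance V_OU(alpha, sigma2).
The predictor is treated as error-free and time-invariant per tip.

Priors follow the comparative-neuroscience defaults: half-Cauchy(0.1) on
alpha and sigma2, Poisson shift count with mean 2% of the branch count
truncated at 20%, theta ~ N(mean(y), 1.5 SD(y)), beta ~ N(PGLS slope,
0.3), shift locations uniform over branches.

The sampler is Metropolis-Hastings within reversible jump with uniform
move-type choice: birth / death / relocation of a shift, log-scale random
walks on alpha and sigma2, Gaussian random walks on each theta_k, beta_k.
Birth draws the new regime's (theta, beta) from their priors, so the
acceptance ratio reduces to the likelihood ratio times the Poisson and
location prior ratios and the dimension-matching proposal ratio. Step
sizes adapt during burn-in only and are frozen afterwards to preserve
detailed balance. Runs are bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

from .phylo import (
    Phylogeny,
    RegimePainting,
    ou_covariance,
    ou_weight_matrix,
    paint_regimes,
)
from .pgls import fit_pgls

__all__ = [
    "OUAllometryParams",
    "PriorSpec",
    "PosteriorChain",
    "ShiftSummary",
    "ou_regression_loglik",
    "log_prior",
    "rjmcmc_run",
    "gelman_rhat",
    "effective_sample_size",
    "chain_diagnostics",
    "summarize_shifts",
]


# ----------------------------------------------------------------------
# Parameters, priors, likelihood
# ----------------------------------------------------------------------

@dataclass
class OUAllometryParams:
    """Multiregime OU regression parameters.

    alpha : attraction strength (1/My); sigma2 : diffusion (log10^2/My);
    theta, beta : per-regime intercepts and slopes, index 0 = ancestral.
    """

    alpha: float
    sigma2: float
    theta: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, float))
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        if self.alpha <= 0 or self.sigma2 <= 0:
            raise ValueError("alpha and sigma2 must be positive")
        if len(self.theta) != len(self.beta):
            raise ValueError("theta and beta must have equal length")

    @property
    def n_regimes(self) -> int:
        return len(self.theta)


@dataclass
class PriorSpec:
    """Prior hyperparameters for the RJ-MCMC."""

    alpha_scale: float = 0.1
    sigma2_scale: float = 0.1
    shift_rate_fraction: float = 0.02  # Poisson mean = fraction * branches
    shift_max_fraction: float = 0.20  # truncation of the shift count
    theta_mu: float = 0.0
    theta_sd: float = 1.0
    beta_mu: float = 0.0
    beta_sd: float = 0.3

    def poisson_mean(self, n_branches: int) -> float:
        return self.shift_rate_fraction * n_branches

    def max_shifts(self, n_branches: int) -> int:
        return int(math.floor(self.shift_max_fraction * n_branches))

    @classmethod
    def from_data(cls, tree: Phylogeny, x: pd.Series, y: pd.Series,
                  **overrides) -> "PriorSpec":
        """Data-driven hyperparameters: theta centered on the trait mean
        with 1.5x its SD, beta centered on the single-line PGLS slope."""
        yv = np.asarray(y.loc[tree.tip_labels], float)
        slope = fit_pgls(
            y, pd.DataFrame({"Intercept": 1.0, "Slope": x}), tree, "REML"
        ).params["Slope"]
        kw = dict(
            theta_mu=float(yv.mean()),
            theta_sd=float(1.5 * yv.std(ddof=1)),
            beta_mu=float(slope),
        )
        kw.update(overrides)
        return cls(**kw)


def ou_regression_loglik(
    x, y, tree: Phylogeny, painting: RegimePainting,
    params: OUAllometryParams,
) -> float:
    """Multivariate-normal log density of y under the multiregime OU
    regression (dense route; the sampler uses a cached equivalent)."""
    if params.n_regimes != painting.n_regimes:
        raise ValueError("params dimension does not match painting")
    xv = np.asarray(x.loc[tree.tip_labels] if isinstance(x, pd.Series) else x,
                    float)
    yv = np.asarray(y.loc[tree.tip_labels] if isinstance(y, pd.Series) else y,
                    float)
    W = ou_weight_matrix(tree, painting, params.alpha)
    mean = W @ params.theta + xv * (W @ params.beta)
    V = ou_covariance(tree, params.alpha, params.sigma2)
    n = len(yv)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(V) / n
        try:
            cf = cho_factor(V + jitter * np.eye(n), lower=True)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(
                f"OU covariance not PSD (cond ~ {np.linalg.cond(V):.2e})"
            ) from exc
    r = yv - mean
    quad = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _halfcauchy_logpdf(v: float, scale: float) -> float:
    if v <= 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale * (1.0 + (v / scale) ** 2)))


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _trunc_poisson_logpmf(m: int, mean: float, mmax: int) -> float:
    if m < 0 or m > mmax:
        return -np.inf
    logZ = np.log(stats.poisson.cdf(mmax, mean))
    return stats.poisson.logpmf(m, mean) - logZ


def log_prior(
    params: OUAllometryParams,
    painting: RegimePainting,
    priors: PriorSpec,
) -> float:
    """Joint log prior: alpha, sigma2 half-Cauchy; shift count truncated
    Poisson; shift locations uniform over branch subsets; per-regime
    theta, beta normal. Shift counts above the truncation bound give -inf
    (rejected state)."""
    n_branches = len(painting.branch_regime) - 1
    m = len(painting.shifts)
    mmax = priors.max_shifts(n_branches)
    lp = _trunc_poisson_logpmf(m, priors.poisson_mean(n_branches), mmax)
    if not np.isfinite(lp):
        return -np.inf
    lp += _halfcauchy_logpdf(params.alpha, priors.alpha_scale)
    lp += _halfcauchy_logpdf(params.sigma2, priors.sigma2_scale)
    lp -= _log_comb(n_branches, m)  # uniform shift-location mass
    lp += float(
        np.sum(stats.norm.logpdf(params.theta, priors.theta_mu,
                                 priors.theta_sd))
        + np.sum(stats.norm.logpdf(params.beta, priors.beta_mu,
                                   priors.beta_sd))
    )
    return lp


# ----------------------------------------------------------------------
# Chains
# ----------------------------------------------------------------------

@dataclass
class PosteriorChain:
    """One sampled chain (thinned; burn-in retained but flagged)."""

    alpha: np.ndarray
    sigma2: np.ndarray
    n_shifts: np.ndarray
    theta_root: np.ndarray
    beta_root: np.ndarray
    logpost: np.ndarray
    shift_states: list  # per sample: dict branch -> (theta, beta)
    n_iter: int
    thin: int
    burn_in: float
    seed: int
    accept_rate: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.alpha)

    @property
    def burn_idx(self) -> int:
        return int(self.burn_in * self.n_samples)

    def trace(self, name: str, post_burnin: bool = True) -> np.ndarray:
        arr = getattr(self, name)
        return arr[self.burn_idx:] if post_burnin else arr

    def post_shift_states(self) -> list:
        return self.shift_states[self.burn_idx:]


# ----------------------------------------------------------------------
# The sampler
# ----------------------------------------------------------------------

_MOVES = ("birth", "death", "relocate", "alpha", "sigma2", "theta",
          "beta", "lineshift")


class _OUSampler:
    """Internal single-chain sampler with per-alpha caches.

    The OU covariance factors as sigma2 * M(alpha) and the weight matrix
    as a regime aggregation of per-branch segment weights E(alpha), so
    only alpha moves pay for a new Cholesky; all other moves reuse it.
    """

    def __init__(self, tree, xv, yv, priors, rng, prior_only=False,
                 step_sizes=None):
        self.tree = tree
        self.x = xv
        self.y = yv
        self.priors = priors
        self.rng = rng
        self.prior_only = prior_only
        self.n = tree.n_tips
        self.N = tree.n_nodes
        self.B = tree.n_branches
        self.mmax = priors.max_shifts(self.B)
        self.T = tree.tree_height
        # static geometry: per-tip path segments as dense masked matrices
        Ti = tree.depth[tree.tip_ids]
        self.Ti = Ti
        # flat sparse layout of root-to-tip path segments
        fi, fj, D0f, D1f = [], [], [], []
        for i, u in enumerate(tree.tip_ids):
            for b in tree.path_to_root(u):
                fi.append(i)
                fj.append(b)
                D0f.append(Ti[i] - tree.depth[tree.parent[b]])
                D1f.append(Ti[i] - tree.depth[b])
        self.fi = np.array(fi, dtype=np.intp)
        self.fj = np.array(fj, dtype=np.intp)
        self.D0f = np.array(D0f)
        self.D1f = np.array(D1f)
        ta = np.zeros((self.n, self.n))
        from .phylo import bm_covariance

        ta[:] = bm_covariance(tree)
        np.fill_diagonal(ta, Ti)
        self.ta = ta
        self.steps = dict(alpha=0.5, sigma2=0.5, theta=0.2, beta=0.1,
                          lineshift=0.1)
        self.xbar = float(xv.mean())
        if step_sizes:
            self.steps.update(step_sizes)
        self.clade_size = np.zeros(self.N, int)
        for b in tree.branch_ids:
            self.clade_size[b] = len(tree.clade_tip_ids(b))
        # fast-painting precomputation: per-branch descendant node masks,
        # and prior tables (truncated Poisson + location combinatorics)
        self.desc = np.zeros((self.N, self.N), bool)
        for u in tree.postorder:
            self.desc[u, u] = True
            for c in tree.children[u]:
                self.desc[u] |= self.desc[c]
        self.node_depth = tree.depth
        # per-branch clade OLS lines for informed birth proposals: the
        # birth draws (theta, beta) from an equal mixture of the prior
        # and a normal centred on the clade's own least-squares line
        # (exact mixture density enters the Hastings ratio)
        self.local_fit = {}
        pos = {u: i for i, u in enumerate(tree.tip_ids)}
        for b in tree.branch_ids:
            ii = [pos[u] for u in tree.clade_tip_ids(b)]
            if len(ii) >= 3 and not prior_only:
                xs, ys = xv[ii], yv[ii]
                vx = xs.var()
                if vx > 1e-12:
                    be = float(np.cov(xs, ys, bias=True)[0, 1] / vx)
                    th = float(ys.mean() - be * xs.mean())
                    self.local_fit[b] = (th, be)
        self.local_sd = (max(0.05, 0.15 * priors.theta_sd),
                         max(0.03, 0.25 * priors.beta_sd))
        mean = priors.poisson_mean(self.B)
        ms = np.arange(self.mmax + 1)
        logpmf = ms * math.log(mean) - mean - gammaln(ms + 1)
        logZ = np.logaddexp.reduce(logpmf)
        self.pois_table = logpmf - logZ
        self.logcomb_table = np.array(
            [_log_comb(self.B, m) for m in ms]
        )
        self._lp_norm_const = -0.5 * math.log(2 * math.pi)

    # -- caches -------------------------------------------------------
    def set_alpha(self, alpha):
        self.alpha = alpha
        if self.prior_only:  # caches feed only the likelihood
            return
        a = alpha
        # exp(-2a(T-ta))(1-exp(-2a ta)) = exp(-2a(T-ta)) - exp(-2aT)
        M = (np.exp(-2 * a * (self.T - self.ta))
             - math.exp(-2 * a * self.T)) / (2 * a)
        self.cf = cho_factor(M, lower=True, check_finite=False)
        self.logdetM = 2.0 * float(np.sum(np.log(np.diag(self.cf[0]))))
        self.E = np.exp(-a * self.D1f) - np.exp(-a * self.D0f)
        self.rootw = np.exp(-a * self.Ti)

    def set_painting(self, shifts: dict):
        """shifts: dict branch -> [theta, beta]; rebuilds regime map + W."""
        self.shifts = shifts
        self.sorted_shifts = sorted(shifts)
        # nearest-ancestral-shift painting: apply descendant masks in
        # order of increasing shift depth so nested shifts override
        reg = np.zeros(self.N, dtype=np.intp)
        order = sorted(
            self.sorted_shifts, key=lambda b: self.node_depth[b]
        )
        idx = {b: k + 1 for k, b in enumerate(self.sorted_shifts)}
        for b in order:
            reg[self.desc[b]] = idx[b]
        self.reg = reg
        self._rebuild_W()

    def _rebuild_W(self):
        if self.prior_only:
            return
        K = len(self.sorted_shifts) + 1
        W = np.zeros((self.n, K))
        np.add.at(W, (self.fi, self.reg[self.fj]), self.E)
        W[:, 0] += self.rootw
        self.W = W

    def theta_beta_vectors(self):
        th = np.empty(len(self.sorted_shifts) + 1)
        be = np.empty_like(th)
        th[0], be[0] = self.theta0, self.beta0
        for k, b in enumerate(self.sorted_shifts):
            th[k + 1], be[k + 1] = self.shifts[b]
        return th, be

    # -- densities ----------------------------------------------------
    def loglik(self):
        if self.prior_only:
            return 0.0
        th, be = self.theta_beta_vectors()
        mean = self.W @ th + self.x * (self.W @ be)
        r = self.y - mean
        quad = float(
            r @ cho_solve(self.cf, r, check_finite=False)
        ) / self.sig2
        return -0.5 * (
            self.n * math.log(2 * math.pi * self.sig2) + self.logdetM + quad
        )

    def _norm_logpdf(self, v, mu, sd):
        return self._lp_norm_const - math.log(sd) - 0.5 * ((v - mu) / sd) ** 2

    def _draw_birth_params(self, b, rng):
        pr = self.priors
        if b in self.local_fit and rng.random() < 0.5:
            lt, lb = self.local_fit[b]
            st, sb = self.local_sd
            return (lt + st * rng.standard_normal(),
                    lb + sb * rng.standard_normal())
        return (pr.theta_mu + pr.theta_sd * rng.standard_normal(),
                pr.beta_mu + pr.beta_sd * rng.standard_normal())

    def _birth_param_logq(self, b, th, be):
        """Density of the birth (theta, beta) proposal at a value: an
        equal mixture of the prior and the branch's local-line normal."""
        pr = self.priors
        lp_prior = (self._norm_logpdf(th, pr.theta_mu, pr.theta_sd)
                    + self._norm_logpdf(be, pr.beta_mu, pr.beta_sd))
        if b not in self.local_fit:
            return lp_prior
        lt, lb = self.local_fit[b]
        st, sb = self.local_sd
        lp_local = (self._norm_logpdf(th, lt, st)
                    + self._norm_logpdf(be, lb, sb))
        return float(np.logaddexp(lp_prior, lp_local)) + math.log(0.5)

    def logprior(self):
        """Fast table-backed equivalent of the public log_prior."""
        pr = self.priors
        m = len(self.shifts)
        if m > self.mmax:
            return -np.inf
        lp = float(self.pois_table[m]) - float(self.logcomb_table[m])
        lp += _halfcauchy_logpdf(self.alpha, pr.alpha_scale)
        lp += _halfcauchy_logpdf(self.sig2, pr.sigma2_scale)
        lp += self._norm_logpdf(self.theta0, pr.theta_mu, pr.theta_sd)
        lp += self._norm_logpdf(self.beta0, pr.beta_mu, pr.beta_sd)
        for th, be in self.shifts.values():
            lp += self._norm_logpdf(th, pr.theta_mu, pr.theta_sd)
            lp += self._norm_logpdf(be, pr.beta_mu, pr.beta_sd)
        return lp

    def logpost(self):
        return self.loglik() + self.logprior()

    # -- moves --------------------------------------------------------
    def propose(self, move):
        """Returns (accepted: bool). State mutated in place on accept."""
        rng = self.rng
        pr = self.priors
        lp0 = self.cur_logpost
        if move == "birth":
            m = len(self.shifts)
            if m >= self.mmax:
                return False
            free = [b for b in range(1, self.N) if b not in self.shifts]
            b = free[rng.integers(len(free))]
            th_new, be_new = self._draw_birth_params(b, rng)
            old = dict(self.shifts)
            self.shifts[b] = (th_new, be_new)
            self.set_painting(self.shifts)
            lp1 = self.logpost()
            # forward: choose branch (1/|free|) and draw (theta, beta)
            # from the birth mixture; reverse: choose the shift to kill
            # (1/(m+1))
            log_q = (
                -math.log(m + 1)
                - (
                    -math.log(len(free))
                    + self._birth_param_logq(b, th_new, be_new)
                )
            )
            if math.log(rng.random()) < lp1 - lp0 + log_q:
                self.cur_logpost = lp1
                return True
            self.set_painting(old)
            return False
        if move == "death":
            m = len(self.shifts)
            if m == 0:
                return False
            b = self.sorted_shifts[rng.integers(m)]
            th_old, be_old = self.shifts[b]
            old = dict(self.shifts)
            del self.shifts[b]
            self.set_painting(self.shifts)
            lp1 = self.logpost()
            free_after = self.B - (m - 1)
            log_q = (
                -math.log(free_after)
                + self._birth_param_logq(b, th_old, be_old)
            ) - (-math.log(m))
            if math.log(rng.random()) < lp1 - lp0 + log_q:
                self.cur_logpost = lp1
                return True
            self.set_painting(old)
            return False
        if move == "relocate":
            m = len(self.shifts)
            if m == 0:
                return False
            b = self.sorted_shifts[rng.integers(m)]
            others = set(self.shifts) - {b}
            free = [c for c in range(1, self.N) if c not in others]
            c = free[rng.integers(len(free))]  # may equal b (null move)
            old = dict(self.shifts)
            val = self.shifts.pop(b)
            self.shifts[c] = val
            self.set_painting(self.shifts)
            lp1 = self.logpost()
            if math.log(rng.random()) < lp1 - lp0:  # symmetric
                self.cur_logpost = lp1
                return True
            self.set_painting(old)
            return False
        if move in ("alpha", "sigma2"):
            cur = self.alpha if move == "alpha" else self.sig2
            new = cur * math.exp(self.steps[move] * rng.standard_normal())
            if move == "alpha":
                if self.prior_only:
                    old_cache = (self.alpha,)
                else:
                    old_cache = (self.alpha, self.cf, self.logdetM,
                                 self.E, self.rootw)
                self.set_alpha(new)
                self._rebuild_W()
            else:
                self.sig2 = new
            lp1 = self.logpost()
            # log-scale walk Jacobian
            if math.log(rng.random()) < lp1 - lp0 + math.log(new / cur):
                self.cur_logpost = lp1
                return True
            if move == "alpha":
                if self.prior_only:
                    self.alpha = old_cache[0]
                else:
                    (self.alpha, self.cf, self.logdetM, self.E,
                     self.rootw) = old_cache
                    self._rebuild_W()
            else:
                self.sig2 = cur
            return False
        if move == "lineshift":
            # pivot a regime's line about the mean predictor: beta_k and
            # theta_k move jointly along their posterior correlation
            # direction (symmetric shear proposal)
            K = len(self.sorted_shifts) + 1
            k = int(rng.integers(K))
            d = self.steps[move] * rng.standard_normal()
            self._bump("beta", k, d)
            self._bump("theta", k, -d * self.xbar)
            lp1 = self.logpost()
            if math.log(rng.random()) < lp1 - lp0:
                self.cur_logpost = lp1
                return True
            self._bump("beta", k, -d)
            self._bump("theta", k, d * self.xbar)
            return False
        # theta / beta random walk on a uniformly chosen regime
        K = len(self.sorted_shifts) + 1
        k = int(rng.integers(K))
        delta = self.steps[move] * rng.standard_normal()
        self._bump(move, k, delta)
        lp1 = self.logpost()
        if math.log(rng.random()) < lp1 - lp0:
            self.cur_logpost = lp1
            return True
        self._bump(move, k, -delta)
        return False

    def _bump(self, which, k, delta):
        if k == 0:
            if which == "theta":
                self.theta0 += delta
            else:
                self.beta0 += delta
        else:
            b = self.sorted_shifts[k - 1]
            th, be = self.shifts[b]
            self.shifts[b] = (
                (th + delta, be) if which == "theta" else (th, be + delta)
            )

    # -- main loop ----------------------------------------------------
    def run(self, n_iter, thin, burn_in, adapt=True):
        rng = self.rng
        pr = self.priors
        # random start
        self.sig2 = float(
            stats.halfcauchy.rvs(scale=pr.sigma2_scale, random_state=rng)
        )
        self.set_alpha(
            float(stats.halfcauchy.rvs(scale=pr.alpha_scale, random_state=rng))
        )
        self.theta0 = pr.theta_mu + pr.theta_sd * rng.standard_normal()
        self.beta0 = pr.beta_mu + pr.beta_sd * rng.standard_normal()
        self.set_painting({})
        self.cur_logpost = self.logpost()

        n_samp = n_iter // thin
        rec = {
            k: np.empty(n_samp)
            for k in ("alpha", "sigma2", "n_shifts", "theta_root",
                      "beta_root", "logpost")
        }
        states = []
        att = {m: 0 for m in _MOVES}
        acc = {m: 0 for m in _MOVES}
        win_att = {m: 0 for m in _MOVES}
        win_acc = {m: 0 for m in _MOVES}
        burn_iters = int(burn_in * n_iter)
        s = 0
        for it in range(n_iter):
            move = _MOVES[rng.integers(len(_MOVES))]
            ok = self.propose(move)
            att[move] += 1
            acc[move] += ok
            if adapt and it < burn_iters and move in self.steps:
                win_att[move] += 1
                win_acc[move] += ok
                if win_att[move] == 50:
                    rate = win_acc[move] / 50.0
                    self.steps[move] *= math.exp(
                        min(0.5, max(-0.5, rate - 0.3))
                    )
                    win_att[move] = win_acc[move] = 0
            if (it + 1) % thin == 0:
                rec["alpha"][s] = self.alpha
                rec["sigma2"][s] = self.sig2
                rec["n_shifts"][s] = len(self.shifts)
                rec["theta_root"][s] = self.theta0
                rec["beta_root"][s] = self.beta0
                rec["logpost"][s] = self.cur_logpost
                states.append(dict(self.shifts))
                s += 1
        rates = {m: (acc[m] / att[m] if att[m] else 0.0) for m in _MOVES}
        return rec, states, rates


def rjmcmc_run(
    x: pd.Series,
    y: pd.Series,
    tree: Phylogeny,
    priors: PriorSpec | None = None,
    n_iter: int = 200_000,
    thin: int = 100,
    burn_in_fraction: float = 0.2,
    n_chains: int = 4,
    seed: int = 0,
    prior_only: bool = False,
) -> list:
    """Run independent RJ-MCMC chains with different random starting points.

    Defaults are desk-scale (4 chains x 200k iterations, thin 100); the
    published-scale 10M-iteration runs are the same call with a larger
    ``n_iter``. ``prior_only=True`` replaces the likelihood by a constant
    (sampler-calibration runs). All randomness derives from ``seed``.
    """
    if n_chains < 2 and not prior_only:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    if priors is None:
        priors = (
            PriorSpec() if prior_only
            else PriorSpec.from_data(tree, x, y)
        )
    xv = np.asarray(x.loc[tree.tip_labels], float)
    yv = np.asarray(y.loc[tree.tip_labels], float)
    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng([seed, c])
        smp = _OUSampler(tree, xv, yv, priors, rng, prior_only=prior_only)
        rec, states, rates = smp.run(n_iter, thin, burn_in_fraction)
        chains.append(
            PosteriorChain(
                alpha=rec["alpha"], sigma2=rec["sigma2"],
                n_shifts=rec["n_shifts"], theta_root=rec["theta_root"],
                beta_root=rec["beta_root"], logpost=rec["logpost"],
                shift_states=states, n_iter=n_iter, thin=thin,
                burn_in=burn_in_fraction, seed=seed, accept_rate=rates,
            )
        )
    return chains


# ----------------------------------------------------------------------
# Diagnostics
# ----------------------------------------------------------------------

def gelman_rhat(chains: list, parameter: str) -> float:
    """Potential scale reduction factor from >= 2 chains (post burn-in)."""
    if len(chains) < 2:
        raise ValueError("R-hat needs at least two chains")
    draws = np.array([c.trace(parameter) for c in chains])
    m, n = draws.shape
    means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def effective_sample_size(trace) -> float:
    """ESS = N / (1 + 2 sum rho_t), autocorrelations summed until the
    first non-positive adjacent pair (Geyer's initial positive sequence).
    Constant traces report N; anti-correlated traces are capped at N."""
    z = np.asarray(trace, float)
    n = len(z)
    if n < 10:
        raise ValueError("trace too short for ESS")
    v = z.var()
    if v == 0:
        return float(n)  # degenerate trace
    zc = z - z.mean()
    acf = np.correlate(zc, zc, "full")[n - 1:] / (v * n)
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = acf[t] + acf[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    ess = n / (1.0 + 2.0 * s)
    return float(min(ess, n))


def chain_diagnostics(chains: list) -> dict:
    """R-hat and pooled ESS for the scalar parameters."""
    out = {}
    for p in ("alpha", "sigma2", "n_shifts", "theta_root", "beta_root"):
        ess = sum(effective_sample_size(c.trace(p)) for c in chains)
        out[p] = dict(rhat=gelman_rhat(chains, p), ess=ess)
    return out


# ----------------------------------------------------------------------
# Shift summarization
# ----------------------------------------------------------------------

@dataclass
class ShiftSummary:
    """Pooled posterior summary of shift locations and regime parameters."""

    pp: pd.Series  # branch id -> posterior shift probability
    accepted: list  # branch ids passing pp and clade-size filters
    regime_params: dict  # branch -> dict(theta=.., beta=..) posterior means
    root_params: dict
    alpha_mean: float
    sigma2_mean: float
    converged: bool
    diagnostics: dict
    pp_threshold: float
    min_clade: int

    def grade_labels(self, tree: Phylogeny) -> pd.Series:
        """Species -> grade label induced by the accepted shifts (grade of
        a tip = nearest accepted shift above it, else the ancestral
        grade). Input for the PGLS merging cascade."""
        painting = paint_regimes(tree, self.accepted)
        names = ["ancestral"] + [f"shift_{b}" for b in painting.shifts]
        lab = [
            names[painting.branch_regime[u]] for u in tree.tip_ids
        ]
        return pd.Series(lab, index=tree.tip_labels, name="grade")


def summarize_shifts(
    chains: list,
    tree: Phylogeny,
    pp_threshold: float = 0.7,
    min_clade: int = 4,
    rhat_gate: float = 1.1,
) -> ShiftSummary:
    """Pool post-burn-in samples; a branch's pp is the fraction of samples
    in which it carries a shift. Accepted shifts need pp > threshold and a
    clade of at least ``min_clade`` tips (the "more than three species"
    rule). Non-convergence (R-hat above the gate on alpha, sigma2 or the
    shift count) does not block the summary but flags it prominently."""
    diag = chain_diagnostics(chains)
    converged = all(
        diag[p]["rhat"] < rhat_gate for p in ("alpha", "sigma2", "n_shifts")
    )
    pooled = [st for c in chains for st in c.post_shift_states()]
    n_samp = len(pooled)
    counts = np.zeros(tree.n_nodes)
    sums = {}
    for st in pooled:
        for b, (th, be) in st.items():
            counts[b] += 1
            if b not in sums:
                sums[b] = [0.0, 0.0]
            sums[b][0] += th
            sums[b][1] += be
    pp = pd.Series(
        counts[1:] / n_samp, index=pd.Index(tree.branch_ids, name="branch")
    )
    accepted = [
        int(b)
        for b in tree.branch_ids
        if pp[b] > pp_threshold and len(tree.clade_tip_ids(b)) >= min_clade
    ]
    regime_params = {
        b: dict(theta=sums[b][0] / counts[b], beta=sums[b][1] / counts[b])
        for b in accepted
    }
    root_params = dict(
        theta=float(np.mean(np.concatenate(
            [c.trace("theta_root") for c in chains]))),
        beta=float(np.mean(np.concatenate(
            [c.trace("beta_root") for c in chains]))),
    )
    return ShiftSummary(
        pp=pp,
        accepted=accepted,
        regime_params=regime_params,
        root_params=root_params,
        alpha_mean=float(np.mean(np.concatenate(
            [c.trace("alpha") for c in chains]))),
        sigma2_mean=float(np.mean(np.concatenate(
            [c.trace("sigma2") for c in chains]))),
        converged=converged,
        diagnostics=diag,
        pp_threshold=pp_threshold,
        min_clade=min_clade,
    )
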