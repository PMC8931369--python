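"""Ancestral state reconstruction under Brownian motion and comparisons of
evolutionary rates of allometric residuals.

The residual of a species from its allometric line measures how loosely
the trait is integrated with its predictor; the Brownian rate (sigma^2) of
those residuals is the looseness of allometric integration of a clade.
This module reconstructs internal-node states (e.g. relative brain size at
ancestors), fits multi-rate BM models over branch paintings, and tests
rate differences between groups of species or between traits with
simulation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .pgls import fit_pgls
from .phylo import (
    Phylogeny,
    RegimePainting,
    bm_covariance,
    painting_from_tip_groups,
)

__all__ = [
    "AncestralEstimates",
    "RateComparison",
    "ancestral_states_bm",
    "ancestral_relative_brain_size",
    "multirate_bm_fit",
    "compare_group_rates",
    "compare_trait_rates",
]


# ----------------------------------------------------------------------
# Ancestral reconstruction (Gaussian message passing on the tree)
# ----------------------------------------------------------------------

@dataclass
class AncestralEstimates:
    """ML states at internal nodes with estimation variances."""

    nodes: np.ndarray  # internal node ids
    estimate: pd.Series  # node id -> state (log10 trait scale)
    variance: pd.Series  # node id -> estimation variance
    sigma2: float  # ML BM rate used for the variances

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimate, "variance": self.variance}
        )


def _combine(msgs):
    """Precision-weighted combination of (mean, var) messages; var 0 wins
    exactly (zero-length pendant branches collapse to the tip value)."""
    for m, s in msgs:
        if s == 0.0:
            return m, 0.0
    prec = sum(1.0 / s for _, s in msgs)
    mean = sum(m / s for m, s in msgs) / prec
    return mean, 1.0 / prec


def ancestral_states_bm(tree: Phylogeny, trait: pd.Series) -> AncestralEstimates:
    """Joint ML ancestral states under BM by two-pass message passing.

    The upward pass aggregates each subtree into a Gaussian message; the
    downward pass carries the information from the rest of the tree, so
    each internal node combines both — this equals the GLS solution of the
    joint tip+node normal model with the root state profiled out.
    """
    y = trait.loc[tree.tip_labels]
    val = {u: float(y.iloc[i]) for i, u in enumerate(tree.tip_ids)}
    up: dict[int, tuple] = {}
    for u in tree.postorder:
        if not tree.children[u]:
            up[u] = (val[u], 0.0)
        else:
            up[u] = _combine(
                [(up[c][0], up[c][1] + tree.length[c])
                 for c in tree.children[u]]
            )
    down: dict[int, tuple] = {}
    order = tree.postorder[::-1]  # preorder
    for u in order:
        for c in tree.children[u]:
            msgs = [
                (up[s][0], up[s][1] + tree.length[s])
                for s in tree.children[u] if s != c
            ]
            if u != 0:
                msgs.append(down[u])
            m, s = _combine(msgs) if msgs else (0.0, np.inf)
            down[c] = (m, s + tree.length[c])
    internal = np.array([u for u in order if tree.children[u]], dtype=int)
    est, var = {}, {}
    for u in internal:
        if u == 0:
            est[u], var[u] = up[u]
        else:
            est[u], var[u] = _combine([up[u], down[u]])
    # ML BM rate from the tips (for reporting estimation variances)
    V = bm_covariance(tree)
    cf = cho_factor(V, lower=True)
    one = np.ones(tree.n_tips)
    yv = y.to_numpy(float)
    w = cho_solve(cf, one)
    mu = float(w @ yv) / float(w @ one)
    r = yv - mu
    s2 = float(r @ cho_solve(cf, r)) / tree.n_tips
    return AncestralEstimates(
        nodes=internal,
        estimate=pd.Series({u: est[u] for u in internal}, name="estimate"),
        variance=pd.Series(
            {u: var[u] * s2 for u in internal}, name="variance"
        ),
        sigma2=s2,
    )


def ancestral_relative_brain_size(
    tree: Phylogeny, brain: pd.Series, body: pd.Series
) -> pd.DataFrame:
    """Relative brain size at ancestors: reconstruct log brain and log body
    independently under BM, then take the node's departure from the
    tip-level PGLS allometric line evaluated at the reconstructed body."""
    asr_brain = ancestral_states_bm(tree, brain)
    asr_body = ancestral_states_bm(tree, body)
    fit = fit_pgls(
        brain, pd.DataFrame({"Intercept": 1.0, "Slope": body}), tree, "REML"
    )
    a, b = fit.line()
    resid = asr_brain.estimate - (a + b * asr_body.estimate)
    return pd.DataFrame(
        {
            "brain": asr_brain.estimate,
            "body": asr_body.estimate,
            "relative_brain_size": resid,
            "node_height": tree.depth[asr_brain.nodes],
        }
    )


# ----------------------------------------------------------------------
# Multi-rate Brownian motion
# ----------------------------------------------------------------------

def _group_path_matrices(tree: Phylogeny, reg: np.ndarray, K: int):
    """V_g[i,j] = total length of regime-g branches on the shared
    root-to-MRCA path of tips i and j, so that V(r) = sum_g r_g V_g."""
    n = tree.n_tips
    pos = {u: i for i, u in enumerate(tree.tip_ids)}
    Vg = np.zeros((K, n, n))
    for b in tree.branch_ids:
        ind = np.zeros(n)
        ind[[pos[u] for u in tree.clade_tip_ids(b)]] = 1.0
        Vg[reg[b]] += tree.length[b] * np.outer(ind, ind)
    return Vg


def multirate_bm_fit(
    tree: Phylogeny,
    trait: pd.Series,
    grouping,
    ancestral=None,
) -> dict:
    """ML Brownian rates with branch lengths scaled per group.

    ``grouping`` is a RegimePainting, or a tip-label -> group mapping that
    is converted to a painting (branches whose descendant tips disagree
    get the ancestral group). With one group this reduces to the standard
    ML BM rate. Returns regime/group -> sigma2 plus fit metadata.
    """
    if isinstance(grouping, RegimePainting):
        painting, names = grouping, list(range(grouping.n_regimes))
    else:
        g = grouping if isinstance(grouping, dict) else dict(grouping)
        painting, names = painting_from_tip_groups(tree, g, ancestral)
    reg = painting.branch_regime
    K = painting.n_regimes
    for k in range(K):
        if (reg[1:] == k).sum() < 3 and K > 1:
            import warnings

            warnings.warn(
                f"group {names[k]!r} spans fewer than 3 branches",
                stacklevel=2,
            )
    y = trait.loc[tree.tip_labels].to_numpy(float)
    n = tree.n_tips
    Vg = _group_path_matrices(tree, reg, K)
    one = np.ones(n)

    def nll(logr):
        V = np.tensordot(np.exp(logr), Vg, axes=1)
        try:
            cf = cho_factor(V + 1e-10 * np.trace(V) / n * np.eye(n),
                            lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        w = cho_solve(cf, one)
        mu = float(w @ y) / float(w @ one)
        r = y - mu
        quad = float(r @ cho_solve(cf, r))
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)

    # start from the single-rate ML estimate
    V1 = Vg.sum(axis=0)
    cf = cho_factor(V1, lower=True)
    w = cho_solve(cf, one)
    mu = float(w @ y) / float(w @ one)
    r = y - mu
    s2_0 = float(r @ cho_solve(cf, r)) / n
    if K == 1:
        return dict(
            rates={names[0]: s2_0},
            loglik=-nll(np.log([s2_0])),
            painting=painting,
            group_names=names,
        )
    res = optimize.minimize(
        nll,
        np.full(K, np.log(s2_0)),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    rates = {names[k]: float(np.exp(res.x[k])) for k in range(K)}
    return dict(
        rates=rates, loglik=-res.fun, painting=painting, group_names=names,
        converged=bool(res.success),
    )


# ----------------------------------------------------------------------
# Rate comparisons with simulation p-values
# ----------------------------------------------------------------------

@dataclass
class RateComparison:
    """Observed per-group (or per-trait) rates, their ratio and a
    simulation p-value under the single-rate null."""

    rates: dict
    ratio: float
    p_value: float
    n_sim: int
    kind: str  # "groups" | "traits"
    statistic: float | None = None  # LR statistic for the traits test


def _group_rate_setup(tree, groups):
    """Pre-factorized per-group machinery for the fast rate estimator."""
    V = bm_covariance(tree)
    idx = {g: np.flatnonzero(groups.to_numpy() == g)
           for g in pd.unique(groups)}
    setups = {}
    for g, ii in idx.items():
        if len(ii) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 species")
        cf = cho_factor(V[np.ix_(ii, ii)], lower=True)
        w = cho_solve(cf, np.ones(len(ii)))
        setups[g] = (ii, cf, w, float(w.sum()))
    return V, setups


def _group_rates(Y: np.ndarray, setups) -> dict:
    """Phylogenetically weighted mean-square rate per group; Y is
    (n_tips, n_datasets)."""
    out = {}
    for g, (ii, cf, w, w1) in setups.items():
        Yg = Y[ii]
        S = cho_solve(cf, Yg)
        q = np.einsum("ij,ij->j", Yg, S)
        mu = (w @ Yg) / w1
        out[g] = (q - mu**2 * w1) / len(ii)
    return out


def compare_group_rates(
    tree: Phylogeny,
    residuals: pd.Series,
    groups: pd.Series,
    n_sim: int = 10_000,
    seed: int = 0,
) -> RateComparison:
    """Do groups of species evolve their allometric residuals at different
    Brownian rates?

    The observed statistic is the max/min ratio of per-group rates (GLS
    mean-square of the residual trait against the group's tip-covariance
    submatrix). The null distribution comes from single-rate BM
    simulations on the same tree at the pooled rate; p is the fraction of
    null ratios at least as large (with the +1 continuity correction that
    keeps p in (0, 1]).
    """
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives unstable p-values")
    rng = np.random.default_rng(seed)
    y = residuals.loc[tree.tip_labels]
    groups = groups.loc[tree.tip_labels]
    V, setups = _group_rate_setup(tree, groups)
    yv = y.to_numpy(float)[:, None]
    obs = {g: float(v[0]) for g, v in _group_rates(yv, setups).items()}
    ratio = max(obs.values()) / min(obs.values())
    # pooled single-rate null (empirical GLS root + pooled sigma2)
    cf = cho_factor(V, lower=True)
    one = np.ones(tree.n_tips)
    w = cho_solve(cf, one)
    mu = float(w @ yv[:, 0]) / float(w @ one)
    r = yv[:, 0] - mu
    s2 = float(r @ cho_solve(cf, r)) / tree.n_tips
    L = np.linalg.cholesky(V + 1e-12 * np.eye(tree.n_tips))
    Y = mu + np.sqrt(s2) * (L @ rng.standard_normal((tree.n_tips, n_sim)))
    null = _group_rates(Y, setups)
    mat = np.vstack([null[g] for g in null])
    null_ratio = mat.max(axis=0) / mat.min(axis=0)
    p = (1 + int(np.sum(null_ratio >= ratio))) / (1 + n_sim)
    return RateComparison(
        rates=obs, ratio=float(ratio), p_value=float(p), n_sim=n_sim,
        kind="groups",
    )


def compare_trait_rates(
    tree: Phylogeny,
    traits: pd.DataFrame,
    n_sim: int = 10_000,
    seed: int = 0,
) -> RateComparison:
    """Do different (residual) traits evolve at different rates on the
    same tree?

    Likelihood ratio of the distinct-rates model (one sigma2 per trait)
    against a common rate, with traits treated as evolutionarily
    independent given their rates; under BM the LR has the closed form
    n * sum_t log(sigma2_common / sigma2_t). Significance by simulating
    the traits under the common-rate null.
    """
    if traits.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives unstable p-values")
    rng = np.random.default_rng(seed)
    Y = traits.loc[tree.tip_labels].to_numpy(float)
    n, p = Y.shape
    V = bm_covariance(tree)
    cf = cho_factor(V, lower=True)
    one = np.ones(n)
    w = cho_solve(cf, one)
    w1 = float(w @ one)

    def per_trait_rates(M):
        S = cho_solve(cf, M)
        q = np.einsum("ij,ij->j", M, S)
        mu = (w @ M) / w1
        return (q - mu**2 * w1) / n

    s2 = per_trait_rates(Y)
    s2c = s2.mean()
    lr_obs = float(n * np.sum(np.log(s2c / s2)))
    rates = {c: float(v) for c, v in zip(traits.columns, s2)}
    ratio = float(max(s2) / min(s2))
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    Z = rng.standard_normal((n, p * n_sim))
    sims = np.sqrt(s2c) * (L @ Z)
    s2_null = per_trait_rates(sims).reshape(n_sim, p)
    s2c_null = s2_null.mean(axis=1)
    lr_null = n * np.sum(np.log(s2c_null[:, None] / s2_null), axis=1)
    pval = (1 + int(np.sum(lr_null >= lr_obs))) / (1 + n_sim)
    return RateComparison(
        rates=rates, ratio=ratio, p_value=float(pval), n_sim=n_sim,
        kind="traits", statistic=lr_obs,
    )
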