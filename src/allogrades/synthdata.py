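"""Synthetic phylogenies and trait datasets with planted scaling regimes.

The generator emulates the statistical structure of comparative
neuron-count datasets: a time-calibrated tree a few hundred My deep, log10
body masses spanning several orders of magnitude, and log10 neuron counts
that follow clade-specific allometric lines (regimes) with phylogenetically
structured residuals. Every dataset carries its ground truth (painting,
regime lines, lambda / OU parameters, residual SD) so recovery tests can
recompute expected values exactly.

Defaults mirror the amniote setting: tree depth 300 My and a log10
body-mass span of about 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import (
    Phylogeny,
    RegimePainting,
    bm_covariance,
    lambda_transform,
    ou_covariance,
    ou_weight_matrix,
    paint_regimes,
)

__all__ = [
    "SyntheticDataset",
    "simulate_tree",
    "simulate_bm",
    "simulate_grade_dataset",
    "amniote_like_preset",
]

#: default tree depth, My (age of the amniote radiation)
TREE_DEPTH = 300.0
#: default log10 body-mass span emulated by the body-mass BM process
BODY_LOG10_SPAN = 5.0


@dataclass
class SyntheticDataset:
    """A simulated comparative dataset plus the truth that generated it."""

    tree: Phylogeny
    traits: pd.DataFrame  # index: species; log10-scale columns
    painting: RegimePainting
    theta: np.ndarray  # per-regime intercepts (log10)
    beta: np.ndarray  # per-regime slopes
    lam: float | None  # lambda of the residual structure (lambda mode)
    alpha: float | None  # OU attraction (ou mode)
    sigma2: float | None  # OU diffusion (ou mode)
    residual_sd: float
    residual_mode: str  # "lambda" | "ou"
    seed: int

    @property
    def regime_of_tip(self) -> np.ndarray:
        """Regime painting each tip's terminal branch."""
        return self.painting.branch_regime[self.tree.tip_ids]


def simulate_tree(n_tips: int, seed: int, depth: float = TREE_DEPTH) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree rescaled to the given depth.

    Lineages split at unit rate; at each event a uniformly chosen extant
    lineage bifurcates. The resulting tree is rescaled so every tip sits at
    ``depth``. Deterministic in ``seed``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    children = [[1, 2], [], []]
    birth = [0.0, 0.0, 0.0]  # time of each node's origin
    extant = [1, 2]
    t = 0.0
    while len(extant) < n_tips:
        t += rng.exponential(1.0 / len(extant))
        i = rng.integers(len(extant))
        u = extant[i]
        a, b = len(parent), len(parent) + 1
        parent += [u, u]
        children[u] = [a, b]
        children += [[], []]
        birth += [t, t]
        extant[i] = a
        extant.append(b)
    t_end = t + rng.exponential(1.0 / len(extant))
    scale = depth / t_end if t_end > 0 else 1.0
    length = np.zeros(len(parent))
    label = [None] * len(parent)
    ntip = 0
    for u in range(1, len(parent)):
        end = t_end if not children[u] else birth[children[u][0]]
        length[u] = (end - birth[u]) * scale
        if not children[u]:
            ntip += 1
            label[u] = f"t{ntip}"
    return Phylogeny(np.array(parent), length, children, label)


def simulate_bm(
    tree: Phylogeny, sigma2: float, root_state: float, seed: int
) -> np.ndarray:
    """Tip values of a Brownian motion: N(root_state, sigma2 * V_BM)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(tree.n_tips)
    if sigma2 == 0:
        return np.full(tree.n_tips, root_state)
    L = np.linalg.cholesky(
        sigma2 * bm_covariance(tree) + 1e-12 * np.eye(tree.n_tips)
    )
    return root_state + L @ z


def simulate_grade_dataset(
    tree: Phylogeny,
    painting: RegimePainting,
    theta,
    beta,
    residual_sd: float,
    seed: int,
    residual_mode: str = "lambda",
    lam: float = 0.9,
    alpha: float | None = None,
    sigma2: float | None = None,
    body_root: float = 2.0,
    body_span: float = BODY_LOG10_SPAN,
) -> SyntheticDataset:
    """Simulate log10 body mass by BM and log10 neuron counts on regime lines.

    Body mass evolves by BM with the diffusion set so the expected tip SD is
    ``body_span / 4`` (a +-2 SD span of about ``body_span`` decades). Neuron
    counts are ``theta_k + beta_k * x`` plus residuals that are either

    * ``"lambda"``: N(0, residual_sd^2 * C) with C the depth-normalized
      lambda-transformed BM correlation (the PGLS generative model; the
      regime of a tip is that of its terminal branch), or
    * ``"ou"``: mean through the OU weight matrix W(alpha) and covariance
      V_OU(alpha, sigma2) (the multiregime-OU generative model).
    """
    theta = np.asarray(theta, float)
    beta = np.asarray(beta, float)
    if len(theta) != painting.n_regimes or len(beta) != painting.n_regimes:
        raise ValueError("theta/beta length must equal the regime count")
    rng = np.random.default_rng(seed)
    T = tree.tree_height
    body_sig2 = (body_span / 4.0) ** 2 / T
    x = simulate_bm(tree, body_sig2, body_root, rng.integers(2**31))
    n = tree.n_tips
    if residual_mode == "lambda":
        reg = painting.branch_regime[tree.tip_ids]
        mean = theta[reg] + beta[reg] * x
        C = lambda_transform(bm_covariance(tree) / T, lam)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
        y = mean + residual_sd * (L @ rng.standard_normal(n))
        alpha_out = sigma2_out = None
        lam_out = lam
    elif residual_mode == "ou":
        if alpha is None or sigma2 is None:
            raise ValueError("ou mode needs alpha and sigma2")
        W = ou_weight_matrix(tree, painting, alpha)
        mean = W @ theta + (W @ beta) * x
        V = ou_covariance(tree, alpha, sigma2)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        y = mean + L @ rng.standard_normal(n)
        alpha_out, sigma2_out = alpha, sigma2
        lam_out = None
    else:
        raise ValueError(f"unknown residual_mode {residual_mode!r}")
    traits = pd.DataFrame(
        {"log_body_mass": x, "log_neurons": y},
        index=pd.Index(tree.tip_labels, name="species"),
    )
    return SyntheticDataset(
        tree=tree,
        traits=traits,
        painting=painting,
        theta=theta,
        beta=beta,
        lam=lam_out,
        alpha=alpha_out,
        sigma2=sigma2_out,
        residual_sd=residual_sd,
        residual_mode=residual_mode,
        seed=seed,
    )


def _largest_disjoint_clades(
    tree: Phylogeny, k: int, lo: int, hi: int,
    exclude_root_children: bool = False,
):
    """k disjoint branches whose clades have between lo and hi tips,
    chosen greedily by clade size (deterministic). Branches hanging off
    the root can be excluded: a shift there is confounded with a
    compensating shift on its sibling plus a different root line."""
    sizes = {b: len(tree.clade_tip_ids(b)) for b in tree.branch_ids}
    chosen: list[int] = []
    taken: set[int] = set()
    for b in sorted(sizes, key=lambda b: (-sizes[b], b)):
        if not lo <= sizes[b] <= hi:
            continue
        if exclude_root_children and tree.parent[b] == 0:
            continue
        tips = set(tree.clade_tip_ids(b))
        if tips & taken:
            continue
        chosen.append(b)
        taken |= tips
        if len(chosen) == k:
            return chosen
    raise ValueError("tree too small to place the requested clades")


def planted_shift_scenario(
    n_tips: int = 128,
    seed: int = 0,
    delta_theta: float = 0.6,
    delta_beta: float = 0.15,
    alpha_times_depth: float = 2.0,
    stationary_sd: float = 0.15,
    base_theta: float = 7.0,
    base_beta: float = 0.5,
) -> SyntheticDataset:
    """Two planted OU regime shifts for sampler-recovery experiments.

    Shifts are placed on the two largest disjoint clades of 8 to n/4 tips
    whose parent is not the root (root-adjacent shifts are symmetric with
    a shifted sibling plus a different root line and therefore not
    identifiable). Both shifted regimes share theta + delta_theta and
    beta + delta_beta; alpha is set via alpha * tree depth and sigma2 via
    the stationary SD, so the intercept shift is delta_theta /
    stationary_sd stationary standard deviations.
    """
    tree = simulate_tree(n_tips, seed)
    lo = max(4, n_tips // 16)
    hi = max(lo + 2, n_tips // 4)

    # Planted branches must make the shift location identifiable:
    # a root-adjacent shift is symmetric with one on its sibling, a shift
    # whose sibling or children are tiny is nearly equivalent to one on
    # the neighbouring branch, and sister clades sharing one line are
    # dominated by a single shift on their covering parent.
    def size(b):
        return len(tree.clade_tip_ids(b))

    margin = 3 if n_tips >= 64 else 2

    def locally_distinct(b):
        if tree.parent[b] == 0 or not (lo <= size(b) <= hi):
            return False
        if size(tree.parent[b]) - size(b) < margin:
            return False
        return all(size(c) >= margin for c in tree.children[b])

    def ancestors(b):
        out = set()
        while b != 0:
            out.add(b)
            b = tree.parent[b]
        return out

    cands = sorted(
        (b for b in tree.branch_ids if locally_distinct(b)),
        key=lambda b: (-size(b), b),
    )
    pair = None
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            a, b = cands[i], cands[j]
            ta = set(tree.clade_tip_ids(a))
            tb = set(tree.clade_tip_ids(b))
            if ta & tb:
                continue
            common = ancestors(a) & ancestors(b)
            extra = (
                min(size(m) for m in common) - len(ta) - len(tb)
                if common else n_tips - len(ta) - len(tb)
            )
            if extra >= max(4, n_tips // 16):
                pair = (a, b)
                break
        if pair:
            break
    if pair is None:
        raise ValueError("tree too small to place the planted clades")
    b1, b2 = sorted(pair)
    painting = paint_regimes(tree, [b1, b2])
    alpha = alpha_times_depth / tree.tree_height
    sigma2 = 2.0 * alpha * stationary_sd**2
    th = base_theta + delta_theta
    be = base_beta + delta_beta
    return simulate_grade_dataset(
        tree, painting,
        [base_theta, th, th], [base_beta, be, be],
        residual_sd=stationary_sd, seed=seed + 1,
        residual_mode="ou", alpha=alpha, sigma2=sigma2,
    )


def amniote_like_preset(n_tips: int = 128, seed: int = 7) -> SyntheticDataset:
    """The default recovery scenario: 3 base grades plus 2 nested convergent
    sub-grades, mimicking the amniote structure (an ancestral low-scaling
    grade, two independently shifted clades, and within each of those a
    nested sub-clade converging on a shared still-higher regime).

    Regime lines (log10 neurons vs log10 body mass):
      0 ancestral      theta 6.8, slope 0.45   (reptile-like)
      1, 2 shifted     theta 8.1, slope 0.55   (bird/mammal-like, convergent)
      3, 4 nested      theta 8.6, slope 0.60   (landbird/primate-like, convergent)
    """
    tree = simulate_tree(n_tips, seed)
    base = _largest_disjoint_clades(
        tree, 2, max(8, n_tips // 8), int(0.4 * n_tips)
    )
    nested = []
    for b in base:
        sub = sorted(
            (c for c in tree.branch_ids
             if set(tree.clade_tip_ids(c)) < set(tree.clade_tip_ids(b))
             and 4 <= len(tree.clade_tip_ids(c))
             <= max(4, len(tree.clade_tip_ids(b)) // 2)),
            key=lambda c: (-len(tree.clade_tip_ids(c)), c),
        )
        if not sub:
            raise ValueError("no nested clade available; try another seed")
        nested.append(sub[0])
    shifts = sorted(base + nested)
    painting = paint_regimes(tree, shifts)
    line_of = {}
    for k, b in enumerate(painting.shifts):
        line_of[k + 1] = (8.1, 0.55) if b in base else (8.6, 0.60)
    theta = [6.8] + [line_of[k][0] for k in range(1, painting.n_regimes)]
    beta = [0.45] + [line_of[k][1] for k in range(1, painting.n_regimes)]
    return simulate_grade_dataset(
        tree, painting, theta, beta,
        residual_sd=0.15, seed=seed + 1, residual_mode="lambda", lam=0.7,
    )
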