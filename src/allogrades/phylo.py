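"""Rooted time-calibrated phylogenies and the covariance machinery built on them.

The tree is the substrate for every model in this package: Brownian-motion
(BM) covariances, Pagel's-lambda transforms, Ornstein-Uhlenbeck (OU)
covariances, and the OU regime-weight matrix that turns a painting of
branches into per-tip regression expectations.

Conventions
-----------
* Nodes are integers assigned in preorder; the root is node 0.
* A *branch* is identified by its child node id (so branch ``b`` runs from
  ``parent[b]`` to ``b``); a binary tree with n tips has 2n-2 branches.
* Branch lengths are in time units (My for the amniote analyses).
* Shifts sit at the rootward origin of a branch: the whole branch and all
  descendant branches belong to the new regime until a nested shift
  overrides it.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "RegimePainting",
    "PhyloError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "bm_covariance",
    "lambda_transform",
    "ou_covariance",
    "ou_weight_matrix",
    "clade_tips",
    "paint_regimes",
    "painting_from_tip_groups",
    "match_tree_to_table",
]

#: relative tolerance on tip-height spread below which a tree counts as
#: ultrametric (time-calibrated); OU closed forms require this.
ULTRAMETRIC_RTOL = 1e-6


class PhyloError(ValueError):
    """Tree-structure or painting contract violation."""


class NewickParseError(PhyloError):
    """Malformed Newick input; the message names the offending token."""


@dataclass
class Phylogeny:
    """A rooted tree stored as flat arrays indexed by preorder node id.

    Attributes
    ----------
    parent : (N,) int array, ``parent[0] == -1`` for the root.
    length : (N,) float array of branch lengths; ``length[0] == 0``.
    children : list of child-id lists (binary after polytomy resolution).
    label : list of node labels (tips always labelled, internals optional).
    """

    parent: np.ndarray
    length: np.ndarray
    children: list
    label: list

    # derived, filled in __post_init__
    depth: np.ndarray = field(init=False)
    tip_ids: np.ndarray = field(init=False)
    tip_labels: list = field(init=False)
    postorder: np.ndarray = field(init=False)
    is_ultrametric: bool = field(init=False)

    def __post_init__(self):
        n = len(self.parent)
        self.depth = np.zeros(n)
        order = []
        stack = [0]
        while stack:  # preorder
            u = stack.pop()
            order.append(u)
            if u != 0:
                self.depth[u] = self.depth[self.parent[u]] + self.length[u]
            stack.extend(reversed(self.children[u]))
        self.postorder = np.array(order[::-1], dtype=int)
        self.tip_ids = np.array(
            [u for u in order if not self.children[u]], dtype=int
        )
        self.tip_labels = [self.label[u] for u in self.tip_ids]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dup = sorted(
                {x for x in self.tip_labels if self.tip_labels.count(x) > 1}
            )
            raise PhyloError(f"duplicate tip labels: {dup}")
        heights = self.depth[self.tip_ids]
        tol = ULTRAMETRIC_RTOL * max(heights.max(), 1.0)
        self.is_ultrametric = bool(heights.max() - heights.min() <= tol)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def branch_ids(self) -> np.ndarray:
        """All branch ids (= non-root node ids)."""
        return np.arange(1, self.n_nodes)

    @property
    def tree_height(self) -> float:
        return float(self.depth[self.tip_ids].max())

    def tip_index(self, labels=None) -> dict:
        """Map tip label -> position in the covariance-matrix ordering."""
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def path_to_root(self, node: int) -> list:
        out = []
        while node != 0:
            out.append(node)
            node = self.parent[node]
        return out

    def clade_tip_ids(self, branch: int) -> np.ndarray:
        if not (1 <= branch < self.n_nodes):
            raise PhyloError(f"unknown branch id {branch}")
        keep = np.zeros(self.n_nodes, dtype=bool)
        stack = [branch]
        while stack:
            u = stack.pop()
            keep[u] = True
            stack.extend(self.children[u])
        return self.tip_ids[keep[self.tip_ids]]

    def prune(self, keep_labels) -> "Phylogeny":
        """Subtree restricted to ``keep_labels``; unifurcations suppressed,
        their branch lengths summed. Root depth is reset to the MRCA of the
        kept tips."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise PhyloError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise PhyloError("pruning needs at least two tips")
        # mark retained nodes (tips kept + their ancestors)
        alive = np.zeros(self.n_nodes, dtype=bool)
        for u in self.tip_ids:
            if self.label[u] in keep:
                v = u
                while v != -1 and not alive[v]:
                    alive[v] = True
                    v = self.parent[v]
        # find new root: deepest alive node with >=2 alive children
        def alive_children(u):
            return [c for c in self.children[u] if alive[c]]

        new_root = 0
        while len(alive_children(new_root)) == 1:
            new_root = alive_children(new_root)[0]

        parent, length, children, label = [], [], [], []

        def build(u, plen, pid):
            ac = alive_children(u)
            while len(ac) == 1:  # suppress unifurcation
                plen += self.length[ac[0]]
                u = ac[0]
                ac = alive_children(u)
            nid = len(parent)
            parent.append(pid)
            length.append(plen)
            children.append([])
            label.append(self.label[u])
            if pid >= 0:
                children[pid].append(nid)
            for c in ac:
                build(c, self.length[c], nid)
            return nid

        build(new_root, 0.0, -1)
        return Phylogeny(
            np.array(parent), np.array(length), children, label
        )


# ----------------------------------------------------------------------
# Newick I/O (dendropy does the parsing; structure is re-indexed here)
# ----------------------------------------------------------------------

def _resolve_polytomies(parent, length, children, label):
    """Deterministically replace k>2 multifurcations with left-ladders of
    zero-length branches, preserving input child order."""
    i = 0
    while i < len(children):
        ch = children[i]
        while len(ch) > 2:
            nid = len(parent)
            a, b = ch[0], ch[1]
            parent.append(i)
            length.append(0.0)
            children.append([a, b])
            label.append(None)
            parent[a] = parent[b] = nid
            ch[:2] = [nid]
        i += 1


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny.

    Polytomies are resolved to zero-length bifurcations in input order so
    that branch counts (2n-2) and the shift-proposal space are well
    defined. A single-tip tree is accepted with a warning.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None

    parent, length, children, label = [], [], [], []
    ids = {}
    for nd in dt.preorder_node_iter():
        nid = len(parent)
        ids[nd] = nid
        if nd.parent_node is None:
            parent.append(-1)
            length.append(0.0)
        else:
            if nd.edge.length is None:
                tok = nd.taxon.label if nd.taxon else "(internal)"
                raise NewickParseError(f"missing branch length at {tok!r}")
            parent.append(ids[nd.parent_node])
            length.append(float(nd.edge.length))
            children[ids[nd.parent_node]].append(nid)
        children.append([])
        if nd.taxon is not None:
            label.append(nd.taxon.label.strip().replace(" ", "_"))
        elif nd.label is not None:
            label.append(str(nd.label).strip().replace(" ", "_"))
        else:
            label.append(None)
    ntips = sum(1 for c in children if not c)
    if ntips == 1:
        warnings.warn("single-tip degenerate tree", stacklevel=2)
    if any(l < 0 for l in length):
        raise NewickParseError("negative branch length")
    _resolve_polytomies(parent, length, children, label)
    return Phylogeny(np.array(parent), np.array(length, float), children, label)


def write_newick(tree: Phylogeny) -> str:
    """Serialize back to Newick (child order preserved, 10 sig. digits)."""
    buf = io.StringIO()

    def rec(u):
        if tree.children[u]:
            buf.write("(")
            for i, c in enumerate(tree.children[u]):
                if i:
                    buf.write(",")
                rec(c)
            buf.write(")")
        if tree.label[u]:
            buf.write(tree.label[u])
        if u != 0:
            buf.write(f":{tree.length[u]:.10g}")

    rec(0)
    buf.write(";")
    return buf.getvalue()


# ----------------------------------------------------------------------
# Covariance builders
# ----------------------------------------------------------------------

def bm_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian covariance: V[i,j] = height of the MRCA of tips i and j
    (shared root-to-tip path length); diagonal = tip heights."""
    n = tree.n_tips
    pos = {u: i for i, u in enumerate(tree.tip_ids)}
    V = np.zeros((n, n))
    # accumulate tip sets bottom-up; cross pairs at node u share depth[u]
    below: dict[int, list] = {}
    for u in tree.postorder:
        if not tree.children[u]:
            below[u] = [pos[u]]
            V[pos[u], pos[u]] = tree.depth[u]
        else:
            kids = [below.pop(c) for c in tree.children[u]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.array(kids[a])[:, None]
                    ib = np.array(kids[b])[None, :]
                    V[ia, ib] = tree.depth[u]
                    V[ib.T, ia.T] = tree.depth[u]
            below[u] = [i for k in kids for i in k]
    return V


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: multiply off-diagonal covariances by lam in [0,1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0,1], got {lam}")
    W = lam * V
    np.fill_diagonal(W, np.diag(V))
    return W


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float) -> np.ndarray:
    """Fixed-root OU covariance on an ultrametric tree of depth T:

        V[i,j] = sigma2/(2 alpha) * exp(-2 alpha (T - t_a)) * (1 - exp(-2 alpha t_a))

    with t_a the MRCA height of tips i,j (t_a = T on the diagonal). The
    root state is a fixed quantity (no stationarity assumed); a
    stationary-root variant adds the stationary variance decay and is
    selected by the model layer, not here.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0; use bm_covariance for the limit")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if not tree.is_ultrametric:
        raise PhyloError("OU closed form requires an ultrametric (time) tree")
    T = tree.tree_height
    ta = bm_covariance(tree)
    np.fill_diagonal(ta, T)
    return (
        sigma2
        / (2.0 * alpha)
        * np.exp(-2.0 * alpha * (T - ta))
        * -np.expm1(-2.0 * alpha * ta)
    )


# ----------------------------------------------------------------------
# Regime paintings and OU weights
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RegimePainting:
    """Assignment of every branch to a scaling regime.

    ``shifts`` is the sorted tuple of branch ids carrying a shift; regime 0
    is the ancestral (root) regime, and shift ``shifts[k-1]`` opens regime
    ``k``, inherited by all descendant branches until a nested shift.
    """

    shifts: tuple
    branch_regime: np.ndarray  # (N,) int; entry 0 (root) fixed at 0
    n_regimes: int

    def regime_of_branch(self, branch: int) -> int:
        return int(self.branch_regime[branch])


def paint_regimes(tree: Phylogeny, shift_branches) -> RegimePainting:
    """Build the branch->regime map induced by a set of shift branches."""
    shifts = tuple(sorted(set(int(b) for b in shift_branches)))
    for b in shifts:
        if not (1 <= b < tree.n_nodes):
            raise PhyloError(f"shift on unknown branch {b}")
    regime_of_shift = {b: k + 1 for k, b in enumerate(shifts)}
    reg = np.zeros(tree.n_nodes, dtype=int)
    stack = [(c, 0) for c in tree.children[0]]
    while stack:
        u, r = stack.pop()
        r = regime_of_shift.get(u, r)
        reg[u] = r
        stack.extend((c, r) for c in tree.children[u])
    return RegimePainting(shifts, reg, len(shifts) + 1)


def painting_from_tip_groups(
    tree: Phylogeny, groups: dict, ancestral: str | None = None
):
    """Convert a tip-label -> group map into a RegimePainting.

    A branch is painted with a group iff every tip below it has that
    group; mixed branches get the ancestral group (default: group of the
    first tip in tree order). Returns (painting, regime->group name list).
    """
    tipgrp = np.array([groups[l] for l in tree.tip_labels], dtype=object)
    if ancestral is None:
        ancestral = tipgrp[0]
    pos = {u: i for i, u in enumerate(tree.tip_ids)}
    node_grp = [None] * tree.n_nodes
    for u in tree.postorder:
        if not tree.children[u]:
            node_grp[u] = tipgrp[pos[u]]
        else:
            gs = {node_grp[c] for c in tree.children[u]}
            node_grp[u] = gs.pop() if len(gs) == 1 else None
    shifts = []
    for b in tree.branch_ids:
        eff = node_grp[b] if node_grp[b] is not None else ancestral
        parent_g = node_grp[tree.parent[b]]
        eff_parent = parent_g if parent_g is not None else ancestral
        if eff != eff_parent:
            shifts.append(b)
    painting = paint_regimes(tree, shifts)
    names = [ancestral] + [
        node_grp[b] if node_grp[b] is not None else ancestral
        for b in painting.shifts
    ]
    return painting, names


def ou_weight_matrix(
    tree: Phylogeny, painting: RegimePainting, alpha: float
) -> np.ndarray:
    """OU regime weights W (n_tips x K): the exponentially discounted time
    each regime spent attracting tip i along its root-to-tip path,

        W[i,k] = sum over regime-k segments of exp(-a(T_i - t_end)) - exp(-a(T_i - t_start)),

    with the residual root weight exp(-a T_i) assigned to the root regime
    (fixed-root convention). Rows sum to 1 exactly (telescoping).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    n, K = tree.n_tips, painting.n_regimes
    W = np.zeros((n, K))
    for i, u in enumerate(tree.tip_ids):
        Ti = tree.depth[u]
        for b in tree.path_to_root(u):
            t0, t1 = tree.depth[tree.parent[b]], tree.depth[b]
            k = painting.branch_regime[b]
            W[i, k] += np.exp(-alpha * (Ti - t1)) - np.exp(-alpha * (Ti - t0))
        W[i, 0] += np.exp(-alpha * Ti)
    return W


def clade_tips(tree: Phylogeny, branch: int) -> set:
    """Tip labels descending from a branch (child-node id)."""
    return {tree.label[u] for u in tree.clade_tip_ids(branch)}


# ----------------------------------------------------------------------
# Name matching
# ----------------------------------------------------------------------

def _norm(name: str) -> str:
    return name.strip().replace(" ", "_")


def match_tree_to_table(tree: Phylogeny, species) -> tuple:
    """Exact match after trim/underscore normalization; returns
    (pruned_tree, matched_labels, dropped_from_table, dropped_from_tree).
    Unmatched species are dropped with a warning."""
    tab = {_norm(s): s for s in species}
    tre = set(tree.tip_labels)
    matched = [l for l in tree.tip_labels if l in tab]
    drop_tab = sorted(set(tab) - tre)
    drop_tre = sorted(tre - set(tab))
    if drop_tab or drop_tre:
        warnings.warn(
            f"dropped {len(drop_tab)} table species and {len(drop_tre)} "
            "tree tips without a match",
            stacklevel=2,
        )
    if len(matched) == len(tree.tip_labels):
        return tree, matched, drop_tab, drop_tre
    return tree.prune(matched), matched, drop_tab, drop_tre
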