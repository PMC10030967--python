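"""Species-tree inference from binary presence/absence profiles.

Maximum likelihood under a two-state Mk-type model with optimized
stationary frequencies ("FO") and free-rate heterogeneity ("R"):

* stationary frequencies ``(π0, π1)``, ``π0 + π1 = 1``, free;
* rate matrix off-diagonals ``(π1, π0)`` rescaled to unit mean rate,
  giving transition probabilities
  ``P_same(t) = π_same + π_other·exp(−μ r t)`` with ``μ = 1/(2 π0 π1)``;
* ``k`` free-rate categories ``(r_j, w_j)`` with ``Σ w_j = 1`` and
  ``Σ w_j r_j = 1`` (default ``k = 2``).

Likelihoods are computed by Felsenstein pruning over site patterns.
The search alternates per-branch Brent branch-length optimization,
joint Nelder-Mead optimization of ``π0`` and the rate distribution,
and full nearest-neighbor-interchange (NNI) sweeps until no move
improves the log-likelihood by more than 1e-6.  The starting tree is
neighbor joining on Hamming distances between species profiles
(negative branch lengths clamped to zero).  Branch support comes from
a standard nonparametric bootstrap (characters resampled with
replacement, search rerun with a reduced NNI budget) rather than an
ultrafast approximation.

No ascertainment-bias correction is applied: cluster-derived matrices
cannot contain all-zero characters by construction, but the model is
otherwise uncorrected, which slightly biases branch lengths (not
topology) on such data.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "MkParams",
    "Tree",
    "Node",
    "mk_loglik",
    "start_tree",
    "ml_search",
    "bootstrap",
    "simulate_characters",
    "hamming_distances",
    "rf_distance",
]

_MIN_BLEN = 1e-8
_MAX_BLEN = 10.0
_TOL = 1e-6


@dataclass
class MkParams:
    """Mk model parameters: π0 and a free-rate distribution.

    Rates are rescaled on construction so the weighted mean rate is 1
    (branch lengths then measure expected changes per character).
    """

    pi0: float = 0.5
    rates: tuple = (1.0,)
    weights: tuple = (1.0,)

    def __post_init__(self):
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError("pi0 must be in (0, 1)")
        r = np.asarray(self.rates, float)
        w = np.asarray(self.weights, float)
        if (r <= 0).any() or (w <= 0).any() or len(r) != len(w):
            raise ValueError("rates and weights must be positive and matched")
        w = w / w.sum()
        r = r / (w @ r)
        self.rates = tuple(r)
        self.weights = tuple(w)

    @classmethod
    def default(cls, k: int = 2) -> "MkParams":
        if k == 1:
            return cls(0.5, (1.0,), (1.0,))
        # mildly spread initial free rates
        return cls(0.5, tuple(0.5 + i for i in range(k)), tuple([1.0 / k] * k))


class Node:
    __slots__ = ("name", "children", "parent", "blen", "support")

    def __init__(self, name=None, blen=0.0):
        self.name = name
        self.children = []
        self.parent = None
        self.blen = blen
        self.support = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)


class Tree:
    """Light unrooted tree (stored rooted at an internal node)."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        def conv(dn):
            node = Node(
                dn.taxon.label if dn.taxon is not None else dn.label,
                dn.edge.length if dn.edge.length is not None else 0.0,
            )
            for c in dn.child_nodes():
                node.add(conv(c))
            return node
        return cls(conv(dt.seed_node))

    def copy(self) -> "Tree":
        def conv(n):
            m = Node(n.name, n.blen)
            m.support = n.support
            for c in n.children:
                m.add(conv(c))
            return m
        return Tree(conv(self.root))

    # -- traversal ------------------------------------------------------

    def postorder(self) -> list:
        out, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        return out

    def leaves(self) -> list:
        return [n for n in self.postorder() if not n.children]

    def leaf_names(self) -> list:
        return [n.name for n in self.leaves()]

    def edges(self) -> list:
        """All non-root nodes (each represents the edge to its parent)."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list:
        return [n for n in self.edges() if n.children]

    # -- splits ---------------------------------------------------------

    def splits(self) -> set:
        """Nontrivial bipartitions, canonicalized by excluding the
        lexicographically smallest leaf's side."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out = set()
        below: dict = {}
        for n in self.postorder():
            if not n.children:
                below[id(n)] = frozenset([n.name])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
        for n in self.edges():
            side = below[id(n)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    # -- output ---------------------------------------------------------

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(n):
            if not n.children:
                label = n.name or ""
            else:
                inner = ",".join(fmt(c) for c in n.children)
                if with_support and n.support is not None:
                    label = f"({inner}){n.support:g}"
                else:
                    label = f"({inner})"
            return f"{label}:{n.blen:.8g}" if n.parent is not None else label
        return fmt(self.root) + ";"

    def __repr__(self):
        return f"Tree({len(self.leaves())} leaves)"


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: bipartitions in one tree but not the other."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees have different leaf sets")
    return len(t1.splits() ^ t2.splits())


# ---------------------------------------------------------------------------
# likelihood


class _SiteData:
    """Pattern-compressed binary matrix keyed by species name."""

    def __init__(self, matrix: pd.DataFrame):
        arr = matrix.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("character matrix must be binary (0/1)")
        patterns, counts = np.unique(arr, axis=1, return_counts=True)
        self.counts = counts.astype(float)
        self.n_chars = arr.shape[1]
        self.leaf_partials = {}
        eye = np.eye(2)
        for i, sp in enumerate(matrix.index):
            self.leaf_partials[sp] = eye[patterns[i]]  # (npat, 2)


def _transition(pi0: float, t: float, rate: float) -> np.ndarray:
    pi1 = 1.0 - pi0
    mu = 1.0 / (2.0 * pi0 * pi1)
    e = np.exp(-mu * rate * max(t, 0.0))
    return np.array([
        [pi0 + pi1 * e, pi1 * (1.0 - e)],
        [pi0 * (1.0 - e), pi1 + pi0 * e],
    ])


def _site_likelihoods(tree: Tree, data: _SiteData, params: MkParams) -> np.ndarray:
    """Per-pattern likelihoods, mixed over rate categories."""
    pi = np.array([params.pi0, 1.0 - params.pi0])
    total = np.zeros(len(data.counts))
    post = tree.postorder()
    for rate, weight in zip(params.rates, params.weights):
        partial = {}
        for n in post:
            if not n.children:
                partial[id(n)] = data.leaf_partials[n.name]
            else:
                prod = None
                for c in n.children:
                    p = _transition(params.pi0, c.blen, rate)
                    contrib = partial[id(c)] @ p.T
                    prod = contrib if prod is None else prod * contrib
                partial[id(n)] = prod
        total += weight * (partial[id(tree.root)] @ pi)
    return total


def mk_loglik(tree: Tree, matrix: pd.DataFrame, params: MkParams) -> float:
    """Log-likelihood of a binary matrix on a tree by pruning.

    ``matrix`` rows are species (matching the tree's leaves exactly),
    columns are characters.
    """
    if set(matrix.index) != set(tree.leaf_names()):
        raise ValueError("tree leaves and matrix species differ")
    data = _SiteData(matrix)
    site = _site_likelihoods(tree, data, params)
    return float(data.counts @ np.log(np.maximum(site, 1e-300)))


# ---------------------------------------------------------------------------
# starting tree


def hamming_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Hamming distance (proportion differing) between species rows."""
    arr = matrix.to_numpy()
    diff = (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
    return pd.DataFrame(diff, index=matrix.index, columns=matrix.index)


def neighbor_joining(dist: pd.DataFrame) -> Tree:
    """Deterministic neighbor joining; ties broken by row/column order.

    Negative branch lengths are clamped to 0.  The returned tree is
    unrooted (trifurcating root).
    """
    names = list(dist.index)
    if len(names) < 4:
        raise ValueError("need at least 4 taxa")
    D = dist.to_numpy().astype(float).copy()
    nodes = {i: Node(nm, 0.0) for i, nm in enumerate(names)}
    active = list(range(len(names)))
    while len(active) > 3:
        n = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (n - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (n - 2))
        vj = D[i, j] - vi
        parent = Node(None, 0.0)
        nodes[i].blen = max(vi, 0.0)
        nodes[j].blen = max(vj, 0.0)
        parent.add(nodes[i])
        parent.add(nodes[j])
        for k in active:
            if k not in (i, j):
                D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        active.remove(j)
    i, j, k = active
    root = Node(None, 0.0)
    nodes[i].blen = max(0.5 * (D[i, j] + D[i, k] - D[j, k]), 0.0)
    nodes[j].blen = max(0.5 * (D[i, j] + D[j, k] - D[i, k]), 0.0)
    nodes[k].blen = max(0.5 * (D[i, k] + D[j, k] - D[i, j]), 0.0)
    for idx in (i, j, k):
        root.add(nodes[idx])
    return Tree(root)


def start_tree(matrix: pd.DataFrame) -> Tree:
    """Neighbor joining on profile Hamming distances; negatives clamped to 0."""
    if len(matrix.index) < 4:
        raise ValueError("need at least 4 species")
    tree = neighbor_joining(hamming_distances(matrix))
    for n in tree.postorder():
        if n.blen is None or n.blen < _MIN_BLEN:
            n.blen = _MIN_BLEN
    return tree


def _derootify(tree: Tree) -> None:
    """Collapse a degree-2 root so the stored root is a trifurcation."""
    root = tree.root
    if len(root.children) == 2 and any(c.children for c in root.children):
        keep = next(c for c in root.children if c.children)
        other = next(c for c in root.children if c is not keep)
        root.children.remove(keep)
        for gc in keep.children:
            root.add(gc)
        other.blen += keep.blen


# ---------------------------------------------------------------------------
# search


def _optimize_branch_lengths(tree, data, params, rounds=2):
    logl = None
    for _ in range(rounds):
        for n in tree.edges():
            def nll(x, n=n):
                n.blen = x
                site = _site_likelihoods(tree, data, params)
                return -float(data.counts @ np.log(np.maximum(site, 1e-300)))
            res = minimize_scalar(
                nll, bounds=(_MIN_BLEN, _MAX_BLEN), method="bounded",
                options={"xatol": 1e-6},
            )
            n.blen = float(res.x)
    site = _site_likelihoods(tree, data, params)
    return float(data.counts @ np.log(np.maximum(site, 1e-300)))


def _pack(params: MkParams) -> np.ndarray:
    x = [np.log(params.pi0 / (1 - params.pi0))]
    k = len(params.rates)
    if k == 2:
        w0 = params.weights[0]
        rho = params.rates[1] / params.rates[0]
        x += [np.log(w0 / (1 - w0)), np.log(rho)]
    return np.array(x)


def _unpack(x: np.ndarray, k: int) -> MkParams:
    pi0 = 1.0 / (1.0 + np.exp(-x[0]))
    pi0 = min(max(pi0, 1e-4), 1 - 1e-4)
    if k == 1:
        return MkParams(pi0, (1.0,), (1.0,))
    w0 = 1.0 / (1.0 + np.exp(-x[1]))
    w0 = min(max(w0, 1e-3), 1 - 1e-3)
    rho = np.exp(min(x[2], 12.0))
    return MkParams(pi0, (1.0, max(rho, 1e-6)), (w0, 1 - w0))


def _optimize_params(tree, data, params):
    k = len(params.rates)

    def nll(x):
        p = _unpack(x, k)
        site = _site_likelihoods(tree, data, p)
        return -float(data.counts @ np.log(np.maximum(site, 1e-300)))

    res = minimize(nll, _pack(params), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 300})
    return _unpack(res.x, k), -float(res.fun)


def _nni_swap(v: Node, a: Node, c: Node) -> None:
    """Swap subtree a (child of v) with subtree c (child of v.parent)."""
    u = v.parent
    v.children[v.children.index(a)] = c
    u.children[u.children.index(c)] = a
    a.parent, c.parent = u, v


def _nni_sweep(tree, data, params, logl):
    improved = False
    for v in tree.internal_edges():
        u = v.parent
        siblings = [x for x in u.children if x is not v]
        if not siblings:
            continue
        c = siblings[0]
        for a in list(v.children):
            _nni_swap(v, a, c)
            site = _site_likelihoods(tree, data, params)
            cand = float(data.counts @ np.log(np.maximum(site, 1e-300)))
            if cand > logl + _TOL:
                logl = cand
                improved = True
                break
            _nni_swap(v, c, a)  # revert
    return logl, improved


def ml_search(
    matrix: pd.DataFrame,
    params_init: MkParams | None = None,
    nni_rounds: int = 10,
    tree: Tree | None = None,
    n_rate_categories: int = 2,
) -> tuple[Tree, MkParams, float]:
    """Hill-climbing ML search: branch lengths + model params + NNI.

    Deterministic given inputs.  Returns ``(tree, params, logL)`` with
    ``logL`` ≥ the starting tree's log-likelihood.
    """
    if params_init is None:
        params_init = MkParams.default(n_rate_categories)
    if tree is None:
        tree = start_tree(matrix)
    else:
        tree = tree.copy()
    data = _SiteData(matrix)
    params = params_init
    logl = -np.inf
    for _ in range(max(nni_rounds, 1)):
        logl = _optimize_branch_lengths(tree, data, params)
        params, logl = _optimize_params(tree, data, params)
        logl, improved = _nni_sweep(tree, data, params, logl)
        if not improved:
            break
    logl = _optimize_branch_lengths(tree, data, params)
    return tree, params, logl


def bootstrap(
    matrix: pd.DataFrame,
    n_replicates: int = 100,
    seed: int = 42,
    nni_rounds: int = 2,
    n_rate_categories: int = 2,
) -> tuple[Tree, MkParams, float]:
    """Nonparametric bootstrap support mapped onto the best tree.

    Characters are resampled with replacement per replicate and the
    search rerun with a reduced NNI budget; split frequencies (percent)
    annotate the internal edges of the full-matrix ML tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    best, params, logl = ml_search(matrix, n_rate_categories=n_rate_categories)
    rng = np.random.default_rng(seed)
    split_hits: dict = {s: 0 for s in best.splits()}
    for _ in range(n_replicates):
        cols = rng.integers(0, matrix.shape[1], matrix.shape[1])
        sub = matrix.iloc[:, cols]
        sub.columns = range(sub.shape[1])
        rep_tree, _, _ = ml_search(
            sub, nni_rounds=nni_rounds, tree=best,
            n_rate_categories=n_rate_categories,
        )
        for s in rep_tree.splits():
            if s in split_hits:
                split_hits[s] += 1
    all_leaves = frozenset(best.leaf_names())
    ref = min(all_leaves)
    below: dict = {}
    for n in best.postorder():
        below[id(n)] = (
            frozenset([n.name]) if not n.children
            else frozenset().union(*(below[id(c)] for c in n.children))
        )
    for n in best.internal_edges():
        side = below[id(n)]
        if ref in side:
            side = all_leaves - side
        if side in split_hits:
            n.support = 100.0 * split_hits[side] / n_replicates
    return best, params, logl


# ---------------------------------------------------------------------------
# character simulation (for validation)


def simulate_characters(
    tree: Tree, n_chars: int, params: MkParams, seed: int = 42
) -> pd.DataFrame:
    """Simulate binary characters on a tree under the Mk model."""
    rng = np.random.default_rng(seed)
    k = len(params.rates)
    cats = rng.choice(k, size=n_chars, p=params.weights)
    states = {id(tree.root): rng.random(n_chars) < (1.0 - params.pi0)}
    order = [n for n in reversed(tree.postorder())]  # preorder
    for n in order:
        if n is tree.root:
            continue
        parent_states = states[id(n.parent)].astype(int)
        out = np.empty(n_chars, dtype=int)
        for j in range(k):
            mask = cats == j
            p = _transition(params.pi0, n.blen, params.rates[j])
            ps = parent_states[mask]
            out[mask] = rng.random(mask.sum()) < p[ps, 1]
        states[id(n)] = out.astype(bool)
    rows = {n.name: states[id(n)].astype(int) for n in tree.leaves()}
    df = pd.DataFrame(rows).T
    df.columns = range(n_chars)
    return df.sort_index()
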