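"""Distance-based phylogenetics: nucleotide distances, NJ, bootstrap, Newick.

Distances are substitutions per site under the usual closed-form models
(p, JC69, K2P, TN93) plus a composite-likelihood variant ("mcl") in which
the TN93 rate parameters are estimated *once* from substitution-pattern
counts pooled over every sequence pair, and each pair then gets a one-
parameter maximum-likelihood distance under those shared rates.  Pooling
stabilises rate estimates for small sets of near-identical sequences —
exactly the 5-strain, >=97%-identity regime this toolkit targets — at the
cost of assuming all pairs share one rate matrix.

Trees are built with Saitou–Nei neighbor joining (Studier–Keppler Q),
negative intermediate branch lengths clamped to zero with the deficit moved
to the sister edge.  Bootstrap support resamples alignment columns with
replacement and reports, for each internal edge of the point-estimate tree,
the percentage of replicate trees containing the same bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import MultipleAlignment

__all__ = [
    "DistanceMatrix",
    "SubstitutionCounts",
    "TreeNode",
    "PhyloTree",
    "PhyloError",
    "SaturationError",
    "substitution_counts",
    "pairwise_distances",
    "neighbor_joining",
    "bootstrap_support",
    "total_branch_length",
    "write_newick",
    "read_newick",
    "random_additive_tree",
    "MODELS",
]

MODELS = ("p", "jc69", "k2p", "tn93", "mcl")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_TRANSITIONS = ((0, 2), (1, 3))  # A<->G, C<->T


class PhyloError(ValueError):
    pass


class SaturationError(PhyloError):
    """A distance could not be computed (log of a non-positive argument)."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.labels)
        if m.shape != (n, n):
            raise PhyloError(f"matrix shape {m.shape} does not match {n} labels")
        if not np.all(np.isfinite(m)):
            raise PhyloError("distances must be finite")
        if np.any(np.diag(m) != 0):
            raise PhyloError("diagonal must be zero")
        if not np.allclose(m, m.T, atol=1e-12):
            raise PhyloError("matrix must be symmetric")
        if np.any(m < 0):
            raise PhyloError("distances must be non-negative")

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class SubstitutionCounts:
    """Observed 4x4 base-pairing tables per pair, plus the pooled total."""

    labels: tuple[str, ...]
    pairs: dict = field(repr=False)    # (i, j) -> 4x4 ndarray, i < j
    pooled: np.ndarray = field(repr=False)
    n_columns: int = 0


def _encode(msa: MultipleAlignment) -> np.ndarray:
    rows = []
    for rid, row in zip(msa.ids, msa.rows):
        try:
            rows.append(np.array([_BASE_INDEX[b] for b in row], dtype=np.uint8))
        except KeyError:
            raise PhyloError(
                f"row {rid!r} contains gaps or ambiguity codes; "
                "run complete_deletion first") from None
    return np.stack(rows)


def substitution_counts(msa: MultipleAlignment) -> SubstitutionCounts:
    codes = _encode(msa)
    n = codes.shape[0]
    pairs: dict[tuple[int, int], np.ndarray] = {}
    pooled = np.zeros((4, 4), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            tab = np.bincount(4 * codes[i] + codes[j], minlength=16).reshape(4, 4)
            pairs[(i, j)] = tab
            pooled += tab
    return SubstitutionCounts(labels=msa.ids, pairs=pairs, pooled=pooled,
                              n_columns=codes.shape[1])


# ---------------------------------------------------------------------------
# Distance models
# ---------------------------------------------------------------------------

def _proportions(tab: np.ndarray) -> tuple[float, float, float]:
    """(P1, P2, Q): A<->G, C<->T and transversion difference proportions."""
    total = tab.sum()
    p1 = (tab[0, 2] + tab[2, 0]) / total
    p2 = (tab[1, 3] + tab[3, 1]) / total
    p = (total - np.trace(tab)) / total
    return float(p1), float(p2), float(p - p1 - p2)


def _safe_log(x: float, pair: str, model: str) -> float:
    if x <= 0:
        raise SaturationError(
            f"{model} distance saturated for pair {pair} (log argument {x:.4g})")
    return math.log(x)


def _p_distance(tab: np.ndarray) -> float:
    total = tab.sum()
    return float((total - np.trace(tab)) / total)


def _jc69(tab: np.ndarray, pair: str) -> float:
    p = _p_distance(tab)
    return -0.75 * _safe_log(1.0 - 4.0 * p / 3.0, pair, "JC69")


def _k2p(tab: np.ndarray, pair: str) -> float:
    p1, p2, q = _proportions(tab)
    p = p1 + p2
    return (-0.5 * _safe_log(1.0 - 2.0 * p - q, pair, "K2P")
            - 0.25 * _safe_log(1.0 - 2.0 * q, pair, "K2P"))


def _pair_freqs(tab: np.ndarray) -> np.ndarray:
    total = tab.sum()
    return (tab.sum(axis=1) + tab.sum(axis=0)) / (2.0 * total)


def _tn93(tab: np.ndarray, pair: str, pi: np.ndarray | None = None) -> float:
    pi = _pair_freqs(tab) if pi is None else pi
    pa, pc, pg, pt = pi
    gr, gy = pa + pg, pc + pt
    if min(gr, gy) <= 0 or pa * pg <= 0 or pc * pt <= 0:
        raise SaturationError(f"TN93 undefined for pair {pair}: degenerate base frequencies")
    k1 = 2.0 * pa * pg / gr
    k2 = 2.0 * pt * pc / gy
    k3 = 2.0 * (gr * gy - pa * pg * gy / gr - pt * pc * gr / gy)
    p1, p2, q = _proportions(tab)
    w1 = 1.0 - p1 / k1 - q / (2.0 * gr)
    w2 = 1.0 - p2 / k2 - q / (2.0 * gy)
    w3 = 1.0 - q / (2.0 * gr * gy)
    return (-k1 * _safe_log(w1, pair, "TN93")
            - k2 * _safe_log(w2, pair, "TN93")
            - k3 * _safe_log(w3, pair, "TN93"))


class _TN93Kernel:
    """TN93 rate matrix with fixed base frequencies and rate ratios.

    Normalised to one expected substitution per site per unit time, so the
    time parameter of :meth:`category_probs` *is* the evolutionary distance.
    """

    def __init__(self, pi: np.ndarray, kappa1: float, kappa2: float):
        self.pi = pi
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = 1.0
                if (i, j) in ((0, 2), (2, 0)):
                    rate = kappa1
                elif (i, j) in ((1, 3), (3, 1)):
                    rate = kappa2
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        q /= mu
        self._evals, self._evecs = np.linalg.eig(q)
        self._inv = np.linalg.inv(self._evecs)

    def category_probs(self, t: float) -> tuple[float, float, float, float]:
        """(P1, P2, Q, identical) expected pattern proportions at distance t."""
        pt = (self._evecs * np.exp(self._evals * t)) @ self._inv
        f = self.pi[:, None] * np.real(pt)
        p1 = f[0, 2] + f[2, 0]
        p2 = f[1, 3] + f[3, 1]
        same = float(np.trace(f))
        return float(p1), float(p2), float(1.0 - p1 - p2 - same), same


def _category_counts(tab: np.ndarray) -> tuple[float, float, float, float]:
    n1 = tab[0, 2] + tab[2, 0]
    n2 = tab[1, 3] + tab[3, 1]
    same = np.trace(tab)
    return float(n1), float(n2), float(tab.sum() - n1 - n2 - same), float(same)


def _multinomial_nll(kernel: _TN93Kernel, t: float, counts) -> float:
    probs = kernel.category_probs(t)
    nll = 0.0
    for n, p in zip(counts, probs):
        if n > 0:
            if p <= 1e-300:
                return 1e12
            nll -= n * math.log(p)
    return nll


_MAX_MCL_DISTANCE = 5.0


def _fit_shared_rates(pooled: np.ndarray, pi: np.ndarray) -> tuple[float, float]:
    """ML estimate of the shared transition/transversion rate ratios.

    Maximises the multinomial likelihood of the pooled pattern counts over
    (log kappa1, log kappa2, log t); only the ratios are retained.
    """
    counts = _category_counts(pooled)
    p = _p_distance(pooled)
    t0 = max(p, 1e-4)

    def nll(x):
        k1, k2, t = (math.exp(v) for v in x)
        if max(k1, k2) > 1e4 or t > _MAX_MCL_DISTANCE:
            return 1e12
        return _multinomial_nll(_TN93Kernel(pi, k1, k2), t, counts)

    res = minimize(nll, x0=[math.log(4.0), math.log(4.0), math.log(t0)],
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    k1, k2 = math.exp(res.x[0]), math.exp(res.x[1])
    return k1, k2


def _mcl_pair_distance(kernel: _TN93Kernel, tab: np.ndarray, pair: str) -> float:
    counts = _category_counts(tab)
    if counts[0] + counts[1] + counts[2] == 0:
        return 0.0
    res = minimize_scalar(lambda t: _multinomial_nll(kernel, t, counts),
                          bounds=(1e-9, _MAX_MCL_DISTANCE), method="bounded",
                          options={"xatol": 1e-10})
    d = float(res.x)
    if d > 0.99 * _MAX_MCL_DISTANCE:
        raise SaturationError(f"composite-likelihood distance saturated for pair {pair}")
    return d


def _counts_to_distances(sub: SubstitutionCounts, model: str) -> DistanceMatrix:
    model = model.lower()
    if model not in MODELS:
        raise PhyloError(f"unknown model {model!r}; choose from {MODELS}")
    n = len(sub.labels)
    d = np.zeros((n, n))
    kernel = None
    if model == "mcl":
        pi = _pair_freqs(sub.pooled)
        k1, k2 = _fit_shared_rates(sub.pooled, pi)
        kernel = _TN93Kernel(pi, k1, k2)
    for (i, j), tab in sub.pairs.items():
        pair = f"({sub.labels[i]}, {sub.labels[j]})"
        if model == "p":
            val = _p_distance(tab)
        elif model == "jc69":
            val = _jc69(tab, pair)
        elif model == "k2p":
            val = _k2p(tab, pair)
        elif model == "tn93":
            val = _tn93(tab, pair)
        else:
            val = _mcl_pair_distance(kernel, tab, pair)
        d[i, j] = d[j, i] = max(val, 0.0)
    return DistanceMatrix(labels=sub.labels, matrix=d)


def pairwise_distances(msa_filtered: MultipleAlignment, model: str = "mcl") -> DistanceMatrix:
    """Distance matrix (substitutions/site) from a gap-free alignment."""
    return _counts_to_distances(substitution_counts(msa_filtered), model)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of an (un)rooted tree; ``length`` is the edge to the parent."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: float | None = None,
                 children: list["TreeNode"] | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children = children or []

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree represented with a (usually trifurcating) root node."""

    root: TreeNode

    @property
    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(n):
            if n.is_leaf():
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves]

    def edges(self):
        """Yield every (parent, child) pair."""

        def walk(n):
            for c in n.children:
                yield n, c
                yield from walk(c)

        yield from walk(self.root)

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalised as the side *not*
        containing the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        splits = set()
        for _, child in self.edges():
            side = frozenset(child.leaf_names())
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            if ref in side:
                side = all_leaves - side
            splits.add(side)
        return splits

    def internal_edges(self):
        """(child_node, canonical bipartition) for each internal edge."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        for _, child in self.edges():
            side = frozenset(child.leaf_names())
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            key = all_leaves - side if ref in side else side
            yield child, key

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        names = sorted(self.leaf_names)
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def below(node):
            """Return {leaf: distance to node}."""
            if node.is_leaf():
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            groups = []
            for c in node.children:
                sub = {k: v + (c.length or 0.0) for k, v in below(c).items()}
                groups.append(sub)
                acc.update(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi].items():
                        for lb, db in groups[gj].items():
                            d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
            return acc

        below(self.root)
        return DistanceMatrix(labels=tuple(names), matrix=d)


def total_branch_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths, in substitutions per site."""
    total = 0.0
    for _, child in tree.edges():
        if child.length is None:
            raise PhyloError(f"edge above {child.name or 'internal node'} has no length")
        total += child.length
    return total


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q criterion.

    Negative intermediate branch lengths are clamped to zero with the
    deficit moved to the sister edge (their sum is preserved).  Ties in Q
    are broken by the smallest (alphabetical) leaf label under each node,
    so the result is invariant to input label order.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError(f"neighbor joining needs >= 3 taxa, got {n}")
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    keys = [lab for lab in dm.labels]  # canonical label per active node
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                cand_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best is None or cand_key < best[2])):
                    best_q = q
                    best = (ai, aj, cand_key)
        ai, aj, _ = best
        i, j = active[ai], active[aj]
        li = sub[ai, aj] / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = sub[ai, aj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, max(lj, 0.0)
        parent = TreeNode(children=[ni, nj])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        # distances from the new node
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = max((d[i, k] + d[j, k] - d[i, j]) / 2.0, 0.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    # final three-way join
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


class BootstrapError(PhyloError):
    pass


def bootstrap_support(msa_filtered: MultipleAlignment, model: str = "mcl",
                      n_reps: int = 1000, seed: int | None = None,
                      resample: Callable | None = None) -> PhyloTree:
    """NJ tree with bootstrap support on internal edges.

    Columns are resampled with replacement ``n_reps`` times (all randomness
    from ``seed``; replicate streams derive deterministically from it).
    Support = percentage of successful replicates whose NJ tree contains
    the same bipartition.  Replicates with saturated distances are dropped
    and counted; more than 10% dropped is an error.  ``resample`` may be a
    ``(rng, n_columns) -> indices`` callable (used in testing).
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    codes = _encode(msa_filtered)
    n_taxa, n_cols = codes.shape
    point = neighbor_joining(_distances_from_codes(codes, msa_filtered.ids, model))
    targets = {key: 0 for _, key in point.internal_edges()}

    rng = np.random.default_rng(seed)
    dropped = 0
    successes = 0
    for _ in range(n_reps):
        idx = (resample(rng, n_cols) if resample is not None
               else rng.integers(0, n_cols, n_cols))
        try:
            dmat = _distances_from_codes(codes[:, idx], msa_filtered.ids, model)
            rep_tree = neighbor_joining(dmat)
        except SaturationError:
            dropped += 1
            continue
        successes += 1
        rep_splits = rep_tree.bipartitions()
        for key in targets:
            if key in rep_splits:
                targets[key] += 1
    if dropped > 0.1 * n_reps:
        raise BootstrapError(
            f"{dropped}/{n_reps} bootstrap replicates dropped (saturation)")
    for child, key in point.internal_edges():
        child.support = 100.0 * targets[key] / successes if successes else 0.0
    return point


def _distances_from_codes(codes: np.ndarray, labels, model: str) -> DistanceMatrix:
    n = codes.shape[0]
    pairs = {}
    pooled = np.zeros((4, 4), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            tab = np.bincount(4 * codes[i] + codes[j], minlength=16).reshape(4, 4)
            pairs[(i, j)] = tab
            pooled += tab
    sub = SubstitutionCounts(labels=tuple(labels), pairs=pairs, pooled=pooled,
                             n_columns=codes.shape[1])
    return _counts_to_distances(sub, model)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed parsing)
# ---------------------------------------------------------------------------

def _to_newick(node: TreeNode, is_root: bool = False) -> str:
    if node.is_leaf():
        body = node.name
    else:
        body = "(" + ",".join(_to_newick(c) for c in node.children) + ")"
        if node.support is not None:
            body += f"{node.support:g}"
        elif node.name:
            body += node.name
    if not is_root and node.length is not None:
        body += f":{node.length:.10g}"
    return body


def tree_to_newick(tree: PhyloTree) -> str:
    return _to_newick(tree.root, is_root=True) + ";"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    """Parse a Newick file; numeric internal labels become support values."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(path=str(path), schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises various parse errors
        raise PhyloError(f"malformed Newick in {path}: {exc}") from exc
    return PhyloTree(root=_from_dendropy(dtree.seed_node))


def newick_to_tree(newick: str) -> PhyloTree:
    import dendropy

    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise PhyloError(f"malformed Newick string: {exc}") from exc
    return PhyloTree(root=_from_dendropy(dtree.seed_node))


def _from_dendropy(dnode) -> TreeNode:
    children = [_from_dendropy(c) for c in dnode.child_nodes()]
    name = dnode.taxon.label if dnode.taxon is not None else None
    support = None
    if children and dnode.label is not None:
        try:
            support = float(dnode.label)
            name = None
        except ValueError:
            name = dnode.label
    return TreeNode(name=name, length=dnode.edge.length, support=support,
                    children=children)


# ---------------------------------------------------------------------------
# Simulation helper
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves: int, seed: int | None = None,
                         length_range: tuple[float, float] = (0.05, 1.0)) -> PhyloTree:
    """A random unrooted binary tree with uniform branch lengths.

    Its patristic distance matrix is additive by construction, so NJ must
    recover the topology and branch lengths exactly — the standard oracle
    for NJ consistency tests.
    """
    if n_leaves < 4:
        raise PhyloError("need >= 4 leaves for a non-trivial unrooted tree")
    rng = np.random.default_rng(seed)
    lo, hi = length_range

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    labels = [f"T{i + 1:02d}" for i in range(n_leaves)]

    def build(group: list[str]) -> TreeNode:
        if len(group) == 1:
            return TreeNode(name=group[0], length=blen())
        cut = int(rng.integers(1, len(group)))
        return TreeNode(length=blen(), children=[build(group[:cut]), build(group[cut:])])

    # trifurcating root => unrooted binary tree with 2n-3 edges
    perm = [labels[i] for i in rng.permutation(n_leaves)]
    c1 = build(perm[:1])
    c2 = build(perm[1:1 + (n_leaves - 1) // 2])
    c3 = build(perm[1 + (n_leaves - 1) // 2:])
    return PhyloTree(root=TreeNode(children=[c1, c2, c3]))
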