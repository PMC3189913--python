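"""Independent reference computations used to check the package.

Everything here deliberately avoids the implementation paths it checks:
parsimony oracles enumerate assignments/topologies outright, the bending
energy oracle integrates the squared second derivatives numerically, and
distance/cluster oracles use naive loops or scipy's linkage.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

MISSING = "?"


# ---------------------------------------------------------------------------
# parsimony: exhaustive minimization over internal-state assignments
# ---------------------------------------------------------------------------


def random_unrooted_tree_edges(n: int, rng) -> list[tuple[int, int]]:
    """Random unrooted binary tree on leaves 0..n-1 by random insertion.

    Returns the edge list; internal nodes are numbered n, n+1, ...
    """
    edges = {(0, n), (1, n), (2, n)}
    next_internal = n + 1
    for leaf in range(3, n):
        u, v = list(edges)[rng.integers(0, len(edges))]
        edges.remove((u, v))
        w = next_internal
        next_internal += 1
        edges |= {(u, w), (v, w), (leaf, w)}
    return sorted(edges)


def exhaustive_fitch_length(
    edges: list[tuple[int, int]], column: np.ndarray, n_leaves: int
) -> int:
    """Minimum mutations for one character by brute force over all
    internal-node (and missing-leaf) state assignments."""
    observed = sorted({s for s in column if s != MISSING})
    if len(observed) <= 1:
        return 0
    nodes = sorted({u for e in edges for u in e})
    free = [u for u in nodes if u >= n_leaves or column[u] == MISSING]
    fixed = {u: column[u] for u in nodes if u < n_leaves and column[u] != MISSING}
    best = None
    for assignment in itertools.product(observed, repeat=len(free)):
        state = dict(zip(free, assignment))
        state.update(fixed)
        steps = sum(1 for u, v in edges if state[u] != state[v])
        if best is None or steps < best:
            best = steps
    return best


def exhaustive_matrix_length(
    edges: list[tuple[int, int]], states: np.ndarray
) -> int:
    """Brute-force parsimony length of a whole matrix on a fixed tree."""
    n_leaves = states.shape[0]
    return sum(
        exhaustive_fitch_length(edges, states[:, j], n_leaves)
        for j in range(states.shape[1])
    )


# ---------------------------------------------------------------------------
# parsimony: exhaustive enumeration of all unrooted topologies
# ---------------------------------------------------------------------------


def _all_rooted_shapes(leaves: list[int]):
    """All rooted binary tree shapes (nested tuples) on the given leaves."""
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert_everywhere(t, leaf))
        trees = nxt
    return trees


def _insert_everywhere(t, x):
    yield (t, x)
    if isinstance(t, tuple):
        a, b = t
        for s in _insert_everywhere(a, x):
            yield (s, b)
        for s in _insert_everywhere(b, x):
            yield (a, s)


def _to_postorder(t, n: int):
    """Children array (n-2, 2) with internal ids n.. in postorder; root last."""
    rows = []

    def walk(node):
        if not isinstance(node, tuple):
            return node
        a = walk(node[0])
        b = walk(node[1])
        rows.append((a, b))
        return n + len(rows) - 1

    walk(t)
    return rows


def _splits_of(t, n: int) -> frozenset:
    """Nontrivial bipartitions of the unrooted tree (side without leaf 0)."""
    leaves_all = frozenset(range(n))
    splits = set()

    def walk(node):
        if not isinstance(node, tuple):
            return frozenset([node])
        s = walk(node[0]) | walk(node[1])
        if 1 < len(s) < n - 1:
            splits.add(s if 0 not in s else leaves_all - s)
        return s

    walk(t)
    return frozenset(splits)


def _encode(states: np.ndarray) -> np.ndarray:
    masks = np.zeros(states.shape, dtype=np.uint16)
    for sym in "0123456789":
        masks |= np.where(states == sym, np.uint16(1 << int(sym)), 0).astype(np.uint16)
    masks[states == MISSING] = np.uint16((1 << 10) - 1)
    return masks


def all_topology_lengths(states: np.ndarray, batch: int = 20000):
    """Fitch length of every unrooted topology on the matrix's taxa.

    Taxa are leaves 0..n-1; each unrooted topology is represented as a
    rooted binary shape on leaves 1..n-1 with leaf 0 joined at the root.
    Returns (lengths array, list of split-sets), index-aligned.
    """
    n = states.shape[0]
    masks = _encode(states)
    shapes = _all_rooted_shapes(list(range(1, n)))
    split_sets = [_splits_of(t, n) for t in shapes]
    children = np.array([_to_postorder(t, n) for t in shapes], dtype=np.int32)
    lengths = np.empty(len(shapes), dtype=np.int64)
    m = masks.shape[1]
    n_int = n - 2
    for lo in range(0, len(shapes), batch):
        ch = children[lo : lo + batch]
        T = ch.shape[0]
        node_states = np.zeros((T, n + n_int, m), dtype=np.uint16)
        node_states[:, 1:n, :] = masks[1:][None, :, :]
        steps = np.zeros((T, m), dtype=np.int32)
        ar = np.arange(T)
        for j in range(n_int):
            s1 = node_states[ar, ch[:, j, 0]]
            s2 = node_states[ar, ch[:, j, 1]]
            inter = s1 & s2
            empty = inter == 0
            steps += empty
            node_states[:, n + j] = np.where(empty, s1 | s2, inter)
        root = node_states[:, n + n_int - 1]
        steps += (root & masks[0][None, :]) == 0
        lengths[lo : lo + batch] = steps.sum(axis=1)
    return lengths, split_sets


def exhaustive_mpt_splits(states: np.ndarray) -> tuple[int, set]:
    """Optimal length and the set of split-sets of all optimal topologies."""
    lengths, split_sets = all_topology_lengths(states)
    best = int(lengths.min())
    return best, {split_sets[i] for i in np.nonzero(lengths == best)[0]}


# ---------------------------------------------------------------------------
# per-character ensemble indices, coded independently and summed naively
# ---------------------------------------------------------------------------


def naive_indices(per_char_steps, per_char_min, per_char_max):
    L = sum(per_char_steps)
    M = sum(per_char_min)
    CI = M / L
    HI = 1 - CI
    g, m, s = [], [], []
    for gi, mi, si in zip(per_char_max, per_char_min, per_char_steps):
        if gi > mi:
            g.append(gi)
            m.append(mi)
            s.append(si)
    RI = (sum(g) - sum(s)) / (sum(g) - sum(m)) if sum(g) > sum(m) else 1.0
    return L, CI, HI, RI, CI * RI


# ---------------------------------------------------------------------------
# TPS bending-energy numerical integration
# ---------------------------------------------------------------------------


def numeric_bending_energy(spline, half_width: float = 60.0, n_grid: int = 3001) -> float:
    """Midpoint-rule integral of f_xx^2 + 2 f_xy^2 + f_yy^2 over a large square.

    Uses the analytic second derivatives of U(r) = r^2 log r^2; grid
    points are offset by irrational fractions of the cell so no landmark
    is hit exactly.
    """
    ref = spline.reference
    W = spline.weights
    xs = np.linspace(-half_width, half_width, n_grid)
    h = xs[1] - xs[0]
    total = 0.0
    for chunk in np.array_split(xs, 40):
        X, Y = np.meshgrid(chunk, xs, indexing="ij")
        pts = np.column_stack([X.ravel() + h / 3, Y.ravel() + h / 7])
        d = pts[:, None, :] - ref[None, :, :]
        r2 = (d**2).sum(-1)
        x, y = d[..., 0], d[..., 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.where(r2 > 0, np.log(r2), 0.0)
            Uxx = 2 * (lg + 1) + 4 * x * x / r2
            Uyy = 2 * (lg + 1) + 4 * y * y / r2
            Uxy = 4 * x * y / r2
        Uxx, Uyy, Uxy = (np.nan_to_num(a) for a in (Uxx, Uyy, Uxy))
        fxx = Uxx @ W
        fyy = Uyy @ W
        fxy = Uxy @ W
        total += float((fxx**2 + 2 * fxy**2 + fyy**2).sum()) * h * h
    return total


# ---------------------------------------------------------------------------
# distances / clustering
# ---------------------------------------------------------------------------


def naive_distances(X: np.ndarray, squared: bool = False) -> np.ndarray:
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
            out[i, j] = d**2 if squared else d
    return out


def scipy_upgma_cophenetic(d: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix of scipy's average-linkage clustering."""
    Z = linkage(squareform(d, checks=False), method="average")
    return squareform(cophenet(Z))
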