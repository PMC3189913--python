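"""Maximum-parsimony inference on unordered multistate character matrices.

Implements the classical cladistic toolkit: Fitch tree length, exact
branch-and-bound search (guaranteed to find every most-parsimonious
tree), random-addition + SPR heuristic search, strict consensus,
nonparametric bootstrap, and the ensemble indices

* ``L``  — tree length (total character-state changes),
* ``CI`` — consistency index, sum of per-character minima over ``L``,
* ``HI`` — homoplasy index, ``1 - CI``,
* ``RI`` — retention index, ``(G - L) / (G - M)``,
* ``RC`` — rescaled consistency index, ``CI * RI``,

where ``M = sum m_i`` (minimum conceivable steps) and ``G = sum g_i``
(maximum steps on the completely unresolved tree).

All characters are unordered with equal weight; ``?`` is treated as the
full state set by Fitch and is excluded from the observed-state counts
entering ``m_i`` and ``g_i``.

Trees cross the public boundary as :class:`dendropy.Tree` objects; a
compact integer-adjacency representation is used internally for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import MISSING, CharacterMatrix, PhyloTree

__all__ = [
    "ParsimonyScore",
    "SearchResult",
    "fitch_length",
    "search_mpt",
    "ensemble_indices",
    "strict_consensus",
    "bootstrap",
    "ParsimonyModel",
    "ParsimonyResults",
]

_FULL_MASK = np.uint16((1 << 10) - 1)


# ---------------------------------------------------------------------------
# internal tree representation: adjacency over integer nodes,
# leaves are 0..n-1 (taxon indices), internal nodes >= n
# ---------------------------------------------------------------------------


class _Tree:
    __slots__ = ("adj", "next_id")

    def __init__(self, adj: dict[int, list[int]], next_id: int):
        self.adj = adj
        self.next_id = next_id

    @classmethod
    def star3(cls, a: int, b: int, c: int, internal_start: int) -> "_Tree":
        h = internal_start
        return cls({a: [h], b: [h], c: [h], h: [a, b, c]}, h + 1)

    def copy(self) -> "_Tree":
        return _Tree({u: list(vs) for u, vs in self.adj.items()}, self.next_id)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, vs in self.adj.items() for v in vs if u < v]

    def leaves(self) -> list[int]:
        return sorted(u for u, vs in self.adj.items() if len(vs) == 1)

    def insert_leaf(self, leaf: int, edge: tuple[int, int]) -> int:
        """Subdivide ``edge`` with a new internal node and hang ``leaf``."""
        u, v = edge
        w = self.next_id
        self.next_id += 1
        self.adj[u][self.adj[u].index(v)] = w
        self.adj[v][self.adj[v].index(u)] = w
        self.adj[w] = [u, v, leaf]
        self.adj[leaf] = [w]
        return w

    def remove_leaf(self, leaf: int) -> None:
        (w,) = self.adj.pop(leaf)
        self.adj[w].remove(leaf)
        if len(self.adj[w]) == 2:
            a, b = self.adj.pop(w)
            self.adj[a][self.adj[a].index(w)] = b
            self.adj[b][self.adj[b].index(w)] = a
            if w == self.next_id - 1:
                self.next_id -= 1

    def postorder(self) -> tuple[list[int], dict[int, int]]:
        adj = self.adj
        root = next((u for u, vs in adj.items() if len(vs) > 1), None)
        if root is None:  # two-leaf tree
            nodes = sorted(adj)
            return nodes, {nodes[0]: nodes[1], nodes[1]: None}
        parent: dict[int, int | None] = {root: None}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        order.reverse()
        return order, parent

    def bipartitions(self, n_taxa_hint: int | None = None) -> frozenset[frozenset[int]]:
        """Nontrivial splits, each encoded as the side not containing the
        smallest leaf id."""
        order, parent = self.postorder()
        leaves = set(self.leaves())
        if not leaves:
            return frozenset()
        anchor = min(leaves)
        below: dict[int, frozenset[int]] = {}
        splits = set()
        for u in order:
            kids = [v for v in self.adj[u] if v != parent[u]]
            if not kids:
                below[u] = frozenset([u])
            else:
                s = frozenset().union(*(below[c] for c in kids))
                below[u] = s
                if parent[u] is not None and 1 < len(s) < len(leaves) - 1:
                    splits.add(s if anchor not in s else frozenset(leaves - s))
        return frozenset(splits)


def _fitch_steps(tree: _Tree, masks: np.ndarray) -> int:
    """Total Fitch length over all characters; ``masks`` is (max_leaf+1, m)."""
    order, parent = tree.postorder()
    adj = tree.adj
    state: dict[int, np.ndarray] = {}
    steps = 0
    for u in order:
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            state[u] = masks[u]
            continue
        s = state[kids[0]]
        for c in kids[1:]:
            inter = s & state[c]
            empty = inter == 0
            steps += int(empty.sum())
            s = np.where(empty, s | state[c], inter)
        state[u] = s
    return steps


def _encode_matrix(matrix: CharacterMatrix) -> np.ndarray:
    """State bitmasks, one uint16 per cell; '?' becomes the full state set."""
    masks = np.zeros((matrix.n_taxa, matrix.n_chars), dtype=np.uint16)
    for symbol in "0123456789":
        masks |= np.where(matrix.states == symbol, np.uint16(1 << int(symbol)), 0).astype(
            np.uint16
        )
    masks[matrix.states == MISSING] = _FULL_MASK
    return masks


# ---------------------------------------------------------------------------
# dendropy conversion
# ---------------------------------------------------------------------------


def _from_dendropy(tree: PhyloTree, taxa: list[str]) -> _Tree:
    index = {name: i for i, name in enumerate(taxa)}
    tree_labels = sorted(
        (lf.taxon.label if lf.taxon else lf.label) for lf in tree.leaf_node_iter()
    )
    if tree_labels != sorted(taxa):
        missing = set(taxa) - set(tree_labels)
        extra = set(tree_labels) - set(taxa)
        raise ValueError(
            f"tree/matrix taxon mismatch: missing from tree {sorted(missing)}, "
            f"not in matrix {sorted(extra)}"
        )
    adj: dict[int, list[int]] = {}
    ids: dict = {}
    next_id = len(taxa)
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if node.is_leaf():
            ids[node] = index[label]
        else:
            ids[node] = next_id
            next_id += 1
        adj[ids[node]] = []
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            adj[ids[node]].append(ids[child])
            adj[ids[child]].append(ids[node])
    t = _Tree(adj, next_id)
    # suppress a degree-2 root so rooted inputs score as unrooted
    for u in [u for u, vs in t.adj.items() if len(vs) == 2]:
        a, b = t.adj.pop(u)
        t.adj[a][t.adj[a].index(u)] = b
        t.adj[b][t.adj[b].index(u)] = a
    return t


def _to_dendropy(
    tree: _Tree,
    taxa: list[str],
    namespace: dendropy.TaxonNamespace | None = None,
) -> PhyloTree:
    ns = namespace or dendropy.TaxonNamespace(taxa)
    out = dendropy.Tree(taxon_namespace=ns)
    adj = tree.adj
    root = next((u for u, vs in adj.items() if len(vs) > 1), min(adj))
    nodes = {root: out.seed_node}
    stack = [(root, None)]
    while stack:
        u, par = stack.pop()
        for v in adj[u]:
            if v == par:
                continue
            child = dendropy.Node()
            nodes[u].add_child(child)
            nodes[v] = child
            if len(adj[v]) == 1:
                child.taxon = ns.get_taxon(taxa[v])
            stack.append((v, u))
    out.is_rooted = False
    return out


def _tree_from_splits(
    taxa: list[str], splits: frozenset[frozenset[int]]
) -> _Tree:
    """Build the (possibly multifurcating) tree displaying exactly ``splits``.

    Splits must be pairwise compatible (guaranteed for a strict consensus).
    """
    n = len(taxa)
    adj: dict[int, list[int]] = {n: []}
    next_id = n + 1
    # parent of every taxon starts at the root; nest splits largest-first
    holder = {i: n for i in range(n)}
    children_sets: dict[int, set[int]] = {n: set(range(n))}
    for s in sorted(splits, key=len, reverse=True):
        host = holder[next(iter(s))]
        node = next_id
        next_id += 1
        adj[node] = []
        children_sets[node] = set(s)
        adj[host].append(node)
        adj[node].append(host)
        for leaf in s:
            holder[leaf] = node
    for leaf in range(n):
        adj[leaf] = [holder[leaf]]
        adj[holder[leaf]].append(leaf)
    return _Tree(adj, next_id)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParsimonyScore:
    """Tree length and the ensemble indices of a tree + matrix pair."""

    L: int
    CI: float
    HI: float
    RI: float
    RC: float

    def __str__(self) -> str:
        return (
            f"L = {self.L}; CI = {self.CI:.2f}; HI = {self.HI:.2f}; "
            f"RI = {self.RI:.2f}; RC = {self.RC:.2f}"
        )


@dataclass
class SearchResult:
    """Most-parsimonious trees plus their shared score."""

    mpts: list[PhyloTree]
    score: ParsimonyScore
    method: str
    replicates: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.mpts)


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Parsimony length of ``tree`` under Fitch optimisation.

    Characters are unordered; ``?`` matches every state.  The length is
    invariant to rooting (degree-2 roots are suppressed) and to taxon
    order.  Multifurcations are scored by sequential pairwise state-set
    combination.
    """
    t = _from_dendropy(tree, matrix.taxa)
    return _fitch_steps(t, _encode_matrix(matrix))


def _per_character_minima(matrix: CharacterMatrix) -> np.ndarray:
    """m_i: observed distinct states (missing excluded) minus one."""
    m = np.zeros(matrix.n_chars, dtype=int)
    for j in range(matrix.n_chars):
        observed = {s for s in matrix.column(j) if s != MISSING}
        m[j] = max(len(observed) - 1, 0)
    return m


def _per_character_maxima(matrix: CharacterMatrix) -> np.ndarray:
    """g_i: scored-taxon count minus the count of the most frequent state."""
    g = np.zeros(matrix.n_chars, dtype=int)
    for j in range(matrix.n_chars):
        col = [s for s in matrix.column(j) if s != MISSING]
        if col:
            top = max(col.count(s) for s in set(col))
            g[j] = len(col) - top
    return g


def _per_character_steps(tree: _Tree, masks: np.ndarray) -> np.ndarray:
    steps = np.zeros(masks.shape[1], dtype=int)
    order, parent = tree.postorder()
    state: dict[int, np.ndarray] = {}
    for u in order:
        kids = [v for v in tree.adj[u] if v != parent[u]]
        if not kids:
            state[u] = masks[u]
            continue
        s = state[kids[0]]
        for c in kids[1:]:
            inter = s & state[c]
            empty = inter == 0
            steps += empty
            s = np.where(empty, s | state[c], inter)
        state[u] = s
    return steps


def ensemble_indices(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    informative_only: bool = False,
) -> ParsimonyScore:
    """Tree length and CI/HI/RI/RC for ``tree`` on ``matrix``.

    ``informative_only=True`` drops characters whose maximum conceivable
    steps equal their minimum (parsimony-uninformative characters, which
    can only inflate CI) from every sum, matching the stricter PAUP
    reporting convention.  RI always excludes such characters, since
    their retention is undefined (zero denominator contribution).
    """
    t = _from_dendropy(tree, matrix.taxa)
    masks = _encode_matrix(matrix)
    s = _per_character_steps(t, masks)
    m = _per_character_minima(matrix)
    g = _per_character_maxima(matrix)
    informative = g > m
    if informative_only:
        s, m, g = s[informative], m[informative], g[informative]
        informative = g > m
    L = int(s.sum())
    if L == 0:
        raise ValueError("tree length is 0 (all characters invariant): CI undefined")
    CI = float(m.sum()) / L
    HI = 1.0 - CI
    gi, mi, si = g[informative], m[informative], s[informative]
    denom = gi.sum() - mi.sum()
    RI = float(gi.sum() - si.sum()) / denom if denom > 0 else 1.0
    return ParsimonyScore(L=L, CI=CI, HI=HI, RI=RI, RC=CI * RI)


def combine_indices(CI: float, RI: float) -> tuple[float, float]:
    """The two identities tying the ensemble indices together:
    HI = 1 - CI and RC = CI * RI."""
    return 1.0 - CI, CI * RI


# -- search ------------------------------------------------------------------


def _greedy_addition(
    order: list[int], masks: np.ndarray, n_taxa: int
) -> tuple[_Tree, int]:
    t = _Tree.star3(order[0], order[1], order[2], n_taxa)
    for leaf in order[3:]:
        best_len, best_edge = None, None
        for edge in t.edges():
            t.insert_leaf(leaf, edge)
            ln = _fitch_steps(t, masks)
            t.remove_leaf(leaf)
            if best_len is None or ln < best_len:
                best_len, best_edge = ln, edge
        t.insert_leaf(leaf, best_edge)
    return t, _fitch_steps(t, masks)


def _spr_neighbors(t: _Tree):
    """Yield all trees one subtree-prune-regraft move away."""
    for u, v in [(a, b) for a in t.adj for b in t.adj[a]]:
        # prune the subtree on the v side of edge (u, v)
        if len(t.adj[u]) == 1:
            continue  # residual would be a single leaf
        work = t.copy()
        work.adj[u].remove(v)
        work.adj[v].remove(u)
        a, b = work.adj.pop(u)  # u had degree 3; suppress it
        work.adj[a][work.adj[a].index(u)] = b
        work.adj[b][work.adj[b].index(u)] = a
        # residual component = the one containing a
        seen = {a}
        stack = [a]
        while stack:
            x = stack.pop()
            for y in work.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        for e0, e1 in [(p, q) for p, q in work.edges() if p in seen and q in seen]:
            if {e0, e1} == {a, b}:
                continue  # reattachment at the original position
            nb = work.copy()
            w = u  # reuse the suppressed node id
            nb.adj[e0][nb.adj[e0].index(e1)] = w
            nb.adj[e1][nb.adj[e1].index(e0)] = w
            nb.adj[w] = [e0, e1, v]
            nb.adj[v].append(w)
            yield nb


def _hill_climb(
    start: _Tree, masks: np.ndarray, max_equal: int = 200
) -> tuple[int, dict[frozenset, _Tree]]:
    """SPR hill-climbing retaining every equally best tree found.

    After no improving move exists, the plateau of equal-length trees is
    explored breadth-first up to ``max_equal`` trees.
    """
    best_len = _fitch_steps(start, masks)
    best: dict[frozenset, _Tree] = {start.bipartitions(): start}
    frontier = [start]
    while frontier:
        tree = frontier.pop()
        for nb in _spr_neighbors(tree):
            ln = _fitch_steps(nb, masks)
            if ln < best_len:
                best_len = ln
                best = {nb.bipartitions(): nb}
                frontier = [nb]
                break
            if ln == best_len and len(best) < max_equal:
                key = nb.bipartitions()
                if key not in best:
                    best[key] = nb
                    frontier.append(nb)
    return best_len, best


def _branch_and_bound(
    matrix: CharacterMatrix, masks: np.ndarray
) -> tuple[int, dict[frozenset, _Tree]]:
    n = matrix.n_taxa
    # initial upper bound from a greedy addition in input order
    _, bound = _greedy_addition(list(range(n)), masks, n)
    best: dict[frozenset, _Tree] = {}
    best_len = bound

    def recurse(t: _Tree, next_leaf: int):
        nonlocal best_len, best
        if next_leaf == n:
            ln = _fitch_steps(t, masks)
            if ln < best_len:
                best_len = ln
                best = {t.bipartitions(): t.copy()}
            elif ln == best_len:
                key = t.bipartitions()
                if key not in best:
                    best[key] = t.copy()
            return
        for edge in list(t.edges()):
            t.insert_leaf(next_leaf, edge)
            if _fitch_steps(t, masks) <= best_len:  # adding taxa never shortens
                recurse(t, next_leaf + 1)
            t.remove_leaf(next_leaf)

    recurse(_Tree.star3(0, 1, 2, n), 3)
    return best_len, best


def search_mpt(
    matrix: CharacterMatrix,
    mode: str = "auto",
    seed: int = 0,
    n_starts: int = 10,
    exact_limit: int = 12,
) -> SearchResult:
    """Find the most-parsimonious tree(s) for a character matrix.

    ``mode='exact'`` (default for <= ``exact_limit`` taxa) runs a
    branch-and-bound over taxon-addition order, guaranteed to return the
    complete MPT set.  ``mode='heuristic'`` runs ``n_starts``
    random-addition sequences each followed by SPR hill-climbing,
    retaining all equally best trees; reproducible for a given ``seed``.
    """
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa for a tree search")
    if mode not in ("auto", "exact", "heuristic"):
        raise ValueError(f"unknown mode {mode!r}")
    masks = _encode_matrix(matrix)
    use_exact = mode == "exact" or (mode == "auto" and matrix.n_taxa <= exact_limit)
    if use_exact:
        best_len, best = _branch_and_bound(matrix, masks)
        method, reps = "exact", 0
    else:
        rng = np.random.default_rng([seed % (2**31), 811])
        best_len, best = None, {}
        for _ in range(n_starts):
            order = list(rng.permutation(matrix.n_taxa))
            start, _ = _greedy_addition(order, masks, matrix.n_taxa)
            ln, trees = _hill_climb(start, masks)
            if best_len is None or ln < best_len:
                best_len, best = ln, dict(trees)
            elif ln == best_len:
                best.update(trees)
        method, reps = "heuristic", n_starts
    ns = dendropy.TaxonNamespace(matrix.taxa)
    mpts = [
        _to_dendropy(t, matrix.taxa, ns)
        for _, t in sorted(best.items(), key=lambda kv: sorted(map(sorted, kv[0])))
    ]
    score = ensemble_indices(mpts[0], matrix)
    return SearchResult(mpts=mpts, score=score, method=method, replicates=reps)


def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """The tree displaying exactly the splits common to every input tree."""
    if not trees:
        raise ValueError("no trees given")
    leaf_sets = [
        sorted((lf.taxon.label if lf.taxon else lf.label) for lf in t.leaf_node_iter())
        for t in trees
    ]
    if any(ls != leaf_sets[0] for ls in leaf_sets[1:]):
        raise ValueError("trees have different leaf sets")
    taxa = leaf_sets[0]
    internal = [_from_dendropy(t, taxa) for t in trees]
    common = internal[0].bipartitions()
    for t in internal[1:]:
        common = common & t.bipartitions()
    return _to_dendropy(_tree_from_splits(taxa, common), taxa)


def bootstrap(
    matrix: CharacterMatrix,
    replicates: int = 1000,
    seed: int = 0,
    n_starts: int = 2,
) -> dict[frozenset, float]:
    """Nonparametric bootstrap clade support.

    Per replicate: resample characters with replacement (same count),
    search heuristically (``n_starts`` random-addition starts + SPR),
    take the strict consensus of the replicate's best trees, and count
    its splits.  Support for a clade (frozenset of taxon labels, the
    side not containing the first taxon) is the percentage of replicates
    whose consensus displays it.
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng([seed % (2**31), 733])
    masks = _encode_matrix(matrix)
    n = matrix.n_taxa
    counts: dict[frozenset, int] = {}
    for _ in range(replicates):
        cols = rng.integers(0, matrix.n_chars, size=matrix.n_chars)
        rep_masks = masks[:, cols]
        best_len, best = None, {}
        for _ in range(n_starts):
            order = list(rng.permutation(n))
            start, _ = _greedy_addition(order, rep_masks, n)
            ln, trees = _hill_climb(start, rep_masks, max_equal=50)
            if best_len is None or ln < best_len:
                best_len, best = ln, dict(trees)
            elif ln == best_len:
                best.update(trees)
        consensus_splits = frozenset.intersection(*best.keys())
        for split in consensus_splits:
            counts[split] = counts.get(split, 0) + 1
    return {
        frozenset(matrix.taxa[i] for i in split): 100.0 * c / replicates
        for split, c in counts.items()
    }


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class ParsimonyModel:
    """Maximum-parsimony analysis of a character matrix as a fittable model."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix

    def fit(self, mode: str = "auto", seed: int = 0, n_starts: int = 10) -> "ParsimonyResults":
        res = search_mpt(self.matrix, mode=mode, seed=seed, n_starts=n_starts)
        return ParsimonyResults(self, res)


class ParsimonyResults:
    """Fitted parsimony search: MPT set, score, consensus and bootstrap."""

    def __init__(self, model: ParsimonyModel, search: SearchResult):
        self.model = model
        self.search = search
        self._bootstrap: dict[frozenset, float] | None = None

    @property
    def mpts(self) -> list[PhyloTree]:
        return self.search.mpts

    @property
    def score(self) -> ParsimonyScore:
        return self.search.score

    def consensus(self) -> PhyloTree:
        return strict_consensus(self.search.mpts)

    def bootstrap_support(
        self, replicates: int = 1000, seed: int = 0
    ) -> dict[frozenset, float]:
        self._bootstrap = bootstrap(self.model.matrix, replicates=replicates, seed=seed)
        return self._bootstrap

    def annotated_consensus(self) -> PhyloTree:
        """Strict consensus with bootstrap supports as internal labels
        (requires :meth:`bootstrap_support` to have been run)."""
        cons = self.consensus()
        if self._bootstrap is None:
            return cons
        for node in cons.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            clade = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            taxa = self.model.matrix.taxa
            key = clade if taxa[0] not in clade else frozenset(taxa) - clade
            if key in self._bootstrap:
                node.label = f"{self._bootstrap[key]:.0f}"
        return cons

    def summary(self) -> str:
        s = self.search
        lines = [
            "Maximum Parsimony Search",
            "=" * 54,
            f"taxa: {self.model.matrix.n_taxa}   characters: {self.model.matrix.n_chars}"
            f"   method: {s.method}"
            + (f" ({s.replicates} random-addition starts)" if s.replicates else ""),
            f"most parsimonious trees: {s.n_trees}",
            str(s.score),
        ]
        if self._bootstrap:
            lines.append("-" * 54)
            lines.append("bootstrap support (clades >= 50%):")
            for clade, pct in sorted(self._bootstrap.items(), key=lambda kv: -kv[1]):
                if pct >= 50:
                    lines.append(f"  {pct:5.1f}%  {{{', '.join(sorted(clade))}}}")
        return "\n".join(lines)
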