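"""Distance matrices from score vectors and UPGMA tree building.

Shape or principal-component score vectors (per specimen or per group
mean) are turned into Euclidean or squared-Euclidean distance matrices
and clustered with UPGMA (unweighted pair-group method with arithmetic
mean), yielding an ultrametric tree whose node heights are half the
merge distances.  Because UPGMA roots by ultrametricity rather than by
an outgroup, :func:`outgroup_orient` only *annotates* whether a chosen
outgroup sits basally; it never re-roots.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import PhyloTree

__all__ = [
    "DistanceMatrix",
    "score_distances",
    "upgma",
    "outgroup_orient",
    "OutgroupReport",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with labels; zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = (v + v.T) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def score_distances(
    scores: pd.DataFrame | np.ndarray,
    metric: str = "euclidean",
    by_group: bool = False,
    labels: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise distances between score vectors.

    ``scores`` is specimens x variables; a DataFrame may carry a
    ``group`` column, used when ``by_group=True`` to take distances
    between group mean vectors instead of specimens.
    """
    if metric not in ("euclidean", "squared_euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    if isinstance(scores, pd.DataFrame):
        df = scores
        if by_group:
            if "group" not in df.columns:
                raise ValueError("by_group requires a 'group' column")
            df = df.groupby("group").mean(numeric_only=True)
        else:
            df = df.drop(columns=["group"], errors="ignore")
        X = df.to_numpy(dtype=float)
        lab = [str(i) for i in df.index]
    else:
        X = np.asarray(scores, dtype=float)
        if X.ndim != 2:
            raise ValueError("scores must be 2-D (specimens x variables)")
        lab = labels if labels is not None else [str(i) for i in range(X.shape[0])]
        if len(lab) != X.shape[0]:
            raise ValueError("labels length mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite score values")
    d = squareform(pdist(X, metric="euclidean"))
    if metric == "squared_euclidean":
        d = d**2
    return DistanceMatrix(labels=lab, values=d, metric_name=metric)


def upgma(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration into an ultrametric tree.

    Each merge joins the pair of clusters at minimal average distance;
    the new node's height is half that distance.  Ties are broken by the
    lexicographically smallest pair of cluster labels (a cluster is
    labelled by its alphabetically first member), so the result is
    deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if np.any(~np.isfinite(dm.values)):
        raise ValueError("NaN/inf distances")
    ns = dendropy.TaxonNamespace(dm.labels)
    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        node.height = 0.0
        nodes[label] = node
    # active clusters: key = alphabetically first member label
    members: dict[str, list[str]] = {l: [l] for l in dm.labels}
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = dm.values[i, j]

    while len(members) > 1:
        best = None
        for key, d in dist.items():
            a, b = sorted(key)
            cand = (d, a, b)
            if best is None or cand < best:
                best = cand
        d, a, b = best
        parent = dendropy.Node()
        parent.height = d / 2.0
        for child_key in (a, b):
            child = nodes.pop(child_key)
            child.edge.length = parent.height - child.height
            parent.add_child(child)
        na, nb = len(members[a]), len(members[b])
        merged = members.pop(a) + members.pop(b)
        new_key = min(a, b)
        for other in members:
            dist[frozenset((new_key, other))] = (
                na * dist.pop(frozenset((a, other)))
                + nb * dist.pop(frozenset((b, other)))
            ) / (na + nb)
        dist.pop(frozenset((a, b)))
        members[new_key] = merged
        nodes[new_key] = parent

    root = next(iter(nodes.values()))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


@dataclass
class OutgroupReport:
    """Whether a designated outgroup sits basally in a rooted tree."""

    outgroup: frozenset
    monophyletic_basal: bool
    offending_clade: frozenset | None = None

    def __str__(self) -> str:
        if self.monophyletic_basal:
            return f"outgroup {sorted(self.outgroup)} is monophyletic and basal"
        return (
            f"outgroup {sorted(self.outgroup)} is NOT basal; smallest containing "
            f"clade is {sorted(self.offending_clade)}"
        )


def outgroup_orient(tree: PhyloTree, outgroup_labels) -> PhyloTree:
    """Annotate a rooted (UPGMA) tree with the basal status of an outgroup.

    The outgroup is *monophyletic-basal* when it is exactly the leaf set
    of one child of the root.  No re-rooting is performed: UPGMA trees
    are rooted by their ultrametricity, so the outgroup only provides a
    check of polarity.  The report is attached as ``tree.outgroup_report``
    and the outgroup's smallest containing clade is labelled.
    """
    og = frozenset(
        lbl.label if hasattr(lbl, "label") else str(lbl) for lbl in outgroup_labels
    )
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = og - leaf_labels
    if unknown:
        raise ValueError(f"unknown outgroup label(s): {sorted(unknown)}")
    root_children = tree.seed_node.child_nodes()
    child_clades = [
        frozenset(lf.taxon.label for lf in c.leaf_iter()) for c in root_children
    ]
    basal = og in child_clades
    if basal:
        report = OutgroupReport(outgroup=og, monophyletic_basal=True)
        node = root_children[child_clades.index(og)]
    else:
        # smallest clade containing the whole outgroup
        node = tree.mrca(taxon_labels=sorted(og))
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        report = OutgroupReport(
            outgroup=og, monophyletic_basal=False, offending_clade=clade
        )
    node.label = "outgroup" if basal else "outgroup-mrca"
    tree.outgroup_report = report
    return tree
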