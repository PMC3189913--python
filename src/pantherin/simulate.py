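"""Synthetic data generators with the statistical structure the analyses assume.

Three generators feed the three analysis tracks:

* :func:`simulate_landmarks` — multi-species landmark samples: isotropic
  Gaussian noise around distinct group mean shapes, then a random
  similarity transform (rotation, scale, translation) per specimen, so
  the Procrustes step has real work to do.
* :func:`simulate_characters` — unordered (binary) characters evolved on
  a known tree: each character marks one internal edge's clade with a
  derived state; with probability ``homoplasy_rate`` one taxon outside
  the clade convergently acquires it.
* :func:`simulate_measurements` — craniodental measurement tables with
  group-specific means, a shared per-specimen lognormal size factor
  (allometry) and lognormal variable noise; values are positive by
  construction.

Each generator draws from its own named substream of the single
``SimSpec.seed``, so adding one generator never perturbs another's
output; identical specs give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .io import CharacterMatrix, LandmarkConfiguration, PhyloTree

__all__ = [
    "SimSpec",
    "GroupSpec",
    "simulate_landmarks",
    "simulate_characters",
    "simulate_measurements",
]

# fixed substream tags: landmark / character / measurement draws are independent
_STREAMS = {"landmarks": 101, "characters": 211, "measurements": 307}


@dataclass
class GroupSpec:
    """One group (species/subspecies) in a simulation."""

    label: str
    n: int
    mean_shape: np.ndarray | None = None  # (k, 2) for landmark sims
    mean_vector: dict[str, float] | None = None  # variable -> mm, for tables
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError(f"group {self.label!r}: noise_sd must be > 0")
        if self.mean_shape is not None:
            self.mean_shape = np.asarray(self.mean_shape, dtype=float)


@dataclass
class SimSpec:
    """Full specification of a synthetic dataset; a pure function input."""

    seed: int
    groups: list[GroupSpec] = field(default_factory=list)
    tree: PhyloTree | None = None
    n_chars: int = 0
    homoplasy_rate: float = 0.0
    cv: float = 0.05  # lognormal coefficient of variation of measurements
    size_sd: float = 0.1  # sd of the shared per-specimen log size factor
    ensure_coverage: bool = False  # cycle characters over internal edges first

    def __post_init__(self) -> None:
        if not 0.0 <= self.homoplasy_rate <= 1.0:
            raise ValueError("homoplasy_rate must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[stream]])


def simulate_landmarks(spec: SimSpec) -> list[LandmarkConfiguration]:
    """Landmark configurations around group mean shapes.

    Each specimen is its group's mean shape plus i.i.d. isotropic
    Gaussian noise (sd ``noise_sd`` per coordinate), then randomly
    rotated, scaled by a factor in [0.5, 2] and translated — the
    nuisance similarity transform that Procrustes superimposition must
    remove.
    """
    shapes = [g.mean_shape for g in spec.groups]
    if any(s is None for s in shapes):
        raise ValueError("every group needs a mean_shape")
    ks = {s.shape[0] for s in shapes}
    if len(ks) != 1:
        raise ValueError(f"mean shapes disagree on landmark count: {sorted(ks)}")
    rng = spec.rng("landmarks")
    configs: list[LandmarkConfiguration] = []
    for g in spec.groups:
        for i in range(g.n):
            coords = g.mean_shape + rng.normal(0.0, g.noise_sd, g.mean_shape.shape)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            scale = rng.uniform(0.5, 2.0)
            shift = rng.uniform(-10.0, 10.0, size=2)
            coords = scale * (coords @ rot.T) + shift
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{g.label}_{i}", coords=coords, group=g.label
                )
            )
    return configs


def _internal_edge_clades(tree: PhyloTree, taxa: list[str]) -> list[frozenset[int]]:
    """Nontrivial clades below each internal edge of a rooted/unrooted tree."""
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    clades = []
    seen = set()  # dedup as unrooted splits (a clade equals its complement)
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(index[lf.taxon.label] for lf in node.leaf_iter())
        key = below if 0 not in below else frozenset(range(n)) - below
        if 1 < len(below) < n - 1 and key not in seen:
            seen.add(key)
            clades.append(below)
    return clades


def simulate_characters(spec: SimSpec) -> CharacterMatrix:
    """Binary characters evolved on ``spec.tree`` with tunable homoplasy.

    Each character picks an internal edge (uniformly, or cycling over
    all internal edges first when ``ensure_coverage`` is set so that
    every edge is marked) and assigns state ``1`` to the clade below it
    — a perfectly tree-compatible character.  With probability
    ``homoplasy_rate`` one uniformly chosen taxon outside the clade also
    gets state ``1``, forcing one extra (convergent) step.
    """
    if spec.tree is None:
        raise ValueError("spec.tree is required")
    taxa = sorted(lf.taxon.label for lf in spec.tree.leaf_node_iter())
    if len(taxa) < 4:
        raise ValueError("generating tree needs at least 4 leaves")
    if spec.n_chars < 1:
        raise ValueError("n_chars must be >= 1")
    clades = _internal_edge_clades(spec.tree, taxa)
    if not clades:
        raise ValueError("tree has no internal edges (star tree)")
    clades = sorted(clades, key=sorted)
    rng = spec.rng("characters")
    n = len(taxa)
    states = np.full((n, spec.n_chars), "0", dtype="<U1")
    for j in range(spec.n_chars):
        if spec.ensure_coverage and j < 2 * len(clades):
            clade = clades[j % len(clades)]
        else:
            clade = clades[rng.integers(0, len(clades))]
        for i in clade:
            states[i, j] = "1"
        if rng.random() < spec.homoplasy_rate:
            outside = sorted(set(range(n)) - clade)
            states[outside[rng.integers(0, len(outside))], j] = "1"
    return CharacterMatrix(taxa=taxa, states=states)


def simulate_measurements(spec: SimSpec) -> pd.DataFrame:
    """Craniodental measurement tables with allometric lognormal noise.

    Per specimen: a shared size factor ``exp(N(0, size_sd))`` multiplies
    every variable (isometric allometry), and each variable additionally
    gets independent lognormal noise ``exp(N(0, cv))``.  Group mean
    vectors must share variable names and include ``CBL``.
    """
    vecs = [g.mean_vector for g in spec.groups]
    if any(v is None for v in vecs):
        raise ValueError("every group needs a mean_vector")
    names = list(vecs[0])
    if any(list(v) != names for v in vecs[1:]):
        raise ValueError("groups disagree on variable names")
    if "CBL" not in names:
        raise ValueError("mean vectors must include CBL")
    if any(val <= 0 for v in vecs for val in v.values()):
        raise ValueError("mean measurements must be positive")
    rng = spec.rng("measurements")
    rows: list[dict[str, Any]] = []
    for g in spec.groups:
        means = np.array([g.mean_vector[v] for v in names])
        for i in range(g.n):
            size = np.exp(rng.normal(0.0, spec.size_sd))
            noise = np.exp(rng.normal(0.0, spec.cv, size=len(names)))
            values = means * size * noise
            row = {"specimen_id": f"{g.label}_{i}", "group": g.label}
            row.update(dict(zip(names, values)))
            rows.append(row)
    return pd.DataFrame(rows).set_index("specimen_id")
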