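"""Procrustes superimposition and thin-plate-spline shape decomposition.

The workflow mirrors the standard 2-D geometric-morphometric toolchain:

1. :func:`generalized_procrustes` removes position, scale and orientation,
   leaving shape coordinates around a consensus (mean) configuration.
2. :func:`tps_fit` interpolates one configuration onto another with the
   thin-plate spline, the unique interpolant minimizing the bending
   energy — the integral over the plane of the squared second derivatives.
3. :func:`partial_warps` decomposes each specimen's deviation from the
   consensus into non-uniform components (projections onto the principal
   warps, i.e. eigenvectors of the consensus bending-energy matrix) plus a
   two-dimensional uniform (affine) component.
4. :func:`relative_warps` performs the relative-warps analysis: at
   ``alpha = 0`` it is exactly a principal components analysis of the
   stacked partial-warp + uniform scores.

A convenience :class:`RelativeWarpsModel` bundles steps 1-4 behind a
statsmodels-style ``Model.fit() -> Results`` interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .io import LandmarkConfiguration

__all__ = [
    "ProcrustesFit",
    "TpsSpline",
    "WarpDecomposition",
    "generalized_procrustes",
    "tps_fit",
    "bending_energy",
    "bending_energy_matrix",
    "partial_warps",
    "relative_warps",
    "RelativeWarpsModel",
    "RelativeWarpsResults",
]


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes superimposition.

    ``aligned`` holds unit-centroid-size, centred, optimally rotated
    copies of the inputs; ``mean_shape`` is their arithmetic mean.
    """

    aligned: np.ndarray  # (n, k, 2)
    mean_shape: np.ndarray  # (k, 2)
    iterations: int
    residual_change: float
    specimen_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def procrustes_distances(self) -> np.ndarray:
        """Root-sum-square distance of each specimen from the consensus."""
        d = self.aligned - self.mean_shape
        return np.sqrt((d**2).sum(axis=(1, 2)))


def _center_scale(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    size = np.sqrt((c**2).sum())
    if size <= 0:
        raise ValueError("configuration has zero centroid size")
    return c / size


def _rotation_to(target: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Least-squares rotation (no reflection) mapping ``source`` onto ``target``."""
    u, _, vt = np.linalg.svd(target.T @ source)
    d = np.sign(np.linalg.det(u @ vt))
    # force det(+1): anatomical lateral views have fixed handedness
    corr = np.diag([1.0, d])
    return (u @ corr @ vt).T


def generalized_procrustes(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesFit:
    """Iteratively superimpose configurations (centre, unit size, rotate).

    Each round rotates every configuration onto the current consensus and
    re-estimates the consensus, until the consensus moves less than
    ``tol``.  Reflections are never used.  For identifiability the final
    solution is rotated so the consensus optimally matches the first
    specimen's (centred, scaled) orientation.
    """
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
        ids = [str(i) for i in range(arr.shape[0])]
        groups = [""] * arr.shape[0]
    else:
        ks = {c.k for c in configs}
        if len(ks) > 1:
            raise ValueError(f"landmark count mismatch: {sorted(ks)}")
        arr = np.stack([c.coords for c in configs])
        ids = [c.specimen_id for c in configs]
        groups = [c.group for c in configs]
    n, k = arr.shape[0], arr.shape[1]
    if n < 2:
        raise ValueError("need at least 2 configurations")
    if k < 3:
        raise ValueError("need at least 3 landmarks")

    aligned = np.stack([_center_scale(x) for x in arr])
    first = aligned[0].copy()
    consensus = first
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ _rotation_to(consensus, aligned[i])
        new_consensus = aligned.mean(axis=0)
        change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if change < tol:
            break
    # orient the whole solution against the first specimen
    rot = _rotation_to(first, consensus)
    consensus = consensus @ rot
    aligned = aligned @ rot
    return ProcrustesFit(
        aligned=aligned,
        mean_shape=consensus,
        iterations=it,
        residual_change=change,
        specimen_ids=ids,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Thin-plate spline
# ---------------------------------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log(r^2), with U(0) = 0 (the limit value)."""
    out = np.zeros_like(r2, dtype=float)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return _tps_kernel((diff**2).sum(axis=-1))


@dataclass
class TpsSpline:
    """A 2-D thin-plate-spline interpolant fixed at the landmarks.

    The map is ``f(p) = affine(p) + sum_i w_i U(|p - P_i|)`` applied
    separately to the x and y output coordinates, where ``U(r) =
    r^2 log(r^2)`` is the fundamental solution of the biharmonic
    equation.  The weights satisfy the side conditions ``sum w_i = 0``
    and ``sum w_i P_i = 0``, which make the bending energy finite.
    """

    reference: np.ndarray  # (k, 2)
    target: np.ndarray  # (k, 2)
    weights: np.ndarray  # (k, 2) — columns are x- and y-output weights
    affine: np.ndarray  # (3, 2) — rows: constant, x, y coefficients

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        K = _kernel_matrix(pts, self.reference)
        P = np.column_stack([np.ones(len(pts)), pts])
        return K @ self.weights + P @ self.affine


def tps_fit(reference: np.ndarray, target: np.ndarray) -> TpsSpline:
    """Fit the thin-plate spline carrying ``reference`` onto ``target``.

    Exact at the landmarks and minimal in bending energy among all
    interpolants.  A collinear reference makes the bordered kernel system
    singular and is rejected.
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference and target must be matching (k, 2) arrays")
    k = ref.shape[0]
    if k < 3:
        raise ValueError("need at least 3 landmarks")
    K = _kernel_matrix(ref, ref)
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    if np.linalg.matrix_rank(P) < 3:
        raise ValueError(
            "reference landmarks are collinear (singular TPS system); "
            "jitter the points or review the landmark scheme"
        )
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system — reference landmarks may be (nearly) "
            "collinear or duplicated; jitter the points or review the "
            "landmark scheme"
        ) from exc
    return TpsSpline(reference=ref, target=tgt, weights=sol[:k], affine=sol[k:])


def bending_energy(spline: TpsSpline) -> float:
    """Bending energy of a spline: the integral over the plane of the
    squared second derivatives, summed over the x and y maps.

    For the thin-plate spline this integral has the closed quadratic form
    ``16*pi * trace(W^T K W)`` in the weights (the factor comes from
    ``laplacian^2 U = 16*pi*delta`` for ``U = r^2 log r^2``), which is
    exact — no numerical integration is involved.  It is zero exactly
    when the map is affine.
    """
    K = _kernel_matrix(spline.reference, spline.reference)
    q = float(np.einsum("ia,ij,ja->", spline.weights, K, spline.weights))
    # tiny negative round-off is clipped; the form is PSD on the side-condition subspace
    return max(16.0 * np.pi * q, 0.0)


# ---------------------------------------------------------------------------
# Partial and relative warps
# ---------------------------------------------------------------------------


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """The k x k bending-energy matrix of a reference configuration.

    Upper-left block of the inverse bordered kernel matrix; positive
    semi-definite with a 3-dimensional null space (the affine functions
    1, x, y), so exactly 3 zero eigenvalues.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    K = _kernel_matrix(ref, ref)
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    Linv = np.linalg.inv(L)
    B = Linv[:k, :k]
    return (B + B.T) / 2.0


@dataclass
class WarpDecomposition:
    """Shape variation decomposed over principal warps plus the uniform part.

    ``scores`` stacks, per specimen, the 2(k-3) partial-warp scores and
    the 2 uniform scores; relative-warp fields are filled by
    :func:`relative_warps`.
    """

    reference: np.ndarray  # (k, 2) consensus
    bending_energy: np.ndarray  # (k, k)
    principal_warps: np.ndarray  # (k, k-3), orthonormal columns
    principal_eigenvalues: np.ndarray  # (k-3,) bending energies, ascending
    partial_warp_scores: np.ndarray  # (n, 2(k-3))
    uniform_scores: np.ndarray  # (n, 2)
    uniform_basis: np.ndarray  # (2k, 2) in stacked [x..., y...] coordinates
    specimen_ids: list[str]
    groups: list[str]
    alpha: float = 0.0
    relative_warp_scores: np.ndarray | None = None
    relative_warp_loadings: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    include_uniform: bool = True

    @property
    def scores(self) -> np.ndarray:
        """Partial-warp scores with the uniform pair appended (n, 2k-4)."""
        return np.hstack([self.partial_warp_scores, self.uniform_scores])


def partial_warps(fit: ProcrustesFit, zero_tol: float = 1e-8) -> WarpDecomposition:
    """Project each specimen's deviation from the consensus onto the
    principal warps (non-uniform) and the uniform (affine) component.

    The principal warps are the eigenvectors of the consensus
    bending-energy matrix with nonzero eigenvalue; each contributes an
    (x, y) score pair.  The uniform component is the orthogonal
    complement of the non-uniform subspace within the tangent space at
    the consensus, so partial + uniform scores jointly preserve the full
    tangent-space variation (a Parseval identity checked in the tests).
    """
    k = fit.k
    if k <= 3:
        raise ValueError("k must exceed 3: a triangle has no bending subspace")
    if fit.n < 3:
        raise ValueError("need at least 3 specimens")
    M = fit.mean_shape
    B = bending_energy_matrix(M)
    evals, evecs = np.linalg.eigh(B)
    scale = np.abs(evals).max()
    null_count = int((evals < zero_tol * max(scale, 1.0)).sum())
    if null_count != 3:
        raise ValueError(
            f"bending-energy matrix has {null_count} (near-)zero eigenvalues, "
            "expected exactly 3 — degenerate consensus configuration?"
        )
    pw_vals = evals[3:]
    pw_vecs = evecs[:, 3:]
    # deterministic sign: largest-magnitude entry of each warp positive
    for j in range(pw_vecs.shape[1]):
        i = int(np.argmax(np.abs(pw_vecs[:, j])))
        if pw_vecs[i, j] < 0:
            pw_vecs[:, j] = -pw_vecs[:, j]

    resid = fit.aligned - M  # (n, k, 2)
    rx = resid[:, :, 0]
    ry = resid[:, :, 1]
    # interleave (warp1 x, warp1 y, warp2 x, ...) as tpsRelw does
    px = rx @ pw_vecs  # (n, k-3)
    py = ry @ pw_vecs
    pw_scores = np.empty((fit.n, 2 * pw_vecs.shape[1]))
    pw_scores[:, 0::2] = px
    pw_scores[:, 1::2] = py

    # uniform component: complement of the non-uniform subspace in the
    # tangent space (stacked [x..., y...] coordinates of length 2k)
    ones = np.ones(k)
    t_x = np.concatenate([ones, np.zeros(k)]) / np.sqrt(k)
    t_y = np.concatenate([np.zeros(k), ones]) / np.sqrt(k)
    s_dir = np.concatenate([M[:, 0], M[:, 1]])
    s_dir /= np.linalg.norm(s_dir)
    r_dir = np.concatenate([-M[:, 1], M[:, 0]])
    r_dir /= np.linalg.norm(r_dir)
    non_uniform = np.zeros((2 * k, 2 * pw_vecs.shape[1]))
    non_uniform[:k, 0::2] = pw_vecs
    non_uniform[k:, 1::2] = pw_vecs
    excluded = np.column_stack([t_x, t_y, s_dir, r_dir, non_uniform])
    uni = null_space(excluded.T)
    if uni.shape[1] != 2:
        raise ValueError(
            f"uniform subspace has dimension {uni.shape[1]}, expected 2"
        )
    for j in range(2):
        i = int(np.argmax(np.abs(uni[:, j])))
        if uni[i, j] < 0:
            uni[:, j] = -uni[:, j]
    resid_vec = np.hstack([rx, ry])  # (n, 2k)
    uni_scores = resid_vec @ uni

    return WarpDecomposition(
        reference=M,
        bending_energy=B,
        principal_warps=pw_vecs,
        principal_eigenvalues=pw_vals,
        partial_warp_scores=pw_scores,
        uniform_scores=uni_scores,
        uniform_basis=uni,
        specimen_ids=list(fit.specimen_ids),
        groups=list(fit.groups),
    )


def relative_warps(
    decomp: WarpDecomposition,
    alpha: float = 0.0,
    include_uniform: bool = True,
) -> WarpDecomposition:
    """Relative-warps analysis of a partial-warp decomposition.

    At ``alpha = 0`` (the only exponent used here by default) this is a
    principal components analysis of the covariance matrix of the
    partial-warp scores, with the uniform pair included unless
    ``include_uniform=False``.  Nonzero ``alpha`` re-weights each
    partial-warp pair by ``lambda^(-alpha/2)`` (bending energy lambda),
    emphasising large-scale (alpha > 0) or small-scale (alpha < 0)
    deformation before the PCA.

    Sign convention: the first nonzero loading of each relative warp is
    positive.  Eigenvalues (descending) sum to the trace of the score
    covariance matrix.
    """
    S = decomp.scores if include_uniform else decomp.partial_warp_scores
    n = S.shape[0]
    if n < 3:
        raise ValueError("need at least 3 specimens for a relative-warps analysis")
    if alpha != 0.0:
        w = np.repeat(decomp.principal_eigenvalues ** (-alpha / 2.0), 2)
        if include_uniform:
            w = np.concatenate([w, np.ones(2)])
        S = S * w
    centred = S - S.mean(axis=0)
    cov = (centred.T @ centred) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        nz = np.nonzero(np.abs(evecs[:, j]) > 1e-12)[0]
        if len(nz) and evecs[nz[0], j] < 0:
            evecs[:, j] = -evecs[:, j]
    out = WarpDecomposition(**{**decomp.__dict__})
    out.alpha = alpha
    out.include_uniform = include_uniform
    out.relative_warp_scores = centred @ evecs
    out.relative_warp_loadings = evecs
    out.eigenvalues = evals
    return out


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class RelativeWarpsModel:
    """Relative-warps analysis of a landmark sample, as a fittable model.

    Parameters
    ----------
    configs : sequence of LandmarkConfiguration
        Homologous 2-D landmark sets, one per specimen.
    alpha : float
        Relative-warps exponent; 0 gives a plain PCA of partial-warp
        (plus uniform) scores.
    include_uniform : bool
        Include the uniform (affine) component in the PCA.
    """

    def __init__(self, configs, alpha: float = 0.0, include_uniform: bool = True):
        self.configs = list(configs)
        self.alpha = alpha
        self.include_uniform = include_uniform

    def fit(self, tol: float = 1e-10) -> "RelativeWarpsResults":
        gpa = generalized_procrustes(self.configs, tol=tol)
        decomp = relative_warps(
            partial_warps(gpa), alpha=self.alpha, include_uniform=self.include_uniform
        )
        return RelativeWarpsResults(self, gpa, decomp)


class RelativeWarpsResults:
    """Fitted relative-warps analysis: scores, eigenvalues, diagnostics."""

    def __init__(self, model, procrustes: ProcrustesFit, decomposition: WarpDecomposition):
        self.model = model
        self.procrustes = procrustes
        self.decomposition = decomposition

    @property
    def scores(self) -> pd.DataFrame:
        d = self.decomposition
        cols = [f"RW{i + 1}" for i in range(d.relative_warp_scores.shape[1])]
        df = pd.DataFrame(d.relative_warp_scores, columns=cols, index=d.specimen_ids)
        df.insert(0, "group", d.groups)
        return df

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.decomposition.eigenvalues

    def explained_variance_ratio(self) -> np.ndarray:
        ev = self.eigenvalues
        total = ev.sum()
        return ev / total if total > 0 else ev

    def group_mean_scores(self) -> pd.DataFrame:
        """Mean relative-warp score vector per group label."""
        df = self.scores
        return df.groupby("group").mean(numeric_only=True)

    def summary(self) -> str:
        d = self.decomposition
        ev = self.eigenvalues
        ratio = self.explained_variance_ratio()
        lines = [
            "Relative Warps Analysis",
            "=" * 54,
            f"specimens: {len(d.specimen_ids)}   landmarks: {d.reference.shape[0]}"
            f"   alpha: {d.alpha:g}   uniform included: {d.include_uniform}",
            f"Procrustes iterations: {self.procrustes.iterations}"
            f"   final consensus change: {self.procrustes.residual_change:.3e}",
            "-" * 54,
            f"{'warp':>6} {'eigenvalue':>14} {'% var':>8} {'cum %':>8}",
        ]
        cum = 0.0
        for i, (e, r) in enumerate(zip(ev, ratio)):
            cum += r
            if i >= 10 and r < 0.01:
                lines.append(f"{'...':>6} ({len(ev) - i} smaller warps omitted)")
                break
            lines.append(f"RW{i + 1:<4} {e:>14.6g} {100 * r:>8.2f} {100 * cum:>8.2f}")
        return "\n".join(lines)
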