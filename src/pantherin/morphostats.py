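"""Craniodental ratio profiling, size-adjusted PCA and discriminant analysis.

The classical ("traditional") morphometric toolkit used to compare a
fossil skull against comparative samples of extant big cats:

* :func:`ratio` / :func:`range_compare` — dimensionless craniodental
  proportions (e.g. canine crown height as a fraction of condylobasal
  length, CBL) judged against per-species observed ranges;
* :func:`size_adjusted_pca` — principal components of size-adjusted
  measurements (variables divided by CBL, or log-shape residuals);
* :class:`DiscriminantModel` / :func:`dfa_jackknife` — linear
  discriminant classification by Mahalanobis distance to group
  centroids under a pooled within-group covariance, with jackknifed
  (leave-one-out) accuracy estimation.

Reported ratios use half-up rounding (3 decimals as fractions, 1
decimal as percent); internal arithmetic keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ratio",
    "RangeTable",
    "range_compare",
    "RangeVerdict",
    "size_adjusted_pca",
    "PCAResult",
    "dfa_jackknife",
    "wilks_forward_selection",
    "DiscriminantModel",
    "DiscriminantResults",
]


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ratio(
    numerator: float,
    denominator: float,
    decimals: int | None = None,
    as_percent: bool = False,
) -> float:
    """Quotient of two linear measurements (mm), optionally rounded.

    ``decimals`` applies half-up rounding at the reporting layer (use 3
    for fractions, 1 for percentages); without it the full-precision
    quotient is returned.  ``as_percent`` multiplies by 100 first.
    """
    if not (numerator > 0 and denominator > 0):
        raise ValueError(
            f"measurements must be positive, got {numerator}/{denominator}"
        )
    value = numerator / denominator
    if as_percent:
        value *= 100.0
    if decimals is not None:
        value = _round_half_up(value, decimals)
    return value


@dataclass
class RangeTable:
    """Observed (min, max) of each ratio per comparative group."""

    ranges: dict[str, dict[str, tuple[float, float]]]  # group -> ratio -> (lo, hi)

    def __post_init__(self) -> None:
        for group, by_ratio in self.ranges.items():
            for name, (lo, hi) in by_ratio.items():
                if lo > hi:
                    raise ValueError(
                        f"range min > max for {group}/{name}: ({lo}, {hi})"
                    )

    def groups_with(self, ratio_name: str) -> list[str]:
        return [g for g, r in self.ranges.items() if ratio_name in r]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RangeTable":
        """Build from a long-format frame with columns group, ratio, min, max."""
        out: dict[str, dict[str, tuple[float, float]]] = {}
        for _, row in df.iterrows():
            out.setdefault(str(row["group"]), {})[str(row["ratio"])] = (
                float(row["min"]),
                float(row["max"]),
            )
        return cls(out)


@dataclass(frozen=True)
class RangeVerdict:
    """Placement of one value against one group's observed range."""

    group: str
    verdict: str  # below | within | above
    lower_half: bool = False

    def __str__(self) -> str:
        if self.verdict == "within" and self.lower_half:
            return f"{self.group}: within (lower range)"
        return f"{self.group}: {self.verdict}"


def range_compare(
    value: float, ranges: RangeTable, ratio_name: str
) -> dict[str, RangeVerdict]:
    """Judge a ratio value against every group's observed range.

    Ranges are closed intervals; a value inside but below the midpoint is
    additionally qualified as lying in the group's *lower range*.
    """
    groups = ranges.groups_with(ratio_name)
    if not groups:
        raise ValueError(f"no group carries ratio {ratio_name!r}")
    out = {}
    for g in groups:
        lo, hi = ranges.ranges[g][ratio_name]
        if value < lo:
            out[g] = RangeVerdict(g, "below")
        elif value > hi:
            out[g] = RangeVerdict(g, "above")
        else:
            out[g] = RangeVerdict(g, "within", lower_half=value < (lo + hi) / 2.0)
    return out


# ---------------------------------------------------------------------------
# size-adjusted PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Covariance-matrix PCA of size-adjusted measurements."""

    scores: pd.DataFrame  # specimens x PCs, 'group' column first if known
    loadings: pd.DataFrame  # variables x PCs
    eigenvalues: np.ndarray
    adjustment: str
    dropped: list[str] = field(default_factory=list)  # incomplete specimens

    def explained_variance_ratio(self) -> np.ndarray:
        t = self.eigenvalues.sum()
        return self.eigenvalues / t if t > 0 else self.eigenvalues


def size_adjusted_pca(
    table: pd.DataFrame,
    adjustment: str = "ratio_cbl",
    cbl_column: str = "CBL",
) -> PCAResult:
    """PCA of craniodental measurements after removing isometric size.

    ``ratio_cbl`` divides every other variable by condylobasal length
    (the conventional craniodental proportion variables); ``log_shape``
    subtracts each
    specimen's mean log-measurement from the log of every variable
    (Mosimann log-shape variables).  Rows with any missing value among
    the used variables are dropped and recorded in ``dropped``.
    Eigenvalues are those of the covariance matrix of the adjusted
    variables and sum to its trace.
    """
    if adjustment not in ("ratio_cbl", "log_shape"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    df = table.copy()
    group = df["group"] if "group" in df.columns else None
    df = df.drop(columns=["group"], errors="ignore")
    num = df.select_dtypes(include=[np.number])
    if adjustment == "ratio_cbl":
        if cbl_column not in num.columns:
            raise ValueError(f"adjustment 'ratio_cbl' needs a {cbl_column!r} column")
        vars_ = [c for c in num.columns if c != cbl_column]
        adjusted = num[vars_].div(num[cbl_column], axis=0)
    else:
        logged = np.log(num)
        adjusted = logged.sub(logged.mean(axis=1), axis=0)
    complete = adjusted.dropna()
    dropped = [str(i) for i in adjusted.index.difference(complete.index)]
    if complete.shape[0] < 3 or complete.shape[1] < 2:
        raise ValueError(
            f"need >=3 complete specimens and >=2 variables, have "
            f"{complete.shape[0]} x {complete.shape[1]}"
        )
    X = complete.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        nz = np.nonzero(np.abs(evecs[:, j]) > 1e-12)[0]
        if len(nz) and evecs[nz[0], j] < 0:
            evecs[:, j] = -evecs[:, j]
    pcs = [f"PC{i + 1}" for i in range(evecs.shape[1])]
    scores = pd.DataFrame(Xc @ evecs, index=complete.index, columns=pcs)
    if group is not None:
        scores.insert(0, "group", group.reindex(complete.index))
    loadings = pd.DataFrame(evecs, index=complete.columns, columns=pcs)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=evals,
        adjustment=adjustment,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# linear discriminant classification
# ---------------------------------------------------------------------------


class DiscriminantModel:
    """Linear discriminant classification of grouped measurement vectors.

    Specimens are assigned to the group whose centroid is nearest in
    Mahalanobis distance under the pooled within-group covariance.  When
    any group has fewer specimens than ``variables + 2`` the pooled
    covariance is shrunk toward its diagonal,
    ``S* = (1 - gamma) S + gamma diag(S)``, to keep it invertible.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        group_column: str = "group",
        shrinkage: float | None = None,
    ):
        if group_column not in data.columns:
            raise ValueError(f"missing group column {group_column!r}")
        self.groups = data[group_column].astype(str)
        self.X = data.drop(columns=[group_column]).select_dtypes(include=[np.number])
        if self.X.isna().any().any():
            raise ValueError("missing values in discriminant variables")
        counts = self.groups.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 groups")
        if (counts < 3).any():
            small = counts[counts < 3].index.tolist()
            raise ValueError(f"groups with fewer than 3 members: {small}")
        self.shrinkage = shrinkage

    def fit(self) -> "DiscriminantResults":
        gamma = self._resolve_shrinkage()
        centroids, cov_inv = self._train(self.X, self.groups, gamma)
        return DiscriminantResults(self, centroids, cov_inv, gamma)

    def _resolve_shrinkage(self) -> float:
        if self.shrinkage is not None:
            return float(self.shrinkage)
        p = self.X.shape[1]
        counts = self.groups.value_counts()
        return 0.25 if (counts < p + 2).any() else 0.0

    @staticmethod
    def _train(X: pd.DataFrame, groups: pd.Series, gamma: float):
        labels = sorted(groups.unique())
        arr = X.to_numpy(dtype=float)
        p = arr.shape[1]
        centroids = {}
        pooled = np.zeros((p, p))
        dof = 0
        for g in labels:
            sub = arr[(groups == g).to_numpy()]
            mu = sub.mean(axis=0)
            centroids[g] = mu
            dev = sub - mu
            pooled += dev.T @ dev
            dof += len(sub) - 1
        pooled /= dof
        if gamma > 0:
            pooled = (1 - gamma) * pooled + gamma * np.diag(np.diag(pooled))
        sign, logdet = np.linalg.slogdet(pooled)
        if sign <= 0 or not np.isfinite(logdet):
            raise ValueError(
                "pooled within-group covariance is singular; set a positive "
                "shrinkage (e.g. DiscriminantModel(..., shrinkage=0.25))"
            )
        return centroids, np.linalg.inv(pooled)


class DiscriminantResults:
    """Fitted discriminant: classification and jackknifed accuracy."""

    def __init__(self, model: DiscriminantModel, centroids, cov_inv, gamma: float):
        self.model = model
        self.centroids = centroids
        self.cov_inv = cov_inv
        self.gamma = gamma

    def mahalanobis(self, x: np.ndarray) -> dict[str, float]:
        return {
            g: float(np.sqrt((x - mu) @ self.cov_inv @ (x - mu)))
            for g, mu in self.centroids.items()
        }

    def classify(self, x) -> str:
        x = np.asarray(x, dtype=float).ravel()
        d = self.mahalanobis(x)
        return min(sorted(d), key=d.get)

    def loo_classifications(self) -> pd.Series:
        """Leave-one-out assignment for every training specimen.

        The entire fit — centroids *and* pooled covariance — is repeated
        with the specimen withheld, so the estimate is honestly jackknifed.
        """
        X, groups = self.model.X, self.model.groups
        out = {}
        for idx in X.index:
            keep = X.index != idx
            centroids, cov_inv = DiscriminantModel._train(
                X.loc[keep], groups.loc[keep], self.gamma
            )
            x = X.loc[idx].to_numpy(dtype=float)
            d = {
                g: float((x - mu) @ cov_inv @ (x - mu))
                for g, mu in centroids.items()
            }
            out[idx] = min(sorted(d), key=d.get)
        return pd.Series(out, name="loo_class")

    def loo_accuracy(self) -> pd.Series:
        """Per-group leave-one-out accuracy plus an 'overall' entry."""
        pred = self.loo_classifications()
        truth = self.model.groups
        acc = {}
        for g in sorted(truth.unique()):
            mask = truth == g
            acc[g] = float((pred[mask.index[mask]] == g).mean())
        acc["overall"] = float((pred == truth).mean())
        return pd.Series(acc, name="loo_accuracy")

    def summary(self) -> str:
        acc = self.loo_accuracy()
        lines = [
            "Linear Discriminant Classification",
            "=" * 54,
            f"groups: {len(self.centroids)}   variables: {self.model.X.shape[1]}"
            f"   specimens: {len(self.model.X)}   shrinkage: {self.gamma:g}",
            "-" * 54,
            "jackknifed (leave-one-out) accuracy:",
        ]
        for g, a in acc.items():
            lines.append(f"  {g:<20} {100 * a:6.1f}%")
        return "\n".join(lines)


def wilks_forward_selection(
    data: pd.DataFrame,
    group_column: str = "group",
    alpha: float = 0.05,
) -> list[str]:
    """Greedy forward variable selection on Wilks' lambda.

    Starting from no variables, repeatedly add the variable that most
    reduces Wilks' lambda (|W| / |W + B|, within over total scatter),
    as long as its partial F-to-enter is significant at ``alpha``.
    A deterministic stand-in for classical stepwise discriminant
    selection; ties favour the earlier column.
    """
    from scipy import stats as _stats

    groups = data[group_column].astype(str)
    X = data.drop(columns=[group_column]).select_dtypes(include=[np.number])
    labels = sorted(groups.unique())
    g = len(labels)
    n = len(X)
    if g < 2:
        raise ValueError("need at least 2 groups")

    def wilks(cols: list[str]) -> float:
        sub = X[cols].to_numpy(dtype=float)
        grand = sub.mean(axis=0)
        T = (sub - grand).T @ (sub - grand)
        W = np.zeros_like(T)
        for lab in labels:
            part = sub[(groups == lab).to_numpy()]
            dev = part - part.mean(axis=0)
            W += dev.T @ dev
        det_t = np.linalg.det(T)
        if det_t <= 0:
            return 1.0
        return float(np.linalg.det(W) / det_t)

    selected: list[str] = []
    lam = 1.0
    while True:
        remaining = [c for c in X.columns if c not in selected]
        if not remaining:
            break
        cand = [(wilks(selected + [c]), c) for c in remaining]
        new_lam, best = min(cand, key=lambda t: (t[0], list(X.columns).index(t[1])))
        p = len(selected)
        dof2 = n - g - p
        if dof2 <= 0 or new_lam <= 0:
            break
        F = (dof2 / (g - 1)) * (lam / new_lam - 1.0)
        p_value = float(_stats.f.sf(F, g - 1, dof2))
        if p_value >= alpha:
            break
        selected.append(best)
        lam = new_lam
    return selected


def dfa_jackknife(
    data: pd.DataFrame,
    group_column: str = "group",
    holdout_label: str | None = None,
    shrinkage: float | None = None,
    select: bool = False,
    select_alpha: float = 0.05,
):
    """Jackknifed discriminant classification, optionally with a holdout.

    ``holdout_label`` names a row (e.g. a fossil of debated affinity)
    that is excluded from training and classified against the remaining
    groups.  ``select=True`` first reduces the variables by greedy
    forward selection on Wilks' lambda (threshold ``select_alpha``).
    Returns ``(holdout_assignment_or_None, loo_accuracy)`` where the
    accuracy Series covers the training specimens.
    """
    df = data.copy()
    if select:
        keep = wilks_forward_selection(
            df.drop(index=[holdout_label], errors="ignore"),
            group_column,
            alpha=select_alpha,
        )
        if not keep:
            raise ValueError("forward selection admitted no variable")
        df = df[[group_column] + keep]
    holdout_class = None
    if holdout_label is not None:
        if holdout_label not in df.index:
            raise ValueError(f"holdout {holdout_label!r} not in table")
        hold = df.loc[[holdout_label]]
        df = df.drop(index=[holdout_label])
        res = DiscriminantModel(df, group_column, shrinkage).fit()
        x = hold.drop(columns=[group_column], errors="ignore").select_dtypes(
            include=[np.number]
        )
        holdout_class = res.classify(x.to_numpy(dtype=float).ravel())
    else:
        res = DiscriminantModel(df, group_column, shrinkage).fit()
    return holdout_class, res.loo_accuracy()
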