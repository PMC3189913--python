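"""Relative bite-force estimation and body-mass prediction for big cats.

The bite-force model is a dry-skull lever estimate: each adductor's
*relative* (not Newton) force output is the square root of a
cross-sectional area proxy times the muscle's inlever moment arm —

* temporalis: ``sqrt(((ZW - (BW + POW)/2) / 2) * TFL) * MAT``
* masseter:   ``sqrt(((CFL + MSW) / 2) * MSL) * MAM``

summed per side and doubled for the whole skull.  All nine input
measurements are in mm (see :class:`BiteForceMeasures`); every output
therefore scales as length squared.

Body mass is predicted from condylobasal length (CBL) by ordinary least
squares of log10(mass, kg) on log10(CBL, mm) over species-mean pairs,
back-transformed without bias correction (``10**yhat``); a smearing
correction is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiteForceMeasures",
    "BiteForceResult",
    "relative_bite_force",
    "BodyMassModel",
    "BodyMassResults",
    "predict_body_mass",
]


@dataclass(frozen=True)
class BiteForceMeasures:
    """The nine skull measurements (mm) entering the bite-force model.

    ZW  internal width across the zygomatic arches
    BW  width across the braincase
    POW width across the postorbital constriction
    TFL anteroposterior length of the temporal fossa
    MAT temporalis inlever moment arm (cotyle to coronoid tip)
    CFL anteroposterior length of the mandibular coronoid fossa
    MSW dorsoventral width of the masseteric scar on the zygomatic arch
    MSL anteroposterior length of the masseteric scar
    MAM masseter inlever moment arm (cotyle to ventral mandibular rim)
    """

    ZW: float
    BW: float
    POW: float
    TFL: float
    MAT: float
    CFL: float
    MSW: float
    MSL: float
    MAM: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive measurement, got {v}")
        if self.ZW < (self.BW + self.POW) / 2.0:
            raise ValueError(
                "ZW < (BW + POW)/2: the temporalis cross-section proxy would be "
                "negative — the zygomatic/braincase measurements are inconsistent"
            )


@dataclass(frozen=True)
class BiteForceResult:
    temporalis: float
    masseter: float
    per_side: float
    total: float


def relative_bite_force(m: BiteForceMeasures) -> BiteForceResult:
    """Relative adductor force outputs (dimension mm^2) for one skull.

    ``per_side`` sums the temporalis and masseter outputs of one side;
    ``total`` doubles it for both sides.
    """
    temporalis = np.sqrt(((m.ZW - (m.BW + m.POW) / 2.0) / 2.0) * m.TFL) * m.MAT
    masseter = np.sqrt(((m.CFL + m.MSW) / 2.0) * m.MSL) * m.MAM
    per_side = temporalis + masseter
    return BiteForceResult(
        temporalis=float(temporalis),
        masseter=float(masseter),
        per_side=float(per_side),
        total=float(2.0 * per_side),
    )


# ---------------------------------------------------------------------------
# body-mass regression
# ---------------------------------------------------------------------------


class BodyMassModel:
    """log10-log10 regression of body mass on condylobasal length.

    Training data are species-mean (CBL mm, mass kg) pairs; specimen
    tables are averaged within species *after* log transformation.
    """

    def __init__(self, cbl: np.ndarray, mass: np.ndarray, species: list[str] | None = None):
        cbl = np.asarray(cbl, dtype=float)
        mass = np.asarray(mass, dtype=float)
        if cbl.shape != mass.shape or cbl.ndim != 1:
            raise ValueError("cbl and mass must be matching 1-D arrays")
        if len(cbl) < 3:
            raise ValueError("need at least 3 training species")
        if np.any(cbl <= 0) or np.any(mass <= 0):
            raise ValueError("CBL and mass must be positive")
        self.cbl = cbl
        self.mass = mass
        self.species = species or [f"sp{i}" for i in range(len(cbl))]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cbl_column: str = "CBL",
        mass_column: str = "mass",
        species_column: str = "species",
    ) -> "BodyMassModel":
        """Build from a per-specimen table, averaging log-values per species."""
        sub = df[[species_column, cbl_column, mass_column]].dropna()
        logged = sub.assign(
            _lc=np.log10(sub[cbl_column]), _lm=np.log10(sub[mass_column])
        )
        means = logged.groupby(species_column)[["_lc", "_lm"]].mean()
        return cls(
            cbl=10 ** means["_lc"].to_numpy(),
            mass=10 ** means["_lm"].to_numpy(),
            species=list(means.index),
        )

    def fit(self) -> "BodyMassResults":
        lx = np.log10(self.cbl)
        ly = np.log10(self.mass)
        reg = stats.linregress(lx, ly)
        return BodyMassResults(self, reg)


class BodyMassResults:
    """Fitted allometric mass regression: slope, intercept, r2, prediction."""

    def __init__(self, model: BodyMassModel, reg):
        self.model = model
        self.slope = float(reg.slope)
        self.intercept = float(reg.intercept)
        self.rvalue = float(reg.rvalue)
        self.stderr = float(reg.stderr)

    @property
    def r_squared(self) -> float:
        return self.rvalue**2

    @property
    def n_species(self) -> int:
        return len(self.model.cbl)

    def predict(self, cbl: float, smearing: bool = False) -> float:
        """Predicted body mass (kg) for a condylobasal length (mm).

        Back-transformed directly as ``10**yhat``; ``smearing=True``
        applies the Duan smearing factor (mean of back-transformed
        residuals) instead of the direct transform.
        """
        if np.any(np.asarray(cbl) <= 0):
            raise ValueError("CBL must be positive")
        yhat = self.intercept + self.slope * np.log10(cbl)
        correction = 1.0
        if smearing:
            resid = np.log10(self.model.mass) - (
                self.intercept + self.slope * np.log10(self.model.cbl)
            )
            correction = float(np.mean(10.0**resid))
        return float(10.0**yhat * correction)

    def summary(self) -> str:
        return "\n".join(
            [
                "Body-Mass Regression (log10 mass ~ log10 CBL)",
                "=" * 54,
                f"species means: {self.n_species}",
                f"slope: {self.slope:.4f}   intercept: {self.intercept:.4f}"
                f"   r^2: {self.r_squared:.4f}",
            ]
        )


def predict_body_mass(
    cbl: float,
    training: pd.DataFrame | np.ndarray,
    smearing: bool = False,
) -> float:
    """Predict body mass (kg) from CBL (mm) given species-mean training pairs.

    ``training`` is either an (n, 2) array of (CBL, mass) species means
    or a DataFrame with ``CBL`` and ``mass`` columns.
    """
    if isinstance(training, pd.DataFrame):
        model = BodyMassModel(
            training["CBL"].to_numpy(), training["mass"].to_numpy()
        )
    else:
        arr = np.asarray(training, dtype=float)
        model = BodyMassModel(arr[:, 0], arr[:, 1])
    return model.fit().predict(cbl, smearing=smearing)
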