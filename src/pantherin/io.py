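"""Readers and writers for the formats the pipeline touches.

Four carriers are supported:

* **TPS landmark files** — the dialect written by common 2-D digitizers
  (``LM=`` count line, one ``x y`` row per landmark, optional ``ID=``,
  ``IMAGE=`` and ``SCALE=`` lines).  Coordinates are real-valued Cartesian
  with *y* increasing upward; no image-row inversion is applied, because
  digitizers differ in that convention.
* **NEXUS** character matrices (DATA/CHARACTERS block only) for discrete
  morphological characters with states ``0``–``9`` and missing ``?``.
* **Newick** trees, with optional branch lengths and support values given
  as internal-node labels.
* **CSV measurement tables** of craniodental linear measurements in mm.

NEXUS and Newick parsing are delegated to :mod:`dendropy`; TPS has no
library reader and is parsed here.
"""

from __future__ import annotations

import io as _stdio
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "CharacterMatrix",
    "PhyloTree",
    "read_tps",
    "write_tps",
    "read_nexus_matrix",
    "write_nexus_matrix",
    "read_newick",
    "write_newick",
    "read_measurements",
    "write_measurements",
    "TpsParseError",
]

#: Trees are carried as dendropy objects throughout the package.
PhyloTree = dendropy.Tree

MISSING = "?"


class TpsParseError(ValueError):
    """Raised for malformed TPS records; the message names the line."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmarks.

    Landmark order must be homologous across specimens of one dataset;
    the anatomical identity of each point is treated as opaque.
    """

    specimen_id: str
    coords: np.ndarray  # (k, 2) float
    group: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if coords.shape[0] < 3:
            raise ValueError(
                f"{self.specimen_id!r}: need at least 3 landmarks, got {coords.shape[0]}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.specimen_id!r}: non-finite coordinate")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid_size(self) -> float:
        """Square root of summed squared landmark distances from the centroid."""
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c**2).sum()))


@dataclass
class CharacterMatrix:
    """Taxa x unordered multistate characters, symbols '0'-'9' and '?'."""

    taxa: list[str]
    states: np.ndarray  # (n_taxa, n_chars) of single-character strings
    character_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D (taxa x characters)")
        if self.states.shape[0] != len(self.taxa):
            raise ValueError("row count does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        bad = ~np.isin(self.states, list("0123456789") + [MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid state symbol {self.states[i, j]!r} at taxon "
                f"{self.taxa[i]!r}, character {j + 1}"
            )
        if self.n_chars and (self.states == MISSING).all(axis=0).any():
            j = int(np.argwhere((self.states == MISSING).all(axis=0))[0])
            raise ValueError(f"character {j + 1} has no scored taxon")
        if self.character_labels and len(self.character_labels) != self.n_chars:
            raise ValueError("character_labels length mismatch")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.states[:, j]


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"


def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file into a list of configurations.

    Records start with ``LM=<k>`` followed by *k* whitespace-separated
    coordinate rows.  ``SCALE=<s>``, if present, multiplies the record's
    coordinates; ``IMAGE=`` lines are ignored; ``ID=`` provides the
    specimen id (defaulting to the record's ordinal).  All records in one
    file must share *k*.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")

    configs: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    record_no = 0
    common_k: int | None = None
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = re.fullmatch(r"LM\s*=\s*(\d+)", line, flags=re.IGNORECASE)
        if not m:
            raise TpsParseError(f"line {i + 1}: expected 'LM=<count>', got {line!r}")
        k = int(m.group(1))
        header_line = i + 1
        i += 1
        coords: list[tuple[float, float]] = []
        while i < n_lines and len(coords) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if re.match(r"^[A-Za-z]+\s*=", row):
                break
            parts = row.split()
            if len(parts) != 2 or not all(re.fullmatch(_NUM, p) for p in parts):
                raise TpsParseError(
                    f"line {i + 1}: expected two numeric coordinates, got {row!r}"
                )
            coords.append((float(parts[0]), float(parts[1])))
            i += 1
        if len(coords) != k:
            raise TpsParseError(
                f"line {header_line}: record declares {k} landmarks "
                f"but {len(coords)} coordinate rows found"
            )
        specimen_id = str(record_no)
        scale = None
        # trailing keyword lines (ID=, IMAGE=, SCALE=) until next LM=
        while i < n_lines:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if re.fullmatch(r"LM\s*=\s*\d+", row, flags=re.IGNORECASE):
                break
            km = re.match(r"^([A-Za-z]+)\s*=\s*(.*)$", row)
            if not km:
                raise TpsParseError(f"line {i + 1}: unexpected content {row!r}")
            key, value = km.group(1).upper(), km.group(2).strip()
            if key == "ID":
                specimen_id = value or specimen_id
            elif key == "SCALE":
                if not re.fullmatch(_NUM, value):
                    raise TpsParseError(f"line {i + 1}: non-numeric SCALE {value!r}")
                scale = float(value)
            # IMAGE=, COMMENT= etc. ignored
            i += 1
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        if common_k is None:
            common_k = k
        elif k != common_k:
            raise TpsParseError(
                f"line {header_line}: record has {k} landmarks, "
                f"earlier records have {common_k}"
            )
        configs.append(LandmarkConfiguration(specimen_id=specimen_id, coords=arr))
        record_no += 1
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations in the dialect accepted by :func:`read_tps`."""
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"heterogeneous landmark counts: {sorted(ks)}")
    out = _stdio.StringIO()
    for c in configs:
        out.write(f"LM={c.k}\n")
        for x, y in c.coords:
            out.write(f"{float(x)!r} {float(y)!r}\n")
        out.write(f"ID={c.specimen_id}\n")
    Path(path).write_text(out.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# NEXUS character matrices (via dendropy)
# ---------------------------------------------------------------------------


def read_nexus_matrix(path) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    Taxon order is preserved; any declared missing symbol is normalized
    to ``'?'``.  NTAX/NCHAR inconsistent with the matrix body is an error.
    """
    try:
        dm = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus"
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"NEXUS parse failure in {path}: {exc}") from exc
    taxa = [t.label for t in dm.taxon_namespace]
    rows = []
    n_chars = None
    for t in dm.taxon_namespace:
        seq = dm[t]
        symbols = [str(s.symbol) for s in seq]
        symbols = [MISSING if s in ("?", "-") else s for s in symbols]
        if n_chars is None:
            n_chars = len(symbols)
        elif len(symbols) != n_chars:
            raise ValueError(f"ragged matrix row for taxon {t.label!r}")
        rows.append(symbols)
    return CharacterMatrix(taxa=taxa, states=np.array(rows, dtype="<U1"))


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    """Write a CharacterMatrix as a NEXUS DATA block readable by PAUP-family tools."""
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=?;',
        "    MATRIX",
    ]
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    for i, taxon in enumerate(matrix.taxa):
        name = f"'{taxon}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", taxon) else taxon
        lines.append(f"    {name:<{width}}{''.join(matrix.states[i])}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Newick (via dendropy)
# ---------------------------------------------------------------------------


def read_newick(text_or_path, *, rooting: str = "default-unrooted") -> PhyloTree:
    """Parse a Newick string (or path to one) into a tree.

    Internal-node labels are retained; numeric ones are commonly bootstrap
    supports in [0, 100].
    """
    src = str(text_or_path)
    if "(" in src:
        tree = dendropy.Tree.get(data=src, schema="newick", rooting=rooting)
    else:
        tree = dendropy.Tree.get(path=src, schema="newick", rooting=rooting)
    return tree


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to a one-line Newick string."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


# ---------------------------------------------------------------------------
# Measurement tables (CSV via pandas)
# ---------------------------------------------------------------------------


def read_measurements(path) -> pd.DataFrame:
    """Read a CSV of linear measurements (mm) into a DataFrame.

    The CSV must have a ``specimen_id`` column (unique) and may have a
    ``group`` column; every other column is coerced to numeric, blanks
    becoming missing.  Non-positive measurements are rejected — lengths
    in mm are strictly positive.
    """
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise ValueError("measurement CSV needs a 'specimen_id' column")
    df["specimen_id"] = df["specimen_id"].astype(str).str.strip()
    dupes = df["specimen_id"][df["specimen_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate specimen_id: {dupes.iloc[0]!r}")
    if "group" in df.columns:
        df["group"] = df["group"].astype(str).str.strip()
    value_cols = [c for c in df.columns if c not in ("specimen_id", "group")]
    for c in value_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[df[c].notna() & (df[c] <= 0)]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValueError(
                f"non-positive measurement {c}={row[c]} for specimen "
                f"{row['specimen_id']!r} (row {bad[0] + 2} of file)"
            )
    return df.set_index("specimen_id")


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write a measurement DataFrame back to CSV (inverse of read)."""
    df.to_csv(path, index=True)
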