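"""Core domain types and shared data plumbing.

Holds the typed containers used throughout the pipeline (mobile-phase
grid, chromatographic records, descriptor and target matrices, subset
splits), CSV input/output with schema validation, and column-wise
autoscaling (z-scoring) with its exact inverse.

Conventions
-----------
* Compounds are addressed by string identifiers in files and by 0-based
  row positions internally.
* Autoscaling uses the sample (n-1) standard deviation.  Constant
  columns scale to all-zeros and record a scale of 0 so that the
  inverse transform restores the constant exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "SplitValidationError",
    "MobilePhaseGrid",
    "ChromatogramRecord",
    "DescriptorMatrix",
    "TargetMatrix",
    "ScalerParams",
    "SubsetSplit",
    "autoscale",
    "descale",
    "validate_split",
    "read_matrix",
    "write_descriptors",
    "write_target",
    "write_chromatograms",
]


class SchemaError(ValueError):
    """A CSV file or in-memory table violates the documented schema."""


class SplitValidationError(ValueError):
    """A train/validation/internal-test split violates its invariants."""


#: Mobile-phase index -> acetonitrile content (% v/v) on the screening grid.
DEFAULT_ACN_PERCENT = {1: 30, 2: 40, 3: 50, 4: 60, 5: 70, 6: 80, 7: 90, 8: 95, 9: 98}

N_MOBILE_PHASES = 9


@dataclass(frozen=True)
class MobilePhaseGrid:
    """The nine buffer/acetonitrile compositions, indexed 1-9.

    Retention on the cellulose column is screened at nine acetonitrile
    fractions from 30 to 98 % (v/v); the index order follows increasing
    organic content.
    """

    acn_percent: tuple = tuple(DEFAULT_ACN_PERCENT[i] for i in range(1, 10))

    def __post_init__(self):
        if len(self.acn_percent) != N_MOBILE_PHASES:
            raise ValueError(f"expected {N_MOBILE_PHASES} mobile phases, got {len(self.acn_percent)}")
        if any(b <= a for a, b in zip(self.acn_percent, self.acn_percent[1:])):
            raise ValueError("acetonitrile percentages must be strictly increasing")

    @property
    def indices(self) -> tuple:
        return tuple(range(1, N_MOBILE_PHASES + 1))

    def acn_fraction(self, mp_index: int) -> float:
        """Volume fraction of acetonitrile (0-1) at a mobile-phase index."""
        return self.acn_percent[mp_index - 1] / 100.0


@dataclass(frozen=True)
class ChromatogramRecord:
    """Raw chromatographic observation for one compound at one mobile phase.

    ``rs`` is the enantioresolution between the two enantiomer peaks,
    ``k2`` the retention factor of the more-retained enantiomer and
    ``k1`` (optional, stored but unused downstream) that of the
    less-retained one.
    """

    compound_id: str
    mp_index: int
    rs: float
    k2: float
    k1: float | None = None

    def __post_init__(self):
        if not 1 <= self.mp_index <= N_MOBILE_PHASES:
            raise ValueError(f"mp_index must be in 1..{N_MOBILE_PHASES}, got {self.mp_index}")
        if self.rs < 0:
            raise ValueError(f"rs must be >= 0, got {self.rs}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be >= 0, got {self.k2}")
        if self.k1 is not None and self.k1 > self.k2:
            raise ValueError(f"k1 ({self.k1}) must not exceed k2 ({self.k2})")


def _check_ids(ids: Sequence[str], what: str) -> tuple:
    ids = tuple(str(i) for i in ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise SchemaError(f"duplicate {what} {i!r}")
        seen.add(i)
    return ids


@dataclass(frozen=True)
class DescriptorMatrix:
    """Molecular descriptor table: one row per compound, one numeric column
    per descriptor variable (62 in the reference setup)."""

    compound_ids: tuple
    columns: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "compound_ids", _check_ids(self.compound_ids, "compound id"))
        object.__setattr__(self, "columns", _check_ids(self.columns, "column"))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.compound_ids), len(self.columns)):
            raise SchemaError(
                f"value shape {vals.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.columns)} columns"
            )
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise SchemaError(
                f"non-finite value at compound {self.compound_ids[r]!r}, column {self.columns[c]!r}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.columns)

    def select(self, ids: Sequence[str]) -> "DescriptorMatrix":
        """Row-subset by compound id, preserving the given order."""
        pos = {cid: i for i, cid in enumerate(self.compound_ids)}
        try:
            rows = [pos[str(i)] for i in ids]
        except KeyError as e:
            raise SchemaError(f"unknown compound id {e.args[0]!r}") from None
        return DescriptorMatrix(tuple(str(i) for i in ids), self.columns, self.values[rows])


@dataclass(frozen=True)
class TargetMatrix:
    """EES response matrix: one row per compound, one column per mobile phase."""

    compound_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "compound_ids", _check_ids(self.compound_ids, "compound id"))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(self.compound_ids), N_MOBILE_PHASES):
            raise SchemaError(
                f"target matrix must be n x {N_MOBILE_PHASES}, got shape {vals.shape}"
            )
        if not np.isfinite(vals).all():
            raise SchemaError("target matrix contains non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)


@dataclass(frozen=True)
class ScalerParams:
    """Per-column center (mean) and scale (sample standard deviation)."""

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float).ravel()
        scale = np.asarray(self.scale, dtype=float).ravel()
        if center.shape != scale.shape:
            raise ValueError("center and scale must have the same length")
        if (scale < 0).any():
            raise ValueError("scale must be nonnegative")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "scale", scale)

    @property
    def n_columns(self) -> int:
        return self.center.size


@dataclass(frozen=True)
class SubsetSplit:
    """Disjoint training / validation / internal-test row partition.

    Training rows drive weight fitting, validation rows drive early
    stopping, and the small internal-test subset conditions only the
    outer model search.
    """

    tr: tuple
    va: tuple
    it: tuple

    def __post_init__(self):
        object.__setattr__(self, "tr", tuple(int(i) for i in self.tr))
        object.__setattr__(self, "va", tuple(int(i) for i in self.va))
        object.__setattr__(self, "it", tuple(int(i) for i in self.it))

    @property
    def n_total(self) -> int:
        return len(self.tr) + len(self.va) + len(self.it)

    def labels(self, n: int) -> np.ndarray:
        """Array of 'tr'/'va'/'it' labels aligned with row positions 0..n-1."""
        lab = np.empty(n, dtype=object)
        lab[list(self.tr)] = "tr"
        lab[list(self.va)] = "va"
        lab[list(self.it)] = "it"
        return lab


def validate_split(split: SubsetSplit, n_compounds: int, sizes: tuple = (7, 3)) -> SubsetSplit:
    """Check a split against the partition rules and return it unchanged.

    ``sizes`` gives the required (validation, internal-test) sizes; the
    training subset must absorb all remaining compounds.
    """
    va_size, it_size = sizes
    if len(split.va) != va_size:
        raise SplitValidationError(f"validation subset has {len(split.va)} rows, expected {va_size}")
    if len(split.it) != it_size:
        raise SplitValidationError(f"internal-test subset has {len(split.it)} rows, expected {it_size}")
    if len(split.tr) != n_compounds - va_size - it_size:
        raise SplitValidationError(
            f"training subset has {len(split.tr)} rows, expected {n_compounds - va_size - it_size}"
        )
    all_idx = split.tr + split.va + split.it
    if any(i < 0 or i >= n_compounds for i in all_idx):
        raise SplitValidationError(f"split contains out-of-range index for n={n_compounds}")
    if len(set(all_idx)) != len(all_idx):
        raise SplitValidationError("split subsets overlap or repeat an index")
    return split


# ---------------------------------------------------------------------------
# autoscaling


def autoscale(matrix: np.ndarray) -> tuple[np.ndarray, ScalerParams]:
    """Column-wise z-score a matrix; returns the scaled copy and the fitted
    parameters.

    Non-constant columns come out with mean 0 and sample (n-1) standard
    deviation 1.  Constant columns map to all-zeros with a recorded
    scale of 0, so :func:`descale` restores the constant exactly.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("autoscale requires a 2-D matrix with at least 2 rows")
    center = m.mean(axis=0)
    scale = m.std(axis=0, ddof=1)
    # exact-equality constancy test: numerical std of an all-equal column
    # can be a nonzero rounding artifact
    constant = (m == m[0]).all(axis=0)
    center = np.where(constant, m[0], center)
    scale = np.where(constant, 0.0, scale)
    safe = np.where(scale > 0, scale, 1.0)
    scaled = (m - center) / safe
    scaled[:, scale == 0] = 0.0
    return scaled, ScalerParams(center, scale)


def descale(scaled: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Invert :func:`autoscale`: ``x * scale + center`` per column."""
    s = np.asarray(scaled, dtype=float)
    if s.ndim != 2 or s.shape[1] != params.n_columns:
        raise ValueError(
            f"matrix has {s.shape[-1] if s.ndim == 2 else '?'} columns, scaler has {params.n_columns}"
        )
    return s * params.scale + params.center


# ---------------------------------------------------------------------------
# CSV I/O
#
# descriptors CSV:   compound_id,x1,...,x62      (descriptor names free)
# target CSV:        compound_id,mp1,...,mp9
# chromatograms CSV: compound_id,mp_index,rs,k2[,k1]


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str}, float_precision="round_trip")
    if "compound_id" not in df.columns:
        raise SchemaError(f"{path}: missing required 'compound_id' column")
    dup = df.columns[df.columns.duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate column header {dup[0]!r}")
    return df


def _numeric_block(df: pd.DataFrame, cols, path) -> np.ndarray:
    block = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = block.isna() & df[cols].notna() | df[cols].isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SchemaError(
            f"{path}: non-numeric or missing cell at row {r + 1} "
            f"(compound {df['compound_id'].iloc[r]!r}), column {cols[c]!r}"
        )
    return block.to_numpy(dtype=float)


def read_matrix(path, kind: str):
    """Read a validated table from CSV.

    ``kind`` selects the schema: ``"descriptor"`` -> :class:`DescriptorMatrix`,
    ``"target"`` -> :class:`TargetMatrix`, ``"chromatogram"`` -> list of
    :class:`ChromatogramRecord`.  Row order is preserved.
    """
    path = Path(path)
    if kind == "descriptor":
        df = _read_csv(path)
        cols = [c for c in df.columns if c != "compound_id"]
        if not cols:
            raise SchemaError(f"{path}: descriptor file has no descriptor columns")
        values = _numeric_block(df, cols, path)
        return DescriptorMatrix(tuple(df["compound_id"]), tuple(cols), values)
    if kind == "target":
        df = _read_csv(path)
        expected = [f"mp{i}" for i in range(1, N_MOBILE_PHASES + 1)]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing target column(s) {missing}")
        values = _numeric_block(df, expected, path)
        return TargetMatrix(tuple(df["compound_id"]), values)
    if kind == "chromatogram":
        df = _read_csv(path)
        required = ["mp_index", "rs", "k2"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing chromatogram column(s) {missing}")
        has_k1 = "k1" in df.columns
        records = []
        for r, row in enumerate(df.itertuples(index=False)):
            try:
                records.append(
                    ChromatogramRecord(
                        compound_id=str(row.compound_id),
                        mp_index=int(row.mp_index),
                        rs=float(row.rs),
                        k2=float(row.k2),
                        k1=float(row.k1) if has_k1 and pd.notna(row.k1) else None,
                    )
                )
            except (TypeError, ValueError) as e:
                raise SchemaError(f"{path}: invalid chromatogram row {r + 1}: {e}") from None
        seen = set()
        for rec in records:
            key = (rec.compound_id, rec.mp_index)
            if key in seen:
                raise SchemaError(
                    f"{path}: duplicate record for compound {rec.compound_id!r} at MP {rec.mp_index}"
                )
            seen.add(key)
        return records
    raise ValueError(f"unknown kind {kind!r}; expected descriptor|target|chromatogram")


def write_descriptors(matrix: DescriptorMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, columns=list(matrix.columns))
    df.insert(0, "compound_id", list(matrix.compound_ids))
    df.to_csv(path, index=False)


def write_target(target: TargetMatrix, path) -> None:
    df = pd.DataFrame(target.values, columns=[f"mp{i}" for i in range(1, N_MOBILE_PHASES + 1)])
    df.insert(0, "compound_id", list(target.compound_ids))
    df.to_csv(path, index=False)


def write_chromatograms(records: Sequence[ChromatogramRecord], path) -> None:
    has_k1 = any(r.k1 is not None for r in records)
    rows = []
    for r in records:
        row = {"compound_id": r.compound_id, "mp_index": r.mp_index, "rs": r.rs, "k2": r.k2}
        if has_k1:
            row["k1"] = r.k1
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
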