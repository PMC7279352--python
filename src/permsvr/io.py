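"""Compound/descriptor table containers and delimited-text I/O.

The central container is :class:`CompoundTable`: an ordered collection of
compounds (identifier, optional SMILES string, optional pKa list, optional
observed log10 effective permeability) together with a numeric descriptor
matrix.  SMILES are carried as opaque text; no structure parsing happens
here.  All files are UTF-8 CSV with a header row; missing values are empty
cells.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "CompoundTable",
    "PredictionSet",
    "read_compound_table",
    "write_compound_table",
    "read_predictions",
    "write_predictions",
    "save_ensemble",
    "load_ensemble",
]

_ENSEMBLE_FORMAT = "permsvr-ensemble"
_ENSEMBLE_VERSION = 1

# columns with reserved meaning in compound CSV files
_SMILES_COLUMN = "smiles"
_PKAS_COLUMN = "pkas"


@dataclass
class CompoundRecord:
    """One compound: identifier plus optional annotation.

    ``pkas`` holds acid-dissociation constants (dimensionless pKa values);
    ``log_peff`` is log10 of the effective permeability in cm/s.
    """

    compound_id: str
    smiles: str | None = None
    pkas: list[float] | None = None
    log_peff: float | None = None

    def __post_init__(self) -> None:
        if not str(self.compound_id):
            raise ValueError("compound_id must be non-empty")
        if self.pkas is not None:
            self.pkas = [float(p) for p in self.pkas]
            if not all(math.isfinite(p) for p in self.pkas):
                raise ValueError(
                    f"compound {self.compound_id!r}: pKa values must be finite"
                )


class CompoundTable:
    """Ordered compounds with an aligned numeric descriptor matrix.

    Parameters
    ----------
    records : sequence of CompoundRecord
        One per row, in table order.
    descriptors : pandas.DataFrame
        Numeric matrix, one row per record, named columns.  The index is
        replaced by the compound identifiers.
    """

    def __init__(self, records: Sequence[CompoundRecord], descriptors: pd.DataFrame):
        records = list(records)
        if len(records) != len(descriptors):
            raise ValueError(
                f"{len(records)} records but {len(descriptors)} descriptor rows"
            )
        ids = [r.compound_id for r in records]
        dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate compound ids: {dupes}")
        names = list(descriptors.columns)
        if len(set(names)) != len(names):
            raise ValueError("descriptor names must be unique")
        desc = descriptors.copy()
        desc.index = pd.Index(ids, name="compound_id")
        for col in desc.columns:
            if desc[col].isna().all():
                raise ValueError(f"descriptor {col!r} is entirely missing")
            desc[col] = pd.to_numeric(desc[col])
        self.records = records
        self.descriptors = desc

    @classmethod
    def _from_parts(
        cls, records: Sequence[CompoundRecord], descriptors: pd.DataFrame
    ) -> "CompoundTable":
        """Internal fast path: build from parts already known to satisfy the
        invariants (aligned rows, unique ids/columns, numeric cells)."""
        obj = cls.__new__(cls)
        obj.records = list(records)
        obj.descriptors = descriptors
        return obj

    # -- basic views ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.descriptors.columns)

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    @property
    def response(self) -> np.ndarray:
        """Observed log Peff per row (NaN where absent)."""
        return np.array(
            [np.nan if r.log_peff is None else float(r.log_peff) for r in self.records]
        )

    def record(self, compound_id: str) -> CompoundRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)

    # -- derived tables ------------------------------------------------
    def subset_descriptors(self, names: Iterable[str]) -> "CompoundTable":
        """Restrict to the named descriptor columns (order as given)."""
        names = list(names)
        missing = [n for n in names if n not in self.descriptors.columns]
        if missing:
            raise KeyError(f"descriptor(s) not in table: {missing}")
        return CompoundTable._from_parts(self.records, self.descriptors[names])

    def select_rows(self, ids: Iterable[str]) -> "CompoundTable":
        """Select compounds by id, in the given order."""
        ids = list(ids)
        by_id = {r.compound_id: i for i, r in enumerate(self.records)}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"compound id(s) not in table: {missing}")
        rows = [by_id[i] for i in ids]
        recs = [self.records[i] for i in rows]
        return CompoundTable._from_parts(recs, self.descriptors.iloc[rows])

    def with_response(self, values: Sequence[float]) -> "CompoundTable":
        """Copy with log_peff replaced row-wise (used by Y-scrambling)."""
        values = np.asarray(values, dtype=float)
        if len(values) != self.n:
            raise ValueError("response length mismatch")
        recs = [
            CompoundRecord(r.compound_id, r.smiles, r.pkas, float(v))
            for r, v in zip(self.records, values)
        ]
        return CompoundTable(recs, self.descriptors)

    def to_dataframe(self, response_column: str = "log_peff") -> pd.DataFrame:
        df = self.descriptors.copy()
        y = self.response
        if not np.all(np.isnan(y)):
            df[response_column] = y
        if any(r.smiles is not None for r in self.records):
            df[_SMILES_COLUMN] = [r.smiles for r in self.records]
        if any(r.pkas is not None for r in self.records):
            df[_PKAS_COLUMN] = [
                None if r.pkas is None else ";".join(repr(p) for p in r.pkas)
                for r in self.records
            ]
        return df


@dataclass
class PredictionSet:
    """Aligned observed/predicted log Peff values for a set of compounds."""

    compound_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(i) for i in self.compound_ids]
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        n = len(self.compound_ids)
        if not (len(self.observed) == len(self.predicted) == n):
            raise ValueError("compound_ids, observed and predicted must align")
        if not (np.all(np.isfinite(self.observed)) and np.all(np.isfinite(self.predicted))):
            raise ValueError("observed and predicted values must be finite")

    @property
    def n(self) -> int:
        return len(self.compound_ids)

    @property
    def residuals(self) -> np.ndarray:
        """Residuals observed − predicted."""
        return self.observed - self.predicted


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_pkas(cell) -> list[float] | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    return [float(tok) for tok in text.replace(",", ";").split(";") if tok.strip()]


def read_compound_table(
    path: str | Path,
    response_column: str | None = "log_peff",
    id_column: str = "compound_id",
) -> CompoundTable:
    """Read a compound/descriptor CSV.

    Every column other than the id, response, ``smiles`` and ``pkas``
    columns is treated as a numeric descriptor.  Pass
    ``response_column=None`` for tables without observed activities.
    """
    df = pd.read_csv(path, dtype={id_column: str}, float_precision="round_trip")
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    if response_column is not None and response_column not in df.columns:
        raise ValueError(f"response column {response_column!r} not found in {path}")

    ids = df[id_column].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate compound ids in {path}: {dupes}")

    special = {id_column, _SMILES_COLUMN, _PKAS_COLUMN}
    if response_column is not None:
        special.add(response_column)
    desc_cols = [c for c in df.columns if c not in special]

    desc = pd.DataFrame(index=df.index)
    for col in desc_cols:
        try:
            desc[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                row, value = bad.index[0], bad.iloc[0]
            else:  # pragma: no cover - defensive
                row, value = "?", "?"
            raise ValueError(
                f"non-numeric descriptor cell in column {col!r}, row {row}: {value!r}"
            ) from exc

    records = []
    for i in df.index:
        smiles = None
        if _SMILES_COLUMN in df.columns and pd.notna(df.loc[i, _SMILES_COLUMN]):
            smiles = str(df.loc[i, _SMILES_COLUMN])
        pkas = _parse_pkas(df.loc[i, _PKAS_COLUMN]) if _PKAS_COLUMN in df.columns else None
        y = None
        if response_column is not None and pd.notna(df.loc[i, response_column]):
            y = float(df.loc[i, response_column])
        records.append(CompoundRecord(str(ids.iloc[i]), smiles, pkas, y))
    return CompoundTable(records, desc)


def write_compound_table(
    table: CompoundTable,
    path: str | Path,
    response_column: str = "log_peff",
    id_column: str = "compound_id",
) -> None:
    df = table.to_dataframe(response_column=response_column)
    df.index.name = id_column
    df.to_csv(path, float_format="%.17g")


def write_predictions(pred: PredictionSet, path: str | Path) -> None:
    """Write id, observed, predicted and residual columns as CSV."""
    df = pd.DataFrame(
        {
            "compound_id": pred.compound_ids,
            "observed": pred.observed,
            "predicted": pred.predicted,
            "residual": pred.residuals,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_predictions(path: str | Path) -> PredictionSet:
    df = pd.read_csv(path, dtype={"compound_id": str}, float_precision="round_trip")
    for col in ("compound_id", "observed", "predicted"):
        if col not in df.columns:
            raise ValueError(f"prediction file {path} lacks column {col!r}")
    return PredictionSet(
        list(df["compound_id"]), df["observed"].to_numpy(), df["predicted"].to_numpy()
    )


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------

def save_ensemble(model, path: str | Path) -> None:
    """Serialize a trained ensemble (or single learner) to a single file.

    The archive is self-describing: it records the format tag, a version
    number and the model object (hyperparameters, per-member descriptor
    subsets, normalization statistics and solver state).  The contract is
    prediction equality after a round trip, not byte equality.
    """
    payload = {
        "format": _ENSEMBLE_FORMAT,
        "version": _ENSEMBLE_VERSION,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_ensemble(path: str | Path):
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError, ImportError) as exc:
        raise ValueError(f"cannot load model archive {path}: corrupted file ({exc})")
    if not isinstance(payload, dict) or payload.get("format") != _ENSEMBLE_FORMAT:
        raise ValueError(f"{path} is not a permsvr model archive")
    if payload.get("version") != _ENSEMBLE_VERSION:
        raise ValueError(
            f"model archive version {payload.get('version')} unsupported "
            f"(expected {_ENSEMBLE_VERSION})"
        )
    return payload["model"]
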