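"""Tabular containers: per-cell tables and per-patient clinical tables.

Both are thin wrappers around pandas DataFrames with a fixed, validated
schema and lossless delimited-text round-trips (comma separated, UTF-8,
"." decimal).  ``write -> read -> write`` is byte-identical.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HISTOLOGIES = ("lepidic", "papillary", "acinar", "micropapillary", "solid")

_CELL_FIXED = ["cell_id", "core_id", "centroid_row", "centroid_col", "lineage"]


@dataclass
class CellTable:
    """One row per segmented cell.

    Columns: cell_id, core_id, centroid_row, centroid_col, lineage,
    then ``expr_<channel>`` mean expressions and ``pos_<marker>``
    functional positivity flags.  ``lineages`` is the configured label
    set (including "undefined") against which rows are validated.
    """

    df: pd.DataFrame
    lineages: tuple[str, ...]
    channels: tuple[str, ...] = ()
    functional: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cols = _CELL_FIXED + [f"expr_{c}" for c in self.channels] + [
            f"pos_{m}" for m in self.functional
        ]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"cell table missing columns: {missing}")
        self.df = self.df[cols].reset_index(drop=True)
        bad = ~self.df["lineage"].isin(self.lineages)
        if bad.any():
            rows = self.df.index[bad].tolist()[:10]
            labels = sorted(self.df.loc[bad, "lineage"].unique())
            raise ValueError(f"unknown lineage labels {labels} in rows {rows}")
        expr = self.df[[f"expr_{c}" for c in self.channels]]
        if len(expr.columns) and not np.isfinite(expr.to_numpy(dtype=float)).all():
            raise ValueError("mean expression values must be finite")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def core_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["core_id"]))

    def for_core(self, core_id: str) -> pd.DataFrame:
        return self.df[self.df["core_id"] == core_id]

    def centroids(self, core_id: str) -> np.ndarray:
        sub = self.for_core(core_id)
        return sub[["centroid_row", "centroid_col"]].to_numpy(dtype=float)


def write_cell_table(table: CellTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    table.df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_cell_table(
    path: str | Path,
    lineages: tuple[str, ...],
    channels: tuple[str, ...] = (),
    functional: tuple[str, ...] = (),
) -> CellTable:
    """Read a cell table written by :func:`write_cell_table`.

    Unknown lineage labels raise, listing the offending rows.
    """
    df = pd.read_csv(Path(path), encoding="utf-8")
    if len(df) == 0:
        # pandas drops dtypes on empty frames; rebuild minimal typed frame
        df = df.astype({"cell_id": np.int64}, errors="ignore")
    return CellTable(df, lineages=lineages, channels=channels, functional=functional)


_CLIN_COLS = [
    "patient_id",
    "core_ids",
    "histology",
    "sex",
    "age",
    "bmi",
    "smoking",
    "pack_years",
    "stage",
    "progression",
    "survival_time",
    "event",
]


@dataclass
class ClinicalTable:
    """One row per patient; ``core_ids`` is a ';'-joined list of cores."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CLIN_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        self.df = self.df[_CLIN_COLS].reset_index(drop=True)
        bad_hist = ~self.df["histology"].isin(HISTOLOGIES)
        if bad_hist.any():
            raise ValueError(
                f"unknown histology values: {sorted(self.df.loc[bad_hist, 'histology'].unique())}"
            )
        if (self.df["survival_time"] < 0).any():
            raise ValueError("survival_time must be >= 0")
        counts: dict[str, str] = {}
        for pid, cores in zip(self.df["patient_id"], self.df["core_ids"]):
            for cid in str(cores).split(";"):
                if cid in counts:
                    raise ValueError(f"core {cid!r} mapped to more than one patient")
                counts[cid] = pid
        self._core_to_patient = counts

    def __len__(self) -> int:
        return len(self.df)

    @property
    def core_to_patient(self) -> dict[str, str]:
        return dict(self._core_to_patient)

    def patient_of(self, core_id: str) -> str:
        return self._core_to_patient[core_id]


def write_clinical_table(table: ClinicalTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    table.df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_clinical_table(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(Path(path), encoding="utf-8"))
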