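"""Tabular and structural file formats used across the pipeline.

All tables are TSV (or CSV) with named headers.  Peak tables carry one row
per assigned amide cross-peak: residue index (1-based, full-length UniProt
numbering), one-letter residue code, the ¹H and ¹⁵N chemical shifts in ppm,
an intensity, and a quality flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PEAK_FLAGS = ("ok", "overlapped", "missing", "broadened")


class FormatError(ValueError):
    """A file does not conform to the expected table dialect."""


@dataclass(frozen=True)
class PeakEntry:
    """One amide cross-peak."""

    residue_index: int
    residue_code: str
    delta_H: float
    delta_N: float
    intensity: float = np.nan
    flag: str = "ok"

    def __post_init__(self):
        if self.flag not in PEAK_FLAGS:
            raise ValueError(f"unknown peak flag {self.flag!r}")
        if self.flag == "ok" and not (
            np.isfinite(self.delta_H) and np.isfinite(self.delta_N)
        ):
            raise ValueError(
                f"residue {self.residue_index}: non-finite shifts with flag='ok'"
            )


@dataclass(frozen=True)
class PeakTable:
    """An assigned peak list for one spectrum.

    Residue indices are strictly increasing; ppm values are finite for
    ``flag == "ok"`` entries (enforced on construction).
    """

    entries: tuple[PeakEntry, ...]

    def __post_init__(self):
        idx = [e.residue_index for e in self.entries]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_residue(self) -> dict[int, PeakEntry]:
        return {e.residue_index: e for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": [e.residue_index for e in self.entries],
                "code": [e.residue_code for e in self.entries],
                "dH": [e.delta_H for e in self.entries],
                "dN": [e.delta_N for e in self.entries],
                "intensity": [e.intensity for e in self.entries],
                "flag": [e.flag for e in self.entries],
            }
        )


_SEP = {"tsv": "\t", "csv": ","}

#: accepted aliases for the mandatory peak-table columns
_COLUMN_ALIASES = {
    "residue": ("residue", "residue_index", "res", "resid"),
    "dH": ("dh", "delta_h", "deltah", "1h", "h"),
    "dN": ("dn", "delta_n", "deltan", "15n", "n"),
}


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lowered = {c.lower(): c for c in columns}
    out = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lowered:
                out[canonical] = lowered[a]
                break
        else:
            raise FormatError(f"peak table is missing mandatory column {canonical!r}")
    return out


def read_peak_table(path: str | Path, dialect: str = "tsv") -> PeakTable:
    """Read a peak table from TSV/CSV.

    Rows whose shift cells cannot be parsed as numbers become
    ``flag="missing"`` entries rather than raising.
    """
    if dialect not in _SEP:
        raise ValueError(f"dialect must be one of {sorted(_SEP)}")
    df = pd.read_csv(path, sep=_SEP[dialect], dtype=str, comment="#")
    cols = _resolve_columns(df.columns)
    code_col = next(
        (c for c in df.columns if c.lower() in ("code", "residue_code", "aa")), None
    )
    int_col = next((c for c in df.columns if c.lower() == "intensity"), None)
    flag_col = next((c for c in df.columns if c.lower() == "flag"), None)

    entries = []
    for _, row in df.iterrows():
        residue = int(row[cols["residue"]])
        code = str(row[code_col]) if code_col is not None else "X"
        flag = str(row[flag_col]) if flag_col is not None and pd.notna(row[flag_col]) else "ok"
        try:
            dH = float(row[cols["dH"]])
            dN = float(row[cols["dN"]])
            if not (np.isfinite(dH) and np.isfinite(dN)):
                raise ValueError
        except (TypeError, ValueError):
            dH, dN, flag = np.nan, np.nan, "missing"
        try:
            inten = float(row[int_col]) if int_col is not None else np.nan
        except (TypeError, ValueError):
            inten = np.nan
        entries.append(PeakEntry(residue, code, dH, dN, inten, flag))
    return PeakTable(tuple(entries))


def write_peak_table(table: PeakTable, path: str | Path, dialect: str = "tsv") -> None:
    table.to_frame().rename(columns={"residue": "residue"}).to_csv(
        path, sep=_SEP[dialect], index=False, float_format="%.6f"
    )


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a result table as TSV with ``# key=value`` metadata header lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
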