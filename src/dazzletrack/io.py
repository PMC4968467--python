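"""Reading and writing trial tables, and the column-mapping layer.

The canonical trial schema is: participant, coloration, contrast,
set_size, mean_error_px, plus the optional is_practice flag (and any
bookkeeping columns such as block_index / trial_index).  External files --
e.g. a supplementary dataset whose column names and delimiter are unknown
in advance -- are adapted through a :class:`ColumnMap`, which names the
source columns and declares any factor-level recodings explicitly; levels
are never guessed silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

log = logging.getLogger("dazzletrack.io")

__all__ = ["ColumnMap", "read_trials", "write_trials", "SCHEMA"]

REQUIRED = ("participant", "coloration", "contrast", "set_size", "mean_error_px")
OPTIONAL = ("is_practice", "block_index", "trial_index")
SCHEMA = REQUIRED + OPTIONAL

COLORATION_LEVELS = {"parallel", "orthogonal", "binary"}
CONTRAST_LEVELS = {"high", "low"}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to source column names.

    ``columns`` maps canonical -> source name (identity by default);
    ``recode`` maps a canonical factor field to a {source value ->
    canonical level} dictionary.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    recode: Mapping[str, Mapping] = field(default_factory=dict)

    def source(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _validate_levels(frame: pd.DataFrame, col: str, allowed: set) -> None:
    bad = ~frame[col].isin(allowed)
    if bad.any():
        rows = frame.index[bad].tolist()[:10]
        vals = sorted(frame.loc[bad, col].unique().tolist())
        raise ValueError(
            f"column {col!r} has unknown levels {vals} (rows {rows}); "
            f"expected {sorted(allowed)} -- declare a recoding in the ColumnMap"
        )


def read_trials(
    path,
    colmap: ColumnMap | None = None,
    sep: str | None = None,
    drop_practice: bool = True,
) -> pd.DataFrame:
    """Read a delimited trial table into the canonical schema.

    ``sep=None`` auto-sniffs the delimiter (comma/tab/semicolon/space).
    Practice trials are dropped when an is_practice column is mapped and
    ``drop_practice`` is set.  Unmapped required columns, unparseable
    numerics and unknown factor levels are all reported with offending
    rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = colmap or ColumnMap()
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")

    missing = [c for c in REQUIRED if colmap.source(c) not in raw.columns]
    if missing:
        raise ValueError(
            f"required columns not found in {path.name}: "
            f"{[(c, colmap.source(c)) for c in missing]}; "
            f"file has {list(raw.columns)}"
        )

    out = pd.DataFrame()
    for canonical in SCHEMA:
        src = colmap.source(canonical)
        if src not in raw.columns:
            continue
        col = raw[src]
        if canonical in colmap.recode:
            col = col.map(dict(colmap.recode[canonical])).fillna(col)
        out[canonical] = col

    for col, caster in [("set_size", int), ("mean_error_px", float)]:
        numeric = pd.to_numeric(out[col], errors="coerce")
        if numeric.isna().any():
            rows = out.index[numeric.isna()].tolist()[:10]
            raise ValueError(f"column {col!r} is not numeric (or missing) "
                             f"at rows {rows}")
        out[col] = numeric.astype(caster)

    out["participant"] = out["participant"].astype(str)
    out["coloration"] = out["coloration"].astype(str).str.lower()
    out["contrast"] = out["contrast"].astype(str).str.lower()
    _validate_levels(out, "coloration", COLORATION_LEVELS)
    _validate_levels(out, "contrast", CONTRAST_LEVELS)

    if "is_practice" in out.columns:
        out["is_practice"] = out["is_practice"].astype(bool)
        if drop_practice:
            dropped = int(out["is_practice"].sum())
            out = out[~out["is_practice"]].reset_index(drop=True)
            if dropped:
                log.info("dropped %d practice trials", dropped)
    log.info("read %d trials from %d participants (%s)",
             len(out), out["participant"].nunique(), path.name)
    return out


def write_trials(frame: pd.DataFrame, path) -> None:
    """Write a canonical trial table as CSV with stable float formatting.

    The fixed 17-significant-digit float format makes write -> read a
    bit-exact round trip, and repeated runs byte-identical.
    """
    frame.to_csv(path, index=False, float_format="%.17g")
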