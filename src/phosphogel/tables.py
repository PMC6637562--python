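"""Spot-volume tables: data model, CSV I/O, normalization and filtering.

A spot-volume table is a long-format :class:`pandas.DataFrame` with one row
per *measured* spot volume:

====================  =======================================================
column                meaning
====================  =======================================================
``spot_id``           spot label (string), matched across gels upstream
``group``             sample-group label (e.g. ``"DFD"``, ``"control"``)
``replicate``         1-based biological replicate index
``channel``           ``"phospho"`` (Pro-Q Diamond) or ``"total"`` (SYPRO Ruby)
``volume``            non-negative spot volume in densitometry units
``present``           bool; a spot absent from a gel simply has no row
====================  =======================================================

Absence is encoded as a *missing row*, never as a zero volume, so the
reproducibility rule (a spot must be detected in at least two of four
replicate gels) can be applied faithfully.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DegenerateGelError, ParseError

CHANNELS = ("phospho", "total")
#: ppm convention: per-gel volumes sum to 1e6 after total-valid-spot normalization
NORMALIZATION_REFERENCE = 1.0e6

SPOT_TABLE_COLUMNS = ["spot_id", "group", "replicate", "channel", "volume"]
_KEY = ["spot_id", "group", "replicate", "channel"]


@dataclass(frozen=True)
class SpotMeta:
    """Per-spot gel metadata: observed/theoretical mass and isoelectric point.

    ``observed_mr`` and ``theoretical_mr`` are in kDa; ``observed_pi`` in pH
    units. ``protein_label`` is a free-text identification such as
    ``"MYLPF (2)"``.
    """

    spot_id: str
    observed_mr: float
    observed_pi: float
    theoretical_mr: float | None = None
    protein_label: str | None = None

    def __post_init__(self):
        if not self.observed_mr > 0:
            raise ValueError(f"observed_mr must be > 0, got {self.observed_mr}")
        if not 0 < self.observed_pi < 14:
            raise ValueError(f"observed_pi must be in (0, 14), got {self.observed_pi}")


def spot_sort_key(spot_id: str):
    """Natural sort key so ``"5" < "10" < "30A"``."""
    m = re.match(r"^(\d+)(.*)$", str(spot_id))
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, 0, str(spot_id))


def validate_spot_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a spot-volume frame in place and return it.

    Checks the required columns, non-negative volumes and uniqueness of the
    (spot_id, group, replicate, channel) key. Adds a ``present`` column
    (all True) when missing.
    """
    missing = [c for c in SPOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}")
    if "present" not in df.columns:
        df = df.assign(present=True)
    bad = df.index[df["present"] & ~(df["volume"] >= 0)]
    if len(bad):
        raise ParseError("negative or non-numeric volume", row=int(bad[0]) + 1)
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        raise ParseError("duplicate (spot_id, group, replicate, channel) key",
                         row=int(np.flatnonzero(dup.to_numpy())[0]) + 1)
    unknown = set(df["channel"].unique()) - set(CHANNELS)
    if unknown:
        raise ParseError(f"unknown channel(s): {sorted(unknown)}")
    return df


def read_spot_table(path) -> pd.DataFrame:
    """Read a spot-volume CSV (header ``spot_id,group,replicate,channel,volume``)."""
    try:
        df = pd.read_csv(path, dtype={"spot_id": str, "group": str, "channel": str})
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(str(exc)) from exc
    if "volume" in df.columns and not pd.api.types.is_numeric_dtype(df["volume"]):
        raise ParseError("volume column is not numeric")
    return validate_spot_table(df)


def write_spot_table(table: pd.DataFrame, path) -> None:
    """Write a spot-volume table as CSV.

    Volumes are written with ``repr`` precision so that a write/read
    round-trip reproduces them bit-for-bit.
    """
    cols = [c for c in SPOT_TABLE_COLUMNS + ["present"] if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_spot_meta(path) -> dict[str, SpotMeta]:
    """Read spot metadata CSV: ``spot_id,observed_mr,observed_pi,theoretical_mr,protein_label``."""
    df = pd.read_csv(path, dtype={"spot_id": str, "protein_label": str})
    out = {}
    for _, row in df.iterrows():
        theo = row.get("theoretical_mr")
        out[row["spot_id"]] = SpotMeta(
            spot_id=row["spot_id"],
            observed_mr=float(row["observed_mr"]),
            observed_pi=float(row["observed_pi"]),
            theoretical_mr=None if pd.isna(theo) else float(theo),
            protein_label=row.get("protein_label"),
        )
    return out


def normalize_total_valid_spot(table: pd.DataFrame,
                               reference: float = NORMALIZATION_REFERENCE) -> pd.DataFrame:
    """Total-valid-spot normalization, per gel image.

    Within each (group, replicate, channel) gel image every present volume is
    divided by the sum of present volumes and multiplied by ``reference``
    (default 1e6, the ppm convention), so per-gel sums equal ``reference``
    afterwards. Idempotent, and invariant to any per-gel multiplicative
    rescaling applied beforehand.
    """
    if table.empty:
        raise ValueError("cannot normalize an empty table")
    table = validate_spot_table(table.copy())
    gel = ["group", "replicate", "channel"]
    present = table[table["present"]]
    sums = present.groupby(gel)["volume"].sum()
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise DegenerateGelError(f"gel {bad} has zero total present volume")
    factors = reference / sums
    f = table.set_index(gel).index.map(factors)
    out = table.copy()
    out.loc[out["present"], "volume"] = (
        table["volume"].to_numpy() * f.to_numpy())[out["present"].to_numpy()]
    return out


def reproducibility_filter(table: pd.DataFrame, min_reps: int = 2) -> pd.DataFrame:
    """Keep, per group and channel, only spots detected in >= ``min_reps`` replicates.

    The rule is applied independently within each group: a spot may survive
    in one group only (a group-unique spot). With ``min_reps=1`` the table is
    returned unchanged.
    """
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    table = validate_spot_table(table.copy())
    if min_reps == 1:
        return table
    counts = (table[table["present"]]
              .groupby(["spot_id", "group", "channel"])["replicate"].nunique())
    keep = counts[counts >= min_reps].index
    idx = pd.MultiIndex.from_frame(table[["spot_id", "group", "channel"]])
    return table[idx.isin(keep)].reset_index(drop=True)


def flag_fragment(meta: SpotMeta, ratio_threshold: float = 0.8) -> bool | None:
    """Flag a spot as a proteolytic fragment by its observed vs theoretical mass.

    Returns True (fragment, to be excluded) when the observed molecular mass
    is below ``ratio_threshold`` times the theoretical full-length mass, and
    ``None`` (not evaluable; spot retained) when no theoretical mass is known.
    The 0.8 default cutoff is a package choice — the comparison itself is the
    established exclusion rule, but no universal threshold exists.
    """
    if meta.theoretical_mr is None:
        return None
    return meta.observed_mr < ratio_threshold * meta.theoretical_mr


def presence_counts(table: pd.DataFrame, channel: str) -> pd.Series:
    """Number of replicates in which each (spot_id, group) is present on ``channel``."""
    sub = table[(table["channel"] == channel) & table["present"]]
    return sub.groupby(["spot_id", "group"])["replicate"].nunique()


def spots_present(table: pd.DataFrame, group: str, channel: str,
                  min_reps: int = 1) -> set[str]:
    """Set of spot ids present on ``channel`` in >= ``min_reps`` replicates of ``group``."""
    counts = presence_counts(table[table["group"] == group], channel)
    if counts.empty:
        return set()
    return {sid for (sid, _g), n in counts.items() if n >= min_reps}


def concat_tables(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate and re-validate several spot tables (e.g. two groups)."""
    return validate_spot_table(pd.concat(list(tables), ignore_index=True))
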