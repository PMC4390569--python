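"""Scan-sampled courtship observation tables.

A male mating progression (MMP) assay records, every 30 seconds for 15
minutes, which of eight ordinally ranked courtship behaviors a male is
performing (1 = not moving ... 8 = copulating), giving 30 observations per
male. This module parses and validates long-format observation tables,
condenses the eight ordinal behaviors into five broader categories A-E that
are robust to scan sampling, computes the per-male MMP summary score (sum of
the 30 ordinal scores, range 30-240), and flags "noninitiator" males that
never score above 2 (movement) during the whole assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "CONDENSE_MAP",
    "MaleSequence",
    "ObservationTable",
    "ObservationError",
    "condense",
    "condense_sequence",
    "mmp_score",
    "flag_noninitiator",
    "arcsin_transform",
    "read_observations",
]

#: Condensed behavioral categories, ordered by courtship intensity.
CATEGORIES: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: Ordinal score -> condensed category. 1-2 no engagement, 3-4 pursuit,
#: 5 wing vibration, 6 genital licking, 7-8 attempted/actual copulation.
CONDENSE_MAP: dict[int, str] = {
    1: "A", 2: "A", 3: "B", 4: "B", 5: "C", 6: "D", 7: "E", 8: "E",
}

#: Category -> ordinal scores that condense to it.
CATEGORY_PREIMAGE: dict[str, tuple[int, ...]] = {
    "A": (1, 2), "B": (3, 4), "C": (5,), "D": (6,), "E": (7, 8),
}

REQUIRED_COLUMNS = (
    "line", "block", "trial", "arena", "male", "timepoint", "score",
)


class ObservationError(ValueError):
    """Raised for structurally invalid observation data."""


def condense(ordinal_score: int) -> str:
    """Map an ordinal MMP score (1-8) to its condensed category A-E."""
    try:
        return CONDENSE_MAP[int(ordinal_score)]
    except (KeyError, TypeError, ValueError) as exc:
        raise ObservationError(
            f"ordinal score must be an integer in 1..8, got {ordinal_score!r}"
        ) from exc


def condense_sequence(ordinal_seq: Sequence[int]) -> list[str]:
    """Condense a whole ordinal sequence to categories A-E."""
    return [condense(s) for s in ordinal_seq]


def mmp_score(ordinal_seq: Sequence[int]) -> int:
    """Sum of ordinal scores over the assay.

    For a full-length assay (T=30 scans) the score ranges from 30 (male
    never moves) to 240 (male copulates at every scan).
    """
    seq = list(ordinal_seq)
    if not seq:
        raise ObservationError("cannot score an empty sequence")
    for s in seq:
        if not 1 <= int(s) <= 8 or int(s) != s:
            raise ObservationError(f"ordinal score out of range 1..8: {s!r}")
    return int(sum(int(s) for s in seq))


def flag_noninitiator(ordinal_seq: Sequence[int]) -> bool:
    """True iff the male never scores above 2 (movement) at any scan."""
    seq = list(ordinal_seq)
    if not seq:
        raise ObservationError("cannot flag an empty sequence")
    return max(int(s) for s in seq) <= 2


def arcsin_transform(p: float) -> float:
    """Arcsine-square-root transform for proportion data.

    Classical variance-stabilizing transform for binomial proportions;
    maps [0, 1] onto [0, pi/2].
    """
    if not 0.0 <= p <= 1.0:
        raise ObservationError(f"proportion must lie in [0, 1], got {p!r}")
    return math.asin(math.sqrt(p))


@dataclass
class MaleSequence:
    """One male's scan-sampling record and derived summaries."""

    line: str
    block: str
    trial: str
    arena: str
    male: str
    ordinal_seq: list[int]
    condensed_seq: list[str] = field(init=False)
    mmp: int = field(init=False)
    noninitiator: bool = field(init=False)

    def __post_init__(self) -> None:
        self.condensed_seq = condense_sequence(self.ordinal_seq)
        self.mmp = mmp_score(self.ordinal_seq)
        self.noninitiator = flag_noninitiator(self.ordinal_seq)

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.line, self.block, self.trial, self.arena, self.male)


class ObservationTable:
    """Validated collection of per-male scan-sampling sequences.

    Parameters
    ----------
    males : iterable of MaleSequence
    T : expected number of scans per male (default 30, i.e. one scan every
        30 s for 15 min starting at t=0).
    """

    def __init__(self, males: Iterable[MaleSequence], T: int = 30):
        self.T = int(T)
        self.males: list[MaleSequence] = list(males)
        keys = [m.key for m in self.males]
        if len(set(keys)) != len(keys):
            raise ObservationError("duplicate male keys in observation table")

    def __len__(self) -> int:
        return len(self.males)

    def __iter__(self):
        return iter(self.males)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame, one row per (male, timepoint)."""
        rows = []
        for m in self.males:
            for t, s in enumerate(m.ordinal_seq):
                rows.append(
                    (m.line, m.block, m.trial, m.arena, m.male, t, s)
                )
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def summary(self) -> pd.DataFrame:
        """Per-male summary: keys, MMP score, noninitiator flag."""
        rows = [
            (m.line, m.block, m.trial, m.arena, m.male, m.mmp,
             m.noninitiator)
            for m in self.males
        ]
        return pd.DataFrame(
            rows,
            columns=["line", "block", "trial", "arena", "male", "mmp",
                     "noninitiator"],
        )

    def noninitiator_proportions(self) -> pd.Series:
        """Per-line proportion of males flagged as noninitiators."""
        s = self.summary()
        return s.groupby("line")["noninitiator"].mean().rename("proportion")

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        T: int = 30,
        strict: bool = True,
        column_map: Mapping[str, str] | None = None,
    ) -> "ObservationTable":
        """Build a validated table from a long-format DataFrame.

        ``column_map`` maps the canonical column names (line, block, trial,
        arena, male, timepoint, score) to the names used in ``df``. An
        optional boolean ``exclude`` column drops flagged males (injured or
        dead flies) at read time. Under ``strict`` males with missing or
        duplicated timepoints are dropped with a report; otherwise partial
        sequences are kept.
        """
        colmap = {c: c for c in REQUIRED_COLUMNS}
        if column_map:
            colmap.update(column_map)
        missing = [c for c in REQUIRED_COLUMNS if colmap[c] not in df.columns]
        if missing:
            raise ObservationError(
                f"missing required column(s): {', '.join(missing)}"
            )
        df = df.rename(columns={v: k for k, v in colmap.items()})

        bad = df[~df["score"].astype(float).isin(range(1, 9))]
        if len(bad):
            rows = ", ".join(str(i) for i in bad.index[:10])
            raise ObservationError(
                f"{len(bad)} row(s) with ordinal score outside 1..8 "
                f"(rows: {rows})"
            )

        if "exclude" in df.columns:
            key_cols = ["line", "block", "trial", "arena", "male"]
            excluded = df.groupby(key_cols)["exclude"].any()
            df = df.set_index(key_cols).loc[~excluded].reset_index()

        males: list[MaleSequence] = []
        dropped: list[tuple] = []
        for key, grp in df.groupby(
            ["line", "block", "trial", "arena", "male"], sort=True
        ):
            tp = grp["timepoint"].astype(int).to_numpy()
            if len(set(tp)) != len(tp):
                raise ObservationError(
                    f"duplicate (male, timepoint) for male {key}"
                )
            grp = grp.sort_values("timepoint")
            tps = grp["timepoint"].astype(int).to_list()
            complete = tps == list(range(T))
            if not complete and strict:
                dropped.append(key)
                continue
            males.append(
                MaleSequence(*(str(k) for k in key),
                             ordinal_seq=grp["score"].astype(int).to_list())
            )
        table = cls(males, T=T)
        table.dropped_males = dropped
        return table


def read_observations(
    path,
    sep: str = "\t",
    T: int = 30,
    strict: bool = True,
    column_map: Mapping[str, str] | None = None,
) -> ObservationTable:
    """Read a long-format TSV/CSV of scan-sampled observations.

    One row per (male, timepoint); required columns line, block, trial,
    arena, male, timepoint, score (names remappable via ``column_map``).
    """
    df = pd.read_csv(path, sep=sep)
    return ObservationTable.from_frame(
        df, T=T, strict=strict, column_map=column_map
    )
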