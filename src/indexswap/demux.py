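"""Demultiplexing and swap classification for non-redundant dual indexes.

Each cluster's observed (i7, i5) pair is resolved against the sample
sheet's per-end index lists.  Under a non-redundant scheme every index
belongs to exactly one sample, so a resolved pair either points at one
sample (matched) or at two different samples — direct evidence that one end
swapped.  Reads failing the index-read quality filter, or whose indexes do
not resolve within the pool at the allowed mismatch tolerance, are excluded
from all swap statistics; foreign indexes therefore never contaminate the
swap matrix, which is what makes within-pool swapping distinguishable from
outside contamination.

Filter precedence is quality → per-end match → pair consistency; the order
matters because it fixes the denominator of every downstream rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .index_sets import DualIndexSet, hamming_distance, min_pairwise_distance
from .simulate import ReadRecord

logger = logging.getLogger(__name__)


class UndefinedRateError(ZeroDivisionError):
    """Swap rate requested on a table with no qualifying reads."""


class ReadClass(Enum):
    MATCHED = "matched"
    SWAPPED = "swapped"
    UNDETERMINED = "undetermined"
    LOW_QUALITY = "low_quality"


class MatchFailure(Enum):
    NO_MATCH = "no_match"
    AMBIGUOUS = "ambiguous"


NO_MATCH = MatchFailure.NO_MATCH
AMBIGUOUS = MatchFailure.AMBIGUOUS


def mean_phred(qual: str) -> float:
    """Mean Phred quality of a Sanger-encoded (+33) quality string."""
    if not qual:
        raise ValueError("empty quality string")
    raw = qual.encode("ascii")
    return sum(raw) / len(raw) - 33.0


def match_index(
    observed: str, candidates: Sequence[str], max_mismatch: int = 1
) -> int | MatchFailure:
    """Resolve an observed index against a candidate list.

    Returns the position of the unique candidate within ``max_mismatch``
    Hamming distance; ``NO_MATCH`` if none qualifies; ``AMBIGUOUS`` if more
    than one does (a conservative rule — a second qualifying candidate at
    any distance spoils the call).
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    hit: int | None = None
    for i, cand in enumerate(candidates):
        if hamming_distance(observed, cand) <= max_mismatch:
            if hit is not None:
                return AMBIGUOUS
            hit = i
    return hit if hit is not None else NO_MATCH


@dataclass(slots=True)
class ReadAssignment:
    """Outcome of classifying one read against the sample sheet."""

    read_class: ReadClass
    sample_id: str | None = None   # MATCHED only
    i7_owner: str | None = None    # MATCHED and SWAPPED
    i5_owner: str | None = None


class Demultiplexer:
    """Streaming classifier for observed index pairs.

    When the sheet's per-end minimum pairwise distance exceeds
    ``2 * max_mismatch``, at most one candidate can ever qualify for a
    query, so an exact-dictionary hit is provably unique and the linear
    scan runs only for inexact observations.  Sheets without that margin
    fall back to a full scan per read to honour the ambiguity rule.
    """

    def __init__(
        self,
        sheet: DualIndexSet,
        max_mismatch: int = 1,
        min_mean_q: float = 30.0,
    ):
        sheet.require_non_redundant()
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.sheet = sheet
        self.max_mismatch = max_mismatch
        self.min_mean_q = min_mean_q
        self._ids = sheet.sample_ids
        self._i7 = sheet.i7_list
        self._i5 = sheet.i5_list
        self._i7_exact = {s: i for i, s in enumerate(self._i7)}
        self._i5_exact = {s: i for i, s in enumerate(self._i5)}
        self._exact_is_unique = {
            end: (
                len(seqs) < 2
                or min_pairwise_distance(seqs) > 2 * max_mismatch
            )
            for end, seqs in (("i7", self._i7), ("i5", self._i5))
        }

    def _resolve(self, observed: str, end: str) -> int | MatchFailure:
        exact = self._i7_exact if end == "i7" else self._i5_exact
        seqs = self._i7 if end == "i7" else self._i5
        if self._exact_is_unique[end]:
            hit = exact.get(observed)
            if hit is not None:
                return hit
            if self.max_mismatch == 0:
                return NO_MATCH
        return match_index(observed, seqs, self.max_mismatch)

    def classify(
        self, i7_obs: str, i5_obs: str, i7_qual: str, i5_qual: str
    ) -> ReadAssignment:
        if (
            mean_phred(i7_qual) < self.min_mean_q
            or mean_phred(i5_qual) < self.min_mean_q
        ):
            return ReadAssignment(ReadClass.LOW_QUALITY)
        r7 = self._resolve(i7_obs, "i7")
        r5 = self._resolve(i5_obs, "i5")
        if isinstance(r7, MatchFailure) or isinstance(r5, MatchFailure):
            return ReadAssignment(ReadClass.UNDETERMINED)
        if r7 == r5:
            sid = self._ids[r7]
            return ReadAssignment(ReadClass.MATCHED, sid, sid, sid)
        return ReadAssignment(
            ReadClass.SWAPPED, None, self._ids[r7], self._ids[r5]
        )

    def classify_record(self, record: ReadRecord) -> ReadAssignment:
        return self.classify(
            record.i7_obs, record.i5_obs, record.i7_qual, record.i5_qual
        )


def classify_read(
    record: ReadRecord,
    sheet: DualIndexSet,
    max_mismatch: int = 1,
    min_mean_q: float = 30.0,
) -> ReadAssignment:
    """One-shot form of :meth:`Demultiplexer.classify_record`."""
    return Demultiplexer(sheet, max_mismatch, min_mean_q).classify_record(record)


@dataclass
class SwapCountTable:
    """Read counts over (i7 owner × i5 owner) combinations plus tallies.

    The diagonal holds matched reads; every off-diagonal cell is a detected
    swap combination.  Undetermined and low-quality reads are tallied
    outside the matrix, so ``matrix.sum() + undetermined_count +
    low_quality_count == total_reads``.
    """

    samples: list[str]
    matrix: np.ndarray
    undetermined_count: int = 0
    low_quality_count: int = 0
    total_reads: int = 0

    @classmethod
    def empty(cls, samples: Sequence[str]) -> "SwapCountTable":
        n = len(samples)
        return cls(list(samples), np.zeros((n, n), dtype=np.int64))

    @property
    def matched_count(self) -> int:
        return int(np.trace(self.matrix))

    @property
    def swapped_count(self) -> int:
        return int(self.matrix.sum() - np.trace(self.matrix))

    @property
    def qualifying_count(self) -> int:
        """Reads whose both indexes resolved within the pool."""
        return int(self.matrix.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.samples, columns=self.samples
        )


@dataclass
class TileCountGrid:
    """Per-(surface, swath, tile) swapped and classified read counts."""

    counts: dict[tuple[int, int, int], list[int]] = field(default_factory=dict)

    def add(self, tile: tuple[int, int, int], swapped: bool) -> None:
        cell = self.counts.setdefault(tile, [0, 0])
        cell[0] += int(swapped)
        cell[1] += 1

    @property
    def swapped_total(self) -> int:
        return sum(c[0] for c in self.counts.values())

    @property
    def classified_total(self) -> int:
        return sum(c[1] for c in self.counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (s, w, t, c[0], c[1])
            for (s, w, t), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["surface", "swath", "tile", "swapped", "total"]
        )


def tabulate(
    records: Iterable[ReadRecord],
    sheet: DualIndexSet,
    max_mismatch: int = 1,
    min_mean_q: float = 30.0,
) -> tuple[SwapCountTable, TileCountGrid]:
    """Single-pass classification of a read stream into count tables."""
    dm = Demultiplexer(sheet, max_mismatch, min_mean_q)
    pos = {sid: i for i, sid in enumerate(sheet.sample_ids)}
    table = SwapCountTable.empty(sheet.sample_ids)
    grid = TileCountGrid()
    warned_no_tile = False
    for rec in records:
        a = dm.classify_record(rec)
        table.total_reads += 1
        if a.read_class is ReadClass.LOW_QUALITY:
            table.low_quality_count += 1
            continue
        if a.read_class is ReadClass.UNDETERMINED:
            table.undetermined_count += 1
            continue
        table.matrix[pos[a.i7_owner], pos[a.i5_owner]] += 1
        if rec.tile is not None:
            grid.add(rec.tile, a.read_class is ReadClass.SWAPPED)
        elif not warned_no_tile:
            logger.info("records without tile info: counted in the table, "
                        "skipped in the tile grid")
            warned_no_tile = True
    return table, grid


def swap_rate(table: SwapCountTable) -> float:
    """Detected swap fraction among pool-resolved, quality-passing reads.

    Denominator is matched + swapped reads only (all passing-filter reads
    whose high-quality index reads both match an index used within the
    pool); undetermined and low-quality reads are excluded.
    """
    denom = table.qualifying_count
    if denom == 0:
        raise UndefinedRateError(
            "no qualifying reads: swap rate is undefined"
        )
    return table.swapped_count / denom
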