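"""Design and validation of non-redundant dual-index sets.

Unique ("non-redundant") dual indexing assigns every pooled sample an i7
barcode and an i5 barcode that no other sample in the pool uses on either
end.  Any single index swap then produces a barcode combination that is
absent from the sample sheet and can be filtered at demultiplexing; only a
double swap landing on another sample's exact pair escapes detection.

This module provides the sequence-level primitives (Hamming distance,
pairwise-distance scans), a constraint checker for the properties that make
index sets robust in practice (end-wise uniqueness, minimum pairwise
Hamming distance, GC content, homopolymer runs, per-cycle color balance),
and a seeded rejection-sampling designer that produces sets passing those
constraints.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

INDEX_ALPHABET = frozenset("ACGT")
DEFAULT_INDEX_LENGTH = 8


class IndexSetError(ValueError):
    """Malformed index sequence, sample sheet, or constraint set."""


class DesignSearchError(RuntimeError):
    """Raised when the rejection-sampling designer exhausts its budget."""

    def __init__(self, message: str, attempts: int):
        super().__init__(f"{message} (attempts made: {attempts})")
        self.attempts = attempts


def as_index(seq: str, length: int | None = None) -> str:
    """Canonicalize an index sequence: uppercase, alphabet {A,C,G,T} only."""
    s = str(seq).strip().upper()
    if not s:
        raise IndexSetError("empty index sequence")
    bad = set(s) - INDEX_ALPHABET
    if bad:
        raise IndexSetError(
            f"index {s!r} contains invalid characters {sorted(bad)}; "
            "alphabet is A/C/G/T"
        )
    if length is not None and len(s) != length:
        raise IndexSetError(f"index {s!r} has length {len(s)}, expected {length}")
    return s


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise IndexSetError(
            f"length mismatch: {len(a)} vs {len(b)} ({a!r} vs {b!r})"
        )
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_distance(seqs: Sequence[str]) -> int:
    """Minimum Hamming distance over all unordered pairs of sequences."""
    if len(seqs) < 2:
        raise IndexSetError("need at least 2 sequences for a pairwise distance")
    return min(hamming_distance(a, b) for a, b in combinations(seqs, 2))


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


@dataclass(frozen=True)
class IndexEntry:
    """One sample's row in a dual-index sample sheet."""

    sample_id: str
    i7: str
    i5: str


@dataclass
class DualIndexSet:
    """An ordered dual-index sample sheet (the pool definition).

    Invariants enforced at construction: unique sample ids, canonical
    uppercase sequences, one common index length per end across entries.
    End-wise sequence uniqueness (the non-redundancy property) is a
    *validated* property, not a construction invariant, so that deliberately
    redundant sheets can still be loaded and reported on.
    """

    entries: list[IndexEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise IndexSetError("sample sheet has no entries")
        canonical = []
        seen_ids: set[str] = set()
        for e in self.entries:
            sid = str(e.sample_id).strip()
            if not sid:
                raise IndexSetError("empty sample_id")
            if sid in seen_ids:
                raise IndexSetError(f"duplicate sample_id {sid!r}")
            seen_ids.add(sid)
            canonical.append(IndexEntry(sid, as_index(e.i7), as_index(e.i5)))
        self.entries = canonical
        for attr in ("i7", "i5"):
            lengths = {len(getattr(e, attr)) for e in self.entries}
            if len(lengths) > 1:
                raise IndexSetError(
                    f"inconsistent {attr} lengths: {sorted(lengths)}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def i7_list(self) -> list[str]:
        return [e.i7 for e in self.entries]

    @property
    def i5_list(self) -> list[str]:
        return [e.i5 for e in self.entries]

    @property
    def index_length(self) -> int:
        return len(self.entries[0].i7)

    def is_non_redundant(self) -> bool:
        return len(set(self.i7_list)) == len(self) and len(
            set(self.i5_list)
        ) == len(self)

    def require_non_redundant(self) -> None:
        if not self.is_non_redundant():
            raise IndexSetError(
                "sample sheet is not non-redundant: an i7 or i5 sequence is "
                "shared between samples"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "DualIndexSet":
        return cls([IndexEntry(sid, i7, i5) for sid, i7, i5 in records])


class Chemistry(str, Enum):
    """Illumina imaging chemistry, which sets the per-cycle signal rule."""

    FOUR_COLOR = "four_color"
    TWO_COLOR = "two_color"


# Channel coverage required at every cycle, per chemistry.  Two-color
# instruments read A as red+green, C as red, T as green and G as dark, so a
# cycle needs at least one red-channel base {A,C} and one green-channel base
# {A,T} across the set.  Four-color instruments pair A/C on one laser and
# G/T on the other.
_CHANNEL_RULES: dict[Chemistry, tuple[tuple[str, frozenset[str]], ...]] = {
    Chemistry.TWO_COLOR: (
        ("red", frozenset("AC")),
        ("green", frozenset("AT")),
    ),
    Chemistry.FOUR_COLOR: (
        ("A/C laser", frozenset("AC")),
        ("G/T laser", frozenset("GT")),
    ),
}


@dataclass
class IndexConstraints:
    """Sequence-quality constraints for a dual-index set.

    min_hamming=3 permits confident single-mismatch correction on 8-mers;
    the GC window and homopolymer cap reflect conventional oligo synthesis
    and sequencing robustness.  Color balance is a set-level property and is
    opt-in because small sets (a single entry in the extreme) cannot cover
    both channels at every cycle.
    """

    min_hamming: int = 3
    gc_min: float = 0.25
    gc_max: float = 0.75
    max_homopolymer: int = 2
    chemistry: Chemistry = Chemistry.FOUR_COLOR
    require_color_balance: bool = False

    def __post_init__(self) -> None:
        self.chemistry = Chemistry(self.chemistry)
        if self.min_hamming < 0:
            raise IndexSetError("min_hamming must be >= 0")
        if self.max_homopolymer < 1:
            raise IndexSetError("max_homopolymer must be >= 1")
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise IndexSetError("require 0 <= gc_min <= gc_max <= 1")


@dataclass(frozen=True)
class Violation:
    constraint: str
    samples: tuple[str, ...]
    detail: str


@dataclass
class IndexSetReport:
    """Constraint-by-constraint validation result for a dual-index set."""

    passed: bool
    min_pairwise_distance_i7: int | None
    min_pairwise_distance_i5: int | None
    violations: list[Violation] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "min_pairwise_distance_i7": self.min_pairwise_distance_i7,
            "min_pairwise_distance_i5": self.min_pairwise_distance_i5,
            "violations": [
                {
                    "constraint": v.constraint,
                    "samples": list(v.samples),
                    "detail": v.detail,
                }
                for v in self.violations
            ],
        }


def _uniqueness_violations(
    end: str, seqs: list[str], ids: list[str]
) -> list[Violation]:
    by_seq: dict[str, list[str]] = {}
    for sid, s in zip(ids, seqs):
        by_seq.setdefault(s, []).append(sid)
    return [
        Violation(
            f"{end}_unique",
            tuple(sids),
            f"{end} sequence {s} shared by {len(sids)} samples",
        )
        for s, sids in by_seq.items()
        if len(sids) > 1
    ]


def _color_balance_violations(
    end: str, seqs: list[str], ids: list[str], chemistry: Chemistry
) -> list[Violation]:
    out = []
    for cycle in range(len(seqs[0])):
        bases = {s[cycle] for s in seqs}
        for channel, members in _CHANNEL_RULES[chemistry]:
            if not bases & members:
                out.append(
                    Violation(
                        "color_balance",
                        tuple(ids),
                        f"{end} cycle {cycle + 1}: no base in the "
                        f"{channel} channel ({chemistry.value})",
                    )
                )
    return out


def validate_dual_index_set(
    index_set: DualIndexSet, constraints: IndexConstraints
) -> IndexSetReport:
    """Check a dual-index set against every constraint, in a fixed order.

    Order: end-wise uniqueness (i7 then i5), minimum pairwise Hamming
    distance per end, per-index GC window, homopolymer cap, and (if
    requested) per-cycle color balance per end.
    """
    ids = index_set.sample_ids
    violations: list[Violation] = []

    violations += _uniqueness_violations("i7", index_set.i7_list, ids)
    violations += _uniqueness_violations("i5", index_set.i5_list, ids)

    dists: dict[str, int | None] = {"i7": None, "i5": None}
    for end, seqs in (("i7", index_set.i7_list), ("i5", index_set.i5_list)):
        if len(seqs) >= 2:
            dists[end] = min_pairwise_distance(seqs)
            if dists[end] < constraints.min_hamming:
                offenders = [
                    (ids[i], ids[j])
                    for i, j in combinations(range(len(seqs)), 2)
                    if hamming_distance(seqs[i], seqs[j]) < constraints.min_hamming
                ]
                for a, b in offenders:
                    violations.append(
                        Violation(
                            f"{end}_min_distance",
                            (a, b),
                            f"{end} pair below Hamming distance "
                            f"{constraints.min_hamming}",
                        )
                    )

    for e in index_set:
        for end, seq in (("i7", e.i7), ("i5", e.i5)):
            gc = gc_fraction(seq)
            if not (constraints.gc_min <= gc <= constraints.gc_max):
                violations.append(
                    Violation(
                        "gc_content",
                        (e.sample_id,),
                        f"{end} {seq} GC {gc:.3f} outside "
                        f"[{constraints.gc_min}, {constraints.gc_max}]",
                    )
                )

    for e in index_set:
        for end, seq in (("i7", e.i7), ("i5", e.i5)):
            run = max_homopolymer_run(seq)
            if run > constraints.max_homopolymer:
                violations.append(
                    Violation(
                        "homopolymer",
                        (e.sample_id,),
                        f"{end} {seq} has a homopolymer run of {run} "
                        f"(max {constraints.max_homopolymer})",
                    )
                )

    if constraints.require_color_balance:
        violations += _color_balance_violations(
            "i7", index_set.i7_list, ids, constraints.chemistry
        )
        violations += _color_balance_violations(
            "i5", index_set.i5_list, ids, constraints.chemistry
        )

    return IndexSetReport(
        passed=not violations,
        min_pairwise_distance_i7=dists["i7"],
        min_pairwise_distance_i5=dists["i5"],
        violations=violations,
    )


_BASES = "ACGT"


def _passes_sequence_rules(seq: str, constraints: IndexConstraints) -> bool:
    return (
        constraints.gc_min <= gc_fraction(seq) <= constraints.gc_max
        and max_homopolymer_run(seq) <= constraints.max_homopolymer
    )


def _design_end_list(
    n: int,
    length: int,
    constraints: IndexConstraints,
    rng: random.Random,
    attempts_per_slot: int,
) -> list[str]:
    min_d = max(constraints.min_hamming, 1)  # non-redundancy needs >= 1
    accepted: list[str] = []
    for _ in range(n):
        for attempt in range(attempts_per_slot):
            seq = "".join(rng.choice(_BASES) for _ in range(length))
            if not _passes_sequence_rules(seq, constraints):
                continue
            if all(hamming_distance(seq, a) >= min_d for a in accepted):
                accepted.append(seq)
                break
        else:
            raise DesignSearchError(
                f"could not place index {len(accepted) + 1} of {n}",
                attempts_per_slot,
            )
    return accepted


def design_index_set(
    n: int,
    constraints: IndexConstraints,
    seed: int,
    length: int = DEFAULT_INDEX_LENGTH,
    sample_prefix: str = "S",
    attempts_per_slot: int = 10_000,
    max_restarts: int = 25,
) -> DualIndexSet:
    """Design an n-sample non-redundant dual-index set by rejection sampling.

    Sequences are proposed uniformly at random and accepted greedily when
    they satisfy the per-sequence rules and the pairwise distance against
    previously accepted sequences of the same end; i7 and i5 lists are
    designed independently (swaps are within-end phenomena).  The finished
    set is re-validated — set-level constraints such as color balance can
    only be judged there — and the whole search restarts on failure.
    Deterministic for a given (n, constraints, seed, length).
    """
    if n < 1:
        raise IndexSetError("n must be >= 1")
    rng = random.Random(seed)
    total_attempts = 0
    for _ in range(max_restarts):
        try:
            i7s = _design_end_list(n, length, constraints, rng, attempts_per_slot)
            i5s = _design_end_list(n, length, constraints, rng, attempts_per_slot)
        except DesignSearchError as err:
            total_attempts += err.attempts
            continue
        width = max(2, len(str(n)))
        ds = DualIndexSet(
            [
                IndexEntry(f"{sample_prefix}{i + 1:0{width}d}", i7, i5)
                for i, (i7, i5) in enumerate(zip(i7s, i5s))
            ]
        )
        total_attempts += 1
        if validate_dual_index_set(ds, constraints).passed:
            return ds
    raise DesignSearchError(
        f"no satisfying {n}-entry set found after {max_restarts} restarts",
        total_attempts,
    )
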