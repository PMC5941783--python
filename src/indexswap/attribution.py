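"""Swap-end attribution for a two-organism mixture pool.

Pooling libraries from two organisms under non-redundant dual indexes makes
the swapped *end* of a fragment partially identifiable: assuming every read
maps to its organism of origin, an index owned by the other organism must
be the one that swapped.  Within-organism swaps remain end-ambiguous and
are allocated between the two ends in proportion to the cross-organism
("known") i7:i5 swap counts.  Double swaps — both indexes owned by the
other organism, or a read carrying another organism's complete valid pair —
are counted toward both ends.

The per-end probability estimates divide the allocated end totals by all
quality-passing reads whose indexes resolved within the pool
(non-swapped + undetermined-end + known i7 + known i5 + double).
Intermediate arithmetic is exact (rational), so the allocation identity
``est_i7 + est_i5 == undetermined + known_i7 + known_i5 + 2·double`` holds
to the last integer; rounding happens only at reporting time (half-up,
4 decimal places).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .demux import ReadAssignment, ReadClass


class AllocationError(ValueError):
    """Undetermined-end swaps cannot be allocated without known-end counts."""


class UnsupportedDesignError(ValueError):
    """The attribution model requires exactly two organism labels."""


class SwapEndClass(Enum):
    NON_SWAP = "non_swap"
    UNDETERMINED_END = "undetermined_end"
    I7_SWAP = "i7_swap"
    I5_SWAP = "i5_swap"
    DOUBLE_SWAP = "double_swap"


def classify_swap_end(
    read_class: ReadClass,
    read_organism: str,
    i7_organism: str,
    i5_organism: str,
) -> SwapEndClass:
    """Classify one pool-resolved read's swap by end.

    ``read_class`` is the demultiplexer's pair-consistency call (MATCHED or
    SWAPPED); the three organism labels are the read's mapped organism and
    the organisms owning the resolved i7 and i5 indexes.  A MATCHED pair
    owned by the *other* organism is the silent double-swap case.
    """
    if read_class not in (ReadClass.MATCHED, ReadClass.SWAPPED):
        raise ValueError(
            "swap-end classification applies only to pool-resolved reads "
            f"(MATCHED or SWAPPED), got {read_class}"
        )
    hop7 = i7_organism != read_organism
    hop5 = i5_organism != read_organism
    if hop7 and hop5:
        return SwapEndClass.DOUBLE_SWAP
    if hop7:
        return SwapEndClass.I7_SWAP
    if hop5:
        return SwapEndClass.I5_SWAP
    if read_class is ReadClass.MATCHED:
        return SwapEndClass.NON_SWAP
    return SwapEndClass.UNDETERMINED_END


@dataclass
class AttributionCounts:
    """Tallies over SwapEndClass for one run."""

    non_swapped: int = 0
    undetermined: int = 0
    known_i7: int = 0
    known_i5: int = 0
    double: int = 0

    _FIELD_OF = {
        SwapEndClass.NON_SWAP: "non_swapped",
        SwapEndClass.UNDETERMINED_END: "undetermined",
        SwapEndClass.I7_SWAP: "known_i7",
        SwapEndClass.I5_SWAP: "known_i5",
        SwapEndClass.DOUBLE_SWAP: "double",
    }

    def add(self, cls: SwapEndClass) -> None:
        name = self._FIELD_OF[cls]
        setattr(self, name, getattr(self, name) + 1)

    @property
    def total(self) -> int:
        return (
            self.non_swapped
            + self.undetermined
            + self.known_i7
            + self.known_i5
            + self.double
        )


def count_swap_ends(
    assignments: Iterable[tuple[ReadAssignment, str]],
    organism_of: Mapping[str, str],
) -> AttributionCounts:
    """Tally swap-end classes over (assignment, read organism) pairs.

    Only MATCHED and SWAPPED assignments contribute; others are ignored
    (they never enter the attribution denominator).  Raises
    :class:`UnsupportedDesignError` unless ``organism_of`` carries exactly
    two labels.
    """
    labels = set(organism_of.values())
    if len(labels) != 2:
        raise UnsupportedDesignError(
            f"attribution requires exactly 2 organism labels, got "
            f"{len(labels)}: {sorted(labels)}"
        )
    counts = AttributionCounts()
    for assignment, organism in assignments:
        if assignment.read_class not in (ReadClass.MATCHED, ReadClass.SWAPPED):
            continue
        counts.add(
            classify_swap_end(
                assignment.read_class,
                organism,
                organism_of[assignment.i7_owner],
                organism_of[assignment.i5_owner],
            )
        )
    return counts


def round_half_up(x: float | Fraction, ndigits: int = 4) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def _nearest_int(x: Fraction) -> int:
    return int((x + Fraction(1, 2)).__floor__())


@dataclass
class MixtureAttribution:
    """End-classified swap counts and per-end probability estimates.

    ``total_pf`` is the attribution denominator N′ = non_swapped +
    undetermined + known_i7 + known_i5 + double.  When independently
    tallied swapped/PF totals are supplied, ``p_total`` uses them and
    ``swapped_total_discrepancy`` records how far they sit from the
    component sum; otherwise ``p_total`` is the component-based rate.
    Estimated totals are kept exact internally (``est_total_i7_exact``).
    """

    non_swapped: int
    undetermined: int
    known_i7: int
    known_i5: int
    double: int
    est_total_i7_exact: Fraction
    est_total_i5_exact: Fraction
    supplied_total_pf: int | None = None
    supplied_total_swapped: int | None = None

    @property
    def total_pf(self) -> int:
        return (
            self.non_swapped
            + self.undetermined
            + self.known_i7
            + self.known_i5
            + self.double
        )

    @property
    def swapped_component_total(self) -> int:
        return self.undetermined + self.known_i7 + self.known_i5 + self.double

    @property
    def swapped_total_discrepancy(self) -> int | None:
        if self.supplied_total_swapped is None:
            return None
        return self.supplied_total_swapped - self.swapped_component_total

    @property
    def est_total_i7(self) -> float:
        return float(self.est_total_i7_exact)

    @property
    def est_total_i5(self) -> float:
        return float(self.est_total_i5_exact)

    @property
    def p_i7(self) -> float:
        return float(self.est_total_i7_exact / self.total_pf)

    @property
    def p_i5(self) -> float:
        return float(self.est_total_i5_exact / self.total_pf)

    @property
    def p_total(self) -> float:
        if (
            self.supplied_total_swapped is not None
            and self.supplied_total_pf is not None
        ):
            return self.supplied_total_swapped / self.supplied_total_pf
        return self.swapped_component_total / self.total_pf

    def to_dict(self) -> dict:
        """Report dictionary with display rounding (4 d.p. / nearest int)."""
        out = {
            "Total PF indexed reads": self.supplied_total_pf
            if self.supplied_total_pf is not None
            else self.total_pf,
            "Total Non-swapped reads": self.non_swapped,
            "Total swapped reads": self.supplied_total_swapped
            if self.supplied_total_swapped is not None
            else self.swapped_component_total,
            "Undetermined i7 or i5 swaps": self.undetermined,
            "Known i7 swaps": self.known_i7,
            "Known i5 swaps": self.known_i5,
            "Known double i7 and i5 swaps": self.double,
            "Estimated total i7 swaps": _nearest_int(self.est_total_i7_exact),
            "Estimated total i5 swaps": _nearest_int(self.est_total_i5_exact),
            "p(Total Swap)": round_half_up(self.p_total),
            "p(i7 Swap)": round_half_up(self.p_i7),
            "p(i5 Swap)": round_half_up(self.p_i5),
            "swapped_component_total": self.swapped_component_total,
        }
        if self.swapped_total_discrepancy is not None:
            out["swapped_total_discrepancy"] = self.swapped_total_discrepancy
            out["p(Total Swap, component-based)"] = round_half_up(
                self.swapped_component_total / self.total_pf
            )
        return out


def estimate_attribution(
    non_swapped: int,
    undetermined: int,
    known_i7: int,
    known_i5: int,
    double: int,
    total_pf: int | None = None,
    total_swapped: int | None = None,
) -> MixtureAttribution:
    """Proportional-allocation estimate of per-end swap totals.

    Undetermined-end swaps are split between the ends by the known-count
    ratio; double swaps count toward both ends::

        est_i7 = K7/(K7+K5) · U + K7 + D
        est_i5 = K5/(K7+K5) · U + K5 + D

    Both estimates divide by N′ = non_swapped + U + K7 + K5 + D to give the
    per-end swap probabilities.
    """
    counts = dict(
        non_swapped=non_swapped,
        undetermined=undetermined,
        known_i7=known_i7,
        known_i5=known_i5,
        double=double,
    )
    for name, v in counts.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    known = known_i7 + known_i5
    if undetermined > 0 and known == 0:
        raise AllocationError(
            "cannot allocate undetermined-end swaps with zero known-end swaps"
        )
    if known > 0:
        frac7 = Fraction(known_i7, known)
    else:
        frac7 = Fraction(0)
    est7 = frac7 * undetermined + known_i7 + double
    est5 = (1 - frac7) * undetermined + known_i5 + double
    return MixtureAttribution(
        non_swapped=non_swapped,
        undetermined=undetermined,
        known_i7=known_i7,
        known_i5=known_i5,
        double=double,
        est_total_i7_exact=est7,
        est_total_i5_exact=est5,
        supplied_total_pf=total_pf,
        supplied_total_swapped=total_swapped,
    )


GC_BIN_WIDTH = 0.05


@dataclass
class PopulationComparison:
    """Fragment-metric contrast between swapped and non-swapped reads.

    ``gc_ratio`` is each population's normalized GC histogram divided by
    the non-swapped histogram, bin width 0.05 over [0, 1].  Metrics of an
    empty population are NaN, never zero.
    """

    n_swapped: int
    n_non_swapped: int
    insert_mean_swapped: float
    insert_mean_non_swapped: float
    insert_sd_swapped: float
    insert_sd_non_swapped: float
    pct_chimeric_swapped: float
    pct_chimeric_non_swapped: float
    gc_bin_edges: np.ndarray
    gc_hist_swapped: np.ndarray
    gc_hist_non_swapped: np.ndarray
    gc_ratio: np.ndarray

    def to_dict(self) -> dict:
        def _clean(x):
            return None if (isinstance(x, float) and np.isnan(x)) else x

        return {
            "n_swapped": self.n_swapped,
            "n_non_swapped": self.n_non_swapped,
            "insert_mean_swapped": _clean(self.insert_mean_swapped),
            "insert_mean_non_swapped": _clean(self.insert_mean_non_swapped),
            "insert_sd_swapped": _clean(self.insert_sd_swapped),
            "insert_sd_non_swapped": _clean(self.insert_sd_non_swapped),
            "pct_chimeric_swapped": _clean(self.pct_chimeric_swapped),
            "pct_chimeric_non_swapped": _clean(self.pct_chimeric_non_swapped),
            "gc_bin_edges": [round(float(e), 10) for e in self.gc_bin_edges],
            "gc_ratio": [
                _clean(float(r)) for r in self.gc_ratio
            ],
        }


def _moments(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return mean, sd


def compare_populations(frame: pd.DataFrame) -> PopulationComparison:
    """Contrast swapped vs non-swapped fragment covariates.

    ``frame`` needs boolean ``swapped`` plus ``insert_len``, ``gc`` and
    ``chimeric`` columns (one row per qualifying read).
    """
    for col in ("swapped", "insert_len", "gc", "chimeric"):
        if col not in frame.columns:
            raise ValueError(f"missing column {col!r}")
    edges = np.round(np.arange(0.0, 1.0 + GC_BIN_WIDTH / 2, GC_BIN_WIDTH), 10)
    sw = frame[frame["swapped"].astype(bool)]
    ns = frame[~frame["swapped"].astype(bool)]

    def _hist(pop: pd.DataFrame) -> np.ndarray:
        if len(pop) == 0:
            return np.full(len(edges) - 1, np.nan)
        h, _ = np.histogram(pop["gc"].to_numpy(dtype=float), bins=edges)
        return h / h.sum()

    h_sw, h_ns = _hist(sw), _hist(ns)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(h_ns > 0, h_sw / h_ns, np.nan)

    im_sw, isd_sw = _moments(sw["insert_len"].to_numpy(dtype=float))
    im_ns, isd_ns = _moments(ns["insert_len"].to_numpy(dtype=float))
    pct_sw = (
        100.0 * float(sw["chimeric"].astype(bool).mean())
        if len(sw)
        else float("nan")
    )
    pct_ns = (
        100.0 * float(ns["chimeric"].astype(bool).mean())
        if len(ns)
        else float("nan")
    )
    return PopulationComparison(
        n_swapped=len(sw),
        n_non_swapped=len(ns),
        insert_mean_swapped=im_sw,
        insert_mean_non_swapped=im_ns,
        insert_sd_swapped=isd_sw,
        insert_sd_non_swapped=isd_ns,
        pct_chimeric_swapped=pct_sw,
        pct_chimeric_non_swapped=pct_ns,
        gc_bin_edges=edges,
        gc_hist_swapped=h_sw,
        gc_hist_non_swapped=h_ns,
        gc_ratio=ratio,
    )
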