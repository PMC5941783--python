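"""End-to-end orchestration: simulate → demultiplex → attribute → report.

A single streaming pass drives every stage: each simulated read is
classified against the sample sheet, folded into the combination matrix and
tile grid, tallied by swap-end class when organism labels are available,
and its fragment covariates accumulated for the swapped/non-swapped
contrast.  No stage sees another's internal state except through these
accumulators, and memory stays flat in the number of reads apart from the
covariate arrays kept for the population comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .attribution import (
    AttributionCounts,
    MixtureAttribution,
    PopulationComparison,
    classify_swap_end,
    compare_populations,
    estimate_attribution,
)
from .demux import (
    Demultiplexer,
    ReadClass,
    SwapCountTable,
    TileCountGrid,
    swap_rate,
)
from .simulate import ReadRecord, SimulationConfig, simulate_pool

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    table: SwapCountTable
    grid: TileCountGrid
    attribution: MixtureAttribution | None
    populations: PopulationComparison | None
    report: dict

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.report, indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def classify_stream(
    records: Iterable[ReadRecord],
    demultiplexer: Demultiplexer,
    organism_of: dict[str, str] | None = None,
    collect_populations: bool = True,
) -> tuple[
    SwapCountTable,
    TileCountGrid,
    AttributionCounts | None,
    pd.DataFrame | None,
]:
    """One pass over a read stream, feeding every accumulator at once."""
    sheet = demultiplexer.sheet
    pos = {sid: i for i, sid in enumerate(sheet.sample_ids)}
    table = SwapCountTable.empty(sheet.sample_ids)
    grid = TileCountGrid()
    att = AttributionCounts() if organism_of else None
    pop_rows: list[tuple[bool, float, float, bool]] | None = (
        [] if collect_populations else None
    )
    warned_no_tile = False

    for rec in records:
        a = demultiplexer.classify_record(rec)
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
            logger.info("records without tile info are skipped in the grid")
            warned_no_tile = True
        if att is not None and rec.organism is not None:
            att.add(
                classify_swap_end(
                    a.read_class,
                    rec.organism,
                    organism_of[a.i7_owner],
                    organism_of[a.i5_owner],
                )
            )
        if pop_rows is not None and rec.insert_len is not None:
            pop_rows.append(
                (
                    a.read_class is ReadClass.SWAPPED,
                    rec.insert_len,
                    rec.gc,
                    bool(rec.chimeric),
                )
            )

    pop_frame = (
        pd.DataFrame(pop_rows, columns=["swapped", "insert_len", "gc", "chimeric"])
        if pop_rows is not None
        else None
    )
    return table, grid, att, pop_frame


def _tile_extremes(grid: TileCountGrid) -> dict:
    rates = [
        (c[0] / c[1], list(t))
        for t, c in grid.counts.items()
        if c[1] > 0
    ]
    if not rates:
        return {"max_rate_tile": None, "min_rate_tile": None}
    hi = max(rates)
    lo = min(rates)
    return {
        "max_rate_tile": {"tile": hi[1], "rate": hi[0]},
        "min_rate_tile": {"tile": lo[1], "rate": lo[0]},
    }


def run_pipeline(
    config: SimulationConfig,
    max_mismatch: int = 1,
    min_mean_q: float = 30.0,
    collect_populations: bool = True,
) -> PipelineResult:
    """Simulate a pool and push it through demultiplexing and attribution.

    Attribution runs only when the configuration carries organism labels
    (a two-organism mixture design); the population contrast is computed
    from the simulator's per-read truth covariates, split by the
    demultiplexer's own swapped/matched calls.  Identical configuration and
    seed give an identical report apart from the timestamp.
    """
    dm = Demultiplexer(config.samplesheet, max_mismatch, min_mean_q)
    organism_of = dict(config.organism_of) if config.organism_of else None
    table, grid, att_counts, pop_frame = classify_stream(
        simulate_pool(config), dm, organism_of, collect_populations
    )

    attribution = None
    if att_counts is not None and att_counts.total > 0:
        attribution = estimate_attribution(
            att_counts.non_swapped,
            att_counts.undetermined,
            att_counts.known_i7,
            att_counts.known_i5,
            att_counts.double,
        )
    populations = (
        compare_populations(pop_frame)
        if pop_frame is not None and len(pop_frame)
        else None
    )

    try:
        rate = swap_rate(table)
    except ZeroDivisionError:
        rate = None

    report = {
        "provenance": {
            "tool": "indexswap",
            "version": __version__,
            "seed": config.seed,
            "n_reads": config.n_reads,
            "n_samples": len(config.samplesheet),
            "max_mismatch": max_mismatch,
            "min_mean_q": min_mean_q,
            "p_swap_i7": config.p_swap_i7,
            "p_swap_i5": config.p_swap_i5,
            "index_error_rate": config.index_error_rate,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "classes": {
            "total_reads": table.total_reads,
            "matched": table.matched_count,
            "swapped": table.swapped_count,
            "undetermined": table.undetermined_count,
            "low_quality": table.low_quality_count,
        },
        "swap_rate": rate,
        "tile_extremes": _tile_extremes(grid),
        "attribution": attribution.to_dict() if attribution else None,
        "populations": populations.to_dict() if populations else None,
    }
    return PipelineResult(table, grid, attribution, populations, report)


def render_tile_heatmap_table(grid: TileCountGrid) -> str:
    """Long-format TSV of per-tile swap counts and rates.

    Columns ``surface swath tile swapped total rate``; the rate field is
    left blank (not zero) for tiles with no classified reads.
    """
    if not grid.counts:
        raise ValueError("empty tile grid")
    lines = ["surface\tswath\ttile\tswapped\ttotal\trate"]
    for (s, w, t), (swapped, total) in sorted(grid.counts.items()):
        rate = f"{swapped / total:.6f}" if total > 0 else ""
        lines.append(f"{s}\t{w}\t{t}\t{swapped}\t{total}\t{rate}")
    return "\n".join(lines) + "\n"
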