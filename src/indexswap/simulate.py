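"""Synthetic pooled dual-indexed read populations with index swapping.

The generator emulates the index reads (I1 = i7, I2 = i5) of a pooled
sequencing lane on a patterned flow cell.  Each simulated cluster draws a
true sample from the pool, fragment covariates (insert length, GC), and then
— independently per adapter end — may undergo an index swap: the end's
barcode is replaced by one drawn from the pool's index pool in proportion to
sample abundance, the "free adapter" model in which the mass of stray index
oligo tracks library mass.  Replacement by the read's own index is allowed
and produces no detectable swap, which is exactly the self-swap blind spot
of real pools.  Swap propensity is optionally tilted toward short, AT-rich
fragments through a logistic link, mirroring the observation that such
fragments amplify (and therefore swap) more readily.  Per-base index
sequencing errors, a two-level quality model, a uniform tile grid and a
chimerism flag complete the record.

Every read carries full ground truth, so downstream demultiplexing and
attribution can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .index_sets import DualIndexSet

_CHUNK = 65_536
_ALT_BASES = {b: "ACGT".replace(b, "") for b in "ACGT"}

TRUTH_COLUMNS = [
    "read_id",
    "true_sample",
    "i7_source",
    "i5_source",
    "organism",
    "insert_len",
    "gc",
    "chimeric",
    "surface",
    "swath",
    "tile",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(slots=True)
class ReadRecord:
    """One simulated (or parsed) cluster's index-read observation.

    ``i7_obs``/``i5_obs`` are the observed index sequences after any swap
    and sequencing error; truth fields are ``None`` for reads parsed from
    plain FASTQ.  ``i7_source``/``i5_source`` name the sample whose adapter
    the end actually carries — equal to ``true_sample`` unless a swap event
    replaced it with another sample's index (a self-replacement keeps them
    equal even though an event occurred; the event flags record that).
    """

    read_id: str
    i7_obs: str
    i5_obs: str
    i7_qual: str
    i5_qual: str
    tile: tuple[int, int, int] | None = None
    true_sample: str | None = None
    i7_source: str | None = None
    i5_source: str | None = None
    organism: str | None = None
    insert_len: float | None = None
    gc: float | None = None
    chimeric: bool | None = None
    i7_swap_event: bool | None = None
    i5_swap_event: bool | None = None


@dataclass
class SimulationConfig:
    """Parameters of one simulated pooled run.

    Probabilities are per read (swap rates are per end); ``abundances``
    defaults to an equal-mass pool.  ``p_swap_i5``/``p_swap_i7`` default to
    the per-end rates estimated for a PCR-free HiSeqX mixture pool, with i5
    swapping roughly twice as often as i7.  Covariate coefficients tilt the
    per-read swap probability on the logit scale per standard deviation of
    log insert length and of GC fraction; negative values make short and
    AT-rich fragments swap more, matching the observed direction.
    """

    samplesheet: DualIndexSet
    n_reads: int
    seed: int = 0
    abundances: Sequence[float] | None = None
    p_swap_i7: float = 0.0131
    p_swap_i5: float = 0.0302
    index_error_rate: float = 0.001
    quality_high: int = 37
    quality_low: int = 11
    tiles: tuple[int, int, int] = (2, 3, 24)
    organism_of: Mapping[str, str] | None = None
    insert_mean_log: float = math.log(350.0)
    insert_sd_log: float = 0.35
    gc_beta_a: float = 6.0
    gc_beta_b: float = 8.6
    swap_length_coeff: float = -0.3
    swap_gc_coeff: float = -0.2
    chimera_rate_base: float = 0.01
    chimera_rate_swapped: float = 0.05
    read_id_prefix: str = "sim"

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")
        self.samplesheet.require_non_redundant()
        n = len(self.samplesheet)
        if self.abundances is not None:
            ab = np.asarray(self.abundances, dtype=float)
            if ab.shape != (n,):
                raise ConfigError(
                    f"abundances must have one entry per sample ({n})"
                )
            if (ab < 0).any():
                raise ConfigError("abundances must be non-negative")
            if abs(ab.sum() - 1.0) > 1e-9:
                raise ConfigError("abundances must sum to 1 (tolerance 1e-9)")
        for name in (
            "p_swap_i7",
            "p_swap_i5",
            "index_error_rate",
            "chimera_rate_base",
            "chimera_rate_swapped",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.insert_sd_log <= 0:
            raise ConfigError("insert_sd_log must be > 0")
        if min(self.gc_beta_a, self.gc_beta_b) <= 0:
            raise ConfigError("gc Beta parameters must be > 0")
        if min(self.tiles) < 1:
            raise ConfigError("tile grid dimensions must be >= 1")
        if self.organism_of is not None:
            missing = set(self.samplesheet.sample_ids) - set(self.organism_of)
            if missing:
                raise ConfigError(
                    f"organism_of missing samples: {sorted(missing)}"
                )

    def resolved_abundances(self) -> np.ndarray:
        n = len(self.samplesheet)
        if self.abundances is None:
            return np.full(n, 1.0 / n)
        return np.asarray(self.abundances, dtype=float)


def _linked_probability(
    p_base: float, z_len: np.ndarray, z_gc: np.ndarray, c_len: float, c_gc: float
) -> np.ndarray:
    """Per-read swap probability through the logistic covariate link."""
    if p_base <= 0.0:
        return np.zeros_like(z_len)
    if p_base >= 1.0:
        return np.ones_like(z_len)
    if c_len == 0.0 and c_gc == 0.0:
        return np.full_like(z_len, p_base)
    return expit(logit(p_base) + c_len * z_len + c_gc * z_gc)


def simulate_pool(config: SimulationConfig) -> Iterator[ReadRecord]:
    """Stream ``config.n_reads`` simulated reads with full ground truth.

    All randomness comes from one generator seeded with ``config.seed`` and
    consumed in a fixed order, so identical configurations yield identical
    streams.  Reads are produced in chunks internally but yielded one at a
    time; memory stays flat in ``n_reads``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sheet = config.samplesheet
    abund = config.resolved_abundances()
    n_samples = len(sheet)
    i7_seqs = sheet.i7_list
    i5_seqs = sheet.i5_list
    ids = sheet.sample_ids
    organisms = (
        [config.organism_of[s] for s in ids] if config.organism_of else None
    )
    L = sheet.index_length
    q_high = chr(config.quality_high + 33) * L
    q_low_char = chr(config.quality_low + 33)

    # Standardization moments of the configured covariate distributions.
    a, b = config.gc_beta_a, config.gc_beta_b
    gc_mean = a / (a + b)
    gc_sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    n_surf, n_swath, n_tile = config.tiles

    emitted = 0
    while emitted < config.n_reads:
        m = min(_CHUNK, config.n_reads - emitted)
        true_idx = rng.choice(n_samples, size=m, p=abund)
        log_insert = rng.normal(config.insert_mean_log, config.insert_sd_log, m)
        insert = np.exp(log_insert)
        gc = rng.beta(a, b, m)
        z_len = (log_insert - config.insert_mean_log) / config.insert_sd_log
        z_gc = (gc - gc_mean) / gc_sd

        p7 = _linked_probability(
            config.p_swap_i7, z_len, z_gc,
            config.swap_length_coeff, config.swap_gc_coeff,
        )
        p5 = _linked_probability(
            config.p_swap_i5, z_len, z_gc,
            config.swap_length_coeff, config.swap_gc_coeff,
        )
        ev7 = rng.random(m) < p7
        ev5 = rng.random(m) < p5
        # Replacement indexes are drawn for every read (fixed draw order);
        # only reads with a swap event use them.
        repl7 = rng.choice(n_samples, size=m, p=abund)
        repl5 = rng.choice(n_samples, size=m, p=abund)
        src7 = np.where(ev7, repl7, true_idx)
        src5 = np.where(ev5, repl5, true_idx)

        if config.index_error_rate > 0.0:
            err7 = rng.random((m, L)) < config.index_error_rate
            err5 = rng.random((m, L)) < config.index_error_rate
            alt7 = rng.integers(0, 3, size=(m, L))
            alt5 = rng.integers(0, 3, size=(m, L))
            err_rows = np.nonzero(err7.any(axis=1) | err5.any(axis=1))[0]
        else:
            err7 = err5 = alt7 = alt5 = None
            err_rows = np.empty(0, dtype=int)
        err_rows = set(err_rows.tolist())

        surface = rng.integers(1, n_surf + 1, m)
        swath = rng.integers(1, n_swath + 1, m)
        tile = rng.integers(1, n_tile + 1, m)

        any_event = ev7 | ev5
        chim_p = np.where(
            any_event, config.chimera_rate_swapped, config.chimera_rate_base
        )
        chimeric = rng.random(m) < chim_p

        for i in range(m):
            s7, s5 = int(src7[i]), int(src5[i])
            seq7, qual7 = i7_seqs[s7], q_high
            seq5, qual5 = i5_seqs[s5], q_high
            if i in err_rows:
                seq7, qual7 = _apply_errors(
                    seq7, err7[i], alt7[i], q_high, q_low_char
                )
                seq5, qual5 = _apply_errors(
                    seq5, err5[i], alt5[i], q_high, q_low_char
                )
            t = int(true_idx[i])
            yield ReadRecord(
                read_id=f"{config.read_id_prefix}:{config.seed}:{emitted + i:09d}",
                i7_obs=seq7,
                i5_obs=seq5,
                i7_qual=qual7,
                i5_qual=qual5,
                tile=(int(surface[i]), int(swath[i]), int(tile[i])),
                true_sample=ids[t],
                i7_source=ids[s7],
                i5_source=ids[s5],
                organism=organisms[t] if organisms else None,
                insert_len=float(insert[i]),
                gc=float(gc[i]),
                chimeric=bool(chimeric[i]),
                i7_swap_event=bool(ev7[i]),
                i5_swap_event=bool(ev5[i]),
            )
        emitted += m


def _apply_errors(
    seq: str,
    err_mask: np.ndarray,
    alt_codes: np.ndarray,
    q_high: str,
    q_low_char: str,
) -> tuple[str, str]:
    if not err_mask.any():
        return seq, q_high
    s = list(seq)
    q = list(q_high)
    for pos in np.nonzero(err_mask)[0]:
        s[pos] = _ALT_BASES[s[pos]][alt_codes[pos]]
        q[pos] = q_low_char
    return "".join(s), "".join(q)


def simulate_mixture(config: SimulationConfig) -> Iterator[ReadRecord]:
    """Simulate a two-organism mixture pool (e.g. human + E. coli halves).

    Identical to :func:`simulate_pool` but requires ``organism_of`` to
    partition the sample sheet into exactly two organism labels, the design
    that lets swap-end attribution identify which adapter end swapped.
    """
    if config.organism_of is None:
        raise ConfigError("simulate_mixture requires an organism_of mapping")
    labels = {config.organism_of[s] for s in config.samplesheet.sample_ids}
    if len(labels) != 2:
        raise ConfigError(
            f"mixture design needs exactly 2 organism labels, got "
            f"{len(labels)}: {sorted(labels)}"
        )
    return simulate_pool(config)


def truth_frame(records: Iterable[ReadRecord]) -> pd.DataFrame:
    """Collect per-read ground truth into a table, one row per read."""
    rows = []
    for r in records:
        surface, swath, tile = r.tile if r.tile else (None, None, None)
        rows.append(
            (
                r.read_id,
                r.true_sample,
                r.i7_source,
                r.i5_source,
                r.organism,
                r.insert_len,
                r.gc,
                r.chimeric,
                surface,
                swath,
                tile,
            )
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def mixture_halves_organisms(
    sheet: DualIndexSet, labels: tuple[str, str] = ("human", "ecoli")
) -> dict[str, str]:
    """Assign the first half of a sheet to one organism, the rest to the other."""
    ids = sheet.sample_ids
    half = len(ids) // 2
    return {
        s: (labels[0] if i < half else labels[1]) for i, s in enumerate(ids)
    }
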