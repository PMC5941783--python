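"""File formats: sample sheet CSV, index-read FASTQ pairs, truth TSV.

The sample sheet is a UTF-8 CSV with header ``sample_id,i7,i5``.  Index
reads travel as an I1/I2 FASTQ pair (I1 = i7, I2 = i5) with identical read
ids in both files; the flow-cell position rides in the id comment as
``surface:swath:tile``.  Ground truth from the simulator is a tab-separated
table, one row per read.  Paths ending in ``.gz`` are compressed
transparently on both read and write.
"""

from __future__ import annotations

import csv
import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO

from .index_sets import DualIndexSet, IndexEntry, IndexSetError
from .simulate import ReadRecord, TRUTH_COLUMNS

SAMPLESHEET_HEADER = ["sample_id", "i7", "i5"]


def _open_text(path: str | Path, mode: str) -> TextIO:
    path = Path(path)
    try:
        if path.suffix == ".gz":
            return gzip.open(path, mode + "t", encoding="utf-8")
        return open(path, mode, encoding="utf-8")
    except OSError as err:
        raise OSError(f"{err.strerror or err}: {path}") from err


def read_samplesheet(path: str | Path) -> DualIndexSet:
    """Load a ``sample_id,i7,i5`` CSV into a dual-index sample sheet."""
    with _open_text(path, "r") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise IndexSetError(f"empty sample sheet: {path}")
        header = [h.strip().lower() for h in header]
        if header != SAMPLESHEET_HEADER:
            raise IndexSetError(
                f"bad sample sheet header {header!r} in {path}; expected "
                f"{SAMPLESHEET_HEADER}"
            )
        entries = [
            IndexEntry(row[0], row[1], row[2]) for row in reader if row
        ]
    return DualIndexSet(entries)


def write_samplesheet(sheet: DualIndexSet, path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SAMPLESHEET_HEADER)
        for e in sheet:
            writer.writerow([e.sample_id, e.i7, e.i5])


def _fastq_entry(read_id: str, comment: str | None, seq: str, qual: str) -> str:
    head = f"@{read_id} {comment}" if comment else f"@{read_id}"
    return f"{head}\n{seq}\n+\n{qual}\n"


def write_index_fastq(
    records: Iterable[ReadRecord],
    i1_path: str | Path,
    i2_path: str | Path,
) -> int:
    """Write a read stream to an I1/I2 FASTQ pair; returns the read count.

    I1 carries the observed i7 sequence, I2 the observed i5; tile
    coordinates (when present) go into the id comment as
    ``surface:swath:tile``.  Record order is preserved.
    """
    n = 0
    with _open_text(i1_path, "w") as f1, _open_text(i2_path, "w") as f2:
        for r in records:
            comment = ":".join(map(str, r.tile)) if r.tile else None
            f1.write(_fastq_entry(r.read_id, comment, r.i7_obs, r.i7_qual))
            f2.write(_fastq_entry(r.read_id, comment, r.i5_obs, r.i5_qual))
            n += 1
    return n


def _parse_tile(description: str) -> tuple[int, int, int] | None:
    parts = description.split(None, 1)
    if len(parts) < 2:
        return None
    fields = parts[1].split(":")
    if len(fields) != 3:
        return None
    try:
        return tuple(int(f) for f in fields)  # type: ignore[return-value]
    except ValueError:
        return None


def _qual_string(rec) -> str:
    return "".join(
        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
    )


def read_index_fastq(
    i1_path: str | Path, i2_path: str | Path
) -> Iterator[ReadRecord]:
    """Stream an I1/I2 FASTQ pair back into read records (no truth fields)."""
    with _open_text(i1_path, "r") as f1, _open_text(i2_path, "r") as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for r1 in it1:
            try:
                r2 = next(it2)
            except StopIteration:
                raise IndexSetError(
                    f"I2 file {i2_path} ended before I1 file {i1_path}"
                )
            if r1.id != r2.id:
                raise IndexSetError(
                    f"read id mismatch between index files: "
                    f"{r1.id!r} vs {r2.id!r}"
                )
            yield ReadRecord(
                read_id=r1.id,
                i7_obs=str(r1.seq),
                i5_obs=str(r2.seq),
                i7_qual=_qual_string(r1),
                i5_qual=_qual_string(r2),
                tile=_parse_tile(r1.description),
            )
        if next(it2, None) is not None:
            raise IndexSetError(
                f"I1 file {i1_path} ended before I2 file {i2_path}"
            )


def write_truth(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(frame.columns)
    if missing:
        raise IndexSetError(f"truth table missing columns: {sorted(missing)}")
    return frame


def read_organisms(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>organism`` mapping."""
    frame = pd.read_csv(path, sep="\t")
    cols = [c.strip().lower() for c in frame.columns]
    frame.columns = cols
    if "sample_id" not in cols or "organism" not in cols:
        raise IndexSetError(
            f"organisms file {path} needs 'sample_id' and 'organism' columns"
        )
    return dict(zip(frame["sample_id"].astype(str), frame["organism"].astype(str)))
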