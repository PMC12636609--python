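"""Readers and writers for the standard formats every analysis stage touches.

Genomic intervals travel as BED (0-based, half-open); RNA sequences as FASTA
or two-column TSV; assay curves (turbidity, anisotropy titrations, CD melts)
as long-format TSV/CSV with ``series``, ``x``, ``y`` columns plus free
metadata columns.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GenomeTable",
    "SequenceRecord",
    "read_bed",
    "write_bed",
    "read_sequences",
    "write_sequences",
    "read_curves",
    "read_genome_table",
]

_RNA_ALPHABET = set("ACGU")


class BedParseError(ValueError):
    """Raised for malformed BED records; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on ``chrom``; the unit of all
    enrichment arithmetic."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval coordinates: start={self.start}, end={self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeTable:
    """Ordered map chromosome name -> length in bp (the shuffle universe)."""

    entries: dict[str, int]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("genome table must contain at least one chromosome")
        for name, length in self.entries.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(self.entries.values())

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class SequenceRecord:
    """Named RNA sequence; DNA input (T) is mapped to U on construction."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        bad = set(seq) - _RNA_ALPHABET
        if not seq:
            raise ValueError(f"record {self.name!r}: empty sequence")
        if bad:
            raise ValueError(
                f"record {self.name!r}: characters outside ACGUT: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a 3-6 column BED file into intervals.

    Track/browser/comment lines are skipped; tabs or runs of spaces are
    accepted as delimiters. Optional columns 4-6 become name/score/strand.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: malformed coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: malformed score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as tab-delimited BED6, preserving input order."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            name = iv.name if iv.name is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Read named RNA sequences from FASTA or a 2-column TSV.

    A leading ``>`` marks FASTA; otherwise a TSV with a ``name``/``sequence``
    header row is expected. T is mapped to U and case folded to uppercase.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        return [
            SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
        ]
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "name" not in cols or "sequence" not in cols:
        raise ValueError("TSV sequence table requires 'name' and 'sequence' columns")
    return [
        SequenceRecord(str(row[cols["name"]]), str(row[cols["sequence"]]))
        for _, row in df.iterrows()
    ]


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write sequence records as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")


def read_curves(path: str | Path) -> pd.DataFrame:
    """Read a long-format curve table (columns ``series``, ``x``, ``y`` plus
    free metadata), sorted by (series, x).

    Raises on non-numeric x/y (naming the row) and on duplicated (series, x)
    pairs, which would make a series ambiguous.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in ("series", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"curve table missing required column {col!r}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = int(coerced.index[coerced.isna()][0])
            raise ValueError(f"non-numeric {col!r} at row {bad}")
        df[col] = coerced
    dup = df.duplicated(subset=["series", "x"])
    if dup.any():
        raise ValueError(
            f"duplicated (series, x) pair at row {int(df.index[dup][0])}"
        )
    return df.sort_values(["series", "x"], kind="stable").reset_index(drop=True)


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a UCSC chrom.sizes-style table (name, length, tab-delimited)."""
    entries: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 'name<TAB>length'")
            name = fields[0]
            if name in entries:
                raise ValueError(f"line {lineno}: duplicate chromosome {name!r}")
            entries[name] = int(fields[1])
    return GenomeTable(entries)
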