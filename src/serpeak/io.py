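"""Readers and writers for the plain-text genomic formats the pipeline touches.

Supported dialects: BED3/BED6, narrowPeak (10 columns, summit as an offset in
column 10), bedGraph (4 columns with a value), and a simple TSV gene table
with header ``gene_id  chrom  strand  tss  tts  [expression]``. All writers
emit sorted, tab-separated, newline-terminated records. Coordinates are
0-based half-open on disk and in memory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .intervals import GeneModel, GenomicInterval

__all__ = [
    "BedRecord",
    "ParseError",
    "read_intervals",
    "write_bed",
    "write_narrowpeak",
    "write_bedgraph",
    "read_genes",
    "write_genes",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in a genomic text file; carries the line number."""


@dataclass(frozen=True)
class BedRecord:
    """One interval plus the per-format payload that travelled with it."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit_offset: Optional[int] = None  # narrowPeak column 10
    value: Optional[float] = None  # bedGraph column 4

    # convenience pass-throughs so records quack like intervals
    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> Optional[int]:
        """Absolute summit coordinate (narrowPeak offset resolved)."""
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset


def _parse_interval(fields: Sequence[str], lineno: int, path: PathLike) -> GenomicInterval:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:{lineno}: malformed line ({exc})") from exc
    try:
        return GenomicInterval(chrom, start, end)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_intervals(path: PathLike, format: str = "bed") -> list[BedRecord]:
    """Read a BED / bedGraph / narrowPeak file into :class:`BedRecord` list.

    Records are returned in file order. Lines starting with ``track``,
    ``browser`` or ``#`` and blank lines are skipped.
    """
    if format not in ("bed", "bedgraph", "narrowpeak"):
        raise ValueError(f"unknown format {format!r}")
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # permit space-separated input
                fields = line.split()
            iv = _parse_interval(fields, lineno, path)
            try:
                if format == "bedgraph":
                    if len(fields) < 4:
                        raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
                    records.append(BedRecord(iv, value=float(fields[3])))
                elif format == "narrowpeak":
                    if len(fields) < 10:
                        raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns")
                    offset = int(fields[9])
                    if offset >= 0 and not iv.contains(iv.start + offset):
                        raise ParseError(
                            f"{path}:{lineno}: summit offset {offset} outside interval"
                        )
                    records.append(
                        BedRecord(
                            iv,
                            name=fields[3],
                            score=float(fields[4]),
                            strand=fields[5],
                            value=float(fields[6]),  # signalValue
                            summit_offset=None if offset < 0 else offset,
                        )
                    )
                else:
                    name = fields[3] if len(fields) > 3 else "."
                    score = float(fields[4]) if len(fields) > 4 else 0.0
                    strand = fields[5] if len(fields) > 5 else "."
                    records.append(BedRecord(iv, name=name, score=score, strand=strand))
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed line ({exc})") from exc
    return records


def _sorted_records(records: Iterable[BedRecord]) -> list[BedRecord]:
    return sorted(records, key=lambda r: r.interval.sort_key())


def write_bed(records: Iterable[BedRecord], path: PathLike, columns: int = 6) -> None:
    """Write BED3 or BED6 (sorted)."""
    if columns not in (3, 6):
        raise ValueError("columns must be 3 or 6")
    with open(path, "w") as fh:
        for r in _sorted_records(records):
            row = [r.chrom, str(r.start), str(r.end)]
            if columns == 6:
                row += [r.name, f"{r.score:g}", r.strand]
            fh.write("\t".join(row) + "\n")


def write_narrowpeak(records: Iterable[BedRecord], path: PathLike) -> None:
    """Write narrowPeak; ``value`` goes to signalValue, summit to column 10."""
    with open(path, "w") as fh:
        for r in _sorted_records(records):
            offset = -1 if r.summit_offset is None else r.summit_offset
            sig = 0.0 if r.value is None else r.value
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.name,
                        f"{r.score:g}",
                        r.strand,
                        f"{sig:g}",
                        "-1",
                        "-1",
                        str(offset),
                    ]
                )
                + "\n"
            )


def write_bedgraph(records: Iterable[BedRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in _sorted_records(records):
            v = 0.0 if r.value is None else r.value
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{v:g}\n")


_GENE_COLS = ["gene_id", "chrom", "strand", "tss", "tts"]


def read_genes(path: PathLike) -> list[GeneModel]:
    """Read the gene annotation TSV (header required)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_GENE_COLS) <= set(reader.fieldnames):
            raise ParseError(f"{path}: gene table must have columns {_GENE_COLS}")
        for lineno, row in enumerate(reader, start=2):
            try:
                expr = row.get("expression")
                genes.append(
                    GeneModel(
                        gene_id=row["gene_id"],
                        chrom=row["chrom"],
                        strand=row["strand"],
                        tss=int(row["tss"]),
                        tts=int(row["tts"]),
                        expression=float(expr) if expr not in (None, "", "NA") else None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_genes(genes: Iterable[GeneModel], path: PathLike) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, min(g.tss, g.tts), g.gene_id))
    has_expr = any(g.expression is not None for g in genes)
    cols = _GENE_COLS + (["expression"] if has_expr else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in genes:
            row = [g.gene_id, g.chrom, g.strand, str(g.tss), str(g.tts)]
            if has_expr:
                row.append("NA" if g.expression is None else f"{g.expression:.6g}")
            fh.write("\t".join(row) + "\n")
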