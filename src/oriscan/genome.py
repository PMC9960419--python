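"""Genome coordinate bookkeeping and file I/O shared by all other modules.

All internal coordinates are 0-based half-open (BED convention).  VCF and
tab-delimited mutation tables carry 1-based positions and are converted on
read, so ``p_vcf = start + 1`` everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mutcontext import MutationRecord

log = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for a malformed BED line; the message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval with optional score and strand."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand is not None and self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeIndex:
    """Chromosome names, lengths and optional assembly-gap regions.

    Chromosome name lookups tolerate the "1" vs "chr1" convention mismatch
    via a configurable alias map (default: add/strip the "chr" prefix).
    """

    chrom_lengths: dict[str, int]
    gap_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) == 0:
            raise ValueError("GenomeIndex needs at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for name, gaps in self.gap_regions.items():
            if name not in self.chrom_lengths:
                raise ValueError(f"gap regions for unknown chromosome {name}")
            for s, e in gaps:
                if not (0 <= s < e <= self.chrom_lengths[name]):
                    raise ValueError(f"gap {name}:{s}-{e} outside chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path, **kwargs) -> "GenomeIndex":
        """Build from a two-column chrom-sizes file (name, length)."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(dict(zip(df["chrom"], df["length"].astype(int))), **kwargs)

    def normalize(self, name: str) -> str | None:
        """Map a chromosome name onto this index, or None if unknown."""
        if name in self.chrom_lengths:
            return name
        if name in self.aliases and self.aliases[name] in self.chrom_lengths:
            return self.aliases[name]
        flipped = name[3:] if name.startswith("chr") else "chr" + name
        if flipped in self.chrom_lengths:
            return flipped
        return None

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]


def read_bed(path: str | Path, index: GenomeIndex | None = None) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into validated intervals.

    Malformed lines raise :class:`BedParseError` naming the line number.
    When *index* is given, records on unknown chromosomes or out of bounds
    are dropped with a logged warning (scaffold-tolerant), not fatal.
    """
    intervals: list[GenomicInterval] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from None
            score = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}: line {lineno}: {exc}") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else None
            if index is not None:
                norm = index.normalize(chrom)
                if norm is None:
                    log.warning("%s: line %d: unknown chromosome %s, record dropped",
                                path, lineno, chrom)
                    n_rejected += 1
                    continue
                chrom = norm
                if end > index.length(chrom) or start < 0:
                    log.warning("%s: line %d: %s:%d-%d out of chromosome bounds, "
                                "record dropped", path, lineno, chrom, start, end)
                    n_rejected += 1
                    continue
            try:
                intervals.append(GenomicInterval(chrom, start, end, score, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from None
    if n_rejected:
        log.warning("%s: %d record(s) rejected against the genome index", path, n_rejected)
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    """Write intervals as tab-delimited BED (score in column 5 when present).

    Scores are written with ``repr`` so the read/write cycle is lossless.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.score is not None or iv.strand is not None:
                cols.append(".")  # name placeholder
                cols.append(repr(iv.score) if iv.score is not None else ".")
            if iv.strand is not None:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


_TABLE_COLUMNS = ("chrom", "pos", "ref", "alt", "sample")


def _read_mutation_table(path: str | Path) -> tuple[list[MutationRecord], int]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation table missing column(s) {missing}")
    records, skipped = [], 0
    has_context = "context" in df.columns
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or "," in alt:
            skipped += 1
            continue
        if ref not in "ACGT" or alt not in "ACGT":
            log.warning("%s: non-ACGT allele %s>%s skipped", path, ref, alt)
            skipped += 1
            continue
        ctx = getattr(row, "context", None) if has_context else None
        if isinstance(ctx, float):  # NaN from pandas
            ctx = None
        records.append(MutationRecord(str(row.chrom), int(row.pos) - 1, ref, alt,
                                      str(row.sample), ctx))
    return records, skipped


def _read_vcf(path: str | Path, sample: str | None) -> tuple[list[MutationRecord], int]:
    import pysam

    records, skipped = [], 0
    with pysam.VariantFile(str(path)) as vf:
        if sample is None:
            samples = list(vf.header.samples)
            sample = samples[0] if samples else Path(path).stem
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                skipped += 1
                continue
            if ref not in "ACGT" or alt not in "ACGT":
                log.warning("%s: non-ACGT allele %s>%s skipped", path, ref, alt)
                skipped += 1
                continue
            records.append(MutationRecord(rec.chrom, rec.start, ref, alt, sample))
    return records, skipped


def read_mutations(path: str | Path, format: str = "auto",
                   sample: str | None = None) -> list[MutationRecord]:
    """Read single-nucleotide substitutions from a VCF or a mutation table.

    Indels and multi-allelic records are skipped; the count is logged.  The
    table format needs a header with chrom/pos/ref/alt/sample (1-based pos)
    and may carry an optional precomputed ``context`` column.
    """
    if format == "auto":
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "table"
    if format == "vcf":
        records, skipped = _read_vcf(path, sample)
    elif format == "table":
        records, skipped = _read_mutation_table(path)
    else:
        raise ValueError(f"unknown mutation format {format!r}")
    if skipped:
        log.warning("%s: skipped %d non-SNV record(s)", path, skipped)
    return records
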