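"""Genomic interval types, interval arithmetic and flat-file readers/writers.

All coordinates are BED convention: 0-based, half-open, everywhere internally.
Gene tables supplied in 1-based coordinates are converted at the reader
boundary (``coords="one-based"``). Chromosome names are matched by exact
string equality; :func:`check_shared_chromosomes` warns when two inputs share
no chromosome at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Region",
    "Gene",
    "AnchorPair",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_genes_table",
    "write_genes_table",
    "overlaps",
    "promoter_extended",
    "shifted_tss",
    "check_shared_chromosomes",
]


class BedParseError(ValueError):
    """Raised on malformed BED/BEDPE/table lines; message names the line."""


@dataclass(frozen=True, order=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor((start + end) / 2)."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Gene:
    """A gene body with its canonical TSS and promoter extension length.

    The TSS is derived from strand: ``region.start`` on ``+``,
    ``region.end - 1`` on ``-``.
    """

    region: Region
    promoter_ext: int = 300

    def __post_init__(self) -> None:
        if self.region.strand not in ("+", "-"):
            raise ValueError("gene region must carry a strand")
        if self.promoter_ext < 0:
            raise ValueError("promoter_ext must be >= 0")

    @property
    def tss(self) -> int:
        if self.region.strand == "+":
            return self.region.start
        return self.region.end - 1

    @property
    def name(self) -> str | None:
        return self.region.name

    @property
    def chrom(self) -> str:
        return self.region.chrom


@dataclass(frozen=True)
class AnchorPair:
    """Two interaction anchors (e.g. one ChIA-PET link) plus optional score."""

    anchor_a: Region
    anchor_b: Region
    score: float | None = None


def overlaps(a: Region, b: Region, min_overlap: int = 1) -> bool:
    """True iff the half-open intersection of ``a`` and ``b`` spans
    at least ``min_overlap`` bases (and the chromosomes match exactly)."""
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap


def promoter_extended(gene: Gene) -> Region:
    """Gene body grown by ``promoter_ext`` bp on the TSS side, clipped at 0."""
    r = gene.region
    if r.strand == "+":
        return Region(r.chrom, max(0, r.start - gene.promoter_ext), r.end,
                      name=r.name, strand=r.strand)
    return Region(r.chrom, r.start, r.end + gene.promoter_ext,
                  name=r.name, strand=r.strand)


def shifted_tss(gene: Gene) -> int:
    """Canonical TSS moved ``promoter_ext`` bp upstream (clipped at 0)."""
    if gene.region.strand == "+":
        return max(0, gene.tss - gene.promoter_ext)
    return gene.tss + gene.promoter_ext


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_region(fields: Sequence[str], path: Path, lineno: int,
                  name: str | None = None, strand: str | None = None) -> Region:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    try:
        return Region(fields[0], start, end, name=name, strand=strand)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path: str | Path) -> list[Region]:
    """Read BED3+ into a list of :class:`Region` (name/strand from cols 4/6)."""
    path = Path(path)
    regions: list[Region] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
        name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else None
        regions.append(_parse_region(fields, path, lineno, name=name, strand=strand))
    return regions


def write_bed(path: str | Path, regions: Iterable[Region],
              scores: Sequence[float | int] | None = None) -> None:
    """Write BED3 (or BED6 when names/strands/scores are present)."""
    regions = list(regions)
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fields = [r.chrom, str(r.start), str(r.end)]
            score = scores[i] if scores is not None else None
            if r.name is not None or r.strand is not None or score is not None:
                fields += [r.name or ".",
                           str(score) if score is not None else "0",
                           r.strand or "."]
            fh.write("\t".join(fields) + "\n")


def read_bedpe(path: str | Path) -> list[AnchorPair]:
    """Read BEDPE (>=6 columns) into anchor pairs; column 7 becomes the score."""
    path = Path(path)
    pairs: list[AnchorPair] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise BedParseError(f"{path}:{lineno}: expected >=6 columns")
        a = _parse_region(fields[0:3], path, lineno)
        b = _parse_region(fields[3:6], path, lineno)
        score: float | None = None
        if len(fields) >= 7 and fields[6] not in (".", ""):
            try:
                score = float(fields[6])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad score {fields[6]!r}") from exc
        pairs.append(AnchorPair(a, b, score))
    return pairs


def write_bedpe(path: str | Path, pairs: Iterable[AnchorPair]) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fields = [p.anchor_a.chrom, str(p.anchor_a.start), str(p.anchor_a.end),
                      p.anchor_b.chrom, str(p.anchor_b.start), str(p.anchor_b.end)]
            if p.score is not None:
                fields.append(f"{p.score:g}")
            fh.write("\t".join(fields) + "\n")


def read_genes_table(path: str | Path, promoter_ext: int = 300,
                     coords: str = "bed") -> list[Gene]:
    """Read a gene table (TSV, header ``chrom start end name strand``).

    ``coords="one-based"`` converts 1-based inclusive starts to BED at the
    boundary; the default assumes BED coordinates.
    """
    if coords not in ("bed", "one-based"):
        raise ValueError(f"coords must be 'bed' or 'one-based', got {coords!r}")
    path = Path(path)
    genes: list[Gene] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chrom", "start", "end", "name", "strand"]
        if header[:5] != required:
            raise BedParseError(
                f"{path}: header must start with {required}, got {header[:5]}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(f"{path}:{lineno}: expected >=5 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if coords == "one-based":
                start -= 1
            if fields[4] not in ("+", "-"):
                raise BedParseError(f"{path}:{lineno}: strand must be + or -")
            try:
                region = Region(fields[0], start, end, name=fields[3], strand=fields[4])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(Gene(region, promoter_ext=promoter_ext))
    return genes


def write_genes_table(path: str | Path, genes: Iterable[Gene]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tstrand\n")
        for g in genes:
            r = g.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.strand}\n")


def check_shared_chromosomes(a: Iterable[Region], b: Iterable[Region]) -> bool:
    """Warn (and return False) when two region sets share zero chromosomes."""
    chroms_a = {r.chrom for r in a}
    chroms_b = {r.chrom for r in b}
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        warnings.warn(
            "inputs share no chromosome names; check naming conventions "
            f"({sorted(chroms_a)[:3]} vs {sorted(chroms_b)[:3]})",
            stacklevel=2)
        return False
    return True
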