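"""Region x timepoint count matrices: counting, normalisation, coverage filter.

Counting uses full-interval half-open overlap (a read overlapping two regions
counts in both). Normalisation scales each timepoint's column by
``library_size(t=0) / library_size(t)`` so every column is expressed at t=0
sequencing depth; an alternative single grand-total scaling is available via
``mode="grand_total"``. The low-coverage filter removes regions whose RAW
count total, summed over all timepoints and assays, falls below ``min_total``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from eplink.genome_io import Region

__all__ = [
    "TimeSeriesSet",
    "count_over_regions",
    "normalize",
    "filter_low_coverage",
    "read_counts_tsv",
    "write_counts_tsv",
]


@dataclass(frozen=True)
class TimeSeriesSet:
    """Counts for one assay: regions x timepoints, plus per-timepoint depth."""

    assay: str
    timepoints: tuple[float, ...]
    region_ids: tuple[str, ...]
    matrix: np.ndarray
    library_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.region_ids), len(self.timepoints)):
            raise ValueError("matrix shape must be (regions, timepoints)")
        if len(self.library_sizes) != len(self.timepoints):
            raise ValueError("library_sizes must align with timepoints")
        if np.any(self.matrix < 0):
            raise ValueError("counts must be non-negative")

    def subset(self, region_ids: list[str]) -> "TimeSeriesSet":
        index = {rid: i for i, rid in enumerate(self.region_ids)}
        rows = [index[rid] for rid in region_ids]
        return replace(self, region_ids=tuple(region_ids),
                       matrix=self.matrix[rows, :])

    def row(self, region_id: str) -> np.ndarray:
        return self.matrix[self.region_ids.index(region_id), :]


def _region_id(region: Region) -> str:
    return region.name or f"{region.chrom}:{region.start}-{region.end}"


def count_over_regions(regions: list[Region],
                       reads_by_timepoint: dict[float, list[Region]],
                       library_sizes: dict[float, float],
                       assay: str = "assay") -> TimeSeriesSet:
    """Count reads (intervals) overlapping each region at each timepoint.

    A read overlaps a region iff their half-open intersection is non-empty;
    the count for region [s, e) equals #{reads: start < e} - #{reads: end <= s}
    on the same chromosome, which is exact because end <= s implies start < e.
    """
    if not regions:
        raise ValueError("region list must be non-empty")
    timepoints = tuple(sorted(reads_by_timepoint))
    if set(library_sizes) < set(timepoints):
        raise ValueError("library_sizes missing for some timepoints")

    matrix = np.zeros((len(regions), len(timepoints)), dtype=float)
    for col, t in enumerate(timepoints):
        starts_by_chrom: dict[str, np.ndarray] = {}
        ends_by_chrom: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[Region]] = {}
        for read in reads_by_timepoint[t]:
            by_chrom.setdefault(read.chrom, []).append(read)
        for chrom, reads in by_chrom.items():
            starts_by_chrom[chrom] = np.sort(np.array([r.start for r in reads]))
            ends_by_chrom[chrom] = np.sort(np.array([r.end for r in reads]))
        for row, region in enumerate(regions):
            starts = starts_by_chrom.get(region.chrom)
            if starts is None:
                continue
            ends = ends_by_chrom[region.chrom]
            n_start_before_end = np.searchsorted(starts, region.end, side="left")
            n_end_at_or_before_start = np.searchsorted(ends, region.start, side="right")
            matrix[row, col] = n_start_before_end - n_end_at_or_before_start

    return TimeSeriesSet(
        assay=assay,
        timepoints=timepoints,
        region_ids=tuple(_region_id(r) for r in regions),
        matrix=matrix,
        library_sizes=tuple(float(library_sizes[t]) for t in timepoints),
    )


def normalize(raw: TimeSeriesSet, mode: str = "per_timepoint") -> TimeSeriesSet:
    """Scale counts to t=0 sequencing depth.

    ``per_timepoint`` (default): cell(j, t) <- raw(j, t) / lib(t) * lib(0).
    ``grand_total``: every cell divided by the grand total of library sizes
    and multiplied by lib(0) (one constant factor).
    """
    if mode not in ("per_timepoint", "grand_total"):
        raise ValueError(f"unknown mode {mode!r}")
    if 0 not in raw.timepoints:
        raise ValueError("normalization requires a t=0 timepoint")
    libs = np.asarray(raw.library_sizes, dtype=float)
    for t, lib in zip(raw.timepoints, libs):
        if lib <= 0:
            raise ValueError(f"library size must be positive at t={t:g}")
    lib0 = libs[raw.timepoints.index(0)]
    if mode == "per_timepoint":
        factors = lib0 / libs
    else:
        factors = np.full_like(libs, lib0 / libs.sum())
    return replace(raw, matrix=raw.matrix * factors[np.newaxis, :])


def filter_low_coverage(ts_by_assay: list[TimeSeriesSet],
                        min_total: int = 30) -> list[str]:
    """Region ids whose raw count total over all assays and timepoints is
    >= ``min_total`` (strict "less than" drops the rest)."""
    if not ts_by_assay:
        return []
    region_ids = ts_by_assay[0].region_ids
    for ts in ts_by_assay[1:]:
        if ts.region_ids != region_ids:
            raise ValueError("all assays must share region_ids in order")
    totals = sum(ts.matrix.sum(axis=1) for ts in ts_by_assay)
    return [rid for rid, tot in zip(region_ids, totals) if tot >= min_total]


def write_counts_tsv(path: str | Path, ts: TimeSeriesSet) -> None:
    df = pd.DataFrame(ts.matrix, index=list(ts.region_ids),
                      columns=[f"t{t:g}" for t in ts.timepoints])
    df.index.name = "region_id"
    with open(path, "w") as fh:
        fh.write(f"# assay={ts.assay}\n")
        fh.write("# library_sizes=" +
                 ",".join(f"{t:g}:{s:g}" for t, s in zip(ts.timepoints, ts.library_sizes)) +
                 "\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_counts_tsv(path: str | Path) -> TimeSeriesSet:
    path = Path(path)
    assay = "assay"
    lib_map: dict[float, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# assay="):
                assay = line.split("=", 1)[1].strip()
            elif line.startswith("# library_sizes="):
                for item in line.split("=", 1)[1].strip().split(","):
                    t, s = item.split(":")
                    lib_map[float(t)] = float(s)
    df = pd.read_csv(path, sep="\t", comment="#", index_col="region_id")
    timepoints = tuple(float(c[1:]) for c in df.columns)
    libs = tuple(lib_map.get(t, 1.0) for t in timepoints)
    return TimeSeriesSet(assay=assay, timepoints=timepoints,
                         region_ids=tuple(str(i) for i in df.index),
                         matrix=df.to_numpy(dtype=float),
                         library_sizes=libs)
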