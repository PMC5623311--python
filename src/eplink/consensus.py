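"""Time-persistent consensus binding sites from per-timepoint peak calls.

Peaks observed across the post-stimulation timepoints are pooled and merged
transitively into connected components by interval overlap; components
supported by at least ``min_support`` distinct timepoints become consensus
enhancers (union span), the rest are discarded. Consensus regions overlapping
promoter-extended genes are then removed to keep only distal (intergenic)
enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass

from eplink.genome_io import Gene, Region, promoter_extended

__all__ = ["PeakSeries", "ConsensusEnhancer", "persistent_union", "filter_distal"]


@dataclass(frozen=True)
class PeakSeries:
    """Per-timepoint peak calls, ordered by time (minutes)."""

    timepoints: tuple[float, ...]
    peaks: tuple[tuple[Region, ...], ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.peaks):
            raise ValueError("timepoints and peak lists must align")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")

    @classmethod
    def from_dict(cls, peaks_by_time: dict[float, list[Region]]) -> "PeakSeries":
        times = tuple(sorted(peaks_by_time))
        return cls(times, tuple(tuple(peaks_by_time[t]) for t in times))


@dataclass(frozen=True)
class ConsensusEnhancer:
    """Union span of a merged peak component with its timepoint support."""

    region: Region
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def center(self) -> int:
        return self.region.center

    @property
    def id(self) -> str:
        return self.region.name or f"{self.region.chrom}:{self.region.start}-{self.region.end}"


def persistent_union(series: PeakSeries, min_support: int = 2,
                     include_t0: bool = False) -> list[ConsensusEnhancer]:
    """Merge pooled peaks into overlap-connected components; keep components
    contributed to by >= ``min_support`` distinct timepoints.

    Peaks at t=0 are excluded from pooling (and support counting) unless
    ``include_t0`` is set. A timepoint counts at most once per component,
    however many of its peaks fall inside. Output is sorted by coordinate and
    regions are pairwise non-overlapping.
    """
    pooled: list[tuple[Region, float]] = []
    for t, peaks in zip(series.timepoints, series.peaks):
        if t == 0 and not include_t0:
            continue
        pooled.extend((p, t) for p in peaks)

    pooled.sort(key=lambda item: (item[0].chrom, item[0].start, item[0].end))

    out: list[ConsensusEnhancer] = []
    i = 0
    while i < len(pooled):
        region, t = pooled[i]
        chrom, start, end = region.chrom, region.start, region.end
        times = {t}
        i += 1
        # sweep: sorted by start, so the component ends when the next peak
        # starts at/after the running union end
        while i < len(pooled):
            nxt, t_nxt = pooled[i]
            if nxt.chrom != chrom or nxt.start >= end:
                break
            end = max(end, nxt.end)
            times.add(t_nxt)
            i += 1
        if len(times) >= min_support:
            name = f"enh:{chrom}:{start}-{end}"
            out.append(ConsensusEnhancer(Region(chrom, start, end, name=name),
                                         support=len(times)))
    return out


def filter_distal(consensus: list[ConsensusEnhancer],
                  genes: list[Gene]) -> list[ConsensusEnhancer]:
    """Drop consensus regions overlapping any promoter-extended gene."""
    ext_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in genes:
        ext = promoter_extended(gene)
        ext_by_chrom.setdefault(ext.chrom, []).append((ext.start, ext.end))
    for intervals in ext_by_chrom.values():
        intervals.sort()

    kept: list[ConsensusEnhancer] = []
    for enh in consensus:
        r = enh.region
        hit = any(s < r.end and r.start < e
                  for s, e in ext_by_chrom.get(r.chrom, ()))
        if not hit:
            kept.append(enh)
    return kept
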