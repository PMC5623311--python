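"""Self-contained synthetic benchmark with planted enhancer-gene links.

The generator emits exactly the text formats the real pipeline consumes:
per-timepoint peak BEDs, per-assay/timepoint read BEDs, a gene table, a
subsampled interaction BEDPE (emulating ground-truth false negatives), a TAD
BED and a complete-truth JSON.

Linked pairs share a smooth latent response profile per assay mixed in with
weight ``signal_strength``; unlinked elements carry independent smooth
profiles. Linked separations are drawn from a log-normal, so both the
correlation and the distance feature carry class signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from eplink.genome_io import (AnchorPair, Gene, Region, promoter_extended,
                              shifted_tss, write_bed, write_bedpe,
                              write_genes_table)

__all__ = ["SynthConfig", "SynthBundle", "generate", "acceptance_config"]

READ_LENGTH = 36


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 12_000_000
    n_genes: int = 400
    n_enhancers: int = 200
    timepoints: tuple[float, ...] = (0, 5, 10, 20, 40, 80, 160, 320)
    assays: tuple[str, ...] = ("ER", "PolII_rep1", "PolII_rep2", "H2AZ", "H3K4me3")
    fraction_linked: float = 0.5
    signal_strength: dict = field(default_factory=lambda: {
        "ER": 0.9, "PolII_rep1": 0.9, "PolII_rep2": 0.9,
        "H2AZ": 0.2, "H3K4me3": 0.2})
    noise_sd: float = 0.3
    linked_log10_dist_mean: float = 4.4   # ~25 kb median separation
    linked_log10_dist_sd: float = 0.35
    truth_sensitivity: float = 0.6
    base_count: float = 80.0
    count_amplitude: float = 0.45
    gene_length: tuple[int, int] = (2_000, 8_000)
    enhancer_width: int = 400
    promoter_ext: int = 300
    n_noise_peaks_per_chrom: int = 5
    tad_size: int = 1_500_000

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.n_genes, self.n_enhancers) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.fraction_linked <= 1.0:
            raise ValueError("fraction_linked must be in [0,1]")
        if not 0.0 <= self.truth_sensitivity <= 1.0:
            raise ValueError("truth_sensitivity must be in [0,1]")
        for assay in self.assays:
            s = self.signal_strength.get(assay, 0.0)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"signal_strength[{assay}] must be in [0,1]")


@dataclass
class SynthBundle:
    """In-memory synthetic dataset; ``write`` emits the pipeline's formats."""

    config: SynthConfig
    genes: list[Gene]
    enhancers: list[Region]                     # planted enhancer regions
    peaks_by_time: dict[float, list[Region]]
    reads: dict[str, dict[float, list[Region]]]  # assay -> time -> read intervals
    library_sizes: dict[str, dict[float, int]]
    truth_links: list[tuple[str, str]]           # (enhancer name, gene name)
    observed_links: list[AnchorPair]
    tads: list[Region]

    @property
    def truth_targets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for enh, gene in self.truth_links:
            out.setdefault(enh, set()).add(gene)
        return out

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        write_genes_table(outdir / "genes.tsv", self.genes)
        manifest["genes"] = "genes.tsv"
        peaks_manifest = {}
        for t, peaks in sorted(self.peaks_by_time.items()):
            fname = f"peaks_t{t:g}.bed"
            write_bed(outdir / fname, peaks)
            peaks_manifest[f"{t:g}"] = fname
        reads_manifest: dict[str, dict[str, dict]] = {}
        for assay, by_time in self.reads.items():
            reads_manifest[assay] = {}
            for t, reads in sorted(by_time.items()):
                fname = f"reads_{assay}_t{t:g}.bed"
                write_bed(outdir / fname, reads)
                reads_manifest[assay][f"{t:g}"] = {
                    "path": fname,
                    "library_size": self.library_sizes[assay][t]}
        write_bedpe(outdir / "observed_links.bedpe", self.observed_links)
        manifest["observed_links"] = "observed_links.bedpe"
        write_bed(outdir / "tads.bed", self.tads)
        manifest["tads"] = "tads.bed"
        truth = {
            "links": [{"enhancer": e, "gene": g} for e, g in self.truth_links],
            "enhancers": [[r.chrom, r.start, r.end, r.name] for r in self.enhancers],
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest["truth"] = "truth.json"
        manifest["peaks"] = peaks_manifest
        manifest["reads"] = reads_manifest
        manifest["config"] = asdict(self.config)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest


def _latent_profile(rng: np.random.Generator, n: int) -> np.ndarray:
    """Cubic-smoothed random walk over the timepoints, z-scored."""
    walk = np.cumsum(rng.normal(size=n))
    x = np.arange(n, dtype=float)
    coeffs = np.polyfit(x, walk, deg=min(3, n - 1))
    smooth = np.polyval(coeffs, x) + 0.3 * (walk - np.polyval(coeffs, x))
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(n)
    return (smooth - smooth.mean()) / sd


def _place_genes(rng: np.random.Generator, cfg: SynthConfig,
                 chrom: str, n: int, offset: int) -> list[Gene]:
    """Genes on a jittered grid; spacing leaves room for intergenic elements."""
    slot = cfg.chrom_length // (n + 1)
    genes = []
    for i in range(n):
        length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1]))
        anchor = (i + 1) * slot + int(rng.integers(-slot // 8, slot // 8))
        start = max(cfg.promoter_ext + 1, anchor - length // 2)
        strand = "+" if rng.random() < 0.5 else "-"
        region = Region(chrom, start, start + length,
                        name=f"gene_{offset + i:05d}", strand=strand)
        genes.append(Gene(region, promoter_ext=cfg.promoter_ext))
    return genes


def _free_position(rng: np.random.Generator, cfg: SynthConfig,
                   occupied: list[tuple[int, int]], chrom_len: int,
                   width: int, preferred: int | None = None,
                   tries: int = 80) -> int | None:
    """A start position whose [start, start+width) hits no occupied interval."""
    for attempt in range(tries):
        if preferred is not None and attempt == 0:
            start = preferred
        else:
            start = int(rng.integers(0, max(1, chrom_len - width)))
        end = start + width
        if start < 0 or end > chrom_len:
            continue
        if all(e <= start or s >= end for s, e in occupied):
            return start
    return None


def generate(config: SynthConfig) -> SynthBundle:
    """Build a fully reproducible synthetic bundle from the seed."""
    rng = np.random.default_rng(config.seed)
    n_tp = len(config.timepoints)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]

    genes: list[Gene] = []
    enhancers: list[Region] = []
    truth_links: list[tuple[str, str]] = []
    # per-element latent signal, keyed by element name then assay
    signals: dict[str, dict[str, np.ndarray]] = {}

    genes_per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        genes_per_chrom[i] += 1
    enh_per_chrom = [config.n_enhancers // config.n_chroms] * config.n_chroms
    for i in range(config.n_enhancers % config.n_chroms):
        enh_per_chrom[i] += 1

    gene_offset = 0
    enh_counter = 0
    for ci, chrom in enumerate(chroms):
        chrom_genes = _place_genes(rng, config, chrom, genes_per_chrom[ci], gene_offset)
        gene_offset += genes_per_chrom[ci]
        genes.extend(chrom_genes)
        # keep enhancers clear of promoter-extended genes
        occupied = sorted((promoter_extended(g).start, promoter_extended(g).end)
                          for g in chrom_genes)

        n_enh = enh_per_chrom[ci]
        n_linked = int(round(config.fraction_linked * n_enh))
        target_order = rng.permutation(len(chrom_genes))
        chrom_enh: list[Region] = []
        for ei in range(n_enh):
            linked_gene: Gene | None = None
            preferred = None
            if ei < n_linked and ei < len(chrom_genes):
                linked_gene = chrom_genes[target_order[ei]]
                sep = int(round(10 ** rng.normal(config.linked_log10_dist_mean,
                                                 config.linked_log10_dist_sd)))
                side = 1 if rng.random() < 0.5 else -1
                center = shifted_tss(linked_gene) + side * sep
                preferred = center - config.enhancer_width // 2
            start = _free_position(rng, config, occupied, config.chrom_length,
                                   config.enhancer_width, preferred=preferred)
            if start is None:
                raise ValueError(
                    f"infeasible placement on {chrom}: too many elements for "
                    f"chrom_length={config.chrom_length}")
            region = Region(chrom, start, start + config.enhancer_width,
                            name=f"penh_{enh_counter:05d}")
            enh_counter += 1
            occupied.append((start, start + config.enhancer_width))
            occupied.sort()
            chrom_enh.append(region)
            if linked_gene is not None:
                truth_links.append((region.name, linked_gene.name))
        enhancers.extend(chrom_enh)

    # --- time-series signal construction -------------------------------
    linked_gene_of = dict(truth_links)
    gene_by_name = {g.name: g for g in genes}
    shared: dict[tuple[str, str], np.ndarray] = {}  # (link, assay) -> profile

    def element_signal(name: str, link_key: str | None) -> dict[str, np.ndarray]:
        per_assay: dict[str, np.ndarray] = {}
        for assay in config.assays:
            own = _latent_profile(rng, n_tp)
            noise = rng.normal(size=n_tp)
            if link_key is not None:
                # sqrt mixing so the linked-pair correlation scales ~ s
                # (both partners carry sqrt(s) of the shared profile)
                s = config.signal_strength.get(assay, 0.0)
                lat = shared.setdefault((link_key, assay), _latent_profile(rng, n_tp))
                v = (np.sqrt(s) * lat + np.sqrt(1.0 - s) * own +
                     config.noise_sd * noise)
            else:
                v = own + config.noise_sd * noise
            per_assay[assay] = v
        return per_assay

    linked_genes = set(linked_gene_of.values())
    for enh in enhancers:
        link_key = enh.name if enh.name in linked_gene_of else None
        signals[enh.name] = element_signal(enh.name, link_key)
    for gene in genes:
        if gene.name in linked_genes:
            # share the latent profile of the enhancer that targets this gene
            enh_name = next(e for e, g in truth_links if g == gene.name)
            signals[gene.name] = element_signal(gene.name, enh_name)
        else:
            signals[gene.name] = element_signal(gene.name, None)

    def counts_from_signal(v: np.ndarray) -> np.ndarray:
        scaled = config.base_count * (1.0 + config.count_amplitude *
                                      np.clip(v, -2.0, 2.0))
        return np.maximum(0, np.round(scaled)).astype(int)

    # --- peaks ---------------------------------------------------------
    post_t0 = [t for t in config.timepoints if t != 0]
    peaks_by_time: dict[float, list[Region]] = {t: [] for t in config.timepoints}
    for enh in enhancers:
        k = int(rng.integers(2, len(post_t0) + 1))
        times = rng.choice(len(post_t0), size=k, replace=False)
        for ti in sorted(times):
            jitter_l = int(rng.integers(0, 60))
            jitter_r = int(rng.integers(0, 60))
            start = enh.start + jitter_l
            end = max(start + 50, enh.end - jitter_r)
            peaks_by_time[post_t0[ti]].append(Region(enh.chrom, start, end))
    # single-occurrence noise peaks, discarded by the persistence rule
    for chrom in chroms:
        for _ in range(config.n_noise_peaks_per_chrom):
            start = int(rng.integers(0, config.chrom_length - 200))
            t = post_t0[int(rng.integers(0, len(post_t0)))]
            peaks_by_time[t].append(Region(chrom, start, start + 200))
    for t in peaks_by_time:
        peaks_by_time[t].sort(key=lambda r: (r.chrom, r.start, r.end))

    # --- reads ---------------------------------------------------------
    reads: dict[str, dict[float, list[Region]]] = {}
    library_sizes: dict[str, dict[float, int]] = {}
    count_regions: list[tuple[str, Region]] = [(e.name, e) for e in enhancers]
    count_regions += [(g.name, promoter_extended(g)) for g in genes]
    for assay in config.assays:
        reads[assay] = {}
        library_sizes[assay] = {}
        counts = {name: counts_from_signal(signals[name][assay])
                  for name, _ in count_regions}
        for tidx, t in enumerate(config.timepoints):
            tp_reads: list[Region] = []
            for name, region in count_regions:
                c = counts[name][tidx]
                if c == 0:
                    continue
                span = max(1, len(region) - READ_LENGTH)
                starts = region.start + rng.integers(0, span, size=c)
                tp_reads.extend(Region(region.chrom, int(s), int(s) + READ_LENGTH)
                                for s in starts)
            tp_reads.sort(key=lambda r: (r.chrom, r.start, r.end))
            reads[assay][t] = tp_reads
            library_sizes[assay][t] = len(tp_reads)

    # --- observed (subsampled) links ----------------------------------
    enh_by_name = {e.name: e for e in enhancers}
    observed: list[AnchorPair] = []
    for enh_name, gene_name in truth_links:
        if rng.random() < config.truth_sensitivity:
            gene = gene_by_name[gene_name]
            ts = shifted_tss(gene)
            prom_anchor = Region(gene.chrom, max(0, ts - 150), ts + 150)
            observed.append(AnchorPair(enh_by_name[enh_name], prom_anchor))

    # --- TADs ----------------------------------------------------------
    tads: list[Region] = []
    for chrom in chroms:
        pos = 0
        while pos < config.chrom_length:
            size = int(config.tad_size * (0.7 + 0.6 * rng.random()))
            end = min(pos + size, config.chrom_length)
            tads.append(Region(chrom, pos, end))
            pos = end

    return SynthBundle(config=config, genes=genes, enhancers=enhancers,
                       peaks_by_time=peaks_by_time, reads=reads,
                       library_sizes=library_sizes, truth_links=truth_links,
                       observed_links=observed, tads=tads)


def acceptance_config(seed: int = 0, **overrides) -> SynthConfig:
    """The frozen benchmark configuration used by the acceptance suite:
    4 chromosomes, 200 enhancers, 400 genes, strong ER/Pol II signal, weak
    histone signal, class-distinct log-normal separations and 60% observed
    truth sensitivity."""
    params = dict(
        seed=seed, n_chroms=4, n_genes=400, n_enhancers=200,
        signal_strength={"ER": 0.9, "PolII_rep1": 0.9, "PolII_rep2": 0.9,
                         "H2AZ": 0.2, "H3K4me3": 0.2},
        noise_sd=0.3, truth_sensitivity=0.6,
    )
    params.update(overrides)
    return SynthConfig(**params)
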