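"""End-to-end orchestration: consensus -> counts -> features -> train ->
predict -> evaluate, over an in-memory bundle or files on disk.

The train/test split follows the odd/even chromosome-number convention; class
densities are fitted on training chromosomes only and the fitted model carries
that provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eplink.classifier import (DEFAULT_MODEL_FEATURES, feature_column,
                               gene_regulation_scores, map_targets,
                               posterior_table, score_pairs)
from eplink.consensus import ConsensusEnhancer, PeakSeries, filter_distal, persistent_union
from eplink.densities import ClassDensities, fit_class_densities
from eplink.evaluation import (SplitSpec, map_accuracy, odd_even_split,
                               precision_at_tpr)
from eplink.features import build_features, label_pairs
from eplink.genome_io import Gene, overlaps, promoter_extended
from eplink.synthetic import SynthBundle
from eplink.timeseries import (TimeSeriesSet, count_over_regions,
                               filter_low_coverage, normalize)

__all__ = ["PipelineResult", "run_bundle", "truth_recovery_report"]


@dataclass
class PipelineResult:
    consensus: list[ConsensusEnhancer]
    genes: list[Gene]
    features: pd.DataFrame          # labeled feature table (all pairs)
    densities: ClassDensities
    posteriors: pd.DataFrame        # per-pair posteriors (all enhancers)
    map_table: pd.DataFrame
    gene_scores: pd.DataFrame
    split: SplitSpec
    model_features: tuple[str, ...]


def _counts_for(regions, reads, library_sizes, assays) -> dict[str, TimeSeriesSet]:
    return {assay: count_over_regions(regions, reads[assay],
                                      library_sizes[assay], assay=assay)
            for assay in assays}


def run_bundle(bundle: SynthBundle,
               model_features: tuple[str, ...] = DEFAULT_MODEL_FEATURES,
               min_support: int = 2,
               min_total: int = 30,
               split: SplitSpec | None = None) -> PipelineResult:
    """Run the whole pipeline on a synthetic bundle."""
    series = PeakSeries.from_dict(bundle.peaks_by_time)
    consensus = persistent_union(series, min_support=min_support)
    distal = filter_distal(consensus, bundle.genes)
    if not distal:
        raise ValueError("no distal consensus enhancers survived filtering")

    assays = bundle.config.assays
    enh_regions = [c.region for c in distal]
    gene_regions = [promoter_extended(g) for g in bundle.genes]
    raw_enh = _counts_for(enh_regions, bundle.reads, bundle.library_sizes, assays)
    raw_gene = _counts_for(gene_regions, bundle.reads, bundle.library_sizes, assays)

    keep_enh = set(filter_low_coverage(list(raw_enh.values()), min_total))
    keep_gene = set(filter_low_coverage(list(raw_gene.values()), min_total))
    distal_kept = [c for c in distal if c.id in keep_enh]
    genes_kept = [g for g in bundle.genes if g.name in keep_gene]

    enh_order = [c.id for c in distal_kept]
    gene_order = [g.name for g in genes_kept]
    norm_enh = {a: normalize(ts.subset(enh_order)) for a, ts in raw_enh.items()}
    norm_gene = {a: normalize(ts.subset(gene_order)) for a, ts in raw_gene.items()}

    feats = build_features(norm_enh, norm_gene, distal_kept, genes_kept)
    labeled = label_pairs(feats, bundle.observed_links, distal_kept, genes_kept)

    if split is None:
        split = odd_even_split(sorted({g.chrom for g in bundle.genes}))
    train = labeled[(labeled["label"] != "unknown") &
                    labeled["chrom"].isin(split.train_chroms)]
    all_cols = tuple(feature_column(f) for f in DEFAULT_MODEL_FEATURES)
    densities = fit_class_densities(train, all_cols)

    scored = score_pairs(labeled, densities, model_features)
    posteriors = posterior_table(scored)
    maps = map_targets(posteriors)
    gscores = gene_regulation_scores(posteriors)
    return PipelineResult(consensus=distal_kept, genes=genes_kept,
                          features=labeled, densities=densities,
                          posteriors=posteriors, map_table=maps,
                          gene_scores=gscores, split=split,
                          model_features=model_features)


def _consensus_truth(bundle: SynthBundle,
                     consensus: list[ConsensusEnhancer]) -> dict[str, set[str]]:
    """Complete-truth targets re-keyed by recovered consensus enhancer id."""
    truth = bundle.truth_targets
    out: dict[str, set[str]] = {}
    planted = [e for e in bundle.enhancers if e.name in truth]
    for c in consensus:
        for p in planted:
            if overlaps(c.region, p):
                out.setdefault(c.id, set()).update(truth[p.name])
    return out


def truth_recovery_report(bundle: SynthBundle, result: PipelineResult,
                          tpr_levels=(0.10, 0.20, 0.30),
                          chroms: frozenset | None = None) -> dict:
    """MAP accuracy and precision-at-TPR against the COMPLETE planted truth
    (not the subsampled observed links), optionally restricted to a
    chromosome set (e.g. the held-out test chromosomes)."""
    truth = _consensus_truth(bundle, result.consensus)
    post = result.posteriors
    if chroms is not None:
        post = post[post["chrom"].isin(chroms)]
    evaluated = post[post["enhancer_id"].isin(truth)]
    if evaluated.empty:
        raise ValueError("no truth enhancer present in the evaluated set")

    labels = np.array([row.gene_id in truth[row.enhancer_id]
                       for row in evaluated.itertuples()], dtype=int)
    scores = evaluated["posterior"].to_numpy(dtype=float)
    prec = precision_at_tpr(scores, labels, tpr_levels)

    maps = result.map_table
    maps = maps[maps["enhancer_id"].isin(evaluated["enhancer_id"].unique())]
    acc = map_accuracy(maps, truth)
    return {
        "n_enhancers": int(evaluated["enhancer_id"].nunique()),
        "n_pairs": int(len(evaluated)),
        "n_true_pairs": int(labels.sum()),
        "precision_at_tpr": prec,
        "map_accuracy": acc,
    }
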