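"""Per-pair attribute vectors: time-course correlations and genomic separation.

For every same-chromosome enhancer-gene pair the feature vector holds one
Pearson correlation per assay (the two polymerase replicates are collapsed to
their average correlation) and the log10 of the bp separation between the
enhancer centre and the promoter-shifted TSS. Pairs are labelled positive /
negative / unknown against interaction ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from eplink.consensus import ConsensusEnhancer
from eplink.genome_io import AnchorPair, Gene, overlaps, promoter_extended, shifted_tss
from eplink.timeseries import TimeSeriesSet

__all__ = [
    "DEFAULT_FEATURE_ASSAYS",
    "FEATURE_COLUMNS",
    "pearson",
    "build_features",
    "label_pairs",
]

# feature name -> assay labels whose per-replicate correlations are averaged
DEFAULT_FEATURE_ASSAYS: dict[str, tuple[str, ...]] = {
    "ER": ("ER",),
    "PolII": ("PolII_rep1", "PolII_rep2"),
    "H2AZ": ("H2AZ",),
    "H3K4me3": ("H3K4me3",),
}

FEATURE_COLUMNS = ("c_ER", "c_PolII", "c_H2AZ", "c_H3K4me3", "log10_dist")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; 0 when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    # exact +/-1 for (anti-)identical centred series, immune to sqrt rounding
    if np.array_equal(xc, yc):
        return 1.0
    if np.array_equal(xc, -yc):
        return -1.0
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def _standardized_rows(matrix: np.ndarray) -> np.ndarray:
    """Rows centred and scaled to unit norm; zero-variance rows become zero
    so their correlation with anything is 0."""
    centred = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centred**2, axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms > 0, centred / norms, 0.0)
    return z


def build_features(enh_ts: dict[str, TimeSeriesSet],
                   gene_ts: dict[str, TimeSeriesSet],
                   enhancers: list[ConsensusEnhancer],
                   genes: list[Gene],
                   feature_assays: dict[str, tuple[str, ...]] | None = None,
                   max_distance: float | None = None) -> pd.DataFrame:
    """Feature table over the candidate universe (all same-chromosome pairs).

    Returns a DataFrame with columns enhancer_id, gene_id, chrom,
    c_<feature>..., distance_bp, log10_dist. Distances use
    |shifted TSS - enhancer centre| with a guarded minimum of 1 bp; an exactly
    zero separation flags a non-distal pair and raises.
    """
    if feature_assays is None:
        feature_assays = DEFAULT_FEATURE_ASSAYS

    enh_by_chrom: dict[str, list[ConsensusEnhancer]] = {}
    for enh in enhancers:
        enh_by_chrom.setdefault(enh.region.chrom, []).append(enh)
    gene_by_chrom: dict[str, list[Gene]] = {}
    for gene in genes:
        gene_by_chrom.setdefault(gene.chrom, []).append(gene)

    # precompute standardized rows once per assay
    z_enh = {a: _standardized_rows(ts.matrix) for a, ts in enh_ts.items()}
    z_gene = {a: _standardized_rows(ts.matrix) for a, ts in gene_ts.items()}
    enh_index = {a: {rid: i for i, rid in enumerate(ts.region_ids)}
                 for a, ts in enh_ts.items()}
    gene_index = {a: {rid: i for i, rid in enumerate(ts.region_ids)}
                  for a, ts in gene_ts.items()}

    records: list[dict] = []
    for chrom in sorted(set(enh_by_chrom) & set(gene_by_chrom)):
        chrom_enh = enh_by_chrom[chrom]
        chrom_genes = gene_by_chrom[chrom]
        corr: dict[str, np.ndarray] = {}
        for feat, assays in feature_assays.items():
            acc = np.zeros((len(chrom_enh), len(chrom_genes)))
            for assay in assays:
                ei = [enh_index[assay][e.id] for e in chrom_enh]
                gi = [gene_index[assay][g.name] for g in chrom_genes]
                acc += z_enh[assay][ei, :] @ z_gene[assay][gi, :].T
            corr[feat] = np.clip(acc / len(assays), -1.0, 1.0)

        for i, enh in enumerate(chrom_enh):
            for j, gene in enumerate(chrom_genes):
                sep = abs(shifted_tss(gene) - enh.center)
                if sep == 0:
                    raise ValueError(
                        f"zero separation for pair ({enh.id}, {gene.name}); "
                        "non-distal pair in candidate universe")
                if max_distance is not None and sep > max_distance:
                    continue
                rec = {"enhancer_id": enh.id, "gene_id": gene.name, "chrom": chrom,
                       "enh_center": enh.center, "tss_shifted": shifted_tss(gene)}
                for feat in feature_assays:
                    rec[f"c_{feat}"] = corr[feat][i, j]
                rec["distance_bp"] = sep
                rec["log10_dist"] = np.log10(max(sep, 1))
                records.append(rec)

    columns = ["enhancer_id", "gene_id", "chrom", "enh_center", "tss_shifted"] + \
        [f"c_{feat}" for feat in feature_assays] + ["distance_bp", "log10_dist"]
    return pd.DataFrame.from_records(records, columns=columns)


def label_pairs(pairs: pd.DataFrame,
                truth: list[AnchorPair],
                enhancers: list[ConsensusEnhancer],
                genes: list[Gene],
                min_overlap: int = 1) -> pd.DataFrame:
    """Attach labels from interaction anchors.

    A pair is *positive* iff one anchor overlaps the enhancer and its mate
    overlaps the promoter-extended gene (either orientation; liberal when an
    anchor overlaps both element types). A pair is *negative* iff its enhancer
    has at least one positive but this gene is not among its targets. Pairs of
    enhancers with no anchor support at all are *unknown* and excluded from
    training.
    """
    positive_pairs: set[tuple[str, str]] = set()
    ext_genes = [(g, promoter_extended(g)) for g in genes]
    for link in truth:
        for enh_anchor, gene_anchor in ((link.anchor_a, link.anchor_b),
                                        (link.anchor_b, link.anchor_a)):
            hit_enh = [e for e in enhancers
                       if overlaps(e.region, enh_anchor, min_overlap)]
            if not hit_enh:
                continue
            hit_genes = [g for g, ext in ext_genes
                         if overlaps(ext, gene_anchor, min_overlap)]
            for e in hit_enh:
                for g in hit_genes:
                    positive_pairs.add((e.id, g.name))

    linked_enh = {eid for eid, _ in positive_pairs}
    out = pairs.copy()
    keys = list(zip(out["enhancer_id"], out["gene_id"]))
    out["label"] = [
        "positive" if key in positive_pairs
        else ("negative" if key[0] in linked_enh else "unknown")
        for key in keys
    ]
    return out
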