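"""Validation machinery: chromosome splits, precision-at-recall, FDR cutoffs,
MAP accuracy, TAD stratification and DE-gene ranking curves.

Ranking conventions: pairs are sorted by score descending and tied scores are
always taken as one block (no sub-ranking randomness). Precision at recall
level tau uses the smallest block-aligned prefix whose recall reaches tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eplink.genome_io import Region

__all__ = [
    "SplitSpec",
    "odd_even_split",
    "chrom_number",
    "precision_at_tpr",
    "fdr_cutoff",
    "map_accuracy",
    "stratify_by_tad",
    "de_gene_validation",
]


def chrom_number(chrom: str) -> int | None:
    """Numeric part of names like chr7 / 7; None for chrX, chrM, ..."""
    token = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return int(token) if token.isdigit() else None


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test chromosome sets."""

    train_chroms: frozenset = field(default_factory=frozenset)
    test_chroms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.train_chroms & self.test_chroms:
            raise ValueError("train and test chromosomes must be disjoint")


def odd_even_split(chroms, include_sex: bool = False) -> SplitSpec:
    """Odd-numbered autosomes train, even-numbered test; non-numeric names
    (chrX, chrY, ...) are excluded unless ``include_sex``, in which case they
    join the training set."""
    train, test = set(), set()
    for chrom in chroms:
        num = chrom_number(chrom)
        if num is None:
            if include_sex:
                train.add(chrom)
            continue
        (train if num % 2 == 1 else test).add(chrom)
    return SplitSpec(frozenset(train), frozenset(test))


def _block_prefix_stats(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP at the end of each tied-score block, descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # block ends: last index of each run of equal scores
    block_end = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    cum_tp = np.cumsum(y)[block_end]
    cum_n = block_end + 1
    thresholds = s[block_end]
    return thresholds, cum_tp, cum_n


def precision_at_tpr(scores, labels, tpr_levels) -> dict[float, float]:
    """Precision of the smallest block-aligned prefix reaching each recall."""
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("need at least one positive label")
    _, cum_tp, cum_n = _block_prefix_stats(scores, labels)
    recall = cum_tp / n_pos
    out: dict[float, float] = {}
    for tau in tpr_levels:
        idx = int(np.argmax(recall >= tau))  # first block with recall >= tau
        out[float(tau)] = float(cum_tp[idx] / cum_n[idx])
    return out


def fdr_cutoff(scores, labels, fdr_levels) -> dict[float, dict | None]:
    """For each FDR level f, the score threshold with the highest TPR among
    all block thresholds whose prefix precision is >= 1 - f; None when no
    threshold qualifies."""
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("need at least one positive label")
    thresholds, cum_tp, cum_n = _block_prefix_stats(scores, labels)
    precision = cum_tp / cum_n
    recall = cum_tp / n_pos
    out: dict[float, dict | None] = {}
    for f in fdr_levels:
        ok = np.nonzero(precision >= 1.0 - f)[0]
        if ok.size == 0:
            out[float(f)] = None
            continue
        best = ok[np.argmax(recall[ok])]  # argmax takes the first (highest
        # threshold) among ties; prefer the largest prefix, i.e. last tie
        ties = ok[recall[ok] == recall[best]]
        best = ties[-1]
        out[float(f)] = {"threshold": float(thresholds[best]),
                         "tpr": float(recall[best]),
                         "precision": float(precision[best]),
                         "n_accepted": int(cum_n[best])}
    return out


def map_accuracy(map_table: pd.DataFrame,
                 truth_targets: dict[str, set[str]]) -> float:
    """Percentage of enhancers whose MAP gene is among their truth targets.

    Only enhancers present in ``truth_targets`` (>=1 confirmed target) are
    evaluated.
    """
    evaluated = map_table[map_table["enhancer_id"].isin(truth_targets)]
    if evaluated.empty:
        raise ValueError("no enhancer with ground truth in the MAP table")
    hits = sum(row.map_gene in truth_targets[row.enhancer_id]
               for row in evaluated.itertuples())
    return 100.0 * hits / len(evaluated)


def _tad_index(tads_by_chrom, chrom: str, pos: int) -> int | None:
    entry = tads_by_chrom.get(chrom)
    if entry is None:
        return None
    starts, ends = entry
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i >= 0 and pos < ends[i]:
        return i
    return None


def stratify_by_tad(pairs: pd.DataFrame, tads: list[Region]) -> np.ndarray:
    """Boolean mask: True where enhancer centre and shifted TSS fall inside
    the SAME TAD; everything else (different TADs, either element outside all
    TADs) is inter. TADs must be non-overlapping per chromosome."""
    tads_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[Region]] = {}
    for tad in tads:
        grouped.setdefault(tad.chrom, []).append(tad)
    for chrom, regs in grouped.items():
        regs.sort(key=lambda r: r.start)
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: [{a.start},{a.end}) and "
                    f"[{b.start},{b.end})")
        tads_by_chrom[chrom] = (np.array([r.start for r in regs]),
                                np.array([r.end for r in regs]))

    intra = np.zeros(len(pairs), dtype=bool)
    for i, row in enumerate(pairs.itertuples()):
        ti = _tad_index(tads_by_chrom, row.chrom, int(row.enh_center))
        tj = _tad_index(tads_by_chrom, row.chrom, int(row.tss_shifted))
        intra[i] = ti is not None and ti == tj
    return intra


def de_gene_validation(gene_scores: pd.DataFrame,
                       de_genes: set[str]) -> pd.DataFrame:
    """Precision/recall along the regulation-score ranking of genes against an
    externally supplied differentially-expressed gene list."""
    if not de_genes:
        raise ValueError("de_genes must be non-empty")
    ranked = gene_scores.sort_values(
        ["regulation_prob", "gene_id"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    hits = ranked["gene_id"].isin(de_genes).to_numpy()
    cum_tp = np.cumsum(hits)
    k = np.arange(1, len(ranked) + 1)
    return pd.DataFrame({
        "gene_id": ranked["gene_id"],
        "regulation_prob": ranked["regulation_prob"],
        "precision": cum_tp / k,
        "recall": cum_tp / len(de_genes),
    })
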