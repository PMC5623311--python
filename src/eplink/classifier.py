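"""Naive Bayes posterior over each enhancer's candidate target genes.

Per pair, the log density ratio sums log P(feature | interacting) minus
log P(feature | background) over the configured feature subset. Because the
single-target structures share the background densities of every non-target
pair, those factors cancel and the posterior over K candidates reduces to a
softmax of log prior + log ratio; the cancellation-free full-product form is
kept in the test suite as an oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from eplink.densities import ClassDensities

__all__ = [
    "DEFAULT_MODEL_FEATURES",
    "feature_column",
    "pair_log_ratio",
    "posterior_over_genes",
    "score_pairs",
    "posterior_table",
    "map_targets",
    "gene_regulation_scores",
]

# model feature names -> feature-table columns
DEFAULT_MODEL_FEATURES = ("ER", "PolII", "H2AZ", "H3K4me3", "dist")


def feature_column(feature: str) -> str:
    return "log10_dist" if feature == "dist" else f"c_{feature}"


def pair_log_ratio(features: pd.DataFrame | pd.Series,
                   densities: ClassDensities,
                   model_features: tuple[str, ...] = DEFAULT_MODEL_FEATURES) -> np.ndarray | float:
    """log r = sum over configured features of log P(x|I=1) - log P(x|I=0)."""
    single = isinstance(features, pd.Series)
    table = features.to_frame().T if single else features
    total = np.zeros(len(table))
    for feat in model_features:
        col = feature_column(feat)
        if col not in table.columns:
            raise KeyError(f"feature column {col!r} missing from table")
        q = table[col].to_numpy(dtype=float)
        total += densities.get(col, "positive").logpdf(q)
        total -= densities.get(col, "negative").logpdf(q)
    return float(total[0]) if single else total


def posterior_over_genes(log_ratios: np.ndarray,
                         prior: np.ndarray | None = None) -> np.ndarray:
    """P(target = k | data) = softmax_k(log prior_k + log r_k)."""
    lr = np.asarray(log_ratios, dtype=float)
    if lr.size == 0:
        raise ValueError("need at least one candidate")
    if prior is None:
        log_prior = np.full(lr.size, -np.log(lr.size))
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != lr.shape:
            raise ValueError("prior must align with candidates")
        if not np.isclose(prior.sum(), 1.0):
            raise ValueError("prior must sum to 1")
        with np.errstate(divide="ignore"):
            log_prior = np.log(prior)
    logits = log_prior + lr
    if not np.any(np.isfinite(logits)):
        raise ValueError("all candidate log-ratios are -inf (degenerate densities)")
    return np.exp(logits - logsumexp(logits))


def score_pairs(pairs: pd.DataFrame, densities: ClassDensities,
                model_features: tuple[str, ...] = DEFAULT_MODEL_FEATURES) -> pd.DataFrame:
    """Append a log_ratio column to a feature table."""
    out = pairs.copy()
    out["log_ratio"] = pair_log_ratio(pairs, densities, model_features)
    return out


def posterior_table(scored: pd.DataFrame,
                    prior: str | dict = "uniform") -> pd.DataFrame:
    """Per-pair posteriors, normalised within each enhancer's candidate set.

    ``prior`` is "uniform" or a mapping enhancer_id -> per-candidate prior
    array aligned with the enhancer's rows (in table order).
    """
    out = scored.reset_index(drop=True)
    post = np.empty(len(out))
    for enh_id, idx in out.groupby("enhancer_id", sort=False).groups.items():
        positions = np.asarray(idx)
        lr = out.loc[idx, "log_ratio"].to_numpy(dtype=float)
        p = None if prior == "uniform" else np.asarray(prior[enh_id], dtype=float)
        post[positions] = posterior_over_genes(lr, p)
    out["posterior"] = post
    return out


def map_targets(posteriors: pd.DataFrame) -> pd.DataFrame:
    """MAP gene per enhancer; ties broken by smaller distance_bp, then
    lexicographic gene_id (deterministic)."""
    ranked = posteriors.sort_values(
        ["enhancer_id", "posterior", "distance_bp", "gene_id"],
        ascending=[True, False, True, True], kind="mergesort")
    top = ranked.groupby("enhancer_id", sort=True).head(1)
    return top[["enhancer_id", "gene_id", "posterior"]].rename(
        columns={"gene_id": "map_gene", "posterior": "map_prob"}).reset_index(drop=True)


def gene_regulation_scores(posteriors: pd.DataFrame) -> pd.DataFrame:
    """Per gene: 1 - prod_j (1 - posterior_j) over enhancers whose candidate
    set contains the gene, i.e. the probability at least one enhancer
    targets it. Computed via log1p for stability."""
    records = []
    for gene_id, sub in posteriors.groupby("gene_id", sort=True):
        p = np.clip(sub["posterior"].to_numpy(dtype=float), 0.0, 1.0)
        if np.any(p >= 1.0):
            score = 1.0
        else:
            score = -np.expm1(np.sum(np.log1p(-p)))
        records.append({"gene_id": gene_id,
                        "regulation_prob": float(np.clip(score, 0.0, 1.0)),
                        "n_enhancers": len(sub)})
    return pd.DataFrame.from_records(
        records, columns=["gene_id", "regulation_prob", "n_enhancers"])
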