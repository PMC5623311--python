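import numpy as np
import pandas as pd
import pytest

from eplink.classifier import (gene_regulation_scores, map_targets,
                               pair_log_ratio, posterior_over_genes,
                               posterior_table, score_pairs)
from eplink.densities import ClassDensities, KdeDensity

FEATS = ("ER", "PolII", "H2AZ", "H3K4me3", "dist")
COLS = ("c_ER", "c_PolII", "c_H2AZ", "c_H3K4me3", "log10_dist")


def random_densities(rng, identical=False):
    densities = {}
    for col in COLS:
        pos = KdeDensity(values=rng.normal(0.4, 0.3, size=rng.integers(5, 25)),
                         bandwidth=float(rng.uniform(0.05, 0.6)),
                         feature=col, klass="positive")
        if identical:
            neg = KdeDensity(values=pos.values, bandwidth=pos.bandwidth,
                             feature=col, klass="negative")
        else:
            neg = KdeDensity(values=rng.normal(0.0, 0.4, size=rng.integers(5, 40)),
                             bandwidth=float(rng.uniform(0.05, 0.6)),
                             feature=col, klass="negative")
        densities[(col, "positive")] = pos
        densities[(col, "negative")] = neg
    return ClassDensities(densities)


def random_pairs(rng, k):
    return pd.DataFrame({
        "enhancer_id": ["E"] * k,
        "gene_id": [f"g{i}" for i in range(k)],
        "chrom": ["chr1"] * k,
        "c_ER": rng.uniform(-1, 1, k),
        "c_PolII": rng.uniform(-1, 1, k),
        "c_H2AZ": rng.uniform(-1, 1, k),
        "c_H3K4me3": rng.uniform(-1, 1, k),
        "log10_dist": rng.uniform(3.7, 8.0, k),
        "distance_bp": rng.integers(5_000, 10**8, k),
    })


def full_likelihood_posterior(pairs, densities, prior=None):
    """Oracle: direct single-target-structure evaluation with the complete
    product over all K pairs per structure -- no cancellation shortcut.
    The per-structure product accumulates every one of the K x 5 factors
    (in log space so extreme queries do not underflow the comparison)."""
    k = len(pairs)
    prior = np.full(k, 1.0 / k) if prior is None else np.asarray(prior)
    logpdfs = {}
    for col in COLS:
        q = pairs[col].to_numpy(dtype=float)
        logpdfs[col] = {kl: [densities.get(col, kl).logpdf(float(x)) for x in q]
                        for kl in ("positive", "negative")}
    log_unnorm = np.zeros(k)
    for target in range(k):
        total = np.log(prior[target])
        for j in range(k):
            klass = "positive" if j == target else "negative"
            for col in COLS:
                total += logpdfs[col][klass][j]
        log_unnorm[target] = total
    shifted = np.exp(log_unnorm - log_unnorm.max())
    return shifted / shifted.sum()


class TestPairLogRatio:
    def test_identical_densities_give_zero(self):
        rng = np.random.default_rng(0)
        densities = random_densities(rng, identical=True)
        pairs = random_pairs(rng, 5)
        np.testing.assert_allclose(pair_log_ratio(pairs, densities, FEATS),
                                   np.zeros(5), atol=1e-12)

    def test_distance_only_ratio(self):
        # P(d|1) = 2 P(d|0) at the query -> log 2 for the {dist} subset
        pos = KdeDensity(values=np.array([5.0]), bandwidth=1.0)
        neg_h = 2.0  # halves the kernel height at the shared mode
        neg = KdeDensity(values=np.array([5.0]), bandwidth=neg_h)
        densities = ClassDensities({("log10_dist", "positive"): pos,
                                    ("log10_dist", "negative"): neg})
        row = pd.Series({"log10_dist": 5.0})
        assert pair_log_ratio(row, densities, ("dist",)) == pytest.approx(np.log(2))

    def test_matches_naive_product_oracle(self):
        rng = np.random.default_rng(1)
        densities = random_densities(rng)
        pairs = random_pairs(rng, 6)
        got = pair_log_ratio(pairs, densities, FEATS)
        for i in range(6):
            log_pos = sum(densities.get(c, "positive").logpdf(float(pairs[c][i]))
                          for c in COLS)
            log_neg = sum(densities.get(c, "negative").logpdf(float(pairs[c][i]))
                          for c in COLS)
            assert got[i] == pytest.approx(log_pos - log_neg, abs=1e-10)

    def test_missing_feature_errors(self):
        rng = np.random.default_rng(2)
        densities = random_densities(rng)
        pairs = random_pairs(rng, 3).drop(columns=["c_H2AZ"])
        with pytest.raises(KeyError):
            pair_log_ratio(pairs, densities, FEATS)


class TestPosteriorOverGenes:
    def test_two_candidates_log3(self):
        post = posterior_over_genes(np.array([np.log(3.0), 0.0]))
        np.testing.assert_allclose(post, [0.75, 0.25])

    def test_equal_ratios_uniform(self):
        post = posterior_over_genes(np.full(7, 2.31))
        np.testing.assert_allclose(post, np.full(7, 1 / 7), atol=1e-15)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            post = posterior_over_genes(rng.normal(scale=30, size=rng.integers(1, 12)))
            assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_full_likelihood_oracle(self):
        rng = np.random.default_rng(3)
        densities = random_densities(rng)
        pairs = random_pairs(rng, 6)
        lr = pair_log_ratio(pairs, densities, FEATS)
        got = posterior_over_genes(lr)
        expected = full_likelihood_posterior(pairs, densities)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_prior_odds_propagate_exactly(self):
        lr = np.array([0.3, -0.2])
        prior = np.array([0.8, 0.2])
        post = posterior_over_genes(lr, prior)
        uniform = posterior_over_genes(lr)
        got_odds = post[0] / post[1]
        assert got_odds == pytest.approx((uniform[0] / uniform[1]) * (0.8 / 0.2))

    def test_monotonicity_in_one_ratio(self):
        rng = np.random.default_rng(4)
        lr = rng.normal(size=5)
        base = posterior_over_genes(lr)
        bumped = lr.copy()
        bumped[2] += 0.5
        new = posterior_over_genes(bumped)
        assert new[2] > base[2]
        for i in (0, 1, 3, 4):
            assert new[i] <= base[i]

    def test_bad_prior_rejected(self):
        with pytest.raises(ValueError):
            posterior_over_genes(np.zeros(2), np.array([0.9, 0.2]))

    def test_all_minus_inf_errors(self):
        with pytest.raises(ValueError):
            posterior_over_genes(np.array([-np.inf, -np.inf]))


class TestMapTargets:
    def make_posteriors(self, probs, dists, genes=None):
        k = len(probs)
        genes = genes or [f"g{i}" for i in range(k)]
        return pd.DataFrame({"enhancer_id": ["E"] * k, "gene_id": genes,
                             "posterior": probs, "distance_bp": dists})

    def test_argmax(self):
        maps = map_targets(self.make_posteriors([0.75, 0.25], [100, 50]))
        assert maps.iloc[0].map_gene == "g0"
        assert maps.iloc[0].map_prob == 0.75

    def test_tie_broken_by_distance(self):
        maps = map_targets(self.make_posteriors([0.5, 0.5], [50_000, 10_000]))
        assert maps.iloc[0].map_gene == "g1"

    def test_tie_broken_by_gene_id(self):
        maps = map_targets(self.make_posteriors([0.5, 0.5], [100, 100],
                                                genes=["gB", "gA"]))
        assert maps.iloc[0].map_gene == "gA"

    def test_single_candidate(self):
        maps = map_targets(self.make_posteriors([1.0], [100]))
        assert maps.iloc[0].map_gene == "g0" and maps.iloc[0].map_prob == 1.0


class TestGeneRegulationScores:
    def make(self, gene_posts):
        rows = []
        for gene, posts in gene_posts.items():
            for i, p in enumerate(posts):
                rows.append({"enhancer_id": f"E{i}", "gene_id": gene,
                             "posterior": p})
        return pd.DataFrame(rows)

    def test_two_halves(self):
        scores = gene_regulation_scores(self.make({"g": [0.5, 0.5]}))
        assert scores.iloc[0].regulation_prob == pytest.approx(0.75)
        assert scores.iloc[0].n_enhancers == 2

    def test_single_enhancer(self):
        scores = gene_regulation_scores(self.make({"g": [0.37]}))
        assert scores.iloc[0].regulation_prob == pytest.approx(0.37)

    def test_certain_enhancer_absorbs(self):
        scores = gene_regulation_scores(self.make({"g": [1.0, 0.01, 0.5]}))
        assert scores.iloc[0].regulation_prob == 1.0

    def test_monotone_in_posteriors_and_contributors(self):
        low = gene_regulation_scores(self.make({"g": [0.2, 0.3]}))
        high = gene_regulation_scores(self.make({"g": [0.2, 0.4]}))
        more = gene_regulation_scores(self.make({"g": [0.2, 0.3, 0.1]}))
        assert high.iloc[0].regulation_prob > low.iloc[0].regulation_prob
        assert more.iloc[0].regulation_prob > low.iloc[0].regulation_prob


class TestPosteriorTable:
    def test_normalized_per_enhancer(self):
        rng = np.random.default_rng(0)
        frames = []
        for e in range(4):
            f = random_pairs(rng, int(rng.integers(2, 9)))
            f["enhancer_id"] = f"E{e}"
            frames.append(f)
        pairs = pd.concat(frames, ignore_index=True)
        densities = random_densities(rng)
        post = posterior_table(score_pairs(pairs, densities, FEATS))
        sums = post.groupby("enhancer_id")["posterior"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert ((post.posterior >= 0) & (post.posterior <= 1)).all()

    def test_uninformative_densities_give_prior(self):
        rng = np.random.default_rng(1)
        pairs = random_pairs(rng, 8)
        densities = random_densities(rng, identical=True)
        post = posterior_table(score_pairs(pairs, densities, FEATS))
        np.testing.assert_allclose(post.posterior, 1 / 8, atol=1e-12)
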