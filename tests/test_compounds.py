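"""Drug-target negatives, strata, motif druggability and variant filtering."""

import itertools
from math import comb, log10

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwas.compounds import (DrugTargetSet, VariantRecord, motif_druggability,
                            promiscuity_stratified_metrics,
                            promiscuous_negatives, rank_targets_for_compound,
                            train_compound_target_models,
                            variant_candidate_filter)
from pwas.nn import FeedForward, MLPSpec
from pwas.word2vec import EmbeddingHyperparams, EmbeddingModel


class TestPromiscuousNegatives:
    def test_toy_cross_product_minus_positives(self):
        positives = DrugTargetSet.from_pairs(
            [("c1", "g1"), ("c2", "g2"),
             ("c1", "g3"), ("c2", "g3"), ("c3", "g3")])
        negs = promiscuous_negatives(positives, n_proteins=3, n_compounds=3)
        # oracle: full 3x3 cross product minus the positives that fall in it
        all_c = {"c1", "c2", "c3"}
        all_g = {"g1", "g2", "g3"}
        oracle = {(c, g) for c in all_c for g in all_g} - positives.positives
        assert negs == oracle
        assert len(negs) == 9 - 5

    def test_positives_covering_cross_product_give_empty_set(self):
        positives = DrugTargetSet.from_pairs(
            [("c1", "g1"), ("c1", "g2"), ("c2", "g1"), ("c2", "g2")])
        assert promiscuous_negatives(positives, 2, 2) == set()

    def test_oversized_request_rejected(self):
        positives = DrugTargetSet.from_pairs([("c1", "g1")])
        with pytest.raises(ValueError):
            promiscuous_negatives(positives, n_proteins=400, n_compounds=400)


@settings(deadline=None, max_examples=40)
@given(st.sets(st.tuples(st.sampled_from(["c1", "c2", "c3", "c4"]),
                         st.sampled_from(["g1", "g2", "g3", "g4"])),
               min_size=1))
def test_negatives_never_intersect_positives(pairs):
    positives = DrugTargetSet.from_pairs(sorted(pairs))
    n = min(2, len(positives.targets_per_compound()),
            len(positives.compounds_per_gene()))
    negs = promiscuous_negatives(positives, n_proteins=n, n_compounds=n)
    assert not negs & positives.positives


class TestModelZoo:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(300, 8))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        return X[:200], y[:200], X[200:], y[200:]

    def test_table_sorted_by_mcc_and_includes_baselines(self):
        X_tr, y_tr, X_te, y_te = self._separable()
        entries = train_compound_target_models(
            X_tr, y_tr, X_te, y_te, specs=[MLPSpec(1, 20, 0.0)], epochs=100)
        names = [e.name for e in entries]
        assert "Logistic Regression" in names and "RFC" in names
        mccs = [e.metrics["mcc"] for e in entries]
        assert mccs == sorted(mccs, reverse=True)
        assert mccs[0] > 0.8

    def test_feature_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_compound_target_models(np.zeros((4, 3)), np.array([0, 1, 0, 1]),
                                         np.zeros((2, 5)), np.array([0, 1]))

    def test_default_zoo_naming_matches_grid(self):
        from pwas.compounds import ZOO_MLP_SPECS
        names = {s.name for s in ZOO_MLP_SPECS}
        assert len(ZOO_MLP_SPECS) == 24
        assert "H100-N2-D0.2" in names
        assert MLPSpec.parse("H100-N2-D0.2") in ZOO_MLP_SPECS


class TestStratifiedMetrics:
    def _predictions(self):
        positives = DrugTargetSet.from_pairs(
            [("mono", "g1"),
             ("duo", "g1"), ("duo", "g2"),
             ("poly", "g1"), ("poly", "g2"), ("poly", "g3")])
        preds = [  # ((compound, gene), true, predicted)
            (("mono", "g1"), 1, 1), (("mono", "g9"), 0, 0),
            (("duo", "g1"), 1, 1), (("duo", "g2"), 1, 0), (("duo", "g9"), 0, 0),
            (("poly", "g1"), 1, 1), (("poly", "g2"), 1, 1),
            (("poly", "g3"), 1, 0), (("poly", "g9"), 0, 1),
        ]
        return preds, positives

    def test_strata_match_confusion_matrix_oracle(self):
        preds, positives = self._predictions()
        out = promiscuity_stratified_metrics(preds, positives)
        assert set(out) == {"1", "2", ">2"}
        assert out["1"]["active"]["recall"] == 1.0
        assert out["1"]["all"]["accuracy"] == 1.0
        # ">2" stratum: tp=2, fn=1, fp=1 among 4 rows
        assert out[">2"]["all"]["accuracy"] == pytest.approx(2 / 4 + 0 / 4 + 0.0)
        assert out[">2"]["active"]["recall"] == pytest.approx(2 / 3)

    def test_single_specific_compound_perfect_precision(self):
        positives = DrugTargetSet.from_pairs([("c", "g")])
        out = promiscuity_stratified_metrics([(("c", "g"), 1, 1)], positives)
        assert out["1"]["active"]["precision"] == 1.0

    def test_pooled_strata_reproduce_global_confusion_matrix(self):
        preds, positives = self._predictions()
        out = promiscuity_stratified_metrics(preds, positives)
        total = sum(
            round(out[s]["all"]["accuracy"] *
                  len([1 for (c, _g), _t, _p in preds
                       if (">2" if positives.targets_per_compound().get(c, 0) > 2
                           else str(positives.targets_per_compound().get(c, 0))) == s]))
            for s in out)
        global_correct = sum(1 for _, t, p in preds if t == p)
        assert total == global_correct


class TestMotifDruggability:
    def test_exact_hypergeometric_tail(self):
        # motif carried by exactly the 5 genes, all drugged; universe 100,
        # 10 drugged: one-sided p = C(10,5)*C(90,0)/C(100,5)
        membership = {f"g{i}": {"M"} if i < 5 else set() for i in range(100)}
        drugged = {f"g{i}" for i in range(10)}
        score = motif_druggability(membership, drugged)
        p_exact = comb(10, 5) * comb(90, 0) / comb(100, 5)
        assert score.motif_scores["M"] == pytest.approx(-log10(p_exact), rel=1e-6)
        assert score.get("g0") == pytest.approx(-log10(p_exact), rel=1e-6)

    def test_gene_without_motifs_scores_zero(self):
        membership = {"a": {"M"}, "b": set()}
        score = motif_druggability(membership, {"a"})
        assert score.get("b") == 0.0

    def test_universal_motif_scores_zero(self):
        membership = {f"g{i}": {"M"} for i in range(10)}
        score = motif_druggability(membership, {"g0", "g1"})
        assert score.motif_scores["M"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_oracle_on_small_universes(self):
        # every (membership, drugged) configuration on a 6-gene universe with
        # one motif, against a direct hypergeometric tail enumeration
        from scipy.stats import hypergeom
        genes = [f"g{i}" for i in range(6)]
        for n_carriers in (1, 3, 5):
            for n_drugged in (1, 2, 4):
                membership = {g: ({"M"} if i < n_carriers else set())
                              for i, g in enumerate(genes)}
                drugged = set(genes[:n_drugged])
                a = len(set(genes[:n_carriers]) & drugged)
                p_oracle = hypergeom.sf(a - 1, 6, n_drugged, n_carriers)
                score = motif_druggability(membership, drugged)
                assert score.motif_scores["M"] == pytest.approx(
                    -log10(p_oracle), rel=1e-9)

    def test_relabelling_motifs_leaves_scores_unchanged(self):
        membership = {"a": {"M1"}, "b": {"M1"}, "c": {"M2"}, "d": set()}
        relabelled = {"a": {"X"}, "b": {"X"}, "c": {"Y"}, "d": set()}
        s1 = motif_druggability(membership, {"a", "c"})
        s2 = motif_druggability(relabelled, {"a", "c"})
        for g in membership:
            assert s1.get(g) == pytest.approx(s2.get(g))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            motif_druggability({}, set())


class TestRankTargets:
    def test_deterministic_and_planted_target_on_top(self):
        rng = np.random.default_rng(0)
        dim = 6
        vocab = ["drug"] + [f"g{i}" for i in range(20)]
        target_vec = rng.normal(size=dim) * 3.0
        vecs = [target_vec]  # the compound shares its direction with g0
        vecs.append(target_vec + rng.normal(scale=0.1, size=dim))
        for _ in range(19):
            vecs.append(rng.normal(size=dim))
        model = EmbeddingModel(cutoff_year=0, vocabulary=vocab,
                               vectors=np.array(vecs),
                               hyperparams=EmbeddingHyperparams(dim=dim))

        class DotScorer:
            """Scores a (gene || compound) feature by gene-compound alignment."""
            def predict_proba(self, X):
                g, c = X[:, :dim], X[:, dim:]
                sims = np.einsum("ij,ij->i", g, c)
                return 1 / (1 + np.exp(-sims))

        r1 = rank_targets_for_compound(DotScorer(), "drug", vocab[1:], model)
        r2 = rank_targets_for_compound(DotScorer(), "drug", vocab[1:], model)
        assert r1 == r2
        assert r1[0][0] == "g0"

    def test_oov_compound_rejected(self):
        model = EmbeddingModel(cutoff_year=0, vocabulary=["g0"],
                               vectors=np.ones((1, 2)),
                               hyperparams=EmbeddingHyperparams(dim=2))
        with pytest.raises(KeyError):
            rank_targets_for_compound(None, "nope", ["g0"], model)


class TestVariantFilter:
    def _record(self, **kw):
        base = dict(gene="GCKR", rsid="rs8179206", amino_acid_change="Glu77Gly",
                    beta=-2.945, minus_log10_p=20.18, n_studies_consistent=2,
                    likelihood=0.9)
        base.update(kw)
        return VariantRecord(**base)

    def test_strong_nonsynonymous_variant_retained(self):
        kept = variant_candidate_filter([self._record()])
        assert [r.rsid for r in kept] == ["rs8179206"]

    def test_boundary_p_value_excluded(self):
        # p exactly 1e-9 fails the strict inequality
        kept = variant_candidate_filter([self._record(minus_log10_p=9.0)])
        assert kept == []

    def test_synonymous_change_excluded(self):
        kept = variant_candidate_filter([self._record(amino_acid_change="Phe150Phe")])
        assert kept == []

    def test_explicit_flag_overrides_parsing(self):
        rec = self._record(amino_acid_change="?", non_synonymous=True)
        assert variant_candidate_filter([rec]) == [rec]

    def test_matches_rowwise_predicate_oracle(self):
        rng = np.random.default_rng(1)
        records = []
        for i in range(10):
            records.append(self._record(
                rsid=f"rs{i}",
                amino_acid_change=["Glu77Gly", "Phe150Phe"][i % 2],
                minus_log10_p=float(rng.uniform(5, 25)),
                n_studies_consistent=int(rng.integers(1, 4)),
                likelihood=float(rng.uniform(0, 1))))
        kept = variant_candidate_filter(records)
        oracle = [r for r in records
                  if r.amino_acid_change == "Glu77Gly"
                  and r.minus_log10_p > 9.0
                  and r.n_studies_consistent >= 2
                  and r.likelihood > 0.3]
        assert kept == oracle

    def test_likelihood_boundary_excluded(self):
        assert variant_candidate_filter([self._record(likelihood=0.3)]) == []
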