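"""Gene-disease ranking, prospective precision, bootstrap and z-scoring."""

import itertools
from dataclasses import dataclass, field

import numpy as np
import pytest
from scipy import stats

from pwas.associations import (ClinicalScore, ComentionIndex, bootstrap_baseline,
                               chembl_score, contextual_linking_words,
                               fit_clinical_score_regressor, novel_top_k,
                               prospective_precision, rank_genes_for_disease,
                               zscore_rankings)
from pwas.nn import MLPSpec
from pwas.word2vec import EmbeddingHyperparams, EmbeddingModel


def _model_from(vocab, vecs):
    return EmbeddingModel(cutoff_year=2005, vocabulary=vocab,
                          vectors=np.asarray(vecs, dtype=float),
                          hyperparams=EmbeddingHyperparams(dim=len(vecs[0])))


@pytest.fixture()
def toy_model():
    rng = np.random.default_rng(0)
    vocab = ["dis"] + [f"g{i}" for i in range(10)] + ["w1", "w2"]
    return _model_from(vocab, rng.normal(size=(13, 8)))


class TestRanking:
    def test_scores_sorted_descending_with_lexicographic_ties(self, toy_model):
        genes = [f"g{i}" for i in range(10)]
        r = rank_genes_for_disease(toy_model, "dis", genes)
        scores = [s for _, s, _ in r.entries]
        assert scores == sorted(scores, reverse=True)
        assert [k for _, _, k in r.entries] == list(range(1, 11))

    def test_input_order_does_not_matter(self, toy_model):
        genes = [f"g{i}" for i in range(10)]
        r1 = rank_genes_for_disease(toy_model, "dis", genes)
        r2 = rank_genes_for_disease(toy_model, "dis", genes[::-1])
        assert r1.entries == r2.entries

    def test_out_of_vocabulary_genes_excluded(self, toy_model):
        r = rank_genes_for_disease(toy_model, "dis", ["g0", "never_seen"])
        assert r.genes == ["g0"]
        assert r.gene_universe_size == 2

    def test_universe_of_one(self, toy_model):
        r = rank_genes_for_disease(toy_model, "dis", ["g3"])
        assert r.entries[0][2] == 1

    def test_oov_disease_rejected(self, toy_model):
        with pytest.raises(KeyError):
            rank_genes_for_disease(toy_model, "unknown_disease", ["g0"])


@pytest.fixture()
def comentions():
    return ComentionIndex({("g0", "dis"): 2001, ("g1", "dis"): 2007,
                           ("g2", "dis"): 2009, ("g5", "dis"): 2012})


class TestNovelAndProspective:
    def test_novel_filter_matches_filter_then_sort_oracle(self, toy_model, comentions):
        r = rank_genes_for_disease(toy_model, "dis", [f"g{i}" for i in range(10)])
        novel = novel_top_k(r, comentions, cutoff_year=2005, k=50)
        oracle = [g for g in r.genes if comentions.first_comention(g, "dis")
                  in (None,) or comentions.first_comention(g, "dis") > 2005]
        assert novel == oracle
        assert "g0" not in novel  # co-mentioned 2001

    def test_all_comentioned_gives_empty_list(self, toy_model, comentions):
        r = rank_genes_for_disease(toy_model, "dis", ["g0"])
        assert novel_top_k(r, comentions, 2005, k=5) == []

    def test_k_must_be_positive(self, toy_model, comentions):
        r = rank_genes_for_disease(toy_model, "dis", ["g0"])
        with pytest.raises(ValueError):
            novel_top_k(r, comentions, 2005, k=0)

    def test_curve_counts_future_comentions(self, comentions):
        curve = prospective_precision(["g1", "g2", "g3", "g4"], comentions,
                                      "dis", 2005, horizon_years=5)
        # g1 reported 2007 (t=2), g2 2009 (t=4); g3, g4 never
        assert curve.tolist() == [0.0, 0.25, 0.25, 0.5, 0.5]

    def test_curve_monotone_and_flat_zero_without_reports(self, comentions):
        curve = prospective_precision(["g8", "g9"], comentions, "dis", 2005, 4)
        assert np.all(curve == 0)
        curve2 = prospective_precision(["g1", "g2"], comentions, "dis", 2005, 10)
        assert np.all(np.diff(curve2) >= 0)

    def test_empty_predictions_rejected(self, comentions):
        with pytest.raises(ValueError):
            prospective_precision([], comentions, "dis", 2005, 3)


class TestBootstrapBaseline:
    def test_mean_matches_exhaustive_enumeration(self):
        # N=20 novel genes, 6 eventually reported, k=5: enumerate all C(20,5)
        universe = [f"g{i}" for i in range(20)]
        idx = ComentionIndex({(f"g{i}", "dis"): 2008 for i in range(6)})
        mean, std, terms = bootstrap_baseline(universe, idx, "dis", 2005,
                                              horizon_years=4, k=5, B=20000,
                                              seed=3)
        reported = set(range(6))
        exact = []
        for combo in itertools.combinations(range(20), 5):
            exact.append(sum(1 for i in combo if i in reported) / 5)
        exact_mean = np.mean(exact)  # = 6/20 by symmetry
        assert exact_mean == pytest.approx(6 / 20)
        se = np.std(exact) / np.sqrt(20000)
        assert mean[-1] == pytest.approx(exact_mean, abs=4 * se)

    def test_single_iteration_reproducible(self):
        universe = [f"g{i}" for i in range(20)]
        idx = ComentionIndex({("g0", "dis"): 2008})
        r1 = bootstrap_baseline(universe, idx, "dis", 2005, 3, k=5, B=1, seed=7)
        r2 = bootstrap_baseline(universe, idx, "dis", 2005, 3, k=5, B=1, seed=7)
        assert np.array_equal(r1[2], r2[2])

    def test_universe_smaller_than_k_rejected(self):
        idx = ComentionIndex({})
        with pytest.raises(ValueError):
            bootstrap_baseline(["g0", "g1"], idx, "dis", 2005, 3, k=5, B=10)


class TestLinkingWords:
    def test_identical_gene_disease_vectors_give_common_neighbours(self):
        vocab = ["gene", "dis", "near", "far"]
        vecs = [[1, 0], [1, 0], [0.9, 0.1], [0, 1]]
        m = _model_from(vocab, vecs)
        words = contextual_linking_words(m, "gene", "dis", top_n=2)
        assert words[0][0] == "near"

    def test_min_aggregation_requires_closeness_to_both(self):
        vocab = ["gene", "dis", "onlygene", "both"]
        vecs = [[1, 0, 0], [0, 1, 0], [1, 0.05, 0], [0.7, 0.7, 0]]
        m = _model_from(vocab, vecs)
        words = dict(contextual_linking_words(m, "gene", "dis", top_n=2))
        assert list(words)[0] == "both"

    def test_unknown_aggregation(self, toy_model):
        with pytest.raises(ValueError):
            contextual_linking_words(toy_model, "g0", "dis", agg="max")


class TestChemblScore:
    @pytest.mark.parametrize("phases, expected", [
        (["phase 1", "phase 3"], 0.7),
        ([], 0.0),
        (["approved"], 1.0),
        (["launched"], 1.0),
        (["phase 1"], 0.1),
        (["phase 2", "phase 2"], 0.2),
    ])
    def test_most_advanced_phase_wins(self, phases, expected):
        assert chembl_score(phases) == expected

    def test_monotone_in_phase_ordering(self):
        order = ["phase 1", "phase 2", "phase 3", "approved"]
        scores = [chembl_score([p]) for p in order]
        assert scores == sorted(scores)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            chembl_score(["phase 7"])


class TestClinicalRegressor:
    def _synthetic_problem(self, seed=0, n_genes=40, n_diseases=12, dim=6):
        rng = np.random.default_rng(seed)
        gene_emb = {f"g{i}": rng.normal(size=dim) for i in range(n_genes)}
        dis_emb = {f"d{i}": rng.normal(size=dim) for i in range(n_diseases)}
        w = rng.normal(size=2 * dim)
        scores = {}
        for d in dis_emb:
            for g in gene_emb:
                x = np.concatenate([gene_emb[g], dis_emb[d]])
                scores[(g, d)] = float(x @ w)
        split = {d: ("test" if i < 3 else "train")
                 for i, d in enumerate(sorted(dis_emb))}
        return gene_emb, dis_emb, ClinicalScore(scores), split

    def test_learnable_linear_scores_give_high_r2(self):
        gene_emb, dis_emb, scores, split = self._synthetic_problem()
        res = fit_clinical_score_regressor(
            gene_emb, dis_emb, scores, split,
            grid=[MLPSpec(1, 100, 0.0)], seed=0, epochs=600, patience=30)
        assert res.test_r2 > 0.9

    def test_missing_split_assignment_rejected(self):
        gene_emb, dis_emb, scores, split = self._synthetic_problem()
        del split["d0"]
        with pytest.raises(ValueError, match="without split"):
            fit_clinical_score_regressor(gene_emb, dis_emb, scores, split,
                                         grid=[MLPSpec(1, 5, 0.0)])

    def test_grid_results_cover_all_specs(self):
        gene_emb, dis_emb, scores, split = self._synthetic_problem(n_genes=10)
        grid = [MLPSpec(1, 5, 0.0), MLPSpec(1, 5, 0.2)]
        res = fit_clinical_score_regressor(gene_emb, dis_emb, scores, split,
                                           grid=grid, epochs=10)
        assert [s for s, _ in res.grid_results] == grid
        assert res.best_spec in grid


class TestZScores:
    def test_matches_closed_form_quantile_oracle(self):
        scores = {f"g{i}": float(i + 1) for i in range(10)}
        z = zscore_rankings(scores, [f"g{i}" for i in range(10)], fill_seed=0)
        # oracle: ranks are 1..10 -> z_i = Phi^-1((i - 0.5)/10)
        for i in range(10):
            expected = stats.norm.ppf((i + 0.5) / 10)
            assert z[f"g{i}"] == pytest.approx(expected)

    def test_mean_near_zero_and_sd_near_one(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(2000)]
        scores = {g: float(rng.random()) for g in universe[:1200]}
        z = zscore_rankings(scores, universe, fill_seed=1)
        vals = np.array(list(z.values()))
        assert abs(vals.mean()) < 1e-6 + 0.01
        assert vals.std() == pytest.approx(1.0, abs=0.02)

    def test_order_preserved_among_scored_genes(self):
        universe = [f"g{i}" for i in range(50)]
        rng = np.random.default_rng(3)
        scores = {g: float(rng.random()) for g in universe[:30]}
        z = zscore_rankings(scores, universe, fill_seed=0)
        ranked = sorted(scores, key=scores.get)
        zs = [z[g] for g in ranked]
        assert zs == sorted(zs)

    def test_unscored_genes_fill_below_scored(self):
        universe = ["a", "b", "c", "d"]
        z = zscore_rankings({"a": 0.5, "b": 0.9}, universe, fill_seed=0)
        assert max(z["c"], z["d"]) < min(z["a"], z["b"])

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            zscore_rankings({"a": 1.0, "b": 1.0}, ["a", "b"])
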