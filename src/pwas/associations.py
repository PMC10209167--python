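"""Gene-disease ranking, prospective evaluation and clinical-score modelling.

A historical embedding model scores every gene in its vocabulary against a
disease token by cosine similarity, yielding a genome-wide ranking.  The
prospective test asks: of the top-k genes that had *never* been co-mentioned
with the disease at the model's cut-off year, what fraction is first
co-mentioned within t years after the cut-off?  That cumulative precision
curve is compared against a bootstrap baseline of random novel genes, drawn
without replacement.

Also here: contextual linking words (vocabulary terms close to both members
of a predicted pair, explaining the inferred link), the clinical-stage
"chembl" score (0.1/0.2/0.7/1.0 for phase 1/2/3/approved), a feed-forward
regressor of that score from concatenated embeddings with a whole-disease
train/test split, and quantile z-scoring for comparing ranking methods that
score different subsets of the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .nn import FeedForward, MLPSpec, hyperparameter_grid
from .word2vec import EmbeddingModel

logger = logging.getLogger(__name__)


@dataclass
class AssociationRanking:
    disease_id: str
    model_year: int
    entries: list[tuple[str, float, int]]  # (gene_id, score, rank), rank 1 = best
    gene_universe_size: int

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def rank_of(self, gene_id: str) -> int | None:
        for g, _, r in self.entries:
            if g == gene_id:
                return r
        return None

    def percentile_of(self, gene_id: str) -> float | None:
        """Rank as a percentage of the ranked universe (low = good)."""
        r = self.rank_of(gene_id)
        if r is None:
            return None
        return 100.0 * r / len(self.entries)


class ComentionIndex:
    """(gene_id, disease_id) -> first year of an abstract-level co-mention."""

    def __init__(self, first_year: Mapping[tuple[str, str], int] | None = None):
        self.first_year: dict[tuple[str, str], int] = dict(first_year or {})

    @classmethod
    def from_corpus(cls, docs: Iterable) -> "ComentionIndex":
        idx: dict[tuple[str, str], int] = {}
        for doc in docs:
            for g in doc.gene_ids:
                for d in doc.disease_ids:
                    key = (g, d)
                    if key not in idx or doc.year < idx[key]:
                        idx[key] = doc.year
        return cls(idx)

    def first_comention(self, gene_id: str, disease_id: str) -> int | None:
        return self.first_year.get((gene_id, disease_id))

    def comentioned_by(self, gene_id: str, disease_id: str, year: int) -> bool:
        y = self.first_year.get((gene_id, disease_id))
        return y is not None and y <= year


def rank_genes_for_disease(
    model: EmbeddingModel,
    disease_id: str,
    gene_universe: Sequence[str],
) -> AssociationRanking:
    """Score every in-vocabulary gene against the disease token, descending.

    Genes absent from the model's vocabulary (never mentioned before the
    cut-off) are excluded and logged.  Ties break lexicographically.
    """
    # sorted so scoring is bit-identical regardless of input order
    in_vocab = sorted(g for g in gene_universe if g in model)
    dropped = len(gene_universe) - len(in_vocab)
    if dropped:
        logger.info("excluded %d genes absent from the %d vocabulary",
                    dropped, model.cutoff_year)
    if disease_id not in model:
        raise KeyError(f"disease token not in model vocabulary: {disease_id!r}")
    sims = model.similarities(disease_id, in_vocab)
    order = sorted(range(len(in_vocab)), key=lambda i: (-sims[i], in_vocab[i]))
    entries = [(in_vocab[i], float(sims[i]), r + 1) for r, i in enumerate(order)]
    return AssociationRanking(disease_id=disease_id, model_year=model.cutoff_year,
                              entries=entries, gene_universe_size=len(gene_universe))


def novel_top_k(
    ranking: AssociationRanking,
    comentions: ComentionIndex,
    cutoff_year: int,
    k: int = 50,
) -> list[str]:
    """Top-k ranked genes with no co-mention at or before the cut-off year."""
    if k < 1:
        raise ValueError("k must be >= 1")
    novel = [g for g, _, _ in ranking.entries
             if not comentions.comentioned_by(g, ranking.disease_id, cutoff_year)]
    if len(novel) < k:
        logger.warning("only %d novel genes available (k=%d)", len(novel), k)
    if not novel:
        logger.warning("no novel genes: all candidates already co-mentioned")
    return novel[:k]


def prospective_precision(
    predictions: Sequence[str],
    comentions: ComentionIndex,
    disease_id: str,
    cutoff_year: int,
    horizon_years: int,
) -> np.ndarray:
    """Cumulative fraction of predictions first co-mentioned within t years.

    Element t-1 of the returned curve is the fraction of predicted genes with
    first co-mention year <= cutoff_year + t; the curve is monotone
    non-decreasing by construction.
    """
    if not predictions:
        raise ValueError("empty prediction list")
    firsts = np.array([
        comentions.first_comention(g, disease_id) or np.iinfo(np.int32).max
        for g in predictions
    ])
    ts = cutoff_year + np.arange(1, horizon_years + 1)
    return (firsts[None, :] <= ts[:, None]).mean(axis=1)


def bootstrap_baseline(
    gene_universe: Sequence[str],
    comentions: ComentionIndex,
    disease_id: str,
    cutoff_year: int,
    horizon_years: int,
    k: int = 50,
    B: int = 10000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap prospective-precision baseline over random novel genes.

    Draws ``B`` samples of ``k`` genes without replacement from the subset of
    ``gene_universe`` not yet co-mentioned with the disease at the cut-off,
    and returns ``(mean_curve, std_curve, terminal_precisions)`` where
    ``terminal_precisions`` holds the final-horizon precision of every
    iteration (for empirical p-values against a model's curve).
    """
    novel = sorted(g for g in gene_universe
                   if not comentions.comentioned_by(g, disease_id, cutoff_year))
    n = len(novel)
    if n < k:
        raise ValueError(f"novel universe ({n}) smaller than k ({k})")
    firsts = np.array([
        comentions.first_comention(g, disease_id) or np.iinfo(np.int32).max
        for g in novel
    ])
    ts = cutoff_year + np.arange(1, horizon_years + 1)
    reported = firsts[None, :] <= ts[:, None]  # T x N
    rng = np.random.default_rng(seed)
    keys = rng.random((B, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]  # B x k without replacement
    curves = reported[:, idx].mean(axis=2)  # T x B
    return curves.mean(axis=1), curves.std(axis=1), curves[-1, :]


def contextual_linking_words(
    model: EmbeddingModel,
    gene_id: str,
    disease_id: str,
    top_n: int = 10,
    entity_tokens: Iterable[str] = (),
    agg: str = "min",
) -> list[tuple[str, float]]:
    """Vocabulary words similar to *both* the gene and the disease.

    Each non-entity token w is scored by ``agg`` of (sim(w, gene),
    sim(w, disease)) -- ``min`` by default, so a linking word must be close to
    both ends of the predicted association; ``mean`` and ``product`` are
    selectable.  The pair itself and all entity tokens are excluded.
    """
    entity = set(entity_tokens) | {gene_id, disease_id}
    candidates = [t for t in model.vocabulary if t not in entity]
    s_g = model.similarities(gene_id, candidates)
    s_d = model.similarities(disease_id, candidates)
    if agg == "min":
        score = np.minimum(s_g, s_d)
    elif agg == "mean":
        score = (s_g + s_d) / 2.0
    elif agg == "product":
        score = s_g * s_d
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    order = sorted(range(len(candidates)), key=lambda i: (-score[i], candidates[i]))
    return [(candidates[i], float(score[i])) for i in order[:top_n]]


# ---------------------------------------------------------------------------
# Clinical-stage scoring

PHASE_SCORES = {
    "1": 0.1, "phase 1": 0.1, "phase i": 0.1,
    "2": 0.2, "phase 2": 0.2, "phase ii": 0.2,
    "3": 0.7, "phase 3": 0.7, "phase iii": 0.7,
    "approved": 1.0, "launched": 1.0, "registered": 1.0,
}


def chembl_score(phase_records: Iterable) -> float:
    """Score of the most advanced clinical phase: 0.1 / 0.2 / 0.7 / 1.0 for
    phase 1 / 2 / 3 / approved-and-launched; 0.0 for a pair with no records."""
    best = 0.0
    for rec in phase_records:
        key = str(rec).strip().lower()
        if key not in PHASE_SCORES:
            raise ValueError(f"unknown clinical phase label: {rec!r}")
        best = max(best, PHASE_SCORES[key])
    return best


@dataclass
class ClinicalScore:
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, target: str, disease: str) -> float:
        return self.scores.get((target, disease), 0.0)

    @classmethod
    def from_phase_table(cls, rows: Iterable[tuple[str, str, str]]) -> "ClinicalScore":
        """Rows of (target, disease, phase); most advanced phase wins."""
        phases: dict[tuple[str, str], list] = {}
        for target, disease, phase in rows:
            phases.setdefault((target, disease), []).append(phase)
        return cls({pair: chembl_score(ps) for pair, ps in phases.items()})


@dataclass
class ClinicalRegressionResult:
    best_spec: MLPSpec
    model: FeedForward
    grid_results: list[tuple[MLPSpec, float]]  # (spec, validation loss)
    test_r2: float
    per_disease_precision: dict[str, float]


def fit_clinical_score_regressor(
    gene_embeddings: Mapping[str, np.ndarray],
    disease_embeddings: Mapping[str, np.ndarray],
    scores: ClinicalScore,
    disease_split: Mapping[str, str],
    grid: Sequence[MLPSpec] | None = None,
    seed: int = 0,
    top_k: int = 10,
    epochs: int = 60,
    patience: int = 10,
    lr: float = 3e-3,
    batch_size: int = 32,
) -> ClinicalRegressionResult:
    """Regress the clinical-stage score from concatenated embeddings.

    ``disease_split`` assigns every disease wholly to ``train`` or ``test``
    (leakage of a disease across the split is an error).  Model selection over
    the hyperparameter grid (default: the standard 60-point grid) uses a
    validation subset of *training* diseases, never the test set.  Evaluation
    reports held-out R^2 and, per test disease, the fraction of its top-k
    scored targets whose true clinical score is positive (i.e. suggestions
    that entered trials).
    """
    grid = list(grid) if grid is not None else hyperparameter_grid()
    pairs = [(t, d) for (t, d) in scores.scores
             if t in gene_embeddings and d in disease_embeddings]
    if not pairs:
        raise ValueError("no scorable pairs with embeddings")
    diseases = {d for _, d in pairs}
    missing = diseases - set(disease_split)
    if missing:
        raise ValueError(f"diseases without split assignment: {sorted(missing)[:5]}")
    train_d = sorted(d for d in diseases if disease_split[d] == "train")
    test_d = sorted(d for d in diseases if disease_split[d] == "test")
    if set(train_d) & set(test_d):
        raise ValueError("disease leakage between train and test")
    rng = np.random.default_rng(seed)
    n_val = max(1, len(train_d) // 10)
    val_d = set(rng.choice(train_d, size=n_val, replace=False))

    def features(ds: set[str]) -> tuple[np.ndarray, np.ndarray, list]:
        sel = [(t, d) for (t, d) in pairs if d in ds]
        X = np.array([np.concatenate([gene_embeddings[t], disease_embeddings[d]])
                      for t, d in sel])
        y = np.array([scores.get(t, d) for t, d in sel])
        return X, y, sel

    X_tr, y_tr, _ = features(set(train_d) - val_d)
    X_val, y_val, _ = features(val_d)
    X_te, y_te, sel_te = features(set(test_d))

    results = []
    best = None
    for i, spec in enumerate(grid):
        net = FeedForward.from_spec(X_tr.shape[1], spec, task="regress", seed=seed + i)
        net.fit(X_tr, y_tr, X_val, y_val, epochs=epochs, patience=patience,
                lr=lr, batch_size=batch_size)
        val_loss = float(np.mean((net.predict(X_val).ravel() - y_val) ** 2))
        results.append((spec, val_loss))
        if best is None or val_loss < best[1]:
            best = (spec, val_loss, net)
    best_spec, _, best_net = best

    pred_te = best_net.predict(X_te).ravel()
    ss_res = float(np.sum((y_te - pred_te) ** 2))
    ss_tot = float(np.sum((y_te - y_te.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    per_disease: dict[str, float] = {}
    for d in test_d:
        rows = [(i, p) for i, ((_, dd), p) in enumerate(zip(sel_te, pred_te)) if dd == d]
        if not rows:
            continue
        rows.sort(key=lambda ip: (-ip[1], sel_te[ip[0]][0]))
        top = rows[:top_k]
        per_disease[d] = float(np.mean([y_te[i] > 0 for i, _ in top]))

    return ClinicalRegressionResult(best_spec=best_spec, model=best_net,
                                    grid_results=results, test_r2=r2,
                                    per_disease_precision=per_disease)


def zscore_rankings(
    method_scores: Mapping[str, float],
    gene_universe: Sequence[str],
    fill_seed: int = 0,
) -> dict[str, float]:
    """Quantile-normalise one method's gene scores onto standard-normal z-scores.

    Genes the method did not score receive a uniform random score in
    (0, min positive observed score) -- below every real score -- then the
    combined vector is rank-transformed through the normal quantile function
    z_i = Phi^-1((r_i - 0.5)/n) with average ranks for ties.  The transform
    preserves the ordering of the originally scored genes.
    """
    scored = {g: s for g, s in method_scores.items() if g in set(gene_universe)}
    if not scored:
        raise ValueError("no scored genes in universe")
    values = np.array(list(scored.values()))
    if np.allclose(values, values[0]):
        raise ValueError("all scores identical; ranking undefined")
    min_pos = values[values > 0].min() if np.any(values > 0) else values.max()
    rng = np.random.default_rng(fill_seed)
    genes = sorted(gene_universe)
    full = np.array([scored.get(g, np.nan) for g in genes])
    unscored = np.isnan(full)
    full[unscored] = rng.uniform(0.0, float(min_pos), size=int(unscored.sum()))
    ranks = stats.rankdata(full, method="average")
    z = stats.norm.ppf((ranks - 0.5) / len(full))
    return dict(zip(genes, z.tolist()))
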