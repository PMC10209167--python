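"""Clinical-target classification and gene-family coherence from embeddings.

Gene embeddings act as literature-derived fingerprints.  A single-hidden-layer
feed-forward classifier with a class-balanced loss predicts whether a gene is
a clinical-stage target (in an active trial, approved, or either), with
metrics reported on a balanced held-out set and confidence intervals from 100
balanced bootstrap resamples.  A shared-input multi-task logistic model
estimates small-molecule (SM) and monoclonal-antibody (AB) tractability
jointly.  Family coherence compares within-family cosine distances against
the all-gene background with Welch's t-test and a Mann-Whitney U test, plus a
silhouette coefficient over family labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import silhouette_score

from .nn import FeedForward, classification_metrics
from .word2vec import EmbeddingModel


@dataclass
class TargetClassifier:
    model: FeedForward
    genes_train: list[str]
    genes_test: list[str]
    test_metrics: dict[str, float]


def train_target_classifier(
    embeddings: Mapping[str, np.ndarray],
    labels: Mapping[str, bool],
    seed: int = 0,
    hidden_size: int = 64,
    test_fraction: float = 0.2,
    epochs: int = 100,
) -> TargetClassifier:
    """Single-hidden-layer classifier with balanced loss and patience-2
    early stopping, on an 80/20 gene-level split."""
    genes = sorted(g for g in labels if g in embeddings)
    y = np.array([int(labels[g]) for g in genes])
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = np.array([embeddings[g] for g in genes])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    n_test = max(1, int(round(test_fraction * len(genes))))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
        raise ValueError("train or test split became single-class; use more genes")
    if set(test_idx) & set(train_idx):
        raise AssertionError("gene leakage between splits")
    net = FeedForward(X.shape[1], hidden_layers=1, hidden_size=hidden_size,
                      task="classify", seed=seed)
    net.fit(X[train_idx], y[train_idx], epochs=epochs, patience=2, balanced=True)
    pred = net.predict(X[test_idx]).ravel()
    return TargetClassifier(
        model=net,
        genes_train=[genes[i] for i in train_idx],
        genes_test=[genes[i] for i in test_idx],
        test_metrics=classification_metrics(y[test_idx], pred),
    )


@dataclass
class BootstrapMetrics:
    """Point estimates (bootstrap means) with empirical 5-95% intervals."""

    accuracy: tuple[float, float, float]
    f1: tuple[float, float, float]
    precision: tuple[float, float, float]
    recall: tuple[float, float, float]


def bootstrap_metrics(
    classifier: FeedForward,
    X_test: np.ndarray,
    y_test: np.ndarray,
    B: int = 100,
    seed: int = 0,
) -> BootstrapMetrics:
    """Metrics over B *balanced* bootstrap resamples of the test set.

    Each resample draws an equal number of positives and negatives (with
    replacement) so the metrics are not driven by class imbalance.  Point
    estimate = mean across resamples; interval = empirical 5th/95th
    percentiles.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    y_test = np.asarray(y_test).ravel().astype(int)
    pos = np.where(y_test == 1)[0]
    neg = np.where(y_test == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("test set must contain both classes")
    n_half = min(len(pos), len(neg))
    rng = np.random.default_rng(seed)
    pred_all = classifier.predict(X_test).ravel()
    rows = {m: [] for m in ("accuracy", "f1", "precision", "recall")}
    for _ in range(B):
        idx = np.concatenate([rng.choice(pos, n_half, replace=True),
                              rng.choice(neg, n_half, replace=True)])
        m = classification_metrics(y_test[idx], pred_all[idx])
        for key in rows:
            rows[key].append(m[key])

    def summarise(vals: list[float]) -> tuple[float, float, float]:
        arr = np.array(vals)
        return float(arr.mean()), float(np.percentile(arr, 5)), float(np.percentile(arr, 95))

    return BootstrapMetrics(**{k: summarise(v) for k, v in rows.items()})


def tractability_multitask(
    embeddings: Mapping[str, np.ndarray],
    sm_labels: Mapping[str, bool],
    ab_labels: Mapping[str, bool],
    seed: int = 0,
    epochs: int = 200,
) -> dict[str, tuple[float, float]]:
    """Joint SM/AB tractability probabilities from one shared-input logistic
    model (two sigmoid outputs on the raw embedding, class-balanced loss).

    Returns gene -> (p_SM, p_AB) for every embedded gene, including genes
    outside the labelled set (generalisation is the point: a membrane protein
    never antibody-drugged may still score high AB tractability)."""
    if set(sm_labels) != set(ab_labels):
        raise ValueError("SM and AB label universes differ")
    genes = sorted(g for g in sm_labels if g in embeddings)
    X = np.array([embeddings[g] for g in genes])
    y = np.array([[int(sm_labels[g]), int(ab_labels[g])] for g in genes])
    net = FeedForward(X.shape[1], hidden_layers=0, n_outputs=2,
                      task="classify", seed=seed)
    net.fit(X, y, epochs=epochs, patience=5, balanced=True)
    all_genes = sorted(embeddings)
    probs = net.predict_proba(np.array([embeddings[g] for g in all_genes]))
    return {g: (float(p[0]), float(p[1])) for g, p in zip(all_genes, probs)}


@dataclass
class FamilyStats:
    mean_intra_distance: float
    t_pvalue: float
    mannwhitney_pvalue: float
    n_members: int


def _pairwise_cosine_distances(unit: np.ndarray, idx: np.ndarray,
                               rng: np.random.Generator | None = None,
                               max_pairs: int = 100_000) -> np.ndarray:
    """Cosine distances (1 - cosine similarity) over pairs within idx.

    All pairs when feasible; a seeded subsample of ``max_pairs`` random pairs
    otherwise (universes above ~2,000 members).
    """
    n = len(idx)
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs or rng is None:
        sub = unit[idx]
        sims = sub @ sub.T
        iu = np.triu_indices(n, k=1)
        return 1.0 - sims[iu]
    a = rng.integers(0, n, size=max_pairs)
    b = rng.integers(0, n, size=max_pairs)
    keep = a != b
    a, b = a[keep], b[keep]
    return 1.0 - np.einsum("ij,ij->i", unit[idx[a]], unit[idx[b]])


def family_cluster_stats(
    model: EmbeddingModel,
    family_assignments: Mapping[str, str],
    seed: int = 0,
    background_max_pairs: int = 100_000,
) -> tuple[dict[str, FamilyStats], float]:
    """Per-family embedding coherence against the all-gene background.

    For each family: mean intra-family cosine distance, a two-sided Welch
    t-test and Mann-Whitney U comparing intra-family vs background pairwise
    distances.  Background = all pairwise distances among every assigned gene
    (seeded subsample beyond ~2,000 genes).  Also returns the mean silhouette
    coefficient over family labels under the cosine metric.
    """
    genes = sorted(g for g in family_assignments if g in model)
    if len(genes) < 3:
        raise ValueError("need at least 3 in-vocabulary genes")
    unit = model.unit_vectors
    gene_idx = np.array([model.index(g) for g in genes])
    rng = np.random.default_rng(seed)
    background = _pairwise_cosine_distances(unit, gene_idx, rng, background_max_pairs)

    families: dict[str, list[int]] = {}
    for g in genes:
        families.setdefault(family_assignments[g], []).append(model.index(g))
    out: dict[str, FamilyStats] = {}
    for fam, members in sorted(families.items()):
        if len(members) < 2:
            raise ValueError(f"family {fam!r} has fewer than 2 in-vocabulary members")
        intra = _pairwise_cosine_distances(unit, np.array(members), rng,
                                           background_max_pairs)
        t_p = stats.ttest_ind(intra, background, equal_var=False).pvalue
        u_p = stats.mannwhitneyu(intra, background, alternative="two-sided").pvalue
        out[fam] = FamilyStats(mean_intra_distance=float(intra.mean()),
                               t_pvalue=float(t_p), mannwhitney_pvalue=float(u_p),
                               n_members=len(members))

    labels = [family_assignments[g] for g in genes]
    if len(set(labels)) > 1:
        sil = float(silhouette_score(unit[gene_idx], labels, metric="cosine"))
    else:
        sil = float("nan")
    return out, sil
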