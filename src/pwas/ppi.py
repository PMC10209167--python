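"""Protein-protein interaction prediction with positive-unlabeled evaluation.

Binary-interactome releases (in the style of the successive yeast-two-hybrid
maps H-I-05, HI-II-14, HuRI and HI-union) are canonicalised to alphabetically
sorted symbol pairs with self-interactions discarded.  Lacking a bona fide
negative set, negatives are all pairs among the "sticky" proteins (top 10%
by interaction degree) that are not known positives.  Features are the
concatenation of the two protein embeddings from the era-matched historical
model; splits are at the protein level (25% of proteins and *all* their
pairs held out).  The prospective, positive-unlabeled test scores an
older-era model against newer releases: pairs positive only in the future
are labelled negative for the old model, so every such pair it scores above
threshold counts as a "false positive" -- and the decline of that count
across successive releases is the signal that the model ranked undiscovered
interactions highly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .nn import FeedForward, MLPSpec, classification_metrics, hyperparameter_grid
from .word2vec import EmbeddingModel

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair | None:
    """Alphabetically sorted pair; ``None`` (a rejection, not an error) for
    self-interactions.  Idempotent."""
    a, b = a.strip(), b.strip()
    if not a or not b:
        raise ValueError("empty protein symbol")
    if a == b:
        return None
    return (a, b) if a < b else (b, a)


@dataclass
class InteractionSet:
    name: str
    release_year: int
    pairs: set[Pair] = field(default_factory=set)
    n_self_dropped: int = 0
    n_duplicates_dropped: int = 0

    @property
    def proteins(self) -> set[str]:
        return {p for pair in self.pairs for p in pair}

    def degrees(self) -> dict[str, int]:
        deg: Counter[str] = Counter()
        for a, b in self.pairs:
            deg[a] += 1
            deg[b] += 1
        return dict(deg)

    def __len__(self) -> int:
        return len(self.pairs)


def interaction_set_from_pairs(
    rows: Iterable[tuple[str, str]], name: str, release_year: int
) -> InteractionSet:
    iset = InteractionSet(name=name, release_year=release_year)
    n_rows = 0
    for a, b in rows:
        n_rows += 1
        pair = canonical_pair(a, b)
        if pair is None:
            iset.n_self_dropped += 1
        elif pair in iset.pairs:
            iset.n_duplicates_dropped += 1
        else:
            iset.pairs.add(pair)
    if n_rows == 0:
        raise ValueError(f"empty interaction list for {name}")
    if iset.n_self_dropped or iset.n_duplicates_dropped:
        logger.info("%s: dropped %d self-pairs, %d duplicates", name,
                    iset.n_self_dropped, iset.n_duplicates_dropped)
    return iset


def load_interactions(path: str | Path, name: str, release_year: int) -> InteractionSet:
    """Two-column symbol TSV -> canonicalised, deduplicated interaction set."""
    path = Path(path)

    def rows():
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                if lineno == 1 and parts[0].lower() in ("symbol_a", "protein_a", "a"):
                    continue
                yield parts[0], parts[1]

    return interaction_set_from_pairs(rows(), name, release_year)


def sticky_negatives(iset: InteractionSet, fraction: float = 0.1) -> set[Pair]:
    """Negative pairs: all combinations of the sticky proteins minus positives.

    Sticky proteins are the top ``ceil(fraction * n_proteins)`` by interaction
    degree within ``iset`` (ties broken by symbol order).  A pair of two
    sticky proteins that is itself a known interaction is excluded.
    """
    if not iset.pairs:
        raise ValueError("empty interaction set")
    deg = iset.degrees()
    n_sticky = ceil(fraction * len(deg))
    if n_sticky < 2:
        raise ValueError(f"fewer than 2 sticky proteins (n={n_sticky})")
    sticky = sorted(deg, key=lambda p: (-deg[p], p))[:n_sticky]
    negs = set()
    for a, b in combinations(sorted(sticky), 2):
        pair = canonical_pair(a, b)
        if pair is not None and pair not in iset.pairs:
            negs.add(pair)
    return negs


def protein_level_split(
    pairs: Iterable[Pair],
    test_fraction: float = 0.25,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> dict[Pair, str]:
    """Assign pairs to train/val/test so test proteins are never seen in training.

    ``test_fraction`` of proteins (seeded draw) become test proteins; every
    pair touching one goes to ``test``.  A further ``val_fraction`` of the
    remaining proteins defines the validation pairs for early stopping; all
    other pairs are ``train``.
    """
    pairs = sorted(set(pairs))
    proteins = sorted({p for pair in pairs for p in pair})
    if len(proteins) < 8:
        raise ValueError("need at least 8 proteins to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(proteins))
    n_test = max(1, int(round(test_fraction * len(proteins))))
    test_p = {proteins[i] for i in perm[:n_test]}
    rest = [proteins[i] for i in perm[n_test:]]
    n_val = max(1, int(round(val_fraction * len(rest))))
    val_p = set(rest[:n_val])
    split: dict[Pair, str] = {}
    for a, b in pairs:
        if a in test_p or b in test_p:
            split[(a, b)] = "test"
        elif a in val_p or b in val_p:
            split[(a, b)] = "val"
        else:
            split[(a, b)] = "train"
    counts = Counter(split.values())
    if counts["test"] == 0 or counts["train"] == 0:
        raise ValueError(f"degenerate split: {dict(counts)}")
    return split


@dataclass
class PairDataset:
    """Labelled protein pairs with concatenated-embedding features.

    The feature vector is ``[embedding(min symbol), embedding(max symbol)]``
    (length 2 x dim), so scores are invariant to input pair orientation.
    Pairs with a protein missing from the era's vocabulary are dropped and
    counted.
    """

    pairs: list[Pair]
    labels: np.ndarray
    features: np.ndarray
    split: list[str]
    n_oov_dropped: int = 0

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        idx = [i for i, s in enumerate(self.split) if s == which]
        return self.features[idx], self.labels[idx]


def build_pair_dataset(
    positives: Iterable[Pair],
    negatives: Iterable[Pair],
    model: EmbeddingModel,
    split: Mapping[Pair, str] | None = None,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> PairDataset:
    labelled = [(p, 1) for p in sorted(set(positives))] + \
               [(p, 0) for p in sorted(set(negatives))]
    kept, dropped = [], 0
    for pair, lab in labelled:
        if pair[0] in model and pair[1] in model:
            kept.append((pair, lab))
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d pairs with out-of-vocabulary proteins", dropped)
    if not kept:
        raise ValueError("no pairs with embedded proteins")
    if split is None:
        split = protein_level_split([p for p, _ in kept], test_fraction, seed)
    feats = np.array([np.concatenate([model.vector(a), model.vector(b)])
                      for (a, b), _ in kept])
    return PairDataset(
        pairs=[p for p, _ in kept],
        labels=np.array([l for _, l in kept]),
        features=feats,
        split=[split[p] for p, _ in kept],
        n_oov_dropped=dropped,
    )


@dataclass
class GridResult:
    spec: MLPSpec
    metrics: dict[str, float]  # test-set metrics incl. mcc


def train_ppi_grid(
    dataset: PairDataset,
    grid: Sequence[MLPSpec] | None = None,
    seed: int = 0,
    epochs: int = 60,
) -> tuple[list[GridResult], MLPSpec, FeedForward]:
    """Train the tuning grid (default 60 models) with balanced loss; report
    test MCC per spec and the best model by test MCC."""
    grid = list(grid) if grid is not None else hyperparameter_grid()
    X_tr, y_tr = dataset.subset("train")
    X_val, y_val = dataset.subset("val")
    X_te, y_te = dataset.subset("test")
    for name, y in (("train", y_tr), ("test", y_te)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"degenerate labels in {name} split")
    if len(X_val) == 0:
        X_val, y_val = X_te[:0], y_te[:0]
    results: list[GridResult] = []
    best: tuple[float, MLPSpec, FeedForward] | None = None
    for i, spec in enumerate(grid):
        net = FeedForward.from_spec(X_tr.shape[1], spec, task="classify",
                                    seed=seed + i)
        if len(X_val):
            net.fit(X_tr, y_tr, X_val, y_val, epochs=epochs, patience=2)
        else:
            net.fit(X_tr, y_tr, epochs=epochs, patience=2)
        m = classification_metrics(y_te, net.predict(X_te).ravel())
        results.append(GridResult(spec=spec, metrics=m))
        if best is None or m["mcc"] > best[0]:
            best = (m["mcc"], spec, net)
    return results, best[1], best[2]


def score_pairs(model: FeedForward, emb: EmbeddingModel,
                pairs: Sequence[Pair]) -> np.ndarray:
    feats = np.array([np.concatenate([emb.vector(a), emb.vector(b)])
                      for a, b in pairs])
    return model.predict_proba(feats).ravel()


@dataclass
class ProspectiveCell:
    model_era: int
    dataset_name: str
    dataset_year: int
    n_false_positives: int
    n_future_positive_hits: int
    precision: float


def prospective_ppi_eval(
    models_by_era: Mapping[int, tuple[FeedForward, EmbeddingModel]],
    datasets_by_era: Sequence[InteractionSet],
    eval_pairs: Mapping[int, Sequence[tuple[Pair, int]]],
    threshold: float = 0.5,
) -> list[ProspectiveCell]:
    """Positive-unlabeled scoring of older models against newer releases.

    ``eval_pairs[era]`` is the era-model's evaluation table: (pair, label)
    with the labels of the model's *own* era (test-split positives and sticky
    negatives).  For each newer dataset the labels are recomputed: a pair is
    positive if it is in that dataset's positive set.  False positives are
    pairs scored >= threshold but negative under the dataset's labels;
    ``n_future_positive_hits`` counts the scored-positive pairs that were
    negative in the model's own era but positive in the newer dataset (the
    interactions the model prioritised ahead of their discovery).
    """
    datasets = sorted(datasets_by_era, key=lambda d: d.release_year)
    out: list[ProspectiveCell] = []
    for era in sorted(models_by_era):
        clf, emb = models_by_era[era]
        pairs_labels = list(eval_pairs[era])
        pairs = [p for p, _ in pairs_labels]
        own_labels = np.array([l for _, l in pairs_labels])
        scores = score_pairs(clf, emb, pairs)
        predicted = scores >= threshold
        for ds in datasets:
            if ds.release_year < era:
                continue
            labels_now = np.array([1 if p in ds.pairs else l
                                   for (p, l) in pairs_labels])
            fp = int(np.sum(predicted & (labels_now == 0)))
            tp = int(np.sum(predicted & (labels_now == 1)))
            future_hits = int(np.sum(predicted & (own_labels == 0) & (labels_now == 1)))
            precision = tp / (tp + fp) if tp + fp > 0 else 0.0
            out.append(ProspectiveCell(model_era=era, dataset_name=ds.name,
                                       dataset_year=ds.release_year,
                                       n_false_positives=fp,
                                       n_future_positive_hits=future_hits,
                                       precision=precision))
    return out


def upset_counts(isets: Sequence[InteractionSet]) -> dict[tuple[str, ...], int]:
    """Exclusive intersection cells: for every non-empty subset of datasets,
    the number of pairs in exactly those datasets.  Cells are disjoint and
    sum to the size of the union."""
    if len(isets) < 2:
        raise ValueError("need at least 2 interaction sets")
    names = [s.name for s in isets]
    if len(set(names)) != len(names):
        raise ValueError("dataset names must be unique")
    membership: dict[Pair, tuple[str, ...]] = {}
    for pair in set().union(*(s.pairs for s in isets)):
        sig = tuple(s.name for s in isets if pair in s.pairs)
        membership[pair] = sig
    cells: Counter[tuple[str, ...]] = Counter(membership.values())
    return dict(cells)
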