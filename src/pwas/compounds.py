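"""Drug-target link prediction, promiscuity strata, motif druggability and
GWAS variant filtering.

Compound and gene tokens live in the same embedding space (compounds are
canonicalised to single tokens exactly like genes), so a drug-target pair is
featurised as the concatenation gene-embedding || compound-embedding and fed
to a model zoo (logistic regression, random forest, and an MLP grid with
dropout).  Hard negatives are the cross product of the most frequently
targeted proteins with the least specific compounds, minus known positives.
Performance is stratified by compound promiscuity (1, 2, or >2 reported
targets): specific compounds are predicted far more precisely than
promiscuous ones.

Motif-based druggability follows the motif-protein-compound graph idea: a
protein inherits the best enrichment of its sequence motifs among drugged
proteins (one-sided Fisher's exact test), so an undrugged protein scores
non-trivially if it shares a motif with a drugged one.  The variant filter
keeps GWAS hits that are non-synonymous, genome-wide significant
(p < 1e-9), directionally consistent across >= 2 studies, and carried by a
gene the compound-target model scores above 0.3.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .nn import FeedForward, MLPSpec, classification_metrics
from .word2vec import EmbeddingModel

logger = logging.getLogger(__name__)

DrugTargetPair = tuple[str, str]  # (compound_id, gene_id)


@dataclass
class DrugTargetSet:
    positives: set[DrugTargetPair] = field(default_factory=set)

    @classmethod
    def from_pairs(cls, rows: Iterable[DrugTargetPair]) -> "DrugTargetSet":
        pairs = set()
        for c, g in rows:
            if not c or not g:
                raise ValueError("empty compound or gene id")
            pairs.add((c, g))
        return cls(positives=pairs)

    def targets_per_compound(self) -> dict[str, int]:
        counts: Counter[str] = Counter(c for c, _ in self.positives)
        return dict(counts)

    def compounds_per_gene(self) -> dict[str, int]:
        counts: Counter[str] = Counter(g for _, g in self.positives)
        return dict(counts)


def promiscuous_negatives(
    positives: DrugTargetSet,
    n_proteins: int = 400,
    n_compounds: int = 400,
) -> set[DrugTargetPair]:
    """Hard negative set: top-n most-targeted proteins x top-n least specific
    compounds, minus the positive set.  Ties break by id order."""
    per_gene = positives.compounds_per_gene()
    per_compound = positives.targets_per_compound()
    if n_proteins > len(per_gene):
        raise ValueError(f"n_proteins={n_proteins} exceeds {len(per_gene)} proteins")
    if n_compounds > len(per_compound):
        raise ValueError(f"n_compounds={n_compounds} exceeds {len(per_compound)} compounds")
    top_genes = sorted(per_gene, key=lambda g: (-per_gene[g], g))[:n_proteins]
    top_compounds = sorted(per_compound, key=lambda c: (-per_compound[c], c))[:n_compounds]
    negs = {(c, g) for c in top_compounds for g in top_genes} - positives.positives
    if not negs:
        logger.warning("positives cover the whole promiscuous cross product")
    assert not negs & positives.positives
    return negs


def pair_features(pairs: Sequence[DrugTargetPair], model: EmbeddingModel) -> np.ndarray:
    """Concatenated gene-first, compound-second embedding features."""
    return np.array([np.concatenate([model.vector(g), model.vector(c)])
                     for c, g in pairs])


# model zoo grid matching the published table: H in {1,10,50,100} x
# N in {1,2,3} x D in {0, 0.2}, plus RFC and logistic regression
ZOO_MLP_SPECS = [MLPSpec(n, h, d) for h in (1, 10, 50, 100)
                 for n in (1, 2, 3) for d in (0.0, 0.2)]


@dataclass
class ZooEntry:
    name: str
    metrics: dict[str, float]
    model: object


def train_compound_target_models(
    X_train: np.ndarray, y_train: np.ndarray,
    X_test: np.ndarray, y_test: np.ndarray,
    specs: Sequence[MLPSpec] | None = None,
    seed: int = 0,
    epochs: int = 60,
) -> list[ZooEntry]:
    """Train the compound-target model zoo; return the per-model test metric
    table sorted by descending MCC (ties by name)."""
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("feature-dimension mismatch between train and test")
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training labels")
    specs = list(specs) if specs is not None else list(ZOO_MLP_SPECS)
    entries: list[ZooEntry] = []
    lr = LogisticRegression(class_weight="balanced", max_iter=2000, random_state=seed)
    lr.fit(X_train, y_train)
    entries.append(ZooEntry("Logistic Regression",
                            classification_metrics(y_test, lr.predict(X_test)), lr))
    rf = RandomForestClassifier(n_estimators=100, class_weight="balanced",
                                random_state=seed)
    rf.fit(X_train, y_train)
    entries.append(ZooEntry("RFC", classification_metrics(y_test, rf.predict(X_test)), rf))
    for i, spec in enumerate(specs):
        net = FeedForward.from_spec(X_train.shape[1], spec, task="classify",
                                    seed=seed + i)
        net.fit(X_train, y_train, epochs=epochs, patience=2)
        entries.append(ZooEntry(spec.name,
                                classification_metrics(y_test, net.predict(X_test).ravel()),
                                net))
    entries.sort(key=lambda e: (-e.metrics["mcc"], e.name))
    return entries


def promiscuity_stratified_metrics(
    predictions: Sequence[tuple[DrugTargetPair, int, int]],
    positives: DrugTargetSet,
) -> dict[str, dict[str, dict[str, float]]]:
    """Classification metrics per compound-promiscuity stratum.

    ``predictions`` rows are ((compound, gene), true_label, predicted_label).
    Strata are "1", "2" and ">2" reported targets per compound; within each,
    metrics are computed separately for the positive-pair subset
    ("pharmacologically active": recall/precision of catching true links) and
    the negative-pair subset ("no active"), mirroring how promiscuous
    compounds degrade precision.  Empty strata are omitted with a log entry.
    """
    per_compound = positives.targets_per_compound()

    def stratum(c: str) -> str:
        n = per_compound.get(c, 0)
        return ">2" if n > 2 else str(n)

    out: dict[str, dict[str, dict[str, float]]] = {}
    for name in ("1", "2", ">2"):
        rows = [(t, p) for (c, _g), t, p in predictions if stratum(c) == name]
        if not rows:
            logger.info("empty promiscuity stratum %s omitted", name)
            continue
        y_true = np.array([t for t, _ in rows])
        y_pred = np.array([p for _, p in rows])
        block: dict[str, dict[str, float]] = {"all": classification_metrics(y_true, y_pred)}
        pos_mask = y_true == 1
        if pos_mask.any():
            tp = float(np.sum(y_pred[pos_mask] == 1))
            block["active"] = {
                "recall": tp / pos_mask.sum(),
                "precision": tp / max(float(np.sum(y_pred == 1)), 1.0),
                "accuracy": float(np.mean(y_true == y_pred)),
            }
        if (~pos_mask).any():
            tn = float(np.sum(y_pred[~pos_mask] == 0))
            block["no_active"] = {
                "recall": tn / (~pos_mask).sum(),
                "precision": tn / max(float(np.sum(y_pred == 0)), 1.0),
                "accuracy": float(np.mean(y_true == y_pred)),
            }
        out[name] = block
    return out


@dataclass
class DruggabilityScore:
    scores: dict[str, float] = field(default_factory=dict)
    motif_scores: dict[str, float] = field(default_factory=dict)

    def get(self, gene_id: str) -> float:
        return self.scores.get(gene_id, 0.0)


def motif_druggability(
    motif_membership: Mapping[str, Iterable[str]],
    drugged_genes: set[str],
) -> DruggabilityScore:
    """Best motif-enrichment score per gene.

    For every motif m, a 2x2 table over the gene universe ({carries m, does
    not} x {drugged, not drugged}) is tested with a one-sided (enrichment)
    Fisher's exact test; the motif score is -log10(p) and a gene inherits the
    maximum over its motifs.  Genes without motifs score 0.
    """
    universe = set(motif_membership)
    if not universe:
        raise ValueError("empty gene universe")
    unknown = drugged_genes - universe
    if unknown:
        raise ValueError(f"drugged genes outside universe: {sorted(unknown)[:5]}")
    motif_to_genes: dict[str, set[str]] = {}
    for gene, motifs in motif_membership.items():
        for m in motifs:
            motif_to_genes.setdefault(m, set()).add(gene)
    n = len(universe)
    n_drugged = len(drugged_genes)
    motif_scores: dict[str, float] = {}
    for m, carriers in motif_to_genes.items():
        a = len(carriers & drugged_genes)
        b = len(carriers) - a
        c = n_drugged - a
        d = n - len(carriers) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        motif_scores[m] = max(0.0, float(-np.log10(max(p, 1e-300))))
    scores = {
        gene: max((motif_scores[m] for m in motifs), default=0.0)
        for gene, motifs in ((g, list(ms)) for g, ms in motif_membership.items())
    }
    return DruggabilityScore(scores=scores, motif_scores=motif_scores)


def rank_targets_for_compound(
    classifier,
    compound_id: str,
    gene_universe: Sequence[str],
    model: EmbeddingModel,
) -> list[tuple[str, float, int]]:
    """Genome-wide modulation likelihoods for one compound, descending.

    Every in-vocabulary gene is scored by the trained pair classifier on the
    (gene || compound) feature; ties break by gene id.
    """
    if compound_id not in model:
        raise KeyError(f"compound not in embedding vocabulary: {compound_id!r}")
    genes = [g for g in gene_universe if g in model]
    if not genes:
        raise ValueError("no genes in vocabulary")
    feats = pair_features([(compound_id, g) for g in genes], model)
    raw = classifier.predict_proba(feats)
    scores = raw[:, 1] if getattr(raw, "ndim", 1) == 2 and raw.shape[1] == 2 \
        else np.asarray(raw).ravel()
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return [(genes[i], float(scores[i]), r + 1) for r, i in enumerate(order)]


# ---------------------------------------------------------------------------
# GWAS variant filtering

_AA_CHANGE_RE = re.compile(r"([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})")


@dataclass
class VariantRecord:
    gene: str
    rsid: str
    amino_acid_change: str
    beta: float
    minus_log10_p: float
    n_studies_consistent: int
    likelihood: float
    non_synonymous: bool | None = None  # overrides amino-acid-change parsing

    def is_non_synonymous(self) -> bool:
        if self.non_synonymous is not None:
            return self.non_synonymous
        m = _AA_CHANGE_RE.fullmatch(self.amino_acid_change.strip())
        if not m:
            return False
        return m.group(1) != m.group(3)


def variant_candidate_filter(
    variants: Sequence[VariantRecord],
    min_likelihood: float = 0.3,
    max_p: float = 1e-9,
    min_consistent_studies: int = 2,
) -> list[VariantRecord]:
    """Keep variants that are non-synonymous, with p strictly below ``max_p``,
    a consistent beta sign in at least ``min_consistent_studies`` studies, and
    a model likelihood strictly above ``min_likelihood``.  Records with
    missing fields are excluded with a log entry."""
    kept = []
    threshold_mlp = -np.log10(max_p)
    for rec in variants:
        try:
            ok = (rec.is_non_synonymous()
                  and rec.minus_log10_p > threshold_mlp
                  and rec.n_studies_consistent >= min_consistent_studies
                  and rec.likelihood > min_likelihood)
        except (TypeError, AttributeError) as exc:
            logger.warning("excluded malformed variant record %r: %s", rec, exc)
            continue
        if rec.minus_log10_p < 0:
            logger.warning("excluded variant %s with negative -log10 p", rec.rsid)
            continue
        if ok:
            kept.append(rec)
    return kept
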