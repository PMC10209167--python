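"""Synthetic time-stamped literature with planted, recoverable structure.

The generator emits bag-of-token "abstracts" (window-based embedding training
only consumes co-occurrence statistics, so no syntax is needed) over a span
of years, with known ground truth planted in:

* **gene-disease emergence**: each planted pair has an emergence year; no
  document co-mentions the pair before that year, and in the
  ``bridge_lead_years`` before it, *bridge documents* place the same unique
  bridge words near the gene (in some documents) and near the disease (in
  others).  That shared context is exactly the channel a pre-emergence
  embedding model can exploit, and what contextual linking words should
  recover.
* **gene families**: every gene belongs to a family whose members co-occur
  with shared family topic words, giving families embedding coherence.
* **protein-protein interactions**: pathway groups of proteins co-occur with
  shared pathway vocabulary from the first year; each within-pathway pair is
  assigned a *discovery era*, defining cumulative interactome releases for
  positive-unlabeled evaluation.
* **drug-target links**: compound tokens co-occur with their target genes
  and a compound topic vocabulary.

Everything is deterministic under the config seed, and the ground truth is
consistent with the corpus by construction (re-scanning the corpus reproduces
the first-co-mention table).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import associations as assoc
from .corpus import CorpusSlice
from .lexicon import Lexicon, TaggedDocument, lexicon_from_pairs, tag_corpus
from .nn import FeedForward
from .ppi import (InteractionSet, build_pair_dataset, interaction_set_from_pairs,
                  protein_level_split, prospective_ppi_eval, score_pairs,
                  sticky_negatives)
from .word2vec import EmbeddingHyperparams, checkpoint_series


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 200
    n_diseases: int = 5
    n_compounds: int = 12
    year_start: int = 2000
    year_end: int = 2012
    docs_per_year: int = 320
    doc_length: int = 30
    topic_vocab_size: int = 6
    background_vocab_size: int = 5000
    n_planted_associations: int = 10
    emergence_years: tuple[int, ...] = (2008, 2010, 2012)
    n_bridge_words: int = 3
    bridge_lead_years: int = 5
    bridge_docs_per_year: int = 3  # per side; 0 disables the planted signal
    emergence_docs_per_year: int = 3
    n_families: int = 8
    n_pathways: int = 6
    pathway_size: int = 6
    ppi_eras: tuple[int, ...] = (2007, 2009, 2011)
    n_random_comentions_per_year: int = 8
    model_years: tuple[int, ...] = (2007, 2009, 2011)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.doc_length < 3:
            raise ValueError("doc_length must be >= 3")
        if self.bridge_lead_years < 1:
            raise ValueError("bridge_lead_years must be >= 1")
        if self.year_end <= self.year_start:
            raise ValueError("empty year range")
        for y in self.emergence_years:
            if not (self.year_start < y <= self.year_end):
                raise ValueError(f"emergence year {y} outside corpus years")
        if min(c for c in (self.n_genes, self.n_diseases, self.n_compounds,
                           self.docs_per_year, self.topic_vocab_size,
                           self.background_vocab_size)) <= 0:
            raise ValueError("all counts must be positive")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    # entity token names (lower-case so text cleaning is the identity)
    def gene_token(self, i: int) -> str:
        return f"gene{i:04d}"

    def disease_token(self, i: int) -> str:
        return f"mesh{i:03d}"

    def compound_token(self, i: int) -> str:
        return f"cmpd{i:03d}"


@dataclass
class PlantedAssociation:
    gene: str
    disease: str
    emergence_year: int
    bridge_words: tuple[str, ...]


@dataclass
class PlantedPPI:
    pair: tuple[str, str]
    pathway: str
    era: int


@dataclass
class GroundTruth:
    associations: list[PlantedAssociation]
    families: dict[str, str]
    ppis: list[PlantedPPI]
    drug_targets: list[tuple[str, str]]  # (compound, gene)
    gene_ids: list[str]
    disease_ids: list[str]
    compound_ids: list[str]

    def association_for(self, gene: str) -> PlantedAssociation | None:
        for a in self.associations:
            if a.gene == gene:
                return a
        return None


def _make_doc(rng: np.random.Generator, length: int, focus: list[str],
              background: list[str]) -> list[str]:
    filler_n = max(0, length - len(focus))
    filler = [background[i] for i in rng.integers(0, len(background), filler_n)]
    doc = list(focus) + filler
    rng.shuffle(doc)
    return doc[:length]


def generate_corpus(cfg: SyntheticConfig) -> tuple[list[dict], GroundTruth]:
    """Generate the corpus (JSONL-ready document dicts) and its ground truth.

    Documents are emitted as ``{doc_id, year, title, abstract}`` with the
    abstract a whitespace-joined token bag.  Exactly ``cfg.docs_per_year``
    documents are produced per year; planted documents are laid down first
    and the remainder is background.  Byte-identical output under one seed.
    """
    needed = (cfg.n_planted_associations + 10 +
              cfg.n_pathways * cfg.pathway_size + 5 +
              sum(i % 3 + 1 for i in range(cfg.n_compounds)))
    if cfg.n_genes < needed:
        raise ValueError(f"n_genes={cfg.n_genes} too small: the planted "
                         f"association, pathway and drug-target blocks need "
                         f"{needed} distinct genes")
    rng = np.random.default_rng(cfg.seed)
    genes = [cfg.gene_token(i) for i in range(cfg.n_genes)]
    diseases = [cfg.disease_token(i) for i in range(cfg.n_diseases)]
    compounds = [cfg.compound_token(i) for i in range(cfg.n_compounds)]
    background = [f"bg{i:04d}" for i in range(cfg.background_vocab_size)]
    tv = cfg.topic_vocab_size

    families = {g: f"family{i % cfg.n_families}" for i, g in enumerate(genes)}
    fam_topics = {f"family{i}": [f"ftop{i}w{j}" for j in range(tv)]
                  for i in range(cfg.n_families)}
    dis_topics = {d: [f"dtop{i}w{j}" for j in range(tv)]
                  for i, d in enumerate(diseases)}
    cmp_topics = {c: [f"ctop{i}w{j}" for j in range(tv)]
                  for i, c in enumerate(compounds)}

    # planted gene-disease associations: dedicated genes, diseases round-robin
    # pairs of one disease share an emergence year so that, at any
    # pre-emergence checkpoint, no sibling pair has emerged yet
    planted: list[PlantedAssociation] = []
    for i in range(cfg.n_planted_associations):
        disease_idx = i % cfg.n_diseases
        planted.append(PlantedAssociation(
            gene=genes[i],
            disease=diseases[disease_idx],
            emergence_year=cfg.emergence_years[disease_idx % len(cfg.emergence_years)],
            bridge_words=tuple(f"bridge{i}w{j}" for j in range(cfg.n_bridge_words)),
        ))
    planted_pairs = {(a.gene, a.disease): a.emergence_year for a in planted}

    # planted PPIs: pathway groups drawn from genes untouched by associations
    ppi_start = cfg.n_planted_associations + 10
    pathways: dict[str, list[str]] = {}
    ppis: list[PlantedPPI] = []
    pw_topics: dict[str, list[str]] = {}
    idx = ppi_start
    for p in range(cfg.n_pathways):
        name = f"pathway{p}"
        members = genes[idx:idx + cfg.pathway_size]
        idx += cfg.pathway_size
        pathways[name] = members
        pw_topics[name] = [f"ptop{p}w{j}" for j in range(tv)]
        within = [(a, b) if a < b else (b, a)
                  for i, a in enumerate(members) for b in members[i + 1:]]
        for j, pair in enumerate(sorted(within)):
            ppis.append(PlantedPPI(pair=pair, pathway=name,
                                   era=cfg.ppi_eras[j % len(cfg.ppi_eras)]))

    # planted drug targets after the PPI block; compounds cycle through
    # 1 / 2 / 3 targets so promiscuity strata are all populated
    gi = idx + 5
    drug_targets = []
    for i, c in enumerate(compounds):
        for _ in range(i % 3 + 1):
            drug_targets.append((c, genes[gi]))
            gi += 1

    docs: list[dict] = []
    doc_no = 0

    def emit(year: int, focus: list[str]) -> None:
        nonlocal doc_no
        tokens = _make_doc(rng, cfg.doc_length, focus, background)
        docs.append({"doc_id": f"syn{doc_no:06d}", "year": year,
                     "title": "", "abstract": " ".join(tokens)})
        doc_no += 1

    for year in cfg.years:
        n_start = len(docs)
        # family maintenance: every gene appears every year
        for fam, topic in fam_topics.items():
            members = [g for g in genes if families[g] == fam]
            for lo in range(0, len(members), 4):
                chunk = members[lo:lo + 4]
                emit(year, [g for g in chunk for _ in range(2)] + topic)
        # disease documents
        for d in diseases:
            for _ in range(2):
                emit(year, [d] * 3 + dis_topics[d])
        # pathway documents: rotating member pairs share pathway vocabulary
        for name, members in pathways.items():
            for k in range(2 * len(members)):
                p1 = members[(year + k) % len(members)]
                p2 = members[(year + k * 3 + 1) % len(members)]
                focus = [p1] * 2 + ([p2] * 2 if p2 != p1 else []) + pw_topics[name]
                emit(year, focus)
        # drug-target documents: the compound co-occurs with its target and
        # its mechanism vocabulary
        for c, g in drug_targets:
            for _ in range(3):
                emit(year, [c] * 3 + [g] * 2 + cmp_topics[c])
        # random gene-disease co-mentions (never a planted pair pre-emergence)
        for _ in range(cfg.n_random_comentions_per_year):
            for _attempt in range(100):
                g = genes[rng.integers(0, cfg.n_genes)]
                d = diseases[rng.integers(0, cfg.n_diseases)]
                em = planted_pairs.get((g, d))
                if em is None or year >= em:
                    break
            emit(year, [g] * 2 + [d] * 2 + dis_topics[d][:3])
        # bridge documents inside [emergence - lead, emergence)
        for a in planted:
            if a.emergence_year - cfg.bridge_lead_years <= year < a.emergence_year:
                bridges = [w for w in a.bridge_words for _ in range(2)]
                for _ in range(cfg.bridge_docs_per_year):
                    emit(year, [a.gene] * 3 + bridges)
                    emit(year, [a.disease] * 3 + bridges)
        # post-emergence direct co-mentions
        for a in planted:
            if year >= a.emergence_year:
                for _ in range(cfg.emergence_docs_per_year):
                    emit(year, [a.gene] * 3 + [a.disease] * 3)
        n_planted_docs = len(docs) - n_start
        if n_planted_docs > cfg.docs_per_year:
            raise ValueError(
                f"docs_per_year={cfg.docs_per_year} too small: year {year} "
                f"needs {n_planted_docs} planted documents")
        for _ in range(cfg.docs_per_year - n_planted_docs):
            emit(year, [])

    truth = GroundTruth(associations=planted, families=families, ppis=ppis,
                        drug_targets=drug_targets, gene_ids=genes,
                        disease_ids=diseases, compound_ids=compounds)
    return docs, truth


def identity_lexicons(truth: GroundTruth) -> tuple[Lexicon, Lexicon]:
    """Gene and disease lexicons mapping each canonical id to itself."""
    genes = lexicon_from_pairs([(g, g) for g in truth.gene_ids], "gene")
    diseases = lexicon_from_pairs([(d, d) for d in truth.disease_ids], "disease")
    return genes, diseases


def first_comention_table(tagged: Sequence[TaggedDocument]) -> dict[tuple[str, str], int]:
    """Re-scan the tagged corpus for first gene-disease co-mention years."""
    return assoc.ComentionIndex.from_corpus(tagged).first_year


@dataclass
class RecoveryReport:
    """What the full pipeline recovered from the planted ground truth."""

    rank_percentiles: dict[tuple[str, str], float]  # planted pair -> percentile
    mean_rank_percentile: float
    bridge_recovery: dict[tuple[str, str], float]  # fraction of bridges in top-10
    bridge_recovery_rate: float
    model_terminal_precision: float
    baseline_mean: float
    baseline_std: float
    empirical_p: float
    ppi_future_positive_mean_score: float | None = None
    ppi_permanent_negative_mean_score: float | None = None
    ppi_false_positive_counts: list[int] | None = None


def evaluate_recovery(
    docs: Sequence[dict],
    truth: GroundTruth,
    cfg: SyntheticConfig,
    dim: int = 64,
    epochs: int = 50,
    k: int = 50,
    bootstrap_B: int = 10000,
    linking_top_n: int = 10,
    include_ppi: bool = True,
    ppi_sticky_fraction: float = 0.4,
    subsample_threshold: float = 1e-2,
) -> RecoveryReport:
    """Run the full pipeline on a synthetic corpus and score recovery.

    Trains one CBOW model per configured checkpoint year, then for every
    planted association uses the latest pre-emergence model to (a) rank the
    planted gene genome-wide among novel genes, (b) recover its bridge words
    as top-``linking_top_n`` contextual linking words.  Prospective precision
    of the top-``k`` novel predictions (averaged over diseases and model
    years) is compared with a ``bootstrap_B``-iteration random baseline
    (one-sided empirical p).  Optionally trains an early-era PPI classifier
    and reports the positive-unlabeled score separation and the prospective
    false-positive counts across successive synthetic releases.

    ``subsample_threshold`` defaults to 1e-2 here (not the production 1e-4):
    the synthetic slices hold ~1e4 in-vocabulary tokens, so the threshold is
    scaled to keep token survival probabilities in the same regime a
    billion-token corpus sees at 1e-4.
    """
    usable = [a for a in truth.associations
              if any(y < a.emergence_year for y in cfg.model_years)]
    if not usable:
        raise ValueError("cutoff after all emergences: nothing to predict")
    genes_lex, diseases_lex = identity_lexicons(truth)
    tagged = tag_corpus(docs, genes_lex, diseases_lex)
    comentions = assoc.ComentionIndex.from_corpus(tagged)
    protected = truth.gene_ids + truth.disease_ids + truth.compound_ids
    hp = EmbeddingHyperparams(task="CBOW", dim=dim, window=10, epochs=epochs,
                              seed=cfg.seed,
                              subsample_threshold=subsample_threshold)
    models = checkpoint_series(tagged, list(cfg.model_years), hp,
                               protected=protected)
    entity_tokens = set(protected)

    rank_pct: dict[tuple[str, str], float] = {}
    bridge_rec: dict[tuple[str, str], float] = {}
    for a in usable:
        cut = max(y for y in cfg.model_years if y < a.emergence_year)
        model = models[cut]
        ranking = assoc.rank_genes_for_disease(model, a.disease, truth.gene_ids)
        novel = [g for g, _, _ in ranking.entries
                 if not comentions.comentioned_by(g, a.disease, cut)]
        pos = novel.index(a.gene) + 1 if a.gene in novel else len(novel)
        rank_pct[(a.gene, a.disease)] = 100.0 * pos / len(novel)
        if cfg.bridge_docs_per_year > 0:
            words = [w for w, _ in assoc.contextual_linking_words(
                model, a.gene, a.disease, top_n=linking_top_n,
                entity_tokens=entity_tokens)]
            hits = sum(1 for w in a.bridge_words if w in words)
            bridge_rec[(a.gene, a.disease)] = hits / len(a.bridge_words)

    # prospective precision vs bootstrap, averaged over (model year, disease)
    cells = []  # (cutoff, disease, horizon)
    for cut in cfg.model_years:
        horizon = cfg.year_end - cut
        if horizon < 1:
            continue
        for d in truth.disease_ids:
            cells.append((cut, d, horizon))
    model_precisions = []
    baseline_draws = np.zeros(bootstrap_B)
    for i, (cut, d, horizon) in enumerate(cells):
        ranking = assoc.rank_genes_for_disease(models[cut], d, truth.gene_ids)
        preds = assoc.novel_top_k(ranking, comentions, cut, k=k)
        curve = assoc.prospective_precision(preds, comentions, d, cut, horizon)
        model_precisions.append(curve[-1])
        _, _, terminals = assoc.bootstrap_baseline(
            truth.gene_ids, comentions, d, cut, horizon, k=k, B=bootstrap_B,
            seed=cfg.seed * 1000 + i)
        baseline_draws += terminals
    baseline_draws /= len(cells)
    model_mean = float(np.mean(model_precisions))
    empirical_p = float((1 + np.sum(baseline_draws >= model_mean)) / (bootstrap_B + 1))

    report = RecoveryReport(
        rank_percentiles=rank_pct,
        mean_rank_percentile=float(np.mean(list(rank_pct.values()))),
        bridge_recovery=bridge_rec,
        bridge_recovery_rate=(float(np.mean(list(bridge_rec.values())))
                              if bridge_rec else float("nan")),
        model_terminal_precision=model_mean,
        baseline_mean=float(baseline_draws.mean()),
        baseline_std=float(baseline_draws.std()),
        empirical_p=empirical_p,
    )

    if include_ppi and truth.ppis:
        report = _evaluate_ppi(report, truth, cfg, models, ppi_sticky_fraction)
    return report


def _evaluate_ppi(report: RecoveryReport, truth: GroundTruth,
                  cfg: SyntheticConfig, models, sticky_fraction: float) -> RecoveryReport:
    """Train the earliest-era PPI classifier and run the PU prospective test."""
    eras = sorted(cfg.ppi_eras)
    era0 = eras[0]
    releases = [interaction_set_from_pairs(
        [p.pair for p in truth.ppis if p.era <= era], f"release{era}", era)
        for era in eras]
    rel0 = releases[0]
    negs = sticky_negatives(
        interaction_set_from_pairs([p.pair for p in truth.ppis], "all",
                                   eras[-1]),
        fraction=sticky_fraction)
    permanent_negs = sorted(negs)  # never positive in any release
    emb = models[max(y for y in cfg.model_years if y <= era0)]
    split = protein_level_split(sorted(rel0.pairs | set(permanent_negs)),
                                test_fraction=0.25, seed=cfg.seed)
    ds = build_pair_dataset(rel0.pairs, permanent_negs, emb, split=split)
    X_tr, y_tr = ds.subset("train")
    X_val, y_val = ds.subset("val")
    clf = FeedForward(X_tr.shape[1], hidden_layers=1, hidden_size=32,
                      task="classify", seed=cfg.seed)
    # few examples: small batches and generous patience so Adam gets enough steps
    if len(X_val) and len(np.unique(y_val)) > 1:
        clf.fit(X_tr, y_tr, X_val, y_val, epochs=400, patience=25, batch_size=16)
    else:
        clf.fit(X_tr, y_tr, epochs=400, patience=25, batch_size=16)

    future = sorted(p.pair for p in truth.ppis if p.era > era0)
    future = [p for p in future if p[0] in emb and p[1] in emb]
    neg_eval = [p for p in permanent_negs if p[0] in emb and p[1] in emb]
    fut_scores = score_pairs(clf, emb, future)
    neg_scores = score_pairs(clf, emb, neg_eval)

    eval_pairs = {era0: [(p, 1) for p in sorted(rel0.pairs)] +
                  [(p, 0) for p in future] + [(p, 0) for p in neg_eval]}
    cells = prospective_ppi_eval({era0: (clf, emb)}, releases, eval_pairs)
    fp_counts = [c.n_false_positives for c in
                 sorted(cells, key=lambda c: c.dataset_year)]
    return replace(report,
                   ppi_future_positive_mean_score=float(fut_scores.mean()),
                   ppi_permanent_negative_mean_score=float(neg_scores.mean()),
                   ppi_false_positive_counts=fp_counts)
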