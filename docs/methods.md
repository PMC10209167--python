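# Methods

This note documents the models, the parameter choices that matter, and what
the synthetic evaluation does and does not establish.

## Corpus preprocessing

Documents are JSON-lines records `{doc_id, year, title, abstract}`;
`Commentary`/`Correction`/`Corrigendum` types are excluded.  Cleaning
lower-cases, deaccents (NFKD, combining marks stripped), removes boilerplate
leading statements (`background:`, `abstract:`, `introduction:`) and strips
edge punctuation.  Stop words are retained.

**Number masking.**  Decimal literals (`5.3`, `.05`) and percentages
(`12%`, `12.5 %`) become the single token `<number>`; the exact pattern is

```
(?<![\w.])(\d+\.\d+|\.\d+|\d+(?:\.\d+)?\s*%)(?![\w.])
```

Bare integers are *not* masked: at cleaning time tokens like `p53` or
dosage counts are still informative, and only floating/percentage forms
bloat the vocabulary.  Version-like strings (`1.2.3`) are left intact by
the look-around guards.

**Entity canonicalisation** is dictionary longest-leftmost matching over the
cleaned token sequence, case-insensitive, with multi-word synonyms matched
as token runs.  A synonym claimed by two identifiers is ambiguous and
dropped at load time (deterministic and loggable; no resolution heuristics).
Nested synonyms resolve to the longest match, so matched spans never
overlap and tagging is idempotent.  The match strategy for nested synonyms
is this package's choice; dictionary tagging itself is a deliberate
replacement for learned NER, since downstream stages only consume canonical
tokens.

**Phrasing** scores adjacent token pairs with NPMI
`ln(p_ab/(p_a p_b)) / (−ln p_ab)` with all probabilities over the total
token count, so a pair that always co-occurs scores exactly 1.  Pairs with
count ≥ 10 and NPMI > 0.7 are joined by `_`; three passes allow 8-grams.
Counts are re-estimated on the re-tokenised corpus each pass.  Canonical
entity tokens never merge into phrases — one token per gene/disease is what
makes a genome-wide ranking possible.

**Vocabulary.**  Tokens appearing more than ten times (strictly), plus
canonical entity identifiers at any count ≥ 1.  An entity never mentioned
before the cut-off is absent, and therefore unrankable by that model — a
structural limitation of literature embeddings.

## Embedding models

One model per historical slice (documents with year ≤ cut-off), trained
from scratch — never incrementally — so each checkpoint is an honest
snapshot of its year.  The trainer implements CBOW (mean of context
vectors) and skip-gram with negative sampling in numpy, the tight loop
compiled with numba:

| parameter | default | note |
|---|---|---|
| dim | 256 (64 for synthetic runs) | grid 128/256/512 |
| window | 10 | per-position shrink drawn uniformly from 1..window |
| epochs | 50 | |
| learning rate | 0.01 → 0.0001 | linear decay over all token positions |
| subsampling t | 1e-4 (1e-2 for synthetic runs) | word2vec keep rule |
| negatives | 5 | unigram^0.75 noise distribution |

All per-epoch randomness (subsampling decisions, window shrinks, negative
draws) is pre-drawn from one seeded generator and consumed by a
single-threaded kernel, so training is bit-reproducible; determinism is
asserted by double-run hashing in the test suite.

The **subsampling threshold is scale-dependent**: the keep probability
depends on a token's corpus frequency relative to t, and at ~1e5
in-vocabulary tokens every token is "frequent" by a threshold tuned for
~1e9-token corpora.  Synthetic evaluations therefore use t = 1e-2, which
puts token survival in the same regime the production value occupies at
literature scale.  This is a property of the corpus size, not a tuning
knob.

**Co-occurrence likelihood** is the cosine similarity of two token vectors
— defined even for pairs never co-mentioned, which is the entire point.
Softmax-style output probabilities were rejected as the likelihood because
they cost a vocabulary-sized normalisation per query.  **Analogy rank**
(a : b :: c : ?) sorts the vocabulary by similarity to b − a + c with the
query tokens excluded; ties above the answer count optimistically.  The
curated analogy set used for hyperparameter selection at literature scale
is not public, so analogy quality is asserted only against brute-force
oracles on constructed vocabularies.

## Prospective gene–disease evaluation

A disease's genome-wide ranking scores every in-vocabulary gene by cosine
similarity, descending, ties lexicographic.  **Novelty** is abstract-level:
a (gene, disease) pair is novel at year Y if no single document up to Y
mentions both (sentence-level granularity is not stored).  "First
reported" = earliest year of such a document.  The top-k novel predictions
(k = 50) are scored by cumulative precision: the fraction first
co-mentioned within t years of the cut-off.  The baseline draws k novel
genes without replacement, 10,000 iterations, and reports mean, standard
deviation, and the per-iteration terminal precisions, from which a
one-sided empirical p is computed as (1 + #{baseline ≥ model}) / (B + 1).
We rank *novel genes only* (rather than filtering novelty out of a mixed
top-50), the reading that makes the prediction list purely prospective.

**Contextual linking words** score every non-entity vocabulary token by
min(sim(w, gene), sim(w, disease)) — a linking word must be close to both
ends; mean and product aggregations are selectable.

**Clinical-stage regression.**  The chembl-style score (0.1/0.2/0.7/1.0 by
most advanced phase) is regressed from concatenated gene ‖ disease
embeddings over the 2 layers × 6 sizes × 5 dropouts = 60 grid.  Whole
diseases are assigned to train or test; model selection uses a validation
subset of *training* diseases.  Selecting on the future test set would leak
the evaluation into model choice, so it is deliberately not done here.

**Cross-method z-scoring.**  Methods that score only part of the genome get
uniform random fill in (0, min positive score) below every real score, then
rank-based quantile normalisation onto standard normal (average ranks for
ties).  The transform is monotone, so within-method orderings survive.

## Target representation

The clinical-target classifier is a single-hidden-layer feed-forward net
with class-balanced binary cross-entropy, Adam, and patience-2 early
stopping, on an 80/20 gene split.  Metrics come with 5–95% intervals from
100 balanced bootstrap resamples of the test set (equal positives and
negatives per resample, drawn with replacement).  Negative genes for
balancing are sampled uniformly at random with a seed.  Tractability is one
shared-input logistic model with two sigmoid outputs (SM and AB), each
column balanced independently; probabilities are produced for every
embedded gene, labelled or not.

Family coherence: cosine distance (1 − similarity) within each family
versus the all-gene background, compared by Welch's t-test and Mann–Whitney
U (both two-sided), plus the mean silhouette over family labels under the
cosine metric.  Backgrounds above ~2,000 genes use a seeded subsample of
1e5 random pairs — large enough that the background mean is stable to three
decimals; exact all-pairs otherwise.  All statistics are invariant to
uniform vector scaling.

## Protein–protein interactions

Pairs are canonicalised to alphabetical order; self-interactions are
rejected (counted, not raised).  Negatives are all pairs among the sticky
proteins — the top ceil(10% · n) by degree, ties by symbol — minus known
positives.  Features concatenate the embeddings with the lexicographically
smaller symbol first, making scores orientation-invariant by construction;
reversed-order augmentation is therefore unnecessary at inference and
duplicate pairs are counted once.  Splits are protein-level: 25% of
proteins and *all* their pairs form the test set; a further 10% of the
remaining proteins defines validation pairs for early stopping (the
train/test description alone does not provide a stopping signal).  Pairs
touching a protein absent from the era's vocabulary are dropped and
counted.

The prospective, positive-unlabeled test scores an era's model against
successive releases.  Classification threshold for "predicted positive" is
0.5 — the natural point of a balanced-loss sigmoid; the original
false-positive accounting does not state its threshold, so this is made
explicit here.  A pair predicted positive but negative under a release's
labels is a false positive *for that release*; pairs negative in the
model's own era and positive in a later release that the model scored
positive are precisely the interactions prioritised ahead of discovery.

## Drug–target prediction

Hard negatives: the n most frequently targeted proteins × the n least
specific compounds (most reported targets), minus positives — "least
specific" and "most frequent" chosen to make the negative set difficult.
Features are gene embedding first, compound second; the relation is
directional, so no symmetrisation.  The model zoo is logistic regression,
a 100-tree random forest (both class-balanced, scikit-learn), and an MLP
grid H ∈ {1,10,50,100} × N ∈ {1,2,3} × D ∈ {0,0.2}, named `H{size}-N{layers}-D{dropout}`
with round-trip parsing (the `D40-N2-S60` percent style is also parsed).
Tiny nets (H1-N3) may collapse to constant predictions; MCC is defined as 0
when its denominator vanishes, so such models report 0 rather than failing.
Metrics are additionally stratified by compound promiscuity (1, 2, > 2
reported targets), separately for the positive-pair ("pharmacologically
active") and negative-pair subsets — the paired-column reading of that
stratification is an interpretation, flagged as such.

Motif druggability: per motif, a 2×2 table over the gene universe
({carries motif, not} × {drugged, not}), one-sided enrichment Fisher exact
test (sidedness is this package's choice); motif score −log10 p, gene score
the maximum over its motifs, 0 without motifs.  Variant filtering keeps
records that are non-synonymous (parsed from the amino-acid change, with an
explicit override flag), −log10 p strictly above 9, beta-consistent in at
least two studies, and model likelihood strictly above 0.3.

## The synthetic corpus

Documents are bags of tokens — window-based training only consumes
co-occurrence statistics, so no syntax is generated.  Defaults (the study
conditions for all seeded evaluations): 200 genes, 5 diseases, 12
compounds, years 2000–2012, 320 documents/year of length 30, 10 planted
associations with emergence years {2008, 2010, 2012}, 3 bridge words per
pair with a 5-year bridge lead, 8 gene families, 6 pathways of 6 proteins
(all within-pathway pairs are interactions, discovery eras {2007, 2009,
2011}), compounds with 1/2/3 targets cyclically, checkpoint models at
{2007, 2009, 2011}, and a 5,000-word uniform background vocabulary.

Design choices worth knowing:

- **Background words mostly fall below the frequency floor.**  They model
  the long tail of irrelevant literature; contexts that survive vocabulary
  filtering are dominated by signal tokens.  A small, heavily reused
  background instead makes every document share its context distribution
  and collapses all embeddings toward cosine 1.
- **Bridge mechanism.**  In the `bridge_lead_years` before a pair's
  emergence, the *same* unique bridge words appear near the gene in some
  documents and near the disease in others — never together with both.  No
  document co-mentions a planted pair before its emergence year (asserted
  by re-scanning), and post-emergence documents co-mention the pair
  directly without repeating bridge words.  Each disease's planted pairs
  share one emergence year, so an emerged sibling pair never floods the
  linking-word neighbourhood of a still-pre-emergence pair.
- **Pathway documents** co-mention rotating member pairs with shared
  pathway vocabulary from the first year, so pathway structure exists in
  the embeddings long before a pair's discovery era — exactly the channel
  the positive-unlabeled test requires.
- **Random gene–disease co-mentions** (8/year, never a planted pair
  pre-emergence) give the bootstrap baseline a realistic non-zero hit rate.

Problem sizes for the seeded evaluations — 3 CBOW models at dim 64, 50
epochs, 10,000 bootstrap iterations — complete in about half a minute on
one CPU; the per-module unit tests use smaller corpora still.

**What passing does and does not show.**  The synthetic corpus plants an
idealised version of the inference channel: unambiguous entities, clean
bridge vocabulary, stationary token distributions, no contradictory or
retracted claims, no citation structure, and planted effects far stronger
than most real literature signals.  Recovery here demonstrates that the
pipeline's machinery is correct and the statistics behave as designed — not
that comparable precision would be obtained on PubMed-scale data, where
entity ambiguity, topic drift and noise dominate.  Conversely, the
published-scale quantities (e.g. the exact interactome release accounting)
depend on external downloads and cannot be reproduced from this repository
alone.

## Known limitations

- Entities absent from a slice's vocabulary cannot be ranked by that model.
- The feed-forward stack is compact numpy code tuned for small synthetic
  problems; at tens of thousands of pairs a GPU framework would be the
  right tool.
- Dictionary tagging does not disambiguate abbreviations or species.
- Multi-worker embedding training would break bit-reproducibility and is
  not implemented.
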