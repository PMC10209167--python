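"""Text cleaning, collocation phrasing, historical slicing and vocabularies.

The preprocessing contract, applied to every abstract before embedding
training:

* lower-case and deaccent;
* strip boilerplate leading statements ("Background:", "Abstract:", ...);
* mask decimal and percentage numerals with a single ``<number>`` token
  (bare integers are left alone — they often carry entity-like meaning,
  e.g. "p53", "2 diabetes" after cleaning);
* keep stop words (they are a negligible fraction of the vocabulary);
* merge strong collocations into single underscore-joined phrase tokens
  using normalised pointwise mutual information (NPMI), repeated for three
  passes so up to 8-grams can form.

Historical corpora are nested year slices: the slice at cut-off year Y holds
every document published on or before 31 December of Y, and one embedding
model is trained per slice.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

NUMBER_MASK = "<number>"

# Decimal ("5.3", ".05") or percentage ("12%", "12.5 %") literals, as a whole
# token.  Bare integers are intentionally NOT covered.
_NUMBER_RE = re.compile(r"(?<![\w.])(\d+\.\d+|\.\d+|\d+(?:\.\d+)?\s*%)(?![\w.])")
# Punctuation stripped from token edges; keeps <number>, hyphens and
# underscores intact inside tokens.
_EDGE_PUNCT = ".,;:!?()[]{}\"'`“”‘’"


@dataclass(frozen=True)
class CleanConfig:
    leading_statements: tuple[str, ...] = ("background:", "abstract:", "introduction:")
    number_mask_token: str = NUMBER_MASK
    min_year: int = 1900
    max_year: int = 2100


def _deaccent(text: str) -> str:
    norm = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in norm if not unicodedata.combining(ch))


def clean_text(raw: str, cfg: CleanConfig | None = None) -> list[str]:
    """Clean one title+abstract string into the training token list."""
    cfg = cfg or CleanConfig()
    if not raw:
        return []
    text = _deaccent(raw).lower()
    for lead in cfg.leading_statements:
        stripped = text.lstrip()
        if stripped.startswith(lead):
            text = stripped[len(lead):]
    text = _NUMBER_RE.sub(f" {cfg.number_mask_token} ", text)
    tokens = []
    for tok in text.split():
        if tok == cfg.number_mask_token:
            tokens.append(tok)
            continue
        tok = tok.strip(_EDGE_PUNCT)
        if tok and any(ch.isalnum() for ch in tok):
            tokens.append(tok)
    return tokens


# ---------------------------------------------------------------------------
# Phrase mining


@dataclass
class PhraseModel:
    """NPMI-scored bigram merger.

    ``bigrams`` maps (token_a, token_b) -> (pair_count, npmi); only pairs with
    ``pair_count >= min_count`` and ``npmi > threshold`` are retained.  A
    full model is the composition of ``passes`` single-pass models, allowing
    phrases of up to 2**passes source tokens (8-grams at three passes).
    """

    min_count: int = 10
    threshold: float = 0.7
    passes: int = 3
    delimiter: str = "_"
    entity_tokens: frozenset[str] = field(default_factory=frozenset)
    pass_tables: list[dict[tuple[str, str], tuple[int, float]]] = field(default_factory=list)

    @property
    def bigrams(self) -> dict[tuple[str, str], tuple[int, float]]:
        merged: dict[tuple[str, str], tuple[int, float]] = {}
        for table in self.pass_tables:
            merged.update(table)
        return merged

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("token_a\ttoken_b\tcount\tnpmi\n")
            for p, table in enumerate(self.pass_tables):
                for (a, b), (c, s) in sorted(table.items()):
                    fh.write(f"{a}\t{b}\t{c}\t{s:.6f}\t{p}\n")


def npmi_scores(
    docs: Sequence[Sequence[str]],
    min_count: int,
    entity_tokens: frozenset[str],
) -> dict[tuple[str, str], tuple[int, float]]:
    """Score adjacent token pairs by NPMI = ln(p_ab/(p_a p_b)) / (-ln p_ab).

    Probabilities use the total token count as denominator for both unigrams
    and bigrams, so a pair that always co-occurs (p_ab = p_a = p_b) scores
    exactly 1.  Pairs touching an entity token are never scored: canonical
    gene/disease/compound ids stay atomic.
    """
    uni: Counter[str] = Counter()
    bi: Counter[tuple[str, str]] = Counter()
    for doc in docs:
        uni.update(doc)
        for a, b in zip(doc, doc[1:]):
            if a not in entity_tokens and b not in entity_tokens:
                bi[(a, b)] += 1
    total = sum(uni.values())
    if total == 0:
        return {}
    out: dict[tuple[str, str], tuple[int, float]] = {}
    for (a, b), c in bi.items():
        if c < min_count:
            continue
        p_ab = c / total
        p_a = uni[a] / total
        p_b = uni[b] / total
        denom = -log(p_ab)
        score = 1.0 if denom == 0 else log(p_ab / (p_a * p_b)) / denom
        out[(a, b)] = (c, score)
    return out


def _apply_pass(
    doc: Sequence[str],
    table: dict[tuple[str, str], tuple[int, float]],
    threshold: float,
    delimiter: str,
) -> list[str]:
    out: list[str] = []
    i = 0
    n = len(doc)
    while i < n:
        if i + 1 < n:
            entry = table.get((doc[i], doc[i + 1]))
            if entry is not None and entry[1] > threshold:
                out.append(doc[i] + delimiter + doc[i + 1])
                i += 2
                continue
        out.append(doc[i])
        i += 1
    return out


def learn_phrases(
    docs: Sequence[Sequence[str]],
    min_count: int = 10,
    threshold: float = 0.7,
    passes: int = 3,
    entity_tokens: Iterable[str] = (),
    delimiter: str = "_",
) -> PhraseModel:
    """Learn a multi-pass NPMI phrase model, re-estimating counts each pass."""
    if not docs:
        raise ValueError("empty corpus")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    entity = frozenset(entity_tokens)
    model = PhraseModel(min_count=min_count, threshold=threshold, passes=passes,
                        delimiter=delimiter, entity_tokens=entity)
    current = [list(d) for d in docs]
    for _ in range(passes):
        table = npmi_scores(current, min_count, entity)
        retained = {k: v for k, v in table.items() if v[1] > threshold}
        model.pass_tables.append(retained)
        if retained:
            current = [_apply_pass(d, retained, threshold, delimiter) for d in current]
    return model


def apply_phrases(tokens: Sequence[str], model: PhraseModel) -> list[str]:
    """Apply a frozen phrase model (each learned pass in order)."""
    out = list(tokens)
    for table in model.pass_tables:
        if table:
            out = _apply_pass(out, table, model.threshold, model.delimiter)
    return out


# ---------------------------------------------------------------------------
# Historical slices and vocabularies


@dataclass
class CorpusSlice:
    cutoff_year: int
    documents: list  # TaggedDocument list; duck-typed on .year/.tokens

    def __len__(self) -> int:
        return len(self.documents)

    def token_lists(self) -> list[list[str]]:
        return [d.tokens for d in self.documents]


def slice_corpus(corpus: Sequence, cutoff_years: Sequence[int]) -> list[CorpusSlice]:
    """One nested slice per cut-off year: documents with year <= cutoff."""
    if list(cutoff_years) != sorted(cutoff_years):
        raise ValueError("cutoff_years must be sorted ascending")
    for doc in corpus:
        if getattr(doc, "year", None) is None:
            raise ValueError(f"document without year: {doc!r}")
    slices = []
    for cutoff in cutoff_years:
        docs = [d for d in corpus if d.year <= cutoff]
        if not docs:
            logger.warning("slice at cutoff %d is empty", cutoff)
        slices.append(CorpusSlice(cutoff_year=cutoff, documents=docs))
    return slices


@dataclass
class Vocabulary:
    """Token frequency map with frequency floor and protected entity ids.

    Ordinary tokens must appear more than ``min_count`` times; protected
    tokens (canonical gene/disease/compound ids) are kept from a single
    mention.  Ids never mentioned are absent.
    """

    counts: dict[str, int]
    protected_tokens: frozenset[str] = field(default_factory=frozenset)
    min_count: int = 10

    def __contains__(self, token: str) -> bool:
        return token in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def tokens(self) -> list[str]:
        return sorted(self.counts)


def build_vocabulary(
    sl: CorpusSlice | Sequence[Sequence[str]],
    protected: Iterable[str] = (),
    min_count: int = 10,
) -> Vocabulary:
    """Count tokens in a slice; keep count > min_count or protected with >= 1."""
    docs = sl.token_lists() if isinstance(sl, CorpusSlice) else list(sl)
    if not docs:
        raise ValueError("empty slice")
    protected_set = frozenset(protected)
    counts: Counter[str] = Counter()
    for toks in docs:
        counts.update(toks)
    kept = {t: c for t, c in counts.items()
            if c > min_count or (t in protected_set and c >= 1)}
    return Vocabulary(counts=kept, protected_tokens=protected_set, min_count=min_count)
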