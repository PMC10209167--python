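"""Time-sliced word-embedding training and similarity queries.

One continuous-bag-of-words (CBOW) or skip-gram (SG) model with negative
sampling is trained, from scratch, per historical corpus slice.  The training
contract:

* embedding size 256 and window 10 by default (grid 128/256/512 x 5/10/15);
* 50 epochs with the learning rate linearly decayed from 0.01 to 0.0001;
* frequent-token subsampling at a 1e-4 threshold;
* 5 negative samples per positive, drawn from the unigram^0.75 distribution;
* deterministic given the seed: all per-epoch randomness (subsampling
  decisions, window shrinks, negative draws) is pre-drawn from a seeded
  generator and consumed by a single-threaded compiled inner loop.

The trained vectors act as a co-occurrence likelihood estimator: the cosine
similarity of two token vectors scores how plausibly the tokens would
co-occur, even for pairs never observed together before the model's cut-off
year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .corpus import CorpusSlice, Vocabulary, build_vocabulary, slice_corpus


@dataclass(frozen=True)
class EmbeddingHyperparams:
    task: str = "CBOW"  # "CBOW" or "SG"
    dim: int = 256
    window: int = 10
    epochs: int = 50
    lr_start: float = 0.01
    lr_end: float = 0.0001
    subsample_threshold: float = 1e-4
    negative_samples: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.task not in ("CBOW", "SG"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.dim <= 0 or self.window <= 0:
            raise ValueError("dim and window must be positive")
        if not (self.lr_start > self.lr_end > 0):
            raise ValueError("need lr_start > lr_end > 0")


@njit(cache=True)
def _sigmoid(x):
    if x > 6.0:
        return 1.0
    if x < -6.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _train_epoch_cbow(tokens, offsets, shrinks, negs, k_neg, w_in, w_out,
                      lr_start, lr_end, pos_start, total_pos):
    dim = w_in.shape[1]
    pos = pos_start
    for d in range(offsets.shape[0] - 1):
        lo, hi = offsets[d], offsets[d + 1]
        for i in range(lo, hi):
            alpha = lr_start - (lr_start - lr_end) * (pos / total_pos)
            pos += 1
            b = shrinks[i]
            left = i - b if i - b > lo else lo
            right = i + b + 1 if i + b + 1 < hi else hi
            cn = right - left - 1
            if cn <= 0:
                continue
            h = np.zeros(dim)
            for j in range(left, right):
                if j != i:
                    h += w_in[tokens[j]]
            h /= cn
            neu1e = np.zeros(dim)
            center = tokens[i]
            for k in range(k_neg + 1):
                if k == 0:
                    target, label = center, 1.0
                else:
                    target = negs[i * k_neg + k - 1]
                    if target == center:
                        continue
                    label = 0.0
                f = 0.0
                for c in range(dim):
                    f += h[c] * w_out[target, c]
                g = (label - _sigmoid(f)) * alpha
                for c in range(dim):
                    neu1e[c] += g * w_out[target, c]
                    w_out[target, c] += g * h[c]
            for j in range(left, right):
                if j != i:
                    for c in range(dim):
                        w_in[tokens[j], c] += neu1e[c] / cn
    return pos


@njit(cache=True)
def _train_epoch_sg(tokens, offsets, shrinks, negs, k_neg, w_in, w_out,
                    lr_start, lr_end, pos_start, total_pos, window):
    dim = w_in.shape[1]
    pos = pos_start
    for d in range(offsets.shape[0] - 1):
        lo, hi = offsets[d], offsets[d + 1]
        for i in range(lo, hi):
            alpha = lr_start - (lr_start - lr_end) * (pos / total_pos)
            pos += 1
            b = shrinks[i]
            left = i - b if i - b > lo else lo
            right = i + b + 1 if i + b + 1 < hi else hi
            center = tokens[i]
            slot = 0
            for j in range(left, right):
                if j == i:
                    continue
                ctx = tokens[j]
                neu1e = np.zeros(dim)
                for k in range(k_neg + 1):
                    if k == 0:
                        target, label = center, 1.0
                    else:
                        target = negs[(i * 2 * window + slot) * k_neg + k - 1]
                        if target == center:
                            continue
                        label = 0.0
                    f = 0.0
                    for c in range(dim):
                        f += w_in[ctx, c] * w_out[target, c]
                    g = (label - _sigmoid(f)) * alpha
                    for c in range(dim):
                        neu1e[c] += g * w_out[target, c]
                        w_out[target, c] += g * w_in[ctx, c]
                for c in range(dim):
                    w_in[ctx, c] += neu1e[c]
                slot += 1
    return pos


class OOVError(KeyError):
    def __init__(self, token: str):
        super().__init__(f"token not in model vocabulary: {token!r}")
        self.token = token


@dataclass
class EmbeddingModel:
    """Vocabulary, vector matrix and the cut-off year of the training slice."""

    cutoff_year: int
    vocabulary: list[str]
    vectors: np.ndarray  # |V| x dim
    hyperparams: EmbeddingHyperparams
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _norms: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("one vector per vocabulary token required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite vectors")
        self._index = {t: i for i, t in enumerate(self.vocabulary)}

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise OOVError(token) from None

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.index(token)]

    @property
    def unit_vectors(self) -> np.ndarray:
        if self._norms is None:
            norms = np.linalg.norm(self.vectors, axis=1)
            norms[norms == 0] = 1.0
            self._norms = self.vectors / norms[:, None]
        return self._norms

    def similarity(self, a: str, b: str) -> float:
        u = self.unit_vectors
        return float(u[self.index(a)] @ u[self.index(b)])

    def similarities(self, token: str, candidates: Sequence[str]) -> np.ndarray:
        u = self.unit_vectors
        idx = np.array([self.index(c) for c in candidates], dtype=np.int64)
        return u[idx] @ u[self.index(token)]

    def save_word2vec(self, path: str | Path) -> None:
        """Word2vec text format: header "V dim", one "token v1 .. vd" per line."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.vectors.shape[1]}\n")
            for tok, vec in zip(self.vocabulary, self.vectors):
                fh.write(tok + " " + " ".join(repr(float(x)) for x in vec) + "\n")

    @classmethod
    def load_word2vec(cls, path: str | Path, cutoff_year: int = 0,
                      hyperparams: EmbeddingHyperparams | None = None) -> "EmbeddingModel":
        with open(path, encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            toks, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                toks.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        vecs = np.array(rows, dtype=np.float64)
        if vecs.shape != (n, dim):
            raise ValueError(f"header says {(n, dim)}, data is {vecs.shape}")
        return cls(cutoff_year=cutoff_year, vocabulary=toks, vectors=vecs,
                   hyperparams=hyperparams or EmbeddingHyperparams(dim=dim))


def cooccurrence_likelihood(model: EmbeddingModel, token_a: str, token_b: str) -> float:
    """Cosine similarity of the two token vectors, in [-1, 1] and symmetric."""
    return model.similarity(token_a, token_b)


def analogy_rank(model: EmbeddingModel, a: str, b: str, c: str, answer: str) -> int:
    """Rank of ``answer`` among candidates ordered by similarity to b - a + c.

    The query tokens a, b, c are excluded from the candidate set; rank 1 is
    best.  Ties above the answer are counted optimistically (rank = 1 + number
    of candidates strictly more similar than the answer).
    """
    for tok in (a, b, c, answer):
        model.index(tok)
    query = model.vector(b) - model.vector(a) + model.vector(c)
    qn = np.linalg.norm(query)
    if qn > 0:
        query = query / qn
    sims = model.unit_vectors @ query
    excluded = {model.index(a), model.index(b), model.index(c)}
    ans_idx = model.index(answer)
    ans_sim = sims[ans_idx]
    rank = 1
    for i, s in enumerate(sims):
        if i in excluded or i == ans_idx:
            continue
        if s > ans_sim:
            rank += 1
    return rank


def train_embeddings(
    sl: CorpusSlice | Sequence[Sequence[str]],
    vocab: Vocabulary,
    hp: EmbeddingHyperparams,
) -> EmbeddingModel:
    """Train one embedding model on a corpus slice.

    Out-of-vocabulary tokens are dropped before windowing (windows close over
    the surviving tokens, and never cross document boundaries).  Subsampling
    discards occurrences of frequent tokens with the standard word2vec keep
    probability, re-drawn each epoch.
    """
    docs = sl.token_lists() if isinstance(sl, CorpusSlice) else list(sl)
    cutoff = sl.cutoff_year if isinstance(sl, CorpusSlice) else 0
    tokens_sorted = vocab.tokens
    if not tokens_sorted:
        raise ValueError("empty vocabulary")
    tok2id = {t: i for i, t in enumerate(tokens_sorted)}
    counts = np.array([vocab.counts[t] for t in tokens_sorted], dtype=np.float64)
    total = counts.sum()

    doc_ids = []
    for doc in docs:
        ids = [tok2id[t] for t in doc if t in tok2id]
        if ids:
            doc_ids.append(np.array(ids, dtype=np.int32))
    if not doc_ids:
        raise ValueError("no in-vocabulary tokens in slice")
    n_positions = int(sum(len(d) for d in doc_ids))

    # subsampling keep probability (word2vec): (sqrt(f/t) + 1) * t/f, capped at 1
    t = hp.subsample_threshold
    freq = counts / total
    with np.errstate(divide="ignore"):
        keep = (np.sqrt(freq / t) + 1.0) * (t / freq)
    keep = np.minimum(keep, 1.0)

    # negative-sampling distribution: unigram^0.75
    noise = counts ** 0.75
    noise_cum = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(hp.seed)
    nv, dim = len(tokens_sorted), hp.dim
    w_in = (rng.random((nv, dim)) - 0.5) / dim
    w_out = np.zeros((nv, dim))

    flat_all = np.concatenate(doc_ids)
    lens = np.array([len(d) for d in doc_ids])
    total_pos = hp.epochs * n_positions
    pos = 0
    k = hp.negative_samples
    for _ in range(hp.epochs):
        keep_draw = rng.random(n_positions)
        mask = keep_draw < keep[flat_all]
        kept_flat = flat_all[mask]
        kept_lens = np.add.reduceat(mask.astype(np.int64), np.concatenate(([0], np.cumsum(lens)[:-1])))
        offsets = np.concatenate(([0], np.cumsum(kept_lens))).astype(np.int64)
        n_kept = int(offsets[-1])
        # learning-rate schedule advances over all positions (kept or not)
        if n_kept == 0:
            pos += n_positions
            continue
        shrinks = rng.integers(1, hp.window + 1, size=n_kept).astype(np.int32)
        if hp.task == "CBOW":
            negs = np.searchsorted(noise_cum, rng.random(n_kept * k)).astype(np.int32)
            _train_epoch_cbow(kept_flat, offsets, shrinks, negs, k, w_in, w_out,
                              hp.lr_start, hp.lr_end, pos, total_pos)
        else:
            negs = np.searchsorted(noise_cum, rng.random(n_kept * 2 * hp.window * k)).astype(np.int32)
            _train_epoch_sg(kept_flat, offsets, shrinks, negs, k, w_in, w_out,
                            hp.lr_start, hp.lr_end, pos, total_pos, hp.window)
        pos += n_positions

    return EmbeddingModel(cutoff_year=cutoff, vocabulary=tokens_sorted,
                          vectors=w_in, hyperparams=hp)


def checkpoint_series(
    corpus: Sequence,
    years: Sequence[int],
    hp: EmbeddingHyperparams,
    protected: Sequence[str] = (),
    min_count: int = 10,
) -> dict[int, EmbeddingModel]:
    """Train one independent model per cut-off year (ascending).

    Each model is trained from scratch on the slice of documents published up
    to 31 December of its year, with its own vocabulary; the per-year seed is
    derived from ``hp.seed`` so models differ only by their slice.
    """
    if list(years) != sorted(years):
        raise ValueError("years must be ascending")
    slices = slice_corpus(corpus, list(years))
    out: dict[int, EmbeddingModel] = {}
    for sl in slices:
        vocab = build_vocabulary(sl, protected=protected, min_count=min_count)
        hp_y = replace(hp, seed=(hp.seed * 100003 + sl.cutoff_year) % (2**31 - 1))
        out[sl.cutoff_year] = train_embeddings(sl, vocab, hp_y)
    return out
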