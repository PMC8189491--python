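"""Disease-keyword discovery by skip-gram embedding similarity.

A skip-gram word2vec model with negative sampling is trained on the query
corpus; every vocabulary unigram is then ranked by cosine similarity to a
small set of seed illness terms ("asthma", "copd", "smoking"), and keywords
are selected as the maximal all-relevant prefix of that ranking — the scan
stops at the first term judged not disease-related.  A curated medication
list augments the embedding-derived set, since patients search for drug
names, dosages and side effects that need not co-occur with illness terms.

The trainer is a compact numpy implementation of skip-gram with negative
sampling (SGNS): for each (center, context) pair within a symmetric window
of size ``w`` it maximises log sigma(v_c . u_o) plus k negative-sample
terms, with vectors of dimension ``d``.  Defaults d=100 and w=6 (a typical
search-query length).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    MissingSeedTermError,
    UndefinedSimilarityError,
    UnlabeledTermError,
)
from .vocab import SEED_TERMS

CATEGORIES = ("symptom", "disease", "medication", "smoking")


class KeywordSet(dict):
    """Mapping keyword -> category; keywords lowercase and unique.

    Behaves as a plain dict so any ``Mapping[str, str]`` consumer accepts
    it; construction validates the invariants.
    """

    def __init__(self, mapping: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        super().__init__(mapping)
        for k, cat in self.items():
            if not isinstance(k, str) or k != k.lower():
                raise InvalidInputError(f"keyword must be lowercase: {k!r}")
            if not cat:
                raise InvalidInputError(f"keyword {k!r} has no category")

    def members(self, category: str) -> list[str]:
        return sorted(k for k, c in self.items() if c == category)


@dataclass
class EmbeddingModel:
    """Trained word vectors plus the parameters they were trained with."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # (V, d)
    d: int
    w: int
    epochs: int
    min_count: int
    seed: int

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocabulary), self.d):
            raise InvalidInputError("vectors shape does not match vocabulary and d")

    def __contains__(self, word: str) -> bool:
        return word in self.vocabulary

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.vectors[self.vocabulary[word]]
        except KeyError:
            raise KeyError(f"word not in embedding vocabulary: {word!r}") from None

    @property
    def words(self) -> list[str]:
        order = sorted(self.vocabulary, key=self.vocabulary.__getitem__)
        return order


@dataclass
class RankedTerms:
    """Vocabulary unigrams ordered by similarity to the seed terms."""

    terms: list[tuple[str, float]]  # (term, cosine score), non-increasing
    seed_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.terms]
        if any(s1 < s2 for s1, s2 in zip(scores, scores[1:])):
            raise InvalidInputError("ranking scores must be non-increasing")
        if any(not (-1.0 - 1e-9 <= s <= 1.0 + 1e-9) for s in scores):
            raise InvalidInputError("cosine scores must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.terms)

    def top(self, n: int) -> list[str]:
        return [t for t, _ in self.terms[:n]]


def train_embedding(
    corpus: Sequence[Sequence[str]],
    d: int = 100,
    w: int = 6,
    epochs: int = 5,
    min_count: int = 5,
    seed: int = 0,
    negatives: int = 5,
    learning_rate: float = 0.025,
    batch_size: int = 512,
) -> EmbeddingModel:
    """Train skip-gram-with-negative-sampling vectors on a token corpus.

    The vocabulary keeps tokens with corpus frequency >= ``min_count``.
    Negative samples follow the unigram distribution raised to 3/4; the
    learning rate decays linearly over all updates.  Deterministic given
    ``seed``.
    """
    corpus = list(corpus)
    if len(corpus) == 0:
        raise InvalidInputError("corpus is empty")
    if d < 2:
        raise InvalidParameterError("embedding dimension d must be at least 2")
    if w < 1:
        raise InvalidParameterError("context window w must be at least 1")
    if epochs < 1 or min_count < 1 or negatives < 1:
        raise InvalidParameterError("epochs, min_count and negatives must be positive")

    counts = Counter(tok for sent in corpus for tok in sent)
    # Deterministic vocab order: frequency-descending, then lexicographic.
    kept = sorted((t for t, c in counts.items() if c >= min_count),
                  key=lambda t: (-counts[t], t))
    if not kept:
        raise InvalidInputError(f"no token reaches min_count={min_count}")
    vocab = {t: i for i, t in enumerate(kept)}
    V = len(vocab)

    encoded = []
    for sent in corpus:
        ids = [vocab[t] for t in sent if t in vocab]
        if len(ids) >= 2:
            encoded.append(np.asarray(ids, dtype=np.int64))

    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for ids in encoded:
        n = ids.size
        for off in range(1, w + 1):
            if n <= off:
                break
            centers.append(ids[:-off]); contexts.append(ids[off:])
            centers.append(ids[off:]);  contexts.append(ids[:-off])
    if not centers:
        # Degenerate corpus (all sentences length 1): return the random init.
        rng = np.random.default_rng(seed)
        vecs = (rng.random((V, d)) - 0.5) / d
        return EmbeddingModel(vocab, vecs, d, w, epochs, min_count, seed)

    center_arr = np.concatenate(centers)
    context_arr = np.concatenate(contexts)
    n_pairs = center_arr.size

    freq = np.array([counts[t] for t in kept], dtype=np.float64)
    noise = freq ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    total_updates = epochs * ((n_pairs + batch_size - 1) // batch_size)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            idx = order[start:start + batch_size]
            c = center_arr[idx]
            o = context_arr[idx]
            neg = rng.choice(V, size=(idx.size, negatives), p=noise)

            lr = learning_rate * max(1e-4, 1.0 - step / total_updates)
            step += 1

            vc = w_in[c]                      # (B, d)
            uo = w_out[o]                     # (B, d)
            un = w_out[neg]                   # (B, k, d)

            g_pos = _sigmoid(np.einsum("bd,bd->b", vc, uo)) - 1.0   # (B,)
            g_neg = _sigmoid(np.einsum("bkd,bd->bk", un, vc))       # (B, k)

            grad_vc = g_pos[:, None] * uo + np.einsum("bk,bkd->bd", g_neg, un)
            grad_uo = g_pos[:, None] * vc
            grad_un = g_neg[..., None] * vc[:, None, :]

            np.add.at(w_in, c, -lr * grad_vc)
            np.add.at(w_out, o, -lr * grad_uo)
            np.add.at(w_out, neg.reshape(-1), -lr * grad_un.reshape(-1, d))

    return EmbeddingModel(vocab, w_in, d, w, epochs, min_count, seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors: u.v / (|u| |v|)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise InvalidParameterError("vectors must be 1-D with equal dimension")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def rank_by_similarity(
    model: EmbeddingModel,
    seed_terms: Sequence[str] = SEED_TERMS,
    aggregation: str = "max",
) -> RankedTerms:
    """Rank every non-seed vocabulary unigram by similarity to the seeds.

    ``aggregation`` is how per-seed cosines combine: "max" (a term strongly
    tied to any one illness qualifies — the default) or "mean".  Ties are
    broken lexicographically for determinism.
    """
    if aggregation not in ("max", "mean"):
        raise InvalidParameterError("aggregation must be 'max' or 'mean'")
    for t in seed_terms:
        if t not in model.vocabulary:
            raise MissingSeedTermError(t)

    seed_idx = [model.vocabulary[t] for t in seed_terms]
    vecs = model.vectors
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1e-300  # zero vectors score ~0 rather than erroring
    unit = vecs / norms[:, None]
    sims = unit @ unit[seed_idx].T  # (V, n_seeds)
    agg = sims.max(axis=1) if aggregation == "max" else sims.mean(axis=1)

    seeds = set(seed_terms)
    scored = [(t, float(agg[i])) for t, i in model.vocabulary.items() if t not in seeds]
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return RankedTerms(scored, tuple(seed_terms))


def select_keywords(
    ranked: RankedTerms,
    relevance_labels: Mapping[str, str | bool | None],
) -> KeywordSet:
    """Take the maximal prefix of the ranking whose terms are all relevant.

    ``relevance_labels`` maps each ranked term to its category string if
    disease-related (``True`` is accepted and treated as category
    "disease"), or to ``None``/``False`` if not.  The scan stops at the
    first non-relevant term; every ranked term up to and including the
    stopping point must be labeled.
    """
    selected: dict[str, str] = {}
    for term, _score in ranked.terms:
        if term not in relevance_labels:
            raise UnlabeledTermError(term)
        label = relevance_labels[term]
        if label is None or label is False:
            break
        category = "disease" if label is True else str(label)
        selected[term] = category
    return KeywordSet(selected)


def augment_with_medications(
    base: Mapping[str, str],
    medication_terms: Sequence[str],
) -> KeywordSet:
    """Union the keyword set with a curated medication list.

    New terms get category "medication"; terms already present keep their
    existing category (first assignment wins).
    """
    for t in medication_terms:
        if t != t.lower():
            raise InvalidParameterError(f"medication terms must be lowercase: {t!r}")
    merged = dict(base)
    for t in medication_terms:
        merged.setdefault(t, "medication")
    return KeywordSet(merged)
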