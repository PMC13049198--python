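"""Domain and domain-architecture embeddings.

Three families of domain embeddings are built from the corpus of unique
DAs, treating each architecture as a short "sentence" of domains:

* **PMI** — each coordinate j of e(Di) is the pointwise mutual information
  log2 P(Di,Dj) / (P(Di) P(Dj)) of the ordered adjacent pair Di→Dj, with a
  pseudocount ψ added to every ordered pair count (default ψ = 0.0009).
  Negative values are retained: under-representation of a domain pair is
  informative at this corpus scale.  Dimension m = |D|.
* **TF-IDF** — coordinate j of e(Di) is tf(Di, Aj) · idf(Di) with
  idf(Di) = N / df(Di) (no logarithm; the plain count ratio), where df is
  the number of unique DAs containing Di.  Dimension m = N.
* **skip-gram** (word2vec SGNS) — a small negative-sampling skip-gram
  trainer over the unique DAs, window w truncated at architecture ends,
  min-count 1 so no domain of a ~1000-domain vocabulary is dropped,
  single-threaded and fully seeded.

An architecture embedding v(A) is the arithmetic mean of the embeddings of
A's constituent domains (repeats counted with multiplicity); it is order
invariant — only skip-gram *training* sees domain order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import Corpus, DAKey

logger = logging.getLogger("archsem")

DEFAULT_PSEUDOCOUNT = 0.0009
SKIPGRAM_EPOCHS = 15

#: the embedding grid evaluated by the pipeline: two sparse encodings and
#: six skip-gram variants, m ∈ {5, 10, 100} × w ∈ {1, 5}
DEFAULT_GRID = (
    "tfidf",
    "pmi",
    "w2v(5,1)",
    "w2v(5,5)",
    "w2v(10,1)",
    "w2v(10,5)",
    "w2v(100,1)",
    "w2v(100,5)",
)


@dataclass
class DomainEmbedding:
    """domain → vector matrix with method metadata."""

    method: str  # "PMI" | "TFIDF" | "SKIPGRAM"
    vocab: tuple[str, ...]
    matrix: np.ndarray  # |D| × m
    params: dict = field(default_factory=dict)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.vocab):
            raise ValueError("matrix rows must match vocabulary size")
        if not self._index:
            self._index = {d: i for i, d in enumerate(self.vocab)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, domain: str) -> np.ndarray:
        return self.matrix[self._index[domain]]

    def __contains__(self, domain: str) -> bool:
        return domain in self._index


@dataclass
class ArchitectureEmbedding:
    """DA → vector matrix, averaged from a domain embedding."""

    keys: tuple[DAKey, ...]
    matrix: np.ndarray  # N × m
    source_method: str
    source_params: dict = field(default_factory=dict)
    _index: dict[DAKey, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {k: i for i, k in enumerate(self.keys)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def vector(self, key: DAKey) -> np.ndarray:
        return self.matrix[self._index[tuple(key)]]

    def __contains__(self, key: DAKey) -> bool:
        return tuple(key) in self._index


# ---------------------------------------------------------------------------
# Sparse encodings
# ---------------------------------------------------------------------------


def pmi_embedding(
    corpus: Corpus,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pairs: str = "adjacent",
) -> DomainEmbedding:
    """PMI matrix over ordered domain pairs.

    ``pairs="adjacent"`` (default) counts immediate successions Di→Dj;
    ``pairs="all_ordered"`` counts every ordered position pair within a DA.
    The pseudocount is added to the count of every ordered pair in D × D
    and the joint table renormalized; marginals are raw unigram
    frequencies.  With ψ = 0 a never-observed pair yields −inf, which is
    flagged.
    """
    if not corpus.bigram_counts:
        raise ValueError("corpus has no adjacent domain pairs")
    if pairs not in ("adjacent", "all_ordered"):
        raise ValueError(f"unknown pair mode {pairs!r}")
    vocab = tuple(sorted(corpus.vocabulary))
    idx = {d: i for i, d in enumerate(vocab)}
    V = len(vocab)

    C = np.zeros((V, V))
    if pairs == "adjacent":
        for (a, b), c in corpus.bigram_counts.items():
            C[idx[a], idx[b]] = c
    else:
        for arch in corpus.architectures:
            doms = arch.domains
            for i in range(len(doms)):
                for j in range(i + 1, len(doms)):
                    C[idx[doms[i]], idx[doms[j]]] += 1

    joint = C + pseudocount
    joint /= joint.sum()
    uni = np.array([corpus.unigram_counts[d] for d in vocab], dtype=float)
    p = uni / uni.sum()
    with np.errstate(divide="ignore"):
        pmi = np.log2(joint) - np.log2(np.outer(p, p))
    if pseudocount == 0 and np.isneginf(pmi).any():
        logger.warning(
            "pmi_embedding: ψ=0 with %d unobserved pairs → -inf entries",
            int(np.isneginf(pmi).sum()),
        )
    return DomainEmbedding(
        method="PMI",
        vocab=vocab,
        matrix=pmi,
        params={"psi": pseudocount, "m": V, "pairs": pairs},
    )


def tfidf_embedding(corpus: Corpus, log_idf: bool = False) -> DomainEmbedding:
    """TF-IDF matrix: e_j(Di) = tf(Di, Aj) · N/df(Di).

    Columns follow the corpus's fixed (lexicographic) DA ordering.  The
    plain-ratio idf is the default; ``log_idf`` switches to the classical
    log(N/df) for comparison.
    """
    vocab = tuple(sorted(corpus.vocabulary))
    idx = {d: i for i, d in enumerate(vocab)}
    N = corpus.N
    tf = np.zeros((len(vocab), N))
    for j, arch in enumerate(corpus.architectures):
        for d in arch.domains:
            tf[idx[d], j] += 1
    df = (tf > 0).sum(axis=1)
    idf = np.log(N / df) if log_idf else N / df
    return DomainEmbedding(
        method="TFIDF",
        vocab=vocab,
        matrix=tf * idf[:, None],
        params={"m": N, "log_idf": log_idf},
    )


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def skipgram_embedding(
    corpus: Corpus,
    m: int,
    window: int,
    epochs: int = SKIPGRAM_EPOCHS,
    seed: int = 0,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> DomainEmbedding:
    """Train a skip-gram (SGNS) domain embedding on the unique DAs.

    Classic word2vec recipe: for each position a reduced window
    b ~ U{1..w} is drawn and all in-sentence context domains within b are
    predicted from the centre via logistic regression against ``negative``
    noise domains sampled from the unigram^0.75 distribution; the learning
    rate decays linearly.  Windows truncate at architecture ends.
    Min-count is 1: every vocabulary domain gets a vector.  Training is
    single-threaded and driven by one seeded generator, so runs are
    bitwise reproducible.
    """
    if m < 1 or window < 1:
        raise ValueError("dimension and window must be >= 1")
    if corpus.N == 0:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(seed)
    vocab = tuple(sorted(corpus.vocabulary))
    idx = {d: i for i, d in enumerate(vocab)}
    V = len(vocab)

    sentences = [np.array([idx[d] for d in a.domains]) for a in corpus.architectures]
    counts = np.array([corpus.unigram_counts[d] for d in vocab], dtype=float)
    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    w_in = (rng.random((V, m)) - 0.5) / m
    w_out = np.zeros((V, m))

    total_tokens = sum(len(s) for s in sentences) * epochs
    seen = 0
    for _epoch in range(epochs):
        for sent in sentences:
            n = len(sent)
            for pos in range(n):
                seen += 1
                if n == 1:
                    continue
                lr = max(min_alpha, alpha * (1.0 - seen / total_tokens))
                b = int(rng.integers(1, window + 1))
                lo, hi = max(0, pos - b), min(n, pos + b + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1 : hi]])
                if ctx.size == 0:
                    continue
                negs = np.searchsorted(noise_cdf, rng.random(ctx.size * negative))
                targets = np.concatenate([ctx, negs])
                labels = np.zeros(targets.size)
                labels[: ctx.size] = 1.0
                c = sent[pos]
                h = w_in[c]
                g = (_sigmoid(w_out[targets] @ h) - labels) * lr
                grad_h = g @ w_out[targets]
                np.add.at(w_out, targets, -np.outer(g, h))
                w_in[c] = h - grad_h
    return DomainEmbedding(
        method="SKIPGRAM",
        vocab=vocab,
        matrix=w_in,
        params={
            "m": m,
            "w": window,
            "epochs": epochs,
            "seed": seed,
            "negative": negative,
            "alpha": alpha,
            "workers": 1,
        },
    )


# ---------------------------------------------------------------------------
# Architecture embedding and the method grid
# ---------------------------------------------------------------------------


def architecture_embedding(corpus: Corpus, emb: DomainEmbedding) -> ArchitectureEmbedding:
    """v(A) = mean of constituent domain vectors (multiplicity counted)."""
    missing = corpus.vocabulary - set(emb.vocab)
    if missing:
        raise ValueError(f"domains missing from embedding: {sorted(missing)[:5]} ...")
    keys = tuple(a.domains for a in corpus.architectures)
    mat = np.empty((corpus.N, emb.dim))
    for i, arch in enumerate(corpus.architectures):
        rows = np.array([emb._index[d] for d in arch.domains])
        mat[i] = emb.matrix[rows].mean(axis=0)
    return ArchitectureEmbedding(
        keys=keys, matrix=mat, source_method=emb.method, source_params=dict(emb.params)
    )


def parse_embedding_id(name: str) -> dict:
    """Parse a grid identifier: ``tfidf``, ``pmi``, ``w2v(m,w)`` or ``w2v:m,w``."""
    s = name.strip().lower()
    if s in ("tfidf", "pmi"):
        return {"kind": s}
    body = None
    if s.startswith("w2v(") and s.endswith(")"):
        body = s[4:-1]
    elif s.startswith("w2v:"):
        body = s[4:]
    if body is not None:
        m_s, w_s = body.split(",")
        return {"kind": "w2v", "m": int(m_s), "w": int(w_s)}
    raise ValueError(f"unrecognized embedding id {name!r}")


def build_embedding(
    corpus: Corpus,
    name: str,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    epochs: int = SKIPGRAM_EPOCHS,
) -> DomainEmbedding:
    """Build one embedding of the grid by identifier."""
    parsed = parse_embedding_id(name)
    if parsed["kind"] == "tfidf":
        return tfidf_embedding(corpus)
    if parsed["kind"] == "pmi":
        return pmi_embedding(corpus, pseudocount=pseudocount)
    return skipgram_embedding(corpus, m=parsed["m"], window=parsed["w"], epochs=epochs, seed=seed)


def write_embedding_tsv(emb: DomainEmbedding, path) -> None:
    import json
    from pathlib import Path

    path = Path(path)
    with path.open("w") as fh:
        fh.write("domain\t" + "\t".join(f"v{i}" for i in range(emb.dim)) + "\n")
        for d, row in zip(emb.vocab, emb.matrix):
            fh.write(d + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    sidecar = {"method": emb.method, "params": emb.params}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_embedding_tsv(path) -> DomainEmbedding:
    import json
    from pathlib import Path

    path = Path(path)
    vocab: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            vocab.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return DomainEmbedding(
        method=meta.get("method", "UNKNOWN"),
        vocab=tuple(vocab),
        matrix=np.array(rows),
        params=meta.get("params", {}),
    )
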