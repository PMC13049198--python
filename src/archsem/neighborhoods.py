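"""Cosine k-nearest annotated neighborhoods and the Jaccard-content control.

For a target architecture A and an annotated multidomain pool A_O, the
*k-neighborhood* is the k pool members closest to A by cosine similarity
in an architecture embedding.  Each neighborhood splits into the *sharing*
subset (members with at least one domain in common with A, content Jaccard
S_J > 0) and the *non-sharing* subset (S_J = 0).  The content Jaccard is a
multiset Jaccard over domain copies: S_J = n_ij / (n_i + n_j − n_ij) where
n_ij is the number of shared domain copies.

The control ranks candidates by S_J itself; by construction its
neighborhoods contain only sharing members.

Ties in similarity are broken deterministically by lexicographic DA key
(the original analysis broke ties arbitrarily and found negligible
impact; determinism is preferred here for reproducibility).  Pools are a
few thousand DAs at most, so search is exact.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import DAKey, DomainArchitecture
from .embeddings import ArchitectureEmbedding

logger = logging.getLogger("archsem")

DEFAULT_K_GRID = (1, 3, 5, 10)


@dataclass
class Neighborhood:
    """Ordered k nearest annotated DAs of one target, with the S_J split."""

    target: DAKey
    ontology: str | None
    k: int  # requested size
    members: tuple[DAKey, ...]  # descending similarity, deterministic ties
    similarities: tuple[float, ...]
    sharing: tuple[DAKey, ...]  # S_J > 0, in neighborhood order
    nonsharing: tuple[DAKey, ...]  # S_J = 0, in neighborhood order

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def k_plus(self) -> int:
        return len(self.sharing)

    @property
    def k_minus(self) -> int:
        return len(self.nonsharing)


def _as_key(a) -> DAKey:
    return a.domains if isinstance(a, DomainArchitecture) else tuple(a)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Standard cosine; 0 by convention if either vector has zero norm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


def content_jaccard(a, b) -> float:
    """Multiset Jaccard over domain copies; 0 iff no shared domain."""
    ka, kb = _as_key(a), _as_key(b)
    ca, cb = Counter(ka), Counter(kb)
    nij = sum(min(ca[d], cb[d]) for d in ca.keys() & cb.keys())
    if nij == 0:
        return 0.0
    return nij / (len(ka) + len(kb) - nij)


def _split(target: DAKey, members: Sequence[DAKey]):
    sharing, nonsharing = [], []
    tset = set(target)
    for mkey in members:
        if tset & set(mkey):
            sharing.append(mkey)
        else:
            nonsharing.append(mkey)
    return tuple(sharing), tuple(nonsharing)


def _normalize_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0  # zero vectors stay zero → cosine 0 convention
    return m / norms


def k_neighborhood(
    target,
    pool: Iterable,
    arch_emb: ArchitectureEmbedding,
    k: int,
    ontology: str | None = None,
) -> Neighborhood:
    """Top-k pool members by cosine to the target in the embedding.

    The target itself is excluded from the pool if present.  When the pool
    is smaller than k, the full pool is returned with a warning and the
    requested k recorded.
    """
    tkey = _as_key(target)
    pool_keys = sorted({_as_key(p) for p in pool} - {tkey})
    if not pool_keys:
        raise ValueError("empty neighbor pool")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(pool_keys):
        logger.warning(
            "k_neighborhood: k=%d exceeds pool size %d; truncating", k, len(pool_keys)
        )
    tvec = arch_emb.vector(tkey)
    mat = np.array([arch_emb.vector(p) for p in pool_keys])
    tn = np.linalg.norm(tvec)
    sims = (
        np.zeros(len(pool_keys))
        if tn == 0.0
        else _normalize_rows(mat) @ (tvec / tn)
    )
    order = np.lexsort((np.arange(len(pool_keys)), -sims))[:k]
    members = tuple(pool_keys[i] for i in order)
    sharing, nonsharing = _split(tkey, members)
    return Neighborhood(
        target=tkey,
        ontology=ontology,
        k=k,
        members=members,
        similarities=tuple(float(sims[i]) for i in order),
        sharing=sharing,
        nonsharing=nonsharing,
    )


def all_k_neighborhoods(
    pool: Iterable,
    arch_emb: ArchitectureEmbedding,
    k: int,
    ontology: str | None = None,
) -> dict[DAKey, Neighborhood]:
    """k-neighborhood of every pool member against the rest of the pool.

    Vectorized over the full cosine matrix; per-row ties break by
    lexicographic DA key, identical to :func:`k_neighborhood`.
    """
    pool_keys = sorted({_as_key(p) for p in pool})
    n = len(pool_keys)
    if n < 2:
        raise ValueError("pool must contain at least two architectures")
    mat = _normalize_rows(np.array([arch_emb.vector(p) for p in pool_keys]))
    sims = mat @ mat.T
    lex = np.arange(n)  # pool_keys already lexicographically sorted
    out: dict[DAKey, Neighborhood] = {}
    kk = min(k, n - 1)
    for i, tkey in enumerate(pool_keys):
        row = sims[i].copy()
        row[i] = -np.inf  # exclude self
        order = np.lexsort((lex, -row))[:kk]
        members = tuple(pool_keys[j] for j in order)
        sharing, nonsharing = _split(tkey, members)
        out[tkey] = Neighborhood(
            target=tkey,
            ontology=ontology,
            k=k,
            members=members,
            similarities=tuple(float(row[j]) for j in order),
            sharing=sharing,
            nonsharing=nonsharing,
        )
    return out


def jaccard_k_neighborhood(
    target, pool: Iterable, k: int, ontology: str | None = None
) -> Neighborhood:
    """Top-k pool members by content Jaccard; only S_J > 0 candidates rank.

    All members share ≥1 domain with the target by construction, so the
    non-sharing subset is empty; if fewer than k candidates share any
    domain, the neighborhood truncates to those.
    """
    tkey = _as_key(target)
    pool_keys = sorted({_as_key(p) for p in pool} - {tkey})
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [(content_jaccard(tkey, p), p) for p in pool_keys]
    scored = [(s, p) for s, p in scored if s > 0.0]
    scored.sort(key=lambda sp: (-sp[0], sp[1]))
    if len(scored) < k:
        logger.debug(
            "jaccard_k_neighborhood: only %d sharing candidates for k=%d", len(scored), k
        )
    top = scored[:k]
    members = tuple(p for _, p in top)
    return Neighborhood(
        target=tkey,
        ontology=ontology,
        k=k,
        members=members,
        similarities=tuple(s for s, _ in top),
        sharing=members,
        nonsharing=(),
    )


def all_jaccard_neighborhoods(
    pool: Iterable, k: int, ontology: str | None = None
) -> dict[DAKey, Neighborhood]:
    """Jaccard-control neighborhoods for every pool member.

    Uses an inverted domain → DA index so only candidates that actually
    share a domain with the target are scored.
    """
    pool_keys = sorted({_as_key(p) for p in pool})
    inverted: dict[str, set[int]] = {}
    counters = [Counter(p) for p in pool_keys]
    for i, p in enumerate(pool_keys):
        for d in set(p):
            inverted.setdefault(d, set()).add(i)
    out: dict[DAKey, Neighborhood] = {}
    for i, tkey in enumerate(pool_keys):
        ct = counters[i]
        cand = set().union(*(inverted[d] for d in ct)) - {i}
        scored = []
        for j in cand:
            cj = counters[j]
            nij = sum(min(c, cj[d]) for d, c in ct.items() if d in cj)
            scored.append((nij / (len(tkey) + len(pool_keys[j]) - nij), pool_keys[j]))
        scored.sort(key=lambda sp: (-sp[0], sp[1]))
        top = scored[:k]
        members = tuple(p for _, p in top)
        out[tkey] = Neighborhood(
            target=tkey,
            ontology=ontology,
            k=k,
            members=members,
            similarities=tuple(s for s, _ in top),
            sharing=members,
            nonsharing=(),
        )
    return out


def write_neighborhoods_tsv(hoods: Mapping[DAKey, Neighborhood], path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("target\trank\tneighbor\tsimilarity\tcontent_jaccard\tsharing\n")
        for tkey in sorted(hoods):
            h = hoods[tkey]
            for r, (mkey, s) in enumerate(zip(h.members, h.similarities), start=1):
                sj = content_jaccard(tkey, mkey)
                fh.write(
                    f"{'-'.join(tkey)}\t{r}\t{'-'.join(mkey)}\t{s:.6f}\t{sj:.6f}\t{int(sj > 0)}\n"
                )
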