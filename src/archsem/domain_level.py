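"""Domain-level (rather than architecture-level) embedding evaluation.

In the absence of a domain-specific function ontology, each domain is
annotated with the union of the GO term sets of every annotated
architecture that harbors it.  Annotation transfer is then scored exactly
as at the architecture level — k nearest annotated domains by cosine in
the *domain* embedding, neighbor-union prediction, precision/recall/MCC —
which lets the contextual information carried by architecture embeddings
be compared with what the domain vectors encode on their own.  Domains
occurring only in unannotated architectures receive empty sets and are
excluded from the evaluation pool (exclusions are counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import AnnotationMap, Corpus
from .embeddings import DomainEmbedding
from .function_metrics import TransferScores, _contingency_scores
from .neighborhoods import _normalize_rows

logger = logging.getLogger("archsem")


@dataclass
class DomainAnnotationMap:
    """domain → GO term set (union over annotated DAs containing it)."""

    ontology: str
    terms_for: dict[str, frozenset[str]]
    n_excluded: int = 0  # domains seen only in unannotated DAs


def annotate_domains(corpus: Corpus, ann: AnnotationMap) -> DomainAnnotationMap:
    """Union semantics: terms_for(d) = ∪ { F_O(A) : A ∋ d, A annotated }."""
    acc: dict[str, set[str]] = {d: set() for d in corpus.vocabulary}
    for arch in corpus.architectures:
        terms = ann.get(arch.domains)
        if not terms:
            continue
        for d in set(arch.domains):
            acc[d].update(terms)
    terms_for = {d: frozenset(t) for d, t in acc.items() if t}
    n_excluded = len(acc) - len(terms_for)
    if n_excluded:
        logger.info(
            "annotate_domains[%s]: %d domains only in unannotated DAs excluded",
            ann.ontology,
            n_excluded,
        )
    return DomainAnnotationMap(
        ontology=ann.ontology, terms_for=terms_for, n_excluded=n_excluded
    )


def domain_knn_eval(
    emb: DomainEmbedding,
    dann: DomainAnnotationMap,
    k: int,
    vocab: frozenset[str] | None = None,
) -> TransferScores:
    """Macro precision/recall/MCC of GO transfer between nearest domains.

    Pool = annotated domains; neighbors by cosine of domain vectors, ties
    broken by domain identifier.  ``vocab`` defaults to the union of all
    domain term sets (mirroring the architecture-level universe choice).
    """
    domains = sorted(d for d in dann.terms_for if d in emb)
    if len(domains) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} annotated domains, have {len(domains)}")
    universe = vocab if vocab is not None else frozenset().union(*dann.terms_for.values())
    n_vocab = len(universe)
    mat = _normalize_rows(np.array([emb.vector(d) for d in domains]))
    sims = mat @ mat.T
    lex = np.arange(len(domains))
    rows = []
    for i, d in enumerate(domains):
        row = sims[i].copy()
        row[i] = -np.inf
        order = np.lexsort((lex, -row))[:k]
        P: set[str] = set()
        for j in order:
            P.update(dann.terms_for[domains[j]])
        p, r, m = _contingency_scores(dann.terms_for[d], frozenset(P), n_vocab)
        rows.append((d, p, r, m))
    df = pd.DataFrame(rows, columns=["domain", "precision", "recall", "mcc"])
    return TransferScores(
        precision=float(df["precision"].mean()),
        recall=float(df["recall"].mean()),
        mcc=float(df["mcc"].mean()),
        n_targets=len(df),
        n_excluded=dann.n_excluded,
        per_target=df,
    )
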