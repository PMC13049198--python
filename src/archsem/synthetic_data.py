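"""Seeded synthetic corpora of domain architectures with planted structure.

The generator emulates the statistical shape of a single-proteome corpus of
unique domain architectures (DAs): ~5000 unique DAs over ~1000 domain
superfamilies, a right-skewed length distribution (median 3, mean ≈ 4.2),
and promiscuous domains (a heavy-tailed domain usage law).

On top of the background it plants *synonym groups*: small sets of domains
that are functionally interchangeable and appear in the same flanking
context — the "domain vocabulary problem" in miniature.  Synonym-bearing
DAs are instantiated from *templates*, sequences of synonym-group slots;
each slot independently picks a group member.  Two instantiations of one
template that disagree at every slot share no domain yet carry identical
function blocks, giving ground-truth non-sharing pairs with functional
similarity 1 (at zero annotation noise).

Annotations are GO-like: each domain (or synonym group) owns a *function
block* of terms in each of three namespaces (MF/BP/CC) drawn from a random
rooted DAG; a DA is annotated with the ancestor closure of the union of its
domains' blocks.  A *null mode* severs annotation from architecture
entirely (each DA draws i.i.d. random blocks), for calibrating the
randomization tests downstream.

The same data can be emitted in the on-disk formats the real pipeline
reads (assignment TSV, OBO, association TSV), so the whole analysis is
testable end-to-end through its real readers.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .corpus_io import (
    AnnotationMap,
    Corpus,
    DomainArchitecture,
    OntologyGraph,
    corpus_from_architectures,
    propagate_ancestors,
)

_NS_LONG = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}


@dataclass
class SynthConfig:
    """Knobs for the synthetic corpus.

    Defaults reproduce the scale of a human-proteome unique-DA corpus:
    ~5000 architectures over 1000 domains, shifted-geometric lengths with
    median 3 and mean 4.2, and a modest planted-synonym component.
    """

    n_domains: int = 1000
    n_architectures: int = 5000
    #: lengths: L = 1 + NB(nb_r, p) with p solved from length_mean, mixed
    #: with a small uniform heavy tail (tail_prob over tail_range) so the
    #: unique corpus is right-skewed with median 3 and mean ≈ 4.2.
    length_mean: float = 4.2
    nb_r: float = 3.0
    tail_prob: float = 0.03
    tail_range: tuple[int, int] = (15, 45)
    #: Zipf-like exponent for background domain usage (promiscuity).
    promiscuity_exponent: float = 0.9
    n_synonym_groups: int = 40
    synonym_group_size: int = 2
    #: fraction of architectures instantiated from synonym templates
    synonym_da_fraction: float = 0.10
    n_synonym_templates: int | None = None  # cap; None = as the budget allows
    template_max_len: int = 4
    #: probability a synonym-group member adopts its group's canonical
    #: flanking context; with 1 − fidelity it is displaced into a random
    #: background architecture instead.
    context_fidelity: float = 1.0
    #: GO-like terms per namespace and block sizes
    n_terms: int = 120
    terms_per_function_block: int = 3
    part_of_prob: float = 0.0
    extra_parent_prob: float = 0.3
    #: probability a DA gains one spurious term per namespace
    annotation_noise: float = 0.0
    namespaces: tuple[str, ...] = ("MF", "BP", "CC")
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_domains,
            self.n_architectures,
            self.n_synonym_groups,
            self.synonym_group_size,
            self.n_terms,
            self.terms_per_function_block,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for p in (
            self.context_fidelity,
            self.annotation_noise,
            self.synonym_da_fraction,
            self.part_of_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        n_syn = self.n_synonym_groups * self.synonym_group_size
        if n_syn >= self.n_domains:
            raise ValueError(
                f"vocabulary too small: {n_syn} synonym-domain slots requested "
                f"but only {self.n_domains} domains available"
            )
        if self.synonym_da_fraction > 0 and self.template_max_len > self.n_synonym_groups:
            raise ValueError(
                "template_max_len exceeds n_synonym_groups; templates draw distinct groups"
            )
        if self.length_mean <= 1:
            raise ValueError("length_mean must exceed 1")


@dataclass
class GroundTruth:
    """What was planted: synonym groups and the domain → function-block map."""

    synonym_groups: list[frozenset[str]]
    function_of_domain: dict[str, int]
    #: each template is a tuple of synonym-group indices
    templates: list[tuple[int, ...]] = field(default_factory=list)

    def template_signature(self, domains: tuple[str, ...]) -> tuple[int, ...] | None:
        """The group-index sequence of a DA if every domain is a synonym
        member, else None.  Two DAs with the same signature but disjoint
        domains are a planted synonym substitution pair."""
        member_group: dict[str, int] = {
            d: gi for gi, grp in enumerate(self.synonym_groups) for d in grp
        }
        sig = tuple(member_group.get(d, -1) for d in domains)
        return None if -1 in sig else sig


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def _draw_lengths(rng: np.random.Generator, cfg: SynthConfig, n: int) -> np.ndarray:
    """Architecture lengths: shifted NB bulk plus a small uniform heavy tail."""
    lo, hi = cfg.tail_range
    bulk_mean = (cfg.length_mean - cfg.tail_prob * (lo + hi) / 2.0) / (1.0 - cfg.tail_prob)
    if bulk_mean <= 1:
        raise ValueError("length_mean too small for the configured tail")
    p = cfg.nb_r / (cfg.nb_r + bulk_mean - 1.0)
    lengths = 1 + rng.negative_binomial(cfg.nb_r, p, size=n)
    tail = rng.random(n) < cfg.tail_prob
    lengths[tail] = rng.integers(lo, hi + 1, size=int(tail.sum()))
    return lengths


def generate_corpus(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus of unique DAs with planted synonym templates.

    The length multiset is drawn first and every generated architecture is
    unique, so the corpus reproduces the configured length law exactly.
    A ``synonym_da_fraction`` share of the lengths is spent on template
    instantiations: each template (a sequence of distinct synonym groups)
    is expanded into *all* member combinations, so at ``context_fidelity``
    1 the members of a group never co-occur yet have exactly identical
    flanking-context statistics, and every template yields non-sharing
    instantiation pairs with identical ground-truth function.  With
    fidelity < 1 a slot's member is displaced into a random background
    architecture instead of its canonical context.  Deterministic per
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    all_domains = [f"D{i:04d}" for i in range(config.n_domains)]
    n_syn = config.n_synonym_groups * config.synonym_group_size
    syn_domains = all_domains[:n_syn]
    background = np.array(all_domains[n_syn:])
    groups = [
        frozenset(syn_domains[g * config.synonym_group_size : (g + 1) * config.synonym_group_size])
        for g in range(config.n_synonym_groups)
    ]
    group_members = [sorted(g) for g in groups]

    # heavy-tailed background usage: a few promiscuous domains, many rare
    w = np.arange(1, len(background) + 1, dtype=float) ** (-config.promiscuity_exponent)
    w /= w.sum()

    lengths = list(_draw_lengths(rng, config, config.n_architectures))
    avail = Counter(lengths)
    n_singles = avail.get(1, 0)
    if n_singles > len(background):
        raise ValueError(
            f"vocabulary too small: {n_singles} single-domain architectures drawn "
            f"but only {len(background)} background domains available"
        )

    seen: set[tuple[str, ...]] = set()
    archs_keys: list[tuple[str, ...]] = []

    def _emit(doms: tuple[str, ...]) -> bool:
        if doms in seen:
            return False
        seen.add(doms)
        archs_keys.append(doms)
        return True

    # --- synonym templates: exhaustively instantiated -------------------
    templates: list[tuple[int, ...]] = []
    budget = int(round(config.synonym_da_fraction * config.n_architectures))
    strays: list[str] = []  # displaced members awaiting a random context
    gsize = config.synonym_group_size
    max_templates = config.n_synonym_templates or config.n_architectures
    while budget > 0 and len(templates) < max_templates:
        feasible = [
            L
            for L in range(2, config.template_max_len + 1)
            if gsize**L <= min(avail.get(L, 0), budget)
        ]
        if not feasible:
            break
        L = int(rng.choice(feasible))
        t = tuple(int(g) for g in rng.choice(config.n_synonym_groups, size=L, replace=False))
        combos = list(itertools.product(*(group_members[g] for g in t)))
        if any(c in seen for c in combos):
            continue  # template collides with an existing instantiation set
        templates.append(t)
        for combo in combos:
            doms = list(combo)
            for j in range(L):
                if rng.random() >= config.context_fidelity:
                    strays.append(doms[j])
                    doms[j] = str(background[int(rng.choice(len(background), p=w))])
            if _emit(tuple(doms)):
                avail[L] -= 1
                budget -= 1

    # --- background architectures ---------------------------------------
    singles = rng.choice(len(background), size=avail.get(1, 0), replace=False, p=w)
    for i in singles:
        _emit((str(background[i]),))
    avail[1] = 0
    for L in sorted(avail):
        for _ in range(avail[L]):
            for _try in range(200):
                doms = [str(d) for d in rng.choice(background, size=L, p=w)]
                if strays:
                    doms.insert(int(rng.integers(0, L + 1)), strays[-1])
                if _emit(tuple(doms)):
                    if strays:
                        strays.pop()
                    break
            else:
                raise ValueError(
                    f"could not generate a unique architecture of length {L}; "
                    "the configuration saturates the vocabulary"
                )

    corpus = corpus_from_architectures(
        DomainArchitecture(domains=k, proteins=frozenset({f"P{i:06d}"}))
        for i, k in enumerate(archs_keys)
    )
    function_of_domain: dict[str, int] = {}
    for gi, members in enumerate(group_members):
        for m in members:
            function_of_domain[m] = gi
    for j, d in enumerate(background):
        function_of_domain[d] = config.n_synonym_groups + j
    truth = GroundTruth(
        synonym_groups=groups,
        function_of_domain=function_of_domain,
        templates=templates,
    )
    return corpus, truth


# ---------------------------------------------------------------------------
# Toy ontology and annotations
# ---------------------------------------------------------------------------


def _toy_ontology(rng: np.random.Generator, cfg: SynthConfig) -> OntologyGraph:
    g = nx.DiGraph()
    namespace: dict[str, str] = {}
    for ns in cfg.namespaces:
        terms = [f"T{ns}{i:04d}" for i in range(cfg.n_terms)]
        for t in terms:
            g.add_node(t)
            namespace[t] = ns
        for i in range(1, cfg.n_terms):
            parents = {int(rng.integers(0, i))}
            if i > 1 and rng.random() < cfg.extra_parent_prob:
                parents.add(int(rng.integers(0, i)))
            for p in parents:
                rel = "part_of" if rng.random() < cfg.part_of_prob else "is_a"
                g.add_edge(terms[i], terms[p], relation=rel)
    return OntologyGraph(graph=g, namespace=namespace)


def generate_annotations(
    corpus: Corpus,
    truth: GroundTruth,
    config: SynthConfig,
    null_mode: bool = False,
) -> tuple[dict[str, AnnotationMap], OntologyGraph]:
    """Annotate each DA with the closed union of its domains' function blocks.

    Returns one :class:`AnnotationMap` per namespace plus the generated
    ontology.  Synonym-group members map to the same block, so swapping
    partners leaves term sets unchanged.  In ``null_mode`` each DA instead
    draws an i.i.d. random set of blocks, making term sets independent of
    architecture (for calibration of the randomization tests).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    graph = _toy_ontology(rng, config)
    n_blocks = max(truth.function_of_domain.values()) + 1

    # block → raw (pre-closure) terms per namespace; non-root terms only
    block_terms: dict[str, list[frozenset[str]]] = {}
    for ns in config.namespaces:
        terms = [f"T{ns}{i:04d}" for i in range(1, config.n_terms)]
        block_terms[ns] = [
            frozenset(rng.choice(terms, size=config.terms_per_function_block, replace=False))
            for _ in range(n_blocks)
        ]

    annotations: dict[str, AnnotationMap] = {}
    raw_for: dict[tuple[str, ...], dict[str, set[str]]] = {}
    for arch in corpus.architectures:
        if null_mode:
            r = 1 + int(rng.poisson(1.5))
            blocks = [int(b) for b in rng.integers(0, n_blocks, size=r)]
        else:
            blocks = [truth.function_of_domain[d] for d in arch.domains]
        per_ns: dict[str, set[str]] = {}
        for ns in config.namespaces:
            raw: set[str] = set()
            for b in blocks:
                raw.update(block_terms[ns][b])
            if config.annotation_noise and rng.random() < config.annotation_noise:
                raw.add(f"T{ns}{int(rng.integers(1, config.n_terms)):04d}")
            per_ns[ns] = raw
        raw_for[arch.domains] = per_ns

    for ns in config.namespaces:
        terms_for = {
            key: propagate_ancestors(per_ns[ns], graph)
            for key, per_ns in raw_for.items()
            if per_ns[ns]
        }
        a_o = {k for k, v in terms_for.items() if len(k) >= 2 and v}
        annotations[ns] = AnnotationMap(
            ontology=ns, terms_for=terms_for, annotated_multidomain=a_o
        )
    return annotations, graph


# ---------------------------------------------------------------------------
# File emission (round-trips through the real readers)
# ---------------------------------------------------------------------------


def write_assignments_tsv(corpus: Corpus, path: str | Path) -> None:
    """Emit per-protein domain hits with bookkeeping coordinates."""
    with Path(path).open("w") as fh:
        fh.write("protein_id\tdomain_id\tstart\tend\n")
        for arch in corpus.architectures:
            for prot in sorted(arch.proteins):
                for i, d in enumerate(arch.domains):
                    start = 1 + 120 * i
                    fh.write(f"{prot}\t{d}\t{start}\t{start + 99}\n")


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(graph.graph.nodes):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            ns = graph.namespace.get(term)
            if ns:
                fh.write(f"namespace: {_NS_LONG[ns]}\n")
            for _, parent, data in graph.graph.out_edges(term, data=True):
                if data.get("relation") == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {data.get('relation')} {parent}\n")


def write_associations_tsv(
    corpus: Corpus, annotations: Mapping[str, AnnotationMap], path: str | Path
) -> None:
    """Emit protein→GO rows; every protein of a DA inherits its DA's terms."""
    with Path(path).open("w") as fh:
        fh.write("protein_id\tgo_id\tnamespace\n")
        for arch in corpus.architectures:
            for ns in sorted(annotations):
                terms = annotations[ns].get(arch.domains)
                for prot in sorted(arch.proteins):
                    for t in sorted(terms):
                        fh.write(f"{prot}\t{t}\t{ns}\n")


def write_synthetic_dataset(
    outdir: str | Path,
    corpus: Corpus,
    annotations: Mapping[str, AnnotationMap],
    graph: OntologyGraph,
) -> dict[str, Path]:
    """Write the three input files the real pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": outdir / "assignments.tsv",
        "obo": outdir / "ontology.obo",
        "associations": outdir / "associations.tsv",
    }
    write_assignments_tsv(corpus, paths["assignments"])
    write_obo(graph, paths["obo"])
    write_associations_tsv(corpus, annotations, paths["associations"])
    return paths
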