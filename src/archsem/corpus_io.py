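"""Build an annotated corpus of unique domain architectures.

A *domain architecture* (DA) is the N→C ordered sequence of structural
domains (here: SCOP/SUPERFAMILY superfamily identifiers) detected on a
protein.  The analysis operates on the set of *unique* DAs of a proteome:
paralogous proteins with identical architectures collapse to a single
corpus entry, so that repeated observations of the same evolutionary event
do not inflate co-occurrence counts.

This module parses per-protein domain assignments (SUPERFAMILY
self-assignment style TSV), extracts and deduplicates architectures, loads
a Gene Ontology graph (OBO, ``is_a``/``part_of`` edges only), and maps DAs
to ancestor-closed GO term sets per sub-ontology using a majority rule:
a DA inherits a term when at least half of its member proteins carry it.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

logger = logging.getLogger("archsem")

#: GO relations retained when building the ontology graph.
GO_RELATIONS = ("is_a", "part_of")

#: The generic "protein binding" MF term; DAs annotated with nothing beyond
#: this term (and its ancestors) are uninformative and excluded from the
#: molecular-function evaluation set.
PROTEIN_BINDING = "GO:0005515"

NAMESPACES = ("MF", "BP", "CC")

_OBO_NAMESPACE = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainHit:
    """One domain assignment on a protein (1-based, inclusive coordinates)."""

    protein_id: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"hit {self.protein_id}/{self.domain_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True, eq=False)
class DomainArchitecture:
    """An ordered domain string plus the proteins exhibiting it.

    Equality and hashing are on the domain sequence only: two DAs are the
    same architecture iff their domain strings match in order and
    multiplicity, regardless of which proteins carry them.
    """

    domains: tuple[str, ...]
    proteins: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.domains) < 1:
            raise ValueError("a domain architecture has at least one domain")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainArchitecture):
            return NotImplemented
        return self.domains == other.domains

    def __hash__(self) -> int:
        return hash(self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def __str__(self) -> str:
        return "-".join(self.domains)


#: DAs are keyed throughout by their domain tuple.
DAKey = tuple[str, ...]


@dataclass
class Corpus:
    """The deduplicated set of unique DAs with co-occurrence counts.

    ``unigram_counts`` and ``bigram_counts`` are computed over the set of
    unique DAs, each counted once; bigrams are ordered, adjacent pairs.
    ``architectures`` is sorted lexicographically by domain tuple so that
    every downstream ordering is deterministic.
    """

    architectures: list[DomainArchitecture]
    vocabulary: frozenset[str]
    unigram_counts: Counter
    bigram_counts: Counter
    _index: dict[DAKey, DomainArchitecture] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {a.domains: a for a in self.architectures}

    @property
    def N(self) -> int:
        return len(self.architectures)

    def __contains__(self, key: DAKey) -> bool:
        return tuple(key) in self._index

    def __getitem__(self, key: DAKey) -> DomainArchitecture:
        return self._index[tuple(key)]

    def keys(self) -> list[DAKey]:
        return [a.domains for a in self.architectures]


@dataclass
class OntologyGraph:
    """A GO DAG restricted to ``is_a``/``part_of`` edges (child → parent)."""

    graph: nx.DiGraph
    namespace: dict[str, str]
    _closure_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` via is_a/part_of (excl. term)."""
        cached = self._closure_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term))
            self._closure_cache[term] = cached
        return cached

    def roots(self, ns: str | None = None) -> set[str]:
        """Terms with no parent (per namespace if given)."""
        out = {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}
        if ns is not None:
            out = {t for t in out if self.namespace.get(t) == ns}
        return out


@dataclass
class AnnotationMap:
    """DA → ancestor-closed GO term sets for one sub-ontology.

    ``annotated_multidomain`` (the evaluation set A_O) holds the keys of
    DAs with ≥2 domains and ≥1 kept term.
    """

    ontology: str
    terms_for: dict[DAKey, frozenset[str]]
    annotated_multidomain: set[DAKey]

    def __contains__(self, key: DAKey) -> bool:
        return tuple(key) in self.terms_for

    def get(self, key: DAKey) -> frozenset[str]:
        return self.terms_for.get(tuple(key), frozenset())


# ---------------------------------------------------------------------------
# Parsing and corpus construction
# ---------------------------------------------------------------------------


def parse_domain_assignments(path: str | Path) -> list[DomainHit]:
    """Read tab-delimited domain hits (protein, domain, start, end).

    A header line is tolerated; malformed rows (wrong arity, non-integer
    coordinates, start > end, empty domain) are skipped and counted in a
    single warning.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    n_bad = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                n_bad += 1
                continue
            prot, dom, s, e = parts[0].strip(), parts[1].strip(), parts[2], parts[3]
            try:
                start, end = int(s), int(e)
            except ValueError:
                if lineno == 0:
                    continue  # header
                n_bad += 1
                continue
            try:
                hits.append(DomainHit(prot, dom, start, end))
            except ValueError:
                n_bad += 1
    if n_bad:
        logger.warning("parse_domain_assignments: skipped %d malformed rows in %s", n_bad, path)
    return hits


def extract_architectures(hits: Iterable[DomainHit]) -> dict[str, DomainArchitecture]:
    """Concatenate each protein's hits, N→C, into its domain architecture.

    Hits are ordered by ascending start; ties break by ascending end, then
    by domain identifier, so overlapping assignments yield a deterministic
    architecture.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: dict[str, DomainArchitecture] = {}
    for prot, phits in by_protein.items():
        phits.sort(key=lambda h: (h.start, h.end, h.domain_id))
        out[prot] = DomainArchitecture(
            domains=tuple(h.domain_id for h in phits), proteins=frozenset({prot})
        )
    return out


def corpus_from_architectures(archs: Iterable[DomainArchitecture]) -> Corpus:
    """Collapse identical domain strings and count n-grams over unique DAs."""
    merged: dict[DAKey, set[str]] = {}
    for a in archs:
        merged.setdefault(a.domains, set()).update(a.proteins)
    unique = [
        DomainArchitecture(domains=k, proteins=frozenset(v))
        for k, v in sorted(merged.items())
    ]
    unigrams: Counter = Counter()
    bigrams: Counter = Counter()
    vocab: set[str] = set()
    for a in unique:
        unigrams.update(a.domains)
        bigrams.update(zip(a.domains, a.domains[1:]))
        vocab.update(a.domains)
    return Corpus(
        architectures=unique,
        vocabulary=frozenset(vocab),
        unigram_counts=unigrams,
        bigram_counts=bigrams,
    )


def deduplicate(per_protein: Mapping[str, DomainArchitecture]) -> Corpus:
    """Build the corpus of unique DAs from per-protein architectures."""
    return corpus_from_architectures(per_protein.values())


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


def load_ontology(path: str | Path) -> OntologyGraph:
    """Load an OBO file, keeping only is_a/part_of edges and live terms."""
    raw = obonet.read_obo(str(path))  # drops obsolete terms by default
    g = nx.DiGraph()
    namespace: dict[str, str] = {}
    for node, data in raw.nodes(data=True):
        g.add_node(node)
        ns = data.get("namespace")
        if ns in _OBO_NAMESPACE:
            namespace[node] = _OBO_NAMESPACE[ns]
    for child, parent, rel in raw.edges(keys=True):
        if rel in GO_RELATIONS:
            g.add_edge(child, parent, relation=rel)
    g.remove_nodes_from([n for n in list(g.nodes) if n not in raw.nodes])
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError(f"ontology {path} contains a cycle among is_a/part_of edges")
    return OntologyGraph(graph=g, namespace=namespace)


def propagate_ancestors(terms: Iterable[str], graph: OntologyGraph) -> frozenset[str]:
    """Close a term set under is_a/part_of ancestor propagation.

    Terms absent from the graph are logged and passed through unexpanded.
    """
    out: set[str] = set()
    for t in terms:
        out.add(t)
        if t in graph.graph:
            out.update(graph.ancestors(t))
        else:
            logger.debug("propagate_ancestors: unknown term %s passed through", t)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def annotate_architectures(
    corpus: Corpus,
    protein_go: Mapping[str, Iterable[str]],
    graph: OntologyGraph,
    ontology: str,
    threshold: float = 0.5,
    exclude_roots: bool = False,
) -> AnnotationMap:
    """Map each unique DA to the GO terms carried by ≥``threshold`` of its proteins.

    Per protein, terms are restricted to the requested sub-ontology and
    ancestor-closed before voting, so an ancestor inherited through any
    child counts toward the majority.  The threshold is inclusive: a term
    present in exactly half of the proteins is kept.  For MF, DAs whose
    kept set is exactly the closure of GO:0005515 (protein binding) are
    dropped entirely.  The evaluation set ``annotated_multidomain`` keeps
    DAs with ≥2 domains and ≥1 term.
    """
    if ontology not in NAMESPACES:
        raise ValueError(f"unknown ontology {ontology!r}")
    roots = graph.roots(ontology) if exclude_roots else frozenset()

    def _closed(terms: Iterable[str]) -> frozenset[str]:
        ns_terms = [t for t in terms if graph.namespace.get(t) == ontology]
        closed = propagate_ancestors(ns_terms, graph)
        closed = frozenset(t for t in closed if graph.namespace.get(t) == ontology)
        return closed - roots if exclude_roots else closed

    binding_closure = (
        _closed({PROTEIN_BINDING}) if PROTEIN_BINDING in graph.graph else frozenset()
    )

    terms_for: dict[DAKey, frozenset[str]] = {}
    a_o: set[DAKey] = set()
    for arch in corpus.architectures:
        votes: Counter = Counter()
        n_prot = len(arch.proteins)
        if n_prot == 0:
            continue
        for prot in arch.proteins:
            votes.update(_closed(protein_go.get(prot, ())))
        kept = frozenset(t for t, c in votes.items() if c / n_prot >= threshold)
        if not kept:
            continue
        if ontology == "MF" and binding_closure and kept == binding_closure:
            continue  # only generic protein-binding: uninformative, removed
        terms_for[arch.domains] = kept
        if len(arch) >= 2:
            a_o.add(arch.domains)
    return AnnotationMap(ontology=ontology, terms_for=terms_for, annotated_multidomain=a_o)


def read_associations(path: str | Path) -> dict[str, set[str]]:
    """Read a tab-delimited protein→GO association table.

    Columns: protein_id, GO id[, namespace ignored].  One row per pair.
    """
    out: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                continue
            if not parts[1].strip()[0].isalpha() and ":" not in parts[1]:
                continue
            out.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return out


# ---------------------------------------------------------------------------
# Serialization and summary statistics
# ---------------------------------------------------------------------------


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a in corpus.architectures:
            fh.write(
                json.dumps({"domains": list(a.domains), "proteins": sorted(a.proteins)})
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> Corpus:
    archs = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            archs.append(
                DomainArchitecture(
                    domains=tuple(rec["domains"]), proteins=frozenset(rec["proteins"])
                )
            )
    return corpus_from_architectures(archs)


def write_annotations_tsv(ann: AnnotationMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("architecture\tontology\tterms\n")
        for key in sorted(ann.terms_for):
            fh.write(
                "-".join(key) + f"\t{ann.ontology}\t" + ";".join(sorted(ann.terms_for[key])) + "\n"
            )


def read_annotations_tsv(path: str | Path) -> AnnotationMap:
    terms_for: dict[DAKey, frozenset[str]] = {}
    ontology = ""
    with Path(path).open() as fh:
        header = fh.readline()
        for line in fh:
            arch_s, ontology, terms_s = line.rstrip("\n").split("\t")
            key = tuple(arch_s.split("-"))
            terms_for[key] = frozenset(terms_s.split(";")) if terms_s else frozenset()
    a_o = {k for k, v in terms_for.items() if len(k) >= 2 and v}
    return AnnotationMap(ontology=ontology, terms_for=terms_for, annotated_multidomain=a_o)


def corpus_statistics(
    corpus: Corpus, annotations: Mapping[str, AnnotationMap] | None = None
) -> dict[str, float]:
    """Summary statistics of a corpus (and optionally its annotations).

    Reports the unique-DA count N, vocabulary size |D|, length summaries,
    and per-ontology annotated counts — the quantities used to sanity-check
    a corpus against its source proteome.
    """
    import numpy as np

    lengths = np.array([len(a) for a in corpus.architectures])
    stats: dict[str, float] = {
        "n_unique_architectures": corpus.N,
        "vocabulary_size": len(corpus.vocabulary),
        "mean_length": float(lengths.mean()) if corpus.N else 0.0,
        "median_length": float(np.median(lengths)) if corpus.N else 0.0,
        "max_length": int(lengths.max()) if corpus.N else 0,
        "n_length_le_30": int((lengths <= 30).sum()),
    }
    if annotations:
        annotated_any: set[DAKey] = set()
        for ns, ann in annotations.items():
            stats[f"n_annotated_{ns}"] = len(
                [k for k, v in ann.terms_for.items() if v]
            )
            stats[f"n_terms_{ns}"] = len(set().union(*ann.terms_for.values())) if ann.terms_for else 0
            stats[f"n_annotated_multidomain_{ns}"] = len(ann.annotated_multidomain)
            annotated_any.update(k for k, v in ann.terms_for.items() if v)
        stats["n_annotated_any"] = len(annotated_any)
    return stats
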