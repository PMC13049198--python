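# archsem — vector semantics of multidomain protein architectures

Multidomain proteins are mosaics of *domains* — structural modules that
recur, in different combinations, across otherwise unrelated proteins.
The *domain architecture* (DA) of a protein is its domains in N→C order,
e.g. `L27-L27-PDZ-SH3-GuK` for a MAGuK-family protein.  Whether a domain
contributes the same function in every context, or whether its functional
role depends on its neighboring domains, is an open question with direct
consequences for protein function prediction.

`archsem` treats architectures as sentences of domain "words" and applies
vector-semantic models from natural language processing to a corpus of
unique DAs from a single proteome.  It is written for computational
biologists studying domain architecture evolution and domain-based
function annotation.

## The models

**Domain embeddings.**  Each domain Dᵢ ∈ D gets a vector e(Dᵢ):

* *PMI* — coordinate j is the pointwise mutual information of the ordered
  adjacent pair DᵢDⱼ,

  PMI(Dᵢ,Dⱼ) = log₂ [ P(Dᵢ,Dⱼ) / (P(Dᵢ)·P(Dⱼ)) ],

  with a pseudocount ψ = 0.0009 added to every ordered pair count.
  Negative values (under-represented pairs) are kept; m = |D|.
* *TF-IDF* — coordinate j is tf(Dᵢ,Aⱼ) · N/df(Dᵢ), the copy count of Dᵢ
  in architecture Aⱼ weighted by the plain inverse document frequency
  (no logarithm); m = N.
* *word2vec skip-gram* — negative-sampling skip-gram trained on the
  unique DAs for 15 epochs, with m ∈ {5, 10, 100} and window w ∈ {1, 5}
  (models named `w2v(m,w)`); windows truncate at architecture ends and
  no domain is dropped (min-count 1).

**Architecture embeddings.**  v(A) = (1/n) Σᵢ e(Dᵢ) over the n domains of
A, repeats included.  Proximity is cosine similarity S_C; the
domain-content control is the multiset Jaccard S_J(Aᵢ,Aⱼ) =
nᵢⱼ/(nᵢ+nⱼ−nᵢⱼ), where nᵢⱼ counts shared domain copies.

**Evaluation.**  Per sub-ontology O ∈ {MF, BP, CC}, each DA is annotated
with the GO terms carried by ≥50 % of its proteins, ancestor-closed over
is_a/part_of; the evaluation set A_O holds annotated DAs with ≥2 domains.
For each target, its k nearest annotated neighbors split into *sharing*
(S_J > 0) and *non-sharing* (S_J = 0) subsets.  Functional similarity
S_F is the Jaccard of term sets; annotation transfer from the neighbor
union is scored with precision, recall and MCC.  A randomization test
asks whether non-sharing nearest neighbors are more functionally similar
than random domain-disjoint partners, using two statistics (count of
pairs with S_F > 0.8, and mean S_F) with empirical p-values from
resampled null replicates and Benjamini–Hochberg correction.

A seeded synthetic generator reproduces the corpus scale of the human
proteome (~5000 unique DAs over ~1000 domains, median length 3, mean
≈ 4.2) and plants *synonym groups* — interchangeable domains sharing
flanking context and function — so the whole pipeline is testable
without downloads, including power (planted-synonym recovery) and
type-I error (annotations independent of architecture).

## Worked example

```python
from archsem import *
from archsem.synthetic_data import SynthConfig
from archsem.neighborhoods import all_k_neighborhoods
from archsem.null_tests import nonsharing_targets, randomization_test

cfg = SynthConfig(n_architectures=1000, n_domains=300, n_synonym_groups=15, seed=42)
corpus, truth = generate_corpus(cfg)
annotations, graph = generate_annotations(corpus, truth, cfg)
ann = annotations["MF"]

emb = pmi_embedding(corpus)                      # psi = 0.0009
arch = architecture_embedding(corpus, emb)
hoods = all_k_neighborhoods(sorted(ann.annotated_multidomain), arch, k=1, ontology="MF")

scores = transfer_scores(hoods, ann, subset="sharing")
pairs = nonsharing_targets(hoods)
results = randomization_test(pairs, ann.annotated_multidomain, ann,
                             replicates=10_000, seed=1, ontology="MF", embedding="pmi")
```

printed output:

```
corpus: N=1000 unique architectures, |D|=297 domains
annotated multidomain architectures (MF): 798
sharing k=1 transfer: precision=0.765 recall=0.809 MCC=0.665
count_above_threshold: observed=10.000 expected=0.014 p=0.0000 (n_pairs=21)
mean_similarity: observed=0.659 expected=0.365 p=0.0000 (n_pairs=21)
```

Reading: the nearest sharing neighbor recovers a target's GO terms with
MCC 0.665; 21 targets have a domain-disjoint nearest neighbor, and 10 of
those pairs exceed functional similarity 0.8 where only 0.014 would be
expected by chance — the embedding has found the planted domain
"synonyms" from co-occurrence context alone.

## Command line

```sh
archsem simulate --seed 3 --out data/synth          # emit input files
archsem run-all --config config.yaml                # full pipeline
```

`run-all` executes corpus → annotations → embeddings → neighborhoods →
transfer/consistency metrics → randomization tests → domain-level
comparison, writing TSV report tables and a manifest with the resolved
configuration.  `build-corpus`, `embed`, `neighbors`, `evaluate`,
`nulltest` and `domain-eval` re-run single stages from serialized
artifacts.  Real-proteome inputs are a tab-delimited domain assignment
file (protein, superfamily, start, end), a GO OBO file, and a
protein→GO association table.

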