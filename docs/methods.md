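# Methods

This note records the models implemented in `archsem`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions a user should know before
interpreting output.

## Corpus model

The unit of analysis is the *unique* domain architecture: proteins with
identical domain strings collapse to one corpus entry carrying the union
of their protein identifiers.  Working on unique DAs avoids counting a
duplicated gene (or a vertically inherited architecture) as repeated
independent observations of domain co-occurrence.  All n-gram statistics
(unigram frequencies, ordered adjacent bigram counts) are computed over
the unique set, each architecture counted once.

Domain hits are ordered by ascending start coordinate; ties break by end
coordinate, then domain identifier.  Overlapping hits are kept — domain
assignment pipelines occasionally emit them and there is no principled
resolution at this level of abstraction.

### GO annotation

Per sub-ontology (MF/BP/CC), a DA inherits a GO term when at least 50 %
of its member proteins carry it, the threshold being inclusive (a term
in exactly half the proteins is kept).  Per-protein term sets are
restricted to the namespace and closed over `is_a`/`part_of` ancestors
*before* voting, so support inherited through different child terms
accumulates.  Namespace roots are retained in closed sets by default;
`exclude_roots=True` drops them, since root terms inflate baseline
similarity (the default mirrors plain ancestor expansion with no
exclusions).  MF sets consisting exactly of the closure of protein
binding (GO:0005515) are removed — such annotations are uninformative.
The evaluation set A_O contains annotated DAs with ≥2 domains.

Two denominators are unknowable from first principles and are documented
choices: the 50 % rule counts *all* proteins mapped to a DA (isoforms
included), and evidence codes are not filtered.

## Embeddings

**PMI** uses ordered *adjacent* pairs by default, consistent with the
windowed-context framing of the other models; `pairs="all_ordered"`
switches to all ordered within-architecture pairs.  The pseudocount
ψ = 0.0009 is added to every ordered pair count in D × D and the joint
table renormalized; marginals are raw unigram frequencies with no
pseudocount.  Negative PMI values are retained: at this corpus scale,
under-representation of a pair is signal, and underflow is not a
concern.  With ψ = 0 an unobserved pair produces −inf and a warning.

**TF-IDF** implements idf(Dᵢ) = N/df(Dᵢ) *without* the classical
logarithm, deliberately; `log_idf=True` provides the classical variant
for comparison.  Columns follow the corpus's fixed lexicographic DA
ordering, so matrices are reproducible byte for byte.

**Skip-gram** is a from-scratch word2vec SGNS trainer (numpy): reduced
window b ~ U{1..w} per position, windows truncated at architecture ends,
negative sampling from the unigram^0.75 distribution (5 negatives),
linear learning-rate decay from 0.025, min-count 1 so none of a
~1000-domain vocabulary is dropped, single-threaded with one seeded
generator — runs are bitwise reproducible, unlike multi-worker trainers.
Hierarchical softmax was not implemented; negative sampling is the
common default at this scale.

**Architecture embedding** is the arithmetic mean of constituent domain
vectors with multiplicity.  It is order-invariant: two architectures
with the same domain multiset get identical vectors, and only the
skip-gram *training* ever sees domain order.  This is a known limitation
of averaging-based document embeddings, inherited deliberately.

## Neighborhoods

Cosine k-nearest neighborhoods are computed exactly (pools are a few
thousand DAs; no approximate indexing).  The pool per ontology is A_O
minus the target.  Ties in similarity break by lexicographic DA key —
arbitrary tie-breaking has negligible effect on the aggregate metrics,
and determinism makes every table reproducible.  A zero-norm vector has
cosine 0 to everything by convention.  When a pool is smaller than k the
neighborhood truncates, with the requested k recorded separately.

The Jaccard control ranks candidates by multiset content similarity; a
candidate sharing no domain is never selected, so control neighborhoods
have an empty non-sharing subset by construction.  In a unique-DA corpus
S_J = 1 against the target can only come from a *permuted* architecture
(same multiset, different order).

## Transfer scoring

For target terms T and neighbor-union prediction P, the contingency is
TP = |T∩P|, FP = |P\T|, FN = |T\P|, TN = |U| − |T∪P| where the universe
U defaults to the set of terms annotated to ≥1 DA in that ontology.  The
choice of U is the one genuinely underdetermined element of MCC here; a
`vocab` argument lets callers substitute the full namespace.  MCC is 0
when any marginal is zero.  Per-target scores are macro-averaged;
targets with empty member sets or empty term sets are excluded and
counted, never imputed as zero.  Consistency metrics (distinct-term
count, mean pairwise S_F) require ≥1 and ≥2 sharing members
respectively, excluded per metric otherwise.

Length dependence is ordinary least squares of target–neighbor S_F on a
covariate (architecture length or term-set size), reported as R²; a
constant covariate leaves R² undefined (NaN), and ≥3 observations are
required.

## Randomization test

A_O− holds targets whose k = 1 nearest annotated neighbor shares no
domain.  Statistics over the genuine pairs: the count with S_F strictly
above 0.8, and the mean S_F.  The 0.8 threshold matches the typical
similarity of *sharing* nearest neighbors, so the count statistic asks
how many non-sharing pairs look as similar as sharing ones; the
comparison at exact ties is strict.  Null replicates resample, per
target independently and with replacement, a partner uniform over all
pool DAs sharing no domain with it; targets with no disjoint candidate
are skipped and logged.  p = (# replicates strictly greater than
observed)/R, with an optional (b+1)/(R+1) estimator off by default.
R defaults to 100 000 for full runs; tests and the acceptance script use
10 000 for speed.  Benjamini–Hochberg correction is applied per
statistic across the embedding × ontology family; the correction method
and family definition are recorded in the output and pluggable, as
neither is canonical.

## Synthetic data

The generator reproduces the *statistics the analysis is sensitive to*:
corpus scale (5000 unique DAs, ~1000 domains), a right-skewed length law
(the length multiset is drawn first — shifted negative binomial, r = 3,
mean 4.2, plus a 3 % uniform tail over 15–45 — and unique architectures
are built to match it exactly, so median 3 and mean ≈ 4.2 hold by
construction), domain promiscuity (Zipf-like background usage,
exponent 0.9), and planted *synonym groups*.

Synonym structure: a template is a sequence of distinct synonym groups;
every template is instantiated with **all** member combinations, so at
`context_fidelity = 1` the members of a group never co-occur, have
exactly identical flanking-context statistics, and every template
contributes non-sharing instantiation pairs whose ground-truth function
blocks are identical (functional similarity 1 at zero annotation noise).
With fidelity < 1 a slot's member is displaced into a random background
architecture instead of its canonical context.  About 10 % of
architectures are template instantiations by default.

Annotations: each domain (each synonym *group*) owns a block of terms
per namespace drawn from a random rooted DAG (is_a edges by default,
part_of optional); a DA's terms are the ancestor closure of its domains'
blocks, plus optional noise terms.  *Null mode* severs annotation from
architecture: each DA draws an i.i.d. random number of random blocks
(1 + Poisson(1.5)), independent of its length and content — this, rather
than a shuffle of the domain→block map, is what makes downstream
p-values uniform, because a shuffle would still couple term sets to
shared domain content.

What the generator does **not** emulate: real GO term depth and
information content, evidence-code structure, isoform inflation,
correlated annotation error, very long repeat architectures (max ~45 vs
249 in the human corpus), and realistic annotation sparsity (every
synthetic DA is annotated).  Passing tests therefore demonstrate
correctness and statistical calibration of the machinery, not biological
conclusions about any proteome.

## Calibration findings worth knowing

* The randomization test's type-I error at α = 0.05 is nominal under
  null-mode annotations (≈ 0.03–0.05 in 200-run calibrations) and its
  p-values pass a KS uniformity check.
* Domain-level evaluation (terms = union over architectures containing
  the domain) carries a structural MCC floor of ≈ 0.2–0.3 even when
  annotations are independent of architecture, because union-set *size*
  tracks domain promiscuity, which embeddings also encode; a random
  embedding scores nearly the same.  Domain-level MCC values should be
  read against that floor, not against zero.  Architecture-level
  transfer exceeds domain-level transfer at matched settings in every
  configuration tested.

## Problem sizes

Default test and acceptance runs use corpora of 200–5000 architectures,
10 000 null replicates, and the full eight-embedding grid at study scale
(the acceptance script completes in a few minutes on one core).  These
sizes were chosen as the smallest at which the corpus statistics and
test calibrations are stable.
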