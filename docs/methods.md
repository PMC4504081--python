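# Methods

This note documents the models and procedures implemented in `ontoqa`,
the parameters that matter, the synthetic study conditions, and the
design choices made where the design was genuinely open.

## Ontology graph and cycle breaking

The ontology graph has one node per class, one edge per subclass axiom
directed parent → child, and one edge per object property directed
domain → range.  With subclass edges oriented this way, an *ancestor* of
a class is any node with a directed path to it, which is what the LCA
machinery needs.  Datatype properties do not become edges; they surface
only as predicates in FILTER-bearing triples (an open design point — the
alternative of making them edges would put literal-valued nodes on
association paths, where they cannot chain further).

When instance data is supplied, each property edge carries an
`instantiated` flag (at least one data triple uses the predicate).
Uninstantiated edges are retained but deprioritized during path
selection rather than removed: removal would make schema-only
deployments behave differently from data-backed ones, and preference at
equal path length achieves the intended emphasis on relationships the
data actually realizes.

Ontology graphs with named properties are usually cyclic; the LCA
precomputation requires a DAG.  The transformation regenerates the graph
depth-first from the root, nodes and out-edges in lexicographic order
(the order is a free choice; fixing it makes the transformation, and
hence the LCA table, reproducible).  An edge whose insertion would close
a directed cycle is rerouted to a split copy of its target named
`<original>_<k>`; split copies carry no outgoing edges, so every input
edge appears exactly once and projecting splits through the provenance
map recovers the input edge multiset exactly — the invariant the test
suite checks on random cyclic graphs.  Split identifiers never leak into
query output; triple generation projects them back first.

## Linguistic pre-processing

Tokens are masked, not deleted, so entity spans keep stable offsets.
Abbreviations come from an editable TSV (`KO → knockout`, `5' → five
prime`, ...), stop words from an editable list, and comparative rules
from a YAML file mapping surface phrases to canonical patterns
(`below → less than`) and canonical patterns to operators
(`less than → <`).  Extraction is two-step: rewrite to canonical
patterns (with `between X and Y → greater than X and less than Y`,
strict bounds, X < Y enforced), then bind each pattern to the numeric
literal in scope and to the governing noun run immediately before it.
A second relation with no noun run of its own (the rewritten *between*,
or "higher than 1 and lower than 2") shares the previous operand.

Part-of-speech tags come from a small closed-class lexicon plus suffix
rules, defaulting open-class words to nouns.  This deliberately simple
tagger is sufficient for the two places tags are used — noun-run
operand detection and noun/verb chunking for the dictionary feature —
and keeps the package dependency-free on this axis.  It does not attempt
full dependency parsing; grammatically unusual questions may confuse
operand attachment.

Strict inequalities for *between* are the default and configurable in
the rule file.  Cross-class arithmetic comparisons ("less than 1.5 of
the log2 ratio") are detected by the pattern *literal + of + noun
phrase* and refused rather than extracted, as are negations and
aggregate phrasings.

## Entity recognition

A linear-chain CRF over BIO-encoded tags (8 upper-level labels → 17
states).  Emission features: lowercased token, 16 orthographic
regular-expression indicators, collapsed word shape, token/shape of
neighbors in a ±2 window (window width configurable; ±2 covers the
two-token entity names common in this vocabulary), and a dictionary
feature that, for each noun/verb chunk, fires an indicator named for the
*nearest* upper-level ancestor of the best-matching ontology element
when the best ISUB score is ≥ 0.6.  "Nearest" (rather than topmost)
ancestor is the choice that keeps the feature informative when upper
labels nest.

Training minimizes the L2-penalized conditional negative log-likelihood
(strength 1.0 by default — a conventional value for corpora of a few
hundred short sequences) with L-BFGS; gradients come from
forward-backward expected counts, all in log space.  Weights start at
zero, so training is deterministic for a fixed corpus; the `seed`
parameter exists for callers that subsample.  Decoding is Viterbi;
maximal runs of identical labels merge into entity spans, and masked
tokens cannot carry a span.  Correctness of the normalization constant
Z_o is verified in the tests against brute-force enumeration of all
label sequences on small instances.

## Ontology element matching

Five similarity measures, each on normalized strings (lowercase,
camelCase split, underscores/hyphens to spaces) and each in [0, 1] with
identity 1.0:

- **ISUB**: iterated longest-common-substring commonality minus a
  difference term damped by a Hamacher t-norm (p = 0.6), plus a
  Winkler-style shared-prefix bonus; the raw score can be negative and
  is clamped at 0.  Because substring-removal tie-breaks depend on
  argument order, the score is computed on the lexicographically ordered
  pair, making symmetry exact.
- **Levenshtein**: 1 − edit distance / max length (edlib).
- **Smith-Waterman**: local alignment score (match 1, mismatch and gap
  −1/3) / max length (Biopython's `PairwiseAligner`).
- **Cosine** over character-frequency vectors.
- **Jaccard** over whitespace token sets.

Default measure and threshold are ISUB at 0.6, both configurable.
Candidates are drawn from S_c — the subtree of the entity's upper-level
label — over element names, `rdfs:label`, and `rdfs:comment` fragments
(tokens and n-grams up to 3; whole-comment similarity to a short entity
is near zero, hence the fragmenting).  Case 2 ranks multiple candidates
by the number of undirected simple paths of length ≤ 3 (bound
configurable) to the other entities' resolved elements, falling back to
their upper labels before resolution.  Case 3 looks up the entity text
by case-insensitive exact match against data literals and instance IRI
local names and takes the instances' `rdf:type` classes (`rdf:type`,
the standard predicate, is what is queried).

The evaluation module reports precision, recall, rejection and F1.
Rejection is computed as correctly rejected dissimilars over all truly
dissimilar entities, the reading under which raising the threshold can
only improve rejection while recall can only fall — the trade-off the
threshold sweep (0.5–0.9 × five measures) is designed to expose.

## Semantic association discovery

**Method 1 (LCA).**  The all-pairs table stores, for every node pair of
the cycle-broken graph, the full set of common ancestors minimizing
ancestral distance d(c,x) + d(c,y), plus that distance.  It is built by
a reachability sweep from every candidate ancestor (O(n·(V+E)) BFS
passes plus per-pair updates) and is validated cell-for-cell against a
brute-force enumeration oracle on random DAGs.  The table serializes to
JSON keyed by a hash of the graph's edge multiset; lookups against a
stale hash are refused, since any schema or instantiation change
invalidates the precomputation.  Multi-element sets reduce by a left
fold in sorted order with backtracking over alternative LCAs,
preferring the deepest (most specific) ancestor and then lexicographic
order; failure to reduce is reported as a no-association outcome, never
silently.  Hub→element paths are shortest paths; among equals, paths
covering matched properties win, then instantiated-edge count, then
lexicographic order.

**Method 2 (path intersection).**  Pairwise undirected simple paths are
enumerated with bounds (≤ 25 paths per pair, length ≤ 10, ≤ 20,000
product combinations — the unbounded "all paths" is not computable, and
these defaults keep the fixture graphs exhaustive); per-combination
common nodes pool into a candidate set, from which the node with
shortest paths to all elements is selected, preferring candidates that
reach every element along directed edges.  Both methods return the same
association shape, and when a unique minimal common ancestor exists they
agree — a cross-method test on random DAGs.

Triple generation walks each hub→element path: property edges become
`(?u, p, ?v)` patterns with one stable variable per class (`?v0, ?v1,
...` in class-sorted order); a subclass edge refines the current
variable's type to the child class instead of emitting a pattern
(subclass axioms hold between classes, not instances, so emitting them
as data patterns would always fail).  Comparatives attach to the
datatype property of their matched element through a shared literal
variable per (class, property) — so a *between* pair constrains one
value, not two independent bindings.  Instance-matched entities add an
`rdfs:label` equality filter carrying the entity's surface text.

## Query formulation and execution

The compiler emits SPARQL 1.1 `SELECT DISTINCT` with `rdf:type`
constraints (no reasoner; subclass expansion would need one and is out
of scope), numeric filters cast through `xsd:decimal`, and
case-insensitive string equality for instance literals.  Projection:
variables of entities appearing before the question's first verb, or
the first recognized entity when the question opens with the verb
("Find all genes ..."), plus any literal-valued variables.  Every
generated query is re-parsed through rdflib's SPARQL grammar before
execution.  The endpoint contract has two implementations — an
in-process rdflib store (used by all tests) and SPARQL-over-HTTP via
the standard library — so the pipeline is store-agnostic.

## Synthetic study conditions

The fixture generator emulates the shape of a provenance ontology for
parasite experimentation at desk scale: 40 classes under eight
upper-level branches, 22 properties of which three close cycles, and
instance data for 12 genes with 1–2 spectral-count measurements
(values uniform on [0, 5]), one log2 ratio (uniform on [−2, 3]),
pathway memberships, gene-function annotations, and two
researcher/sequence-extraction chains.  Embedded in the hierarchy are
three worked association topologies (a chain whose LCA is *cell
cloning*; a fork whose hub is *proteome analysis*; four branches that
reduce recursively to *process*) and the two-edge
parameter/data-collection cycle whose breaking produces the split node
`data collection_1`.

The corpus is 200 templated questions (mix: 35 % without comparatives,
45 % with one, 20 % with two; 15 % abbreviation rate; 10 % instance-only
entities; 20 % near-miss surfaces such as *spectra score*), each with
token-level gold labels, gold element matches, and — for satisfiable
patterns — gold triple sequences and gold answer rows computed by
direct scans of the instance data, independent of the pipeline.  All
randomness flows from one seed; emitted artifacts record it in a header.

What the fixtures do *not* emulate: real question grammar variety
(templates are regular, so recognizer scores here exceed what free-form
questions would yield), ontology scale (hundreds of thousands of
classes would stress the O(n²) table), OWL restrictions/equivalence,
and noisy annotation.  Passing tests demonstrate correctness of the
machinery under controlled conditions, not field performance.

The four-scenario system evaluation (no corrections; gold entities;
gold entities + elements; gold triples) retrains the recognizer per
fold on seeded partitions (k = 2 in the shipped runs, sized to keep the
evaluation fast at this corpus scale).  Scenario F1 is expected to be
monotone non-decreasing in the amount of injected gold on this corpus;
that is an empirical property of the deterministic downstream, checked
per corpus rather than a theorem — a lucky wrong-entity answer could in
principle break it on other data.

## Known limitations

- The POS tagger is lexicon-based; operand extraction can mis-attach in
  grammatically complex questions.
- Case-2 context ranking counts bounded undirected paths; on densely
  connected ontologies the bound (3) may need raising.
- Method 2's bounds make it incomplete on graphs with very long
  connecting paths.
- No OWL reasoning: `rdf:type` is matched directly, and equivalence or
  inverse axioms are ignored.
- Refusal detection is keyword-based; an unusual phrasing of negation
  or aggregation can slip through to (harmless but wrong) compilation.
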