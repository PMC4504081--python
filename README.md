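# ontoqa

Natural-language question answering over RDF data annotated with an OWL
ontology.

Biomedical repositories increasingly store experiment data as RDF triples
annotated by a domain ontology — for example, provenance-style ontologies
that model the experimentation processes behind parasite genomics and
proteomics data.  Writing SPARQL against such a store requires knowing the
ontology's structure: the question *"Which researchers study Neomycin drug
resistance?"* corresponds to a path through an intermediate class
(*sequence extraction*) and two properties (*has agent*, *has output
value*) that the question never mentions.  `ontoqa` closes that gap: it
translates a plain-language question into an RDF triple query and executes
it, so the scientist never sees the ontology or the query language.

## The pipeline

Five stages, mirroring the architecture of ontology-based QA systems for
experimental biology:

1. **Linguistic pre-processing** — tokenization, stop-word/punctuation
   masking, abbreviation expansion, number-word normalization, and
   extraction of comparative relations: *"standard deviation below 0.5"*
   becomes the symbolic constraint (standard deviation, <, 0.5);
   *"between 40 and 50"* becomes the pair (>, 40) and (<, 50).
2. **Entity recognition** — a linear-chain conditional random field tags
   each token with one of 8 upper-level ontology labels (or OUTSIDE).
   The CRF defines P(s|o) = (1/Z_o) exp(Σᵢ Σⱼ λⱼ fⱼ(sᵢ₋₁, sᵢ, o, i)) over
   binary features: token strings, orthographic regular-expression
   indicators (HASDASH, INITCAPS, GENEPATT, DNASEQUENCE, ...), collapsed
   word shapes, a ±2 context window, and a dictionary feature that fires
   the upper-level ancestor of the best similarity match in the ontology.
   Weights λⱼ are fit by L-BFGS on the penalized conditional likelihood.
3. **Ontology element matching** — each entity labeled c is refined to a
   specific element of S_c (the hierarchy rooted at c) by string
   similarity (ISUB by default, threshold 0.6; Levenshtein,
   Smith-Waterman, character-cosine and Jaccard are also available)
   against element names, `rdfs:label` and `rdfs:comment` strings.  A
   single candidate is kept directly; multiple candidates are ranked by
   direct graph paths to the other entities' elements; an empty candidate
   list falls back to exact lexical matching against instances in the
   data, taking the instance's `rdf:type` class.
4. **Semantic association discovery** — the matched elements are joined
   at a *hub*: the lowest common ancestor (LCA) under minimal ancestral
   distance d(c,x) + d(c,y), looked up in a precomputed n×n all-pairs
   table over the cycle-broken ontology graph (cycles are removed by
   splitting the closing node into `name_1`, `name_2`, ... copies, with a
   provenance map back to the originals).  Multi-element sets reduce
   recursively through pairwise LCAs.  An alternative method enumerates
   bounded pairwise paths and intersects them.  Shortest hub→element
   paths become the association.
5. **Query formulation** — the association compiles to a SPARQL 1.1
   SELECT: one graph pattern per property edge, `rdf:type` constraints
   per class variable, one numeric FILTER per comparative.  Execution
   goes through an endpoint contract (in-process rdflib store, or SPARQL
   over HTTP).

Questions requiring negation, aggregates, nested/grouped queries, or
cross-class arithmetic comparisons are detected and refused with a
reason, as is a question mentioning a single entity.

Because real annotated corpora and lab triple stores are not
distributable, the package ships a first-class synthetic fixture module
(`ontoqa.fixtures`) that generates an ontology with embedded worked
topologies and cycles, typed instance data, and a templated labeled
question corpus with gold matches, gold triple sequences and gold answer
rows computed by direct data scans.

## Worked example

```python
from ontoqa import fixtures as fx, ontology as om, association as am, sparql as sp
from ontoqa import recognition as rec
from ontoqa.pipeline import Pipeline

spec = fx.FixtureSpec(seed=7)
fixture = fx.generate_ontology(spec)
corpus, _ = fx.generate_corpus(spec, fixture)
model = om.load_ontology(fixture.ontology, list(spec.labels))
graph = om.build_property_graph(model, fixture.data)
dag = om.to_dag(graph, roots=[model.root])
table = am.build_lca_table(dag)
crf = rec.train(rec.TrainingCorpus(corpus.items[:160]), seed=7, model=model)
pipe = Pipeline(model, graph, dag, table, crf, sp.LocalEndpoint(fixture.data), fixture.data)

res = pipe.answer("Find all genes with spectra score greater than 2.")
```

The recognizer finds `genes` (label *material*) and `spectra score`
(label *data collection*); ISUB matching refines them to the classes
`gene` and `spectral count` (score 0.666 ≥ 0.6 for the near-miss
surface); the LCA hub is `gene` itself, one property edge away from
`spectral count`.  The compiled query is

```sparql
SELECT DISTINCT ?v0 ?lit0
WHERE {
  ?v0 rdf:type <http://example.org/onto#gene> .
  ?v1 rdf:type <http://example.org/onto#spectral_count> .
  ?v0 <http://example.org/onto#has_measurement> ?v1 .
  ?v1 <http://example.org/onto#has_value> ?lit0 .
  FILTER (xsd:decimal(?lit0) > 2.0)
}
```

and `res.answers` holds 12 rows such as
`('http://example.org/data#gene_1', '2.42')` — each a gene whose
measured spectral count exceeds the threshold, exactly the rows a direct
scan of the data yields.

A command-line interface wraps the same library:

```
ontoqa fixtures --out fixtures/            # emit ontology.ttl, data.ttl, corpus.conll, gold files
ontoqa train --corpus fixtures/corpus.conll --ontology fixtures/ontology.ttl --out model.json
ontoqa precompute-lca --ontology fixtures/ontology.ttl --data fixtures/data.ttl --out lca.json
ontoqa ask "Find all genes with spectral count greater than 2." --config cfg.yaml --show-sparql
ontoqa eval --out results/ --kfold 2 --seed 7
```

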