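# Methods

## What the package computes

`sbpkb` turns a relational export of a standard-biological-parts registry —
a parts table and a position-based sequence-feature table — into an RDF
knowledge graph organized by an SBOL-style information model, and answers
part-retrieval questions over that graph with SPARQL. The representational
core is small:

- a **part** is an individual typed `sbolcore:Part`, carrying its registry
  attributes (name, type, short/long description, author, status, id,
  owner id, date, DNA sequence) as literal properties;
- each hierarchical **category** tag on a part (`//regulation/positive`)
  becomes an OWL class, and the part gets an `rdf:type` assertion for it;
- each **sequence feature** row becomes a `SequenceAnnotation` individual
  (start, end, direction) linked from its part, pointing at a typed,
  labeled `Feature` individual (e.g. an operator site).

The query bank then implements stepwise refinement: all parts of a class →
parts with a deposited sequence and not marked `Deleted` → parts typed by a
conjunction of classes (e.g. promoter ∧ sigma-70 context, or the
dual-regulation conjunction) → parts that additionally carry at least one
annotated transcription-factor binding site. Result sizes are always counts
of *distinct* part subjects, so a part can never be double-counted however
many rows mention it.

## Category classes

Category paths are parsed from the `//a/b/c` syntax, lower-cased, segments
restricted to `[a-z0-9_]+`. The class name for a path is its segments
reversed and underscore-joined (`//rnap/prokaryote/ecoli/sigma70` →
`sigma70_ecoli_prokaryote_rnap`); this reproduces the registry-derived
class vocabulary verbatim and keeps every name a legal local name. Because
segments may themselves contain underscores, two distinct paths can reverse
to the same name; `emit_class_axioms` detects the collision and raises
rather than merging.

The category forest is prefix-closed (missing ancestors are auto-inserted)
and every root class is subclassed under a single neutral
`sbolcore:RegistryCategory` anchor. The anchor deliberately asserts nothing
biological: the vocabulary mixes functional, host, and bookkeeping axes and
is a semi-structured controlled vocabulary, not a formal ontology, so no
OWL-DL restrictions or disjointness axioms are emitted.

## Superclass materialization

Queries for a superclass (`promoter`) must match parts tagged only with a
subcategory. Rather than requiring an RDFS-inferencing query engine, the
builder **materializes** ancestor classes by default: a part tagged
`//regulation/positive` is also typed `pr:regulation`. This keeps the query
layer dialect-plain SPARQL 1.1 with no entailment regime. Materialization
is monotone (the statement set with it on is a superset of off) and can be
disabled (`--no-materialize`) when the downstream store does its own
inference.

## Identifier minting

Individuals get deterministic opaque ids: `"r"` + base62 of the first six
bytes of SHA-256 over `kind|registry_id|name` + the registry id digits.
Identical inputs always mint identical ids, so rebuilding from the same
tables is byte-reproducible (stable diffs); a guard raises on the
practically-unreachable event of two distinct inputs colliding. The scheme
version is recorded in the graph's provenance note.

## Numerical and representational choices

- **Literal typing**: registry ids, owner ids and feature coordinates are
  `xsd:integer`; everything else is a plain string. Dates are kept verbatim
  (`9/11/2007`) — parsing locale-ambiguous registry dates would invent
  information.
- **Missing sequence** omits the `dnaSequence` property entirely rather
  than asserting an empty literal; "has a sequence" is property existence,
  which is what the cleaning queries test.
- **Status** is normalized case-insensitively onto
  {Available, Sent, Deleted, Planning, Unavailable}; unknown tokens are
  preserved verbatim and reported, never dropped. The cleaning filter
  compares the normalized token exactly.
- **Coordinates** are 1-based inclusive on the part's own sequence. A
  feature running past the sequence end warns but is still represented —
  registry data is imperfect and silently dropping rows would bias queries.
- **Serialization**: Turtle output is written one triple per line in sorted
  term order, so equal graphs serialize byte-identically; RDF/XML uses the
  standard serializer. Both re-parse to the same statement set.
- **Strictness**: transforms fail on structural defects (orphan features,
  duplicate ids, non-ACGT sequences) unless `--lenient` degrades them to
  warnings; missing sequences and nonstandard statuses are reported but are
  data facts, not errors.

## Synthetic data

The statistical generator emulates the *schema and dirtiness* of a registry
export, not its scale or empirical frequencies: category tags are
independent Bernoulli draws per path over the real vocabulary used in the
worked example, statuses follow a categorical distribution
(Available 0.50, Sent 0.15, Planning 0.15, Unavailable 0.12, Deleted 0.08),
10% of parts lack a deposited sequence, sequences are uniform random ACGT
of 40–120 nt, and sequenced parts carry Poisson(1.2) features placed
strictly in-bounds. Defects (orphan features, nonstandard statuses) can be
injected in known numbers. Every assignment is recorded in a ground-truth
manifest, so an independent brute-force filter over plain records is the
oracle for every graph query. Default problem sizes — 500-part fixtures,
20 seeds in the test battery, 5 in the acceptance script — were chosen as
the package's own desk-scale study conditions.

What passing these tests does **not** show: agreement with any real
registry snapshot's absolute counts (the historical dump is not modeled),
realistic category co-occurrence structure, or free-text quality. The
worked promoter example is the exception — its seven encoded records and
their operator-site features are fixed ground truth, and the final
refinement query must return exactly its six dual-regulated parts with the
published (part, feature-label) pairs, invariant to distractor promoters
that each miss at least one criterion.

## Known limitations

- Sub-part composition (a composite part whose segments are themselves
  parts) is represented only through the annotation→feature mapping, not as
  nested `Part` individuals.
- No OWL reasoning: consistency checking and classification are out of
  scope; materialization substitutes for subclass entailment only.
- The `DESCRIBE`-style query returns all asserted statements about the
  matched subjects (symmetric concise bounded description over a graph
  with no blank nodes); no HTTP endpoint ships in the default install.
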