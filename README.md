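# sbpkb

Build and query a **Standard Biological Parts knowledgebase**: transform a
parts registry's relational export (a parts table plus a position-based
sequence-feature table) into an SBOL-semantic RDF knowledge graph, with an
OWL class hierarchy auto-generated from the registry's hierarchical
category vocabulary, and retrieve parts through a bank of named SPARQL
queries that implement stepwise design-query refinement.

**Who it is for.** Synthetic biologists (and the CAD tools they use) who
need to *search* a parts catalog by precise criteria — "promoters that are
both positively and negatively regulatable and have annotated operator
sites" — instead of browsing catalog web pages and de-duplicating
spreadsheets by hand.

## The model in brief

Each part record becomes an RDF individual:

```
pr:<part>  rdf:type        sbolcore:Part , pr:promoter , pr:positive_regulation , … ;
           sbolcore:name   "BBa_I746365" ;
           sbolcore:status "Available" ;
           sbolcore:dnaSequence "cgcttt…" ;
           sbolcore:annotation [ a sbolcore:SequenceAnnotation ;
                                 sbolcore:start 5 ; sbolcore:end 16 ;
                                 sbolcore:feature [ a sbolcore:Feature, pr:operator ;
                                                    sbolcore:name "OR1 lambda" ] ] .
```

Category paths such as `//rnap/prokaryote/ecoli/sigma70` become classes
named by reversing the segments (`sigma70_ecoli_prokaryote_rnap`),
subclassed along the category tree. Ancestor classes are *materialized* as
extra `rdf:type` statements by default, so a plain SPARQL query for
`pr:promoter` also finds parts tagged only with a promoter subcategory —
no inference engine required. See `docs/methods.md` for the full account.

## Worked example

Generate the built-in worked fixture (seven promoter records — one
sigma-70 example part plus six dual-regulated promoters with operator-site
features — and three distractor promoters), transform it to Turtle, and run
the final refinement query:

```sh
sbpkb fixgen --out-dir fx --inpaper --n-distractors 3 --seed 2
sbpkb transform --parts fx/parts.tsv --features fx/features.tsv --out kb.ttl
sbpkb query --graph kb.ttl --name dual_regulated_features
```

The transform logs `parts: 10  features: 18` and
`wrote 346 statements to kb.ttl`; the query logs
`15 rows, 6 distinct parts` and prints a TSV whose rows pair each
dual-regulated promoter with one of its binding-site labels, e.g.

```
part    name    short   author  feature_label
…#r13TPL5CLD1051    BBa_I1051   Lux cassette right promoter  Mahajan, V.S., …  LuxR/HSL
…#r1ASSF0HA714016   BBa_I14016  P(Las) CIO                   Vijayan, V., …    CI lambda O1
…#rVNwonzH512040    BBa_I12040  Modified lambda P(RM) promoter  ryhsiao        OR1 434
```

Six distinct parts survive the full refinement chain (promoter → dual
regulation → has operator-site features); the ten input promoters included
three distractors and one singly-regulated part that drop out along the
way. Raw SPARQL works too (`sbpkb query --graph kb.ttl --sparql -`), and
`sbpkb fixgen` without `--inpaper` emits seeded synthetic registry tables
with a ground-truth manifest for testing.

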