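"""SPARQL execution and the promoter query-refinement bank.

The named queries implement a stepwise refinement workflow over the parts
knowledge graph:

1. ``parts_by_class``       — all parts typed by one category class
2. ``describe_class``       — every statement about parts of a class
3./4. ``clean_parts``       — drop parts without a DNA sequence or marked
                              Deleted (for one class, or the whole graph)
5. ``by_status``            — parts whose status is in a given token set
6./7. ``conjunctive``       — parts typed by ALL of several classes (e.g.
                              promoter ∧ sigma70_ecoli_prokaryote_rnap, or
                              the dual-regulated promoter conjunction)
Fig-4 ``dual_regulated_features`` — dual-regulated promoters that carry at
    least one annotated operator-site feature, with descriptions and
    feature labels.

Superclass semantics come from materialized type statements asserted at
build time; queries run under plain SPARQL semantics with no entailment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from string import Template
from typing import Iterable, Mapping, Sequence

from rdflib import Literal, RDF, URIRef
from rdflib.namespace import OWL

from .sbol_model import CORE, PR, NAMESPACE_BINDINGS, KnowledgeGraph, Triple

__all__ = [
    "QuerySpec",
    "QueryResult",
    "QueryWarning",
    "execute",
    "execute_raw",
    "q_parts_by_class",
    "q_describe_class",
    "q_clean_parts",
    "q_by_status",
    "q_conjunctive_classes",
    "q_dual_regulated_with_features",
    "NAMED_QUERIES",
    "result_to_tsv",
]

_CLASS_TOKEN_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")
_STATUS_TOKEN_RE = re.compile(r"[A-Za-z0-9_ ()-]+\Z")

#: Core classes addressable by local name in class-parameterized queries.
_CORE_CLASSES = {"Part", "SequenceAnnotation", "Feature", "RegistryCategory"}


class QueryWarning(UserWarning):
    """Non-fatal query condition, e.g. an unknown class name."""


@dataclass(frozen=True)
class QuerySpec:
    """A named SPARQL template plus its parameter bindings.

    Templates use ``$placeholder`` substitution; parameters are validated
    as bare tokens before rendering, so no SPARQL syntax can be injected
    through them.
    """

    name: str
    sparql_template: str
    params: Mapping[str, str] = field(default_factory=dict)
    subject_var: str = "part"

    def render(self) -> str:
        for key, value in self.params.items():
            if not _CLASS_TOKEN_RE.match(value) and not _STATUS_TOKEN_RE.match(
                value
            ):
                raise ValueError(f"illegal query parameter {key}={value!r}")
        return Template(self.sparql_template).substitute(self.params)


@dataclass
class QueryResult:
    """Ordered variable bindings from one query execution.

    ``distinct_subjects`` counts unique part subjects across rows — the
    counting convention used for every reported result size, so a part can
    never be counted twice no matter how many rows mention it.
    """

    variables: list[str]
    rows: list[dict[str, "URIRef | Literal"]]
    subject_var: str = "part"

    @property
    def distinct_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subjects(self) -> frozenset[URIRef]:
        return frozenset(
            row[self.subject_var]
            for row in self.rows
            if self.subject_var in row
        )

    def column(self, var: str) -> list["URIRef | Literal"]:
        return [row[var] for row in self.rows if var in row]

    def __len__(self) -> int:
        return len(self.rows)


def _class_uri(name: str) -> URIRef:
    if not _CLASS_TOKEN_RE.match(name):
        raise ValueError(f"illegal class name {name!r}")
    return CORE[name] if name in _CORE_CLASSES else PR[name]


def _class_prefixed(name: str) -> str:
    return ("sbolcore:" if name in _CORE_CLASSES else "pr:") + name


def execute_raw(kg: KnowledgeGraph, sparql: str,
                subject_var: str = "part") -> QueryResult:
    """Run raw SPARQL text over the graph (SELECT form)."""
    result = kg.graph.query(sparql, initNs=NAMESPACE_BINDINGS)
    variables = [str(v) for v in (result.vars or [])]
    rows = []
    for binding in result:
        row = {}
        for var, value in zip(variables, binding):
            if value is not None:
                row[var] = value
        rows.append(row)
    return QueryResult(variables=variables, rows=rows, subject_var=subject_var)


def execute(kg: KnowledgeGraph, query: QuerySpec) -> QueryResult:
    """Render a QuerySpec and run it under plain SPARQL 1.1 semantics."""
    return execute_raw(kg, query.render(), subject_var=query.subject_var)


def _warn_if_unknown_class(kg: KnowledgeGraph, class_name: str) -> None:
    uri = _class_uri(class_name)
    if (uri, RDF.type, OWL.Class) not in kg.graph:
        warnings.warn(
            f"class {class_name!r} is not declared in this graph",
            QueryWarning,
            stacklevel=3,
        )


def q_parts_by_class(kg: KnowledgeGraph, class_name: str) -> QueryResult:
    """Query #1 shape: all distinct parts typed by one category class."""
    _warn_if_unknown_class(kg, class_name)
    sparql = (
        "SELECT DISTINCT ?part WHERE {\n"
        f"  ?part rdf:type {_class_prefixed(class_name)} ;"
        " rdf:type sbolcore:Part .\n"
        "}"
    )
    return execute_raw(kg, sparql)


def q_describe_class(kg: KnowledgeGraph, class_name: str) -> list[Triple]:
    """Query #2 shape: DESCRIBE every part of a class.

    Returns all statements whose subject is typed by the class — the
    complete property set a researcher scans to find refinement criteria.
    """
    _warn_if_unknown_class(kg, class_name)
    uri = _class_uri(class_name)
    triples: list[Triple] = []
    for subject in sorted(kg.graph.subjects(RDF.type, uri)):
        for pred, obj in sorted(kg.graph.predicate_objects(subject)):
            triples.append((subject, pred, obj))
    return triples


def q_clean_parts(
    kg: KnowledgeGraph, class_name: str | None = None
) -> QueryResult:
    """Queries #3/#4 shape: parts with a DNA sequence, not marked Deleted.

    Presence of the ``dnaSequence`` property is the "has sequence" test
    (parts without one carry no such statement at all); the status test is
    an exact match on the normalized token.
    """
    if class_name is not None:
        _warn_if_unknown_class(kg, class_name)
        type_clause = f"rdf:type {_class_prefixed(class_name)} ; "
    else:
        type_clause = ""
    sparql = (
        "SELECT DISTINCT ?part WHERE {\n"
        f"  ?part rdf:type sbolcore:Part ; {type_clause}\n"
        "        sbolcore:dnaSequence ?seq ; sbolcore:status ?status .\n"
        '  FILTER(?status != "Deleted")\n'
        "}"
    )
    return execute_raw(kg, sparql)


def q_by_status(kg: KnowledgeGraph, statuses: Iterable[str]) -> QueryResult:
    """Query #5 shape: parts whose status token is in the given set."""
    tokens = sorted(set(statuses))
    if not tokens:
        return QueryResult(variables=["part"], rows=[])
    for tok in tokens:
        if not _STATUS_TOKEN_RE.match(tok):
            raise ValueError(f"illegal status token {tok!r}")
    values = ", ".join(f'"{tok}"' for tok in tokens)
    sparql = (
        "SELECT DISTINCT ?part WHERE {\n"
        "  ?part rdf:type sbolcore:Part ; sbolcore:status ?status .\n"
        f"  FILTER(?status IN ({values}))\n"
        "}"
    )
    return execute_raw(kg, sparql)


def q_conjunctive_classes(
    kg: KnowledgeGraph, class_names: Sequence[str]
) -> QueryResult:
    """Queries #6/#7 shape: parts typed by ALL of the listed classes.

    The classes are independent category axes (a promoter is separately
    tagged with its polymerase context and its regulation modes), so the
    conjunction is a multi-type pattern, not a subclass walk.
    """
    if not class_names:
        raise ValueError("at least one class name required")
    for name in class_names:
        _warn_if_unknown_class(kg, name)
    types = " ; ".join(
        f"rdf:type {_class_prefixed(n)}" for n in class_names
    )
    sparql = (
        "SELECT DISTINCT ?part WHERE {\n"
        f"  ?part rdf:type sbolcore:Part ; {types} .\n"
        "}"
    )
    return execute_raw(kg, sparql)


DUAL_REGULATED_FEATURES_SPARQL = """\
SELECT DISTINCT ?part ?name ?short ?author ?feature_label WHERE {
  ?part rdf:type sbolcore:Part ;
        rdf:type pr:promoter ;
        rdf:type pr:positive_regulation ;
        rdf:type pr:negative_regulation ;
        sbolcore:name ?name ;
        sbolcore:shortDescription ?short ;
        sbolcore:author ?author ;
        sbolcore:annotation ?ann .
  ?ann sbolcore:feature ?feat .
  ?feat sbolcore:name ?feature_label .
}"""


def q_dual_regulated_with_features(kg: KnowledgeGraph) -> QueryResult:
    """The final refinement: dual-regulated promoters with operator sites.

    Returns (part, name, short description, author, feature label) rows for
    promoters typed both positively and negatively regulated that carry at
    least one annotation→feature chain; parts with no features drop out of
    the join.  ``distinct_subjects`` counts unique parts.
    """
    return execute_raw(kg, DUAL_REGULATED_FEATURES_SPARQL)


def _run_named(name: str):
    def runner(kg: KnowledgeGraph, **params) -> QueryResult:
        if name == "parts_by_class":
            return q_parts_by_class(kg, params["class"])
        if name == "clean_parts":
            return q_clean_parts(kg, params.get("class"))
        if name == "by_status":
            return q_by_status(kg, params["statuses"].split(","))
        if name == "conjunctive":
            return q_conjunctive_classes(kg, params["classes"].split(","))
        if name == "dual_regulated_features":
            return q_dual_regulated_with_features(kg)
        raise KeyError(name)

    return runner


#: Query-bank registry for the CLI: name → callable(kg, **params).
NAMED_QUERIES = {
    name: _run_named(name)
    for name in (
        "parts_by_class",
        "clean_parts",
        "by_status",
        "conjunctive",
        "dual_regulated_features",
    )
}


def result_to_json(result: QueryResult) -> str:
    """Render a result in the standard SPARQL-results JSON shape."""
    import json

    bindings = []
    for row in result.rows:
        entry = {}
        for var, value in row.items():
            if isinstance(value, URIRef):
                entry[var] = {"type": "uri", "value": str(value)}
            else:
                entry[var] = {"type": "literal", "value": str(value)}
        bindings.append(entry)
    return json.dumps(
        {
            "head": {"vars": result.variables},
            "results": {"bindings": bindings},
        },
        indent=1,
    )


def result_to_tsv(result: QueryResult) -> str:
    """Render a result as a TSV table (header = variable names)."""
    lines = ["\t".join(result.variables)]
    for row in result.rows:
        lines.append(
            "\t".join(str(row.get(var, "")) for var in result.variables)
        )
    return "\n".join(lines) + "\n"
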