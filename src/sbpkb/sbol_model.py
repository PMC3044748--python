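"""Transform validated Registry records into the SBOL-semantic knowledge graph.

Parts become individuals typed ``sbolcore:Part`` plus one type per category
class (and, with materialization on, per ancestor category class), carrying
their Registry attributes as literal properties.  Sequence-feature rows
become SequenceAnnotation individuals hung off the part, each pointing at a
typed, labeled Feature individual.  Identifiers are minted deterministically
from a digest of the record identity, so rebuilding the graph from the same
tables is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL, XSD

from .category_ontology import (
    ANCHOR_CLASS,
    CategoryTree,
    ClassDef,
    ancestors,
    class_name_for,
    emit_class_axioms,
    parse_category,
)
from .registry_io import FeatureRecord, PartRecord

__all__ = [
    "CORE",
    "PR",
    "KnowledgeGraph",
    "Triple",
    "IdMintingError",
    "UnknownCategoryError",
    "FeatureBoundsWarning",
    "mint_id",
    "mint_uri",
    "part_to_statements",
    "feature_to_statements",
    "class_axiom_statements",
    "build_knowledgebase",
    "serialize",
    "parse_graph",
]

#: Core SBOL-semantic namespace (classes Part, SequenceAnnotation, Feature,
#: the RegistryCategory anchor, and all literal/object properties).
CORE = Namespace("http://sbols.org/sbol-semantic#")
#: Namespace for classes auto-generated from the Registry category vocabulary.
PR = Namespace("http://partsregistry.org/sbol#")

NAMESPACE_BINDINGS = {
    "sbolcore": CORE,
    "pr": PR,
    "rdf": RDF,
    "rdfs": RDFS,
    "owl": OWL,
    "xsd": XSD,
}

#: PartRecord attribute → literal property, in Registry column order.
PART_LITERAL_PROPERTIES = (
    ("name", CORE.name),
    ("part_type", CORE.type),
    ("short_desc", CORE.shortDescription),
    ("long_desc", CORE.longDescription),
    ("author", CORE.author),
    ("status", CORE.status),
)

Triple = tuple[URIRef, URIRef, "URIRef | Literal"]

_B62 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"

#: Bump when the minting recipe changes; part of every graph's provenance.
ID_SCHEME_VERSION = "digest-v1"


class IdMintingError(ValueError):
    """Two distinct inputs minted the same identifier."""


class UnknownCategoryError(ValueError):
    """A part references a category absent from the tree (strict mode)."""


class FeatureBoundsWarning(UserWarning):
    """A feature's end coordinate runs past its part's sequence."""


def _base62(n: int) -> str:
    if n == 0:
        return _B62[0]
    digits = []
    while n:
        n, r = divmod(n, 62)
        digits.append(_B62[r])
    return "".join(reversed(digits))


def mint_id(kind: str, registry_id: int, name: str) -> str:
    """Deterministic opaque local name for an individual.

    ``"r"`` + base62 of the first six digest bytes of ``kind|id|name`` + the
    registry id digits; the same record always mints the same id, and the
    digest keeps distinct records apart.
    """
    if not name:
        raise ValueError("cannot mint an id for an empty name")
    digest = hashlib.sha256(f"{kind}|{registry_id}|{name}".encode()).digest()
    return f"r{_base62(int.from_bytes(digest[:6], 'big'))}{registry_id}"


def mint_uri(kind: str, registry_id: int, name: str) -> URIRef:
    return CORE[mint_id(kind, registry_id, name)]


class _MintGuard:
    """Raises if distinct (kind, id, name) inputs ever collide."""

    def __init__(self) -> None:
        self._seen: dict[str, tuple[str, int, str]] = {}

    def mint(self, kind: str, registry_id: int, name: str) -> URIRef:
        local = mint_id(kind, registry_id, name)
        key = (kind, registry_id, name)
        prior = self._seen.setdefault(local, key)
        if prior != key:
            raise IdMintingError(
                f"id collision: {prior} and {key} both mint {local!r}"
            )
        return CORE[local]


@dataclass
class KnowledgeGraph:
    """Statement set with namespace bindings — the SBPkb itself.

    Thin wrapper over an :class:`rdflib.Graph` (set semantics: duplicate
    statements collapse) plus a provenance note recording where the data
    came from and which id-minting scheme produced the individuals.
    """

    graph: Graph = field(default_factory=Graph)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prefix, ns in NAMESPACE_BINDINGS.items():
            self.graph.bind(prefix, ns, override=True, replace=True)

    def add(self, triple: Triple) -> None:
        self.graph.add(triple)

    def update(self, triples: Iterable[Triple]) -> None:
        for t in triples:
            self.graph.add(t)

    @property
    def statements(self) -> frozenset[Triple]:
        return frozenset(self.graph)

    def __len__(self) -> int:
        return len(self.graph)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.graph


def class_axiom_statements(tree: CategoryTree) -> list[Triple]:
    """OWL class declarations and subclass axioms for the category tree.

    Includes the core classes (Part, SequenceAnnotation, Feature and the
    RegistryCategory anchor) so every emitted class has a declared parent.
    """
    triples: list[Triple] = []
    for cls in (CORE.Part, CORE.SequenceAnnotation, CORE.Feature,
                CORE[ANCHOR_CLASS]):
        triples.append((cls, RDF.type, OWL.Class))
    for cdef in emit_class_axioms(tree):
        subject = _class_uri(cdef)
        triples.append((subject, RDF.type, OWL.Class))
        if cdef.parent_local_name is not None:
            parent = (
                CORE[cdef.parent_local_name]
                if cdef.parent_local_name == ANCHOR_CLASS
                else PR[cdef.parent_local_name]
            )
            triples.append((subject, RDFS.subClassOf, parent))
    return triples


def _class_uri(cdef: ClassDef) -> URIRef:
    return (CORE if cdef.namespace == "core-sbol" else PR)[cdef.local_name]


def part_to_statements(
    record: PartRecord,
    tree: CategoryTree,
    materialize: bool = True,
    strict: bool = True,
) -> list[Triple]:
    """Statements describing one part individual.

    Always asserts ``rdf:type sbolcore:Part`` and one type per category
    class; with ``materialize`` on, also one type per ancestor category
    class, so plain SPARQL matches superclass queries without inference.
    ``sbolcore:dnaSequence`` is omitted entirely (not an empty literal) when
    no sequence is deposited — cleaning queries test property presence.
    """
    subject = mint_uri("part", record.registry_id, record.name)
    triples: list[Triple] = [(subject, RDF.type, CORE.Part)]
    for raw in record.categories:
        path = parse_category(raw)
        if path not in tree:
            if strict:
                raise UnknownCategoryError(
                    f"part {record.name}: category {raw!r} not in tree"
                )
            warnings.warn(
                f"part {record.name}: auto-inserting unknown category {raw!r}",
                UserWarning,
                stacklevel=2,
            )
            tree.add(path)
        triples.append((subject, RDF.type, PR[class_name_for(path)]))
        if materialize:
            for anc in ancestors(path):
                triples.append((subject, RDF.type, PR[class_name_for(anc)]))
    for attr, prop in PART_LITERAL_PROPERTIES:
        triples.append((subject, prop, Literal(getattr(record, attr))))
    triples.append((subject, CORE.id, Literal(record.registry_id)))
    triples.append((subject, CORE.owner_id, Literal(record.owner_id)))
    triples.append((subject, CORE.date, Literal(record.date)))
    if record.has_sequence:
        triples.append((subject, CORE.dnaSequence, Literal(record.dna_sequence)))
    return triples


def feature_to_statements(
    feature: FeatureRecord,
    part_uri: URIRef,
    part_sequence_length: int | None = None,
) -> list[Triple]:
    """Statements for one sequence feature: annotation + feature individuals.

    The part links via ``sbolcore:annotation`` to a SequenceAnnotation
    carrying start/end/direction, which links via ``sbolcore:feature`` to a
    Feature individual typed by its feature type and labeled with the
    feature's name.  An end coordinate past the sequence length only warns
    (Registry data is imperfect); the statements are still emitted.
    """
    if (
        part_sequence_length is not None
        and feature.end > part_sequence_length
    ):
        warnings.warn(
            f"feature {feature.feature_id} ({feature.label!r}) ends at "
            f"{feature.end}, past sequence length {part_sequence_length}",
            FeatureBoundsWarning,
            stacklevel=2,
        )
    ann = mint_uri("annotation", feature.feature_id, feature.label)
    feat = mint_uri("feature", feature.feature_id, feature.label)
    triples: list[Triple] = [
        (part_uri, CORE.annotation, ann),
        (ann, RDF.type, CORE.SequenceAnnotation),
        (ann, CORE.start, Literal(feature.start)),
        (ann, CORE.end, Literal(feature.end)),
        (ann, CORE.direction, Literal(feature.direction)),
        (ann, CORE.feature, feat),
        (feat, RDF.type, CORE.Feature),
        (feat, CORE.name, Literal(feature.label)),
    ]
    if feature.feature_type:
        type_token = feature.feature_type.strip().lower().replace(" ", "_")
        triples.append((feat, RDF.type, PR[type_token]))
        triples.append((PR[type_token], RDF.type, OWL.Class))
    return triples


def build_knowledgebase(
    parts: Sequence[PartRecord],
    features: Sequence[FeatureRecord],
    tree: CategoryTree,
    materialize: bool = True,
    strict: bool = True,
    source: str = "",
) -> KnowledgeGraph:
    """Assemble the full knowledge graph from validated record lists.

    Union of the category class axioms, all part statements, and all
    feature statements; features attach to their part via the foreign key
    (an orphan feature raises here — run validation first to surface them
    all at once).
    """
    kg = KnowledgeGraph(
        provenance={"source": source, "id_scheme": ID_SCHEME_VERSION}
    )
    kg.update(class_axiom_statements(tree))
    guard = _MintGuard()
    part_uri: dict[int, URIRef] = {}
    seq_len: dict[int, int] = {}
    for record in parts:
        uri = guard.mint("part", record.registry_id, record.name)
        part_uri[record.registry_id] = uri
        seq_len[record.registry_id] = len(record.dna_sequence)
        kg.update(part_to_statements(record, tree, materialize, strict))
    for feat in features:
        if feat.part_registry_id not in part_uri:
            raise KeyError(
                f"feature {feat.feature_id} references unknown part "
                f"{feat.part_registry_id}"
            )
        guard.mint("annotation", feat.feature_id, feat.label)
        guard.mint("feature", feat.feature_id, feat.label)
        kg.update(
            feature_to_statements(
                feat,
                part_uri[feat.part_registry_id],
                part_sequence_length=seq_len[feat.part_registry_id] or None,
            )
        )
    return kg


def _canonical_turtle(kg: KnowledgeGraph) -> str:
    # One triple per line in sorted order: deterministic output, and still
    # valid Turtle. rdflib's own serializer groups by subject in store order.
    nm = kg.graph.namespace_manager
    lines = [
        f"@prefix {prefix}: <{ns}> ."
        for prefix, ns in sorted(NAMESPACE_BINDINGS.items())
    ]
    lines.append("")
    body = sorted(kg.graph, key=lambda t: (t[0].n3(), t[1].n3(), t[2].n3()))
    for s, p, o in body:
        lines.append(f"{s.n3(nm)} {p.n3(nm)} {o.n3(nm)} .")
    lines.append("")
    return "\n".join(lines)


def serialize(
    kg: KnowledgeGraph, format: str, path: str | Path
) -> Path:
    """Write the graph as ``turtle`` or ``rdfxml``.

    Turtle output is canonically ordered, so identical graphs serialize to
    byte-identical files; both formats re-parse to the same statement set.
    """
    path = Path(path)
    if format == "turtle":
        path.write_text(_canonical_turtle(kg), encoding="utf-8")
    elif format == "rdfxml":
        kg.graph.serialize(destination=str(path), format="xml")
    else:
        raise ValueError(f"unknown format {format!r} (expected turtle|rdfxml)")
    return path


def parse_graph(path: str | Path, format: str | None = None) -> KnowledgeGraph:
    """Load a serialized graph back into a :class:`KnowledgeGraph`."""
    fmt = format
    if fmt is None:
        fmt = "turtle" if str(path).endswith((".ttl", ".turtle")) else "xml"
    elif fmt == "rdfxml":
        fmt = "xml"
    kg = KnowledgeGraph()
    kg.graph.parse(str(path), format=fmt)
    return kg
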