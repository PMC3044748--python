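"""Registry category vocabulary → class hierarchy.

Registry parts carry hierarchical category tags written as slash paths
(``//rnap/prokaryote/ecoli/sigma70``).  This module parses those paths into
a tree and auto-generates the matching class structure: one class per
category node, named by the path's segments reversed and underscore-joined
(``sigma70_ecoli_prokaryote_rnap``), each subclassed under its category
parent's class.  Root categories are anchored under a single neutral
``RegistryCategory`` class in the core namespace so the generated hierarchy
stays connected to the core model without asserting false is-a relations.

The result is deliberately a semi-structured controlled vocabulary, not a
formal ontology: no OWL-DL restrictions or disjointness axioms are emitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "CategoryPath",
    "CategoryTree",
    "ClassDef",
    "CategoryParseError",
    "ClassNameCollisionError",
    "ANCHOR_CLASS",
    "parse_category",
    "build_tree",
    "class_name_for",
    "emit_class_axioms",
    "ancestors",
    "read_category_file",
]

_SEGMENT_RE = re.compile(r"[a-z0-9_]+\Z")

#: Local name of the core-namespace class every category root subclasses.
ANCHOR_CLASS = "RegistryCategory"


class CategoryParseError(ValueError):
    """A raw category string does not follow the ``//a/b/c`` syntax."""


class ClassNameCollisionError(ValueError):
    """Two distinct category paths reverse to the same class name."""


@dataclass(frozen=True)
class CategoryPath:
    """A parsed category path: raw string plus normalized segment tuple."""

    raw: str
    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise CategoryParseError("category path has no segments")

    @property
    def depth(self) -> int:
        return len(self.segments)

    @property
    def is_root(self) -> bool:
        return len(self.segments) == 1

    def parent(self) -> "CategoryPath | None":
        if self.is_root:
            return None
        return _from_segments(self.segments[:-1])

    def __str__(self) -> str:
        return "//" + "/".join(self.segments)


def _from_segments(segments: tuple[str, ...]) -> CategoryPath:
    return CategoryPath(raw="//" + "/".join(segments), segments=segments)


def parse_category(raw: str) -> CategoryPath:
    """Parse one raw category string.

    Requires the leading ``//``; segments are lower-cased and must match
    ``[a-z0-9_]+`` after normalization — empty segments and internal
    whitespace are rejected rather than repaired.
    """
    if not raw:
        raise CategoryParseError("empty category string")
    text = raw.strip()
    if not text.startswith("//"):
        raise CategoryParseError(f"category must start with '//': {raw!r}")
    body = text[2:]
    if not body:
        raise CategoryParseError(f"category has no segments: {raw!r}")
    segments = []
    for seg in body.split("/"):
        seg = seg.lower()
        if not seg:
            raise CategoryParseError(f"empty segment in category: {raw!r}")
        if not _SEGMENT_RE.match(seg):
            raise CategoryParseError(
                f"invalid segment {seg!r} in category {raw!r} "
                "(expected [a-z0-9_]+)"
            )
        segments.append(seg)
    return CategoryPath(raw=text, segments=tuple(segments))


def ancestors(path: CategoryPath) -> list[CategoryPath]:
    """Proper prefixes of the path, nearest first; empty for a root."""
    return [
        _from_segments(path.segments[:k]) for k in range(path.depth - 1, 0, -1)
    ]


class CategoryTree:
    """The category hierarchy: nodes keyed by segment tuple.

    Parent of a node is the path with its last segment removed; missing
    ancestors are auto-inserted so the forest is always prefix-closed.
    """

    def __init__(self) -> None:
        self._nodes: dict[tuple[str, ...], CategoryPath] = {}

    def add(self, path: CategoryPath) -> None:
        """Insert a path and every ancestor of it."""
        for k in range(1, path.depth + 1):
            key = path.segments[:k]
            if key not in self._nodes:
                self._nodes[key] = _from_segments(key)
        # keep the caller's raw spelling for the full path
        self._nodes[path.segments] = path

    def __contains__(self, path: CategoryPath) -> bool:
        return path.segments in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[CategoryPath]:
        return iter(sorted(self._nodes.values(), key=lambda p: p.segments))

    @property
    def nodes(self) -> list[CategoryPath]:
        return list(self)

    @property
    def roots(self) -> list[CategoryPath]:
        return [p for p in self if p.is_root]

    def parent_of(self, path: CategoryPath) -> CategoryPath | None:
        if path.segments not in self._nodes:
            raise KeyError(f"path not in tree: {path}")
        parent = path.parent()
        return None if parent is None else self._nodes[parent.segments]


def build_tree(paths: Iterable[CategoryPath]) -> CategoryTree:
    """Assemble the tree; all ancestor paths are present afterwards, and the
    root count equals the number of distinct first segments."""
    tree = CategoryTree()
    for p in paths:
        tree.add(p)
    return tree


def class_name_for(path: CategoryPath) -> str:
    """Class name for a category: segments reversed, underscore-joined.

    ``//rnap/prokaryote/ecoli/sigma70`` → ``sigma70_ecoli_prokaryote_rnap``;
    a root like ``//promoter`` keeps its own name.
    """
    return "_".join(reversed(path.segments))


@dataclass(frozen=True)
class ClassDef:
    """One auto-generated class: local name, namespace, and its parent.

    Category-derived classes live in the partsregistry namespace; the single
    anchor parent of the roots lives in the core namespace.
    """

    local_name: str
    namespace: str  # "core-sbol" | "partsregistry"
    parent_local_name: str | None


def emit_class_axioms(tree: CategoryTree) -> list[ClassDef]:
    """One ClassDef per tree node; subclass edges mirror the tree.

    Segments may themselves contain underscores, so two distinct paths can
    reverse to the same name (``//a_b`` vs ``//b/a``); that ambiguity is
    detected and raised, never silently merged.
    """
    by_name: dict[str, CategoryPath] = {}
    defs: list[ClassDef] = []
    for node in tree:
        name = class_name_for(node)
        if name in by_name:
            raise ClassNameCollisionError(
                f"class name {name!r} generated by both "
                f"{by_name[name]} and {node}"
            )
        by_name[name] = node
        parent = tree.parent_of(node)
        defs.append(
            ClassDef(
                local_name=name,
                namespace="partsregistry",
                parent_local_name=(
                    ANCHOR_CLASS if parent is None else class_name_for(parent)
                ),
            )
        )
    return defs


def read_category_file(path: str | Path) -> list[CategoryPath]:
    """Read a plain-text category list, one ``//a/b`` path per line.

    Blank lines and ``#`` comment lines are skipped.
    """
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(parse_category(line))
    return out
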