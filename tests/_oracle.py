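"""Brute-force reference filters over fixture manifests.

These operate directly on the generator's ground-truth manifest — plain
dicts, no RDF, no SPARQL, and a locally re-derived naming rule — so they
are an independent oracle for every named query on the graph side.
Results are sets of part names.
"""


def _closure_names(raw_path: str) -> set[str]:
    # reversed-segment class name for the path and every prefix of it
    segments = raw_path.lstrip("/").split("/")
    return {
        "_".join(reversed(segments[:k])) for k in range(1, len(segments) + 1)
    }


def _classes_of(part: dict) -> set[str]:
    names: set[str] = set()
    for cat in part["categories"]:
        names |= _closure_names(cat)
    return names


def parts_by_class(manifest: dict, class_name: str) -> set[str]:
    return {
        p["name"]
        for p in manifest["parts"]
        if class_name in _classes_of(p)
    }


def clean_parts(manifest: dict, class_name: str | None = None) -> set[str]:
    return {
        p["name"]
        for p in manifest["parts"]
        if p["has_sequence"]
        and p["status"] != "Deleted"
        and (class_name is None or class_name in _classes_of(p))
    }


def by_status(manifest: dict, statuses) -> set[str]:
    allowed = set(statuses)
    return {p["name"] for p in manifest["parts"] if p["status"] in allowed}


def conjunctive(manifest: dict, class_names) -> set[str]:
    wanted = set(class_names)
    return {
        p["name"] for p in manifest["parts"] if wanted <= _classes_of(p)
    }


def dual_regulated_with_features(manifest: dict) -> set[str]:
    dual = conjunctive(
        manifest, ("promoter", "positive_regulation", "negative_regulation")
    )
    return {
        p["name"]
        for p in manifest["parts"]
        if p["name"] in dual and p["features"]
    }


def dual_feature_pairs(manifest: dict) -> set[tuple[str, str]]:
    dual = dual_regulated_with_features(manifest)
    return {
        (p["name"], f["label"])
        for p in manifest["parts"]
        if p["name"] in dual
        for f in p["features"]
    }
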