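"""Synthetic Registry tables with known ground truth.

Two generators, both fully deterministic given a seed:

``generate``
    Registry-like tables with controlled statistical structure — category
    tags drawn per-path from Bernoulli weights, statuses from a categorical
    distribution, a fraction of parts without deposited sequences, and
    Poisson-many positioned features per sequenced part.  A manifest records
    every assignment, so an independent brute-force filter over the manifest
    is the oracle for every graph query.

``inpaper_fixture``
    The worked promoter example: one positively regulated sigma-70 promoter
    with its full property set, six dual-regulated promoters with their
    operator-site features, plus configurable distractor promoters that each
    fail at least one criterion of the final refinement query.  Feature
    coordinates are synthesized from the seed (the published tables print
    labels, not coordinates) and kept within sequence bounds.

Neither generator attempts to match the real Registry's 13k-part scale or
its category frequency profile; they emulate its schema, vocabulary reuse,
and dirtiness (missing sequences, deleted parts, nonstandard statuses,
optionally orphaned features) at desk scale.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .registry_io import (
    FeatureRecord,
    PartRecord,
    write_features_table,
    write_parts_table,
)

__all__ = [
    "FixtureConfig",
    "GeneratedFixture",
    "DEFAULT_CATEGORY_WEIGHTS",
    "DEFAULT_STATUS_DISTRIBUTION",
    "generate",
    "inpaper_fixture",
    "TABLE2_ROWS",
]

#: Per-path Bernoulli probability that a part carries the category tag.
#: Paths are the real Registry vocabulary used throughout the worked
#: examples; probabilities are desk-scale choices, not Registry frequencies.
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "//promoter": 0.30,
    "//regulation/positive": 0.18,
    "//regulation/negative": 0.18,
    "//rnap/prokaryote/ecoli/sigma70": 0.12,
    "//chassis/prokaryote/ecoli": 0.30,
    "//direction/forward": 0.45,
    "//direction/reverse": 0.10,
    "//terminator": 0.10,
    "//rbs": 0.10,
    "//classic": 0.08,
    "//dna": 0.05,
    "//function/reporter": 0.06,
    "//plasmid": 0.04,
}

DEFAULT_STATUS_DISTRIBUTION: dict[str, float] = {
    "Available": 0.50,
    "Sent": 0.15,
    "Planning": 0.15,
    "Unavailable": 0.12,
    "Deleted": 0.08,
}

_FEATURE_LABELS = (
    "OR1 lambda",
    "OR2 lambda",
    "OR1 434",
    "TetR",
    "CI lambda O1",
    "LuxR/HSL",
    "lacO",
    "araI1",
)
_FEATURE_TYPES = ("operator", "terminator", "rbs", "primer_binding_site")
_AUTHORS = ("Hans", "mcnamara", "ryhsiao", "A. Student", "B. Builder")
_PART_TYPES = ("Regulatory", "Terminator", "RBS", "DNA", "Composite")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the statistical generator; defaults are the study setup."""

    n_parts: int = 500
    seed: int = 0
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    status_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_DISTRIBUTION)
    )
    p_missing_sequence: float = 0.10
    mean_features_per_part: float = 1.2
    sequence_length_range: tuple[int, int] = (40, 120)
    n_orphan_features: int = 0
    n_nonstandard_status: int = 0

    def __post_init__(self) -> None:
        for p in self.category_weights.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("category weights must be probabilities")
        total = sum(self.status_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"status distribution must sum to 1, got {total}"
            )
        lo, hi = self.sequence_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad sequence_length_range")
        if self.mean_features_per_part > 0 and hi < 8:
            raise ValueError(
                "sequences too short to place features"
            )


@dataclass
class GeneratedFixture:
    """Emitted table files plus the in-memory records and manifest."""

    parts_path: Path
    features_path: Path
    manifest_path: Path
    parts: list[PartRecord]
    features: list[FeatureRecord]
    manifest: dict


def _poisson(rng: random.Random, mean: float) -> int:
    # Knuth sampler; fine for the small means used here.
    import math

    limit = math.exp(-mean)
    k, prod = 0, rng.random()
    while prod > limit:
        k += 1
        prod *= rng.random()
    return k


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("acgt") for _ in range(length))


def _manifest_entry(part: PartRecord, feats: list[FeatureRecord]) -> dict:
    return {
        "registry_id": part.registry_id,
        "name": part.name,
        "status": part.status,
        "has_sequence": part.has_sequence,
        "categories": list(part.categories),
        "features": [
            {
                "feature_id": f.feature_id,
                "label": f.label,
                "feature_type": f.feature_type,
                "start": f.start,
                "end": f.end,
                "direction": f.direction,
            }
            for f in feats
        ],
    }


def _write(
    out_dir: str | Path,
    parts: list[PartRecord],
    features: list[FeatureRecord],
    manifest: dict,
) -> GeneratedFixture:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parts_path = out_dir / "parts.tsv"
    features_path = out_dir / "features.tsv"
    manifest_path = out_dir / "manifest.json"
    write_parts_table(parts, parts_path)
    write_features_table(features, features_path)
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return GeneratedFixture(
        parts_path=parts_path,
        features_path=features_path,
        manifest_path=manifest_path,
        parts=parts,
        features=features,
        manifest=manifest,
    )


def generate(config: FixtureConfig, out_dir: str | Path) -> GeneratedFixture:
    """Emit a seeded synthetic table pair plus its ground-truth manifest.

    Same config → byte-identical files.  Sequences are uniform random over
    {a,c,g,t}; features are placed strictly within their part's sequence.
    """
    rng = random.Random(config.seed)
    parts: list[PartRecord] = []
    features: list[FeatureRecord] = []
    manifest_parts: list[dict] = []
    status_tokens = sorted(config.status_distribution)
    status_weights = [config.status_distribution[s] for s in status_tokens]
    cat_paths = sorted(config.category_weights)
    lo, hi = config.sequence_length_range

    nonstandard_ids: list[int] = []
    missing_ids: list[int] = []
    next_feature_id = 1
    for i in range(config.n_parts):
        rid = 1000 + i
        name = f"BBa_T{rid}"
        cats = tuple(
            p for p in cat_paths if rng.random() < config.category_weights[p]
        )
        status = rng.choices(status_tokens, weights=status_weights)[0]
        if i < config.n_nonstandard_status:
            status = "Informational"
            nonstandard_ids.append(rid)
        missing = rng.random() < config.p_missing_sequence
        seq = "" if missing else _random_sequence(rng, rng.randint(lo, hi))
        if missing:
            missing_ids.append(rid)
        part = PartRecord(
            registry_id=rid,
            name=name,
            part_type=rng.choice(_PART_TYPES),
            short_desc=f"synthetic part {name}",
            long_desc=f"Synthetic registry-style record number {i}.",
            author=rng.choice(_AUTHORS),
            owner_id=rng.randint(100, 5000),
            status=status,
            date=f"{rng.randint(1, 12)}/{rng.randint(1, 28)}/"
            f"{rng.randint(2004, 2010)}",
            categories=cats,
            dna_sequence=seq,
            status_raw=status,
        )
        parts.append(part)
        part_feats: list[FeatureRecord] = []
        if seq:
            for _ in range(_poisson(rng, config.mean_features_per_part)):
                flen = rng.randint(4, min(12, len(seq)))
                start = rng.randint(1, len(seq) - flen + 1)
                part_feats.append(
                    FeatureRecord(
                        feature_id=next_feature_id,
                        part_registry_id=rid,
                        label=rng.choice(_FEATURE_LABELS),
                        feature_type=rng.choice(_FEATURE_TYPES),
                        start=start,
                        end=start + flen - 1,
                        direction=rng.choice(("forward", "reverse")),
                    )
                )
                next_feature_id += 1
        features.extend(part_feats)
        manifest_parts.append(_manifest_entry(part, part_feats))

    orphan_ids: list[int] = []
    for k in range(config.n_orphan_features):
        orphan_ids.append(next_feature_id)
        features.append(
            FeatureRecord(
                feature_id=next_feature_id,
                part_registry_id=900000 + k,  # resolves to no part
                label="orphan",
                feature_type="operator",
                start=1,
                end=4,
                direction="forward",
            )
        )
        next_feature_id += 1

    manifest = {
        "config": asdict(config),
        "category_paths": cat_paths,
        "parts": manifest_parts,
        "defects": {
            "orphan_feature_ids": orphan_ids,
            "nonstandard_status_ids": nonstandard_ids,
            "missing_sequence_ids": missing_ids,
        },
    }
    return _write(out_dir, parts, features, manifest)


# --- The worked promoter example -------------------------------------------

#: The DESCRIBE example part: a positively regulated, forward-oriented
#: sigma-70 E. coli promoter with its full printed property set.
DESCRIBE_EXAMPLE_PART = dict(
    registry_id=9598,
    name="BBa_I746365",
    part_type="Regulatory",
    short_desc="PLL promoter from P4 phage",
    long_desc=(
        "This is the PLL promoter taken from the P4 phage genome. It is an "
        "inducible promoter that is activated by a class of activators, "
        "including P2 ogr (I746350), PSP3 pag (I746351) and phiR73 delta "
        "(I746352). These different activators should cause different "
        "levels of activity of the PLL promoter."
    ),
    author="Stefan Milde",
    owner_id=2122,
    status="Available",
    date="9/11/2007",
    categories=(
        "//promoter",
        "//regulation/positive",
        "//direction/forward",
        "//chassis/prokaryote/ecoli",
        "//rnap/prokaryote/ecoli/sigma70",
    ),
    dna_sequence=(
        "cgctttattttgtgaatattttcagcagacgcaacaggggggatttgttcaggctgtctt"
        "acaatggctgtgtgttttttgttcatctccac"
    ),
)

#: The six dual-regulated promoters with their operator-site feature labels.
TABLE2_ROWS: tuple[tuple[str, str, str, tuple[str, ...]], ...] = (
    (
        "BBa_I12036",
        "Modified lamdba Prm promoter",
        "Hans",
        ("OR1 lambda", "OR2 lambda", "OR1 434", "OR2 434"),
    ),
    (
        "BBa_I12006",
        "Modified lamdba Prm promoter",
        "mcnamara",
        ("OR1 lambda", "OR2 lambda", "OR1 434"),
    ),
    (
        "BBa_I12040",
        "Modified lambda P(RM) promoter",
        "ryhsiao",
        ("OR1 lambda", "OR2 lambda", "OR1 434", "OR2 434"),
    ),
    (
        "BBa_I14015",
        "P(Las) TetO",
        "Vijayan, V., Hsu, A., Fomundam, L.",
        ("TetR",),
    ),
    (
        "BBa_I14016",
        "P(Las) CIO",
        "Vijayan, V., Hsu, A., Fomundam, L.",
        ("CI lambda O1",),
    ),
    (
        "BBa_I1051",
        "Lux cassette right promoter",
        "Mahajan, V.S., Marinescu, V.D., Chow, B., Wissner-Gross, A.D., "
        "Carr, P.",
        ("cI (OR1)", "LuxR/HSL"),
    ),
)

_DUAL_CATEGORIES = (
    "//promoter",
    "//regulation/positive",
    "//regulation/negative",
)


def inpaper_fixture(
    n_distractors: int = 0, seed: int = 0, out_dir: str | Path = "."
) -> GeneratedFixture:
    """Encode the worked promoter example as a table pair.

    Seven base records: the DESCRIBE example part and the six dual-regulated
    promoters (one operator feature per published feature label, coordinates
    synthesized in-bounds from the seed).  Distractors are promoter parts
    that each miss at least one criterion of the final refinement — a
    regulation mode, or any feature at all — so the refinement query's
    answer set is invariant to how many are added.
    """
    if n_distractors < 0:
        raise ValueError("n_distractors must be >= 0")
    rng = random.Random(seed)
    parts: list[PartRecord] = [PartRecord(**DESCRIBE_EXAMPLE_PART)]
    features: list[FeatureRecord] = []
    manifest_parts: list[dict] = [_manifest_entry(parts[0], [])]

    next_feature_id = 1
    for name, short, author, labels in TABLE2_ROWS:
        rid = int("".join(ch for ch in name if ch.isdigit()))
        seq = _random_sequence(rng, 80)
        part = PartRecord(
            registry_id=rid,
            name=name,
            part_type="Regulatory",
            short_desc=short,
            long_desc=f"{short} (dual-regulated promoter).",
            author=author,
            owner_id=rng.randint(100, 5000),
            status="Available",
            date=f"{rng.randint(1, 12)}/{rng.randint(1, 28)}/2004",
            categories=_DUAL_CATEGORIES,
            dna_sequence=seq,
        )
        parts.append(part)
        part_feats = []
        for k, label in enumerate(labels):
            start = 5 + 15 * k
            part_feats.append(
                FeatureRecord(
                    feature_id=next_feature_id,
                    part_registry_id=rid,
                    label=label,
                    feature_type="operator",
                    start=start,
                    end=start + 11,
                    direction="forward",
                )
            )
            next_feature_id += 1
        features.extend(part_feats)
        manifest_parts.append(_manifest_entry(part, part_feats))

    # Distractor styles cycle: promoter lacking one or both regulation modes,
    # or dual-regulated but featureless.
    distractor_cats = (
        ("//promoter", "//regulation/positive"),
        ("//promoter", "//regulation/negative"),
        ("//promoter",),
        _DUAL_CATEGORIES,
    )
    for j in range(n_distractors):
        rid = 500000 + j
        cats = distractor_cats[j % len(distractor_cats)]
        seq = _random_sequence(rng, 60)
        part = PartRecord(
            registry_id=rid,
            name=f"BBa_D{rid}",
            part_type="Regulatory",
            short_desc="distractor promoter",
            long_desc="Promoter failing at least one refinement criterion.",
            author=rng.choice(_AUTHORS),
            owner_id=rng.randint(100, 5000),
            status="Available",
            date=f"{rng.randint(1, 12)}/{rng.randint(1, 28)}/2005",
            categories=cats,
            dna_sequence=seq,
        )
        parts.append(part)
        feats: list[FeatureRecord] = []
        if cats != _DUAL_CATEGORIES:
            # non-dual distractors may carry features; dual ones must not
            start = rng.randint(1, 40)
            feats.append(
                FeatureRecord(
                    feature_id=next_feature_id,
                    part_registry_id=rid,
                    label=rng.choice(_FEATURE_LABELS),
                    feature_type="operator",
                    start=start,
                    end=start + 9,
                    direction="forward",
                )
            )
            next_feature_id += 1
        features.extend(feats)
        manifest_parts.append(_manifest_entry(part, feats))

    all_paths = sorted(
        {p for part in parts for p in part.categories}
    )
    manifest = {
        "config": {"n_distractors": n_distractors, "seed": seed},
        "category_paths": all_paths,
        "parts": manifest_parts,
        "defects": {
            "orphan_feature_ids": [],
            "nonstandard_status_ids": [],
            "missing_sequence_ids": [],
        },
    }
    return _write(out_dir, parts, features, manifest)
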