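import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from sbpkb import build_tree, parse_category, read_features_table, read_parts_table
from sbpkb.fixtures import inpaper_fixture
from sbpkb.sbol_model import build_knowledgebase


def build_fixture_kg(fx, materialize=True):
    """Read a generated fixture back off disk and build its graph."""
    parts = read_parts_table(fx.parts_path)
    features = read_features_table(fx.features_path)
    tree = build_tree(
        parse_category(c) for c in fx.manifest["category_paths"]
    )
    kg = build_knowledgebase(
        parts, features, tree, materialize=materialize, source=str(fx.parts_path)
    )
    return parts, features, tree, kg


@pytest.fixture(scope="session")
def inpaper_fx(tmp_path_factory):
    """Worked promoter example with a handful of distractor promoters."""
    return inpaper_fixture(
        n_distractors=5, seed=11, out_dir=tmp_path_factory.mktemp("inpaper")
    )


@pytest.fixture(scope="session")
def inpaper_kg(inpaper_fx):
    return build_fixture_kg(inpaper_fx)[3]


@pytest.fixture(scope="session")
def inpaper_plain_fx(tmp_path_factory):
    """Worked example with no distractors: exactly the seven base records."""
    return inpaper_fixture(
        n_distractors=0, seed=11, out_dir=tmp_path_factory.mktemp("inpaper0")
    )


@pytest.fixture(scope="session")
def inpaper_plain_kg(inpaper_plain_fx):
    return build_fixture_kg(inpaper_plain_fx)[3]
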