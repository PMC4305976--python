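import pytest

from crowdihc import (
    Canvas,
    Click,
    FieldConfig,
    Judgment,
    NucleusClass,
    Point,
    generate_field,
    perfect_worker,
    simulate_judgment,
)


@pytest.fixture(scope="session")
def table1():
    """The bundled 13-image reference positivity table as two columns."""
    from crowdihc import load_table1_fixture
    rows = load_table1_fixture()
    gold = [g for _, g, _ in rows]
    crowd = [c for _, _, c in rows]
    return gold, crowd


@pytest.fixture(scope="session")
def small_field():
    """A deterministic 30-positive / 70-negative / 20-other field."""
    return generate_field(FieldConfig(
        n_positive=30, n_negative=70, n_other=20, seed=42, image_id="field-a"))


@pytest.fixture(scope="session")
def perfect_crowd(small_field):
    """Ten error-free judgments of the small field (distinct workers)."""
    return [
        simulate_judgment(small_field, perfect_worker(f"p{i}"), seed=100 + i)
        for i in range(10)
    ]


def make_judgment(clicks_spec, image_id="img", worker_id="w", **meta):
    """Build a judgment from (x, y, 'P'|'N') triples."""
    clicks = [Click(Point(float(x), float(y)), NucleusClass.from_code(lbl))
              for x, y, lbl in clicks_spec]
    return Judgment(image_id=image_id, worker_id=worker_id, clicks=clicks, **meta)


@pytest.fixture
def canvas():
    return Canvas(772, 1044)
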