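import numpy as np
import pandas as pd
import pytest

from trlfm.io import AnnotationMap, Dataset, OntologyGraph


def make_discrete_dataset(rows, class_domain=("Case", "Control"), columns=None):
    """Build a small discrete Dataset from (values..., label) tuples."""
    columns = columns or [f"v{i + 1}" for i in range(len(rows[0]) - 1)]
    values = pd.DataFrame(
        [r[:-1] for r in rows],
        index=pd.Index([f"s{i + 1}" for i in range(len(rows))], name="sample"),
        columns=columns,
    ).astype(int)
    return Dataset(
        values=values,
        class_labels=[r[-1] for r in rows],
        class_domain=tuple(class_domain),
        discrete=True,
    )


@pytest.fixture
def diamond_ontology():
    # a -> b, a -> c, b -> d, c -> d : single root d, two paths retained
    return OntologyGraph([("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")])


@pytest.fixture
def two_branch_ontology():
    """Root R with branches X (x1, x2) and Y (y1, y2)."""
    return OntologyGraph(
        [("x1", "X"), ("x2", "X"), ("y1", "Y"), ("y2", "Y"), ("X", "R"), ("Y", "R")]
    )


@pytest.fixture
def two_branch_annotations():
    return AnnotationMap(
        {
            "g1": {"x1", "x2"},
            "g2": {"x1"},
            "g3": {"x2"},
            "g4": {"y1", "y2"},
            "g5": {"y1"},
            "g6": {"y2"},
        }
    )


def random_discrete_dataset(rng, n_vars=3, n_samples=8, n_intervals=2,
                            class_domain=("Case", "Control")):
    rows = []
    for _ in range(n_samples):
        vals = [int(rng.integers(n_intervals)) for _ in range(n_vars)]
        rows.append(tuple(vals) + (class_domain[int(rng.integers(len(class_domain)))],))
    # ensure both classes appear
    rows[0] = rows[0][:-1] + (class_domain[0],)
    rows[-1] = rows[-1][:-1] + (class_domain[1],)
    return make_discrete_dataset(rows)
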