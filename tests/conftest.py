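from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from amlmeta.cohort import (
    Cohort,
    ColumnSpec,
    FeatureSchema,
    generate_cohort,
    separated_spec,
)
from amlmeta.grid import collect_passing, reduced_registry, run_grid
from amlmeta.meta import build_membership_matrix, reduce_and_cluster
from amlmeta.preprocess import Preprocessor


def make_cohort(columns: dict[str, tuple[str, list]], categories=None, labels=None) -> Cohort:
    """Hand-built cohort: {name: (kind, values)} plus optional level lists."""
    categories = categories or {}
    specs = []
    data = {}
    for name, (kind, values) in columns.items():
        specs.append(ColumnSpec(name, kind, tuple(categories.get(name, ()))))
        data[name] = values
    return Cohort(pd.DataFrame(data), FeatureSchema(tuple(specs)), true_labels=labels)


@pytest.fixture(scope="session")
def recovery():
    """Planted-partition recovery experiment shared across grid/meta/transfer
    tests: strongly separated 4-cluster cohort (n=800), reduced grid with 10
    seeded iterations, consensus meta-clustering."""
    spec = separated_spec(n_patients=800, seed=42)
    cohort = generate_cohort(spec)
    pre = Preprocessor()
    matrix = pre.fit_transform(cohort)
    results = run_grid(reduced_registry(), matrix, master_seed=42, n_iterations=10)
    passing = collect_passing(results)
    membership = build_membership_matrix(passing)
    model = reduce_and_cluster(membership, d=3)
    return SimpleNamespace(
        spec=spec,
        cohort=cohort,
        pre=pre,
        matrix=matrix,
        results=results,
        passing=passing,
        membership=membership,
        model=model,
    )
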