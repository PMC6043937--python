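import numpy as np
import pytest

from paom import ExpressionMatrix, InteractionMatrix, RelationTable
from paom.compare import RELATION_COLUMNS

import pandas as pd


def make_expr(values, condition="", species="", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{k}" for k in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, condition, species)


def make_interaction(values, mrnas=None, mirnas=None):
    # default miRNA column IDs match make_expr's default gene IDs so the
    # two factories compose through forward()
    values = np.asarray(values, dtype=float)
    mrnas = mrnas or [f"t{i}" for i in range(values.shape[0])]
    mirnas = mirnas or [f"g{j}" for j in range(values.shape[1])]
    return InteractionMatrix(mrnas, mirnas, values)


def make_relations(rows):
    """rows: iterable of (mrna, mirna, cv) or dicts with full columns."""
    records = []
    for r in rows:
        if isinstance(r, dict):
            rec = dict(r)
        else:
            mrna, mirna, cv = r
            rec = {"mrna_id": mrna, "mirna_id": mirna, "cv": cv}
        rec.setdefault("a_normal", -0.5)
        rec.setdefault("a_cancer", -1.5)
        rec.setdefault("negative_in_cancer", rec["a_cancer"] < 0)
        rec.setdefault("reportable", rec["cv"] >= 5.0)
        rec.setdefault("sources", frozenset())
        rec.setdefault("passed_filter", False)
        records.append(rec)
    return RelationTable(pd.DataFrame(records, columns=RELATION_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_node_dataset():
    """4 mRNAs x 4 miRNAs with enough samples for exact identification."""
    from paom import generate

    return generate(
        n=4, m=4, k_normal=8, k_cancer=8, edge_density=0.5,
        change_fraction=0.25, effect_multiplier=3.0, noise_sd=0.0, seed=7,
    )
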