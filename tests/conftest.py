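import numpy as np
import pandas as pd
import pytest

import ctnet


@pytest.fixture(scope="session")
def default_truth():
    return ctnet.make_truth(seed=1)


@pytest.fixture(scope="session")
def default_expr(default_truth):
    ct = ctnet.generate_ct_table(default_truth)
    return ctnet.normalize(ct)


@pytest.fixture(scope="session")
def default_networks(default_expr):
    return ctnet.spearman_networks(default_expr)


def make_ct_table(values: dict, time_h=None, ref_values=None, ref_gene="GAPDH"):
    """Hand-build a small CtTable; values maps gene -> list of Ct per cell."""
    df = pd.DataFrame(values)
    n = len(df)
    if ref_values is None:
        ref_values = [15.0] * n
    df[ref_gene] = ref_values
    df.index = [f"c{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "time_h": time_h if time_h is not None else [0.0] * n,
            "replicate": "r1",
            "treatment": "none",
        },
        index=df.index,
    )
    return ctnet.CtTable(df, meta)


def make_expression(expr: pd.DataFrame, time_h=None, scale_factor=1.0):
    """Hand-build an ExpressionMatrix from a cells x genes frame."""
    meta = pd.DataFrame(
        {
            "time_h": time_h if time_h is not None else [0.0] * len(expr),
            "replicate": "r1",
            "treatment": "none",
        },
        index=expr.index,
    )
    return ctnet.ExpressionMatrix(expr, expr / scale_factor >= 0.5, meta, scale_factor)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
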