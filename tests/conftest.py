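"""Shared fixtures: all test data is generated programmatically."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import heartnet as hn


@pytest.fixture(scope="session")
def default_dataset():
    """The default 2,000-gene synthetic time course (seed 0)."""
    cfg = hn.SimulationConfig(seed=0)
    expr, truth = hn.simulate_timecourse(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def default_chain(default_dataset):
    """Full stage chain on the default dataset: selection -> network -> TOM.

    Session-scoped because several modules and the acceptance tests probe
    different aspects of the same chain.
    """
    cfg, expr, truth = default_dataset
    res = hn.moderated_t_test(expr, hn.INJURED_VS_HEALTHIER)
    selected = hn.select_genes(res, 0.005)
    corr = hn.correlation_matrix(expr, selected.genes)
    net = hn.soft_threshold(corr, beta=6)
    net_t = hn.threshold_edges(net, 0.26)
    return {
        "config": cfg,
        "expr": expr,
        "truth": truth,
        "de": res,
        "selected": selected,
        "corr": corr,
        "net": net,
        "net_t": net_t,
    }


@pytest.fixture()
def tiny_expr():
    """Hand-sized expression matrix: 6 genes x 6 samples, two groups."""
    rng = np.random.default_rng(42)
    cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    values = pd.DataFrame(
        rng.normal(8, 1, (6, 6)), index=[f"g{i}" for i in range(6)], columns=cols
    )
    meta = pd.DataFrame(
        {"group": ["A"] * 3 + ["B"] * 3, "replicate": [1, 2, 3, 1, 2, 3]}, index=cols
    )
    return hn.ExpressionMatrix(values, meta)


def best_match_jaccard(truth, module_set, universe):
    """Mean best-match Jaccard of planted modules vs a detected catalogue,
    with planted modules restricted to the analysed node set."""
    universe = set(universe)
    scores = []
    for m in truth.modules:
        tg = set(truth.module_members(m)) & universe
        if not tg:
            continue
        best = max(
            (len(tg & set(mm.genes)) / len(tg | set(mm.genes)) for mm in module_set),
            default=0.0,
        )
        scores.append(best)
    return float(np.mean(scores)) if scores else 0.0
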