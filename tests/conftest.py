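import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tregsig import (
    CellExpressionSet,
    PlantedGene,
    ScSimConfig,
    SurvivalCohort,
    SurvSimConfig,
    normalize_lognorm,
    simulate_sc_cohort,
    simulate_survival_cohort,
    zscore_genes,
)

LN2 = math.log(2)


def make_cset(counts, tissue=None, lineage=None, genes=None):
    """Tiny hand-built CellExpressionSet from a dense count array."""
    counts = np.asarray(counts)
    ng, nc = counts.shape
    return CellExpressionSet(
        counts=sp.csc_matrix(counts),
        genes=pd.Index(genes if genes is not None else [f"g{i}" for i in range(ng)]),
        cells=pd.Index([f"c{i}" for i in range(nc)]),
        tissue=np.array(tissue if tissue is not None else ["TI"] * nc, dtype=object),
        lineage=np.array(lineage if lineage is not None else ["Treg"] * nc, dtype=object),
    )


def make_survival(time, event, expr=None, genes=None, cohort="toy", grade=None):
    time = np.asarray(time, dtype=float)
    n = len(time)
    if expr is None:
        expr = np.zeros((1, n))
    expr = np.asarray(expr, dtype=float)
    samples = pd.Index([f"s{i}" for i in range(n)])
    return SurvivalCohort(
        expr=pd.DataFrame(
            expr,
            index=pd.Index(genes if genes is not None else [f"g{i}" for i in range(expr.shape[0])]),
            columns=samples,
        ),
        time=pd.Series(time, index=samples),
        event=pd.Series(np.asarray(event, dtype=int), index=samples),
        cohort=cohort,
        grade=None if grade is None else pd.Series(grade, index=samples),
    )


@pytest.fixture(scope="session")
def planted_sc_set():
    """Simulated two-tissue Treg cohort with two planted DE genes,
    normalized and z-scored (session-wide, deterministic)."""
    cfg = ScSimConfig(
        n_genes=200,
        lineages={"Treg": {"PB": 300, "TI": 300}, "CD8": {"PB": 100, "TI": 100}},
        planted_de=[
            PlantedGene(0, 3.0, 0.6, 0.1),
            PlantedGene(1, 1.8, 0.5, 0.2),
        ],
        seed=11,
    )
    return zscore_genes(normalize_lognorm(simulate_sc_cohort(cfg)))


@pytest.fixture(scope="session")
def prognostic_cohort():
    """Survival cohort with 6 planted prognostic genes (beta = ln 2) among 60."""
    cfg = SurvSimConfig(
        n_samples=200,
        n_genes=60,
        planted_prognostic=[(i, LN2) for i in range(6)],
        baseline_hazard=0.1,
        censoring_hazard=0.05,
        seed=3,
    )
    return simulate_survival_cohort(cfg)
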