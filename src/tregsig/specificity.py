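"""Lineage-specificity gene filter applied before signature development.

A candidate gene is kept only if it is significantly upregulated in the
target lineage (tumor-infiltrating Treg cells, by default) against enough of
the other tumor-infiltrating immune lineages: log-fold change >= ``min_logfc``
(non-strict) with Benjamini-Hochberg FDR < ``max_fdr``, in at least
``min_comparisons`` of the pairwise lineage comparisons.  Each comparison is
FDR-adjusted independently — this is deliberately a different multiple-testing
correction from the Bonferroni one used for the tumor-vs-blood DE step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .deg import rank_sum_de
from .io import CellExpressionSet

__all__ = ["lineage_specificity_filter"]

DEFAULT_OTHER_LINEAGES = ("CD4conv", "CD8", "NK", "B", "myeloid")


def lineage_specificity_filter(
    cset: CellExpressionSet,
    target_lineage: str = "Treg",
    other_lineages: tuple[str, ...] = DEFAULT_OTHER_LINEAGES,
    min_logfc: float = 1.0,
    max_fdr: float = 0.05,
    min_comparisons: int = 3,
    tissue: str | None = "TI",
) -> pd.Index:
    """Genes upregulated in the target lineage in >= ``min_comparisons`` of
    the per-lineage comparisons.

    Comparisons are restricted to the given ``tissue`` compartment
    (``None`` = all cells).  Returns passing genes in matrix order.
    """
    if len(other_lineages) < min_comparisons:
        raise ValueError(
            f"{len(other_lineages)} reference lineages declared but "
            f"min_comparisons={min_comparisons}"
        )
    target_mask = cset.cell_mask(tissue=tissue, lineage=target_lineage)
    if target_mask.sum() < 2:
        raise ValueError(f"target lineage {target_lineage!r} has < 2 cells")

    n_pass = np.zeros(cset.n_genes, dtype=int)
    for other in other_lineages:
        other_mask = cset.cell_mask(tissue=tissue, lineage=other)
        if other_mask.sum() < 2:
            raise ValueError(f"reference lineage {other!r} has < 2 cells")
        table = rank_sum_de(cset, target_mask, other_mask)
        fdr = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        n_pass += ((table["logfc"].to_numpy() >= min_logfc) & (fdr < max_fdr)).astype(int)
    return cset.genes[n_pass >= min_comparisons]
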