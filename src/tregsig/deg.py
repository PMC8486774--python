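"""Differential expression between cell groups and cross-cohort comparison.

The per-gene test is the two-sided Wilcoxon rank-sum on depth-normalized
log expression, Bonferroni-adjusted over all genes in the matrix.  Alongside
the p-value the table carries the log-fold change and the per-group
percent-expressed statistics, because the downstream filters threshold all
three.

Conventions (fixed, since they change the numbers):

* logFC is the natural-log fold change of group means on the
  depth-normalized scale with a pseudocount of one:
  ``ln(mean_a(expm1(normalized)) + 1) - ln(mean_b(...) + 1)`` — the
  convention of the standard single-cell toolchain.
* "expressing the gene" means raw count > 0; ``delta_pct`` is the
  percent-expressed difference in percentage points, ``(pct_a - pct_b) * 100``.
* The rank-sum p uses mid-ranks with the tie variance correction and a
  continuity correction; for small tie-free groups (both sides <= 12 cells)
  the exact permutation distribution is used instead, where the normal
  approximation is not yet reliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats import norm

from .io import CellExpressionSet

__all__ = [
    "DegFilter",
    "rank_sum_de",
    "apply_deg_filter",
    "overlap_coefficient",
    "shared_degs",
]

_EXACT_MAX = 12  # per-group size below which the exact rank-sum p is used


@dataclass(frozen=True)
class DegFilter:
    """Thresholds for calling a gene differentially expressed.

    All comparisons are strict: ``|logfc| > min_logfc``, ``p_adj < max_padj``
    and ``|delta_pct| > min_delta_pct`` (percentage points; the headline
    volcano labeling uses 20).
    """

    min_logfc: float = 1.0
    max_padj: float = 0.05
    min_delta_pct: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.min_logfc, self.max_padj, self.min_delta_pct):
            if not np.isfinite(v):
                raise ValueError("filter thresholds must be finite")


def _ranksum_asymptotic(x: np.ndarray, n_a: int) -> np.ndarray:
    """Vectorized two-sided rank-sum p (rows = genes) with tie correction
    and continuity correction."""
    n = x.shape[1]
    n_b = n - n_a
    ranks = scipy.stats.rankdata(x, axis=1)
    r_a = ranks[:, :n_a].sum(axis=1)
    u = r_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    # tie correction: sum over tie groups of (t^3 - t) per gene
    xs = np.sort(x, axis=1)
    same = np.concatenate(
        [np.zeros((x.shape[0], 1), bool), xs[:, 1:] == xs[:, :-1]], axis=1
    )
    tie_term = np.zeros(x.shape[0])
    for g in range(x.shape[0]):
        runs = np.flatnonzero(~same[g])
        t = np.diff(np.append(runs, n))
        tie_term[g] = float(np.sum(t**3 - t))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(x.shape[0])
    ok = var > 0
    z = (np.abs(u[ok] - mu) - 0.5) / np.sqrt(var[ok])
    p[ok] = np.minimum(1.0, 2.0 * norm.sf(np.maximum(z, 0.0)))
    return p


def _ranksum_small(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p for one gene when tie-free, else the
    tie-corrected approximation."""
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0
    if np.unique(combined).size == a.size + b.size:
        return float(scipy.stats.mannwhitneyu(a, b, method="exact").pvalue)
    return float(
        scipy.stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=True).pvalue
    )


def rank_sum_de(
    cset: CellExpressionSet, group_a: np.ndarray, group_b: np.ndarray
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two disjoint cell groups.

    Returns a DataFrame indexed by gene with columns ``logfc``, ``pct_a``,
    ``pct_b``, ``delta_pct``, ``p``, ``p_adj`` (Bonferroni over all genes in
    the matrix — no expression pre-filter).
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if (group_a & group_b).any():
        raise ValueError("cell groups must be disjoint")
    n_a, n_b = int(group_a.sum()), int(group_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 cells")

    norm_m = cset.normalized_dense()
    counts = cset.counts_dense()
    a = norm_m[:, group_a]
    b = norm_m[:, group_b]

    pct_a = (counts[:, group_a] > 0).mean(axis=1)
    pct_b = (counts[:, group_b] > 0).mean(axis=1)
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    logfc = np.log(mean_a + 1.0) - np.log(mean_b + 1.0)

    if max(n_a, n_b) <= _EXACT_MAX:
        p = np.array([_ranksum_small(a[g], b[g]) for g in range(a.shape[0])])
    else:
        p = _ranksum_asymptotic(np.concatenate([a, b], axis=1), n_a)
    p_adj = np.minimum(1.0, p * cset.n_genes)

    return pd.DataFrame(
        {
            "logfc": logfc,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "delta_pct": (pct_a - pct_b) * 100.0,
            "p": p,
            "p_adj": p_adj,
        },
        index=cset.genes,
    )


def apply_deg_filter(
    table: pd.DataFrame, deg_filter: DegFilter = DegFilter(), direction: str = "up"
) -> pd.Index:
    """Genes passing the DE thresholds, in table order.

    ``direction``: ``up`` keeps ``logfc > min_logfc`` (and
    ``delta_pct > min_delta_pct``), ``down`` the mirrored negative
    thresholds, ``both`` either.  All inequalities strict; ``p_adj`` always
    ``< max_padj``.
    """
    f = deg_filter
    up = (table["logfc"] > f.min_logfc) & (table["delta_pct"] > f.min_delta_pct)
    down = (table["logfc"] < -f.min_logfc) & (table["delta_pct"] < -f.min_delta_pct)
    if direction == "up":
        keep = up
    elif direction == "down":
        keep = down
    elif direction == "both":
        keep = up | down
    else:
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    keep &= table["p_adj"] < f.max_padj
    return table.index[keep]


def overlap_coefficient(a, b) -> float:
    """Szymkiewicz–Simpson overlap coefficient |a∩b| / min(|a|, |b|)."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty gene sets")
    return len(a & b) / min(len(a), len(b))


def shared_degs(
    tables: list[pd.DataFrame],
    deg_filter: DegFilter = DegFilter(),
    direction: str = "up",
) -> pd.Index:
    """Intersection of per-cohort filtered DEG sets over a common universe.

    The returned genes keep the first table's order.
    """
    if len(tables) < 2:
        raise ValueError("need at least two DEG tables to intersect")
    universe = set(tables[0].index)
    for t in tables[1:]:
        universe &= set(t.index)
    if not universe:
        raise ValueError("DEG tables share no genes")
    shared = set(apply_deg_filter(tables[0], deg_filter, direction))
    for t in tables[1:]:
        shared &= set(apply_deg_filter(t, deg_filter, direction))
    return pd.Index([g for g in tables[0].index if g in shared], name="gene")
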