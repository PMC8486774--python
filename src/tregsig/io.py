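"""Containers and I/O for expression data, plus cell-level QC and normalization.

Two containers cover the pipeline's inputs: :class:`CellExpressionSet` for
gene x cell count matrices with tissue/lineage annotations (single-cell side)
and :class:`SurvivalCohort` for gene x sample expression with overall-survival
follow-up (bulk side).  On-disk formats are the 10x-style matrix-market
triplet (matrix.mtx + genes.tsv + barcodes.tsv with annotation columns) and a
flat TSV survival table; both round-trip losslessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

TISSUES = ("PB", "TI", "other")

__all__ = [
    "CellExpressionSet",
    "SurvivalCohort",
    "qc_filter_cells",
    "normalize_lognorm",
    "zscore_genes",
    "write_sc_triplet",
    "read_sc_triplet",
    "write_survival_tsv",
    "read_survival_tsv",
]


@dataclass
class CellExpressionSet:
    """Gene x cell counts with per-cell tissue and lineage annotations.

    Parameters
    ----------
    counts
        Nonnegative integer gene x cell matrix (dense or scipy sparse).
    genes, cells
        Unique, ordered gene symbols and cell identifiers.
    tissue
        Per-cell compartment label, one of ``PB`` (peripheral blood),
        ``TI`` (tumor-infiltrating) or ``other``.
    lineage
        Per-cell immune lineage label (e.g. Treg, CD4conv, CD8, NK, B,
        myeloid).
    normalized
        Optional depth-normalized log matrix (see :func:`normalize_lognorm`).
    zscored
        Optional per-gene z-scored matrix (see :func:`zscore_genes`).
    """

    counts: sp.spmatrix | np.ndarray
    genes: pd.Index
    cells: pd.Index
    tissue: np.ndarray
    lineage: np.ndarray
    normalized: Optional[sp.spmatrix | np.ndarray] = None
    zscored: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        self.tissue = np.asarray(self.tissue, dtype=object)
        self.lineage = np.asarray(self.lineage, dtype=object)
        if not self.genes.is_unique:
            dup = self.genes[self.genes.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r}; refusing to aggregate")
        if not self.cells.is_unique:
            raise ValueError("cell identifiers must be unique")
        ng, nc = self.shape
        if len(self.genes) != ng or len(self.cells) != nc:
            raise ValueError("gene/cell label lengths do not match matrix shape")
        if len(self.tissue) != nc or len(self.lineage) != nc:
            raise ValueError("per-cell annotation length does not match cell count")
        bad = set(np.unique(self.tissue)) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue labels {sorted(bad)}; expected {TISSUES}")
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if data.size and (np.amin(data) < 0 or np.any(data != np.floor(data))):
            raise ValueError("counts must be nonnegative integers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_mask(self, tissue: str | None = None, lineage: str | None = None) -> np.ndarray:
        """Boolean mask over cells matching the given tissue and/or lineage."""
        mask = np.ones(self.n_cells, dtype=bool)
        if tissue is not None:
            mask &= self.tissue == tissue
        if lineage is not None:
            mask &= self.lineage == lineage
        return mask

    def subset_cells(self, mask: np.ndarray) -> "CellExpressionSet":
        """New set restricted to cells where ``mask`` is True (order kept)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask

        def _take(m):
            if m is None:
                return None
            return m.tocsc()[:, idx] if sp.issparse(m) else np.asarray(m)[:, idx]

        return CellExpressionSet(
            counts=_take(self.counts),
            genes=self.genes,
            cells=self.cells[idx],
            tissue=self.tissue[idx],
            lineage=self.lineage[idx],
            normalized=_take(self.normalized),
            zscored=_take(self.zscored),
        )

    def counts_dense(self) -> np.ndarray:
        c = self.counts
        return c.toarray() if sp.issparse(c) else np.asarray(c)

    def normalized_dense(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("normalized matrix absent; run normalize_lognorm first")
        m = self.normalized
        return m.toarray() if sp.issparse(m) else np.asarray(m)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes, counts in X)."""
        import anndata as ad

        X = self.counts.T.tocsr() if sp.issparse(self.counts) else np.asarray(self.counts).T
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(
                {"tissue": self.tissue, "lineage": self.lineage},
                index=self.cells.astype(str),
            ),
            var=pd.DataFrame(index=self.genes.astype(str)),
        )
        if self.normalized is not None:
            m = self.normalized
            adata.layers["lognorm"] = m.T.tocsr() if sp.issparse(m) else np.asarray(m).T
        return adata


@dataclass
class SurvivalCohort:
    """Gene x sample expression with overall-survival follow-up.

    ``expr`` holds real-valued (log2-scale expected) expression, genes as the
    row index and sample ids as columns.  ``time`` is nonnegative follow-up,
    ``event`` is 1 for an observed death and 0 for censoring.  ``grade`` is an
    optional per-sample ordinal histological grade.
    """

    expr: pd.DataFrame
    time: pd.Series
    event: pd.Series
    cohort: str = "cohort"
    grade: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.expr = pd.DataFrame(self.expr)
        samples = self.expr.columns
        if not samples.is_unique or not self.expr.index.is_unique:
            raise ValueError("sample ids and gene symbols must be unique")
        self.time = pd.Series(self.time, index=samples, dtype=float)
        self.event = pd.Series(self.event, index=samples, dtype=int)
        if (self.time < 0).any():
            raise ValueError("follow-up times must be nonnegative")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if self.grade is not None:
            self.grade = pd.Series(self.grade, index=samples)

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def subset_samples(self, samples: Sequence) -> "SurvivalCohort":
        samples = pd.Index(samples)
        return SurvivalCohort(
            expr=self.expr[samples],
            time=self.time[samples],
            event=self.event[samples],
            cohort=self.cohort,
            grade=None if self.grade is None else self.grade[samples],
        )


def qc_filter_cells(
    cset: CellExpressionSet, min_genes: int = 200, max_genes: int = 5000
) -> CellExpressionSet:
    """Remove cells by unique-gene count, keeping the closed interval
    [``min_genes``, ``max_genes``].

    A cell's unique-gene count is its number of genes with raw count > 0.
    Defaults remove cells with fewer than 200 or more than 5000 unique genes,
    the standard droplet-QC band.  Cell order is preserved; an empty result is
    permitted with a warning.
    """
    c = cset.counts
    if sp.issparse(c):
        per_cell = np.asarray((c > 0).sum(axis=0)).ravel()
    else:
        per_cell = (np.asarray(c) > 0).sum(axis=0)
    keep = (per_cell >= min_genes) & (per_cell <= max_genes)
    if not keep.any():
        warnings.warn("QC filter removed every cell", UserWarning, stacklevel=2)
    return cset.subset_cells(keep)


def normalize_lognorm(cset: CellExpressionSet, scale_total: float = 1e4) -> CellExpressionSet:
    """Depth-normalize and log-transform counts.

    Each cell's counts are scaled so its total equals ``scale_total``
    (default 10,000), then natural-log transformed after adding a pseudocount
    of one: ``ln(count / total * scale_total + 1)``.  Raw counts are kept
    untouched; the result is stored in ``normalized``.
    """
    c = cset.counts
    if sp.issparse(c):
        totals = np.asarray(c.sum(axis=0)).ravel()
    else:
        totals = np.asarray(c).sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError(
            "cells with zero total counts present; run qc_filter_cells before normalizing"
        )
    if sp.issparse(c):
        norm = c.tocsc().astype(float)
        norm = norm.multiply(sp.csr_matrix(scale_total / totals)).tocsc()
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(np.asarray(c, dtype=float) / totals * scale_total)
    return replace(cset, normalized=norm, zscored=None)


def zscore_genes(cset: CellExpressionSet) -> CellExpressionSet:
    """Z-score each gene's normalized values to mean 0, sd 1 across cells.

    Uses the population standard deviation (divisor n).  Zero-variance genes
    map to all-zeros.  Result stored densely in ``zscored``.
    """
    m = cset.normalized_dense()
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (m - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return replace(cset, zscored=z)


# ---------------------------------------------------------------------------
# on-disk formats


def write_sc_triplet(cset: CellExpressionSet, outdir: str | Path) -> None:
    """Write the 10x-style triplet: matrix.mtx, genes.tsv, barcodes.tsv.

    The matrix is gene-major (genes as rows).  barcodes.tsv carries the
    tissue and lineage annotation columns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = cset.counts if sp.issparse(cset.counts) else sp.coo_matrix(cset.counts)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat.astype(int))
    pd.Series(cset.genes).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame(
        {"barcode": cset.cells, "tissue": cset.tissue, "lineage": cset.lineage}
    ).to_csv(outdir / "barcodes.tsv", sep="\t", index=False)


def read_sc_triplet(indir: str | Path) -> CellExpressionSet:
    """Read a triplet written by :func:`write_sc_triplet`."""
    indir = Path(indir)
    counts = sp.csc_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    ann = pd.read_csv(indir / "barcodes.tsv", sep="\t", dtype=str)
    return CellExpressionSet(
        counts=counts,
        genes=pd.Index(genes),
        cells=pd.Index(ann["barcode"]),
        tissue=ann["tissue"].to_numpy(),
        lineage=ann["lineage"].to_numpy(),
    )


def write_survival_tsv(cohort: SurvivalCohort, path: str | Path) -> None:
    """Write sample_id, time, event, grade, then one column per gene."""
    df = pd.DataFrame(
        {
            "sample_id": cohort.samples,
            "time": cohort.time.to_numpy(),
            "event": cohort.event.to_numpy(),
            "grade": (
                cohort.grade.to_numpy() if cohort.grade is not None else [""] * cohort.n_samples
            ),
        }
    )
    df = pd.concat([df.reset_index(drop=True), cohort.expr.T.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_survival_tsv(path: str | Path, cohort: str | None = None) -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t")
    meta = ["sample_id", "time", "event", "grade"]
    genes = [c for c in df.columns if c not in meta]
    grade = None
    if "grade" in df.columns and not df["grade"].isna().all():
        grade = pd.Series(df["grade"].to_numpy(), index=df["sample_id"])
    return SurvivalCohort(
        expr=pd.DataFrame(
            df[genes].to_numpy().T, index=pd.Index(genes, name="gene"), columns=df["sample_id"]
        ),
        time=pd.Series(df["time"].to_numpy(), index=df["sample_id"]),
        event=pd.Series(df["event"].to_numpy(), index=df["sample_id"]),
        cohort=cohort or Path(path).stem,
        grade=grade,
    )
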