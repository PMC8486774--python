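"""T-cell phenotype gene sets and a mean z-score cell scorer.

The bundled fixtures are the four T-cell state signatures used throughout
the analysis (cytotoxicity, exhaustion, naive, effector/memory).  Scoring is
the declared simplification of single-sample enrichment: the per-cell mean of
z-scored expression over the set members present in the matrix — deterministic
and directly checkable against hand arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import CellExpressionSet

__all__ = ["GeneSet", "read_gmt", "write_gmt", "bundled_gene_sets", "score_cells", "ScoreResult"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


@dataclass(frozen=True)
class ScoreResult:
    """Per-cell scores plus how much of the set was actually found."""

    scores: pd.Series
    genes_found: tuple[str, ...]
    fraction_found: float


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: one set per line, tab-separated name, description, genes."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(name=fields[0], genes=tuple(fields[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, "na", *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def bundled_gene_sets() -> dict[str, GeneSet]:
    """The four bundled T-cell phenotype signatures, keyed by name."""
    with resources.as_file(
        resources.files("tregsig").joinpath("data/tcell_signatures.gmt")
    ) as p:
        return {s.name: s for s in read_gmt(p)}


def score_cells(cset: CellExpressionSet, gene_set: GeneSet) -> ScoreResult:
    """Mean z-scored expression of the set's present members, per cell."""
    if cset.zscored is None:
        raise ValueError("z-scored values absent; run zscore_genes first")
    present = [g for g in gene_set.genes if g in cset.genes]
    if not present:
        raise ValueError(f"no member of gene set {gene_set.name!r} is in the matrix")
    idx = cset.genes.get_indexer(present)
    scores = np.asarray(cset.zscored)[idx].mean(axis=0)
    return ScoreResult(
        scores=pd.Series(scores, index=cset.cells, name=gene_set.name),
        genes_found=tuple(present),
        fraction_found=len(present) / len(gene_set.genes),
    )
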