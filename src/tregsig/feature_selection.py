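"""Randomized ensemble best-subset feature selection.

Exhaustive best-subset regression is infeasible over hundreds of candidate
genes at once, so the signature is built by a randomized ensemble: in each
round the candidate genes are shuffled and partitioned into small disjoint
groups (default < 30 genes each), an exact best five-predictor least-squares
model is found within every group, and each gene of a winning model earns a
point.  Rounds repeat until every gene has taken part in exactly ``rounds``
best-subset selections (default 500); the genes with the highest point
tallies (default six) form the signature.

``best_subset`` itself is exact, never heuristic: it enumerates every
size-k subset and scores residual sums of squares with batched linear
algebra on the centered Gram matrix, which is fast for the group sizes this
schedule produces (C(29,5) = 118,755 subsets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SurvivalCohort

__all__ = [
    "EnsembleConfig",
    "EnsembleScore",
    "best_subset",
    "ensemble_score",
    "select_signature",
]

_MAX_SUBSETS = 5_000_000  # guard: beyond this, exhaustive enumeration refused

RESPONSE_MODES = ("event", "log_time", "martingale")


@dataclass
class EnsembleConfig:
    """Parameters of the ensemble scoring schedule.

    ``rounds`` is the per-gene replication target (every candidate ends up in
    exactly this many best-subset models); ``max_group_size`` caps the random
    groups (the schedule uses groups of fewer than 30 genes);
    ``subset_size`` is the exact size of the winning model (five predictors);
    ``signature_size`` is how many top-tally genes form the signature (six).

    ``response`` picks the numeric least-squares response derived from the
    survival outcome: ``martingale`` (default) regresses on the martingale
    residual of a covariate-free Cox fit — the standard working response for
    least-squares screening of censored outcomes; ``event`` uses the raw 0/1
    event indicator (it ignores follow-up time and is markedly less
    sensitive); ``log_time`` uses log observed time.
    """

    candidate_genes: Sequence[str]
    rounds: int = 500
    max_group_size: int = 29
    subset_size: int = 5
    signature_size: int = 6
    response: str = "martingale"
    seed: int = 0

    def __post_init__(self) -> None:
        self.candidate_genes = list(self.candidate_genes)
        if len(set(self.candidate_genes)) != len(self.candidate_genes):
            raise ValueError("candidate genes must be unique")
        if self.rounds < 1:
            raise ValueError("rounds must be positive")
        if not (0 < self.max_group_size < 30):
            raise ValueError("max_group_size must be in [1, 29]")
        if self.subset_size < 1 or self.subset_size > self.max_group_size:
            raise ValueError("need 1 <= subset_size <= max_group_size")
        if len(self.candidate_genes) < self.subset_size:
            raise ValueError(
                f"{len(self.candidate_genes)} candidates < subset_size {self.subset_size}"
            )
        if self.signature_size < 1 or self.signature_size > len(self.candidate_genes):
            raise ValueError("signature_size must be in [1, n_candidates]")
        if self.response not in RESPONSE_MODES:
            raise ValueError(f"response must be one of {RESPONSE_MODES}")


@dataclass
class EnsembleScore:
    """Result of the ensemble schedule.

    ``points`` counts winning-model memberships per gene; ``inclusions``
    counts the best-subset runs each gene participated in (identical across
    genes at completion, equal to ``rounds``); ``rss_gain`` accumulates, for
    each gene, the (intercept-only RSS - winning-model RSS) of the models it
    won — used only as the deterministic tie-break.  ``history`` lists every
    winning subset as (round, genes).
    """

    points: pd.Series
    inclusions: pd.Series
    rss_gain: pd.Series
    history: list[tuple[int, tuple[str, ...]]] = field(default_factory=list)
    n_models: int = 0
    subset_size: int = 5


def _subset_index_array(p: int, k: int) -> np.ndarray:
    n = math.comb(p, k)
    if n > _MAX_SUBSETS:
        raise ValueError(
            f"C({p},{k}) = {n} subsets exceeds the exhaustive-enumeration guard"
        )
    return np.fromiter(
        (i for c in combinations(range(p), k) for i in c), dtype=np.intp, count=n * k
    ).reshape(n, k)


def best_subset(
    features: np.ndarray, response: np.ndarray, k: int, return_rss: bool = False
):
    """Exact size-k best subset for least squares with intercept.

    ``features`` is feature x sample; returns the indices (ascending) of the
    subset minimizing the residual sum of squares, ties broken toward the
    lexicographically smallest index tuple.  With ``return_rss``, also
    returns (best RSS, intercept-only RSS).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(response, dtype=float)
    p, n = X.shape
    if k > p:
        raise ValueError(f"k={k} exceeds {p} features")
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("constant response")

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    G = Xc @ Xc.T
    b = Xc @ yc
    tss = float(yc @ yc)

    subsets = _subset_index_array(p, k)
    Gs = G[subsets[:, :, None], subsets[:, None, :]]  # (n_subsets, k, k)
    bs = b[subsets]  # (n_subsets, k)
    try:
        coef = np.linalg.solve(Gs, bs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        warnings.warn(
            "rank-deficient subset design; refitting with an epsilon ridge",
            UserWarning,
            stacklevel=2,
        )
        eps = 1e-8 * (np.trace(G) / max(p, 1) or 1.0)
        Gs = Gs + eps * np.eye(k)
        coef = np.linalg.solve(Gs, bs[..., None])[..., 0]
    rss = tss - np.einsum("ij,ij->i", bs, coef)
    bad = ~np.isfinite(rss)
    if bad.any():
        warnings.warn(
            "rank-deficient subset design; refitting with an epsilon ridge",
            UserWarning,
            stacklevel=2,
        )
        eps = 1e-8 * (np.trace(G) / max(p, 1) or 1.0)
        Gb = Gs[bad] + eps * np.eye(k)
        coef_b = np.linalg.solve(Gb, bs[bad][..., None])[..., 0]
        rss[bad] = tss - np.einsum("ij,ij->i", bs[bad], coef_b)
    best = int(np.argmin(rss))  # argmin takes the first = lexicographic winner
    idx = subsets[best]
    if return_rss:
        return idx, float(rss[best]), tss
    return idx


def _response_vector(cohort: SurvivalCohort, mode: str) -> np.ndarray:
    """Numeric least-squares response derived from the survival outcome."""
    if mode == "event":
        return cohort.event.to_numpy(dtype=float)
    if mode == "log_time":
        return np.log(cohort.time.to_numpy(dtype=float) + 1e-9)
    if mode == "martingale":
        # Martingale residual of a covariate-free Cox model: event - Nelson-
        # Aalen cumulative hazard at the observed time.
        from lifelines import NelsonAalenFitter

        naf = NelsonAalenFitter()
        naf.fit(cohort.time, event_observed=cohort.event)
        h = naf.cumulative_hazard_at_times(cohort.time).to_numpy()
        return cohort.event.to_numpy(dtype=float) - h
    raise ValueError(mode)


def _round_rng(seed: int, round_idx: int) -> np.random.Generator:
    """Counter-based per-round stream: any round is reproducible alone."""
    return np.random.Generator(
        np.random.Philox(key=seed & ((1 << 64) - 1), counter=[0, 0, 0, round_idx])
    )


def ensemble_score(cohort: SurvivalCohort, config: EnsembleConfig) -> EnsembleScore:
    """Run the randomized ensemble best-subset schedule to completion.

    Each round partitions the shuffled candidates into disjoint groups of at
    most ``max_group_size`` genes (a remainder smaller than ``subset_size``
    is merged into the previous group), runs the exact best
    ``subset_size``-predictor selection within each group against the
    survival response, and awards one point to every gene of each winning
    model.  Every candidate is in exactly one group per round, so after
    ``rounds`` rounds all inclusion counts equal ``rounds``.
    """
    genes = list(config.candidate_genes)
    missing = [g for g in genes if g not in cohort.genes]
    if missing:
        raise ValueError(f"candidate genes absent from cohort: {missing[:5]}")
    expr = cohort.expr.loc[genes].to_numpy(dtype=float)
    mu = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    expr = (expr - mu) / sd
    y = _response_vector(cohort, config.response)
    if np.ptp(y) == 0:
        raise ValueError("survival response is constant; cannot rank models")

    m = len(genes)
    points = np.zeros(m, dtype=int)
    inclusions = np.zeros(m, dtype=int)
    rss_gain = np.zeros(m, dtype=float)
    history: list[tuple[int, tuple[str, ...]]] = []
    n_models = 0

    for r in range(config.rounds):
        order = _round_rng(config.seed, r).permutation(m)
        bounds = list(range(0, m, config.max_group_size))
        groups = [order[i : i + config.max_group_size] for i in bounds]
        if len(groups) > 1 and len(groups[-1]) < config.subset_size:
            tail = groups.pop()
            groups[-1] = np.concatenate([groups[-1], tail])
        for grp in groups:
            idx, rss, tss = best_subset(
                expr[grp], y, config.subset_size, return_rss=True
            )
            winners = grp[idx]
            points[winners] += 1
            rss_gain[winners] += tss - rss
            inclusions[grp] += 1
            n_models += 1
            history.append((r, tuple(genes[i] for i in sorted(winners))))

    gi = pd.Index(genes, name="gene")
    return EnsembleScore(
        points=pd.Series(points, index=gi, name="points"),
        inclusions=pd.Series(inclusions, index=gi, name="inclusions"),
        rss_gain=pd.Series(rss_gain, index=gi, name="rss_gain"),
        history=history,
        n_models=n_models,
        subset_size=config.subset_size,
    )


def select_signature(score: EnsembleScore, config: EnsembleConfig) -> list[str]:
    """Top ``signature_size`` genes by point tally, ordered descending.

    Ties are broken deterministically: higher cumulative RSS improvement in
    the models the gene won, then lexicographic gene symbol.
    """
    df = pd.DataFrame(
        {
            "points": score.points.to_numpy(),
            "rss_gain": score.rss_gain.to_numpy(),
            "gene": score.points.index.to_numpy(),
        }
    )
    df = df.sort_values(
        ["points", "rss_gain", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    return df["gene"].head(config.signature_size).tolist()
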