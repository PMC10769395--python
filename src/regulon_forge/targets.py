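"""Threshold-filtering of differential-expression tables and the set
algebra that calls direct targets (bound AND deregulated genes).

Fold-change thresholds are accepted on the linear scale (e.g. 1.5-fold)
and compared on the log2 scale, inclusively; FDR thresholds are strict
(``fdr < cutoff``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genomic_io import DERecord

__all__ = [
    "DegSet",
    "DirectTargetSet",
    "filter_degs",
    "intersect_experiments",
    "filter_by_gene_list",
    "call_direct_targets",
    "overlap_classes",
]


@dataclass(frozen=True)
class DegSet:
    """Up/down deregulated gene sets from one experiment at fixed thresholds."""

    experiment_id: str
    up: frozenset[str]
    down: frozenset[str]
    fc_threshold: float
    fdr_threshold: float

    def __post_init__(self) -> None:
        common = self.up & self.down
        if common:
            raise ValueError(f"genes in both up and down sets: {sorted(common)[:5]}")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    def write(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        for label, genes in (("up", self.up), ("down", self.down)):
            with open(directory / f"{prefix}{self.experiment_id}_{label}.txt", "w") as fh:
                for g in sorted(genes):
                    fh.write(g + "\n")


@dataclass(frozen=True)
class DirectTargetSet:
    """Bound genes split by regulation sign after intersection with a DegSet."""

    bound: frozenset[str]
    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive <= self.bound or not self.negative <= self.bound:
            raise ValueError("target sets must be subsets of the bound set")
        if self.positive & self.negative:
            raise ValueError("positive and negative target sets overlap")

    @property
    def targets(self) -> frozenset[str]:
        return self.positive | self.negative

    @property
    def n_targets(self) -> int:
        return len(self.targets)


def filter_degs(
    records: Sequence[DERecord],
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    experiment_id: str = "experiment",
) -> DegSet:
    """Select up/down deregulated genes at a fold-change and FDR cutoff.

    ``up``: ``log2fc >= log2(fc_threshold)``; ``down``:
    ``log2fc <= -log2(fc_threshold)``; both require ``fdr < fdr_threshold``.
    The fold-change boundary is inclusive, the FDR boundary strict.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold is a linear fold change and must be >= 1")
    if not 0 < fdr_threshold <= 1:
        raise ValueError("fdr_threshold must be in (0, 1]")
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene_id {r.gene_id!r}")
        seen.add(r.gene_id)
    log2_cut = math.log2(fc_threshold)
    up = frozenset(
        r.gene_id for r in records if r.log2fc >= log2_cut and r.fdr < fdr_threshold
    )
    # at fc_threshold == 1 the cut is 0 and a zero-fold-change gene would
    # satisfy both directions; up wins so the sets stay disjoint
    down = frozenset(
        r.gene_id
        for r in records
        if r.log2fc <= -log2_cut and r.fdr < fdr_threshold and r.gene_id not in up
    )
    return DegSet(
        experiment_id=experiment_id,
        up=up,
        down=down,
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
    )


def intersect_experiments(sets: Sequence[DegSet], experiment_id: str = "intersection") -> DegSet:
    """Genes consistently up (or down) across all experiments.

    A gene must appear with the same sign in every set; genes that flip
    sign anywhere are excluded from both directions.
    """
    if len(sets) < 2:
        raise ValueError("intersect_experiments requires at least two DegSets")
    up = frozenset.intersection(*(s.up for s in sets))
    down = frozenset.intersection(*(s.down for s in sets))
    # a gene up in one experiment and down in another is contradictory
    conflicted = frozenset(
        g
        for g in (up | down)
        if any(g in s.down for s in sets) and any(g in s.up for s in sets)
    )
    return DegSet(
        experiment_id=experiment_id,
        up=up - conflicted,
        down=down - conflicted,
        fc_threshold=max(s.fc_threshold for s in sets),
        fdr_threshold=min(s.fdr_threshold for s in sets),
    )


def filter_by_gene_list(deg_set: DegSet, curated_list: Iterable[str]) -> DegSet:
    """Restrict a DegSet to a curated identifier list (e.g. TF genes)."""
    curated = frozenset(curated_list)
    if not curated:
        raise ValueError("curated list must be non-empty")
    return DegSet(
        experiment_id=f"{deg_set.experiment_id}|curated",
        up=deg_set.up & curated,
        down=deg_set.down & curated,
        fc_threshold=deg_set.fc_threshold,
        fdr_threshold=deg_set.fdr_threshold,
    )


def call_direct_targets(bound_genes: Iterable[str], deg_set: DegSet) -> DirectTargetSet:
    """Intersect factor-bound genes with a DegSet.

    Positive targets are bound and up; negative targets bound and down.
    """
    bound = frozenset(bound_genes)
    return DirectTargetSet(
        bound=bound, positive=bound & deg_set.up, negative=bound & deg_set.down
    )


@dataclass(frozen=True)
class OverlapResult:
    n_overlap: int
    n_a: int
    n_b: int
    jaccard: float
    members: frozenset[str]


def overlap_classes(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapResult:
    """Overlap statistics between two gene sets (counts + Jaccard)."""
    a, b = frozenset(set_a), frozenset(set_b)
    inter = a & b
    union = a | b
    return OverlapResult(
        n_overlap=len(inter),
        n_a=len(a),
        n_b=len(b),
        jaccard=len(inter) / len(union) if union else 0.0,
        members=inter,
    )
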