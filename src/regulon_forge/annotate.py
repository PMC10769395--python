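"""Promoter/distal classification of peaks, peak-to-gene assignment, and
repressive histone-mark category calling per gene locus.

The promoter of a gene is the strand-aware window of positions whose
signed distance ``d`` to the TSS satisfies ``-3000 <= d < +1000``, where
``d = p - t`` on the plus strand and ``d = t - p`` on the minus strand
(``t`` = BED start for plus genes, BED end - 1 for minus genes). A peak
is *promoter* when its summit lies in any gene's promoter window, else
*distal*.

Distances between disjoint half-open intervals are base-pair gaps:
adjacent intervals ``[a,b)`` / ``[b,c)`` have distance 0 without
overlapping.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genomic_io import GeneModel, Peak

__all__ = [
    "PromoterInterval",
    "MarkCategory",
    "MARK_CATEGORIES",
    "tss",
    "promoter_interval",
    "classify_peak",
    "promoter_fraction",
    "assign_peaks_to_genes",
    "interval_gap",
    "mark_category",
    "summarize_mark_categories",
]

PROMOTER_UPSTREAM = 3000
PROMOTER_DOWNSTREAM = 1000

MARK_CATEGORIES = ("H3K9me3_only", "H3K27me3_only", "both", "none")


def tss(gene: GeneModel) -> int:
    """Transcription start site: BED start on +, BED end - 1 on -."""
    return gene.start if gene.strand == "+" else gene.end - 1


@dataclass(frozen=True)
class PromoterInterval:
    """Half-open promoter window [start, end) of one gene."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end


def promoter_interval(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PromoterInterval:
    """The strand-aware promoter window around the TSS.

    Solving ``-upstream <= d < downstream`` for the position gives
    ``[t - upstream, t + downstream)`` on the plus strand and
    ``[t - downstream + 1, t + upstream + 1)`` on the minus strand; both
    have length ``upstream + downstream`` and contain the TSS. The window
    may extend past chromosome bounds; callers clamp if needed.
    """
    t = tss(gene)
    if gene.strand == "+":
        start, end = t - upstream, t + downstream
    else:
        start, end = t - downstream + 1, t + upstream + 1
    return PromoterInterval(gene_id=gene.gene_id, chrom=gene.chrom, start=start, end=end)


def _promoters_by_chrom(
    genes: Sequence[GeneModel], upstream: int, downstream: int
) -> dict[str, list[PromoterInterval]]:
    index: dict[str, list[PromoterInterval]] = defaultdict(list)
    for gene in genes:
        p = promoter_interval(gene, upstream, downstream)
        index[p.chrom].append(p)
    return index


def classify_peak(
    peak: Peak,
    genes: Sequence[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    use_summit: bool = True,
) -> str:
    """Classify one peak as ``promoter`` or ``distal``.

    Membership is tested at the summit by default; ``use_summit=False``
    switches to any-overlap between the peak interval and the promoter.
    """
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        window = promoter_interval(gene, upstream, downstream)
        if use_summit:
            if peak.summit in window:
                return "promoter"
        else:
            if peak.start < window.end and window.start < peak.end:
                return "promoter"
    return "distal"


def promoter_fraction(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> float:
    """Percentage of peaks classified as promoter, in [0, 100]."""
    if not peaks:
        raise ValueError("promoter_fraction requires a non-empty peak list")
    index = _promoters_by_chrom(genes, upstream, downstream)
    n_prom = 0
    for peak in peaks:
        if any(peak.summit in w for w in index.get(peak.chrom, ())):
            n_prom += 1
    return 100.0 * n_prom / len(peaks)


def assign_peaks_to_genes(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], flank: int = 5000
) -> dict[str, list[Peak]]:
    """Assign each peak to every gene whose flank-extended span it overlaps.

    The extended span is ``[max(start - flank, 0), end + flank)``; overlap
    is half-open interval intersection. A gene is "bound" iff its list is
    non-empty; unbound genes map to empty lists.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)
    assignment: dict[str, list[Peak]] = {}
    for gene in genes:
        lo = max(gene.start - flank, 0)
        hi = gene.end + flank
        assignment[gene.gene_id] = [
            p for p in by_chrom.get(gene.chrom, ()) if p.start < hi and lo < p.end
        ]
    return assignment


def bound_genes(assignment: dict[str, list[Peak]]) -> set[str]:
    return {g for g, hits in assignment.items() if hits}


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Base-pair gap between two half-open intervals; 0 if they overlap
    or are directly adjacent."""
    if a_start < b_end and b_start < a_end:
        return 0
    if b_start >= a_end:
        return b_start - a_end
    return a_start - b_end


@dataclass(frozen=True)
class MarkCategory:
    """Repressive-mark assignment of one gene locus."""

    gene_id: str
    category: str
    closest_mark: str
    distance_k9: int | None
    distance_k27: int | None

    def __post_init__(self) -> None:
        if self.category not in MARK_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _nearest_gap(gene: GeneModel, marks: Iterable[Peak]) -> int | None:
    gaps = [
        interval_gap(gene.start, gene.end, m.start, m.end)
        for m in marks
        if m.chrom == gene.chrom
    ]
    return min(gaps) if gaps else None


def mark_category(
    gene: GeneModel,
    k9_peaks: Sequence[Peak],
    k27_peaks: Sequence[Peak],
    window: int = 10000,
) -> MarkCategory:
    """Assign a repressive-mark category to one gene locus.

    A mark is *present* when the nearest peak of that mark lies within
    ``window`` bp of the gene span (gap 0 for overlap). ``closest_mark``
    is the present mark with the smaller gap; an exact tie between two
    present marks reports ``both_tied``.
    """
    d9 = _nearest_gap(gene, k9_peaks)
    d27 = _nearest_gap(gene, k27_peaks)
    has9 = d9 is not None and d9 <= window
    has27 = d27 is not None and d27 <= window
    if has9 and has27:
        category = "both"
        if d9 == d27:
            closest = "both_tied"
        else:
            closest = "H3K9me3" if d9 < d27 else "H3K27me3"
    elif has9:
        category, closest = "H3K9me3_only", "H3K9me3"
    elif has27:
        category, closest = "H3K27me3_only", "H3K27me3"
    else:
        category, closest = "none", "none"
    return MarkCategory(
        gene_id=gene.gene_id,
        category=category,
        closest_mark=closest,
        distance_k9=d9,
        distance_k27=d27,
    )


@dataclass(frozen=True)
class MarkCategorySummary:
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]          # exact values
    percentages_rounded: dict[str, int]    # nearest integer, as reported

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\tpct\tpct_rounded\n")
            for cat in MARK_CATEGORIES:
                fh.write(
                    f"{cat}\t{self.counts[cat]}\t{self.percentages[cat]:.4f}\t"
                    f"{self.percentages_rounded[cat]}\n"
                )


def summarize_mark_categories(categories: Sequence[MarkCategory]) -> MarkCategorySummary:
    """Count and percentage per category over a list of gene loci."""
    if not categories:
        raise ValueError("summarize_mark_categories requires a non-empty list")
    counts = {c: 0 for c in MARK_CATEGORIES}
    for mc in categories:
        counts[mc.category] += 1
    total = len(categories)
    pct = {c: 100.0 * counts[c] / total for c in MARK_CATEGORIES}
    # round-half-up to the nearest integer for reporting
    rounded = {c: int(pct[c] + 0.5) for c in MARK_CATEGORIES}
    return MarkCategorySummary(
        total=total, counts=counts, percentages=pct, percentages_rounded=rounded
    )
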