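"""Consecutive GGAA/TTCC repeat-run profiling in windows around peak summits.

A *run* is a maximal stretch of gapless, tandem copies of a 4-bp motif:
``GGAAGGAAGGAA`` is one run with multiplicity ``n = 3``, never three runs
of 1 or nested shorter runs. Runs of the two motifs are scanned
independently over the forward strand and, by default, pooled — a
plus-strand GGAA microsatellite and its minus-strand TTCC image are the
same element, so pooling counts each element once.

Runs are binned by multiplicity into the five classes ``1, 2, 3, 4, >4``
and summarized per peak set as the percentage of peaks with at least one
run in the bin and the average number of runs per peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genomic_io import Genome, Peak

__all__ = [
    "MotifRun",
    "SummitWindow",
    "RepeatProfile",
    "BINS",
    "DEFAULT_MOTIFS",
    "extract_summit_window",
    "find_motif_runs",
    "bin_label",
    "profile_peaks",
    "reverse_complement",
]

#: run-multiplicity classes, in report order
BINS: tuple[str, ...] = ("1", "2", "3", "4", ">4")

DEFAULT_MOTIFS: tuple[str, str] = ("GGAA", "TTCC")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifRun:
    """A maximal gapless run of ``n`` tandem copies of ``motif``."""

    window_offset: int
    motif: str
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("run multiplicity must be >= 1")


@dataclass(frozen=True)
class SummitWindow:
    """An extracted summit-centered slice, flagged if chromosome-end clamped."""

    chrom: str
    start: int
    end: int
    sequence: str
    truncated: bool


def extract_summit_window(
    peak: Peak, genome: Genome, width: int = 500
) -> SummitWindow:
    """Extract the ``width``-bp genomic window centered on the peak summit.

    The window is ``[summit - width/2, summit + width/2)``; when no summit
    was called the interval midpoint stands in. Windows running off a
    chromosome end are clamped and flagged ``truncated``.
    """
    if width < 4 or width % 2 != 0:
        raise ValueError(f"width must be even and >= 4, got {width}")
    if peak.chrom not in genome:
        raise KeyError(f"chromosome {peak.chrom!r} not in genome")
    chrom = genome[peak.chrom]
    half = width // 2
    summit = peak.summit
    lo, hi = summit - half, summit + half
    start, end = max(lo, 0), min(hi, len(chrom))
    if start >= end:
        raise ValueError(
            f"window [{lo}, {hi}) for peak {peak.name!r} lies entirely "
            f"outside chromosome {peak.chrom!r}"
        )
    return SummitWindow(
        chrom=peak.chrom,
        start=start,
        end=end,
        sequence=chrom.slice(start, end),
        truncated=(start != lo or end != hi),
    )


def find_motif_runs(sequence: str, motif: str) -> list[MotifRun]:
    """Scan ``sequence`` left to right for maximal gapless runs of ``motif``.

    Greedy left-to-right consumption is unambiguous for motifs (like GGAA
    and TTCC) with no non-trivial self-overlap.
    """
    if len(motif) != 4:
        raise ValueError(f"motif must have length 4, got {motif!r}")
    k = 4
    runs: list[MotifRun] = []
    i = 0
    limit = len(sequence) - k
    while i <= limit:
        if sequence[i : i + k] == motif:
            n = 1
            j = i + k
            while sequence[j : j + k] == motif:
                n += 1
                j += k
            runs.append(MotifRun(window_offset=i, motif=motif, n=n))
            i = j
        else:
            i += 1
    return runs


def bin_label(n: int) -> str:
    """Map a run multiplicity to its report bin."""
    if n < 1:
        raise ValueError("multiplicity must be >= 1")
    return str(n) if n <= 4 else ">4"


@dataclass(frozen=True)
class RepeatProfile:
    """Per-bin summary of repeat runs over a peak set.

    For each bin: how many peaks carry at least one run in the bin, the
    percentage of peaks that do, the total run count, and the mean number
    of runs per peak.
    """

    n_peaks: int
    peaks_with_at_least_one: dict[str, int]
    total_runs: dict[str, int]

    def pct_peaks(self, b: str) -> float:
        return 100.0 * self.peaks_with_at_least_one[b] / self.n_peaks

    def mean_runs_per_peak(self, b: str) -> float:
        return self.total_runs[b] / self.n_peaks

    def run_histogram(self) -> dict[str, int]:
        return dict(self.total_runs)

    def to_rows(self) -> list[dict]:
        return [
            {
                "bin": b,
                "n_peaks": self.n_peaks,
                "peaks_with_at_least_one": self.peaks_with_at_least_one[b],
                "pct_peaks": self.pct_peaks(b),
                "total_runs": self.total_runs[b],
                "mean_runs_per_peak": self.mean_runs_per_peak(b),
            }
            for b in BINS
        ]

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(
                "bin\tn_peaks\tpeaks_with_at_least_one\tpct_peaks\t"
                "total_runs\tmean_runs_per_peak\n"
            )
            for row in self.to_rows():
                fh.write(
                    f"{row['bin']}\t{row['n_peaks']}\t{row['peaks_with_at_least_one']}\t"
                    f"{row['pct_peaks']:.4f}\t{row['total_runs']}\t"
                    f"{row['mean_runs_per_peak']:.6f}\n"
                )


def profile_window_runs(
    sequence: str, motifs: Sequence[str] = DEFAULT_MOTIFS
) -> list[MotifRun]:
    """All maximal runs of every requested motif in one window, pooled."""
    runs: list[MotifRun] = []
    for motif in motifs:
        runs.extend(find_motif_runs(sequence, motif))
    runs.sort(key=lambda r: r.window_offset)
    return runs


def profile_peaks(
    peaks: Sequence[Peak],
    genome: Genome,
    width: int = 500,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
) -> RepeatProfile:
    """Profile repeat runs in summit windows over a peak set.

    Pools runs of all requested motifs per window (default GGAA + TTCC),
    bins by multiplicity, and aggregates per-bin statistics.
    """
    if not peaks:
        raise ValueError("profile_peaks requires a non-empty peak list")
    with_run = {b: 0 for b in BINS}
    totals = {b: 0 for b in BINS}
    for peak in peaks:
        window = extract_summit_window(peak, genome, width=width)
        runs = profile_window_runs(window.sequence, motifs)
        seen_bins: set[str] = set()
        for run in runs:
            b = bin_label(run.n)
            totals[b] += 1
            seen_bins.add(b)
        for b in seen_bins:
            with_run[b] += 1
    return RepeatProfile(
        n_peaks=len(peaks), peaks_with_at_least_one=with_run, total_runs=totals
    )
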