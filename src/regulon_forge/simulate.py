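"""Synthetic-data generators with ground-truth sidecars.

Every input the pipeline consumes can be generated here: genomes with
peaks carrying planted GGAA/TTCC repeat runs, gene models with planted
differential expression, tumor/cell-line expression cohorts with planted
location shifts and correlated regulator-target pairs, histone-mark peak
sets with planted per-gene categories, survival tables with a planted
hazard ratio, and nucleus-detection tables with known path lengths.

Determinism: every generator derives its random stream from
``(config.seed, stream_id)``, so adding a generator never perturbs the
randomness of the others and identical configs yield byte-identical
output files.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    DERecord,
    ExpressionMatrix,
    GeneModel,
    Genome,
    GenomeSequence,
    Peak,
    SurvivalRecord,
    write_de_table,
    write_gene_models,
    write_genome,
    write_intervals,
)

__all__ = [
    "SimulationConfig",
    "simulate_genome_and_peaks",
    "simulate_gene_models_and_de",
    "simulate_mark_peaks",
    "simulate_cohort",
    "simulate_survival",
    "simulate_tracks",
    "write_bundle",
]

# fixed per-generator stream identifiers (never reuse or renumber)
_STREAMS = {
    "genome": 1,
    "de": 2,
    "cohort": 3,
    "tracks": 4,
    "survival": 5,
    "marks": 6,
}

_BASES = np.array(list("ACGT"))

# base written at a planted-run boundary so the run cannot be extended:
# it must differ from the motif's last base (left side) and first base
# (right side); one choice per motif satisfies both.
_BREAKER = {"GGAA": "C", "TTCC": "G"}


def _rng(config: "SimulationConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


@dataclass(frozen=True)
class SimulationConfig:
    """One config drives all generators; fields group by generator."""

    seed: int = 0
    # genome + peaks
    genome_length: int = 100_000          # per chromosome
    n_chromosomes: int = 2
    planted_runs: tuple[tuple[str, int, int], ...] = ()  # (motif, n, count)
    n_peaks: int = 50
    peak_width: int = 400
    window: int = 500                     # profiling window planted runs must fit in
    # gene models + DE
    n_genes: int = 100
    gene_length: int = 2_000
    de_fraction_up: float = 0.1
    de_fraction_down: float = 0.1
    de_effect_log2: float = 1.0
    # marks
    mark_counts: tuple[int, int, int, int] = (23, 9, 7, 21)  # k9/k27/both/none
    mark_window: int = 10_000
    mark_peak_width: int = 1_000
    # cohort
    cohort_n_tumors: int = 79
    cohort_n_celllines: int = 42
    n_null_genes: int = 100
    n_shifted_genes: int = 5
    n_pairs: int = 1
    planted_rho: float = 0.9
    shift_delta: float = 2.0
    # survival
    surv_n: int = 85
    surv_hazard_ratio: float = 3.0
    surv_baseline_hazard: float = 0.02
    surv_censor_time: float = 200.0
    # tracks
    n_tracks: int = 10
    n_frames: int = 49                    # 96 h at 2-h intervals -> 49 time points
    frame_interval: float = 2.0
    speed: float = 5.0
    jitter_sd: float = 1.0
    quality_mean: float = 150.0
    quality_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.de_fraction_up < 0 or self.de_fraction_down < 0:
            raise ValueError("DE fractions must be >= 0")
        if self.de_fraction_up + self.de_fraction_down > 1:
            raise ValueError("DE fractions must sum to <= 1")
        if not -1 < self.planted_rho < 1:
            raise ValueError("planted_rho must lie in (-1, 1)")
        if self.window % 2 != 0 or self.window < 8:
            raise ValueError("window must be even and >= 8")
        for motif, n, count in self.planted_runs:
            if motif not in ("GGAA", "TTCC"):
                raise ValueError(f"planted motif must be GGAA or TTCC, got {motif!r}")
            if n < 1 or count < 0:
                raise ValueError("planted run lengths must be >= 1 and counts >= 0")
        if any(c < 0 for c in self.mark_counts):
            raise ValueError("mark_counts must be non-negative")


# ---------------------------------------------------------------------------
# genome + peaks with planted repeat runs
# ---------------------------------------------------------------------------


@dataclass
class GenomePeaksTruth:
    genome: Genome
    peaks: list[Peak]
    runs: pd.DataFrame  # peak, chrom, genomic_start, window_offset, motif, n, planted

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths = {
            "genome": outdir / "genome.fa",
            "peaks": outdir / "peaks.narrowPeak",
            "runs_truth": outdir / "truth_runs.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_intervals(self.peaks, paths["peaks"], "narrowPeak")
        self.runs.to_csv(paths["runs_truth"], sep="\t", index=False)
        return paths


def _scan_runs_regex(sequence: str) -> list[tuple[int, str, int]]:
    """Independent regex oracle for maximal motif runs: (offset, motif, n)."""
    found: list[tuple[int, str, int]] = []
    for motif in ("GGAA", "TTCC"):
        for m in re.finditer(f"(?:{motif})+", sequence):
            found.append((m.start(), motif, (m.end() - m.start()) // 4))
    found.sort()
    return found


def simulate_genome_and_peaks(config: SimulationConfig) -> GenomePeaksTruth:
    """Generate a uniform-background genome, non-overlapping summit-bearing
    peaks, and planted repeat runs inside the profiling windows.

    Each planted run of ``n`` gapless motif copies is written at a random
    offset within its peak's summit window and flanked by breaker bases so
    it stays maximal at exactly ``n``. The truth table is produced by a
    post-generation regex scan of every window, so it also records any
    accidental background runs (mostly singletons).
    """
    rng = _rng(config, "genome")
    n_chrom = config.n_chromosomes
    if n_chrom < 1 or config.n_peaks < 1:
        raise ValueError("need at least one chromosome and one peak")

    # expand planted runs into per-instance list, one instance per peak
    instances: list[tuple[str, int]] = []
    for motif, n, count in config.planted_runs:
        instances.extend([(motif, n)] * count)
    if len(instances) > config.n_peaks:
        raise ValueError(
            f"{len(instances)} planted runs exceed {config.n_peaks} peaks"
        )
    for motif, n in instances:
        if 4 * n + 2 > config.window:
            raise ValueError(f"planted run ({motif}, n={n}) does not fit the window")

    # non-overlapping peak placement: fixed slots per chromosome
    per_chrom = math.ceil(config.n_peaks / n_chrom)
    slot = config.genome_length // per_chrom
    needed = max(config.peak_width, config.window)
    if slot < needed + 8:
        raise ValueError(
            f"infeasible packing: {config.n_peaks} peaks of footprint {needed} bp "
            f"do not fit {n_chrom} x {config.genome_length} bp"
        )

    seqs = [
        rng.choice(_BASES, size=config.genome_length).tolist()
        for _ in range(n_chrom)
    ]

    peaks: list[Peak] = []
    jitter_max = max(0, (slot - needed) // 2 - 2)
    for i in range(config.n_peaks):
        ci = i % n_chrom
        si = i // n_chrom
        jitter = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
        summit = si * slot + slot // 2 + jitter
        start = summit - config.peak_width // 2
        peaks.append(
            Peak(
                chrom=f"chr{ci + 1}",
                start=start,
                end=start + config.peak_width,
                name=f"peak_{i:05d}",
                score=1000.0,
                strand=".",
                signal=10.0,
                pvalue_neglog10=5.0,
                qvalue_neglog10=3.0,
                summit_offset=config.peak_width // 2,
            )
        )

    half = config.window // 2
    planted_positions: set[tuple[str, int]] = set()
    for (motif, n), peak in zip(instances, peaks):
        run_len = 4 * n
        offset = int(rng.integers(1, config.window - run_len))
        pos = peak.summit - half + offset
        ci = int(peak.chrom[3:]) - 1
        seq = seqs[ci]
        seq[pos : pos + run_len] = list(motif * n)
        breaker = _BREAKER[motif]
        seq[pos - 1] = breaker
        if pos + run_len < len(seq):
            seq[pos + run_len] = breaker
        planted_positions.add((peak.name, offset))

    genome = Genome(
        GenomeSequence(name=f"chr{ci + 1}", sequence="".join(seq))
        for ci, seq in enumerate(seqs)
    )

    # post-generation oracle scan of every window -> truth
    rows = []
    for peak in peaks:
        wstart = peak.summit - half
        window_seq = genome.fetch(peak.chrom, wstart, peak.summit + half)
        for offset, motif, n in _scan_runs_regex(window_seq):
            rows.append(
                {
                    "peak": peak.name,
                    "chrom": peak.chrom,
                    "genomic_start": wstart + offset,
                    "window_offset": offset,
                    "motif": motif,
                    "n": n,
                    "planted": (peak.name, offset) in planted_positions,
                }
            )
    runs = pd.DataFrame(
        rows,
        columns=["peak", "chrom", "genomic_start", "window_offset", "motif", "n", "planted"],
    )
    return GenomePeaksTruth(genome=genome, peaks=peaks, runs=runs)


# ---------------------------------------------------------------------------
# gene models + differential expression
# ---------------------------------------------------------------------------


@dataclass
class GeneDeTruth:
    genes: list[GeneModel]
    de_records: list[DERecord]
    truth: pd.DataFrame  # gene_id, label in {up, down, null}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths = {
            "genes": outdir / "genes.bed",
            "de": outdir / "de_table.tsv",
            "de_truth": outdir / "truth_de.tsv",
        }
        write_gene_models(self.genes, paths["genes"])
        write_de_table(self.de_records, paths["de"])
        self.truth.to_csv(paths["de_truth"], sep="\t", index=False)
        return paths

    def truth_sets(self) -> tuple[set[str], set[str]]:
        up = set(self.truth.loc[self.truth.label == "up", "gene_id"])
        down = set(self.truth.loc[self.truth.label == "down", "gene_id"])
        return up, down


def simulate_gene_models_and_de(config: SimulationConfig) -> GeneDeTruth:
    """Non-overlapping strand-randomized gene spans plus a DE table with
    planted up/down effects.

    Planted genes get ``log2fc = +-de_effect_log2`` with FDR drawn below
    0.05; nulls get ``log2fc ~ N(0, 0.1)`` and FDR uniform on [0.05, 1).
    Gene slots are wide enough that a mark peak planted near one gene
    (see :func:`simulate_mark_peaks`) can never sit within the mark
    window of a neighbouring gene.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(config, "de")
    slot = config.gene_length + 2 * (config.mark_window + 2 * config.mark_peak_width) + 1000
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        start = i * slot + config.mark_window + 2 * config.mark_peak_width
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                chrom="chrDE",
                start=start,
                end=start + config.gene_length,
                gene_id=f"gene_{i:05d}",
                strand=strand,
            )
        )

    n_up = round(config.n_genes * config.de_fraction_up)
    n_down = round(config.n_genes * config.de_fraction_down)
    labels = ["up"] * n_up + ["down"] * n_down + ["null"] * (config.n_genes - n_up - n_down)
    perm = rng.permutation(config.n_genes)
    assigned = [labels[int(j)] for j in np.argsort(perm)]

    records: list[DERecord] = []
    for gene, label in zip(genes, assigned):
        if label == "up":
            lfc = config.de_effect_log2
            fdr = float(rng.uniform(1e-6, 0.05))
        elif label == "down":
            lfc = -config.de_effect_log2
            fdr = float(rng.uniform(1e-6, 0.05))
        else:
            lfc = float(rng.normal(0.0, 0.1))
            fdr = float(rng.uniform(0.05, 1.0))
        records.append(DERecord(gene_id=gene.gene_id, log2fc=lfc, fdr=fdr))

    truth = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "label": assigned}
    )
    return GeneDeTruth(genes=genes, de_records=records, truth=truth)


# ---------------------------------------------------------------------------
# histone-mark peaks with planted per-gene categories
# ---------------------------------------------------------------------------


@dataclass
class MarkTruth:
    k9_peaks: list[Peak]
    k27_peaks: list[Peak]
    truth: pd.DataFrame  # gene_id, category, closest_mark

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths = {
            "k9": outdir / "h3k9me3.broadPeak",
            "k27": outdir / "h3k27me3.broadPeak",
            "marks_truth": outdir / "truth_marks.tsv",
        }
        write_intervals(self.k9_peaks, paths["k9"], "broadPeak")
        write_intervals(self.k27_peaks, paths["k27"], "broadPeak")
        self.truth.to_csv(paths["marks_truth"], sep="\t", index=False)
        return paths


def simulate_mark_peaks(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> MarkTruth:
    """Plant repressive-mark broadPeaks so genes fall into the four
    categories (K9-only / K27-only / both / none) with exact counts.

    Present marks are placed downstream of the gene end at distinct gaps
    within the mark window (distinct so the closest mark is unambiguous);
    ``none`` genes get no nearby peak.
    """
    n_needed = sum(config.mark_counts)
    if n_needed > len(genes):
        raise ValueError(
            f"mark_counts require {n_needed} genes but only {len(genes)} supplied"
        )
    rng = _rng(config, "marks")
    chosen = [genes[int(i)] for i in rng.permutation(len(genes))[:n_needed]]
    categories = (
        ["H3K9me3_only"] * config.mark_counts[0]
        + ["H3K27me3_only"] * config.mark_counts[1]
        + ["both"] * config.mark_counts[2]
        + ["none"] * config.mark_counts[3]
    )
    half_w = config.mark_window // 2
    k9: list[Peak] = []
    k27: list[Peak] = []
    rows = []

    def make_peak(gene: GeneModel, gap: int, mark: str, idx: int) -> Peak:
        start = gene.end + gap
        return Peak(
            chrom=gene.chrom,
            start=start,
            end=start + config.mark_peak_width,
            name=f"{mark}_{idx:04d}",
            score=500.0,
            strand=".",
            signal=5.0,
            pvalue_neglog10=4.0,
            qvalue_neglog10=2.5,
        )

    for idx, (gene, cat) in enumerate(zip(chosen, categories)):
        gap_a = int(rng.integers(0, half_w))
        gap_b = gap_a + 1 + int(rng.integers(0, half_w - 1))  # distinct, still <= window
        if cat == "H3K9me3_only":
            k9.append(make_peak(gene, gap_a, "k9", idx))
            closest = "H3K9me3"
        elif cat == "H3K27me3_only":
            k27.append(make_peak(gene, gap_a, "k27", idx))
            closest = "H3K27me3"
        elif cat == "both":
            if rng.random() < 0.5:
                k9.append(make_peak(gene, gap_a, "k9", idx))
                k27.append(make_peak(gene, gap_b, "k27", idx))
                closest = "H3K9me3"
            else:
                k27.append(make_peak(gene, gap_a, "k27", idx))
                k9.append(make_peak(gene, gap_b, "k9", idx))
                closest = "H3K27me3"
        else:
            closest = "none"
        rows.append({"gene_id": gene.gene_id, "category": cat, "closest_mark": closest})
    truth = pd.DataFrame(rows, columns=["gene_id", "category", "closest_mark"])
    return MarkTruth(k9_peaks=k9, k27_peaks=k27, truth=truth)


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortTruth:
    tumors: ExpressionMatrix
    celllines: ExpressionMatrix
    truth: pd.DataFrame  # gene_id, role, shift_delta, rho, partner

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths = {
            "tumors": outdir / "tumors.tsv",
            "celllines": outdir / "celllines.tsv",
            "cohort_truth": outdir / "truth_cohort.tsv",
        }
        self.tumors.to_tsv(paths["tumors"])
        self.celllines.to_tsv(paths["celllines"])
        self.truth.to_csv(paths["cohort_truth"], sep="\t", index=False)
        return paths


_LOG_MU = 5.0  # mean log2-expression of the background


def _expr_from_log2(z: np.ndarray) -> np.ndarray:
    # 2**z - 1 maps Gaussian log2 values to non-negative, RPKM-like skewed
    # expression; log2(x + 1) inverts it exactly.
    return np.power(2.0, np.clip(z, 0.0, None)) - 1.0


def simulate_cohort(config: SimulationConfig) -> CohortTruth:
    """Tumor and cell-line expression matrices with planted structure.

    Null genes are i.i.d. in both groups; shifted genes have their tumor
    log2 mean raised by ``shift_delta``; each regulator-target pair is
    drawn (within tumors) from a bivariate normal with correlation
    ``planted_rho`` on the log2 scale. All values are mapped to
    non-negative expression via ``2**z - 1``.
    """
    if config.cohort_n_tumors < 3 or config.cohort_n_celllines < 3:
        raise ValueError("cohort sizes must be >= 3")
    rng = _rng(config, "cohort")
    nt, nc = config.cohort_n_tumors, config.cohort_n_celllines
    rows_t: dict[str, np.ndarray] = {}
    rows_c: dict[str, np.ndarray] = {}
    truth_rows = []

    for i in range(config.n_null_genes):
        g = f"null_{i:04d}"
        rows_t[g] = _expr_from_log2(rng.normal(_LOG_MU, 1.0, nt))
        rows_c[g] = _expr_from_log2(rng.normal(_LOG_MU, 1.0, nc))
        truth_rows.append({"gene_id": g, "role": "null", "shift_delta": 0.0,
                           "rho": 0.0, "partner": ""})

    for i in range(config.n_shifted_genes):
        g = f"shift_{i:04d}"
        rows_t[g] = _expr_from_log2(rng.normal(_LOG_MU + config.shift_delta, 1.0, nt))
        rows_c[g] = _expr_from_log2(rng.normal(_LOG_MU, 1.0, nc))
        truth_rows.append({"gene_id": g, "role": "shifted",
                           "shift_delta": config.shift_delta, "rho": 0.0, "partner": ""})

    cov = np.array([[1.0, config.planted_rho], [config.planted_rho, 1.0]])
    for i in range(config.n_pairs):
        reg, tgt = f"reg_{i:04d}", f"tgt_{i:04d}"
        z = rng.multivariate_normal([_LOG_MU, _LOG_MU], cov, size=nt)
        rows_t[reg] = _expr_from_log2(z[:, 0])
        rows_t[tgt] = _expr_from_log2(z[:, 1])
        rows_c[reg] = _expr_from_log2(rng.normal(_LOG_MU, 1.0, nc))
        rows_c[tgt] = _expr_from_log2(rng.normal(_LOG_MU, 1.0, nc))
        truth_rows.append({"gene_id": reg, "role": "regulator", "shift_delta": 0.0,
                           "rho": config.planted_rho, "partner": tgt})
        truth_rows.append({"gene_id": tgt, "role": "target", "shift_delta": 0.0,
                           "rho": config.planted_rho, "partner": reg})

    tumor_frame = pd.DataFrame(
        rows_t, index=[f"T{j:03d}" for j in range(nt)]
    ).T
    cell_frame = pd.DataFrame(
        rows_c, index=[f"C{j:03d}" for j in range(nc)]
    ).T
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "role", "shift_delta", "rho", "partner"]
    )
    return CohortTruth(
        tumors=ExpressionMatrix(tumor_frame),
        celllines=ExpressionMatrix(cell_frame),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalTruth:
    records: list[SurvivalRecord]
    hazard_ratio: float
    cutoff: float

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        path = outdir / "survival.tsv"
        with open(path, "w") as fh:
            fh.write("sample_id\ttime\tevent\texpression\n")
            for r in self.records:
                fh.write(f"{r.sample_id}\t{r.time!r}\t{r.event}\t{r.expression!r}\n")
        return {"survival": path}


def simulate_survival(config: SimulationConfig) -> SurvivalTruth:
    """Exponential survival times with the planted hazard ratio applied to
    the above-median-expression group; uniform censoring."""
    rng = _rng(config, "survival")
    n = config.surv_n
    if n < 4:
        raise ValueError("surv_n must be >= 4")
    expr = rng.normal(_LOG_MU, 1.0, n)
    cutoff = float(np.median(expr))
    high = expr > cutoff
    hazard = config.surv_baseline_hazard * np.where(high, config.surv_hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.surv_censor_time, n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    records = [
        SurvivalRecord(
            sample_id=f"S{j:03d}",
            time=float(time[j]),
            event=int(event[j]),
            expression=float(expr[j]),
        )
        for j in range(n)
    ]
    return SurvivalTruth(records=records, hazard_ratio=config.surv_hazard_ratio,
                         cutoff=cutoff)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class TracksTruth:
    detections: pd.DataFrame  # track_id, frame, x, y, quality
    truth: pd.DataFrame       # track_id, kind, path_length

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths = {
            "detections": outdir / "detections.tsv",
            "tracks_truth": outdir / "truth_tracks.tsv",
        }
        self.detections.to_csv(paths["detections"], sep="\t", index=False)
        self.truth.to_csv(paths["tracks_truth"], sep="\t", index=False)
        return paths


def simulate_tracks(config: SimulationConfig) -> TracksTruth:
    """Directed (constant-velocity) and confined (zero-mean jitter) tracks.

    Starting positions are spaced so far apart that trajectories of
    different tracks can never approach each other, keeping greedy
    nearest-neighbour linking exact. The truth path length is the exact
    sum of Euclidean step lengths of the emitted positions.
    """
    if config.n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = _rng(config, "tracks")
    spacing = 2.0 * config.n_frames * max(config.speed, 3.0 * config.jitter_sd) + 100.0
    det_rows = []
    truth_rows = []
    for i in range(config.n_tracks):
        kind = "directed" if i % 2 == 0 else "confined"
        x0, y0 = i * spacing, 0.0
        if kind == "directed":
            angle = rng.uniform(0.0, 2.0 * np.pi)
            steps = np.full((config.n_frames - 1, 2), config.speed) * np.array(
                [np.cos(angle), np.sin(angle)]
            )
        else:
            steps = rng.normal(0.0, config.jitter_sd, size=(config.n_frames - 1, 2))
        pos = np.vstack([[x0, y0], np.cumsum(steps, axis=0) + [x0, y0]])
        quality = rng.normal(config.quality_mean, config.quality_sd, config.n_frames)
        tid = f"truth_{i:04d}"
        for f in range(config.n_frames):
            det_rows.append(
                {
                    "track_id": tid,
                    "frame": f,
                    "x": float(pos[f, 0]),
                    "y": float(pos[f, 1]),
                    "quality": float(quality[f]),
                }
            )
        path_length = float(np.hypot(*np.diff(pos, axis=0).T).sum())
        truth_rows.append({"track_id": tid, "kind": kind, "path_length": path_length})
    detections = pd.DataFrame(det_rows, columns=["track_id", "frame", "x", "y", "quality"])
    truth = pd.DataFrame(truth_rows, columns=["track_id", "kind", "path_length"])
    return TracksTruth(detections=detections, truth=truth)


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator and write all inputs + truth sidecars to a
    directory; returns the name -> path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gp = simulate_genome_and_peaks(config)
    paths.update(gp.write(outdir))
    gd = simulate_gene_models_and_de(config)
    paths.update(gd.write(outdir))
    marks = simulate_mark_peaks(config, gd.genes)
    paths.update(marks.write(outdir))
    cohort = simulate_cohort(config)
    paths.update(cohort.write(outdir))
    surv = simulate_survival(config)
    paths.update(surv.write(outdir))
    tracks = simulate_tracks(config)
    paths.update(tracks.write(outdir))
    return paths
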