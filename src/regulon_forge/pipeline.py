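"""End-to-end orchestration: simulate -> repeats -> annotate -> targets ->
cohort -> survival -> motility, driven by one YAML config, with a JSON
manifest recording checksums and timing per stage for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    assign_peaks_to_genes,
    bound_genes,
    classify_peak,
    mark_category,
    promoter_fraction,
    summarize_mark_categories,
)
from .cohort import correlation_screen, km_logrank, quartile_concordance, range_screen
from .genomic_io import (
    read_gene_models,
    read_genome,
    read_intervals,
    read_table,
)
from .motility import (
    filter_tracks,
    link_detections,
    metrics_table,
    trajectories_from_table,
)
from .repeats import profile_peaks
from .simulate import SimulationConfig, write_bundle
from .targets import call_direct_targets, filter_degs

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("simulate", "repeats", "annotate", "targets", "cohort", "survival", "motility")

#: per-stage input files (relative to the inputs directory)
_STAGE_INPUTS = {
    "repeats": ("genome.fa", "peaks.narrowPeak"),
    "annotate": ("peaks.narrowPeak", "genes.bed", "h3k9me3.broadPeak", "h3k27me3.broadPeak"),
    "targets": ("de_table.tsv", "genes.bed", "peaks.narrowPeak"),
    "cohort": ("tumors.tsv", "celllines.tsv"),
    "survival": ("survival.tsv",),
    "motility": ("detections.tsv",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (one block per stage)."""

    seed: int = 0
    outdir: Path = Path("regulon_forge_out")
    stages: tuple[str, ...] = ALL_STAGES
    simulate: dict[str, Any] = field(default_factory=dict)
    repeats: dict[str, Any] = field(default_factory=lambda: {"window": 500})
    annotate: dict[str, Any] = field(
        default_factory=lambda: {"flank": 5000, "mark_window": 10000}
    )
    targets: dict[str, Any] = field(
        default_factory=lambda: {"fc": 1.5, "fdr": 0.05, "flank": 5000}
    )
    cohort: dict[str, Any] = field(
        default_factory=lambda: {
            "method": "pearson",
            "q_cut": 0.01,
            "p_cut": 0.01,
            "regulator": "reg_0000",
        }
    )
    survival: dict[str, Any] = field(default_factory=lambda: {"split": "median"})
    motility: dict[str, Any] = field(
        default_factory=lambda: {
            "link_max": 20.0,
            "min_quality": 100.0,
            "min_occurrences": 10,
            "roi": None,
            "use_track_id": True,
        }
    )

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")

    @property
    def inputs_dir(self) -> Path:
        return self.outdir / "inputs"

    def canonical(self) -> str:
        payload = {
            "seed": self.seed,
            "stages": list(self.stages),
            "simulate": self.simulate,
            "repeats": self.repeats,
            "annotate": self.annotate,
            "targets": self.targets,
            "cohort": self.cohort,
            "survival": self.survival,
            "motility": self.motility,
        }
        return yaml.safe_dump(payload, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineError("config file must contain a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_dependencies(config: RunConfig) -> None:
    """Fail before any stage runs if a requested stage lacks its inputs."""
    will_simulate = "simulate" in config.stages
    for stage in config.stages:
        if stage == "simulate":
            continue
        for name in _STAGE_INPUTS[stage]:
            path = config.inputs_dir / name
            if not will_simulate and not path.exists():
                raise PipelineError(
                    f"stage {stage!r} requires {path} which does not exist and "
                    f"the simulate stage was not requested"
                )


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    sim = SimulationConfig(seed=config.seed, **config.simulate)
    paths = write_bundle(sim, config.inputs_dir)
    return list(paths.values())


def _stage_repeats(config: RunConfig, outdir: Path) -> list[Path]:
    genome = read_genome(config.inputs_dir / "genome.fa")
    peaks = read_intervals(config.inputs_dir / "peaks.narrowPeak", "narrowPeak")
    window = int(config.repeats.get("window", 500))
    profile = profile_peaks(peaks, genome, width=window)
    out = outdir / "repeats_profile.tsv"
    profile.to_tsv(out, header_comment=f"window={window} motifs=GGAA+TTCC")
    return [out]


def _stage_annotate(config: RunConfig, outdir: Path) -> list[Path]:
    peaks = read_intervals(config.inputs_dir / "peaks.narrowPeak", "narrowPeak")
    genes = read_gene_models(config.inputs_dir / "genes.bed")
    k9 = read_intervals(config.inputs_dir / "h3k9me3.broadPeak", "broadPeak")
    k27 = read_intervals(config.inputs_dir / "h3k27me3.broadPeak", "broadPeak")
    flank = int(config.annotate.get("flank", 5000))
    mark_window = int(config.annotate.get("mark_window", 10000))

    class_path = outdir / "peak_classification.tsv"
    with open(class_path, "w") as fh:
        fh.write("# promoter window: -3000/+1000 around TSS, summit membership\n")
        fh.write("peak\tchrom\tsummit\tclass\n")
        for p in peaks:
            fh.write(f"{p.name}\t{p.chrom}\t{p.summit}\t{classify_peak(p, genes)}\n")

    frac = promoter_fraction(peaks, genes)
    assignment = assign_peaks_to_genes(peaks, genes, flank=flank)
    bind_path = outdir / "gene_binding.tsv"
    with open(bind_path, "w") as fh:
        fh.write(f"# flank={flank} promoter_fraction_pct={frac:.4f}\n")
        fh.write("gene_id\tn_peaks\tbound\tpeaks\n")
        for g in genes:
            hits = assignment[g.gene_id]
            fh.write(
                f"{g.gene_id}\t{len(hits)}\t{int(bool(hits))}\t"
                f"{','.join(p.name for p in hits)}\n"
            )

    cats = [mark_category(g, k9, k27, window=mark_window) for g in genes]
    cat_path = outdir / "mark_categories.tsv"
    with open(cat_path, "w") as fh:
        fh.write(f"# mark_window={mark_window}\n")
        fh.write("gene_id\tcategory\tclosest_mark\tdistance_k9\tdistance_k27\n")
        for c in cats:
            d9 = "" if c.distance_k9 is None else str(c.distance_k9)
            d27 = "" if c.distance_k27 is None else str(c.distance_k27)
            fh.write(f"{c.gene_id}\t{c.category}\t{c.closest_mark}\t{d9}\t{d27}\n")
    summary_path = outdir / "mark_category_summary.tsv"
    summarize_mark_categories(cats).to_tsv(summary_path)
    return [class_path, bind_path, cat_path, summary_path]


def _stage_targets(config: RunConfig, outdir: Path) -> list[Path]:
    records = read_table(config.inputs_dir / "de_table.tsv", "de")
    genes = read_gene_models(config.inputs_dir / "genes.bed")
    peaks = read_intervals(config.inputs_dir / "peaks.narrowPeak", "narrowPeak")
    fc = float(config.targets.get("fc", 1.5))
    fdr = float(config.targets.get("fdr", 0.05))
    flank = int(config.targets.get("flank", 5000))
    deg = filter_degs(records, fc_threshold=fc, fdr_threshold=fdr, experiment_id="de")
    bound = bound_genes(assign_peaks_to_genes(peaks, genes, flank=flank))
    result = call_direct_targets(bound, deg)
    counts_path = outdir / "target_counts.tsv"
    with open(counts_path, "w") as fh:
        fh.write(f"# fc={fc} fdr={fdr} flank={flank}\n")
        fh.write("metric\tcount\n")
        fh.write(f"deg_up\t{deg.n_up}\n")
        fh.write(f"deg_down\t{deg.n_down}\n")
        fh.write(f"bound\t{len(result.bound)}\n")
        fh.write(f"targets_positive\t{len(result.positive)}\n")
        fh.write(f"targets_negative\t{len(result.negative)}\n")
    lists_path = outdir / "direct_targets.tsv"
    with open(lists_path, "w") as fh:
        fh.write("gene_id\tdirection\n")
        for g in sorted(result.positive):
            fh.write(f"{g}\tpositive\n")
        for g in sorted(result.negative):
            fh.write(f"{g}\tnegative\n")
    return [counts_path, lists_path]


def _stage_cohort(config: RunConfig, outdir: Path) -> list[Path]:
    tumors = read_table(config.inputs_dir / "tumors.tsv", "expression")
    celllines = read_table(config.inputs_dir / "celllines.tsv", "expression")
    p_cut = float(config.cohort.get("p_cut", 0.01))
    q_cut = float(config.cohort.get("q_cut", 0.01))
    method = str(config.cohort.get("method", "pearson"))
    shared = [g for g in tumors.gene_ids if g in celllines]
    passed, skipped = range_screen(tumors, celllines, shared, p_cut=p_cut)
    range_path = outdir / "range_screen.tsv"
    with open(range_path, "w") as fh:
        fh.write(f"# p_cut={p_cut} n_tested={len(shared)} n_skipped={len(skipped)}\n")
        fh.write("gene_id\tpassed\n")
        for g in shared:
            fh.write(f"{g}\t{int(g in passed)}\n")

    regulator = str(config.cohort.get("regulator", "reg_0000"))
    corr_path = outdir / "correlation_screen.tsv"
    outputs = [range_path]
    if regulator in tumors:
        candidates = [g for g in tumors.gene_ids if g != regulator]
        results = correlation_screen(
            tumors, regulator, candidates, method=method, q_cut=q_cut
        )
        with open(corr_path, "w") as fh:
            fh.write(f"# regulator={regulator} method={method} q_cut={q_cut}\n")
            fh.write("gene_id\tr\tp\tq\tdefined\tpassed\n")
            for r in results:
                fh.write(
                    f"{r.gene_id}\t{r.r:.6f}\t{r.p:.6g}\t{r.q:.6g}\t"
                    f"{int(r.defined)}\t{int(r.passed)}\n"
                )
        outputs.append(corr_path)
        quart_path = outdir / "quartile_concordance.tsv"
        with open(quart_path, "w") as fh:
            fh.write("regulator\ttarget\tk\tn\n")
            for r in results:
                if r.passed:
                    k, n = quartile_concordance(tumors, regulator, r.gene_id)
                    fh.write(f"{regulator}\t{r.gene_id}\t{k}\t{n}\n")
        outputs.append(quart_path)
    return outputs


def _stage_survival(config: RunConfig, outdir: Path) -> list[Path]:
    records = read_table(config.inputs_dir / "survival.tsv", "survival")
    split = config.survival.get("split", "median")
    high, low, chi2, p = km_logrank(records, split=split)
    out = outdir / "survival_logrank.tsv"
    with open(out, "w") as fh:
        fh.write(f"# split={split}\n")
        fh.write("group\tn_times\tchi2\tp\n")
        fh.write(f"high\t{len(high.times)}\t{chi2:.6f}\t{p:.6g}\n")
        fh.write(f"low\t{len(low.times)}\t{chi2:.6f}\t{p:.6g}\n")
    curves = outdir / "survival_curves.tsv"
    with open(curves, "w") as fh:
        fh.write("group\ttime\tsurvival\tat_risk\n")
        for label, curve in (("high", high), ("low", low)):
            for t, s, n in zip(curve.times, curve.survival, curve.at_risk):
                fh.write(f"{label}\t{t!r}\t{s!r}\t{n}\n")
    return [out, curves]


def _stage_motility(config: RunConfig, outdir: Path) -> list[Path]:
    detections = read_table(config.inputs_dir / "detections.tsv", "tracks")
    block = config.motility
    if block.get("use_track_id", True) and "track_id" in detections.columns:
        tracks = trajectories_from_table(detections)
    else:
        tracks = link_detections(detections, float(block.get("link_max", 20.0)))
    roi = block.get("roi")
    kept = filter_tracks(
        tracks,
        min_mean_quality=float(block.get("min_quality", 100.0)),
        min_occurrences=int(block.get("min_occurrences", 10)),
        roi=tuple(roi) if roi else None,
    )
    table = metrics_table(kept)
    out = outdir / "track_metrics.tsv"
    with open(out, "w") as fh:
        fh.write(
            f"# min_quality={block.get('min_quality', 100.0)} "
            f"min_occurrences={block.get('min_occurrences', 10)} "
            f"n_tracks_in={len(tracks)} n_tracks_kept={len(kept)}\n"
        )
        table.to_csv(fh, sep="\t", index=False)
    return [out]


_STAGE_FUNCS: dict[str, Callable[[RunConfig, Path], list[Path]]] = {
    "simulate": _stage_simulate,
    "repeats": _stage_repeats,
    "annotate": _stage_annotate,
    "targets": _stage_targets,
    "cohort": _stage_cohort,
    "survival": _stage_survival,
    "motility": _stage_motility,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write a
    manifest (``manifest.json``) with per-output checksums.

    A stage failure halts the run with a stage-named error; outputs of
    completed stages are preserved.
    """
    _validate_dependencies(config)
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "regulon-forge",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "stages": {},
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        stage_dir = config.outdir / stage if stage != "simulate" else config.outdir
        stage_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, stage_dir)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "wall_seconds": round(time.perf_counter() - t0, 4),
            "outputs": {str(p.relative_to(config.outdir)): _sha256(p) for p in outputs},
        }
    manifest_path = config.outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
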