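"""Plain-text genomic file I/O: FASTA genomes, BED/narrowPeak/broadPeak
intervals, and tab-delimited analysis tables.

All interval coordinates are 0-based, half-open ``[start, end)``. The
narrowPeak dialect carries a summit offset in column 10 (``-1`` meaning
"no summit called"); broadPeak and BED6 records never carry a summit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Peak",
    "GeneModel",
    "DERecord",
    "SurvivalRecord",
    "GenomeSequence",
    "Genome",
    "ExpressionMatrix",
    "read_intervals",
    "write_intervals",
    "read_genome",
    "write_genome",
    "read_table",
    "write_de_table",
    "DIALECTS",
]

#: column counts per supported interval dialect
DIALECTS = {"bed6": 6, "narrowPeak": 10, "broadPeak": 9}

_VALID_BASES = frozenset("ACGTN")
_SKIP_PREFIXES = ("#", "track", "browser")


class FormatError(ValueError):
    """Raised for malformed lines, coordinates, or table cells."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """A called peak (binding site or histone-mark region).

    ``summit_offset`` is the offset of the summit from ``start`` when a
    summit was called (narrowPeak column 10 >= 0), else ``None``.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    pvalue_neglog10: float = -1.0
    qvalue_neglog10: float = -1.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"peak {self.name!r}: negative start {self.start}")
        if not self.start < self.end:
            raise FormatError(
                f"peak {self.name!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"peak {self.name!r}: bad strand {self.strand!r}")
        if self.summit_offset is not None:
            if self.summit_offset < 0:
                raise FormatError(
                    f"peak {self.name!r}: negative summit offset {self.summit_offset}"
                )
            if self.start + self.summit_offset >= self.end:
                raise FormatError(
                    f"peak {self.name!r}: summit offset {self.summit_offset} "
                    f"falls outside [{self.start}, {self.end})"
                )

    @property
    def summit(self) -> int:
        """Genomic summit position; interval midpoint when no summit was called."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene span (BED6); the TSS is derived downstream."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"gene {self.gene_id!r}: negative start")
        if not self.start < self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}"
            )


@dataclass(frozen=True)
class DERecord:
    """One differential-expression row: gene, log2 fold-change, FDR."""

    gene_id: str
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("DERecord with empty gene_id")
        if not 0.0 <= self.fdr <= 1.0:
            raise FormatError(f"gene {self.gene_id!r}: fdr {self.fdr} outside [0,1]")


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int
    expression: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise FormatError(f"sample {self.sample_id!r}: negative time")
        if self.event not in (0, 1):
            raise FormatError(f"sample {self.sample_id!r}: event must be 0/1")


# ---------------------------------------------------------------------------
# genome sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome, uppercase-normalized over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"chromosome {self.name!r} has empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"chromosome {self.name!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Return ``sequence[start:end)``; both bounds must be inside."""
        if start < 0 or end > len(self.sequence) or start > end:
            raise FormatError(
                f"slice [{start}, {end}) outside chromosome {self.name!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]

    @staticmethod
    def from_raw(name: str, raw: str) -> "GenomeSequence":
        """Uppercase and map anything outside {A,C,G,T} to N."""
        up = raw.upper()
        normalized = "".join(c if c in _VALID_BASES else "N" for c in up)
        return GenomeSequence(name=name, sequence=normalized)


class Genome:
    """In-memory, name-addressable collection of chromosomes."""

    def __init__(self, sequences: Iterable[GenomeSequence] = ()) -> None:
        self._seqs: dict[str, GenomeSequence] = {}
        for seq in sequences:
            self.add(seq)

    def add(self, seq: GenomeSequence) -> None:
        if seq.name in self._seqs:
            raise FormatError(f"duplicate chromosome name {seq.name!r}")
        self._seqs[seq.name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> GenomeSequence:
        try:
            return self._seqs[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in genome") from None

    def __iter__(self) -> Iterator[GenomeSequence]:
        return iter(self._seqs.values())

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self[chrom].slice(start, end)


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA file into memory with uppercase/N normalization.

    Headers are truncated at the first whitespace; duplicates are an error.
    """
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome.add(GenomeSequence.from_raw(rec.id, str(rec.seq)))
    if len(genome) == 0:
        raise FormatError(f"no FASTA records found in {path}")
    return genome


def write_genome(genome: Genome, path: str | Path, line_width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq.sequence), id=seq.name, description="") for seq in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# interval dialects
# ---------------------------------------------------------------------------


def _parse_int(token: str, line_no: int, col: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(
            f"line {line_no}: field {col!r} is not an integer: {token!r}"
        ) from None


def _parse_float(token: str, line_no: int, col: str, dot_as_zero: bool = False) -> float:
    if dot_as_zero and token == ".":
        return 0.0
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"line {line_no}: field {col!r} is not numeric: {token!r}"
        ) from None


def read_intervals(path: str | Path, dialect: str) -> list[Peak]:
    """Read an interval file in one of the supported dialects.

    Comment/track/browser lines are skipped. Column counts are enforced
    (6/10/9 for bed6/narrowPeak/broadPeak); errors carry the 1-based line
    number of the offending record.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    ncols = DIALECTS[dialect]
    peaks: list[Peak] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise FormatError(
                    f"line {line_no}: expected {ncols} columns for {dialect}, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], line_no, "start")
            end = _parse_int(fields[2], line_no, "end")
            name = fields[3]
            score = _parse_float(fields[4], line_no, "score", dot_as_zero=True)
            strand = fields[5]
            signal = pval = qval = -1.0
            summit: int | None = None
            if dialect in ("narrowPeak", "broadPeak"):
                signal = _parse_float(fields[6], line_no, "signalValue")
                pval = _parse_float(fields[7], line_no, "pValue")
                qval = _parse_float(fields[8], line_no, "qValue")
            if dialect == "narrowPeak":
                offset = _parse_int(fields[9], line_no, "summit")
                summit = None if offset == -1 else offset
            try:
                peaks.append(
                    Peak(
                        chrom=chrom,
                        start=start,
                        end=end,
                        name=name,
                        score=score,
                        strand=strand,
                        signal=signal if signal is not None else 0.0,
                        pvalue_neglog10=pval,
                        qvalue_neglog10=qval,
                        summit_offset=summit,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"line {line_no}: {exc}") from None
    return peaks


def _fmt(x: float) -> str:
    # compact numeric formatting that survives a round trip
    return repr(float(x)) if x != int(x) else str(int(x))


def write_intervals(peaks: Iterable[Peak], path: str | Path, dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            fields = [p.chrom, str(p.start), str(p.end), p.name, _fmt(p.score), p.strand]
            if dialect in ("narrowPeak", "broadPeak"):
                fields += [_fmt(p.signal), _fmt(p.pvalue_neglog10), _fmt(p.qvalue_neglog10)]
            if dialect == "narrowPeak":
                fields.append(str(p.summit_offset) if p.summit_offset is not None else "-1")
            fh.write("\t".join(fields) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read BED6 gene spans; gene IDs (column 4) must be unique."""
    peaks = read_intervals(path, "bed6")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for p in peaks:
        if p.name in seen:
            raise FormatError(f"duplicate gene_id {p.name!r}")
        seen.add(p.name)
        genes.append(
            GeneModel(chrom=p.chrom, start=p.start, end=p.end, gene_id=p.name,
                      strand=p.strand, score=p.score)
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    write_intervals(
        [Peak(g.chrom, g.start, g.end, g.gene_id, g.score, g.strand) for g in genes],
        path,
        "bed6",
    )


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Genes x samples matrix of non-negative normalized expression values."""

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene_ids: {dups}")
        if frame.columns.duplicated().any():
            dups = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample_ids: {dups}")
        if (frame.values < 0).any():
            raise FormatError("expression values must be non-negative")
        self._frame = frame.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def gene_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self._frame.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._frame.index

    def values_for(self, gene_id: str):
        if gene_id not in self._frame.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self._frame.loc[gene_id].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self._frame.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# tab-delimited tables
# ---------------------------------------------------------------------------

_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "de": ("gene_id", "log2fc", "fdr"),
    "survival": ("sample_id", "time", "event", "expression"),
    "tracks": ("frame", "x", "y", "quality"),
    "expression": ("gene_id",),
}

_NUMERIC_COLS: Mapping[str, tuple[str, ...]] = {
    "de": ("log2fc", "fdr"),
    "survival": ("time", "event", "expression"),
    "tracks": ("frame", "x", "y", "quality"),
}


def _coerce_numeric(df: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    # float() per cell: exact round-trip parsing (pd.to_numeric is lossy)
    out = df.copy()
    for col in cols:
        values = []
        for row, token in enumerate(out[col]):
            try:
                values.append(float(token))
            except (TypeError, ValueError):
                raise FormatError(
                    f"column {col!r}: non-numeric value {token!r} at row {row}"
                ) from None
        out[col] = values
    return out


def read_table(path: str | Path, schema: str):
    """Read a tab-delimited table with a header row, typed per ``schema``.

    Schemas: ``de`` -> list[DERecord]; ``survival`` -> list[SurvivalRecord];
    ``tracks`` -> DataFrame (optional ``track_id`` column preserved);
    ``expression`` -> ExpressionMatrix. Extra columns are ignored. Errors
    name the missing column or the offending row index.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     float_precision="round_trip")
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")

    if schema == "expression":
        df = df.set_index("gene_id")
        try:
            numeric = df.astype(float)
        except ValueError:
            probe = df.apply(pd.to_numeric, errors="coerce")
            col = probe.columns[probe.isna().any()][0]
            row = probe.index[probe[col].isna()][0]
            raise FormatError(
                f"column {col!r}: non-numeric value at gene {row!r}"
            ) from None
        return ExpressionMatrix(numeric)

    df = _coerce_numeric(df.reset_index(drop=True), _NUMERIC_COLS[schema])
    if schema == "de":
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id {dup!r} in DE table")
        return [
            DERecord(str(r.gene_id), float(r.log2fc), float(r.fdr))
            for r in df.itertuples(index=False)
        ]
    if schema == "survival":
        return [
            SurvivalRecord(str(r.sample_id), float(r.time), int(r.event), float(r.expression))
            for r in df.itertuples(index=False)
        ]
    # tracks: keep as a frame; linking/metrics consume it columnwise
    df["frame"] = df["frame"].astype(int)
    return df


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tfdr\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc!r}\t{r.fdr!r}\n")
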