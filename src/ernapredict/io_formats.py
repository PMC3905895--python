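"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates inside the package are 0-based half-open; conversion
(if a format required any) would happen only here. Formats handled:

* BED3/BED6 — mapped reads and peak calls (columns 4-6 optional; ``track``
  and ``browser`` lines are skipped).
* BED4-with-value — mappability segments (value in [0, 1]).
* TSV gene table — refFlat-like minimal five columns
  (gene_id, chrom, strand, txStart, txEnd); the TSS is derived strand-aware.
* TSV expression table — gene_id, FPKM.
* YAML run configuration — every threshold and seed a run depends on.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded); ``score`` is optional.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene with a strand-aware TSS (the 5' base) and its body span."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.body_start <= self.tss <= self.body_end):
            raise ValueError(f"gene {self.gene_id}: TSS outside body span")


@dataclass(frozen=True)
class MappabilitySegment:
    interval: GenomicInterval
    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(
                f"mappability value {self.value} outside [0, 1] at "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"gene {self.gene_id}: FPKM must be >= 0")


@dataclass
class RunConfig:
    """Run configuration: track paths plus every tunable threshold.

    Defaults follow the analysis conventions: enhancers must sit at least
    3 kb from any TSS or promoter-like (H3K4me3) region, mean mappability
    below 0.85 disqualifies a window, genes are assigned within 100 kb,
    H3K27ac status uses a 2 kb distance, and model selection runs 10-fold
    nested cross-validation keeping the top 5% of subsets.
    """

    tracks: dict[str, str] = field(default_factory=dict)
    gro_plus: str = ""
    gro_minus: str = ""
    peaks: str = ""
    k4me3_peaks: str = ""
    k27ac_peaks: str = ""
    genes: str = ""
    mappability: str = ""
    expression: str = ""

    mappability_min: float = 0.85
    tss_exclusion_bp: int = 3000
    k27ac_dist_bp: int = 2000
    gene_assign_max_bp: int = 100_000
    window_half_bp: int = 1000
    pseudocount: float = 1.0
    log_base: float = 2.0
    cv_folds: int = 10
    inner_folds: int = 10
    top_fraction: float = 0.05
    top_n_inner: int = 10
    subset_sizes: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    ridge_lambda: float = 1e-6
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.mappability_min <= 0 or self.tss_exclusion_bp <= 0:
            raise ValueError("thresholds must be positive")
        if self.k27ac_dist_bp <= 0 or self.gene_assign_max_bp <= 0:
            raise ValueError("thresholds must be positive")
        if self.window_half_bp <= 0 or self.pseudocount <= 0:
            raise ValueError("window half-width and pseudocount must be positive")
        if self.log_base <= 1:
            raise ValueError("log base must exceed 1")
        if self.cv_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top fraction must lie in (0, 1]")
        if self.top_n_inner < 1:
            raise ValueError("top_n_inner must be >= 1")
        return self


def _data_lines(path: str) -> Iterable[tuple[int, str]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            if line.startswith("track") or line.startswith("browser"):
                continue
            yield lineno, line


def read_bed(path: str, stranded: bool = False) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, preserving order.

    With ``stranded=True`` the sixth column is required on every line.
    Malformed lines raise :class:`ParseError` naming the line number.
    """
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
        name = fields[3] if len(fields) > 3 else ""
        score: float | None = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        strand = "."
        if len(fields) > 5:
            strand = fields[5]
        elif stranded:
            raise ParseError(f"{path}:{lineno}: strand column required")
        if stranded and strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
        try:
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path: str, intervals: Sequence[GenomicInterval]) -> None:
    """Write intervals as BED; emits exactly the columns that carry data."""
    n_cols = 3
    for iv in intervals:
        if iv.strand != ".":
            n_cols = 6
            break
        if iv.score is not None:
            n_cols = max(n_cols, 5)
        elif iv.name:
            n_cols = max(n_cols, 4)
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if n_cols > 3:
                cols.append(iv.name or ".")
            if n_cols > 4:
                cols.append(_fmt(iv.score) if iv.score is not None else "0")
            if n_cols > 5:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else repr(float(x))


def read_gene_table(path: str) -> list[GeneRecord]:
    """Read a minimal refFlat-like gene table.

    Columns: gene_id, chrom, strand, txStart, txEnd (tab-separated, '#'
    header lines allowed). The TSS is the strand-aware 5' base: txStart for
    '+' genes, txEnd - 1 (last covered base, 0-based) for '-' genes.
    """
    genes: list[GeneRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns")
        gene_id, chrom, strand = fields[0], fields[1], fields[2]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
        try:
            tx_start, tx_end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
        if tx_start >= tx_end:
            raise ParseError(f"{path}:{lineno}: txStart >= txEnd")
        tss = tx_start if strand == "+" else tx_end - 1
        genes.append(GeneRecord(gene_id, chrom, strand, tss, tx_start, tx_end))
    return genes


def write_gene_table(path: str, genes: Sequence[GeneRecord]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#gene_id\tchrom\tstrand\ttxStart\ttxEnd\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.body_start}\t{g.body_end}\n")


def read_mappability(path: str) -> list[MappabilitySegment]:
    """Read a BED4-with-value mappability track.

    Values outside [0, 1] and overlapping segments on one chromosome are
    rejected (the track is expected to be a partition-like tiling).
    """
    segs: list[MappabilitySegment] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns (chrom start end value)")
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
        try:
            segs.append(MappabilitySegment(GenomicInterval(fields[0], start, end), value))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    by_chrom: dict[str, list[MappabilitySegment]] = {}
    for s in segs:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    for chrom, chrom_segs in by_chrom.items():
        ordered = sorted(chrom_segs, key=lambda s: s.interval.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.interval.start < a.interval.end:
                raise ParseError(
                    f"{path}: overlapping mappability segments on {chrom} at "
                    f"{b.interval.start}"
                )
    return segs


def write_mappability(path: str, segs: Sequence[MappabilitySegment]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for s in segs:
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                f"{_fmt(s.value)}\n"
            )


def read_expression(path: str) -> list[ExpressionRecord]:
    out: list[ExpressionRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected gene_id and FPKM")
        try:
            fpkm = float(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric FPKM") from exc
        try:
            out.append(ExpressionRecord(fields[0], fpkm))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_expression(path: str, records: Sequence[ExpressionRecord]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#gene_id\tfpkm\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.fpkm:.6g}\n")


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str) -> RunConfig:
    """Load a YAML run configuration, applying documented defaults.

    Relative track paths are resolved against the config file's directory.
    Unknown keys raise so that typos never silently fall back to defaults.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p: str) -> str:
        return p if (not p or os.path.isabs(p)) else os.path.join(base, p)

    cfg.tracks = {k: _resolve(v) for k, v in (cfg.tracks or {}).items()}
    for attr in ("gro_plus", "gro_minus", "peaks", "k4me3_peaks", "k27ac_peaks",
                 "genes", "mappability", "expression"):
        setattr(cfg, attr, _resolve(getattr(cfg, attr)))
    return cfg.validate()
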