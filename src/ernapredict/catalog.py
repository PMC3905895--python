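"""Enhancer catalog construction and the log-density signal matrix.

The catalog stage turns candidate peaks (P300-bound, or H3K4me1-enriched in
cell types lacking P300 data) into intergenic enhancer windows:

1. drop peaks overlapping any gene body;
2. drop windows closer than the exclusion distance (default 3 kb) to any TSS
   or to any H3K4me3-enriched (promoter-like) region;
3. drop windows whose length-weighted mean mappability falls below the
   threshold (default 0.85; bases not covered by the track count as 0).

Signal windows are centered on the peak midpoint (default +/- 1 kb). The
signal value for mark i at enhancer j is

    x_ij = log2( density_ij + pseudocount ),
    density_ij = (reads with midpoint in window / window length in kb)
                 / (total track reads / 1e6)

i.e. an RPKM-like, depth-normalized average read density; GRO-seq sense and
antisense densities (y+_j, y-_j) are computed the same way per strand.
Distances are edge-to-edge gaps (0 when overlapping); all coordinates are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneRecord, GenomicInterval, MappabilitySegment


@dataclass(frozen=True)
class EnhancerRegion:
    """A candidate enhancer: fixed signal window around a source peak."""

    id: str
    interval: GenomicInterval          # the signal window
    source_peak: GenomicInterval
    provenance: str = "P300"           # or "H3K4me1+me3-"
    mean_mappability: float = float("nan")


class TrackLibrary:
    """Read midpoints per chromosome for one or more tracks, plus totals."""

    def __init__(self) -> None:
        self._mids: dict[str, dict[str, np.ndarray]] = {}
        self._totals: dict[str, int] = {}

    @property
    def names(self) -> list[str]:
        return list(self._mids)

    def total(self, name: str) -> int:
        return self._totals[name]

    def add_intervals(self, name: str, intervals: Iterable[GenomicInterval],
                      total: int | None = None) -> None:
        """Register reads; ``total`` overrides the mapped-read count when the
        intervals are a subsample of a larger track."""
        by_chrom: dict[str, list[int]] = {}
        n = 0
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)
            n += 1
        self._mids[name] = {c: np.sort(np.asarray(v, dtype=np.int64))
                            for c, v in by_chrom.items()}
        self._totals[name] = n if total is None else total

    def add_dataframe(self, name: str, df: pd.DataFrame) -> None:
        """Register a (chrom, start, end) frame of reads without file I/O."""
        mids = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2)
        chrom = df["chrom"].to_numpy()
        self._mids[name] = {c: np.sort(mids[chrom == c])
                            for c in pd.unique(chrom)}
        self._totals[name] = len(df)

    def add_bed_file(self, name: str, path: str) -> None:
        """Fast path for large read files (C parser; midpoints only)."""
        try:
            df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                             names=["chrom", "start", "end"],
                             dtype={"chrom": str, "start": np.int64, "end": np.int64},
                             comment="#")
        except pd.errors.EmptyDataError:
            self._mids[name], self._totals[name] = {}, 0
            return
        mids = ((df["start"] + df["end"]) // 2).to_numpy()
        self._mids[name] = {
            c: np.sort(mids[(df["chrom"] == c).to_numpy()])
            for c in df["chrom"].unique()
        }
        self._totals[name] = len(df)

    def count_in_windows(self, name: str, chroms: Sequence[str],
                         starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Number of reads whose midpoint falls inside each [start, end)."""
        mids = self._mids[name]
        out = np.zeros(len(starts), dtype=np.int64)
        for c in set(chroms):
            arr = mids.get(c)
            if arr is None:
                continue
            idx = np.array([i for i, cc in enumerate(chroms) if cc == c])
            lo = np.searchsorted(arr, starts[idx], side="left")
            hi = np.searchsorted(arr, ends[idx], side="left")
            out[idx] = hi - lo
        return out


@dataclass
class SignalMatrix:
    """Enhancers x tracks matrix of log-transformed average read densities."""

    marks: pd.DataFrame                # index: enhancer ids; columns: mark names
    y_plus: pd.Series | None = None    # log sense GRO-seq density
    y_minus: pd.Series | None = None   # log antisense GRO-seq density

    @property
    def enhancer_ids(self) -> list[str]:
        return list(self.marks.index)

    def subset_rows(self, ids: Sequence[str]) -> "SignalMatrix":
        return SignalMatrix(
            self.marks.loc[list(ids)],
            None if self.y_plus is None else self.y_plus.loc[list(ids)],
            None if self.y_minus is None else self.y_minus.loc[list(ids)],
        )

    def to_tsv(self, path: str) -> None:
        df = self.marks.copy()
        if self.y_plus is not None:
            df["groseq_plus"] = self.y_plus
        if self.y_minus is not None:
            df["groseq_minus"] = self.y_minus
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#enhancer_id\t" + "\t".join(df.columns) + "\n")
            df.to_csv(fh, sep="\t", header=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str) -> "SignalMatrix":
        with open(path, "rt", encoding="utf-8") as fh:
            header = fh.readline().lstrip("#").rstrip("\n").split("\t")
            df = pd.read_csv(fh, sep="\t", header=None, names=header,
                             index_col=0)
        yp = df.pop("groseq_plus") if "groseq_plus" in df.columns else None
        ym = df.pop("groseq_minus") if "groseq_minus" in df.columns else None
        return cls(df, yp, ym)


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    intervals = sorted(intervals)
    starts, ends = [intervals[0][0]], [intervals[0][1]]
    for a, b in intervals[1:]:
        if a <= ends[-1]:
            ends[-1] = max(ends[-1], b)
        else:
            starts.append(a)
            ends.append(b)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _overlaps_any(starts: np.ndarray, ends: np.ndarray, a: int, b: int) -> bool:
    """Does [a, b) overlap any of the merged intervals?"""
    j = int(np.searchsorted(starts, b, side="left"))
    return j > 0 and ends[j - 1] > a


def _gap_to_nearest_point(points: np.ndarray, a: int, b: int) -> float:
    """Edge-to-edge gap between [a, b) and the nearest point (inf if none)."""
    if len(points) == 0:
        return float("inf")
    j = int(np.searchsorted(points, a))
    best = float("inf")
    for jj in (j - 1, j, j + 1):
        if 0 <= jj < len(points):
            p = int(points[jj])
            gap = 0 if a <= p < b else (a - p if p < a else p - (b - 1))
            best = min(best, gap)
    return best


def define_intergenic_enhancers(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    k4me3_regions: Sequence[GenomicInterval],
    exclusion_bp: int = 3000,
    window_half_bp: int = 1000,
    provenance: str = "P300",
) -> tuple[list[EnhancerRegion], dict[str, str]]:
    """Build the intergenic enhancer catalog from candidate peaks.

    Returns the retained regions plus a map of removed-enhancer id to the
    first triggered removal reason (``gene_body``, ``tss_proximal`` or
    ``k4me3_proximal``). An empty peak set yields an empty catalog.
    """
    bodies: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tss: dict[str, np.ndarray] = {}
    for chrom in {g.chrom for g in genes}:
        bodies[chrom] = _merge([(g.body_start, g.body_end)
                                for g in genes if g.chrom == chrom])
        tss[chrom] = np.sort(np.asarray([g.tss for g in genes if g.chrom == chrom]))
    k4me3_exp: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in k4me3_regions}:
        k4me3_exp[chrom] = _merge([(r.start - exclusion_bp, r.end + exclusion_bp)
                                   for r in k4me3_regions if r.chrom == chrom])

    retained: list[EnhancerRegion] = []
    removed: dict[str, str] = {}
    for i, peak in enumerate(peaks):
        eid = peak.name or f"enh{i:05d}"
        mid = peak.midpoint
        win = GenomicInterval(peak.chrom, mid - window_half_bp, mid + window_half_bp,
                              name=eid)
        bs, be = bodies.get(peak.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        if _overlaps_any(bs, be, peak.start, peak.end):
            removed[eid] = "gene_body"
            continue
        pts = tss.get(peak.chrom, np.empty(0, np.int64))
        if _gap_to_nearest_point(pts, win.start, win.end) < exclusion_bp:
            removed[eid] = "tss_proximal"
            continue
        ks, ke = k4me3_exp.get(peak.chrom,
                               (np.empty(0, np.int64), np.empty(0, np.int64)))
        if _overlaps_any(ks, ke, win.start, win.end):
            removed[eid] = "k4me3_proximal"
            continue
        retained.append(EnhancerRegion(eid, win, peak, provenance))
    return retained, removed


def apply_mappability_filter(
    enhancers: Sequence[EnhancerRegion],
    segments: Sequence[MappabilitySegment],
    min_mean: float = 0.85,
) -> tuple[list[EnhancerRegion], list[str]]:
    """Drop enhancers with length-weighted mean window mappability < min_mean.

    Uncovered bases count as 0 (conservative). The computed mean is stored on
    each retained record. Returns (retained, removed ids).
    """
    seg_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {s.interval.chrom for s in segments}:
        items = sorted((s.interval.start, s.interval.end, s.value)
                       for s in segments if s.interval.chrom == chrom)
        seg_by_chrom[chrom] = (
            np.asarray([a for a, _, _ in items], dtype=np.int64),
            np.asarray([b for _, b, _ in items], dtype=np.int64),
            np.asarray([v for _, _, v in items], dtype=float),
        )
    retained: list[EnhancerRegion] = []
    removed: list[str] = []
    for enh in enhancers:
        win = enh.interval
        starts, ends, values = seg_by_chrom.get(
            win.chrom, (np.empty(0, np.int64), np.empty(0, np.int64),
                        np.empty(0, float)))
        lo = int(np.searchsorted(ends, win.start, side="right"))
        hi = int(np.searchsorted(starts, win.end, side="left"))
        weighted = 0.0
        for k in range(lo, hi):
            ov = min(int(ends[k]), win.end) - max(int(starts[k]), win.start)
            if ov > 0:
                weighted += ov * float(values[k])
        mean = weighted / len(win)
        if mean < min_mean:
            removed.append(enh.id)
        else:
            retained.append(replace(enh, mean_mappability=mean))
    return retained, removed


def compute_signal_matrix(
    enhancers: Sequence[EnhancerRegion],
    tracks: TrackLibrary,
    gro_tracks: TrackLibrary | None = None,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
) -> SignalMatrix:
    """Average read density per (track, enhancer window), log-transformed.

    Reads are assigned to a window when their midpoint falls inside it, so no
    read is counted twice at window edges. A track with zero total reads
    cannot be depth-normalized and raises.
    """
    ids = [e.id for e in enhancers]
    chroms = [e.interval.chrom for e in enhancers]
    starts = np.asarray([e.interval.start for e in enhancers], dtype=np.int64)
    ends = np.asarray([e.interval.end for e in enhancers], dtype=np.int64)
    len_kb = (ends - starts) / 1000.0

    def _col(lib: TrackLibrary, name: str) -> np.ndarray:
        total = lib.total(name)
        if total <= 0:
            raise ValueError(f"track {name!r} has zero total reads")
        counts = lib.count_in_windows(name, chroms, starts, ends)
        density = (counts / len_kb) / (total / 1e6)
        return np.log(density + pseudocount) / np.log(log_base)

    data = {name: _col(tracks, name) for name in tracks.names}
    marks = pd.DataFrame(data, index=pd.Index(ids, name="enhancer_id"))
    y_plus = y_minus = None
    if gro_tracks is not None:
        y_plus = pd.Series(_col(gro_tracks, "groseq_plus"), index=marks.index,
                           name="groseq_plus")
        y_minus = pd.Series(_col(gro_tracks, "groseq_minus"), index=marks.index,
                            name="groseq_minus")
    if not np.isfinite(marks.to_numpy()).all():
        raise ValueError("non-finite signal values")
    return SignalMatrix(marks, y_plus, y_minus)
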