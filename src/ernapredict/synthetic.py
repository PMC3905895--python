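"""Synthetic read-level dataset generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, on a small two-chromosome toy genome:

* each enhancer carries a latent active/inactive state drawn Bernoulli(pi);
* per-mark read counts are Poisson on an exponentiated Gaussian, so log
  densities are approximately Gaussian within each state and the state shifts
  them by a per-mark effect (in natural-log units). Acetylation marks share a
  latent factor (correlation ``rho``) so subset selection faces genuine
  redundancy; the repressive mark gets a negative effect;
* GRO-seq sense and antisense are both elevated at active enhancers
  (bidirectional transcription), producing a bimodal log-density histogram;
* mappability is 1.0 everywhere except planted 0.5 segments over a stated
  fraction of enhancers, to exercise the <0.85 filter deterministically;
* genes nearest an active enhancer draw elevated log-FPKM.

Everything is deterministic under ``GeneratorConfig.seed`` and the module can
also plant a stated number of rule-violating enhancer sites (inside gene
bodies / too close to a TSS) so that catalog filters can be tested exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    GeneRecord,
    GenomicInterval,
    MappabilitySegment,
    write_bed,
    write_expression,
    write_gene_table,
    write_mappability,
    ExpressionRecord,
)

DEFAULT_MARK_GROUPS: dict[str, list[str]] = {
    "acetyl": ["H3K27ac", "H3K9ac", "H2BK120ac"],
    "repressive": ["H3K27me3"],
    "elongation": ["H3K79me1", "H3K36me3"],
    "neutral": ["H3K4me2", "H4K20me1", "H3K9me3", "H2A.Z"],
}

DEFAULT_EFFECTS: dict[str, float] = {
    "H3K27ac": 1.8,
    "H3K9ac": 1.6,
    "H2BK120ac": 1.5,
    "H3K27me3": -1.6,
    "H3K79me1": 0.0,
    "H3K36me3": 0.0,
    "H3K4me2": 0.0,
    "H4K20me1": 0.0,
    "H3K9me3": 0.0,
    "H2A.Z": 0.0,
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic experiment.

    Effects are shifts of the log read rate (natural-log units) between the
    active and inactive state; ``noise_sd`` is the per-enhancer Gaussian noise
    on that log rate; ``rho`` the within-acetyl-group correlation (shared
    latent factor). ``depth`` / ``gro_depth`` set the expected inactive-state
    read count per window for marks / GRO-seq.
    """

    n_enhancers: int = 2000
    n_genes: int = 2400
    mark_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARK_GROUPS.items()}
    )
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    rho: float = 0.10
    noise_sd: float = 1.0
    fraction_active: float = 0.55
    depth: float = 20.0
    gro_depth: float = 4.0
    gro_effect: float = 4.0
    read_len: int = 50
    window_half_bp: int = 1000
    tss_exclusion_bp: int = 3000
    fraction_low_mappability: float = 0.05
    expression_shift: float = 2.0
    expression_noise_sd: float = 0.5
    baseline_log_fpkm_mean: float = 2.0
    baseline_log_fpkm_sd: float = 1.0
    k4me3_fraction: float = 0.7
    background_per_kb: float = 0.02
    n_plant_genebody: int = 0
    n_plant_tss_proximal: int = 0
    seed: int = 0

    @property
    def marks(self) -> list[str]:
        return [m for grp in self.mark_groups.values() for m in grp]

    def validate(self) -> "GeneratorConfig":
        if not (0.0 <= self.fraction_active <= 1.0):
            raise ValueError("fraction_active must lie in [0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.depth < 0 or self.gro_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.n_genes < self.n_enhancers:
            raise ValueError("need at least one gene per enhancer")
        for m in self.marks:
            if m not in self.effects or not np.isfinite(self.effects[m]):
                raise ValueError(f"mark {m!r} needs a finite effect size")
        if not (0.0 <= self.fraction_low_mappability <= 1.0):
            raise ValueError("fraction_low_mappability must lie in [0, 1]")
        return self


@dataclass
class SyntheticTruth:
    """Planted ground truth consumed by recovery tests, never by the pipeline."""

    states: dict[str, bool]                 # enhancer id -> active?
    effects: dict[str, float]               # mark -> planted log-rate shift
    links: dict[str, str | None]            # enhancer id -> nearest gene id
    gene_baseline: dict[str, float]         # gene id -> baseline log-FPKM
    violations: dict[str, str]              # enhancer id -> planted violation kind
    low_mappability_ids: list[str]

    def active_linked_genes(self) -> set[str]:
        return {
            g for e, g in self.links.items()
            if g is not None and self.states[e] and e not in self.violations
        }


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_annotation(
    cfg: GeneratorConfig,
) -> tuple[list[GeneRecord], list[GenomicInterval], SyntheticTruth]:
    """Lay out genes and enhancer sites on a two-chromosome toy genome.

    Clean sites respect the intergenic rules by construction (outside gene
    bodies, window at least ``tss_exclusion_bp`` from every TSS and promoter
    H3K4me3 region); ``n_plant_genebody`` / ``n_plant_tss_proximal`` extra
    sites deliberately violate them so catalog filters remove exactly those.
    """
    cfg.validate()
    rng, = _rngs(cfg.seed, 1)
    half = cfg.window_half_bp
    excl = cfg.tss_exclusion_bp

    genes: list[GeneRecord] = []
    sites: list[GenomicInterval] = []
    states_arr = rng.random(cfg.n_enhancers + cfg.n_plant_genebody
                            + cfg.n_plant_tss_proximal) < cfg.fraction_active

    n_per_chrom = (cfg.n_genes + 1) // 2
    cursor = 10_000
    chrom_of_gene: list[str] = []
    for gi in range(cfg.n_genes):
        chrom = "chr1" if gi < n_per_chrom else "chr2"
        if gi == n_per_chrom:
            cursor = 10_000
        body_len = int(rng.integers(5_000, 20_000))
        strand = "+" if gi % 2 == 0 else "-"
        body_start = cursor
        body_end = body_start + body_len
        tss = body_start if strand == "+" else body_end - 1
        gid = f"gene{gi:05d}"
        genes.append(GeneRecord(gid, chrom, strand, tss, body_start, body_end))
        chrom_of_gene.append(chrom)
        cursor = body_end
        if gi < cfg.n_enhancers:
            # clean site: window edge stays >= excl from flanking TSSs and
            # >= excl from promoter K4me3 edges (TSS +/- 500)
            s1 = excl + half + 800 + int(rng.integers(0, 1500))
            mid = cursor + s1
            w = int(rng.integers(200, 600))
            sites.append(GenomicInterval(chrom, mid - w // 2, mid + (w + 1) // 2,
                                         name=f"enh{gi:05d}"))
            s2 = excl + half + 800 + int(rng.integers(0, 1500))
            cursor = mid + s2
        else:
            cursor = body_end + int(rng.integers(2_000, 6_000))

    violations: dict[str, str] = {}
    vidx = cfg.n_enhancers
    # planted gene-body sites: peak centered deep inside a gene body
    big_bodies = [g for g in genes if (g.body_end - g.body_start) >= 8_000]
    if cfg.n_plant_genebody > len(big_bodies):
        raise ValueError("genome too small to place requested gene-body violations")
    for k in range(cfg.n_plant_genebody):
        g = big_bodies[int(rng.integers(0, len(big_bodies)))]
        mid = (g.body_start + g.body_end) // 2
        eid = f"enhV{vidx:05d}"
        sites.append(GenomicInterval(g.chrom, mid - 150, mid + 150, name=eid))
        violations[eid] = "gene_body"
        vidx += 1
    # planted TSS-proximal sites: outside the body, window within excl of a TSS
    plus_genes = [g for g in genes if g.strand == "+"]
    if cfg.n_plant_tss_proximal > len(plus_genes):
        raise ValueError("genome too small to place requested TSS-proximal violations")
    for k in range(cfg.n_plant_tss_proximal):
        g = plus_genes[k]
        mid = g.tss - 1_500                  # upstream of a '+' TSS, outside the body
        eid = f"enhV{vidx:05d}"
        sites.append(GenomicInterval(g.chrom, mid - 150, mid + 150, name=eid))
        violations[eid] = "tss_proximal"
        vidx += 1

    # nearest-TSS links (within 100 kb) for clean sites
    tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in ("chr1", "chr2"):
        items = sorted((g.tss, g.gene_id) for g in genes if g.chrom == chrom)
        tss_by_chrom[chrom] = (np.array([t for t, _ in items]), [i for _, i in items])
    links: dict[str, str | None] = {}
    for site in sites:
        pos_arr, ids = tss_by_chrom[site.chrom]
        j = int(np.searchsorted(pos_arr, site.midpoint))
        best, bestd = None, None
        # visiting the lower-coordinate TSS first makes ties resolve low
        for jj in (j - 1, j):
            if 0 <= jj < len(pos_arr):
                d = abs(int(pos_arr[jj]) - site.midpoint)
                if bestd is None or d < bestd:
                    best, bestd = ids[jj], d
        links[site.name] = best if (bestd is not None and bestd <= 100_000) else None

    states = {s.name: bool(states_arr[i]) for i, s in enumerate(sites)}
    baseline = {
        g.gene_id: float(v)
        for g, v in zip(genes, rng.normal(cfg.baseline_log_fpkm_mean,
                                          cfg.baseline_log_fpkm_sd, cfg.n_genes))
    }

    clean_ids = [s.name for s in sites if s.name not in violations]
    n_low = int(round(cfg.fraction_low_mappability * len(clean_ids)))
    low_ids = sorted(rng.choice(clean_ids, size=n_low, replace=False).tolist())

    truth = SyntheticTruth(states, dict(cfg.effects), links, baseline,
                           violations, low_ids)
    return genes, sites, truth


def generate_reads(
    cfg: GeneratorConfig,
    truth: SyntheticTruth,
    genes: list[GeneRecord],
    sites: list[GenomicInterval],
) -> dict[str, pd.DataFrame]:
    """Draw per-track reads: Poisson counts on an exponentiated Gaussian.

    Returns one DataFrame (chrom, start, end, strand) per track; GRO-seq
    appears as ``groseq_plus`` / ``groseq_minus``. Background reads are
    scattered uniformly so track totals are not purely enhancer-driven.
    """
    cfg.validate()
    _, rng, _ = _rngs(cfg.seed, 3)
    half = cfg.window_half_bp
    n = len(sites)
    active = np.array([truth.states[s.name] for s in sites], dtype=float)

    chrom_len = {c: max((g.body_end for g in genes if g.chrom == c), default=0)
                 + 50_000 for c in ("chr1", "chr2")}
    site_chrom = np.array([s.chrom for s in sites])
    site_mid = np.array([s.midpoint for s in sites])

    def _draw_track(rate: np.ndarray, strand: str) -> pd.DataFrame:
        counts = rng.poisson(rate)
        reps_chrom = np.repeat(site_chrom, counts)
        reps_mid = np.repeat(site_mid, counts)
        offs = rng.integers(-half, half, size=int(counts.sum()))
        mids = reps_mid + offs
        starts = mids - cfg.read_len // 2
        frames = [pd.DataFrame({"chrom": reps_chrom, "start": starts,
                                "end": starts + cfg.read_len})]
        for c, L in chrom_len.items():
            nbg = rng.poisson(cfg.background_per_kb * L / 1000.0)
            bstart = rng.integers(0, max(L - cfg.read_len, 1), size=nbg)
            frames.append(pd.DataFrame({"chrom": c, "start": bstart,
                                        "end": bstart + cfg.read_len}))
        df = pd.concat(frames, ignore_index=True)
        df["strand"] = strand
        return df

    tracks: dict[str, pd.DataFrame] = {}
    eps_scale = cfg.noise_sd
    for group, marks in cfg.mark_groups.items():
        shared = rng.normal(size=n) if group == "acetyl" and cfg.rho > 0 else None
        for m in marks:
            z = rng.normal(size=n)
            if shared is not None:
                eps = eps_scale * (np.sqrt(cfg.rho) * shared
                                   + np.sqrt(1 - cfg.rho) * z)
            else:
                eps = eps_scale * z
            rate = cfg.depth * np.exp(truth.effects[m] * active + eps)
            tracks[m] = _draw_track(rate, ".")
    for name, strand in (("groseq_plus", "+"), ("groseq_minus", "-")):
        eps = eps_scale * rng.normal(size=n)
        rate = cfg.gro_depth * np.exp(cfg.gro_effect * active + eps)
        tracks[name] = _draw_track(rate, strand)
    return tracks


def generate_expression(
    cfg: GeneratorConfig, truth: SyntheticTruth
) -> list[ExpressionRecord]:
    """Log-normal FPKM per gene, shifted up for genes linked to active enhancers."""
    cfg.validate()
    _, _, rng = _rngs(cfg.seed, 3)
    active_genes = truth.active_linked_genes()
    out = []
    for gid in sorted(truth.gene_baseline):
        mu = truth.gene_baseline[gid] + (cfg.expression_shift if gid in active_genes else 0.0)
        out.append(ExpressionRecord(gid, float(np.exp(mu + cfg.expression_noise_sd
                                                      * rng.normal()))))
    return out


def _mappability_track(
    cfg: GeneratorConfig, genes: list[GeneRecord], sites: list[GenomicInterval],
    truth: SyntheticTruth,
) -> list[MappabilitySegment]:
    """Tile each chromosome at 1.0 with 0.5 holes over planted low-map windows."""
    half = cfg.window_half_bp
    low = {s.name: s for s in sites if s.name in set(truth.low_mappability_ids)}
    segs: list[MappabilitySegment] = []
    for chrom in ("chr1", "chr2"):
        L = max((g.body_end for g in genes if g.chrom == chrom), default=0) + 50_000
        holes = sorted((s.midpoint - half - 10, s.midpoint + half + 10)
                       for s in low.values() if s.chrom == chrom)
        cur = 0
        for h0, h1 in holes:
            if h0 > cur:
                segs.append(MappabilitySegment(GenomicInterval(chrom, cur, h0), 1.0))
            segs.append(MappabilitySegment(GenomicInterval(chrom, h0, h1), 0.5))
            cur = h1
        if cur < L:
            segs.append(MappabilitySegment(GenomicInterval(chrom, cur, L), 1.0))
    return segs


def _peak_calls(
    cfg: GeneratorConfig, genes: list[GeneRecord], sites: list[GenomicInterval],
    tracks: dict[str, pd.DataFrame], truth: SyntheticTruth,
) -> dict[str, list[GenomicInterval]]:
    """Derive synthetic 'peak calls': promoter K4me3, K27ac where signal is high."""
    k4me3 = []
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed ^ 0x5EED))
    for g in genes:
        if rng.random() < cfg.k4me3_fraction:
            k4me3.append(GenomicInterval(g.chrom, max(g.tss - 500, 0), g.tss + 500,
                                         name=f"k4me3_{g.gene_id}"))
    # K27ac peaks at enhancers whose realized K27ac read count is promoter-like high
    half = cfg.window_half_bp
    k27 = tracks.get("H3K27ac")
    k27ac_peaks: list[GenomicInterval] = []
    if k27 is not None:
        mids = ((k27["start"] + k27["end"]) // 2).to_numpy()
        chroms = k27["chrom"].to_numpy()
        cut = cfg.depth * np.exp(abs(truth.effects.get("H3K27ac", 1.0)) / 2.0)
        for s in sites:
            cnt = int(np.sum((chroms == s.chrom) & (mids >= s.midpoint - half)
                             & (mids < s.midpoint + half)))
            if cnt > cut:
                k27ac_peaks.append(GenomicInterval(s.chrom, s.midpoint - half,
                                                   s.midpoint + half,
                                                   name=f"k27ac_{s.name}"))
    k4me1 = [GenomicInterval(s.chrom, s.start - 100, s.end + 100,
                             name=f"k4me1_{s.name}") for s in sites]
    return {"k4me3": k4me3, "k27ac": k27ac_peaks, "k4me1": k4me1}


def generate_dataset(cfg: GeneratorConfig, outdir: str) -> dict[str, str]:
    """Write a complete synthetic dataset plus truth tables and a manifest.

    Returns a mapping role -> path. Also writes ``dataset_config.yaml``, a run
    configuration pointing at the emitted files, so the analysis stages can be
    launched directly on the dataset.
    """
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    genes, sites, truth = generate_annotation(cfg)
    tracks = generate_reads(cfg, truth, genes, sites)
    expr = generate_expression(cfg, truth)
    peaks = _peak_calls(cfg, genes, sites, tracks, truth)
    mapp = _mappability_track(cfg, genes, sites, truth)

    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        return os.path.join(outdir, name)

    trackdir = os.path.join(outdir, "tracks")
    os.makedirs(trackdir, exist_ok=True)
    for name, df in tracks.items():
        path = os.path.join(trackdir, f"{name}.bed")
        stranded = name.startswith("groseq")
        cols = df[["chrom", "start", "end"]].copy()
        if stranded:
            cols["name"] = "."
            cols["score"] = 0
            cols["strand"] = df["strand"]
        cols.to_csv(path, sep="\t", header=False, index=False)
        paths[f"track:{name}"] = path

    write_bed(_p("p300_peaks.bed"), sites)
    write_bed(_p("k4me3_peaks.bed"), peaks["k4me3"])
    write_bed(_p("k27ac_peaks.bed"), peaks["k27ac"])
    write_bed(_p("k4me1_peaks.bed"), peaks["k4me1"])
    write_gene_table(_p("genes.tsv"), genes)
    write_mappability(_p("mappability.bed"), mapp)
    write_expression(_p("expression.tsv"), expr)
    paths.update({
        "peaks": _p("p300_peaks.bed"), "k4me3_peaks": _p("k4me3_peaks.bed"),
        "k27ac_peaks": _p("k27ac_peaks.bed"), "k4me1_peaks": _p("k4me1_peaks.bed"),
        "genes": _p("genes.tsv"), "mappability": _p("mappability.bed"),
        "expression": _p("expression.tsv"),
    })

    with open(_p("truth_enhancers.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("#enhancer_id\tactive\tviolation\tlinked_gene\tlow_mappability\n")
        low = set(truth.low_mappability_ids)
        for s in sites:
            eid = s.name
            fh.write(f"{eid}\t{int(truth.states[eid])}\t"
                     f"{truth.violations.get(eid, '.')}\t"
                     f"{truth.links.get(eid) or '.'}\t{int(eid in low)}\n")
    with open(_p("truth_genes.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("#gene_id\tbaseline_log_fpkm\tactive_linked\n")
        act = truth.active_linked_genes()
        for gid in sorted(truth.gene_baseline):
            fh.write(f"{gid}\t{truth.gene_baseline[gid]:.6f}\t{int(gid in act)}\n")
    with open(_p("truth_effects.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("#mark\teffect\n")
        for m in cfg.marks:
            fh.write(f"{m}\t{cfg.effects[m]:.6f}\n")
    paths["truth_enhancers"] = _p("truth_enhancers.tsv")
    paths["truth_genes"] = _p("truth_genes.tsv")
    paths["truth_effects"] = _p("truth_effects.tsv")

    run_cfg = {
        "tracks": {m: os.path.join("tracks", f"{m}.bed") for m in cfg.marks},
        "gro_plus": os.path.join("tracks", "groseq_plus.bed"),
        "gro_minus": os.path.join("tracks", "groseq_minus.bed"),
        "peaks": "p300_peaks.bed",
        "k4me3_peaks": "k4me3_peaks.bed",
        "k27ac_peaks": "k27ac_peaks.bed",
        "genes": "genes.tsv",
        "mappability": "mappability.bed",
        "expression": "expression.tsv",
        "window_half_bp": cfg.window_half_bp,
        "tss_exclusion_bp": cfg.tss_exclusion_bp,
        "seed": cfg.seed,
    }
    with open(_p("dataset_config.yaml"), "wt", encoding="utf-8") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    paths["config"] = _p("dataset_config.yaml")

    with open(_p("manifest.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("#role\tpath\n")
        for role in sorted(paths):
            fh.write(f"{role}\t{os.path.relpath(paths[role], outdir)}\n")
    paths["manifest"] = _p("manifest.tsv")
    return paths


def read_truth(outdir: str) -> SyntheticTruth:
    """Load the truth tables written by :func:`generate_dataset`."""
    enh = pd.read_csv(os.path.join(outdir, "truth_enhancers.tsv"), sep="\t")
    enh.columns = [c.lstrip("#") for c in enh.columns]
    gen = pd.read_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
    gen.columns = [c.lstrip("#") for c in gen.columns]
    eff = pd.read_csv(os.path.join(outdir, "truth_effects.tsv"), sep="\t")
    eff.columns = [c.lstrip("#") for c in eff.columns]
    return SyntheticTruth(
        states={r.enhancer_id: bool(r.active) for r in enh.itertuples()},
        effects={r.mark: float(r.effect) for r in eff.itertuples()},
        links={r.enhancer_id: (None if r.linked_gene == "." else r.linked_gene)
               for r in enh.itertuples()},
        gene_baseline={r.gene_id: float(r.baseline_log_fpkm) for r in gen.itertuples()},
        violations={r.enhancer_id: r.violation for r in enh.itertuples()
                    if r.violation != "."},
        low_mappability_ids=[r.enhancer_id for r in enh.itertuples()
                             if r.low_mappability],
    )
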