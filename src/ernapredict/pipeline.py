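"""End-to-end orchestration: simulate -> catalog -> label -> train -> select
-> predict -> analyze, reproducibly from a single configuration and seed.

Each stage reads only files written by its declared dependencies and appends
an entry (with SHA-256 digests of its outputs) to ``manifest.tsv`` in the
output directory. One global seed fans out to per-stage seeds derived by
hashing the stage name, so any stage can be rerun independently yet
reproducibly. Timestamps appear only in the manifest; all data outputs are
pure functions of the configuration and seed.
"""

from __future__ import annotations

import hashlib
import logging
import os
import time
import zlib
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from . import activity, labeling, selection
from .catalog import (EnhancerRegion, SignalMatrix, TrackLibrary,
                      apply_mappability_filter, compute_signal_matrix,
                      define_intergenic_enhancers)
from .io_formats import (GenomicInterval, RunConfig, read_bed, read_expression,
                         read_gene_table, read_mappability)
from .logit import LogitModel, fit_logistic, predict_proba
from .synthetic import GeneratorConfig, generate_dataset

log = logging.getLogger("ernapredict")

STAGES = ("simulate", "catalog", "label", "train", "select", "predict", "analyze")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: stage-name CRC folded into the global seed (< 2^31)."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 0x9E3779B1)) % (2**31 - 1)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class DependencyError(FileNotFoundError):
    pass


class Pipeline:
    """Stage runner bound to a config, an output directory and a seed."""

    def __init__(self, config: RunConfig, outdir: str,
                 gen_cfg: GeneratorConfig | None = None) -> None:
        self.config = config.validate()
        self.outdir = outdir
        self.gen_cfg = gen_cfg
        os.makedirs(outdir, exist_ok=True)

    def _p(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def _require(self, stage: str, *paths: str) -> None:
        for p in paths:
            if not p or not os.path.exists(p):
                raise DependencyError(f"stage {stage!r}: missing dependency {p!r}")

    def _manifest(self, stage: str, outputs: list[str]) -> None:
        path = self._p("manifest.tsv")
        new = not os.path.exists(path)
        with open(path, "at", encoding="utf-8") as fh:
            if new:
                fh.write("#stage\ttimestamp\tseed\tfile\tsha256\n")
            ts = time.strftime("%Y-%m-%dT%H:%M:%S")
            for out in outputs:
                fh.write(f"{stage}\t{ts}\t{stage_seed(self.config.seed, stage)}\t"
                         f"{os.path.relpath(out, self.outdir)}\t{_sha256(out)}\n")

    # ---------------------------------------------------------------- stages

    def simulate(self) -> dict[str, str]:
        if self.gen_cfg is None:
            raise ValueError("simulate stage requested without generator settings")
        gcfg = dc_replace(self.gen_cfg,
                          seed=stage_seed(self.config.seed, "simulate"))
        dataset_dir = self._p("dataset")
        paths = generate_dataset(gcfg, dataset_dir)
        # point the run config at the simulated files
        self.config.tracks = {m: paths[f"track:{m}"] for m in gcfg.marks}
        self.config.gro_plus = paths["track:groseq_plus"]
        self.config.gro_minus = paths["track:groseq_minus"]
        self.config.peaks = paths["peaks"]
        self.config.k4me3_peaks = paths["k4me3_peaks"]
        self.config.k27ac_peaks = paths["k27ac_peaks"]
        self.config.genes = paths["genes"]
        self.config.mappability = paths["mappability"]
        self.config.expression = paths["expression"]
        log.info("simulate: wrote %d files under %s", len(paths), dataset_dir)
        self._manifest("simulate", [paths["manifest"]])
        return paths

    def catalog(self) -> None:
        cfg = self.config
        self._require("catalog", cfg.peaks, cfg.k4me3_peaks, cfg.genes,
                      cfg.mappability, *cfg.tracks.values(),
                      cfg.gro_plus, cfg.gro_minus)
        peaks = read_bed(cfg.peaks)
        genes = read_gene_table(cfg.genes)
        k4me3 = read_bed(cfg.k4me3_peaks)
        regions, removed = define_intergenic_enhancers(
            peaks, genes, k4me3, cfg.tss_exclusion_bp, cfg.window_half_bp)
        log.info("catalog: %d peaks -> %d intergenic (%d removed)",
                 len(peaks), len(regions), len(removed))
        mapp = read_mappability(cfg.mappability)
        kept, dropped_map = apply_mappability_filter(regions, mapp,
                                                     cfg.mappability_min)
        log.info("catalog: %d pass mappability >= %.2f (%d dropped)",
                 len(kept), cfg.mappability_min, len(dropped_map))

        tracks = TrackLibrary()
        for mark, path in cfg.tracks.items():
            tracks.add_bed_file(mark, path)
        gro = TrackLibrary()
        gro.add_bed_file("groseq_plus", cfg.gro_plus)
        gro.add_bed_file("groseq_minus", cfg.gro_minus)
        signal = compute_signal_matrix(kept, tracks, gro, cfg.pseudocount,
                                       cfg.log_base)

        with open(self._p("catalog.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("#chrom\tstart\tend\tid\tprovenance\tmean_mappability\t"
                     "peak_start\tpeak_end\n")
            for r in kept:
                fh.write(f"{r.interval.chrom}\t{r.interval.start}\t"
                         f"{r.interval.end}\t{r.id}\t{r.provenance}\t"
                         f"{r.mean_mappability:.6f}\t{r.source_peak.start}\t"
                         f"{r.source_peak.end}\n")
        reasons = pd.Series(list(removed.values()) + ["low_mappability"] *
                            len(dropped_map))
        with open(self._p("filter_counts.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("#step\tcount\n")
            fh.write(f"input_peaks\t{len(peaks)}\n")
            fh.write(f"intergenic\t{len(regions)}\n")
            for reason, cnt in sorted(reasons.value_counts().items()):
                fh.write(f"removed_{reason}\t{cnt}\n")
            fh.write(f"final_catalog\t{len(kept)}\n")
        signal.to_tsv(self._p("signal.tsv"))
        self._manifest("catalog", [self._p("catalog.tsv"),
                                   self._p("filter_counts.tsv"),
                                   self._p("signal.tsv")])

    def label(self) -> None:
        self._require("label", self._p("signal.tsv"))
        signal = SignalMatrix.from_tsv(self._p("signal.tsv"))
        labels = labeling.label_enhancers(signal)
        counts = labels.labels.value_counts()
        log.info("label: %s", counts.to_dict())
        labels.to_tsv(self._p("labels.tsv"), signal)
        self._manifest("label", [self._p("labels.tsv")])

    def train(self) -> None:
        self._require("train", self._p("signal.tsv"), self._p("labels.tsv"))
        signal, labels = self._load_signal_labels()
        model = fit_logistic(signal, labels,
                             ridge_lambda=self.config.ridge_lambda)
        model.to_tsv(self._p("model_full.tsv"))
        plan = selection.make_cv_plan(labels, self.config.cv_folds,
                                      self.config.inner_folds,
                                      stage_seed(self.config.seed, "train"))
        full = selection.nested_cv_evaluate(
            signal, labels, [tuple(signal.marks.columns)], plan,
            top_n_inner=1, ridge_lambda=self.config.ridge_lambda)[0]
        with open(self._p("cv_full.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("#model\tmean_auc\tmean_mcc\n")
            fh.write(f"full\t{full.mean_auc:.6f}\t{full.mean_mcc:.6f}\n")
        log.info("train: full model CV AUC %.4f MCC %.4f",
                 full.mean_auc, full.mean_mcc)
        self._manifest("train", [self._p("model_full.tsv"), self._p("cv_full.tsv")])

    def select(self) -> None:
        self._require("select", self._p("signal.tsv"), self._p("labels.tsv"),
                      self._p("cv_full.tsv"))
        cfg = self.config
        signal, labels = self._load_signal_labels()
        marks = list(signal.marks.columns)
        plan = selection.make_cv_plan(labels, cfg.cv_folds, cfg.inner_folds,
                                      stage_seed(cfg.seed, "select"))
        full_row = pd.read_csv(self._p("cv_full.tsv"), sep="\t", comment=None,
                               names=["model", "mean_auc", "mean_mcc"],
                               skiprows=1)
        full_auc = float(full_row["mean_auc"].iloc[0])
        full_mcc = float(full_row["mean_mcc"].iloc[0])

        results_by_m: dict[int, list[selection.SubsetResult]] = {}
        outputs = []
        for m in cfg.subset_sizes:
            subsets = selection.enumerate_subsets(marks, m)
            results = selection.nested_cv_evaluate(
                signal, labels, subsets, plan, cfg.top_n_inner,
                cfg.ridge_lambda)
            results_by_m[m] = results
            path = self._p(f"subset_results_m{m}.tsv")
            selection.results_to_tsv(path, results)
            outputs.append(path)
            best = selection.rank_results(results)[0]
            log.info("select: m=%d best %s AUC %.4f MCC %.4f", m,
                     "+".join(best.subset), best.mean_auc, best.mean_mcc)

        m_sel = max(cfg.subset_sizes)
        evaluated = [r.subset for r in results_by_m[m_sel]]
        rep_frac = selection.select_top_models(
            results_by_m[m_sel], "top_fraction", top_fraction=cfg.top_fraction)
        rep_rel = selection.select_top_models(
            results_by_m[m_sel], "relative", relative_r=0.95,
            full_auc=full_auc, full_mcc=full_mcc)
        with open(self._p("selection.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("#rule\tsubset\tmean_auc\tmean_mcc\n")
            by_subset = {r.subset: r for r in results_by_m[m_sel]}
            for rep, rule in ((rep_frac, "top_fraction"), (rep_rel, "relative")):
                for sub in rep.selected:
                    r = by_subset[sub]
                    fh.write(f"{rule}\t{'+'.join(sub)}\t{r.mean_auc:.6f}\t"
                             f"{r.mean_mcc:.6f}\n")
        # enrichment is computed over the best-scored (relative-rule) models,
        # the larger and more stable selection; falls back to top-fraction
        report = rep_rel if rep_rel.selected else rep_frac
        if report.selected:
            enr = selection.enrichment_table(report, evaluated)
            enr.to_csv(self._p("enrichment.tsv"), sep="\t", index=False,
                       float_format="%.6g")
        else:
            log.warning("select: empty selection; no enrichment computed")
            pd.DataFrame(columns=["mark", "k_selected", "n_selected",
                                  "k_population", "n_population",
                                  "p_value"]).to_csv(
                self._p("enrichment.tsv"), sep="\t", index=False)
        with open(self._p("m_comparison.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("#m\tm_plus_1\twilcoxon_p_auc\n")
            ms = sorted(results_by_m)
            for a, b in zip(ms, ms[1:]):
                try:
                    p = selection.compare_m_performance(results_by_m[a],
                                                        results_by_m[b])
                    fh.write(f"{a}\t{b}\t{p:.6g}\n")
                except ValueError:
                    fh.write(f"{a}\t{b}\tNA\n")
        outputs += [self._p("selection.tsv"), self._p("enrichment.tsv"),
                    self._p("m_comparison.tsv")]
        self._manifest("select", outputs)

    def predict(self) -> None:
        self._require("predict", self._p("signal.tsv"), self._p("labels.tsv"))
        cfg = self.config
        signal, labels = self._load_signal_labels()
        m_sel = max(cfg.subset_sizes)
        best_path = self._p(f"subset_results_m{m_sel}.tsv")
        if os.path.exists(best_path):
            with open(best_path, "rt", encoding="utf-8") as fh:
                fh.readline()
                best_subset = tuple(fh.readline().split("\t")[0].split("+"))
        else:                       # select stage skipped: use the full model
            best_subset = tuple(signal.marks.columns)
        model = fit_logistic(signal, labels, list(best_subset),
                             ridge_lambda=cfg.ridge_lambda)
        model.to_tsv(self._p("model_best.tsv"))
        probs = predict_proba(model, signal)
        with open(self._p("predictions.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("#enhancer_id\tp_erna\tcall\tmeasured_label\n")
            for eid in signal.enhancer_ids:
                p = probs.loc[eid]
                call = labeling.POSITIVE if p >= 0.5 else labeling.NEGATIVE
                fh.write(f"{eid}\t{p:.6f}\t{call}\t"
                         f"{labels.labels.loc[eid]}\n")
        log.info("predict: best subset %s; %d enhancers scored",
                 "+".join(best_subset), len(probs))
        self._manifest("predict", [self._p("model_best.tsv"),
                                   self._p("predictions.tsv")])

    def analyze(self) -> None:
        cfg = self.config
        self._require("analyze", self._p("catalog.tsv"), self._p("labels.tsv"),
                      self._p("predictions.tsv"), cfg.genes, cfg.expression,
                      cfg.k27ac_peaks)
        regions = read_catalog(self._p("catalog.tsv"))
        genes = read_gene_table(cfg.genes)
        expr = read_expression(cfg.expression)
        k27ac = read_bed(cfg.k27ac_peaks)
        labels_df = pd.read_csv(self._p("labels.tsv"), sep="\t")
        labels_df.columns = [c.lstrip("#") for c in labels_df.columns]
        measured = labels_df.set_index("enhancer_id")["label"]
        pred_df = pd.read_csv(self._p("predictions.tsv"), sep="\t")
        pred_df.columns = [c.lstrip("#") for c in pred_df.columns]
        predicted = pred_df.set_index("enhancer_id")["call"]

        links = activity.assign_genes(regions, genes, cfg.gene_assign_max_bp)
        with open(self._p("links.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("#enhancer_id\tgene_id\tdistance\n")
            for l in links:
                fh.write(f"{l.enhancer_id}\t{l.gene_id or '.'}\t"
                         f"{l.distance if l.distance is not None else '.'}\n")
        k27 = activity.classify_h3k27ac(regions, k27ac, cfg.k27ac_dist_bp)
        outputs = [self._p("links.tsv")]
        for status, tag in ((measured, "measured"), (predicted, "predicted")):
            sub = activity.subgroup_enhancers(status, k27)
            sub_path = self._p(f"subgroups_{tag}.tsv")
            with open(sub_path, "wt", encoding="utf-8") as fh:
                fh.write("#enhancer_id\tsubgroup\n")
                for eid in sorted(sub.index):
                    fh.write(f"{eid}\t{sub.loc[eid]}\n")
            comp = activity.compare_expression(sub, links, expr)
            comp_path = self._p(f"expression_comparison_{tag}.tsv")
            comp.to_csv(comp_path, sep="\t", index=False, float_format="%.6g")
            outputs += [sub_path, comp_path]
            log.info("analyze (%s): %s", tag,
                     sub.value_counts().to_dict())
        self._manifest("analyze", outputs)

    # ------------------------------------------------------------- plumbing

    def _load_signal_labels(self) -> tuple[SignalMatrix, labeling.ErnaLabelSet]:
        signal = SignalMatrix.from_tsv(self._p("signal.tsv"))
        labels = labeling.label_enhancers(signal)
        return signal, labels

    def run_stage(self, name: str) -> None:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
        getattr(self, name)()

    def run_all(self) -> None:
        start = STAGES if self.gen_cfg is not None else STAGES[1:]
        for name in start:
            log.info("=== stage %s ===", name)
            self.run_stage(name)


def read_catalog(path: str) -> list[EnhancerRegion]:
    regions = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            (chrom, start, end, eid, prov, mapp, ps, pe) = \
                line.rstrip("\n").split("\t")
            regions.append(EnhancerRegion(
                eid, GenomicInterval(chrom, int(start), int(end), name=eid),
                GenomicInterval(chrom, int(ps), int(pe), name=eid),
                prov, float(mapp)))
    return regions


def run_synthetic_experiment(outdir: str, seed: int,
                             gen_cfg: GeneratorConfig | None = None,
                             run_cfg: RunConfig | None = None) -> Pipeline:
    """One-call convenience: full synthetic pipeline under a single seed."""
    cfg = run_cfg if run_cfg is not None else RunConfig()
    cfg.seed = seed
    pipe = Pipeline(cfg, outdir, gen_cfg or GeneratorConfig())
    pipe.run_all()
    return pipe
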