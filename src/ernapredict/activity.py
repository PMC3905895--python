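"""Enhancer activity stratification via associated gene expression.

Each enhancer is assigned to the gene whose TSS is nearest its window center
(at most 100 kb away). Enhancers within 2 kb of an H3K27ac-enriched region
are H3K27ac+. Crossing eRNA status (measured or model-predicted) with
H3K27ac status yields four subgroups — eRNA+K27ac+, eRNA+K27ac-,
eRNA-K27ac+, eRNA-K27ac- — whose associated-gene FPKM distributions are
compared pairwise with two-sided Mann-Whitney rank-sum tests. A gene linked
by several enhancers of one group counts once in that group.

The fitted model also transfers across cell types: predictions on another
cell type's signal matrix use the marks shared with training, standardized
on the target cell type by default so the model sees comparably scaled
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import EnhancerRegion, SignalMatrix
from .io_formats import ExpressionRecord, GeneRecord, GenomicInterval
from .labeling import AMBIGUOUS, POSITIVE
from .logit import LogitModel, predict_proba
from .metrics import auc_score, mcc_at_threshold

SUBGROUPS = ("eRNA+K27ac+", "eRNA+K27ac-", "eRNA-K27ac+", "eRNA-K27ac-")


@dataclass(frozen=True)
class EnhancerGeneLink:
    enhancer_id: str
    gene_id: str | None
    distance: int | None


def assign_genes(enhancers: list[EnhancerRegion], genes: list[GeneRecord],
                 max_dist: int = 100_000) -> list[EnhancerGeneLink]:
    """Link each enhancer to the gene with the nearest TSS (window center to
    TSS distance, at most ``max_dist``); equidistant ties go to the
    lower-coordinate TSS."""
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {g.chrom for g in genes}:
        items = sorted((g.tss, g.gene_id) for g in genes if g.chrom == chrom)
        by_chrom[chrom] = (np.asarray([t for t, _ in items], dtype=np.int64),
                          [gid for _, gid in items])
    links: list[EnhancerGeneLink] = []
    for enh in enhancers:
        center = enh.interval.midpoint
        entry = by_chrom.get(enh.interval.chrom)
        best_gene, best_d = None, None
        if entry is not None:
            pos, gids = entry
            j = int(np.searchsorted(pos, center))
            # lower-coordinate candidate first so ties resolve low
            for jj in (j - 1, j):
                if 0 <= jj < len(pos):
                    d = abs(int(pos[jj]) - center)
                    if best_d is None or d < best_d:
                        best_gene, best_d = gids[jj], d
        if best_d is None or best_d > max_dist:
            links.append(EnhancerGeneLink(enh.id, None, None))
        else:
            links.append(EnhancerGeneLink(enh.id, best_gene, best_d))
    return links


def classify_h3k27ac(enhancers: list[EnhancerRegion],
                     k27ac_peaks: list[GenomicInterval],
                     dist: int = 2000) -> pd.Series:
    """H3K27ac status: '+' iff the edge-to-edge gap to any peak is <= dist."""
    from .catalog import _merge

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in k27ac_peaks}:
        by_chrom[chrom] = _merge([(p.start, p.end)
                                  for p in k27ac_peaks if p.chrom == chrom])
    status = {}
    for enh in enhancers:
        win = enh.interval
        entry = by_chrom.get(win.chrom)
        hit = False
        if entry is not None:
            starts, ends = entry     # merged, so starts and ends both sorted
            j = int(np.searchsorted(starts, win.end + dist, side="right"))
            if j > 0:
                gap = max(int(starts[j - 1]) - win.end,
                          win.start - int(ends[j - 1]), 0)
                hit = gap <= dist
        status[enh.id] = "+" if hit else "-"
    return pd.Series(status, name="k27ac_status")


def subgroup_enhancers(erna_status: pd.Series, k27ac_status: pd.Series) -> pd.Series:
    """Cross eRNA and H3K27ac status into the four activity subgroups.

    ``erna_status`` holds 'positive'/'negative'/'ambiguous' labels (measured
    or predicted); ambiguous enhancers are excluded from the result.
    """
    common = erna_status.index.intersection(k27ac_status.index)
    out = {}
    for eid in common:
        lab = erna_status.loc[eid]
        if lab == AMBIGUOUS:
            continue
        e = "+" if lab == POSITIVE else "-"
        out[eid] = f"eRNA{e}K27ac{k27ac_status.loc[eid]}"
    return pd.Series(out, name="subgroup")


def _group_fpkms(group_ids, links: list[EnhancerGeneLink],
                 expression: list[ExpressionRecord]) -> np.ndarray:
    fpkm = {r.gene_id: r.fpkm for r in expression}
    link_map = {l.enhancer_id: l.gene_id for l in links}
    genes = {link_map[e] for e in group_ids
             if link_map.get(e) is not None and link_map[e] in fpkm}
    return np.asarray([fpkm[g] for g in sorted(genes)], dtype=float)


def compare_expression(
    subgroups: pd.Series,
    links: list[EnhancerGeneLink],
    expression: list[ExpressionRecord],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests on associated-gene FPKM.

    Each linked gene counts once per group. The exact null distribution is
    used for small groups (both n <= 50 and no ties), the normal
    approximation with continuity correction otherwise. Pairs with an empty
    group are skipped (reported with NaN p).
    """
    groups = {g: subgroups.index[subgroups == g].tolist()
              for g in subgroups.unique()}
    if pairs is None:
        names = [g for g in SUBGROUPS if g in groups] + \
                [g for g in groups if g not in SUBGROUPS]
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        xa = _group_fpkms(groups.get(a, []), links, expression)
        xb = _group_fpkms(groups.get(b, []), links, expression)
        row = {"group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb),
               "median_a": float(np.median(xa)) if len(xa) else np.nan,
               "median_b": float(np.median(xb)) if len(xb) else np.nan}
        if len(xa) == 0 or len(xb) == 0:
            row.update({"u_statistic": np.nan, "p_value": np.nan})
        else:
            both = np.concatenate([xa, xb])
            if np.ptp(both) == 0:        # identical constant samples: no evidence
                row.update({"u_statistic": len(xa) * len(xb) / 2.0, "p_value": 1.0})
            else:
                small = max(len(xa), len(xb)) <= 50
                ties = len(np.unique(both)) < len(both)
                method = "exact" if (small and not ties) else "asymptotic"
                res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                         method=method, use_continuity=True)
                row.update({"u_statistic": float(res.statistic),
                            "p_value": float(res.pvalue)})
        rows.append(row)
    return pd.DataFrame(rows)


def cross_celltype_predict(
    model: LogitModel,
    signal_other: SignalMatrix,
    labels_other: pd.Series | None = None,
    restandardize: bool = True,
) -> tuple[pd.Series, dict | None]:
    """Apply a trained model to another cell type's signal matrix.

    With ``restandardize`` (default) the model's marks are re-standardized on
    the target cell type so the linear predictor sees comparably scaled
    inputs; otherwise the training-cell standardization is used. If 0/1
    labels are supplied, AUC and MCC@0.5 are reported alongside.
    """
    missing = [m for m in model.marks if m not in signal_other.marks.columns]
    if missing:
        raise ValueError(f"target cell type lacks model mark(s): {missing}")
    if restandardize:
        X = signal_other.marks[model.marks]
        mu = X.mean(axis=0).to_numpy()
        sd = X.std(axis=0, ddof=0).to_numpy()
        if np.any(sd <= 0):
            raise ValueError("constant mark in target cell type")
        local = LogitModel(model.marks, model.beta0, model.beta, mu, sd,
                           model.ridge_lambda, model.converged, model.n_iter,
                           model.loglik)
        probs = predict_proba(local, signal_other)
    else:
        probs = predict_proba(model, signal_other)
    evaluation = None
    if labels_other is not None:
        common = probs.index.intersection(labels_other.index)
        y = labels_other.loc[common].to_numpy()
        p = probs.loc[common].to_numpy()
        evaluation = {"auc": auc_score(y, p),
                      "mcc": mcc_at_threshold(y, p, 0.5),
                      "n": int(len(common))}
    return probs, evaluation
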