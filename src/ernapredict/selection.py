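"""Exhaustive mark-subset enumeration under nested cross-validation.

All C(n_marks, m) size-m subsets are candidate models. Performance is
estimated without selection bias by nested cross-validation: the labeled
enhancers are split into K stratified outer folds (K = 10 by default); within
each outer-training set an inner K-fold cross-validation ranks every subset
by mean validation AUC; the top subsets are refit on the whole outer-training
set and scored on the held-out fold, which the inner loop never saw. Outer
AUC/MCC are averaged over the folds where a subset reached the inner top
list; subsets that never reached it carry no outer score and are dropped.

Selected models are summarized two ways (both reported by rule name):
``top_fraction`` — the intersection of the top fraction by mean AUC and by
mean MCC (default 5%); ``relative`` — subsets achieving at least r of the
full-model AUC and MCC (default r = 0.95). Over-representation of a mark
among selected subsets is scored with a one-sided upper-tail hypergeometric
test (raw p-values, no multiplicity correction). Performance of the best
m- vs (m+1)-subset is compared with a paired two-sided Wilcoxon signed-rank
test across the shared outer folds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import SignalMatrix
from .labeling import ErnaLabelSet
from .logit import newton_logistic, _sigmoid
from .metrics import auc_score, mcc_at_threshold


def enumerate_subsets(marks: list[str], m: int) -> list[tuple[str, ...]]:
    """All size-m subsets in lexicographic order of the given mark order."""
    if not (1 <= m <= len(marks)):
        raise ValueError(f"subset size m={m} out of range 1..{len(marks)}")
    out = list(itertools.combinations(marks, m))
    assert len(out) == comb(len(marks), m)
    return out


@dataclass
class CvPlan:
    """Stratified outer folds (lists of enhancer ids) plus inner fold count."""

    folds: list[list[str]]
    inner_k: int
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def ids(self) -> list[str]:
        return [i for f in self.folds for i in f]


def _stratified_folds(ids: np.ndarray, y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Deal shuffled positives then negatives round-robin into k folds."""
    folds: list[list] = [[] for _ in range(k)]
    for cls in (1, 0):
        members = ids[y == cls]
        perm = rng.permutation(len(members))
        for j, idx in enumerate(perm):
            folds[j % k].append(members[idx])
    return [np.asarray(f) for f in folds]


def make_cv_plan(labels: ErnaLabelSet | pd.Series, k: int = 10,
                 inner_k: int = 10, seed: int = 0) -> CvPlan:
    """Stratified K-fold partition of the unambiguous labeled enhancers."""
    y_ser = labels.binary() if isinstance(labels, ErnaLabelSet) else labels.astype(int)
    if k < 2 or inner_k < 2:
        raise ValueError("fold counts must be >= 2")
    if len(y_ser) < k:
        raise ValueError("fewer labeled enhancers than folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC5]))
    ids = np.asarray(y_ser.index)
    folds = _stratified_folds(ids, y_ser.to_numpy(), k, rng)
    return CvPlan([f.tolist() for f in folds], inner_k, seed)


@dataclass
class SubsetResult:
    """Outer-CV performance of one mark subset (folds where it was scored)."""

    subset: tuple[str, ...]
    fold_aucs: dict[int, float]
    fold_mccs: dict[int, float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(list(self.fold_aucs.values())))

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(list(self.fold_mccs.values())))


def _rank_key(r: SubsetResult) -> tuple:
    return (-r.mean_auc, -r.mean_mcc, r.subset)


def rank_results(results: list[SubsetResult]) -> list[SubsetResult]:
    """Mean outer AUC descending; ties by mean MCC, then subset order."""
    return sorted(results, key=_rank_key)


def _fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                 lam: float) -> np.ndarray:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0           # constant column: standardizes to 0, slope ~0
    coef, _, _, _ = newton_logistic((Xtr - mu) / sd, ytr, lam)
    eta = coef[0] + ((Xte - mu) / sd) @ coef[1:]
    return _sigmoid(eta)


def nested_cv_evaluate(
    signal: SignalMatrix,
    labels: ErnaLabelSet | pd.Series,
    subsets: list[tuple[str, ...]],
    plan: CvPlan,
    top_n_inner: int = 10,
    ridge_lambda: float = 1e-6,
) -> list[SubsetResult]:
    """Score mark subsets by nested cross-validation (see module docstring)."""
    if not subsets:
        raise ValueError("no candidate subsets")
    if top_n_inner < 1:
        raise ValueError("top_n_inner must be >= 1")
    y_ser = labels.binary() if isinstance(labels, ErnaLabelSet) else labels.astype(int)
    all_marks = list(signal.marks.columns)
    col = {mname: i for i, mname in enumerate(all_marks)}
    for sub in subsets:
        for mname in sub:
            if mname not in col:
                raise ValueError(f"mark {mname!r} absent from signal matrix")
    ids = plan.ids
    X = signal.marks.loc[ids].to_numpy(dtype=float)
    y = y_ser.loc[ids].to_numpy(dtype=float)
    pos_of = {eid: i for i, eid in enumerate(ids)}
    fold_idx = [np.asarray([pos_of[e] for e in f]) for f in plan.folds]
    sub_cols = [np.asarray([col[mname] for mname in sub]) for sub in subsets]

    fold_aucs: dict[int, dict[int, float]] = {}   # subset index -> fold -> auc
    fold_mccs: dict[int, dict[int, float]] = {}
    for f in range(plan.k):
        test_idx = fold_idx[f]
        train_idx = np.concatenate([fold_idx[g] for g in range(plan.k) if g != f])
        Xtr_all, ytr = X[train_idx], y[train_idx]
        rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 0x1A, f]))
        inner = _stratified_folds(np.arange(len(train_idx)), ytr, plan.inner_k, rng)
        inner_scores = np.zeros(len(subsets))
        for g in range(plan.inner_k):
            val = inner[g]
            tr = np.concatenate([inner[h] for h in range(plan.inner_k) if h != g])
            Xi, yi = Xtr_all[tr], ytr[tr]
            mu = Xi.mean(axis=0)
            sd = Xi.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xi_s = (Xi - mu) / sd
            Xv_s = (Xtr_all[val] - mu) / sd
            yv = ytr[val]
            for si, cols in enumerate(sub_cols):
                coef, _, _, _ = newton_logistic(Xi_s[:, cols], yi, ridge_lambda)
                eta = coef[0] + Xv_s[:, cols] @ coef[1:]
                inner_scores[si] += auc_score(yv, eta)
        inner_scores /= plan.inner_k
        # rank candidates by mean inner AUC; ties resolved lexicographically
        order = sorted(range(len(subsets)),
                       key=lambda si: (-inner_scores[si], subsets[si]))
        top = order[:top_n_inner]
        yte = y[test_idx]
        for si in top:
            p = _fit_predict(Xtr_all[:, sub_cols[si]], ytr,
                             X[test_idx][:, sub_cols[si]], ridge_lambda)
            fold_aucs.setdefault(si, {})[f] = auc_score(yte, p)
            fold_mccs.setdefault(si, {})[f] = mcc_at_threshold(yte, p, 0.5)

    results = [SubsetResult(subsets[si], fold_aucs[si], fold_mccs[si])
               for si in sorted(fold_aucs)]
    return rank_results(results)


@dataclass
class SelectionReport:
    """Selected top subsets plus the rule that produced them."""

    results: list[SubsetResult]
    selected: list[tuple[str, ...]]
    rule: str
    params: dict = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None


def select_top_models(
    results: list[SubsetResult],
    rule: str = "top_fraction",
    top_fraction: float = 0.05,
    relative_r: float = 0.95,
    full_auc: float | None = None,
    full_mcc: float | None = None,
) -> SelectionReport:
    """Select top subsets by one of the two documented rules.

    ``top_fraction``: intersection of the top fraction ranked by mean AUC and
    the top fraction ranked by mean MCC. ``relative``: subsets reaching at
    least ``relative_r`` of the supplied full-model AUC and MCC.
    """
    if not results:
        raise ValueError("no results to select from")
    if rule == "top_fraction":
        n_top = int(np.ceil(top_fraction * len(results)))
        by_auc = sorted(results, key=lambda r: (-r.mean_auc, r.subset))[:n_top]
        by_mcc = sorted(results, key=lambda r: (-r.mean_mcc, r.subset))[:n_top]
        chosen = {r.subset for r in by_auc} & {r.subset for r in by_mcc}
        params = {"top_fraction": top_fraction, "n_top": n_top}
    elif rule == "relative":
        if full_auc is None or full_mcc is None:
            raise ValueError("relative rule needs full-model AUC and MCC")
        chosen = {r.subset for r in results
                  if r.mean_auc >= relative_r * full_auc
                  and r.mean_mcc >= relative_r * full_mcc}
        params = {"relative_r": relative_r, "full_auc": full_auc,
                  "full_mcc": full_mcc}
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    selected = [r.subset for r in rank_results(results) if r.subset in chosen]
    return SelectionReport(results, selected, rule, params)


def mark_enrichment(report: SelectionReport,
                    all_subsets: list[tuple[str, ...]], mark: str) -> float:
    """Upper-tail hypergeometric p for over-representation of one mark.

    Population: the evaluated subsets; successes: subsets containing the
    mark; draws: the selected subsets. p = P(X >= k observed).
    """
    universe = {m for sub in all_subsets for m in sub}
    if mark not in universe:
        raise ValueError(f"mark {mark!r} absent from the subset universe")
    if not report.selected:
        raise ValueError("empty selection")
    n_pop = len(all_subsets)
    k_pop = sum(mark in sub for sub in all_subsets)
    n_sel = len(report.selected)
    k_sel = sum(mark in sub for sub in report.selected)
    return float(stats.hypergeom.sf(k_sel - 1, n_pop, k_pop, n_sel))


def enrichment_table(report: SelectionReport,
                     all_subsets: list[tuple[str, ...]]) -> pd.DataFrame:
    """Per-mark enrichment over the selection, sorted by p-value."""
    universe = sorted({m for sub in all_subsets for m in sub})
    rows = []
    for mname in universe:
        rows.append({
            "mark": mname,
            "k_selected": sum(mname in sub for sub in report.selected),
            "n_selected": len(report.selected),
            "k_population": sum(mname in sub for sub in all_subsets),
            "n_population": len(all_subsets),
            "p_value": mark_enrichment(report, all_subsets, mname),
        })
    df = pd.DataFrame(rows).sort_values(["p_value", "mark"]).reset_index(drop=True)
    return df


def compare_m_performance(results_m: list[SubsetResult],
                          results_m_plus_1: list[SubsetResult],
                          metric: str = "auc") -> float:
    """Paired two-sided Wilcoxon signed-rank on per-fold scores of the best
    subset at m vs at m+1 (exact null distribution for small fold counts)."""
    best_m = rank_results(results_m)[0]
    best_m1 = rank_results(results_m_plus_1)[0]
    scores_m = best_m.fold_aucs if metric == "auc" else best_m.fold_mccs
    scores_m1 = best_m1.fold_aucs if metric == "auc" else best_m1.fold_mccs
    folds = sorted(scores_m)
    if folds != sorted(scores_m1):
        raise ValueError("best subsets were scored on different outer folds")
    if len(folds) < 2:
        raise ValueError("need at least two paired folds")
    x = np.asarray([scores_m[f] for f in folds])
    z = np.asarray([scores_m1[f] for f in folds])
    d = z - x
    if np.all(d == 0):
        return 1.0
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.pvalue)


def results_to_tsv(path: str, results: list[SubsetResult]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#subset\tm\tmean_auc\tmean_mcc\tfold_aucs\tfold_mccs\n")
        for r in rank_results(results):
            fa = ",".join(f"{f}:{v:.6f}" for f, v in sorted(r.fold_aucs.items()))
            fm = ",".join(f"{f}:{v:.6f}" for f, v in sorted(r.fold_mccs.items()))
            fh.write(f"{'+'.join(r.subset)}\t{len(r.subset)}\t"
                     f"{r.mean_auc:.6f}\t{r.mean_mcc:.6f}\t{fa}\t{fm}\n")
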