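"""Logistic regression linking chromatin-mark log densities to eRNA status.

The model is  logit p_j = beta0 + sum_i beta_i x_ij  where x_ij is the log
average read density of mark i at enhancer j and p_j the probability the
enhancer produces eRNA. Fitting is penalized maximum likelihood by
Newton-Raphson on standardized features: a small L2 penalty (default 1e-6,
slopes only) guards against complete separation, and step-halving enforces a
non-decreasing penalized log-likelihood. Standardization parameters are
stored on the model so coefficients are comparable across marks; raw-scale
coefficients remain recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import SignalMatrix
from .labeling import ErnaLabelSet

_P_EPS = 1e-12


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, int, bool]:
    """Newton-Raphson fit on an already-standardized design (no intercept col).

    Returns (coef including leading intercept, final penalized log-likelihood,
    iterations, converged). Convergence: max |score| < tol.
    """
    n, m = X.shape
    Z = np.empty((n, m + 1))
    Z[:, 0] = 1.0
    Z[:, 1:] = X
    beta = np.zeros(m + 1)
    pen = np.zeros(m + 1)
    pen[1:] = lam

    def _pll(b: np.ndarray) -> float:
        eta = Z @ b
        # log(1 + e^eta) computed stably
        ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(pen @ (b * b))

    ll = _pll(beta)
    iters = 0
    converged = False
    while iters < max_iter:
        p = _sigmoid(Z @ beta)
        grad = Z.T @ (y - p) - pen * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = p * (1.0 - p) + _P_EPS
        H = (Z * w[:, None]).T @ Z
        H[np.diag_indices_from(H)] += pen
        step = np.linalg.solve(H, grad)
        iters += 1
        # step-halving: never let the penalized log-likelihood decrease
        t, improved = 1.0, False
        for _ in range(30):
            cand = beta + t * step
            ll_new = _pll(cand)
            if ll_new >= ll - 1e-12:
                beta, ll, improved = cand, ll_new, True
                break
            t *= 0.5
        if not improved:          # no ascent direction left; report state as-is
            break
    else:
        p = _sigmoid(Z @ beta)
        grad = Z.T @ (y - p) - pen * beta
        converged = bool(np.max(np.abs(grad)) < tol)
    return beta, ll, iters, converged


@dataclass
class LogitModel:
    """A fitted mark-subset logistic regression with its standardization."""

    marks: list[str]
    beta0: float                       # intercept, standardized scale
    beta: np.ndarray                   # slopes, standardized scale
    means: np.ndarray                  # per-mark standardization mean
    sds: np.ndarray                    # per-mark standardization sd (> 0)
    ridge_lambda: float = 1e-6
    converged: bool = True
    n_iter: int = 0
    loglik: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    @property
    def raw_beta(self) -> np.ndarray:
        """Slopes on the raw (unstandardized) log-density scale."""
        return self.beta / self.sds

    @property
    def raw_beta0(self) -> float:
        return float(self.beta0 - np.sum(self.beta * self.means / self.sds))

    def to_tsv(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(f"#ridge_lambda\t{self.ridge_lambda:g}\n")
            fh.write(f"#converged\t{int(self.converged)}\tn_iter\t{self.n_iter}"
                     f"\tloglik\t{self.loglik:.6f}\n")
            fh.write("#term\tbeta_std\tbeta_raw\tmean\tsd\n")
            fh.write(f"(intercept)\t{self.beta0:.10g}\t{self.raw_beta0:.10g}\t.\t.\n")
            for i, mname in enumerate(self.marks):
                fh.write(f"{mname}\t{self.beta[i]:.10g}\t{self.raw_beta[i]:.10g}\t"
                         f"{self.means[i]:.10g}\t{self.sds[i]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "LogitModel":
        lam, converged, n_iter, loglik = 1e-6, True, 0, float("nan")
        marks, beta, means, sds = [], [], [], []
        beta0 = 0.0
        with open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#ridge_lambda"):
                    lam = float(parts[1])
                elif line.startswith("#converged"):
                    converged, n_iter = bool(int(parts[1])), int(parts[3])
                    loglik = float(parts[5])
                elif line.startswith("#"):
                    continue
                elif parts[0] == "(intercept)":
                    beta0 = float(parts[1])
                else:
                    marks.append(parts[0])
                    beta.append(float(parts[1]))
                    means.append(float(parts[3]))
                    sds.append(float(parts[4]))
        return cls(marks, beta0, np.asarray(beta), np.asarray(means),
                   np.asarray(sds), lam, converged, n_iter, loglik)


def fit_logistic(
    signal: SignalMatrix,
    labels: ErnaLabelSet | pd.Series,
    marks: list[str] | None = None,
    ridge_lambda: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogitModel:
    """Fit the eRNA logistic regression on the labeled (unambiguous) enhancers.

    ``labels`` may be an :class:`ErnaLabelSet` (its unambiguous enhancers are
    used) or a 0/1 Series indexed by enhancer id. Requires both classes and
    finite features; constant features cannot be standardized and raise.
    """
    if isinstance(labels, ErnaLabelSet):
        y_ser = labels.binary()
    else:
        y_ser = labels.astype(int)
    ids = [i for i in y_ser.index if i in signal.marks.index]
    if len(ids) != len(y_ser):
        raise ValueError("labels refer to enhancers missing from the signal matrix")
    marks = list(marks) if marks is not None else list(signal.marks.columns)
    missing = [m for m in marks if m not in signal.marks.columns]
    if missing:
        raise ValueError(f"marks absent from signal matrix: {missing}")
    X = signal.marks.loc[ids, marks].to_numpy(dtype=float)
    y = y_ser.loc[ids].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds <= 0):
        bad = [marks[i] for i in np.where(sds <= 0)[0]]
        raise ValueError(f"constant feature(s), cannot standardize: {bad}")
    Xs = (X - means) / sds
    coef, ll, it, conv = newton_logistic(Xs, y, ridge_lambda, tol, max_iter)
    return LogitModel(marks, float(coef[0]), coef[1:], means, sds,
                      ridge_lambda, conv, it, ll,
                      diagnostics={"n_train": len(y), "n_pos": int(y.sum())})


def predict_proba(model: LogitModel, signal: SignalMatrix | pd.DataFrame) -> pd.Series:
    """Probability p_j that each enhancer is eRNA+, strictly inside (0, 1).

    Uses the standardization stored on the model; every model mark must be
    present in the input columns.
    """
    df = signal.marks if isinstance(signal, SignalMatrix) else signal
    missing = [m for m in model.marks if m not in df.columns]
    if missing:
        raise ValueError(f"marks absent from input: {missing}")
    X = df[model.marks].to_numpy(dtype=float)
    Xs = (X - model.means) / model.sds
    eta = model.beta0 + Xs @ model.beta
    p = np.clip(_sigmoid(eta), _P_EPS, 1.0 - _P_EPS)
    return pd.Series(p, index=df.index, name="p_erna")
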