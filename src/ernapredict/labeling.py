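"""eRNA+/- labeling from stranded GRO-seq log densities.

Because eRNAs are bidirectionally transcribed, an enhancer is called eRNA+
only when it falls in the high cluster on BOTH the sense and antisense
strands, eRNA- when it is low on both, and ambiguous otherwise (mixed-strand
enhancers are kept in the label set but excluded from supervised training).

The per-strand partition is an exact 1-D 2-means: because optimal clusters of
one-dimensional data are contiguous in sorted order, scanning the n-1 split
points of the sorted values and minimizing within-cluster sum of squares
yields the global optimum with no initialization randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import SignalMatrix

POSITIVE = "positive"
NEGATIVE = "negative"
AMBIGUOUS = "ambiguous"


class DegenerateInputError(ValueError):
    """All values identical: a 2-means partition is undefined."""


@dataclass
class ClusterResult:
    assignment: np.ndarray       # True where value belongs to the high cluster
    mean_low: float
    mean_high: float
    threshold: float             # midpoint between the boundary members


@dataclass
class ErnaLabelSet:
    """Per-enhancer eRNA label plus the per-strand clustering diagnostics."""

    labels: pd.Series                    # enhancer id -> label
    sense: ClusterResult
    antisense: ClusterResult

    @property
    def positive_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == POSITIVE])

    @property
    def negative_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == NEGATIVE])

    @property
    def ambiguous_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == AMBIGUOUS])

    @property
    def training_ids(self) -> list[str]:
        """Unambiguous enhancers, usable as supervised examples."""
        return list(self.labels.index[self.labels != AMBIGUOUS])

    def binary(self, ids: list[str] | None = None) -> pd.Series:
        """0/1 labels (eRNA+ = 1) over unambiguous enhancers."""
        ids = self.training_ids if ids is None else ids
        sub = self.labels.loc[ids]
        if (sub == AMBIGUOUS).any():
            raise ValueError("binary() requested for ambiguous enhancers")
        return (sub == POSITIVE).astype(int)

    def to_tsv(self, path: str, signal: SignalMatrix | None = None) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#enhancer_id\tlabel\ty_plus\ty_minus\tsense_call\tantisense_call\n")
            yp = signal.y_plus if signal is not None else None
            ym = signal.y_minus if signal is not None else None
            sense_high = pd.Series(self.sense.assignment, index=self.labels.index)
            anti_high = pd.Series(self.antisense.assignment, index=self.labels.index)
            for eid, lab in self.labels.items():
                vp = f"{yp.loc[eid]:.6f}" if yp is not None else "."
                vm = f"{ym.loc[eid]:.6f}" if ym is not None else "."
                fh.write(f"{eid}\t{lab}\t{vp}\t{vm}\t"
                         f"{'high' if sense_high.loc[eid] else 'low'}\t"
                         f"{'high' if anti_high.loc[eid] else 'low'}\n")


def kmeans_1d_two(values: np.ndarray) -> ClusterResult:
    """Exact 2-means of 1-D data by scanning all splits of the sorted values.

    Returns the assignment (True = high cluster, the one with the larger
    mean) and the threshold, defined as the midpoint between the largest low
    member and the smallest high member. Values exactly at the threshold sit
    in the low cluster (the split is below the smallest high member).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least two values")
    if np.ptp(values) == 0:
        raise DegenerateInputError("all values identical; 2-means undefined")
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)                      # low cluster = first k sorted values
    sum_lo, sum_hi = csum[k - 1], csum[-1] - csum[k - 1]
    sq_lo, sq_hi = csq[k - 1], csq[-1] - csq[k - 1]
    wss = (sq_lo - sum_lo**2 / k) + (sq_hi - sum_hi**2 / (n - k))
    best = int(np.argmin(wss)) + 1           # size of the low cluster
    assignment = np.zeros(n, dtype=bool)
    assignment[order[best:]] = True
    mean_low = float(csum[best - 1] / best)
    mean_high = float((csum[-1] - csum[best - 1]) / (n - best))
    threshold = float((x[best - 1] + x[best]) / 2.0)
    return ClusterResult(assignment, mean_low, mean_high, threshold)


def label_enhancers(signal: SignalMatrix) -> ErnaLabelSet:
    """Two independent per-strand clusterings combined into eRNA labels."""
    if signal.y_plus is None or signal.y_minus is None:
        raise ValueError("signal matrix lacks stranded GRO-seq columns")
    sense = kmeans_1d_two(signal.y_plus.to_numpy())
    antisense = kmeans_1d_two(signal.y_minus.to_numpy())
    both_high = sense.assignment & antisense.assignment
    both_low = ~sense.assignment & ~antisense.assignment
    labels = np.where(both_high, POSITIVE, np.where(both_low, NEGATIVE, AMBIGUOUS))
    return ErnaLabelSet(pd.Series(labels, index=signal.marks.index, name="label"),
                        sense, antisense)
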