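"""Measure sweeps, correlation matrices, and classifier-ranking agreement.

The sweep machinery evaluates every measure (CEN, MCEN, MCC*, ACC*, and
the IN/OUT entropies) over a parameter grid of a matrix family and feeds
Pearson correlation analyses.  The ranking utilities compare orderings of
classifiers produced by different measures: Hamming distance between
orderings, the degree-of-consistency indicator c (concordant-pair
fraction), and the "criterion of entropy" reference ranking (OUT entropy
ascending, ties broken by IN entropy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core_metrics import ConfusionMatrix, score

__all__ = [
    "MEASURES",
    "SweepTable",
    "RankingComparison",
    "sweep",
    "correlation_matrix",
    "rank_by_measure",
    "entropy_criterion_rank",
    "hamming_distance",
    "consistency_degree",
    "compare_rankings",
]

#: Canonical sweep columns, in reporting order.
MEASURES = ("CEN", "MCEN", "MCC*", "ACC*", "IN", "OUT")

_FIELD_BY_MEASURE = {
    "CEN": "cen",
    "MCEN": "mcen",
    "MCC*": "mcc_star",
    "ACC*": "acc_star",
    "IN": "entropy_in",
    "OUT": "entropy_out",
}


@dataclass(frozen=True)
class SweepTable:
    """Measure values over a parameter grid of one family."""

    param_name: str
    param_values: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self):
        n = len(self.param_values)
        for name, col in self.values.items():
            if len(col) != n:
                raise ValueError(f"column {name!r} has length {len(col)} != {n}")
            if not np.all(np.isfinite(col)):
                raise ValueError(f"column {name!r} contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values)
        df.insert(0, self.param_name, self.param_values)
        return df


def sweep(
    family: Callable[[float], ConfusionMatrix],
    grid: Sequence[float] | np.ndarray,
    measures: Sequence[str] = MEASURES,
    param_name: str = "A",
) -> SweepTable:
    """Evaluate measures for ``family(param)`` at every grid point."""
    unknown = set(measures) - set(_FIELD_BY_MEASURE)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    grid = np.asarray(grid, dtype=float)
    cols: dict[str, list[float]] = {m: [] for m in measures}
    for t in grid:
        rep = score(family(t))
        for m in measures:
            cols[m].append(getattr(rep, _FIELD_BY_MEASURE[m]))
    return SweepTable(
        param_name=param_name,
        param_values=grid,
        values={m: np.asarray(v) for m, v in cols.items()},
    )


def correlation_matrix(table: SweepTable) -> pd.DataFrame:
    """Pearson correlation matrix of the sweep's measure columns.

    Requires at least three grid points.  A constant column has no defined
    correlation and is reported as NaN against every other column.
    """
    if len(table.param_values) < 3:
        raise ValueError("need at least 3 grid points for a correlation")
    df = pd.DataFrame(table.values)
    return df.corr(method="pearson")  # pandas yields NaN for constant columns


# ---------------------------------------------------------------------------
# Ranking agreement
# ---------------------------------------------------------------------------

def rank_by_measure(
    values: Sequence[float], lower_is_better: bool = True
) -> tuple[int, ...]:
    """Ordering of item indices from best to worst.

    Stable: ties keep input order.  All four scaled measures (CEN, MCEN,
    ACC*, MCC*) are lower-is-better, the default polarity.
    """
    v = np.asarray(values, dtype=float)
    key = v if lower_is_better else -v
    return tuple(int(i) for i in np.argsort(key, kind="stable"))


def entropy_criterion_rank(matrices: Iterable[ConfusionMatrix]) -> tuple[int, ...]:
    """Reference ranking by the criterion of entropy.

    Classifiers are ordered by OUT entropy ascending; ties are broken by IN
    entropy ascending, then by input order.
    """
    reports = [score(m) for m in matrices]
    keys = [(r.entropy_out, r.entropy_in) for r in reports]
    return tuple(
        int(i) for i in sorted(range(len(keys)), key=lambda i: (keys[i], i))
    )


def hamming_distance(order1: Sequence[int], order2: Sequence[int]) -> int:
    """Number of positions at which two orderings hold different items."""
    o1, o2 = list(order1), list(order2)
    if sorted(o1) != sorted(o2):
        raise ValueError("orderings must be permutations of the same items")
    return int(sum(a != b for a, b in zip(o1, o2)))


def consistency_degree(
    scores1: Sequence[float], scores2: Sequence[float]
) -> float:
    """Degree of consistency c between two score lists, in [0, 1].

    c is the fraction of item pairs ordered the same way by both lists,
    among pairs untied in both (ties in either list are excluded).  It is
    invariant under strictly monotone transforms of either list.  Returns
    NaN when every pair is tied.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("score lists must be 1-D and of equal length")
    i, j = np.triu_indices(len(s1), k=1)
    d1 = s1[i] - s1[j]
    d2 = s2[i] - s2[j]
    untied = (d1 != 0) & (d2 != 0)
    n_untied = int(untied.sum())
    if n_untied == 0:
        return float("nan")
    concordant = int(((d1 * d2) > 0).sum())
    return concordant / n_untied


@dataclass(frozen=True)
class RankingComparison:
    """Agreement between the rankings induced by two measures."""

    names: tuple[str, ...]
    orderings: dict[str, tuple[int, ...]]
    hamming: dict[tuple[str, str], int]
    consistency_c: dict[tuple[str, str], float]

    def to_dict(self) -> dict:
        return {
            "classifiers": list(self.names),
            "orderings": {m: list(o) for m, o in self.orderings.items()},
            "hamming": {f"{a}|{b}": v for (a, b), v in self.hamming.items()},
            "consistency_c": {
                f"{a}|{b}": v for (a, b), v in self.consistency_c.items()
            },
        }


def compare_rankings(
    matrices: Sequence[ConfusionMatrix],
    names: Sequence[str] | None = None,
    measures: Sequence[str] = ("CEN", "MCEN", "ACC*", "MCC*"),
) -> RankingComparison:
    """Rank a set of classifiers by each measure and by the entropy criterion.

    Returns the per-measure orderings plus pairwise Hamming distances and
    degrees of consistency against the entropy-criterion reference.
    """
    matrices = list(matrices)
    if names is None:
        names = tuple(f"C{i + 1}" for i in range(len(matrices)))
    else:
        names = tuple(names)
    reports = [score(m) for m in matrices]
    score_lists = {
        m: [getattr(r, _FIELD_BY_MEASURE[m]) for r in reports] for m in measures
    }
    orderings = {m: rank_by_measure(v) for m, v in score_lists.items()}
    orderings["entropy"] = entropy_criterion_rank(matrices)
    # rank under the entropy criterion is a monotone score for computing c
    ent_rank = {item: pos for pos, item in enumerate(orderings["entropy"])}
    ent_score_list = [ent_rank[i] for i in range(len(matrices))]
    hamming = {}
    consistency = {}
    for m in measures:
        hamming[(m, "entropy")] = hamming_distance(orderings[m], orderings["entropy"])
        consistency[(m, "entropy")] = consistency_degree(
            score_lists[m], ent_score_list
        )
    for a_i, a in enumerate(measures):
        for b in measures[a_i + 1:]:
            hamming[(a, b)] = hamming_distance(orderings[a], orderings[b])
            consistency[(a, b)] = consistency_degree(score_lists[a], score_lists[b])
    return RankingComparison(
        names=names,
        orderings=orderings,
        hamming=hamming,
        consistency_c=consistency,
    )
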