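"""Entropy-based performance measures for confusion matrices.

Implements the Confusion Entropy (CEN) of Wang et al. and its modified
variant MCEN, together with the rescaled companions ACC* = 1 - Accuracy and
MCC* = (1 - MCC)/2 and the Shannon entropies generated inside (IN) and
outside (OUT) the main diagonal.

Conventions used throughout:

* rows index the true class, columns the predicted class;
* entries are non-negative reals (counts or scaled counts) — every measure
  here is invariant under multiplication of the whole matrix by a positive
  constant, so real-valued parametric families are first-class inputs;
* ``0 * log 0 = 0``;
* per-class CEN/MCEN entropies use logarithms in base ``2(N-1)`` (base 2
  when N = 2), while IN/OUT/overall entropies are plain base-2 Shannon
  entropies of the corresponding cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy

__all__ = [
    "ConfusionMatrixError",
    "NonSquareError",
    "NegativeEntryError",
    "ZeroMatrixError",
    "TooFewClassesError",
    "ConfusionMatrix",
    "ProbabilityTables",
    "MetricReport",
    "validate",
    "shannon_entropy",
    "entropy_in",
    "entropy_out",
    "entropy_overall",
    "probability_tables",
    "cen",
    "cen_class",
    "mcen",
    "mcen_class",
    "acc_star",
    "mcc",
    "mcc_star",
    "score",
]


class ConfusionMatrixError(ValueError):
    """Base class for invalid confusion-matrix input."""


class NonSquareError(ConfusionMatrixError):
    """Input is not a square two-dimensional table."""


class NegativeEntryError(ConfusionMatrixError):
    """Input contains a negative entry."""


class ZeroMatrixError(ConfusionMatrixError):
    """All entries are zero (no cases at all)."""


class TooFewClassesError(ConfusionMatrixError):
    """Fewer than two classes."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """A validated N x N confusion matrix (rows = true class).

    Use :func:`validate` to construct instances; it enforces the
    invariants (square, N >= 2, non-negative, at least one positive
    entry, distinct labels).
    """

    entries: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_classes(self) -> int:
        return self.entries.shape[0]

    @property
    def total(self) -> float:
        """S, the total number of (possibly scaled) cases."""
        return float(self.entries.sum())

    @property
    def binary_counts(self) -> tuple[float, float, float, float]:
        """(TP, FN, FP, TN) taking class 1 as reference; binary only."""
        if self.n_classes != 2:
            raise ConfusionMatrixError(
                "binary_counts is defined only for N = 2, got N = "
                f"{self.n_classes}"
            )
        c = self.entries
        return float(c[0, 0]), float(c[0, 1]), float(c[1, 0]), float(c[1, 1])

    def scaled(self, factor: float) -> "ConfusionMatrix":
        """Return the matrix with every entry multiplied by ``factor`` > 0."""
        if factor <= 0:
            raise ConfusionMatrixError("scale factor must be positive")
        return ConfusionMatrix(self.entries * factor, self.labels)


def validate(
    entries: Sequence[Sequence[float]] | np.ndarray,
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Validate raw input and build a :class:`ConfusionMatrix`.

    Parameters
    ----------
    entries
        Square array-like of non-negative reals; rows are true classes.
    labels
        Optional class identifiers; defaults to "1".."N".

    Raises
    ------
    NonSquareError, NegativeEntryError, ZeroMatrixError,
    TooFewClassesError, ConfusionMatrixError
    """
    try:
        arr = np.asarray(entries, dtype=float)
    except (TypeError, ValueError) as exc:
        raise NonSquareError(f"entries are not a numeric rectangular table: {exc}")
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise NonSquareError(f"expected a square matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ConfusionMatrixError("entries must be finite")
    if np.any(arr < 0):
        raise NegativeEntryError("confusion-matrix entries must be non-negative")
    n = arr.shape[0]
    if n < 2:
        raise TooFewClassesError(f"need at least 2 classes, got {n}")
    if arr.sum() == 0:
        raise ZeroMatrixError("all entries are zero")
    if labels is None:
        labels = tuple(str(i + 1) for i in range(n))
    else:
        labels = tuple(str(lab) for lab in labels)
        if len(labels) != n:
            raise ConfusionMatrixError(
                f"{len(labels)} labels for {n} classes"
            )
        if len(set(labels)) != n:
            raise ConfusionMatrixError("class labels must be distinct")
    arr = arr.copy()
    arr.flags.writeable = False
    return ConfusionMatrix(arr, labels)


def _as_matrix(C) -> ConfusionMatrix:
    if isinstance(C, ConfusionMatrix):
        return C
    return validate(C)


# ---------------------------------------------------------------------------
# Shannon entropies of matrix cells (base 2, unnormalized)
# ---------------------------------------------------------------------------

def shannon_entropy(values: Sequence[float] | np.ndarray) -> float:
    """Base-2 Shannon entropy of a set of non-negative numbers.

    The numbers are normalized to a probability vector; ``0 log 0 = 0``.
    Raises :class:`ZeroMatrixError` if all values are zero.
    """
    v = np.asarray(values, dtype=float).ravel()
    if np.any(v < 0):
        raise NegativeEntryError("entropy inputs must be non-negative")
    s = v.sum()
    if s == 0:
        raise ZeroMatrixError("entropy of an all-zero set is undefined")
    p = v / s
    return float(-xlogy(p, p).sum() / np.log(2.0)) + 0.0  # avoid -0.0


def entropy_in(C) -> float:
    """IN(C): base-2 entropy of the diagonal cells; 0 if the diagonal is all-zero."""
    c = _as_matrix(C)
    d = np.diag(c.entries)
    if d.sum() == 0:
        return 0.0
    return shannon_entropy(d)


def entropy_out(C) -> float:
    """OUT(C): base-2 entropy of the off-diagonal cells; 0 if they are all zero."""
    c = _as_matrix(C)
    off = c.entries[~np.eye(c.n_classes, dtype=bool)]
    if off.sum() == 0:
        return 0.0
    return shannon_entropy(off)


def entropy_overall(C) -> float:
    """Base-2 entropy of all N^2 cells of the matrix."""
    c = _as_matrix(C)
    return shannon_entropy(c.entries)


# ---------------------------------------------------------------------------
# Misclassification probabilities and weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityTables:
    """Misclassification probabilities and class weights for CEN and MCEN.

    ``p_subject_col[i, j]`` is the probability of classifying class-i cases
    as class j "subject to class j" (denominator: row sum + column sum of
    class j); ``p_subject_row[i, j]`` the analogue subject to class i.  The
    ``p_mod_*`` tables remove the double-counted diagonal term from the
    denominator.  Diagonal positions are 0 by convention, as are entries
    whose denominator vanishes (a class absent from both its row and its
    column).
    """

    p_subject_col: np.ndarray
    p_subject_row: np.ndarray
    p_mod_subject_col: np.ndarray
    p_mod_subject_row: np.ndarray
    weights_cen: np.ndarray
    weights_mcen: np.ndarray
    alpha: float


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def probability_tables(C) -> ProbabilityTables:
    """Compute all CEN/MCEN probabilities and weights for a matrix."""
    c = _as_matrix(C)
    a = c.entries
    n = c.n_classes
    s = c.total
    diag = np.diag(a)
    # D_j = sum_k (C_{j,k} + C_{k,j}) = row sum + column sum of class j
    d = a.sum(axis=1) + a.sum(axis=0)
    d_mod = d - diag  # diagonal counted once instead of twice

    off = ~np.eye(n, dtype=bool)
    p_col = _safe_div(a, d[np.newaxis, :]) * off
    p_row = _safe_div(a, d[:, np.newaxis]) * off
    pm_col = _safe_div(a, d_mod[np.newaxis, :]) * off
    pm_row = _safe_div(a, d_mod[:, np.newaxis]) * off

    alpha = 0.5 if n == 2 else 1.0
    w_cen = d / (2.0 * s)
    w_mcen = d_mod / (2.0 * s - alpha * diag.sum())
    return ProbabilityTables(p_col, p_row, pm_col, pm_row, w_cen, w_mcen, alpha)


# ---------------------------------------------------------------------------
# CEN and MCEN
# ---------------------------------------------------------------------------

def _class_entropies(p_col: np.ndarray, p_row: np.ndarray, n: int) -> np.ndarray:
    """Per-class confusion entropies in base 2(N-1) from probability tables.

    For class j the entropy sums, over k != j, the contributions of the
    entries of row j (subject to class j) and of column j (subject to
    class j).
    """
    log_base = np.log(2.0 * (n - 1))
    # row j of p_row has the class-j denominator; column j of p_col likewise.
    h_row = -xlogy(p_row, p_row).sum(axis=1)
    h_col = -xlogy(p_col, p_col).sum(axis=0)
    return (h_row + h_col) / log_base


def cen_class(C, j: int | None = None):
    """Per-class Confusion Entropy CEN_j (all classes, or one index)."""
    c = _as_matrix(C)
    t = probability_tables(c)
    vals = _class_entropies(t.p_subject_col, t.p_subject_row, c.n_classes)
    return vals if j is None else float(vals[j])


def mcen_class(C, j: int | None = None):
    """Per-class modified Confusion Entropy MCEN_j."""
    c = _as_matrix(C)
    t = probability_tables(c)
    vals = _class_entropies(t.p_mod_subject_col, t.p_mod_subject_row, c.n_classes)
    return vals if j is None else float(vals[j])


def cen(C) -> float:
    """Overall Confusion Entropy: convex combination of CEN_j with weights P_j.

    CEN lies in [0, 1] for N > 2 but may exceed 1 in the binary case —
    the pathology MCEN was designed to remove.
    """
    c = _as_matrix(C)
    t = probability_tables(c)
    vals = _class_entropies(t.p_subject_col, t.p_subject_row, c.n_classes)
    return float(t.weights_cen @ vals)


def mcen(C) -> float:
    """Modified Confusion Entropy; guaranteed in [0, 1] for every N >= 2."""
    c = _as_matrix(C)
    t = probability_tables(c)
    vals = _class_entropies(t.p_mod_subject_col, t.p_mod_subject_row, c.n_classes)
    return float(t.weights_mcen @ vals)


# ---------------------------------------------------------------------------
# Scaled accuracy and Matthews correlation
# ---------------------------------------------------------------------------

def acc_star(C) -> float:
    """ACC* = 1 - Accuracy = 1 - trace(C)/S, in [0, 1] (lower is better)."""
    c = _as_matrix(C)
    return float(1.0 - np.trace(c.entries) / c.total)


def mcc(C) -> float:
    """Matthews correlation coefficient, in [-1, 1].

    For N = 2 this is the classical (TP*TN - FP*FN) / sqrt(...) form; for
    N > 2 the generalized correlation between true and predicted labels
    computed directly from the confusion matrix (Gorodkin's R_K), which
    reduces to the binary formula at N = 2.  A vanishing denominator
    (e.g. an empty row or column making one marginal constant) yields 0.
    """
    c = _as_matrix(C)
    a = c.entries / c.total  # normalize first: keeps the value scale invariant
    n = c.n_classes
    t = a.sum(axis=1)  # true-class marginals
    p = a.sum(axis=0)  # predicted-class marginals
    # All covariance terms are written as sums/differences of non-negative
    # products so that no catastrophic cancellation occurs even under
    # extreme class imbalance (keeps scale invariance at the 1e-12 level):
    #   cov_xy = sum_k [ C_kk * R_k - o_k * q_k ]   (= trace * s - p.t)
    # with o_k / q_k the off-diagonal column/row sums and R_k the total
    # mass outside both row k and column k.
    off = ~np.eye(n, dtype=bool)
    a_off = a * off
    o = a_off.sum(axis=0)
    q = a_off.sum(axis=1)
    d = np.diag(a)
    keep = [np.arange(n) != k for k in range(n)]
    R = np.array([a[np.ix_(keep[k], keep[k])].sum() for k in range(n)])
    cov_xy = float(np.sum(d * R - o * q))
    # s^2 - sum_k p_k^2 as the pairwise sum over distinct marginal pairs
    cov_xx = float(np.outer(p, p)[off].sum())
    cov_yy = float(np.outer(t, t)[off].sum())
    denom = cov_xx * cov_yy
    if denom <= 0:
        return 0.0
    return float(np.clip(cov_xy / np.sqrt(denom), -1.0, 1.0))


def mcc_star(C) -> float:
    """MCC* = (1 - MCC)/2, rescaled to [0, 1] so that lower is better."""
    return float((1.0 - mcc(C)) / 2.0)


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricReport:
    """All measures of one confusion matrix in one deterministic bundle."""

    cen: float
    mcen: float
    acc_star: float
    mcc: float
    mcc_star: float
    entropy_in: float
    entropy_out: float
    entropy_overall: float
    cen_class: np.ndarray = field(repr=False)
    mcen_class: np.ndarray = field(repr=False)
    weights_cen: np.ndarray = field(repr=False)
    weights_mcen: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = field(repr=False)

    def to_dict(self) -> dict:
        """JSON-ready representation."""
        return {
            "cen": self.cen,
            "mcen": self.mcen,
            "acc_star": self.acc_star,
            "mcc": self.mcc,
            "mcc_star": self.mcc_star,
            "entropy_in": self.entropy_in,
            "entropy_out": self.entropy_out,
            "entropy_overall": self.entropy_overall,
            "per_class": {
                "labels": list(self.labels),
                "cen": self.cen_class.tolist(),
                "mcen": self.mcen_class.tolist(),
            },
            "weights": {
                "cen": self.weights_cen.tolist(),
                "mcen": self.weights_mcen.tolist(),
            },
        }


def score(C) -> MetricReport:
    """Score a confusion matrix with every measure in the library."""
    c = _as_matrix(C)
    t = probability_tables(c)
    n = c.n_classes
    cen_j = _class_entropies(t.p_subject_col, t.p_subject_row, n)
    mcen_j = _class_entropies(t.p_mod_subject_col, t.p_mod_subject_row, n)
    m = mcc(c)
    return MetricReport(
        cen=float(t.weights_cen @ cen_j),
        mcen=float(t.weights_mcen @ mcen_j),
        acc_star=acc_star(c),
        mcc=m,
        mcc_star=float((1.0 - m) / 2.0),
        entropy_in=entropy_in(c),
        entropy_out=entropy_out(c),
        entropy_overall=entropy_overall(c),
        cen_class=cen_j,
        mcen_class=mcen_j,
        weights_cen=t.weights_cen,
        weights_mcen=t.weights_mcen,
        labels=c.labels,
    )
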