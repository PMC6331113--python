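"""Generators for the parametric confusion-matrix families.

Every generator returns a validated :class:`~mcen.core_metrics.ConfusionMatrix`
with exactly the stated entries; the closed forms in
:mod:`mcen.closed_forms` evaluate the same families analytically.  Since all
measures are scale invariant, families defined at real-valued parameters
(e.g. U_{1/1000}) score identically to their scaled integer representatives.
"""

from __future__ import annotations

import numpy as np

from .core_metrics import ConfusionMatrix, validate

__all__ = [
    "make_symbal",
    "make_u",
    "make_v",
    "make_x",
    "make_y",
    "make_z",
    "make_m",
    "make_w",
    "make_xalpha",
    "make_ybeta",
    "default_grid",
    "MW_GRID",
    "INDEX_GRID",
    "table_matrices",
]

#: Integer parameter grid used for the M_A / W_A correlation sweeps.
MW_GRID = np.arange(1, 101)

#: Index grid for the minority-class improvement families (alpha, beta).
INDEX_GRID = np.arange(1, 102)


def _positive(name: str, value: float) -> float:
    value = float(value)
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return value


def make_symbal(n_classes: int, T: float, F: float) -> ConfusionMatrix:
    """Perfectly symmetric and balanced matrix: diagonal T, off-diagonal F > 0."""
    n = int(n_classes)
    if n < 2:
        raise ValueError("need N >= 2")
    if T < 0:
        raise ValueError("T must be >= 0")
    F = _positive("F", F)
    a = np.full((n, n), F, dtype=float)
    np.fill_diagonal(a, float(T))
    return validate(a)


def make_u(A: float) -> ConfusionMatrix:
    """U_A = (1, A; A, 0)."""
    A = _positive("A", A)
    return validate([[1.0, A], [A, 0.0]])


def make_v(A: float) -> ConfusionMatrix:
    """V_A = (1, A; 1, 0)."""
    A = _positive("A", A)
    return validate([[1.0, A], [1.0, 0.0]])


def make_x(A: float, r: float) -> ConfusionMatrix:
    """X_{A,r} = (A, rA; rA, 1)."""
    A = _positive("A", A)
    r = _positive("r", r)
    return validate([[A, r * A], [r * A, 1.0]])


def make_y(A: float, r: float) -> ConfusionMatrix:
    """Y_{A,r} = (rA, rA; A, 1)."""
    A = _positive("A", A)
    r = _positive("r", r)
    return validate([[r * A, r * A], [A, 1.0]])


def make_z(n_classes: int, A: float) -> ConfusionMatrix:
    """Z_A: all-ones N x N with the bottom-left entry (N, 1) set to A."""
    n = int(n_classes)
    if n < 2:
        raise ValueError("need N >= 2")
    A = _positive("A", A)
    a = np.ones((n, n), dtype=float)
    a[n - 1, 0] = A
    return validate(a)


def make_m(A: float) -> ConfusionMatrix:
    """M_A = (1, 50; A, 1): constant diagonal, used for the OUT-entropy sweep."""
    A = _positive("A", A)
    return validate([[1.0, 50.0], [A, 1.0]])


def make_w(A: float) -> ConfusionMatrix:
    """W_A = (50, 1; 1, A): constant off-diagonal, used for the IN-entropy sweep."""
    A = _positive("A", A)
    return validate([[50.0, 1.0], [1.0, A]])


def make_xalpha(alpha_idx: int) -> ConfusionMatrix:
    """Minority-class improvement family (50, 100; 101-alpha, alpha).

    alpha runs over 1..101; alpha = 1 is X_{50,2} (minority class classified
    very badly) and alpha = 101 gives perfect classification of class 2
    while the class imbalance stays fixed.
    """
    a = int(alpha_idx)
    if not 1 <= a <= 101:
        raise ValueError(f"alpha index must be in 1..101, got {a}")
    return validate([[50.0, 100.0], [101.0 - a, float(a)]])


def make_ybeta(beta_idx: int) -> ConfusionMatrix:
    """Minority-class improvement family (100, 100; 101-beta, beta), beta = 1..101."""
    b = int(beta_idx)
    if not 1 <= b <= 101:
        raise ValueError(f"beta index must be in 1..101, got {b}")
    return validate([[100.0, 100.0], [101.0 - b, float(b)]])


def default_grid(lo: float = 1e-3, hi: float = 1e3, n: int = 400) -> np.ndarray:
    """Log-spaced default parameter grid for the continuous families."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


# ---------------------------------------------------------------------------
# The matrices printed in the worked-example tables
# ---------------------------------------------------------------------------

def table_matrices(table_id: int) -> dict[str, ConfusionMatrix]:
    """Matrices of one printed example table, keyed by column heading.

    Tables 1 and 5 share the symmetric balanced S = 12 sequence; Table 2
    perturbs the constant matrix inside/outside the diagonal; Tables 6-8
    sample the U, V and Z families (scaled integer representatives for
    parameters below 1); Table 11 holds the two toy comparison pairs.
    """
    t = int(table_id)
    if t in (1, 5):
        cols = [(6, 0), (5, 1), (4, 2), (3, 3), (2, 4), (1, 5), (0, 6)]
        return {
            f"({T}{F}{F}{T})": make_symbal(2, T, F) if F else validate([[T, 0], [0, T]])
            for T, F in cols
        }
    if t == 2:
        mats = {
            "(3333)": [[3, 3], [3, 3]],
            "(2334)": [[2, 3], [3, 4]],
            "(1335)": [[1, 3], [3, 5]],
            "(0336)": [[0, 3], [3, 6]],
            "(3243)": [[3, 2], [4, 3]],
            "(3153)": [[3, 1], [5, 3]],
            "(3063)": [[3, 0], [6, 3]],
        }
        return {k: validate(v) for k, v in mats.items()}
    if t == 6:
        out = {}
        for exp in (3, 2, 1):  # A = 10^-exp, printed as the scaled (B,1;1,0)
            b = 10.0 ** exp
            out[f"A=1e-{exp}"] = validate([[b, 1.0], [1.0, 0.0]])
        for a in (1.0, 10.0, 100.0, 1000.0):
            out[f"A={a:g}"] = make_u(a)
        return out
    if t == 7:
        out = {}
        for exp in (3, 2, 1):  # V_{1/B} is equivalent to (B,1;B,0)
            b = 10.0 ** exp
            out[f"A=1e-{exp}"] = validate([[b, 1.0], [b, 0.0]])
        out["A=1"] = make_v(1.0)
        out["A=1.2"] = validate([[5.0, 6.0], [5.0, 0.0]])  # 5 * V_1.2
        for a in (10.0, 100.0, 1000.0):
            out[f"A={a:g}"] = make_v(a)
        return out
    if t == 8:
        out = {}
        for a, scale in [(0.1, 10.0), (0.5, 2.0), (1.0, 1.0), (2.0, 1.0), (10.0, 1.0)]:
            out[f"N=2,A={a:g}"] = make_z(2, a).scaled(scale) if scale != 1 else make_z(2, a)
        for a, scale in [(0.01, 100.0), (0.1, 10.0), (1.0, 1.0), (10.0, 1.0), (100.0, 1.0)]:
            out[f"N=4,A={a:g}"] = make_z(4, a).scaled(scale) if scale != 1 else make_z(4, a)
        return out
    if t == 11:
        mats = {
            "A": [[10, 0], [10, 10]],
            "B": [[0, 10], [10, 10]],
            "C": [[10, 0, 0], [10, 10, 0], [0, 0, 10]],
            "D": [[10, 0, 0], [0, 10, 10], [10, 0, 0]],
        }
        return {k: validate(v) for k, v in mats.items()}
    raise ValueError(f"no printed matrices for table {table_id}")
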