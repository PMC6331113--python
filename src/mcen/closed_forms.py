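"""Analytic expressions for the parametric confusion-matrix families.

Each family admits closed forms for CEN, MCEN, ACC* and MCC* as functions
of its parameters; those expressions serve as an independent oracle for the
general-purpose implementation in :mod:`mcen.core_metrics`, and the
numerical utilities here locate the extrema, unit crossings and limits
that characterize CEN's out-of-range behaviour in the binary case.

Families (all binary unless noted):

* ``symbal``  — diagonal T, off-diagonal F, any N; parametrized by
  gamma = T/F.
* ``binary_general`` — arbitrary (TP, FN, FP, TN).
* ``U_A = (1, A; A, 0)`` — symmetric, unbalanced.
* ``V_A = (1, A; 1, 0)`` — asymmetric, class 2 always misclassified.
* ``X_{A,r} = (A, rA; rA, 1)`` — symmetric, doubly indexed.
* ``Y_{A,r} = (rA, rA; A, 1)`` — asymmetric, same overall entropy as X.
* ``Z_A`` — all-ones N x N with entry (N, 1) = A.

The printed prose for some of these expressions loses fraction bars in
transcription; all forms below were re-derived from the general binary
closed forms and agree with the general implementation to machine
precision (the test suite checks this on dense parameter grids).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import xlogy

__all__ = [
    "FamilyParams",
    "ExtremaResult",
    "NoRootError",
    "symbal",
    "binary_general",
    "u_family",
    "v_family",
    "x_family",
    "y_family",
    "z_family",
    "x_limits",
    "y_limits",
    "find_extremum",
    "find_unit_crossings",
    "find_crossing",
    "limit_at_infinity",
    "family_measures",
]

MeasureName = Literal["cen", "mcen", "acc_star", "mcc_star"]

LOG2 = np.log(2.0)


class NoRootError(ValueError):
    """No sign change of the target function inside the bracket."""


@dataclass(frozen=True)
class FamilyParams:
    """Parameter bundle identifying one member of a matrix family."""

    family: str
    n_classes: int = 2
    T: float | None = None
    F: float | None = None
    gamma: float | None = None
    A: float | None = None
    r: float | None = None
    alpha_idx: int | None = None
    beta_idx: int | None = None


@dataclass(frozen=True)
class ExtremaResult:
    """A numerically located feature of a measure along a family."""

    location: float
    value: float
    kind: Literal["argmax", "argmin", "root", "crossing", "limit"]


def _xlog2(x: float) -> float:
    """x * log2(x) with the 0 log 0 = 0 convention."""
    return float(xlogy(x, x) / LOG2)


def _log2(x: float) -> float:
    return float(np.log(x) / LOG2)


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def symbal(n_classes: int, gamma: float) -> dict[str, float]:
    """Measures in the perfectly symmetric and balanced case.

    Diagonal T, off-diagonal F > 0, gamma = T/F >= 0.  With
    delta = 2(N-1) + 2*gamma and delta~ = 2(N-1) + gamma:

    * N > 2:  CEN = (2(N-1)/delta) log_{2(N-1)} delta, MCEN likewise with
      delta~ — hence the duality MCEN(2 gamma) = CEN(gamma);
    * N = 2:  CEN = log2(delta)/(1+gamma), MCEN = log2(delta~)/(1+3gamma/4);
    * ACC* = (N-1)/(gamma+N-1), MCC* = N/(2(gamma+N-1)).
    """
    n = int(n_classes)
    if n < 2:
        raise ValueError("need N >= 2")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    delta = 2.0 * (n - 1) + 2.0 * gamma
    delta_t = 2.0 * (n - 1) + gamma
    if n == 2:
        cen = _log2(delta) / (1.0 + gamma)
        mcen = _log2(delta_t) / (1.0 + 0.75 * gamma)
    else:
        base = np.log(2.0 * (n - 1))
        cen = (2.0 * (n - 1) / delta) * np.log(delta) / base
        mcen = (2.0 * (n - 1) / delta_t) * np.log(delta_t) / base
    return {
        "cen": float(cen),
        "mcen": float(mcen),
        "acc_star": (n - 1.0) / (gamma + n - 1.0),
        "mcc_star": n / (2.0 * (gamma + n - 1.0)),
    }


def binary_general(TP: float, FN: float, FP: float, TN: float) -> dict[str, float]:
    """Closed forms for an arbitrary binary matrix (TP, FN; FP, TN)."""
    if min(TP, FN, FP, TN) < 0:
        raise ValueError("counts must be non-negative")
    S = TP + FN + FP + TN
    if S <= 0:
        raise ValueError("S must be positive")
    mis = FN + FP
    cross = _xlog2(FN) + _xlog2(FP)  # FN log2 FN + FP log2 FP
    if mis == 0:
        cen_v = mcen_v = 0.0
    else:
        cen_v = mis * _log2(S * S - (TP - TN) ** 2) / (2.0 * S) - cross / S
        mcen_v = (
            2.0 * mis * _log2((S - TN) * (S - TP)) - 4.0 * cross
        ) / (3.0 * S + mis)
    denom = (TP + FN) * (FP + TN) * (TP + FP) * (TN + FN)
    m = 0.0 if denom <= 0 else (TP * TN - FP * FN) / np.sqrt(denom)
    return {
        "cen": float(cen_v),
        "mcen": float(mcen_v),
        "acc_star": float(mis / S),
        "mcc_star": float((1.0 - m) / 2.0),
    }


def u_family(A: float) -> dict[str, float]:
    """U_A = (1, A; A, 0): symmetric, unbalanced; CEN > 1 for every A > 1."""
    if A <= 0:
        raise ValueError("A must be positive")
    cen_v = (A * _log2((2 * A + 1) ** 2 - 1) - 2 * A * _log2(A)) / (2 * A + 1)
    mcen_v = (4 * A * _log2(2 * A * (2 * A + 1)) - 8 * A * _log2(A)) / (
        3 * (2 * A + 1) + 2 * A
    )
    return {
        "cen": float(cen_v),
        "mcen": float(mcen_v),
        "acc_star": 2 * A / (2 * A + 1),
        "mcc_star": (2 * A + 1) / (2 * (A + 1)),
    }


def v_family(A: float) -> dict[str, float]:
    """V_A = (1, A; 1, 0): asymmetric; CEN > 1 only on (1, ~1.414)."""
    if A <= 0:
        raise ValueError("A must be positive")
    cen_v = ((A + 1) * _log2((A + 2) ** 2 - 1) - 2 * A * _log2(A)) / (2 * (A + 2))
    mcen_v = (2 * (A + 1) * _log2((A + 1) * (A + 2)) - 4 * A * _log2(A)) / (
        3 * (A + 2) + (A + 1)
    )
    return {
        "cen": float(cen_v),
        "mcen": float(mcen_v),
        "acc_star": (A + 1) / (A + 2),
        "mcc_star": (1.0 + np.sqrt(A / (2.0 * (A + 1)))) / 2.0,
    }


def x_family(A: float, r: float) -> dict[str, float]:
    """X_{A,r} = (A, rA; rA, 1): symmetric, doubly indexed."""
    if A <= 0 or r <= 0:
        raise ValueError("A and r must be positive")
    S = (2 * r + 1) * A + 1
    cen_v = -(r * A / S) * _log2(r * r * A / (4 * (r + 1) * (r * A + 1)))
    mcen_v = -(4 * r * A / ((8 * r + 3) * A + 3)) * _log2(
        r * r * A / ((2 * r + 1) * (2 * r * A + 1))
    )
    return {
        "cen": float(cen_v),
        "mcen": float(mcen_v),
        "acc_star": 2 * r * A / S,
        "mcc_star": (2 * r * r * A + r * A + r) / (2 * (r + 1) * (r * A + 1)),
    }


def y_family(A: float, r: float) -> dict[str, float]:
    """Y_{A,r} = (rA, rA; A, 1): asymmetric, same overall entropy as X_{A,r}."""
    if A <= 0 or r <= 0:
        raise ValueError("A and r must be positive")
    S = (2 * r + 1) * A + 1
    num = (
        (r + 1) * A * _log2(((r + 1) * A + 2) * (3 * r + 1))
        + (r - 1) * A * _log2(A)
        - 2 * r * A * _log2(r * A)
    )
    cen_v = num / (2.0 * S)
    num_m = (
        (r + 1) * A * _log2(((r + 1) * A + 1) * (2 * r + 1))
        + (r - 1) * A * _log2(A)
        - 2 * r * A * _log2(r * A)
    )
    mcen_v = 2.0 * num_m / (3.0 * S + (r + 1) * A)
    m = r * (1 - A) / np.sqrt(2 * r * (A + 1) * (r + 1) * (r * A + 1))
    return {
        "cen": float(cen_v),
        "mcen": float(mcen_v),
        "acc_star": (r + 1) * A / S,
        "mcc_star": float((1.0 - m) / 2.0),
    }


def z_family(n_classes: int, A: float) -> dict[str, float]:
    """Z_A: all-ones N x N with entry (N, 1) = A."""
    n = int(n_classes)
    if n < 2:
        raise ValueError("need N >= 2")
    if A <= 0:
        raise ValueError("A must be positive")
    if n == 2:
        cen_v = ((A + 1) * _log2(A + 3) - A * _log2(A)) / (A + 3)
        mcen_v = 2.0 * ((A + 1) * _log2(A + 2) - A * _log2(A)) / (2 * A + 5)
    else:
        base = np.log(2.0 * (n - 1))

        def logb(x: float) -> float:
            return float(np.log(x) / base)

        common = (n - 1) * (n - 2)
        cen_v = (
            common * logb(2 * n)
            + (2 * n + A - 3) * logb(2 * n + A - 1)
            - A * logb(A)
        ) / (n * n + A - 1)
        mcen_v = (
            2.0
            / (2 * (n * n + A - 1) - n)
            * (
                common * logb(2 * n - 1)
                + (2 * n + A - 3) * logb(2 * n + A - 2)
                - A * logb(A)
            )
        )
    q = n * n + 2 * (A - 1)
    mcc_star_v = (n * q - (n * n + A - 1)) / (2 * (n - 1) * q)
    acc_star_v = (n * n - n + (A - 1)) / (n * n + A - 1)
    return {
        "cen": float(cen_v),
        "mcen": float(mcen_v),
        "acc_star": float(acc_star_v),
        "mcc_star": float(mcc_star_v),
    }


def family_measures(params: FamilyParams) -> dict[str, float]:
    """Evaluate the closed forms for any :class:`FamilyParams`."""
    f = params.family.lower()
    if f == "symbal":
        g = params.gamma if params.gamma is not None else params.T / params.F
        return symbal(params.n_classes, g)
    if f == "u":
        return u_family(params.A)
    if f == "v":
        return v_family(params.A)
    if f == "x":
        return x_family(params.A, params.r)
    if f == "y":
        return y_family(params.A, params.r)
    if f == "z":
        return z_family(params.n_classes, params.A)
    raise ValueError(f"no closed form for family {params.family!r}")


# ---------------------------------------------------------------------------
# Limits as A (or gamma) tends to infinity
# ---------------------------------------------------------------------------

def x_limits(r: float) -> dict[str, float]:
    """lim_{A -> inf} of each measure along X_{A,r}, as functions of r."""
    if r <= 0:
        raise ValueError("r must be positive")
    return {
        "cen": r / (2 * r + 1) * _log2(4 * (r + 1) / r),
        "mcen": 4 * r / (8 * r + 3) * _log2(2 * (2 * r + 1) / r),
        "acc_star": 2 * r / (2 * r + 1),
        "mcc_star": (2 * r + 1) / (2 * (r + 1)),
    }


def y_limits(r: float) -> dict[str, float]:
    """lim_{A -> inf} of each measure along Y_{A,r}, as functions of r."""
    if r <= 0:
        raise ValueError("r must be positive")
    # log2( ((3r+1)(r+1))^(r+1) / r^(2r) ) expanded to avoid overflow
    cen_l = (
        (r + 1) * _log2((3 * r + 1) * (r + 1)) - 2 * r * _log2(r)
    ) / (2 * (2 * r + 1))
    mcen_l = (
        2.0
        * ((r + 1) * _log2((2 * r + 1) * (r + 1)) - 2 * r * _log2(r))
        / (3 * (2 * r + 1) + (r + 1))
    )
    return {
        "cen": float(cen_l),
        "mcen": float(mcen_l),
        "acc_star": (r + 1) / (2 * r + 1),
        "mcc_star": 0.5 + 1.0 / (2.0 * np.sqrt(2.0 * (r + 1))),
    }


_LIMITS_AT_INF: dict[str, Callable[[FamilyParams], dict[str, float]]] = {
    "symbal": lambda p: {"cen": 0.0, "mcen": 0.0, "acc_star": 0.0, "mcc_star": 0.0},
    "u": lambda p: {"cen": 1.0, "mcen": 1.0, "acc_star": 1.0, "mcc_star": 1.0},
    "v": lambda p: {
        "cen": 0.0,
        "mcen": 0.0,
        "acc_star": 1.0,
        "mcc_star": (2.0 + np.sqrt(2.0)) / 4.0,
    },
    "x": lambda p: x_limits(p.r),
    "y": lambda p: y_limits(p.r),
    "z": lambda p: {
        "cen": 0.0,
        "mcen": 0.0,
        "acc_star": 1.0,
        "mcc_star": (2 * p.n_classes - 1) / (4.0 * (p.n_classes - 1)),
    },
}


def limit_at_infinity(measure: MeasureName, params: FamilyParams) -> float:
    """Limit of a measure as the family's scale parameter tends to infinity.

    Uses the printed limit expression where one exists; families without a
    printed expression would be evaluated numerically at large parameter,
    but every supported family has one.
    """
    f = params.family.lower()
    if f not in _LIMITS_AT_INF:
        raise ValueError(f"no limit known for family {params.family!r}")
    return float(_LIMITS_AT_INF[f](params)[measure])


# ---------------------------------------------------------------------------
# Numerical extrema / roots along a family
# ---------------------------------------------------------------------------

def _scalar_fn(
    family: str | Callable[[float], dict[str, float]],
    measure: MeasureName,
    **fixed,
) -> Callable[[float], float]:
    if callable(family):
        return lambda t: family(t)[measure]
    f = family.lower()
    if f == "symbal":
        n = int(fixed.get("n_classes", 2))
        return lambda g: symbal(n, g)[measure]
    if f == "u":
        return lambda a: u_family(a)[measure]
    if f == "v":
        return lambda a: v_family(a)[measure]
    if f == "x":
        r = float(fixed["r"])
        return lambda a: x_family(a, r)[measure]
    if f == "y":
        r = float(fixed["r"])
        return lambda a: y_family(a, r)[measure]
    if f == "z":
        n = int(fixed.get("n_classes", 2))
        return lambda a: z_family(n, a)[measure]
    raise ValueError(f"unknown family {family!r}")


def find_extremum(
    measure: MeasureName,
    family: str | Callable[[float], dict[str, float]],
    bracket: tuple[float, float],
    kind: Literal["argmax", "argmin"] = "argmax",
    xtol: float = 1e-10,
    **fixed,
) -> ExtremaResult:
    """Locate the extremum of one measure along a one-parameter family.

    Bounded scalar minimization (Brent) to ``|dparam| <= xtol``; returns the
    parameter value and the measure there.
    """
    fn = _scalar_fn(family, measure, **fixed)
    sign = -1.0 if kind == "argmax" else 1.0
    res = minimize_scalar(
        lambda t: sign * fn(t),
        bounds=bracket,
        method="bounded",
        options={"xatol": xtol},
    )
    return ExtremaResult(location=float(res.x), value=float(fn(res.x)), kind=kind)


def find_unit_crossings(
    measure: MeasureName,
    family: str | Callable[[float], dict[str, float]],
    bracket: tuple[float, float],
    target: float = 1.0,
    n_scan: int = 512,
    **fixed,
) -> list[ExtremaResult]:
    """All parameter values in the bracket where the measure equals ``target``.

    Scans a dense grid for sign changes of ``f - target`` and polishes each
    with Brent's method; points where the function touches the target at a
    grid node are included.  Raises :class:`NoRootError` if none is found.
    """
    fn = _scalar_fn(family, measure, **fixed)
    lo, hi = bracket
    ts = np.linspace(lo, hi, n_scan)
    vals = np.array([fn(t) - target for t in ts])
    roots: list[float] = []
    for i in range(len(ts) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(ts[i]))
        elif a * b < 0:
            roots.append(float(brentq(lambda t: fn(t) - target, ts[i], ts[i + 1],
                                      xtol=1e-12)))
    if vals[-1] == 0.0:
        roots.append(float(ts[-1]))
    # deduplicate near-identical roots from touching + crossing
    out: list[ExtremaResult] = []
    for r in roots:
        if not out or abs(r - out[-1].location) > 1e-9:
            out.append(ExtremaResult(location=r, value=float(fn(r)), kind="root"))
    if not out:
        raise NoRootError(
            f"{measure} - {target} has no sign change on {bracket}"
        )
    return out


def find_crossing(
    measure_a: MeasureName,
    measure_b: MeasureName,
    family: str | Callable[[float], dict[str, float]],
    bracket: tuple[float, float],
    **fixed,
) -> ExtremaResult:
    """Parameter value where two measures of the same family intersect."""
    fa = _scalar_fn(family, measure_a, **fixed)
    fb = _scalar_fn(family, measure_b, **fixed)
    lo, hi = bracket
    g = lambda t: fa(t) - fb(t)
    if g(lo) * g(hi) > 0:
        raise NoRootError(
            f"{measure_a} - {measure_b} does not change sign on {bracket}"
        )
    loc = float(brentq(g, lo, hi, xtol=1e-12))
    return ExtremaResult(location=loc, value=float(fa(loc)), kind="crossing")
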