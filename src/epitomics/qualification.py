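"""mAb qualification from capture-inhibition dose-response curves.

In the high-throughput single-binder capture inhibition assay (sbCIA), an
immobilized mAb binds a labelled tracer while dilutions of unlabelled plasma
compete it off. The Vmax (or RLU) response versus competitor dilution is fit
with the four-parameter logistic (4PL) Hill-slope model

    y = d + (a - d) / (1 + (x / c)**b)

on a log10 dilution axis. A mAb qualifies when the 4PL describes its
inhibition curve with R^2 strictly greater than 0.9, and qualifying mAbs are
assigned to the QP69 (total-plasma tracer) or QP300 (abundant-protein-depleted
tracer) library according to which tracer they qualified with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "InhibitionCurve",
    "FourPLFit",
    "four_pl",
    "fit_4pl",
    "qualify_mab",
    "assign_library",
    "vmax_from_trace",
]


@dataclass
class InhibitionCurve:
    mab_id: str
    tracer_kind: str  # "total_plasma" or "depleted_plasma"
    dilutions: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.dilutions = np.asarray(self.dilutions, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.dilutions.shape != self.responses.shape:
            raise ValueError("dilutions and responses must have equal length")
        if np.any(self.dilutions <= 0):
            raise ValueError("dilutions must be positive")
        if np.any(self.responses < 0):
            raise ValueError("responses must be non-negative")


@dataclass
class FourPLFit:
    a: float  # upper asymptote
    b: float  # Hill slope
    c: float  # inflection (EC50, units of x)
    d: float  # lower asymptote
    r2: float
    converged: bool = True
    log_linear_r2: float = float("nan")

    def predict(self, x) -> np.ndarray:
        return four_pl(np.asarray(x, dtype=float), self.a, self.b, self.c, self.d)


def four_pl(x, a, b, c, d):
    """Evaluate the 4PL Hill-slope model."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        # constant response: the model explains nothing beyond the mean
        return -math.inf if ss_res > 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_4pl(curve: InhibitionCurve) -> FourPLFit:
    """Least-squares 4PL fit on the log10(dilution) axis.

    Deterministic initialization: a = max(y), d = min(y), c = geometric mean
    of x, b = 1. The fit is canonicalized to a >= d (the 4PL is invariant
    under swapping asymptotes and negating the slope). Non-convergence is
    flagged with r2 = -inf so the fit fails the qualification gate.
    """
    x, y = curve.dilutions, curve.responses
    if np.unique(x).size < 4:
        raise ValueError(f"{curve.mab_id}: need >=4 distinct dilutions, got {np.unique(x).size}")
    lx = np.log10(x)
    lc0 = float(np.mean(lx))  # log10 of the geometric mean of x

    def model(theta, lx):
        a, b, lc, d = theta
        return d + (a - d) / (1.0 + 10.0 ** (b * (lx - lc)))

    theta0 = np.array([float(y.max()), 1.0, lc0, float(y.min())])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(lambda t: model(t, lx) - y, theta0, method="lm", max_nfev=10000)
        ok = sol.success and np.all(np.isfinite(sol.x))
    except Exception:
        ok = False
    if not ok:
        return FourPLFit(a=float("nan"), b=float("nan"), c=float("nan"), d=float("nan"),
                         r2=-math.inf, converged=False)
    a, b, lc, d = sol.x
    if a < d:  # canonicalize: a is the upper asymptote
        a, d, b = d, a, -b
    c = float(10.0 ** lc)
    r2 = _r2(y, four_pl(x, a, b, c, d))
    # secondary straight-line R^2 on the log axis, reported for transparency
    coef = np.polyfit(lx, y, 1)
    loglin_r2 = _r2(y, np.polyval(coef, lx))
    return FourPLFit(a=float(a), b=float(b), c=c, d=float(d), r2=r2, log_linear_r2=loglin_r2)


def qualify_mab(fit: FourPLFit, threshold: float = 0.9) -> bool:
    """Strict gate: qualified iff r2 > threshold."""
    return bool(fit.r2 > threshold)


def assign_library(qualifications) -> dict:
    """Assign qualified mAbs to libraries by the tracer they qualified with.

    ``qualifications`` is an iterable of (mab_id, tracer_kind, qualified).
    Total-plasma qualifiers go to QP69, depleted-plasma qualifiers to QP300;
    mAbs qualifying with both tracers land in both sets and are flagged.
    """
    qp69, qp300 = set(), set()
    for mab_id, tracer_kind, qualified in qualifications:
        if not qualified:
            continue
        if tracer_kind == "total_plasma":
            qp69.add(mab_id)
        elif tracer_kind == "depleted_plasma":
            qp300.add(mab_id)
        else:
            raise ValueError(f"unknown tracer kind {tracer_kind!r}")
    return {"QP69": qp69, "QP300": qp300, "dual": qp69 & qp300}


def vmax_from_trace(times, od) -> float:
    """Max slope of a synthetic kinetic read (helper for generated traces only)."""
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    slopes = np.diff(od) / np.diff(times)
    return float(np.max(slopes))
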