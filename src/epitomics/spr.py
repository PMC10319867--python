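"""Surface plasmon resonance: two-state binding kinetics and competition IC50.

The antibody-peptide interaction is modelled as a two-state (conformation
change) reaction,

    A + L  <-(ka1/kd1)->  AL  <-(ka2/kd2)->  AL*

with the chip response R = AL + AL* (resonance units, RU) and Rmax the
saturating surface capacity. The apparent affinity constant is

    K = (ka1/kd1) * (1 + ka2/kd2),      K_D = 1/K

For a piecewise-constant analyte concentration the mass-action ODEs

    d[AL]/dt  = ka1*C*(Rmax - AL - AL*) - kd1*AL - ka2*AL + kd2*AL*
    d[AL*]/dt = ka2*AL - kd2*AL*

are linear, so sensorgrams are computed exactly from the 2x2 matrix
exponential (eigendecomposition), with C = 0 during dissociation.

Competition assays (plasma or purified protein titrated against a fixed mAb
concentration) are read at the start of the dissociation phase; IC50 is the
inflection of a four-parameter sigmoid fitted on the log-competitor axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from epitomics.qualification import FourPLFit, fit_4pl, InhibitionCurve

__all__ = [
    "TwoStateParams",
    "Sensorgram",
    "CompetitionFit",
    "apparent_K",
    "simulate_two_state",
    "fit_two_state",
    "fit_ic50",
    "CONCENTRATION_SERIES_NM",
]

#: standard antibody dilution series used for kinetic titrations (nM)
CONCENTRATION_SERIES_NM = (666.0, 266.0, 133.0, 66.0, 27.0, 13.0)


@dataclass
class TwoStateParams:
    ka1: float   # 1/(M*s)
    kd1: float   # 1/s
    ka2: float   # 1/s
    kd2: float   # 1/s
    Rmax: float  # RU

    def __post_init__(self) -> None:
        for name in ("ka1", "kd1", "ka2", "kd2", "Rmax"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class Sensorgram:
    concentration: float        # analyte concentration, M
    times: np.ndarray           # s
    response: np.ndarray        # RU
    assoc_end: float            # time of association end / dissociation start
    trace_id: str = ""

    @property
    def phase(self) -> np.ndarray:
        return np.where(self.times <= self.assoc_end, "association", "dissociation")


def apparent_K(params: TwoStateParams) -> tuple[float, float]:
    """Apparent affinity K = (ka1/kd1)*(1 + ka2/kd2) [1/M] and K_D = 1/K [M]."""
    if params.kd1 == 0 or params.kd2 == 0:
        raise ValueError("kd1 and kd2 must be > 0 for the apparent affinity")
    K = (params.ka1 / params.kd1) * (1.0 + params.ka2 / params.kd2)
    return float(K), float(1.0 / K)


def _coeffs(p: TwoStateParams, C: float) -> tuple[np.ndarray, np.ndarray]:
    A = np.array(
        [[-(p.ka1 * C + p.kd1 + p.ka2), -p.ka1 * C + p.kd2],
         [p.ka2, -p.kd2]]
    )
    b = np.array([p.ka1 * C * p.Rmax, 0.0])
    return A, b


def _propagate(x0: np.ndarray, A: np.ndarray, b: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Exact solution of dx/dt = A x + b from x(0) = x0 at times ts (2x2)."""
    if np.allclose(b, 0.0):
        xp = np.zeros(2)
    else:
        xp = np.linalg.solve(A, -b)
    w, V = np.linalg.eig(A)
    try:
        c = np.linalg.solve(V, x0 - xp)
        out = xp[:, None] + V @ (np.exp(np.outer(w, ts)) * c[:, None])
        out = np.real(out)
    except np.linalg.LinAlgError:  # defective matrix: step with expm
        out = np.empty((2, ts.size))
        for k, t in enumerate(ts):
            out[:, k] = xp + expm(A * t) @ (x0 - xp)
    out[:, ts == 0.0] = x0[:, None]  # exact initial condition, no round-off
    return out


def simulate_two_state(
    params: TwoStateParams,
    concentration: float,
    t_assoc: float = 180.0,
    t_dissoc: float = 120.0,
    step: float = 1.0,
    trace_id: str = "",
) -> Sensorgram:
    """Noise-free two-state sensorgram: association then dissociation (C = 0)."""
    if concentration < 0:
        raise ValueError("analyte concentration must be >= 0")
    if t_assoc <= 0 or t_dissoc < 0 or step <= 0:
        raise ValueError("durations and step must be positive")
    t_a = np.arange(0.0, t_assoc + step / 2, step)
    A, b = _coeffs(params, concentration)
    xa = _propagate(np.zeros(2), A, b, t_a)
    t_d = np.arange(step, t_dissoc + step / 2, step)
    Ad, bd = _coeffs(params, 0.0)
    xd = _propagate(xa[:, -1], Ad, bd, t_d) if t_d.size else np.empty((2, 0))
    times = np.concatenate([t_a, t_a[-1] + t_d])
    resp = np.concatenate([xa.sum(axis=0), xd.sum(axis=0)])
    return Sensorgram(
        concentration=float(concentration),
        times=times,
        response=resp,
        assoc_end=float(t_a[-1]),
        trace_id=trace_id,
    )


def _residuals(theta: np.ndarray, grams: list[Sensorgram]) -> np.ndarray:
    p = TwoStateParams(*np.power(10.0, theta))
    res = []
    for g in grams:
        sim = simulate_two_state(
            p,
            g.concentration,
            t_assoc=g.assoc_end,
            t_dissoc=float(g.times[-1] - g.assoc_end),
            step=float(g.times[1] - g.times[0]),
        )
        res.append(np.interp(g.times, sim.times, sim.response) - g.response)
    return np.concatenate(res)


def fit_two_state(sensorgrams: list[Sensorgram]) -> tuple[TwoStateParams, float]:
    """Global least-squares two-state fit across a concentration series.

    Parameters are optimized in log10 space from a fixed multi-start grid
    (deterministic); the best-cost solution is kept. Returns the parameters
    and the derived K_D. Raises if no start converges.
    """
    grams = sorted(sensorgrams, key=lambda g: -g.concentration)
    if len(grams) < 3:
        raise ValueError("need sensorgrams at >=3 analyte concentrations")
    rmax0 = float(max(g.response.max() for g in grams)) * 1.2
    starts = [
        np.log10([ka1, 1e-2, ka2, 1e-2, rmax0])
        for ka1 in (1e4, 1e5, 1e6)
        for ka2 in (1e-3, 1e-2)
    ]
    best = None
    for theta0 in starts:
        try:
            sol = least_squares(
                _residuals, theta0, args=(grams,), method="trf",
                bounds=(np.full(5, -12.0), np.full(5, 12.0)), max_nfev=400,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("two-state fit failed to converge from every start")
    params = TwoStateParams(*np.power(10.0, best.x))
    _, kd = apparent_K(params)
    return params, kd


@dataclass
class CompetitionFit:
    levels: np.ndarray        # competitor level (% plasma or molar ratio)
    signals: np.ndarray       # RU at the start of dissociation
    ic50: float
    fit: FourPLFit
    extrapolated: bool = False
    flags: list = field(default_factory=list)


def fit_ic50(levels, signals) -> CompetitionFit:
    """Sigmoidal (4PL on log-x) competition fit; IC50 = back-transformed inflection.

    Zero competitor levels anchor the top plateau but cannot enter the log
    fit; at least four positive levels are required. Curves with no downward
    transition in range are flagged (``no_inhibition`` / ``extrapolated``).
    """
    levels = np.asarray(levels, dtype=float)
    signals = np.asarray(signals, dtype=float)
    pos = levels > 0
    if pos.sum() < 4:
        raise ValueError("need >=4 positive competitor levels for the sigmoid fit")
    curve = InhibitionCurve(
        mab_id="competition", tracer_kind="total_plasma",
        dilutions=levels[pos], responses=np.clip(signals[pos], 0.0, None),
    )
    fit = fit_4pl(curve)
    flags = []
    extrapolated = False
    if not fit.converged or not math.isfinite(fit.c):
        flags.append("fit_failed")
        extrapolated = True
    else:
        if fit.b <= 0:  # canonical a >= d: b > 0 means signal falls with competitor
            flags.append("no_inhibition")
            extrapolated = True
        if not (levels[pos].min() <= fit.c <= levels[pos].max()):
            flags.append("extrapolated")
            extrapolated = True
    return CompetitionFit(
        levels=levels, signals=signals, ic50=float(fit.c), fit=fit,
        extrapolated=extrapolated, flags=flags,
    )
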