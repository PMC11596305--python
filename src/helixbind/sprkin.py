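"""Simulation and global fitting of 1:1 Langmuir binding sensograms.

Association follows ``R(t) = Req (1 - exp(-(ka C + kd) t))`` with
``Req = Rmax C / (C + KD)``; dissociation decays exponentially with
``kd`` from the association end-point.  A multi-concentration series is
fit globally (shared ka, kd, Rmax) by derivative-free simplex search
from several log-spaced starts, and leave-one-out refits over the
concentration series provide mean/SD uncertainty for ka, kd and KD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import AlignmentError, DegenerateFitError, FitError, InsufficientDataError

__all__ = [
    "KineticParams",
    "Sensogram",
    "KineticFit",
    "simulate_sensogram",
    "double_reference",
    "fit_1to1",
    "loo_stats",
]


@dataclass(frozen=True)
class KineticParams:
    """1:1 binding parameters: ka (1/M/s), kd (1/s), Rmax (RU)."""

    ka: float
    kd: float
    rmax: float

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and Rmax must all be positive")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant ``kd / ka`` (M)."""
        return self.kd / self.ka


@dataclass(frozen=True)
class Sensogram:
    """Concentration-stamped response time series.

    Spans default to a 180 s injection followed by 600 s of dissociation.
    """

    concentration: float
    time: np.ndarray
    response: np.ndarray
    t_assoc: float = 180.0
    t_dissoc: float = 600.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("time and response must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)


@dataclass(frozen=True)
class KineticFit:
    """Global point estimate plus leave-one-out spread."""

    params: KineticParams
    loo_estimates: tuple[KineticParams, ...]
    ka_mean: float
    ka_sd: float
    kd_mean: float
    kd_sd: float
    KD_mean: float
    KD_sd: float
    sse: float


def model_response(
    params: KineticParams, concentration: float, time: np.ndarray, t_assoc: float
) -> np.ndarray:
    """Closed-form 1:1 response on an arbitrary time grid."""
    t = np.asarray(time, dtype=float)
    c = float(concentration)
    if c == 0.0:
        return np.zeros_like(t)
    req = params.rmax * c / (c + params.KD)
    kobs = params.ka * c + params.kd
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-params.kd * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, assoc, dissoc)


def simulate_sensogram(
    params: KineticParams,
    concentration: float,
    grid: np.ndarray | None = None,
    dt: float = 1.0,
    t_assoc: float = 180.0,
    t_dissoc: float = 600.0,
    noise_sd: float = 0.0,
    drift: float = 0.0,
    seed: int | None = None,
) -> Sensogram:
    """Simulate one sensogram, optionally with Gaussian noise and drift.

    ``noise_sd`` is additive white noise in RU; ``drift`` adds a linear
    baseline in RU/s.  ``grid`` overrides the default uniform grid.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if grid is None:
        grid = np.arange(0.0, t_assoc + t_dissoc + dt / 2.0, dt)
    t = np.asarray(grid, dtype=float)
    r = model_response(params, concentration, t, t_assoc)
    if drift:
        r = r + drift * t
    if noise_sd:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=t.shape)
    return Sensogram(
        concentration=concentration, time=t, response=r,
        t_assoc=t_assoc, t_dissoc=t_dissoc,
    )


def double_reference(
    sample: Sensogram, reference_surface: Sensogram, zero_concentration: Sensogram
) -> Sensogram:
    """Subtract reference-surface and zero-concentration responses.

    All three sensograms must share one time grid; the correction is
    linear, so common drift cancels exactly.
    """
    for other, name in (
        (reference_surface, "reference"),
        (zero_concentration, "zero-concentration"),
    ):
        if sample.time.shape != other.time.shape or not np.allclose(
            sample.time, other.time, rtol=0.0, atol=1e-9
        ):
            raise AlignmentError(f"{name} sensogram time grid does not match sample")
    corrected = sample.response - reference_surface.response - zero_concentration.response
    return Sensogram(
        concentration=sample.concentration,
        time=sample.time,
        response=corrected,
        t_assoc=sample.t_assoc,
        t_dissoc=sample.t_dissoc,
    )


def _sse(theta: np.ndarray, sensograms: Sequence[Sensogram]) -> float:
    ka, kd, rmax = np.exp(theta)
    params = KineticParams(ka=ka, kd=kd, rmax=rmax)
    total = 0.0
    for s in sensograms:
        resid = s.response - model_response(params, s.concentration, s.time, s.t_assoc)
        total += float(resid @ resid)
    return total


def _fit_once(
    sensograms: Sequence[Sensogram], theta0: np.ndarray
) -> tuple[np.ndarray, float]:
    res = minimize(
        _sse,
        theta0,
        args=(sensograms,),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 6000, "maxfev": 9000},
    )
    return res.x, float(res.fun)


def _global_fit(sensograms: Sequence[Sensogram], starts: Sequence[np.ndarray]) -> tuple[KineticParams, float]:
    best: tuple[np.ndarray, float] | None = None
    for theta0 in starts:
        theta, sse = _fit_once(sensograms, theta0)
        if best is None or sse < best[1]:
            best = (theta, sse)
    if best is None:
        raise FitError("no optimization start succeeded")
    # polish the winner once more
    theta, sse = _fit_once(sensograms, best[0])
    if sse > best[1]:
        theta, sse = best
    ka, kd, rmax = np.exp(theta)
    return KineticParams(ka=ka, kd=kd, rmax=rmax), sse


def _default_starts(rmax0: float) -> list[np.ndarray]:
    starts = []
    for ka0 in (1e4, 1e5, 1e6, 1e7):
        for kd0 in (1e-4, 1e-2):
            starts.append(np.log(np.array([ka0, kd0, rmax0])))
    return starts


def fit_1to1(sensograms: Sequence[Sensogram], loo: bool = True) -> KineticFit:
    """Global 1:1 fit sharing (ka, kd, Rmax) across a concentration series.

    Requires at least two nonzero concentrations spanning more than a
    two-fold range.  Leave-one-out refits (one concentration curve
    omitted at a time) supply mean and sample SD for ka, kd and KD.

    Raises
    ------
    InsufficientDataError
        On too few concentrations or too narrow a range.
    DegenerateFitError
        When the series carries no signal.
    """
    series = [s for s in sensograms if s.concentration > 0]
    if len(series) < 2:
        raise InsufficientDataError("need >= 2 nonzero concentrations")
    concs = sorted(s.concentration for s in series)
    if concs[-1] / concs[0] <= 2.0:
        raise InsufficientDataError("concentration range must span > 2-fold")
    peak = max(float(np.max(np.abs(s.response))) for s in series)
    if peak < 1e-9:
        raise DegenerateFitError("flat signal: nothing to fit")

    params, sse = _global_fit(series, _default_starts(peak))

    loo_estimates: list[KineticParams] = []
    if loo:
        warm = np.log(np.array([params.ka, params.kd, params.rmax]))
        for i in range(len(series)):
            subset = series[:i] + series[i + 1:]
            theta, _ = _fit_once(subset, warm)
            ka, kd, rmax = np.exp(theta)
            loo_estimates.append(KineticParams(ka=ka, kd=kd, rmax=rmax))

    if len(loo_estimates) >= 2:
        ka_mean, ka_sd = loo_stats([p.ka for p in loo_estimates])
        kd_mean, kd_sd = loo_stats([p.kd for p in loo_estimates])
        KD_mean, KD_sd = loo_stats([p.KD for p in loo_estimates])
    else:
        ka_mean, ka_sd = params.ka, 0.0
        kd_mean, kd_sd = params.kd, 0.0
        KD_mean, KD_sd = params.KD, 0.0

    return KineticFit(
        params=params,
        loo_estimates=tuple(loo_estimates),
        ka_mean=ka_mean, ka_sd=ka_sd,
        kd_mean=kd_mean, kd_sd=kd_sd,
        KD_mean=KD_mean, KD_sd=KD_sd,
        sse=sse,
    )


def fit_per_curve(sensograms: Sequence[Sensogram]) -> list[KineticParams]:
    """Independent 1:1 fit of each curve (diagnostic alternative mode)."""
    out = []
    for s in sensograms:
        if s.concentration <= 0:
            continue
        peak = float(np.max(np.abs(s.response)))
        if peak < 1e-9:
            raise DegenerateFitError("flat signal: nothing to fit")
        params, _ = _global_fit([s], _default_starts(peak))
        out.append(params)
    return out


def loo_stats(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) SD of >= 2 values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values")
    return float(vals.mean()), float(vals.std(ddof=1))
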