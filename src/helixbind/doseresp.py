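"""Four-parameter logistic dose-response fitting and potency estimation.

Responses are min-max normalized against positive/negative control
wells, fit with a 4PL curve by Nelder-Mead simplex from data-driven
starts (hill initialized at both signs), and potency (EC50 or IC50) is
summarized across replicates — plain mean/SD for equal replicate
designs, leave-one-out statistics when replicate sizes differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import (
    DataError,
    DegenerateControlsError,
    DegenerateFitError,
    FitError,
    InsufficientDataError,
)

__all__ = [
    "FourPLParams",
    "DoseResponseData",
    "PotencyEstimate",
    "fourpl_eval",
    "normalize_to_controls",
    "fit_fourpl",
    "estimate_potency",
]


@dataclass(frozen=True)
class FourPLParams:
    """4PL parameters: bottom, top (response units), ec50 (M), hill."""

    bottom: float
    top: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.top == self.bottom:
            raise ValueError("top must differ from bottom")


@dataclass(frozen=True)
class DoseResponseData:
    """Concentration-response series with control wells."""

    concentrations: np.ndarray
    responses: np.ndarray
    positive_controls: np.ndarray | None = None
    negative_controls: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise DataError("concentrations and responses must be 1-D and equal length")
        if np.any(c < 0):
            raise DataError("concentrations must be >= 0")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)
        for name in ("positive_controls", "negative_controls"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    def normalized(self) -> "DoseResponseData":
        """Copy with responses on the percent control scale."""
        if self.positive_controls is None or self.negative_controls is None:
            raise DataError("both control sets required for normalization")
        pct = normalize_to_controls(
            self.responses, self.positive_controls, self.negative_controls
        )
        return DoseResponseData(concentrations=self.concentrations, responses=pct)


@dataclass(frozen=True)
class PotencyEstimate:
    """EC50/IC50 replicate summary (mean within value range, SD >= 0)."""

    kind: str
    values: tuple[float, ...]
    mean: float
    sd: float
    method: str  # "replicates" | "leave-one-out"

    def __post_init__(self) -> None:
        if self.kind not in ("EC50", "IC50"):
            raise ValueError("kind must be 'EC50' or 'IC50'")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def fourpl_eval(params: FourPLParams, concentration: float) -> float:
    """Evaluate ``bottom + (top - bottom) / (1 + (ec50/c)^hill)``.

    The zero-concentration point takes the analytic limit: ``bottom``
    for positive hill, ``top`` for negative hill.
    """
    c = float(concentration)
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if c == 0.0:
        return params.bottom if params.hill > 0 else params.top
    ratio = (params.ec50 / c) ** params.hill
    return params.bottom + (params.top - params.bottom) / (1.0 + ratio)


def _fourpl_array(theta: np.ndarray, conc: np.ndarray) -> np.ndarray:
    bottom, top, log_ec50, hill = theta
    ec50 = np.exp(log_ec50)
    out = np.empty_like(conc)
    zero = conc == 0.0
    out[zero] = bottom if hill > 0 else top
    nz = ~zero
    # evaluate the power in clipped log space to avoid overflow at
    # extreme hill values visited by the simplex
    log_ratio = np.clip(hill * (log_ec50 - np.log(conc[nz])), -700.0, 700.0)
    out[nz] = bottom + (top - bottom) / (1.0 + np.exp(log_ratio))
    return out


def normalize_to_controls(
    responses: Sequence[float],
    positive_controls: Sequence[float],
    negative_controls: Sequence[float],
) -> np.ndarray:
    """Min-max normalization to percent of control: ``100 (x - neg) / (pos - neg)``."""
    r = np.asarray(responses, dtype=float)
    pos = np.asarray(positive_controls, dtype=float)
    neg = np.asarray(negative_controls, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both control sets must be non-empty")
    span = pos.mean() - neg.mean()
    if span == 0:
        raise DegenerateControlsError("positive and negative control means coincide")
    return 100.0 * (r - neg.mean()) / span


def fit_fourpl(data: DoseResponseData, seed: int = 0) -> FourPLParams:
    """Least-squares 4PL fit by Nelder-Mead with data-driven restarts.

    Starts use bottom = min(response), top = max(response), ec50 = the
    geometric mid of the nonzero concentrations and hill in {+1, -1};
    a few seeded jittered restarts guard against poor local minima.

    Raises
    ------
    InsufficientDataError
        With fewer than 4 distinct nonzero concentrations.
    DegenerateFitError
        For flat response data.
    """
    conc = data.concentrations
    resp = data.responses
    if len(set(conc[conc > 0])) < 4:
        raise InsufficientDataError("need >= 4 distinct nonzero concentrations")
    spread = float(resp.max() - resp.min())
    if spread <= 1e-12 * max(1.0, abs(float(resp.mean()))):
        raise DegenerateFitError("responses are constant; 4PL undefined")

    nz = conc[conc > 0]
    log_mid = float(np.mean(np.log(nz)))
    base = [
        np.array([resp.min(), resp.max(), log_mid, 1.0]),
        np.array([resp.min(), resp.max(), log_mid, -1.0]),
        np.array([resp.min(), resp.max(), log_mid, 2.0]),
        np.array([resp.min(), resp.max(), log_mid, -2.0]),
    ]
    rng = np.random.default_rng(seed)
    starts = list(base)
    for theta in base[:2]:
        jitter = rng.normal(0.0, [0.1 * spread, 0.1 * spread, 0.5, 0.3])
        starts.append(theta + jitter)

    def sse(theta: np.ndarray) -> float:
        resid = resp - _fourpl_array(theta, conc)
        return float(resid @ resid)

    best: tuple[np.ndarray, float] | None = None
    for theta0 in starts:
        res = minimize(
            sse, theta0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000, "maxfev": 8000},
        )
        if best is None or res.fun < best[1]:
            best = (res.x, float(res.fun))
    if best is None or not np.all(np.isfinite(best[0])):
        raise FitError("4PL optimization failed from every start")
    bottom, top, log_ec50, hill = best[0]
    if top == bottom:
        raise DegenerateFitError("fit collapsed to a flat curve")
    return FourPLParams(bottom=bottom, top=top, ec50=float(np.exp(log_ec50)), hill=hill)


def _potency_of(params: FourPLParams) -> float:
    return params.ec50


def estimate_potency(
    replicates: Sequence[DoseResponseData],
    kind: str = "IC50",
    normalize: bool = True,
    seed: int = 0,
) -> PotencyEstimate:
    """Per-replicate 4PL fits summarized across replicates.

    Each replicate is normalized against its own controls (when present
    and ``normalize`` is true) and fit separately.  Replicates of equal
    size are summarized by plain mean and sample SD of the fitted
    midpoints; unequal replicate sizes switch to leave-one-out fitting
    on the pooled data (one replicate omitted per refit).
    """
    if not replicates:
        raise InsufficientDataError("need at least one replicate")
    prepared: list[DoseResponseData] = []
    for rep in replicates:
        if normalize and rep.positive_controls is not None and rep.negative_controls is not None:
            prepared.append(rep.normalized())
        else:
            prepared.append(rep)

    fits: list[float] = []
    failures: list[str] = []
    for rep in prepared:
        try:
            fits.append(_potency_of(fit_fourpl(rep, seed=seed)))
        except (DegenerateFitError, InsufficientDataError, FitError) as exc:
            failures.append(str(exc))
    if not fits:
        raise FitError("all replicate fits failed: " + "; ".join(failures))

    sizes = {len(rep.concentrations) for rep in prepared}
    if len(prepared) >= 2 and len(sizes) > 1:
        # unequal designs: leave-one-replicate-out on pooled data
        values: list[float] = []
        for i in range(len(prepared)):
            rest = [r for j, r in enumerate(prepared) if j != i]
            pooled = DoseResponseData(
                concentrations=np.concatenate([r.concentrations for r in rest]),
                responses=np.concatenate([r.responses for r in rest]),
            )
            values.append(_potency_of(fit_fourpl(pooled, seed=seed)))
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1))
        return PotencyEstimate(
            kind=kind, values=tuple(values), mean=mean, sd=sd, method="leave-one-out"
        )

    mean = float(np.mean(fits))
    sd = 0.0 if len(fits) == 1 else float(np.std(fits, ddof=1))
    return PotencyEstimate(
        kind=kind, values=tuple(fits), mean=mean, sd=sd, method="replicates"
    )
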