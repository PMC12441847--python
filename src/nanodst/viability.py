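"""Resazurin relative viability and variable-slope (4PL) IC50 fitting.

Relative viability expresses metabolic activity as a percentage of the
untreated control:

    viability % = 100 * (A_exp - A_bg) / (A_ctrl - A_bg)

and the dose-response curve is the four-parameter logistic ("variable slope")
model

    v(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

fit by nonlinear least squares in linear parameter space, so that
zero-concentration wells enter through the upper asymptote instead of being
dropped by a log transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


def relative_viability(
    abs_experiment: float | np.ndarray,
    abs_control: float | np.ndarray,
    abs_background: float | np.ndarray,
) -> float | np.ndarray:
    """Percent viability relative to the untreated control.

    Not clipped: values above 100 or below 0 are legitimate readouts.
    """
    denom = np.asarray(abs_control, dtype=float) - np.asarray(abs_background, dtype=float)
    if np.any(denom == 0):
        raise ZeroDivisionError("control and background absorbances are equal")
    out = 100.0 * (np.asarray(abs_experiment, dtype=float) - abs_background) / denom
    return float(out) if np.isscalar(abs_experiment) else out


def four_pl(
    concentration: np.ndarray | float,
    bottom: float,
    top: float,
    ic50: float,
    hill: float,
) -> np.ndarray | float:
    """Four-parameter logistic curve, defined at c = 0 via its asymptote."""
    c = np.atleast_1d(np.asarray(concentration, dtype=float))
    out = np.empty_like(c)
    zero = c == 0
    with np.errstate(over="ignore"):
        ratio = np.power(c[~zero] / ic50, hill)
    out[~zero] = bottom + (top - bottom) / (1.0 + ratio)
    # c -> 0 limit: top when hill > 0, bottom when hill < 0, midpoint at hill = 0
    if hill > 0:
        out[zero] = top
    elif hill < 0:
        out[zero] = bottom
    else:
        out[zero] = (top + bottom) / 2.0
    return float(out[0]) if np.isscalar(concentration) else out


@dataclass
class DoseResponseData:
    """Per-well concentrations with either raw absorbances or viability."""

    concentration_uM: np.ndarray
    abs_experiment: np.ndarray | None = None
    abs_control: np.ndarray | None = None
    abs_background: np.ndarray | None = None
    viability_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration_uM = np.asarray(self.concentration_uM, dtype=float)
        if np.any(self.concentration_uM < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.viability_pct is None:
            if self.abs_experiment is None:
                raise ValueError("need either viability_pct or absorbances")
            self.viability_pct = relative_viability(
                np.asarray(self.abs_experiment, dtype=float),
                np.asarray(self.abs_control, dtype=float),
                np.asarray(self.abs_background, dtype=float),
            )
        self.viability_pct = np.asarray(self.viability_pct, dtype=float)
        if not np.all(np.isfinite(self.viability_pct)):
            raise ValueError("viabilities must be finite")


@dataclass(frozen=True)
class FourPLFit:
    bottom_pct: float
    top_pct: float
    ic50_uM: float
    hill_slope: float
    rss: float
    converged: bool
    message: str = ""

    def predict(self, concentration):
        return four_pl(
            concentration, self.bottom_pct, self.top_pct, self.ic50_uM, self.hill_slope
        )


def _initial_guess(conc: np.ndarray, viab: np.ndarray) -> tuple[float, float, float, float]:
    top0 = float(np.max(viab))
    bottom0 = float(np.min(viab))
    pos = conc > 0
    # sign of the trend over positive concentrations decides the hill sign
    order = np.argsort(conc[pos])
    v_sorted = viab[pos][order]
    decreasing = v_sorted[-1] <= v_sorted[0]
    hill0 = 1.0 if decreasing else -1.0
    half = (top0 + bottom0) / 2.0
    c_sorted = np.sort(conc[pos])
    v_at = viab[pos][order]
    crossings = np.nonzero(np.diff(np.sign(v_at - half)))[0]
    if crossings.size:
        i = crossings[0]
        ic50_0 = float(np.sqrt(c_sorted[i] * c_sorted[i + 1]))  # log-midpoint
    else:
        ic50_0 = float(np.exp(np.mean(np.log(c_sorted))))
    return bottom0, top0, ic50_0, hill0


def fit_ic50(data: DoseResponseData) -> FourPLFit:
    """Variable-slope 4PL fit; non-convergence is flagged, not raised.

    Bounds: bottom >= -10 %, top <= 150 %, IC50 > 0, hill free-sign.
    """
    conc = data.concentration_uM
    viab = data.viability_pct
    if np.unique(conc).size < 5:
        raise ValueError("need at least 5 distinct concentrations")

    bottom0, top0, ic50_0, hill0 = _initial_guess(conc, viab)
    x0 = np.array([max(bottom0, -10.0), min(top0, 150.0), np.log(ic50_0), hill0])

    def residuals(params):
        bottom, top, log_ic50, hill = params
        return four_pl(conc, bottom, top, np.exp(log_ic50), hill) - viab

    lower = np.array([-10.0, -np.inf, -np.inf, -np.inf])
    upper = np.array([np.inf, 150.0, np.inf, np.inf])
    try:
        res = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        ok = bool(res.success)
        message = res.message
        bottom, top, log_ic50, hill = res.x
        rss = float(np.sum(res.fun**2))
    except Exception as exc:  # pragma: no cover - defensive
        return FourPLFit(
            bottom_pct=float(x0[0]),
            top_pct=float(x0[1]),
            ic50_uM=float(np.exp(x0[2])),
            hill_slope=float(x0[3]),
            rss=float(np.inf),
            converged=False,
            message=str(exc),
        )
    return FourPLFit(
        bottom_pct=float(bottom),
        top_pct=float(top),
        ic50_uM=float(np.exp(log_ic50)),
        hill_slope=float(hill),
        rss=rss,
        converged=ok,
        message=message,
    )
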