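"""Power-law fits of normalized SNR against habitus parameters.

Per patient, the normalized SNR is averaged over all reconstructions and
regressed on a habitus parameter p (body mass, length, BMI, mass/length
or lean body mass) with the two-parameter power model

    SNRnorm,fit = a · p^(−d)

by unweighted nonlinear least squares on the natural scale, seeded from
the log–log ordinary regression.  R² is reported on the natural scale;
the 95 % interval for d is Wald/t at n−2 degrees of freedom.  Residuals
are expressed as the relative error (fit − observed)/fit · 100 %, whose
SD is the statistic used to compare habitus parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["PowerFit", "linear_r2", "power_fit", "relative_errors"]


@dataclass(frozen=True)
class PowerFit:
    """Result of fitting a·p^(−d)."""

    a: float
    d: float
    r2: float
    d_ci95: tuple[float, float]
    residual_pct: np.ndarray
    residual_sd_pct: float
    n: int

    def predict(self, p: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(p, dtype=float) ** (-self.d)


def linear_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of y on x (ordinary linear fit)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("x and y must both be non-constant")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def _loglog_seed(p: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(np.log(p), np.log(y), 1)
    return float(np.exp(intercept)), float(-slope)


def power_fit(p: np.ndarray, snr_norm: np.ndarray) -> PowerFit:
    """Nonlinear least squares of ``a·p^(−d)`` on (p, mean SNRnorm).

    Requires all parameter values and responses strictly positive and at
    least three points.  Raises on non-convergence, carrying the log–log
    seed estimates in the message.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(snr_norm, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 points to fit")
    if np.any(p <= 0) or np.any(y <= 0):
        raise ValueError("parameter values and responses must be > 0")
    a0, d0 = _loglog_seed(p, y)

    def model(x, a, d):
        return a * x ** (-d)

    try:
        popt, pcov = optimize.curve_fit(model, p, y, p0=(a0, d0), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RuntimeError(
            f"power fit failed to converge (log–log seed a={a0:.4g}, d={d0:.4g})"
        ) from exc
    a_hat, d_hat = (float(v) for v in popt)
    fitted = model(p, a_hat, d_hat)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_se = float(np.sqrt(pcov[1, 1]))
    tq = stats.t.ppf(0.975, max(p.size - 2, 1))
    residual_pct, residual_sd = relative_errors(y, fitted)
    return PowerFit(
        a=a_hat,
        d=d_hat,
        r2=r2,
        d_ci95=(d_hat - tq * d_se, d_hat + tq * d_se),
        residual_pct=residual_pct,
        residual_sd_pct=residual_sd,
        n=int(p.size),
    )


def relative_errors(
    observed: np.ndarray, fitted: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-point relative error (fit − observed)/fit · 100 % and its SD.

    Positive when the fit overshoots the observation.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if np.any(fitted == 0):
        raise ValueError("fitted values must be nonzero")
    pct = (fitted - observed) / fitted * 100.0
    sd = float(pct.std(ddof=1)) if pct.size > 1 else 0.0
    return pct, sd
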