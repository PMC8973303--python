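"""Percent-maximum normalisation and four-parameter logistic (4PL) fitting.

The dose-response model is the variable-slope sigmoid on log10
concentration:

    y = bottom + (top − bottom) / (1 + 10^((logEC50 − log10 c) · hill))

Raw per-well statistics are first converted to percent of maximum activity
within the dataset (0 at the observed minimum, 100 at the maximum), then the
four parameters are estimated by unweighted least squares with a
deterministic multi-start over the hill-slope sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponseFit", "four_param_logistic", "normalize_percent_max",
           "fit_4pl"]


def four_param_logistic(logc, bottom, top, logec50, hill):
    """4PL response at log10 concentration(s) ``logc``."""
    logc = np.asarray(logc, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - logc) * hill))


def normalize_percent_max(responses) -> np.ndarray:
    """Internal percent-maximum normalisation: 100·(y − min)/(max − min)."""
    y = np.asarray(responses, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 responses")
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        raise ValueError("responses are constant; percent-max undefined")
    return 100.0 * (y - lo) / (hi - lo)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters, their standard errors, and the residual SS."""

    bottom: float
    top: float
    logec50: float     # log10 μM (or the unit of the input concentrations)
    hill: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    n: int = 0
    concentration_unit: str = "uM"

    @property
    def ec50(self) -> float:
        return 10.0 ** self.logec50

    def predict(self, concentrations) -> np.ndarray:
        logc = np.log10(np.asarray(concentrations, dtype=float))
        return four_param_logistic(logc, self.bottom, self.top,
                                   self.logec50, self.hill)


def fit_4pl(concentrations, responses, concentration_unit: str = "uM"
            ) -> DoseResponseFit:
    """Unweighted least-squares 4PL fit on log10 concentration.

    Initialisation: top/bottom from the data extremes, logEC50 from the
    concentration whose mean response is nearest half-maximal, and a
    multi-start over hill ∈ {+1, −1}; the start with the lower residual sum
    of squares wins.  Raises on fewer than 4 distinct concentrations or if
    no start converges; warns when the concentrations span less than one
    decade (EC50 poorly identified) or the responses are flat.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    uniq = np.unique(c)
    if uniq.size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    span = np.log10(uniq.max() / uniq.min())
    if span < 1.0:
        warnings.warn("concentrations span less than one decade; "
                      "EC50 is poorly identified")
    logc = np.log10(c)

    y_lo, y_hi = float(y.min()), float(y.max())
    if y_hi - y_lo < 1e-12 * max(1.0, abs(y_hi)):
        warnings.warn("responses do not vary with concentration; "
                      "fit is non-identifiable")
    # log EC50 start: concentration with mean response nearest half-max
    half = 0.5 * (y_lo + y_hi)
    means = np.array([y[c == u].mean() for u in uniq])
    log_mid = float(np.log10(uniq[int(np.argmin(np.abs(means - half)))]))

    def resid(theta):
        return four_param_logistic(logc, *theta) - y

    best = None
    for hill0 in (1.0, -1.0):
        x0 = np.array([y_lo, y_hi, log_mid, hill0])
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=10000)
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("4PL fit failed to converge from either "
                           "hill-slope start; check the data for "
                           "monotone dose dependence")
    rss, sol = best
    bottom, top, logec50, hill = (float(v) for v in sol.x)

    n, p = y.size, 4
    se = {}
    if n > p:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (rss / (n - p))
            names = ("bottom", "top", "logec50", "hill")
            se = {k: float(np.sqrt(max(v, 0.0)))
                  for k, v in zip(names, np.diag(cov))}
        except np.linalg.LinAlgError:
            se = {}
    # canonical orientation: top >= bottom (equivalent curve, hill negated)
    if top < bottom:
        bottom, top, hill = top, bottom, -hill
        if se:
            se["bottom"], se["top"] = se["top"], se["bottom"]
    return DoseResponseFit(bottom=bottom, top=top, logec50=logec50, hill=hill,
                           se=se, rss=rss, n=int(n),
                           concentration_unit=concentration_unit)
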