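"""Hill fits to sugar-depletion curves and derived metabolic statistics.

Bulk glucose and galactose measurements from a diauxic culture decay
sigmoidally as the population grows into the supply.  Each depletion curve
is summarised by a decreasing Hill function of time,

    s(t) = floor + (s0 - floor) * k_half^n / (k_half^n + t^n),

whose half-max time ``k_half`` anchors the comparisons used downstream: the
fractional shift in galactose half-depletion between conditions, the
metabolic delay between glucose and galactose (sequential consumption), and
the expected galactose consumption of the activated subpopulation were it
consuming at the rate of a galactose-only culture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "NonDecayingError",
    "fit_hill_decay",
    "halfmax_shift",
    "metabolic_delay",
    "od_growth_rate",
    "expected_consumption",
]


class NonDecayingError(ValueError):
    """Raised when a sugar series shows no substantial decline to fit."""


@dataclass
class HillFit:
    """Decreasing Hill fit of a sugar time series (% w/v, hours)."""

    s0: float
    k_half: float
    n_hill: float
    floor: float
    rss: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.floor + (self.s0 - self.floor) * self.k_half**self.n_hill / (
            self.k_half**self.n_hill + np.maximum(t, 0.0) ** self.n_hill
        )

    def rate(self, t):
        """Consumption rate -ds/dt (% w/v per hour), analytic."""
        t = np.maximum(np.asarray(t, dtype=float), 1e-12)
        kn = self.k_half**self.n_hill
        tn = t**self.n_hill
        return (
            (self.s0 - self.floor)
            * kn
            * self.n_hill
            * tn
            / (t * (kn + tn) ** 2)
        )


def _hill_decay(t, s0, k_half, n_hill, floor):
    kn = k_half**n_hill
    return floor + (s0 - floor) * kn / (kn + np.maximum(t, 0.0) ** n_hill)


def fit_hill_decay(
    t: np.ndarray,
    concentration: np.ndarray,
    fit_floor: bool = False,
    min_decline: float = 0.2,
) -> HillFit:
    """Nonlinear least-squares fit of a decreasing Hill function.

    Initialised at k_half = time of the sample nearest half of the initial
    level, n = 4, floor = observed minimum.  By default the floor is pinned
    at zero (residual sugar below the assay floor); pass ``fit_floor=True``
    to free it within [0, min(concentration)].
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(concentration, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points to fit a Hill decay")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite concentrations")
    ymax, ymin = float(y.max()), float(y.min())
    if ymax <= 0 or (ymax - ymin) < min_decline * ymax:
        raise NonDecayingError(
            f"series declines by less than {min_decline:.0%} of its maximum"
        )
    s0_init = ymax
    k_init = float(t[np.argmin(np.abs(y - 0.5 * s0_init))])
    k_init = max(k_init, float(np.min(t[t > 0], initial=1.0)))
    tmax = float(t.max())

    last_err: Optional[Exception] = None
    for k_try, n_try in ((k_init, 4.0), (0.5 * tmax, 2.0), (0.25 * tmax, 6.0)):
        try:
            if fit_floor:
                p0 = [s0_init, k_try, n_try, ymin]
                lo = [0.0, 1e-6, 1e-2, 0.0]
                hi = [2.0 * ymax, 10.0 * tmax, 50.0, max(ymin, 1e-12)]
                popt, _ = curve_fit(
                    _hill_decay, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
                )
                s0, k_half, n_hill, floor = popt
            else:
                p0 = [s0_init, k_try, n_try]
                lo = [0.0, 1e-6, 1e-2]
                hi = [2.0 * ymax, 10.0 * tmax, 50.0]
                popt, _ = curve_fit(
                    lambda tt, s0, k, n: _hill_decay(tt, s0, k, n, 0.0),
                    t,
                    y,
                    p0=p0,
                    bounds=(lo, hi),
                    maxfev=20000,
                )
                s0, k_half, n_hill = popt
                floor = 0.0
            resid = y - _hill_decay(t, s0, k_half, n_hill, floor)
            return HillFit(
                s0=float(s0),
                k_half=float(k_half),
                n_hill=float(n_hill),
                floor=float(floor),
                rss=float(np.sum(resid**2)),
            )
        except RuntimeError as err:  # non-convergence; retry from another start
            last_err = err
    raise RuntimeError(f"Hill fit failed to converge after restarts: {last_err}")


def halfmax_shift(fit: HillFit, reference: HillFit) -> float:
    """Fractional change in half-depletion time relative to a reference fit."""
    if reference.k_half == 0:
        raise ZeroDivisionError("reference half-max time is zero")
    return (fit.k_half - reference.k_half) / reference.k_half


def metabolic_delay(glu_fit: HillFit, gal_fit: HillFit) -> float:
    """Hours between glucose and galactose half-depletion (sequential use)."""
    return gal_fit.k_half - glu_fit.k_half


def od_growth_rate(
    t: np.ndarray,
    od600: np.ndarray,
    smooth_window: Optional[int] = 5,
):
    """Instantaneous population growth rate from an OD600 series (1/h).

    rate_i = (ln OD_{i+1} - ln OD_i) / (t_{i+1} - t_i), reported at interval
    midpoints; a centered moving average of odd width ``smooth_window`` is
    applied when requested (None disables smoothing).  Exact on noiseless
    exponentials: the log-difference quotient of e^{mu t} is mu on any grid.
    """
    t = np.asarray(t, dtype=float)
    od = np.asarray(od600, dtype=float)
    if np.any(od <= 0):
        raise ValueError("OD600 must be positive")
    if t.size < 2:
        raise ValueError("need at least 2 points")
    rate = np.diff(np.log(od)) / np.diff(t)
    t_mid = 0.5 * (t[:-1] + t[1:])
    if smooth_window is not None and smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        w = np.ones(smooth_window)
        # edge-aware normalization keeps the average exact on constants
        rate = np.convolve(rate, w, mode="same") / np.convolve(
            np.ones_like(rate), w, mode="same"
        )
    return t_mid, rate


def expected_consumption(
    t: np.ndarray,
    f_on: np.ndarray,
    reference_fit: HillFit,
    reference_density: tuple,
    density: tuple,
):
    """Expected galactose consumption if ON cells consumed at the reference rate.

    The per-density reference rate is the analytic decay rate of the
    galactose-only culture's Hill fit divided by that culture's density; the
    expected rate in the mixed-sugar culture is that rate times its own
    density times the ON fraction.  Series on other time grids are resampled
    by linear interpolation.  Returns (expected rate, cumulative consumption)
    on the ``t`` grid (% w/v per h, % w/v).
    """
    t = np.asarray(t, dtype=float)
    f = np.clip(np.asarray(f_on, dtype=float), 0.0, 1.0)
    if t.shape != f.shape:
        raise ValueError("t and f_on must share a grid")
    t_ref, n_ref = (np.asarray(a, dtype=float) for a in reference_density)
    t_own, n_own = (np.asarray(a, dtype=float) for a in density)
    n_ref_i = np.interp(t, t_ref, n_ref)
    n_own_i = np.interp(t, t_own, n_own)
    if np.any(n_ref_i <= 0):
        raise ValueError("reference density must be positive")
    per_density_rate = reference_fit.rate(t) / n_ref_i
    rate = f * per_density_rate * n_own_i
    cumulative = np.concatenate([[0.0], cumulative_trapezoid(rate, t)])
    return rate, cumulative
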