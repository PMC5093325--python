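"""Linear growth-law kinetics of filament elongation.

The model: a preformed filament elongates by monomer addition at rate
``k_on * c`` (μm/min, with ``c`` the local free-monomer concentration in mM)
and shortens by subunit loss at rate ``k_off`` (μm/min), so the net growth
rate is the linear law

    R(c) = k_on * c - k_off,

which crosses zero at the critical concentration ``c_s = k_off / k_on``:
above ``c_s`` the filament grows, below it it shrinks. The model describes
the maturation (elongation) of preformed structures only; nucleation is a
separate process and is deliberately out of scope.

This module provides the law itself, least-squares estimation of
``(k_on, k_off)`` from (concentration, rate) data, per-terminus rate
estimation from position time series, and a statistical classification of a
filament's growth as unidirectional (one active terminus) or bidirectional
(both active).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigError,
    DegenerateDesignError,
    UndefinedCriticalConcentrationError,
)

__all__ = [
    "KineticParameters",
    "FF_KINETICS",
    "CYCLOFF_KINETICS",
    "RateFit",
    "EndRateEstimate",
    "DirectionalityCall",
    "net_growth_rate",
    "critical_concentration",
    "fit_growth_law",
    "estimate_terminus_rate",
    "classify_directionality",
]


@dataclass(frozen=True)
class KineticParameters:
    """The pair (k_on, k_off) defining the linear growth law.

    Parameters
    ----------
    k_on
        Elongation rate constant, μm·min⁻¹·mM⁻¹.
    k_off
        Dissociation rate, μm·min⁻¹.

    Notes
    -----
    Physical rates are non-negative, and the simulator enforces that on its
    own configuration; here negative values are tolerated so that noisy
    least-squares *estimates* of the parameters remain representable.
    Non-finite values are rejected.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_on) and math.isfinite(self.k_off)):
            raise ConfigError(
                f"rates must be finite, got k_on={self.k_on!r} k_off={self.k_off!r}"
            )

    @property
    def critical_concentration(self) -> float:
        """c_s = k_off / k_on (mM); requires k_on > 0."""
        return critical_concentration(self)


#: Fitted growth-law parameters for FF nanotubes in water.
FF_KINETICS = KineticParameters(k_on=3.36, k_off=7.4)
#: Fitted growth-law parameters for cycloFF needles in DMSO.
CYCLOFF_KINETICS = KineticParameters(k_on=0.15, k_off=1.2)


def net_growth_rate(c: float, p: KineticParameters) -> float:
    """Net elongation rate R = k_on·c − k_off (μm/min) at concentration ``c`` (mM).

    Negative values mean net shortening.
    """
    if c < 0:
        raise ConfigError(f"concentration must be >= 0, got {c!r}")
    return p.k_on * c - p.k_off


def critical_concentration(p: KineticParameters) -> float:
    """Critical concentration c_s = k_off/k_on (mM), the zero of the growth law."""
    if not p.k_on > 0:
        raise UndefinedCriticalConcentrationError(
            f"critical concentration undefined for k_on={p.k_on!r}"
        )
    return p.k_off / p.k_on


@dataclass(frozen=True)
class RateFit:
    """Estimated growth-law parameters from a (concentration, rate) regression.

    ``cov_on_off`` is the sampling covariance between the k_on and k_off
    estimates (note k_off is the negated intercept, so this is minus the
    slope–intercept covariance). ``df_resid`` is the residual degrees of
    freedom of the fit; ``None`` means "treat the errors as exact" and makes
    confidence intervals use normal rather than Student-t quantiles.
    """

    params: KineticParameters
    se_k_on: float
    se_k_off: float
    r_squared: float
    n_points: int
    cov_on_off: float = 0.0
    df_resid: int | None = None

    def conf_int(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Marginal confidence intervals for k_on and k_off."""
        q = _quantile(level, self.df_resid)
        return {
            "k_on": (
                self.params.k_on - q * self.se_k_on,
                self.params.k_on + q * self.se_k_on,
            ),
            "k_off": (
                self.params.k_off - q * self.se_k_off,
                self.params.k_off + q * self.se_k_off,
            ),
        }


def _quantile(level: float, df_resid: int | None) -> float:
    alpha = 1.0 - level
    if df_resid is not None and df_resid > 0:
        return float(stats.t.ppf(1 - alpha / 2, df_resid))
    return float(stats.norm.ppf(1 - alpha / 2))


def fit_growth_law(
    concentrations: Sequence[float],
    rates: Sequence[float],
    weights: Sequence[float] | None = None,
) -> RateFit:
    """Fit R = k_on·c − k_off by (weighted) ordinary least squares.

    Parameters
    ----------
    concentrations, rates
        Paired observations of free-monomer concentration (mM) and net
        growth rate (μm/min); at least two distinct concentrations.
    weights
        Optional inverse-variance weights (non-negative). ``None`` gives an
        unweighted fit.

    Returns
    -------
    RateFit
        Slope → k_on, negated intercept → k_off, with conventional OLS/WLS
        standard errors and (weighted) R².
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(rates, dtype=float)
    if c.ndim != 1 or c.shape != r.shape:
        raise ConfigError("concentrations and rates must be equal-length 1-d")
    if np.unique(c).size < 2:
        raise DegenerateDesignError(
            "growth-law fit needs >= 2 distinct concentrations"
        )
    X = sm.add_constant(c)
    # errstate: a two-point exact fit has zero residual dof; statsmodels'
    # scale then divides by zero and we map the resulting nan SEs to 0 below
    with np.errstate(divide="ignore", invalid="ignore"):
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            if w.shape != c.shape:
                raise ConfigError("weights must match the number of points")
            if np.any(w < 0):
                raise ConfigError("weights must be non-negative")
            res = sm.WLS(r, X, weights=w).fit()
        else:
            res = sm.OLS(r, X).fit()

        intercept, slope = res.params
        se_int, se_slope = res.bse
        cov = res.cov_params()
        r2 = float(res.rsquared)
    # k_off = -intercept, so cov(k_on, k_off) = -cov(slope, intercept)
    cov_on_off = -float(np.asarray(cov)[1, 0])
    if not math.isfinite(se_slope):  # exact-fit / zero-dof edge
        se_slope, se_int, cov_on_off = 0.0, 0.0, 0.0
    if not math.isfinite(r2):
        # all responses identical: a flat line fits exactly
        r2 = 1.0 if res.ssr < 1e-12 else 0.0
    return RateFit(
        params=KineticParameters(k_on=float(slope), k_off=float(-intercept)),
        se_k_on=float(se_slope),
        se_k_off=float(se_int),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(c.size),
        cov_on_off=cov_on_off,
        df_resid=int(res.df_resid),
    )


@dataclass(frozen=True)
class EndRateEstimate:
    """Estimated outward growth rate of one terminus.

    ``rate`` follows the outward-positive convention: positive means the
    terminus moves away from the filament midpoint (growth), for either end.
    """

    rate: float
    se: float
    n_frames: int


def estimate_terminus_rate(
    times: Sequence[float],
    positions: Sequence[float],
    orientation: int = 1,
) -> EndRateEstimate:
    """Estimate a terminus rate as the OLS slope of position vs time.

    Parameters
    ----------
    times
        Frame times in minutes, strictly increasing, length >= 2.
    positions
        Terminus coordinate at each frame, μm.
    orientation
        +1 for the terminus at the higher coordinate (outward = increasing
        position), −1 for the terminus at the lower coordinate. The slope is
        multiplied by this sign so that positive always means outward growth.

    Notes
    -----
    A single whole-trace least-squares slope is used rather than
    frame-to-frame finite differences: for a constant-rate segment it is the
    minimum-variance linear estimator, and it matches reporting one rate per
    terminus per condition. The standard error is the usual OLS slope SE
    (0 for an exactly linear trace or with only two frames).
    """
    if orientation not in (-1, 1):
        raise ConfigError(f"orientation must be +1 or -1, got {orientation!r}")
    t = np.asarray(times, dtype=float)
    x = np.asarray(positions, dtype=float)
    if t.ndim != 1 or t.shape != x.shape or t.size < 2:
        raise ConfigError("need matching 1-d times/positions with >= 2 frames")
    if np.any(np.diff(t) <= 0):
        raise ConfigError("times must be strictly increasing (no duplicates)")

    n = t.size
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ x) / sxx
    resid = x - x.mean() - slope * tc
    ssr = float(resid @ resid)
    if n > 2 and ssr > 0:
        se = math.sqrt(ssr / (n - 2) / sxx)
    else:
        se = 0.0
    return EndRateEstimate(rate=orientation * slope, se=se, n_frames=n)


@dataclass(frozen=True)
class DirectionalityCall:
    """Outcome of the unidirectional/bidirectional classification.

    ``label`` is one of ``unidirectional`` / ``bidirectional`` / ``stalled``
    / ``indeterminate``; ``active_ends`` counts termini whose rate differs
    from zero at level alpha; ``z_statistic`` is the two-sample statistic for
    equality of the two end rates, reported for diagnostic use.
    """

    label: str
    active_ends: int
    z_statistic: float
    alpha: float


def classify_directionality(
    end_a: EndRateEstimate,
    end_b: EndRateEstimate,
    alpha: float = 0.05,
) -> DirectionalityCall:
    """Classify a filament's growth mode from its two terminus rates.

    A terminus is *active* when its |rate| exceeds the two-sided normal
    critical value times its standard error (an SE of zero is treated as an
    exact measurement, so any non-zero rate is active). Exactly one active
    end → ``unidirectional``; two → ``bidirectional``; none → ``stalled``.
    Non-finite inputs yield ``indeterminate`` with a warning rather than an
    exception, so one corrupt tube cannot abort a batch analysis.
    """
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha!r}")
    vals = (end_a.rate, end_a.se, end_b.rate, end_b.se)
    if not all(math.isfinite(v) for v in vals):
        warnings.warn(
            "non-finite rate or SE; directionality is indeterminate",
            RuntimeWarning,
            stacklevel=2,
        )
        return DirectionalityCall("indeterminate", 0, math.nan, alpha)
    if end_a.se < 0 or end_b.se < 0:
        raise ConfigError("standard errors must be >= 0")

    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    active = [abs(e.rate) > zcrit * e.se for e in (end_a, end_b)]
    n_active = sum(active)
    pooled = math.hypot(end_a.se, end_b.se)
    diff = end_a.rate - end_b.rate
    if pooled > 0:
        z = diff / pooled
    else:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    label = {0: "stalled", 1: "unidirectional", 2: "bidirectional"}[n_active]
    return DirectionalityCall(label, n_active, z, alpha)
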