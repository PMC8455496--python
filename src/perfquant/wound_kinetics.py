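"""Scratch wound-healing kinetics: free-area detection and exponential fits.

A scratch assay tracks the cell-free area of a wounded monolayer over
time.  Per-timepoint areas are normalised to the time-0 wound (so the
series starts at 100%) and modelled as

    y(t) = y0 · exp(t / τ),        τ < 0 for a closing wound,

with amplitude y0 (%) and time constant τ (hours).  The half-closure
time is T50 = −τ · ln 2.  A smaller |τ| means faster closure, i.e. a
more migratory phenotype.

The module is organised around a model/results pair:
:class:`WoundClosureModel` holds the observations and ``fit()`` returns
an :class:`ExponentialFit` carrying the estimates, the 95% confidence
interval on τ, R² and T50, with ``summary()``, ``predict()`` and
``plot()``.  Free functions (:func:`fit_exponential`,
:func:`half_closure_time`, :func:`compare_conditions`) wrap the same
machinery.

The confidence interval is computed on the rate k = 1/τ from the
asymptotic covariance of the least-squares fit (Student-t critical
value, n − p degrees of freedom) and transformed to τ, which yields an
asymmetric interval in τ as typically printed by curve-fitting software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .image_io import PixelGrid
from .segmentation import (
    DegenerateHistogramError,
    IntensityHistogram,
    otsu_threshold,
)
from .stats import TestResult, mann_whitney

__all__ = [
    "WoundSeries",
    "ExponentialFit",
    "WoundClosureModel",
    "ConditionComparison",
    "FitError",
    "CLOSED_FLOOR_PCT",
    "detect_free_area",
    "normalize_series",
    "fit_exponential",
    "half_closure_time",
    "compare_conditions",
]

#: Fully closed wounds are floored at this percentage so the exponential
#: model (which never reaches zero) remains well defined on the log scale.
CLOSED_FLOOR_PCT = 0.01

_LN2 = float(np.log(2.0))


class FitError(RuntimeError):
    """Raised when the exponential fit fails to converge."""


class DegenerateTextureError(ValueError):
    """Raised when an image has no texture contrast to segment."""


@dataclass(frozen=True)
class WoundSeries:
    """Normalised cell-free percentages over time for one condition.

    ``times`` are hours, strictly increasing and starting at 0;
    ``free_pct`` is the percentage of the time-0 cell-free area, 100 at
    t = 0 by construction and floored at :data:`CLOSED_FLOOR_PCT`.
    """

    times: np.ndarray
    free_pct: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        y = np.asarray(self.free_pct, dtype=np.float64)
        if t.size != y.size or t.size < 1:
            raise ValueError("times and free_pct must be equal-length, non-empty")
        if t[0] != 0:
            raise ValueError("first time point must be 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if abs(y[0] - 100.0) > 1e-9:
            raise ValueError("free_pct must equal 100 at time 0")
        if np.any(y <= 0) or np.any(y > 100.0 + 1e-9):
            raise ValueError("free_pct values must lie in (0, 100]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "free_pct", y)

    def __len__(self) -> int:
        return int(self.times.size)


def normalize_series(
    times: Sequence[float],
    fractions: Sequence[float],
    condition: str = "",
) -> WoundSeries:
    """Normalise raw free-area fractions to the time-0 wound.

    free_pct(t) = 100 · fraction(t) / fraction(0); exact zeros (fully
    repopulated wounds) are replaced by the 0.01% floor.
    """
    t = np.asarray(times, dtype=np.float64)
    f = np.asarray(fractions, dtype=np.float64)
    if t.size != f.size or t.size < 1:
        raise ValueError("times and fractions must be equal-length, non-empty")
    if t[0] != 0:
        raise ValueError("first time point must be 0")
    if f[0] <= 0:
        raise ZeroDivisionError("fraction at time 0 must be > 0 to normalise")
    pct = 100.0 * f / f[0]
    pct[pct <= 0] = CLOSED_FLOOR_PCT
    return WoundSeries(times=t, free_pct=pct, condition=condition)


def detect_free_area(img: PixelGrid, texture_window: int = 15) -> float:
    """Cell-free fraction of a phase-contrast frame from local texture.

    A confluent monolayer is texture-rich while the wound is smooth, so
    the local standard deviation over ``texture_window`` separates the
    two.  The deviation map is quantised to 256 levels and thresholded
    with Otsu's method; the low-texture fraction is returned.  When the
    two texture classes are not genuinely distinct (their mean local
    deviations differ by less than a factor of two, as in a fully
    confluent frame), no wound is detectable and 0.0 is returned.
    """
    if texture_window < 3 or texture_window % 2 == 0:
        raise ValueError("texture_window must be odd and >= 3")
    from scipy.ndimage import uniform_filter

    x = img.values.astype(np.float64)
    m = uniform_filter(x, size=texture_window, mode="nearest")
    m2 = uniform_filter(x * x, size=texture_window, mode="nearest")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    lo, hi = float(s.min()), float(s.max())
    if hi <= lo:
        raise DegenerateTextureError("constant texture map; nothing to segment")
    q = np.round((s - lo) / (hi - lo) * 255.0).astype(np.uint8)
    t = otsu_threshold(IntensityHistogram(np.bincount(q.ravel(), minlength=256)))
    low = q <= t
    # bimodality guard: require real contrast between the two classes
    mean_low = float(s[low].mean())
    mean_high = float(s[~low].mean()) if (~low).any() else mean_low
    if mean_high <= 0 or mean_low > 0.5 * mean_high:
        return 0.0
    return float(low.mean())


@dataclass(frozen=True)
class ExponentialFit:
    """Results of the exponential closure fit y(t) = y0 · exp(t/τ).

    ``tau`` is in hours (negative for closure), ``ci_tau`` its 95%
    interval, ``t50 = −τ·ln 2`` the half-closure time, ``r2`` the
    coefficient of determination against the mean-only model.
    ``at_boundary`` flags a rate driven to zero (a non-closing series,
    τ → −∞).
    """

    y0: float
    tau: float
    ci_tau: tuple[float, float]
    r2: float
    t50: float
    k: float
    se_k: float
    n_obs: int
    at_boundary: bool = False
    condition: str = ""

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=np.float64)
        return self.y0 * np.exp(t / self.tau)

    def conf_int(self) -> tuple[float, float]:
        return self.ci_tau

    def summary(self) -> str:
        lines = [
            "Exponential wound-closure fit: y(t) = y0 * exp(t / tau)",
            "=" * 56,
            f"condition:        {self.condition or '-'}",
            f"n observations:   {self.n_obs}",
            f"y0 (%):           {self.y0:10.3f}",
            f"tau (h):          {self.tau:10.3f}",
            f"95% CI tau (h):   [{self.ci_tau[0]:.3f}, {self.ci_tau[1]:.3f}]",
            f"R^2:              {self.r2:10.4f}",
            f"T50 (h):          {self.t50:10.3f}",
        ]
        if self.at_boundary:
            lines.append("warning: rate at boundary (series not closing; tau -> -inf)")
        return "\n".join(lines)

    def plot(self, series: "WoundSeries | None" = None, ax=None):
        """Plot observations (if given) and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if series is not None:
            ax.plot(series.times, series.free_pct, "o", label="observed")
            tmax = series.times.max()
        else:
            tmax = 3 * abs(self.tau)
        tt = np.linspace(0, tmax, 200)
        ax.plot(tt, self.predict(tt), "-", label="fit")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cell-free area (% of t0)")
        ax.legend()
        return ax


class WoundClosureModel:
    """Exponential closure model bound to one observed series.

    Accepts either a :class:`WoundSeries` or raw ``times``/``free_pct``
    arrays (useful for fitting all replicate observations, where times
    may repeat and the series invariants do not apply).
    """

    def __init__(self, series: WoundSeries | None = None, *, times=None, free_pct=None,
                 condition: str = ""):
        if series is not None:
            self.times = series.times
            self.y = series.free_pct
            self.condition = series.condition or condition
            self.series = series
        else:
            self.times = np.asarray(times, dtype=np.float64)
            self.y = np.asarray(free_pct, dtype=np.float64)
            self.condition = condition
            self.series = None
        if self.times.size != self.y.size or self.times.size < 3:
            raise ValueError("need >= 3 (time, value) observations")
        if np.any(self.y <= 0):
            raise ValueError("free percentages must be positive")

    @classmethod
    def from_dataframe(cls, df, time_col: str = "time_h", value_col: str = "free_pct",
                       condition: str = "") -> "WoundClosureModel":
        return cls(times=df[time_col].to_numpy(), free_pct=df[value_col].to_numpy(),
                   condition=condition)

    def _prefit(self) -> tuple[float, float]:
        slope, intercept = np.polyfit(self.times, np.log(self.y), 1)
        return float(np.exp(intercept)), min(float(slope), -1e-9)

    def fit(self, constrain_y0: bool = False, plateau: bool = False,
            alpha: float = 0.05) -> ExponentialFit:
        """Least-squares fit with τ < 0 enforced.

        ``constrain_y0`` fixes y0 = 100; ``plateau`` adds an additive
        offset c (sensitivity variant y0·exp(t/τ) + c).  The CI on τ is
        the Student-t interval on the rate k = 1/τ, transformed.
        """
        t, y = self.times, self.y
        y0_init, k_init = self._prefit()

        if plateau:
            def f(tt, y0, k, c):
                return y0 * np.exp(k * tt) + c
            p0 = [y0_init, k_init, 0.0]
            bounds = ([0.0, -np.inf, -np.inf], [np.inf, -1e-12, np.inf])
            k_index = 1
        elif constrain_y0:
            def f(tt, k):
                return 100.0 * np.exp(k * tt)
            p0 = [k_init]
            bounds = ([-np.inf], [-1e-12])
            k_index = 0
        else:
            def f(tt, y0, k):
                return y0 * np.exp(k * tt)
            p0 = [y0_init, k_init]
            bounds = ([0.0, -np.inf], [np.inf, -1e-12])
            k_index = 1

        last_err: Exception | None = None
        popt = pcov = None
        for scale in (1.0, 0.5, 2.0, 0.1):
            try:
                start = list(p0)
                start[k_index] = p0[k_index] * scale
                popt, pcov = optimize.curve_fit(
                    f, t, y, p0=start, bounds=bounds, maxfev=20000,
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                break
            except (RuntimeError, optimize.OptimizeWarning) as err:  # pragma: no cover
                last_err = err
        if popt is None:  # pragma: no cover
            raise FitError(f"exponential fit did not converge: {last_err}")

        k = float(popt[k_index])
        se_k = float(np.sqrt(pcov[k_index, k_index]))
        n, p = t.size, len(popt)
        dof = max(n - p, 1)
        tcrit = float(sps.t.ppf(1.0 - alpha / 2.0, dof))
        k_lo, k_hi = k - tcrit * se_k, k + tcrit * se_k

        at_boundary = k > -1e-8
        if at_boundary:
            warnings.warn(
                "fitted rate at the tau < 0 boundary; series is not closing",
                RuntimeWarning,
                stacklevel=2,
            )
        tau = 1.0 / k if k < 0 else -np.inf
        ci_lo = 1.0 / k_hi if k_hi < 0 else -np.inf
        ci_hi = 1.0 / k_lo if k_lo < 0 else -np.inf
        yhat = f(t, *popt)
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        y0 = 100.0 if constrain_y0 else float(popt[0])
        return ExponentialFit(
            y0=y0,
            tau=float(tau),
            ci_tau=(float(ci_lo), float(ci_hi)),
            r2=r2,
            t50=half_closure_time(tau) if np.isfinite(tau) else float("inf"),
            k=k,
            se_k=se_k,
            n_obs=n,
            at_boundary=at_boundary,
            condition=self.condition,
        )


def fit_exponential(series: WoundSeries, **kwargs) -> ExponentialFit:
    """Fit the exponential closure model to a normalised series."""
    return WoundClosureModel(series).fit(**kwargs)


def half_closure_time(fit_or_tau) -> float:
    """T50 = −τ · ln 2 for a closing series (τ < 0)."""
    tau = fit_or_tau.tau if isinstance(fit_or_tau, ExponentialFit) else float(fit_or_tau)
    if not (tau < 0):
        raise ValueError(f"half-closure time undefined for tau = {tau} (needs tau < 0)")
    return -tau * _LN2


@dataclass(frozen=True)
class ConditionComparison:
    """Two fitted conditions with per-timepoint replicate comparisons."""

    fit_a: ExponentialFit
    fit_b: ExponentialFit
    tau_ratio: float
    per_time: dict[float, TestResult] = field(default_factory=dict)


def compare_conditions(
    series_a: WoundSeries,
    series_b: WoundSeries,
    replicates_a: Mapping[float, Sequence[float]] | None = None,
    replicates_b: Mapping[float, Sequence[float]] | None = None,
) -> ConditionComparison:
    """Fit both conditions and compare them.

    ``tau_ratio`` is τ_a / τ_b (> 1 when condition b closes faster).
    When per-timepoint replicate values are supplied for both
    conditions, a Mann–Whitney test is run at each shared time point.
    """
    fit_a = fit_exponential(series_a)
    fit_b = fit_exponential(series_b)
    per_time: dict[float, TestResult] = {}
    if replicates_a is not None and replicates_b is not None:
        for t in sorted(set(replicates_a) & set(replicates_b)):
            per_time[float(t)] = mann_whitney(replicates_a[t], replicates_b[t])
    return ConditionComparison(
        fit_a=fit_a,
        fit_b=fit_b,
        tau_ratio=float(fit_a.tau / fit_b.tau),
        per_time=per_time,
    )
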