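"""Logistic growth-curve kinetics.

The model is the standard logistic

    N(t) = K / (1 + A exp(-r t)),     A = (K - N0) / N0,

with carrying capacity ``K`` (OD units), intrinsic growth rate ``r`` (h^-1)
and initial size ``N0``.  Four kinetic parameters are extracted per well:

* ``latency``  — time for OD600 to first exceed a threshold (default 0.25),
  measured directly from the curve with linear interpolation;
* ``r``        — from the nonlinear least-squares logistic fit;
* ``max_od``   — maximum observed OD within the analysis window (24 h);
* ``auc``      — the closed-form integral of the fitted logistic over the
  window (an empirical trapezoid AUC is kept as a diagnostic).

The Model/Results split follows the statsmodels convention:
``LogisticGrowthModel(times, od).fit()`` returns a
:class:`LogisticGrowthResults` carrying estimates and diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import AnalysisError
from .io_plate import GrowthCurve

__all__ = [
    "FitConfig",
    "GrowthParameters",
    "LogisticGrowthModel",
    "LogisticGrowthResults",
    "extract_growth_parameters",
    "latency",
    "logistic_auc",
    "logistic_od",
    "max_od",
]


def logistic_od(t, K: float, r: float, N0: float):
    """Logistic OD at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    A = (K - N0) / N0
    return K / (1.0 + A * np.exp(-r * t))


def logistic_auc(K: float, r: float, N0: float, t_end: float) -> float:
    """Closed-form integral of the logistic over ``[0, t_end]``.

    AUC = (K/r) [ ln(A + e^{r t_end}) - ln(A + 1) ].  Evaluated in
    log-space so late-saturating curves (large ``A``) stay accurate.
    """
    if t_end <= 0:
        raise AnalysisError(f"t_end must be positive, got {t_end}")
    if not (0 < N0 <= K) or r <= 0:
        raise AnalysisError(f"invalid logistic parameters K={K}, r={r}, N0={N0}")
    A = (K - N0) / N0
    upper = r * t_end + math.log1p(A * math.exp(-r * t_end))
    lower = math.log1p(A)
    return (K / r) * (upper - lower)


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the kinetic extraction.

    ``latency_threshold`` and ``window_h`` default to 0.25 OD and 24 h.
    ``od_offset`` is an optional constant background subtracted before
    fitting (default 0: raw signal).  Non-converged fits are retried from
    ``n_restarts`` jittered starts seeded by ``restart_seed``.
    """

    latency_threshold: float = 0.25
    window_h: float = 24.0
    interpolate_latency: bool = True
    od_offset: float = 0.0
    n_restarts: int = 5
    restart_seed: int = 20240
    max_rate: float = 10.0


@dataclass(frozen=True)
class GrowthParameters:
    """The four kinetic parameters for one culture replicate.

    ``latency_h`` is NaN when the threshold is never exceeded; ``r`` and
    ``auc`` are NaN when the logistic fit failed (``converged=False``).
    """

    culture_id: str
    replicate: int
    latency_h: float
    r: float
    max_od: float
    auc: float
    K: float = float("nan")
    N0: float = float("nan")
    rss: float = float("nan")
    converged: bool = False
    auc_trapezoid: float = float("nan")


class LogisticGrowthModel:
    """Nonlinear least-squares logistic model of one OD600 time series."""

    def __init__(self, times, od, culture_id: str = ""):
        self.times = np.asarray(times, dtype=float)
        self.od = np.asarray(od, dtype=float)
        self.culture_id = culture_id
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise AnalysisError("times and od must be 1-D arrays of equal length")
        if len(self.times) < 6:
            raise AnalysisError(f"curve {culture_id!r}: need at least 6 points to fit, got {len(self.times)}")

    @classmethod
    def from_curve(cls, curve: GrowthCurve, config: FitConfig | None = None) -> "LogisticGrowthModel":
        config = config or FitConfig()
        mask = curve.times <= config.window_h + 1e-9
        od = np.clip(curve.od[mask] - config.od_offset, 0.0, None)
        return cls(curve.times[mask], od, curve.culture_id)

    # -- initial guesses ---------------------------------------------------
    def _start(self) -> np.ndarray:
        od = self.od
        K0 = float(np.max(od))
        N00 = float(max(od[0], 1e-3))
        r0 = self._log_slope(K0)
        return np.array([K0, r0, min(N00, 0.9 * K0)])

    def _log_slope(self, K0: float) -> float:
        # slope of log OD during early (sub-half-capacity) growth
        mask = (self.od > 1e-4) & (self.od < 0.5 * K0)
        if mask.sum() >= 3:
            t, y = self.times[mask], np.log(self.od[mask])
            slope = np.polyfit(t, y, 1)[0]
            if np.isfinite(slope) and slope > 0:
                return float(np.clip(slope, 0.02, 5.0))
        return 0.3

    def fit(self, config: FitConfig | None = None) -> "LogisticGrowthResults":
        config = config or FitConfig()
        od = self.od
        odmax = float(np.max(od))
        # degenerate, non-growing signal: no logistic information
        if odmax <= 0 or odmax < 1.2 * max(od[0], 1e-3):
            return LogisticGrowthResults(self, odmax, float("nan"), odmax,
                                         float(np.sum((od - np.mean(od)) ** 2)), False, config)
        lo = np.array([1e-6, 1e-4, 1e-9])
        hi = np.array([3.0 * odmax, config.max_rate, 3.0 * odmax])

        def resid(p):
            return logistic_od(self.times, *p) - od

        def attempt(x0, hi):
            x0 = np.clip(x0, lo * 1.001, hi * 0.999)
            try:
                return least_squares(resid, x0, bounds=(lo, hi), xtol=1e-13, ftol=1e-13, gtol=1e-13)
            except Exception:
                return None

        def solve(x0):
            # an unsaturated curve (no plateau within the window) carries a
            # K above the default cap: widen the bound while the optimum
            # presses against it
            hi_cur = hi.copy()
            sol = attempt(x0, hi_cur)
            while (sol is not None and sol.success and sol.x[0] > 0.95 * hi_cur[0]
                   and hi_cur[0] < 100.0 * odmax):
                hi_cur = hi_cur.copy()
                hi_cur[0] *= 10.0
                nxt = attempt(sol.x, hi_cur)
                if nxt is None or not nxt.success or nxt.cost >= sol.cost:
                    break
                sol = nxt
            return sol

        best = solve(self._start())
        if best is None or not best.success:
            rng = np.random.default_rng(config.restart_seed)
            for _ in range(config.n_restarts):
                jitter = np.exp(rng.normal(0.0, 0.4, size=3))
                sol = solve(self._start() * jitter)
                if sol is not None and sol.success and (best is None or sol.cost < best.cost):
                    best = sol
        if best is None or not best.success:
            return LogisticGrowthResults(self, float("nan"), float("nan"), float("nan"),
                                         float("nan"), False, config)
        K, r, N0 = (float(v) for v in best.x)
        rss = float(2.0 * best.cost)
        # a fit collapsing onto K ~ N0 carries no growth signal
        converged = bool(K > 0 and 0 < N0 < K and r > 1e-3 and K > 1.2 * N0)
        return LogisticGrowthResults(self, K, r, N0, rss, converged, config)


@dataclass(frozen=True)
class LogisticGrowthResults:
    """Estimates and diagnostics of a logistic growth fit."""

    model: LogisticGrowthModel
    K: float
    r: float
    N0: float
    rss: float
    converged: bool
    config: FitConfig = field(default_factory=FitConfig)

    def predict(self, t):
        if not self.converged:
            raise AnalysisError("cannot predict from a non-converged fit")
        return logistic_od(t, self.K, self.r, self.N0)

    def auc(self, t_end: float | None = None) -> float:
        """Model-based AUC over ``[0, t_end]`` (default: the fit window)."""
        if not self.converged:
            return float("nan")
        return logistic_auc(self.K, self.r, self.N0, t_end if t_end is not None else self.config.window_h)

    def summary(self) -> str:
        lines = [
            "Logistic growth fit" + (f" — {self.model.culture_id}" if self.model.culture_id else ""),
            "=" * 40,
            f"{'n obs':<22}{len(self.model.times):>16d}",
            f"{'converged':<22}{str(self.converged):>16}",
            f"{'K (OD)':<22}{self.K:>16.6g}",
            f"{'r (1/h)':<22}{self.r:>16.6g}",
            f"{'N0 (OD)':<22}{self.N0:>16.6g}",
            f"{'RSS':<22}{self.rss:>16.6g}",
        ]
        if self.converged:
            lines.append(f"{'AUC (OD·h)':<22}{self.auc():>16.6g}")
        return "\n".join(lines)


def latency(curve: GrowthCurve, threshold: float = 0.25, interpolate: bool = True) -> float:
    """First time the OD exceeds ``threshold``; NaN if it never does.

    With ``interpolate`` the crossing is linearly interpolated between the
    bracketing samples (the 30-min grid is coarse); otherwise the first
    sample time above threshold is returned.
    """
    if threshold <= 0:
        raise AnalysisError(f"latency threshold must be positive, got {threshold}")
    above = curve.od > threshold
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(curve.times[0])
    if not interpolate:
        return float(curve.times[i])
    t0, t1 = curve.times[i - 1], curve.times[i]
    y0, y1 = curve.od[i - 1], curve.od[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def max_od(curve: GrowthCurve, window_h: float = 24.0) -> float:
    """Maximum observed OD within ``[0, window_h]``."""
    mask = curve.times <= window_h + 1e-9
    if not mask.any():
        raise AnalysisError(f"curve {curve.culture_id!r}: no samples within the window")
    return float(np.max(curve.od[mask]))


def extract_growth_parameters(curve: GrowthCurve, config: FitConfig | None = None,
                              replicate: int = 0) -> GrowthParameters:
    """Bundle the four kinetic parameters for one curve.

    Latency and maxOD are measured directly; r and AUC come from the
    logistic fit and are NaN when the fit fails (the record is still
    returned so direct measures survive).
    """
    config = config or FitConfig()
    mask = curve.times <= config.window_h + 1e-9
    trimmed = GrowthCurve(curve.culture_id, curve.times[mask],
                          np.clip(curve.od[mask] - config.od_offset, 0.0, None))
    res = LogisticGrowthModel.from_curve(curve, config).fit(config)
    auc_emp = float(np.trapezoid(trimmed.od, trimmed.times))
    return GrowthParameters(
        culture_id=curve.culture_id,
        replicate=replicate,
        latency_h=latency(trimmed, config.latency_threshold, config.interpolate_latency),
        r=res.r if res.converged else float("nan"),
        max_od=max_od(trimmed, config.window_h),
        auc=res.auc() if res.converged else float("nan"),
        K=res.K,
        N0=res.N0,
        rss=res.rss,
        converged=res.converged,
        auc_trapezoid=auc_emp,
    )
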