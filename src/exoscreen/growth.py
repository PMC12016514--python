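"""Microplate growth-screen analysis.

Plate readers that image through the plate bottom report arbitrary
"green values"; a supplier standard curve converts them to OD600.  Each
well's log-OD trajectory is smoothed with a cubic spline, the maximum
specific growth rate mu_max (1/h) is the largest first derivative of the
smoothed curve on a fine grid, the minimum generation time is
``ln 2 / mu_max`` (h), and the lag phase is where the tangent at the
mu_max point crosses the initial log-OD level — the standard tangent
construction of growth-curve analysis.

Strain-versus-control contrasts use Welch two-sample t-tests; p-values
are Benjamini-Hochberg adjusted across all strain x metric comparisons
of one screen and summarised with the usual star notation
(ns > 0.05 >= * > 0.01 >= ** > 0.001 >= *** > 0.0001 >= ****).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import InterpolatedUnivariateSpline, UnivariateSpline
from scipy.stats import ttest_ind

from .enrichment import adjust

__all__ = [
    "CalibrationCurve",
    "GrowthCurve",
    "GrowthParams",
    "StrainComparison",
    "calibrate",
    "fit_growth",
    "compare_strains",
    "adjust_comparisons",
    "stars_for",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone (green value, OD600) pairs; interpolated piecewise-linearly."""

    green: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.green, dtype=float)
        o = np.asarray(self.od, dtype=float)
        if len(g) < 2 or len(g) != len(o):
            raise ValueError("calibration needs >= 2 (green, od) pairs of equal length")
        if not (np.all(np.diff(g) > 0) and np.all(np.diff(o) > 0)):
            raise ValueError("calibration curve must be strictly increasing in both coordinates")

    @classmethod
    def from_csv(cls, path: str) -> "CalibrationCurve":
        df = pd.read_csv(path)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        return cls(green=tuple(df["green_value"]), od=tuple(df["od600"]))


def calibrate(green: Sequence[float], curve: CalibrationCurve) -> np.ndarray:
    """Convert green values to OD600 by monotone linear interpolation.

    Values below the curve domain are clamped to the smallest OD with a
    warning (plate background); values above refuse to extrapolate.
    """
    g = np.asarray(green, dtype=float)
    lo, hi = curve.green[0], curve.green[-1]
    if (g > hi).any():
        raise ValueError(f"green value above calibration domain (max {hi})")
    if (g < lo).any():
        warnings.warn(
            "green value(s) below calibration domain clamped to the smallest OD",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.interp(g, curve.green, curve.od)


@dataclass
class GrowthCurve:
    """One well: strain, replicate index, hours and positive OD values."""

    strain: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        o = np.asarray(self.od, dtype=float)
        if len(t) != len(o):
            raise ValueError("times and od differ in length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        self.times, self.od = t, o


@dataclass
class GrowthParams:
    """Spline-derived kinetics for one well."""

    strain: str
    replicate: int
    mu_max: float
    min_generation_time: float
    lag_h: float
    od0: float
    fit_ok: bool


def _noise_sigma(y: np.ndarray) -> float:
    """Robust noise scale from second differences of log-OD.

    The second difference of a smooth trend is near zero at plate-reader
    sampling density, so its spread estimates measurement noise.
    """
    d2 = np.diff(y, n=2)
    if len(d2) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d2)) / math.sqrt(6.0))


def fit_growth(
    curve: GrowthCurve,
    smoothing: Optional[float] = None,
    grid_factor: int = 10,
) -> GrowthParams:
    """Fit a smoothing spline to log-OD and extract kinetic parameters.

    ``smoothing`` is the spline's residual budget ``s``; by default it is
    ``m * sigma_hat**2`` with ``sigma_hat`` estimated from second
    differences, which collapses to interpolation on noiseless data.
    The derivative is maximised on a grid ``grid_factor`` times denser
    than the input sampling.  Degenerate fits (mu_max <= 0) return
    ``fit_ok=False`` instead of raising.
    """
    t, od = curve.times, curve.od
    if len(t) < 8:
        raise ValueError("need at least 8 time points")
    if (od <= 0).any():
        raise ValueError("OD values must be positive (calibrate first)")
    y = np.log(od)
    od0 = float(od[:3].mean())
    s = smoothing if smoothing is not None else len(y) * _noise_sigma(y) ** 2
    if s > 1e-10:
        spl = UnivariateSpline(t, y, k=3, s=s)
    else:  # effectively noiseless data: interpolate
        spl = InterpolatedUnivariateSpline(t, y, k=3)
    grid = np.linspace(t[0], t[-1], len(t) * grid_factor)
    deriv = spl.derivative()(grid)
    i = int(np.argmax(deriv))
    mu_max = float(deriv[i])
    if not np.isfinite(mu_max) or mu_max <= 1e-9:
        return GrowthParams(curve.strain, curve.replicate, math.nan, math.nan, math.nan, od0, False)
    t_star = float(grid[i])
    # tangent at the mu_max point down to the initial log-OD level
    lag = t_star - (float(spl(t_star)) - math.log(od0)) / mu_max
    lag = min(max(lag, 0.0), float(t[-1]))
    return GrowthParams(
        strain=curve.strain,
        replicate=curve.replicate,
        mu_max=mu_max,
        min_generation_time=math.log(2.0) / mu_max,
        lag_h=lag,
        od0=od0,
        fit_ok=True,
    )


_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for(p: float) -> str:
    """Map a p-value to the conventional significance stars (ns above 0.05)."""
    for cut, stars in _STAR_THRESHOLDS:
        if p <= cut:
            return stars
    return "ns"


@dataclass
class StrainComparison:
    strain: str
    metric: str  # "generation_time" or "lag"
    mean_test: float
    mean_control: float
    percent_change: float
    t_stat: float
    p_raw: float
    p_adj: float = math.nan
    stars: str = ""


_METRIC_ATTR = {"generation_time": "min_generation_time", "lag": "lag_h"}


def compare_strains(
    test: Sequence[GrowthParams],
    control: Sequence[GrowthParams],
    metric: str,
    strain: Optional[str] = None,
) -> StrainComparison:
    """Welch t-test of one strain against the control on one metric.

    ``p_adj`` and ``stars`` are left blank; :func:`adjust_comparisons`
    fills them across the whole screen's family of comparisons.
    """
    attr = _METRIC_ATTR.get(metric)
    if attr is None:
        raise ValueError(f"metric must be one of {sorted(_METRIC_ATTR)}")
    a = np.array([getattr(p, attr) for p in test if p.fit_ok], dtype=float)
    b = np.array([getattr(p, attr) for p in control if p.fit_ok], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 successful replicate fits per group")
    res = ttest_ind(a, b, equal_var=False)
    mean_test, mean_control = float(a.mean()), float(b.mean())
    t_stat = float(res.statistic)
    p_raw = float(res.pvalue)
    if not np.isfinite(t_stat):  # identical constant groups
        t_stat, p_raw = 0.0, 1.0
    return StrainComparison(
        strain=strain or test[0].strain,
        metric=metric,
        mean_test=mean_test,
        mean_control=mean_control,
        percent_change=100.0 * (mean_test - mean_control) / mean_control,
        t_stat=t_stat,
        p_raw=p_raw,
    )


def adjust_comparisons(
    comparisons: Sequence[StrainComparison], method: str = "bh"
) -> list[StrainComparison]:
    """BH-adjust p-values across all strain x metric tests of one screen."""
    comps = list(comparisons)
    if not comps:
        return []
    p_adj = adjust([c.p_raw for c in comps], method=method)
    for c, p in zip(comps, p_adj):
        c.p_adj = float(p)
        c.stars = stars_for(float(p))
    return comps


def comparisons_to_frame(comparisons: Sequence[StrainComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.strain, c.metric, c.mean_test, c.mean_control, c.percent_change,
             c.t_stat, c.p_raw, c.p_adj, c.stars)
            for c in comparisons
        ],
        columns=["strain", "metric", "mean_test", "mean_control", "percent_change",
                 "t_stat", "p_raw", "p_adj", "stars"],
    )


def read_growth_csv(path: str) -> pd.DataFrame:
    """Read a long-format screen CSV.

    Columns: ``strain, replicate, time_h`` and either ``od`` or
    ``green_value`` (convert the latter with :func:`calibrate`).
    """
    df = pd.read_csv(path)
    required = {"strain", "replicate", "time_h"}
    if not required <= set(df.columns):
        raise ValueError(f"growth CSV needs columns {sorted(required)} plus od or green_value")
    if "od" not in df.columns and "green_value" not in df.columns:
        raise ValueError("growth CSV needs an 'od' or 'green_value' column")
    return df


def curves_from_frame(df: pd.DataFrame, value_col: str = "od") -> list[GrowthCurve]:
    curves = []
    for (strain, rep), sub in df.groupby(["strain", "replicate"], sort=True):
        sub = sub.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain=str(strain),
                replicate=int(rep),
                times=sub["time_h"].to_numpy(float),
                od=sub[value_col].to_numpy(float),
            )
        )
    return curves
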