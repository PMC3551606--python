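"""Protease inhibition metrics from fluorogenic (AMC-release) progress curves.

Cathepsin activity is followed by the fluorescence of AMC released from a
peptidyl-AMC substrate (emission 440 nm, excitation 380 nm).  The initial
slope of each progress curve is the reaction rate; residual activity is the
inhibited rate as a percentage of the uninhibited control.  The
concentration of active enzyme is obtained by titration with the
irreversible inhibitor E-64: in the stoichiometric depletion regime the
rate falls linearly with [E-64] and extrapolates to zero at the active-site
concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProgressCurve",
    "ActivityResult",
    "TitrationResult",
    "initial_rate",
    "residual_activity",
    "dose_series",
    "e64_titration",
]


@dataclass
class ProgressCurve:
    """Time course of released-AMC fluorescence for one assay condition."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    inhibitor: str = ""
    concentration_uM: float = float("nan")
    enzyme: str = "CTSB"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.time_s) < 6:
            raise ValueError("progress curve needs at least 6 points")
        if len(self.time_s) != len(self.fluorescence):
            raise ValueError("time and fluorescence lengths differ")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly ascending")
        if self.time_s.min() < 0:
            raise ValueError("time must be non-negative")


@dataclass(frozen=True)
class ActivityResult:
    """Initial rate and residual/reduced activity at one inhibitor concentration."""

    rate: float
    residual_pct: float
    concentration_uM: float = float("nan")

    @property
    def reduction_pct(self) -> float:
        return 100.0 - self.residual_pct


@dataclass(frozen=True)
class TitrationResult:
    """Active enzyme concentration from an E-64 titration line."""

    active_concentration_nM: float
    slope: float
    r_squared: float
    valid: bool


def initial_rate(curve: ProgressCurve, window: float = 0.25) -> float:
    """Initial reaction rate (AU/s) from an OLS slope over the early points.

    ``window`` is the fraction of points used, from the start of the curve
    (default the first 25%); it must cover at least 4 points.  Negative
    slopes are clipped to zero with a warning.
    """
    if not 0 < window <= 1:
        raise ValueError("window must be a fraction in (0, 1]")
    n = max(int(round(window * len(curve.time_s))), 4)
    if n > len(curve.time_s):
        raise ValueError(
            f"window of {n} points exceeds curve length {len(curve.time_s)}"
        )
    t = curve.time_s[:n]
    f = curve.fluorescence[:n]
    slope = float(np.polyfit(t, f, 1)[0])
    if slope < 0:
        # round-off on flat curves produces ~-1e-16 slopes; only a genuinely
        # negative trend deserves a warning
        if slope < -1e-12 * (1.0 + float(np.max(np.abs(f)))):
            warnings.warn(f"negative initial rate {slope:.3g} AU/s clipped to 0", stacklevel=2)
        return 0.0
    return slope


def residual_activity(
    rate_inhibited: float, rate_control: float, concentration_uM: float = float("nan")
) -> ActivityResult:
    """Residual activity as a percentage of the uninhibited control rate."""
    if rate_control <= 0:
        raise ValueError("control rate must be positive")
    if rate_inhibited < 0:
        raise ValueError("inhibited rate must be non-negative")
    return ActivityResult(
        rate=rate_inhibited,
        residual_pct=100.0 * rate_inhibited / rate_control,
        concentration_uM=concentration_uM,
    )


def dose_series(results: Sequence[ActivityResult]) -> tuple[pd.DataFrame, float | None]:
    """Order a residual-activity series by concentration; interpolate an IC50.

    Duplicate concentrations are averaged (with a warning).  The IC50 is the
    concentration at which residual activity crosses 50%, found by linear
    interpolation of residual % versus log10(concentration); it is reported
    only when the series brackets 50% at positive concentrations, otherwise
    ``None``.
    """
    if not results:
        raise ValueError("empty dose series")
    df = pd.DataFrame(
        {
            "concentration_uM": [r.concentration_uM for r in results],
            "rate": [r.rate for r in results],
            "residual_pct": [r.residual_pct for r in results],
        }
    )
    if df["concentration_uM"].duplicated().any():
        warnings.warn("duplicate concentrations averaged in dose series", stacklevel=2)
        df = df.groupby("concentration_uM", as_index=False).mean()
    df = df.sort_values("concentration_uM", ignore_index=True)
    df["reduction_pct"] = 100.0 - df["residual_pct"]

    ic50 = None
    pos = df[df["concentration_uM"] > 0]
    if len(pos) >= 2:
        logc = np.log10(pos["concentration_uM"].to_numpy())
        res = pos["residual_pct"].to_numpy()
        for i in range(len(res) - 1):
            lo, hi = res[i], res[i + 1]
            if (lo - 50.0) * (hi - 50.0) <= 0 and lo != hi:
                frac = (50.0 - lo) / (hi - lo)
                ic50 = float(10 ** (logc[i] + frac * (logc[i + 1] - logc[i])))
                break
    return df, ic50


def e64_titration(rates: Sequence[tuple[float, float]], r2_min: float = 0.95) -> TitrationResult:
    """Active-site titration with E-64: x-intercept of rate vs [E-64].

    ``rates`` are (E-64 concentration in nM, rate in AU/s) pairs, at least
    three, in the stoichiometric regime where the rate declines linearly.
    The active enzyme concentration is the x-intercept of the least-squares
    line; the result is flagged invalid when r^2 < ``r2_min``.
    """
    if len(rates) < 3:
        raise ValueError("E-64 titration needs at least 3 concentrations")
    conc = np.asarray([c for c, _ in rates], dtype=float)
    rate = np.asarray([r for _, r in rates], dtype=float)
    order = np.argsort(conc)
    conc, rate = conc[order], rate[order]
    reg = stats.linregress(conc, rate)
    if reg.slope >= 0 or rate[-1] >= rate[0]:
        raise ValueError("rates do not decrease with [E-64]: outside the titration regime")
    x_intercept = -reg.intercept / reg.slope
    r2 = float(reg.rvalue**2)
    return TitrationResult(
        active_concentration_nM=float(x_intercept),
        slope=float(reg.slope),
        r_squared=r2,
        valid=r2 >= r2_min,
    )
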