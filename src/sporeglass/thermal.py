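"""Heat-activation/inactivation summaries and decimal reduction times.

Dormant ascospores need a heat shock before they germinate, so survival
curves at a lethal temperature first rise (activation) and then fall
(inactivation).  The decimal reduction time D is the exposure time that kills
90% of the spores; on the post-activation decay phase ``log10(germination)``
is linear in time with slope ``-1/D``.

The D-value estimate follows the statsmodels pattern: build a
:class:`ThermalInactivationModel` from a :class:`SurvivalTable` and a decay
window, call :meth:`~ThermalInactivationModel.fit`, and read the estimate and
its uncertainty off the returned :class:`DValueResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SurvivalTable",
    "ThermalInactivationModel",
    "DValueResults",
    "d_value",
    "survival_summary",
]


@dataclass
class SurvivalTable:
    """Germination percentages over heating time for one treatment.

    Attributes
    ----------
    times : array of float
        Heating times in minutes, strictly increasing, non-negative.
    germination : array of float
        Germinated fraction in percent of total spores, in [0, 100].
    n_counted : array of int
        Spores evaluated per time point.
    metadata : dict
        Treatment descriptors (temperature_C, humidity regime, species ...).
    """

    times: np.ndarray
    germination: np.ndarray
    n_counted: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.germination = np.asarray(self.germination, dtype=float)
        self.n_counted = np.asarray(self.n_counted, dtype=int)
        n = self.times.size
        if self.germination.size != n or self.n_counted.size != n:
            raise ValueError("times, germination, n_counted must have equal length")
        if n and (self.times[0] < 0 or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any((self.germination < 0) | (self.germination > 100)):
            raise ValueError("germination must lie in [0, 100] percent")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "germination_pct": self.germination,
                "n_counted": self.n_counted,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "SurvivalTable":
        return cls(
            df["time_min"].to_numpy(),
            df["germination_pct"].to_numpy(),
            df["n_counted"].to_numpy(),
            dict(metadata or {}),
        )


@dataclass
class DValueResults:
    """Log-linear inactivation fit.

    ``d_min`` is ``inf`` (with ``finite_d=False``) when the fitted slope is
    non-negative, i.e. the data show no inactivation inside the window.
    """

    d_min: float
    slope: float  # log10 % per min
    intercept: float
    slope_se: float
    n_points: int
    n_excluded_zero: int
    window: tuple[float, float]

    @property
    def finite_d(self) -> bool:
        return math.isfinite(self.d_min)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-approximation confidence interval for D (min)."""
        from scipy import stats

        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo_s, hi_s = self.slope - z * self.slope_se, self.slope + z * self.slope_se
        bounds = sorted(
            (-1.0 / s) if s < 0 else math.inf for s in (lo_s, hi_s)
        )
        return bounds[0], bounds[1]

    def summary(self) -> str:
        lines = [
            "Thermal inactivation (log-linear survivor fit)",
            f"  window          : {self.window[0]:g} - {self.window[1]:g} min",
            f"  points used     : {self.n_points}"
            + (f" ({self.n_excluded_zero} zero-germination points excluded)"
               if self.n_excluded_zero else ""),
            f"  slope           : {self.slope:.4f} log10(%)/min (se {self.slope_se:.4f})",
        ]
        if self.finite_d:
            lines.append(f"  D-value         : {self.d_min:.3g} min")
        else:
            lines.append("  D-value         : not finite (no inactivation in window)")
        return "\n".join(lines)


class ThermalInactivationModel:
    """OLS of log10(germination %) against time inside a decay window.

    The window is user-supplied rather than found automatically: activation
    and inactivation phases must be separated by the analyst, since typical
    series have too few points for a robust change-point search.  Points with
    zero germination cannot enter a log fit and are excluded with a warning.
    """

    def __init__(self, table: SurvivalTable, window: tuple[float, float]):
        self.table = table
        self.window = (float(window[0]), float(window[1]))
        if self.window[0] >= self.window[1]:
            raise ValueError("window must satisfy lo < hi")

    def fit(self) -> DValueResults:
        t, g = self.table.times, self.table.germination
        in_win = (t >= self.window[0]) & (t <= self.window[1])
        zero = in_win & (g <= 0)
        use = in_win & (g > 0)
        n_zero = int(zero.sum())
        if n_zero:
            warnings.warn(
                f"excluded {n_zero} zero-germination point(s) from the log fit",
                stacklevel=2,
            )
        if use.sum() < 2:
            raise ValueError(
                f"need >= 2 points with germination > 0 in window {self.window}, "
                f"got {int(use.sum())}"
            )
        y = np.log10(g[use])
        X = sm.add_constant(t[use])
        res = sm.OLS(y, X).fit()
        intercept, slope = res.params
        slope_se = res.bse[1] if np.isfinite(res.bse[1]) else 0.0
        d = -1.0 / slope if slope < -1e-12 else math.inf
        return DValueResults(
            d_min=d,
            slope=float(slope),
            intercept=float(intercept),
            slope_se=float(slope_se),
            n_points=int(use.sum()),
            n_excluded_zero=n_zero,
            window=self.window,
        )


def d_value(table: SurvivalTable, window: tuple[float, float]) -> float:
    """Decimal reduction time in minutes (``inf`` if non-inactivating)."""
    return ThermalInactivationModel(table, window).fit().d_min


def survival_summary(tables: Sequence[SurvivalTable]) -> pd.DataFrame:
    """Per-treatment summary: activation maximum, terminal survival, decay flag.

    ``finite_d`` reports whether a log-linear fit from the time of maximal
    germination to the end of the series yields a finite D (it is left
    missing when fewer than two usable points remain).
    """
    if not len(tables):
        raise ValueError("need at least one survival table")
    rows = []
    for tab in tables:
        i_max = int(np.argmax(tab.germination))
        finite = None
        try:
            res = ThermalInactivationModel(
                tab, (tab.times[i_max], tab.times[-1])
            ).fit()
            finite = res.finite_d
        except ValueError:
            pass
        rows.append(
            {
                "treatment": tab.metadata.get("treatment", ""),
                "max_germination_pct": float(tab.germination[i_max]),
                "time_of_max_min": float(tab.times[i_max]),
                "terminal_germination_pct": float(tab.germination[-1]),
                "finite_d": finite,
            }
        )
    return pd.DataFrame(rows)
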