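"""Glass-transition analysis of temperature-series infrared spectra.

Dried sugar glasses are followed through a heat/cool/heat temperature ramp
while the OH-stretch band (3000-3600 cm^-1) is recorded.  The band position,
taken at 75% of the baseline-corrected peak height, moves linearly with
temperature but with distinct slopes below and above the glass transition:
hydrogen bonds loosen slowly in the solid-like glass and quickly in the
liquid.  Fitting one regression line to each regime and intersecting them
gives the glass transition temperature T_g; the slope itself is the
wavenumber-temperature coefficient (WTC, cm^-1 per degC), a measure of
hydrogen-bond strength (lower WTC = denser glass).

Crystallization (e.g. of mannitol) replaces the broad amorphous band with a
sharp peak near 3250 cm^-1 and invalidates the regression; it is detected
from band sharpening and flagged so no T_g is reported for affected scans.

Workflow: :func:`band_position_series` turns a
:class:`~sporeglass.spectra.SpectrumSeries` into positions;
:class:`GlassTransitionModel` fits the two-segment regression and its
:meth:`~GlassTransitionModel.fit` returns :class:`GlassTransitionResults`;
:func:`analyze_protocol` runs the whole heat1/heat2 protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .spectra import Spectrum, SpectrumSeries, SpectrumContentError, crop

__all__ = [
    "DEFAULT_REGION",
    "BandShapeError",
    "BandPositionSeries",
    "GlassTransitionModel",
    "GlassTransitionResults",
    "CrystallizationReport",
    "ScanResult",
    "band_position",
    "band_fwhm",
    "band_position_series",
    "fit_two_segment",
    "wtc_of",
    "detect_crystallization",
    "analyze_protocol",
]

DEFAULT_REGION = (3000.0, 3600.0)


class BandShapeError(ValueError):
    """The analysed region does not contain a usable single band."""


class DegenerateFitError(ValueError):
    """The two segments are indistinguishable (collinear data)."""


class FitQualityError(ValueError):
    """The regression intersection falls far outside the data range."""


# ---------------------------------------------------------------------------
# Band position
# ---------------------------------------------------------------------------

def _baseline_corrected(s: Spectrum, region: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    c = crop(s, region[0], region[1])
    x, y = c.axis, c.intensity
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    return x, y - baseline


def _level_crossings(x: np.ndarray, y: np.ndarray, level: float, i_peak: int) -> tuple[float, float]:
    """Outermost flank crossings of ``level`` on either side of the peak."""
    left = None
    for i in range(i_peak, 0, -1):
        if y[i - 1] < level <= y[i]:
            f = (level - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + f * (x[i] - x[i - 1])
            break
    right = None
    for i in range(i_peak, x.size - 1):
        if y[i] >= level > y[i + 1]:
            f = (y[i] - level) / (y[i] - y[i + 1])
            right = x[i] + f * (x[i + 1] - x[i])
            break
    if left is None or right is None:
        raise BandShapeError(
            f"band does not cross the {level:.3g} level on both flanks"
        )
    return left, right


def band_position(
    s: Spectrum,
    region: tuple[float, float] = DEFAULT_REGION,
    n_contour: int = 50,
    level_fraction: float = 0.75,
) -> float:
    """Band position as the mean of ``n_contour`` points at 75% peak height.

    The region is baseline-corrected by a straight line between its
    endpoints, the 75%-of-maximum contour level is intersected with both
    flanks by linear interpolation, and the position is the mean wavenumber
    of ``n_contour`` points placed uniformly across the contour — which is
    the midpoint of the two flank crossings.
    """
    x, yc = _baseline_corrected(s, region)
    i_peak = int(np.argmax(yc))
    if i_peak in (0, x.size - 1):
        raise BandShapeError("band maximum lies at the edge of the region")
    peak = yc[i_peak]
    if peak <= 0:
        raise BandShapeError("no band above the baseline in the region")
    left, right = _level_crossings(x, yc, level_fraction * peak, i_peak)
    contour = np.linspace(left, right, max(int(n_contour), 2))
    return float(contour.mean())


def band_fwhm(s: Spectrum, region: tuple[float, float] = DEFAULT_REGION) -> float:
    """Full width at half the baseline-corrected peak height, cm^-1."""
    x, yc = _baseline_corrected(s, region)
    i_peak = int(np.argmax(yc))
    if i_peak in (0, x.size - 1) or yc[i_peak] <= 0:
        raise BandShapeError("no interior band in the region")
    left, right = _level_crossings(x, yc, 0.5 * yc[i_peak], i_peak)
    return float(right - left)


@dataclass
class BandPositionSeries:
    """Band position per spectrum of a temperature series."""

    temperatures: np.ndarray
    positions: np.ndarray
    scan_labels: list[str]

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.scan_labels = list(self.scan_labels)
        if not (
            self.temperatures.size == self.positions.size == len(self.scan_labels)
        ):
            raise ValueError("temperatures, positions, scan_labels must align")

    def __len__(self) -> int:
        return self.temperatures.size

    def select(self, scan_label: str) -> "BandPositionSeries":
        idx = [i for i, s in enumerate(self.scan_labels) if s == scan_label]
        return BandPositionSeries(
            self.temperatures[idx], self.positions[idx],
            [self.scan_labels[i] for i in idx],
        )


def band_position_series(
    series: SpectrumSeries,
    region: tuple[float, float] = DEFAULT_REGION,
    n_contour: int = 50,
) -> BandPositionSeries:
    """Band position for every spectrum; failures name the offending
    temperature."""
    positions = []
    for spec, temp in zip(series.spectra, series.temperatures):
        try:
            positions.append(band_position(spec, region, n_contour))
        except (BandShapeError, SpectrumContentError) as exc:
            raise BandShapeError(
                f"band position failed at temperature {temp:g} degC: {exc}"
            ) from exc
    return BandPositionSeries(series.temperatures, np.array(positions), series.scan_labels)


# ---------------------------------------------------------------------------
# Two-segment regression
# ---------------------------------------------------------------------------

@dataclass
class GlassTransitionResults:
    """Two-segment regression of band position against temperature.

    ``tg`` is the temperature where the lower- and upper-segment regression
    lines cross; slopes are the WTC of each regime.  Standard errors come
    from the per-segment OLS fits.
    """

    tg: float
    slope_lower: float
    slope_upper: float
    intercept_lower: float
    intercept_upper: float
    slope_lower_se: float
    slope_upper_se: float
    breakpoint_index: int
    sse: float
    n_lower: int
    n_upper: int

    def wtc(self, segment: str = "above_tg") -> float:
        """Wavenumber-temperature coefficient of one regime (cm^-1/degC)."""
        if segment == "above_tg":
            return self.slope_upper
        if segment == "below_tg":
            return self.slope_lower
        raise ValueError("segment must be 'above_tg' or 'below_tg'")

    def summary(self) -> str:
        return "\n".join(
            [
                "Glass transition (two-segment band-position regression)",
                f"  T_g                : {self.tg:.2f} degC",
                f"  WTC below T_g      : {self.slope_lower:.4f} "
                f"+/- {self.slope_lower_se:.4f} cm^-1/degC ({self.n_lower} pts)",
                f"  WTC above T_g      : {self.slope_upper:.4f} "
                f"+/- {self.slope_upper_se:.4f} cm^-1/degC ({self.n_upper} pts)",
                f"  pooled SSE         : {self.sse:.4g}",
            ]
        )

    def plot(self, bp: "BandPositionSeries | None" = None, ax=None):
        """Band positions with the two regression lines and their crossing."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if bp is not None:
            ax.plot(bp.temperatures, bp.positions, "o", ms=4, label="band position")
            lo_t = np.array([bp.temperatures.min(), self.tg])
            hi_t = np.array([self.tg, bp.temperatures.max()])
        else:
            lo_t = np.array([self.tg - 50.0, self.tg])
            hi_t = np.array([self.tg, self.tg + 30.0])
        ax.plot(lo_t, self.intercept_lower + self.slope_lower * lo_t, "-", label="glass")
        ax.plot(hi_t, self.intercept_upper + self.slope_upper * hi_t, "-", label="liquid")
        ax.axvline(self.tg, ls=":", color="k")
        ax.set_xlabel("temperature (degC)")
        ax.set_ylabel("OH-stretch band position (cm$^{-1}$)")
        ax.legend()
        return ax


class GlassTransitionModel:
    """Breakpoint search over all splits with >= ``min_segment`` points/side.

    Each candidate split fits independent OLS lines to the lower- and
    upper-temperature subsets; the split minimizing pooled SSE wins, with
    ties broken toward the split nearest the median temperature.  The data
    are sorted by temperature first, so cooling scans fit identically to
    heating scans.
    """

    def __init__(
        self,
        temperatures: Sequence[float],
        positions: Sequence[float],
        min_segment: int = 4,
    ):
        t = np.asarray(temperatures, dtype=float)
        y = np.asarray(positions, dtype=float)
        if t.size != y.size:
            raise ValueError("temperatures and positions must have equal length")
        if t.size < 2 * min_segment:
            raise ValueError(
                f"need >= {2 * min_segment} points spanning both regimes, got {t.size}"
            )
        order = np.argsort(t, kind="stable")
        self.temperatures = t[order]
        self.positions = y[order]
        self.min_segment = int(min_segment)

    @classmethod
    def from_band_positions(cls, bp: BandPositionSeries, **kw) -> "GlassTransitionModel":
        return cls(bp.temperatures, bp.positions, **kw)

    @staticmethod
    def _ols_sse(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        """(slope, intercept, sse) by least squares."""
        A = np.column_stack([t, np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        return float(coef[0]), float(coef[1]), float(resid @ resid)

    def fit(self) -> GlassTransitionResults:
        t, y = self.temperatures, self.positions
        n, k = t.size, self.min_segment
        best: tuple[float, float, int] | None = None  # (sse, median_dist, split)
        t_median = float(np.median(t))
        for split in range(k, n - k + 1):
            _, _, sse_lo = self._ols_sse(t[:split], y[:split])
            _, _, sse_hi = self._ols_sse(t[split:], y[split:])
            sse = sse_lo + sse_hi
            dist = abs(float(t[split - 1] + t[split]) / 2.0 - t_median)
            cand = (sse, dist, split)
            if best is None or cand[:2] < best[:2]:
                best = cand
        assert best is not None
        split = best[2]

        lo = sm.OLS(y[:split], sm.add_constant(t[:split])).fit()
        hi = sm.OLS(y[split:], sm.add_constant(t[split:])).fit()
        b1, m1 = lo.params
        b2, m2 = hi.params
        if abs(m1 - m2) < 1e-6:
            raise DegenerateFitError(
                f"segment slopes equal within 1e-6 ({m1:.6g} vs {m2:.6g}): "
                "data are collinear"
            )
        tg = float((b2 - b1) / (m1 - m2))
        if not (t[0] - 20.0 <= tg <= t[-1] + 20.0):
            raise FitQualityError(
                f"regression intersection {tg:.1f} degC lies outside "
                f"[{t[0] - 20:.1f}, {t[-1] + 20:.1f}]"
            )
        se = lambda res: float(res.bse[1]) if np.all(np.isfinite(res.bse)) else 0.0
        return GlassTransitionResults(
            tg=tg,
            slope_lower=float(m1),
            slope_upper=float(m2),
            intercept_lower=float(b1),
            intercept_upper=float(b2),
            slope_lower_se=se(lo),
            slope_upper_se=se(hi),
            breakpoint_index=split,
            sse=float(best[0]),
            n_lower=split,
            n_upper=n - split,
        )


def fit_two_segment(bp: BandPositionSeries, min_segment: int = 4) -> GlassTransitionResults:
    """Two-segment regression of a band-position series (see
    :class:`GlassTransitionModel`)."""
    return GlassTransitionModel.from_band_positions(bp, min_segment=min_segment).fit()


def wtc_of(fit: GlassTransitionResults, segment: str = "above_tg") -> float:
    """WTC of the chosen regime; the liquid-side slope by default."""
    return fit.wtc(segment)


# ---------------------------------------------------------------------------
# Crystallization
# ---------------------------------------------------------------------------

@dataclass
class CrystallizationReport:
    crystallized: bool
    onset: float | None  # degC
    onset_scan: str | None


def detect_crystallization(
    series: SpectrumSeries,
    region: tuple[float, float] = DEFAULT_REGION,
    fwhm_ratio: float = 0.6,
    subpeak_region: tuple[float, float] = (3200.0, 3300.0),
    subpeak_max_width: float = 60.0,
    subpeak_prominence: float = 0.15,
) -> CrystallizationReport:
    """Flag the sharp crystalline peak replacing the broad amorphous band.

    Two detectors run per spectrum, in acquisition order: (a) the band FWHM
    falling below ``fwhm_ratio`` times the first spectrum's FWHM, and (b) a
    resolved sub-peak narrower than ``subpeak_max_width`` cm^-1 appearing
    within ``subpeak_region`` with prominence at least ``subpeak_prominence``
    of the band maximum.  The onset is the temperature of the first spectrum
    either detector fires on.
    """
    from scipy.signal import find_peaks, peak_widths

    if len(series) < 2:
        raise ValueError("need at least 2 spectra")
    fwhm0 = None
    for i, (spec, temp, scan) in enumerate(
        zip(series.spectra, series.temperatures, series.scan_labels)
    ):
        w = None
        try:
            w = band_fwhm(spec, region)
        except BandShapeError:
            pass
        if w is not None:
            if fwhm0 is None:
                fwhm0 = w
            elif i > 0 and w < fwhm_ratio * fwhm0:
                return CrystallizationReport(True, float(temp), scan)
        # sub-peak detector in the crystalline window
        x, yc = _baseline_corrected(spec, region)
        mask = (x >= subpeak_region[0]) & (x <= subpeak_region[1])
        if mask.sum() >= 5:
            idx = np.flatnonzero(mask)
            seg = yc[idx]
            peaks, props = find_peaks(seg, prominence=subpeak_prominence * yc.max())
            if peaks.size:
                dx = float(np.mean(np.diff(x[idx])))
                widths = peak_widths(seg, peaks, rel_height=0.5)[0] * dx
                if np.any(widths < subpeak_max_width):
                    return CrystallizationReport(True, float(temp), scan)
    return CrystallizationReport(False, None, None)


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Table-style record for one sample's heat1/heat2 protocol.

    T_g and WTC values are ``None`` for scans invalidated by
    crystallization — no regression line exists for a crystalline sample.
    """

    tg1: float | None
    wtc1: float | None
    tg2: float | None
    wtc2: float | None
    crystallized: bool
    crystallization_onset: float | None
    fits: dict

    def summary(self) -> str:
        fmt = lambda v, spec: ("n.d." if v is None else format(v, spec))
        lines = [
            "Glass-transition protocol (heat1 / heat2)",
            f"  T_g1 : {fmt(self.tg1, '.1f')} degC   WTC_1: {fmt(self.wtc1, '.3f')} cm^-1/degC",
            f"  T_g2 : {fmt(self.tg2, '.1f')} degC   WTC_2: {fmt(self.wtc2, '.3f')} cm^-1/degC",
            f"  crystallized: {self.crystallized}"
            + (f" (onset {self.crystallization_onset:g} degC)" if self.crystallized else ""),
        ]
        return "\n".join(lines)


def analyze_protocol(
    series: SpectrumSeries,
    region: tuple[float, float] = DEFAULT_REGION,
    wtc_segment: str = "above_tg",
    **crystallization_kw,
) -> ScanResult:
    """T_g and WTC from the first and second heating scans of a protocol.

    Requires ``heat1`` and ``heat2`` scans (``cool`` optional).
    Crystallization is checked scan by scan in acquisition order; once a scan
    crystallizes, that scan and all later ones report no T_g/WTC.
    """
    labels = set(series.scan_labels)
    if "heat1" not in labels or "heat2" not in labels:
        raise SpectrumContentError(
            f"protocol needs scans 'heat1' and 'heat2'; found {sorted(labels)}"
        )
    ordered = [lab for lab in ("heat1", "cool", "heat2") if lab in labels]
    crystallized_from: int | None = None
    report = CrystallizationReport(False, None, None)
    for i, lab in enumerate(ordered):
        sub = series.select(lab)
        if len(sub) < 2:
            continue
        rep = detect_crystallization(sub, region, **crystallization_kw)
        if rep.crystallized:
            crystallized_from = i
            report = rep
            break

    fits: dict = {}

    def fit_scan(lab: str):
        if crystallized_from is not None and ordered.index(lab) >= crystallized_from:
            return None
        bp = band_position_series(series.select(lab), region)
        res = fit_two_segment(bp)
        fits[lab] = res
        return res

    r1 = fit_scan("heat1")
    r2 = fit_scan("heat2")
    return ScanResult(
        tg1=None if r1 is None else r1.tg,
        wtc1=None if r1 is None else r1.wtc(wtc_segment),
        tg2=None if r2 is None else r2.tg,
        wtc2=None if r2 is None else r2.wtc(wtc_segment),
        crystallized=report.crystallized,
        crystallization_onset=report.onset,
        fits=fits,
    )
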