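"""Compatible-solute quantification from chromatograms and spore geometry.

Per-spore solute masses come from HPLC peak areas via linear calibration
curves; intracellular molarities follow by dividing the per-spore mass by
the cytoplasmic volume computed from the spore's measured dimensions
(sphere for *Neosartorya fischeri*, prolate spheroid for *Talaromyces
macrosporus*, cell wall excluded).  Composition proportions express the four
trehalose-family sugars (trehalose and its tri-/tetra-/penta-saccharide
extensions) as percentages of their summed amount.

Unit conventions: spore dimensions in micrometres, volumes in femtolitres
(1 um^3 = 1 fl), per-spore masses in picograms, molar masses in g/mol,
concentrations in millimolar.  Calibration curves relate detector peak area
to extract concentration in mg/ml; extract volumes are in ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .spectra import Spectrum, SpectrumContentError

__all__ = [
    "MOLAR_MASSES",
    "SporeGeometry",
    "AnalyteDef",
    "CalibrationCurve",
    "CalibrationModel",
    "SoluteQuantity",
    "cytoplasmic_volume",
    "mass_to_molarity",
    "fit_calibration",
    "integrate_peaks",
    "quantify_sample",
    "composition_proportions",
    "CompositionProportions",
]

#: Anhydrous molar masses (g/mol) of the analyte panel.
MOLAR_MASSES = {
    "glycerol": 92.09,
    "glucose": 180.16,
    "mannitol": 182.17,
    "trehalose": 342.30,
    "isobemisiose": 504.44,
    "neosartose": 666.58,
    "fischerose": 828.72,
}

#: The four trehalose-family sugars entering composition proportions.
TOS_PANEL = ("trehalose", "isobemisiose", "neosartose", "fischerose")


@dataclass
class SporeGeometry:
    """Wall-excluded protoplast dimensions of an ascospore.

    ``sphere``: ``semi_axis_a`` is the radius.  ``prolate_spheroid``:
    ``semi_axis_a`` is the long semi-axis, ``semi_axis_b`` the short one.
    ``wall_thickness`` is documentation only — dimensions already exclude
    the wall.
    """

    shape: str  # "sphere" | "prolate_spheroid"
    semi_axis_a: float  # um
    semi_axis_b: float | None = None  # um, prolate only
    wall_thickness: float | None = None  # um, informational

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "prolate_spheroid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.semi_axis_a <= 0:
            raise ValueError("semi_axis_a must be positive")
        if self.shape == "prolate_spheroid":
            if self.semi_axis_b is None or self.semi_axis_b <= 0:
                raise ValueError("prolate_spheroid needs a positive semi_axis_b")


def cytoplasmic_volume(g: SporeGeometry) -> float:
    """Cytoplasmic volume in femtolitres.

    Sphere: V = (4/3) pi r^3.  Prolate spheroid: V = (4/3) pi a b^2 with a
    the long and b the short semi-axis.  1 um^3 = 1 fl.
    """
    if g.shape == "sphere":
        return 4.0 / 3.0 * math.pi * g.semi_axis_a**3
    return 4.0 / 3.0 * math.pi * g.semi_axis_a * g.semi_axis_b**2


def mass_to_molarity(pg_per_spore: float, molar_mass: float, volume_fl: float) -> float:
    """Millimolar concentration of ``pg_per_spore`` picograms dissolved in
    ``volume_fl`` femtolitres.

    mM = (pg / (g/mol)) / fl * 1e6, since 1 pg / 1 fl = 1 g/l.
    """
    if pg_per_spore < 0:
        raise ValueError("pg_per_spore must be non-negative")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    if volume_fl <= 0:
        raise SpectrumContentError("volume must be positive")
    return pg_per_spore / molar_mass / volume_fl * 1e6


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class AnalyteDef:
    name: str
    molar_mass: float  # g/mol
    retention_window: tuple[float, float]  # min

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if not self.retention_window[0] < self.retention_window[1]:
            raise ValueError("retention_window must be a non-empty interval")


@dataclass
class CalibrationCurve:
    """Linear detector response: area = slope * concentration + intercept."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def invert(self, area: float) -> float:
        """Concentration for a peak area (may be negative below the LOQ)."""
        return (area - self.intercept) / self.slope


class CalibrationModel:
    """Unweighted OLS of peak area against standard concentration.

    Refractive-index detection is linear over the dilute standard range, so
    a free-intercept straight line with equal weights is fitted.
    """

    def __init__(self, concentrations, areas, analyte: str = ""):
        c = np.asarray(concentrations, dtype=float)
        a = np.asarray(areas, dtype=float)
        if c.size != a.size:
            raise ValueError("concentrations and areas must have equal length")
        if np.any(c < 0):
            raise ValueError("standard concentrations must be non-negative")
        if np.unique(c).size < 2:
            raise ValueError("need at least 2 distinct standard concentrations")
        self.concentrations = c
        self.areas = a
        self.analyte = analyte

    def fit(self) -> CalibrationCurve:
        res = sm.OLS(self.areas, sm.add_constant(self.concentrations)).fit()
        intercept, slope = res.params
        r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 1.0
        return CalibrationCurve(
            analyte=self.analyte,
            slope=float(slope),
            intercept=float(intercept),
            r_squared=min(max(r2, 0.0), 1.0),
        )


def fit_calibration(standards, analyte: str = "") -> CalibrationCurve:
    """Fit a calibration line from ``(concentration, peak_area)`` pairs."""
    standards = list(standards)
    conc = [s[0] for s in standards]
    area = [s[1] for s in standards]
    return CalibrationModel(conc, area, analyte).fit()


# ---------------------------------------------------------------------------
# Peak integration
# ---------------------------------------------------------------------------

def integrate_peaks(chrom: Spectrum, analytes: list[AnalyteDef]) -> dict[str, float]:
    """Trapezoidal peak area above a local linear baseline per analyte window.

    The baseline is the straight line between the chromatogram values at the
    window endpoints.  Windows must not overlap and must lie inside the time
    axis.
    """
    windows = sorted(
        ((a.retention_window, a.name) for a in analytes), key=lambda w: w[0][0]
    )
    for (w1, n1), (w2, n2) in zip(windows, windows[1:]):
        if w2[0] < w1[1]:
            raise ValueError(
                f"retention windows of {n1!r} {w1} and {n2!r} {w2} overlap"
            )
    t = chrom.axis
    areas: dict[str, float] = {}
    for a in analytes:
        lo, hi = a.retention_window
        if lo < t[0] or hi > t[-1]:
            raise SpectrumContentError(
                f"window {a.retention_window} of {a.name!r} outside the time axis "
                f"[{t[0]:g}, {t[-1]:g}]"
            )
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 2:
            raise SpectrumContentError(
                f"window of {a.name!r} covers fewer than 2 samples"
            )
        x = t[mask]
        y = chrom.intensity[mask]
        baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        areas[a.name] = float(np.trapezoid(y - baseline, x))
    return areas


# ---------------------------------------------------------------------------
# Sample quantification
# ---------------------------------------------------------------------------

@dataclass
class SoluteQuantity:
    """Per-spore mass and intracellular molarity of one analyte."""

    analyte: str
    peak_area: float
    pg_per_spore: float
    concentration_mM: float
    below_loq: bool = False


def quantify_sample(
    chrom: Spectrum,
    curves: dict[str, CalibrationCurve],
    analytes: list[AnalyteDef],
    spores_in_sample: float,
    extract_volume_ml: float,
    geometry: SporeGeometry,
    loq_mg_ml: float = 1e-9,
) -> list[SoluteQuantity]:
    """Full chain: integrate -> invert calibration -> per-spore mass -> mM.

    Calibration concentrations are in mg/ml of extract; the extract mass is
    concentration x ``extract_volume_ml`` and is divided over
    ``spores_in_sample`` spores.  Concentrations at or below ``loq_mg_ml``
    (a numerical floor far beneath any real detector's quantification
    limit) yield zero with ``below_loq`` set.
    """
    if spores_in_sample <= 0:
        raise SpectrumContentError("spores_in_sample must be positive")
    if extract_volume_ml <= 0:
        raise SpectrumContentError("extract_volume_ml must be positive")
    for a in analytes:
        if a.name not in curves:
            raise ValueError(f"no calibration curve for analyte {a.name!r}")
    areas = integrate_peaks(chrom, analytes)
    volume_fl = cytoplasmic_volume(geometry)
    out = []
    for a in analytes:
        area = areas[a.name]
        conc_mg_ml = curves[a.name].invert(area)
        below = conc_mg_ml <= loq_mg_ml
        conc_mg_ml = 0.0 if below else conc_mg_ml
        mass_mg = conc_mg_ml * extract_volume_ml
        pg = mass_mg * 1e9 / spores_in_sample
        out.append(
            SoluteQuantity(
                analyte=a.name,
                peak_area=area,
                pg_per_spore=pg,
                concentration_mM=mass_to_molarity(pg, a.molar_mass, volume_fl),
                below_loq=below,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Composition proportions
# ---------------------------------------------------------------------------

@dataclass
class CompositionProportions:
    """Sugar composition as fractions (sum exactly 1) and display percents."""

    fractions: dict[str, float]
    percents: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.percents = {k: round(100.0 * v) for k, v in self.fractions.items()}


def composition_proportions(amounts: dict[str, float]) -> CompositionProportions:
    """Proportion of each trehalose-family sugar as % of their total.

    ``amounts`` maps the four sugar names (trehalose, isobemisiose,
    neosartose, fischerose) to amounts in any common unit; mannitol and
    other solutes are outside the normalization.  Missing sugars count as
    zero; an all-zero panel is an error.
    """
    amts = {}
    for name in TOS_PANEL:
        v = float(amounts.get(name, 0.0))
        if v < 0:
            raise ValueError(f"negative amount for {name!r}")
        amts[name] = v
    unknown = set(amounts) - set(TOS_PANEL)
    if unknown:
        raise ValueError(f"unknown sugars in amounts: {sorted(unknown)}")
    total = sum(amts.values())
    if total <= 0:
        raise ValueError("at least one sugar amount must be positive")
    return CompositionProportions({k: v / total for k, v in amts.items()})
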