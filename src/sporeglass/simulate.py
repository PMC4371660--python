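"""Seeded simulators for the instrument data the analysis stages consume.

Four generators emulate the statistical structure of the measurements made on
heat-resistant ascospores and their sugar glasses:

* FTIR temperature series — a Gaussian OH-stretch band whose centre moves
  piecewise-linearly with temperature around the glass transition, with an
  optional sharp crystallization peak appearing above an onset temperature;
* ESR spin-probe spectra — a narrow first-derivative nitroxide triplet
  (intracellular probe) superposed on a broadened triplet (extracellular,
  quencher-broadened background), built by inverting the line-width/height
  relation so a prescribed rotational correlation time is the ground truth;
* HPLC chromatograms — Gaussian component peaks on a drifting linear
  baseline;
* thermal survival series — heat-activation followed by first-order
  (log-linear) inactivation, with binomial counting noise.

All generators are pure functions of their parameters and an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra import Spectrum, SpectrumSeries, SpectrumContentError
from .thermal import SurvivalTable

__all__ = [
    "CrystallizationParams",
    "GlassModelParams",
    "EsrSimParams",
    "ChromComponent",
    "ChromSimParams",
    "ThermalSimParams",
    "band_centre_model",
    "position_noise_to_absorbance",
    "generate_ftir_series",
    "generate_ftir_protocol",
    "lorentzian_derivative",
    "esr_components",
    "generate_esr_spectrum",
    "generate_chromatogram",
    "generate_survival_series",
    "KIVELSON_K",
]

#: Kivelson proportionality constant for the fast-motion nitroxide regime,
#: in seconds per gauss of low-field peak-to-peak width.
KIVELSON_K = 6.5e-10


# ---------------------------------------------------------------------------
# FTIR glass model
# ---------------------------------------------------------------------------

@dataclass
class CrystallizationParams:
    """Additive sharp crystalline band appearing at and above ``onset``."""

    onset: float  # degC
    centre: float = 3250.0  # cm^-1
    fwhm: float = 40.0  # cm^-1
    amplitude: float = 0.8  # absorbance, relative to unit amorphous band


@dataclass
class GlassModelParams:
    """Two-slope band-position model for an amorphous sugar glass.

    The OH-stretch band centre follows

        nu(T) = nu_tg + wtc_glass * (T - tg)   for T <  tg
        nu(T) = nu_tg + wtc_liquid * (T - tg)  for T >= tg

    with ``wtc_liquid > wtc_glass > 0``: hydrogen bonds loosen faster with
    temperature once the glass has melted.  Defaults mirror a trehalose-like
    glass (transition near 108 degC, liquid-side coefficient 0.272 cm^-1/degC)
    scanned from -10 to 140 degC in 2 degC steps.
    """

    tg: float = 108.0  # degC
    wtc_glass: float = 0.06  # cm^-1 per degC, below tg
    wtc_liquid: float = 0.272  # cm^-1 per degC, above tg
    nu_tg: float = 3320.0  # band centre at tg, cm^-1
    band_fwhm: float = 180.0  # cm^-1
    band_amplitude: float = 1.0  # absorbance
    noise_sd: float = 0.0  # absorbance units, per point
    temperatures: Sequence[float] = field(
        default_factory=lambda: np.arange(-10.0, 140.0 + 1e-9, 2.0)
    )
    crystallization: CrystallizationParams | None = None
    region: tuple[float, float] = (3000.0, 3600.0)  # cm^-1
    grid_step: float = 2.0  # cm^-1

    def __post_init__(self) -> None:
        if not (self.wtc_liquid > self.wtc_glass > 0):
            raise ValueError("need wtc_liquid > wtc_glass > 0")
        if self.band_fwhm <= 0:
            raise ValueError("band_fwhm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def band_centre_model(p: GlassModelParams, temperature: float) -> float:
    """Noise-free band centre nu(T) of the two-slope glass model."""
    slope = p.wtc_glass if temperature < p.tg else p.wtc_liquid
    return p.nu_tg + slope * (temperature - p.tg)


def _gaussian(x: np.ndarray, centre: float, fwhm: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-4.0 * math.log(2.0) * (x - centre) ** 2 / fwhm**2)


def position_noise_to_absorbance(p: GlassModelParams, position_sd: float) -> float:
    """Absorbance noise that propagates to ~``position_sd`` cm^-1 of band-position
    scatter.

    The band position is the midpoint of the two 75%-level flank crossings.
    Each crossing moves by ``noise / |slope|`` where the slope is that of the
    Gaussian flank at 75% height; averaging two independent crossings divides
    the scatter by sqrt(2).
    """
    x75 = p.band_fwhm * math.sqrt(math.log(4.0 / 3.0) / (4.0 * math.log(2.0)))
    flank_slope = (
        8.0 * math.log(2.0) * x75 / p.band_fwhm**2 * 0.75 * p.band_amplitude
    )
    return position_sd * flank_slope * math.sqrt(2.0)


def generate_ftir_series(
    p: GlassModelParams, seed: int, scan_label: str = "heat1"
) -> SpectrumSeries:
    """One Gaussian-band spectrum per temperature on a shared wavenumber grid."""
    temps = np.asarray(p.temperatures, dtype=float)
    if temps.size == 0:
        raise SpectrumContentError("temperatures must not be empty")
    rng = np.random.default_rng(seed)
    grid = np.arange(p.region[0], p.region[1] + 1e-9, p.grid_step)
    spectra = []
    for t in temps:
        y = _gaussian(grid, band_centre_model(p, t), p.band_fwhm, p.band_amplitude)
        c = p.crystallization
        if c is not None and t >= c.onset:
            y = y + _gaussian(grid, c.centre, c.fwhm, c.amplitude)
        if p.noise_sd > 0:
            y = y + rng.normal(0.0, p.noise_sd, size=grid.size)
        spectra.append(
            Spectrum(
                grid.copy(),
                y,
                "wavenumber_cm-1",
                {"temperature_C": float(t), "scan": scan_label},
            )
        )
    return SpectrumSeries(spectra, temps, [scan_label] * temps.size)


def generate_ftir_protocol(
    heat1: GlassModelParams,
    heat2: GlassModelParams,
    seed: int,
    cool: GlassModelParams | None = None,
) -> SpectrumSeries:
    """Full heat/cool/heat measurement protocol as one ordered series.

    ``heat1`` and ``heat2`` typically differ in ``tg`` (the first heating
    matures the glass, raising its transition).  If ``cool`` is omitted, the
    cooling scan reuses the ``heat2`` parameters with reversed temperatures.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    parts = [generate_ftir_series(heat1, int(seeds[0]), "heat1")]
    if cool is None:
        cool_p = GlassModelParams(**{**heat2.__dict__})
        cool_p.temperatures = np.asarray(heat2.temperatures, dtype=float)[::-1]
        cool = cool_p
    parts.append(generate_ftir_series(cool, int(seeds[1]), "cool"))
    parts.append(generate_ftir_series(heat2, int(seeds[2]), "heat2"))
    return SpectrumSeries.concat(parts)


# ---------------------------------------------------------------------------
# ESR nitroxide triplet
# ---------------------------------------------------------------------------

@dataclass
class ExtracellularParams:
    """Quencher-broadened extracellular triplet sharing the narrow line positions."""

    line_width: float = 5.0  # gauss, peak-to-peak
    relative_amplitude: float = 0.8  # peak-to-peak height / narrow amplitude


@dataclass
class EsrSimParams:
    """First-derivative three-line nitroxide spectrum with a broad background.

    The narrow triplet realizes a prescribed rotational correlation time
    ``tau_c`` by inverting the fast-motion line-width relation: with equal
    integrated line intensities the derivative peak-to-peak height scales as
    width^-2, so setting the high-field width to
    ``dW_plus1 * sqrt(h_ratio)`` with
    ``h_ratio = (tau_c / (K * dW_plus1) + 1)**2`` reproduces the height
    asymmetry from which the analysis recovers ``tau_c``.
    """

    tau_c: float = 4.3e-10  # s
    dW_plus1: float = 1.0  # gauss, low-field peak-to-peak width
    hyperfine_splitting: float = 16.0  # gauss
    centre_field: float = 3350.0  # gauss
    narrow_amplitude: float = 1.0  # peak-to-peak height of the low-field line
    extracellular: ExtracellularParams = field(default_factory=ExtracellularParams)
    noise_sd: float = 0.0  # intensity units, per point
    field_grid: np.ndarray | None = None  # gauss; default centre +/- 3 splittings
    kivelson_k: float = KIVELSON_K

    def __post_init__(self) -> None:
        if self.tau_c < 0:
            raise ValueError("tau_c must be non-negative")
        if self.dW_plus1 <= 0 or self.hyperfine_splitting <= 0:
            raise ValueError("widths must be positive")
        if self.extracellular.line_width <= 0:
            raise ValueError("extracellular line width must be positive")
        if self.extracellular.relative_amplitude < 0:
            raise ValueError("relative_amplitude must be non-negative")
        if self.field_grid is None:
            half = 3.0 * self.hyperfine_splitting
            self.field_grid = np.arange(
                self.centre_field - half, self.centre_field + half + 1e-9, 0.05
            )
        else:
            self.field_grid = np.asarray(self.field_grid, dtype=float)

    @property
    def height_ratio(self) -> float:
        """Ground-truth h_+1 / h_-1 implied by tau_c."""
        return (self.tau_c / (self.kivelson_k * self.dW_plus1) + 1.0) ** 2

    @property
    def line_positions(self) -> tuple[float, float, float]:
        """Low-field, centre, high-field line positions in gauss."""
        a = self.hyperfine_splitting
        return (self.centre_field - a, self.centre_field, self.centre_field + a)


def lorentzian_derivative(
    field: np.ndarray, centre: float, pp_width: float, pp_height: float
) -> np.ndarray:
    """First-derivative Lorentzian line.

    ``pp_width`` is the field separation of the derivative extrema
    (= Gamma/sqrt(3) for a Lorentzian of FWHM Gamma) and ``pp_height`` the
    max-minus-min intensity.  The positive lobe sits on the low-field side,
    as in an absorption-mode ESR derivative.
    """
    gamma = math.sqrt(3.0) * pp_width / 2.0  # half width at half maximum
    x = field - centre
    # unit-area absorption Lorentzian derivative, then rescaled to pp_height
    y = -(2.0 / math.pi) * gamma * x / (x**2 + gamma**2) ** 2
    unit_pp = math.sqrt(3.0) / (math.pi * pp_width**2)  # pp height at unit area
    return y * (pp_height / unit_pp)


def _triplet(
    field: np.ndarray,
    positions: Sequence[float],
    widths: Sequence[float],
    low_field_pp_height: float,
) -> np.ndarray:
    """Three derivative Lorentzians with equal integrated intensity.

    The common line area is set so the low-field line has the requested
    peak-to-peak height; the other heights then follow the width^-2 law.
    """
    area = low_field_pp_height * math.pi * widths[0] ** 2 / math.sqrt(3.0)
    y = np.zeros_like(field)
    for pos, w in zip(positions, widths):
        pp_h = area * math.sqrt(3.0) / (math.pi * w**2)
        y = y + lorentzian_derivative(field, pos, w, pp_h)
    return y


def esr_components(p: EsrSimParams) -> tuple[Spectrum, Spectrum]:
    """Noise-free (narrow, broad) components of the simulated spectrum."""
    grid = p.field_grid
    positions = p.line_positions
    if grid[0] > positions[0] - 2 * p.dW_plus1 or grid[-1] < positions[2] + 2 * p.dW_plus1:
        raise SpectrumContentError("field_grid does not cover all three lines")
    ratio = p.height_ratio
    widths = (p.dW_plus1, p.dW_plus1, p.dW_plus1 * math.sqrt(ratio))
    narrow = _triplet(grid, positions, widths, p.narrow_amplitude)
    wb = p.extracellular.line_width
    broad = _triplet(
        grid, positions, (wb, wb, wb), p.extracellular.relative_amplitude * p.narrow_amplitude
    )
    meta = {
        "centre_field": p.centre_field,
        "hyperfine_splitting": p.hyperfine_splitting,
    }
    return (
        Spectrum(grid.copy(), narrow, "field_gauss", dict(meta)),
        Spectrum(grid.copy(), broad, "field_gauss", dict(meta)),
    )


def generate_esr_spectrum(p: EsrSimParams, seed: int) -> tuple[Spectrum, Spectrum]:
    """Simulate (total, supernatant) spectra.

    ``total`` = narrow + broad triplet + noise; ``supernatant`` = the broad
    triplet alone with independent noise, standing in for the spectrum of the
    spore-free suspension medium.
    """
    rng = np.random.default_rng(seed)
    narrow, broad = esr_components(p)
    total_y = narrow.intensity + broad.intensity
    sup_y = broad.intensity.copy()
    if p.noise_sd > 0:
        total_y = total_y + rng.normal(0.0, p.noise_sd, size=total_y.size)
        sup_y = sup_y + rng.normal(0.0, p.noise_sd, size=sup_y.size)
    total = Spectrum(p.field_grid.copy(), total_y, "field_gauss", dict(narrow.metadata))
    sup = Spectrum(p.field_grid.copy(), sup_y, "field_gauss", dict(narrow.metadata))
    return total, sup


# ---------------------------------------------------------------------------
# HPLC chromatograms
# ---------------------------------------------------------------------------

@dataclass
class ChromComponent:
    name: str
    retention_time: float  # min
    width: float  # min, Gaussian sigma
    amount: float  # arbitrary mass/concentration units
    response_factor: float = 1.0  # peak area per unit amount

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.amount < 0:
            raise ValueError("amount must be non-negative")


@dataclass
class ChromSimParams:
    components: list[ChromComponent] = field(default_factory=list)
    baseline_offset: float = 0.0
    baseline_drift: float = 0.0  # per min
    noise_sd: float = 0.0
    time_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 20.0, 0.005)
    )

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)


def generate_chromatogram(p: ChromSimParams, seed: int) -> Spectrum:
    """Sum of Gaussian peaks (area = amount x response_factor) on a linear
    baseline, plus white noise."""
    rng = np.random.default_rng(seed)
    t = p.time_grid
    y = p.baseline_offset + p.baseline_drift * t
    for c in p.components:
        area = c.amount * c.response_factor
        y = y + area / (c.width * math.sqrt(2.0 * math.pi)) * np.exp(
            -0.5 * ((t - c.retention_time) / c.width) ** 2
        )
    if p.noise_sd > 0:
        y = y + rng.normal(0.0, p.noise_sd, size=t.size)
    return Spectrum(t.copy(), y, "time_min", {"kind": "chromatogram"})


# ---------------------------------------------------------------------------
# Thermal survival
# ---------------------------------------------------------------------------

@dataclass
class ThermalSimParams:
    """Activation-then-inactivation germination model.

    Expected germination follows ``S(t) = A * (1 - exp(-k_a t)) * 10**(-t/D)``:
    dormant spores are activated at rate ``k_a`` towards plateau ``A`` while
    heat kills at one decade per ``D`` minutes.  Observed percentages are
    binomial counts out of ``binomial_n`` spores per time point.
    """

    activation_rate: float = 2.0  # per min
    plateau: float = 95.0  # % germination
    d_value: float = 12.0  # min
    times: Sequence[float] = field(default_factory=lambda: np.arange(0.0, 31.0, 2.0))
    binomial_n: int = 300

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau <= 100.0:
            raise ValueError("plateau must be in [0, 100]")
        if self.d_value <= 0:
            raise ValueError("d_value must be positive")
        if self.binomial_n < 1:
            raise ValueError("binomial_n must be >= 1")

    def expected(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.plateau
            * (1.0 - np.exp(-self.activation_rate * t))
            * 10.0 ** (-t / self.d_value)
        )


def generate_survival_series(p: ThermalSimParams, seed: int) -> SurvivalTable:
    """Binomial-sampled germination percentages at the requested times."""
    rng = np.random.default_rng(seed)
    t = np.asarray(p.times, dtype=float)
    expect = p.expected(t)
    counts = rng.binomial(p.binomial_n, np.clip(expect / 100.0, 0.0, 1.0))
    germ = 100.0 * counts / p.binomial_n
    return SurvivalTable(
        times=t,
        germination=germ,
        n_counted=np.full(t.size, p.binomial_n, dtype=int),
        metadata={"simulated_D_min": p.d_value, "simulated_plateau_pct": p.plateau},
    )
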