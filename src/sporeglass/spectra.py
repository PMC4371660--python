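"""Spectral traces and temperature-indexed series.

A :class:`Spectrum` is a single one-dimensional instrument trace: an ordered
axis (infrared wavenumber in cm^-1, ESR magnetic field in gauss, or
chromatographic time in minutes) with one intensity value per axis point and
free-form metadata.  A :class:`SpectrumSeries` bundles the spectra of a
temperature ramp, tagging each spectrum with its temperature and its position
in the heat/cool/heat measurement protocol.

Two plain-text file formats are supported: a commented CSV dialect
(``# key=value`` header lines, one column header row, comma-separated data)
and a restricted JCAMP-DX subset covering ``XYPOINTS=(XY..XY)`` and
``XYDATA=(X++(Y..Y))`` tables, which is what infrared spectrometers commonly
export.  Binary vendor formats are out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AXIS_KINDS",
    "SCAN_LABELS",
    "Spectrum",
    "SpectrumSeries",
    "SpectrumContentError",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "crop",
    "resample",
]

#: Recognized axis kinds and the default column header used for each.
AXIS_KINDS = {
    "wavenumber_cm-1": "absorbance",
    "field_gauss": "intensity",
    "time_min": "response",
}

#: Scan labels of the FTIR temperature protocol, in acquisition order.
SCAN_LABELS = ("heat1", "cool", "heat2")


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed in the declared dialect."""


class SpectrumContentError(ValueError):
    """Spectrum data violates a structural requirement."""


@dataclass
class Spectrum:
    """One spectral trace.

    Parameters
    ----------
    axis : array-like
        Strictly monotonic axis values.  Descending axes (the native FTIR
        display convention) are normalized to ascending order on
        construction, with the intensities reordered consistently.
    intensity : array-like
        One intensity per axis point.
    axis_kind : str
        One of ``wavenumber_cm-1``, ``field_gauss`` or ``time_min``.
    metadata : dict
        Free-form string-keyed metadata (sample id, temperature_C, scan,
        units ...).  Values are kept as strings or numbers.
    """

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = "wavenumber_cm-1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis_kind not in AXIS_KINDS:
            raise SpectrumContentError(
                f"unknown axis_kind {self.axis_kind!r}; "
                f"expected one of {sorted(AXIS_KINDS)}"
            )
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumContentError("axis and intensity must be 1-D")
        if self.axis.size != self.intensity.size:
            raise SpectrumContentError(
                f"axis has {self.axis.size} points but intensity has "
                f"{self.intensity.size}"
            )
        if self.axis.size < 2:
            raise SpectrumContentError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(self.axis)) and np.all(np.isfinite(self.intensity))):
            raise SpectrumContentError("non-finite values in spectrum")
        d = np.diff(self.axis)
        if np.all(d < 0):  # normalize descending to ascending
            self.axis = self.axis[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise SpectrumContentError("axis must be strictly monotonic")

    def __len__(self) -> int:
        return self.axis.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.axis[0]), float(self.axis[-1])

    def copy(self, **updates) -> "Spectrum":
        kw = dict(
            axis=self.axis.copy(),
            intensity=self.intensity.copy(),
            axis_kind=self.axis_kind,
            metadata=dict(self.metadata),
        )
        kw.update(updates)
        return Spectrum(**kw)

    def allclose(self, other: "Spectrum", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        """Value equality within text round-trip precision (metadata ignored)."""
        return (
            self.axis_kind == other.axis_kind
            and self.axis.size == other.axis.size
            and np.allclose(self.axis, other.axis, rtol=rtol, atol=atol)
            and np.allclose(self.intensity, other.intensity, rtol=rtol, atol=atol)
        )


@dataclass
class SpectrumSeries:
    """Ordered collection of spectra from a temperature ramp protocol."""

    spectra: list[Spectrum]
    temperatures: np.ndarray
    scan_labels: list[str]

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.scan_labels = list(self.scan_labels)
        n = len(self.spectra)
        if self.temperatures.size != n or len(self.scan_labels) != n:
            raise SpectrumContentError(
                "need exactly one temperature and one scan label per spectrum"
            )
        for lab in self.scan_labels:
            if lab not in SCAN_LABELS:
                raise SpectrumContentError(
                    f"unknown scan label {lab!r}; expected one of {SCAN_LABELS}"
                )
        # within one scan, temperatures follow acquisition order monotonically
        for lab in set(self.scan_labels):
            t = self.temperatures[[i for i, s in enumerate(self.scan_labels) if s == lab]]
            if t.size >= 2:
                d = np.diff(t)
                if not (np.all(d > 0) or np.all(d < 0)):
                    raise SpectrumContentError(
                        f"temperatures within scan {lab!r} must be monotonic"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def select(self, scan_label: str) -> "SpectrumSeries":
        """Sub-series of a single scan label, acquisition order preserved."""
        idx = [i for i, s in enumerate(self.scan_labels) if s == scan_label]
        return SpectrumSeries(
            [self.spectra[i] for i in idx],
            self.temperatures[idx],
            [self.scan_labels[i] for i in idx],
        )

    @staticmethod
    def concat(parts: Iterable["SpectrumSeries"]) -> "SpectrumSeries":
        parts = list(parts)
        return SpectrumSeries(
            [s for p in parts for s in p.spectra],
            np.concatenate([p.temperatures for p in parts]),
            [l for p in parts for l in p.scan_labels],
        )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _format_meta_value(v) -> str:
    return repr(v) if isinstance(v, float) else str(v)


def _parse_meta_value(s: str):
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def _write_csv(s: Spectrum, path: Path) -> None:
    ycol = s.metadata.get("intensity_label", AXIS_KINDS[s.axis_kind])
    lines = [f"# {k}={_format_meta_value(v)}" for k, v in s.metadata.items()]
    lines.append(f"{s.axis_kind},{ycol}")
    lines.extend(f"{float(x)!r},{float(y)!r}" for x, y in zip(s.axis, s.intensity))
    path.write_text("\n".join(lines) + "\n")


def _read_csv(path: Path, axis_kind: str | None) -> Spectrum:
    metadata: dict = {}
    header: list[str] | None = None
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                metadata[k.strip()] = _parse_meta_value(v.strip())
            continue
        cells = [c.strip() for c in line.split(",")]
        if len(cells) < 2:
            raise SpectrumParseError(f"{path}:{lineno}: expected 2 comma-separated cells")
        if header is None:
            try:
                float(cells[0])
            except ValueError:
                header = cells
                continue
            header = []  # headerless file: first row is data
        try:
            xs.append(float(cells[0]))
            ys.append(float(cells[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(xs) < 2:
        raise SpectrumContentError(f"{path}: fewer than 2 data points")
    if axis_kind is None:
        if header and header[0] in AXIS_KINDS:
            axis_kind = header[0]
        else:
            axis_kind = "wavenumber_cm-1"
    if header and len(header) > 1:
        metadata.setdefault("intensity_label", header[1])
    return Spectrum(np.array(xs), np.array(ys), axis_kind=axis_kind, metadata=metadata)


# ---------------------------------------------------------------------------
# JCAMP-DX subset: XYPOINTS=(XY..XY) and XYDATA=(X++(Y..Y))
# ---------------------------------------------------------------------------

_LDR = re.compile(r"^##(?P<label>[^=]+)=(?P<value>.*)$")
_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")

_AXIS_TO_XUNITS = {
    "wavenumber_cm-1": "1/CM",
    "field_gauss": "GAUSS",
    "time_min": "MINUTES",
}
_XUNITS_TO_AXIS = {v: k for k, v in _AXIS_TO_XUNITS.items()}


def _write_jcamp(s: Spectrum, path: Path) -> None:
    meta = dict(s.metadata)
    lines = [
        f"##TITLE={meta.pop('title', 'sporeglass spectrum')}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=SPECTRUM",
        f"##XUNITS={_AXIS_TO_XUNITS[s.axis_kind]}",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={len(s)}",
        f"##FIRSTX={float(s.axis[0])!r}",
        f"##LASTX={float(s.axis[-1])!r}",
    ]
    for k, v in meta.items():
        lines.append(f"##${k}={_format_meta_value(v)}")
    lines.append("##XYPOINTS=(XY..XY)")
    lines.extend(f"{float(x)!r}, {float(y)!r}" for x, y in zip(s.axis, s.intensity))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path, axis_kind: str | None) -> Spectrum:
    text = path.read_text().splitlines()
    records: dict[str, str] = {}
    metadata: dict = {}
    table_mode: str | None = None
    table_lines: list[str] = []
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        m = _LDR.match(line)
        if m:
            raw_label = m.group("label").strip()
            label = raw_label.upper()
            value = m.group("value").strip()
            if label in ("XYPOINTS", "XYDATA"):
                table_mode = label
                records[label] = value
                table_lines = []
            elif label == "END":
                break
            elif label.startswith("$"):
                # user-defined labels keep their original case
                metadata[raw_label[1:]] = _parse_meta_value(value)
            else:
                table_mode = None
                records[label] = value
        elif table_mode is not None:
            table_lines.append(line)
        # stray non-LDR lines outside a table are ignored (comments)
    if table_mode is None:
        raise SpectrumParseError(f"{path}: no XYPOINTS or XYDATA table found")

    xfactor = float(records.get("XFACTOR", 1.0))
    yfactor = float(records.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    if table_mode == "XYPOINTS":
        for off, line in enumerate(table_lines):
            nums = _NUM.findall(line)
            if len(nums) % 2:
                raise SpectrumParseError(
                    f"{path}: odd number of values in XYPOINTS line {off + 1}"
                )
            for i in range(0, len(nums), 2):
                xs.append(float(nums[i]) * xfactor)
                ys.append(float(nums[i + 1]) * yfactor)
    else:  # XYDATA=(X++(Y..Y))
        if "(X++(Y..Y))" not in records["XYDATA"].replace(" ", ""):
            raise SpectrumParseError(
                f"{path}: unsupported XYDATA form {records['XYDATA']!r}"
            )
        npoints = int(float(records["NPOINTS"]))
        firstx = float(records["FIRSTX"])
        lastx = float(records["LASTX"])
        deltax = (lastx - firstx) / (npoints - 1) if npoints > 1 else 0.0
        for line in table_lines:
            nums = _NUM.findall(line)
            if not nums:
                continue
            # leading value is the X of the first Y on the line (a check value)
            for y in nums[1:]:
                xs.append(firstx + len(xs) * deltax)
                ys.append(float(y) * yfactor)
        xs = [x * xfactor for x in xs]
        if npoints and len(xs) != npoints:
            raise SpectrumParseError(
                f"{path}: NPOINTS={npoints} but table holds {len(xs)} points"
            )
    if len(xs) < 2:
        raise SpectrumContentError(f"{path}: fewer than 2 data points")
    if axis_kind is None:
        axis_kind = _XUNITS_TO_AXIS.get(records.get("XUNITS", "").upper(), "wavenumber_cm-1")
    title = records.get("TITLE")
    if title and title != "sporeglass spectrum":
        metadata.setdefault("title", title)
    return Spectrum(np.array(xs), np.array(ys), axis_kind=axis_kind, metadata=metadata)


# ---------------------------------------------------------------------------
# Public I/O and manipulation
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jcamp_dx"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    return "jcamp_dx" if path.suffix.lower() in (".jdx", ".dx", ".jcamp") else "csv"


def read_spectrum(path, format: str | None = None, axis_kind: str | None = None) -> Spectrum:
    """Read a spectrum from ``path`` in the CSV dialect or JCAMP-DX subset.

    The axis is normalized to increasing order; the column header (CSV) or
    XUNITS (JCAMP) determines ``axis_kind`` unless overridden.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path, axis_kind)
    return _read_jcamp(path, axis_kind)


def write_spectrum(s: Spectrum, path, format: str | None = None) -> None:
    """Write ``s`` so that :func:`read_spectrum` recovers an equal spectrum."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(s, path)
    else:
        _write_jcamp(s, path)


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict to axis points with ``lo <= axis <= hi`` (metadata kept)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    mask = (s.axis >= lo) & (s.axis <= hi)
    if mask.sum() < 2:
        raise SpectrumContentError(
            f"crop window [{lo}, {hi}] leaves {int(mask.sum())} points of "
            f"axis span [{s.axis[0]}, {s.axis[-1]}]"
        )
    return Spectrum(s.axis[mask], s.intensity[mask], s.axis_kind, dict(s.metadata))


def resample(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linear interpolation onto ``grid``; no extrapolation outside the span."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.span
    if grid.min() < lo - 1e-12 * max(1.0, abs(lo)) or grid.max() > hi + 1e-12 * max(1.0, abs(hi)):
        raise SpectrumContentError(
            f"resample grid [{grid.min()}, {grid.max()}] extends outside the "
            f"axis span [{lo}, {hi}]"
        )
    y = np.interp(grid, s.axis, s.intensity)
    return Spectrum(grid, y, s.axis_kind, dict(s.metadata))
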