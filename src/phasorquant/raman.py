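"""Single-droplet Raman spectroscopy: background subtraction, peak-ratio
measurement, linear calibration, and estimation of lipid composition.

Two compositional quantities are estimated from fingerprint-region band
ratios of background-corrected spectra of individual lipid droplets:

* **Unsaturation degree** — the mean number of C=C bonds per fatty-acyl
  chain, from the 1654 cm^-1 C=C stretching band normalised by the
  1445 cm^-1 CH2 bending band.  The calibration line is fitted on fatty-acid
  standards with known C=C counts (palmitate 0, oleate 1, linoleate 2).
* **Cholesteryl-ester (CE) percentage** — mol% CE in the droplet's neutral
  lipid, from the cholesterol ring band near 702 cm^-1 normalised by the
  same 1445 cm^-1 band, calibrated on CE/triacylglycerol emulsions of known
  molar composition.

Peak intensity is the maximum of the spectrum over the band window after
subtracting the straight line through the window endpoints, which cancels
any locally linear baseline (and any global offset exactly).  Note the
cholesterol band is quoted at both 702 and 704 cm^-1 in the literature; the
default centre here is 702 cm^-1 with a half-window wide enough to cover
both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RamanSpectrum",
    "BandDefinition",
    "CalibrationModel",
    "LDComposition",
    "UnnormalizableError",
    "BAND_CC_STRETCH",
    "BAND_CH2_BEND",
    "BAND_CHOLESTEROL",
    "BAND_ESTER",
    "BAND_CH_UNSAT",
    "subtract_background",
    "measure_peak",
    "band_ratio",
    "fit_calibration",
    "estimate_unsaturation",
    "estimate_ce_percent",
]


class UnnormalizableError(ValueError):
    """Normaliser band intensity below the floor: ratios are undefined."""


@dataclass
class RamanSpectrum:
    """A (wavenumber, intensity) spectrum with ascending axis in cm^-1."""

    wavenumbers: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumbers.shape != self.intensity.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and intensity must be equal-length 1-D vectors")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be ascending")

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavenumbers[0] <= lo and self.wavenumbers[-1] >= hi


@dataclass(frozen=True)
class BandDefinition:
    """A named band window [center - half_window, center + half_window]."""

    name: str
    center: float
    half_window: float
    role: str = "analyte"  # or "normalizer"

    def __post_init__(self) -> None:
        if self.half_window <= 0:
            raise ValueError("half_window must be > 0")
        if self.role not in ("analyte", "normalizer"):
            raise ValueError("role must be 'analyte' or 'normalizer'")


# canonical fingerprint/high-wavenumber bands used throughout
BAND_CC_STRETCH = BandDefinition("cc_stretch_1654", 1654.0, 12.0, "analyte")
BAND_CH2_BEND = BandDefinition("ch2_bend_1445", 1445.0, 12.0, "normalizer")
# half-window covers the 702 vs 704 cm^-1 ambiguity of the cholesterol band
BAND_CHOLESTEROL = BandDefinition("cholesterol_702", 702.0, 8.0, "analyte")
BAND_ESTER = BandDefinition("ester_co_1740", 1740.0, 12.0, "analyte")
BAND_CH_UNSAT = BandDefinition("ch_unsat_3002", 3002.0, 12.0, "analyte")


@dataclass
class CalibrationModel:
    """Fitted line ratio = slope * x + intercept with goodness-of-fit.

    ``kind`` is "unsaturation" (x = number of C=C bonds per chain) or
    "ce_percent" (x = mol% CE).  A non-increasing fitted slope is kept but
    flagged through ``warning`` — such a calibration cannot be inverted
    meaningfully.
    """

    kind: str
    slope: float
    intercept: float
    r_squared: float
    x_units: str = ""
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("unsaturation", "ce_percent"):
            raise ValueError("kind must be 'unsaturation' or 'ce_percent'")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "x_units": self.x_units, "warning": self.warning,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(kind=d["kind"], slope=float(d["slope"]), intercept=float(d["intercept"]),
                   r_squared=float(d["r_squared"]), x_units=d.get("x_units", ""),
                   warning=d.get("warning"))

    def invert(self, ratio: float) -> float:
        if self.slope <= 0:
            raise ValueError("non-increasing calibration cannot be inverted")
        return (ratio - self.intercept) / self.slope


@dataclass(frozen=True)
class LDComposition:
    """Estimated droplet composition; raw and clamped variants both kept so
    downstream statistics can choose which to aggregate."""

    unsaturation_raw: float | None = None
    unsaturation: float | None = None  # clamped at 0
    ce_percent_raw: float | None = None
    ce_percent: float | None = None  # clamped to [0, 100]

    def __post_init__(self) -> None:
        if self.unsaturation is not None and self.unsaturation < 0:
            raise ValueError("clamped unsaturation must be >= 0")
        if self.ce_percent is not None and not 0 <= self.ce_percent <= 100:
            raise ValueError("clamped ce_percent must lie in [0, 100]")


def subtract_background(
    spec: RamanSpectrum,
    reference: RamanSpectrum,
    fit_region: tuple[float, float] | list[tuple[float, float]] = ((600.0, 650.0), (1750.0, 1800.0)),
) -> RamanSpectrum:
    """Remove a scaled substrate (e.g. glass) background from a spectrum.

    The scale ``c`` minimises ``|spec - c*reference|^2`` over ``fit_region``
    (one interval or several, assumed analyte-free); the reference is
    resampled onto the spectrum's axis by linear interpolation.
    """
    regions = [fit_region] if isinstance(fit_region[0], (int, float)) else list(fit_region)
    wn = spec.wavenumbers
    if reference.wavenumbers[0] > wn[0] or reference.wavenumbers[-1] < wn[-1]:
        raise ValueError("reference axis does not cover the spectrum axis")
    ref = np.interp(wn, reference.wavenumbers, reference.intensity)
    sel = np.zeros(wn.shape, dtype=bool)
    for lo, hi in regions:
        sel |= (wn >= lo) & (wn <= hi)
    if not sel.any():
        raise ValueError("fit_region does not overlap the spectrum axis")
    denom = float(np.dot(ref[sel], ref[sel]))
    c = 0.0 if denom == 0.0 else float(np.dot(ref[sel], spec.intensity[sel])) / denom
    return RamanSpectrum(
        wavenumbers=wn.copy(),
        intensity=spec.intensity - c * ref,
        meta={**spec.meta, "background_scale": c},
    )


def measure_peak(spec: RamanSpectrum, band: BandDefinition, mode: str = "height") -> float:
    """Baseline-corrected band intensity.

    ``mode="height"`` (default): maximum over the band window of the
    spectrum minus the straight line through the window endpoints — exactly
    invariant to a global offset and to any linear ramp.  ``mode="area"``:
    trapezoidal integral of the same baseline-corrected window.
    """
    lo, hi = band.center - band.half_window, band.center + band.half_window
    wn = spec.wavenumbers
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(
            f"band {band.name!r} window [{lo}, {hi}] outside spectral range "
            f"[{wn[0]}, {wn[-1]}]"
        )
    sel = (wn >= lo) & (wn <= hi)
    if sel.sum() < 3:
        raise ValueError(f"band {band.name!r} window covers fewer than 3 samples")
    x, y = wn[sel], spec.intensity[sel]
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    corrected = y - baseline
    if mode == "height":
        return float(corrected.max())
    if mode == "area":
        return float(np.trapezoid(corrected, x))
    raise ValueError("mode must be 'height' or 'area'")


def band_ratio(
    spec: RamanSpectrum,
    analyte: BandDefinition,
    normalizer: BandDefinition,
    floor: float = 1e-9,
    mode: str = "height",
) -> float:
    """Ratio of baseline-corrected analyte to normaliser band intensity."""
    denom = measure_peak(spec, normalizer, mode=mode)
    if denom <= floor:
        raise UnnormalizableError(
            f"normaliser band {normalizer.name!r} intensity {denom:g} at or below floor {floor:g}"
        )
    return measure_peak(spec, analyte, mode=mode) / denom


def fit_calibration(standards: list[tuple[float, float]], kind: str) -> CalibrationModel:
    """Ordinary least-squares line through (x, ratio) standards.

    The intercept is fitted, not forced through the origin.  At least two
    distinct x values are required; a fitted slope <= 0 is flagged as a
    non-increasing calibration (warning state, not an error).
    """
    if kind not in ("unsaturation", "ce_percent"):
        raise ValueError("kind must be 'unsaturation' or 'ce_percent'")
    xs = np.array([x for x, _ in standards], dtype=float)
    ys = np.array([r for _, r in standards], dtype=float)
    if np.unique(xs).size < 2:
        raise ValueError("need at least 2 distinct x values to fit a calibration line")
    res = stats.linregress(xs, ys)
    r2 = float(res.rvalue**2)
    warning = None
    if res.slope <= 0:
        warning = "non-increasing calibration"
        warnings.warn("fitted calibration slope is non-increasing", stacklevel=2)
    units = "number of C=C bonds" if kind == "unsaturation" else "mol% CE"
    return CalibrationModel(kind=kind, slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=min(r2, 1.0), x_units=units, warning=warning)


def estimate_unsaturation(
    spec: RamanSpectrum,
    model: CalibrationModel,
    analyte: BandDefinition = BAND_CC_STRETCH,
    normalizer: BandDefinition = BAND_CH2_BEND,
) -> LDComposition:
    """Unsaturation degree of a droplet: invert the C=C calibration on the
    spectrum's 1654/1445 band ratio.  Raw and clamped-at-0 values returned."""
    if model.kind != "unsaturation":
        raise ValueError("model.kind must be 'unsaturation'")
    raw = model.invert(band_ratio(spec, analyte, normalizer))
    return LDComposition(unsaturation_raw=raw, unsaturation=max(raw, 0.0))


def estimate_ce_percent(
    spec: RamanSpectrum,
    model: CalibrationModel,
    analyte: BandDefinition = BAND_CHOLESTEROL,
    normalizer: BandDefinition = BAND_CH2_BEND,
) -> LDComposition:
    """CE mol% of a droplet: invert the CE calibration on the spectrum's
    702/1445 band ratio.  Raw and clamped-to-[0, 100] values returned."""
    if model.kind != "ce_percent":
        raise ValueError("model.kind must be 'ce_percent'")
    raw = model.invert(band_ratio(spec, analyte, normalizer))
    return LDComposition(ce_percent_raw=raw, ce_percent=float(np.clip(raw, 0.0, 100.0)))
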