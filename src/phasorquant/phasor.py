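"""Phasor transform of delay-scan and hyperspectral stacks, and
reference-based segmentation of the phasor cloud.

The phasor transform maps each pixel's trace (over delay or wavenumber) to a
pair of normalised first-harmonic Fourier coordinates

    g = sum_k I_k cos(2*pi*n*k/K) / sum_k I_k
    s = sum_k I_k sin(2*pi*n*k/K) / sum_k I_k

treating the scan window as one period.  Trace *shapes* become points: a
sharp SRS cross-correlation peak, a pigment decay-plus-plateau trace and a
flat background land in different regions, so classes can be separated by
simple geometric gates.  The transform is linear in nonnegative mixtures:
the phasor of a sum of traces is the total-intensity-weighted mean of the
component phasors — the property the gating relies on.

Negative-going (pheomelanin-like) traces are routed by the sign of the
summed intensity *before* distance gating, because a signed denominator
makes (g, s) unstable near zero total intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath

__all__ = [
    "DelayStack",
    "SpectralStack",
    "PhasorField",
    "ReferenceSet",
    "LabelMap",
    "CLASS_BACKGROUND",
    "CLASS_OTHER",
    "CLASS_PIGMENT_NEGATIVE",
    "phasor_transform",
    "spectral_phasor_transform",
    "build_references",
    "segment_phasor",
    "default_intensity_floor",
]

# reserved label indices; reference entries are numbered 1..n_refs in order
CLASS_BACKGROUND = 0
CLASS_OTHER = 254
CLASS_PIGMENT_NEGATIVE = 255


@dataclass
class DelayStack:
    """Delay-scan cube: ``intensities[k, y, x]`` at delay ``delays[k]`` (ps)."""

    intensities: np.ndarray
    delays: np.ndarray
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a (delay, y, x) cube")
        if self.delays.ndim != 1 or self.delays.size != self.intensities.shape[0]:
            raise ValueError("delay axis length must match the cube's first axis")
        d = np.diff(self.delays)
        if not np.all(d > 0):
            raise ValueError("delays must be strictly increasing")
        if d.size and not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
            raise ValueError("delays must be uniformly spaced (rtol 1e-6)")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]


@dataclass
class SpectralStack:
    """Hyperspectral cube: ``intensities[k, y, x]`` at ``wavenumbers[k]`` (cm^-1)."""

    intensities: np.ndarray
    wavenumbers: np.ndarray
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a (wavenumber, y, x) cube")
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size != self.intensities.shape[0]:
            raise ValueError("wavenumber axis length must match the cube's first axis")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be ascending")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite (no NaN)")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates with total intensity and validity mask.

    ``g`` and ``s`` are finite wherever ``mask`` is True; the mask is False
    wherever ``|total|`` falls below the intensity floor used at transform
    time.
    """

    g: np.ndarray
    s: np.ndarray
    total: np.ndarray
    harmonic: int
    mask: np.ndarray
    floor: float = 0.0

    def __post_init__(self) -> None:
        shapes = {self.g.shape, self.s.shape, self.total.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("g, s, total and mask must share one shape")
        if self.harmonic < 1:
            raise ValueError("harmonic must be a positive integer")
        if not (np.all(np.isfinite(self.g[self.mask])) and np.all(np.isfinite(self.s[self.mask]))):
            raise ValueError("g and s must be finite on masked-in pixels")


@dataclass(frozen=True)
class ReferenceEntry:
    label: str
    g: float
    s: float
    polygon: tuple[tuple[float, float], ...] | None = None


@dataclass
class ReferenceSet:
    """Phasor-space class references: centroids and optional polygon gates.

    The gate geometry of the original analysis is not published, so
    references are built from user ROIs (or from rendered pure-class
    signals); ``max_distance`` bounds the centroid assignment radius.
    """

    entries: list[ReferenceEntry]
    max_distance: float = 0.15

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("reference labels must be unique")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def to_dict(self) -> dict:
        return {
            "max_distance": self.max_distance,
            "entries": [
                {"label": e.label, "g": e.g, "s": e.s,
                 "polygon": list(map(list, e.polygon)) if e.polygon else None}
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceSet":
        entries = [
            ReferenceEntry(
                label=e["label"], g=float(e["g"]), s=float(e["s"]),
                polygon=tuple(tuple(p) for p in e["polygon"]) if e.get("polygon") else None,
            )
            for e in d["entries"]
        ]
        return cls(entries=entries, max_distance=float(d.get("max_distance", 0.15)))


@dataclass
class LabelMap:
    """Integer class image plus a label -> name legend (background = 0)."""

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        if CLASS_BACKGROUND not in self.legend:
            self.legend[CLASS_BACKGROUND] = "background"
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")

    def class_mask(self, name: str) -> np.ndarray:
        idx = [k for k, v in self.legend.items() if v == name]
        if not idx:
            raise KeyError(f"class {name!r} not in legend")
        return np.isin(self.labels, idx)


def default_intensity_floor(totals: np.ndarray) -> float:
    """Intensity floor: 3x the median absolute deviation of per-pixel |totals|
    in the darkest decile — keeps noise-only background out of the phasor
    cloud without clipping dim signal."""
    a = np.abs(np.asarray(totals, dtype=float)).ravel()
    if a.size == 0:
        return 0.0
    decile = np.quantile(a, 0.1)
    dark = a[a <= decile]
    if dark.size == 0:
        return 0.0
    mad = np.median(np.abs(dark - np.median(dark)))
    return float(3.0 * mad)


def _phasor_of_cube(cube: np.ndarray, harmonic: int, floor: float | None) -> PhasorField:
    K = cube.shape[0]
    if K < 8:
        raise ValueError(f"need at least 8 samples along the scan axis, got {K}")
    if harmonic >= K / 2:
        raise ValueError(f"harmonic {harmonic} too high for {K} samples (must be < K/2)")
    theta = 2.0 * np.pi * harmonic * np.arange(K) / K
    cos_t = np.cos(theta)
    sin_t = np.sin(theta)
    total = cube.sum(axis=0)
    num_g = np.tensordot(cos_t, cube, axes=(0, 0))
    num_s = np.tensordot(sin_t, cube, axes=(0, 0))
    if floor is None:
        floor = default_intensity_floor(total)
    mask = np.abs(total) >= max(floor, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(mask, num_g / np.where(mask, total, 1.0), 0.0)
        s = np.where(mask, num_s / np.where(mask, total, 1.0), 0.0)
    return PhasorField(g=g, s=s, total=total, harmonic=harmonic, mask=mask, floor=float(floor))


def phasor_transform(stack: DelayStack, harmonic: int = 1, floor: float | None = None) -> PhasorField:
    """Phasor transform of a delay-scan stack.

    ``theta_k = 2*pi*harmonic*k/K`` treats the scan window as one period,
    which makes a constant trace map exactly to (0, 0) and an impulse in the
    first frame to (1, 0).  ``floor=None`` selects the MAD-based default.
    """
    return _phasor_of_cube(stack.intensities, harmonic, floor)


def spectral_phasor_transform(stack: SpectralStack, harmonic: int = 1, floor: float | None = None) -> PhasorField:
    """Spectral phasor of a hyperspectral stack (wavenumber axis as the period)."""
    return _phasor_of_cube(stack.intensities, harmonic, floor)


def build_references(
    field_: PhasorField,
    roi_masks: dict[str, np.ndarray],
    max_distance: float = 0.15,
) -> ReferenceSet:
    """Build class reference centroids from ROIs on a phasor field.

    Each centroid is the total-intensity-weighted mean of the ROI pixels'
    (g, s) — by phasor linearity this equals the phasor of the pooled ROI
    trace, so a noise-free pure-class ROI lands exactly on the class's
    analytic phasor.
    """
    entries: list[ReferenceEntry] = []
    for label, roi in roi_masks.items():
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != field_.g.shape:
            raise ValueError(f"ROI {label!r} shape {roi.shape} != field shape {field_.g.shape}")
        sel = roi & field_.mask
        if not sel.any():
            raise ValueError(f"ROI {label!r} contains no masked-in pixels")
        w = field_.total[sel]
        wsum = w.sum()
        if wsum == 0:
            raise ValueError(f"ROI {label!r} has zero total intensity")
        entries.append(
            ReferenceEntry(
                label=label,
                g=float(np.dot(w, field_.g[sel]) / wsum),
                s=float(np.dot(w, field_.s[sel]) / wsum),
            )
        )
    return ReferenceSet(entries=entries, max_distance=max_distance)


def segment_phasor(
    field_: PhasorField,
    refs: ReferenceSet,
    sign_map: np.ndarray | None = None,
) -> LabelMap:
    """Assign each pixel a class from its phasor position.

    Order of precedence per pixel: masked-out -> background; negative
    ``sign_map`` -> pigment_negative (signed traces are routed before
    distance gating); inside a reference polygon gate -> that label;
    otherwise nearest reference centroid in Euclidean (g, s) distance if
    within ``refs.max_distance``, else "other".  Ties go to the lower
    reference index.
    """
    if not refs.entries:
        raise ValueError("reference set is empty")
    shape = field_.g.shape
    labels = np.zeros(shape, dtype=np.uint8)
    legend: dict[int, str] = {CLASS_BACKGROUND: "background"}
    for i, e in enumerate(refs.entries, start=1):
        legend[i] = e.label
    legend[CLASS_OTHER] = "other"
    legend[CLASS_PIGMENT_NEGATIVE] = "pigment_negative"

    live = field_.mask.copy()
    if sign_map is not None:
        sign_map = np.asarray(sign_map, dtype=float)
        if sign_map.shape != shape:
            raise ValueError("sign_map shape must match the field")
        neg = live & (sign_map < 0)
        labels[neg] = CLASS_PIGMENT_NEGATIVE
        live &= ~neg
    if not live.any():
        return LabelMap(labels=labels, legend=legend)

    gs = np.stack([field_.g[live], field_.s[live]], axis=1)  # (N, 2)
    cent = np.array([[e.g, e.s] for e in refs.entries])  # (R, 2)
    d = np.linalg.norm(gs[:, None, :] - cent[None, :, :], axis=2)  # (N, R)
    nearest = np.argmin(d, axis=1)  # ties -> lower index (argmin is first-min)
    dist_min = d[np.arange(d.shape[0]), nearest]
    assign = np.where(dist_min <= refs.max_distance, nearest + 1, CLASS_OTHER).astype(np.uint8)

    # polygon gates take precedence over centroid distances
    for i, e in enumerate(refs.entries, start=1):
        if e.polygon:
            inside = _MplPath(np.asarray(e.polygon)).contains_points(gs)
            assign[inside] = i

    labels[live] = assign
    return LabelMap(labels=labels, legend=legend)
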