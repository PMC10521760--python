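"""Ground-truthed synthetic data for every input the pipeline consumes.

The original imaging data (melanoma cell and tissue fields, single-droplet
Raman spectra, fatty-acid and CE/triacylglycerol calibration standards) are
not publicly deposited, so this module generates physically structured
stand-ins with complete bookkeeping:

* **Delay-scan scenes** — fields of cells containing disk-shaped droplets of
  three classes: lipid droplets (sharp Gaussian SRS cross-correlation
  trace), eumelanin-like pigment (positive fast-decay-plus-plateau trace)
  and pheomelanin-like pigment (the same shape with negative sign).
  Background pixels carry noise only.
* **Hyperspectral scenes** — the same geometry with nucleus / ER / cytoplasm
  / LD regions, each carrying a distinct C-H-region spectrum.
* **Single-droplet Raman spectra** — sums of Gaussian band templates whose
  1654 cm^-1 amplitude scales linearly with the mean number of C=C bonds
  per chain and whose 702 cm^-1 amplitude scales linearly with the CE mol
  fraction, over a composition-independent 1445 cm^-1 CH2 band; plus an
  optional polynomial baseline and seeded noise.

Every artifact is reconstructible bit-identically from its truth record and
seed.  Band amplitude anchors (e.g. an oleate-like 1654/1445 ratio of 0.4
at one C=C per chain) are internal conventions chosen to be of realistic
magnitude; they are not measured values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .raman import (
    BAND_CC_STRETCH,
    BAND_CH2_BEND,
    BAND_CHOLESTEROL,
    BandDefinition,
    RamanSpectrum,
)
from .signal_models import PumpProbeParams, SRSParams, pump_probe_response, srs_response
from .phasor import DelayStack, SpectralStack

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "BandTemplate",
    "SpectrumTruth",
    "PackingError",
    "delay_scene_config",
    "spectral_scene_config",
    "make_scene",
    "render_delay_stack",
    "render_spectral_stack",
    "default_delays",
    "default_ch_wavenumbers",
    "default_fingerprint_wavenumbers",
    "default_band_templates",
    "default_signal_params",
    "default_class_spectra",
    "synth_raman_spectrum",
    "make_calibration_standards",
    "analytic_calibration",
    "UNSATURATION_STANDARD_X",
    "CE_STANDARD_X",
]


class PackingError(RuntimeError):
    """Raised when the requested droplets cannot be placed in the field."""


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Generative settings for one synthetic field of cells.

    kind            : "delay" (SRS / pump-probe droplet classes) or
                      "spectral" (nucleus / ER / cytoplasm / LD regions)
    shape           : field size (rows, cols) in pixels
    pixel_size      : microns per pixel
    n_cells         : number of cell disks placed in the field
    cell_radius     : (min, max) cell radius in px
    droplet_counts  : droplets requested per class name
    droplet_radius  : (min, max) droplet radius in px
    noise_sigma     : additive Gaussian noise sigma (a.u.; peak signal is 1)
    noise_relative  : optional signal-proportional noise coefficient
    min_gap         : minimum edge-to-edge droplet separation in px (keeps
                      rasterised disks 8-disconnected)
    """

    kind: str = "delay"
    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.5
    n_cells: int = 4
    cell_radius: tuple[float, float] = (16.0, 20.0)
    droplet_counts: dict[str, int] = field(default_factory=dict)
    droplet_radius: tuple[float, float] = (2.0, 3.5)
    noise_sigma: float = 0.02
    noise_relative: float = 0.0
    min_gap: float = 3.0
    max_tries: int = 20000

    def __post_init__(self) -> None:
        if self.kind not in ("delay", "spectral"):
            raise ValueError("kind must be 'delay' or 'spectral'")
        if not self.droplet_counts:
            if self.kind == "delay":
                self.droplet_counts = {"LD": 10, "pigment_positive": 5, "pigment_negative": 4}
            else:
                self.droplet_counts = {"LD": 8}


def delay_scene_config(**overrides) -> SceneConfig:
    """Default delay-scan scene: 3 cells, LD + both pigment classes."""
    return SceneConfig(kind="delay", **overrides)


def spectral_scene_config(**overrides) -> SceneConfig:
    """Default hyperspectral scene: 3 cells with nucleus/ER/cytoplasm/LD."""
    return SceneConfig(kind="spectral", **overrides)


@dataclass(frozen=True)
class Droplet:
    droplet_id: int
    class_name: str
    cx: float
    cy: float
    radius: float
    area_px: int


@dataclass
class SceneTruth:
    """Full generative ground truth for one rendered scene."""

    config: SceneConfig
    seed: int
    cells: list[tuple[float, float, float]]  # (cx, cy, radius)
    droplets: list[Droplet]
    class_map: np.ndarray  # uint8, legend below
    legend: dict[int, str]
    signal_params: dict[str, SRSParams | PumpProbeParams]
    class_spectra: dict[str, list[tuple[float, float, float]]]  # (center, sigma, amp)

    @property
    def cell_count(self) -> int:
        return len(self.cells)

    def class_mask(self, name: str) -> np.ndarray:
        idx = [k for k, v in self.legend.items() if v == name]
        return np.isin(self.class_map, idx)

    def droplet_mask(self) -> np.ndarray:
        names = set(d.class_name for d in self.droplets)
        out = np.zeros(self.class_map.shape, dtype=bool)
        for n in names:
            out |= self.class_mask(n)
        return out

    def class_area_px(self, name: str) -> int:
        return sum(d.area_px for d in self.droplets if d.class_name == name)

    def area_fraction_pct(self, name: str) -> float:
        h, w = self.class_map.shape
        return self.class_area_px(name) / float(h * w) * 100.0

    def to_dict(self) -> dict:
        return {
            "config": {**asdict(self.config),
                       "shape": list(self.config.shape),
                       "cell_radius": list(self.config.cell_radius),
                       "droplet_radius": list(self.config.droplet_radius)},
            "seed": self.seed,
            "cells": [list(c) for c in self.cells],
            "droplets": [asdict(d) for d in self.droplets],
            "legend": {str(k): v for k, v in self.legend.items()},
            "signal_params": {k: v.to_dict() for k, v in self.signal_params.items()},
            "class_spectra": {k: [list(b) for b in v] for k, v in self.class_spectra.items()},
            "class_map": self.class_map.tolist(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneTruth":
        cfgd = dict(d["config"])
        cfgd["shape"] = tuple(cfgd["shape"])
        cfgd["cell_radius"] = tuple(cfgd["cell_radius"])
        cfgd["droplet_radius"] = tuple(cfgd["droplet_radius"])
        params: dict[str, SRSParams | PumpProbeParams] = {}
        for k, pd_ in d["signal_params"].items():
            pd_ = dict(pd_)
            kind = pd_.pop("kind")
            params[k] = SRSParams(**pd_) if kind == "srs" else PumpProbeParams(**pd_)
        return cls(
            config=SceneConfig(**cfgd),
            seed=int(d["seed"]),
            cells=[tuple(c) for c in d["cells"]],
            droplets=[Droplet(**dd) for dd in d["droplets"]],
            class_map=np.asarray(d["class_map"], dtype=np.uint8),
            legend={int(k): v for k, v in d["legend"].items()},
            signal_params=params,
            class_spectra={k: [tuple(b) for b in v] for k, v in d["class_spectra"].items()},
        )

    @classmethod
    def load_json(cls, path) -> "SceneTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_signal_params() -> dict[str, SRSParams | PumpProbeParams]:
    """Canonical per-class time-domain parameters (peak amplitudes ~1 a.u.).

    The pigment decay constant (0.3 ps) puts the fast transient-absorption
    component well inside the first picosecond, with a photothermal plateau
    at 20% of the onset amplitude persisting over the scan.
    """
    return {
        "LD": SRSParams(amplitude=1.0, t0=0.0, width=0.25),
        "pigment_positive": PumpProbeParams(a_ta=0.8, tau=0.3, a_pt=0.2, sign=+1),
        "pigment_negative": PumpProbeParams(a_ta=0.6, tau=0.4, a_pt=0.15, sign=-1),
    }


def default_class_spectra() -> dict[str, list[tuple[float, float, float]]]:
    """C-H-region spectral templates per subcellular class as Gaussian bands
    (center cm^-1, sigma cm^-1, amplitude): LDs dominated by the 2850 CH2
    stretch, protein-rich compartments by the 2930 CH3 stretch."""
    return {
        "LD": [(2850.0, 20.0, 1.0), (2885.0, 20.0, 0.35)],
        "ER": [(2850.0, 20.0, 0.45), (2930.0, 25.0, 0.45)],
        "cytoplasm": [(2930.0, 25.0, 0.75), (2885.0, 20.0, 0.15)],
        "nucleus": [(2930.0, 25.0, 0.40), (2970.0, 20.0, 0.30)],
    }


def default_delays() -> np.ndarray:
    """Delay axis -1 to +10 ps in 0.1 ps steps (a configuration default;
    the real scan range is instrument-dependent)."""
    return np.round(np.arange(-10, 101) * 0.1, 10)


def default_ch_wavenumbers() -> np.ndarray:
    """Hyperspectral C-H window, 2800-3050 cm^-1 in 5 cm^-1 steps."""
    return np.arange(2800.0, 3051.0, 5.0)


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def make_scene(config: SceneConfig | None = None, seed: int = 0) -> SceneTruth:
    """Place cells and droplets and rasterise the ground-truth class map.

    Deterministic given ``seed``.  Droplets are disks sampled inside cells
    with an enforced ``min_gap`` edge separation, so rasterised droplets are
    pairwise 8-disconnected (exact particle-count bookkeeping).  Raises
    :class:`PackingError` when a feasible placement is not found within
    ``max_tries`` proposals.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    h, w = cfg.shape

    # --- cells: non-overlapping disks fully inside the field
    cells: list[tuple[float, float, float]] = []
    tries = 0
    while len(cells) < cfg.n_cells:
        if tries > cfg.max_tries:
            raise PackingError(f"could not place {cfg.n_cells} cells in a {cfg.shape} field")
        tries += 1
        r = rng.uniform(*cfg.cell_radius)
        cx = rng.uniform(r + 1, w - r - 1)
        cy = rng.uniform(r + 1, h - r - 1)
        if all((cx - ox) ** 2 + (cy - oy) ** 2 >= (r + orr + 1) ** 2 for ox, oy, orr in cells):
            cells.append((float(cx), float(cy), float(r)))

    if cfg.kind == "spectral":
        legend = {0: "background", 1: "cytoplasm", 2: "nucleus", 3: "ER", 4: "LD"}
    else:
        legend = {0: "background"}
        for i, name in enumerate(sorted(cfg.droplet_counts), start=1):
            legend[i] = name
    name_to_idx = {v: k for k, v in legend.items()}

    class_map = np.zeros(cfg.shape, dtype=np.uint8)
    nuclei: list[tuple[float, float, float]] = []
    if cfg.kind == "spectral":
        for cx, cy, r in cells:
            class_map[_disk_mask(cfg.shape, cx, cy, r)] = name_to_idx["cytoplasm"]
        for cx, cy, r in cells:
            rn = 0.40 * r
            nuclei.append((cx, cy, rn))
            er = _disk_mask(cfg.shape, cx, cy, rn + 3.0) & ~_disk_mask(cfg.shape, cx, cy, rn)
            class_map[er] = name_to_idx["ER"]
            class_map[_disk_mask(cfg.shape, cx, cy, rn)] = name_to_idx["nucleus"]

    # --- droplets: inside cells, pairwise separated, away from nucleus+ER
    droplets: list[Droplet] = []
    placed: list[tuple[float, float, float]] = []
    droplet_id = 0
    for name in sorted(cfg.droplet_counts):
        want = cfg.droplet_counts[name]
        got = 0
        tries = 0
        while got < want:
            if tries > cfg.max_tries:
                raise PackingError(
                    f"could not place droplet {got + 1}/{want} of class {name!r}"
                )
            tries += 1
            r = rng.uniform(*cfg.droplet_radius)
            cx_c, cy_c, r_c = cells[rng.integers(len(cells))]
            rho = rng.uniform(0, max(r_c - r - 1.5, 0.0))
            ang = rng.uniform(0, 2 * math.pi)
            cx = cx_c + rho * math.cos(ang)
            cy = cy_c + rho * math.sin(ang)
            if cfg.kind == "spectral":
                # keep LDs in the cytoplasm, clear of the nucleus + ER annulus
                rn = 0.40 * r_c
                if (cx - cx_c) ** 2 + (cy - cy_c) ** 2 < (rn + 3.0 + r + 1.5) ** 2:
                    continue
            if any(
                math.hypot(cx - ox, cy - oy) < r + orr + cfg.min_gap
                for ox, oy, orr in placed
            ):
                continue
            mask = _disk_mask(cfg.shape, cx, cy, r)
            area = int(mask.sum())
            if area < 4:  # below the default particle-analysis min_area
                continue
            droplet_id += 1
            droplets.append(Droplet(droplet_id, name, float(cx), float(cy), float(r), area))
            placed.append((cx, cy, r))
            class_map[mask] = name_to_idx[name if cfg.kind == "delay" else "LD"]
            got += 1

    return SceneTruth(
        config=cfg,
        seed=int(seed),
        cells=cells,
        droplets=droplets,
        class_map=class_map,
        legend=legend,
        signal_params=default_signal_params(),
        class_spectra=default_class_spectra(),
    )


def _eval_bands(bands: list[tuple[float, float, float]], axis: np.ndarray) -> np.ndarray:
    out = np.zeros_like(axis, dtype=float)
    for center, sigma, amp in bands:
        out += amp * np.exp(-((axis - center) ** 2) / (2.0 * sigma * sigma))
    return out


def render_delay_stack(truth: SceneTruth, delays: np.ndarray | None = None) -> DelayStack:
    """Render a delay-scan cube from a scene truth.

    Each droplet pixel carries its class's time-domain model trace; all
    other pixels are zero before noise.  Additive (and optional
    signal-proportional) Gaussian noise is drawn from a generator seeded by
    the scene seed, so repeated renders are bit-identical.
    """
    if truth.config.kind != "delay":
        raise ValueError("truth was generated for a spectral scene")
    t = default_delays() if delays is None else np.asarray(delays, dtype=float)
    K = t.size
    cube = np.zeros((K,) + truth.class_map.shape, dtype=float)
    for name, p in truth.signal_params.items():
        mask = truth.class_mask(name)
        if not mask.any():
            continue
        trace = srs_response(t, p) if isinstance(p, SRSParams) else pump_probe_response(t, p)
        cube[:, mask] = trace[:, None]
    rng = np.random.default_rng([truth.seed, 1])
    if truth.config.noise_relative > 0:
        cube = cube + truth.config.noise_relative * np.abs(cube) * rng.standard_normal(cube.shape)
    if truth.config.noise_sigma > 0:
        cube = cube + truth.config.noise_sigma * rng.standard_normal(cube.shape)
    return DelayStack(intensities=cube, delays=t, pixel_size=truth.config.pixel_size,
                      meta={"seed": truth.seed, "kind": "delay"})


def render_spectral_stack(truth: SceneTruth, wavenumbers: np.ndarray | None = None) -> SpectralStack:
    """Render a hyperspectral cube: each class region carries its spectral
    template plus seeded noise; background is noise-only."""
    if truth.config.kind != "spectral":
        raise ValueError("truth was generated for a delay scene")
    wn = default_ch_wavenumbers() if wavenumbers is None else np.asarray(wavenumbers, dtype=float)
    cube = np.zeros((wn.size,) + truth.class_map.shape, dtype=float)
    for name, bands in truth.class_spectra.items():
        mask = truth.class_mask(name)
        if not mask.any():
            continue
        cube[:, mask] = _eval_bands(bands, wn)[:, None]
    rng = np.random.default_rng([truth.seed, 2])
    if truth.config.noise_relative > 0:
        cube = cube + truth.config.noise_relative * np.abs(cube) * rng.standard_normal(cube.shape)
    if truth.config.noise_sigma > 0:
        cube = cube + truth.config.noise_sigma * rng.standard_normal(cube.shape)
    return SpectralStack(intensities=cube, wavenumbers=wn, pixel_size=truth.config.pixel_size,
                         meta={"seed": truth.seed, "kind": "spectral"})


# ---------------------------------------------------------------------------
# single-droplet Raman spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandTemplate:
    """One Gaussian band whose amplitude is affine in the composition:
    ``amp = base + cc_coeff * n_cc + ce_coeff * ce_fraction``."""

    center: float
    sigma: float
    base: float = 0.0
    cc_coeff: float = 0.0
    ce_coeff: float = 0.0

    def amplitude(self, n_cc: float, ce_fraction: float) -> float:
        return self.base + self.cc_coeff * n_cc + self.ce_coeff * ce_fraction


# amplitude anchors: 1445 CH2 bend is the composition-independent unit; one
# C=C per chain gives an oleate-like 1654/1445 ratio of 0.4; pure CE gives a
# 702 amplitude equal to the 1445 amplitude.  Internal conventions.
def default_band_templates(include_high_wavenumber: bool = False) -> list[BandTemplate]:
    bands = [
        BandTemplate(center=702.0, sigma=10.0, ce_coeff=1.0),
        BandTemplate(center=1445.0, sigma=10.0, base=1.0),
        BandTemplate(center=1654.0, sigma=10.0, cc_coeff=0.4),
        BandTemplate(center=1740.0, sigma=10.0, base=0.3),
    ]
    if include_high_wavenumber:
        bands += [
            BandTemplate(center=2850.0, sigma=12.0, base=1.5),
            BandTemplate(center=3002.0, sigma=10.0, cc_coeff=0.25),
        ]
    return bands


@dataclass
class SpectrumTruth:
    """Ground truth for one synthetic single-droplet Raman spectrum."""

    n_cc: float = 1.0  # mean C=C bonds per acyl chain
    ce_fraction: float = 0.0  # CE mol fraction in [0, 1]
    bands: list[BandTemplate] = field(default_factory=default_band_templates)
    baseline_coeffs: tuple[float, ...] = ()  # polynomial in (wn - 1200)/600
    noise_sigma: float = 0.0  # additive per-point Gaussian sigma (a.u.)
    noise_relative: float = 0.0  # per-point signal-proportional sigma
    gain_sigma: float = 0.0  # per-spectrum multiplicative gain sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ce_fraction <= 1.0:
            raise ValueError("ce_fraction must lie in [0, 1]")
        if self.n_cc < 0:
            raise ValueError("n_cc must be >= 0")


def default_fingerprint_wavenumbers() -> np.ndarray:
    """Fingerprint axis 600-1800 cm^-1 at 1 cm^-1, covering all default bands."""
    return np.arange(600.0, 1801.0, 1.0)


def synth_raman_spectrum(
    truth: SpectrumTruth, wavenumbers: np.ndarray | None = None
) -> RamanSpectrum:
    """Render a single-droplet Raman spectrum from its composition truth.

    The axis must cover every band template (center +- 2 sigma) with no
    sampling gap wider than the band sigma.
    """
    wn = default_fingerprint_wavenumbers() if wavenumbers is None else np.asarray(wavenumbers, dtype=float)
    step = float(np.max(np.diff(wn)))
    for b in truth.bands:
        if b.center - 2 * b.sigma < wn[0] or b.center + 2 * b.sigma > wn[-1]:
            raise ValueError(f"axis does not cover the {b.center:g} cm^-1 band")
        if step > b.sigma:
            raise ValueError(f"axis sampling gap {step:g} cm^-1 exceeds band sigma {b.sigma:g}")
    y = np.zeros_like(wn)
    for b in truth.bands:
        y += b.amplitude(truth.n_cc, truth.ce_fraction) * np.exp(
            -((wn - b.center) ** 2) / (2.0 * b.sigma * b.sigma)
        )
    if truth.baseline_coeffs:
        u = (wn - 1200.0) / 600.0
        y += np.polyval(truth.baseline_coeffs, u)
    rng = np.random.default_rng([truth.seed, 3])
    if truth.gain_sigma > 0:
        # acquisition-to-acquisition intensity-scale fluctuation (laser power,
        # focus): one multiplicative gain per spectrum
        y = y * (1.0 + truth.gain_sigma * rng.standard_normal())
    if truth.noise_relative > 0:
        y = y * (1.0 + truth.noise_relative * rng.standard_normal(y.shape))
    if truth.noise_sigma > 0:
        y = y + truth.noise_sigma * rng.standard_normal(y.shape)
    return RamanSpectrum(wavenumbers=wn, intensity=y,
                         meta={"n_cc": truth.n_cc, "ce_fraction": truth.ce_fraction,
                               "seed": truth.seed})


UNSATURATION_STANDARD_X = (0.0, 1.0, 2.0)  # palmitate, oleate, linoleate
CE_STANDARD_X = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)  # mol% CE in emulsion


def make_calibration_standards(
    kind: str,
    wavenumbers: np.ndarray | None = None,
    noise_relative: float = 0.0,
    noise_sigma: float = 0.0,
    gain_sigma: float = 0.0,
    seed: int = 0,
    bands: list[BandTemplate] | None = None,
) -> list[tuple[float, RamanSpectrum]]:
    """Synthetic calibration standards.

    ``kind="unsaturation"``: fatty-acid standards with 0, 1 and 2 C=C bonds
    per chain (palmitate-, oleate- and linoleate-like).
    ``kind="ce_percent"``: CE/triacylglycerol emulsions at 0-100 mol% CE in
    20-point steps.
    """
    if kind == "unsaturation":
        xs = UNSATURATION_STANDARD_X
    elif kind == "ce_percent":
        xs = CE_STANDARD_X
    else:
        raise ValueError("kind must be 'unsaturation' or 'ce_percent'")
    out = []
    for i, x in enumerate(xs):
        truth = SpectrumTruth(
            n_cc=x if kind == "unsaturation" else 0.0,
            ce_fraction=x / 100.0 if kind == "ce_percent" else 0.0,
            bands=bands if bands is not None else default_band_templates(),
            noise_sigma=noise_sigma,
            noise_relative=noise_relative,
            gain_sigma=gain_sigma,
            seed=seed * 1009 + i,
        )
        out.append((float(x), synth_raman_spectrum(truth, wavenumbers)))
    return out


def _measured_fraction(band: BandDefinition, sigma: float) -> float:
    # endpoint-baseline peak measurement of a grid-centred Gaussian of unit
    # amplitude returns 1 - exp(-h^2 / (2 sigma^2))
    h = band.half_window
    return 1.0 - math.exp(-(h * h) / (2.0 * sigma * sigma))


def analytic_calibration(
    kind: str,
    bands: list[BandTemplate] | None = None,
    analyte: BandDefinition | None = None,
    normalizer: BandDefinition = BAND_CH2_BEND,
) -> tuple[float, float]:
    """Closed-form (slope, intercept) of the measured-ratio calibration the
    generator implies, independent of the measurement pipeline.

    For Gaussian templates centred on the sampling grid, the
    endpoint-baseline peak height of a band of amplitude A and width sigma
    is ``A * (1 - exp(-h^2/(2 sigma^2)))``; the ratio of analyte to
    normaliser is therefore affine in the composition variable with the
    coefficients returned here (cross-band tails are negligible for the
    default, well-separated band set).
    """
    bands = bands if bands is not None else default_band_templates()
    if analyte is None:
        analyte = BAND_CC_STRETCH if kind == "unsaturation" else BAND_CHOLESTEROL
    by_center = {b.center: b for b in bands}
    ba = by_center[analyte.center]
    bn = by_center[normalizer.center]
    fa = _measured_fraction(analyte, ba.sigma)
    fn = _measured_fraction(normalizer, bn.sigma)
    norm_height = bn.base * fn
    if kind == "unsaturation":
        slope = ba.cc_coeff * fa / norm_height
    elif kind == "ce_percent":
        slope = ba.ce_coeff / 100.0 * fa / norm_height  # per mol%
    else:
        raise ValueError("kind must be 'unsaturation' or 'ce_percent'")
    intercept = ba.base * fa / norm_height
    return slope, intercept
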