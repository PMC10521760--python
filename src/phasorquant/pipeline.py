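"""Config-driven orchestration: simulate -> transform -> segment -> quantify.

A run is described by a :class:`RunConfig` (JSON or YAML on disk).  Three
modes exist: ``simulate`` renders a synthetic scene to TIFF + truth JSON;
``analyze`` runs phasor segmentation and particle quantification on an
existing delay stack; ``end_to_end`` chains the two in memory and reports
recovered class area fractions next to the generative truth.  All
randomness flows from the single config seed, and repeated runs with the
same config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import io as pqio
from .phasor import (
    DelayStack,
    LabelMap,
    PhasorField,
    ReferenceSet,
    build_references,
    phasor_transform,
    segment_phasor,
)
from .quantify import area_fractions, extract_droplets
from .raman import fit_calibration, band_ratio, BAND_CC_STRETCH, BAND_CHOLESTEROL, BAND_CH2_BEND
from .synthetic import (
    SceneConfig,
    SceneTruth,
    make_calibration_standards,
    make_scene,
    render_delay_stack,
)

__all__ = [
    "RunConfig", "SceneSettings", "PhasorSettings", "DropletSettings",
    "StatsSettings", "ConfigError", "DataError",
    "run", "load_config", "references_from_truth", "label_accuracy",
    "analyze_delay_scene",
]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed input data (CLI exit code 3)."""


class SceneSettings(BaseModel):
    kind: Literal["delay", "spectral"] = "delay"
    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.5
    n_cells: int = 4
    droplet_counts: dict[str, int] = Field(
        default_factory=lambda: {"LD": 10, "pigment_positive": 5, "pigment_negative": 4}
    )
    noise_sigma: float = 0.02
    noise_relative: float = 0.0

    def to_scene_config(self) -> SceneConfig:
        return SceneConfig(
            kind=self.kind, shape=tuple(self.shape), pixel_size=self.pixel_size,
            n_cells=self.n_cells, droplet_counts=dict(self.droplet_counts),
            noise_sigma=self.noise_sigma, noise_relative=self.noise_relative,
        )


class PhasorSettings(BaseModel):
    harmonic: int = 1
    floor: Optional[float] = None  # None -> derived from noise model / MAD default
    max_distance: float = 0.15


class DropletSettings(BaseModel):
    min_area: int = 4


class StatsSettings(BaseModel):
    alpha: float = 0.05
    tail: Literal["greater", "less", "two-sided"] = "two-sided"


class RunConfig(BaseModel):
    mode: Literal["simulate", "analyze", "end_to_end"] = "end_to_end"
    seed: int = 0
    outdir: str = "phasorquant_run"
    scene: SceneSettings = Field(default_factory=SceneSettings)
    input_stack: Optional[str] = None  # analyze mode: delay-stack TIFF
    input_truth: Optional[str] = None  # optional truth JSON (references, cell count)
    input_references: Optional[str] = None  # optional ReferenceSet JSON
    cell_count: Optional[int] = None  # overrides truth cell count in analyze mode
    phasor: PhasorSettings = Field(default_factory=PhasorSettings)
    droplets: DropletSettings = Field(default_factory=DropletSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)
    calibrate: bool = False  # also fit + save the Raman calibration models


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON or YAML, raising ConfigError on violations."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    except (json.JSONDecodeError, Exception) as exc:  # yaml errors included
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc


def references_from_truth(
    truth: SceneTruth,
    delays: np.ndarray,
    harmonic: int = 1,
    max_distance: float = 0.15,
) -> ReferenceSet:
    """Reference centroids from the scene's own class signal models.

    Each positive-signed class trace is rendered noise-free on the scan
    axis and phasor-transformed; negative-signed classes are excluded
    because those pixels are routed by sign, not by distance.
    """
    from .signal_models import PumpProbeParams, SRSParams, pump_probe_response, srs_response

    rois: dict[str, np.ndarray] = {}
    traces = []
    names = []
    for name, p in truth.signal_params.items():
        if isinstance(p, PumpProbeParams) and p.sign < 0:
            continue
        trace = srs_response(delays, p) if isinstance(p, SRSParams) else pump_probe_response(delays, p)
        traces.append(trace)
        names.append(name)
    cube = np.stack(traces, axis=1)[:, :, None]  # (K, n, 1)
    field = phasor_transform(DelayStack(intensities=cube, delays=delays), harmonic=harmonic, floor=0.0)
    for i, name in enumerate(names):
        roi = np.zeros(field.g.shape, dtype=bool)
        roi[i, 0] = True
        rois[name] = roi
    return build_references(field, rois, max_distance=max_distance)


def label_accuracy(seg: LabelMap, truth: SceneTruth, mask: np.ndarray | None = None) -> float:
    """Fraction of pixels whose segmented class *name* matches the truth.

    ``mask=None`` scores every pixel (background included); pass the phasor
    validity mask to score masked-in pixels only.
    """
    seg_names = np.array([seg.legend.get(i, "?") for i in range(256)])[seg.labels]
    lut = np.array([truth.legend.get(i, "?") for i in range(256)])
    truth_names = lut[truth.class_map]
    agree = seg_names == truth_names
    if mask is not None:
        if not mask.any():
            return float("nan")
        return float(agree[mask].mean())
    return float(agree.mean())


def _derived_floor(noise_sigma: float, n_samples: int, field: PhasorField | None = None) -> float | None:
    """Intensity floor for scenes with a known additive-noise sigma: 4x the
    standard deviation of a pure-noise pixel's summed trace."""
    if noise_sigma > 0:
        return 4.0 * noise_sigma * float(np.sqrt(n_samples))
    return 0.0


def analyze_delay_scene(
    stack: DelayStack,
    refs: ReferenceSet,
    cell_count: int,
    floor: float | None = None,
    harmonic: int = 1,
    min_area: int = 4,
) -> dict:
    """Phasor-transform, segment and quantify one delay stack.

    The per-pixel summed intensity doubles as the sign map: strongly
    negative totals are routed to the pheomelanin-like class before
    centroid gating.  Returns the phasor field, label map, droplet table
    and field-level quantities.
    """
    field = phasor_transform(stack, harmonic=harmonic, floor=floor)
    seg = segment_phasor(field, refs, sign_map=field.total)
    intensity = np.abs(stack.intensities).sum(axis=0)
    table = extract_droplets(seg, intensity=intensity, min_area=min_area,
                             pixel_size=stack.pixel_size)
    quant = area_fractions(table, field_shape=seg.labels.shape,
                           pixel_size=stack.pixel_size, cell_count=cell_count)
    return {"field": field, "labels": seg, "droplets": table, "quant": quant}


def _write_outputs(outdir: Path, result: dict, manifest: dict, written: list[Path]) -> None:
    lm_path = outdir / "label_map.tif"
    pqio.save_label_map(result["labels"], lm_path)
    written += [lm_path, lm_path.with_suffix(".legend.csv")]
    dt_path = outdir / "droplets.csv"
    result["droplets"].to_csv(dt_path, index=False, float_format="%.10g")
    written.append(dt_path)
    q = result["quant"]
    fq_rows = [
        {"class_name": name, "area_fraction_pct": q.area_fraction_pct[name],
         "droplets_per_cell": q.droplets_per_cell.get(name, 0.0),
         "cell_count": q.cell_count}
        for name in sorted(q.area_fraction_pct)
    ]
    fq_path = outdir / "field_quant.csv"
    pd.DataFrame(fq_rows, columns=["class_name", "area_fraction_pct",
                                   "droplets_per_cell", "cell_count"]
                 ).to_csv(fq_path, index=False, float_format="%.10g")
    written.append(fq_path)
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, sort_keys=True, indent=2))
    written.append(man_path)


def run(config: RunConfig) -> dict:
    """Execute one configured run; returns the run report dictionary.

    Outputs are written under ``config.outdir``; on failure, files written
    by the failing run are removed so no partial output set remains.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_inner(config, outdir, written)
    except Exception:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise


def _run_inner(config: RunConfig, outdir: Path, written: list[Path]) -> dict:
    from . import __version__

    cfg_json = config.model_dump_json()
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
    }
    report: dict = {"mode": config.mode, "seed": config.seed, "outdir": str(outdir)}

    truth: SceneTruth | None = None
    stack: DelayStack | None = None

    if config.mode in ("simulate", "end_to_end"):
        truth = make_scene(config.scene.to_scene_config(), seed=config.seed)
        stack = render_delay_stack(truth)
        stack_path = outdir / "delay_stack.tif"
        pqio.save_stack(stack, stack_path)
        truth.save_json(outdir / "scene_truth.json")
        written += [stack_path, Path(str(stack_path) + ".axis.json"), outdir / "scene_truth.json"]
        report["stack_path"] = str(stack_path)
        if config.mode == "simulate":
            manifest["outputs"] = sorted(p.name for p in written)
            (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
            return report

    if config.mode == "analyze":
        if not config.input_stack:
            raise ConfigError("analyze mode requires input_stack")
        try:
            stack = pqio.load_delay_stack(config.input_stack)
        except (FileNotFoundError, ValueError) as exc:
            raise DataError(str(exc)) from exc
        if config.input_truth:
            try:
                truth = SceneTruth.load_json(config.input_truth)
            except FileNotFoundError as exc:
                raise DataError(str(exc)) from exc

    assert stack is not None
    # references: explicit file > derived from truth signal models
    if config.input_references:
        try:
            refs = pqio.load_references(config.input_references)
        except FileNotFoundError as exc:
            raise DataError(str(exc)) from exc
    elif truth is not None:
        refs = references_from_truth(truth, stack.delays, harmonic=config.phasor.harmonic,
                                     max_distance=config.phasor.max_distance)
    else:
        raise ConfigError("analyze mode needs input_references or input_truth for gating")

    floor = config.phasor.floor
    if floor is None and truth is not None:
        floor = _derived_floor(truth.config.noise_sigma, stack.n_samples)
    cell_count = config.cell_count or (truth.cell_count if truth is not None else 1)

    result = analyze_delay_scene(
        stack, refs, cell_count=cell_count, floor=floor,
        harmonic=config.phasor.harmonic, min_area=config.droplets.min_area,
    )
    refs_path = outdir / "references.json"
    pqio.save_references(refs, refs_path)
    written.append(refs_path)

    report["cell_count"] = cell_count
    report["area_fraction_pct"] = dict(sorted(result["quant"].area_fraction_pct.items()))
    report["droplets_per_cell"] = dict(sorted(result["quant"].droplets_per_cell.items()))
    report["n_droplets"] = int(len(result["droplets"]))
    if truth is not None:
        report["truth_area_fraction_pct"] = {
            name: truth.area_fraction_pct(name) for name in sorted(truth.config.droplet_counts)
        }
        report["label_accuracy"] = label_accuracy(result["labels"], truth)

    if config.calibrate:
        report["calibration"] = _fit_and_save_calibrations(outdir, written)

    manifest["outputs"] = sorted(p.name for p in written) + ["label_map.tif"]
    _write_outputs(outdir, result, manifest, written)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2))
    written.append(report_path)
    return report


def _fit_and_save_calibrations(outdir: Path, written: list[Path]) -> dict:
    out = {}
    for kind, analyte in (("unsaturation", BAND_CC_STRETCH), ("ce_percent", BAND_CHOLESTEROL)):
        standards = make_calibration_standards(kind)
        pairs = [(x, band_ratio(s, analyte, BAND_CH2_BEND)) for x, s in standards]
        model = fit_calibration(pairs, kind)
        path = outdir / f"calibration_{kind}.json"
        path.write_text(json.dumps(model.to_dict(), sort_keys=True, indent=2))
        written.append(path)
        out[kind] = model.to_dict()
    return out
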