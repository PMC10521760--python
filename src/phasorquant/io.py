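"""Reading and writing the pipeline's on-disk formats.

Stacks travel as multi-page TIFF with the calibrated axis (delay in ps or
wavenumber in cm^-1) and pixel size in a JSON sidecar named
``<stack>.axis.json``; spectra as two-column CSV (wavenumber, intensity);
reference sets and statistics as JSON; label maps as TIFF plus a CSV
legend.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phasor import DelayStack, SpectralStack, LabelMap, PhasorField, ReferenceSet
from .raman import RamanSpectrum

__all__ = [
    "save_stack", "load_delay_stack", "load_spectral_stack",
    "save_label_map", "load_label_map",
    "save_phasor_field", "load_phasor_field",
    "save_references", "load_references",
    "save_spectrum_csv", "load_spectrum_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".axis.json")


def save_stack(stack: DelayStack | SpectralStack, path: str | Path) -> Path:
    """Write a stack as multi-page float32 TIFF + JSON axis sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32), photometric="minisblack")
    if isinstance(stack, DelayStack):
        axis = {"axis_kind": "delay_ps", "axis": stack.delays.tolist()}
    else:
        axis = {"axis_kind": "wavenumber_cm1", "axis": stack.wavenumbers.tolist()}
    axis.update({"pixel_size_um": stack.pixel_size, "meta": stack.meta})
    _sidecar(path).write_text(json.dumps(axis, sort_keys=True))
    return path


def _load_stack(path: Path) -> tuple[np.ndarray, dict]:
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"axis sidecar not found: {side}")
    cube = np.asarray(tifffile.imread(path), dtype=float)
    if cube.ndim == 2:
        cube = cube[None]
    return cube, json.loads(side.read_text())


def load_delay_stack(path: str | Path) -> DelayStack:
    cube, axis = _load_stack(Path(path))
    if axis.get("axis_kind") != "delay_ps":
        raise ValueError(f"{path}: sidecar axis_kind is not 'delay_ps'")
    return DelayStack(intensities=cube, delays=np.asarray(axis["axis"], dtype=float),
                      pixel_size=float(axis.get("pixel_size_um", 1.0)),
                      meta=axis.get("meta", {}))


def load_spectral_stack(path: str | Path) -> SpectralStack:
    cube, axis = _load_stack(Path(path))
    if axis.get("axis_kind") != "wavenumber_cm1":
        raise ValueError(f"{path}: sidecar axis_kind is not 'wavenumber_cm1'")
    return SpectralStack(intensities=cube, wavenumbers=np.asarray(axis["axis"], dtype=float),
                         pixel_size=float(axis.get("pixel_size_um", 1.0)),
                         meta=axis.get("meta", {}))


def save_label_map(lm: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, lm.labels.astype(np.uint8))
    legend = pd.DataFrame(sorted(lm.legend.items()), columns=["label", "name"])
    legend.to_csv(path.with_suffix(".legend.csv"), index=False)
    return path


def load_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    labels = np.asarray(tifffile.imread(path))
    legend_df = pd.read_csv(path.with_suffix(".legend.csv"))
    legend = {int(r.label): str(r.name) for r in legend_df.itertuples()}
    return LabelMap(labels=labels, legend=legend)


def save_phasor_field(field: PhasorField, path: str | Path) -> Path:
    """Write a phasor field as a 4-page float32 TIFF (g, s, total, mask)
    plus a JSON sidecar with the harmonic and floor."""
    path = Path(path)
    pages = np.stack([field.g, field.s, field.total, field.mask.astype(float)])
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps(
        {"axis_kind": "phasor_gstm", "harmonic": field.harmonic, "floor": field.floor},
        sort_keys=True))
    return path


def load_phasor_field(path: str | Path) -> PhasorField:
    cube, axis = _load_stack(Path(path))
    if axis.get("axis_kind") != "phasor_gstm" or cube.shape[0] != 4:
        raise ValueError(f"{path}: not a phasor-field TIFF")
    return PhasorField(g=cube[0], s=cube[1], total=cube[2], mask=cube[3] > 0.5,
                       harmonic=int(axis["harmonic"]), floor=float(axis.get("floor", 0.0)))


def save_references(refs: ReferenceSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(refs.to_dict(), sort_keys=True, indent=2))
    return path


def load_references(path: str | Path) -> ReferenceSet:
    return ReferenceSet.from_dict(json.loads(Path(path).read_text()))


def save_spectrum_csv(spec: RamanSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"wavenumber_cm1": spec.wavenumbers, "intensity": spec.intensity}).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


def load_spectrum_csv(path: str | Path) -> RamanSpectrum:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    return RamanSpectrum(wavenumbers=df.iloc[:, 0].to_numpy(float),
                         intensity=df.iloc[:, 1].to_numpy(float))
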