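"""Particle analysis, per-cell quantities and two-sample statistics.

Mirrors the downstream quantification of a segmented field: connected
components of each droplet class become particle records, class areas are
expressed as a percentage of the field and normalised to the number of
cells, deuterium-label (C-D channel) uptake is summed over droplet pixels
per cell, and group comparisons go through a normality-gated test choice
(one-tailed Student's t when both samples look Gaussian by Shapiro-Wilk,
Mann-Whitney U otherwise).  No multiple-testing correction is applied;
callers comparing many endpoints should correct externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure as skmeasure

from .phasor import LabelMap, CLASS_BACKGROUND

__all__ = [
    "FieldQuant",
    "StatResult",
    "extract_droplets",
    "area_fractions",
    "cd_uptake",
    "ratiometric_order",
    "excimer_monomer_ratio",
    "compare_groups",
]

DROPLET_COLUMNS = [
    "droplet_id", "class_name", "area_px", "area_um2",
    "centroid_x", "centroid_y", "mean_intensity",
]


@dataclass(frozen=True)
class FieldQuant:
    """Field-level quantities: per-class area fraction (%), droplet counts
    and C-D intensity normalised to the cell count."""

    area_fraction_pct: dict[str, float]
    cell_count: int
    droplets_per_cell: dict[str, float]
    cd_per_cell: float | None = None

    def __post_init__(self) -> None:
        if self.cell_count < 1:
            raise ValueError("cell_count must be >= 1")
        for name, f in self.area_fraction_pct.items():
            if not 0.0 <= f <= 100.0:
                raise ValueError(f"area fraction for {name!r} out of [0, 100]: {f}")
        if sum(self.area_fraction_pct.values()) > 100.0 + 1e-9:
            raise ValueError("class area fractions sum above 100%")


@dataclass(frozen=True)
class StatResult:
    """Outcome of a two-sample comparison with the test that was chosen."""

    test_name: str  # "one-tailed t" or "Mann-Whitney U"
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    tail: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name, "statistic": self.statistic,
            "p_value": self.p_value, "significant": self.significant,
            "alpha": self.alpha, "tail": self.tail,
        }


def extract_droplets(
    labels: LabelMap,
    intensity: np.ndarray | None = None,
    min_area: int = 4,
    pixel_size: float = 1.0,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Particle analysis of a label map: one row per 8-connected component.

    Components smaller than ``min_area`` pixels are dropped.  ``classes``
    restricts the analysis to the named droplet classes (all non-background
    classes by default).  Centroids are (x, y) in 0-based pixel coordinates,
    origin top-left.
    """
    img = labels.labels
    if intensity is None:
        intensity = np.zeros(img.shape, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != img.shape:
        raise ValueError("labels and intensity must have the same shape")
    wanted = classes if classes is not None else [
        v for k, v in sorted(labels.legend.items()) if k != CLASS_BACKGROUND
    ]
    rows = []
    droplet_id = 0
    for name in wanted:
        cls_mask = labels.class_mask(name)
        cc = skmeasure.label(cls_mask, connectivity=2)
        for prop in skmeasure.regionprops(cc, intensity_image=intensity):
            if prop.area < min_area:
                continue
            droplet_id += 1
            cy, cx = prop.centroid
            rows.append({
                "droplet_id": droplet_id,
                "class_name": name,
                "area_px": int(prop.area),
                "area_um2": float(prop.area) * pixel_size**2,
                "centroid_x": float(cx),
                "centroid_y": float(cy),
                "mean_intensity": float(prop.intensity_mean),
            })
    return pd.DataFrame(rows, columns=DROPLET_COLUMNS)


def area_fractions(
    table: pd.DataFrame,
    field_shape: tuple[int, int],
    pixel_size: float = 1.0,
    cell_count: int = 1,
    cd_total: float | None = None,
) -> FieldQuant:
    """Per-class area fraction of the field (%) and per-cell droplet counts.

    Fractions depend only on the label geometry (never on intensity);
    per-cell quantities divide by ``cell_count``.
    """
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    field_px = float(field_shape[0] * field_shape[1])
    if field_px <= 0:
        raise ValueError("field must be non-empty")
    fractions: dict[str, float] = {}
    per_cell: dict[str, float] = {}
    if len(table):
        for name, grp in table.groupby("class_name", sort=True):
            fractions[str(name)] = float(grp["area_px"].sum()) / field_px * 100.0
            per_cell[str(name)] = float(len(grp)) / cell_count
    return FieldQuant(
        area_fraction_pct=fractions,
        cell_count=int(cell_count),
        droplets_per_cell=per_cell,
        cd_per_cell=None if cd_total is None else float(cd_total) / cell_count,
    )


def cd_uptake(image: np.ndarray, droplet_mask: np.ndarray, cell_count: int) -> float:
    """Deuterium-label uptake: total C-D channel intensity over droplet
    pixels, normalised by the number of cells in the field."""
    image = np.asarray(image, dtype=float)
    droplet_mask = np.asarray(droplet_mask, dtype=bool)
    if image.shape != droplet_mask.shape:
        raise ValueError("image and droplet_mask must have the same shape")
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    return float(image[droplet_mask].sum()) / cell_count


def ratiometric_order(
    ordered: np.ndarray,
    disordered: np.ndarray,
    floor: float = 1e-9,
) -> tuple[np.ma.MaskedArray, float | None]:
    """Per-pixel ordered/disordered lipid ratio map and its mean.

    Pixels whose disordered-channel reading falls below ``floor`` are
    masked.  The mean is None (flagged undefined) when every pixel is
    masked.
    """
    ordered = np.asarray(ordered, dtype=float)
    disordered = np.asarray(disordered, dtype=float)
    if ordered.shape != disordered.shape:
        raise ValueError("channel images must have the same shape")
    invalid = disordered < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.ma.masked_array(
            np.where(invalid, 0.0, ordered / np.where(invalid, 1.0, disordered)),
            mask=invalid,
        )
    mean = None if invalid.all() else float(ratio.mean())
    return ratio, mean


def excimer_monomer_ratio(f_excimer: float, f_monomer: float) -> float:
    """Membrane-fluidity readout: excimer / monomer fluorescence of a
    pyrene probe; a higher ratio indicates higher fluidity."""
    if f_monomer <= 0:
        raise ValueError("monomer fluorescence must be > 0")
    return float(f_excimer) / float(f_monomer)


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    tail: str = "two-sided",
) -> StatResult:
    """Two-sample comparison with a normality-gated choice of test.

    Both samples are tested with Shapiro-Wilk at ``alpha``; if neither is
    detectably non-Gaussian a Student's t-test is used (one-tailed in the
    caller-supplied direction, ``tail`` in {"greater", "less"}), otherwise
    the nonparametric Mann-Whitney U test with the same alternative.  The
    tail direction is a scientific choice the caller must make;
    ``"two-sided"`` is accepted for symmetric hypotheses.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample must have n >= 3")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    gaussian = (stats.shapiro(a).pvalue > alpha) and (stats.shapiro(b).pvalue > alpha)
    if gaussian:
        res = stats.ttest_ind(a, b, alternative=tail)
        name = "one-tailed t" if tail != "two-sided" else "two-tailed t"
    else:
        res = stats.mannwhitneyu(a, b, alternative=tail)
        name = "Mann-Whitney U"
    p = float(res.pvalue)
    return StatResult(
        test_name=name, statistic=float(res.statistic), p_value=p,
        significant=bool(p < alpha), alpha=alpha, tail=tail,
    )
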