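"""Thermogram preprocessing: temperature decoding, floor, feet, angiosomes.

Plantar thermograms arrive as 8-bit grayscale images whose intensity scale is
anchored by a per-image temperature range (t_min, t_max) taken from the
camera's colorbar. Decoding is linear. A lower temperature limit (18 °C by
default) masks out pixels too cold to be foot tissue; a subject is usable only
if, after the floor, every angiosome of both feet still contains valid pixels.

The four plantar angiosomes per foot are the territories of the medial plantar
(MPA), lateral plantar (LPA), medial calcaneal (MCA) and lateral calcaneal
(LCA) arteries. Their exact anatomical boundaries are not recoverable from a
segmentation mask, so a geometric proxy is used: the posterior ``heel_fraction``
of the foot's bounding box is the calcaneal (heel) region, the rest is plantar,
and each is split into medial/lateral halves across the foot's principal axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 18.0  # °C, lower validity limit for plantar tissue
ANGIOSOMES = ("MPA", "LPA", "MCA", "LCA")


class SingleFootError(ValueError):
    """The segmentation mask contains a single connected component.

    Feet cannot be separated, so the subject is flagged unusable.
    """


@dataclass
class TemperatureMap:
    """Per-pixel temperatures (°C) with a validity mask.

    ``valid_mask`` marks pixels that are inside the foot segmentation and, once
    :func:`apply_floor` has run, at or above the floor temperature.
    """

    temps: np.ndarray
    valid_mask: np.ndarray
    floor: float | None = None

    def __post_init__(self) -> None:
        if self.temps.shape != self.valid_mask.shape:
            raise ValueError("temps and valid_mask shapes differ")


@dataclass
class AngiosomeSet:
    """Disjoint region masks for one subject.

    ``masks`` holds boolean arrays keyed by 'L', 'R' (whole feet) and
    'L_MPA' ... 'R_LCA' (the eight foot-angiosomes). The four angiosomes of one
    foot partition that foot's mask.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    REGION_KEYS = ("L", "R") + tuple(
        f"{s}_{a}" for s in ("L", "R") for a in ANGIOSOMES
    )

    def __getitem__(self, key: str) -> np.ndarray:
        return self.masks[key]


def decode_temperature(
    gray_image: np.ndarray,
    t_min: float,
    t_max: float,
    foot_mask: np.ndarray | None = None,
) -> TemperatureMap:
    """Convert an 8-bit grayscale thermogram to temperatures.

    T(p) = t_min + g(p)/255 * (t_max - t_min); linear and monotone in g, so
    g=0 maps to t_min and g=255 to t_max.
    """
    if t_min >= t_max:
        raise ValueError(f"t_min ({t_min}) must be < t_max ({t_max})")
    gray_image = np.asarray(gray_image)
    if gray_image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit (uint8) image, got {gray_image.dtype}")
    temps = t_min + gray_image.astype(np.float64) / 255.0 * (t_max - t_min)
    if foot_mask is None:
        valid = np.ones_like(temps, dtype=bool)
    else:
        valid = np.asarray(foot_mask).astype(bool)
        if valid.shape != temps.shape:
            raise ValueError("foot_mask shape differs from image shape")
    return TemperatureMap(temps=temps, valid_mask=valid)


def apply_floor(tmap: TemperatureMap, floor: float = DEFAULT_FLOOR) -> TemperatureMap:
    """Remove pixels colder than ``floor`` from the validity mask.

    Temperatures themselves are untouched; only ``valid_mask`` shrinks.
    """
    valid = tmap.valid_mask & (tmap.temps >= floor)
    return TemperatureMap(temps=tmap.temps, valid_mask=valid, floor=floor)


def split_feet(
    foot_mask: np.ndarray, left_on_image_right: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Split a binary segmentation mask into (left_foot, right_foot) masks.

    Plantar thermograms image the sole, so the subject's left foot appears on
    the image's right by default (``left_on_image_right``). The two largest
    connected components are kept; smaller ones are discarded with a warning.

    Raises
    ------
    ValueError
        If the mask is empty.
    SingleFootError
        If only one connected component exists; the subject is unusable.
    """
    foot_mask = np.asarray(foot_mask).astype(bool)
    labeled, n = ndimage.label(foot_mask)
    if n == 0:
        raise ValueError("empty segmentation mask: no connected components")
    if n == 1:
        raise SingleFootError("mask has a single connected component; feet cannot be split")
    sizes = ndimage.sum_labels(foot_mask, labeled, index=np.arange(1, n + 1))
    if n > 2:
        logger.warning("mask has %d components; keeping the two largest", n)
    keep = np.argsort(sizes)[::-1][:2] + 1
    comp_a = labeled == keep[0]
    comp_b = labeled == keep[1]
    col_a = ndimage.center_of_mass(comp_a)[1]
    col_b = ndimage.center_of_mass(comp_b)[1]
    high, low = (comp_a, comp_b) if col_a > col_b else (comp_b, comp_a)
    return (high, low) if left_on_image_right else (low, high)


def _cross_axis_coordinate(foot_mask: np.ndarray) -> np.ndarray:
    """Signed distance of each foot pixel across the foot's principal axis.

    Positive values lie toward increasing column index. Degenerate (nearly
    isotropic or single-pixel) masks fall back to the column offset from the
    centroid.
    """
    rows, cols = np.nonzero(foot_mask)
    coords = np.stack([rows, cols], axis=1).astype(np.float64)
    center = coords.mean(axis=0)
    centered = coords - center
    if len(rows) < 3:
        return centered[:, 1]
    cov = centered.T @ centered / len(rows)
    evals, evecs = np.linalg.eigh(cov)
    # eigh sorts ascending: the minor axis (cross-track) is column 0
    cross = evecs[:, 0]
    if abs(cross[1]) < 1e-12:  # cross axis has no column component
        return centered[:, 1]
    if cross[1] < 0:
        cross = -cross
    return centered @ cross


def partition_angiosomes(
    foot_mask: np.ndarray, side: str, heel_fraction: float = 0.30
) -> dict[str, np.ndarray]:
    """Partition one foot mask into the four plantar angiosome masks.

    The posterior ``heel_fraction`` of the foot's bounding-box rows (toes-up
    orientation: the bottom of the image) is the calcaneal region, split into
    MCA (medial) and LCA (lateral) across the principal axis; the anterior rest
    is split into MPA (medial) and LPA (lateral). Which image side is medial
    depends on ``side``: the left foot appears on the image's right, so its
    medial edge faces smaller columns, and vice versa.

    Returns a dict MPA/LPA/MCA/LCA of disjoint masks whose union is the foot.
    """
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    foot_mask = np.asarray(foot_mask).astype(bool)
    if not foot_mask.any():
        raise ValueError("empty foot mask")
    if not 0 < heel_fraction < 1:
        raise ValueError("heel_fraction must be in (0, 1)")

    rows, cols = np.nonzero(foot_mask)
    r0, r1 = rows.min(), rows.max()
    height = r1 - r0 + 1
    heel_cut = r0 + int(round((1.0 - heel_fraction) * height))

    s = _cross_axis_coordinate(foot_mask)
    # medial side of the left foot (image right) faces decreasing columns
    medial = s <= 0 if side == "L" else s >= 0
    heel = rows >= heel_cut

    out = {a: np.zeros_like(foot_mask) for a in ANGIOSOMES}
    out["MPA"][rows[~heel & medial], cols[~heel & medial]] = True
    out["LPA"][rows[~heel & ~medial], cols[~heel & ~medial]] = True
    out["MCA"][rows[heel & medial], cols[heel & medial]] = True
    out["LCA"][rows[heel & ~medial], cols[heel & ~medial]] = True
    return out


def build_angiosome_set(
    foot_mask: np.ndarray,
    heel_fraction: float = 0.30,
    left_on_image_right: bool = True,
) -> AngiosomeSet:
    """Split feet and partition both into angiosomes."""
    left, right = split_feet(foot_mask, left_on_image_right=left_on_image_right)
    masks: dict[str, np.ndarray] = {"L": left, "R": right}
    for side, foot in (("L", left), ("R", right)):
        parts = partition_angiosomes(foot, side, heel_fraction=heel_fraction)
        for a, m in parts.items():
            masks[f"{side}_{a}"] = m
    return AngiosomeSet(masks=masks)


@dataclass
class QCResult:
    keep: bool
    reasons: list[str] = field(default_factory=list)


def subject_qc(angiosomes: AngiosomeSet, tmap: TemperatureMap) -> QCResult:
    """Keep a subject only if all eight angiosomes have valid pixels.

    An angiosome entirely below the temperature floor has no valid pixels (its
    mean would be undefined), so the subject is dropped with a logged reason.
    """
    reasons = []
    for side in ("L", "R"):
        for a in ANGIOSOMES:
            key = f"{side}_{a}"
            n_valid = int((angiosomes[key] & tmap.valid_mask).sum())
            if n_valid == 0:
                reasons.append(f"{key} has no valid pixels after the temperature floor")
    if reasons:
        logger.info("subject dropped: %s", "; ".join(reasons))
    return QCResult(keep=not reasons, reasons=reasons)
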