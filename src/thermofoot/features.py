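"""The 188-feature plantar-temperature vector.

Feature nomenclature: a leading 'L'/'R' names the foot, followed by the
angiosome (omitted for whole-foot features), followed by the statistic —
lowercase for ordinary moments (mean, std, max, min, skew, kurtosis) and
capitals for the composite indices: HSE (hot spot estimator), ET (estimated
temperature), ETD (estimated temperature difference), TCI (thermal change
index) and NTR_C1..C5 (normalized temperature range classes). Bilateral
regions pool both feet: 'MPA_mean' is the mean over left and right MPA pixels
together, 'Foot_ETD' the absolute left-right whole-foot mean difference.

Default registry inventory (188 features):

* 10 unilateral regions (L, R and the 8 foot-angiosomes) x 12 statistics
  {mean, std, max, min, skew, kurtosis, HSE, NTR_C1..C5} = 120
* 4 bilateral angiosomes (MPA, LPA, MCA, LCA) x 14 statistics
  {mean, std, max, min, skew, kurtosis, HSE, ET, ETD, NTR_C1..C5} = 56
* bilateral Foot x 12 {mean, std, max, min, ET, ETD, TCI, NTR_C1..C5} = 12

The composite-index formulas (HSE top fraction, pooled ET, subject-normalized
NTR bins, TCI reference temperatures) are reconstructions of indices defined in
the angiosome-thermometry literature; every knob is exposed on
:class:`FeatureConfig` so alternative definitions are drop-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ANGIOSOMES, AngiosomeSet, TemperatureMap

MOMENT_STATS = ("mean", "std", "max", "min", "skew", "kurtosis")


def default_tci_reference() -> dict[str, float]:
    """Healthy-control angiosome reference temperatures (°C)."""
    return {"MPA": 30.5, "LPA": 30.0, "MCA": 29.0, "LCA": 28.5}


@dataclass
class FeatureConfig:
    """Knobs for the composite temperature indices."""

    hse_fraction: float = 0.05      # hottest fraction of pixels averaged by HSE
    ntr_classes: int = 5            # number of normalized-range bins
    floor: float = 18.0             # °C, lower anchor of the NTR normalization
    tci_reference: dict[str, float] = field(default_factory=default_tci_reference)


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    region: str     # 'L', 'R', 'L_MPA'..'R_LCA', 'MPA'..'LCA', 'Foot'
    statistic: str  # 'mean', .., 'HSE', 'ET', 'ETD', 'TCI', 'NTR_C1'..


def build_default_registry(n_ntr_classes: int = 5) -> list[RegistryEntry]:
    """The default 188-entry feature registry, in stable order."""
    ntr = tuple(f"NTR_C{k}" for k in range(1, n_ntr_classes + 1))
    entries: list[RegistryEntry] = []

    unilateral = ["L", "R"] + [f"{s}_{a}" for s in ("L", "R") for a in ANGIOSOMES]
    for region in unilateral:
        for stat in MOMENT_STATS + ("HSE",) + ntr:
            entries.append(RegistryEntry(f"{region}_{stat}", region, stat))

    for region in ANGIOSOMES:
        for stat in MOMENT_STATS + ("HSE", "ET", "ETD") + ntr:
            entries.append(RegistryEntry(f"{region}_{stat}", region, stat))

    for stat in ("mean", "std", "max", "min", "ET", "ETD", "TCI") + ntr:
        entries.append(RegistryEntry(f"Foot_{stat}", "Foot", stat))

    names = [e.name for e in entries]
    assert len(names) == len(set(names)), "registry names must be unique"
    return entries


def basic_stats(region_temps: np.ndarray) -> dict[str, float]:
    """Population moments of a region's temperatures.

    skew = m3 / m2^1.5 and kurtosis = m4 / m2^2 - 3 (excess), with the
    zero-variance convention skew = kurtosis = 0.
    """
    x = np.asarray(region_temps, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2 - 3.0
    return {
        "mean": mean,
        "std": math.sqrt(m2),
        "max": float(x.max()),
        "min": float(x.min()),
        "skew": skew,
        "kurtosis": kurt,
    }


def hse(region_temps: np.ndarray, fraction: float = 0.05) -> float:
    """Hot spot estimator: mean of the hottest ``ceil(fraction * n)`` pixels."""
    x = np.asarray(region_temps, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    k = max(1, math.ceil(fraction * x.size))
    hottest = np.partition(x, x.size - k)[x.size - k:]
    return float(hottest.mean())


def ntr(
    region_temps: np.ndarray,
    subject_max: float,
    floor: float = 18.0,
    n_classes: int = 5,
) -> np.ndarray:
    """Normalized temperature range class fractions.

    Each pixel is normalized to u = (T - floor) / (T_subject_max - floor) and
    binned into ``n_classes`` equal classes of [0, 1] (last bin closed); the
    returned fractions sum to 1. A degenerate subject (max == floor) puts all
    mass in class 1.
    """
    x = np.asarray(region_temps, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    span = subject_max - floor
    out = np.zeros(n_classes)
    if span <= 0:
        out[0] = 1.0
        return out
    u = (x - floor) / span
    idx = np.clip(np.floor(u * n_classes).astype(int), 0, n_classes - 1)
    counts = np.bincount(idx, minlength=n_classes)
    return counts / x.size


def et(left_region_temps: np.ndarray, right_region_temps: np.ndarray) -> float:
    """Estimated temperature: pixel-count-weighted mean of the pooled bilateral region."""
    left = np.asarray(left_region_temps, dtype=np.float64).ravel()
    right = np.asarray(right_region_temps, dtype=np.float64).ravel()
    if left.size == 0 or right.size == 0:
        raise ValueError("both regions must be non-empty")
    return float(np.concatenate([left, right]).mean())


def etd(left_region_temps: np.ndarray, right_region_temps: np.ndarray) -> float:
    """Estimated temperature difference: |mean(left) - mean(right)|."""
    left = np.asarray(left_region_temps, dtype=np.float64).ravel()
    right = np.asarray(right_region_temps, dtype=np.float64).ravel()
    if left.size == 0 or right.size == 0:
        raise ValueError("both regions must be non-empty")
    return float(abs(left.mean() - right.mean()))


def tci(angiosome_means: dict[str, float], reference: dict[str, float]) -> float:
    """Thermal change index: mean absolute deviation of the eight angiosome
    means from healthy-control reference temperatures."""
    devs = []
    for side in ("L", "R"):
        for a in ANGIOSOMES:
            devs.append(abs(angiosome_means[f"{side}_{a}"] - reference[a]))
    return float(np.mean(devs))


def _region_pixels(
    region: str, tmap: TemperatureMap, angiosomes: AngiosomeSet
) -> np.ndarray:
    """Valid temperatures of a (possibly pooled bilateral) region."""
    if region == "Foot":
        mask = angiosomes["L"] | angiosomes["R"]
    elif region in ANGIOSOMES:
        mask = angiosomes[f"L_{region}"] | angiosomes[f"R_{region}"]
    else:
        mask = angiosomes[region]
    return tmap.temps[mask & tmap.valid_mask]


def extract_features(
    tmap: TemperatureMap,
    angiosomes: AngiosomeSet,
    registry: list[RegistryEntry] | None = None,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Compute one named value per registry entry, in registry order.

    The subject must have passed QC: an empty region raises, naming it.
    """
    if registry is None:
        registry = build_default_registry()
    if config is None:
        config = FeatureConfig()

    pixels: dict[str, np.ndarray] = {}
    regions = {e.region for e in registry}
    for region in regions:
        px = _region_pixels(region, tmap, angiosomes)
        if px.size == 0:
            raise ValueError(f"region {region} has no valid pixels; run subject QC first")
        pixels[region] = px

    subject_max = float(np.concatenate(list(pixels.values())).max())
    angio_means = {
        f"{side}_{a}": float(_region_pixels(f"{side}_{a}", tmap, angiosomes).mean())
        for side in ("L", "R")
        for a in ANGIOSOMES
    }

    moments = {r: basic_stats(px) for r, px in pixels.items()}
    ntrs = {
        r: ntr(px, subject_max, floor=config.floor, n_classes=config.ntr_classes)
        for r, px in pixels.items()
    }

    def bilateral_sides(region: str) -> tuple[np.ndarray, np.ndarray]:
        if region == "Foot":
            return (
                tmap.temps[angiosomes["L"] & tmap.valid_mask],
                tmap.temps[angiosomes["R"] & tmap.valid_mask],
            )
        return (
            tmap.temps[angiosomes[f"L_{region}"] & tmap.valid_mask],
            tmap.temps[angiosomes[f"R_{region}"] & tmap.valid_mask],
        )

    out: dict[str, float] = {}
    for entry in registry:
        region, stat = entry.region, entry.statistic
        if stat in MOMENT_STATS:
            value = moments[region][stat]
        elif stat == "HSE":
            value = hse(pixels[region], fraction=config.hse_fraction)
        elif stat == "ET":
            value = et(*bilateral_sides(region))
        elif stat == "ETD":
            value = etd(*bilateral_sides(region))
        elif stat == "TCI":
            value = tci(angio_means, config.tci_reference)
        elif stat.startswith("NTR_C"):
            value = float(ntrs[region][int(stat.removeprefix("NTR_C")) - 1])
        else:
            raise ValueError(f"unknown statistic {stat!r} in registry")
        out[entry.name] = value
    return out


def extract_table(
    subjects: list[tuple[str, TemperatureMap, AngiosomeSet, int]],
    registry: list[RegistryEntry] | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table: one row per (id, map, angiosomes, label) subject."""
    if registry is None:
        registry = build_default_registry()
    rows = []
    for sid, tmap, angios, label in subjects:
        vec = extract_features(tmap, angios, registry=registry, config=config)
        vec["label"] = label
        rows.append(pd.Series(vec, name=sid))
    return pd.DataFrame(rows)
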