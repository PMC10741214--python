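"""Synthetic plantar thermograms and planted feature tables.

Two generators make every pipeline stage testable without patient data:

* **Thermal phantoms** — grayscale images of two foot-shaped blobs whose
  angiosome regions carry configured mean temperatures. Healthy subjects show
  the symmetric, butterfly-like pattern of intact perfusion; diabetic subjects
  receive a left-right asymmetry offset on one randomly chosen foot plus focal
  Gaussian hot spots mimicking local inflammation. Temperatures are clipped to
  the colorbar range and encoded linearly to 8 bits, background at gray 0, so
  the decode step is an exact inverse up to quantization.

* **Planted tables** — feature matrices where a known subset of columns
  separates the classes by a configured standardized effect size, optionally
  with a block of near-duplicate correlated columns. For a standardized shift
  d between classes, the single-feature ROC AUC is Phi(d / sqrt(2)) in closed
  form, which anchors the recovery benchmarks for the feature selectors.

Angiosome ground truth aligns with the preprocessing stage by construction:
the phantom paints temperatures using the very same geometric partition rule
that preprocessing applies when it re-reads the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import ANGIOSOMES, partition_angiosomes, split_feet

SIDES = ("L", "R")
ANGIO_KEYS = tuple(f"{s}_{a}" for s in SIDES for a in ANGIOSOMES)


def default_angiosome_means() -> dict[str, float]:
    """Healthy butterfly pattern: both feet warm, heel slightly cooler (°C)."""
    per_foot = {"MPA": 30.5, "LPA": 30.0, "MCA": 29.0, "LCA": 28.5}
    return {f"{s}_{a}": t for s in SIDES for a, t in per_foot.items()}


@dataclass
class PhantomConfig:
    """Parameters of the thermal phantom generator.

    Temperatures in °C. ``class_counts`` is (n_diabetic, n_healthy), matching
    the imbalance regimes of public plantar-thermogram datasets (e.g. 88:34,
    210:101). ``n_frozen_subjects`` marks that many subjects with one angiosome
    forced below the validity floor, to exercise subject-level QC.
    """

    image_height: int = 120
    image_width: int = 160
    t_min: float = 15.0
    t_max: float = 40.0
    healthy_angiosome_means: dict[str, float] = field(default_factory=default_angiosome_means)
    diabetic_asymmetry_delta: float = 2.0
    hotspot_count: int = 3
    hotspot_delta: float = 3.0
    hotspot_sigma: float = 5.0
    noise_sd: float = 0.3
    class_counts: tuple[int, int] = (88, 34)
    heel_fraction: float = 0.30
    n_frozen_subjects: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_min >= self.t_max:
            raise ValueError("t_min must be < t_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be >= 0")
        for key, t in self.healthy_angiosome_means.items():
            if not self.t_min < t < self.t_max:
                raise ValueError(f"angiosome mean {key}={t} outside ({self.t_min}, {self.t_max})")


@dataclass
class PhantomSubject:
    subject_id: str
    gray_image: np.ndarray          # uint8, background at 0
    t_range: tuple[float, float]
    foot_mask: np.ndarray           # bool, two connected components
    label: int                      # 1 = diabetic, 0 = healthy
    truth: dict[str, float]         # constructed angiosome mean temperatures


def _foot_blob(height: int, width: int, center_col: float) -> np.ndarray:
    """One foot: a long plantar ellipse merged with a heel lobe."""
    rr, cc = np.mgrid[0:height, 0:width]
    sole = ((rr - 0.42 * height) / (0.33 * height)) ** 2 + (
        (cc - center_col) / (0.095 * width)
    ) ** 2 <= 1.0
    heel = ((rr - 0.78 * height) / (0.12 * height)) ** 2 + (
        (cc - center_col) / (0.075 * width)
    ) ** 2 <= 1.0
    return sole | heel


def render_foot_masks(height: int, width: int) -> np.ndarray:
    """Two mirrored foot blobs; subject's left foot on the image's right."""
    left = _foot_blob(height, width, center_col=0.70 * width)
    right = _foot_blob(height, width, center_col=0.30 * width)
    return left | right


def generate_phantom_subject(
    config: PhantomConfig,
    label: int,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "s000",
    frozen_angiosome: bool = False,
) -> PhantomSubject:
    """Render one synthetic subject.

    Healthy subjects get the configured symmetric angiosome means; diabetic
    subjects additionally receive ``diabetic_asymmetry_delta`` on one randomly
    chosen foot's angiosomes and ``hotspot_count`` Gaussian hot spots. The
    temperature field is clipped to [t_min, t_max] and linearly encoded to
    8-bit grayscale; identical seeds give bit-identical images.
    """
    rng = np.random.default_rng(rng)
    h, w = config.image_height, config.image_width
    foot_mask = render_foot_masks(h, w)
    if not foot_mask.any():
        raise ValueError("zero-area foot mask; image too small for the foot template")

    left, right = split_feet(foot_mask)
    angio = {}
    for side, foot in (("L", left), ("R", right)):
        parts = partition_angiosomes(foot, side, heel_fraction=config.heel_fraction)
        for a, m in parts.items():
            angio[f"{side}_{a}"] = m

    truth = dict(config.healthy_angiosome_means)
    if label == 1:
        warm_side = SIDES[rng.integers(2)]
        for a in ANGIOSOMES:
            truth[f"{warm_side}_{a}"] += config.diabetic_asymmetry_delta

    temps = np.full((h, w), config.t_min, dtype=np.float64)
    for key, mask in angio.items():
        temps[mask] = truth[key]

    if label == 1 and config.hotspot_count > 0:
        rows, cols = np.nonzero(foot_mask)
        rr, cc = np.mgrid[0:h, 0:w]
        for _ in range(config.hotspot_count):
            k = rng.integers(len(rows))
            d2 = (rr - rows[k]) ** 2 + (cc - cols[k]) ** 2
            bump = config.hotspot_delta * np.exp(-d2 / (2 * config.hotspot_sigma**2))
            temps[foot_mask] += bump[foot_mask]

    if config.noise_sd > 0:
        temps[foot_mask] += rng.normal(0.0, config.noise_sd, size=int(foot_mask.sum()))

    if frozen_angiosome:
        key = ANGIO_KEYS[rng.integers(len(ANGIO_KEYS))]
        temps[angio[key]] = config.t_min
        truth[key] = config.t_min

    temps = np.clip(temps, config.t_min, config.t_max)
    span = config.t_max - config.t_min
    gray = np.zeros((h, w), dtype=np.uint8)
    gray[foot_mask] = np.round(255.0 * (temps[foot_mask] - config.t_min) / span).astype(np.uint8)

    return PhantomSubject(
        subject_id=subject_id,
        gray_image=gray,
        t_range=(config.t_min, config.t_max),
        foot_mask=foot_mask,
        label=label,
        truth=truth,
    )


def generate_phantom_dataset(
    config: PhantomConfig, out_dir: str | Path | None = None
) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate the full cohort plus its manifest.

    Exactly ``n_diabetic + n_healthy`` subjects, diabetic first. Each subject
    draws from an independent stream seeded by (dataset seed, subject index),
    so any subject is reproducible in isolation. When ``out_dir`` is given,
    images and masks are written as 8-bit PNGs and the manifest as CSV with
    columns id, image_path, mask_path, t_min, t_max, label.
    """
    n_diabetic, n_healthy = config.class_counts
    labels = [1] * n_diabetic + [0] * n_healthy
    subjects, rows = [], []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for idx, label in enumerate(labels):
        rng = np.random.default_rng([config.seed, idx])
        subj = generate_phantom_subject(
            config,
            label,
            rng=rng,
            subject_id=f"s{idx:03d}",
            frozen_angiosome=idx < config.n_frozen_subjects,
        )
        subjects.append(subj)
        row = {
            "id": subj.subject_id,
            "image_path": "",
            "mask_path": "",
            "t_min": config.t_min,
            "t_max": config.t_max,
            "label": label,
        }
        if out_dir is not None:
            img_path = out_dir / f"{subj.subject_id}_thermo.png"
            mask_path = out_dir / f"{subj.subject_id}_mask.png"
            Image.fromarray(subj.gray_image, mode="L").save(img_path)
            Image.fromarray((subj.foot_mask * 255).astype(np.uint8), mode="L").save(mask_path)
            row["image_path"] = str(img_path)
            row["mask_path"] = str(mask_path)
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return subjects, manifest


@dataclass
class PlantedTableConfig:
    """Parameters of the planted feature-table benchmark.

    ``effect_size`` is the standardized mean shift of informative features
    between classes (single-feature AUC = Phi(effect_size / sqrt(2))). A block
    of ``correlation_block_size`` noise features with pairwise correlation
    ``correlation_r`` exercises the correlation pruning step. Majority class is
    labeled 1 (cases), minority 0, matching case-heavy screening datasets.
    """

    n_majority: int = 88
    n_minority: int = 34
    n_features: int = 141
    n_informative: int = 10
    effect_size: float = 3.0
    correlation_block_size: int = 0
    correlation_r: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if abs(self.correlation_r) > 1:
            raise ValueError("|correlation_r| must be <= 1")
        if self.correlation_block_size + self.n_informative > self.n_features:
            raise ValueError("informative + correlated block exceed n_features")


def generate_planted_table(
    config: PlantedTableConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Sample the planted table.

    Returns the subjects x features DataFrame (label column last, majority
    class = 1) and the list of informative feature names. Informative columns
    are shifted by ``effect_size`` (in SD units) in the majority class; the
    correlated block shares a latent factor giving pairwise correlation
    ``correlation_r``; everything else is independent standard normal noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_majority + config.n_minority
    y = np.concatenate([np.ones(config.n_majority, int), np.zeros(config.n_minority, int)])

    X = rng.standard_normal((n, config.n_features))
    names = [f"f{i:03d}" for i in range(config.n_features)]

    informative_idx = rng.choice(config.n_features, size=config.n_informative, replace=False)
    X[np.ix_(y == 1, informative_idx)] += config.effect_size

    if config.correlation_block_size >= 2:
        r = config.correlation_r
        free = sorted(set(range(config.n_features)) - set(informative_idx.tolist()))
        block = free[: config.correlation_block_size]
        z = rng.standard_normal(n)
        for j in block:
            X[:, j] = np.sqrt(abs(r)) * z + np.sqrt(1 - abs(r)) * rng.standard_normal(n)

    df = pd.DataFrame(X, columns=names)
    df["label"] = y
    informative = [names[i] for i in sorted(informative_idx.tolist())]
    return df, informative
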