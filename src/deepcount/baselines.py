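"""Area-based counting baseline.

The classical alternative to count regression: convert to YCbCr, isolate
fruit pixels by chroma thresholds (ripe/half-ripe fruit sit at high Cr
and low-to-mid Cb), denoise the mask with mathematical morphology, and
divide the total fruit area by a calibrated per-fruit unit area.  The
unit area is fit by grid search to minimize the summed absolute count
error on calibration scenes.  The method's known failure mode is
occlusion: overlapped or hidden fruit contribute less area than a full
disk, so the count is biased low on cluttered scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.morphology import closing, disk, opening


@dataclass
class AreaBaselineConfig:
    """Chroma thresholds (0-255 axes), morphology plan, calibrated unit area."""

    cr_min: int = 150
    cb_max: int = 120
    morphology_plan: tuple[tuple[str, int], ...] = (("opening", 1), ("closing", 2))
    unit_area: float | None = None   # pixels per fruit; set by calibration

    def __post_init__(self) -> None:
        if not (0 <= self.cr_min <= 255 and 0 <= self.cb_max <= 255):
            raise ValueError("chroma thresholds must be in [0, 255]")
        for op, r in self.morphology_plan:
            if op not in ("opening", "closing"):
                raise ValueError(f"unknown morphology op {op!r}")
            if r < 1:
                raise ValueError("structuring radius must be >= 1")
        if self.unit_area is not None and self.unit_area <= 0:
            raise ValueError("unit_area must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "AreaBaselineConfig":
        d = json.loads(text)
        d["morphology_plan"] = tuple((op, r) for op, r in d["morphology_plan"])
        return cls(**d)


def rgb_to_ycbcr(image: np.ndarray) -> np.ndarray:
    """BT.601 full-range RGB -> (Y, Cb, Cr), uint8.

    Gray maps to (g, 128, 128); pure red to about (76, 85, 255).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected H×W×3 RGB, got shape {img.shape}")
    rgb = img.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    out = np.stack([y, cb, cr], axis=-1)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def segment_fruit_mask(image: np.ndarray, config: AreaBaselineConfig
                       ) -> np.ndarray:
    """Binary fruit-pixel mask: chroma thresholds then the morphology plan."""
    ycc = rgb_to_ycbcr(image)
    mask = (ycc[..., 2] >= config.cr_min) & (ycc[..., 1] <= config.cb_max)
    for op, r in config.morphology_plan:
        se = disk(r)
        mask = opening(mask, se) if op == "opening" else closing(mask, se)
    return mask.astype(bool)


def area_count(mask: np.ndarray, unit_area: float) -> float:
    """Count = total fruit pixels / calibrated pixels-per-fruit."""
    if unit_area <= 0:
        raise ValueError("unit_area must be > 0")
    return float(np.count_nonzero(mask)) / float(unit_area)


def calibrate_unit_area(scenes: Sequence[tuple[np.ndarray, int]],
                        config: AreaBaselineConfig,
                        grid: Iterable[float] | None = None) -> float:
    """Grid-search the unit area minimizing sum |area count - actual count|.

    Ties break toward the smaller unit area.  The default grid is 50
    log-spaced candidates between 0.25x and 4x the mean segmented area
    per fruit over the calibration scenes.
    """
    scenes = list(scenes)
    if not scenes:
        raise ValueError("calibration requires at least one scene")
    areas = np.array([float(np.count_nonzero(segment_fruit_mask(img, config)))
                      for img, _ in scenes])
    counts = np.array([float(c) for _, c in scenes])
    if grid is None:
        total = counts.sum()
        mean_per_fruit = areas.sum() / total if total > 0 else 1.0
        mean_per_fruit = max(mean_per_fruit, 1.0)
        grid = np.geomspace(0.25 * mean_per_fruit, 4.0 * mean_per_fruit, 50)
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("calibration grid is empty")
    best, best_err = None, np.inf
    for ua in grid:
        if ua <= 0:
            raise ValueError("grid unit areas must be > 0")
        err = float(np.abs(areas / ua - counts).sum())
        if err < best_err:  # strict: ties keep the earlier (smaller) candidate
            best, best_err = ua, err
    return best


def area_predictor(config: AreaBaselineConfig):
    """Return an image -> real count callable using the calibrated config."""
    if config.unit_area is None:
        raise ValueError("config.unit_area is not calibrated")

    def predict(image: np.ndarray) -> float:
        return area_count(segment_fruit_mask(image, config), config.unit_area)

    return predict


def save_config(config: AreaBaselineConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_json())


def load_config(path: str | Path) -> AreaBaselineConfig:
    return AreaBaselineConfig.from_json(Path(path).read_text())
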