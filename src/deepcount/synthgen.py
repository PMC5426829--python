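"""Synthetic tomato-scene generator with exact count labels.

A scene is rendered in a fixed order: the canvas is filled with green
and brown background circles ("foliage and soil"), blurred with a
Gaussian filter, then variable-sized fruit disks are drawn at random
positions with radial shading, a specular highlight and optional
per-fruit shadow; foliage blobs may then occlude fruit, and finally a
low-frequency multiplicative illumination field is applied.  The label
is the exact number of fruit disks drawn: occluded fruit still count, as
long as at least ``min_visible_fraction`` of each disk stays visible
(fruit buried deeper than that are re-placed so the label stays honest).

The same (config, seed) pair always renders byte-identical pixels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

RIPE = "ripe"
HALF_RIPE = "half_ripe"

# base colors: RGB triples.  Background colors are jittered mostly in
# brightness so browns stay chromatically brown (Cr below the fruit hues):
# soil/branch pixels and tomato pixels must remain separable in chroma,
# which is the premise of area-based fruit segmentation.
_GREENS = ((34, 80, 30), (52, 110, 44), (72, 132, 58), (24, 64, 28))
_BROWNS = ((100, 78, 50), (84, 66, 44), (70, 54, 34))
_RIPE_BASE = (205, 32, 24)
_HALF_RIPE_BASE = (232, 142, 34)


class SceneConfigError(ValueError):
    """Raised when a SceneConfig violates its invariants."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene distribution.

    Counts are drawn uniformly from ``fruit_count_range`` (inclusive);
    radii uniformly from ``fruit_radius_range`` as fractions of the image
    side.  ``ripeness_mix`` is the probability a fruit is ripe (red)
    rather than half-ripe (orange).  ``illumination_amplitude`` scales a
    smooth multiplicative brightness field; ``shadow_prob`` darkens
    individual fruit; ``occluder_prob`` draws a foliage blob over the
    fruit layer near a fruit.
    """

    image_size: int = 128
    fruit_count_range: tuple[int, int] = (1, 40)
    fruit_radius_range: tuple[float, float] = (0.03, 0.12)
    ripeness_mix: float = 0.7
    background_blob_count_range: tuple[int, int] = (40, 80)
    background_palette: tuple[tuple[int, int, int], ...] = _GREENS + _BROWNS
    background_jitter: int = 6   # per-channel; brightness varies 0.8-1.2x
    blur_sigma: float = 2.0
    full_image_blur_sigma: float = 0.0  # light camera softness; off by default
    illumination_amplitude: float = 0.3
    shadow_prob: float = 0.25
    occluder_prob: float = 0.2
    min_visible_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise SceneConfigError("image_size must be >= 16")
        lo, hi = self.fruit_count_range
        if lo < 0 or hi < lo:
            raise SceneConfigError("fruit_count_range must satisfy 0 <= low <= high")
        rlo, rhi = self.fruit_radius_range
        if not (0.0 < rlo <= rhi < 0.5):
            raise SceneConfigError("fruit_radius_range fractions must lie in (0, 0.5)")
        for name in ("ripeness_mix", "illumination_amplitude", "shadow_prob",
                     "occluder_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SceneConfigError(f"{name} must be in [0, 1]")
        if not (0.0 < self.min_visible_fraction <= 1.0):
            raise SceneConfigError("min_visible_fraction must be in (0, 1]")
        blo, bhi = self.background_blob_count_range
        if blo < 0 or bhi < blo:
            raise SceneConfigError("background_blob_count_range invalid")
        if self.blur_sigma < 0 or self.full_image_blur_sigma < 0:
            raise SceneConfigError("blur sigmas must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for key in ("fruit_count_range", "fruit_radius_range",
                    "background_blob_count_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "background_palette" in d:
            d["background_palette"] = tuple(tuple(c) for c in d["background_palette"])
        return cls(**d)


@dataclass
class FruitRecord:
    center: tuple[float, float]  # (x, y) pixels
    radius: float                # pixels
    ripeness: str                # RIPE or HALF_RIPE
    visible_fraction: float


@dataclass
class LabeledImage:
    pixels: np.ndarray          # H×W×3 uint8
    count: int
    fruits: list[FruitRecord]
    seed: int


@dataclass
class DatasetManifest:
    split_name: str
    entries: list[tuple[str, int]]   # (image path relative to root, count)
    config_snapshot: SceneConfig
    seed: int
    root: Path = field(default_factory=Path)

    def paths(self) -> list[Path]:
        return [self.root / p for p, _ in self.entries]


# ----------------------------------------------------------------------
# rendering primitives


def _disk_mask(size: int, cx: float, cy: float, r: float):
    """Boolean mask of the disk within its clipped bounding box; returns
    (y0, y1, x0, x1, mask, d2) with d2 the squared distance / r^2 field."""
    x0 = max(int(np.floor(cx - r)) - 1, 0)
    x1 = min(int(np.ceil(cx + r)) + 2, size)
    y0 = max(int(np.floor(cy - r)) - 1, 0)
    y1 = min(int(np.ceil(cy + r)) + 2, size)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (r * r)
    return y0, y1, x0, x1, d2 <= 1.0, d2


def _paint_disk(img: np.ndarray, cx: float, cy: float, r: float,
                color: np.ndarray) -> None:
    y0, y1, x0, x1, mask, _ = _disk_mask(img.shape[0], cx, cy, r)
    img[y0:y1, x0:x1][mask] = color


def _paint_fruit(img: np.ndarray, owner: np.ndarray, idx: int, cx: float,
                 cy: float, r: float, base: np.ndarray, light: np.ndarray,
                 shadow: bool) -> None:
    """Shaded fruit disk: darker rim, offset specular highlight."""
    size = img.shape[0]
    y0, y1, x0, x1, mask, d2 = _disk_mask(size, cx, cy, r)
    shade = (1.0 - 0.45 * d2[mask])[:, None]
    col = base[None, :] * shade
    # specular highlight offset toward the light direction
    hx, hy = cx + 0.4 * r * light[0], cy + 0.4 * r * light[1]
    yy, xx = np.ogrid[y0:y1, x0:x1]
    dh2 = ((xx - hx) ** 2 + (yy - hy) ** 2) / max((0.28 * r) ** 2, 1e-6)
    glint = np.exp(-0.5 * dh2)[mask][:, None]
    col = col + 0.85 * glint * (255.0 - col)
    if shadow:
        col *= 0.55
    img[y0:y1, x0:x1][mask] = col
    owner[y0:y1, x0:x1][mask] = idx


def _stamp_owner(owner: np.ndarray, idx: int, cx: float, cy: float, r: float) -> int:
    """Write ``idx`` into the ownership map; returns the disk pixel count."""
    y0, y1, x0, x1, mask, _ = _disk_mask(owner.shape[0], cx, cy, r)
    owner[y0:y1, x0:x1][mask] = idx
    return int(mask.sum())


def _illumination_field(size: int, amplitude: float,
                        rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0.0:
        return np.ones((size, size), dtype=np.float32)
    noise = rng.standard_normal((size, size))
    smooth = gaussian_filter(noise, sigma=size / 4.0)
    peak = np.max(np.abs(smooth))
    if peak > 0:
        smooth = smooth / peak
    return (1.0 + amplitude * smooth).astype(np.float32)


# ----------------------------------------------------------------------


def render_scene(config: SceneConfig, seed: int) -> LabeledImage:
    """Render one synthetic scene; deterministic in (config, seed)."""
    rng = np.random.default_rng(seed)
    size = config.image_size

    # --- background: green/brown circles, then Gaussian blur
    img = np.zeros((size, size, 3), dtype=np.float32)
    img[:] = np.array(config.background_palette[0], dtype=np.float32) * 0.6
    blo, bhi = config.background_blob_count_range
    n_blobs = int(rng.integers(blo, bhi + 1))
    palette = np.array(config.background_palette, dtype=np.float32)
    for _ in range(n_blobs):
        base = palette[rng.integers(len(palette))]
        bright = rng.uniform(0.8, 1.2)
        jit = rng.uniform(-config.background_jitter, config.background_jitter, 3)
        color = np.clip(base * bright + jit, 0, 255)
        r = rng.uniform(0.05, 0.25) * size
        cx, cy = rng.uniform(0, size, 2)
        _paint_disk(img, cx, cy, r, color)
    if config.blur_sigma > 0:
        for ch in range(3):
            img[:, :, ch] = gaussian_filter(img[:, :, ch], config.blur_sigma)

    # --- plan fruit and occluders
    lo, hi = config.fruit_count_range
    count = int(rng.integers(lo, hi + 1))
    rlo, rhi = config.fruit_radius_range
    light = rng.uniform(-1.0, 1.0, 2)
    norm = np.hypot(*light)
    light = light / norm if norm > 0 else np.array([1.0, 0.0])

    radii = rng.uniform(rlo, rhi, count) * size
    centers = np.empty((count, 2))
    for i, r in enumerate(radii):
        m = min(r, (size - 1) / 2.0)
        centers[i] = rng.uniform(m, size - 1 - m, 2)
    ripe = rng.random(count) < config.ripeness_mix
    shadowed = rng.random(count) < config.shadow_prob
    jitters = rng.uniform(-18, 18, (count, 3))
    has_occ = rng.random(count) < config.occluder_prob
    occ_scale = rng.uniform(0.6, 1.3, count)
    occ_angle = rng.uniform(0, 2 * np.pi, count)
    occ_dist = rng.uniform(0.3, 1.1, count)
    occ_jit = rng.uniform(-config.background_jitter, config.background_jitter,
                          (count, 3))
    occ_bright = rng.uniform(0.8, 1.2, count)
    occ_color_idx = rng.integers(0, len(_GREENS), count)

    def occluder_geometry(i: int) -> tuple[float, float, float]:
        r = radii[i] * occ_scale[i]
        d = occ_dist[i] * radii[i]
        cx = centers[i, 0] + d * np.cos(occ_angle[i])
        cy = centers[i, 1] + d * np.sin(occ_angle[i])
        return cx, cy, r

    # --- visibility resolution: re-place fruit buried below the floor
    order = list(range(count))
    disk_px = np.zeros(count)
    visible = np.ones(count)
    for round_ in range(120):
        owner = np.full((size, size), -1, dtype=np.int32)
        for i in order:
            disk_px[i] = _stamp_owner(owner, i, centers[i, 0], centers[i, 1],
                                      radii[i])
        for i in order:
            if has_occ[i]:
                cx, cy, r = occluder_geometry(i)
                _stamp_owner(owner, -2, cx, cy, r)
        own_counts = np.bincount(owner[owner >= 0].ravel(), minlength=count) \
            if count else np.zeros(0)
        visible = np.where(disk_px > 0, own_counts / np.maximum(disk_px, 1), 0.0)
        violators = [i for i in range(count)
                     if visible[i] < config.min_visible_fraction]
        if not violators:
            break
        for i in violators:
            m = min(radii[i], (size - 1) / 2.0)
            centers[i] = rng.uniform(m, size - 1 - m, 2)
            occ_angle[i] = rng.uniform(0, 2 * np.pi)
        if round_ >= 40:
            # stubborn cases: draw violators last and drop their occluders
            order = [i for i in order if i not in violators] + violators
            for i in violators:
                has_occ[i] = False

    # --- paint fruit in the resolved order, then occluders
    owner = np.full((size, size), -1, dtype=np.int32)
    ripe_base = np.array(_RIPE_BASE, dtype=np.float32)
    half_base = np.array(_HALF_RIPE_BASE, dtype=np.float32)
    for i in order:
        base = np.clip((ripe_base if ripe[i] else half_base) + jitters[i], 0, 255)
        _paint_fruit(img, owner, i, centers[i, 0], centers[i, 1], radii[i],
                     base, light, bool(shadowed[i]))
    for i in order:
        if has_occ[i]:
            cx, cy, r = occluder_geometry(i)
            color = np.clip(np.array(_GREENS[occ_color_idx[i]], dtype=np.float32)
                            * occ_bright[i] + occ_jit[i], 0, 255)
            _paint_disk(img, cx, cy, r, color)
            _stamp_owner(owner, -2, cx, cy, r)

    # recompute final visibility from pixel ownership
    if count:
        own_counts = np.bincount(owner[owner >= 0].ravel(), minlength=count)
        visible = own_counts / np.maximum(disk_px, 1)

    # --- illumination field and optional camera softness
    field_ = _illumination_field(size, config.illumination_amplitude, rng)
    img *= field_[:, :, None]
    if config.full_image_blur_sigma > 0:
        for ch in range(3):
            img[:, :, ch] = gaussian_filter(img[:, :, ch],
                                            config.full_image_blur_sigma)

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    fruits = [FruitRecord(center=(float(centers[i, 0]), float(centers[i, 1])),
                          radius=float(radii[i]),
                          ripeness=RIPE if ripe[i] else HALF_RIPE,
                          visible_fraction=float(visible[i]))
              for i in range(count)]
    return LabeledImage(pixels=pixels, count=count, fruits=fruits, seed=seed)


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-image seed: datasets are order-independent and resumable."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def render_batch(config: SceneConfig, n: int, seed: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render ``n`` scenes in memory; returns (images uint8 N×S×S×3, counts)."""
    images = np.empty((n, config.image_size, config.image_size, 3), dtype=np.uint8)
    counts = np.empty(n, dtype=np.int64)
    for i in range(n):
        scene = render_scene(config, derive_seed(seed, i))
        images[i] = scene.pixels
        counts[i] = scene.count
    return images, counts


# ----------------------------------------------------------------------
# dataset I/O: PNG images, CSV manifest (path,count), sidecar JSON


def generate_dataset(config: SceneConfig, n: int, split_name: str,
                     out_dir: str | Path, seed: int) -> DatasetManifest:
    """Write ``n`` rendered scenes and a manifest under ``out_dir``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries: list[tuple[str, int]] = []
    for i in range(n):
        scene = render_scene(config, derive_seed(seed, i))
        rel = f"{split_name}_{i:05d}.png"
        Image.fromarray(scene.pixels).save(out / rel)
        entries.append((rel, scene.count))
    manifest = DatasetManifest(split_name=split_name, entries=entries,
                               config_snapshot=config, seed=seed, root=out)
    save_manifest(manifest)
    return manifest


def save_manifest(manifest: DatasetManifest) -> Path:
    csv_path = manifest.root / f"{manifest.split_name}_manifest.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "count"])
        writer.writerows(manifest.entries)
    sidecar = {
        "split_name": manifest.split_name,
        "seed": manifest.seed,
        "config": manifest.config_snapshot.to_dict(),
    }
    (manifest.root / f"{manifest.split_name}_manifest.json").write_text(
        json.dumps(sidecar, indent=1))
    return csv_path


def load_manifest(csv_path: str | Path) -> DatasetManifest:
    csv_path = Path(csv_path)
    root = csv_path.parent
    split = csv_path.stem.replace("_manifest", "")
    entries = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append((row["path"], int(row["count"])))
    sidecar_path = root / f"{split}_manifest.json"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        config = SceneConfig.from_dict(sidecar["config"])
        seed = sidecar["seed"]
    else:
        config, seed = SceneConfig(), 0
    return DatasetManifest(split_name=split, entries=entries,
                           config_snapshot=config, seed=seed, root=root)


def load_dataset(manifest: DatasetManifest) -> Iterator[tuple[np.ndarray, int]]:
    """Yield (image, count) pairs in manifest order; counts round-trip
    exactly.  A missing file raises with the offending path."""
    for rel, count in manifest.entries:
        path = manifest.root / rel
        if not path.exists():
            raise FileNotFoundError(f"dataset image missing: {path}")
        yield np.asarray(Image.open(path).convert("RGB")), count
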