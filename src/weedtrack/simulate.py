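"""Synthetic UAV strip-survey scenes for end-to-end testing.

The generator emulates a nadir-view camera translating at constant
speed over a field of stationary plants: in image coordinates every
plant scrolls upward by exactly ``scroll_speed`` pixels per frame.
Plants are placed uniformly, without overlap unless occluded pairs are
requested, in a virtual strip long enough that the camera sweeps over
all of them during ``n_frames`` frames.  All plants start below the
counting line — the camera starts at the field edge — so a counted
plant's full crossing is always observable.

Per frame, every fully visible plant yields a ground-truth box.  The
detection stream is the ground truth corrupted by the failure modes a
real detector exhibits:

* missed detections — each box dropped with probability ``miss_prob``;
* localization jitter — Gaussian noise of std ``jitter_std`` on each
  box corner;
* spurious detections — Poisson(``fp_rate``) random boxes per frame;
* appearance noise — per-plant unit-norm prototype feature vectors
  perturbed by Gaussian noise of scale ``feature_noise`` and
  renormalized (spurious boxes get fresh random features).

A single seeded generator drives every draw, so a scene is a pure
function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import json

import numpy as np

from .counting import crossing_check
from .geometry import BoundingBox
from .io import Detection, GTRecord, write_mot_file

__all__ = ["SimConfig", "SimScene", "generate_scene", "write_fixture", "read_manifest"]


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters; defaults give a moderate-density noiseless pass."""

    image_width: int = 640
    image_height: int = 480
    n_plants: int = 25
    plant_size_range: tuple[float, float] = (24.0, 48.0)
    scroll_speed: float = 4.0
    n_frames: int = 150
    miss_prob: float = 0.0
    fp_rate: float = 0.0
    jitter_std: float = 0.0
    conf_range: tuple[float, float] = (0.6, 1.0)
    feature_dim: int = 16
    feature_noise: float = 0.0
    occlusion_pairs: int = 0
    line_y: Optional[float] = None  # default: image mid-height
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_prob <= 1.0):
            raise ValueError("miss_prob must be in [0, 1]")
        if self.scroll_speed <= 0:
            raise ValueError("scroll_speed must be positive")
        if self.fp_rate < 0 or self.jitter_std < 0 or self.feature_noise < 0:
            raise ValueError("noise parameters must be non-negative")
        lo, hi = self.plant_size_range
        if not (0 < lo <= hi):
            raise ValueError("plant_size_range must satisfy 0 < min <= max")
        clo, chi = self.conf_range
        if not (0.0 <= clo <= chi <= 1.0):
            raise ValueError("conf_range must be within [0, 1] with lo <= hi")

    @property
    def effective_line_y(self) -> float:
        return self.image_height / 2.0 if self.line_y is None else self.line_y


@dataclass
class SimScene:
    """Generated scene: ground truth, corrupted detections, true line count."""

    config: SimConfig
    gt: list[GTRecord] = field(default_factory=list)
    detections: list[Detection] = field(default_factory=list)
    true_count: int = 0


class GenerationError(RuntimeError):
    """Raised when non-overlapping placement cannot be satisfied."""


def _place_plants(cfg: SimConfig, rng: np.random.Generator) -> list[BoundingBox]:
    """Place plant boxes in strip coordinates (frame-1 image coordinates).

    Strip rows run from just below the counting line down to the last
    row the camera sweep reaches; x must keep the box fully in frame.
    """
    lo, hi = cfg.plant_size_range
    y_top = cfg.effective_line_y + 1.0
    y_bot = cfg.image_height + cfg.n_frames * cfg.scroll_speed
    placed: list[BoundingBox] = []
    n_solo = cfg.n_plants - 2 * cfg.occlusion_pairs
    if n_solo < 0:
        raise ValueError("occlusion_pairs demands more plants than n_plants")

    def sample_box() -> BoundingBox:
        w = rng.uniform(lo, hi)
        h = rng.uniform(lo, hi)
        x = rng.uniform(0.0, cfg.image_width - w)
        y = rng.uniform(y_top, max(y_top, y_bot - h))
        return BoundingBox(x, y, x + w, y + h)

    def overlaps_any(box: BoundingBox, others: list[BoundingBox]) -> bool:
        return any(
            not (box.x2 <= o.x1 or o.x2 <= box.x1 or box.y2 <= o.y1 or o.y2 <= box.y1)
            for o in others
        )

    for _ in range(n_solo):
        for _attempt in range(1000):
            box = sample_box()
            if not overlaps_any(box, placed):
                placed.append(box)
                break
        else:
            raise GenerationError(
                "could not place non-overlapping plants; lower n_plants or shrink sizes"
            )
    for _ in range(cfg.occlusion_pairs):
        for _attempt in range(1000):
            a = sample_box()
            if overlaps_any(a, placed):
                continue
            # partner shifted by about half a box: deliberate partial overlap
            dx = rng.uniform(0.3, 0.6) * a.width * rng.choice([-1.0, 1.0])
            dy = rng.uniform(0.3, 0.6) * a.height * rng.choice([-1.0, 1.0])
            try:
                b = a.shifted(dx, dy)
            except ValueError:
                continue
            if b.x1 < 0 or b.x2 > cfg.image_width or b.y1 < y_top or b.y2 > y_bot:
                continue
            if overlaps_any(b, placed):
                continue
            placed.extend([a, b])
            break
        else:
            raise GenerationError("could not place occluded pair; lower density")
    return placed


def _prototype_features(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm, mutually near-orthogonal prototype vectors (QR when n <= dim)."""
    raw = rng.standard_normal((max(n, 1), dim))
    if n <= dim:
        q, _ = np.linalg.qr(raw.T[:, :n])
        protos = q.T
    else:
        protos = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    return protos[:n]


def generate_scene(config: SimConfig) -> SimScene:
    """Generate ground truth and corrupted detections from a config.

    Deterministic in ``config`` (including ``seed``): draws are consumed
    in a fixed order — placement, prototypes, then per frame misses,
    jitter, confidences, feature noise, and spurious boxes.
    """
    rng = np.random.default_rng(config.seed)
    plants = _place_plants(config, rng)
    protos = _prototype_features(config.n_plants, config.feature_dim, rng)
    scene = SimScene(config=config)
    line_y = config.effective_line_y
    counted: set[int] = set()
    lo, hi = config.conf_range

    for frame in range(1, config.n_frames + 1):
        dy = -(frame - 1) * config.scroll_speed
        for pid, base in enumerate(plants, start=1):
            box = base.shifted(0.0, dy)
            # plant participates only while fully inside the frame
            if box.y1 < 0 or box.y2 > config.image_height:
                continue
            scene.gt.append(GTRecord(frame, pid, box))
            if crossing_check(box, line_y):
                counted.add(pid)
            if rng.uniform() < config.miss_prob:
                continue
            if config.jitter_std > 0:
                jit = rng.normal(0.0, config.jitter_std, size=4)
                x1, y1 = box.x1 + jit[0], box.y1 + jit[1]
                x2, y2 = max(box.x2 + jit[2], x1 + 1.0), max(box.y2 + jit[3], y1 + 1.0)
                dbox = BoundingBox(x1, y1, x2, y2)
            else:
                dbox = box
            conf = float(rng.uniform(lo, hi))
            feat = protos[pid - 1]
            if config.feature_noise > 0:
                feat = feat + rng.normal(0.0, config.feature_noise, size=config.feature_dim)
                feat = feat / np.linalg.norm(feat)
            scene.detections.append(Detection(frame, dbox, conf, feat))
        n_fp = int(rng.poisson(config.fp_rate)) if config.fp_rate > 0 else 0
        for _ in range(n_fp):
            w = rng.uniform(*config.plant_size_range)
            h = rng.uniform(*config.plant_size_range)
            x = rng.uniform(0.0, config.image_width - w)
            y = rng.uniform(0.0, config.image_height - h)
            conf = float(rng.uniform(lo, hi))
            feat = rng.standard_normal(config.feature_dim)
            feat = feat / np.linalg.norm(feat)
            scene.detections.append(
                Detection(frame, BoundingBox(x, y, x + w, y + h), conf, feat)
            )

    scene.true_count = len(counted)
    return scene


def write_fixture(scene: SimScene, directory: str | Path) -> None:
    """Write gt.txt, det.txt (MOT dialect) and manifest.json to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mot_file(scene.gt, directory / "gt.txt")
    write_mot_file(scene.detections, directory / "det.txt")
    cfg = asdict(scene.config)
    cfg["plant_size_range"] = list(cfg["plant_size_range"])
    cfg["conf_range"] = list(cfg["conf_range"])
    manifest = {"config": cfg, "true_count": scene.true_count}
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def read_manifest(directory: str | Path) -> dict:
    with open(Path(directory) / "manifest.json", "r", encoding="utf-8") as fh:
        return json.load(fh)
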