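"""Trainable AFOG pixel classification and wound / collagen / leukocyte metrics.

A random-forest pixel classifier over handcrafted color-texture features
stands in for commercial trainable-segmentation tools: the user supplies
sparse class scribbles on trichrome-like RGB sections, the classifier labels
every pixel as background / muscle / fibrin / collagen, and per-heart metrics
are formed by summing areas across evenly spaced serial sections before
taking ratios.  Valves (or any other region to ignore) are excluded with a
user-supplied mask and never contribute to any area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import blob_log
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "CLASS_NAMES",
    "SectionImage",
    "ClassMap",
    "PixelClassifier",
    "WoundMetrics",
    "LeukocyteDensity",
    "TrainingError",
    "extract_pixel_features",
    "train_segmenter",
    "segment_section",
    "quantify_wound",
    "quantify_collagen_homeostasis",
    "count_leukocytes",
]

#: 4-class alphabet; label codes are indices into this tuple.
CLASS_NAMES: tuple[str, ...] = ("background", "muscle", "fibrin", "collagen")
DEFAULT_FEATURE_SCALES: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)


class TrainingError(ValueError):
    """Raised when scribbles cannot support training (e.g. a missing class)."""


@dataclass
class SectionImage:
    """RGB histology section with physical pixel size.

    ``exclusion_mask`` (True = excluded) removes regions such as valves from
    every downstream measurement.
    """

    pixels: np.ndarray
    pixel_size_um: float
    exclusion_mask: np.ndarray | None = None
    section_id: str = ""
    heart_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an RGB raster of shape (h, w, 3)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask).astype(bool)
            if self.exclusion_mask.shape != self.pixels.shape[:2]:
                raise ValueError("exclusion_mask shape must match pixels")


@dataclass
class ClassMap:
    """Per-pixel labels over {background=0, muscle=1, fibrin=2, collagen=3}."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if self.labels.size and self.labels.max() >= len(CLASS_NAMES):
            raise ValueError("labels outside the 4-class alphabet")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def area_um2(self, class_name: str) -> float:
        code = CLASS_NAMES.index(class_name)
        return float((self.labels == code).sum()) * self.pixel_size_um**2


@dataclass
class WoundMetrics:
    """Per-heart wound quantification (areas summed across sections first)."""

    heart_id: str
    muscle_area_um2: float
    fibrin_area_um2: float
    collagen_area_um2: float
    wound_pct: float
    collagen_in_wound_pct: float
    n_sections: int


@dataclass
class LeukocyteDensity:
    section_id: str
    cell_count: int
    muscle_area_um2: float
    density_per_1000um2: float


@dataclass
class PixelClassifier:
    """Random-forest pixel classifier plus its feature recipe.

    The feature recipe (smoothing scales) is stored with the model so that a
    section segmented later is guaranteed to be featurized identically;
    reloading a saved classifier reproduces predictions exactly.
    """

    model: RandomForestClassifier
    feature_scales: tuple[float, ...]
    classes: tuple[str, ...]
    seed: int
    holdout_accuracy: float | None = None
    n_training_pixels: int = 0

    @property
    def n_features(self) -> int:
        return 3 + 6 * len(self.feature_scales)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PixelClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, PixelClassifier):
            raise TypeError(f"{path} does not contain a PixelClassifier")
        return obj


# ---------------------------------------------------------------------------
# features


def extract_pixel_features(
    img: SectionImage | np.ndarray,
    scales_px: Sequence[float] = DEFAULT_FEATURE_SCALES,
) -> np.ndarray:
    """Per-pixel feature stack: raw RGB, per-channel Gaussian smoothings and
    per-channel gradient magnitudes at each scale.

    Returns an array of shape (h, w, 3 + 6*len(scales_px)), float32.
    """
    pixels = img.pixels if isinstance(img, SectionImage) else np.asarray(img)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an RGB raster of shape (h, w, 3)")
    if any(s <= 0 for s in scales_px):
        raise ValueError("feature scales must be positive")
    data = pixels.astype(np.float32)
    feats = [data[..., c] for c in range(3)]
    for s in scales_px:
        for c in range(3):
            feats.append(ndi.gaussian_filter(data[..., c], s).astype(np.float32))
        for c in range(3):
            feats.append(
                ndi.gaussian_gradient_magnitude(data[..., c], s).astype(np.float32)
            )
    return np.stack(feats, axis=-1)


# ---------------------------------------------------------------------------
# training / inference


def train_segmenter(
    imgs: Sequence[SectionImage],
    scribbles: Sequence[np.ndarray],
    seed: int = 0,
    scales_px: Sequence[float] = DEFAULT_FEATURE_SCALES,
    holdout_fraction: float = 0.2,
    max_pixels_per_class: int = 4000,
    min_pixels_per_class: int = 50,
    n_estimators: int = 100,
) -> PixelClassifier:
    """Train a pixel classifier from sparse scribbles.

    Scribble rasters use 0 = unlabeled and code+1 for a class (1 = background
    ... 4 = collagen), so that background pixels can be scribbled despite
    carrying class code 0.  Every class needs at least
    ``min_pixels_per_class`` scribbled pixels.  A stratified random
    ``holdout_fraction`` of scribble pixels is held out and the held-out
    accuracy stored on the returned classifier.  Deterministic given ``seed``.
    """
    if len(imgs) != len(scribbles):
        raise ValueError("imgs and scribbles must have equal length")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for img, scr in zip(imgs, scribbles):
        scr = np.asarray(scr)
        if scr.shape != img.pixels.shape[:2]:
            raise ValueError("scribble shape must match image")
        feats = extract_pixel_features(img, scales_px)
        mask = scr > 0
        X_parts.append(feats[mask])
        y_parts.append(scr[mask].astype(int) - 1)
    X = np.concatenate(X_parts) if X_parts else np.empty((0, 3))
    y = np.concatenate(y_parts) if y_parts else np.empty(0, dtype=int)

    for code, name in enumerate(CLASS_NAMES):
        n = int((y == code).sum())
        if n == 0:
            raise TrainingError(f"class {name} has no training pixels")
        if n < min_pixels_per_class:
            raise TrainingError(
                f"class {name} has only {n} training pixels "
                f"(minimum {min_pixels_per_class})"
            )

    # per-class subsample, then stratified holdout split
    train_idx, hold_idx = [], []
    for code in range(len(CLASS_NAMES)):
        idx = np.flatnonzero(y == code)
        rng.shuffle(idx)
        idx = idx[:max_pixels_per_class]
        n_hold = max(1, int(round(holdout_fraction * len(idx))))
        hold_idx.append(idx[:n_hold])
        train_idx.append(idx[n_hold:])
    train_idx = np.concatenate(train_idx)
    hold_idx = np.concatenate(hold_idx)

    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(X[train_idx], y[train_idx])
    acc = float(np.mean(model.predict(X[hold_idx]) == y[hold_idx]))
    return PixelClassifier(
        model=model,
        feature_scales=tuple(float(s) for s in scales_px),
        classes=CLASS_NAMES,
        seed=seed,
        holdout_accuracy=acc,
        n_training_pixels=int(len(train_idx)),
    )


def segment_section(model: PixelClassifier, img: SectionImage) -> ClassMap:
    """Apply a trained classifier to every pixel; excluded pixels become
    background.  Deterministic."""
    feats = extract_pixel_features(img, model.feature_scales)
    h, w, f = feats.shape
    expected = int(getattr(model.model, "n_features_in_", model.n_features))
    if f != model.n_features or f != expected:
        raise ValueError(
            f"feature recipe mismatch: image yields {f} features, "
            f"model expects {expected}"
        )
    pred = model.model.predict(feats.reshape(-1, f)).reshape(h, w).astype(np.uint8)
    if img.exclusion_mask is not None:
        pred[img.exclusion_mask] = 0
    return ClassMap(labels=pred, pixel_size_um=img.pixel_size_um)


# ---------------------------------------------------------------------------
# metrics


def _summed_areas(maps: Sequence[ClassMap]) -> dict[str, float]:
    if not maps:
        raise ValueError("need at least one section")
    ps = maps[0].pixel_size_um
    if any(abs(m.pixel_size_um - ps) > 1e-9 for m in maps):
        raise ValueError("all sections of a heart must share one pixel size")
    return {name: float(sum(m.area_um2(name) for m in maps)) for name in CLASS_NAMES}


def quantify_wound(maps: Sequence[ClassMap], heart_id: str = "") -> WoundMetrics:
    """Per-heart wound metrics from the heart's serial sections.

    Areas are summed across sections in µm² before forming ratios, i.e. one
    ratio per heart: wound_pct = 100*(fibrin+collagen)/muscle and
    collagen_in_wound_pct = 100*collagen/(fibrin+collagen) (0 for an
    uninjured heart with no wound).
    """
    areas = _summed_areas(maps)
    muscle = areas["muscle"]
    if muscle == 0:
        raise ValueError(f"heart {heart_id!r} has zero muscle area")
    wound = areas["fibrin"] + areas["collagen"]
    return WoundMetrics(
        heart_id=heart_id,
        muscle_area_um2=muscle,
        fibrin_area_um2=areas["fibrin"],
        collagen_area_um2=areas["collagen"],
        wound_pct=100.0 * wound / muscle,
        collagen_in_wound_pct=100.0 * areas["collagen"] / wound if wound > 0 else 0.0,
        n_sections=len(maps),
    )


def quantify_collagen_homeostasis(maps: Sequence[ClassMap]) -> float:
    """Collagen as a percentage of muscle (uninjured / sham hearts)."""
    areas = _summed_areas(maps)
    if areas["muscle"] == 0:
        raise ValueError("zero muscle area")
    return 100.0 * areas["collagen"] / areas["muscle"]


def count_leukocytes(
    cells_channel: np.ndarray,
    muscle: np.ndarray | PixelClassifier,
    pixel_size_um: float,
    blob_params: Mapping[str, float] | None = None,
    section_id: str = "",
) -> LeukocyteDensity:
    """Count fluorescent leukocytes and normalize to muscle area.

    Cells are detected as Laplacian-of-Gaussian blobs in ``cells_channel``;
    only blobs whose center lies inside the muscle region count.  ``muscle``
    is either a binary mask or a trained :class:`PixelClassifier`, in which
    case the (single-channel) muscle image is classified after replication to
    pseudo-RGB and the muscle class taken as the region.  Density is
    cells per 1000 µm² of muscle.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    cells_channel = np.asarray(cells_channel, dtype=float)
    if isinstance(muscle, PixelClassifier):
        pseudo = np.repeat(cells_channel[..., None], 3, axis=2).astype(np.uint8)
        cm = segment_section(
            muscle, SectionImage(pixels=pseudo, pixel_size_um=pixel_size_um)
        )
        muscle_mask = cm.labels == CLASS_NAMES.index("muscle")
    else:
        muscle_mask = np.asarray(muscle).astype(bool)
        if muscle_mask.shape != cells_channel.shape:
            raise ValueError("muscle mask shape must match cells channel")
    muscle_area = float(muscle_mask.sum()) * pixel_size_um**2
    if muscle_area == 0:
        raise ValueError("zero muscle area; density undefined")

    params = dict(min_sigma=1.5, max_sigma=4.0, threshold=0.05)
    if blob_params:
        params.update(blob_params)
    # absolute floor rejects LoG responses arising from background noise
    min_intensity = params.pop(
        "min_intensity", cells_channel.mean() + 5.0 * cells_channel.std()
    )
    span = cells_channel.max() - cells_channel.min()
    norm = (cells_channel - cells_channel.min()) / (span if span > 0 else 1.0)
    blobs = blob_log(norm, **params)
    count = 0
    for by, bx, _ in blobs:
        iy, ix = int(round(by)), int(round(bx))
        if 0 <= iy < muscle_mask.shape[0] and 0 <= ix < muscle_mask.shape[1]:
            if muscle_mask[iy, ix] and cells_channel[iy, ix] >= min_intensity:
                count += 1
    return LeukocyteDensity(
        section_id=section_id,
        cell_count=count,
        muscle_area_um2=muscle_area,
        density_per_1000um2=1000.0 * count / muscle_area,
    )
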