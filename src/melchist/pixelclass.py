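"""Three-class random-forest pixel classification (nuclei / membrane / ECM).

The classifier mirrors an Ilastik-style workflow: a small manually (or, for
synthetic data, automatically) labeled region trains a random forest on
multi-scale image features computed from two intensity images — the nuclear
(DAPI-like) channel and the sum of all membrane stainings.  The trained
model produces per-pixel probability maps that can be reused on further
images of the same kind without retraining.  The ECM class is the residual:
every pixel that is neither nucleus nor membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor, structure_tensor_eigenvalues
from sklearn.ensemble import RandomForestClassifier

from .io import ConfigError, MarkerSpec, ValidationError

DEFAULT_SCALES = (0.7, 1.0, 1.6, 3.5, 5.0)
FEATURE_KINDS = ("gaussian", "gradient_magnitude", "laplacian_of_gaussian",
                 "structure_tensor_eig1", "structure_tensor_eig2")
CLASS_NUCLEI, CLASS_MEMBRANE, CLASS_ECM = 1, 2, 3


class TrainingError(ValueError):
    """Training labels do not support fitting the classifier."""


@dataclass
class ProbabilityMaps:
    """Per-pixel class probabilities; p_nuc + p_mem + p_ecm = 1 everywhere."""

    p_nuc: np.ndarray
    p_mem: np.ndarray
    p_ecm: np.ndarray

    def __post_init__(self) -> None:
        total = self.p_nuc + self.p_mem + self.p_ecm
        if np.abs(total - 1.0).max() > 1e-6:
            raise ValidationError("probability maps must sum to 1 pixelwise")
        for p in (self.p_nuc, self.p_mem, self.p_ecm):
            if p.min() < -1e-9 or p.max() > 1 + 1e-9:
                raise ValidationError("probabilities must lie in [0, 1]")

    def argmax_class(self) -> np.ndarray:
        stacked = np.stack([self.p_nuc, self.p_mem, self.p_ecm])
        return np.argmax(stacked, axis=0) + 1


def validate_label_mask(labels: np.ndarray, min_per_class: int = 50) -> None:
    labels = np.asarray(labels)
    if not np.isin(np.unique(labels), [0, 1, 2, 3]).all():
        raise ValidationError("label mask values must be in {0, 1, 2, 3}")
    for cls in (CLASS_NUCLEI, CLASS_MEMBRANE, CLASS_ECM):
        n = int((labels == cls).sum())
        if n < min_per_class:
            raise TrainingError(f"class {cls} has {n} labeled pixels, need >= {min_per_class}")


def sum_membranes(corrected: dict[str, np.ndarray], panel: list[MarkerSpec]) -> np.ndarray:
    """Composite of all membrane-localized stainings, rescaled to [0, 1]."""
    membrane = [m.name for m in panel if m.localization == "membrane"]
    if not membrane:
        raise ConfigError("panel has no membrane-localized markers")
    missing = [m for m in membrane if m not in corrected]
    if missing:
        raise ConfigError(f"corrected images missing membrane markers: {missing}")
    total = np.zeros_like(next(iter(corrected.values())), dtype=np.float64)
    for m in membrane:
        total = total + corrected[m]
    peak = total.max()
    return total / peak if peak > 0 else total


def compute_pixel_features(
    intensity_images: tuple[np.ndarray, np.ndarray],
    scales: tuple[float, ...] = DEFAULT_SCALES,
) -> tuple[np.ndarray, list[str]]:
    """Multi-scale feature stack for pixel classification.

    Per input image and per scale sigma: Gaussian-smoothed intensity,
    Gaussian gradient magnitude, Laplacian of Gaussian, and the two
    structure-tensor eigenvalues.  Returns (H, W, n_features) float32 plus
    the deterministic feature-name list (the recipe).
    """
    if not scales:
        raise ConfigError("scales must be nonempty")
    names: list[str] = []
    planes: list[np.ndarray] = []
    for idx, img in enumerate(intensity_images):
        img = np.asarray(img, dtype=np.float64)
        for s in scales:
            planes.append(ndimage.gaussian_filter(img, s, mode="nearest"))
            planes.append(ndimage.gaussian_gradient_magnitude(img, s, mode="nearest"))
            planes.append(ndimage.gaussian_laplace(img, s, mode="nearest"))
            tensor = structure_tensor(img, sigma=s, order="rc", mode="nearest")
            eig1, eig2 = structure_tensor_eigenvalues(tensor)
            planes.extend([eig1, eig2])
            names.extend(f"img{idx}_{kind}_s{s}" for kind in FEATURE_KINDS)
    return np.stack(planes, axis=-1).astype(np.float32), names


@dataclass
class ClassifierModel:
    """Trained random forest + frozen feature recipe + training metadata."""

    forest: RandomForestClassifier
    feature_names: list[str]
    scales: tuple[float, ...]
    seed: int
    n_trees: int
    label_counts: dict[int, int]
    oob_accuracy: float | None = None
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, ClassifierModel):
            raise ValidationError(f"{path} does not contain a ClassifierModel")
        return model


def train_pixel_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_trees: int = 100,
    feature_names: list[str] | None = None,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    max_per_class: int = 20000,
) -> ClassifierModel:
    """Fit the forest on labeled pixels with class-balanced subsampling.

    Deterministic given ``seed``.  Out-of-bag accuracy is recorded on the
    sampled training pixels.
    """
    validate_label_mask(labels)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n_per_class = min(
        min(int((labels == c).sum()) for c in (1, 2, 3)), max_per_class
    )
    rows, cols, vals = [], [], []
    for cls in (CLASS_NUCLEI, CLASS_MEMBRANE, CLASS_ECM):
        r, c = np.nonzero(labels == cls)
        pick = rng.choice(len(r), size=n_per_class, replace=False)
        pick.sort()
        rows.append(r[pick])
        cols.append(c[pick])
        vals.append(np.full(n_per_class, cls))
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    y = np.concatenate(vals)
    x = features[rr, cc, :]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(seed) % (2**31),
        n_jobs=1,
        oob_score=True,
    )
    forest.fit(x, y)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(features.shape[-1])]
    if len(feature_names) != features.shape[-1]:
        raise ValidationError("feature_names length does not match feature stack")
    return ClassifierModel(
        forest=forest,
        feature_names=list(feature_names),
        scales=tuple(scales),
        seed=seed,
        n_trees=n_trees,
        label_counts={c: int((labels == c).sum()) for c in (1, 2, 3)},
        oob_accuracy=float(forest.oob_score_),
    )


def predict_probability_maps(model: ClassifierModel, features: np.ndarray,
                             feature_names: list[str] | None = None) -> ProbabilityMaps:
    """Apply a trained model to a (new) feature stack.

    If ``feature_names`` is given it must be a permutation of the model's
    recipe; columns are reordered to match the recipe before prediction.
    """
    if features.shape[-1] != len(model.feature_names):
        raise ValidationError(
            f"feature stack has {features.shape[-1]} features, model expects "
            f"{len(model.feature_names)}"
        )
    if feature_names is not None:
        if sorted(feature_names) != sorted(model.feature_names):
            raise ValidationError("feature recipe does not match the trained model")
        order = [feature_names.index(n) for n in model.feature_names]
        features = features[..., order]
    h, w, f = features.shape
    proba = model.forest.predict_proba(features.reshape(-1, f))
    classes = list(model.forest.classes_)
    maps = {c: proba[:, classes.index(c)].reshape(h, w) for c in (1, 2, 3)}
    total = maps[1] + maps[2] + maps[3]
    return ProbabilityMaps(
        p_nuc=maps[1] / total, p_mem=maps[2] / total, p_ecm=maps[3] / total
    )


def labels_from_truth(
    class_image: np.ndarray,
    fraction: float = 0.06,
    seed: int = 0,
    erode_px: int = 1,
) -> np.ndarray:
    """Auto-derived training labels from a ground-truth class image.

    Emulates manual scribbling in a small region: a centered window covering
    ``fraction`` of the image area is fully labeled with the true classes,
    each class region first eroded by ``erode_px`` to keep labels off the
    ambiguous class boundaries.  Pixels outside the window stay 0 and serve
    as held-out evaluation data.
    """
    class_image = np.asarray(class_image)
    h, w = class_image.shape
    side = np.sqrt(fraction)
    wh, ww = int(round(h * side)), int(round(w * side))
    rng = np.random.default_rng(seed)
    r0 = int(rng.integers(0, h - wh + 1))
    c0 = int(rng.integers(0, w - ww + 1))
    labels = np.zeros_like(class_image, dtype=np.int32)
    window = np.zeros((h, w), dtype=bool)
    window[r0:r0 + wh, c0:c0 + ww] = True
    structure = ndimage.generate_binary_structure(2, 1)
    for cls in (CLASS_NUCLEI, CLASS_MEMBRANE, CLASS_ECM):
        region = class_image == cls
        if erode_px:
            region = ndimage.binary_erosion(region, structure, iterations=erode_px)
        labels[region & window] = cls
    return labels
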