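"""Hand-crafted baseline: HOG descriptors + a linear max-margin classifier.

The descriptor geometry follows the comparison protocol this package
benchmarks against: 6x6-pixel cells, 2x2-cell blocks at 50% overlap (one
cell stride), 9 unsigned orientation bins, L2 block normalization.  On a
227x227 patch that yields 36*36 block positions * 4 cells * 9 bins = 46,656
features.  Classification is one-vs-rest linear SVM (soft margin, C=1).

Patches are reduced to a single channel before the gradient computation:
luminance for RGB, the near-infrared band for multispectral input (both
configurable).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.feature import hog as _skimage_hog
from sklearn.svm import LinearSVC

from .synthetic import LabeledPatchSet

__all__ = ["HOGConfig", "hog_features", "to_single_channel", "BaselineClassifier",
           "train_baseline", "predict_baseline"]

_LUMA = np.array([0.299, 0.587, 0.114])
_NIR_BAND = 3  # channel index of the 840 nm band


@dataclasses.dataclass(frozen=True)
class HOGConfig:
    cell_side: int = 6
    block_cells: int = 2
    block_overlap: float = 0.5
    orientations: int = 9  # unsigned, over [0, 180) degrees
    channel: int | str = "auto"  # "auto": luminance (RGB) / NIR (MS)

    def __post_init__(self):
        if self.cell_side < 2:
            raise ValueError("cell side must be >= 2 pixels")
        if not 0.0 <= self.block_overlap < 1.0:
            raise ValueError("block overlap must lie in [0, 1)")
        # the descriptor strides one cell per block position, so the overlap
        # achievable with a b-cell block is (b-1)/b
        implied = (self.block_cells - 1) / self.block_cells
        if abs(self.block_overlap - implied) > 1e-9:
            raise ValueError(
                f"one-cell block stride implies overlap {implied:.2f} for a "
                f"{self.block_cells}x{self.block_cells} block"
            )


def to_single_channel(patch: np.ndarray, cfg: HOGConfig) -> np.ndarray:
    """Reduce a (h, w, c) patch to one channel per the config selector."""
    if patch.ndim == 2:
        return np.asarray(patch, dtype=np.float64)
    c = patch.shape[-1]
    if cfg.channel == "auto":
        if c == 3:
            return patch @ _LUMA
        if c == 5:
            return np.asarray(patch[..., _NIR_BAND], dtype=np.float64)
        raise ValueError(f"cannot infer channel reduction for {c}-channel input")
    return np.asarray(patch[..., int(cfg.channel)], dtype=np.float64)


def hog_features(image: np.ndarray, cfg: HOGConfig = HOGConfig()) -> np.ndarray:
    """HOG descriptor of one patch.

    Length depends only on image size and config:
    n_blocks_y * n_blocks_x * block_cells**2 * orientations, with block
    stride fixed at one cell.  A constant image yields the all-zero
    descriptor (the epsilon guard in the block norm leaves 0/eps = 0).
    """
    gray = to_single_channel(np.asarray(image, dtype=np.float64), cfg)
    min_side = cfg.cell_side * cfg.block_cells
    if gray.shape[0] < min_side or gray.shape[1] < min_side:
        raise ValueError(f"image smaller than one {min_side}px block")
    return _skimage_hog(
        gray,
        orientations=cfg.orientations,
        pixels_per_cell=(cfg.cell_side, cfg.cell_side),
        cells_per_block=(cfg.block_cells, cfg.block_cells),
        block_norm="L2",
        feature_vector=True,
    )


@dataclasses.dataclass
class BaselineClassifier:
    svm: LinearSVC
    cfg: HOGConfig

    def predict(self, patches: np.ndarray) -> np.ndarray:
        feats = np.stack([hog_features(p, self.cfg) for p in patches])
        return self.svm.predict(feats)


def train_baseline(trainset: LabeledPatchSet, cfg: HOGConfig = HOGConfig(),
                   C: float = 1.0, seed: int = 0) -> BaselineClassifier:
    """Fit a one-vs-rest linear SVM on HOG features."""
    if len(np.unique(trainset.labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    feats = np.stack([hog_features(p, cfg) for p in trainset.patches])
    svm = LinearSVC(C=C, random_state=seed)
    svm.fit(feats, trainset.labels)
    return BaselineClassifier(svm=svm, cfg=cfg)


def predict_baseline(classifier: BaselineClassifier,
                     testset: LabeledPatchSet) -> float:
    """Test-set accuracy of a fitted baseline."""
    if len(testset) == 0:
        raise ValueError("empty test set")
    pred = classifier.predict(testset.patches)
    return float(np.mean(pred == testset.labels))
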