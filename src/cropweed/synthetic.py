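"""Synthetic labeled patch benchmarks in RGB and 5-band multispectral modality.

Generates square reflectance patches for six visually distinct plant classes
(three weeds, three crops), with the class layout of the field benchmark this
package targets: per-class patch counts, 6-character one-hot label codes,
227x227 default patch side, and the 90/180/270-degree rotation augmentation.

The patch content model is deliberately simple: a per-class base reflectance
field, Gaussian "leaf" blobs with random sign and amplitude, and i.i.d.
Gaussian pixel noise, clipped to [0, 1].  Class palettes are the difficulty
knob: well-separated palettes give a nearly separable benchmark, close
palettes a hard one.
"""

from __future__ import annotations

import dataclasses
import pathlib

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "BAND_CENTERS_NM",
    "CLASS_NAMES",
    "TRAIN_COUNTS",
    "TEST_COUNTS",
    "SpeciesSpec",
    "LabeledPatchSet",
    "one_hot_code",
    "default_species",
    "separate_palettes",
    "generate_patch",
    "augment_rotations",
    "build_benchmark",
    "write_dataset",
    "read_dataset",
]

#: Center wavelengths (nm) of the five multispectral bands, in channel order:
#: blue, green, red, near-infrared, red-edge.
BAND_CENTERS_NM = (475, 560, 668, 840, 717)

#: The six classes: three weeds followed by three crops.
CLASS_NAMES = (
    "Chenopodium album",
    "Humulus scandens",
    "Xanthium sibiricum",
    "maize",
    "peanut",
    "wheat",
)

#: Default per-class patch counts of the benchmark's train and test splits.
TRAIN_COUNTS = (370, 252, 227, 490, 490, 458)
TEST_COUNTS = (158, 108, 97, 210, 210, 196)

N_CLASSES = 6


def one_hot_code(class_index: int, n_classes: int = N_CLASSES) -> str:
    """Return the one-hot label string for a class, e.g. 0 -> ``"100000"``."""
    if not 0 <= class_index < n_classes:
        raise ValueError(f"class_index {class_index} out of range 0..{n_classes - 1}")
    return "".join("1" if i == class_index else "0" for i in range(n_classes))


def _code_to_index(code: str) -> int:
    if code.count("1") != 1 or set(code) - {"0", "1"}:
        raise ValueError(f"label code {code!r} is not one-hot")
    return code.index("1")


@dataclasses.dataclass(frozen=True)
class SpeciesSpec:
    """Appearance model of one plant class.

    Parameters
    ----------
    class_index
        Class id in 0..5.
    rgb_mean, ms_mean
        Mean reflectance per channel, in [0, 1].  ``ms_mean`` follows the
        band order of :data:`BAND_CENTERS_NM`.
    rgb_noise_sd, ms_noise_sd
        Standard deviation of the i.i.d. Gaussian pixel noise per modality.
    blob_density
        Expected number of leaf blobs per pixel (Poisson intensity); the
        expected blob count of a patch is ``blob_density * side**2``.
    blob_radius
        (min, max) blob radius in pixels, sampled uniformly.
    blob_amplitude_sd
        Blob amplitudes are drawn N(0, sd); zero-mean so blobs perturb
        texture without biasing the per-channel patch mean.
    """

    class_index: int
    rgb_mean: tuple[float, float, float]
    ms_mean: tuple[float, float, float, float, float]
    rgb_noise_sd: float = 0.05
    ms_noise_sd: float = 0.05
    blob_density: float = 0.002
    blob_radius: tuple[float, float] = (2.0, 6.0)
    blob_amplitude_sd: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.class_index < N_CLASSES:
            raise ValueError("class_index must be in 0..5")
        for name in ("rgb_mean", "ms_mean"):
            vals = getattr(self, name)
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if not 0.0 <= self.rgb_noise_sd <= 1.0 or not 0.0 <= self.ms_noise_sd <= 1.0:
            raise ValueError("noise sd must lie in [0, 1]")
        if self.blob_radius[0] > self.blob_radius[1]:
            raise ValueError("blob radius min must be <= max")
        if self.blob_density < 0:
            raise ValueError("blob_density must be >= 0")

    @property
    def label_code(self) -> str:
        return one_hot_code(self.class_index)

    def mean_for(self, modality: str) -> np.ndarray:
        if modality == "rgb":
            return np.asarray(self.rgb_mean, dtype=np.float64)
        if modality == "ms":
            return np.asarray(self.ms_mean, dtype=np.float64)
        raise ValueError(f"unknown modality {modality!r} (expected 'rgb' or 'ms')")

    def noise_for(self, modality: str) -> float:
        return self.rgb_noise_sd if modality == "rgb" else self.ms_noise_sd


def default_species() -> list[SpeciesSpec]:
    """Six distinct specs: greens differ in hue/brightness, spectra in the
    red/NIR/red-edge balance typical of broadleaf weeds vs. crop canopies."""
    rgb = [
        (0.36, 0.55, 0.30),  # Chenopodium album: pale grey-green
        (0.25, 0.45, 0.22),  # Humulus scandens: dark green vine
        (0.40, 0.50, 0.24),  # Xanthium: yellow-green broadleaf
        (0.30, 0.62, 0.33),  # maize: bright green rows
        (0.34, 0.52, 0.40),  # peanut: blue-green low canopy
        (0.48, 0.56, 0.32),  # wheat: yellowish dense sward
    ]
    # (blue, green, red, NIR, red-edge) reflectance
    ms = [
        (0.30, 0.50, 0.36, 0.62, 0.46),
        (0.24, 0.42, 0.28, 0.72, 0.50),
        (0.34, 0.48, 0.40, 0.56, 0.44),
        (0.26, 0.56, 0.30, 0.80, 0.56),
        (0.32, 0.50, 0.26, 0.68, 0.40),
        (0.40, 0.54, 0.44, 0.64, 0.52),
    ]
    return [
        SpeciesSpec(class_index=i, rgb_mean=rgb[i], ms_mean=ms[i])
        for i in range(N_CLASSES)
    ]


def separate_palettes(specs: list[SpeciesSpec], factor: float) -> list[SpeciesSpec]:
    """Rescale every palette's deviation from the across-class mean by
    ``factor``, clipping to [0, 1].  factor > 1 spreads the classes apart
    (easier), factor < 1 pulls them together (harder)."""
    out = []
    rgb_center = np.mean([s.rgb_mean for s in specs], axis=0)
    ms_center = np.mean([s.ms_mean for s in specs], axis=0)
    for s in specs:
        rgb = np.clip(rgb_center + factor * (np.asarray(s.rgb_mean) - rgb_center), 0, 1)
        ms = np.clip(ms_center + factor * (np.asarray(s.ms_mean) - ms_center), 0, 1)
        out.append(dataclasses.replace(s, rgb_mean=tuple(rgb), ms_mean=tuple(ms)))
    return out


@dataclasses.dataclass
class LabeledPatchSet:
    """A stack of labeled reflectance patches of one modality.

    ``patches`` has shape (n, side, side, channels) with values in [0, 1];
    ``labels`` holds class indices 0..5.
    """

    patches: np.ndarray
    labels: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.patches.ndim != 4:
            raise ValueError("patches must be a 4-d (n, h, w, c) array")
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels length mismatch")
        expected_c = {"rgb": 3, "ms": 5}.get(self.modality)
        if expected_c is None:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.patches.shape[-1] != expected_c:
            raise ValueError(
                f"{self.modality} patches need {expected_c} channels, "
                f"got {self.patches.shape[-1]}"
            )

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def side(self) -> int:
        return self.patches.shape[1]

    @property
    def n_channels(self) -> int:
        return self.patches.shape[-1]

    def class_histogram(self, n_classes: int = N_CLASSES) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)

    def subset(self, indices) -> "LabeledPatchSet":
        idx = np.asarray(indices)
        return LabeledPatchSet(self.patches[idx], self.labels[idx], self.modality)


def generate_patch(
    spec: SpeciesSpec,
    modality: str = "rgb",
    side: int = 227,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Draw one (side, side, channels) reflectance patch for a class.

    Deterministic for a given integer seed or generator state.  The pixel
    process is base mean + zero-mean Gaussian leaf blobs + i.i.d. Gaussian
    noise, clipped to [0, 1]; with zero noise and zero blob density every
    pixel equals the class mean exactly.
    """
    if side < 16:
        raise ValueError("side must be >= 16 pixels")
    means = spec.mean_for(modality)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    img = np.broadcast_to(means, (side, side, means.size)).astype(np.float64).copy()

    n_blobs = rng.poisson(spec.blob_density * side * side)
    if n_blobs:
        yy, xx = np.mgrid[0:side, 0:side]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, side, size=2)
            radius = rng.uniform(*spec.blob_radius)
            amp = rng.normal(0.0, spec.blob_amplitude_sd)
            profile = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * radius**2))
            img += amp * profile[:, :, None]

    sd = spec.noise_for(modality)
    if sd > 0:
        img += rng.normal(0.0, sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def augment_rotations(dataset: LabeledPatchSet) -> LabeledPatchSet:
    """Append the 90, 180 and 270-degree rotations of every patch.

    Output size is exactly four times the input size and each rotated copy
    keeps its source label, so the class histogram scales by four.
    """
    if len(dataset) == 0:
        raise ValueError("cannot augment an empty dataset")
    if dataset.patches.shape[1] != dataset.patches.shape[2]:
        raise ValueError("rotation augmentation requires square patches")
    rotated = [dataset.patches]
    for k in (1, 2, 3):
        rotated.append(np.rot90(dataset.patches, k=k, axes=(1, 2)))
    patches = np.concatenate(rotated, axis=0)
    labels = np.tile(dataset.labels, 4)
    return LabeledPatchSet(patches, labels, dataset.modality)


def build_benchmark(
    train_counts: tuple[int, ...] = TRAIN_COUNTS,
    test_counts: tuple[int, ...] = TEST_COUNTS,
    modality: str = "rgb",
    side: int = 227,
    seed: int = 0,
    specs: list[SpeciesSpec] | None = None,
) -> tuple[LabeledPatchSet, LabeledPatchSet]:
    """Generate a train/test benchmark with exact per-class patch counts.

    The default counts reproduce the reference sample collection: a
    2,287-patch training split and a 979-patch test split over six classes.
    """
    specs = default_species() if specs is None else specs
    if len(train_counts) != len(specs) or len(test_counts) != len(specs):
        raise ValueError("need one train and one test count per class")
    if any(c < 0 for c in train_counts + tuple(test_counts)):
        raise ValueError("counts must be >= 0")
    if sum(train_counts) + sum(test_counts) == 0:
        raise ValueError("all counts are zero")

    rng = np.random.default_rng(seed)

    def _make(counts) -> LabeledPatchSet:
        patches, labels = [], []
        for spec, count in zip(specs, counts):
            for _ in range(count):
                patches.append(generate_patch(spec, modality, side, rng))
                labels.append(spec.class_index)
        n_ch = 3 if modality == "rgb" else 5
        if not patches:
            return LabeledPatchSet(
                np.empty((0, side, side, n_ch), np.float32), np.empty(0, int), modality
            )
        return LabeledPatchSet(np.stack(patches), np.array(labels), modality)

    return _make(train_counts), _make(test_counts)


# ---------------------------------------------------------------------------
# on-disk format: PNG (RGB, 8-bit) / multi-band TIFF (MS, 16-bit) + manifest
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.csv"


def write_dataset(
    dataset: LabeledPatchSet, directory: str | pathlib.Path, split: str = "train"
) -> pathlib.Path:
    """Write patches plus a CSV manifest (filename, label_code, class_name,
    split, modality).  RGB patches go to 8-bit PNG, multispectral ones to
    16-bit 5-band TIFF; reflectance is rescaled from [0, 1] to the integer
    range, so the round-trip is lossless up to that quantization."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (patch, label) in enumerate(zip(dataset.patches, dataset.labels)):
        if dataset.modality == "rgb":
            fname = f"patch_{i:05d}.png"
            iio.imwrite(directory / fname, np.round(patch * 255).astype(np.uint8))
        else:
            fname = f"patch_{i:05d}.tif"
            tifffile.imwrite(
                directory / fname, np.round(patch * 65535).astype(np.uint16)
            )
        rows.append(
            {
                "filename": fname,
                "label_code": one_hot_code(int(label)),
                "class_name": CLASS_NAMES[int(label)],
                "split": split,
                "modality": dataset.modality,
            }
        )
    pd.DataFrame(rows).to_csv(directory / _MANIFEST, index=False)
    return directory


def read_dataset(directory: str | pathlib.Path) -> LabeledPatchSet:
    """Load a dataset written by :func:`write_dataset`.

    Raises ``FileNotFoundError`` for a manifest entry whose image file is
    missing and ``ValueError`` for a corrupt band count.
    """
    directory = pathlib.Path(directory)
    manifest = pd.read_csv(
        directory / _MANIFEST, dtype={"label_code": str, "filename": str}
    )
    modality = str(manifest["modality"].iloc[0])
    expected_c = 3 if modality == "rgb" else 5
    patches, labels = [], []
    for row in manifest.itertuples():
        path = directory / row.filename
        if not path.exists():
            raise FileNotFoundError(f"manifest entry {row.filename} missing on disk")
        if modality == "rgb":
            arr = iio.imread(path).astype(np.float32) / 255.0
        else:
            arr = tifffile.imread(path).astype(np.float32) / 65535.0
        if arr.ndim != 3 or arr.shape[-1] != expected_c:
            raise ValueError(
                f"{row.filename}: expected {expected_c} bands, got shape {arr.shape}"
            )
        patches.append(arr)
        labels.append(_code_to_index(row.label_code))
    if not patches:
        raise ValueError("empty manifest")
    return LabeledPatchSet(np.stack(patches), np.array(labels), modality)
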