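"""CT volume preparation: HU windowing, slicing, relevance filtering,
normalisation and flip/rotation augmentation.

Volumes arrive as 3-D Hounsfield-unit scalar fields with an aligned
integer label field (0 = background, 1 = kidney, 2 = tumor), the layout
used by the KiTS kidney-tumor challenge.  The pipeline is:

1. ``window_clip`` — clamp intensities to a soft-tissue window
   (default [-200, 500] HU) to suppress bone and air extremes.
2. ``extract_slices`` — split the volume into axial 2-D samples with a
   binary task mask (kidney task: labels >= 1, i.e. tumor voxels count
   as kidney, matching the nested annotation convention; tumor task:
   labels == 2).
3. ``filter_relevant`` — drop slices whose mask is empty.
4. ``normalize`` — affine map of the window to [0, 1].
5. ``augment`` — random 90-degree rotation then horizontal/vertical flips
   (each with probability 0.5), applied identically to image and mask;
   training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

Task = Literal["kidney", "tumor"]
VALID_LABELS = frozenset({0, 1, 2})


@dataclass(frozen=True)
class WindowSpec:
    """HU clipping window; defaults to the soft-tissue window [-200, 500]."""

    lo: float = -200.0
    hi: float = 500.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")


@dataclass
class CTVolume:
    """A 3-D CT scan: HU voxels, aligned integer labels, voxel spacing (mm)."""

    voxels: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = "case"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.labels = np.asarray(self.labels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        if self.voxels.shape != self.labels.shape:
            raise ValueError(
                f"voxels {self.voxels.shape} and labels {self.labels.shape} differ")
        if not set(np.unique(self.labels)).issubset(VALID_LABELS):
            raise ValueError("labels must be drawn from {0, 1, 2}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class SliceSample:
    """One axial 2-D training sample: normalised image + binary task mask."""

    image: np.ndarray
    mask: np.ndarray
    case_id: str
    slice_index: int
    task: Task

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def window_clip(volume: CTVolume, spec: WindowSpec = WindowSpec()) -> CTVolume:
    """Clamp every voxel into [spec.lo, spec.hi]; labels are untouched."""
    if not np.isfinite(volume.voxels).all():
        raise ValueError("volume contains non-finite HU values")
    clipped = np.clip(volume.voxels, spec.lo, spec.hi)
    return CTVolume(clipped, volume.labels, volume.spacing, volume.case_id)


def normalize(image_hu: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Affine map [lo, hi] -> [0, 1].  Input must already be windowed."""
    img = np.asarray(image_hu, dtype=np.float32)
    if img.min() < spec.lo or img.max() > spec.hi:
        raise ValueError(
            "values outside the window; run window_clip before normalize")
    return (img - spec.lo) / (spec.hi - spec.lo)


def _task_mask(labels: np.ndarray, task: Task) -> np.ndarray:
    if task == "kidney":
        return (labels >= 1).astype(np.uint8)
    if task == "tumor":
        return (labels == 2).astype(np.uint8)
    raise ValueError(f"unknown task {task!r}")


def extract_slices(volume: CTVolume, task: Task,
                   spec: WindowSpec = WindowSpec()) -> list[SliceSample]:
    """Split a windowed volume into per-axial-index normalised samples."""
    if volume.voxels.size == 0:
        raise ValueError("cannot slice an empty volume")
    samples = []
    for k in range(volume.voxels.shape[0]):
        img = normalize(volume.voxels[k], spec)
        mask = _task_mask(volume.labels[k], task)
        samples.append(SliceSample(img, mask, volume.case_id, k, task))
    return samples


def filter_relevant(samples: Iterable[SliceSample]) -> list[SliceSample]:
    """Keep only slices whose mask has at least one foreground pixel."""
    return [s for s in samples if s.mask.any()]


def augment(sample: SliceSample, rng_seed: int) -> SliceSample:
    """Random k*90-degree rotation, then horizontal and vertical flips
    (probability 0.5 each), identical on image and mask; deterministic
    for a given seed.  Requires a square image (90-degree rotation would
    otherwise change the shape)."""
    h, w = sample.image.shape
    if h != w:
        raise ValueError("augmentation requires square slices")
    rng = np.random.default_rng(rng_seed)
    k = int(rng.integers(0, 4))
    do_h = bool(rng.random() < 0.5)
    do_v = bool(rng.random() < 0.5)

    def tf(a: np.ndarray) -> np.ndarray:
        a = np.rot90(a, k)
        if do_h:
            a = a[:, ::-1]
        if do_v:
            a = a[::-1, :]
        return np.ascontiguousarray(a)

    return replace(sample, image=tf(sample.image), mask=tf(sample.mask))


def split_cases(case_ids: Sequence[str], fractions: Sequence[float],
                ) -> dict[str, list[str]]:
    """Partition case ids into train/val/test by the given fractions.

    Sizes are floored; remainder cases go to train.  Order is preserved
    (the caller shuffles if random assignment is wanted).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if len(fractions) != 3:
        raise ValueError("expected (train, val, test) fractions")
    n = len(case_ids)
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0 or (fractions[1] > 0 and n_val == 0) \
            or (fractions[2] > 0 and n_test == 0):
        raise ValueError(f"{n} cases are too few for fractions {fractions}")
    ids = list(case_ids)
    return {
        "train": ids[:n_train],
        "val": ids[n_train:n_train + n_val],
        "test": ids[n_train + n_val:],
    }


# ---------------------------------------------------------------------------
# Disk I/O (KiTS-style layout: <dir>/<case_id>/imaging.nii.gz + segmentation.nii.gz)
# ---------------------------------------------------------------------------

def load_case(case_dir: Path) -> CTVolume:
    """Read one case directory of NIfTI image + segmentation."""
    import nibabel as nib

    case_dir = Path(case_dir)
    img_path = _find_nifti(case_dir, ("imaging", "image"))
    seg_path = _find_nifti(case_dir, ("segmentation", "seg", "label"))
    img = nib.load(str(img_path))
    seg = nib.load(str(seg_path))
    voxels = np.asarray(img.dataobj, dtype=np.float32)
    labels = np.rint(np.asarray(seg.dataobj)).astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    return CTVolume(voxels, labels, tuple(float(z) for z in zooms), case_dir.name)


def _find_nifti(case_dir: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in (".nii.gz", ".nii"):
            p = case_dir / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(f"no NIfTI with stem {stems} in {case_dir}")


def write_slices(samples: Iterable[SliceSample], out_dir: Path, split: str,
                 ) -> "pandas.DataFrame":
    """Write samples as 8-bit PNG image/mask pairs plus a manifest table."""
    import pandas as pd
    from PIL import Image

    out_dir = Path(out_dir)
    rows = []
    for s in samples:
        img_dir = out_dir / s.task / split / "images"
        msk_dir = out_dir / s.task / split / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        name = f"{s.case_id}_{s.slice_index:04d}.png"
        img8 = np.clip(np.rint(s.image * 255), 0, 255).astype(np.uint8)
        Image.fromarray(img8).save(img_dir / name)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(msk_dir / name)
        rows.append({"case_id": s.case_id, "slice_index": s.slice_index,
                     "task": s.task, "split": split,
                     "image_path": str(img_dir / name),
                     "mask_path": str(msk_dir / name)})
    return pd.DataFrame(rows)


def load_slice_png(image_path: Path, mask_path: Path, case_id: str,
                   slice_index: int, task: Task) -> SliceSample:
    """Read an 8-bit PNG image/mask pair back into a SliceSample."""
    from PIL import Image

    img = np.asarray(Image.open(image_path), dtype=np.float32) / 255.0
    mask = (np.asarray(Image.open(mask_path)) > 127).astype(np.uint8)
    return SliceSample(img, mask, case_id, slice_index, task)
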