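"""KiTS-like phantom CT volumes for desk-scale testing and training.

The phantoms are geometric, not anatomical: a soft-tissue background with
an air margin (outside the body), a bone-density spine column, and
elliptical kidneys that may contain a smaller spherical tumor.  Tissue
means are placed so that bone (700 HU) and air (-1000 HU) fall outside
the [-200, 500] soft-tissue window while kidney (120 HU), tumor (70 HU)
and background (40 HU) fall inside it — windowing therefore provably
acts on every generated volume.  Per-voxel Gaussian noise emulates CT
quantum noise.

Everything is deterministic given ``PhantomSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import (CTVolume, SliceSample, Task, WindowSpec, augment,
                            extract_slices, filter_relevant, split_cases,
                            window_clip)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the phantom generator.

    ``kidney_axes`` gives per-axis (lo, hi) semi-axis ranges in voxels;
    tumor radius is drawn in voxels and constrained to fit strictly
    inside its kidney.  HU means: background soft tissue 40, kidney 120,
    tumor 70, bone 700, air -1000; noise_sd 15 HU.
    """

    shape: tuple[int, int, int] = (32, 128, 128)
    n_kidneys: int = 2
    kidney_axes: tuple[tuple[float, float], ...] = ((4, 8), (12, 20), (12, 20))
    tumor_prob: float = 0.8
    tumor_radius: tuple[float, float] = (3.0, 6.0)
    hu_background: float = 40.0
    hu_kidney: float = 120.0
    hu_tumor: float = 70.0
    hu_bone: float = 700.0
    hu_air: float = -1000.0
    noise_sd: float = 15.0
    air_margin: int = 4
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.tumor_prob <= 1):
            raise ValueError("tumor_prob must be in [0, 1]")
        if self.n_kidneys < 0:
            raise ValueError("n_kidneys must be non-negative")

    @staticmethod
    def scaled(shape: tuple[int, int, int], seed: int = 0, **overrides) -> "PhantomSpec":
        """A spec whose kidney/tumor geometry scales with the volume shape,
        keeping the default proportions of the 32 x 128 x 128 phantom."""
        nz, ny, nx = shape
        fields = dict(
            shape=shape,
            kidney_axes=((0.125 * nz, 0.25 * nz),
                         (0.094 * ny, 0.156 * ny),
                         (0.094 * nx, 0.156 * nx)),
            tumor_radius=(max(0.023 * nx, 1.5), max(0.047 * nx, 2.25)),
            seed=seed,
        )
        fields.update(overrides)
        return PhantomSpec(**fields)


def desk_spec(seed: int = 0) -> PhantomSpec:
    """The desk-scale phantom configuration used by the package's own
    training experiments: 16 x 64 x 64 volumes, proportionally scaled
    kidneys and tumors, default tissue intensities and noise."""
    return PhantomSpec(shape=(16, 64, 64),
                       kidney_axes=((2.5, 4), (8, 13), (8, 13)),
                       tumor_radius=(2.5, 4.5), seed=seed)


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def generate_volume(spec: PhantomSpec, case_id: str = "case_00000",
                    return_geometry: bool = False):
    """One phantom volume with labels 0 (background), 1 (kidney), 2 (tumor).

    With ``return_geometry=True`` also returns the list of placed shapes
    (kidney ellipsoid centres/axes and tumor sphere centres/radii) so
    geometric properties can be verified independently.  The random
    stream is consumed identically whether or not a tumor is placed, so
    two specs differing only in ``tumor_prob`` yield identical kidneys.
    """
    rng = np.random.default_rng(spec.seed)
    geometry = []
    nz, ny, nx = spec.shape
    m = spec.air_margin

    margins = (1, m, m)  # the air frame is in-plane only
    for (lo, hi), dim, mg in zip(spec.kidney_axes, spec.shape, margins):
        if 2 * hi > dim - 2 * mg:
            raise ValueError(
                f"kidney semi-axis up to {hi} cannot fit in dimension {dim} "
                f"with margin {mg}")

    voxels = np.full(spec.shape, spec.hu_background, dtype=np.float32)
    labels = np.zeros(spec.shape, dtype=np.int16)

    # air outside the "body": a margin frame in every axial slice
    if m > 0:
        voxels[:, :m, :] = spec.hu_air
        voxels[:, -m:, :] = spec.hu_air
        voxels[:, :, :m] = spec.hu_air
        voxels[:, :, -m:] = spec.hu_air

    # spine: a bone-density column along z at the posterior centre
    spine_r = max(nx // 20, 2)
    spine = _ellipsoid_mask((ny, nx), (0.78 * ny, 0.5 * nx), (spine_r, spine_r))
    voxels[:, spine] = spec.hu_bone

    # lateral slots keep kidneys off the spine and each other
    slots = np.linspace(0.28, 0.72, max(spec.n_kidneys, 1))
    for k in range(spec.n_kidneys):
        axes = [rng.uniform(lo, hi) for lo, hi in spec.kidney_axes]
        z_lo, z_hi = 1 + axes[0], nz - 1 - axes[0]
        x_lo, x_hi = m + axes[2], nx - m - axes[2]
        center = [
            rng.uniform(min(z_lo, z_hi), max(z_lo, z_hi)),
            rng.uniform(0.35 * ny, 0.55 * ny),
            np.clip(slots[k] * nx + rng.uniform(-3, 3),
                    min(x_lo, x_hi), max(x_lo, x_hi)),
        ]
        kidney = _ellipsoid_mask(spec.shape, center, axes)
        voxels[kidney] = spec.hu_kidney
        labels[kidney] = 1
        geometry.append({"kind": "kidney", "center": tuple(center),
                         "axes": tuple(axes)})

        # draw tumor parameters unconditionally so the stream is stable
        place_tumor = rng.random() < spec.tumor_prob
        r = rng.uniform(*spec.tumor_radius)
        r = min(r, 0.7 * min(axes))
        # offset in the ellipsoid's normalised coordinates; the bound
        # |o/a| + r/min(a) <= 0.95 guarantees the sphere is strictly
        # inside the kidney ellipsoid
        budget = 0.95 - r / min(axes)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rho = rng.uniform(0, max(budget, 0.0))
        if place_tumor:
            offset = direction * rho * np.asarray(axes)
            tcenter = np.asarray(center) + offset
            tumor = _ellipsoid_mask(spec.shape, tcenter, (r, r, r))
            voxels[tumor] = spec.hu_tumor
            labels[tumor] = 2
            geometry.append({"kind": "tumor", "center": tuple(tcenter),
                             "radius": float(r)})

    if spec.noise_sd > 0:
        voxels += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
    volume = CTVolume(voxels, labels, (3.0, 1.0, 1.0), case_id)
    return (volume, geometry) if return_geometry else volume


@dataclass
class SliceDataset:
    """Per-split slice samples plus a per-slice manifest table."""

    splits: dict[str, list[SliceSample]]
    manifest: "pandas.DataFrame"

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.splits.items()}


def generate_dataset(spec: PhantomSpec, n_volumes: int,
                     fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                     task: Task = "kidney",
                     window: WindowSpec = WindowSpec()) -> SliceDataset:
    """Generate phantoms, run the real preprocessing pipeline and split.

    Volumes are split case-level (floor the val/test sizes, remainder to
    train) so no case contributes slices to two splits.  Only relevant
    slices (non-empty task mask) are kept.
    """
    import pandas as pd

    if n_volumes < 1:
        raise ValueError("need at least one volume")
    children = np.random.SeedSequence(spec.seed).spawn(n_volumes)
    case_ids = [f"case_{i:05d}" for i in range(n_volumes)]
    assignment = split_cases(case_ids, fractions)

    by_case: dict[str, list[SliceSample]] = {}
    for cid, child in zip(case_ids, children):
        vspec = PhantomSpec(**{**spec.__dict__, "seed": int(child.generate_state(1)[0] % 2**31)})
        vol = window_clip(generate_volume(vspec, cid), window)
        by_case[cid] = filter_relevant(extract_slices(vol, task, window))

    splits: dict[str, list[SliceSample]] = {}
    rows = []
    for split, ids in assignment.items():
        samples = [s for cid in ids for s in by_case[cid]]
        splits[split] = samples
        rows += [{"case_id": s.case_id, "slice_index": s.slice_index,
                  "task": s.task, "split": split} for s in samples]
    return SliceDataset(splits, pd.DataFrame(rows))


def write_volumes(spec: PhantomSpec, n_volumes: int, out_dir) -> list[str]:
    """Write phantom volumes to disk in the KiTS-style NIfTI layout."""
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    children = np.random.SeedSequence(spec.seed).spawn(n_volumes)
    case_ids = []
    for i, child in enumerate(children):
        cid = f"case_{i:05d}"
        vspec = PhantomSpec(**{**spec.__dict__, "seed": int(child.generate_state(1)[0] % 2**31)})
        vol = generate_volume(vspec, cid)
        case_dir = out_dir / cid
        case_dir.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*vol.spacing, 1.0])
        nib.save(nib.Nifti1Image(vol.voxels, affine), case_dir / "imaging.nii.gz")
        nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), affine),
                 case_dir / "segmentation.nii.gz")
        case_ids.append(cid)
    return case_ids
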