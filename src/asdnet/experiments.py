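"""Canonical desk-scale experiments.

These are the package's reference demonstrations, shared by the test
suite and the reproduction script so both exercise exactly the same
computation:

* :func:`overfit_capacity` — can the full assembly drive the combined
  loss to near zero on a fixed two-slice batch?  (A failure indicates a
  wiring or gradient defect, not a data problem.)
* :func:`desk_scale_training` — train a reduced-width network on the
  default ten-volume phantom corpus and report the best validation DSC.
  Kidney phantoms check absolute segmentation competence; the tumor task
  compares the dual-encoder network against a plain U-Net of matched
  width trained identically (a directional ablation).
* :func:`pipeline_metrics_csv` — the seeded synth -> preprocess -> train
  -> evaluate pipeline, returning the evaluation table as CSV text so
  two runs can be compared byte-for-byte.

Problem sizes (64 x 64 slices, ten volumes, 30 epochs, base width 8) are
chosen so each experiment completes in minutes on one CPU core.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .network import ASDNet, NetworkConfig, build_network
from .runtime import TrainConfig, TrainHistory, evaluate, train, train_step
from .synthetic_data import PhantomSpec, desk_spec, generate_dataset

#: width of the reduced desk-scale network
DESK_BASE_CHANNELS = 8
#: epochs of the desk-scale training runs
DESK_EPOCHS = 30
#: volumes in the desk-scale phantom corpus
DESK_VOLUMES = 10


def overfit_capacity(seed: int = 0, steps: int = 200, lr: float = 1e-3,
                     ) -> list[float]:
    """Loss trajectory of overfitting a fixed 2-slice kidney batch.

    Uses an aggressive constant learning rate (1e-3): the check targets
    the assembly's ability to fit, not the production schedule.
    """
    ds = generate_dataset(desk_spec(seed=seed + 1), 4,
                          fractions=(0.5, 0.25, 0.25), task="kidney")
    batch = ds.splits["train"][:2]
    images = np.stack([s.image for s in batch]).astype(np.float32)[:, None]
    masks = np.stack([s.mask for s in batch]).astype(np.float32)[:, None]
    model = ASDNet(NetworkConfig(base_channels=DESK_BASE_CHANNELS), seed=seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    return [train_step(model, opt, images, masks) for _ in range(steps)]


def desk_scale_training(task: str, arch: str = "asdnet", seed: int = 0,
                        epochs: int = DESK_EPOCHS,
                        n_volumes: int = DESK_VOLUMES) -> TrainHistory:
    """Train a reduced network on the desk-scale phantom corpus."""
    ds = generate_dataset(desk_spec(seed=seed + 1), n_volumes, task=task)
    model = build_network(NetworkConfig(base_channels=DESK_BASE_CHANNELS),
                          seed=seed + 2, arch=arch)
    cfg = TrainConfig(epochs=epochs, seed=seed + 3)
    history, _ = train(model, ds.splits["train"], ds.splits["val"], cfg)
    return history


def pipeline_metrics_csv(seed: int = 0) -> str:
    """Seeded end-to-end pipeline; returns the per-slice metric table as CSV.

    Kept deliberately tiny (four 8 x 48 x 48 volumes, three epochs, base
    width 4) — the property of interest is bit-level reproducibility, not
    accuracy.
    """
    spec = PhantomSpec.scaled((8, 48, 48), seed=seed + 1)
    ds = generate_dataset(spec, 4, fractions=(0.5, 0.25, 0.25), task="kidney")
    model = ASDNet(NetworkConfig(base_channels=4), seed=seed + 2)
    cfg = TrainConfig(epochs=3, seed=seed + 3)
    _, best_state = train(model, ds.splits["train"], ds.splits["val"], cfg)
    model.load_state_dict(best_state)
    table, _ = evaluate(model, ds.splits["test"], threshold=cfg.threshold)
    return table.to_csv(index=False)
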