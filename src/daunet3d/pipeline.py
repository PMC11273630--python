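"""Training, evaluation and ablation orchestration.

The training recipe: Adam (lr 1e-3), Tversky loss (alpha 0.7, beta 0.3),
batch size 1, up to 200 epochs with early stopping after 30 validation
epochs without improvement in validation Dice.  Each optimisation step
feeds one randomly cropped (and optionally rotated/scaled) patch of one
case.  Everything is driven by a single seed: the train/validation split,
the per-epoch case order, and every augmentation draw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import TverskyParams, tversky_loss
from .metrics import EmptySurfaceError, dice, evaluate_case, voe
from .network import (DAResUNet, NetworkConfig, build_model, load_checkpoint,
                      predict_mask, save_checkpoint)
from .nn import Adam, no_grad
from .preprocessing import AugmentSpec, PreprocessSpec, augment, preprocess_case
from .volume_io import CTVolume, SegmentationMask, read_mask, read_volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the training recipe (defaults are the recipe)."""

    epochs: int = 200
    early_stopping_patience: int = 30
    batch_size: int = 1
    learning_rate: float = 1e-3
    loss: TverskyParams = field(default_factory=TverskyParams)
    patch_shape: tuple[int, int, int] = (32, 256, 256)
    val_fraction: float = 0.2
    seed: int = 0
    max_steps: int | None = None
    augment_spec: AugmentSpec | None = None
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1 or self.early_stopping_patience < 0:
            raise ValueError("epochs must be >= 1 and patience >= 0")
        if self.batch_size != 1:
            raise ValueError("the recipe trains one volume at a time (batch_size 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class TrainResult:
    model: DAResUNet
    history: pd.DataFrame  # epoch, mean_train_loss, val_dice
    steps: int
    best_val_dice: float
    final_train_dice: float
    stopped_early: bool


def _load_cases(manifest) -> list[tuple[str, CTVolume, SegmentationMask]]:
    """Manifest (dict or JSON path) -> list of (case_id, volume, mask)."""
    if isinstance(manifest, (str, Path)):
        with open(manifest) as f:
            manifest = json.load(f)
    cases = manifest["cases"] if isinstance(manifest, dict) else manifest
    out = []
    for c in cases:
        if isinstance(c, dict):
            out.append((c["case_id"], read_volume(c["image"]), read_mask(c["mask"])))
        else:  # already-loaded (case_id, vol, mask) triple
            out.append(tuple(c))
    if not out:
        raise ValueError("empty dataset manifest")
    return out


def _random_crop(vol: CTVolume, mask: SegmentationMask,
                 patch: tuple[int, int, int], rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    shape = vol.shape
    if any(p > s for p, s in zip(patch, shape)):
        raise ValueError(f"patch {patch} larger than volume {shape}")
    starts = [int(rng.integers(0, s - p + 1)) for p, s in zip(patch, shape)]
    sl = tuple(slice(a, a + p) for a, p in zip(starts, patch))
    return vol.voxels[sl], mask.voxels[sl]


def _hard_dice(model: DAResUNet, cases, patch, threshold) -> float:
    scores = []
    for _, vol, mask in cases:
        pred = predict_mask(model, vol, threshold=threshold, tile_shape=patch)
        scores.append(dice(pred, mask))
    return float(np.mean(scores))


def train(net_config: NetworkConfig, train_config: TrainConfig, manifest,
          preprocess_spec: PreprocessSpec | None = None,
          checkpoint_path=None) -> TrainResult:
    """Run the epoch loop and return the best-validation model.

    ``preprocess_spec`` defaults to window clipping + unit normalisation
    with no resampling (phantom datasets are generated on the target grid).
    Cases are split by case id into train/validation; with
    ``val_fraction = 0`` all cases train and early stopping is disabled
    (the overfitting regime).
    """
    pp = preprocess_spec or PreprocessSpec(target_inplane=None,
                                           target_axial_spacing=None)
    raw = _load_cases(manifest)
    cases = []
    for cid, vol, mask in raw:
        v, m = preprocess_case(vol, mask, pp)
        cases.append((cid, v, m))

    rng = np.random.default_rng(train_config.seed)
    order = rng.permutation(len(cases))
    n_val = int(round(train_config.val_fraction * len(cases)))
    if train_config.val_fraction > 0:
        n_val = max(1, n_val)
    if len(cases) - n_val < 1:
        raise ValueError("need at least one training case after the split")
    val_cases = [cases[i] for i in order[:n_val]]
    train_cases = [cases[i] for i in order[n_val:]]

    model = build_model(net_config, seed=train_config.seed)
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    patch = train_config.patch_shape

    history = []
    best_val, best_state, stall, steps = -np.inf, None, 0, 0
    stopped_early = False
    for epoch in range(train_config.epochs):
        epoch_losses = []
        for i in rng.permutation(len(train_cases)):
            cid, vol, mask = train_cases[i]
            if train_config.augment_spec is not None:
                step_seed = int(rng.integers(0, 2 ** 31))
                aug = replace(train_config.augment_spec, seed=step_seed,
                              fill_value=0.0 if pp.normalize_to_unit
                              else pp.hu_window[0])
                vol, mask = augment(vol, mask, aug)
            img, gt = _random_crop(vol, mask, patch, rng)
            prob = model(img[None])
            loss = tversky_loss(prob, gt[None], train_config.loss)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss at step {steps} (case {cid}); aborting")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(lv)
            steps += 1
            if train_config.max_steps and steps >= train_config.max_steps:
                break

        val_dice = (_hard_dice(model, val_cases, patch, train_config.threshold)
                    if val_cases else np.nan)
        history.append({"epoch": epoch, "mean_train_loss": np.mean(epoch_losses),
                        "val_dice": val_dice})
        logger.info("epoch %d: loss %.4f val-dice %s",
                    epoch, history[-1]["mean_train_loss"], val_dice)

        if val_cases:
            if val_dice > best_val:
                best_val, best_state, stall = val_dice, model.state_dict(), 0
            else:
                stall += 1
                if stall >= train_config.early_stopping_patience > 0:
                    stopped_early = True
                    break
        if train_config.max_steps and steps >= train_config.max_steps:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    final_train_dice = _hard_dice(model, train_cases, patch,
                                  train_config.threshold)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return TrainResult(model=model, history=pd.DataFrame(history), steps=steps,
                       best_val_dice=float(best_val) if val_cases else np.nan,
                       final_train_dice=final_train_dice,
                       stopped_early=stopped_early)


def _case_id_from_path(path: Path) -> str:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    for suffix in ("_pred", "_mask"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def _nifti_files(d: Path) -> dict[str, Path]:
    return {_case_id_from_path(p): p
            for p in sorted(d.iterdir())
            if p.name.endswith((".nii", ".nii.gz"))}


def evaluate(pred_dir, gt_dir) -> tuple[pd.DataFrame, list[str]]:
    """Pair prediction/truth files by case id and compute the four metrics.

    Returns a per-case table (DSC and VOE in percent, distances in mm) with
    a final ``mean`` row, plus the list of unmatched case ids (callers
    should treat a nonempty list as a partial-evaluation condition).
    """
    preds = _nifti_files(Path(pred_dir))
    gts = _nifti_files(Path(gt_dir))
    matched = sorted(set(preds) & set(gts))
    unmatched = sorted(set(preds) ^ set(gts))
    for cid in unmatched:
        logger.warning("unmatched case skipped: %s", cid)
    if not matched:
        raise ValueError("no case ids shared between directories")
    rows = []
    for cid in matched:
        pred, gt = read_mask(preds[cid]), read_mask(gts[cid])
        try:
            r = evaluate_case(pred, gt, case_id=cid)
            rows.append({"case_id": cid, "dsc_pct": 100 * r.dsc,
                         "voe_pct": 100 * r.voe, "hd95_mm": r.hd95_mm,
                         "rmsd_mm": r.rmsd_mm})
        except EmptySurfaceError:
            logger.warning("case %s has an empty surface; distances undefined", cid)
            rows.append({"case_id": cid, "dsc_pct": 100 * dice(pred, gt),
                         "voe_pct": 100 * voe(pred, gt),
                         "hd95_mm": np.nan, "rmsd_mm": np.nan})
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns="case_id").mean(numeric_only=True)
    df = pd.concat([df, pd.DataFrame([{"case_id": "mean", **mean_row}])],
                   ignore_index=True)
    return df, unmatched


def run_ablation(configs: dict[str, NetworkConfig], train_config: TrainConfig,
                 manifest, preprocess_spec: PreprocessSpec | None = None
                 ) -> pd.DataFrame:
    """Train/evaluate each configuration on the same split and seed.

    One row per configuration: parameter count, final training Dice and
    best validation Dice — the shape of an attention-placement ablation
    table, at whatever data scale the manifest provides.
    """
    rows = []
    for name, cfg in configs.items():
        res = train(cfg, train_config, manifest, preprocess_spec)
        rows.append({"config": name,
                     "parameters": res.model.num_parameters(),
                     "train_dice_pct": 100 * res.final_train_dice,
                     "val_dice_pct": 100 * res.best_val_dice,
                     "mean_train_loss": res.history["mean_train_loss"].iloc[-1]})
    return pd.DataFrame(rows)


def predict_volume(checkpoint_path, image_path, out_path,
                   preprocess_spec: PreprocessSpec | None = None,
                   threshold: float = 0.5,
                   tile_shape: tuple[int, int, int] | None = None) -> Path:
    """Load a checkpoint, preprocess one scan, write the predicted mask."""
    model = load_checkpoint(checkpoint_path)
    vol = read_volume(image_path)
    pp = preprocess_spec or PreprocessSpec(target_inplane=None,
                                           target_axial_spacing=None)
    vol, _ = preprocess_case(vol, None, pp)
    mask = predict_mask(model, vol, threshold=threshold, tile_shape=tile_shape)
    from .volume_io import write_volume
    return write_volume(mask, out_path)
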