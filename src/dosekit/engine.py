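"""Training and inference engine for the three dose-map correction tasks.

Tasks (and nothing else) bind the correction states of input and reference:

====  ===========  ===============
task  model input  model reference
====  ===========  ===============
AC    NC dose map  AC dose map
SC    AC dose map  ASC dose map
ASC   NC dose map  ASC dose map
====  ===========  ===============

Every dose map carries its correction state, and feeding a map whose state
does not match the task raises — the contract is enforced totally, not by
convention.  Training follows a 5-fold cross-validation protocol: five
models, each trained on four folds, ensembled at inference time by
voxelwise averaging; inference tiles arbitrary volumes with training-sized
patches (sliding window, 50% overlap, uniform blend weights).  Dose maps
are normalised by a fixed 200 Gy maximum *without clipping* (a 400 Gy voxel
maps to 2.0), so the normalisation is exactly invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .image import VolumetricImage
from .ldm import DoseMap
from .regressors import FeatureSpec, IdentityRegressor, LocalFeatureMLP

__all__ = [
    "CorrectionTask",
    "TrainingConfig",
    "RegressorEnsemble",
    "TaskContractError",
    "normalise",
    "denormalise",
    "make_folds",
    "sample_training_patches",
    "train_task",
    "predict",
    "sliding_window_predict",
]


class TaskContractError(ValueError):
    """A dose map's correction state does not match the task definition."""


class CorrectionTask(Enum):
    """The three learnable corrections, keyed by what they add."""

    AC = ("NC", "AC")
    SC = ("AC", "ASC")
    ASC = ("NC", "ASC")

    @property
    def input_state(self) -> str:
        return self.value[0]

    @property
    def reference_state(self) -> str:
        return self.value[1]

    def check_pair(self, inp: DoseMap, ref: DoseMap) -> None:
        if inp.correction_state != self.input_state:
            raise TaskContractError(
                f"task {self.name} expects {self.input_state} input, "
                f"got {inp.correction_state}")
        if ref.correction_state != self.reference_state:
            raise TaskContractError(
                f"task {self.name} expects {self.reference_state} reference, "
                f"got {ref.correction_state}")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the correction training protocol.

    Defaults are the full-scale protocol: 64^3 patches, Adam with learning
    rate 1e-3 and weight decay 1e-4, batch size 2, L1 loss, 200 epochs,
    dropout 0.1, 5 folds, rotation/flip augmentation only (deformable
    augmentation would corrupt the quantitative dose values), 0-200 Gy
    normalisation.  ``desk()`` returns a CPU-scale profile.
    """

    patch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 2
    epochs: int = 200
    dropout: float = 0.1
    loss: str = "L1"
    folds: int = 5
    augment: bool = True
    normalisation_max_gy: float = 200.0
    patches_per_volume: int = 4
    hidden: int = 16
    use_depth: bool = True
    probe_init: bool = True
    probe_voxels: int = 50000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.loss != "L1":
            raise ValueError("only the L1 loss is supported")
        if self.normalisation_max_gy <= 0:
            raise ValueError("normalisation maximum must be positive")

    @classmethod
    def desk(cls, **overrides) -> "TrainingConfig":
        """CPU desk-scale profile: 32^3 patches, 10 epochs."""
        base = dict(patch_size=32, epochs=10, patches_per_volume=4)
        base.update(overrides)
        return cls(**base)

    def feature_spec(self) -> FeatureSpec:
        return FeatureSpec(use_depth=self.use_depth)


def normalise(dose: DoseMap | np.ndarray,
              max_gy: float = 200.0) -> np.ndarray:
    """Map Gy to the unit scale: value / max_gy, without clipping."""
    if max_gy <= 0:
        raise ValueError("normalisation maximum must be positive")
    values = dose.values if isinstance(dose, DoseMap) else np.asarray(dose)
    return np.asarray(values, dtype=float) / max_gy


def denormalise(values: np.ndarray, max_gy: float = 200.0) -> np.ndarray:
    if max_gy <= 0:
        raise ValueError("normalisation maximum must be positive")
    return np.asarray(values, dtype=float) * max_gy


def make_folds(case_ids: Sequence, n_folds: int = 5,
               seed: int = 0) -> List[List]:
    """Deterministic partition into folds whose sizes differ by at most one.

    Cases are shuffled under the seed and dealt round-robin; each case lands
    in exactly one validation fold.
    """
    ids = list(case_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} cases, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    folds: List[List] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(ids[idx])
    return folds


_ROT_PLANES = ((0, 1), (0, 2), (1, 2))


def _augment_pair(feat: np.ndarray, ref: np.ndarray, rng: np.random.Generator
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one random 90-degree rotation and random flips, identically to
    the (C, px, py, pz) feature patch and the (px, py, pz) reference."""
    k = int(rng.integers(0, 4))
    plane = _ROT_PLANES[int(rng.integers(0, 3))]
    if k:
        feat = np.rot90(feat, k, axes=(plane[0] + 1, plane[1] + 1))
        ref = np.rot90(ref, k, axes=plane)
    for ax in range(3):
        if rng.random() < 0.5:
            feat = np.flip(feat, axis=ax + 1)
            ref = np.flip(ref, axis=ax)
    return np.ascontiguousarray(feat), np.ascontiguousarray(ref)


def _pad_to(arr: np.ndarray, size: int) -> np.ndarray:
    """Zero-pad the trailing 3 axes up to ``size`` where shorter."""
    spatial = arr.shape[-3:]
    pad = [(0, 0)] * (arr.ndim - 3) + [(0, max(0, size - s)) for s in spatial]
    if any(p[1] for p in pad):
        arr = np.pad(arr, pad)
    return arr


def sample_training_patches(feat_volume: np.ndarray, ref_volume: np.ndarray,
                            config: TrainingConfig,
                            rng: np.random.Generator,
                            n_patches: Optional[int] = None,
                            ) -> Iterator[Tuple[np.ndarray, np.ndarray]]:
    """Yield paired (feature, reference) patches of config.patch_size^3.

    Crops at random positions (identical for both volumes), zero-padding
    volumes smaller than the patch.  Augmentation applies the same
    rotation/flip to both members of a pair.
    """
    if feat_volume.shape[-3:] != ref_volume.shape:
        raise ValueError("input and reference volumes must share a grid")
    p = config.patch_size
    feat_volume = _pad_to(feat_volume, p)
    ref_volume = _pad_to(ref_volume, p)
    dims = ref_volume.shape
    n = n_patches if n_patches is not None else config.patches_per_volume
    for _ in range(n):
        start = [int(rng.integers(0, d - p + 1)) for d in dims]
        sl = tuple(slice(s, s + p) for s in start)
        fp = feat_volume[(slice(None),) + sl]
        rp = ref_volume[sl]
        if config.augment:
            fp, rp = _augment_pair(fp, rp, rng)
        yield fp, rp


@dataclass
class RegressorEnsemble:
    """The five fold models of one task plus shared preprocessing spec.

    Prediction is the voxelwise arithmetic mean of the member predictions
    (implemented as a running mean, so an ensemble of identical members
    reproduces the single-member output bit for bit).
    """

    task: CorrectionTask
    members: List
    config: TrainingConfig
    history: List[Dict[str, List[float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        spec = {
            "task": self.task.name,
            "config": asdict(self.config),
            "members": [m.spec() for m in self.members],
            "history": self.history,
        }
        (directory / "ensemble.json").write_text(json.dumps(spec, indent=2))
        for i, m in enumerate(self.members):
            np.savez(directory / f"fold_{i}.npz", **m.get_weights())

    @classmethod
    def load(cls, directory: str | Path) -> "RegressorEnsemble":
        directory = Path(directory)
        spec = json.loads((directory / "ensemble.json").read_text())
        config = TrainingConfig(**spec["config"])
        members = []
        for i, mspec in enumerate(spec["members"]):
            if mspec["kind"] == "identity":
                m = IdentityRegressor()
            else:
                m = LocalFeatureMLP.from_spec(
                    mspec, learning_rate=config.learning_rate,
                    weight_decay=config.weight_decay)
            weights = np.load(directory / f"fold_{i}.npz")
            m.set_weights({k: weights[k] for k in weights.files})
            members.append(m)
        return cls(CorrectionTask[spec["task"]], members, config,
                   spec.get("history", []))


def _window_starts(dim: int, patch: int, stride: int) -> List[int]:
    if dim <= patch:
        return [0]
    starts = list(range(0, dim - patch + 1, stride))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return starts


def sliding_window_predict(member, feat_volume: np.ndarray,
                           patch_size: int, overlap: float = 0.5
                           ) -> np.ndarray:
    """Tile the volume with patch_size^3 windows, predict each, blend
    overlaps with uniform weights."""
    spatial = feat_volume.shape[-3:]
    padded = _pad_to(feat_volume, patch_size)
    dims = padded.shape[-3:]
    stride = max(1, int(round(patch_size * (1.0 - overlap))))
    acc = np.zeros(dims)
    weight = np.zeros(dims)
    for sx in _window_starts(dims[0], patch_size, stride):
        for sy in _window_starts(dims[1], patch_size, stride):
            for sz in _window_starts(dims[2], patch_size, stride):
                sl = (slice(sx, sx + patch_size), slice(sy, sy + patch_size),
                      slice(sz, sz + patch_size))
                acc[sl] += member.predict_patch(padded[(slice(None),) + sl]
                                                if padded.ndim == 4 else padded[sl])
                weight[sl] += 1.0
    out = acc / weight
    return out[tuple(slice(0, s) for s in spatial)]


def train_task(dataset: Sequence[Tuple[DoseMap, DoseMap]],
               task: CorrectionTask,
               config: TrainingConfig = TrainingConfig(),
               regressor_factory=None) -> RegressorEnsemble:
    """Train the fold ensemble of one correction task.

    ``dataset`` is a list of (input, reference) dose-map pairs whose states
    must match the task.  Each fold model trains on the other folds' cases
    with L1 loss on normalised patches; per-epoch training and validation
    losses are logged in ``ensemble.history``.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    for inp, ref in dataset:
        task.check_pair(inp, ref)
        inp.image.require_same_grid(ref.image)

    max_gy = config.normalisation_max_gy
    if regressor_factory is None:
        def regressor_factory(seed: int):
            return LocalFeatureMLP(config.feature_spec(), hidden=config.hidden,
                                   learning_rate=config.learning_rate,
                                   weight_decay=config.weight_decay,
                                   dropout=config.dropout, seed=seed)

    folds = make_folds(list(range(len(dataset))), config.folds, config.seed)
    # featurise each case once (features are model-independent here)
    feat_spec = config.feature_spec()
    feats = [feat_spec.compute(normalise(inp, max_gy), inp.image.spacing)
             for inp, _ in dataset]
    refs = [normalise(ref, max_gy) for _, ref in dataset]

    members: List = []
    history: List[Dict[str, List[float]]] = []
    for fold_idx, val_ids in enumerate(folds):
        member = regressor_factory(seed=config.seed * 1000 + fold_idx)
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, fold_idx, 17]))
        train_ids = [i for i in range(len(dataset)) if i not in val_ids]
        if not train_ids:
            train_ids = list(val_ids)
        if config.probe_init and hasattr(member, "init_linear"):
            n_per = max(1, config.probe_voxels // len(train_ids))
            cols, targets = [], []
            for cid in train_ids:
                flat = feats[cid].reshape(feats[cid].shape[0], -1)
                pick = rng.choice(flat.shape[1], min(n_per, flat.shape[1]),
                                  replace=False)
                cols.append(flat[:, pick])
                targets.append(refs[cid].reshape(-1)[pick])
            member.init_linear(np.concatenate(cols, axis=1),
                               np.concatenate(targets))
        curves: Dict[str, List[float]] = {"train_l1": [], "val_l1": []}
        for _epoch in range(config.epochs):
            order = rng.permutation(train_ids)  # shuffle to prevent order bias
            batch_f: List[np.ndarray] = []
            batch_r: List[np.ndarray] = []
            losses: List[float] = []
            for cid in order:
                for fp, rp in sample_training_patches(
                        feats[cid], refs[cid], config, rng):
                    batch_f.append(fp)
                    batch_r.append(rp)
                    if len(batch_f) == config.batch_size:
                        losses.append(member.train_step(
                            np.stack(batch_f), np.stack(batch_r)))
                        batch_f, batch_r = [], []
            if batch_f:
                losses.append(member.train_step(np.stack(batch_f),
                                                np.stack(batch_r)))
            val = [float(np.mean(np.abs(member.predict_patch(feats[i]) - refs[i])))
                   for i in val_ids]
            curves["train_l1"].append(float(np.mean(losses)) if losses else np.nan)
            curves["val_l1"].append(float(np.mean(val)) if val else np.nan)
        members.append(member)
        history.append(curves)
    return RegressorEnsemble(task, members, config, history)


def predict(ensemble: RegressorEnsemble, input_dose: DoseMap) -> DoseMap:
    """Ensemble sliding-window inference: normalised input -> corrected Gy.

    Raises :class:`TaskContractError` on a state mismatch.  The output is
    denormalised and clamped at zero (absorbed dose is non-negative), and
    tagged with the task's reference state.
    """
    if input_dose.correction_state != ensemble.task.input_state:
        raise TaskContractError(
            f"task {ensemble.task.name} expects {ensemble.task.input_state} "
            f"input, got {input_dose.correction_state}")
    if min(input_dose.image.shape) < 1:
        raise ValueError("degenerate input geometry")
    cfg = ensemble.config
    norm = normalise(input_dose, cfg.normalisation_max_gy)
    mean: Optional[np.ndarray] = None
    for k, member in enumerate(ensemble.members, start=1):
        feat = member.featurise(norm, input_dose.image.spacing)
        out = sliding_window_predict(member, feat, cfg.patch_size)
        if mean is None:
            mean = out
        else:
            mean += (out - mean) / k  # running mean: exact for equal members
    dose = np.maximum(denormalise(mean, cfg.normalisation_max_gy), 0.0)
    return DoseMap(input_dose.image.with_values(dose),
                   ensemble.task.reference_state,  # type: ignore[arg-type]
                   provenance=f"dl:{ensemble.task.name}")
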