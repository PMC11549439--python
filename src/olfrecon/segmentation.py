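"""Training, inference and evaluation of the per-structure segmentation CNNs.

One independent U-Net is trained per structure of interest on 4-channel tiles
with paired truth masks.  Training follows a staged schedule with decreasing
learning rates; at the end of each stage the weights with the best validation
DSC seed the next stage.  Per-channel uniform intensity augmentation makes
the network indifferent to overall channel brightness.  Full sections are
predicted by overlapping tiling in which only each tile's centre pixels are
kept (edge tiles keep their outer border), so every pixel is predicted
exactly once.  The binarisation threshold is the candidate cut-off that
maximises DSC on the validation set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import block_reduce
from skimage.transform import resize

from .unet import Adam, UNet, UNetConfig, cross_entropy


@dataclass(frozen=True)
class TrainPlan:
    """Staged schedule: list of (learning_rate, epochs).

    The default mirrors the ~100-epoch three-stage schedule (1e-4, 5e-5,
    1e-5, ~35 epochs each); :func:`bulb_plan` gives the two-stage olfactory
    bulb variant.  ``steps_per_epoch`` random-crop batches are drawn per
    epoch.
    """

    stages: tuple[tuple[float, int], ...] = ((1e-4, 35), (5e-5, 35), (1e-5, 35))
    batch_size: int = 32
    steps_per_epoch: int = 8
    augment_amplitude: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lrs = [lr for lr, _ in self.stages]
        if any(b >= a for a, b in zip(lrs, lrs[1:])) and len(lrs) > 1:
            raise ValueError("learning rates must strictly decrease across stages")
        if any(ep <= 0 for _, ep in self.stages):
            raise ValueError("epochs must be positive")


def bulb_plan(**kwargs) -> TrainPlan:
    return TrainPlan(stages=((1e-4, 200), (1e-5, 200)), **kwargs)


@dataclass
class Metrics:
    dsc: float
    precision: float
    recall: float
    bce: float | None = None


@dataclass
class SegmentationModel:
    """A trained network plus its DSC-optimal binarisation threshold."""

    config: UNetConfig
    net: UNet
    threshold: float = 0.5
    structure: str | None = None
    history: list = field(default_factory=list)

    def predict(self, channels: np.ndarray, tile_size: int | None = None,
                margin: int = 16) -> np.ndarray:
        """Foreground probability map for a full (4, H, W) section."""
        f = self.config.downsample_factor
        x = channels
        if f > 1:
            x = block_reduce(channels, (1, f, f), np.mean).astype(np.float32)
        prob = tile_and_assemble(
            x, self.net.predict_proba, tile_size or self.config.tile_size, margin
        )
        if f > 1:
            prob = resize(prob, channels.shape[1:], order=1, anti_aliasing=False)
        return prob

    def predict_mask(self, channels: np.ndarray, **kw) -> np.ndarray:
        return self.predict(channels, **kw) >= self.threshold

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.net.state_dict())
        meta = {
            "config": {
                "tile_size": self.config.tile_size,
                "in_channels": self.config.in_channels,
                "encoder_features": list(self.config.encoder_features),
                "bottleneck_features": self.config.bottleneck_features,
                "dropout": self.config.dropout,
                "out_classes": self.config.out_classes,
                "downsample_factor": self.config.downsample_factor,
            },
            "threshold": self.threshold,
            "structure": self.structure,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        c = meta["config"]
        c["encoder_features"] = tuple(c["encoder_features"])
        config = UNetConfig(**c)
        net = UNet(config, seed=0)
        with np.load(path.with_suffix(".npz")) as z:
            net.load_state_dict({k: z[k] for k in z.files})
        return cls(
            config=config,
            net=net,
            threshold=meta["threshold"],
            structure=meta.get("structure"),
            history=meta.get("history", []),
        )


# ---------------------------------------------------------------------------
# metrics


def metrics(pred_mask: np.ndarray, truth_mask: np.ndarray,
            prob_map: np.ndarray | None = None) -> Metrics:
    """DSC, precision and recall of a binary prediction against truth.

    Two empty masks agree perfectly: all three metrics are 1.0 in that case.
    """
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    denom = pred.sum() + truth.sum()
    dsc = 2 * tp / denom if denom else 1.0
    bce = None
    if prob_map is not None:
        bce = cross_entropy(np.asarray(prob_map)[None], truth[None])
    return Metrics(dsc=float(dsc), precision=float(precision),
                   recall=float(recall), bce=bce)


def dsc(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y| / (|X|+|Y|); empty-vs-empty is 1."""
    return metrics(x, y).dsc


# ---------------------------------------------------------------------------
# augmentation and tiling


def augment_intensity(tile: np.ndarray, amplitude: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Add one uniform offset in [-amplitude, amplitude] per channel, clip."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return tile
    offsets = rng.uniform(-amplitude, amplitude, size=tile.shape[0])
    return np.clip(tile + offsets[:, None, None], 0.0, 1.0).astype(tile.dtype)


def _tile_intervals(total: int, tile_size: int, margin: int):
    """Tile origins with kept intervals forming a contiguous partition.

    Interior tiles keep their centre ``[margin, tile_size - margin)``; the
    first and last tiles additionally keep their outer border.  Yields
    ``(origin, keep_lo, keep_hi)`` in absolute coordinates.
    """
    step = tile_size - 2 * margin
    if total == tile_size:
        return [(0, 0, total)]
    pos = list(range(0, total - tile_size, step))
    pos.append(total - tile_size)  # last tile flush with the border
    out, prev_end = [], 0
    for i, origin in enumerate(pos):
        lo = prev_end
        hi = total if i == len(pos) - 1 else origin + tile_size - margin
        out.append((origin, lo, hi))
        prev_end = hi
    return out


def tile_and_assemble(channels: np.ndarray, predict_fn, tile_size: int,
                      margin: int) -> np.ndarray:
    """Predict a full section from overlapping tiles, centre pixels only.

    Tiles step by ``tile_size - 2*margin``; the kept centre regions partition
    the plane exactly, with tiles at the image border keeping their outer
    border too, so every pixel is predicted exactly once.  ``predict_fn``
    maps a (C, t, t) tile to a (t, t) probability map.
    """
    if margin < 0 or 2 * margin >= tile_size:
        raise ValueError("margin must satisfy 0 <= margin < tile_size/2")
    c, h, w = channels.shape
    ph, pw = max(h, tile_size), max(w, tile_size)
    padded = np.zeros((c, ph, pw), dtype=channels.dtype)
    padded[:, :h, :w] = channels
    out = np.full((ph, pw), np.nan, dtype=np.float32)

    for r0, rlo, rhi in _tile_intervals(ph, tile_size, margin):
        for c0, clo, chi in _tile_intervals(pw, tile_size, margin):
            tile = padded[:, r0 : r0 + tile_size, c0 : c0 + tile_size]
            prob = np.asarray(predict_fn(tile), dtype=np.float32)
            out[rlo:rhi, clo:chi] = prob[rlo - r0 : rhi - r0, clo - c0 : chi - c0]
    assert not np.isnan(out).any(), "assembly left unpredicted pixels"
    return out[:h, :w]


def assembly_coverage(shape, tile_size: int, margin: int) -> np.ndarray:
    """How many times each pixel is written during assembly (should be 1)."""
    h, w = shape
    ph, pw = max(h, tile_size), max(w, tile_size)
    cov = np.zeros((ph, pw), dtype=int)
    for _, rlo, rhi in _tile_intervals(ph, tile_size, margin):
        for _, clo, chi in _tile_intervals(pw, tile_size, margin):
            cov[rlo:rhi, clo:chi] += 1
    return cov[:h, :w]


# ---------------------------------------------------------------------------
# threshold selection


def select_threshold(prob_map: np.ndarray, truth_mask: np.ndarray,
                     grid: np.ndarray | None = None) -> tuple[float, float]:
    """DSC-maximising cut-off on a candidate grid; ties go to the smallest.

    Returns ``(threshold, best_dsc)``.  The default grid is 99 points
    0.01..0.99.  Raises on an empty truth mask, where thresholding against
    DSC is meaningless.
    """
    truth = np.asarray(truth_mask).astype(bool)
    if not truth.any():
        raise ValueError("truth mask is empty; DSC-based threshold undefined")
    if grid is None:
        grid = np.linspace(0.01, 0.99, 99)
    prob = np.asarray(prob_map)
    best_t, best_d = float(grid[0]), -1.0
    for t in grid:
        d = dsc(prob >= t, truth)
        if d > best_d:  # strict: ties keep the smallest t
            best_t, best_d = float(t), d
    return best_t, best_d


# ---------------------------------------------------------------------------
# training


def _prepare(sections, structure: str, factor: int):
    """Stack channels/masks for one structure, downsampling if requested."""
    X = np.stack([s.channels for s in sections]).astype(np.float32)
    Y = np.stack([s.mask(structure) for s in sections])
    if factor > 1:
        X = block_reduce(X, (1, 1, factor, factor), np.mean).astype(np.float32)
        Y = block_reduce(Y.astype(np.float32), (1, factor, factor), np.mean) > 0.5
    return X, Y


def _validation_dsc(net, Xva, Yva, thr=0.5):
    probs = net.forward(Xva, training=False)[:, 1]
    return dsc(probs >= thr, Yva), cross_entropy(probs, Yva)


def train(model: SegmentationModel, training_sections, validation_sections,
          plan: TrainPlan, structure: str | None = None):
    """Staged training; best-validation weights seed each next stage.

    Returns ``(model, history)`` where ``history`` holds one record per epoch
    with validation DSC and binary cross-entropy.  With an empty plan the
    model is returned unchanged with empty history.  Deterministic under the
    plan seed (single-threaded NumPy).
    """
    structure = structure or model.structure
    if structure is None:
        raise ValueError("a target structure must be given")
    model.structure = structure
    factor = model.config.downsample_factor
    Xtr, Ytr = _prepare(training_sections, structure, factor)
    Xva, Yva = _prepare(validation_sections, structure, factor)
    if not Ytr.any():
        raise ValueError(f"structure {structure!r} is empty in every training mask")

    history: list[dict] = []
    if not plan.stages:
        return model, history

    net = model.net
    rng = np.random.default_rng(plan.seed)
    ts = min(model.config.tile_size, Xtr.shape[2], Xtr.shape[3])
    ts -= ts % (2 ** len(model.config.encoder_features))
    n_tr, _, H, W = Xtr.shape

    for stage_i, (lr, epochs) in enumerate(plan.stages):
        opt = Adam(net, lr=lr)
        best = (-1.0, net.state_dict())
        for epoch in range(epochs):
            for _ in range(plan.steps_per_epoch):
                xs, ys = [], []
                for _ in range(plan.batch_size):
                    si = rng.integers(0, n_tr)
                    r0 = rng.integers(0, H - ts + 1)
                    c0 = rng.integers(0, W - ts + 1)
                    x = Xtr[si, :, r0 : r0 + ts, c0 : c0 + ts]
                    xs.append(augment_intensity(x, plan.augment_amplitude, rng))
                    ys.append(Ytr[si, r0 : r0 + ts, c0 : c0 + ts])
                net.forward(np.stack(xs), training=True)
                net.backward_from_loss(np.stack(ys))
                opt.step()
            vdsc, vbce = _validation_dsc(net, Xva, Yva)
            history.append(
                {"stage": stage_i, "lr": lr, "epoch": epoch,
                 "val_dsc": vdsc, "val_bce": vbce}
            )
            if vdsc > best[0]:
                best = (vdsc, net.state_dict())
        net.load_state_dict(best[1])  # best weights seed the next stage

    # final DSC-optimal threshold on the validation set
    probs = net.forward(Xva, training=False)[:, 1]
    if Yva.any():
        model.threshold, _ = select_threshold(probs, Yva)
    model.history = history
    return model, history


def add_sections_and_retrain(model: SegmentationModel, new_sections,
                             training_sections, validation_sections,
                             plan: TrainPlan):
    """Bootstrap hook: manually corrected sections enlarge the training set.

    The correction itself is a human act; this only reruns :func:`train` on
    the extended dataset starting from the current weights.
    """
    return train(model, list(training_sections) + list(new_sections),
                 validation_sections, plan)


def build_model(config: UNetConfig | None = None, structure: str | None = None,
                seed: int = 0) -> SegmentationModel:
    config = config or UNetConfig()
    return SegmentationModel(config=config, net=UNet(config, seed=seed),
                             structure=structure)
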