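"""3D encoder–decoder hematoma segmentation.

A compact U-Net-style network (configurable width/depth, skip connections,
input dropout) trained with soft-Dice loss, Adam and cosine-annealed
learning rate, with random-flip augmentation and sliding-window inference
with Gaussian blending. Cross-validation folds are assigned at the patient
level so a patient's baseline and follow-up scans never straddle folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .core import CtVolume, LesionMask
from .errors import ModelUsageError, StratificationError
from .metrics import overlap_metrics
from .nn.functional import sigmoid
from .preprocess import BRAIN_WINDOW, WindowSpec, apply_window


@dataclass
class SegConfig:
    """Training recipe for the segmentation network.

    ``input_shape`` is the sliding-window size; the full-scale profile is
    (512, 512, 48), the miniature profile used throughout the tests is the
    whole phantom grid. Spatial dims must be divisible by ``2**depth``.
    """

    input_shape: tuple[int, int, int] = (512, 512, 48)
    base_width: int = 16
    depth: int = 2
    convs_per_stage: int = 2
    dropout_prob: float = 0.2            # input-tensor dropout during training
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 2
    # patch-based training: None trains on whole scans; a shape samples
    # lesion-biased patches each epoch (fresh draws act as augmentation)
    train_patch_shape: tuple[int, int, int] | None = None
    patches_per_scan: int = 2
    sliding_window_overlap: float = 0.25
    flip_axes: tuple[int, ...] = (0, 1, 2)
    threshold: float = 0.5
    window: WindowSpec = field(default_factory=lambda: BRAIN_WINDOW)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if any(s % (2 ** self.depth) for s in self.input_shape):
            raise ValueError(
                f"input shape {self.input_shape} not divisible by 2^{self.depth}"
            )


@dataclass
class SegPrediction:
    probabilities: np.ndarray
    mask: LesionMask
    threshold: float
    source_id: str


class UNet3D:
    """Hand-wired 3D encoder–decoder with ``depth`` poolings and additive
    skip connections (residual-U-Net style): the upsampled deeper features are
    projected to the skip width by a 1×1 conv and summed with the encoder
    features before the decoder convolutions."""

    def __init__(self, in_ch: int = 1, width: int = 16, depth: int = 2,
                 dropout: float = 0.2, convs_per_stage: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(int(rng.integers(2**31)))
        self.in_ch, self.width, self.depth, self.dropout_p = in_ch, width, depth, dropout
        self.convs_per_stage = convs_per_stage
        self.input_dropout = nn.Dropout(dropout, self.drop_rng)
        widths = [width * 2 ** d for d in range(depth + 1)]
        self.widths = widths

        def stage(cin, cout, first=False):
            layers = [nn.Conv3d(cin, cout, 3, rng=rng, skip_input_grad=first),
                      nn.ReLU()]
            for _ in range(convs_per_stage - 1):
                layers += [nn.Conv3d(cout, cout, 3, rng=rng), nn.ReLU()]
            return nn.Sequential(*layers)

        self.encs = []
        ch = in_ch
        for d in range(depth + 1):
            self.encs.append(stage(ch, widths[d], first=(d == 0)))
            ch = widths[d]
        self.pools = [nn.AvgPool2() for _ in range(depth)]
        self.ups = [nn.Upsample2() for _ in range(depth)]
        self.projs = [nn.Conv3d(widths[d + 1], widths[d], 1, rng=rng)
                      for d in range(depth)]
        self.decs = [stage(widths[d], widths[d]) for d in range(depth)]
        self.final = nn.Conv3d(widths[0], 1, 1, rng=rng)
        self.training = False

    def params(self) -> list[nn.Param]:
        out = []
        for m in [*self.encs, *self.projs, *self.decs, self.final]:
            out.extend(m.params())
        return out

    def train(self):
        self.training = True
        self.input_dropout.active = self.dropout_p > 0

    def eval(self):
        self.training = False
        self.input_dropout.active = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x - np.float32(0.5)      # center windowed [0,1] input for ReLUs
        x = self.input_dropout.forward(x)
        skips = []
        for d in range(self.depth):
            x = self.encs[d].forward(x)
            skips.append(x)
            x = self.pools[d].forward(x)
        x = self.encs[self.depth].forward(x)
        for d in reversed(range(self.depth)):
            x = self.ups[d].forward(self.projs[d].forward(x))
            x = x + skips[d]
            x = self.decs[d].forward(x)
        return self.final.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.final.backward(dlogits)
        dskip_acc = [None] * self.depth
        for d in range(self.depth):
            dx = self.decs[d].backward(dx)
            dskip_acc[d] = dx                      # additive skip: same grad
            dx = self.projs[d].backward(self.ups[d].backward(dx))
        dx = self.encs[self.depth].backward(dx)
        for d in reversed(range(self.depth)):
            dx = self.pools[d].backward(dx)
            dx = dx + dskip_acc[d]
            dx = self.encs[d].backward(dx)
        if dx is not None:
            self.input_dropout.backward(dx)

    # ------------------------------------------------------------- persistence
    def save(self, path):
        meta = {"in_ch": self.in_ch, "width": self.width,
                "depth": self.depth, "dropout": self.dropout_p,
                "convs_per_stage": self.convs_per_stage}
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "UNet3D":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(**meta)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        return model


@dataclass
class SegTrainResult:
    model: UNet3D
    config: SegConfig
    fold_metrics: list[dict]
    loss_log: list[dict]
    fold_assignment: dict[str, int]


def _windowed_array(vol: CtVolume, window: WindowSpec) -> np.ndarray:
    return apply_window(vol, window).values[None]      # (1, D, H, W)


def _random_flip(x: np.ndarray, y: np.ndarray, axes, rng):
    for ax in axes:
        if rng.random() < 0.5:
            x = np.flip(x, axis=2 + ax)
            y = np.flip(y, axis=2 + ax)
    return np.ascontiguousarray(x), np.ascontiguousarray(y)


def _sample_patch(x: np.ndarray, y: np.ndarray, patch, rng):
    """Lesion-biased patch: half the draws contain a lesion voxel placed
    uniformly within the patch (not centered, to avoid a positional prior)."""
    shape = x.shape[1:]
    lesion = np.argwhere(y[0] > 0)
    if lesion.size and rng.random() < 0.5:
        v = lesion[rng.integers(lesion.shape[0])]
        origin = [int(np.clip(c - rng.integers(p), 0, s - p))
                  for c, p, s in zip(v, patch, shape)]
    else:
        origin = [int(rng.integers(s - p + 1)) for p, s in zip(patch, shape)]
    sl = tuple(slice(a, a + p) for a, p in zip(origin, patch))
    return x[:, sl[0], sl[1], sl[2]], y[:, sl[0], sl[1], sl[2]]


def _fit(model: UNet3D, xs: list[np.ndarray], ys: list[np.ndarray],
         config: SegConfig, seed: int) -> list[dict]:
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.params(), lr=config.lr)
    sched = nn.CosineAnnealingLR(opt, t_max=config.epochs)
    log = []
    patch = config.train_patch_shape
    if patch is not None and any(p % (2 ** config.depth) for p in patch):
        raise ValueError(f"patch shape {patch} not divisible by 2^{config.depth}")
    for epoch in range(config.epochs):
        model.train()
        if patch is None:
            pool_x, pool_y = list(xs), list(ys)
        else:
            pool_x, pool_y = [], []
            for x, y in zip(xs, ys):
                for _ in range(config.patches_per_scan):
                    px, py = _sample_patch(x, y, patch, rng)
                    pool_x.append(px)
                    pool_y.append(py)
        idx = rng.permutation(len(pool_x))
        losses = []
        for start in range(0, idx.size, config.batch_size):
            sel = idx[start:start + config.batch_size]
            xb = np.stack([pool_x[i] for i in sel])
            yb = np.stack([pool_y[i] for i in sel])
            xb, yb = _random_flip(xb, yb, config.flip_axes, rng)
            logits = model.forward(xb)
            loss, grad = nn.soft_dice_with_logits(logits, yb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        sched.step()
        log.append({"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses))})
    model.eval()
    return log


def patient_folds(patient_ids: list[str], folds: int, seed: int) -> dict[str, int]:
    """Deterministic patient-level fold assignment (scans share the fold)."""
    unique = sorted(set(patient_ids))
    if len(unique) < folds:
        raise StratificationError(f"{len(unique)} patients cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique))
    return {pid: i % folds for i, pid in enumerate(order)}


def train_segmenter(cases: list[tuple[CtVolume, LesionMask]], config: SegConfig,
                    folds: int, seed: int,
                    patient_ids: list[str] | None = None,
                    refit: bool = True) -> SegTrainResult:
    """K-fold cross-validate, then refit on all scans.

    ``cases`` are (scan, ground-truth mask) pairs, already skull-stripped;
    windowing is applied internally. ``patient_ids`` ties multiple scans of
    one patient into the same fold (defaults to one patient per case).
    Returns the refit model plus per-fold Dice/VS on held-out scans;
    ``refit=False`` returns the last fold model instead (cross-validation
    metrics only).
    """
    if len(cases) < folds:
        raise StratificationError(f"{len(cases)} cases cannot fill {folds} folds")
    if patient_ids is None:
        patient_ids = [f"p{i}" for i in range(len(cases))]
    assignment = patient_folds(patient_ids, folds, seed)
    fold_of = np.array([assignment[p] for p in patient_ids])

    xs = [_windowed_array(v, config.window) for v, _ in cases]
    ys = [m.values[None].astype(np.float32) for _, m in cases]
    for f in range(folds):
        if sum(ys[i].sum() for i in np.flatnonzero(fold_of == f)) == 0:
            raise StratificationError(f"fold {f} contains no lesion voxels")

    fold_metrics = []
    loss_log = None
    for f in range(folds):
        tr = np.flatnonzero(fold_of != f)
        va = np.flatnonzero(fold_of == f)
        model = UNet3D(1, config.base_width, config.depth, config.dropout_prob,
                       convs_per_stage=config.convs_per_stage, seed=seed + 1000 * f)
        loss_log = _fit(model, [xs[i] for i in tr], [ys[i] for i in tr],
                        config, seed + f)
        dices, vss = [], []
        for i in va:
            pred = infer_mask(model, cases[i][0], config)
            d, v = overlap_metrics(cases[i][1].values, pred.mask.values,
                                   spacing_mm=cases[i][1].spacing_mm)
            dices.append(d)
            vss.append(v)
        fold_metrics.append({"fold": f, "dice": float(np.mean(dices)),
                             "vs": float(np.mean(vss)), "n_val": int(va.size)})

    if refit:
        model = UNet3D(1, config.base_width, config.depth, config.dropout_prob,
                       convs_per_stage=config.convs_per_stage, seed=seed)
        loss_log = _fit(model, xs, ys, config, seed)
    return SegTrainResult(model=model, config=config, fold_metrics=fold_metrics,
                          loss_log=loss_log, fold_assignment=assignment)


def _gaussian_importance(shape) -> np.ndarray:
    grids = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    g = np.ones(shape)
    for ax, (n, c) in enumerate(zip(shape, grids)):
        sig = max(n / 8.0, 1.0)
        w = np.exp(-0.5 * (c / sig) ** 2)
        g = g * w.reshape([-1 if i == ax else 1 for i in range(3)])
    return np.maximum(g, 1e-3)


def infer_mask(model: UNet3D, volume: CtVolume,
               config: SegConfig | None = None) -> SegPrediction:
    """Sliding-window inference with Gaussian blending.

    Tiles of ``config.input_shape`` with the configured overlap are predicted
    independently and blended; a window at least as large as the volume
    degenerates to a single full pass.
    """
    if model is None:
        raise ModelUsageError("segmentation model is not trained")
    config = config or SegConfig()
    x = _windowed_array(volume, config.window)
    shape = x.shape[1:]
    win = tuple(min(w, s) for w, s in zip(config.input_shape, shape))
    win = tuple(w - w % (2 ** model.depth) for w in win)
    model.eval()

    if win == tuple(shape):
        logits = model.forward(x[None])[0, 0]
        prob = sigmoid(logits)
    else:
        stride = [max(int(round(w * (1 - config.sliding_window_overlap))), 1)
                  for w in win]
        imp = _gaussian_importance(win)
        acc = np.zeros(shape)
        wsum = np.zeros(shape)
        starts = [sorted({min(s, dim - w) for s in range(0, dim, st)})
                  for dim, w, st in zip(shape, win, stride)]
        for i in starts[0]:
            for j in starts[1]:
                for k in starts[2]:
                    sl = (slice(i, i + win[0]), slice(j, j + win[1]),
                          slice(k, k + win[2]))
                    logits = model.forward(x[None][:, :, sl[0], sl[1], sl[2]])[0, 0]
                    acc[sl] += sigmoid(logits) * imp
                    wsum[sl] += imp
        prob = acc / wsum

    binary = (prob >= config.threshold).astype(np.uint8)
    return SegPrediction(
        probabilities=prob.astype(np.float32),
        mask=LesionMask(binary, volume.spacing_mm, id=volume.id),
        threshold=config.threshold,
        source_id=volume.id,
    )
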