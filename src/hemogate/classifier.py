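"""Dual-input 3D DenseNet-style classifier for hematoma expansion.

The network takes the two aligned channels produced by preprocessing —
windowed CT crop and dilated lesion mask — and outputs a single expansion
logit (sigmoid probability). Densely connected convolution blocks with
transition layers mirror the DenseNet design at a configurable scale: the
full profile approximates the 121-layer layout, the miniature profile used
in the tests has two blocks of two layers. Dropout layers stay activatable
at inference so the same model supports Monte-Carlo-dropout uncertainty.

Training follows: static augmentation (random flips on all axes, isotropic
zoom 0.8–1.2, rotations within ±0.2 rad per axis, shear within 0.2) applied
once with class balancing, additional dynamic augmentation re-drawn every
epoch, binary cross-entropy on logits, Adam (lr 0.001, weight decay 1e-5),
step learning-rate decay (step 15) and early stopping with patience 15.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .core import DualInput
from .errors import BalancingError, ModelUsageError, StratificationError
from .metrics import roc_auc
from .nn.functional import sigmoid


@dataclass(frozen=True)
class AugmentationPolicy:
    """Joint geometric transforms; the mask channel is resampled nearest-neighbor."""

    flip_axes: tuple[int, ...] = (0, 1, 2)
    zoom_range: tuple[float, float] = (0.8, 1.2)
    rotate_rad: float = 0.2          # per-axis rotation range (±)
    shear: float = 0.2               # shear coefficient range (±)

    def __post_init__(self):
        if not 0 < self.zoom_range[0] <= self.zoom_range[1]:
            raise ValueError("invalid zoom range")


@dataclass
class ClfConfig:
    channels: str = "ct+mask"        # "ct" (single-input arm) or "ct+mask"
    input_pool: int = 0              # initial 2x average-poolings (mini profile)
    width: int = 8
    growth: int = 4
    block_layers: int = 2
    n_blocks: int = 2
    dropout: float = 0.2
    hidden_dense: int = 0            # optional hidden head width (0 = linear head)
    weight_decay: float = 1e-5
    lr: float = 1e-3
    lr_step: int = 15
    lr_gamma: float = 0.5
    patience: int = 15
    max_epochs: int = 100
    batch_size: int = 8
    static_factor: int = 4
    balance: bool = True
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    dynamic_augment: str = "flips"   # "flips" | "full" | "none"
    monitor: str = "val_loss"        # early-stopping monitor ("val_loss"|"val_auc")
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.dropout < 1.0:
            raise ValueError("dropout must be in (0,1): MC dropout requires > 0")
        if self.channels not in ("ct", "ct+mask"):
            raise ValueError(f"unknown channel selection {self.channels!r}")
        if self.dynamic_augment not in ("flips", "full", "none"):
            raise ValueError(f"unknown dynamic_augment {self.dynamic_augment!r}")

    @property
    def in_channels(self) -> int:
        return 1 if self.channels == "ct" else 2


class _DenseBlock:
    """Densely connected 3x3x3 conv layers; output concatenates every feature."""

    def __init__(self, cin: int, growth: int, n_layers: int, rng):
        self.cin, self.growth = cin, growth
        self.convs = [nn.Conv3d(cin + i * growth, growth, 3, rng=rng)
                      for i in range(n_layers)]
        self.relus = [nn.ReLU() for _ in range(n_layers)]

    @property
    def cout(self) -> int:
        return self.cin + len(self.convs) * self.growth

    def params(self):
        out = []
        for c in self.convs:
            out.extend(c.params())
        return out

    def forward(self, x):
        segs = [x]
        for conv, relu in zip(self.convs, self.relus):
            cat = segs[0] if len(segs) == 1 else np.concatenate(segs, axis=1)
            segs.append(relu.forward(conv.forward(cat)))
        return np.concatenate(segs, axis=1)

    def backward(self, dy):
        widths = [self.cin] + [self.growth] * len(self.convs)
        bounds = np.cumsum([0] + widths)
        gs = [dy[:, bounds[i]:bounds[i + 1]].copy() for i in range(len(widths))]
        for i in reversed(range(len(self.convs))):
            din = self.convs[i].backward(self.relus[i].backward(gs[i + 1]))
            ofs = 0
            for j in range(i + 1):
                gs[j] += din[:, ofs:ofs + widths[j]]
                ofs += widths[j]
        return gs[0]


class DenseNet3DClassifier:
    """Dense blocks + transitions + global pooling + dropout + linear logit."""

    def __init__(self, in_ch: int = 2, width: int = 8, growth: int = 4,
                 block_layers: int = 2, n_blocks: int = 2,
                 dropout: float = 0.2, input_pool: int = 0,
                 hidden_dense: int = 0, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(int(rng.integers(2**31)))
        self.hyper = dict(in_ch=in_ch, width=width, growth=growth,
                          block_layers=block_layers, n_blocks=n_blocks,
                          dropout=dropout, input_pool=input_pool,
                          hidden_dense=hidden_dense)
        self.input_pools = [nn.AvgPool2() for _ in range(input_pool)]
        self.conv0 = nn.Conv3d(in_ch, width, 3, stride=2, rng=rng,
                               skip_input_grad=True)
        self.relu0 = nn.ReLU()
        self.pool0 = nn.AvgPool2()
        self.blocks, self.transitions = [], []
        ch = width
        for b in range(n_blocks):
            block = _DenseBlock(ch, growth, block_layers, rng)
            trans = nn.Sequential(
                nn.Conv3d(block.cout, width, 1, rng=rng),
                nn.ReLU(),
                nn.Dropout(dropout, self.drop_rng),
            )
            if b < n_blocks - 1:
                trans.layers.append(nn.AvgPool2())
            self.blocks.append(block)
            self.transitions.append(trans)
            ch = width
        self.gap = nn.GlobalAvgPool()
        self.head_dropout = nn.Dropout(dropout, self.drop_rng)
        if hidden_dense > 0:
            self.head = nn.Sequential(nn.Dense(width, hidden_dense, rng=rng),
                                      nn.ReLU())
            self.dense = nn.Dense(hidden_dense, 1, rng=rng)
        else:
            self.head = None
            self.dense = nn.Dense(width, 1, rng=rng)
        self.training = False
        self._trained = False

    # ------------------------------------------------------------- plumbing
    def _dropouts(self):
        outs = [self.head_dropout]
        for t in self.transitions:
            outs.extend(l for l in t.layers if isinstance(l, nn.Dropout))
        return outs

    def params(self):
        out = list(self.conv0.params())
        for b, t in zip(self.blocks, self.transitions):
            out.extend(b.params())
            out.extend(t.params())
        if self.head is not None:
            out.extend(self.head.params())
        out.extend(self.dense.params())
        return out

    def set_dropout(self, active: bool, rate: float | None = None,
                    seed: int | None = None):
        if seed is not None:
            self.drop_rng = np.random.default_rng(seed)
        for d in self._dropouts():
            d.active = active
            d.rng = self.drop_rng
            if rate is not None:
                d.p = rate

    def train(self):
        self.training = True
        self.set_dropout(True)

    def eval(self):
        self.training = False
        self.set_dropout(False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x - np.float32(0.5)      # center [0,1] channels to keep ReLUs alive
        for p in self.input_pools:
            x = p.forward(x)
        x = self.pool0.forward(self.relu0.forward(self.conv0.forward(x)))
        for b, t in zip(self.blocks, self.transitions):
            x = t.forward(b.forward(x))
        x = self.head_dropout.forward(self.gap.forward(x))
        if self.head is not None:
            x = self.head.forward(x)
        return self.dense.forward(x)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.dense.backward(dlogits[:, None])
        if self.head is not None:
            dy = self.head.backward(dy)
        dy = self.gap.backward(self.head_dropout.backward(dy))
        for b, t in zip(reversed(self.blocks), reversed(self.transitions)):
            dy = b.backward(t.backward(dy))
        self.conv0.backward(self.relu0.backward(self.pool0.backward(dy)))

    def predict_proba(self, x: np.ndarray, dropout_active: bool = False,
                      dropout_rate: float | None = None, seed: int | None = None,
                      batch_size: int = 16) -> np.ndarray:
        """Sigmoid probabilities for a batch (N,C,D,H,W).

        With ``dropout_active`` the dropout layers stay on (Monte Carlo
        inference); ``seed`` makes the stochastic passes reproducible.
        """
        if not self._trained:
            raise ModelUsageError("classifier has not been trained")
        if x.ndim != 5 or x.shape[1] != self.hyper["in_ch"]:
            raise ModelUsageError(
                f"expected (N,{self.hyper['in_ch']},D,H,W) input, got {x.shape}"
            )
        self.training = False
        self.set_dropout(dropout_active, rate=dropout_rate, seed=seed)
        out = []
        for start in range(0, x.shape[0], batch_size):
            out.append(sigmoid(self.forward(x[start:start + batch_size])))
        self.set_dropout(False)
        return np.concatenate(out) if out else np.array([])

    # ------------------------------------------------------------- persistence
    def save(self, path):
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path, meta=json.dumps(self.hyper),
                 trained=np.array(int(self._trained)), **arrays)

    @classmethod
    def load(cls, path) -> "DenseNet3DClassifier":
        data = np.load(path, allow_pickle=False)
        model = cls(**json.loads(str(data["meta"])))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        model._trained = bool(int(data["trained"]))
        return model


# ------------------------------------------------------------------ augmentation

def _draw_affine(policy: AugmentationPolicy, rng) -> np.ndarray:
    """Random zoom/rotation/shear as one 3x3 output-to-input matrix."""
    zoom = rng.uniform(*policy.zoom_range)
    angles = rng.uniform(-policy.rotate_rad, policy.rotate_rad, 3)
    shears = rng.uniform(-policy.shear, policy.shear, 2)
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    sh = np.eye(3)
    sh[0, 1], sh[0, 2] = shears
    # output->input mapping: inverse zoom on the sampling grid
    return (rx @ ry @ rz @ sh) / zoom


def _apply_affine(x: np.ndarray, matrix: np.ndarray,
                  mask_channels: tuple[int, ...]) -> np.ndarray:
    """Apply one affine to every channel of (C,D,H,W), center-anchored."""
    center = (np.asarray(x.shape[1:]) - 1) / 2.0
    offset = center - matrix @ center
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        order = 0 if c in mask_channels else 1
        out[c] = ndimage.affine_transform(x[c], matrix, offset=offset,
                                          order=order, mode="constant", cval=0.0)
    return out


def _flip(x: np.ndarray, axes, rng) -> np.ndarray:
    for ax in axes:
        if rng.random() < 0.5:
            x = np.flip(x, axis=1 + ax)
    return np.ascontiguousarray(x)


def _augment_one(x: np.ndarray, policy: AugmentationPolicy, rng,
                 mask_channels=(1,)) -> np.ndarray:
    x = _flip(x, policy.flip_axes, rng)
    return _apply_affine(x, _draw_affine(policy, rng), mask_channels)


def augment_batch(inputs: list[DualInput], labels, factor: int = 4,
                  balance: bool = True,
                  policy: AugmentationPolicy | None = None, seed: int = 0):
    """Static augmentation: ``factor`` × the data, optionally class-balanced.

    Every geometric transform is applied jointly to both channels (the mask
    nearest-neighbor, so it stays binary). With ``balance`` the positive and
    negative replicate counts are equal, oversampling the minority class with
    fresh augmentations; the first replicate of each source case is the
    untransformed original. Returns (X of shape (factor·n, 2, D, H, W), y).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    policy = policy or AugmentationPolicy()
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    n = len(inputs)
    if n != y.size:
        raise ValueError("inputs and labels disagree in length")
    total = factor * n

    if balance:
        if y.min() == y.max():
            raise BalancingError("cannot balance a single-class cohort")
        quotas = {1: total // 2, 0: total - total // 2}
    else:
        quotas = {c: factor * int((y == c).sum()) for c in np.unique(y)}

    shape = inputs[0].ct.shape
    total_out = int(sum(quotas.values()))
    xs = np.empty((total_out, 2) + shape, dtype=np.float32)
    ys = np.empty(total_out, dtype=int)
    k = 0
    for cls, quota in sorted(quotas.items()):
        members = np.flatnonzero(y == cls)
        reps = np.full(members.size, quota // members.size)
        reps[: quota % members.size] += 1
        for m, r in zip(members, reps):
            base = inputs[m].stacked("ct+mask")
            for j in range(r):
                xs[k] = base if j == 0 else _augment_one(base, policy, rng)
                ys[k] = cls
                k += 1
    return xs, ys


# ------------------------------------------------------------------ training

@dataclass
class ClfTrainResult:
    model: DenseNet3DClassifier
    config: ClfConfig
    log: list[dict]
    best_epoch: int


def _select_channels(x: np.ndarray, channels: str) -> np.ndarray:
    return x[:, :1] if channels == "ct" else x


def train_classifier(train: list[tuple[DualInput, int]],
                     val: list[tuple[DualInput, int]],
                     config: ClfConfig) -> ClfTrainResult:
    """Train with static + dynamic augmentation and early stopping.

    ``train``/``val`` are (dual input, expansion label) pairs; both must
    contain both classes. The best checkpoint by validation loss is returned
    together with the per-epoch log.
    """
    for name, cohort in (("train", train), ("val", val)):
        ys = {int(lbl) for _, lbl in cohort}
        if ys != {0, 1}:
            raise StratificationError(f"{name} cohort must contain both classes")

    # canonical order: val predictions must not depend on caller's ordering
    train = sorted(train, key=lambda t: (int(t[1]), t[0].id))
    rng = np.random.default_rng(config.seed)

    x_aug, y_aug = augment_batch([d for d, _ in train], [l for _, l in train],
                                 factor=config.static_factor,
                                 balance=config.balance, policy=config.policy,
                                 seed=config.seed)
    x_aug = _select_channels(x_aug, config.channels).astype(np.float32)
    x_val = _select_channels(
        np.stack([d.stacked("ct+mask") for d, _ in val]), config.channels
    ).astype(np.float32)
    y_val = np.asarray([l for _, l in val], dtype=float)

    model = DenseNet3DClassifier(
        in_ch=config.in_channels, width=config.width, growth=config.growth,
        block_layers=config.block_layers, n_blocks=config.n_blocks,
        dropout=config.dropout, input_pool=config.input_pool,
        hidden_dense=config.hidden_dense, seed=config.seed,
    )
    model._trained = True
    opt = nn.Adam(model.params(), lr=config.lr, weight_decay=config.weight_decay)
    sched = nn.StepLR(opt, step_size=config.lr_step, gamma=config.lr_gamma)

    mask_ch = (1,) if config.channels == "ct+mask" else ()
    best = {"epoch": -1, "monitor": np.inf, "params": None}
    log: list[dict] = []
    idx = np.arange(x_aug.shape[0])
    sign = 1.0 if config.monitor == "val_loss" else -1.0

    for epoch in range(config.max_epochs):
        model.train()
        rng.shuffle(idx)
        losses = []
        for start in range(0, idx.size, config.batch_size):
            sel = idx[start:start + config.batch_size]
            xb = x_aug[sel]
            if config.dynamic_augment == "flips":
                xb = np.stack([_flip(v, config.policy.flip_axes, rng) for v in xb])
            elif config.dynamic_augment == "full":
                xb = np.stack([_augment_one(v, config.policy, rng, mask_ch)
                               for v in xb])
            logits = model.forward(xb)
            loss, grad = nn.bce_with_logits(logits, y_aug[sel])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        sched.step()

        p_val = model.predict_proba(x_val)
        val_loss, _ = nn.bce_with_logits(
            np.log(np.clip(p_val, 1e-7, 1 - 1e-7) / np.clip(1 - p_val, 1e-7, 1)),
            y_val,
        )
        val_auc = roc_auc(y_val.astype(bool), p_val)
        log.append({"epoch": epoch, "lr": opt.lr,
                    "train_loss": float(np.mean(losses)),
                    "val_loss": float(val_loss), "val_auc": float(val_auc)})

        monitored = sign * (val_loss if config.monitor == "val_loss" else val_auc)
        if monitored < best["monitor"] - 1e-12:
            best = {"epoch": epoch, "monitor": monitored,
                    "params": [p.value.copy() for p in model.params()]}
        elif epoch - best["epoch"] >= config.patience:
            break

    if best["params"] is not None:
        for p, v in zip(model.params(), best["params"]):
            p.value[...] = v
    model.eval()
    return ClfTrainResult(model=model, config=config, log=log,
                          best_epoch=best["epoch"])


def predict_prob(model: DenseNet3DClassifier, dual: DualInput,
                 channels: str = "ct+mask", dropout_active: bool = False,
                 seed: int | None = None) -> float:
    """Expansion probability for one case (deterministic with dropout off)."""
    x = _select_channels(dual.stacked("ct+mask")[None], channels)
    return float(model.predict_proba(x.astype(np.float32),
                                     dropout_active=dropout_active, seed=seed)[0])


def mc_dropout_cohort(model: DenseNet3DClassifier, x: np.ndarray, ids: list[str],
                      t: int = 100, dropout_rate: float = 0.2, seed: int = 0,
                      batch_size: int = 16):
    """T stochastic forward passes per patient over a whole cohort.

    Returns a list of per-patient probability vectors of length ``t``,
    ordered like ``ids``; reproducible from ``seed``.
    """
    from .uncertainty import McDropoutSamples

    if t < 1:
        raise ValueError("T must be >= 1")
    if dropout_rate == 0.0:
        warnings.warn("dropout rate 0 makes MC sampling degenerate "
                      "(all passes identical)", stacklevel=2)
        p = model.predict_proba(x, batch_size=batch_size)
        return [McDropoutSamples(i, np.full(t, pi)) for i, pi in zip(ids, p)]
    probs = np.empty((t, x.shape[0]))
    for k in range(t):
        probs[k] = model.predict_proba(
            x, dropout_active=True, dropout_rate=dropout_rate,
            seed=None if k else seed, batch_size=batch_size,
        )
    return [McDropoutSamples(i, probs[:, j]) for j, i in enumerate(ids)]
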