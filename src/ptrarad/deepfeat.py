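"""Self-supervised degradation-pretext encoder and the 78 deep features.

A four-block SE-CNN is trained to classify 64x64 abdominal-CT patches into
five classes (normal or one of four computer-generated degradations: blur,
noise, morphological distortion, position displacement).  The trained trunk
is then run fully convolutionally over a whole slice; the six final-block
channels carrying the largest fully-connected weight mass ("information-
dense maps", D1..D6) are bilinearly upsampled to the image grid, and 13
statistics per map are computed inside the ROI — a node mean, six histogram
statistics and six GLCM statistics reusing the handcrafted formulas — giving
6 x 13 = 78 features per region.  The pretext task never sees outcome
labels, so the encoder can be trained once on unlabeled data and reused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import handcrafted as hc
from .nn import (
    Adam,
    BatchNorm2d,
    Conv1x1,
    Conv2x2,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2x2,
    ReLU,
    SqueezeExcite,
    cross_entropy,
    softmax,
)

N_CLASSES = 5
N_CHANNELS = 8
N_BLOCKS = 4
N_SELECTED = 6
PATCH_SIZE = 64
DEEP_GLCM_BINS = 16

DEEP_H_STATS = ("variance", "skewness", "kurtosis", "entropy", "uniformity", "range")
DEEP_GLCM_STATS = ("contrast", "correlation", "energy", "entropy", "homogeneity2", "cluster_shade")

#: Affine HU normalization applied before the network (air ~ 0, water ~ 0.91).
HU_OFFSET, HU_SCALE = 1000.0, 1100.0


def deep_catalog(n_selected: int = N_SELECTED) -> list[str]:
    """Ordered names of the deep features: Dk_node_mean, Dk_H_*, Dk_GLCM_*."""
    names = []
    for k in range(1, n_selected + 1):
        names.append(f"D{k}_node_mean")
        names += [f"D{k}_H_{s}" for s in DEEP_H_STATS]
        names += [f"D{k}_GLCM_{s}" for s in DEEP_GLCM_STATS]
    return names


def normalize_hu(x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=np.float64) + HU_OFFSET) / HU_SCALE


class _Block:
    """conv 2x2 -> conv 2x2 -> BN -> ReLU -> SE, plus a 1x1-conv skip, then pool."""

    def __init__(self, cin: int, rng: np.random.Generator, name: str):
        self.conv1 = Conv2x2(cin, N_CHANNELS, rng, f"{name}.conv1")
        self.conv2 = Conv2x2(N_CHANNELS, N_CHANNELS, rng, f"{name}.conv2")
        self.bn = BatchNorm2d(N_CHANNELS, name=f"{name}.bn")
        self.relu = ReLU()
        self.se = SqueezeExcite(N_CHANNELS, rng=rng, name=f"{name}.se")
        self.skip = Conv1x1(cin, N_CHANNELS, rng, f"{name}.skip")
        self.pool = MaxPool2x2()

    def params(self):
        out = []
        for layer in (self.conv1, self.conv2, self.bn, self.se, self.skip):
            out += layer.params()
        return out

    def forward(self, x, train):
        h = self.conv1.forward(x, train)
        h = self.conv2.forward(h, train)
        h = self.bn.forward(h, train)
        h = self.relu.forward(h, train)
        h = self.se.forward(h, train)
        self._merged = h + self.skip.forward(x, train)
        return self.pool.forward(self._merged, train)

    def forward_prepool(self, x, train=False):
        """Block output before pooling (used for whole-slice feature maps)."""
        h = self.conv1.forward(x, train)
        h = self.conv2.forward(h, train)
        h = self.bn.forward(h, train)
        h = self.relu.forward(h, train)
        h = self.se.forward(h, train)
        return h + self.skip.forward(x, train)

    def backward(self, dout):
        dmerged = self.pool.backward(dout)
        dx = self.skip.backward(dmerged)
        dh = self.se.backward(dmerged)
        dh = self.relu.backward(dh)
        dh = self.bn.backward(dh)
        dh = self.conv2.backward(dh)
        dx += self.conv1.backward(dh)
        return dx


class DegradationEncoder:
    """The pretext network: 4 SE-conv blocks -> GAP(8) -> dropout -> FC(8->5) -> softmax."""

    def __init__(self, seed: int = 0, dropout: float = 0.3):
        rng = np.random.default_rng(seed)
        self.blocks = [_Block(1 if b == 0 else N_CHANNELS, rng, f"block{b+1}") for b in range(N_BLOCKS)]
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(dropout, np.random.default_rng(seed + 1))
        self.fc = Dense(N_CHANNELS, N_CLASSES, rng, "fc")
        self.seed = seed

    def params(self):
        out = []
        for b in self.blocks:
            out += b.params()
        return out + self.fc.params()

    def _check_patch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != PATCH_SIZE or x.shape[3] != PATCH_SIZE:
            raise ValueError(f"training expects {PATCH_SIZE}x{PATCH_SIZE} patches, got {x.shape}")
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for b in self.blocks:
            x = b.forward(x, train)
        v = self.gap.forward(x, train)
        v = self.dropout.forward(v, train)
        return self.fc.forward(v, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.gap.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """5-class probabilities for raw (unnormalized) HU patches."""
        x = self._check_patch(normalize_hu(patches))
        return softmax(self.forward_logits(x, train=False))

    def trunk_maps(self, image_hu: np.ndarray) -> np.ndarray:
        """Final-block pre-pool activation maps for a whole HU slice.

        The trunk is fully convolutional; the slice is reflect-padded to a
        multiple of 16 so every pooling stage sees even dimensions.  Returns
        maps of shape (8, H/16, W/16) on the padded grid plus the padding.
        """
        img = normalize_hu(image_hu)
        h, w = img.shape
        ph = (-h) % 16
        pw = (-w) % 16
        x = np.pad(img, ((0, ph), (0, pw)), mode="reflect")[None, None]
        for b in self.blocks[:-1]:
            x = b.forward(x, train=False)
        maps = self.blocks[-1].forward_prepool(x, train=False)[0]
        return maps, (h + ph, w + pw)

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.params()}
        for i, b in enumerate(self.blocks):
            state[f"block{i+1}.bn.running_mean"] = b.bn.running_mean
            state[f"block{i+1}.bn.running_var"] = b.bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, b in enumerate(self.blocks):
            b.bn.running_mean[...] = state[f"block{i+1}.bn.running_mean"]
            b.bn.running_var[...] = state[f"block{i+1}.bn.running_var"]

    def save(self, path: str) -> None:
        state = {k: v.tolist() for k, v in self.state_dict().items()}
        manifest = {
            "architecture": "4x[conv2x2(8)-conv2x2(8)-BN-ReLU-SE-skip1x1]-pool, GAP(8), FC(8->5)",
            "seed": self.seed,
            "weights": state,
        }
        with open(path, "w") as fh:
            json.dump(manifest, fh)

    @classmethod
    def load(cls, path: str) -> "DegradationEncoder":
        with open(path) as fh:
            manifest = json.load(fh)
        enc = cls(seed=manifest["seed"])
        enc.load_state_dict({k: np.asarray(v) for k, v in manifest["weights"].items()})
        return enc


def build_encoder(seed: int = 0, dropout: float = 0.3) -> DegradationEncoder:
    """Construct the untrained pretext network (deterministic in the seed)."""
    return DegradationEncoder(seed=seed, dropout=dropout)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainingSchedule:
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    lr_patience: int = 5  # epochs without validation improvement before LR x 0.1
    stop_patience: int = 10  # epochs without improvement before halting
    lr_factor: float = 0.1
    l1: float = 1e-4  # L1 penalty on the FC weights
    l2: float = 1e-4  # L2 penalty on the FC weights
    seed: int = 0


@dataclass
class TrainedEncoder:
    model: DegradationEncoder
    log: list = field(default_factory=list)
    best_epoch: int = 0
    stop_epoch: int = 0
    best_val_accuracy: float = 0.0
    selected_channels: list = field(default_factory=list)

    def log_frame(self):
        import pandas as pd

        return pd.DataFrame(self.log)


def _val_accuracy(model, patches, labels, batch: int = 64) -> float:
    correct = 0
    for s in range(0, len(patches), batch):
        probs = model.predict_proba(patches[s : s + batch])
        correct += int((probs.argmax(axis=1) == labels[s : s + batch]).sum())
    return correct / len(patches)


def train_pretext(
    model: DegradationEncoder,
    train_patches: np.ndarray,
    train_labels: np.ndarray,
    val_patches: np.ndarray,
    val_labels: np.ndarray,
    schedule: TrainingSchedule | None = None,
    val_metric_fn=None,
) -> TrainedEncoder:
    """Train on the 5-class degradation pretext with categorical cross-entropy.

    The learning rate is multiplied by ``lr_factor`` after ``lr_patience``
    epochs without validation improvement, and training halts after
    ``stop_patience`` such epochs.  The FC layer carries an elastic-net
    penalty: the L2 part enters the gradient, the L1 part is applied as a
    proximal soft-threshold after each optimizer step (so uninformative GAP
    nodes are driven exactly to zero).  ``val_metric_fn`` can replace the
    validation metric (used to verify the scheduling rules in isolation).

    Returns a :class:`TrainedEncoder` whose log records per-epoch losses,
    LR changes and the stopping epoch, with information-dense channels
    already selected.
    """
    sched = schedule or TrainingSchedule()
    if len(train_patches) == 0 or len(val_patches) == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(sched.seed)
    xtr = normalize_hu(train_patches)
    opt = Adam(model.params(), lr=sched.lr)
    best, best_epoch, since_best = -np.inf, 0, 0
    best_state = model.state_dict()
    log = []
    lr_events = 0
    fcW = model.fc.W
    stop_epoch = sched.max_epochs
    for epoch in range(1, sched.max_epochs + 1):
        order = rng.permutation(len(xtr))
        losses = []
        for s in range(0, len(order), sched.batch_size):
            idx = order[s : s + sched.batch_size]
            xb = model._check_patch(xtr[idx])
            yb = train_labels[idx]
            opt.zero_grad()
            logits = model.forward_logits(xb, train=True)
            probs = softmax(logits)
            loss, dlogits = cross_entropy(probs, yb)
            loss += sched.l1 * np.abs(fcW.value).sum() + sched.l2 * (fcW.value**2).sum()
            fcW.grad += 2.0 * sched.l2 * fcW.value
            model.backward(dlogits)
            opt.step()
            # proximal step for the L1 part of the elastic net
            thr = opt.lr * sched.l1
            fcW.value[...] = np.sign(fcW.value) * np.maximum(np.abs(fcW.value) - thr, 0.0)
            losses.append(loss)
        if val_metric_fn is not None:
            val_acc = float(val_metric_fn(epoch))
        else:
            val_acc = _val_accuracy(model, val_patches, val_labels)
        event = ""
        if val_acc > best:
            best, best_epoch, since_best = val_acc, epoch, 0
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        else:
            since_best += 1
            if since_best % sched.lr_patience == 0:
                opt.lr *= sched.lr_factor
                lr_events += 1
                event = f"lr->{opt.lr:.2e}"
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_accuracy": val_acc,
                "lr": opt.lr,
                "event": event,
            }
        )
        if since_best >= sched.stop_patience:
            log[-1]["event"] = (event + ";" if event else "") + "early_stop"
            stop_epoch = epoch
            break
    else:
        stop_epoch = sched.max_epochs
    model.load_state_dict(best_state)
    trained = TrainedEncoder(
        model=model,
        log=log,
        best_epoch=best_epoch,
        stop_epoch=stop_epoch,
        best_val_accuracy=float(best) if np.isfinite(best) else 0.0,
    )
    trained.selected_channels = select_information_dense_maps(model)
    return trained


def select_information_dense_maps(model: DegradationEncoder, n_selected: int = N_SELECTED) -> list[int]:
    """Rank GAP nodes by total absolute FC weight mass; keep the top ``n_selected``.

    Channel k's score is sum over classes of |W[k, class]|.  Ties break
    toward the lower channel index.  The returned indices are in rank order,
    i.e. position 0 is D1.
    """
    w = model.fc.W.value  # (8 nodes, 5 classes)
    scores = np.abs(w).sum(axis=1)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [int(i) for i in order[:n_selected]]


# ---------------------------------------------------------------------------
# deep feature extraction
# ---------------------------------------------------------------------------


def extract_deep(
    encoder: DegradationEncoder,
    study,
    mask: np.ndarray,
    selected_channels: list[int] | None = None,
):
    """Extract the 78 deep features for one region from the standardized X image.

    The trunk runs fully convolutionally on the whole slice; each selected
    final-block map is bilinearly upsampled to the image grid and summarized
    over the ROI by 13 statistics (node mean, 6 histogram, 6 GLCM with
    16-bin in-ROI discretization).  Requires the ROI bounding box to cover at
    least one 16x16-pixel feature-map cell.

    Returns ``(pandas.Series indexed by deep_catalog(), report dict)``.
    """
    import pandas as pd

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    if (rows[-1] - rows[0] + 1) < 16 or (cols[-1] - cols[0] + 1) < 16:
        raise ValueError("ROI smaller than one feature-map cell (16x16 input pixels)")

    if selected_channels is None:
        selected_channels = select_information_dense_maps(encoder)
    img = study.X.pixels
    maps, padded_shape = encoder.trunk_maps(img)
    h, w = img.shape
    values = {}
    report = {}
    for rank, ch in enumerate(selected_channels, start=1):
        up = resize(maps[ch], padded_shape, order=1, mode="edge", anti_aliasing=False)
        up = up[:h, :w]
        roi_vals = up[mask]
        values[f"D{rank}_node_mean"] = float(roi_vals.mean())
        try:
            hfeats = hc.histogram_features(up, mask, n_bins=DEEP_GLCM_BINS)
            for s in DEEP_H_STATS:
                values[f"D{rank}_H_{s}"] = hfeats[s]
        except Exception as exc:  # noqa: BLE001
            for s in DEEP_H_STATS:
                values[f"D{rank}_H_{s}"] = np.nan
            report[f"D{rank}_H"] = str(exc)
        try:
            gfeats = hc.glcm_features(up, mask, n_bins=DEEP_GLCM_BINS)
            for s in DEEP_GLCM_STATS:
                values[f"D{rank}_GLCM_{s}"] = gfeats[s]
        except Exception as exc:  # noqa: BLE001
            for s in DEEP_GLCM_STATS:
                values[f"D{rank}_GLCM_{s}"] = np.nan
            report[f"D{rank}_GLCM"] = str(exc)
    names = deep_catalog(len(selected_channels))
    series = pd.Series([values[n] for n in names], index=names, dtype=np.float64)
    return series, report
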