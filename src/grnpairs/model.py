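"""Image-pair classifier: architectures, preprocessing and training.

An instance is a vertically concatenated image pair — the TF image on top,
its candidate target below — classified by a CNN that ends in a 128-unit
tanh layer (with batch normalization and dropout) followed by a single
sigmoid output, the probability of a regulatory link.

Two backbones are available:

``resnet50_style``
    A ResNet-50 layout (7x7/64 stride-2 stem, 3x3 stride-2 max pool, then
    bottleneck stages of 3/4/6/3 units with 256/512/1024/2048 output
    channels, global average pooling).  On the default 256x320 concatenated
    input the stage feature maps are 128x160, 64x80, 32x40, 16x20, 8x10.
``small_cnn``
    A shallow three-stage convolutional stack with the same head contract,
    trainable from scratch on a CPU in minutes; intended for synthetic
    corpora and tests.

Training minimizes binary cross-entropy with plain SGD.  The ``fit`` entry
point follows the Model/Results convention: ``PairClassifier(...).fit(...)``
returns a ``PairClassifierResults`` carrying the trained network, the
per-epoch history and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .dataset import GeneImageSet, ImagePairInstance

__all__ = [
    "ModelConfig", "TrainConfig", "build_model", "stage_output_sizes",
    "concat_pair", "normalize", "score_arrays", "score_instances",
    "score_instance", "train", "PairClassifier", "PairClassifierResults",
]


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "resnet50_style"  # or "small_cnn"
    in_channels: int = 3
    pretrained_init: str | None = None  # path to an .npz of weights, or None
    freeze_backbone: bool = False
    head_hidden_dim: int = 128
    head_activation: str = "tanh"
    head_dropout: float = 0.3
    head_batchnorm: bool = True
    norm_mean: float = 0.5  # applied after scaling pixels to [0,1]
    norm_std: float = 0.5

    def validate(self) -> None:
        if self.backbone not in ("resnet50_style", "small_cnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.head_hidden_dim < 1:
            raise ValueError("head_hidden_dim must be >= 1")
        if not 0.0 <= self.head_dropout < 1.0:
            raise ValueError("head_dropout must be in [0,1)")
        if self.head_activation not in ("tanh", "relu"):
            raise ValueError(f"unsupported head activation {self.head_activation!r}")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "sgd"
    learning_rate: float = 0.001
    momentum: float = 0.0
    epochs: int = 60
    batch_size: int = 32
    seed: int = 0
    checkpoint_policy: str = "best_val_accuracy"  # or "last"
    # halve the learning rate at these 1-based epochs (empty = constant)
    lr_decay_epochs: tuple[int, ...] = ()
    # "balanced" reweights instances so both classes contribute equally to
    # the loss (instance counts per pair vary, skewing inherited labels)
    class_weight: str | None = None

    def validate(self) -> None:
        if self.optimizer != "sgd":
            raise ValueError("only the SGD optimizer is implemented")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _head(n_in: int, cfg: ModelConfig, rng: np.random.Generator) -> list[nn.Layer]:
    act = nn.Tanh() if cfg.head_activation == "tanh" else nn.ReLU()
    layers: list[nn.Layer] = [nn.Linear(n_in, cfg.head_hidden_dim, rng=rng)]
    if cfg.head_batchnorm:
        layers.append(nn.BatchNorm1d(cfg.head_hidden_dim))
    layers.append(act)
    if cfg.head_dropout > 0:
        layers.append(nn.Dropout(cfg.head_dropout, rng=rng))
    layers.append(nn.Linear(cfg.head_hidden_dim, 1, rng=rng))
    return layers


def _resnet50(cfg: ModelConfig, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    stages: list[nn.Layer] = [
        nn.Conv2d(cfg.in_channels, 64, 7, stride=2, pad=3, bias=False, rng=rng),
        nn.BatchNorm2d(64), nn.ReLU(),
        nn.MaxPool2d(3, 2, pad=1),
    ]
    plan = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)]
    in_ch = 64
    for mid, out, blocks, stride in plan:
        for b in range(blocks):
            stages.append(nn.Bottleneck(in_ch, mid, out,
                                        stride=stride if b == 0 else 1, rng=rng))
            in_ch = out
    stages.append(nn.GlobalAvgPool2d())
    return nn.Sequential(*stages), 2048


def _small_cnn(cfg: ModelConfig, rng: np.random.Generator,
               input_hw: tuple[int, int]) -> tuple[nn.Sequential, int]:
    h, w = input_hw
    if h % 16 or w % 8:
        raise ValueError("small_cnn needs the concatenated height divisible by "
                         f"16 and width by 8, got {h}x{w}")
    h8 = h // 8
    # Three conv/pool stages extract local staining features; the
    # "cross-half" conv spans half the downsampled map vertically, so each
    # output cell compares the TF half with the vertically aligned position
    # of the target half; global max pooling then asks whether such a
    # co-localization exists *anywhere* — translation-invariant by design,
    # which keeps the classifier from memorizing absolute positions.
    seq = nn.Sequential(
        nn.Conv2d(cfg.in_channels, 8, 3, stride=1, pad=1, bias=False, rng=rng),
        nn.BatchNorm2d(8), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(8, 16, 3, stride=1, pad=1, bias=False, rng=rng),
        nn.BatchNorm2d(16), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(16, 32, 3, stride=1, pad=1, bias=False, rng=rng),
        nn.BatchNorm2d(32), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(32, 32, (h8 // 2 + 1, 3), stride=1, pad=(0, 1),
                  bias=False, rng=rng),
        nn.BatchNorm2d(32), nn.ReLU(),
        nn.GlobalMaxPool2d(),
    )
    return seq, 32


def build_model(cfg: ModelConfig, input_hw: tuple[int, int] = (256, 320),
                seed: int = 0) -> nn.Network:
    """Construct the classifier network (untrained, eval mode).

    ``input_hw`` is the concatenated (2H, W) input geometry.  The network's
    final Linear emits a logit; ``score_arrays`` applies the sigmoid, so
    emitted probabilities are strictly inside (0, 1).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    if cfg.backbone == "resnet50_style":
        h, w = input_hw
        if h % 32 or w % 32:
            raise ValueError(
                f"resnet50_style downsamples by 32; input {h}x{w} is incompatible "
                "(first failing stage: conv1/maxpool chain)")
        backbone, feat = _resnet50(cfg, rng)
    else:
        backbone, feat = _small_cnn(cfg, rng, input_hw)
    n_backbone = len(list(backbone.walk()))
    seq = nn.Sequential(backbone, *_head(feat, cfg, rng))
    net = nn.Network(seq, meta={"config": cfg, "input_hw": tuple(input_hw),
                                "n_backbone_layers": n_backbone})
    if cfg.pretrained_init:
        net.load(cfg.pretrained_init)
    if cfg.freeze_backbone:
        for lyr in backbone.walk():
            lyr.frozen = True
    return net.eval()


def stage_output_sizes(net: nn.Network, x: np.ndarray) -> dict[str, tuple[int, int]]:
    """Run a real forward pass and record per-stage feature-map sizes.

    Only meaningful for the resnet50_style backbone; keys are conv1,
    conv2_x .. conv5_x and pool (the global average pool, reported as 1x1).
    """
    backbone = net.seq.layers[0]
    sizes: dict[str, tuple[int, int]] = {}
    training = net.training
    h = x
    stage_names = iter(["conv2_x", "conv3_x", "conv4_x", "conv5_x"])
    current, current_ch = None, None
    for lyr in backbone.layers:
        h = lyr.forward(h, training)
        if isinstance(lyr, nn.Conv2d) and "conv1" not in sizes:
            sizes["conv1"] = (h.shape[2], h.shape[3])
        elif isinstance(lyr, nn.Bottleneck):
            # a stage boundary is where the channel count changes
            if current is None or h.shape[1] != current_ch:
                current = next(stage_names)
                current_ch = h.shape[1]
            sizes[current] = (h.shape[2], h.shape[3])
        elif isinstance(lyr, nn.GlobalAvgPool2d):
            sizes["pool"] = (1, 1)
    return sizes


# ---------------------------------------------------------------------------
# preprocessing


def concat_pair(tf_img: np.ndarray, target_img: np.ndarray) -> np.ndarray:
    """Vertically stack an image pair: TF on top, target below (uint8 HxW)."""
    if tf_img.shape != target_img.shape:
        raise ValueError(f"image shapes differ: {tf_img.shape} vs {target_img.shape}")
    return np.concatenate([tf_img, target_img], axis=0)


def normalize(concat: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """uint8 (2H,W) -> float32 (C,2H,W), scaled to [0,1] then standardized.

    Grayscale input is replicated across ``in_channels`` so channel-expecting
    backbones (e.g. ones initialized from natural-image weights) apply.
    """
    x = concat.astype(np.float32) / 255.0
    x = (x - cfg.norm_mean) / cfg.norm_std
    return np.repeat(x[None], cfg.in_channels, axis=0)


def _instance_tensor(instances, image_sets: dict[str, GeneImageSet],
                     cfg: ModelConfig) -> np.ndarray:
    batch = []
    for ins in instances:
        g, o, p = ins.tf_image
        tf_img = image_sets[g].image(o, p)
        g2, o2, q = ins.target_image
        tg_img = image_sets[g2].image(o2, q)
        batch.append(normalize(concat_pair(tf_img, tg_img), cfg))
    return np.stack(batch)


def score_arrays(net: nn.Network, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Probabilities for a batch of preprocessed (N,C,2H,W) inputs (eval mode).

    Runs in float64 so the result is independent of how instances are
    batched (float32 BLAS accumulation order varies with batch size).
    """
    was_training = net.training
    net.eval()
    x = x.astype(np.float64, copy=False)
    out = []
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i:i + batch_size])
        out.append(nn.sigmoid(logits)[:, 0])
    if was_training:
        net.train()
    return np.concatenate(out) if out else np.empty(0, dtype=np.float32)


def score_instances(net: nn.Network, instances,
                    image_sets: dict[str, GeneImageSet],
                    batch_size: int = 64) -> np.ndarray:
    if not instances:
        return np.empty(0, dtype=np.float32)
    cfg: ModelConfig = net.meta["config"]
    exp_h, exp_w = net.meta["input_hw"]
    g, o, p = instances[0].tf_image
    img = image_sets[g].image(o, p)
    if (2 * img.shape[0], img.shape[1]) != (exp_h, exp_w):
        raise ValueError(f"images of shape {img.shape} concatenate to "
                         f"{2 * img.shape[0]}x{img.shape[1]}, but the model "
                         f"expects {exp_h}x{exp_w}")
    x = _instance_tensor(instances, image_sets, cfg)
    return score_arrays(net, x, batch_size)


def score_instance(net: nn.Network, instance: ImagePairInstance,
                   image_sets: dict[str, GeneImageSet]) -> float:
    """Probability for a single image-pair instance (deterministic in eval)."""
    return float(score_instances(net, [instance], image_sets)[0])


# ---------------------------------------------------------------------------
# training


def _epoch_metrics(net, x, y, batch_size):
    probs = score_arrays(net, x, batch_size)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(probs + eps)
                          + (1 - y) * np.log(1 - probs + eps)))
    acc = float(np.mean((probs >= 0.5) == (y == 1)))
    return loss, acc


def train(net: nn.Network, train_instances, val_instances,
          image_sets: dict[str, GeneImageSet], cfg: TrainConfig,
          verbose: bool = False) -> pd.DataFrame:
    """SGD training on image-pair instances; returns the per-epoch history.

    The best-validation-accuracy checkpoint (per ``cfg.checkpoint_policy``)
    is restored into ``net`` before returning.  Fully reproducible given
    ``cfg.seed``.
    """
    cfg.validate()
    if not train_instances:
        raise ValueError("empty training set")
    y_tr = np.array([i.label for i in train_instances], dtype=np.float32)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set contains a single class; the binary "
                         "problem is degenerate")
    mcfg: ModelConfig = net.meta["config"]
    x_tr = _instance_tensor(train_instances, image_sets, mcfg)
    x_va = (_instance_tensor(val_instances, image_sets, mcfg)
            if val_instances else None)
    y_va = (np.array([i.label for i in val_instances], dtype=np.float32)
            if val_instances else None)

    if cfg.class_weight == "balanced":
        n_pos = float(y_tr.sum())
        n_neg = float(len(y_tr) - n_pos)
        w_tr = np.where(y_tr == 1, len(y_tr) / (2 * n_pos),
                        len(y_tr) / (2 * n_neg)).astype(np.float32)
    else:
        w_tr = np.ones(len(y_tr), dtype=np.float32)

    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(net, lr=cfg.learning_rate, momentum=cfg.momentum)
    rows = []
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        if (epoch + 1) in cfg.lr_decay_epochs:
            opt.lr *= 0.5
        net.train()
        order = rng.permutation(len(x_tr))
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            opt.zero_grad()
            logits = net.forward(x_tr[sel])
            g = nn.bce_with_logits_grad(logits, y_tr[sel])
            g *= w_tr[sel][:, None]
            net.seq.backward(g)
            opt.step()
        net.eval()
        tr_loss, tr_acc = _epoch_metrics(net, x_tr, y_tr, cfg.batch_size)
        if x_va is not None and len(x_va):
            va_loss, va_acc = _epoch_metrics(net, x_va, y_va, cfg.batch_size)
        else:
            va_loss, va_acc = np.nan, np.nan
        rows.append({"epoch": epoch + 1, "train_loss": tr_loss,
                     "train_accuracy": tr_acc, "val_loss": va_loss,
                     "val_accuracy": va_acc})
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {tr_loss:.4f}  acc {tr_acc:.3f}"
                  f"  val_acc {va_acc:.3f}")
        crit = va_acc if x_va is not None and len(x_va) else tr_acc
        if cfg.checkpoint_policy == "best_val_accuracy" and crit > best[0]:
            best = (crit, net.copy_state())
    if cfg.checkpoint_policy == "best_val_accuracy" and best[1] is not None:
        net.load_state(best[1])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results objects


class PairClassifier:
    """Image-pair link classifier (Model object).

    Parameters
    ----------
    model_config : ModelConfig
    input_hw : (int, int)
        Concatenated input geometry (2H, W).
    seed : int
        Weight-initialization seed.
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 input_hw: tuple[int, int] = (256, 320), seed: int = 0):
        self.config = model_config or ModelConfig()
        self.input_hw = tuple(input_hw)
        self.seed = seed
        self.network = build_model(self.config, self.input_hw, seed)

    def fit(self, train_instances, val_instances,
            image_sets: dict[str, GeneImageSet],
            train_config: TrainConfig | None = None,
            verbose: bool = False) -> "PairClassifierResults":
        tcfg = train_config or TrainConfig()
        history = train(self.network, train_instances, val_instances,
                        image_sets, tcfg, verbose=verbose)
        return PairClassifierResults(self, history, tcfg)


@dataclass
class PairClassifierResults:
    """Fit results: trained network, per-epoch history, summary table."""

    model: PairClassifier
    history: pd.DataFrame
    train_config: TrainConfig

    @property
    def network(self) -> nn.Network:
        return self.model.network

    @property
    def best_epoch(self) -> int:
        col = ("val_accuracy"
               if self.history["val_accuracy"].notna().any() else "train_accuracy")
        return int(self.history[col].idxmax()) + 1

    def score_instances(self, instances, image_sets) -> np.ndarray:
        return score_instances(self.network, instances, image_sets)

    def predict_links(self, pairs, image_sets, threshold: float = 0.5):
        from .inference import predict_links
        return predict_links(self.network, pairs, image_sets, threshold)

    def save_history(self, path) -> None:
        self.history.to_csv(path, index=False)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_accuracy"],
                label="train")
        if self.history["val_accuracy"].notna().any():
            ax.plot(self.history["epoch"], self.history["val_accuracy"],
                    label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("accuracy")
        ax.legend()
        return ax

    def summary(self) -> str:
        h = self.history
        buf = io.StringIO()
        cfg = self.model.config
        last = h.iloc[-1]
        print("Image-pair link classifier", file=buf)
        print("=" * 44, file=buf)
        print(f"backbone:          {cfg.backbone}", file=buf)
        print(f"input (2H x W):    {self.model.input_hw[0]} x "
              f"{self.model.input_hw[1]}", file=buf)
        print(f"head:              {cfg.head_hidden_dim}-{cfg.head_activation}"
              f" (dropout {cfg.head_dropout}) -> 1-sigmoid", file=buf)
        print(f"optimizer:         {self.train_config.optimizer} "
              f"(lr {self.train_config.learning_rate})", file=buf)
        print(f"epochs:            {len(h)}", file=buf)
        print(f"best epoch:        {self.best_epoch}", file=buf)
        print(f"final train acc:   {last['train_accuracy']:.3f}", file=buf)
        if np.isfinite(last["val_accuracy"]):
            best_va = h["val_accuracy"].max()
            print(f"best val acc:      {best_va:.3f}", file=buf)
        return buf.getvalue()
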