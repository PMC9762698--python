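"""The convolutional-recurrent scratch classifier (CRNN).

A per-frame residual CNN encoder turns each of the N window frames into an
embedding vector; a two-layer bidirectional GRU reads the embedding
sequence to capture the rhythmic hind-paw dynamics; a fully connected head
maps the fused recurrent features to two class scores (non-scratching = 0,
scratching = 1), decided by argmax.

Two backbones share the same code path: ``resnet18`` is the standard
ResNet-18 layout (grayscale stem, [2,2,2,2] blocks, 64-512 channels) with
its classification layer replaced by an embedding layer, intended for
256x256 inputs; ``tiny`` is a 3-block residual net for 64x64 inputs that
trains in minutes on one CPU and is the default for synthetic studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for convenience alongside the model)
    BatchNorm2d,
    BiGRU,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    softmax,
)

__all__ = ["CRNNConfig", "CRNNModel", "ResidualBlock", "build_model",
           "save_checkpoint", "load_checkpoint", "model_summary"]


@dataclass(frozen=True)
class CRNNConfig:
    """Architecture hyperparameters.

    ``feature_fusion`` selects how the classifier combines CNN and RNN
    features: ``concat_cnn_mean`` (default) concatenates the final hidden
    states of both GRU directions with the mean of the N per-frame CNN
    embeddings, so the head sees both dynamic and static features;
    ``gru_only`` feeds the recurrent states alone.
    """

    input_size: tuple[int, int] = (256, 256)
    n: int = 45
    cnn_variant: str = "resnet18"
    cnn_embedding: int = 256
    gru_layers: int = 2
    gru_hidden: int = 512
    fc_hidden: int = 256
    n_classes: int = 2
    fc_dropout: float = 0.2
    feature_fusion: str = "concat_cnn_mean"

    def __post_init__(self):
        if self.n_classes != 2:
            raise ValueError("the scratch classifier is binary (n_classes = 2)")
        if self.cnn_variant not in ("resnet18", "tiny"):
            raise ValueError(f"unknown cnn_variant {self.cnn_variant!r}")
        if self.feature_fusion not in ("gru_only", "concat_cnn_mean"):
            raise ValueError(f"unknown feature_fusion {self.feature_fusion!r}")
        if not 0.0 <= self.fc_dropout < 1.0:
            raise ValueError("fc_dropout must be in [0, 1)")
        for field_name in ("n", "cnn_embedding", "gru_layers", "gru_hidden",
                           "fc_hidden"):
            if getattr(self, field_name) < 1:
                raise ValueError(f"{field_name} must be >= 1")

    @classmethod
    def full_scale(cls, n: int = 45, **kw) -> "CRNNConfig":
        return cls(n=n, **kw)

    @classmethod
    def tiny(cls, n: int = 7, **kw) -> "CRNNConfig":
        defaults = dict(
            input_size=(64, 64), cnn_variant="tiny", cnn_embedding=64,
            gru_hidden=64, fc_hidden=64,
        )
        defaults.update(kw)
        return cls(n=n, **defaults)

    @property
    def fusion_dim(self) -> int:
        dim = 2 * self.gru_hidden
        if self.feature_fusion == "concat_cnn_mean":
            dim += self.cnn_embedding
        return dim


class ResidualBlock(Module):
    """Two 3x3 conv/BN stages with an identity (or 1x1 projection) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, 1, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, 1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu_out = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride, 0, rng=rng)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x):
        main = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        short = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return self.relu_out(main + short)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))
            )
        )
        if self.proj is not None:
            dshort = self.proj.backward(self.proj_bn.backward(d))
        else:
            dshort = d
        return dmain + dshort


def _build_backbone(cfg: CRNNConfig, rng: np.random.Generator) -> Sequential:
    if cfg.cnn_variant == "resnet18":
        layers: list[Module] = [
            Conv2d(1, 64, 7, 2, 3, rng=rng), BatchNorm2d(64), ReLU(),
            MaxPool2d(3, 2, 1),
        ]
        in_ch = 64
        for out_ch, stride, blocks in ((64, 1, 2), (128, 2, 2),
                                       (256, 2, 2), (512, 2, 2)):
            for b in range(blocks):
                layers.append(
                    ResidualBlock(in_ch, out_ch, stride if b == 0 else 1, rng)
                )
                in_ch = out_ch
        layers += [GlobalAvgPool(), Linear(in_ch, cfg.cnn_embedding, rng=rng)]
    else:  # tiny
        layers = [Conv2d(1, 8, 3, 2, 1, rng=rng), BatchNorm2d(8), ReLU()]
        in_ch = 8
        for out_ch in (16, 32, 64):
            layers.append(ResidualBlock(in_ch, out_ch, 2, rng))
            in_ch = out_ch
        layers += [GlobalAvgPool(), Linear(in_ch, cfg.cnn_embedding, rng=rng)]
    return Sequential(*layers)


class CRNNModel(Module):
    """CNN encoder + bidirectional GRU + FC classifier head."""

    def __init__(self, config: CRNNConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.cnn = _build_backbone(config, rng)
        self.gru = BiGRU(config.cnn_embedding, config.gru_hidden,
                         config.gru_layers, rng)
        self.fc1 = Linear(config.fusion_dim, config.fc_hidden, rng=rng)
        self.relu = ReLU()
        self.dropout = Dropout(config.fc_dropout,
                               rng=np.random.default_rng(seed + 1))
        self.fc2 = Linear(config.fc_hidden, config.n_classes, rng=rng)

    # -- full forward / backward (training, saliency) --------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, N, H, W) windows -> (B, 2) class scores."""
        b, n, h, w = x.shape
        if n != self.config.n or (h, w) != tuple(self.config.input_size):
            raise ValueError(
                f"window geometry {(n, h, w)} does not match config "
                f"(N={self.config.n}, input_size={self.config.input_size})"
            )
        feats = self.cnn(x.reshape(b * n, 1, h, w))
        emb = feats.reshape(b, n, self.config.cnn_embedding)
        out = self.gru(emb)
        fused = self.gru.final_hidden(out)
        if self.config.feature_fusion == "concat_cnn_mean":
            fused = np.concatenate([fused, emb.mean(axis=1)], axis=1)
        self._cache = (x.shape, out.shape)
        return self.fc2(self.dropout(self.relu(self.fc1(fused))))

    def backward(
        self, dlogits: np.ndarray, input_grad: bool = True
    ) -> np.ndarray | None:
        """Backpropagate; returns the input-pixel gradient (B, N, H, W),
        or None when ``input_grad`` is False (training only needs the
        parameter gradients)."""
        (b, n, h, w), out_shape = self._cache
        dfused = self.fc1.backward(
            self.relu.backward(self.dropout.backward(self.fc2.backward(dlogits)))
        )
        gru_dim = 2 * self.config.gru_hidden
        dout = self.gru.inject_final_hidden_grad(out_shape, dfused[:, :gru_dim])
        demb = self.gru.backward(dout)
        if self.config.feature_fusion == "concat_cnn_mean":
            demb = demb + dfused[:, gru_dim:][:, None, :] / n
        dx = self.cnn.backward(
            demb.reshape(b * n, self.config.cnn_embedding),
            need_input_grad=input_grad,
        )
        self._cache = None
        return None if dx is None else dx.reshape(b, n, h, w)

    # -- split forward used by stride-1 inference -------------------------

    def encode_frames(self, frames: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Embed a stack of frames (M, H, W) -> (M, cnn_embedding).

        Stride-1 inference evaluates overlapping windows, so each frame is
        embedded once here and the recurrent head is run per window.
        """
        chunks = []
        for i in range(0, frames.shape[0], batch_size):
            chunk = frames[i : i + batch_size]
            chunks.append(self.cnn(chunk[:, None, :, :]))
        return np.concatenate(chunks, axis=0)

    def classify_embeddings(self, emb: np.ndarray) -> np.ndarray:
        """Embedding windows (B, N, E) -> class scores (B, 2)."""
        out = self.gru(emb)
        fused = self.gru.final_hidden(out)
        if self.config.feature_fusion == "concat_cnn_mean":
            fused = np.concatenate([fused, emb.mean(axis=1)], axis=1)
        return self.fc2(self.dropout(self.relu(self.fc1(fused))))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x), axis=1)


def build_model(config: CRNNConfig, seed: int = 0) -> CRNNModel:
    """Instantiate a CRNN with seed-deterministic initial parameters."""
    return CRNNModel(config, seed=seed)


# -- checkpoints ----------------------------------------------------------


def _named_arrays(module: Module, prefix: str = ""):
    from .nn.layers import Parameter

    for name, val in module.__dict__.items():
        if isinstance(val, Parameter):
            yield f"{prefix}{name}", val
        elif isinstance(val, np.ndarray) and name.startswith("running_"):
            yield f"{prefix}{name}", val
        elif isinstance(val, Module):
            yield from _named_arrays(val, f"{prefix}{name}.")
        elif isinstance(val, (list, tuple)):
            for i, item in enumerate(val):
                if isinstance(item, Module):
                    yield from _named_arrays(item, f"{prefix}{name}.{i}.")


def save_checkpoint(model: CRNNModel, path) -> None:
    from .nn.layers import Parameter

    arrays = {}
    for name, val in _named_arrays(model):
        arrays[name] = val.value if isinstance(val, Parameter) else val
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> CRNNModel:
    from .nn.layers import Parameter

    data = np.load(path)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
    model = CRNNModel(CRNNConfig(**cfg_dict), seed=0)
    stored = {k: v for k, v in data.items() if k != "__config__"}
    for name, val in _named_arrays(model):
        if name not in stored:
            raise ValueError(f"checkpoint missing array {name}")
        if isinstance(val, Parameter):
            val.value = stored[name].copy()
            val.grad = np.zeros_like(val.value)
        else:
            val[...] = stored[name]
    return model


def model_summary(model: CRNNModel) -> str:
    from .nn.layers import Parameter

    lines = [f"CRNN ({model.config.cnn_variant}, N={model.config.n}, "
             f"input={model.config.input_size})"]
    total = 0
    for name, val in _named_arrays(model):
        if isinstance(val, Parameter):
            lines.append(f"  {name:50s} {str(val.value.shape):20s} "
                         f"{val.value.size:>10d}")
            total += val.value.size
    lines.append(f"  {'total trainable parameters':50s} {'':20s} {total:>10d}")
    return "\n".join(lines)
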