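"""Shared encoder-decoder network with four task heads.

The backbone is a U-Net whose encoder is the 13-convolution VGG-16
feature stack (3x3 kernels, ReLU, four 2x2 max-pools, no batch
normalization, no pool after the fifth block), so the bottleneck sits at
1/16 resolution with 512 channels.  The decoder has four stages, each a
parameter-free bilinear x2 upsampling, concatenation with the matching
encoder block's pre-pool activation (512/256/128/64 skip channels) and a
single 3x3 convolution + ReLU.  Three 1x1-convolution heads on the final
decoder feature map produce the optic-disc map (sigmoid), optic-cup map
(sigmoid) and fovea saliency map (identity); a classifier head branches
from the bottleneck: global average pooling -> 512->256 dense + ReLU ->
256->1 dense + sigmoid, giving the glaucoma probability.

With the default widths the full four-task network has exactly
17,169,188 trainable parameters (14,714,688 of them the canonical VGG-16
convolution stack), and the four single-task variants together total
65,958,884 - about 3.8x larger than the shared model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Parameter

ALL_TASKS = ("od", "oc", "fovea", "glaucoma")
MAP_TASKS = ("od", "oc", "fovea")

DEFAULT_ENCODER_WIDTHS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))
DEFAULT_DECODER_WIDTHS = (192, 96, 64, 32)


class ConfigError(ValueError):
    """Invalid model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults pin the published layout."""

    input_size: int = 512
    encoder_widths: tuple = DEFAULT_ENCODER_WIDTHS
    decoder_widths: tuple = DEFAULT_DECODER_WIDTHS
    classifier_hidden: int = 256
    tasks: tuple = ALL_TASKS
    pretrained_encoder_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 16 != 0 or self.input_size <= 0:
            raise ConfigError(f"input_size must be a positive multiple of 16, got {self.input_size}")
        if len(self.encoder_widths) != 5:
            raise ConfigError("encoder_widths must have 5 blocks")
        if len(self.decoder_widths) != 4:
            raise ConfigError("decoder_widths must have exactly 4 entries")
        bad = set(self.tasks) - set(ALL_TASKS)
        if bad:
            raise ConfigError(f"unknown tasks: {sorted(bad)}")
        if not self.tasks:
            raise ConfigError("tasks must be nonempty")
        object.__setattr__(self, "tasks", tuple(t for t in ALL_TASKS if t in self.tasks))


@dataclass
class ForwardOutputs:
    """Per-task raw outputs of one forward pass (None for absent tasks)."""

    od_map: np.ndarray | None = None      # (B, H, W) probabilities
    oc_map: np.ndarray | None = None      # (B, H, W) probabilities
    fovea_map: np.ndarray | None = None   # (B, H, W) real-valued
    glaucoma_prob: np.ndarray | None = None  # (B,) probabilities


class MultiTaskNet:
    """The network with explicit forward/backward passes.

    ``forward`` caches every intermediate needed for backpropagation;
    ``backward_map_task`` / ``backward_classifier`` then accumulate
    gradients into each :class:`~fundusmtl.nn.Parameter`'s ``grad`` slot.
    The classifier branch deliberately stops its backward pass at the
    bottleneck, so the glaucoma loss trains only the two dense layers.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Parameter] = {}
        self._build()
        self._cache = None

    # -- construction -------------------------------------------------

    def _add(self, name: str, data: np.ndarray) -> Parameter:
        p = Parameter(name, data)
        self.params[name] = p
        return p

    def _build(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        c_in = 3
        for b, block in enumerate(cfg.encoder_widths, start=1):
            for i, c_out in enumerate(block, start=1):
                fan_in = c_in * 9
                self._add(f"conv{b}_{i}.weight", nn.kaiming_uniform(rng, fan_in, (c_out, fan_in)))
                self._add(f"conv{b}_{i}.bias", np.zeros(c_out))
                c_in = c_out
        self.has_decoder = any(t in cfg.tasks for t in MAP_TASKS)
        if self.has_decoder:
            skip_widths = [blk[-1] for blk in cfg.encoder_widths[:4]][::-1]  # 512,256,128,64
            c_prev = cfg.encoder_widths[4][-1]
            for i, c_out in enumerate(cfg.decoder_widths):
                fan_in = (c_prev + skip_widths[i]) * 9
                self._add(f"dec{i}.weight", nn.kaiming_uniform(rng, fan_in, (c_out, fan_in)))
                self._add(f"dec{i}.bias", np.zeros(c_out))
                c_prev = c_out
            for t in MAP_TASKS:
                if t in cfg.tasks:
                    self._add(f"head_{t}.weight", nn.kaiming_uniform(rng, c_prev, (1, c_prev)))
                    self._add(f"head_{t}.bias", np.zeros(1))
        if "glaucoma" in cfg.tasks:
            c_bot = cfg.encoder_widths[4][-1]
            h = cfg.classifier_hidden
            self._add("fc1.weight", nn.kaiming_uniform(rng, c_bot, (h, c_bot)))
            self._add("fc1.bias", np.zeros(h))
            self._add("fc2.weight", nn.kaiming_uniform(rng, h, (1, h)))
            self._add("fc2.bias", np.zeros(1))
        if cfg.pretrained_encoder_path is not None:
            self.load_encoder_weights(cfg.pretrained_encoder_path)

    def load_encoder_weights(self, path: str):
        """Load encoder convolutions from a named-array (.npz) container."""
        try:
            arrays = np.load(path)
        except OSError as e:
            raise IOError(f"cannot read pretrained encoder file {path!r}: {e}") from e
        for b, block in enumerate(self.config.encoder_widths, start=1):
            for i, _ in enumerate(block, start=1):
                for kind in ("weight", "bias"):
                    name = f"conv{b}_{i}.{kind}"
                    if name not in arrays:
                        raise IOError(f"pretrained container missing array {name!r}")
                    arr = np.asarray(arrays[name], dtype=nn.DTYPE)
                    target = self.params[name].data
                    if kind == "weight" and arr.ndim == 4:
                        arr = arr.reshape(arr.shape[0], -1)
                    if arr.shape != target.shape:
                        raise IOError(f"shape mismatch for {name}: {arr.shape} vs {target.shape}")
                    self.params[name].data = np.ascontiguousarray(arr)

    # -- gradient bookkeeping -----------------------------------------

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def grads(self) -> dict[str, np.ndarray]:
        return {k: p.grad for k, p in self.params.items() if p.grad is not None}

    # -- forward -------------------------------------------------------

    def forward(self, images: np.ndarray, need_maps: bool = True) -> ForwardOutputs:
        """Run the network on a ``(B, 3, H, W)`` batch scaled to [0, 1].

        ``need_maps=False`` skips the decoder and map heads (used by
        classifier-only steps, where the decoder output is never read).
        """
        cfg = self.config
        x = np.ascontiguousarray(images, dtype=nn.DTYPE)
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ValueError(
                f"expected batch of shape (B, 3, {cfg.input_size}, {cfg.input_size}), got {x.shape}"
            )
        cache = {"conv": {}, "relu": {}, "pool": {}, "skips": []}
        for b, block in enumerate(cfg.encoder_widths, start=1):
            for i, _ in enumerate(block, start=1):
                name = f"conv{b}_{i}"
                x, cache["conv"][name] = nn.conv3x3_forward(x, self.params[name + ".weight"], self.params[name + ".bias"])
                x, cache["relu"][name] = nn.relu_forward(x)
            if b < 5:
                cache["skips"].append(x)
                x, cache["pool"][b] = nn.maxpool2_forward(x)
        bottleneck = x
        cache["bottleneck_shape"] = bottleneck.shape
        out = ForwardOutputs()

        if self.has_decoder and need_maps:
            skips = cache["skips"][::-1]
            cache["dec_conv"], cache["dec_relu"], cache["dec_split"] = {}, {}, {}
            y = bottleneck
            for i in range(4):
                y, _ = nn.upsample2_forward(y)
                cache["dec_split"][i] = y.shape[1]
                y = np.concatenate([y, skips[i]], axis=1)
                name = f"dec{i}"
                y, cache["dec_conv"][i] = nn.conv3x3_forward(y, self.params[name + ".weight"], self.params[name + ".bias"])
                y, cache["dec_relu"][i] = nn.relu_forward(y)
            cache["dec_out"] = y
            cache["head"] = {}
            for t in MAP_TASKS:
                if t in cfg.tasks:
                    z, cache["head"][t] = nn.conv1x1_forward(y, self.params[f"head_{t}.weight"], self.params[f"head_{t}.bias"])
                    zmap = z[:, 0]
                    if t == "fovea":
                        setattr(out, "fovea_map", zmap)
                    else:
                        setattr(out, f"{t}_map", nn.sigmoid(zmap))

        if "glaucoma" in cfg.tasks:
            pooled, cache["gap"] = nn.global_avg_pool_forward(bottleneck)
            h1, cache["fc1"] = nn.linear_forward(pooled, self.params["fc1.weight"], self.params["fc1.bias"])
            h1r, cache["fc1_relu"] = nn.relu_forward(h1)
            z2, cache["fc2"] = nn.linear_forward(h1r, self.params["fc2.weight"], self.params["fc2.bias"])
            out.glaucoma_prob = nn.sigmoid(z2[:, 0])
        self._cache = cache
        return out

    # -- backward ------------------------------------------------------

    def _backward_encoder(self, dx: np.ndarray, dskips: list | None):
        """Backprop through the encoder given d(bottleneck) and per-skip grads."""
        cache = self._cache
        for b in range(5, 0, -1):
            if b < 5:
                dx = nn.maxpool2_backward(dx, cache["pool"][b])
                if dskips is not None and dskips[b - 1] is not None:
                    dx = dx + dskips[b - 1]
            for i in range(len(self.config.encoder_widths[b - 1]), 0, -1):
                name = f"conv{b}_{i}"
                dx = nn.relu_backward(dx, cache["relu"][name])
                dx = nn.conv3x3_backward(dx, cache["conv"][name], self.params[name + ".weight"], self.params[name + ".bias"])
        return dx

    def backward_map_task(self, task: str, dz: np.ndarray):
        """Backprop a map-head gradient ``dz`` = dL/d(pre-activation), (B, H, W)."""
        if task not in MAP_TASKS or task not in self.config.tasks:
            raise ValueError(f"no map head for task {task!r}")
        cache = self._cache
        if cache is None or "head" not in cache:
            raise RuntimeError("forward(need_maps=True) must precede backward_map_task")
        d = np.ascontiguousarray(dz[:, None], dtype=nn.DTYPE)
        dy = nn.conv1x1_backward(d, cache["head"][task], self.params[f"head_{task}.weight"], self.params[f"head_{task}.bias"])
        dskips = [None] * 4
        for i in range(3, -1, -1):
            name = f"dec{i}"
            dy = nn.relu_backward(dy, cache["dec_relu"][i])
            dy = nn.conv3x3_backward(dy, cache["dec_conv"][i], self.params[name + ".weight"], self.params[name + ".bias"])
            split = cache["dec_split"][i]
            dskips[3 - i] = dy[:, split:]  # skip for encoder block 4-i
            dy = nn.upsample2_backward(dy[:, :split])
        self._backward_encoder(dy, dskips)

    def backward_classifier(self, dz2: np.ndarray, into_encoder: bool = False):
        """Backprop dL/d(fc2 pre-activation), shape (B,).

        By default the gradient stays inside the dense branch (fc1/fc2);
        with ``into_encoder=True`` it continues through the global
        average pooling into the encoder convolutions, which is how the
        glaucoma-only single-task model is trained.
        """
        cache = self._cache
        if cache is None or "fc2" not in cache:
            raise RuntimeError("forward must precede backward_classifier")
        d = np.ascontiguousarray(dz2[:, None], dtype=nn.DTYPE)
        d = nn.linear_backward(d, cache["fc2"], self.params["fc2.weight"], self.params["fc2.bias"])
        d = nn.relu_backward(d, cache["fc1_relu"])
        d = nn.linear_backward(d, cache["fc1"], self.params["fc1.weight"], self.params["fc1.bias"])
        if into_encoder:
            d = nn.global_avg_pool_backward(d, cache["gap"])
            self._backward_encoder(d, None)

    # -- persistence ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, p in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k!r}")
            arr = np.asarray(state[k], dtype=nn.DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = np.ascontiguousarray(arr)

    def save(self, path: str):
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path: str, config: ModelConfig) -> "MultiTaskNet":
        model = cls(config)
        with np.load(path) as data:
            model.load_state_dict(dict(data))
        return model


def build_model(config: ModelConfig) -> MultiTaskNet:
    """Construct the network described by ``config``."""
    return MultiTaskNet(config)


def count_parameters(model: MultiTaskNet) -> int:
    """Exact number of trainable scalar parameters."""
    return sum(p.size for p in model.params.values())


def single_task_counts(base: ModelConfig = None) -> dict[str, int]:
    """Parameter counts of the four single-task variants of ``base``."""
    base = base or ModelConfig(input_size=64)
    out = {}
    for t in ALL_TASKS:
        cfg = ModelConfig(
            input_size=base.input_size,
            encoder_widths=base.encoder_widths,
            decoder_widths=base.decoder_widths,
            classifier_hidden=base.classifier_hidden,
            tasks=(t,),
        )
        out[t] = count_parameters(build_model(cfg))
    return out
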