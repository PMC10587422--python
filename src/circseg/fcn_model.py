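"""The binding-site segmentation network.

A 1-D fully convolutional encoder-decoder that maps an M x 4 one-hot window
to M per-site two-class scores (class 1 = bound).  The encoder stacks
feature-extraction modules (same-padded conv -> ReLU -> ceil-mode max-pool ->
dropout); an optional global-average context injection sits at the
bottleneck.  The decoder stacks deconvolutional modules (nearest-neighbour
upsample to the mirrored stage's recorded pre-pool length -> skip summation
-> BN -> ReLU -> conv); the final module has upsample factor 1 and emits the
two-class head.  Because there are no dense layers, the output length always
mirrors the input length.

Three members of the family are registered:

======== ==================== =========================================
variant  encoder + decoder    notes
======== ==================== =========================================
fcn-2x2  2 + 2                shallowest; no refinement module
fcn-3x3  3 + 3                symmetric
fcn-3x4  3 + 4 (default)      extra refinement module before the head
======== ==================== =========================================

Skip connections sum the decoder stream with the mirrored encoder stage's
pre-pool activation; a width-1 conv adapter is inserted automatically when
channel counts differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm1D,
    Conv1D,
    Dropout,
    GlobalContext,
    Layer,
    MaxPool1D,
    Param,
    ReLU,
    UpsampleNearest,
)


@dataclass
class EncoderStageSpec:
    """conv -> ReLU -> max-pool -> dropout."""

    kernel_width: int
    n_filters: int
    pool_factor: int = 2
    dropout_rate: float = 0.2
    bias: bool = True

    def __post_init__(self) -> None:
        if self.kernel_width < 1 or self.pool_factor < 1:
            raise ValueError("kernel_width and pool_factor must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class DecoderStageSpec:
    """upsample -> (+skip) -> BN -> ReLU -> conv."""

    kernel_width: int
    n_filters: int
    mirror: int | None = None  # index of the encoder stage whose pre-pool length is restored
    bias: bool = True

    def __post_init__(self) -> None:
        if self.kernel_width < 1:
            raise ValueError("kernel_width must be >= 1")


@dataclass
class ModelConfig:
    """Architecture description; ``n_classes`` is fixed at 2 (unbound/bound)."""

    input_length: int = 101
    encoder: list[EncoderStageSpec] = field(default_factory=list)
    decoder: list[DecoderStageSpec] = field(default_factory=list)
    use_global_avg_pool: bool = False
    n_classes: int = 2
    variant: str = "custom"

    def __post_init__(self) -> None:
        if self.encoder and self.decoder:
            if len(self.decoder) not in (len(self.encoder), len(self.encoder) + 1):
                raise ValueError(
                    "decoder must have as many stages as the encoder, or one more "
                    f"(got {len(self.encoder)}+{len(self.decoder)})"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder"] = [EncoderStageSpec(**e) for e in d.get("encoder", [])]
        d["decoder"] = [DecoderStageSpec(**e) for e in d.get("decoder", [])]
        return cls(**d)


#: registered variants: (encoder filter counts, with-refinement-module?)
VARIANTS = {
    "fcn-2x2": dict(n_enc=2, refine=False),
    "fcn-3x3": dict(n_enc=3, refine=False),
    "fcn-3x4": dict(n_enc=3, refine=True),
}

_ENC_FILTERS = (16, 32, 64)
_FIRST_KERNEL = 10  # first-layer filters double as 10-nt motif scanners
_LATER_KERNEL = 3


def make_config(
    variant: str = "fcn-3x4",
    input_length: int = 101,
    use_global_avg_pool: bool = False,
    dropout_rate: float = 0.2,
) -> ModelConfig:
    """Default configuration for a registered variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    v = VARIANTS[variant]
    n_enc = v["n_enc"]
    enc = [
        EncoderStageSpec(
            kernel_width=_FIRST_KERNEL if i == 0 else _LATER_KERNEL,
            n_filters=_ENC_FILTERS[i],
            pool_factor=2,
            dropout_rate=dropout_rate,
        )
        for i in range(n_enc)
    ]
    # decoder stage j restores encoder stage (n_enc-1-j) and outputs that
    # stage's *input* channel count so the next skip sums without an adapter
    dec = []
    for j in range(n_enc):
        mirror = n_enc - 1 - j
        out_ch = _ENC_FILTERS[mirror - 1] if mirror > 0 else _ENC_FILTERS[0]
        dec.append(DecoderStageSpec(kernel_width=_LATER_KERNEL, n_filters=out_ch, mirror=mirror))
    if v["refine"]:
        dec.append(DecoderStageSpec(kernel_width=_LATER_KERNEL, n_filters=2, mirror=None))
    else:
        dec[-1] = DecoderStageSpec(kernel_width=_LATER_KERNEL, n_filters=2, mirror=0)
    return ModelConfig(
        input_length=input_length,
        encoder=enc,
        decoder=dec,
        use_global_avg_pool=use_global_avg_pool,
        variant=variant,
    )


class _EncoderStage:
    def __init__(self, in_ch: int, spec: EncoderStageSpec, rng: np.random.Generator,
                 drop_rng: np.random.Generator, name: str) -> None:
        self.conv = Conv1D(in_ch, spec.n_filters, spec.kernel_width, rng,
                           bias=spec.bias, name=f"{name}.conv")
        self.relu = ReLU()
        self.pool = MaxPool1D(spec.pool_factor)
        self.drop = Dropout(spec.dropout_rate, drop_rng)
        self.out_ch = spec.n_filters
        self.pre_pool_length: int | None = None
        self.skip: np.ndarray | None = None  # pre-pool activation, for the decoder
        self._skip_grad: np.ndarray | None = None

    def params(self) -> list[Param]:
        return self.conv.params()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        a = self.relu.forward(self.conv.forward(x, training), training)
        self.pre_pool_length = a.shape[1]
        self.skip = a
        self._skip_grad = None
        pooled = self.pool.forward(a, training)
        if pooled.shape[1] < 1:
            raise ValueError("pooled length would be 0; reduce pool factors")
        return self.drop.forward(pooled, training)

    def add_skip_grad(self, g: np.ndarray) -> None:
        self._skip_grad = g if self._skip_grad is None else self._skip_grad + g

    def backward(self, dout: np.ndarray) -> np.ndarray:
        da = self.pool.backward(self.drop.backward(dout))
        if self._skip_grad is not None:
            da = da + self._skip_grad
        return self.conv.backward(self.relu.backward(da))


class _DecoderStage:
    def __init__(self, in_ch: int, spec: DecoderStageSpec, skip_ch: int | None,
                 rng: np.random.Generator, name: str) -> None:
        self.spec = spec
        self.up: UpsampleNearest | None = None  # target bound at forward time
        self.adapter: Conv1D | None = None
        if skip_ch is not None and skip_ch != in_ch:
            self.adapter = Conv1D(skip_ch, in_ch, 1, rng, bias=False, name=f"{name}.adapter")
        self.bn = BatchNorm1D(in_ch, name=f"{name}.bn")
        self.relu = ReLU()
        self.conv = Conv1D(in_ch, spec.n_filters, spec.kernel_width, rng,
                           bias=spec.bias, name=f"{name}.conv")
        self.out_ch = spec.n_filters

    def params(self) -> list[Param]:
        ps = self.bn.params() + self.conv.params()
        if self.adapter is not None:
            ps = self.adapter.params() + ps
        return ps

    def forward(self, x: np.ndarray, skip: np.ndarray | None, target_length: int,
                training: bool) -> np.ndarray:
        self.up = UpsampleNearest(target_length)
        h = self.up.forward(x, training)
        self._had_skip = skip is not None
        if skip is not None:
            s = self.adapter.forward(skip, training) if self.adapter is not None else skip
            if s.shape != h.shape:
                raise ValueError(
                    f"skip shape {s.shape} irreconcilable with decoder stream {h.shape}"
                )
            h = h + s
        h = self.relu.forward(self.bn.forward(h, training), training)
        return self.conv.forward(h, training)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        dh = self.bn.backward(self.relu.backward(self.conv.backward(dout)))
        dskip = None
        if self._had_skip:
            dskip = self.adapter.backward(dh) if self.adapter is not None else dh
        return self.up.backward(dh), dskip


class FCNModel:
    """The full encoder-decoder; see the module docstring for the layout."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        if not config.encoder or not config.decoder:
            raise ValueError("config must define encoder and decoder stages")
        self.config = config
        self.seed = seed
        init_rng = np.random.default_rng((seed, 0))
        self.drop_rng = np.random.default_rng((seed, 1))

        self.enc_stages: list[_EncoderStage] = []
        in_ch = 4
        for i, spec in enumerate(config.encoder):
            st = _EncoderStage(in_ch, spec, init_rng, self.drop_rng, name=f"enc{i}")
            self.enc_stages.append(st)
            in_ch = st.out_ch
        self.context = GlobalContext() if config.use_global_avg_pool else None

        self.dec_stages: list[_DecoderStage] = []
        for j, spec in enumerate(config.decoder):
            skip_ch = (
                self.enc_stages[spec.mirror].out_ch if spec.mirror is not None else None
            )
            st = _DecoderStage(in_ch, spec, skip_ch, init_rng, name=f"dec{j}")
            self.dec_stages.append(st)
            in_ch = st.out_ch
        if in_ch != config.n_classes:
            raise ValueError(
                f"last decoder stage emits {in_ch} channels; expected {config.n_classes}"
            )

    # -- parameter access -------------------------------------------------
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for st in self.enc_stages:
            ps.extend(st.params())
        for st in self.dec_stages:
            ps.extend(st.params())
        return ps

    @property
    def first_conv_weights(self) -> np.ndarray:
        """(kernel_width, 4, n_filters) weights of the first encoder conv —
        the learned motif scanners used for motif extraction."""
        return self.enc_stages[0].conv.W.value

    # -- forward / backward ------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """One-hot batch (B, M, 4) -> per-site logits (B, M, 2)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[2] != 4:
            raise ValueError("input must have shape (batch, positions, 4)")
        h = X
        for st in self.enc_stages:
            h = st.forward(h, training)
        if self.context is not None:
            h = self.context.forward(h, training)
        for st in self.dec_stages:
            if st.spec.mirror is not None:
                enc = self.enc_stages[st.spec.mirror]
                target, skip = enc.pre_pool_length, enc.skip
            else:
                target, skip = h.shape[1], None
            h = st.forward(h, skip, target, training)
        if h.shape[1] != X.shape[1]:
            raise AssertionError("decoder failed to restore the input length")
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for st in reversed(self.dec_stages):
            g, dskip = st.backward(g)
            if dskip is not None:
                self.enc_stages[st.spec.mirror].add_skip_grad(dskip)
        if self.context is not None:
            g = self.context.backward(g)
        for st in reversed(self.enc_stages):
            g = st.backward(g)

    def predict(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-site hard labels (B, M) via argmax over the two classes."""
        outs = []
        for i in range(0, len(X), batch_size):
            logits = self.forward(X[i : i + batch_size], training=False)
            outs.append(logits.argmax(axis=2))
        return np.concatenate(outs, axis=0)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: npz of parameters + BN statistics with embedded config."""
        arrays = {p.name: p.value for p in self.params()}
        for j, st in enumerate(self.dec_stages):
            arrays[f"dec{j}.bn.running_mean"] = st.bn.running_mean
            arrays[f"dec{j}.bn.running_var"] = st.bn.running_var
        arrays["__config__"] = np.frombuffer(
            json.dumps({"config": self.config.to_dict(), "seed": self.seed}).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FCNModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__config__"]).decode())
        model = cls(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
        by_name = {p.name: p for p in model.params()}
        for name, p in by_name.items():
            p.value[...] = data[name]
        for j, st in enumerate(model.dec_stages):
            st.bn.running_mean[...] = data[f"dec{j}.bn.running_mean"]
            st.bn.running_var[...] = data[f"dec{j}.bn.running_var"]
        return model


def build_model(config: ModelConfig | str, seed: int = 0, **kwargs) -> FCNModel:
    """Build a model from a full config or a registered variant name."""
    if isinstance(config, str):
        config = make_config(config, **kwargs)
    return FCNModel(config, seed=seed)
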