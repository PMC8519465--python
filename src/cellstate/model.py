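"""The shared-encoder / per-cell-decoder denoising autoencoder.

Architecture: dropout on the input, an encoder of two leaky-ReLU dense
layers feeding a leaky-ReLU latent layer with an L1 activity penalty,
and one decoder per cell type whose two leaky-ReLU layers mirror the
encoder widths in reverse; the output layer adds a learned per-gene leak
of the (post-dropout) input vector to the dense pre-activation before
the tanh — a direct skip path that lets each input gene's value be
copied straight to its own output when the decoder cannot predict it.

Cross-cell prediction is encode-then-decode: the profile observed in any
cell type is encoded to the cell-neutral latent code and decoded with
the target cell's decoder.  All inference paths run with dropout off and
are deterministic given fixed weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from cellstate.errors import ConfigError, ContractError
from cellstate.nn import (
    Dense,
    ElementwiseScale,
    dropout_mask,
    leaky_relu,
    leaky_relu_grad,
)
from cellstate.profiles import GeneSpace, Profile


@dataclass
class ModelConfig:
    input_dim: int
    encoder_widths: tuple[int, ...] = (512, 256)
    latent_dim: int = 128
    decoder_widths: tuple[int, ...] | None = None  # defaults to reversed encoder
    dropout_rate: float = 0.5
    leaky_alpha: float = 0.2
    l1_latent: float = 1e-6
    learning_rate: float = 1e-4
    batch_size: int = 128
    patience: int = 5
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decoder_widths is None:
            self.decoder_widths = tuple(reversed(self.encoder_widths))
        self.encoder_widths = tuple(self.encoder_widths)
        self.decoder_widths = tuple(self.decoder_widths)
        if self.latent_dim >= self.input_dim:
            raise ConfigError(
                f"latent_dim ({self.latent_dim}) must be smaller than "
                f"input_dim ({self.input_dim})"
            )
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.l1_latent < 0 or self.learning_rate <= 0:
            raise ConfigError("invalid regularization or learning rate")


@dataclass
class LatentCode:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ContractError("latent code contains non-finite entries")


@dataclass
class TrainedModel:
    """Weights plus the gene space and normalization scale they assume."""

    config: ModelConfig
    gene_space: GeneSpace
    normalization_scale: float
    encoder: list[Dense]
    decoders: dict[str, list[Dense]]
    shared_decoder: list[Dense]
    training_log: list[dict] = field(default_factory=list)
    training_drugs: set[str] = field(default_factory=set)

    @property
    def cell_types(self) -> list[str]:
        return list(self.decoders)

    def copy(self) -> "TrainedModel":
        return TrainedModel(
            config=self.config,
            gene_space=self.gene_space,
            normalization_scale=self.normalization_scale,
            encoder=[l.copy() for l in self.encoder],
            decoders={c: [l.copy() for l in ls] for c, ls in self.decoders.items()},
            shared_decoder=[l.copy() for l in self.shared_decoder],
            training_log=list(self.training_log),
            training_drugs=set(self.training_drugs),
        )


def _make_decoder(rng: np.random.Generator, cfg: ModelConfig) -> list[Dense]:
    w1, w2 = cfg.decoder_widths
    return [
        Dense.init(rng, cfg.latent_dim, w1),
        Dense.init(rng, w1, w2),
        Dense.init(rng, w2, cfg.input_dim),
        ElementwiseScale.init(rng, cfg.input_dim),  # per-gene skip leak
    ]


def build_model(config: ModelConfig, cell_types: list[str],
                gene_space: GeneSpace | None = None,
                normalization_scale: float = 1.0) -> TrainedModel:
    """Construct an untrained model with one decoder per cell type.

    If ``gene_space`` is omitted a generic ``g0..g{G-1}`` space is used.
    """
    if not cell_types:
        raise ConfigError("at least one cell type required")
    if len(set(cell_types)) != len(cell_types):
        raise ConfigError("duplicate cell types")
    if gene_space is None:
        gene_space = GeneSpace(tuple(f"g{i}" for i in range(config.input_dim)))
    if len(gene_space) != config.input_dim:
        raise ConfigError("gene space size does not match input_dim")

    rng = np.random.default_rng(config.seed)
    e1, e2 = config.encoder_widths
    encoder = [
        Dense.init(rng, config.input_dim, e1),
        Dense.init(rng, e1, e2),
        Dense.init(rng, e2, config.latent_dim),
    ]
    shared = _make_decoder(rng, config)
    decoders = {c: _make_decoder(rng, config) for c in cell_types}
    return TrainedModel(
        config=config,
        gene_space=gene_space,
        normalization_scale=normalization_scale,
        encoder=encoder,
        decoders=decoders,
        shared_decoder=shared,
    )


def parameter_count(model: TrainedModel) -> int:
    """Weights + biases over the encoder and all per-cell decoders."""
    n = sum(l.n_params for l in model.encoder)
    for layers in model.decoders.values():
        n += sum(l.n_params for l in layers)
    return n


# ---------------------------------------------------------------------------
# forward / backward


def forward_batch(model: TrainedModel, X: np.ndarray, cell: str | None,
                  dropout_rng: np.random.Generator | None = None) -> dict:
    """Full forward pass; returns all intermediates needed for backprop.

    ``cell=None`` selects the shared (pretraining) decoder.  Dropout is
    applied to the input only when ``dropout_rng`` is given (training);
    the skip path branches after dropout.
    """
    cfg = model.config
    alpha = cfg.leaky_alpha
    if X.shape[1] != cfg.input_dim:
        raise ContractError(f"input has {X.shape[1]} genes, model expects {cfg.input_dim}")
    if dropout_rng is not None:
        Xd = X * dropout_mask(dropout_rng, X.shape, cfg.dropout_rate)
    else:
        Xd = X
    e1, e2, e3 = model.encoder
    a1 = e1.forward(Xd); h1 = leaky_relu(a1, alpha)
    a2 = e2.forward(h1); h2 = leaky_relu(a2, alpha)
    a3 = e3.forward(h2); z = leaky_relu(a3, alpha)
    decoder = model.shared_decoder if cell is None else _get_decoder(model, cell)
    d1, d2, d3, skip = decoder
    b1 = d1.forward(z); u1 = leaky_relu(b1, alpha)
    b2 = d2.forward(u1); u2 = leaky_relu(b2, alpha)
    y = np.tanh(d3.forward(u2) + skip.forward(Xd))
    return dict(Xd=Xd, a1=a1, h1=h1, a2=a2, h2=h2, a3=a3, z=z,
                b1=b1, u1=u1, b2=b2, u2=u2, y=y, decoder=decoder)


def backward_batch(model: TrainedModel, cache: dict, gY: np.ndarray,
                   gZ_extra: np.ndarray | None = None) -> np.ndarray:
    """Backprop dL/dy through decoder, skip path and encoder.

    Accumulates parameter gradients in place and returns dL/d(post-dropout
    input), summing the encoder and skip contributions.  ``gZ_extra``
    (e.g. the L1 sparsity term) is added to the latent gradient.
    """
    alpha = model.config.leaky_alpha
    e1, e2, e3 = model.encoder
    d1, d2, d3, skip = cache["decoder"]

    g3 = gY * (1.0 - cache["y"] ** 2)
    gu2 = d3.backward(cache["u2"], g3)
    gskip = skip.backward(cache["Xd"], g3)
    gb2 = gu2 * leaky_relu_grad(cache["b2"], alpha)
    gu1 = d2.backward(cache["u1"], gb2)
    gb1 = gu1 * leaky_relu_grad(cache["b1"], alpha)
    gz = d1.backward(cache["z"], gb1)
    if gZ_extra is not None:
        gz = gz + gZ_extra
    ga3 = gz * leaky_relu_grad(cache["a3"], alpha)
    gh2 = e3.backward(cache["h2"], ga3)
    ga2 = gh2 * leaky_relu_grad(cache["a2"], alpha)
    gh1 = e2.backward(cache["h1"], ga2)
    ga1 = gh1 * leaky_relu_grad(cache["a1"], alpha)
    gX = e1.backward(cache["Xd"], ga1)
    return gX + gskip


def _get_decoder(model: TrainedModel, cell: str) -> list[Dense]:
    try:
        return model.decoders[cell]
    except KeyError:
        raise ContractError(
            f"no decoder for cell type {cell!r}; available: {sorted(model.decoders)}"
        ) from None


# ---------------------------------------------------------------------------
# inference


def encode_batch(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    alpha = model.config.leaky_alpha
    if X.ndim != 2 or X.shape[1] != model.config.input_dim:
        raise ContractError(
            f"expected (n, {model.config.input_dim}) input, got {X.shape}"
        )
    e1, e2, e3 = model.encoder
    h1 = leaky_relu(e1.forward(X), alpha)
    h2 = leaky_relu(e2.forward(h1), alpha)
    return leaky_relu(e3.forward(h2), alpha)


def decode_batch(model: TrainedModel, Z: np.ndarray, Xskip: np.ndarray,
                 cell: str) -> np.ndarray:
    alpha = model.config.leaky_alpha
    d1, d2, d3, skip = _get_decoder(model, cell)
    u1 = leaky_relu(d1.forward(Z), alpha)
    u2 = leaky_relu(d2.forward(u1), alpha)
    return np.tanh(d3.forward(u2) + skip.forward(Xskip))


def predict_batch(model: TrainedModel, X: np.ndarray, cell: str) -> np.ndarray:
    """encode + decode for a stack of profiles, dropout off."""
    return decode_batch(model, encode_batch(model, X), X, cell)


def encode(model: TrainedModel, profile: Profile) -> LatentCode:
    """Map one profile to its cell-neutral latent code (deterministic)."""
    if len(profile.values) != model.config.input_dim:
        raise ContractError(
            f"profile has {len(profile.values)} genes, model expects "
            f"{model.config.input_dim}"
        )
    return LatentCode(encode_batch(model, profile.values[None, :])[0])


def decode(model: TrainedModel, code: LatentCode, skip_input: Profile,
           cell_type: str) -> Profile:
    """Decode a latent code with one cell's decoder (deterministic).

    ``skip_input`` supplies the vector fed to the output layer's direct
    input connection; at inference this is the full, un-dropped profile.
    """
    if len(skip_input.values) != model.config.input_dim:
        raise ContractError("skip input does not match model gene space size")
    y = decode_batch(model, code.values[None, :], skip_input.values[None, :], cell_type)[0]
    return Profile(values=y, perturbagen_id=skip_input.perturbagen_id,
                   cell_type=cell_type, perturbagen_type=skip_input.perturbagen_type)


def predict_response(model: TrainedModel, input_profile: Profile,
                     target_cell: str) -> Profile:
    """Predict the target cell's response from another cell's profile.

    The input may come from any cell type, including one never seen in
    training.
    """
    return decode(model, encode(model, input_profile), input_profile, target_cell)


def predict_multi(model: TrainedModel, inputs: dict[str, Profile],
                  target_cell: str) -> Profile:
    """Per-gene mean of single-cell predictions over several input cells."""
    if not inputs:
        raise ContractError("predict_multi needs at least one input profile")
    preds = [predict_response(model, p, target_cell).values for p in inputs.values()]
    first = next(iter(inputs.values()))
    return Profile(values=np.mean(preds, axis=0),
                   perturbagen_id=first.perturbagen_id, cell_type=target_cell,
                   perturbagen_type=first.perturbagen_type)


def input_gradient(model: TrainedModel, x: np.ndarray, cell: str,
                   gene_index: int) -> np.ndarray:
    """d output[gene_index] / d input, dropout off, weights untouched."""
    cache = forward_batch(model, x[None, :], cell)
    gY = np.zeros_like(cache["y"])
    gY[0, gene_index] = 1.0
    saved = [(l.gW.copy(), l.gb.copy()) for l in _all_layers(model)]
    g = backward_batch(model, cache, gY)[0]
    for l, (gW, gb) in zip(_all_layers(model), saved):  # restore accumulators
        l.gW[...] = gW
        l.gb[...] = gb
    if not np.all(np.isfinite(g)):
        raise ContractError("non-finite input gradient")
    return g


def _all_layers(model: TrainedModel) -> list[Dense]:
    layers = list(model.encoder) + list(model.shared_decoder)
    for ls in model.decoders.values():
        layers += ls
    return layers


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedModel, path: str) -> None:
    """Write the model as a single NPZ archive (bit-exact round trip)."""
    meta = {
        "config": asdict(model.config),
        "cell_types": model.cell_types,
        "gene_space": list(model.gene_space.genes),
        "normalization_scale": model.normalization_scale,
        "training_log": model.training_log,
        "training_drugs": sorted(model.training_drugs),
    }
    arrays: dict[str, np.ndarray] = {
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    }
    for i, l in enumerate(model.encoder):
        arrays[f"enc{i}_W"], arrays[f"enc{i}_b"] = l.W, l.b
    for i, l in enumerate(model.shared_decoder):
        arrays[f"shared{i}_W"], arrays[f"shared{i}_b"] = l.W, l.b
    for ci, cell in enumerate(model.cell_types):
        for i, l in enumerate(model.decoders[cell]):
            arrays[f"dec{ci}_{i}_W"], arrays[f"dec{ci}_{i}_b"] = l.W, l.b
    np.savez(path, **arrays)


def load_model(path: str) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg = meta["config"]
        cfg["encoder_widths"] = tuple(cfg["encoder_widths"])
        cfg["decoder_widths"] = tuple(cfg["decoder_widths"])
        config = ModelConfig(**cfg)
        def make(kind, prefix, i):
            return kind(W=data[f"{prefix}{i}_W"].copy(), b=data[f"{prefix}{i}_b"].copy())

        def decoder_layers(prefix):
            return [make(Dense, prefix, i) for i in range(3)] + \
                   [make(ElementwiseScale, prefix, 3)]

        encoder = [make(Dense, "enc", i) for i in range(3)]
        shared = decoder_layers("shared")
        decoders = {cell: decoder_layers(f"dec{ci}_")
                    for ci, cell in enumerate(meta["cell_types"])}
    return TrainedModel(
        config=config,
        gene_space=GeneSpace(tuple(meta["gene_space"])),
        normalization_scale=meta["normalization_scale"],
        encoder=encoder,
        decoders=decoders,
        shared_decoder=shared,
        training_log=meta["training_log"],
        training_drugs=set(meta["training_drugs"]),
    )
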