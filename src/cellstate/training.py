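"""Three-stage training protocol and transfer fine-tuning.

Stage 1 trains a plain denoising autoencoder (shared encoder + one
shared decoder) on profiles of every cell type, input = target.  Stage 2
copies the shared decoder into one decoder per cell type and trains them
round-robin together with the encoder, each decoder seeing (profile of
drug d in any cell x -> profile of d in its own cell).  Stage 3 freezes
the encoder and continues training the decoders alone.  Every stage uses
validation-loss early stopping with best-weights restoration; the
validation split is by drug, never by profile, so no drug leaks across
cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cellstate.errors import ContractError
from cellstate.model import TrainedModel, backward_batch, forward_batch, predict_batch
from cellstate.nn import Adam, Dense
from cellstate.profiles import PairedSet


@dataclass
class TrainingPlan:
    paired: PairedSet
    validation_fraction: float = 0.1
    stage_order: list[str] = field(default_factory=list)
    seed: int = 0
    #: optional cell -> fraction of training drugs KEPT for that cell's profiles
    subsample: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stage_order:
            self.stage_order = list(self.paired.cell_types)
        unknown = [c for c in self.stage_order if c not in self.paired.cell_types]
        if unknown:
            raise ContractError(f"stage_order cells not in paired set: {unknown}")
        if not (0 < self.validation_fraction < 1):
            raise ContractError("validation_fraction must be in (0, 1)")
        if len(self.paired.drugs) < 2:
            raise ContractError("need at least 2 drugs to split off validation")

    def split_drugs(self) -> tuple[list[str], list[str]]:
        """Seeded by-drug split into (training drugs, validation drugs)."""
        rng = np.random.default_rng(self.seed)
        drugs = list(self.paired.drugs)
        order = rng.permutation(len(drugs))
        n_val = max(1, int(round(self.validation_fraction * len(drugs))))
        n_val = min(n_val, len(drugs) - 1)
        val = [drugs[i] for i in order[:n_val]]
        train = [drugs[i] for i in order[n_val:]]
        return train, val

    def drugs_for_cell(self, cell: str, drugs: list[str]) -> list[str]:
        """Seeded per-cell subsample of training drugs (all kept by default)."""
        frac = self.subsample.get(cell)
        if frac is None:
            return list(drugs)
        if not (0 < frac <= 1):
            raise ContractError(f"subsample fraction for {cell!r} must be in (0, 1]")
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 97, self.paired.cell_types.index(cell)])
        )
        keep = max(1, int(round(frac * len(drugs))))
        idx = sorted(rng.permutation(len(drugs))[:keep])
        return [drugs[i] for i in idx]


def _batch_size(cfg, n: int) -> int:
    if n < cfg.batch_size:
        warnings.warn(
            f"dataset size {n} below batch size {cfg.batch_size}; using {n}",
            stacklevel=3,
        )
        return n
    return cfg.batch_size


def _train_batch(model: TrainedModel, X: np.ndarray, T: np.ndarray,
                 cell: str | None, optimizers: list[Adam],
                 trained_layers: list[Dense],
                 dropout_rng: np.random.Generator) -> float:
    """One gradient step; returns the batch reconstruction MSE."""
    cfg = model.config
    cache = forward_batch(model, X, cell, dropout_rng=dropout_rng)
    y, z = cache["y"], cache["z"]
    n = X.shape[0]
    gY = 2.0 * (y - T) / (n * y.shape[1])
    gz_extra = cfg.l1_latent * np.sign(z) / n if cfg.l1_latent > 0 else None
    backward_batch(model, cache, gY, gZ_extra=gz_extra)
    for opt in optimizers:
        opt.step()
    for layer in trained_layers:
        layer.zero_grad()
    return float(np.mean((y - T) ** 2))


def _mse(model: TrainedModel, X: np.ndarray, T: np.ndarray, cell: str | None) -> float:
    if cell is None:
        cache = forward_batch(model, X, None)
        y = cache["y"]
    else:
        y = predict_batch(model, X, cell)
    return float(np.mean((y - T) ** 2))


def _snapshot(layers: list[Dense]) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(l.W.copy(), l.b.copy()) for l in layers]


def _restore(layers: list[Dense], snap) -> None:
    for l, (W, b) in zip(layers, snap):
        l.W[...] = W
        l.b[...] = b


def pretrain_joint_autoencoder(model: TrainedModel, plan: TrainingPlan) -> TrainedModel:
    """Stage 1: identity reconstruction with all cell types pooled."""
    cfg = model.config
    paired = plan.paired
    train_drugs, val_drugs = plan.split_drugs()
    X = np.concatenate(
        [paired.subset(plan.drugs_for_cell(c, train_drugs)).matrix(c)
         for c in paired.cell_types]
    )
    Xval = np.concatenate([paired.subset(val_drugs).matrix(c) for c in paired.cell_types])

    layers = list(model.encoder) + list(model.shared_decoder)
    opt = Adam(layers, cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 1]))
    bs = _batch_size(cfg, X.shape[0])

    best = np.inf
    best_snap = _snapshot(layers)
    bad = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(X.shape[0])
        losses = []
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            losses.append(_train_batch(model, X[idx], X[idx], None, [opt], layers, rng))
        val = _mse(model, Xval, Xval, None)
        model.training_log.append(dict(epoch=epoch, stage=1, cell="shared",
                                       train_mse=float(np.mean(losses)), val_mse=val))
        if val < best - 1e-12:
            best, best_snap, bad = val, _snapshot(layers), 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    _restore(layers, best_snap)
    model.training_drugs.update(train_drugs)
    return model


def _stage_pairs(paired: PairedSet, drugs: list[str], cell: str,
                 plan: TrainingPlan | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Cross-cell training pairs for one decoder: (any cell -> cell).

    With a plan carrying per-cell subsampling, a (x -> cell) pair for
    drug d survives only if d is kept for both cells.
    """
    if plan is None or not plan.subsample:
        sub = paired.subset(drugs)
        T_own = sub.matrix(cell)
        X = np.concatenate([sub.matrix(c) for c in paired.cell_types])
        T = np.concatenate([T_own] * len(paired.cell_types))
        return X, T
    drugs_c = set(plan.drugs_for_cell(cell, drugs))
    Xs, Ts = [], []
    for x_cell in paired.cell_types:
        pair_drugs = [d for d in plan.drugs_for_cell(x_cell, drugs) if d in drugs_c]
        if not pair_drugs:
            continue
        sub = paired.subset(pair_drugs)
        Xs.append(sub.matrix(x_cell))
        Ts.append(sub.matrix(cell))
    if not Xs:
        raise ContractError(f"subsampling left no training pairs for cell {cell!r}")
    return np.concatenate(Xs), np.concatenate(Ts)


def _pooled_val(model: TrainedModel, paired: PairedSet, val_drugs: list[str]) -> float:
    total, n = 0.0, 0
    for cell in paired.cell_types:
        X, T = _stage_pairs(paired, val_drugs, cell)
        total += float(np.sum((predict_batch(model, X, cell) - T) ** 2))
        n += T.size
    return total / n


def _train_decoders(model: TrainedModel, plan: TrainingPlan, stage: int,
                    update_encoder: bool, seed_stream: int) -> None:
    """Round-robin decoder training shared by stages 2, 3 and fine-tuning."""
    cfg = model.config
    paired = plan.paired
    train_drugs, val_drugs = plan.split_drugs()
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, seed_stream]))

    enc_layers = list(model.encoder)
    opt_enc = Adam(enc_layers, cfg.learning_rate) if update_encoder else None
    opts = {c: Adam(list(model.decoders[c]), cfg.learning_rate)
            for c in plan.stage_order}
    data = {c: _stage_pairs(paired, train_drugs, c, plan) for c in plan.stage_order}

    watched = ([l for c in plan.stage_order for l in model.decoders[c]]
               + (enc_layers if update_encoder else []))
    best = np.inf
    best_snap = _snapshot(watched)
    bad = 0
    for epoch in range(cfg.max_epochs):
        for cell in plan.stage_order:
            X, T = data[cell]
            bs = _batch_size(cfg, X.shape[0])
            order = rng.permutation(X.shape[0])
            losses = []
            trained = list(model.decoders[cell]) + enc_layers
            optimizers = [opts[cell]] + ([opt_enc] if opt_enc else [])
            for start in range(0, len(order), bs):
                idx = order[start:start + bs]
                losses.append(_train_batch(model, X[idx], T[idx], cell,
                                           optimizers, trained, rng))
            val = _pooled_val(model, paired, val_drugs)
            model.training_log.append(dict(epoch=epoch, stage=stage, cell=cell,
                                           train_mse=float(np.mean(losses)),
                                           val_mse=val))
        val = _pooled_val(model, paired, val_drugs)
        if val < best - 1e-12:
            best, best_snap, bad = val, _snapshot(watched), 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    _restore(watched, best_snap)
    model.training_drugs.update(train_drugs)


def train_cell_decoders(model: TrainedModel, plan: TrainingPlan) -> TrainedModel:
    """Stages 2 and 3 on a pretrained model.

    Decoders start as copies of the pretrained shared decoder; stage 2
    trains each decoder round-robin jointly with the encoder; stage 3
    freezes the encoder and continues on the decoders until validation
    stops improving.  Best-validation weights are restored after each
    stage.
    """
    missing = [c for c in plan.stage_order if c not in model.decoders]
    if missing:
        raise ContractError(f"model lacks decoders for: {missing}")
    for cell in plan.stage_order:
        for dst, src in zip(model.decoders[cell], model.shared_decoder):
            dst.W[...] = src.W
            dst.b[...] = src.b
    _train_decoders(model, plan, stage=2, update_encoder=True, seed_stream=2)
    _train_decoders(model, plan, stage=3, update_encoder=False, seed_stream=3)
    return model


def transfer_finetune(model: TrainedModel, small_set: PairedSet,
                      held_out_drug: str, validation_fraction: float = 0.2,
                      seed: int = 0) -> TrainedModel:
    """Continue stage-2-style training on a small external set.

    ``held_out_drug`` is excluded from all fine-tuning pairs; the
    original model is left unchanged and a fine-tuned copy is returned.
    """
    if held_out_drug not in small_set.drugs:
        raise ContractError(f"held-out drug {held_out_drug!r} not in the small set")
    extra = [c for c in small_set.cell_types if c not in model.decoders]
    if extra:
        raise ContractError(f"small set has cells without decoders: {extra}")
    tuned = model.copy()
    rest = [d for d in small_set.drugs if d != held_out_drug]
    plan = TrainingPlan(paired=small_set.subset(rest),
                        validation_fraction=validation_fraction,
                        stage_order=list(small_set.cell_types), seed=seed)
    finetune_drugs = set(plan.split_drugs()[0])
    if held_out_drug in finetune_drugs:
        raise ContractError("held-out drug leaked into fine-tuning pairs")
    if tuned.config.max_epochs > 0:
        _train_decoders(tuned, plan, stage=2, update_encoder=True, seed_stream=4)
    else:
        tuned.training_drugs.update(finetune_drugs)
    return tuned
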