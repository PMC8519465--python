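"""Interpretation of a trained model.

Four procedures: (1) a latent alignment matrix showing that the same
drug encodes similarly across cell types even when the raw profiles do
not correlate; (2) TF-target inference by gradient ascent on the input —
find the input profile that maximizes one gene's value in a target-cell
decoder and read the other top-activated genes as predicted targets;
(3) an exact binomial enrichment statistic for the overlap between a
predicted and a reference gene set; (4) decoder gene importance by
scoring many random masked input subsets and ranking genes by how often
they occur in the best-performing subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from cellstate.errors import ContractError
from cellstate.evaluation import pearson_cc
from cellstate.model import (
    TrainedModel,
    encode_batch,
    input_gradient,
    predict_batch,
)
from cellstate.profiles import PairedSet, Profile, ProfileSet


@dataclass
class LatentAlignmentMatrix:
    drugs: list[str]                # sorted by descending input-space diagonal
    matrix: np.ndarray              # latent-space PCCs, |drugs| x |drugs|
    input_matrix: np.ndarray        # input-space PCCs, same shape/order

    def diagonal_mean(self) -> float:
        return float(np.mean(np.diag(self.matrix)))

    def off_diagonal_mean(self) -> float:
        mask = ~np.eye(len(self.drugs), dtype=bool)
        return float(np.mean(self.matrix[mask]))

    def input_diagonal_mean(self) -> float:
        return float(np.mean(np.diag(self.input_matrix)))


@dataclass
class TFTargetPrediction:
    tf: str
    optimized_profile: Profile
    predicted_targets: list[str]
    objective_trace: list[float] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    overlap: int
    expected: float
    fold: float
    p_value: float


@dataclass
class ImportanceRanking:
    counts: dict[str, int]
    ranked: list[str]


def _cross_pcc_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """PCC of every row of A against every row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(Ac, axis=1)
    sb = np.linalg.norm(Bc, axis=1)
    if np.any(sa == 0) or np.any(sb == 0):
        raise ContractError("zero variance: correlation undefined")
    return np.clip((Ac @ Bc.T) / np.outer(sa, sb), -1.0, 1.0)


def latent_alignment(model: TrainedModel, paired_test: PairedSet,
                     cellA: str, cellB: str) -> LatentAlignmentMatrix:
    """Drug x drug latent-code correlations between two cell types.

    Entry (i, j) correlates drug i's latent code in ``cellA`` with drug
    j's code in ``cellB``; ``input_matrix`` is the analogue on the raw
    profiles.  Rows/columns are sorted by descending input-space
    diagonal, so a strong latent diagonal on the right half of the order
    shows alignment even where the inputs disagree.
    """
    for c in (cellA, cellB):
        if c not in paired_test.cell_types:
            raise ContractError(f"cell {c!r} not in test set")
    XA = paired_test.matrix(cellA)
    XB = paired_test.matrix(cellB)
    input_m = _cross_pcc_matrix(XA, XB)
    latent_m = _cross_pcc_matrix(encode_batch(model, XA), encode_batch(model, XB))

    order = np.argsort(-np.diag(input_m), kind="stable")
    return LatentAlignmentMatrix(
        drugs=[paired_test.drugs[i] for i in order],
        matrix=latent_m[np.ix_(order, order)],
        input_matrix=input_m[np.ix_(order, order)],
    )


def predict_tf_targets(model: TrainedModel, tf: str, target_cell: str,
                       n_targets: int = 50, steps: int = 500,
                       step_size: float = 0.1, init_scale: float = 0.1,
                       seed: int = 0) -> TFTargetPrediction:
    """Infer a TF's targets by gradient ascent on the model input.

    Starting from a small seeded random profile, the input is updated to
    maximize the TF gene's value in the target-cell decoder output
    (weights frozen), clipping to [-1, 1] after every step and halving
    the step size whenever a step would decrease the objective.  The
    ``n_targets`` highest-valued genes of the optimized input profile —
    excluding the TF itself — are the predicted targets.
    """
    gi = model.gene_space.index_of(tf)
    rng = np.random.default_rng(seed)
    g = len(model.gene_space)
    x = rng.uniform(-init_scale, init_scale, size=g)

    def objective(v: np.ndarray) -> float:
        return float(predict_batch(model, v[None, :], target_cell)[0, gi])

    obj = objective(x)
    trace = [obj]
    lr = step_size
    for _ in range(steps):
        grad = input_gradient(model, x, target_cell, gi)
        candidate = np.clip(x + lr * grad, -1.0, 1.0)
        cand_obj = objective(candidate)
        if cand_obj >= obj:
            x, obj = candidate, cand_obj
        else:
            lr *= 0.5
            if lr < 1e-8:
                break
        trace.append(obj)

    order = np.argsort(-x, kind="stable")  # ties broken by gene order
    targets = [model.gene_space.genes[i] for i in order if i != gi][:n_targets]
    profile = Profile(values=x, perturbagen_id=f"opt:{tf}", cell_type=target_cell,
                      perturbagen_type="other")
    return TFTargetPrediction(tf=tf, optimized_profile=profile,
                              predicted_targets=targets, objective_trace=trace)


def filter_tfs(tf_targets: dict[str, list[tuple[str, float]]],
               profiles: ProfileSet, min_targets: int = 50,
               score_min: float = 100.0, upreg_min: float = 0.5
               ) -> dict[str, list[str]]:
    """Keep TFs that are upregulated somewhere and well-covered by targets.

    A TF survives if (a) its value exceeds ``upreg_min`` in at least one
    profile and (b) it has at least ``min_targets`` reference targets
    with binding score >= ``score_min``.  Survivors map to their top
    ``min_targets`` targets by descending score (ties by target name).
    """
    out: dict[str, list[str]] = {}
    for tf, scored in tf_targets.items():
        if tf not in profiles.gene_space:
            continue
        gi = profiles.gene_space.index_of(tf)
        if not any(p.values[gi] > upreg_min for p in profiles):
            continue
        strong = [(t, s) for t, s in scored if s >= score_min]
        if len(strong) < min_targets:
            continue
        strong.sort(key=lambda ts: (-ts[1], ts[0]))
        out[tf] = [t for t, _ in strong[:min_targets]]
    return out


def binomial_enrichment(predicted: set[str], reference: set[str],
                        universe_size: int) -> EnrichmentResult:
    """Exact binomial enrichment of the overlap between two gene sets.

    With n = |predicted| draws and per-draw success probability
    |reference| / universe_size, the p-value is the upper-tail
    probability of at least the observed overlap.
    """
    if not predicted:
        raise ContractError("empty predicted set")
    if universe_size < len(predicted | reference):
        raise ContractError("universe smaller than the union of the sets")
    overlap = len(predicted & reference)
    p_success = len(reference) / universe_size
    expected = len(predicted) * p_success
    fold = overlap / expected if expected > 0 else float("inf")
    # P(X >= overlap), exact
    p_value = float(stats.binom.sf(overlap - 1, len(predicted), p_success))
    return EnrichmentResult(overlap=overlap, expected=expected, fold=fold,
                            p_value=min(p_value, 1.0))


def decoder_gene_importance(model: TrainedModel, paired: PairedSet,
                            input_cell: str, target_cell: str,
                            n_subsets: int = 100, subset_size: int = 100,
                            top_k: int = 10, seed: int = 0) -> ImportanceRanking:
    """Rank genes by how often they appear in the best masked subsets.

    Per drug: draw ``n_subsets`` random gene subsets of ``subset_size``;
    keep only subset genes of the input profile (others zeroed, dropout
    off), predict the target cell response, and score by PCC against the
    observed target profile.  The genes of the ``top_k`` best subsets per
    drug are counted; the ranking sorts by descending count (ties by
    gene order).
    """
    g = len(model.gene_space)
    if subset_size > g:
        raise ContractError(f"subset_size {subset_size} exceeds {g} genes")
    if top_k > n_subsets:
        raise ContractError("top_k cannot exceed n_subsets")
    for c in (input_cell, target_cell):
        if c not in paired.cell_types:
            raise ContractError(f"cell {c!r} not in the data")

    rng = np.random.default_rng(seed)
    counts = np.zeros(g, dtype=np.int64)
    for drug in paired.drugs:
        x = paired.profile(drug, input_cell).values
        truth = paired.profile(drug, target_cell).values
        subsets = np.stack([rng.choice(g, size=subset_size, replace=False)
                            for _ in range(n_subsets)])
        masked = np.zeros((n_subsets, g))
        rows = np.arange(n_subsets)[:, None]
        masked[rows, subsets] = x[subsets]
        preds = predict_batch(model, masked, target_cell)
        scores = np.array([pearson_cc(pred, truth) for pred in preds])
        best = np.argsort(-scores, kind="stable")[:top_k]
        for b in best:
            counts[subsets[b]] += 1

    genes = model.gene_space.genes
    ranked_idx = sorted(range(g), key=lambda i: (-counts[i], i))
    return ImportanceRanking(
        counts={genes[i]: int(counts[i]) for i in range(g)},
        ranked=[genes[i] for i in ranked_idx],
    )
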