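"""Baseline, per-drug metrics, fold-change and cross-validation schemes.

The baseline for predicting a drug's response in a target cell is the
observed response to the same drug in the input cell; both the model
prediction and the baseline are scored by Pearson correlation against
the measured target-cell profile, and fold-change is their ratio.
Cross-validation holds out drugs (or whole drug families sharing a mode
of action) so the model is always scored on perturbations it never saw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from cellstate.errors import ContractError
from cellstate.model import (
    ModelConfig,
    TrainedModel,
    build_model,
    predict_multi,
)
from cellstate.profiles import PairedSet, Profile
from cellstate.training import TrainingPlan, pretrain_joint_autoencoder, train_cell_decoders

#: baselines at or below this magnitude make fold-change undefined
FOLD_CHANGE_EPS = 0.01


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; raises on unequal length or zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError(f"incompatible shapes {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ContractError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        raise ContractError("zero variance: correlation undefined")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def baseline_pcc(input_profile: Profile, truth: Profile) -> float:
    """Score of the copy-the-other-cell baseline."""
    if len(input_profile.values) != len(truth.values):
        raise ContractError("profiles are on different gene spaces")
    return pearson_cc(input_profile.values, truth.values)


def fold_change(pcc_pred: float, pcc_baseline: float,
                eps: float = FOLD_CHANGE_EPS) -> float | None:
    """pcc_pred / pcc_baseline, or None when the baseline is ~zero."""
    if pcc_baseline <= eps:
        return None
    return pcc_pred / pcc_baseline


@dataclass(frozen=True)
class EvalRow:
    drug: str
    input_cell: str
    target_cell: str
    pcc_pred: float
    pcc_baseline: float
    fold_change: float | None


@dataclass
class EvalReport:
    rows: list[EvalRow]
    n_skipped: int = 0

    @property
    def mean_pcc_pred(self) -> float:
        return float(np.mean([r.pcc_pred for r in self.rows]))

    @property
    def mean_pcc_baseline(self) -> float:
        return float(np.mean([r.pcc_baseline for r in self.rows]))

    @property
    def mean_fold_change(self) -> float:
        defined = [r.fold_change for r in self.rows if r.fold_change is not None]
        if not defined:
            return float("nan")
        return float(np.mean(defined))

    @property
    def p_value(self) -> float:
        """Two-sided paired t-test of per-row prediction vs baseline PCC."""
        preds = np.array([r.pcc_pred for r in self.rows])
        bases = np.array([r.pcc_baseline for r in self.rows])
        if len(preds) < 3:
            return float("nan")
        return float(stats.ttest_rel(preds, bases).pvalue)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def summary(self) -> dict:
        return {
            "n_rows": len(self.rows),
            "n_skipped": self.n_skipped,
            "mean_pcc_pred": self.mean_pcc_pred,
            "mean_pcc_baseline": self.mean_pcc_baseline,
            "mean_fold_change": self.mean_fold_change,
            "p_value": self.p_value,
        }

    @classmethod
    def merge(cls, reports: "list[EvalReport]") -> "EvalReport":
        return cls(rows=[r for rep in reports for r in rep.rows],
                   n_skipped=sum(rep.n_skipped for rep in reports))


def evaluate_predictions(model: TrainedModel, test_block: PairedSet,
                         input_cells: list[str], target_cell: str) -> EvalReport:
    """Score multi-input predictions against the target-cell ground truth.

    One row per test drug: the prediction is the mean over single-cell
    predictions from ``input_cells``; the baseline PCC is computed per
    input cell and averaged.
    """
    if target_cell not in test_block.cell_types:
        raise ContractError(f"target cell {target_cell!r} not in the test block")
    bad = [c for c in input_cells if c not in test_block.cell_types]
    if bad:
        raise ContractError(f"input cells not in the test block: {bad}")
    if not input_cells:
        raise ContractError("need at least one input cell")
    overlap = set(test_block.drugs) & model.training_drugs
    if overlap:
        raise ContractError(f"test drugs seen in training: {sorted(overlap)[:5]}")

    label = "+".join(input_cells)
    rows: list[EvalRow] = []
    n_skipped = 0
    for drug in test_block.drugs:
        truth = test_block.profile(drug, target_cell)
        inputs = {c: test_block.profile(drug, c) for c in input_cells}
        try:
            pred = predict_multi(model, inputs, target_cell)
            pcc_pred = pearson_cc(pred.values, truth.values)
            pcc_base = float(np.mean([baseline_pcc(p, truth) for p in inputs.values()]))
        except ContractError as exc:
            warnings.warn(f"skipping drug {drug}: {exc}", stacklevel=2)
            n_skipped += 1
            continue
        rows.append(EvalRow(drug, label, target_cell, pcc_pred, pcc_base,
                            fold_change(pcc_pred, pcc_base)))
    return EvalReport(rows=rows, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# cross-validation


def partition_drugs(drugs: list[str], k: int, seed: int,
                    families: dict[str, str] | None = None) -> list[list[str]]:
    """Split drugs into k disjoint folds; families are never split.

    Drugs without a family entry are singleton families.  Families are
    shuffled with the seed and assigned greedily to the currently
    smallest fold, so oversized families simply make their fold larger
    (logged via a warning).
    """
    if k < 2:
        raise ContractError("k must be at least 2")
    if len(drugs) < k:
        raise ContractError(f"cannot make {k} folds from {len(drugs)} drugs")
    families = families or {}
    groups: dict[str, list[str]] = {}
    for d in drugs:
        groups.setdefault(families.get(d, f"__singleton__{d}"), []).append(d)

    rng = np.random.default_rng(seed)
    keys = list(groups)
    order = rng.permutation(len(keys))
    folds: list[list[str]] = [[] for _ in range(k)]
    target = len(drugs) / k
    for i in order:
        members = groups[keys[i]]
        if len(members) > target:
            warnings.warn(
                f"family {keys[i]!r} ({len(members)} drugs) exceeds the nominal "
                f"fold size {target:.1f}; folds rebalanced", stacklevel=2)
        smallest = min(range(k), key=lambda j: (len(folds[j]), j))
        folds[smallest].extend(members)
    return [f for f in folds]


def _train_on(data: PairedSet, train_drugs: list[str], config: ModelConfig,
              seed: int, validation_fraction: float,
              subsample: dict[str, float] | None) -> TrainedModel:
    model = build_model(config, list(data.cell_types), gene_space=data.gene_space,
                        normalization_scale=data.normalization_scale or 1.0)
    plan = TrainingPlan(paired=data.subset(train_drugs),
                        validation_fraction=validation_fraction,
                        seed=seed, subsample=dict(subsample or {}))
    pretrain_joint_autoencoder(model, plan)
    train_cell_decoders(model, plan)
    return model


def _eval_directions(model: TrainedModel, test_block: PairedSet) -> EvalReport:
    """Single-input rows for every ordered (input cell -> target cell) pair."""
    reports = []
    for target in test_block.cell_types:
        for inp in test_block.cell_types:
            if inp == target:
                continue
            reports.append(evaluate_predictions(model, test_block, [inp], target))
    return EvalReport.merge(reports)


def crossval_by_drug(data: PairedSet, k: int = 10,
                     config: ModelConfig | None = None, seed: int = 0,
                     families: dict[str, str] | None = None,
                     validation_fraction: float = 0.1,
                     subsample: dict[str, float] | None = None,
                     ) -> tuple[list[EvalReport], EvalReport]:
    """k-fold drug-holdout cross-validation.

    Per fold a fresh model is trained on the remaining drugs (with an
    internal by-drug validation split for early stopping) and evaluated
    on the held-out drugs in every input->target direction.  Returns the
    per-fold reports and the pooled report.  Supplying ``families``
    delegates to :func:`holdout_families`.
    """
    if families is not None:
        return holdout_families(data, families, k=k, config=config, seed=seed,
                                validation_fraction=validation_fraction,
                                subsample=subsample)
    if config is None:
        config = ModelConfig(input_dim=len(data.gene_space))
    folds = partition_drugs(list(data.drugs), k, seed)
    reports = []
    all_drugs = set(data.drugs)
    for i, test_drugs in enumerate(folds):
        train_drugs = [d for d in data.drugs if d not in set(test_drugs)]
        assert set(test_drugs).isdisjoint(train_drugs)
        model = _train_on(data, train_drugs, dc_replace(config, seed=config.seed + i),
                          seed=seed + i, validation_fraction=validation_fraction,
                          subsample=subsample)
        assert model.training_drugs.isdisjoint(test_drugs)
        assert model.training_drugs <= all_drugs
        reports.append(_eval_directions(model, data.subset(test_drugs)))
    return reports, EvalReport.merge(reports)


def holdout_families(data: PairedSet, families: dict[str, str], k: int = 10,
                     config: ModelConfig | None = None, seed: int = 0,
                     validation_fraction: float = 0.1,
                     subsample: dict[str, float] | None = None,
                     ) -> tuple[list[EvalReport], EvalReport]:
    """Drug-family holdout: drugs sharing a mode of action stay in one fold."""
    if config is None:
        config = ModelConfig(input_dim=len(data.gene_space))
    folds = partition_drugs(list(data.drugs), k, seed, families=families)
    reports = []
    for i, test_drugs in enumerate(folds):
        train_drugs = [d for d in data.drugs if d not in set(test_drugs)]
        fams_in_test = {families.get(d) for d in test_drugs} - {None}
        leaked = [d for d in train_drugs if families.get(d) in fams_in_test]
        assert not leaked, f"family split leak: {leaked}"
        model = _train_on(data, train_drugs, dc_replace(config, seed=config.seed + i),
                          seed=seed + i, validation_fraction=validation_fraction,
                          subsample=subsample)
        assert model.training_drugs.isdisjoint(test_drugs)
        reports.append(_eval_directions(model, data.subset(test_drugs)))
    return reports, EvalReport.merge(reports)
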