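import numpy as np
import pytest

from cellstate import (
    GeneSpace,
    Profile,
    ProfileSet,
    TrainingPlan,
    build_model,
    evaluate_predictions,
    generate_cohort,
    pretrain_joint_autoencoder,
    train_cell_decoders,
)
from cellstate.evaluation import EvalReport
from cellstate.synthetic import fixture_model_config


@pytest.fixture
def tiny_space() -> GeneSpace:
    return GeneSpace(("g0", "g1", "g2", "g3", "g4"))


@pytest.fixture
def small_profile_set(tiny_space) -> ProfileSet:
    rng = np.random.default_rng(0)
    profiles = []
    for drug in ("dA", "dB", "dC"):
        for cell in ("MCF7", "PC3"):
            for t, dose in (("6 h", "1 uM"), ("24 h", "10 uM")):
                profiles.append(Profile(values=rng.normal(size=5),
                                        perturbagen_id=drug, cell_type=cell,
                                        timepoint=t, dose=dose))
    return ProfileSet(gene_space=tiny_space, profiles=profiles)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The default synthetic cohort, shared across the session."""
    paired, truth = generate_cohort(300, ["cellA", "cellB"], 200, 16,
                                    shared_fraction=0.6, noise_sd=0.3, seed=7)
    return paired, truth


@pytest.fixture(scope="session")
def trained_fixture(fixture_cohort):
    """A scaled model trained on 240 fixture drugs, plus its test block."""
    paired, _ = fixture_cohort
    train = paired.subset(paired.drugs[:240])
    test = paired.subset(paired.drugs[240:])
    config = fixture_model_config(input_dim=len(paired.gene_space), seed=0)
    model = build_model(config, list(paired.cell_types),
                        gene_space=paired.gene_space,
                        normalization_scale=paired.normalization_scale)
    plan = TrainingPlan(paired=train, seed=1)
    pretrain_joint_autoencoder(model, plan)
    train_cell_decoders(model, plan)
    return model, test


def eval_both_directions(model, test) -> EvalReport:
    a, b = test.cell_types
    return EvalReport.merge([
        evaluate_predictions(model, test, [a], b),
        evaluate_predictions(model, test, [b], a),
    ])
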