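"""Synthetic paired perturbation cohorts with known ground truth.

Each drug gets one latent effect code shared by every cell type; each
cell type gets its own mixing map (a shared base map plus a small
cell-specific jitter) with a tanh squash.  A profile is

    shared_fraction       * tanh(M_c @ z_d)          (shared drug effect)
  + (1 - shared_fraction) * tanh(M_c @ u_{d,c})      (cell x drug specific)
  + noise_sd * eps                                    (gene-level noise)

followed by global max-|value| normalization.  Because the cell maps are
correlated across cells, the expected cross-cell correlation of the same
drug's profiles grows monotonically with ``shared_fraction`` — the
structure a shared-latent model is supposed to exploit.  The generative
truth (codes, maps, planted gene sets) is returned alongside the cohort
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cellstate.errors import ConfigError, ContractError
from cellstate.profiles import (
    GeneSpace,
    PairedSet,
    Profile,
    ProfileSet,
    build_paired_set,
    normalize_global,
)

#: relative weight of the cell-specific jitter added to the shared base map;
#: sized so same-drug profiles correlate moderately across cells at shared_fraction 0.6
MAP_JITTER = 0.8


@dataclass
class SyntheticTruth:
    """Generative latents and maps behind one synthetic cohort."""

    drugs: list[str]
    cell_types: list[str]
    gene_space: GeneSpace
    latent_factors: np.ndarray            # (n_drugs, k) shared drug codes
    specific_factors: dict[str, np.ndarray]  # cell -> (n_drugs, k) private codes
    cell_maps: dict[str, np.ndarray]      # cell -> (k, G) mixing map
    shared_fraction: float
    noise_sd: float
    seed: int
    planted_tf_sets: dict[int, list[str]] = field(default_factory=dict)
    planted_importance_genes: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.latent_factors.shape[1]


def _make_truth(n_drugs: int, cell_types: list[str], n_genes: int, k: int,
                shared_fraction: float, noise_sd: float, seed: int,
                drug_prefix: str = "drug") -> SyntheticTruth:
    if k >= n_genes:
        raise ConfigError("latent size k must be smaller than n_genes")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ConfigError("shared_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    if n_drugs < 1 or len(cell_types) < 2:
        raise ConfigError("need at least 1 drug and 2 cell types")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    scale = 1.0 / np.sqrt(k)  # unit pre-tanh variance of M @ z
    base_map = rng.normal(0.0, scale, size=(k, n_genes))
    truth = SyntheticTruth(
        drugs=[f"{drug_prefix}{i:04d}" for i in range(n_drugs)],
        cell_types=list(cell_types),
        gene_space=GeneSpace(tuple(f"g{i:04d}" for i in range(n_genes))),
        latent_factors=rng.normal(size=(n_drugs, k)),
        specific_factors={c: rng.normal(size=(n_drugs, k)) for c in cell_types},
        cell_maps={
            c: base_map + MAP_JITTER * rng.normal(0.0, scale, size=(k, n_genes))
            for c in cell_types
        },
        shared_fraction=shared_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )
    return truth


def raw_matrices(truth: SyntheticTruth) -> dict[str, np.ndarray]:
    """Un-normalized (n_drugs, G) matrices per cell.

    The gene-noise stream depends only on the seed and cohort shape, so
    editing the maps (e.g. planting TF structure) and re-rendering
    changes only the columns the edit touches.
    """
    rho = truth.shared_fraction
    noise_rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    out = {}
    for cell in truth.cell_types:
        M = truth.cell_maps[cell]
        shared = np.tanh(truth.latent_factors @ M)
        specific = np.tanh(truth.specific_factors[cell] @ M)
        noise = truth.noise_sd * noise_rng.normal(size=shared.shape)
        mat = rho * shared + (1.0 - rho) * specific + noise
        if not np.all(np.isfinite(mat)):
            raise ContractError("generator produced non-finite values")
        out[cell] = mat
    return out


def cohort_from_truth(truth: SyntheticTruth) -> PairedSet:
    """Render the normalized paired cohort from a (possibly edited) truth."""
    mats = raw_matrices(truth)
    profiles = [
        Profile(values=mats[cell][i], perturbagen_id=drug, cell_type=cell)
        for cell in truth.cell_types
        for i, drug in enumerate(truth.drugs)
    ]
    ps = normalize_global(ProfileSet(gene_space=truth.gene_space, profiles=profiles))
    return build_paired_set(ps, truth.cell_types)


def generate_cohort(n_drugs: int, cell_types: list[str], n_genes: int, k: int,
                    shared_fraction: float, noise_sd: float, seed: int,
                    drug_prefix: str = "drug"
                    ) -> tuple[PairedSet, SyntheticTruth]:
    """Generate a complete drug x cell cohort plus its generative truth."""
    truth = _make_truth(n_drugs, cell_types, n_genes, k,
                        shared_fraction, noise_sd, seed, drug_prefix=drug_prefix)
    return cohort_from_truth(truth), truth


def default_fixture(seed: int = 7) -> tuple[PairedSet, SyntheticTruth]:
    """The standard test cohort: 300 drugs, 2 cells, 200 genes, k=16."""
    return generate_cohort(n_drugs=300, cell_types=["cellA", "cellB"],
                           n_genes=200, k=16, shared_fraction=0.6,
                           noise_sd=0.3, seed=seed)


def fixture_model_config(input_dim: int = 200, latent_dim: int = 32,
                         seed: int = 0, max_epochs: int = 60):
    """Model config scaled to train on the synthetic fixture in seconds.

    Same architecture family as the full-size model, with smaller widths
    and a learning rate raised to converge within the reduced epoch
    budget on one CPU.
    """
    from cellstate.model import ModelConfig

    return ModelConfig(input_dim=input_dim, encoder_widths=(128, 64),
                       latent_dim=latent_dim, learning_rate=1e-3,
                       max_epochs=max_epochs, seed=seed)


def plant_tf_structure(truth: SyntheticTruth, factor: int, tf_gene: str,
                       target_genes: list[str]) -> SyntheticTruth:
    """Make one latent factor load only on a TF and its target genes.

    In every cell map, row ``factor`` is zeroed except at ``tf_gene`` and
    ``target_genes``, which receive positive loadings at least 5x the
    background loading RMS.  The planted set is recorded on the truth.
    Re-render with :func:`cohort_from_truth` afterwards.
    """
    if not (0 <= factor < truth.k):
        raise ContractError(f"factor {factor} out of range [0, {truth.k})")
    genes = [tf_gene] + [g for g in target_genes if g != tf_gene]
    idx = [truth.gene_space.index_of(g) for g in genes]

    # per-gene loadings vary (but stay >= 5x background and identical across
    # cells) so the planted block keeps cross-gene variance under tanh
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2, factor]))
    magnitudes = rng.uniform(5.0, 9.0, size=len(idx))
    for cell, M in truth.cell_maps.items():
        background_rms = float(np.sqrt(np.mean(M ** 2)))
        row = np.zeros(M.shape[1])
        row[idx] = magnitudes * background_rms
        M[factor, :] = row
    truth.planted_tf_sets[factor] = genes
    return truth


def plant_importance_structure(truth: SyntheticTruth, cell: str,
                               driver_genes: list[str]) -> SyntheticTruth:
    """Restrict one cell's signal to a planted driver gene set.

    Zeroes every non-driver column of that cell's mixing map, so in the
    rendered cohort only the driver genes of that cell carry signal
    (everything else is noise).  A model trained with this cell as input
    can then only read the drivers — the ground truth for masked-subset
    importance recovery.
    """
    if cell not in truth.cell_maps:
        raise ContractError(f"unknown cell {cell!r}")
    keep = np.zeros(len(truth.gene_space), dtype=bool)
    for g in driver_genes:
        keep[truth.gene_space.index_of(g)] = True
    truth.cell_maps[cell][:, ~keep] = 0.0
    truth.planted_importance_genes = list(driver_genes)
    return truth
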