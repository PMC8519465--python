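"""Reading, aggregating, normalizing and pairing perturbation-response profiles.

Profiles are differential-expression vectors over a fixed, ordered gene
space (978 landmark genes for L1000 data; arbitrary for synthetic data).
The processing pipeline mirrors the standard preparation of level-5
signatures: average replicates of the same drug across timepoints and
doses, normalize the whole matrix into [-1, 1] by its global maximum
absolute value, and keep only drugs measured in every cell type of
interest.  Conversion helpers map external count or mean-expression
tables onto the landmark space as log2 fold-change profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cellstate.errors import ContractError, ParseError

AVERAGED = "averaged"

#: metadata columns expected in a sample-annotation sidecar
META_COLUMNS = ("sample_id", "pert_id", "cell_id", "pert_type", "pert_time", "pert_dose")


@dataclass(frozen=True)
class GeneSpace:
    """An ordered list of unique gene identifiers shared by a dataset."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ContractError("gene identifiers must be unique")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    def __len__(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]  # type: ignore[attr-defined]
        except KeyError:
            raise ContractError(f"gene {gene!r} not in gene space") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index  # type: ignore[attr-defined]


@dataclass
class Profile:
    """One perturbation-response vector with its condition metadata."""

    values: np.ndarray
    perturbagen_id: str
    cell_type: str
    perturbagen_type: str = "compound"
    timepoint: str = AVERAGED
    dose: str = AVERAGED

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ContractError("profile values must be one-dimensional")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.perturbagen_id, self.cell_type, self.timepoint, self.dose)


@dataclass
class ProfileSet:
    """A collection of profiles over one gene space.

    At most one profile may exist per
    (perturbagen, cell type, timepoint, dose) key.
    ``normalization_scale`` is ``None`` until :func:`normalize_global`
    is applied; afterwards it records the divisor needed to undo the
    normalization.
    """

    gene_space: GeneSpace
    profiles: list[Profile] = field(default_factory=list)
    normalization_scale: float | None = None

    def __post_init__(self) -> None:
        g = len(self.gene_space)
        seen: set[tuple] = set()
        for p in self.profiles:
            if len(p.values) != g:
                raise ContractError(
                    f"profile {p.perturbagen_id}/{p.cell_type} has {len(p.values)} "
                    f"values but gene space has {g}"
                )
            if p.key in seen:
                raise ContractError(f"duplicate profile key {p.key}")
            seen.add(p.key)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def matrix(self) -> np.ndarray:
        """Profiles stacked as an (n_profiles, n_genes) array."""
        return np.stack([p.values for p in self.profiles])

    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(p.cell_type, None)
        return list(seen)

    def drugs(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(p.perturbagen_id, None)
        return list(seen)


@dataclass
class PairedSet:
    """A complete drug x cell-type block of averaged profiles."""

    gene_space: GeneSpace
    cell_types: list[str]
    drugs: list[str]
    block: dict[tuple[str, str], Profile]
    normalization_scale: float | None = None

    def __post_init__(self) -> None:
        for d in self.drugs:
            for c in self.cell_types:
                p = self.block.get((d, c))
                if p is None:
                    raise ContractError(f"paired block incomplete: missing ({d}, {c})")
                if p.timepoint != AVERAGED or p.dose != AVERAGED:
                    raise ContractError(
                        f"paired profiles must be averaged; ({d}, {c}) is not"
                    )

    def profile(self, drug: str, cell: str) -> Profile:
        try:
            return self.block[(drug, cell)]
        except KeyError:
            raise ContractError(f"no profile for ({drug}, {cell})") from None

    def matrix(self, cell: str) -> np.ndarray:
        """(n_drugs, n_genes) matrix for one cell type, drug order preserved."""
        if cell not in self.cell_types:
            raise ContractError(f"unknown cell type {cell!r}")
        return np.stack([self.block[(d, cell)].values for d in self.drugs])

    def subset(self, drugs: Sequence[str]) -> "PairedSet":
        missing = [d for d in drugs if d not in set(self.drugs)]
        if missing:
            raise ContractError(f"drugs not in paired set: {missing}")
        return PairedSet(
            gene_space=self.gene_space,
            cell_types=list(self.cell_types),
            drugs=list(drugs),
            block={(d, c): self.block[(d, c)] for d in drugs for c in self.cell_types},
            normalization_scale=self.normalization_scale,
        )

    def to_profile_set(self) -> ProfileSet:
        return ProfileSet(
            gene_space=self.gene_space,
            profiles=[self.block[(d, c)] for d in self.drugs for c in self.cell_types],
            normalization_scale=self.normalization_scale,
        )


# ---------------------------------------------------------------------------
# reading / writing


def _read_meta(metadata: "pd.DataFrame | str") -> pd.DataFrame:
    if isinstance(metadata, (str, bytes)) or hasattr(metadata, "__fspath__"):
        metadata = pd.read_csv(metadata, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in metadata.columns]
    if missing:
        raise ContractError(f"metadata missing columns: {missing}")
    return metadata.set_index("sample_id")


def _parse_gct(path: str) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise ParseError(f"{path}:1: unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ParseError(f"{path}:2: malformed dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_rmeta = int(dims[2]) if version == "#1.3" and len(dims) > 2 else 0
        n_cmeta = int(dims[3]) if version == "#1.3" and len(dims) > 3 else 0
        if version == "#1.2":
            n_rmeta = 1  # Description column
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1 + n_rmeta:]
        if len(sample_ids) != n_cols:
            raise ParseError(
                f"{path}:3: header names {len(sample_ids)} samples, expected {n_cols}"
            )
        for _ in range(n_cmeta):  # column-metadata rows are skipped
            fh.readline()
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=4 + n_cmeta):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 1 + n_rmeta + n_cols:
                raise ParseError(f"{path}:{lineno}: expected {1 + n_rmeta + n_cols} fields")
            genes.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1 + n_rmeta:1 + n_rmeta + n_cols]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
        if len(genes) != n_rows:
            raise ParseError(f"{path}: found {len(genes)} data rows, expected {n_rows}")
    return pd.DataFrame(rows, index=genes, columns=sample_ids)


def _parse_gctx(path: str) -> pd.DataFrame:
    import h5py

    with h5py.File(path, "r") as f:
        try:
            mat = f["0/DATA/0/matrix"][()]
            rids = [r.decode() if isinstance(r, bytes) else str(r) for r in f["0/META/ROW/id"][()]]
            cids = [c.decode() if isinstance(c, bytes) else str(c) for c in f["0/META/COL/id"][()]]
        except KeyError as exc:
            raise ParseError(f"{path}: not a GCTX file ({exc})") from None
    rids = [r.strip() for r in rids]
    cids = [c.strip() for c in cids]
    # GCTX stores the matrix samples x genes
    if mat.shape == (len(cids), len(rids)):
        mat = mat.T
    return pd.DataFrame(np.asarray(mat, dtype=np.float64), index=rids, columns=cids)


def read_matrix(path: str, format: str, metadata: "pd.DataFrame | str") -> ProfileSet:
    """Read a genes x samples matrix into a :class:`ProfileSet`.

    ``format`` is one of ``gct``, ``gctx`` or ``tsv``; ``metadata`` is a
    sample-annotation table (or path to a TSV) with columns
    ``sample_id, pert_id, cell_id, pert_type, pert_time, pert_dose``.
    Gene order is taken from the file row order; values are not
    transformed.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from None
    elif format == "gct":
        df = _parse_gct(path)
    elif format == "gctx":
        df = _parse_gctx(path)
    else:
        raise ContractError(f"unknown format {format!r}; expected gct, gctx or tsv")

    meta = _read_meta(metadata)
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise ContractError(f"samples missing from metadata: {missing}")

    space = GeneSpace(tuple(str(g) for g in df.index))
    profiles = []
    for sample in df.columns:
        row = meta.loc[sample]
        profiles.append(
            Profile(
                values=df[sample].to_numpy(dtype=np.float64),
                perturbagen_id=str(row["pert_id"]),
                cell_type=str(row["cell_id"]),
                perturbagen_type=str(row["pert_type"]),
                timepoint=str(row["pert_time"]),
                dose=str(row["pert_dose"]),
            )
        )
    return ProfileSet(gene_space=space, profiles=profiles)


def write_tsv(ps: ProfileSet, matrix_path: str, meta_path: str) -> None:
    """Write a profile set as a genes x samples TSV plus a metadata sidecar."""
    ids, rows = [], []
    for i, p in enumerate(ps.profiles):
        sid = f"s{i}"
        ids.append(sid)
        rows.append((sid, p.perturbagen_id, p.cell_type, p.perturbagen_type,
                     p.timepoint, p.dose))
    df = pd.DataFrame(ps.matrix().T, index=list(ps.gene_space.genes), columns=ids)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t")
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(meta_path, sep="\t", index=False)


def write_gct(ps: ProfileSet, path: str) -> None:
    ids = [f"s{i}" for i in range(len(ps.profiles))]
    mat = ps.matrix().T
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{mat.shape[0]}\t{mat.shape[1]}\t0\t0\n")
        fh.write("id\t" + "\t".join(ids) + "\n")
        for g, row in zip(ps.gene_space.genes, mat):
            fh.write(g + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# aggregation / normalization / pairing


def average_condition_replicates(ps: ProfileSet) -> ProfileSet:
    """Average profiles of the same (drug, cell type) across timepoints and doses.

    Returns one profile per (perturbagen, cell type), values equal to the
    unweighted per-gene arithmetic mean, with timepoint and dose marked
    as averaged.
    """
    if not ps.profiles:
        raise ContractError("cannot average an empty profile set")
    groups: dict[tuple[str, str], list[Profile]] = {}
    for p in ps.profiles:
        groups.setdefault((p.perturbagen_id, p.cell_type), []).append(p)
    out = []
    for (pert, cell), members in groups.items():
        vals = np.mean([m.values for m in members], axis=0)
        out.append(
            Profile(
                values=vals,
                perturbagen_id=pert,
                cell_type=cell,
                perturbagen_type=members[0].perturbagen_type,
                timepoint=AVERAGED,
                dose=AVERAGED,
            )
        )
    return ProfileSet(gene_space=ps.gene_space, profiles=out,
                      normalization_scale=ps.normalization_scale)


def normalize_global(ps: ProfileSet) -> ProfileSet:
    """Scale the whole matrix into [-1, 1] by its global max absolute value.

    The scale is recorded on the result so the transform can be inverted
    and so later inputs (external data included) can be mapped into the
    same coordinate system.
    """
    if not ps.profiles:
        raise ContractError("cannot normalize an empty profile set")
    scale = float(np.max(np.abs(ps.matrix())))
    if scale == 0.0:
        raise ContractError("all-zero matrix: normalization scale undefined")
    out = [replace(p, values=p.values / scale) for p in ps.profiles]
    return ProfileSet(gene_space=ps.gene_space, profiles=out, normalization_scale=scale)


def denormalize(ps: ProfileSet) -> ProfileSet:
    """Invert :func:`normalize_global` using the recorded scale."""
    if ps.normalization_scale is None:
        raise ContractError("profile set carries no normalization scale")
    s = ps.normalization_scale
    out = [replace(p, values=p.values * s) for p in ps.profiles]
    return ProfileSet(gene_space=ps.gene_space, profiles=out, normalization_scale=None)


def build_paired_set(ps: ProfileSet, cell_types: Sequence[str]) -> PairedSet:
    """Keep only drugs measured in every one of ``cell_types``.

    Requires an already-averaged set (one profile per drug x cell).
    """
    if len(cell_types) < 2:
        raise ContractError("a paired set needs at least two cell types")
    present = set(ps.cell_types())
    absent = [c for c in cell_types if c not in present]
    if absent:
        raise ContractError(f"cell types absent from profile set: {absent}")

    by_cell: dict[str, dict[str, Profile]] = {c: {} for c in cell_types}
    for p in ps.profiles:
        if p.cell_type not in by_cell:
            continue
        if p.timepoint != AVERAGED or p.dose != AVERAGED:
            raise ContractError(
                "build_paired_set requires averaged profiles; "
                f"({p.perturbagen_id}, {p.cell_type}) is not averaged"
            )
        by_cell[p.cell_type][p.perturbagen_id] = p

    common: set[str] | None = None
    for c in cell_types:
        ds = set(by_cell[c])
        common = ds if common is None else common & ds
    assert common is not None
    if not common:
        raise ContractError("no drug is shared by all requested cell types")

    # preserve the first cell type's drug order for determinism
    order = [d for d in by_cell[cell_types[0]] if d in common]
    block = {(d, c): by_cell[c][d] for d in order for c in cell_types}
    return PairedSet(
        gene_space=ps.gene_space,
        cell_types=list(cell_types),
        drugs=order,
        block=block,
        normalization_scale=ps.normalization_scale,
    )


# ---------------------------------------------------------------------------
# external-data conversion


def _map_to_landmarks(values: Mapping[str, float], gene_space: GeneSpace) -> np.ndarray:
    """Exact symbol match after upper-casing; unmatched landmark genes get 0."""
    lut = {str(k).upper(): float(v) for k, v in values.items()}
    return np.array([lut.get(g.upper(), 0.0) for g in gene_space.genes])


def cage_counts_to_profiles(
    counts: pd.DataFrame,
    condition: Mapping[str, str],
    control: str,
    gene_space: GeneSpace,
    pseudo_count: float = 2.0,
    cell_type: str = "external",
) -> ProfileSet:
    """Convert per-gene CAGE tag counts to landmark log2 fold-change profiles.

    ``counts`` is a genes x replicates table; ``condition`` maps each
    replicate column to its condition label, one of which is ``control``.
    Per replicate, ``pseudo_count`` is added to every gene and the column
    is scaled to counts-per-million; replicates are averaged within each
    condition and every treatment condition becomes one profile of
    per-gene log2(treatment / control), restricted to the landmark space
    with missing genes set to 0.
    """
    if pseudo_count <= 0:
        raise ContractError("pseudo_count must be positive")
    if (counts.to_numpy() < 0).any():
        raise ContractError("negative counts")
    unknown = [s for s in counts.columns if s not in condition]
    if unknown:
        raise ContractError(f"replicates without a condition label: {unknown}")
    labels = {condition[s] for s in counts.columns}
    if control not in labels:
        raise ContractError(f"control condition {control!r} not present")
    if labels == {control}:
        raise ContractError("no treatment condition present")

    cpm = counts.astype(float) + pseudo_count
    cpm = cpm * 1e6 / cpm.sum(axis=0)

    cond_means: dict[str, pd.Series] = {}
    for label in labels:
        cols = [s for s in counts.columns if condition[s] == label]
        cond_means[label] = cpm[cols].mean(axis=1)

    ctrl = cond_means[control]
    profiles = []
    for label in sorted(labels - {control}):
        lfc = np.log2(cond_means[label] / ctrl)
        vals = _map_to_landmarks(dict(zip(counts.index, lfc)), gene_space)
        profiles.append(Profile(values=vals, perturbagen_id=label, cell_type=cell_type))
    return ProfileSet(gene_space=gene_space, profiles=profiles)


def logfc_profile(
    control_mean: Mapping[str, float],
    treatment_mean: Mapping[str, float],
    gene_space: GeneSpace,
    perturbagen_id: str = "external",
    cell_type: str = "external",
) -> Profile:
    """Per-gene log2(treatment / control) mapped onto the landmark space.

    Genes absent from the input tables get value 0.  Both means must be
    strictly positive for every shared gene.
    """
    if set(control_mean) != set(treatment_mean):
        raise ContractError("control and treatment tables cover different genes")
    lfc: dict[str, float] = {}
    for g, c in control_mean.items():
        t = treatment_mean[g]
        if c <= 0:
            raise ContractError(f"nonpositive control mean for gene {g!r}")
        if t <= 0:
            raise ContractError(f"nonpositive treatment mean for gene {g!r}")
        lfc[g] = float(np.log2(t / c))
    return Profile(
        values=_map_to_landmarks(lfc, gene_space),
        perturbagen_id=perturbagen_id,
        cell_type=cell_type,
    )


def rescale_external(ps: ProfileSet, training_scale: float) -> ProfileSet:
    """Map external profiles into a trained model's coordinate system.

    Divides by the training normalization scale and clips to [-1, 1]
    (external values are not re-normalized by their own maximum).
    """
    if training_scale <= 0:
        raise ContractError("training scale must be positive")
    out = [replace(p, values=np.clip(p.values / training_scale, -1.0, 1.0))
           for p in ps.profiles]
    return ProfileSet(gene_space=ps.gene_space, profiles=out,
                      normalization_scale=training_scale)


def filter_timepoint(ps: ProfileSet, timepoint: str = "24 h") -> ProfileSet:
    """Keep only profiles at one timepoint (default the 24 h point)."""
    kept = [p for p in ps.profiles if p.timepoint == timepoint]
    if not kept:
        raise ContractError(f"no profiles at timepoint {timepoint!r}")
    return ProfileSet(gene_space=ps.gene_space, profiles=kept,
                      normalization_scale=ps.normalization_scale)
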