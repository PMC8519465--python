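import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cellstate import (
    GeneSpace,
    Profile,
    ProfileSet,
    average_condition_replicates,
    build_paired_set,
    cage_counts_to_profiles,
    logfc_profile,
    normalize_global,
    read_matrix,
)
from cellstate.errors import ContractError, ParseError
from cellstate.profiles import denormalize, filter_timepoint, rescale_external, write_gct, write_tsv


def _meta(samples, perts, cells, times=None, doses=None):
    n = len(samples)
    return pd.DataFrame({
        "sample_id": samples,
        "pert_id": perts,
        "cell_id": cells,
        "pert_type": ["compound"] * n,
        "pert_time": times or ["24 h"] * n,
        "pert_dose": doses or ["10 uM"] * n,
    })


class TestGeneSpace:
    def test_unique(self):
        with pytest.raises(ContractError):
            GeneSpace(("a", "a"))

    def test_index(self, tiny_space):
        assert tiny_space.index_of("g3") == 3
        assert "g3" in tiny_space
        with pytest.raises(ContractError):
            tiny_space.index_of("nope")


class TestReadMatrix:
    def test_tsv_shape(self, tmp_path):
        path = tmp_path / "m.tsv"
        pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                     index=["gA", "gB", "gC"], columns=["s1", "s2"]).to_csv(
            path, sep="\t")
        ps = read_matrix(str(path), "tsv", _meta(["s1", "s2"], ["d1", "d2"],
                                                 ["MCF7", "MCF7"]))
        assert len(ps) == 2
        assert len(ps.gene_space) == 3
        assert ps.profiles[0].values.tolist() == [1.0, 3.0, 5.0]

    def test_deterministic(self, tmp_path):
        path = tmp_path / "m.tsv"
        pd.DataFrame(np.arange(6.0).reshape(3, 2), index=list("abc"),
                     columns=["s1", "s2"]).to_csv(path, sep="\t")
        meta = _meta(["s1", "s2"], ["d1", "d2"], ["X", "Y"])
        a = read_matrix(str(path), "tsv", meta)
        b = read_matrix(str(path), "tsv", meta)
        assert np.array_equal(a.matrix(), b.matrix())
        assert a.gene_space == b.gene_space

    def test_gct_matches_text_oracle(self, tmp_path):
        # independent parse of the same GCT text with plain string splitting
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(978, 4))
        genes = [f"G{i}" for i in range(978)]
        path = tmp_path / "m.gct"
        with open(path, "w") as fh:
            fh.write("#1.3\n978\t4\t0\t0\nid\ts0\ts1\ts2\ts3\n")
            for g, row in zip(genes, mat):
                fh.write(g + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")
        ps = read_matrix(str(path), "gct",
                         _meta([f"s{i}" for i in range(4)],
                               [f"d{i}" for i in range(4)], ["MCF7"] * 4))
        oracle = []
        for line in open(path).read().splitlines()[3:]:
            oracle.append([float(v) for v in line.split("\t")[1:]])
        assert np.array_equal(ps.matrix().T, np.array(oracle))
        assert list(ps.gene_space.genes) == genes

    def test_gctx_roundtrip(self, tmp_path):
        import h5py

        mat = np.arange(12.0).reshape(4, 3)  # samples x genes
        path = tmp_path / "m.gctx"
        with h5py.File(path, "w") as f:
            f.create_dataset("0/DATA/0/matrix", data=mat)
            f.create_dataset("0/META/ROW/id", data=[b"gA", b"gB", b"gC"])
            f.create_dataset("0/META/COL/id",
                             data=[b"s0", b"s1", b"s2", b"s3"])
        ps = read_matrix(str(path), "gctx",
                         _meta([f"s{i}" for i in range(4)],
                               [f"d{i}" for i in range(4)], ["X"] * 4))
        assert np.array_equal(ps.matrix(), mat)

    def test_malformed_gct(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#9.9\n")
        with pytest.raises(ParseError):
            read_matrix(str(path), "gct", _meta(["s1"], ["d"], ["c"]))

    def test_metadata_mismatch(self, tmp_path):
        path = tmp_path / "m.tsv"
        pd.DataFrame([[1.0]], index=["g"], columns=["s1"]).to_csv(path, sep="\t")
        with pytest.raises(ContractError):
            read_matrix(str(path), "tsv", _meta(["other"], ["d"], ["c"]))

    def test_write_read_roundtrip(self, tmp_path, small_profile_set):
        write_tsv(small_profile_set, tmp_path / "m.tsv", tmp_path / "meta.tsv")
        back = read_matrix(str(tmp_path / "m.tsv"), "tsv", str(tmp_path / "meta.tsv"))
        assert np.allclose(back.matrix(), small_profile_set.matrix())
        write_gct(small_profile_set, tmp_path / "m.gct")
        back2 = read_matrix(str(tmp_path / "m.gct"), "gct", str(tmp_path / "meta.tsv"))
        assert np.allclose(back2.matrix(), small_profile_set.matrix())


class TestAverage:
    def test_mean_of_two(self, tiny_space):
        space = GeneSpace(("x", "y"))
        ps = ProfileSet(gene_space=space, profiles=[
            Profile([1, 3], "drugA", "MCF7", timepoint="6 h"),
            Profile([3, 5], "drugA", "MCF7", timepoint="24 h"),
        ])
        out = average_condition_replicates(ps)
        assert len(out) == 1
        assert out.profiles[0].values.tolist() == [2.0, 4.0]
        assert out.profiles[0].timepoint == "averaged"
        assert out.profiles[0].dose == "averaged"

    def test_identity_when_single(self, small_profile_set):
        singles = ProfileSet(
            gene_space=small_profile_set.gene_space,
            profiles=[p for p in small_profile_set.profiles
                      if p.timepoint == "6 h"],
        )
        out = average_condition_replicates(singles)
        assert len(out) == len(singles)
        for a, b in zip(sorted(out, key=lambda p: p.key),
                        sorted(singles, key=lambda p: p.key[:2])):
            assert np.array_equal(a.values, b.values)

    def test_brute_force_mean(self):
        rng = np.random.default_rng(5)
        space = GeneSpace(tuple(f"g{i}" for i in range(5)))
        mats = rng.normal(size=(4, 5))
        profiles = [Profile(mats[i], "d", "c", timepoint=f"t{i // 2}",
                            dose=f"d{i % 2}") for i in range(4)]
        out = average_condition_replicates(ProfileSet(gene_space=space,
                                                      profiles=profiles))
        expected = mats.mean(axis=0)  # independent column mean
        assert np.allclose(out.profiles[0].values, expected)

    def test_empty(self, tiny_space):
        with pytest.raises(ContractError):
            average_condition_replicates(ProfileSet(gene_space=tiny_space))


class TestNormalize:
    def test_division(self):
        space = GeneSpace(("x", "y"))
        ps = ProfileSet(gene_space=space,
                        profiles=[Profile([2.5, -5.0], "d", "c")])
        out = normalize_global(ps)
        assert out.normalization_scale == 5.0
        assert out.profiles[0].values.tolist() == [0.5, -1.0]

    def test_identity_when_normalized(self):
        space = GeneSpace(("x", "y"))
        ps = ProfileSet(gene_space=space, profiles=[Profile([1.0, -0.5], "d", "c")])
        out = normalize_global(ps)
        assert out.normalization_scale == 1.0
        assert np.array_equal(out.matrix(), ps.matrix())

    def test_all_zero(self):
        space = GeneSpace(("x",))
        with pytest.raises(ContractError):
            normalize_global(ProfileSet(gene_space=space,
                                        profiles=[Profile([0.0], "d", "c")]))

    @given(arrays(np.float64, (10, 10),
                  elements=st.floats(-100, 100, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip(self, mat):
        if np.max(np.abs(mat)) == 0:
            return
        space = GeneSpace(tuple(f"g{i}" for i in range(10)))
        ps = ProfileSet(gene_space=space,
                        profiles=[Profile(mat[i], f"d{i}", "c") for i in range(10)])
        norm = normalize_global(ps)
        assert np.max(np.abs(norm.matrix())) == 1.0
        back = denormalize(norm)
        scale = np.max(np.abs(mat))
        assert np.allclose(back.matrix(), mat, rtol=1e-12, atol=1e-12 * scale)


class TestBuildPairedSet:
    def _ps(self, cell_drugs: dict) -> ProfileSet:
        space = GeneSpace(("x", "y", "z"))
        rng = np.random.default_rng(1)
        profiles = [Profile(rng.normal(size=3), d, c)
                    for c, ds in cell_drugs.items() for d in ds]
        return ProfileSet(gene_space=space, profiles=profiles)

    def test_intersection(self):
        paired = build_paired_set(
            self._ps({"cellA": ["a", "b", "c"], "cellB": ["b", "c", "d"]}),
            ["cellA", "cellB"])
        assert sorted(paired.drugs) == ["b", "c"]

    def test_identical_lists(self):
        paired = build_paired_set(
            self._ps({"A": ["a", "b"], "B": ["a", "b"]}), ["A", "B"])
        assert sorted(paired.drugs) == ["a", "b"]

    def test_triple_intersection_oracle(self):
        lists = {"A": ["a", "b", "c", "d"], "B": ["b", "c", "d", "e"],
                 "C": ["c", "d", "e", "f"]}
        paired = build_paired_set(self._ps(lists), ["A", "B", "C"])
        brute = set(lists["A"]) & set(lists["B"]) & set(lists["C"])
        assert set(paired.drugs) == brute
        assert len(paired.block) == len(brute) * 3

    def test_empty_intersection(self):
        with pytest.raises(ContractError):
            build_paired_set(self._ps({"A": ["a"], "B": ["b"]}), ["A", "B"])

    def test_missing_cell(self):
        with pytest.raises(ContractError):
            build_paired_set(self._ps({"A": ["a"]}), ["A", "Z"])

    def test_pipeline_idempotent(self, small_profile_set):
        ps = normalize_global(average_condition_replicates(small_profile_set))
        paired = build_paired_set(ps, ["MCF7", "PC3"])
        again = build_paired_set(
            normalize_global(average_condition_replicates(paired.to_profile_set())),
            ["MCF7", "PC3"])
        for key in paired.block:
            assert np.allclose(paired.block[key].values, again.block[key].values)


class TestExternalConversion:
    def test_cage_zero_logfc(self):
        space = GeneSpace(("A", "B"))
        counts = pd.DataFrame({"c1": [10, 20], "t1": [10, 20]}, index=["A", "B"])
        ps = cage_counts_to_profiles(counts, {"c1": "ctrl", "t1": "drug"},
                                     "ctrl", space)
        assert np.allclose(ps.profiles[0].values, 0.0)

    def test_cage_cpm_hand_arithmetic(self):
        # counts [0, 8] with c = 2 -> [2, 10] -> CPM [1e6/6, 5e6/6]
        space = GeneSpace(("A", "B"))
        counts = pd.DataFrame({"c1": [4, 4], "t1": [0, 8]}, index=["A", "B"])
        ps = cage_counts_to_profiles(counts, {"c1": "ctrl", "t1": "drug"},
                                     "ctrl", space, pseudo_count=2.0)
        cpm_t = np.array([2, 10]) * 1e6 / 12
        assert np.allclose(cpm_t, [166666.66666667, 833333.33333333])
        cpm_c = np.array([6, 6]) * 1e6 / 12
        assert np.allclose(ps.profiles[0].values, np.log2(cpm_t / cpm_c))

    def test_cage_missing_landmark_is_zero(self):
        space = GeneSpace(("A", "B", "MISSING"))
        counts = pd.DataFrame({"c1": [1, 2], "t1": [2, 4]}, index=["A", "B"])
        ps = cage_counts_to_profiles(counts, {"c1": "ctrl", "t1": "drug"},
                                     "ctrl", space)
        assert ps.profiles[0].values[2] == 0.0

    def test_cage_errors(self):
        space = GeneSpace(("A",))
        counts = pd.DataFrame({"t1": [1]}, index=["A"])
        with pytest.raises(ContractError):
            cage_counts_to_profiles(counts, {"t1": "drug"}, "ctrl", space)
        with pytest.raises(ContractError):
            cage_counts_to_profiles(pd.DataFrame({"c": [-1], "t": [1]},
                                                 index=["A"]),
                                    {"c": "ctrl", "t": "drug"}, "ctrl", space)

    def test_logfc_basics(self):
        space = GeneSpace(("A",))
        p = logfc_profile({"A": 4.0}, {"A": 8.0}, space)
        assert p.values.tolist() == [1.0]
        p0 = logfc_profile({"A": 3.0}, {"A": 3.0}, space)
        assert p0.values.tolist() == [0.0]

    def test_logfc_oracle(self):
        rng = np.random.default_rng(9)
        genes = tuple(f"G{i}" for i in range(20))
        space = GeneSpace(genes)
        ctrl = {g: float(v) for g, v in zip(genes, rng.uniform(0.5, 10, 20))}
        trt = {g: float(v) for g, v in zip(genes, rng.uniform(0.5, 10, 20))}
        p = logfc_profile(ctrl, trt, space)
        expected = [np.log2(trt[g] / ctrl[g]) for g in genes]
        assert np.allclose(p.values, expected)

    def test_logfc_nonpositive(self):
        space = GeneSpace(("A",))
        with pytest.raises(ContractError):
            logfc_profile({"A": 0.0}, {"A": 1.0}, space)

    def test_rescale_external_clips(self):
        space = GeneSpace(("A", "B"))
        ps = ProfileSet(gene_space=space, profiles=[Profile([4.0, -10.0], "d", "c")])
        out = rescale_external(ps, training_scale=5.0)
        assert out.profiles[0].values.tolist() == [0.8, -1.0]

    def test_filter_timepoint(self, small_profile_set):
        out = filter_timepoint(small_profile_set, "24 h")
        assert all(p.timepoint == "24 h" for p in out)
        assert len(out) == len(small_profile_set) // 2


class TestProfileSetInvariants:
    def test_duplicate_key(self, tiny_space):
        p = Profile(np.zeros(5), "d", "c")
        with pytest.raises(ContractError):
            ProfileSet(gene_space=tiny_space, profiles=[p, Profile(np.ones(5), "d", "c")])

    def test_wrong_length(self, tiny_space):
        with pytest.raises(ContractError):
            ProfileSet(gene_space=tiny_space, profiles=[Profile(np.zeros(3), "d", "c")])
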