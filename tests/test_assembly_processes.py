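import io
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblyscape import assembly_processes as ap
from assemblyscape import synthetic_community as sc
from assemblyscape.io_core import OtuTable
from assemblyscape.pairwise import PairwiseMatrix

from conftest import brute_force_beta_mntd, random_table


def _table(rows, index, columns):
    return OtuTable(pd.DataFrame(rows, index=index, columns=columns))


class TestPatristicDistances:
    def test_worked_tree(self, toy_distances):
        d = toy_distances
        assert d.otu_ids == ["A", "B", "C"]
        expected = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        np.testing.assert_allclose(d.d, expected)

    def test_star_tree_and_zero_cherry(self):
        star = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1);"), format="newick")
        d = ap.patristic_distances(star)
        off = d.d[np.triu_indices(4, 1)]
        np.testing.assert_allclose(off, 2.0)
        cherry = TreeNode.read(io.StringIO("(A:0,B:0);"), format="newick")
        assert ap.patristic_distances(cherry).d[0, 1] == 0.0

    def test_mismatched_ids_error(self, toy_tree):
        with pytest.raises(KeyError, match="D"):
            ap.patristic_distances(toy_tree, ["A", "B", "D"])


class TestBetaMntd:
    def test_worked_examples(self, toy_distances):
        # single-tip communities on the worked tree
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        assert ap.beta_mntd(a, b, toy_distances) == pytest.approx(2.0)
        # weighted mixed community
        mixed = np.array([0.75, 0.0, 0.25])
        assert ap.beta_mntd(mixed, b, toy_distances) == pytest.approx(2.25)

    def test_shared_taxa_identity(self, toy_distances):
        f = np.array([0.5, 0.25, 0.25])
        assert ap.beta_mntd(f, f, toy_distances) == pytest.approx(0.0)

    def test_empty_community_error(self, toy_distances):
        with pytest.raises(ValueError):
            ap.beta_mntd(np.zeros(3), np.array([1.0, 0, 0]), toy_distances)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force(self, weighted):
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            tree = sc.simulate_tree(n, int(rng.integers(2**31)))
            otus = [t.name for t in tree.tips()]
            d = ap.patristic_distances(tree, otus)
            a = rng.random(n) * (rng.random(n) < 0.7)
            b = rng.random(n) * (rng.random(n) < 0.7)
            a[int(rng.integers(n))] += 0.1
            b[int(rng.integers(n))] += 0.1
            a, b = a / a.sum(), b / b.sum()
            ours = ap.beta_mntd(a, b, d, abundance_weighted=weighted)
            oracle = brute_force_beta_mntd(a, b, d.d, abundance_weighted=weighted)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(42)
        table = random_table(rng, 5, 10)
        tree = sc.simulate_tree(10, 7)
        table = OtuTable(table.counts.set_axis([t.name for t in tree.tips()], axis=1))
        d = ap.patristic_distances(tree, table.otu_ids)
        m = ap.beta_mntd_matrix(table, d)
        f = table.relative_abundance()
        for i in range(5):
            for j in range(i + 1, 5):
                assert m.values[i, j] == pytest.approx(ap.beta_mntd(f[i], f[j], d), abs=1e-12)

    def test_matches_picante_comdistnt(self, tmp_path):
        """Cross-check against the R reference implementation."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        tree = sc.simulate_tree(12, 5)
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 20, size=(4, 12))
        counts[counts < 5] = 0
        counts[:, 0] += 1
        otus = [t.name for t in tree.tips()]
        table = _table(counts, [f"s{i}" for i in range(4)], otus)
        ours = ap.beta_mntd_matrix(table, ap.patristic_distances(tree, otus))
        tree.write(str(tmp_path / "t.nwk"), format="newick")
        table.counts.to_csv(tmp_path / "comm.csv")
        script = (
            "suppressMessages(library(picante));"
            f"tree <- read.tree('{tmp_path}/t.nwk');"
            "tree$tip.label <- gsub(\"'\", '', tree$tip.label);"
            f"comm <- as.matrix(read.csv('{tmp_path}/comm.csv', row.names=1, check.names=FALSE));"
            "m <- as.matrix(comdistnt(comm, cophenetic(tree), abundance.weighted=TRUE));"
            f"write.csv(m[rownames(comm), rownames(comm)], '{tmp_path}/out.csv')"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "out.csv", index_col=0).to_numpy()
        np.testing.assert_allclose(ours.values, theirs, atol=1e-8)


class TestBnti:
    @pytest.fixture(scope="class")
    def small_case(self):
        tree = sc.simulate_tree(40, 61)
        otus = [t.name for t in tree.tips()]
        rng = np.random.default_rng(62)
        counts = rng.integers(0, 30, size=(6, 40))
        counts[counts < 12] = 0
        counts[:, 0] += 1
        table = _table(counts, [f"s{i}" for i in range(6)], otus)
        return table, ap.patristic_distances(tree, otus)

    def test_deterministic_given_seed(self, small_case):
        table, d = small_case
        cfg = ap.NullModelConfig(n_null=49, seed=9)
        a = ap.bnti_matrix(table, d, cfg)
        b = ap.bnti_matrix(table, d, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_observed_beta_mntd_invariant_to_relabeling(self, small_case):
        table, d = small_case
        perm = np.random.default_rng(63).permutation(len(table.otu_ids))
        new_ids = [f"X{i}" for i in range(len(table.otu_ids))]
        shuffled = OtuTable(
            table.counts.iloc[:, perm].set_axis([new_ids[i] for i in range(len(perm))], axis=1)
        )
        d_shuffled = ap.PhyloDistances(new_ids, d.d[np.ix_(perm, perm)])
        a = ap.beta_mntd_matrix(table, d)
        b = ap.beta_mntd_matrix(shuffled, d_shuffled)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_identical_compositions_are_degenerate(self, toy_distances):
        table = _table([[3, 1, 0], [3, 1, 0]], ["s1", "s2"], ["A", "B", "C"])
        with pytest.warns(UserWarning, match="degenerate"):
            res = ap.bnti_matrix(table, toy_distances, ap.NullModelConfig(n_null=19, seed=0))
        assert np.isnan(res.values[0, 1])


class TestRcBray:
    def test_identical_samples_give_minus_one(self):
        rng = np.random.default_rng(71)
        row = rng.integers(1, 20, size=30)
        counts = np.vstack([row, row] + [rng.integers(0, 20, size=30) + 1 for _ in range(4)])
        table = _table(counts, [f"s{i}" for i in range(6)], [f"o{i}" for i in range(30)])
        rc = ap.rc_bray_matrix(table, ap.NullModelConfig(n_null=199, seed=5))
        assert rc.values[0, 1] == pytest.approx(-1.0)

    def test_disjoint_samples_near_plus_one(self):
        rng = np.random.default_rng(72)
        a = np.concatenate([rng.integers(3, 20, size=20), np.zeros(20, dtype=int)])
        b = np.concatenate([np.zeros(20, dtype=int), rng.integers(3, 20, size=20)])
        table = _table([a, b], ["s1", "s2"], [f"o{i}" for i in range(40)])
        rc = ap.rc_bray_matrix(table, ap.NullModelConfig(n_null=199, seed=6))
        assert rc.values[0, 1] > 0.95

    def test_bounds_and_determinism(self):
        table = random_table(np.random.default_rng(73), 5, 25)
        cfg = ap.NullModelConfig(n_null=99, seed=7)
        a = ap.rc_bray_matrix(table, cfg)
        b = ap.rc_bray_matrix(table, cfg)
        np.testing.assert_array_equal(a.values, b.values)
        off = a.condensed()
        assert (off >= -1).all() and (off <= 1).all()


class TestClassification:
    @pytest.mark.parametrize(
        "bnti, rc, label",
        [
            (2.5, 0.1, "heterogeneous_selection"),
            (-2.5, 0.1, "homogeneous_selection"),
            (0.3, 0.97, "dispersal_limitation"),
            (0.3, -0.97, "homogenizing_dispersal"),
            (0.3, -0.2, "drift"),
            # boundary conventions: strict inequalities as printed
            (2.0, 0.97, "dispersal_limitation"),
            (-2.0, -0.97, "homogenizing_dispersal"),
            (0.0, 0.95, "drift"),
            (0.0, -0.95, "drift"),
        ],
    )
    def test_truth_table(self, bnti, rc, label):
        assert ap.classify_pair(bnti, rc) == label

    def test_classify_matrix_excludes_nan(self):
        ids = ["a", "b", "c"]
        b = np.array([[0, 2.5, np.nan], [2.5, 0, 1.0], [np.nan, 1.0, 0]])
        r = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="excluded"):
            cls = ap.classify_processes(
                PairwiseMatrix(ids, b, "bnti"), PairwiseMatrix(ids, r, "rcbray")
            )
        assert len(cls) == 2
        assert set(cls["label"]) == {"heterogeneous_selection", "drift"}


class TestContributions:
    @pytest.fixture
    def classification(self):
        return pd.DataFrame(
            {
                "sample_i": ["a", "a", "a", "b"],
                "sample_j": ["b", "c", "d", "c"],
                "bnti": [3.0, 3.0, 3.0, 0.0],
                "rcbray": [0.0, 0.0, 0.0, 0.0],
                "label": ["heterogeneous_selection"] * 3 + ["drift"],
            }
        )

    def test_simple_percentages(self, classification):
        out = ap.process_contributions(classification)
        assert out.loc["all", "heterogeneous_selection"] == pytest.approx(75.0)
        assert out.loc["all", "drift"] == pytest.approx(25.0)
        assert out.loc["all", "homogeneous_selection"] == 0.0
        assert out.loc["all", list(ap.PROCESSES)].sum() == pytest.approx(100.0)

    def test_single_pair(self, classification):
        out = ap.process_contributions(classification.iloc[:1])
        assert out.loc["all", "heterogeneous_selection"] == pytest.approx(100.0)

    def test_binned_consistency(self, classification):
        ids = ["a", "b", "c", "d"]
        lat = np.array([0.0, 1.0, 6.0, 12.0])
        dlat = PairwiseMatrix(ids, np.abs(lat[:, None] - lat[None, :]), "delta_latitude")
        binned = ap.binned_contributions(classification, dlat, [0, 5, 10, 15])
        pooled = ap.process_contributions(classification)
        # pooled over bins (pair-count weighted) equals the unstratified result
        weights = binned["n_pairs"] / binned["n_pairs"].sum()
        recon = (binned[list(ap.PROCESSES)].T * weights).T.sum()
        np.testing.assert_allclose(recon, pooled.loc["all", list(ap.PROCESSES)], atol=1e-9)

    def test_boundary_falls_in_upper_bin(self, classification):
        ids = ["a", "b", "c", "d"]
        lat = np.array([0.0, 5.0, 5.0, 5.0])
        dlat = PairwiseMatrix(ids, np.abs(lat[:, None] - lat[None, :]), "delta_latitude")
        binned = ap.binned_contributions(classification, dlat, [0, 5, 10])
        assert binned.loc["5-10", "n_pairs"] == 3  # Δ=5 goes to [5,10)

    def test_out_of_range_error(self, classification):
        ids = ["a", "b", "c", "d"]
        lat = np.array([0.0, 1.0, 6.0, 30.0])
        dlat = PairwiseMatrix(ids, np.abs(lat[:, None] - lat[None, :]), "delta_latitude")
        with pytest.raises(ValueError, match="extend"):
            ap.binned_contributions(classification, dlat, [0, 5, 10, 15])


class TestScaleRegression:
    def test_exact_linear(self):
        ids = [f"s{i}" for i in range(6)]
        lat = np.arange(6.0)
        dlat = np.abs(lat[:, None] - lat[None, :])
        bnti = 0.5 * dlat - 1.0
        reg = ap.bnti_scale_regression(
            PairwiseMatrix(ids, bnti, "bnti"), PairwiseMatrix(ids, dlat, "delta_latitude")
        )
        assert reg.slope == pytest.approx(0.5)
        assert reg.r_squared == pytest.approx(1.0)

    def test_shuffled_has_no_signal(self):
        rng = np.random.default_rng(81)
        ids = [f"s{i}" for i in range(20)]
        lat = np.linspace(0, 20, 20)
        dlat = np.abs(lat[:, None] - lat[None, :])
        from conftest import random_symmetric

        bnti = random_symmetric(rng, 20)
        reg = ap.bnti_scale_regression(
            PairwiseMatrix(ids, bnti, "bnti"), PairwiseMatrix(ids, dlat, "delta_latitude")
        )
        assert reg.r_squared < 0.05

    def test_constant_dlat_error(self):
        ids = ["a", "b", "c"]
        z = np.zeros((3, 3))
        with pytest.raises(ValueError):
            ap.bnti_scale_regression(
                PairwiseMatrix(ids, z, "bnti"), PairwiseMatrix(ids, z, "delta_latitude")
            )


def _make_classification(dlat_values, labels):
    n = len(dlat_values)
    return (
        pd.DataFrame(
            {
                "sample_i": [f"p{i}a" for i in range(n)],
                "sample_j": [f"p{i}b" for i in range(n)],
                "bnti": 0.0,
                "rcbray": 0.0,
                "label": labels,
            }
        ),
        np.asarray(dlat_values, dtype=float),
    )


class TestDominantThreshold:
    def _detect(self, dlat_values, labels, **kw):
        cls, dl = _make_classification(dlat_values, labels)
        ids = sorted(set(cls["sample_i"]) | set(cls["sample_j"]))
        # fabricate a Δlat matrix holding the right per-pair values
        idx = {s: k for k, s in enumerate(ids)}
        m = np.zeros((len(ids), len(ids)))
        for (si, sj), v in zip(zip(cls["sample_i"], cls["sample_j"]), dl):
            m[idx[si], idx[sj]] = m[idx[sj], idx[si]] = v
        return ap.dominant_process_threshold(
            cls, PairwiseMatrix(ids, m, "delta_latitude"), **kw
        )

    def test_clean_switch_detected(self):
        dlat = np.repeat([1, 3, 5, 7, 9, 11], 10)
        labels = ["drift"] * 40 + ["heterogeneous_selection"] * 20
        assert self._detect(dlat, labels, bin_width=2.0) == 8.0

    def test_no_switch_returns_none(self):
        dlat = np.repeat([1, 3, 5], 10)
        assert self._detect(dlat, ["drift"] * 30, bin_width=2.0) is None

    def test_exact_tie_counts_as_stochastic(self):
        dlat = np.repeat([1, 3, 5], 10)
        labels = (
            ["drift"] * 10
            + ["drift"] * 5 + ["heterogeneous_selection"] * 5  # 50/50 tie
            + ["heterogeneous_selection"] * 10
        )
        assert self._detect(dlat, labels, bin_width=2.0) == 4.0

    def test_sparse_bins_excluded(self):
        dlat = np.concatenate([np.repeat([1, 3], 10), [5, 5], np.repeat(7, 10)])
        labels = (
            ["drift"] * 20 + ["drift"] * 2 + ["heterogeneous_selection"] * 10
        )
        # the 2-pair bin is ignored by the scan
        assert self._detect(dlat, labels, bin_width=2.0, min_pairs=5) == 6.0
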