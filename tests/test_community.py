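"""OTU table model, rarefaction, diversity, ordination and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from peatmethane.community import (
    DistanceMatrix,
    OTUTable,
    SampleMetadata,
    alpha_diversity,
    beta_dissimilarity,
    pcoa,
    permanova,
    rarefy,
    read_metadata,
    read_otu_table,
)

from _oracles import permanova_f_from_coords


# --------------------------------------------------------------------------
# table model and I/O
# --------------------------------------------------------------------------

class TestOTUTable:
    def test_roundtrip_write_read(self, small_table, tmp_path):
        p = tmp_path / "t.tsv"
        small_table.to_tsv(p)
        back = read_otu_table(p)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)

    def test_literal_fixture_counts(self, tiny_table):
        assert tiny_table.counts.loc["OTU1", "S1"] == 5
        assert tiny_table.counts.loc["OTU3", "S2"] == 8
        assert tiny_table.n_taxa == 3 and tiny_table.n_samples == 2

    def test_duplicate_taxon_id_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["A", "A"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="A"):
            OTUTable(df)

    def test_negative_count_rejected(self):
        df = pd.DataFrame([[1, -2]], index=["A"], columns=["S1", "S2"])
        df.loc["B"] = [0, 1]
        with pytest.raises(ValueError, match="negative"):
            OTUTable(df)

    def test_non_numeric_read_error_names_context(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("taxon_id\tS1\tS2\nA\t3\tx\nB\t1\t2\n")
        with pytest.raises(ValueError, match="S2"):
            read_otu_table(p)

    def test_samples_as_rows_transposed(self, small_table, tmp_path):
        p = tmp_path / "wide.tsv"
        t = small_table.counts.T.copy()
        t.index.name = "sample_id"
        t.to_csv(p, sep="\t")
        back = read_otu_table(p)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)


class TestMetadata:
    def test_roundtrip_and_groups(self, tmp_path):
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b", "c"],
                    "site": ["X", "X", "Y"],
                    "depth_layer": ["0-5", "0-5", "10-15"],
                    "water_table_level": [-8.07, 2.65, -1.01],
                }
            )
        )
        p = tmp_path / "meta.tsv"
        meta.to_tsv(p)
        back = read_metadata(p)
        assert list(back.group_labels("site", ["c", "a"])) == ["Y", "X"]

    def test_implausible_water_table_rejected(self):
        with pytest.raises(ValueError, match="water_table_level"):
            SampleMetadata(
                pd.DataFrame(
                    {
                        "sample_id": ["a", "b"],
                        "site": ["X", "X"],
                        "depth_layer": ["0-5", "0-5"],
                        "water_table_level": [150.0, 0.0],
                    }
                )
            )


# --------------------------------------------------------------------------
# rarefaction
# --------------------------------------------------------------------------

class TestRarefy:
    def test_columns_sum_to_depth_and_subset(self, small_table):
        depth = int(small_table.sample_depths().min())
        out = rarefy(small_table, depth, seed=0)
        assert (out.sample_depths() == depth).all()
        assert (out.counts.to_numpy() <= small_table.counts.to_numpy()).all()
        assert out.taxon_ids == small_table.taxon_ids

    def test_full_depth_is_identity(self, tiny_table):
        out = rarefy(tiny_table, 10, seed=3)  # both columns sum to 10
        pd.testing.assert_frame_equal(out.counts, tiny_table.counts)

    def test_deterministic_given_seed(self, small_table):
        a = rarefy(small_table, 50, seed=11)
        b = rarefy(small_table, 50, seed=11)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_hypergeometric_mean(self):
        # sample [8, 2] at depth 5: E[taxon1 draws] = 5 * 8/10 = 4.0
        table = OTUTable(
            pd.DataFrame({"S1": [8, 2], "S2": [8, 2]}, index=["A", "B"])
        )
        draws = [
            rarefy(table, 5, seed=s).counts.loc["A", "S1"] for s in range(10_000)
        ]
        assert np.mean(draws) == pytest.approx(4.0, abs=0.03)

    def test_depth_too_large_lists_samples(self, tiny_table):
        with pytest.raises(ValueError, match="S1"):
            rarefy(tiny_table, 1000, seed=0)


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------

class TestAlphaDiversity:
    def test_uniform_community(self):
        t = OTUTable(
            pd.DataFrame({"S1": [10, 10, 10, 10], "S2": [10, 10, 10, 10]},
                         index=list("abcd"))
        )
        a = alpha_diversity(t)
        assert a.loc["S1", "shannon"] == pytest.approx(np.log(4))
        assert a.loc["S1", "simpson"] == pytest.approx(0.75)
        assert a.loc["S1", "pielou_evenness"] == pytest.approx(1.0)

    def test_single_taxon_sample(self):
        t = OTUTable(pd.DataFrame({"S1": [7, 0], "S2": [3, 3]}, index=["a", "b"]))
        a = alpha_diversity(t)
        assert a.loc["S1", "shannon"] == 0.0
        assert a.loc["S1", "simpson"] == 0.0
        assert a.loc["S1", "pielou_evenness"] == 0.0
        assert a.loc["S1", "observed_richness"] == 1

    def test_direct_arithmetic_532(self):
        t = OTUTable(pd.DataFrame({"S1": [5, 3, 2], "S2": [1, 1, 1]},
                                  index=list("abc")))
        h = alpha_diversity(t).loc["S1", "shannon"]
        assert h == pytest.approx(1.02965, abs=1e-4)

    def test_matches_scikit_bio(self, small_table):
        skbio_div = pytest.importorskip("skbio.diversity.alpha")
        ours = alpha_diversity(small_table)
        for s in small_table.sample_ids:
            counts = small_table.counts[s].to_numpy()
            assert ours.loc[s, "shannon"] == pytest.approx(
                float(skbio_div.shannon(counts, base=np.e))
            )
            assert ours.loc[s, "simpson"] == pytest.approx(
                float(skbio_div.simpson(counts))
            )


# --------------------------------------------------------------------------
# beta dissimilarity
# --------------------------------------------------------------------------

class TestBetaDissimilarity:
    def test_identical_columns_zero(self):
        t = OTUTable(pd.DataFrame({"S1": [4, 1], "S2": [4, 1]}, index=["a", "b"]))
        for metric in ("bray_curtis", "jaccard"):
            assert beta_dissimilarity(t, metric).values[0, 1] == 0.0

    def test_disjoint_taxa_one(self):
        t = OTUTable(pd.DataFrame({"S1": [4, 0], "S2": [0, 9]}, index=["a", "b"]))
        for metric in ("bray_curtis", "jaccard"):
            assert beta_dissimilarity(t, metric).values[0, 1] == 1.0

    def test_jaccard_abc_bcd(self):
        t = OTUTable(
            pd.DataFrame({"S1": [1, 1, 1, 0], "S2": [0, 2, 5, 1]},
                         index=list("abcd"))
        )
        assert beta_dissimilarity(t, "jaccard").values[0, 1] == pytest.approx(0.5)

    def test_matches_scipy_braycurtis(self, small_table):
        ours = beta_dissimilarity(small_table, "bray_curtis").values
        ref = squareform(pdist(small_table.counts.to_numpy().T, "braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)


# --------------------------------------------------------------------------
# PCoA
# --------------------------------------------------------------------------

class TestPCoA:
    def test_reconstructs_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [-1.0, 1.0]])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, list("abcd"), "euclidean"))
        emb = res.coordinates.to_numpy()
        np.testing.assert_allclose(squareform(pdist(emb)), d, atol=1e-9)

    def test_explained_fractions_sorted_and_sum_one(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, [f"s{i}" for i in range(6)], "euclidean"))
        assert np.all(np.diff(res.explained) <= 1e-12)
        assert res.explained.sum() == pytest.approx(1.0)

    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, list("abc"), "euclidean"))
        assert res.explained[0] == pytest.approx(1.0)

    def test_all_zero_distances_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            pcoa(DistanceMatrix(np.zeros((3, 3)), list("abc"), "x"))

    def test_matches_scikit_bio(self, small_table):
        skbio = pytest.importorskip("skbio")
        dm = beta_dissimilarity(small_table, "bray_curtis")
        ours = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, dm.sample_ids)
        )
        n_pos = len(ours.eigenvalues)
        np.testing.assert_allclose(
            ours.eigenvalues,
            ref.eigvals.to_numpy()[:n_pos],
            rtol=1e-8, atol=1e-10,
        )


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

class TestPermanova:
    @staticmethod
    def _euclid_dm(pts):
        return DistanceMatrix(
            squareform(pdist(pts)), [f"s{i}" for i in range(len(pts))], "euclidean"
        )

    def test_f_matches_centroid_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        res = permanova(self._euclid_dm(pts), labels, n_permutations=99, seed=0)
        f_ref = permanova_f_from_coords(pts, labels)
        assert res.pseudo_f == pytest.approx(f_ref, rel=1e-10)

    def test_label_attached_reordering_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 2))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        r1 = permanova(self._euclid_dm(pts), labels, 99, seed=1)
        r2 = permanova(self._euclid_dm(pts[perm]), labels[perm], 99, seed=1)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-10)

    def test_disjoint_groups_minimal_p(self):
        # all between-distances 1, within 0 -> observed F is maximal; with
        # groups of 8 a random permutation reproducing the same partition
        # has probability 2/C(16,8) ~ 1.6e-4, so no permutation ties
        d = np.ones((16, 16))
        d[:8, :8] = 0.0
        d[8:, 8:] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(16)], "binary")
        res = permanova(dm, ["a"] * 8 + ["b"] * 8, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / (199 + 1))

    def test_singleton_group_rejected(self):
        pts = np.arange(8.0).reshape(-1, 1)
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(self._euclid_dm(pts), ["a"] + ["b"] * 7, 99, 0)

    def test_matches_scikit_bio_statistic(self, small_table):
        skbio = pytest.importorskip("skbio")
        dm = beta_dissimilarity(small_table, "bray_curtis")
        labels = ["x"] * 4 + ["y"] * 4
        ours = permanova(dm, labels, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, dm.sample_ids),
            grouping=labels, permutations=0,
        )
        assert ours.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-10)
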