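import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ampliscreen import community as comm
from ampliscreen.seqtable import UniqueSeqTable


def table_from(counts: dict, metadata=None, taxonomy=None) -> comm.AbundanceTable:
    df = pd.DataFrame(counts)
    meta = metadata if metadata is not None else pd.DataFrame(index=df.columns)
    tax = taxonomy if taxonomy is not None else pd.Series("", index=df.index)
    return comm.AbundanceTable(df, tax, meta)


class TestBrayCurtis:
    def test_identical_vectors(self):
        t = pd.DataFrame({"a": [2, 1, 0], "b": [2, 1, 0]})
        assert comm.bray_curtis(t)["a", "b"] == 0.0

    def test_disjoint_supports(self):
        t = pd.DataFrame({"a": [2, 0], "b": [0, 3]})
        assert comm.bray_curtis(t)["a", "b"] == 1.0

    def test_hand_example(self):
        t = pd.DataFrame({"a": [2, 1, 0], "b": [0, 1, 3]})
        assert comm.bray_curtis(t)["a", "b"] == pytest.approx(5 / 7)

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(ValueError):
            comm.bray_curtis(pd.DataFrame({"a": [1, 1], "b": [0, 0]}))

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 50, size=(30, 8)),
                         columns=[f"s{i}" for i in range(8)])
        t.iloc[0] += 1  # no zero-sum columns
        d = comm.bray_curtis(t).data
        assert np.allclose(d, d.T) and (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0)


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self):
        t = pd.DataFrame({"a": [5, 5], "b": [10, 10]}, index=["A", "B"])
        d = comm.weighted_unifrac(t, "(A:1,B:1);")
        assert d["a", "b"] == pytest.approx(0.0)

    def test_star_tree_collapses_to_l1(self):
        """With unit tip branches and zero-length internal branches, weighted
        UniFrac is the L1 distance between relative-abundance profiles."""
        t = pd.DataFrame({"a": [6, 2, 2], "b": [1, 1, 2]}, index=["A", "B", "C"])
        d = comm.weighted_unifrac(t, "((A:1,B:1):0,C:1);")
        pa = t["a"] / t["a"].sum()
        pb = t["b"] / t["b"].sum()
        assert d["a", "b"] == pytest.approx(np.abs(pa - pb).sum())

    def test_missing_asv_listed(self):
        t = pd.DataFrame({"a": [1, 1], "b": [1, 1]}, index=["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            comm.weighted_unifrac(t, "(A:1,B:1);")


class TestPCoA:
    def test_two_points(self):
        d = np.array([[0.0, 0.8], [0.8, 0.0]])
        res = comm.pcoa(d, ids=["a", "b"])
        coords = res.coordinates["PC1"].to_numpy()
        assert sorted(coords) == pytest.approx([-0.4, 0.4])
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_round_trip(self):
        """PCoA of Euclidean distances reproduces the pairwise geometry."""
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        res = comm.pcoa(d)
        back = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(back - d).max() < 1e-8

    def test_all_zero_distances(self):
        res = comm.pcoa(np.zeros((4, 4)))
        assert np.allclose(res.coordinates.to_numpy(), 0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            comm.pcoa(np.zeros((1, 1)))

    def test_agrees_with_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.integers(1, 40, size=(20, 10)),
                         columns=[f"s{i}" for i in range(10)])
        dm = comm.bray_curtis(t)
        mine = comm.pcoa(dm)
        theirs = skbio_pcoa(dm, method="eigh")
        k = len(mine.eigenvalues)
        assert np.allclose(mine.eigenvalues, theirs.eigvals.to_numpy()[:k], atol=1e-10)
        assert np.allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :k]),
            atol=1e-8,
        )


class TestAsvTable:
    def _seqtable(self, depths):
        counts = pd.DataFrame({s: {"A" * 20: d} for s, d in depths.items()})
        return UniqueSeqTable("bacteria_16s", counts)

    def test_depth_boundary(self):
        meta = pd.DataFrame(index=["ok", "low"])
        t = comm.build_asv_table(self._seqtable({"ok": 5000, "low": 4999}), meta)
        assert t.sample_ids == ["ok"]

    def test_missing_metadata_named(self):
        meta = pd.DataFrame(index=["other"])
        with pytest.raises(ValueError, match="ok"):
            comm.build_asv_table(self._seqtable({"ok": 6000}), meta)

    def test_all_filtered_is_error(self):
        with pytest.raises(ValueError):
            comm.build_asv_table(self._seqtable({"low": 10}), pd.DataFrame(index=["low"]))


class TestRelativeAbundance:
    def _table(self):
        counts = pd.DataFrame(
            {"s1": [980, 15, 5], "s2": [940, 40, 5]},
            index=["asv1", "asv2", "asv3"],
        )
        tax = pd.Series(
            {
                "asv1": "Bacteria;Proteobacteria;Pseudomonas",
                "asv2": "Bacteria;Firmicutes;Bacillus",
                "asv3": "Bacteria;Rare;X",
            }
        )
        meta = pd.DataFrame({"location": ["k", "k"]}, index=["s1", "s2"])
        return comm.AbundanceTable(counts, tax, meta)

    def test_proportions_sum_to_one(self):
        out = comm.relative_abundance(self._table(), rank="phylum")
        assert out.sum(axis=1).to_numpy() == pytest.approx([1.0])

    def test_minor_phyla_pooled(self):
        out = comm.relative_abundance(self._table(), rank="phylum")
        assert "Rare" not in out.columns
        assert any(c.startswith("<") for c in out.columns)

    def test_single_taxon_is_unity(self):
        counts = pd.DataFrame({"s1": [7]}, index=["asv1"])
        tax = pd.Series({"asv1": "Bacteria;OnlyPhylum;G"})
        meta = pd.DataFrame({"location": ["k"]}, index=["s1"])
        out = comm.relative_abundance(comm.AbundanceTable(counts, tax, meta), rank="phylum")
        assert out.loc["k", "OnlyPhylum"] == pytest.approx(1.0)

    def test_unknown_rank(self):
        with pytest.raises(ValueError):
            comm.relative_abundance(self._table(), rank="order")
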