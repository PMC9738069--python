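"""Profile parsing, rarefaction, alpha/beta diversity and PERMANOVA."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gutqs
from gutqs import profiles_diversity as pdv


PROFILE_TSV = "\n".join(
    [
        "clade_name\tS1",
        "k__Bacteria\t100.0",
        "k__Bacteria|p__Bacteroidetes\t100.0",
        "k__Bacteria|p__Bacteroidetes|c__C|o__O|f__F|g__G|s__X\t60.0",
        "k__Bacteria|p__Bacteroidetes|c__C|o__O|f__F|g__G|s__Y\t40.0",
    ]
)


class TestParsing:
    def test_lineages_split_by_deepest_rank(self):
        profiles = pdv.parse_taxonomic_profiles(io.StringIO(PROFILE_TSV), {"S1": 333})
        (p,) = profiles
        assert p.species() == {"X": 60.0, "Y": 40.0}
        assert p.rank_tables["p"] == {"Bacteroidetes": 100.0}
        assert p.total_reads == 333

    def test_empty_stream_gives_empty_set(self):
        assert pdv.parse_taxonomic_profiles(io.StringIO("")) == []

    def test_negative_abundance_rejected(self):
        bad = "clade_name\tS1\nk__Bacteria\t-5.0"
        with pytest.raises(ValueError, match="negative"):
            pdv.parse_taxonomic_profiles(io.StringIO(bad))

    def test_duplicate_sample_column_rejected(self):
        bad = "clade_name\tS1\tS1\nk__Bacteria\t50\t50"
        with pytest.raises(ValueError, match="duplicated"):
            pdv.parse_taxonomic_profiles(io.StringIO(bad))

    def test_unparseable_lineage_names_line(self):
        bad = "clade_name\tS1\nk__Bacteria\t100\nnonsense\t1.0"
        with pytest.raises(ValueError, match="line 3"):
            pdv.parse_taxonomic_profiles(io.StringIO(bad))

    def test_writer_parser_roundtrip(self, small_config):
        from gutqs import synthetic_data as sd

        profiles, truth = sd.simulate_community(small_config)
        buf = io.StringIO()
        import tempfile, os

        with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
            path = fh.name
        sd.write_profiles_tsv(profiles, truth.lineages, path)
        parsed = pdv.parse_taxonomic_profiles(
            path, {p.sample_id: p.total_reads for p in profiles}
        )
        os.unlink(path)
        got = gutqs.species_table(parsed)
        want = gutqs.species_table(profiles)
        pd.testing.assert_frame_equal(got, want, atol=1e-8, rtol=0)


class TestCounts:
    @pytest.mark.parametrize(
        "rel,total,expected",
        [(50.0, 1000, 500), (0.0, 1000, 0), (60.0, 333, 200), (40.0, 333, 133)],
    )
    def test_scale_to_counts_rounds_half_away(self, rel, total, expected):
        p = pdv.TaxonomicProfile("s", {"s": {"A": rel}}, total)
        assert pdv.scale_to_counts(p)["A"] == expected

    def test_missing_total_reads_is_an_error(self):
        p = pdv.TaxonomicProfile("s", {"s": {"A": 50.0}}, None)
        with pytest.raises(ValueError, match="total_reads"):
            pdv.scale_to_counts(p)


class TestRarefy:
    def test_row_at_depth_unchanged(self, rng):
        ct = pdv.CountTable(pd.DataFrame({"A": [30], "B": [70]}, index=["s"]))
        out = pdv.rarefy(ct, depth=100, seed=rng)
        assert out.data.loc["s"].tolist() == [30, 70]
        assert out.provenance == "rarefied" and out.depth == 100

    def test_single_species_row(self, rng):
        ct = pdv.CountTable(pd.DataFrame({"A": [10]}, index=["s"]))
        assert pdv.rarefy(ct, depth=5, seed=rng).data.loc["s", "A"] == 5

    def test_rows_sum_to_depth_and_shallow_dropped(self, rng, caplog):
        ct = pdv.CountTable(
            pd.DataFrame({"A": [500, 30], "B": [700, 20]}, index=["deep", "shallow"])
        )
        with caplog.at_level("WARNING"):
            out = pdv.rarefy(ct, depth=100, seed=rng)
        assert list(out.data.index) == ["deep"]
        assert out.data.sum(axis=1).eq(100).all()
        assert "shallow" in caplog.text

    def test_subsampling_matches_hypergeometric_expectation(self, rng):
        ct = pdv.CountTable(pd.DataFrame({"A": [900], "B": [100]}, index=["s"]))
        draws = [
            pdv.rarefy(ct, depth=100, seed=rng).data.loc["s", "A"] for _ in range(1000)
        ]
        # E[A] = 90; sd of one draw = sqrt(100*.9*.1*(900/999)) ~ 2.85
        se = 2.85 / np.sqrt(1000)
        assert abs(np.mean(draws) - 90.0) < 3 * se


class TestAlpha:
    def test_uniform_four_species(self):
        assert pdv.observed_species([5, 5, 5, 5]) == 4
        assert pdv.shannon([5, 5, 5, 5]) == pytest.approx(2.0)

    def test_single_species_zero_entropy(self):
        assert pdv.shannon([42]) == pytest.approx(0.0)

    def test_half_quarter_quarter_is_1_5_bits(self):
        assert pdv.shannon([2, 1, 1]) == pytest.approx(1.5)

    def test_all_zero_row_raises(self):
        with pytest.raises(ValueError):
            pdv.shannon([0, 0])
        with pytest.raises(ValueError):
            pdv.observed_species([0, 0])

    @given(st.lists(st.integers(1, 50), min_size=2, max_size=12))
    def test_shannon_maximal_for_uniform_and_relabel_invariant(self, counts):
        n = len(counts)
        h = pdv.shannon(counts)
        assert h <= pdv.shannon([1] * n) + 1e-9
        assert h == pytest.approx(pdv.shannon(list(reversed(counts))))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        assert pdv.bray_curtis([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        assert pdv.bray_curtis([1, 0], [0, 4]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert pdv.bray_curtis([2, 2], [1, 3]) == pytest.approx(0.25)

    def test_both_zero_rows_error(self):
        with pytest.raises(ValueError):
            pdv.bray_curtis([0, 0], [0, 0])

    @given(
        st.lists(st.integers(0, 100), min_size=3, max_size=8),
        st.lists(st.integers(0, 100), min_size=3, max_size=8),
    )
    def test_matches_scipy_and_is_symmetric(self, x, y):
        from scipy.spatial.distance import braycurtis

        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) == 0 or sum(y) == 0 or all(a + b == 0 for a, b in zip(x, y)):
            return
        ours = pdv.bray_curtis(x, y)
        assert ours == pytest.approx(braycurtis(x, y), abs=1e-12)
        assert ours == pytest.approx(pdv.bray_curtis(y, x))
        assert 0.0 <= ours <= 1.0


class TestPcoa:
    def test_two_samples_at_distance_d(self):
        d = 0.42
        dm = pdv.DistanceMatrix(["a", "b"], np.array([[0, d], [d, 0]]))
        res = pdv.pcoa(dm)
        coords = res.coordinates["PCo1"].to_numpy()
        assert sorted(np.round(coords, 12)) == pytest.approx([-d / 2, d / 2])
        assert res.explained.sum() <= 1.0 + 1e-12

    def test_euclidean_configuration_reconstructed(self, rng):
        pts = rng.normal(size=(4, 3))
        from scipy.spatial.distance import squareform, pdist

        dm = pdv.DistanceMatrix(list("abcd"), squareform(pdist(pts)))
        res = pdv.pcoa(dm)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, dm.data, atol=1e-8)

    def test_skbio_agreement_on_eigenvalues(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.random((6, 4))
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(pts, metric="braycurtis"))
        ids = [f"s{i}" for i in range(6)]
        ours = pdv.pcoa(pdv.DistanceMatrix(ids, d))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids))
        k = len(ours.eigenvalues)
        assert np.allclose(ours.eigenvalues, ref.eigvals.to_numpy()[:k], atol=1e-8)


class TestPermanova:
    def _toy(self, rng, n=5):
        pts = rng.normal(size=(n, 3))
        from scipy.spatial.distance import squareform, pdist

        return pdv.DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(pts)))

    def test_exhaustive_oracle_five_samples(self, rng):
        """Permutation p matches full enumeration of label orderings."""
        dm = self._toy(rng)
        labels = np.array(["A", "A", "B", "B", "B"])
        res = pdv.permanova(dm, labels, n_permutations=4999, seed=rng)

        d2 = dm.data ** 2
        uniq = np.unique(labels)

        def f_of(lab):
            lab = np.asarray(lab)
            n, a = len(lab), len(uniq)
            sst = d2.sum() / (2 * n)
            ssw = sum(
                d2[np.ix_(lab == u, lab == u)].sum() / (2 * (lab == u).sum())
                for u in uniq
            )
            return ((sst - ssw) / (a - 1)) / (ssw / (n - a))

        f_obs = f_of(labels)
        perms = list(itertools.permutations(labels))
        exact_p = np.mean([f_of(p) >= f_obs - 1e-12 for p in perms])
        assert res.pseudo_f == pytest.approx(f_obs)
        assert abs(res.p_value - exact_p) < 0.03  # Monte-Carlo slack

    def test_separated_clusters_reach_minimum_p(self, rng):
        # unbalanced groups: no label permutation can reproduce the
        # observed partition, so only the observed F attains the maximum
        pts = np.vstack([rng.normal(0, 0.01, (4, 2)), rng.normal(10, 0.01, (6, 2))])
        from scipy.spatial.distance import squareform, pdist

        dm = pdv.DistanceMatrix([f"s{i}" for i in range(10)], squareform(pdist(pts)))
        labels = ["A"] * 4 + ["B"] * 6
        res = pdv.permanova(dm, labels, n_permutations=199, seed=rng)
        assert res.p_value == pytest.approx(1 / 200)

    def test_small_group_rejected(self, rng):
        dm = self._toy(rng)
        with pytest.raises(ValueError):
            pdv.permanova(dm, ["A", "B", "B", "B", "B"], 99, rng)

    def test_skbio_pseudo_f_agreement(self, rng):
        skbio = pytest.importorskip("skbio")
        dm = self._toy(rng, n=8)
        labels = ["A"] * 4 + ["B"] * 4
        ours = pdv.permanova(dm, labels, n_permutations=99, seed=rng)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, dm.ids), grouping=list(labels), permutations=99
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)
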