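"""Rarefaction, diversity, ordination, PERMANOVA and differential abundance."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import shannon as skbio_shannon
from skbio.stats.distance import permanova as skbio_permanova

from tmapro.community import (
    OtuTable,
    alpha_diversity,
    bray_curtis,
    differential_abundance,
    pcoa,
    permanova,
    presence,
    rarefy,
    relative_abundance,
)


def table_from(rows, sample_ids=None, otu_ids=None, **kw):
    rows = np.atleast_2d(np.asarray(rows))
    sample_ids = sample_ids or [f"s{i}" for i in range(rows.shape[0])]
    otu_ids = otu_ids or [f"o{i}" for i in range(rows.shape[1])]
    return OtuTable(pd.DataFrame(rows, index=sample_ids, columns=otu_ids), **kw)


class TestOtuTable:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            table_from([[1, -1]])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            OtuTable(pd.DataFrame([[0.5, 1.0]], index=["s"], columns=["a", "b"]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            table_from([[1, 2]], otu_ids=["a", "a"])

    def test_genus_aggregation_pools_lineages(self):
        t = table_from(
            [[3, 4, 5]],
            otu_ids=["a", "b", "c"],
            taxonomy=pd.Series(
                ["k__B;g__X;s__1", "k__B;g__X;s__2", "k__B;f__F"],
                index=["a", "b", "c"],
            ),
        )
        genus = t.genus_table()
        assert genus.counts.loc["s0", "g__X"] == 7
        assert genus.counts.loc["s0", "g__unclassified"] == 5


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = table_from([[30, 20, 50]])
        out = rarefy(t, depth=100, seed=0)
        assert (out.counts.to_numpy() == [[30, 20, 50]]).all()

    def test_single_otu_sample_collapses_to_depth(self):
        t = table_from([[200, 0]])
        out = rarefy(t, depth=100, seed=0)
        assert out.counts.iloc[0].tolist() == [100, 0]

    def test_sums_exact_and_support_subset(self, rng):
        counts = rng.integers(0, 500, size=(4, 12))
        counts[:, 0] += 200  # guarantee enough depth
        t = table_from(counts)
        out = rarefy(t, depth=150, seed=5)
        assert (out.sample_sums() == 150).all()
        assert ((out.counts.to_numpy() > 0) <= (counts > 0)).all()

    def test_below_depth_samples_dropped(self):
        t = table_from([[5, 5], [100, 100]])
        out = rarefy(t, depth=50, seed=0)
        assert out.sample_ids == ["s1"]

    def test_fixed_seed_reproducible(self):
        t = table_from([[40, 60, 100]])
        a = rarefy(t, depth=50, seed=7).counts
        b = rarefy(t, depth=50, seed=7).counts
        assert a.equals(b)

    def test_mean_counts_match_hypergeometric_expectation(self):
        counts = np.array([[30, 50, 20]])
        t = table_from(counts)
        depth = 40
        draws = np.array(
            [rarefy(t, depth=depth, seed=s).counts.to_numpy()[0] for s in range(1000)]
        )
        expected = depth * counts[0] / counts.sum()
        n_total, n_draw = counts.sum(), depth
        var = (
            n_draw
            * (counts[0] / n_total)
            * (1 - counts[0] / n_total)
            * (n_total - n_draw)
            / (n_total - 1)
        )
        se = np.sqrt(var / 1000)
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9).all()

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy(table_from([[1, 2]]), depth=0)


class TestRelativeAbundance:
    def test_examples(self):
        t = table_from([[4, 0, 0], [1, 1, 2]])
        ra = relative_abundance(t)
        assert ra.iloc[0].tolist() == [1.0, 0.0, 0.0]
        assert ra.iloc[1].tolist() == [0.25, 0.25, 0.5]
        assert np.allclose(ra.sum(axis=1), 1.0)

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance(table_from([[0, 0]]))

    def test_planted_key_taxon_fraction(self, default_study):
        info = default_study.truth["key_taxa"]["Emergencia_timonensis"]
        ra = relative_abundance(default_study.otu_table)
        carrier = info["carrier_samples"][0]
        expected = info["reads_per_carrier"] / 61600
        assert ra.loc[carrier, info["otu_id"]] == pytest.approx(expected)
        assert expected == pytest.approx(8e-5, rel=0.02)


class TestAlphaDiversity:
    def test_uniform_four_taxa_shannon_ln4(self):
        out = alpha_diversity(table_from([[10, 10, 10, 10]]))
        assert out["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert out["observed_otus"].iloc[0] == 4

    def test_chao1_equals_observed_without_singletons(self):
        out = alpha_diversity(table_from([[5, 3, 2, 8]]))
        assert out["chao1"].iloc[0] == out["observed_otus"].iloc[0]

    def test_chao1_bias_corrected_when_no_doubletons(self):
        out = alpha_diversity(table_from([[5, 1, 1]]))
        assert out["chao1"].iloc[0] == pytest.approx(4.0)

    def test_shannon_matches_skbio(self, rng):
        row = rng.integers(0, 50, size=20)
        row[0] += 1
        ours = alpha_diversity(table_from([row]))["shannon"].iloc[0]
        assert ours == pytest.approx(skbio_shannon(row, base=np.e))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity(table_from([[0, 0]]))


class TestBrayCurtis:
    def test_identical_disjoint_and_worked_example(self):
        t = table_from([[2, 0, 2], [2, 0, 2], [0, 2, 2], [0, 3, 0]])
        dm = bray_curtis(t)
        assert dm["s0", "s1"] == 0.0
        assert dm["s0", "s3"] == 1.0  # disjoint supports
        assert dm["s0", "s2"] == pytest.approx(0.5)

    def test_bounds_and_symmetry(self, rng):
        t = table_from(rng.integers(0, 30, size=(6, 10)) + np.eye(6, 10, dtype=int))
        d = dm = bray_curtis(t).data
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestPcoa:
    def test_three_equidistant_points_two_equal_eigenvalues(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        res = pcoa(dm)
        eig = np.asarray(res.eigvals)[:2]
        assert eig[0] == pytest.approx(eig[1])
        assert (eig > 0).all()

    def test_euclidean_roundtrip_recovers_distances(self, rng):
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d))
        coords = res.samples.to_numpy()[:, :2]
        d2 = squareform(pdist(coords))
        assert np.allclose(d, d2, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        d = np.array([[0, 0, 2.0], [0, 0, 2.0], [2.0, 2.0, 0]])
        res = pcoa(DistanceMatrix(d))
        coords = res.samples.to_numpy()
        assert np.allclose(coords[0], coords[1], atol=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(Exception):
            pcoa(np.array([[0, 1.0], [2.0, 0]]))


class TestPermanova:
    def make_separated(self, per_group=8):
        # large enough groups that a permutation recreating the exact
        # partition (which would tie the observed pseudo-F) is not sampled
        a = np.tile([10, 0, 0, 5], (per_group, 1))
        b = np.tile([0, 10, 5, 0], (per_group, 1))
        return table_from(np.vstack([a, b])), np.array(
            ["A"] * per_group + ["B"] * per_group
        )

    def test_perfect_separation(self):
        t, g = self.make_separated()
        res = permanova(bray_curtis(t), g, n_permutations=199, seed=0)
        assert res.r_squared > 0.99
        assert res.p_value == pytest.approx(1 / 200)

    def test_r_squared_deterministic_across_seeds(self, rng):
        t = table_from(rng.integers(1, 50, size=(10, 8)))
        g = np.array(["A"] * 5 + ["B"] * 5)
        dm = bray_curtis(t)
        r1 = permanova(dm, g, n_permutations=99, seed=1).r_squared
        r2 = permanova(dm, g, n_permutations=99, seed=2).r_squared
        assert r1 == r2

    def test_pseudo_f_matches_skbio(self, rng):
        t = table_from(rng.integers(1, 50, size=(12, 9)))
        g = np.array(["A"] * 6 + ["B"] * 6)
        dm = bray_curtis(t)
        ours = permanova(dm, g, n_permutations=99, seed=0)
        ref = skbio_permanova(dm, grouping=list(g), permutations=99)
        assert ours.statistic == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_single_group_rejected(self):
        t, _ = self.make_separated()
        with pytest.raises(ValueError):
            permanova(bray_curtis(t), ["A"] * t.n_samples)


class TestDifferentialAbundance:
    def test_identical_groups_empty(self):
        counts = np.tile([5, 5, 5, 5], (8, 1))
        t = table_from(counts)
        out = differential_abundance(t, np.array(["A"] * 4 + ["B"] * 4))
        assert len(out) == 0

    def test_disjoint_support_otu_survives_fdr(self, rng):
        n = 20
        base = rng.integers(10, 40, size=(2 * n, 4))
        marker = np.concatenate([rng.integers(50, 90, size=n), np.zeros(n, int)])
        t = table_from(np.column_stack([base, marker]))
        groups = np.array(["A"] * n + ["B"] * n)
        out = differential_abundance(t, groups, fdr_threshold=0.01)
        assert "o4" in set(out["otu_id"])
        row = out[out.otu_id == "o4"].iloc[0]
        from scipy.special import comb

        min_exact_p = 2 / comb(2 * n, n, exact=True)
        assert min_exact_p <= row.p_value < 1e-6
        assert row.enriched_in == "A"

    def test_null_mean_false_positives_bounded(self, rng):
        m, fails = 40, []
        fp_counts = []
        for _ in range(30):
            counts = rng.integers(1, 60, size=(16, m))
            t = table_from(counts)
            out = differential_abundance(t, np.array(["A"] * 8 + ["B"] * 8), fdr_threshold=0.05)
            fp_counts.append(len(out))
        assert np.mean(fp_counts) <= 0.05 * m


class TestPresence:
    def test_thresholds(self):
        t = table_from([[0, 1, 5]])
        assert not presence(t, "o0").iloc[0]
        assert presence(t, "o1").iloc[0]
        assert not presence(t, "o1", min_reads=2).iloc[0]

    def test_unknown_otu_rejected(self):
        with pytest.raises(KeyError):
            presence(table_from([[1]]), "nope")

    def test_planted_key_taxon_presence_sums(self, default_study):
        truth = default_study.truth["key_taxa"]["Emergencia_timonensis"]
        vec = presence(default_study.otu_table, truth["otu_id"])
        meta = default_study.otu_table.sample_metadata
        high = meta["producer_status"] == "high"
        assert int(vec[high].sum()) == 13
        assert int(vec[~high].sum()) == 0
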