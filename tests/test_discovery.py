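"""hGM set algebra, d9 producer calls and presence/absence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmapro.community import OtuTable
from tmapro.discovery import (
    HgmExperiment,
    HgmGroup,
    candidate_taxa,
    combination_search,
    core_otus,
    d9_producer_call,
    diagnostic_metrics,
    producer_enriched_taxa,
)


def d9_frame(rows):
    return pd.DataFrame(rows, columns=["time_h", "analyte", "value"])


class TestD9ProducerCall:
    def test_all_zero_is_nonproducer(self):
        curves = d9_frame([(t, a, 0.0) for t in (0, 4, 8) for a in ("d9-TMA", "d9-TMAO")])
        assert d9_producer_call(curves, lod=0.05) is False

    def test_single_value_above_lod_is_producer(self):
        curves = d9_frame([(0, "d9-TMA", 0.0), (4, "d9-TMA", 1.2), (8, "d9-TMA", 0.0)])
        assert d9_producer_call(curves, lod=0.05) is True

    def test_baseline_signal_ignored(self):
        curves = d9_frame([(0, "d9-TMA", 5.0), (4, "d9-TMA", 0.0)])
        assert d9_producer_call(curves, lod=0.05) is False

    def test_gbb_alone_never_calls_producer(self):
        curves = d9_frame([(4, "d9-gBB", 3.0), (4, "d9-TMA", 0.0)])
        assert d9_producer_call(curves, lod=0.05) is False

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            d9_producer_call(d9_frame([]), lod=0.05)

    def test_exactly_one_producer_group_in_fixture(self, default_study):
        d9 = default_study.hgm_d9_curves
        calls = {
            g: any(
                d9_producer_call(sub, lod=0.05)
                for _, sub in d9[d9.group == g].groupby("mouse_id")
            )
            for g in d9.group.unique()
        }
        assert sum(calls.values()) == 1
        assert calls[default_study.truth["hgm"]["producer_group"]]


def make_group(name, mice, producer=False, donor="D"):
    return HgmGroup(
        name=name,
        donor_id=donor,
        producer=producer,
        mice={f"{name}_m{i}": frozenset(s) for i, s in enumerate(mice)},
    )


class TestCoreOtus:
    def test_single_mouse_core_is_its_set(self):
        g = make_group("g", [{"a", "b"}])
        assert core_otus(g) == {"a", "b"}

    def test_disjoint_mice_empty_core(self):
        g = make_group("g", [{"a"}, {"b"}])
        assert core_otus(g) == frozenset()

    def test_fixture_core_cardinality(self, default_study):
        producer = next(g for g in default_study.hgm_experiment.groups if g.producer)
        assert len(core_otus(producer)) == 78


class TestCandidateTaxa:
    def build(self, producer_mice, nonproducer_mice, donor):
        groups = (
            make_group("P", producer_mice, producer=True, donor="DP"),
            make_group("N", nonproducer_mice, donor="DN"),
        )
        donors = {"DP": frozenset(donor), "DN": frozenset().union(*map(frozenset, nonproducer_mice))}
        return HgmExperiment(groups=groups, donors=donors)

    def test_handcrafted_exclusion(self):
        exp = self.build(
            producer_mice=[{"a", "b", "c", "x"}, {"a", "b", "c", "y"}],
            nonproducer_mice=[{"b"}, {"c", "z"}],
            donor={"a", "b", "c", "x", "y"},
        )
        assert candidate_taxa(exp) == {"a"}

    def test_core_subset_of_nonproducer_union_empty(self):
        exp = self.build(
            producer_mice=[{"a", "b"}],
            nonproducer_mice=[{"a"}, {"b"}],
            donor={"a", "b"},
        )
        assert candidate_taxa(exp) == frozenset()

    def test_no_producer_group_rejected(self):
        exp = self.build([{"a"}], [{"b"}], {"a"})
        groups = tuple(
            HgmGroup(g.name, g.donor_id, False, g.mice) for g in exp.groups
        )
        with pytest.raises(ValueError):
            candidate_taxa(HgmExperiment(groups=groups, donors=dict(exp.donors)))

    def brute_force(self, exp):
        """Per-OTU membership test over the whole universe."""
        producer = next(g for g in exp.groups if g.producer)
        universe = set(exp.donors[producer.donor_id])
        for g in exp.groups:
            for s in g.mice.values():
                universe |= s
        out = set()
        for otu in universe:
            in_every_producer_mouse = all(otu in s for s in producer.mice.values())
            in_donor = otu in exp.donors[producer.donor_id]
            seen_elsewhere = any(
                otu in s
                for g in exp.groups
                if not g.producer
                for s in g.mice.values()
            )
            if in_every_producer_mouse and in_donor and not seen_elsewhere:
                out.add(otu)
        return frozenset(out)

    def test_matches_brute_force_on_random_universes(self, rng):
        universe = [f"u{i}" for i in range(30)]
        for _ in range(200):
            donor = set(rng.choice(universe, size=rng.integers(5, 25), replace=False))
            producer_mice = [
                set(rng.choice(sorted(donor), size=rng.integers(1, len(donor) + 1), replace=False))
                for _ in range(rng.integers(1, 4))
            ]
            nonproducer_mice = [
                set(rng.choice(universe, size=rng.integers(0, 15), replace=False))
                for _ in range(rng.integers(1, 4))
            ]
            exp = self.build(producer_mice, nonproducer_mice, donor)
            assert candidate_taxa(exp) == self.brute_force(exp)

    @given(
        extra=st.sets(st.sampled_from([f"u{i}" for i in range(12)]), max_size=6)
    )
    @settings(max_examples=40, derandomize=True)
    def test_antimonotone_in_nonproducer_observations(self, extra):
        producer_mice = [{"a", "b", "c"}, {"a", "b", "c", "u1"}]
        base_non = [{"b"}, {"c"}]
        exp1 = self.build(producer_mice, base_non, {"a", "b", "c", "u1"})
        grown = [base_non[0] | extra, base_non[1]]
        exp2 = self.build(producer_mice, grown, {"a", "b", "c", "u1"})
        assert candidate_taxa(exp2) <= candidate_taxa(exp1)

    def test_core_exclusion_variant_is_weaker(self):
        exp = self.build(
            producer_mice=[{"a", "b", "c"}],
            nonproducer_mice=[{"a"}, {"b"}],  # union covers a,b; core is empty
            donor={"a", "b", "c"},
        )
        assert candidate_taxa(exp, exclude="observed") == {"c"}
        assert candidate_taxa(exp, exclude="core") == {"a", "b", "c"}


class TestDiagnosticMetrics:
    def test_printed_detection_tables(self):
        # 13/51 positives, 0/61 negatives
        det = np.array([True] * 13 + [False] * 38 + [False] * 61)
        pos = np.array([True] * 51 + [False] * 61)
        res = diagnostic_metrics(det, pos)
        assert res.as_dict()["sensitivity"] == 25.5
        assert res.as_dict()["specificity"] == 100.0
        # 22/51 positives, 2/61 negatives
        det = np.array([True] * 22 + [False] * 29 + [True] * 2 + [False] * 59)
        res = diagnostic_metrics(det, pos)
        d = res.as_dict()
        assert (d["sensitivity"], d["specificity"], d["ppv"]) == (43.1, 96.7, 91.7)

    def test_nothing_detected(self):
        res = diagnostic_metrics([False, False], [True, False])
        d = res.as_dict()
        assert d["sensitivity"] == 0.0 and d["specificity"] == 100.0
        assert d["ppv"] is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics([], [])

    @given(
        det=st.lists(st.booleans(), min_size=1, max_size=40),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=60, derandomize=True)
    def test_count_identities(self, det, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 2, size=len(det)).astype(bool)
        r = diagnostic_metrics(det, pos)
        assert r.tp + r.fn == pos.sum()
        assert r.tn + r.fp == (~pos).sum()
        if r.n_positive:
            assert r.sensitivity == pytest.approx(100 * r.tp / r.n_positive)
        if r.n_negative:
            assert r.specificity == pytest.approx(100 * r.tn / r.n_negative)


class TestCombinationSearch:
    def presence_frame(self, rng, n=40, taxa=("A", "B", "C", "D", "E")):
        return pd.DataFrame(
            rng.integers(0, 2, size=(n, len(taxa))).astype(bool), columns=list(taxa)
        )

    def test_single_candidate_equals_direct_metrics(self, rng):
        pres = self.presence_frame(rng)
        pos = rng.integers(0, 2, size=40).astype(bool)
        out = combination_search(["A"], pres, pos)
        direct = diagnostic_metrics(pres["A"], pos, rule=("A",))
        assert len(out) == 1
        assert out.iloc[0].accuracy == pytest.approx(direct.accuracy)

    def test_constructed_optimum_pair(self):
        pos = np.array([True] * 10 + [False] * 10)
        pres = pd.DataFrame(
            {
                "A": [True] * 5 + [False] * 15,
                "B": [False] * 5 + [True] * 5 + [False] * 10,
                "C": [False] * 20,
            }
        )
        out = combination_search(["A", "B", "C"], pres, pos)
        best = out.iloc[0]
        assert best.rule == ("A", "B")
        assert best.sensitivity == 100.0 and best.specificity == 100.0

    def test_matches_per_subset_recomputation(self, rng):
        pres = self.presence_frame(rng)
        pos = rng.integers(0, 2, size=40).astype(bool)
        out = combination_search(list("ABCDE"), pres, pos)
        assert len(out) == 31
        for _, row in out.iterrows():
            direct = diagnostic_metrics(
                pres[list(row.rule)].to_numpy().any(axis=1), pos, rule=row.rule
            )
            assert row.tp == direct.tp and row.accuracy == pytest.approx(direct.accuracy)

    def test_invariant_to_candidate_order(self, rng):
        pres = self.presence_frame(rng)
        pos = rng.integers(0, 2, size=40).astype(bool)
        a = combination_search(list("ABCDE"), pres, pos)
        b = combination_search(list("EDCBA"), pres, pos)
        assert a["rule"].tolist() == b["rule"].tolist()

    def test_or_rule_monotonicity(self, rng):
        pres = self.presence_frame(rng)
        pos = rng.integers(0, 2, size=40).astype(bool)
        out = combination_search(list("ABC"), pres, pos).set_index("rule")
        for rule in out.index:
            for other in out.index:
                if set(rule) <= set(other):
                    assert out.loc[[other]].sensitivity.iloc[0] >= out.loc[[rule]].sensitivity.iloc[0] - 1e-9
                    assert out.loc[[other]].specificity.iloc[0] <= out.loc[[rule]].specificity.iloc[0] + 1e-9

    def test_candidate_cap_enforced(self, rng):
        pres = self.presence_frame(rng, taxa=[f"t{i}" for i in range(25)])
        with pytest.raises(ValueError, match="cap"):
            combination_search(list(pres.columns), pres, np.ones(40, bool))


class TestProducerEnrichedTaxa:
    def build_table(self, producer_counts, nonproducer_counts, genera):
        rows = np.vstack([producer_counts, nonproducer_counts])
        n_p = len(producer_counts)
        mice = [f"p{i}" for i in range(n_p)] + [f"n{i}" for i in range(len(nonproducer_counts))]
        table = OtuTable(
            pd.DataFrame(rows, index=mice, columns=[f"o{j}" for j in range(rows.shape[1])]),
            taxonomy=pd.Series(genera, index=[f"o{j}" for j in range(rows.shape[1])]),
        )
        flags = pd.Series([True] * n_p + [False] * len(nonproducer_counts), index=mice)
        return table, flags

    def test_planted_enriched_genus_found_and_filter_applies(self, rng):
        # o0/o1 share an enriched genus; o2 is flat background
        producer = np.column_stack(
            [rng.integers(400, 600, size=8), rng.integers(400, 600, size=8),
             rng.integers(50, 60, size=8)]
        )
        nonproducer = np.column_stack(
            [rng.integers(1, 10, size=8), rng.integers(1, 10, size=8),
             rng.integers(50, 60, size=8)]
        )
        genera = ["g__Hit;s__a", "g__Hit;s__b", "g__Flat;s__c"]
        table, flags = self.build_table(producer, nonproducer, genera)
        out = producer_enriched_taxa(table, flags, fdr_threshold=0.05)
        assert out["taxon"].tolist() == ["g__Hit"]
        # absent from one producer mouse -> excluded by the core filter
        producer2 = producer.copy()
        producer2[0, :2] = 0
        table2, flags2 = self.build_table(producer2, nonproducer, genera)
        out2 = producer_enriched_taxa(table2, flags2, fdr_threshold=0.05)
        assert "g__Hit" not in set(out2["taxon"])
        out3 = producer_enriched_taxa(
            table2, flags2, fdr_threshold=0.05, require_in_every_producer_mouse=False
        )
        assert "g__Hit" in set(out3["taxon"])

    def test_identical_groups_empty(self, rng):
        counts = rng.integers(10, 30, size=(6, 3))
        table, flags = self.build_table(counts[:3], counts[3:], ["g__A;s__x"] * 3)
        assert len(producer_enriched_taxa(table, flags)) == 0
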