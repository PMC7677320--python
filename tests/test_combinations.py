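"""Drug-combination canonicalization, partner statistics and group trends."""

import numpy as np
import pandas as pd
import pytest

from ahnet.combinations import (
    group_pair_distribution,
    load_combinations,
    pair_target_overlap,
    partner_overlap_pct,
    partner_stats,
    standardize_name,
    standardize_names,
)


class TestStandardizeNames:
    def test_case_space_and_salt_variants(self):
        canonical, _ = standardize_name("Hydrochlorothiazide  ")
        assert canonical == "hydrochlorothiazide"
        canonical, _ = standardize_name("Amlodipine Besylate")
        assert canonical == "amlodipine"

    def test_synonym_mapping(self):
        canonical, mapped = standardize_name("hctz", {"hctz": "hydrochlorothiazide"})
        assert canonical == "hydrochlorothiazide" and mapped

    def test_unmapped_name_flagged_not_dropped(self):
        df = standardize_names(["novel compound"], {"a": "b"})
        assert df.iloc[0]["canonical"] == "novel compound"
        assert not df.iloc[0]["mapped"]

    def test_empty_name_errors(self):
        with pytest.raises(ValueError):
            standardize_name("  ")


class TestLoadCombinations:
    def test_unordered_dedup(self):
        table = pd.DataFrame({"drug_a": ["a", "b"], "drug_b": ["b", "a"]})
        assert load_combinations(table).pairs == [("a", "b")]

    def test_targetless_drug_excluded_with_report(self):
        table = pd.DataFrame({"drug_a": ["a"], "drug_b": ["b"]})
        out = load_combinations(table, validated_drugs={"a"})
        assert out.pairs == []
        assert out.excluded[0]["reason"] == "no_validated_target"
        assert out.excluded[0]["drugs"] == ["b"]

    def test_self_pair_is_error_record(self):
        table = pd.DataFrame({"drug_a": ["a", "a"], "drug_b": ["A ", "b"]})
        out = load_combinations(table)
        assert out.pairs == [("a", "b")]
        assert "self-pair" in out.errors[0]["error"]

    def test_empty_table(self):
        table = pd.DataFrame(columns=["drug_a", "drug_b"])
        assert load_combinations(table).pairs == []


class TestPartnerStats:
    def test_counts_and_percentages(self):
        stats = partner_stats([("a", "b"), ("a", "c")]).set_index("drug")
        assert stats.loc["a", "n_pairs"] == 2
        assert stats.loc["a", "pct_of_pairs"] == 100.0
        assert stats.loc["b", "pct_of_pairs"] == 50.0

    def test_handshake_identity_random_pairs(self):
        rng = np.random.default_rng(13)
        drugs = [f"d{i}" for i in range(12)]
        pairs = set()
        while len(pairs) < 20:
            a, b = rng.choice(drugs, size=2, replace=False)
            pairs.add((min(a, b), max(a, b)))
        stats = partner_stats(sorted(pairs))
        assert stats["n_pairs"].sum() == 2 * len(pairs)

    def test_orientation_invariance(self):
        fwd = partner_stats([("a", "b"), ("a", "c")])
        rev = partner_stats([("c", "a"), ("b", "a")])
        assert fwd.equals(rev)


class TestPartnerOverlap:
    def test_identical_partner_sets(self):
        pairs = [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")]
        assert partner_overlap_pct(pairs, "a", "b") == 100.0

    def test_disjoint_unpaired(self):
        pairs = [("a", "x"), ("b", "y")]
        assert partner_overlap_pct(pairs, "a", "b") == 0.0

    def test_hand_derived_including_each_other(self):
        # P(a)={b,x,y}, P(b)={a,x}, (a,b) paired:
        # shared {x} ∪ {a,b} = 3, union {a,b,x,y} = 4 -> 75%
        pairs = [("a", "b"), ("a", "x"), ("a", "y"), ("b", "x")]
        assert partner_overlap_pct(pairs, "a", "b") == 75.0
        # alternative reading, without the mutual-pair augmentation
        assert partner_overlap_pct(pairs, "a", "b", include_each_other=False) == 25.0

    def test_absent_drug_errors(self):
        with pytest.raises(ValueError):
            partner_overlap_pct([("a", "b")], "a", "z")


class TestGroupPairDistribution:
    def test_all_pairs_within_one_group(self):
        pairs = [("a", "b"), ("a", "c")]
        groups = {"a": "g2", "b": "g2", "c": "g2"}
        dist = group_pair_distribution(pairs, groups)
        assert dist.within_group_pct["g2"] == 100.0
        assert dist.pair_counts[("g2", "g2")] == 2

    def test_counts_sum_to_pair_count(self):
        pairs = [("a", "b"), ("a", "c"), ("b", "d")]
        groups = {"a": "g1", "b": "g2", "c": "g3", "d": "g2"}
        dist = group_pair_distribution(pairs, groups)
        assert sum(dist.pair_counts.values()) == len(pairs)

    def test_unassigned_drug_excluded_with_warning(self):
        pairs = [("a", "b"), ("a", "c")]
        groups = {"a": "g1", "b": "g2", "c": "unassigned"}
        dist = group_pair_distribution(pairs, groups)
        assert sum(dist.pair_counts.values()) == 1
        assert dist.excluded[0]["reason"] == "unassigned_drug"

    def test_planted_trend_recovered(self, pipeline_run, bundle):
        report, _ = pipeline_run
        expected = bundle.ground_truth["combinations"]["trend"]
        assert report["combinations"]["trend"] == " > ".join(
            " = ".join(tie) for tie in expected
        )
        assert report["combinations"]["within_group_pct"]["g2"] == pytest.approx(
            bundle.ground_truth["combinations"]["within_g2_pct"], abs=0.01
        )


class TestPairTargetOverlap:
    def test_disjoint_and_identical_target_sets(self):
        targets = {"a": {"P1", "P2"}, "b": {"P3"}, "c": {"P1", "P2"}}
        df = pair_target_overlap([("a", "b"), ("a", "c")], targets).set_index("drug_b")
        assert df.loc["b", "shared_targets"] == 0 and df.loc["b", "disjoint"]
        assert df.loc["c", "shared_targets"] == 2 and not df.loc["c", "disjoint"]

    def test_drug_without_edges_flagged_unknown(self):
        df = pair_target_overlap([("a", "z")], {"a": {"P1"}})
        assert df.iloc[0]["unknown"] and not df.iloc[0]["disjoint"]

    def test_against_set_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        drugs = [f"d{i}" for i in range(8)]
        universe = [f"P{i}" for i in range(10)]
        targets = {
            d: set(rng.choice(universe, size=rng.integers(1, 5), replace=False))
            for d in drugs
        }
        pairs = [("d0", "d1"), ("d2", "d3"), ("d4", "d5"), ("d6", "d7")]
        df = pair_target_overlap(pairs, targets)
        for _, row in df.iterrows():
            shared = sum(
                1
                for t in universe
                if t in targets[row["drug_a"]] and t in targets[row["drug_b"]]
            )
            assert row["shared_targets"] == shared
            assert row["disjoint"] == (shared == 0)


def test_hub_partner_statistics_recovered(bundle, pipeline_run):
    """The planted hub sits in 13 of 21 pairs (61.9%), the secondary hub in
    4 (19.0%), echoing the study's two highest-degree combination drugs."""
    report, _ = pipeline_run
    top = report["combinations"]["top_partners"]
    hubs = bundle.ground_truth["combinations"]["hubs"]
    assert top[0]["drug"] == hubs["primary"]
    assert top[0]["n_pairs"] == 13
    assert top[0]["pct_of_pairs"] == pytest.approx(61.9, abs=0.1)
    assert top[1]["drug"] == hubs["secondary"]
    assert top[1]["pct_of_pairs"] == pytest.approx(19.0, abs=0.1)
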