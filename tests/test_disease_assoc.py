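"""Association scoring, p-value filtering and condition ranking."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahnet.disease_assoc import (
    association_score,
    common_gene_condition_pct,
    condition_gene_counts,
    derive_p_threshold,
    filter_associations,
    top_conditions,
)
from ahnet.structure_grouping import GROUPS


def _assoc(gene, disease, p, name=None, F=0.5, S=0.5, C=0.5):
    return {
        "gene_symbol": gene,
        "disease_id": disease,
        "disease_name": name or disease,
        "p_value": p,
        "F": F,
        "S": S,
        "C": C,
    }


class TestAssociationScore:
    @pytest.mark.parametrize(
        "F, S, C, s", [(1, 1, 1, 1), (0.5, 0.4, 0.9, 0.18), (0, 0.9, 0.9, 0)]
    )
    def test_examples(self, F, S, C, s):
        assert association_score(F, S, C) == pytest.approx(s)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            association_score(1.2, 0.5, 0.5)

    @given(
        F=st.floats(0, 1), S=st.floats(0, 1), C=st.floats(0, 1)
    )
    @settings(max_examples=100, derandomize=True)
    def test_commutative_and_bounded_by_each_factor(self, F, S, C):
        s = association_score(F, S, C)
        # commutative up to float rounding (product order differs by ulps)
        assert s == pytest.approx(association_score(C, F, S), rel=1e-12)
        assert s == pytest.approx(association_score(S, C, F), rel=1e-12)
        assert s <= min(F, S, C) + 1e-12
        assert 0 <= s <= 1


class TestFilterAssociations:
    @pytest.mark.parametrize(
        "p, kept", [(1.0e-12, True), (3.0e-9, False), (2.0e-9, True)]
    )
    def test_threshold_boundary_inclusive(self, p, kept):
        df = pd.DataFrame([_assoc("G", "EFO:1", p)])
        result, _ = filter_associations(df)
        assert (len(result) == 1) is kept

    def test_non_positive_p_is_error_record(self):
        df = pd.DataFrame([_assoc("G", "EFO:1", 0.0), _assoc("H", "EFO:2", 1e-10)])
        kept, errors = filter_associations(df)
        assert list(kept["gene_symbol"]) == ["H"]
        assert list(errors["gene_symbol"]) == ["G"]

    def test_monotone_and_idempotent(self):
        df = pd.DataFrame(
            [_assoc(f"G{i}", f"EFO:{i}", 10.0 ** -(i + 3)) for i in range(12)]
        )
        loose, _ = filter_associations(df, 1e-8)
        tight, _ = filter_associations(df, 1e-11)
        assert set(tight["gene_symbol"]) <= set(loose["gene_symbol"])
        again, _ = filter_associations(loose, 1e-8)
        assert len(again) == len(loose)

    def test_score_column_added(self):
        kept, _ = filter_associations(
            pd.DataFrame([_assoc("G", "EFO:1", 1e-10, F=0.5, S=0.4, C=0.9)])
        )
        assert kept.iloc[0]["score"] == pytest.approx(0.18)


class TestDeriveThreshold:
    def test_max_of_group_minima(self):
        minima = [1e-12, 1e-10, 2e-9, 1e-11, 1e-15, 1e-13]
        groups = {
            f"g{i + 1}": pd.DataFrame([_assoc("G", "E", p), _assoc("G", "E2", p * 10)])
            for i, p in enumerate(minima)
        }
        assert derive_p_threshold(groups) == 2e-9

    def test_all_groups_share_minimum(self):
        groups = {g: pd.DataFrame([_assoc("G", "E", 1e-9)]) for g in GROUPS}
        assert derive_p_threshold(groups) == 1e-9

    def test_single_group(self):
        assert derive_p_threshold({"g1": pd.DataFrame([_assoc("G", "E", 1e-7)])}) == 1e-7

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            derive_p_threshold({"g1": pd.DataFrame(columns=["p_value"])})

    def test_planted_threshold_recovered_exactly(self, bundle):
        gt = bundle.ground_truth
        per_group = {
            g: bundle.associations[
                bundle.associations["gene_symbol"].isin(gt["gene_sets"][g])
            ]
            for g in GROUPS
        }
        assert derive_p_threshold(per_group) == gt["associations"]["derived_threshold"]


class TestTopConditions:
    def test_order_and_truncation(self):
        df = pd.DataFrame(
            [
                _assoc("G1", "EFO:a", 1e-20, "aneurysm"),
                _assoc("G1", "EFO:b", 1e-15, "brain ischemia"),
                _assoc("G2", "EFO:c", 1e-10, "croup"),
            ]
        )
        top = top_conditions(df, k=2)
        assert list(top["disease_id"]) == ["EFO:a", "EFO:b"]

    def test_tie_broken_alphabetically(self):
        df = pd.DataFrame(
            [_assoc("G", "EFO:z", 1e-10, "zoster"), _assoc("G", "EFO:a", 1e-10, "anxiety")]
        )
        assert list(top_conditions(df, 2)["disease_name"]) == ["anxiety", "zoster"]

    def test_stability_under_weak_additions(self):
        base = pd.DataFrame(
            [_assoc("G", f"EFO:{i}", 10.0 ** -(20 - i)) for i in range(5)]
        )
        extra = pd.concat(
            [base, pd.DataFrame([_assoc("G", "EFO:9", 1e-9, "weak")])],
            ignore_index=True,
        )
        k = 3
        assert list(top_conditions(base, k)["disease_id"]) == list(
            top_conditions(extra, k)["disease_id"]
        )

    def test_planted_top20_recovered_exactly(self, bundle):
        gt = bundle.ground_truth
        kept, _ = filter_associations(bundle.associations)
        for g in GROUPS:
            view = kept[kept["gene_symbol"].isin(gt["gene_sets"][g])]
            top = top_conditions(view, k=20)
            assert set(top["disease_id"]) == set(
                gt["associations"]["planted_conditions"][g]
            )


class TestConditionGeneCounts:
    def test_full_coverage_condition(self, bundle):
        gt = bundle.ground_truth
        full = gt["associations"]["full_coverage_condition"]["g4"]
        kept, _ = filter_associations(bundle.associations)
        view = kept[kept["gene_symbol"].isin(gt["gene_sets"]["g4"])]
        counts = condition_gene_counts(view, [full["id"]])
        assert counts[full["id"]] == full["n_genes"]

    def test_absent_condition_counts_zero(self):
        df = pd.DataFrame([_assoc("G", "EFO:1", 1e-10)])
        assert condition_gene_counts(df, ["EFO:nothere"])["EFO:nothere"] == 0

    def test_counts_bounded_by_gene_set_size(self, bundle):
        gt = bundle.ground_truth
        kept, _ = filter_associations(bundle.associations)
        for g in GROUPS:
            genes = set(gt["gene_sets"][g])
            view = kept[kept["gene_symbol"].isin(genes)]
            assert (condition_gene_counts(view) <= len(genes)).all()


class TestCommonGenePct:
    def test_empty_common_set_errors(self):
        with pytest.raises(ValueError):
            common_gene_condition_pct(set(), pd.DataFrame([_assoc("G", "E", 1e-10)]))

    def test_planted_common_condition_percentages(self, bundle):
        """All 14 triple-common genes hit anxiety (100%); 11 of 14 hit the
        sleep disorder (78.6%), the three excluded ones standing apart."""
        gt = bundle.ground_truth["associations"]
        core = bundle.ground_truth["gene_meta"]["core"]
        kept, _ = filter_associations(bundle.associations)
        pct = common_gene_condition_pct(
            core, kept, [gt["anxiety"]["id"], gt["sleep_disorder"]["id"]]
        )
        assert pct[gt["anxiety"]["id"]] == pytest.approx(100.0)
        assert pct[gt["sleep_disorder"]["id"]] == pytest.approx(78.6, abs=0.1)
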