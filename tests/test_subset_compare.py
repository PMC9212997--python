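"""DE filtering, membership subsets, BH correction, per-codon comparison,
and Venn overlap accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codonbias.errors import DataError
from codonbias.genetic_code import STANDARD_CODE
from codonbias.subset_compare import (
    DERecord,
    GeneSubset,
    bh_adjust,
    compare_codon_usage,
    filter_de,
    membership_subset,
    overlap_counts,
)
from codonbias.synthetic_data import (
    BiasSpec,
    LengthModel,
    simulate_de_table,
    simulate_membership_file,
    simulate_two_group_selection,
    simulate_weight_model,
)

from oracles import oracle_bh, oracle_filter, oracle_regions

CODE = STANDARD_CODE


def subset(name, genes):
    return GeneSubset(name, frozenset(genes), "explicit")


class TestFilterDe:
    def test_passing_record_included(self):
        out = filter_de([DERecord("g", 0.8, 0.04)], direction="up")
        assert out.members == {"g"}

    @pytest.mark.parametrize(
        "lfc,padj",
        [(0.7, 0.04), (0.8, 0.05), (0.7, 0.05), (0.8, np.nan)],
        ids=["lfc-boundary", "padj-boundary", "both-boundary", "missing-padj"],
    )
    def test_strict_thresholds_exclude_boundaries(self, lfc, padj):
        out = filter_de([DERecord("g", lfc, padj)], direction="up")
        assert out.members == frozenset()

    def test_direction_down_and_both(self):
        records = [DERecord("up", 1.0, 0.01), DERecord("down", -1.0, 0.01)]
        assert filter_de(records, direction="down").members == {"down"}
        assert filter_de(records, direction="both").members == {"up", "down"}

    def test_conflicting_duplicates_error_names_gene(self):
        records = [DERecord("gX", 1.0, 0.01), DERecord("gX", 2.0, 0.01)]
        with pytest.raises(DataError, match="gX"):
            filter_de(records)

    def test_identical_duplicates_tolerated(self):
        records = [DERecord("gX", 1.0, 0.01)] * 2
        assert filter_de(records).members == {"gX"}

    def test_planted_truth_count_recovered(self):
        table, truth = simulate_de_table(1000, 137, seed=42)
        out = filter_de(table, direction="both")
        assert len(out.members) == 137
        assert out.members == set(truth.loc[truth.passes, "gene_id"])
        assert filter_de(table, direction="up").members == out.members

    @pytest.mark.parametrize("direction", ["up", "down", "both"])
    def test_matches_brute_force_row_scan(self, rng, direction):
        n = 400
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log2fc": rng.normal(0, 1.2, n),
                "padj": np.where(rng.random(n) < 0.1, np.nan, rng.random(n)),
            }
        )
        out = filter_de(df, 0.05, 0.7, direction)
        expected = oracle_filter(df.itertuples(index=False), 0.05, 0.7, direction)
        assert out.members == expected


class TestMembershipSubset:
    def test_gmt_line_parsed(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("GO:0001649\tosteoblast differentiation\tg1\tg2\n")
        assert membership_subset(p, "GO:0001649").members == {"g1", "g2"}

    def test_repeated_term_unions(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T\td\tg1\tg2\nT\td\tg2\tg3\n")
        assert membership_subset(p, "T").members == {"g1", "g2", "g3"}

    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "sets.tsv"
        p.write_text("T1\tg1\nT1\tg2\nT2\tg3\n")
        assert membership_subset(p, "T2").members == {"g3"}

    def test_absent_term_lists_available(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\td\tg1\tg2\n")
        with pytest.raises(DataError, match="T1"):
            membership_subset(p, "T9")

    def test_synthetic_membership_round_trip(self, tmp_path):
        p = tmp_path / "synthetic.gmt"
        truth = simulate_membership_file(p, n_terms=50, seed=9)
        for term, genes in truth.items():
            assert membership_subset(p, term).members == genes


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_missing_entries_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.02, 0.03])
        assert np.isnan(q[1])
        assert np.allclose(np.delete(q, 1), [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.1, 1.5])

    def test_thousand_random_pvalues_match_quadratic_oracle(self, rng):
        p = rng.random(1000)
        assert np.allclose(bh_adjust(p), oracle_bh(list(p)), atol=0, rtol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_oracle_equivalence_and_monotonicity(self, p):
        q = bh_adjust(p)
        assert np.allclose(q, oracle_bh(p), atol=1e-15)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()  # monotone in p-rank
        assert ((q >= np.asarray(p) - 1e-15) & (q <= 1)).all()


@pytest.fixture(scope="module")
def null_study():
    model = simulate_weight_model(2.0, seed=101)
    sel, sub, bg, _ = simulate_two_group_selection(
        60, 60, model, length_model=LengthModel(200, 5.0), seed=102
    )
    return sel, subset("s", sub), subset("b", bg)


class TestCompareCodonUsage:
    def test_identical_groups_give_zero_statistics(self, null_study):
        sel, sub, _ = null_study
        dup = sel.loc[list(sub.members)]
        mirrored = pd.concat(
            [dup, dup.rename(index=lambda g: g + "_copy")]
        )
        out = compare_codon_usage(
            mirrored,
            subset("a", dup.index),
            subset("b", [g + "_copy" for g in dup.index]),
        )
        tested = out[out.note.isin(["", "degenerate_constant"])]
        assert (tested.relative_change.fillna(0) == 0).all()
        assert (tested.t_stat == 0).all()

    def test_single_codon_families_degenerate_p1(self, null_study):
        sel, sub, bg = null_study
        out = compare_codon_usage(sel, sub, bg).set_index("codon")
        for codon in ("ATG", "TGG"):
            assert out.loc[codon, "note"] == "degenerate_constant"
            assert out.loc[codon, "p_value"] == 1.0
            assert out.loc[codon, "t_stat"] == 0.0

    def test_group_means_and_counts_match_manual(self, null_study):
        sel, sub, bg = null_study
        out = compare_codon_usage(sel, sub, bg).set_index("codon")
        a = sel.loc[[g for g in sel.index if g in sub.members]]
        b = sel.loc[[g for g in sel.index if g in bg.members]]
        codon = "CTG"
        assert out.loc[codon, "mean_subset"] == pytest.approx(a[codon].mean())
        assert out.loc[codon, "mean_background"] == pytest.approx(b[codon].mean())
        assert out.loc[codon, "n_subset"] == a[codon].notna().sum()
        expected_rc = (a[codon].mean() - b[codon].mean()) / b[codon].mean()
        assert out.loc[codon, "relative_change"] == pytest.approx(expected_rc)

    def test_background_defaults_to_complement(self, null_study):
        sel, sub, bg = null_study
        explicit = compare_codon_usage(sel, sub, bg)
        implicit = compare_codon_usage(sel, sub)
        pd.testing.assert_frame_equal(explicit, implicit)

    def test_min_n_failures_reported_not_dropped(self, null_study):
        sel, sub, bg = null_study
        out = compare_codon_usage(sel, sub, bg, min_n=10**6)
        assert len(out) == 61
        assert (out.note == "min_n_not_met").all()
        assert out.p_value.isna().all() and out.q_value.isna().all()

    def test_empty_subset_intersection_errors(self, null_study):
        sel, _, bg = null_study
        with pytest.raises(DataError, match="no genes"):
            compare_codon_usage(sel, subset("ghost", {"nope"}), bg)

    def test_subset_equal_to_background_errors(self, null_study):
        sel, sub, _ = null_study
        with pytest.raises(DataError, match="disjoint"):
            compare_codon_usage(sel.loc[list(sub.members)], sub)

    def test_welch_differs_from_student_under_unequal_n(self, null_study):
        sel, sub, bg = null_study
        small = subset("small", list(sub.members)[:15])
        student = compare_codon_usage(sel, small, bg, equal_var=True)
        welch = compare_codon_usage(sel, small, bg, equal_var=False)
        both = student.p_value.notna() & welch.p_value.notna() & (student.note == "")
        assert not np.allclose(
            student.p_value[both], welch.p_value[both], atol=1e-12
        )

    def test_injected_ctg_bias_detected_with_family_sum_conserved(self):
        model = simulate_weight_model(2.0, seed=7)
        bias = BiasSpec(frozenset({"CTG"}), 3.0)
        sel, sub, bg, _ = simulate_two_group_selection(
            150, 150, model, bias=bias, length_model=LengthModel(300, 5.0), seed=8
        )
        out = compare_codon_usage(sel, subset("s", sub), subset("b", bg)).set_index("codon")
        assert out.loc["CTG", "relative_change"] > 0
        assert out.loc["CTG", "q_value"] < 0.05
        leu = list(CODE.families["L"])
        for ids in (sub, bg):
            sums = sel.loc[list(ids), leu].sum(axis=1)
            assert np.allclose(sums.dropna(), 1.0, atol=1e-12)


class TestOverlapCounts:
    def test_two_set_hand_case(self):
        out = overlap_counts([subset("A", {"g1", "g2"}), subset("B", {"g2", "g3"})])
        assert out.regions == {"+-": 1, "-+": 1, "++": 1}
        assert out.core_genes == ("g2",)

    def test_four_disjoint_sets(self):
        sets = [subset(n, {f"{n}{i}" for i in range(3 + k)}) for k, n in enumerate("ABCD")]
        out = overlap_counts(sets)
        for pattern, count in out.regions.items():
            if pattern.count("+") == 1:
                assert count == 3 + pattern.index("+")
            else:
                assert count == 0
        assert out.core_genes == ()

    def test_duplicate_names_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            overlap_counts([subset("A", {"g"}), subset("A", {"h"})])

    def test_random_sets_match_brute_force_partition(self, rng):
        pool = [f"g{i}" for i in range(1200)]
        named = {
            name: set(rng.choice(pool, size=300, replace=False)) for name in "ABCD"
        }
        out = overlap_counts([subset(n, s) for n, s in named.items()])
        expected = oracle_regions(named)
        union = set().union(*named.values())
        assert out.union_size == len(union)
        for pattern, count in out.regions.items():
            assert count == expected.get(pattern, 0)
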