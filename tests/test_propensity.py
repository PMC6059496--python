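import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prldscreen import (
    AMINO_ACIDS,
    AminoAcidScale,
    LibraryCounts,
    PeptideWindow,
    build_propensity_table,
    count_residues,
    exact_enrichment_test,
    load_published_frequencies,
    odds_ratio,
    propensity_score,
    published_scale,
    published_table,
    score_to_scale,
    table_from_frequencies,
)
from prldscreen.propensity import EstimationError

from _oracles import fisher_two_sided_exact


class TestCountResidues:
    def test_homopolymer(self):
        counts = count_residues([PeptideWindow("AAAAAAAA")])
        assert counts.counts == {"A": 8}
        assert counts.total == 8

    def test_two_screen_isolates(self):
        counts = count_residues([PeptideWindow("MMIWGRLA"), PeptideWindow("AVLLWTSG")])
        assert counts.total == 16
        assert counts.counts["L"] == 3
        assert counts.counts["W"] == 2
        assert counts.counts["A"] == 2
        assert counts.counts["M"] == 2
        assert counts.count("ILMV") == 7

    def test_empty(self):
        counts = count_residues([])
        assert counts.counts == {} and counts.total == 0

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            count_residues([PeptideWindow("AA"), PeptideWindow("AAA")])


class TestOddsRatio:
    def test_published_hydrophobic_group_value(self):
        # selected 0.291 vs reference 0.100: ln(OR) ~ 1.31, printed 1.30
        assert propensity_score(odds_ratio(0.291, 0.100)) == pytest.approx(1.3067, abs=5e-4)

    def test_equal_frequencies_give_unit_odds(self):
        assert odds_ratio(0.5, 0.5) == pytest.approx(1.0)
        assert propensity_score(odds_ratio(0.5, 0.5)) == 0.0

    def test_published_leucine_value(self):
        assert propensity_score(odds_ratio(0.125, 0.045)) == pytest.approx(1.109, abs=5e-4)

    @pytest.mark.parametrize("f_sel,f_ref", [(0.0, 0.5), (0.5, 1.0), (-0.1, 0.5)])
    def test_frequencies_outside_open_interval_rejected(self, f_sel, f_ref):
        with pytest.raises(ValueError, match="pseudocount"):
            odds_ratio(f_sel, f_ref)

    def test_log_of_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            propensity_score(0.0)

    def test_log_examples(self):
        assert propensity_score(1.0) == 0.0
        assert propensity_score(math.e) == pytest.approx(1.0)
        assert propensity_score(odds_ratio(0.060, 0.120)) == pytest.approx(-0.759, abs=5e-4)


class TestExactEnrichmentTest:
    def test_frozen_example(self):
        assert exact_enrichment_test(2, 10, 8, 10) == pytest.approx(0.023014, abs=1e-6)

    def test_identical_rows_are_modal(self):
        assert exact_enrichment_test(3, 10, 3, 10) == pytest.approx(1.0)

    def test_degenerate_margin_convention(self):
        assert exact_enrichment_test(0, 10, 0, 10) == 1.0
        assert exact_enrichment_test(10, 10, 10, 10) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            exact_enrichment_test(11, 10, 2, 10)
        with pytest.raises(ValueError):
            exact_enrichment_test(-1, 10, 2, 10)

    def test_matches_enumeration_oracle_on_small_tables(self):
        # exhaustive over all tables with totals <= 8
        for total_sel in range(1, 9):
            for total_ref in range(1, 9):
                for a in range(total_sel + 1):
                    for c in range(total_ref + 1):
                        expected = float(
                            fisher_two_sided_exact(a, total_sel - a, c, total_ref - c)
                        )
                        got = exact_enrichment_test(a, total_sel, c, total_ref)
                        assert got == pytest.approx(expected, abs=1e-9), (a, total_sel, c, total_ref)


counts_strategy = st.lists(st.integers(0, 40), min_size=20, max_size=20)


class TestBuildPropensityTable:
    def _library(self, values, window_len=8):
        counts = dict(zip(AMINO_ACIDS, values))
        total = sum(values)
        # geometry bookkeeping: fabricate isolates of the right total
        return LibraryCounts(counts=counts, n_isolates=total, window_len=1)

    def test_identical_libraries_give_zero_scores_and_unit_p(self):
        lib = self._library([5] * 20)
        table = build_propensity_table(lib, lib)
        assert np.allclose(table["score"], 0.0)
        assert np.allclose(table["p_value"], 1.0)

    @given(counts_strategy, counts_strategy)
    @settings(deadline=None, max_examples=20)
    def test_antisymmetry_under_library_swap(self, sel_counts, ref_counts):
        sel = self._library([c + 1 for c in sel_counts])
        ref = self._library([c + 1 for c in ref_counts])
        forward = build_propensity_table(sel, ref)
        backward = build_propensity_table(ref, sel)
        assert np.allclose(forward["score"], -backward["score"], atol=1e-12)
        assert np.allclose(forward["p_value"], backward["p_value"], atol=1e-12)

    def test_haldane_pseudocount_keeps_absent_residue_finite(self):
        sel = self._library([0] + [10] * 19)  # alanine absent from selected
        ref = self._library([10] * 20)
        table = build_propensity_table(sel, ref)
        row = table.loc[table.residue == "A"].iloc[0]
        assert math.isfinite(row["score"]) and row["score"] < 0
        assert row["pseudocounted"]
        assert not table.loc[table.residue == "L", "pseudocounted"].item()

    def test_group_rows_pool_member_counts(self):
        sel = self._library(range(1, 21))
        ref = self._library([10] * 20)
        table = build_propensity_table(sel, ref)
        qn = table.loc[table.residue == "QN"].iloc[0]
        q = sel.counts["Q"] + sel.counts["N"]
        assert qn["f_sel"] == pytest.approx(q / sel.total)

    def test_empty_reference_rejected(self):
        sel = self._library([5] * 20)
        empty = LibraryCounts(counts={}, n_isolates=0, window_len=8)
        with pytest.raises(EstimationError):
            build_propensity_table(sel, empty)


class TestPublishedTables:
    @pytest.mark.parametrize("kind", ["degradation", "prion"])
    @pytest.mark.parametrize("context", ["A1", "A2"])
    def test_printed_scores_consistent_with_frequency_rounding(self, kind, context):
        """Propagating the +/-0.0005 rounding interval of each printed
        frequency through the odds-ratio formula always brackets the
        printed ln(OR) — the printed columns are mutually consistent."""
        df = load_published_frequencies(kind)
        slice_ = df.loc[df["context"] == context]
        for _, row in slice_.iterrows():
            corners = []
            for fs in (row.f_sel - 5e-4, row.f_sel + 5e-4):
                for fr in (row.f_ref - 5e-4, row.f_ref + 5e-4):
                    corners.append(math.log(odds_ratio(fs, fr)))
            assert min(corners) - 5e-3 <= row.ln_or_printed <= max(corners) + 5e-3, row.residue

    def test_arginine_score_regenerated(self):
        table = published_table("degradation", "A2")
        assert table.loc[table.residue == "R", "score"].item() == pytest.approx(-0.77, abs=0.05)

    def test_qn_group_frequency_is_member_sum_within_rounding(self):
        df = load_published_frequencies("degradation")
        a2 = df.loc[df["context"] == "A2"].set_index("residue")
        # each printed frequency carries up to 5e-4 rounding error
        assert a2.loc["QN", "f_sel"] == pytest.approx(
            a2.loc["Q", "f_sel"] + a2.loc["N", "f_sel"], abs=1.5e-3
        )

    def test_unknown_kind_or_context_rejected(self):
        with pytest.raises(ValueError):
            load_published_frequencies("bogus")
        with pytest.raises(ValueError):
            published_table("degradation", "A3")


class TestScales:
    def test_published_scale_values(self):
        assert published_scale("a2_degradation")["N"] == pytest.approx(-1.91)
        assert published_scale("a2_prion")["F"] == pytest.approx(0.90)

    def test_score_to_scale_extracts_twenty_residues(self):
        table = published_table("degradation", "A2")
        scale = score_to_scale(table)
        assert scale.complete
        assert scale.kind == "degradation" and scale.context == "A2"
        assert scale["N"] == pytest.approx(-1.91, abs=0.05)

    def test_zero_table_gives_zero_scale(self):
        freqs = {aa: 0.05 for aa in AMINO_ACIDS}
        scale = score_to_scale(table_from_frequencies(freqs, freqs))
        assert all(scale[aa] == 0.0 for aa in AMINO_ACIDS)

    def test_incomplete_table_rejected(self):
        table = published_table("degradation", "A2")
        with pytest.raises(EstimationError):
            score_to_scale(table.loc[table.residue != "N"])

    def test_json_round_trip(self, tmp_path, a2_degradation):
        path = tmp_path / "scale.json"
        a2_degradation.to_json(path)
        loaded = AminoAcidScale.from_json(path)
        assert loaded == a2_degradation

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValueError):
            AminoAcidScale("bad", {"A": float("nan")})
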