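"""Variant databases, b/y fragment masses, and the flanking-ion filter."""

import numpy as np
import pandas as pd
import pytest

from tdpq.masses import WATER, peptide_mass
from tdpq.prsm_io import NamedMod
from tdpq.saav import (SAAVCall, VariantRecord, VariantValidationError,
                       apply_variants, flanking_cleavages, match_fragments,
                       saav_confidence_filter, theoretical_fragments)


class TestApplyVariants:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))

    def test_single_substitution_entry(self):
        ref = {"TP53": self.seq[:71] + "P" + self.seq[72:]}
        out = apply_variants(ref, [VariantRecord("TP53", 72, "P", "R")])
        assert set(out) == {"TP53", "TP53_P72R"}
        diffs = [i for i, (a, b) in enumerate(zip(out["TP53"], out["TP53_P72R"]))
                 if a != b]
        assert diffs == [71]
        assert out["TP53_P72R"][71] == "R"

    def test_empty_variant_table_identity(self):
        ref = {"P1": self.seq}
        out = apply_variants(ref, pd.DataFrame(
            columns=["protein_accession", "position", "ref", "alt"]))
        assert out == ref

    def test_two_variants_two_entries(self):
        ref = {"P1": "ACDEFGHIKL"}
        out = apply_variants(ref, [VariantRecord("P1", 1, "A", "G"),
                                   VariantRecord("P1", 5, "F", "Y")])
        assert set(out) == {"P1", "P1_A1G", "P1_F5Y"}
        # each entry carries exactly one substitution
        assert out["P1_A1G"] == "GCDEFGHIKL"
        assert out["P1_F5Y"] == "ACDEYGHIKL"

    def test_reference_mismatch_lists_offenders(self):
        ref = {"P1": "ACDEFGHIKL"}
        with pytest.raises(VariantValidationError) as err:
            apply_variants(ref, [VariantRecord("P1", 1, "C", "G"),
                                 VariantRecord("P2", 1, "A", "G")])
        assert len(err.value.offenders) == 2


class TestTheoreticalFragments:
    def test_glycine_dipeptide_hand_sums(self):
        frags = theoretical_fragments("GG")
        by = {(r.ion_type, r.frag_index): r.mass for r in frags.itertuples()}
        assert by[("b", 1)] == pytest.approx(57.02146, abs=1e-4)
        assert by[("y", 1)] == pytest.approx(75.03203, abs=1e-4)

    def test_fragment_cardinality(self):
        assert len(theoretical_fragments("PEPTIDEK")) == 2 * (8 - 1)

    def test_fixed_carbamidomethyl_on_cysteine(self):
        with_c = theoretical_fragments("ACK")
        no_fix = theoretical_fragments("ACK", fixed_carbamidomethyl=False)
        b2 = with_c.query("ion_type == 'b' and frag_index == 2")["mass"].iloc[0]
        b2_raw = no_fix.query("ion_type == 'b' and frag_index == 2")["mass"].iloc[0]
        assert b2 - b2_raw == pytest.approx(57.02146)

    def test_by_complementarity(self):
        seq = "MKWVTFISLLFLFSSAYS"
        frags = theoretical_fragments(seq)
        total = peptide_mass(seq)
        n = len(seq)
        b = frags[frags["ion_type"] == "b"].set_index("frag_index")["mass"]
        y = frags[frags["ion_type"] == "y"].set_index("frag_index")["mass"]
        for k in range(1, n):
            assert b[k] + y[n - k] == pytest.approx(total, abs=1e-9)

    def test_named_mod_included_only_when_contained(self):
        mods = [NamedMod(3, 4, "phospho", 79.96633)]
        frags = theoretical_fragments("AAAAAA", mods)
        b = frags[frags["ion_type"] == "b"].set_index("frag_index")["mass"]
        plain = theoretical_fragments("AAAAAA")
        b0 = plain[plain["ion_type"] == "b"].set_index("frag_index")["mass"]
        assert b[2] == b0[2]                       # cuts before the span
        assert b[4] - b0[4] == pytest.approx(79.96633)  # contains the span
        assert b[3] == b0[3]                       # cuts through the span

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            theoretical_fragments("AXZ")


class TestMatching:
    def test_within_tolerance_matches(self):
        frags = theoretical_fragments("PEPTIDEK")
        obs = frags["mass"] * (1 + 10e-6)  # +10 ppm on every fragment
        assert match_fragments(frags, obs, tol_ppm=15).all()

    def test_outside_tolerance_misses(self):
        frags = theoretical_fragments("PEPTIDEK")
        obs = frags["mass"] * (1 + 30e-6)
        assert not match_fragments(frags, obs, tol_ppm=15).any()

    def test_empty_observed(self):
        frags = theoretical_fragments("PEPTIDEK")
        assert not match_fragments(frags, [], tol_ppm=15).any()

    def test_tolerance_validation(self):
        with pytest.raises(ValueError):
            match_fragments(theoretical_fragments("GG"), [100.0], tol_ppm=0)


class TestFlankingGeometry:
    def test_shift_right_of_site(self):
        assert flanking_cleavages(5, (9, 12), 20) == {5, 6, 7, 8}

    def test_shift_left_of_site(self):
        assert flanking_cleavages(10, (2, 4), 20) == {4, 5, 6, 7, 8, 9}

    def test_site_inside_shift_interval(self):
        assert flanking_cleavages(5, (3, 8), 20) == set()

    def test_either_side_mode_superset(self):
        between = flanking_cleavages(5, (9, 12), 20, "toward_shift")
        both = flanking_cleavages(5, (9, 12), 20, "either_side")
        assert between < both
        assert {1, 2, 3, 4} <= both


class TestConfidenceFilter:
    SEQ = "AAAAKAAAAKAAAAKAAAAK"  # 20 residues; site 5, shift interval (12, 15)

    def run_filter(self, n_flanking):
        frags = theoretical_fragments(self.SEQ)
        # observe exactly n_flanking b ions at cleavages 5, 6, ... plus a far y ion
        chosen = frags[(frags["ion_type"] == "b")
                       & frags["cleavage"].isin(range(5, 5 + n_flanking))]
        far = frags[(frags["ion_type"] == "y") & (frags["cleavage"] == 18)]
        obs = pd.concat([chosen, far])["mass"]
        call = SAAVCall("pf", sites=[5], shift_interval=(12, 15), shift_mass=80.0)
        return saav_confidence_filter(call, frags, obs, n_residues=len(self.SEQ))

    def test_no_shift_confident_even_without_fragments(self):
        frags = theoretical_fragments(self.SEQ)
        call = SAAVCall("pf", sites=[5], shift_interval=None)
        out = saav_confidence_filter(call, frags, [], n_residues=len(self.SEQ))
        assert out.confident is True

    def test_two_flanking_ions_not_confident(self):
        out = self.run_filter(2)
        assert out.flanking_counts[5] == 2
        assert out.confident is False

    def test_three_flanking_ions_confident(self):
        out = self.run_filter(3)
        assert out.flanking_counts[5] == 3
        assert out.confident is True

    def test_b_and_y_species_counted_separately(self):
        frags = theoretical_fragments(self.SEQ)
        # one b and one y at cleavage 6 plus one b at 7: three ion species
        sel = frags[((frags["ion_type"] == "b") & frags["cleavage"].isin([6, 7]))
                    | ((frags["ion_type"] == "y") & (frags["cleavage"] == 6))]
        call = SAAVCall("pf", sites=[5], shift_interval=(12, 15))
        out = saav_confidence_filter(call, frags, sel["mass"],
                                     n_residues=len(self.SEQ))
        assert out.flanking_counts[5] == 3
        assert out.confident is True


class TestAgainstSyntheticGroundTruth:
    def test_verdicts_match_generator_truth(self):
        from tdpq.pipeline import saav_calls_from_truth
        from tdpq.simulate import SimConfig, generate_fragment_data, generate_truth

        cfg = SimConfig(n_proteins=40, n_saav_proteoforms=12, saav_shift_prob=0.6,
                        fragment_coverage_prob=0.35, seed=11)
        truth = generate_truth(cfg)
        fragments, verdicts = generate_fragment_data(truth, cfg)
        calls = {c.proteoform_key: c for c in saav_calls_from_truth(truth, fragments)}
        assert len(calls) == 12
        shifted = verdicts["shift_start"].notna()
        assert shifted.any() and (~shifted).any()  # both regimes exercised
        for row in verdicts.itertuples(index=False):
            call = calls[row.proteoform_id]
            assert call.confident == row.confident
            if not np.isnan(row.shift_start):
                assert call.flanking_counts[row.site_core] == row.flanking_count
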