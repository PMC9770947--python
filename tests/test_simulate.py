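"""Generator contracts: determinism, noise structure, exchangeability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdpq.saav import flanking_cleavages, theoretical_fragments
from tdpq.simulate import (ConfigurationError, SimConfig, generate_fragment_data,
                           generate_prsm_tables, generate_reference_proteome,
                           generate_truth, proteoform_core)

AA = set("ACDEFGHIKLMNPQRSTVWY")


class TestReferenceProteome:
    def test_seed_determinism(self):
        t1, _ = generate_reference_proteome(SimConfig(n_proteins=1, seed=7))
        t2, _ = generate_reference_proteome(SimConfig(n_proteins=1, seed=7))
        assert t1 == t2

    def test_cardinality_and_decoy_prefix(self):
        targets, decoys = generate_reference_proteome(SimConfig(n_proteins=100, seed=0))
        assert len(targets) == 100 and len(decoys) == 100
        assert all(a.startswith("DECOY_") for a in decoys)

    def test_alphabet(self):
        targets, decoys = generate_reference_proteome(SimConfig(n_proteins=10, seed=1))
        for seq in list(targets.values()) + list(decoys.values()):
            assert set(seq) <= AA

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_proteins=0)


class TestPrsmTables:
    def test_tables_hash_stable_under_seed(self):
        cfg = SimConfig(n_proteins=20, n_saav_proteoforms=3, n_differential=5, seed=42)
        out1 = generate_prsm_tables(cfg, generate_truth(cfg))[0]
        out2 = generate_prsm_tables(cfg, generate_truth(cfg))[0]
        h1 = pd.util.hash_pandas_object(out1).to_numpy()
        h2 = pd.util.hash_pandas_object(out2).to_numpy()
        assert (h1 == h2).all()

    def test_noise_off_masses_exact(self):
        cfg = SimConfig(n_proteins=15, mass_error_ppm_sd=0.0, isotope_error_prob=0.0,
                        true_hit_fraction=1.0, seed=3)
        truth = generate_truth(cfg)
        prsms, labels = generate_prsm_tables(cfg, truth)
        truth_mass = truth.registry.set_index("proteoform_id")["mass"]
        merged = prsms.merge(labels, on="spectrum_id")
        assert (merged["is_true"]).all()
        expected = truth_mass.loc[merged["proteoform_id"]].to_numpy()
        np.testing.assert_allclose(merged["precursor_mass"].to_numpy(), expected)

    def test_exchangeable_background_when_no_true_hits(self):
        cfg = SimConfig(n_proteins=10, true_hit_fraction=0.0,
                        background_prsms_per_run=80, seed=5)
        prsms, labels = generate_prsm_tables(cfg, generate_truth(cfg))
        assert len(prsms) >= 2000
        assert not labels["is_true"].any()
        n_decoy = int(prsms["is_decoy"].sum())
        n_false_target = int((~prsms["is_decoy"]).sum())
        n = len(prsms)
        # decoy count within 4 binomial SDs of half
        assert abs(n_decoy - n / 2) <= 4 * np.sqrt(n * 0.25)
        assert n_decoy + n_false_target == n

    def test_no_differential_means_equal_truth(self):
        cfg = SimConfig(n_proteins=15, n_differential=0, seed=6)
        reg = generate_truth(cfg).registry
        np.testing.assert_array_equal(reg["abund_SW480"], reg["abund_SW620"])
        assert not reg["differential"].any()

    def test_differential_spikes_recorded(self):
        cfg = SimConfig(n_proteins=30, n_differential=10,
                        fold_changes=(2.0, -1.0), seed=7)
        reg = generate_truth(cfg).registry
        assert reg["differential"].sum() == 10
        spiked = reg[reg["differential"]]
        np.testing.assert_allclose(spiked["abund_SW620"] - spiked["abund_SW480"],
                                   spiked["log2_fc"])

    def test_isotope_errors_land_on_averagine_spacing(self):
        cfg = SimConfig(n_proteins=15, mass_error_ppm_sd=0.0, isotope_error_prob=0.5,
                        true_hit_fraction=1.0, seed=8)
        truth = generate_truth(cfg)
        prsms, labels = generate_prsm_tables(cfg, truth)
        truth_mass = truth.registry.set_index("proteoform_id")["mass"]
        merged = prsms.merge(labels, on="spectrum_id")
        delta = merged["precursor_mass"].to_numpy() - \
            truth_mass.loc[merged["proteoform_id"]].to_numpy()
        buckets = np.round(np.abs(delta), 5)
        assert set(buckets) <= {0.0, 1.00235}
        frac = (buckets > 0).mean()
        assert 0.4 < frac < 0.6

    def test_per_condition_marginal_intensity_lognormal(self):
        cfg = SimConfig(n_proteins=250, proteoforms_per_protein=3.0,
                        true_hit_fraction=1.0, seed=5)
        prsms, _ = generate_prsm_tables(cfg, generate_truth(cfg))
        for cond, sub in prsms.groupby("condition"):
            x = np.log2(sub["intensity"].to_numpy())
            assert len(x) >= 5000
            ks = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).statistic
            assert ks <= 0.05

    def test_missingness_is_intensity_dependent(self):
        # weak proteoforms must drop out more often than strong ones
        cfg = SimConfig(n_proteins=80, intensity_log2_mean_range=(12.0, 24.0),
                        true_hit_fraction=1.0, seed=9)
        truth = generate_truth(cfg)
        prsms, labels = generate_prsm_tables(cfg, truth)
        counts = labels.groupby("proteoform_id").size()
        reg = truth.registry.set_index("proteoform_id")
        abund = reg["abund_SW480"].reindex(counts.index)
        observed = counts.reindex(reg.index).fillna(0)
        lo = observed[reg["abund_SW480"] < 15].mean()
        hi = observed[reg["abund_SW480"] > 21].mean()
        assert hi > 2 * max(lo, 0.5)


class TestFragmentData:
    def make(self, coverage, seed=11, shift_prob=0.5):
        cfg = SimConfig(n_proteins=30, n_saav_proteoforms=8,
                        saav_shift_prob=shift_prob,
                        fragment_coverage_prob=coverage, seed=seed)
        truth = generate_truth(cfg)
        frags, verdicts = generate_fragment_data(truth, cfg)
        return cfg, truth, frags, verdicts

    def test_full_coverage_emits_every_noncrossing_fragment(self):
        cfg, truth, frags, _ = self.make(coverage=1.0)
        reg = truth.registry[truth.registry["saav_ref"] != ""]
        for _, row in reg.iterrows():
            core = proteoform_core(truth, row)
            named, shifts = truth.mods[row["proteoform_id"]]
            theo = theoretical_fragments(core, list(named))
            if shifts:
                a, b = shifts[0].start, shifts[0].end
                theo = theo[(theo["cleavage"] < a) | (theo["cleavage"] > b - 1)]
            got = frags[frags["proteoform_id"] == row["proteoform_id"]]
            assert len(got) == len(theo)

    def test_zero_coverage_empty(self):
        _, _, frags, _ = self.make(coverage=0.0)
        assert len(frags) == 0

    def test_jitter_within_matching_tolerance(self):
        cfg, truth, frags, _ = self.make(coverage=1.0)
        reg = truth.registry[truth.registry["saav_ref"] != ""]
        row = reg.iloc[0]
        core = proteoform_core(truth, row)
        named, _ = truth.mods[row["proteoform_id"]]
        theo = theoretical_fragments(core, list(named))
        got = frags[frags["proteoform_id"] == row["proteoform_id"]]
        merged = got.merge(theo, on=["ion_type", "frag_index", "cleavage"])
        ppm = (merged["observed_mass"] - merged["mass"]).abs() / merged["mass"] * 1e6
        assert (ppm <= 15.0).all()

    def test_flanking_counts_match_brute_force_recount(self):
        _, truth, frags, verdicts = self.make(coverage=0.5, seed=13, shift_prob=1.0)
        for row in verdicts.itertuples(index=False):
            reg_row = truth.registry.set_index("proteoform_id").loc[row.proteoform_id]
            core = proteoform_core(truth, reg_row)
            named, shifts = truth.mods[row.proteoform_id]
            theo = theoretical_fragments(core, list(named))
            ok = flanking_cleavages(int(row.site_core),
                                    (int(row.shift_start), int(row.shift_end)),
                                    len(core))
            obs = frags.loc[frags["proteoform_id"] == row.proteoform_id,
                            "observed_mass"].to_numpy()
            recount = sum(
                1 for t in theo.itertuples(index=False)
                if t.cleavage in ok
                and np.any(np.abs(obs - t.mass) / t.mass * 1e6 <= 15.0))
            assert recount == row.flanking_count

    def test_verdict_threshold(self):
        *_, verdicts = self.make(coverage=0.5, seed=17, shift_prob=1.0)
        for row in verdicts.itertuples(index=False):
            assert row.confident == (row.flanking_count >= 3)
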