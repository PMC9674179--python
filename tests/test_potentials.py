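import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cglandscape import potentials as pot
from cglandscape import synthetic as syn
from cglandscape.structures import (CGSite, CGStructure, Ensemble, PROTEIN,
                                    RNA)


def pair_complex(r, type_a="ALA", type_b="GLY"):
    """Two single-residue chains separated by r."""
    return CGStructure([
        CGSite("A", 1, type_a, PROTEIN, [0.0, 0.0, 0.0]),
        CGSite("B", 1, type_b, PROTEIN, [r, 0.0, 0.0]),
    ])


class TestContactCounting:
    def test_zero_cutoff_empty(self, reference_complex):
        assert pot.count_atomic_contacts(reference_complex, cutoff=0) == {}

    def test_cutoff_monotonicity(self, reference_complex):
        small = pot.count_atomic_contacts(reference_complex, cutoff=4.5)
        big = pot.count_atomic_contacts(reference_complex, cutoff=9.0)
        for pair, c in small.items():
            assert big.get(pair, 0) >= c

    def test_requires_rna(self):
        with pytest.raises(pot.PotentialError, match="RNA"):
            pot.count_atomic_contacts(pair_complex(5.0))


class TestBuildPotential:
    def test_single_type_pair_normalization(self, reference_complex):
        table = pot.build_residue_base_potential(
            reference_complex, {(4, 1): 4}, lam=1.0)
        assert len(table.residue_base_norm) == 1
        ((_, _), v), = table.residue_base_norm.items()
        assert v == 1.0

    def test_pooled_counts_and_scaling(self, reference_complex):
        # residues 4 (LYS) and 68 (THR) against bases 1 (A) and 3 (G)
        counts = {(4, 1): 4, (68, 3): 2}
        p2 = pot.build_residue_base_potential(reference_complex, counts,
                                              lam=2.0)
        eps = p2.residue_base_strengths
        assert eps[("LYS", "A")] == pytest.approx(2.0)
        assert eps[("THR", "G")] == pytest.approx(1.0)

    def test_lambda_linearity(self, demo_potential):
        doubled = demo_potential.with_lambda(2.0)
        for key, v in demo_potential.residue_base_strengths.items():
            assert doubled.residue_base_strengths[key] == \
                pytest.approx(2.0 * v)

    def test_empty_counts_rejected(self, reference_complex):
        with pytest.raises(pot.PotentialError):
            pot.build_residue_base_potential(reference_complex, {})

    def test_tsv_round_trip(self, demo_potential, tmp_path):
        path = tmp_path / "pot.tsv"
        demo_potential.save_tsv(path)
        back = pot.ContactPotential.load_tsv(path)
        assert back.lam == demo_potential.lam
        assert back.residue_base_norm == pytest.approx(
            demo_potential.residue_base_norm)


class TestBindingEnergy:
    def test_out_of_range_is_zero(self):
        p = pot.ContactPotential(default_protein_strength=-1.0)
        c = pair_complex(p.contact_range + 3 * p.well_width + 0.1)
        assert pot.binding_energy(c, "A", "B", p) == 0.0

    def test_single_pair_at_contact_range(self):
        p = pot.ContactPotential(default_protein_strength=-1.0)
        c = pair_complex(p.contact_range)
        assert pot.binding_energy(c, "A", "B", p) == pytest.approx(
            -1.0, abs=1e-6)

    def test_rigid_motion_invariance(self, spec, demo_potential):
        s = syn.make_two_domain_receptor(spec)[1]
        e0 = pot.binding_energy(s, "A", "B", demo_potential)
        rot = Rotation.random(random_state=5).as_matrix()
        moved = s.with_coords(s.coords @ rot.T + [3.0, 1.0, -9.0])
        assert pot.binding_energy(moved, "A", "B", demo_potential) == \
            pytest.approx(e0, abs=1e-9)
        assert e0 < 0

    def test_additivity_over_chain_pairs(self, spec, demo_potential):
        s = syn.make_sumo_mimic_complex(spec)
        p = pot.hydrophobicity_scan_potential(1.0)
        e_total = pot.binding_energy(s, {"A"}, {"B", "S"}, p)
        e_b = pot.binding_energy(s, {"A"}, {"B"}, p)
        e_s = pot.binding_energy(s, {"A"}, {"S"}, p)
        assert e_total == pytest.approx(e_b + e_s, abs=1e-9)

    def test_overlapping_partners_rejected(self, closed_receptor,
                                           demo_potential):
        with pytest.raises(pot.PotentialError, match="overlap"):
            pot.binding_energy(closed_receptor, {"A"}, {"A", "B"},
                               demo_potential)


class TestFrustration:
    @staticmethod
    def planted_complex():
        """Strong native ILE-ILE contact in a weak polar background."""
        sites = []
        for i, t in enumerate(["ILE", "SER", "SER", "SER", "SER", "SER"]):
            sites.append(CGSite("A", i + 1, t, PROTEIN,
                                [0.0, 3.8 * i, 0.0]))
        for i, t in enumerate(["ILE", "SER", "SER", "SER", "SER", "SER"]):
            sites.append(CGSite("B", i + 1, t, PROTEIN,
                                [5.0, 3.8 * i, 0.0]))
        return CGStructure(sites)

    def test_homogeneous_composition_is_degenerate(self):
        s = pair_complex(5.0, "ALA", "ALA")
        p = pot.hydrophobicity_scan_potential(1.0)
        with pytest.raises(pot.PotentialError, match="zero decoy"):
            pot.frustration_zscores(s, p, n_decoys=200, seed=0)

    def test_planted_strong_pair_minimally_frustrated(self):
        s = self.planted_complex()
        p = pot.hydrophobicity_scan_potential(1.0)
        rep = pot.frustration_zscores(s, p, n_decoys=2000, seed=1)
        df = rep.contacts
        ii = df[(df.native_energy < -0.9)]
        assert len(ii) >= 1
        assert (ii.z > rep.z_threshold).all()
        assert rep.n_minimally_frustrated >= 1

    def test_count_non_increasing_in_threshold(self):
        s = self.planted_complex()
        p = pot.hydrophobicity_scan_potential(1.0)
        counts = []
        for zt in (0.3, 0.78, 1.5):
            rep = pot.frustration_zscores(s, p, n_decoys=1000, seed=2,
                                          z_threshold=zt)
            counts.append(rep.n_minimally_frustrated)
        assert counts[0] >= counts[1] >= counts[2]

    def test_matches_closed_form_two_type_decoys(self):
        """With a 2-type composition the decoy distribution is a known
        finite mixture; the Monte-Carlo z must match it within 3 SE."""
        s = self.planted_complex()
        p = pot.hydrophobicity_scan_potential(1.0)
        n_decoys = 10000
        rep = pot.frustration_zscores(s, p, n_decoys=n_decoys, seed=3)
        # composition: 2/12 ILE, 10/12 SER; decoy energies per pair type
        h_i = 1.0
        f_i = 2.0 / 12.0
        probs = {
            (-h_i * h_i): f_i * f_i,          # ILE-ILE
            0.0: 1.0 - f_i * f_i,             # any pair involving SER
        }
        mean = sum(e * p_ for e, p_ in probs.items())
        var = sum((e - mean) ** 2 * p_ for e, p_ in probs.items())
        row = rep.contacts.iloc[
            rep.contacts.native_energy.idxmin()]
        sw = row.native_energy / (-h_i * h_i)  # switching factor
        se_mean = np.sqrt(var) * abs(sw) / np.sqrt(n_decoys)
        assert row.decoy_mean == pytest.approx(mean * sw, abs=3 * se_mean)
        z_expect = (mean * sw - row.native_energy) / (np.sqrt(var) * sw)
        assert row.z == pytest.approx(z_expect, rel=0.1)


class TestRankModels:
    @staticmethod
    def two_frame_ensemble():
        s = TestFrustration.planted_complex()
        # frame 1: pull the strong pair apart so it loses its contact
        c2 = s.coords.copy()
        c2[6] += [8.0, 0.0, 0.0]
        return Ensemble(s, np.array([s.coords, c2]))

    def test_count_dominates_energy(self):
        ens = self.two_frame_ensemble()
        p = pot.hydrophobicity_scan_potential(1.0)
        df, selected = pot.rank_models(ens, p, n_decoys=500, seed=4)
        assert df.loc[0, "n_minimally_frustrated"] >= \
            df.loc[1, "n_minimally_frustrated"]
        assert selected == int(df.sort_values(
            ["n_minimally_frustrated", "energy"],
            ascending=[False, True]).iloc[0]["frame"])

    def test_tie_broken_by_lowest_energy(self):
        import pandas as pd
        df = pd.DataFrame({
            "frame": [0, 1],
            "energy": [-5.0, -7.0],
            "n_minimally_frustrated": [4, 4],
        })
        order = df.sort_values(["n_minimally_frustrated", "energy",
                                "frame"], ascending=[False, True, True])
        assert int(order.iloc[0]["frame"]) == 1

    def test_single_frame(self):
        s = TestFrustration.planted_complex()
        ens = Ensemble(s, s.coords[None])
        p = pot.hydrophobicity_scan_potential(1.0)
        _, selected = pot.rank_models(ens, p, n_decoys=300, seed=5)
        assert selected == 0


class TestSequenceScan:
    def test_threading_own_sequence_matches_reference(self):
        template = syn.make_sim_template()
        p = pot.hydrophobicity_scan_potential(1.0)
        own = "".join(
            {"VAL": "V", "ILE": "I", "LEU": "L"}[
                template.sites[i].residue_type]
            for i in template.annotation_indices("peptide"))
        profile, ref_e = pot.scan_sequence_binding(own, template,
                                                   "peptide", p)
        assert profile.iloc[0]["energy"] == pytest.approx(ref_e, abs=1e-12)

    def test_unknown_residue_rejected(self):
        template = syn.make_sim_template()
        p = pot.hydrophobicity_scan_potential(1.0)
        with pytest.raises(pot.PotentialError, match="window"):
            pot.scan_sequence_binding("ACDXKL", template, "peptide", p)


class TestCalibrateScale:
    def test_recovers_planted_lambda(self):
        """A noiseless monotone affinity model: calibration recovers the
        scale that generated the target."""
        lam_star = 1.7

        def affinity(lam):
            return 8.0 * (lam / lam_star) ** 2.2, 0.1

        target, _ = affinity(lam_star)
        lam, dg, _ = pot.calibrate_scale(affinity, target, tolerance=0.05)
        assert lam == pytest.approx(lam_star, rel=0.1)
        assert dg == pytest.approx(8.0, abs=0.06)

    def test_unreachable_target_reports_bracketing(self):
        def affinity(lam):
            return 1.0, 0.1  # flat: can never reach 8

        with pytest.raises(pot.PotentialError, match="bracket"):
            pot.calibrate_scale(affinity, 8.0, tolerance=0.1,
                                max_expand=2)

    def test_monotonicity_checked_on_bracket(self):
        calls = []

        def affinity(lam):
            calls.append(lam)
            return {1.0: 9.0, 2.0: 2.0}.get(lam, 5.0), 0.1

        with pytest.raises(pot.PotentialError):
            pot.calibrate_scale(affinity, 8.0, tolerance=0.1,
                                bracket=(1.0, 2.0), max_expand=0)
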