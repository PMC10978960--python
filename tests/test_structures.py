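"""Coordinate parsing, landmark mapping, gate state, H-bonds, tautomers,
cations, ASU chain RMSD, interdomain rotation and the peptide-plane flip."""

import numpy as np
import pytest

from sahhkit.errors import GeometryError, InputError, MappingError
from sahhkit.refdata import get_reference
from sahhkit.sequences import ProteinSequence
from sahhkit.structures import (
    asu_chain_rmsd,
    classify_gate_state,
    detect_cation,
    domain_rotation_angle,
    enumerate_hbonds,
    infer_tautomer,
    load_and_inventory,
    load_structure,
    map_reference_residues,
    peptide_flip_angle,
    structure_report,
)
from sahhkit.synthetic import (
    ToySiteSpec,
    flip_landmarks,
    make_flip_pair,
    make_toy_dimer,
    make_toy_site,
    make_two_domain_pair,
    toy_landmarks,
    toy_site_model,
)

from conftest import ca_model_from_sequence
from oracles import brute_force_polar_pairs


@pytest.fixture()
def in_site(tmp_path):
    path, truth = make_toy_site(
        ToySiteSpec(d_gate=4.2, ligand="inosine", cation="NA", seed=0),
        tmp_path / "site_in.pdb",
    )
    return path, truth


class TestLoading:
    def test_round_trip_reproduces_target_geometry(self, in_site):
        path, _ = in_site
        model, inventory = load_and_inventory(path)
        assert inventory["nucleoside"] == ["INO"]
        assert inventory["ion"] == ["NA"]
        gate = classify_gate_state(model, toy_landmarks(model))[0]
        assert gate.d_gate == pytest.approx(4.2, abs=1e-6)
        assert gate.d_his_o5prime == pytest.approx(2.7, abs=1e-6)

    def test_atom_only_file_has_empty_het_inventory(self, tmp_path):
        path, _ = make_toy_site(
            ToySiteSpec(ligand=None, cation=None, seed=0), tmp_path / "bare.pdb"
        )
        _, inventory = load_and_inventory(path)
        assert all(not v for v in inventory.values())

    def test_unparseable_file_raises_format_error(self, tmp_path):
        from sahhkit.errors import FormatError

        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\nnot a coordinate file {{{\n")
        with pytest.raises((FormatError, InputError)):
            load_structure(bad)

    def test_altloc_keeps_highest_occupancy_conformer(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70 10.00           C\n"
            "ATOM      3  CB AALA A   1       1.000   0.000   0.000  0.50 10.00           C\n"
            "ATOM      4  CB BALA A   1       6.000   0.000   0.000  0.50 10.00           C\n"
            "END\n"
        )
        model = load_structure(pdb)
        res = model.chains[0].residues[0]
        assert res.coord("CA")[0] == pytest.approx(5.0)  # higher occupancy wins
        assert res.coord("CB")[0] == pytest.approx(1.0)  # tie -> altloc A


class TestResidueMapping:
    def test_reference_chain_maps_identically(self, pfu_ref):
        model = ca_model_from_sequence(pfu_ref.ref_sequence.residues)
        rmap = map_reference_residues(model, pfu_ref)
        assert rmap["A"]["gate_his"].seqid == 298
        assert rmap["A"]["gate_phe"].seqid == 299
        assert rmap["A"]["catalytic_asp"].seqid == 128
        assert rmap["A"]["motif_5"].seqid == 59

    def test_lys74_lands_on_motif_position_5_of_mma(self, pfu_ref):
        mma = get_reference("mma")
        model = ca_model_from_sequence(mma.ref_sequence.residues)
        rmap = map_reference_residues(model, mma)
        assert rmap["A"]["motif_5"].seqid == 74
        assert rmap["A"]["c6_partner"].seqid == 362

    def test_unrelated_chain_raises_mapping_error(self, pfu_ref):
        rng = np.random.default_rng(0)
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 300))
        model = ca_model_from_sequence(seq)
        with pytest.raises(MappingError):
            map_reference_residues(model, pfu_ref, identity_floor_pct=60.0)


class TestGateState:
    @pytest.mark.parametrize(
        "d_gate,partner,expected",
        [(3.0, False, "IN"), (4.2, False, "IN"), (6.9, False, "undetermined"),
         (8.5, True, "OUT"), (10.4, True, "OUT")],
    )
    def test_constructed_distances_classify_as_designed(
        self, d_gate, partner, expected
    ):
        model = toy_site_model(
            ToySiteSpec(d_gate=d_gate, place_out_partner=partner, seed=1)
        )
        gate = classify_gate_state(model, toy_landmarks(model))[0]
        assert gate.state == expected
        assert gate.d_gate == pytest.approx(d_gate, abs=1e-6)
        if partner:
            assert gate.d_out_partner == pytest.approx(2.7, abs=1e-6)

    def test_far_gate_without_out_partner_contact_is_undetermined(self):
        model = toy_site_model(ToySiteSpec(d_gate=10.4, place_out_partner=False))
        gate = classify_gate_state(model, toy_landmarks(model))[0]
        assert gate.state == "undetermined"

    def test_missing_side_chain_atoms_reported(self):
        model = toy_site_model(ToySiteSpec(d_gate=4.2))
        his = toy_landmarks(model)["A"]["gate_his"]
        for name in ("CG", "ND1", "CD2", "CE1", "NE2"):
            his.atoms.pop(name)
        gate = classify_gate_state(model, toy_landmarks(model))[0]
        assert gate.state == "undetermined"
        assert "missing" in gate.reason

    def test_rotamer_and_chi_angles_reported(self):
        model = toy_site_model(ToySiteSpec(d_gate=4.2))
        gate = classify_gate_state(model, toy_landmarks(model))[0]
        assert gate.chi1 is not None and gate.chi2 is not None
        assert gate.rotamer in ("gauche-", "gauche+", "trans")


class TestHBonds:
    def test_matches_brute_force_all_pairs_scan(self):
        model = toy_site_model(ToySiteSpec(d_gate=4.2, place_out_partner=True))
        for cutoff in (2.0, 3.0, 3.5, 5.0, 8.0):
            bonds = enumerate_hbonds(model, "INO", cutoff=cutoff)
            got = {
                (b.ligand_atom, b.partner_chain, b.partner_residue, b.partner_atom)
                for b in bonds
            }
            lig = next(r for _, r in model.het_groups if r.name == "INO")
            lig_atoms = [
                (a.name, a.pos) for a in lig.atoms.values()
                if a.element in ("N", "O", "S")
            ]
            prot = [
                (c.id, r.label, a.name, a.pos)
                for c in model.chains
                for r in c.residues
                for a in r.atoms.values()
                if a.element in ("N", "O", "S")
            ]
            assert got == brute_force_polar_pairs(lig_atoms, prot, cutoff)

    def test_monotone_in_cutoff_and_empty_at_zero(self):
        model = toy_site_model(ToySiteSpec(d_gate=4.2))
        previous = set()
        for cutoff in (0.0, 2.5, 3.0, 3.5, 4.5, 6.0):
            bonds = {
                (b.ligand_atom, b.partner_residue, b.partner_atom)
                for b in enumerate_hbonds(model, "INO", cutoff=cutoff)
            }
            if cutoff == 0.0:
                assert bonds == set()
            assert previous.issubset(bonds)
            previous = bonds

    def test_his_nd1_to_o5prime_contact_found(self):
        model = toy_site_model(ToySiteSpec(d_gate=4.2, d_his_o5prime=2.7))
        bonds = enumerate_hbonds(model, "INO", cutoff=3.5)
        contact = [
            b for b in bonds if b.ligand_atom == "O5'" and b.partner_atom == "ND1"
        ]
        assert len(contact) == 1
        assert contact[0].distance == pytest.approx(2.7, abs=1e-6)
        assert not contact[0].partner_is_mainchain

    def test_absent_ligand_rejected(self):
        model = toy_site_model(ToySiteSpec(ligand=None))
        with pytest.raises(InputError):
            enumerate_hbonds(model, "INO")

    def test_results_sorted_by_distance(self):
        model = toy_site_model(ToySiteSpec(d_gate=4.2))
        bonds = enumerate_hbonds(model, "INO", cutoff=6.0)
        distances = [b.distance for b in bonds]
        assert distances == sorted(distances)


class TestTautomer:
    def test_o6_mainchain_contact_implies_imino_hydroxy(self):
        model = toy_site_model(ToySiteSpec(ligand="inosine", o6_contact=True))
        bonds = enumerate_hbonds(model, "INO")
        call = infer_tautomer(bonds, "INO")
        assert call.call == "imino_hydroxy"
        assert call.evidence and call.evidence[0].ligand_atom == "O6"

    def test_no_o6_contact_defaults_to_amino_oxo(self):
        model = toy_site_model(ToySiteSpec(ligand="inosine", o6_contact=False))
        call = infer_tautomer(enumerate_hbonds(model, "INO"), "INO")
        assert call.call == "amino_oxo"

    def test_adenosine_called_amino(self):
        model = toy_site_model(ToySiteSpec(ligand="adenosine", o6_contact=True))
        call = infer_tautomer(enumerate_hbonds(model, "ADN"), "ADN")
        assert call.call == "amino"
        assert call.evidence[0].ligand_atom == "N6"

    def test_unknown_ligand_undetermined(self):
        assert infer_tautomer([], "XYZ").call == "undetermined"


class TestCations:
    def test_planted_cation_detected_near_hinge(self):
        model = toy_site_model(ToySiteSpec(cation="K", d_cation=5.0))
        hinge = [r for c in model.chains for r in c.residues if r.seqid == 200]
        report = detect_cation(model, hinge, cutoff=8.0)
        assert len(report) == 1
        assert report[0]["element"] == "K"
        assert report[0]["min_distance"] == pytest.approx(5.0, abs=1e-6)

    def test_absence_gives_empty_report(self):
        model = toy_site_model(ToySiteSpec(cation=None))
        hinge = [r for c in model.chains for r in c.residues if r.seqid == 200]
        assert detect_cation(model, hinge, cutoff=8.0) == []

    def test_cation_outside_cutoff_not_reported(self):
        model = toy_site_model(ToySiteSpec(cation="NA", d_cation=9.5))
        hinge = [r for c in model.chains for r in c.residues if r.seqid == 200]
        assert detect_cation(model, hinge, cutoff=8.0) == []


class TestAsuChainRmsd:
    def test_rigid_copy_has_zero_rmsd(self):
        model = make_toy_dimer(n_residues=80, sigma=0.0, seed=0)
        table = asu_chain_rmsd(model)
        assert len(table) == 1
        assert table.iloc[0]["rmsd"] == pytest.approx(0.0, abs=1e-9)
        assert table.iloc[0]["n_atoms"] == 80

    def test_noise_recovers_sigma_sqrt3(self):
        sigma = 0.3
        values = [
            asu_chain_rmsd(make_toy_dimer(120, sigma=sigma, seed=s)).iloc[0]["rmsd"]
            for s in range(20)
        ]
        assert np.mean(values) == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_single_chain_yields_empty_table(self):
        model = make_toy_dimer(40, seed=0)
        model.chains = model.chains[:1]
        assert asu_chain_rmsd(model).empty


class TestDomainRotation:
    def test_self_comparison_is_zero(self):
        model, _, ranges = make_two_domain_pair(10.0, seed=0)
        call = domain_rotation_angle(model, model, ranges)
        assert call.angle_deg < 0.1
        assert call.call == "closed"

    @pytest.mark.parametrize("angle", [2.0, 8.0, 18.0, 27.0, 40.0])
    def test_constructed_rotation_recovered(self, angle):
        ma, mb, ranges = make_two_domain_pair(angle, seed=5)
        call = domain_rotation_angle(ma, mb, ranges)
        assert call.angle_deg == pytest.approx(angle, abs=0.2)

    def test_open_anchor_vicinity_calls_open(self):
        ma, mb, ranges = make_two_domain_pair(18.0, seed=7)
        call = domain_rotation_angle(ma, mb, ranges, reference_state="closed")
        assert call.call == "open"

    def test_missing_domain_range_rejected(self):
        from sahhkit.errors import ConfigurationError

        ma, mb, _ = make_two_domain_pair(10.0, seed=0)
        with pytest.raises(ConfigurationError):
            domain_rotation_angle(ma, mb, {"cofactor_binding": (1, 40)})


class TestPeptideFlip:
    def test_constructed_flip_measures_180_degrees(self):
        a, b = make_flip_pair()
        angle, flipped = peptide_flip_angle(
            a, b, flip_landmarks(a), flip_landmarks(b)
        )
        assert angle == pytest.approx(180.0, abs=1.0)
        assert flipped

    def test_self_comparison_no_flip(self):
        a, _ = make_flip_pair()
        angle, flipped = peptide_flip_angle(
            a, a, flip_landmarks(a), flip_landmarks(a)
        )
        assert angle == pytest.approx(0.0, abs=1e-6)
        assert not flipped

    def test_missing_backbone_atom_rejected(self):
        a, b = make_flip_pair()
        flip_landmarks(a)["A"]["gate_his"].atoms.pop("O")
        with pytest.raises(GeometryError):
            peptide_flip_angle(a, b, flip_landmarks(a), flip_landmarks(b))


class TestStructureReport:
    def test_combined_report_for_toy_site(self):
        model = toy_site_model(
            ToySiteSpec(d_gate=4.2, ligand="inosine", cation="NA", n_chains=2,
                        seed=3)
        )
        report = structure_report(model, residue_map=toy_landmarks(model))
        assert report["inventory"]["nucleoside"] == ["INO", "INO"]
        states = {g["chain_id"]: g["state"] for g in report["gate_states"]}
        assert states == {"A": "IN", "B": "IN"}
        assert any(v["tautomer"] == "imino_hydroxy" for v in report["ligands"].values())
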