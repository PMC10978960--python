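"""Alignment, fingerprint-motif extraction/classification, architecture
features, homologue scan and pathway inference."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from sahhkit.errors import ConfigurationError, InputError
from sahhkit.sequences import (
    FingerprintMotif,
    ProteinSequence,
    classify_motif,
    detect_architecture_features,
    extract_fingerprint,
    global_align,
    infer_pathway,
    scan_homolog,
)
from sahhkit.refdata import get_homolog_reference

from oracles import brute_force_global_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def _seq(residues, sid="q"):
    return ProteinSequence(sid, residues)


class TestGlobalAlign:
    def test_identity_alignment_scores_diagonal_sum(self):
        aln = global_align(_seq("HSTME"), _seq("HSTME", "r"))
        expected = sum(BLOSUM62[c, c] for c in "HSTME")
        assert aln.score == expected
        assert aln.aligned_query == aln.aligned_ref == "HSTME"
        assert aln.mapping == {i: i for i in range(1, 6)}

    def test_gapped_alignment_matches_enumeration_oracle(self):
        aln = global_align(_seq("HATGE"), _seq("HGE", "r"))
        assert aln.score == brute_force_global_score("HATGE", "HGE")

    @pytest.mark.parametrize("seed", range(25))
    def test_score_matches_oracle_on_short_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(1, 9)))
        b = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(1, 9)))
        assert global_align(_seq(a), _seq(b, "r")).score == pytest.approx(
            brute_force_global_score(a, b)
        )

    @given(st.data())
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_alignment_invariants(self, data):
        a = data.draw(st.text(alphabet=AA, min_size=1, max_size=30))
        b = data.draw(st.text(alphabet=AA, min_size=1, max_size=30))
        aln = global_align(_seq(a), _seq(b, "r"))
        # gap removal reproduces the inputs
        assert aln.aligned_query.replace("-", "") == a
        assert aln.aligned_ref.replace("-", "") == b
        # mapping strictly increasing in both coordinates
        items = sorted(aln.mapping.items())
        assert all(q1 < q2 for (_, q1), (_, q2) in zip(items, items[1:]))
        # symmetric substitution matrix -> symmetric score
        assert aln.score == global_align(_seq(b), _seq(a, "r")).score

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            ProteinSequence("x", "")

    def test_invalid_characters_rejected(self):
        with pytest.raises(InputError):
            ProteinSequence("x", "ACDZ")

    def test_case_and_stop_normalisation(self):
        assert ProteinSequence("x", "acDef*").residues == "ACDEF"


class TestFingerprint:
    def test_reference_motif_extracted_from_itself(self, pfu_ref):
        aln = global_align(pfu_ref.ref_sequence, pfu_ref.ref_sequence)
        motif = extract_fingerprint(pfu_ref.ref_sequence, pfu_ref, aln)
        assert motif.motif_class == "HxExK"
        assert motif.query_positions == (55, 56, 57, 58, 59)
        assert motif.residues[0] == "H" and motif.residues[2] == "E"

    def test_crenarchaeal_scaffold_maps_thr53_onto_motif_position_3(
        self, pfu_ref, sac_ref
    ):
        aln = global_align(sac_ref.ref_sequence, pfu_ref.ref_sequence)
        assert aln.mapping[57] == 53  # Glu57 column holds Thr53
        motif = extract_fingerprint(sac_ref.ref_sequence, pfu_ref, aln)
        assert motif.motif_class == "HxTxE"
        assert motif.query_positions[2] == 53
        assert sac_ref.residue(53) == "T"

    def test_unalignable_query_is_undetermined(self, pfu_ref):
        query = _seq("GGGGGGGGGG")
        aln = global_align(query, pfu_ref.ref_sequence)
        motif = extract_fingerprint(query, pfu_ref, aln)
        assert motif.motif_class == "undetermined"
        assert classify_motif(motif).label == "unknown"


class TestClassifyMotif:
    def test_total_over_all_anchor_patterns(self):
        """Exactly H?E?K -> SIH-preferring and H?T?E / H?T?Q -> SAH."""
        for a1, a3, a5 in itertools.product(AA + "X", repeat=3):
            motif = FingerprintMotif(
                residues=f"{a1}G{a3}G{a5}",
                query_positions=(1, 2, 3, 4, 5),
                motif_class={
                    ("H", "E", "K"): "HxExK",
                    ("H", "T", "E"): "HxTxE",
                    ("H", "T", "Q"): "HxTxQ",
                }.get((a1, a3, a5), "other"),
            )
            label = classify_motif(motif).label
            if (a1, a3, a5) == ("H", "E", "K"):
                assert label == "SIH-preferring"
            elif (a1, a3) == ("H", "T") and a5 in "EQ":
                assert label == "SAH-preferring"
            else:
                assert label == "unknown"

    def test_non_his_anchor_forces_unknown_with_warning_note(self):
        motif = FingerprintMotif("AGEGK", (1, 2, 3, 4, 5), "other")
        pred = classify_motif(motif)
        assert pred.label == "unknown"
        assert not pred.valid_catalytic_his
        assert "His residue is important for catalysis" in pred.basis


class TestArchitecture:
    def test_reference_against_itself(self, bacterial_ref):
        aln = global_align(bacterial_ref.ref_sequence, bacterial_ref.ref_sequence)
        feats = detect_architecture_features(
            bacterial_ref.ref_sequence, bacterial_ref, aln
        )
        assert feats.segment40_present
        assert feats.cterm_delta == 0
        assert not feats.thermophile_flag

    def test_segment_deleted_query_reported_missing(self, bacterial_ref):
        from sahhkit.synthetic import ToySeqSpec, make_motif_sequences

        seqs, _ = make_motif_sequences(
            ToySeqSpec(motif_class="HxTxQ", delete_segment40=True, seed=4), n=1
        )
        aln = global_align(seqs[0], bacterial_ref.ref_sequence)
        feats = detect_architecture_features(seqs[0], bacterial_ref, aln)
        assert not feats.segment40_present

    def test_short_cterm_flags_thermophile(self, bacterial_ref):
        from sahhkit.synthetic import ToySeqSpec, make_motif_sequences

        seqs, _ = make_motif_sequences(
            ToySeqSpec(motif_class="HxExK", cterm_truncation=25, seed=4), n=1
        )
        aln = global_align(seqs[0], bacterial_ref.ref_sequence)
        feats = detect_architecture_features(seqs[0], bacterial_ref, aln)
        assert feats.cterm_delta == -25
        assert feats.thermophile_flag

    def test_reference_without_segment_annotation_rejected(self, pfu_ref):
        aln = global_align(pfu_ref.ref_sequence, pfu_ref.ref_sequence)
        with pytest.raises(ConfigurationError):
            detect_architecture_features(pfu_ref.ref_sequence, pfu_ref, aln)


class TestHomologScan:
    def test_exact_copy_is_a_full_identity_hit(self):
        ref = get_homolog_reference("DadD")
        rng = np.random.default_rng(1)
        decoys = [
            _seq("".join(AA[i] for i in rng.integers(0, 20, 300)), f"d{k}")
            for k in range(5)
        ]
        hit = scan_homolog(decoys + [_seq(ref.residues, "copy")], ref)
        assert hit.present
        assert hit.best_query_id == "copy"
        assert hit.identity_pct == pytest.approx(100.0)
        assert hit.coverage_pct == pytest.approx(100.0)

    def test_random_proteome_below_thresholds(self):
        ref = get_homolog_reference("MTAN")
        rng = np.random.default_rng(2)
        proteome = [
            _seq("".join(AA[i] for i in rng.integers(0, 20, 300)), f"r{k}")
            for k in range(50)
        ]
        hit = scan_homolog(proteome, ref, reference_name="MTAN")
        assert not hit.present

    def test_empty_proteome_rejected(self):
        with pytest.raises(InputError):
            scan_homolog([], get_homolog_reference("DadD"))


class TestPathwayInference:
    TRUTH_TABLE = {
        # (class, dadd, mtan): expected routes
        ("SIH-preferring", True, False): {"SAHH_direct", "deamination_SIH"},
        ("SIH-preferring", True, True): {"SAHH_direct", "deamination_SIH", "MTAN_LuxS"},
        ("SIH-preferring", False, False): {"SAHH_direct"},
        ("SIH-preferring", False, True): {"SAHH_direct", "MTAN_LuxS"},
        ("SAH-preferring", True, False): {"SAHH_direct"},
        ("SAH-preferring", True, True): {"SAHH_direct", "MTAN_LuxS"},
        ("SAH-preferring", False, False): {"SAHH_direct"},
        ("SAH-preferring", False, True): {"SAHH_direct", "MTAN_LuxS"},
        ("unknown", True, False): {"none"},
        ("unknown", True, True): {"MTAN_LuxS"},
        ("unknown", False, False): {"none"},
        ("unknown", False, True): {"MTAN_LuxS"},
    }

    def test_truth_table_exhaustive(self):
        for (label, dadd, mtan), expected in self.TRUTH_TABLE.items():
            call = infer_pathway(label, dadd, mtan)
            assert set(call.routes) == expected, (label, dadd, mtan)

    def test_deaminase_with_sah_only_hydrolase_flags_other_pathway(self):
        call = infer_pathway("SAH-preferring", dadd_present=True, mtan_present=False)
        assert "SIH metabolised by another pathway" in call.rationale

    def test_determinism(self):
        a = infer_pathway("SIH-preferring", True, False)
        b = infer_pathway("SIH-preferring", True, False)
        assert a == b
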