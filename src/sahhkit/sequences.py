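"""Sequence-level analysis of SAH/SIH hydrolases.

SAHH/SIHH enzymes carry a five-residue fingerprint motif in the
substrate-binding domain that contacts the nucleobase of the substrate:
the catalytic His at motif position 1, an N1-hydrogen-bonding residue at
position 3 (Glu in SIH-preferring enzymes, Thr otherwise) and a position-5
residue (Lys in SIH-preferring enzymes) that can hydrogen-bond the C6
oxygen of hypoxanthine.  ``HxExK`` homologues prefer S-inosyl-homocysteine
(SIH) as substrate, ``HxTxE``/``HxTxQ`` homologues prefer
S-adenosyl-homocysteine (SAH).

This module aligns query sequences against annotated references, extracts
and classifies the motif, detects architecture features (the 40-residue
catalytic-domain segment, C-terminus length) and scans proteomes for
homologues of the deaminase DadD and the nucleosidase MTAN, which feed the
SAH-degradation route inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, InputError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: motif anchor pattern (positions 1, 3, 5) -> motif class
_ANCHOR_CLASSES = {
    ("H", "E", "K"): "HxExK",
    ("H", "T", "E"): "HxTxE",
    ("H", "T", "Q"): "HxTxQ",
}

#: motif class -> predicted substrate preference
MOTIF_PREFERENCE = {
    "HxExK": "SIH-preferring",
    "HxTxE": "SAH-preferring",
    "HxTxQ": "SAH-preferring",
}


@dataclass(frozen=True)
class ProteinSequence:
    """A validated one-letter amino-acid sequence.

    Input is read case-insensitively and trailing stop characters (``*``)
    are stripped; any character outside the 20-letter alphabet plus X is
    rejected.
    """

    id: str
    residues: str
    organism: Optional[str] = None
    phylum: Optional[str] = None

    def __post_init__(self) -> None:
        cleaned = self.residues.upper().rstrip("*")
        object.__setattr__(self, "residues", cleaned)
        if not cleaned:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(cleaned) - AA_ALPHABET
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Landmark residues of a reference enzyme, 1-based.

    ``motif_start`` is the position of the motif His; the gate pair, the
    catalytic Asp towards which the gate His points in the His-IN state,
    the Glu partner it hydrogen-bonds in the His-OUT state and the
    main-chain partner of the nucleobase C6 substituent are all single
    indices.  ``domain_ranges`` maps domain names (substrate_binding,
    cofactor_binding, dimerisation, hinge) to closed 1-based intervals;
    ``segment40`` is the interval of the 40-residue catalytic-domain
    segment in a segment-containing reference, or None.
    """

    ref_id: str
    ref_sequence: ProteinSequence
    motif_start: int
    gate_his: int
    gate_phe: int
    catalytic_asp: int
    out_partner_glu: int
    c6_partner: int
    domain_ranges: Mapping[str, Tuple[int, int] | List[Tuple[int, int]]] = field(
        default_factory=dict
    )
    segment40: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        n = len(self.ref_sequence)
        for name in (
            "motif_start",
            "gate_his",
            "gate_phe",
            "catalytic_asp",
            "out_partner_glu",
            "c6_partner",
        ):
            idx = getattr(self, name)
            if not 1 <= idx <= n:
                raise ConfigurationError(
                    f"{self.ref_id}: landmark {name}={idx} outside [1, {n}]"
                )
        if self.motif_start + 4 > n:
            raise ConfigurationError(f"{self.ref_id}: motif extends past sequence end")
        if self.residue(self.motif_start) != "H":
            raise ConfigurationError(
                f"{self.ref_id}: motif position 1 must be the catalytic His"
            )
        if self.segment40 is not None:
            s, e = self.segment40
            if not (1 <= s <= e <= n):
                raise ConfigurationError(f"{self.ref_id}: segment40 interval invalid")

    def residue(self, index: int) -> str:
        """Return the one-letter residue at a 1-based index."""
        return self.ref_sequence.residues[index - 1]

    @property
    def motif_positions(self) -> Tuple[int, int, int, int, int]:
        return tuple(self.motif_start + i for i in range(5))  # type: ignore[return-value]


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment with a match-column coordinate mapping.

    ``mapping`` sends 1-based reference residue indices to 1-based query
    indices, for match/mismatch columns only; it is strictly increasing in
    both coordinates.
    """

    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float
    mapping: Mapping[int, int]

    @property
    def identity_pct(self) -> float:
        """Percent identical residues over all alignment columns."""
        n_id = sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_ref)
            if a == b and a != "-"
        )
        return 100.0 * n_id / len(self.aligned_ref)


@dataclass(frozen=True)
class FingerprintMotif:
    """The extracted nucleobase-binding fingerprint.

    ``residues`` holds the query characters at the five reference-anchored
    positions ('-' where the query is gapped); ``query_positions`` holds
    the corresponding 1-based query indices (None where gapped).  The
    class is derived from relative positions 1, 3 and 5 only.
    """

    residues: str
    query_positions: Tuple[Optional[int], ...]
    motif_class: str


@dataclass(frozen=True)
class PreferencePrediction:
    label: str  # SIH-preferring | SAH-preferring | unknown
    basis: str
    valid_catalytic_his: bool


@dataclass(frozen=True)
class ArchitectureFeatures:
    segment40_present: bool
    cterm_delta: int
    thermophile_flag: bool


@dataclass(frozen=True)
class HomologHit:
    reference_name: str
    present: bool
    best_query_id: Optional[str]
    identity_pct: float
    coverage_pct: float


@dataclass(frozen=True)
class PathwayCall:
    routes: frozenset
    rationale: str


def _make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0,
    mode: str = "global",
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length L costs gap_open + (L - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def _column_mapping(aligned_query: str, aligned_ref: str) -> Dict[int, int]:
    mapping: Dict[int, int] = {}
    q = r = 0
    for cq, cr in zip(aligned_query, aligned_ref):
        if cq != "-":
            q += 1
        if cr != "-":
            r += 1
        if cq != "-" and cr != "-":
            mapping[r] = q
    return mapping


def global_align(
    query: ProteinSequence,
    ref: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment (Needleman-Wunsch with affine gaps).

    The first optimal traceback reported by the aligner is returned, which
    makes the output deterministic for a given Biopython version.
    """
    if not query.residues or not ref.residues:
        raise InputError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode="global")
    aln = aligner.align(query.residues, ref.residues)[0]
    aligned_query, aligned_ref = str(aln[0]), str(aln[1])
    return AlignmentResult(
        query_id=query.id,
        ref_id=ref.id,
        aligned_query=aligned_query,
        aligned_ref=aligned_ref,
        score=float(aln.score),
        mapping=_column_mapping(aligned_query, aligned_ref),
    )


def extract_fingerprint(
    query: ProteinSequence, ref: ReferenceAnnotation, aln: AlignmentResult
) -> FingerprintMotif:
    """Read the query residues aligned to the reference motif window.

    Positions where the query is gapped are recorded as absent; if any of
    the three anchor positions (1, 3, 5) is unaligned the class is
    ``undetermined``.
    """
    positions: List[Optional[int]] = []
    chars: List[str] = []
    for ref_pos in ref.motif_positions:
        qpos = aln.mapping.get(ref_pos)
        positions.append(qpos)
        chars.append(query.residues[qpos - 1] if qpos is not None else "-")
    anchors = (positions[0], positions[2], positions[4])
    if any(p is None for p in anchors):
        motif_class = "undetermined"
    else:
        key = (chars[0], chars[2], chars[4])
        if key in _ANCHOR_CLASSES:
            motif_class = _ANCHOR_CLASSES[key]
        elif chars[0] == "H" and chars[2] == "E":
            motif_class = "HxExX"
        else:
            motif_class = "other"
    return FingerprintMotif(
        residues="".join(chars),
        query_positions=tuple(positions),
        motif_class=motif_class,
    )


def classify_motif(motif: FingerprintMotif) -> PreferencePrediction:
    """Predict substrate preference from the fingerprint class.

    HxExK homologues prefer SIH; HxTxE/HxTxQ homologues prefer SAH.  Any
    other pattern gives ``unknown``.  A non-His residue at motif position 1
    forces ``unknown``: the His residue is important for catalysis.
    """
    valid_his = motif.residues[:1] == "H"
    if not valid_his:
        return PreferencePrediction(
            label="unknown",
            basis=(
                f"motif position 1 is {motif.residues[:1] or '-'}; "
                "The His residue is important for catalysis"
            ),
            valid_catalytic_his=False,
        )
    label = MOTIF_PREFERENCE.get(motif.motif_class, "unknown")
    return PreferencePrediction(
        label=label,
        basis=f"fingerprint motif class {motif.motif_class}",
        valid_catalytic_his=True,
    )


def detect_architecture_features(
    query: ProteinSequence,
    ref: ReferenceAnnotation,
    aln: AlignmentResult,
    thermophile_cterm_delta: int = -15,
) -> ArchitectureFeatures:
    """Detect the 40-residue segment and the relative C-terminus length.

    The segment counts as present when at least half of its reference
    columns align to query residues.  ``cterm_delta`` is the signed count
    of query residues past the last aligned column minus reference
    residues past it; against a long-C-terminus mesophilic reference a
    strongly negative delta is a (heuristic) thermophily flag.
    """
    if ref.segment40 is None:
        raise ConfigurationError(
            f"reference {ref.ref_id} has no 40-residue segment annotation"
        )
    if not aln.mapping:
        raise InputError("alignment has no matched columns")
    s, e = ref.segment40
    n_cols = e - s + 1
    n_present = sum(1 for p in range(s, e + 1) if p in aln.mapping)
    last_ref = max(aln.mapping)
    q_past = len(query) - aln.mapping[last_ref]
    r_past = len(ref.ref_sequence) - last_ref
    delta = q_past - r_past
    return ArchitectureFeatures(
        segment40_present=n_present >= n_cols / 2,
        cterm_delta=delta,
        thermophile_flag=delta <= thermophile_cterm_delta,
    )


def scan_homolog(
    proteome: Iterable[ProteinSequence],
    reference: ProteinSequence,
    reference_name: str = "DadD",
    identity_threshold: float = 30.0,
    coverage_threshold: float = 70.0,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> HomologHit:
    """Smith-Waterman scan of a proteome for a homologue of ``reference``.

    The best hit by local-alignment score is reported; presence requires
    identity over the aligned length and coverage of the reference to both
    clear their thresholds (defaults: 30% identity, 70% coverage).
    """
    proteome = list(proteome)
    if not proteome:
        raise InputError("proteome is empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode="local")
    best_score = float("-inf")
    best: Optional[Tuple[ProteinSequence, object]] = None
    for seq in proteome:
        aln = aligner.align(seq.residues, reference.residues)[0]
        if aln.score > best_score:
            best_score = float(aln.score)
            best = (seq, aln)
    assert best is not None
    seq, aln = best
    aligned_query, aligned_ref = str(aln[0]), str(aln[1])  # type: ignore[index]
    n_cols = len(aligned_ref)
    n_id = sum(
        1 for a, b in zip(aligned_query, aligned_ref) if a == b and a != "-"
    )
    n_ref_in_aln = sum(1 for c in aligned_ref if c != "-")
    identity = 100.0 * n_id / n_cols if n_cols else 0.0
    coverage = 100.0 * n_ref_in_aln / len(reference)
    return HomologHit(
        reference_name=reference_name,
        present=identity >= identity_threshold and coverage >= coverage_threshold,
        best_query_id=seq.id,
        identity_pct=identity,
        coverage_pct=coverage,
    )


def infer_pathway(
    sahh_class: str, dadd_present: bool, mtan_present: bool
) -> PathwayCall:
    """Deterministic SAH-degradation route call.

    Routes: direct SAHH cleavage of SAH; the deamination route (DadD turns
    SAH into SIH, cleaved by an SIH-preferring hydrolase); the two-step
    MTAN/LuxS route.  An organism with a deaminase but an SAH-only
    hydrolase and no MTAN must metabolise SIH by another pathway.
    """
    routes = set()
    notes = []
    if sahh_class in ("SAH-preferring", "SIH-preferring"):
        # SIH-preferring enzymes retain SAH activity (dual function)
        routes.add("SAHH_direct")
    if dadd_present and sahh_class == "SIH-preferring":
        routes.add("deamination_SIH")
        notes.append("dual function for SIH and SAH metabolism")
    if mtan_present:
        routes.add("MTAN_LuxS")
    if dadd_present and sahh_class == "SAH-preferring" and not mtan_present:
        notes.append("SIH metabolised by another pathway")
    if not routes:
        routes.add("none")
        notes.append("no degradation route supported by the evidence")
    return PathwayCall(routes=frozenset(routes), rationale="; ".join(notes))


def annotate_sequence(
    query: ProteinSequence,
    ref: ReferenceAnnotation,
    segment_ref: Optional[ReferenceAnnotation] = None,
) -> Dict[str, object]:
    """Full per-sequence report row: motif, class, prediction, architecture."""
    aln = global_align(query, ref.ref_sequence)
    motif = extract_fingerprint(query, ref, aln)
    pred = classify_motif(motif)
    row: Dict[str, object] = {
        "id": query.id,
        "organism": query.organism or "",
        "phylum": query.phylum or "",
        "reference": ref.ref_id,
        "motif_residues": motif.residues,
        "motif_class": motif.motif_class,
        "predicted_preference": pred.label,
        "valid_catalytic_his": pred.valid_catalytic_his,
        "basis": pred.basis,
    }
    arch_ref = segment_ref if segment_ref is not None else (
        ref if ref.segment40 is not None else None
    )
    if arch_ref is not None:
        arch_aln = aln if arch_ref is ref else global_align(query, arch_ref.ref_sequence)
        feats = detect_architecture_features(query, arch_ref, arch_aln)
        row.update(
            segment40_present=feats.segment40_present,
            cterm_delta=feats.cterm_delta,
            thermophile_flag=feats.thermophile_flag,
        )
    return row
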