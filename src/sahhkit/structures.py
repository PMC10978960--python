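"""Crystal-structure geometry analysis for SAH/SIH hydrolases.

Reads PDB/mmCIF coordinate files, maps reference landmark residues onto
each chain by sequence alignment (so renumbered depositions are
tolerated), and measures the features the family is characterised by:

* the molecular gate: a conserved His/Phe pair at the channel entrance.
  In the His-IN state the His imidazole points at the catalytic Asp
  carboxylate (gate shut); in the His-OUT state it swings away and
  hydrogen-bonds a nearby Glu (gate open).  The two states interconvert
  via a ~180 degree flip of the His-Phe peptide plane.
* ligand hydrogen-bond networks in the nucleobase pocket, from which the
  tautomeric form of the bound purine is inferred (an O6 contact to a
  main-chain carbonyl oxygen implies the imino-hydroxy form of
  hypoxanthine; the exo-amino N6 contact of adenine implies the amino
  form).
* monovalent cations (Na+/K+) coordinated near the hinge element, present
  in bacterial/eukaryotic but absent in archaeal homologues.
* rigid-body comparisons: Kabsch superposition, asymmetric-unit chain
  RMSD over matched C-alpha atoms, and the open/closed interdomain
  rotation angle (~18 degrees between states).

Distances are heavy-atom Angstrom distances throughout; hydrogens are not
modelled at these resolutions, so the hydrogen-bond criterion is a plain
donor/acceptor heavy-atom cutoff without an angle term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    GeometryError,
    InputError,
    MappingError,
)
from .geometry import (
    Superposition,
    angle_between_deg,
    dihedral_deg,
    min_distance,
    rotation_angle_deg,
    superpose_kabsch,
)
from .sequences import (
    AlignmentResult,
    ProteinSequence,
    ReferenceAnnotation,
    global_align,
)

# ---------------------------------------------------------------------------
# model containers

HIS_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")
ASP_CARBOXYLATE = ("OD1", "OD2")
GLU_CARBOXYLATE = ("OE1", "OE2")
MAINCHAIN_POLAR = ("N", "O", "OXT")

LIGAND_CLASSES = {
    "NAD": "cofactor", "NAI": "cofactor", "NAJ": "cofactor",
    "ADN": "nucleoside", "INO": "nucleoside", "NOS": "nucleoside",
    "SAH": "thioether", "SIH": "thioether", "SAM": "thioether",
}
MONOVALENT_CATIONS = ("NA", "K")
ION_ELEMENTS = {"NA", "K", "MG", "CA", "ZN", "CL", "MN", "FE", "BR", "I"}


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    seqid: int
    icode: str
    name: str
    atoms: Dict[str, Atom] = field(default_factory=dict)

    def coord(self, atom_name: str) -> Optional[np.ndarray]:
        a = self.atoms.get(atom_name)
        return None if a is None else a.pos

    def coords(self, atom_names: Iterable[str]) -> np.ndarray:
        pts = [self.atoms[n].pos for n in atom_names if n in self.atoms]
        return np.array(pts, dtype=float).reshape(-1, 3)

    @property
    def label(self) -> str:
        return f"{self.name}{self.seqid}{self.icode.strip()}"


@dataclass
class Chain:
    id: str
    residues: List[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(_one_letter(r.name) for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array(
            [r.coord("CA") for r in self.residues if r.coord("CA") is not None]
        )


@dataclass
class StructureModel:
    structure_id: str
    chains: List[Chain] = field(default_factory=list)
    het_groups: List[Tuple[str, Residue]] = field(default_factory=list)
    ions: List[Tuple[str, Residue]] = field(default_factory=list)
    waters: List[Tuple[str, Residue]] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise InputError(f"no chain {chain_id!r} in {self.structure_id}")

    def ligands(self, classes: Sequence[str] = ("nucleoside", "thioether")) -> List[Tuple[str, Residue]]:
        return [
            (cid, r)
            for cid, r in self.het_groups
            if LIGAND_CLASSES.get(r.name) in classes
        ]


@dataclass(frozen=True)
class GateState:
    chain_id: str
    state: str  # IN | OUT | undetermined
    d_gate: Optional[float]
    d_gate_centroid: Optional[float]
    d_out_partner: Optional[float]
    d_his_o5prime: Optional[float]
    chi1: Optional[float]
    chi2: Optional[float]
    rotamer: Optional[str]
    reason: str = ""


@dataclass(frozen=True)
class HBond:
    ligand_atom: str
    partner_chain: str
    partner_residue: str
    partner_atom: str
    distance: float
    partner_is_mainchain: bool


@dataclass(frozen=True)
class TautomerCall:
    ligand: str
    call: str  # amino_oxo | imino_hydroxy | amino | undetermined
    evidence: Tuple[HBond, ...]


@dataclass(frozen=True)
class ConformationCall:
    angle_deg: float
    call: str  # open | closed | undetermined


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


_ATOM_NAME_ALIASES = {"O5*": "O5'", "O5´": "O5'", "O3*": "O3'", "O2*": "O2'"}


def _normalise_atom_name(name: str) -> str:
    return _ATOM_NAME_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# loading

def _convert_residue(res: gemmi.Residue) -> Residue:
    """Convert a gemmi residue, applying the altloc policy.

    Of alternate locations of the same atom the highest-occupancy one is
    kept; ties go to the alphabetically first altloc identifier.
    """
    out = Residue(seqid=res.seqid.num, icode=res.seqid.icode.strip(), name=res.name)
    best: Dict[str, Tuple[float, str]] = {}
    for atom in res:
        if atom.element.is_hydrogen:
            continue
        name = _normalise_atom_name(atom.name)
        key = (-atom.occ, atom.altloc or "A")
        if name not in best or key < best[name]:
            best[name] = key
            out.atoms[name] = Atom(
                name=name,
                element=atom.element.name.upper(),
                pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                occupancy=atom.occ,
                altloc=atom.altloc,
            )
    return out


def load_structure(path) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (first model only)."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse coordinate file {path}: {exc}") from exc
    if len(st) == 0:
        raise InputError(f"{path}: no models in file")
    st.setup_entities()
    model = st[0]
    out = StructureModel(structure_id=st.name or "structure")
    for ch in model:
        polymer = Chain(id=ch.name)
        for res in ch:
            conv = _convert_residue(res)
            if not conv.atoms:
                continue
            if res.name == "HOH":
                out.waters.append((ch.name, conv))
            elif _is_amino_acid(res.name):
                polymer.residues.append(conv)
            elif len(conv.atoms) == 1 and next(
                iter(conv.atoms.values())
            ).element in ION_ELEMENTS:
                out.ions.append((ch.name, conv))
            else:
                out.het_groups.append((ch.name, conv))
        if polymer.residues:
            out.chains.append(polymer)
    if not out.chains and not out.het_groups and not out.ions:
        raise InputError(f"{path}: empty model")
    return out


def ligand_inventory(model: StructureModel) -> Dict[str, List[str]]:
    """Classify het groups into cofactor/nucleoside/thioether/ion/other."""
    inv: Dict[str, List[str]] = {
        "cofactor": [], "nucleoside": [], "thioether": [], "ion": [], "other": []
    }
    for _, res in model.het_groups:
        inv[LIGAND_CLASSES.get(res.name, "other")].append(res.name)
    for _, res in model.ions:
        inv["ion"].append(res.name)
    return inv


def load_and_inventory(path) -> Tuple[StructureModel, Dict[str, List[str]]]:
    model = load_structure(path)
    return model, ligand_inventory(model)


# ---------------------------------------------------------------------------
# reference mapping

LANDMARKS = (
    "gate_his", "gate_phe", "catalytic_asp", "out_partner_glu", "c6_partner"
)

_EXPECTED_LANDMARK_AA = {
    "gate_his": "H", "gate_phe": "F", "catalytic_asp": "D",
    "out_partner_glu": "E",
}

ResidueMap = Dict[str, Dict[str, Residue]]


def chain_alignment(chain: Chain, ref: ReferenceAnnotation) -> AlignmentResult:
    seq = ProteinSequence(f"chain_{chain.id}", chain.sequence())
    return global_align(seq, ref.ref_sequence)


def map_reference_residues(
    model: StructureModel,
    ref: ReferenceAnnotation,
    identity_floor_pct: float = 30.0,
) -> ResidueMap:
    """Locate reference landmark residues on every mappable chain.

    Chains are aligned to the reference sequence; landmarks fall onto the
    structure residue their reference index maps to.  Unresolved residues
    are reported absent; a residue-type mismatch warns but does not fail.
    """
    out: ResidueMap = {}
    for chain in model.chains:
        aln = chain_alignment(chain, ref)
        if aln.identity_pct < identity_floor_pct:
            continue
        landmarks: Dict[str, Residue] = {}
        targets = {name: getattr(ref, name) for name in LANDMARKS}
        for i, pos in enumerate(ref.motif_positions, start=1):
            targets[f"motif_{i}"] = pos
        for name, ref_idx in targets.items():
            q_idx = aln.mapping.get(ref_idx)
            if q_idx is None:
                continue
            residue = chain.residues[q_idx - 1]
            expected = _EXPECTED_LANDMARK_AA.get(name)
            if expected and _one_letter(residue.name) != expected:
                warnings.warn(
                    f"{model.structure_id}/{chain.id}: landmark {name} maps to "
                    f"{residue.label}, expected {expected}",
                    stacklevel=2,
                )
            landmarks[name] = residue
        if landmarks:
            out[chain.id] = landmarks
    if not out:
        raise MappingError(
            f"no chain of {model.structure_id} aligns to {ref.ref_id} above "
            f"{identity_floor_pct}% identity"
        )
    return out


# ---------------------------------------------------------------------------
# gate state

def _nearest_ligand_o5prime(model: StructureModel, point: np.ndarray) -> Optional[float]:
    best = None
    for _, res in model.ligands():
        pos = res.coord("O5'")
        if pos is not None:
            d = float(np.linalg.norm(pos - point))
            best = d if best is None or d < best else best
    return best


def classify_gate_state(
    model: StructureModel,
    residue_map: ResidueMap,
    in_threshold: float = 6.0,
    out_threshold: float = 8.0,
    hbond_cutoff: float = 3.5,
) -> List[GateState]:
    """Per-chain molecular-gate call.

    ``d_gate`` is the minimum heavy-atom distance between the gate-His
    imidazole ring atoms and the catalytic-Asp carboxylate oxygens
    (centroid-centroid is reported alongside for diagnostics).  IN means
    d_gate <= in_threshold; OUT requires d_gate >= out_threshold plus a
    hydrogen-bond contact to the His-OUT partner Glu; anything between is
    undetermined.
    """
    results: List[GateState] = []
    for chain_id, landmarks in residue_map.items():
        his = landmarks.get("gate_his")
        asp = landmarks.get("catalytic_asp")
        glu = landmarks.get("out_partner_glu")
        if his is None or asp is None:
            results.append(GateState(
                chain_id, "undetermined", None, None, None, None, None, None,
                None, reason="gate His or catalytic Asp not mapped"))
            continue
        ring = his.coords(HIS_RING_ATOMS)
        carbox = asp.coords(ASP_CARBOXYLATE)
        if ring.shape[0] < 3 or carbox.shape[0] == 0:
            results.append(GateState(
                chain_id, "undetermined", None, None, None, None, None, None,
                None, reason="missing side-chain atoms"))
            continue
        d_gate = min_distance(ring, carbox)
        d_centroid = float(
            np.linalg.norm(ring.mean(axis=0) - carbox.mean(axis=0))
        )
        d_out = None
        if glu is not None:
            oe = glu.coords(GLU_CARBOXYLATE)
            if oe.shape[0]:
                d_out = min_distance(ring, oe)
        nd1 = his.coord("ND1")
        d_o5 = _nearest_ligand_o5prime(model, nd1) if nd1 is not None else None
        chi1 = chi2 = None
        rotamer = None
        needed = ("N", "CA", "CB", "CG", "ND1")
        if all(n in his.atoms for n in needed):
            chi1 = dihedral_deg(
                his.coord("N"), his.coord("CA"), his.coord("CB"), his.coord("CG")
            )
            chi2 = dihedral_deg(
                his.coord("CA"), his.coord("CB"), his.coord("CG"), his.coord("ND1")
            )
            rotamer = _coarse_rotamer(chi2)
        if d_gate <= in_threshold:
            state, reason = "IN", ""
        elif d_gate >= out_threshold and d_out is not None and d_out <= hbond_cutoff:
            state, reason = "OUT", ""
        else:
            state = "undetermined"
            reason = "gate distance in the ambiguous band or no OUT-partner contact"
        results.append(GateState(
            chain_id=chain_id, state=state, d_gate=d_gate,
            d_gate_centroid=d_centroid, d_out_partner=d_out,
            d_his_o5prime=d_o5, chi1=chi1, chi2=chi2, rotamer=rotamer,
            reason=reason,
        ))
    return results


def _coarse_rotamer(chi2: float) -> str:
    """Coarse chi2 rotamer bin: gauche-(-60), gauche+(+60) or trans(180)."""
    bins = {"gauche-": -60.0, "gauche+": 60.0, "trans": 180.0}
    def circ_dist(a: float, b: float) -> float:
        return abs((a - b + 180.0) % 360.0 - 180.0)
    return min(bins, key=lambda k: circ_dist(chi2, bins[k]))


# ---------------------------------------------------------------------------
# hydrogen bonds and tautomers

POLAR_ELEMENTS = ("N", "O", "S")


def enumerate_hbonds(
    model: StructureModel,
    ligand: Residue | str,
    cutoff: float = 3.5,
    include_water: bool = False,
) -> List[HBond]:
    """All ligand-protein donor/acceptor heavy-atom pairs within ``cutoff``.

    Donor and acceptor atoms are N/O/S heavy atoms; partners are annotated
    as main chain or side chain.  Waters are excluded by default.  The
    result is deduplicated and sorted by distance (ties broken by atom
    names for determinism).
    """
    if isinstance(ligand, str):
        matches = [r for _, r in model.het_groups if r.name == ligand]
        if not matches:
            raise InputError(f"ligand {ligand!r} absent from {model.structure_id}")
        ligand_res = matches[0]
    else:
        ligand_res = ligand
    lig_atoms = [
        a for a in ligand_res.atoms.values() if a.element in POLAR_ELEMENTS
    ]
    partners: List[Tuple[str, Residue, Atom]] = []
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms.values():
                if a.element in POLAR_ELEMENTS:
                    partners.append((chain.id, res, a))
    if include_water:
        for cid, res in model.waters:
            for a in res.atoms.values():
                partners.append((cid, res, a))
    seen = set()
    bonds: List[HBond] = []
    for la in lig_atoms:
        for cid, res, pa in partners:
            d = float(np.linalg.norm(la.pos - pa.pos))
            if d > cutoff:
                continue
            key = (la.name, cid, res.seqid, res.icode, pa.name)
            if key in seen:
                continue
            seen.add(key)
            bonds.append(HBond(
                ligand_atom=la.name,
                partner_chain=cid,
                partner_residue=res.label,
                partner_atom=pa.name,
                distance=d,
                partner_is_mainchain=pa.name in MAINCHAIN_POLAR,
            ))
    bonds.sort(key=lambda b: (b.distance, b.ligand_atom, b.partner_residue, b.partner_atom))
    return bonds


def infer_tautomer(
    hbonds: Sequence[HBond], ligand_name: str, cutoff: float = 3.5
) -> TautomerCall:
    """Tautomer call for the bound purine from its C6-substituent contacts.

    For hypoxanthine ligands (inosine, SIH) an O6 contact to a main-chain
    carbonyl oxygen implies O6 donates a hydrogen, i.e. the imino-hydroxy
    form; without such a contact the default is the amino-oxo form, the
    most stable form in water.  For adenine ligands the exo-amino N6
    contact supports the preferred amino form.
    """
    hypoxanthine = ligand_name in ("INO", "SIH", "NOS")
    adenine = ligand_name in ("ADN", "SAH")
    if not (hypoxanthine or adenine):
        return TautomerCall(ligand=ligand_name, call="undetermined", evidence=())
    target = "O6" if hypoxanthine else "N6"
    evidence = tuple(
        b for b in hbonds
        if b.ligand_atom == target and b.partner_atom == "O"
        and b.partner_is_mainchain and b.distance <= cutoff
    )
    if hypoxanthine:
        call = "imino_hydroxy" if evidence else "amino_oxo"
    else:
        call = "amino"
    return TautomerCall(ligand=ligand_name, call=call, evidence=evidence)


# ---------------------------------------------------------------------------
# cations

def detect_cation(
    model: StructureModel,
    selection: Optional[Sequence[Residue]] = None,
    cutoff: float = 6.0,
    coordination_cutoff: float = 3.5,
) -> List[Dict[str, object]]:
    """Monovalent cations (Na+/K+) near a residue selection.

    ``selection`` is normally the hinge-element residues; if None, the
    nucleobase-pocket fallback (all ligand atoms) is used.  An empty
    report means absence.
    """
    if selection:
        sel_atoms = [a for r in selection for a in r.atoms.values()]
    else:
        sel_atoms = [
            a for _, r in model.ligands() for a in r.atoms.values()
        ]
    if not sel_atoms:
        return []
    sel_coords = np.array([a.pos for a in sel_atoms])
    report: List[Dict[str, object]] = []
    for cid, res in model.ions:
        atom = next(iter(res.atoms.values()))
        if atom.element not in MONOVALENT_CATIONS:
            continue
        d = np.linalg.norm(sel_coords - atom.pos, axis=1)
        if d.min() > cutoff:
            continue
        coordinating = [
            f"{sel_atoms[i].name}@{d[i]:.2f}"
            for i in np.argsort(d)
            if d[i] <= coordination_cutoff
        ]
        report.append({
            "element": atom.element,
            "chain": cid,
            "seqid": res.seqid,
            "min_distance": float(d.min()),
            "coordinating_atoms": coordinating,
        })
    return report


# ---------------------------------------------------------------------------
# chain RMSD / domain rotation / peptide flip

def _matched_ca(chain_a: Chain, chain_b: Chain) -> Tuple[np.ndarray, np.ndarray]:
    seq_a = ProteinSequence("a", chain_a.sequence())
    seq_b = ProteinSequence("b", chain_b.sequence())
    aln = global_align(seq_a, seq_b)
    pa, pb = [], []
    for b_idx, a_idx in aln.mapping.items():
        ca_a = chain_a.residues[a_idx - 1].coord("CA")
        ca_b = chain_b.residues[b_idx - 1].coord("CA")
        if ca_a is not None and ca_b is not None:
            pa.append(ca_a)
            pb.append(ca_b)
    return np.array(pa).reshape(-1, 3), np.array(pb).reshape(-1, 3)


def asu_chain_rmsd(model: StructureModel) -> pd.DataFrame:
    """Pairwise C-alpha RMSD between the protein chains of one model.

    Chains are paired by sequence alignment; the table reports the RMSD
    after Kabsch superposition and the matched-atom count.  A single-chain
    model yields an empty table.
    """
    rows = []
    chains = model.chains
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            pa, pb = _matched_ca(chains[i], chains[j])
            if pa.shape[0] < 3:
                continue
            sup = superpose_kabsch(pa, pb)
            rows.append({
                "chain_a": chains[i].id,
                "chain_b": chains[j].id,
                "rmsd": sup.rmsd,
                "n_atoms": sup.n_atoms,
            })
    return pd.DataFrame(rows, columns=["chain_a", "chain_b", "rmsd", "n_atoms"])


def _domain_ca(
    chain: Chain, seqid_range: Tuple[int, int]
) -> Dict[int, np.ndarray]:
    s, e = seqid_range
    out = {}
    for r in chain.residues:
        if s <= r.seqid <= e and r.coord("CA") is not None and not r.icode:
            out[r.seqid] = r.coord("CA")
    return out


def resolve_domain_ranges(
    chain: Chain, ref: ReferenceAnnotation
) -> Dict[str, Tuple[int, int]]:
    """Translate reference domain intervals into structure seqid intervals."""
    aln = chain_alignment(chain, ref)
    out: Dict[str, Tuple[int, int]] = {}
    for name in ("cofactor_binding", "substrate_binding"):
        rng = ref.domain_ranges.get(name)
        if rng is None:
            raise ConfigurationError(f"reference lacks domain range {name!r}")
        s, e = rng if not isinstance(rng, list) else rng[0]
        mapped = [aln.mapping[p] for p in range(s, e + 1) if p in aln.mapping]
        if len(mapped) < 3:
            raise ConfigurationError(f"domain {name!r} unresolvable on chain")
        out[name] = (
            chain.residues[min(mapped) - 1].seqid,
            chain.residues[max(mapped) - 1].seqid,
        )
    return out


def domain_rotation_angle(
    model_a: StructureModel,
    model_b: StructureModel,
    domain_ranges: Mapping[str, Tuple[int, int]],
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
    reference_state: str = "closed",
    open_anchor_deg: float = 18.0,
    angle_tol_deg: float = 6.0,
) -> ConformationCall:
    """Interdomain rotation of A's substrate-binding domain relative to B.

    Both models are superposed on their cofactor-binding-domain C-alpha
    atoms (matched by sequence id); the residual Kabsch rotation mapping
    A's substrate-binding domain onto B's gives the reorientation angle.
    With ``model_b`` in a known ``reference_state``, an angle within
    ``angle_tol_deg`` of zero keeps that state, an angle within tolerance
    of the open/closed anchor (~18 degrees) flips it, anything else is
    undetermined.
    """
    ch_a = model_a.chain(chain_a) if chain_a else model_a.chains[0]
    ch_b = model_b.chain(chain_b) if chain_b else model_b.chains[0]
    try:
        cof_range = domain_ranges["cofactor_binding"]
        sub_range = domain_ranges["substrate_binding"]
    except KeyError as exc:
        raise ConfigurationError(f"missing domain range: {exc}") from exc

    def shared(rng):
        da = _domain_ca(ch_a, rng)
        db = _domain_ca(ch_b, rng)
        ids = sorted(set(da) & set(db))
        if len(ids) < 3:
            raise ConfigurationError(
                f"domain {rng} unresolvable in both models"
            )
        return (
            np.array([da[i] for i in ids]),
            np.array([db[i] for i in ids]),
        )

    cof_a, cof_b = shared(cof_range)
    sub_a, sub_b = shared(sub_range)
    sup_cof = superpose_kabsch(cof_b, cof_a)  # bring B into A's cofactor frame
    sub_b_in_a = sup_cof.apply(sub_b)
    sup_sub = superpose_kabsch(sub_a, sub_b_in_a)
    angle = rotation_angle_deg(sup_sub.rotation)
    other = {"closed": "open", "open": "closed"}[reference_state]
    if angle <= angle_tol_deg:
        call = reference_state
    elif abs(angle - open_anchor_deg) <= angle_tol_deg:
        call = other
    else:
        call = "undetermined"
    return ConformationCall(angle_deg=angle, call=call)


_PLANE_ATOMS = ("CA", "C", "O")  # of His, plus N of Phe


def _peptide_plane_normal(his: Residue, phe: Residue) -> np.ndarray:
    for atom in _PLANE_ATOMS:
        if his.coord(atom) is None:
            raise GeometryError(f"missing backbone atom {atom} on {his.label}")
    if phe.coord("N") is None:
        raise GeometryError(f"missing backbone N on {phe.label}")
    ca, c = his.coord("CA"), his.coord("C")
    n = phe.coord("N")
    # oriented normal: consistent atom order keeps the sign comparable
    normal = np.cross(c - ca, n - ca)
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        raise GeometryError("degenerate peptide plane")
    return normal / norm


def _flip_window(chain: Chain, his: Residue, phe: Residue) -> List[Residue]:
    idx_his = chain.residues.index(his)
    idx_phe = chain.residues.index(phe)
    lo = max(0, idx_his - 2)
    hi = min(len(chain.residues), idx_phe + 3)
    return chain.residues[lo:hi]


def peptide_flip_angle(
    model_a: StructureModel,
    model_b: StructureModel,
    map_a: ResidueMap,
    map_b: ResidueMap,
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
    flip_threshold_deg: float = 120.0,
) -> Tuple[float, bool]:
    """Angle between the His-Phe peptide planes of two models.

    The local backbone (C-alpha of His-2 .. Phe+2) of B is superposed onto
    A, then the angle between the oriented normals of the two peptide
    planes (through CA/C/O of His and N of Phe) is returned.  A true
    peptide-plane flip is ~180 degrees; the default call threshold is 120.
    """
    cid_a = chain_a or next(iter(map_a))
    cid_b = chain_b or next(iter(map_b))
    try:
        his_a, phe_a = map_a[cid_a]["gate_his"], map_a[cid_a]["gate_phe"]
        his_b, phe_b = map_b[cid_b]["gate_his"], map_b[cid_b]["gate_phe"]
    except KeyError as exc:
        raise GeometryError(f"gate residues not mapped: {exc}") from exc
    ch_a, ch_b = model_a.chain(cid_a), model_b.chain(cid_b)
    win_a = _flip_window(ch_a, his_a, phe_a)
    win_b = _flip_window(ch_b, his_b, phe_b)
    ca_a = np.array([r.coord("CA") for r in win_a if r.coord("CA") is not None])
    ca_b = np.array([r.coord("CA") for r in win_b if r.coord("CA") is not None])
    if ca_a.shape[0] < 3 or ca_a.shape != ca_b.shape:
        raise GeometryError("insufficient backbone window for superposition")
    sup = superpose_kabsch(ca_b, ca_a)
    n_a = _peptide_plane_normal(his_a, phe_a)
    moved_his = Residue(his_b.seqid, his_b.icode, his_b.name, {
        k: Atom(a.name, a.element, sup.apply(a.pos[None, :])[0]) for k, a in his_b.atoms.items()
    })
    moved_phe = Residue(phe_b.seqid, phe_b.icode, phe_b.name, {
        k: Atom(a.name, a.element, sup.apply(a.pos[None, :])[0]) for k, a in phe_b.atoms.items()
    })
    n_b = _peptide_plane_normal(moved_his, moved_phe)
    angle = angle_between_deg(n_a, n_b)
    return angle, angle >= flip_threshold_deg


# ---------------------------------------------------------------------------
# combined per-structure report

def structure_report(
    model: StructureModel,
    ref: Optional[ReferenceAnnotation] = None,
    residue_map: Optional[ResidueMap] = None,
    gate_in_threshold: float = 6.0,
    gate_out_threshold: float = 8.0,
    hbond_cutoff: float = 3.5,
) -> Dict[str, object]:
    """Full structure report: inventory, per-chain gate state, H-bonds,
    tautomer calls, cation report and the ASU chain RMSD table."""
    if residue_map is None:
        if ref is None:
            raise ConfigurationError("either ref or residue_map is required")
        residue_map = map_reference_residues(model, ref)
    inv = ligand_inventory(model)
    gates = classify_gate_state(
        model, residue_map, gate_in_threshold, gate_out_threshold, hbond_cutoff
    )
    ligands = {}
    for _, res in model.ligands():
        bonds = enumerate_hbonds(model, res, cutoff=hbond_cutoff)
        taut = infer_tautomer(bonds, res.name, cutoff=hbond_cutoff)
        ligands[res.label] = {
            "hbonds": [b.__dict__ for b in bonds],
            "tautomer": taut.call,
        }
    cations = detect_cation(model)
    rmsd_table = asu_chain_rmsd(model)
    return {
        "structure_id": model.structure_id,
        "inventory": inv,
        "gate_states": [g.__dict__ for g in gates],
        "ligands": ligands,
        "cations": cations,
        "asu_chain_rmsd": rmsd_table.to_dict(orient="records"),
    }
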