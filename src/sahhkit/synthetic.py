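"""Synthetic fixtures with recorded ground truth.

Everything the pipeline consumes can be generated here without downloads:

* toy active-site coordinate files with controlled gate geometry,
  ligand contacts and optional cations (idealised residue geometry; the
  realism is limited to what the geometric classifiers measure),
* scaffold sequences with planted fingerprint motifs, optional
  40-residue-segment deletion and C-terminal truncation,
* HPLC peak tables with known true conversion, response factors and
  noise.

All generators are deterministic under their seed, and ground truth is
written as a sidecar JSON next to each generated file.  Base-chain toy
coordinates are constructed on the 0.001 Angstrom grid of the PDB
coordinate field, with distance-controlled atoms placed by exact axis
offsets, so the written file reproduces the target distances exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from .assay import PeakTable
from .errors import GenerationError, InputError
from .geometry import rotation_about_axis
from .sequences import ProteinSequence
from .structures import Atom, Chain, Residue, StructureModel

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _r3(x) -> np.ndarray:
    """Snap coordinates to the 0.001 A grid of the PDB coordinate field."""
    return np.round(np.asarray(x, dtype=float), 3)


# ---------------------------------------------------------------------------
# toy active sites


@dataclass
class ToySiteSpec:
    """Construction targets for a toy active site.

    ``d_gate`` is the minimum distance between the gate-His imidazole ring
    and the catalytic-Asp carboxylate oxygens; ``d_out_partner`` the
    ring-to-Glu-carboxylate distance when ``place_out_partner`` is set
    (otherwise the Glu sits 20 A away); ``d_his_o5prime`` the His ND1 to
    ligand O5' distance.  ``o6_contact`` places the ligand O6 (inosine) or
    N6 (adenosine) 2.9 A from a main-chain carbonyl oxygen.  Extra chains
    are rigid-moved copies with optional isotropic coordinate noise.
    """

    d_gate: float = 4.2
    place_out_partner: bool = False
    d_out_partner: float = 2.7
    ligand: Optional[str] = "inosine"  # inosine | adenosine | None
    d_his_o5prime: float = 2.7
    o6_contact: bool = True
    d_o6_contact: float = 2.9
    cation: Optional[str] = None  # NA | K
    d_cation: float = 5.0
    n_chains: int = 1
    chain_noise_sigma: float = 0.0
    seed: int = 0


_HIS_ATOMS = {
    "N": (-0.500, -1.400, 0.0), "CA": (0.0, 0.0, 0.0),
    "C": (-1.000, 1.000, 0.0), "O": (-1.900, 1.800, 0.0),
    "CB": (1.530, 0.0, 0.0), "CG": (2.290, 1.280, 0.0),
    "ND1": (3.660, 1.280, 0.0), "CD2": (1.862, 2.581, 0.0),
    "CE1": (4.072, 2.590, 0.0), "NE2": (2.984, 3.443, 0.0),
}
_RING_MAX_X = "CE1"  # the ring atom nearest an Asp placed along +x
_RING_MIN_X = "CD2"  # the ring atom nearest a Glu placed along -x


def _chain_offsets(base: np.ndarray, offsets: Dict[str, Tuple[float, float, float]]):
    return {name: _r3(base + np.array(off)) for name, off in offsets.items()}


def _toy_site_atoms(spec: ToySiteSpec) -> List[Tuple[str, int, bool, str, str, np.ndarray]]:
    """Atom records (resname, seqid, het, atom name, element, xyz) for chain A."""
    if spec.d_gate <= 0:
        raise GenerationError("d_gate must be positive")
    atoms: List[Tuple[str, int, bool, str, str, np.ndarray]] = []

    his = {k: _r3(v) for k, v in _HIS_ATOMS.items()}
    for name, pos in his.items():
        atoms.append(("HIS", 298, False, name, name[0], pos))

    # catalytic Asp along +x: OD1 exactly d_gate from the nearest ring atom
    od1 = _r3(his[_RING_MAX_X] + np.array([spec.d_gate, 0.0, 0.0]))
    asp = _chain_offsets(od1, {
        "OD1": (0.0, 0.0, 0.0), "CG": (1.100, 0.600, 0.0),
        "OD2": (1.600, 1.750, 0.0), "CB": (2.400, -0.200, 0.0),
        "CA": (3.930, -0.200, 0.0), "N": (4.430, 1.200, 0.0),
        "C": (5.030, -1.200, 0.0), "O": (5.630, -2.300, 0.0),
    })
    for name, pos in asp.items():
        atoms.append(("ASP", 128, False, name, name[0], pos))

    # His-OUT partner Glu along -x (20 A away when not placed as partner)
    h = spec.d_out_partner if spec.place_out_partner else 20.0
    oe1 = _r3(his[_RING_MIN_X] - np.array([h, 0.0, 0.0]))
    glu = _chain_offsets(oe1, {
        "OE1": (0.0, 0.0, 0.0), "CD": (-1.100, 0.600, 0.0),
        "OE2": (-1.600, 1.750, 0.0), "CG": (-2.400, -0.200, 0.0),
        "CB": (-3.930, -0.200, 0.0), "CA": (-4.430, -1.600, 0.0),
        "N": (-4.930, -0.200, 0.0), "C": (-5.530, -2.600, 0.0),
        "O": (-6.130, -3.700, 0.0),
    })
    for name, pos in glu.items():
        atoms.append(("GLU", 302, False, name, name[0], pos))

    # hinge marker residue
    gly = _chain_offsets(_r3((0.0, -6.0, 0.0)), {
        "N": (-0.500, 1.400, 0.0), "CA": (0.0, 0.0, 0.0),
        "C": (1.100, -1.000, 0.0), "O": (1.700, -2.100, 0.0),
    })
    for name, pos in gly.items():
        atoms.append(("GLY", 200, False, name, name[0], pos))

    if spec.ligand is not None:
        if spec.ligand not in ("inosine", "adenosine"):
            raise GenerationError(f"unknown toy ligand {spec.ligand!r}")
        resname = "INO" if spec.ligand == "inosine" else "ADN"
        c6_sub = "O6" if spec.ligand == "inosine" else "N6"
        o5 = _r3(his["ND1"] + np.array([0.0, 0.0, spec.d_his_o5prime]))
        lig = {"O5'": o5, "C5'": _r3(o5 + np.array([1.400, 0.0, 0.300]))}
        if spec.o6_contact:
            x6 = _r3(asp["O"] + np.array([0.0, 0.0, spec.d_o6_contact]))
        else:
            x6 = _r3(o5 + np.array([2.000, 2.000, 1.500]))
        lig[c6_sub] = x6
        lig["C6"] = _r3(x6 + np.array([0.400, 1.150, 0.300]))
        lig["N1"] = _r3(lig["C6"] + np.array([1.300, 0.400, 0.0]))
        for name, pos in lig.items():
            atoms.append((resname, 401, True, name, name[0], pos))

    if spec.cation is not None:
        if spec.cation not in ("NA", "K"):
            raise GenerationError(f"unsupported cation {spec.cation!r}")
        pos = _r3(gly["O"] + np.array([0.0, 0.0, spec.d_cation]))
        atoms.append((spec.cation, 501, True, spec.cation, spec.cation, pos))

    coords = np.array([a[5] for a in atoms])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    if dist.min() < 1.0:
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        raise GenerationError(
            f"infeasible geometry: atoms {atoms[i][3]}/{atoms[j][3]} overlap "
            f"at {dist[i, j]:.2f} A"
        )
    return atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _toy_site_all_chains(spec: ToySiteSpec):
    base = _toy_site_atoms(spec)
    rng = np.random.default_rng(spec.seed)
    chains = []
    for i in range(spec.n_chains):
        cid = chr(ord("A") + i)
        if i == 0:
            chains.append((cid, base))
            continue
        R = _random_rotation(rng)
        t = np.array([60.0 * i, 0.0, 0.0]) + rng.uniform(-5, 5, size=3)
        moved = []
        for resname, seqid, het, aname, elem, pos in base:
            new = R @ pos + t
            if spec.chain_noise_sigma > 0:
                new = new + rng.normal(0.0, spec.chain_noise_sigma, size=3)
            moved.append((resname, seqid, het, aname, elem, _r3(new)))
        chains.append((cid, moved))
    return chains


def _chains_to_model(structure_id: str, chains) -> StructureModel:
    model = StructureModel(structure_id=structure_id)
    for cid, atoms in chains:
        polymer = Chain(id=cid)
        residues: Dict[Tuple[int, str], Residue] = {}
        for resname, seqid, het, aname, elem, pos in atoms:
            key = (seqid, resname)
            res = residues.get(key)
            if res is None:
                res = Residue(seqid=seqid, icode="", name=resname)
                residues[key] = res
                if het:
                    if len([a for a in atoms if a[1] == seqid]) == 1 and elem in ("NA", "K"):
                        model.ions.append((cid, res))
                    else:
                        model.het_groups.append((cid, res))
                else:
                    polymer.residues.append(res)
            res.atoms[aname] = Atom(name=aname, element=elem, pos=np.array(pos))
        if polymer.residues:
            model.chains.append(polymer)
    return model


def _chains_to_pdb(structure_id: str, chains) -> str:
    st = gemmi.Structure()
    st.name = structure_id
    st.cell = gemmi.UnitCell(200, 200, 200, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    for cid, atoms in chains:
        gchain = gemmi.Chain(cid)
        current: Optional[gemmi.Residue] = None
        for resname, seqid, het, aname, elem, pos in atoms:
            if current is None or current.seqid.num != seqid or current.name != resname:
                current = gemmi.Residue()
                current.name = resname
                current.seqid = gemmi.SeqId(seqid, " ")
                current.het_flag = "H" if het else "A"
                gchain.add_residue(current)
                current = gchain[len(gchain) - 1]
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            atom.b_iso = 20.0
            current.add_atom(atom)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    return st.make_pdb_string()


def toy_site_model(spec: ToySiteSpec) -> StructureModel:
    """The toy site as an in-memory model (identical geometry to the file)."""
    return _chains_to_model("toy_site", _toy_site_all_chains(spec))


def make_toy_site(spec: ToySiteSpec, out_path) -> Tuple[Path, Dict]:
    """Write the toy site as a PDB file plus a sidecar ground-truth JSON."""
    out_path = Path(out_path)
    chains = _toy_site_all_chains(spec)
    out_path.write_text(_chains_to_pdb("toy_site", chains))
    truth = {
        "spec": asdict(spec),
        "landmarks": {"gate_his": 298, "gate_phe": None, "catalytic_asp": 128,
                      "out_partner_glu": 302, "hinge": 200},
        "expected_state": (
            "IN" if spec.d_gate <= 6.0
            else "OUT" if spec.d_gate >= 8.0 and spec.place_out_partner
            else "undetermined"
        ),
    }
    sidecar = out_path.with_suffix(out_path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2))
    return out_path, truth


def toy_landmarks(model: StructureModel) -> Dict[str, Dict[str, Residue]]:
    """Residue map for toy sites, built from the fixed toy numbering."""
    out: Dict[str, Dict[str, Residue]] = {}
    for chain in model.chains:
        landmarks = {}
        for res in chain.residues:
            if res.seqid == 298:
                landmarks["gate_his"] = res
            elif res.seqid == 128:
                landmarks["catalytic_asp"] = res
            elif res.seqid == 302:
                landmarks["out_partner_glu"] = res
            elif res.seqid == 200:
                landmarks["hinge"] = res
        out[chain.id] = landmarks
    return out


# ---------------------------------------------------------------------------
# toy peptide-flip and two-domain pairs


def make_flip_pair(flipped: bool = True) -> Tuple[StructureModel, StructureModel]:
    """A gate-loop backbone segment and a copy with the His-Phe peptide
    plane rotated 180 degrees about the C-alpha/C-alpha axis."""
    names = ["GLY", "GLY", "HIS", "PHE", "GLY", "GLY"]
    seqids = [296, 297, 298, 299, 300, 301]

    def ca_of(i: int) -> np.ndarray:
        # zigzag trace: the C-alpha window must not be collinear
        return np.array([3.8 * i, 0.8 * (i % 2), 0.0])

    def backbone(i: int) -> Dict[str, np.ndarray]:
        ca = ca_of(i)
        return {
            "N": _r3(ca + np.array([-1.200, 0.800, 0.0])),
            "CA": _r3(ca),
            "C": _r3(ca + np.array([1.200, 0.800, 0.0])),
            "O": _r3(ca + np.array([1.600, 1.950, 0.0])),
        }

    # 180-degree rotation about the His-Phe C-alpha/C-alpha axis
    ca_his, ca_phe = ca_of(2), ca_of(3)
    R = rotation_about_axis(ca_phe - ca_his, 180.0)

    def flip_atom(pos: np.ndarray) -> np.ndarray:
        return _r3(R @ (pos - ca_his) + ca_his)

    def build(flip: bool) -> StructureModel:
        atoms = []
        for i, (name, seqid) in enumerate(zip(names, seqids)):
            bb = backbone(i)
            if flip and seqid == 298:
                for aname in ("C", "O"):
                    bb[aname] = flip_atom(bb[aname])
            if flip and seqid == 299:
                bb["N"] = flip_atom(bb["N"])
            for aname, pos in bb.items():
                atoms.append((name, seqid, False, aname, aname[0], pos))
        return _chains_to_model("flip_toy", [("A", atoms)])

    return build(False), build(flipped)


def flip_landmarks(model: StructureModel) -> Dict[str, Dict[str, Residue]]:
    out: Dict[str, Dict[str, Residue]] = {}
    for chain in model.chains:
        landmarks = {}
        for res in chain.residues:
            if res.seqid == 298:
                landmarks["gate_his"] = res
            elif res.seqid == 299:
                landmarks["gate_phe"] = res
        out[chain.id] = landmarks
    return out


def make_two_domain_pair(
    angle_deg: float, seed: int = 0, axis: Optional[Sequence[float]] = None,
) -> Tuple[StructureModel, StructureModel, Dict[str, Tuple[int, int]]]:
    """A two-domain C-alpha model and a copy whose substrate-binding
    domain is rotated by ``angle_deg`` about a fixed axis through its
    centroid (the copy is additionally rigid-moved as a whole)."""
    rng = np.random.default_rng(seed)
    n_dom = 40
    cof = rng.uniform(-8, 8, size=(n_dom, 3))
    sub = rng.uniform(-8, 8, size=(n_dom, 3)) + np.array([25.0, 0.0, 0.0])
    if axis is None:
        axis = rng.normal(size=3)
    R_dom = rotation_about_axis(axis, angle_deg)
    centroid = sub.mean(axis=0)
    sub_rot = (sub - centroid) @ R_dom.T + centroid
    R_glob = _random_rotation(rng)
    t_glob = rng.uniform(-30, 30, size=3)

    def build(cof_c, sub_c, rigid: bool) -> StructureModel:
        chain = Chain(id="A")
        coords = np.vstack([cof_c, sub_c])
        if rigid:
            coords = coords @ R_glob.T + t_glob
        for i, pos in enumerate(coords, start=1):
            res = Residue(seqid=i, icode="", name="ALA")
            res.atoms["CA"] = Atom(name="CA", element="C", pos=pos.copy())
            chain.residues.append(res)
        return StructureModel(structure_id="two_domain_toy", chains=[chain])

    ranges = {"cofactor_binding": (1, n_dom), "substrate_binding": (n_dom + 1, 2 * n_dom)}
    return build(cof, sub, False), build(cof, sub_rot, True), ranges


def make_toy_dimer(
    n_residues: int = 120, sigma: float = 0.0, seed: int = 0
) -> StructureModel:
    """A two-chain model: chain B is a rigid-moved copy of chain A with
    optional isotropic C-alpha noise of standard deviation ``sigma``."""
    rng = np.random.default_rng(seed)
    seq = "".join(_AA20[i] for i in rng.integers(0, 20, size=n_residues))
    # a loose helix-like trace so the coordinates are not degenerate
    t = np.arange(n_residues)
    coords = np.stack([
        10.0 * np.cos(t / 3.0), 10.0 * np.sin(t / 3.0), 1.5 * t
    ], axis=1)
    R = _random_rotation(rng)
    shift = np.array([80.0, 0.0, 0.0]) + rng.uniform(-5, 5, size=3)
    coords_b = coords @ R.T + shift
    if sigma > 0:
        coords_b = coords_b + rng.normal(0.0, sigma, size=coords_b.shape)

    def chain(cid: str, xyz: np.ndarray) -> Chain:
        c = Chain(id=cid)
        for i, (aa, pos) in enumerate(zip(seq, xyz), start=1):
            res = Residue(seqid=i, icode="", name=_ONE_TO_THREE[aa])
            res.atoms["CA"] = Atom(name="CA", element="C", pos=pos.copy())
            c.residues.append(res)
        return c

    return StructureModel(
        structure_id="dimer_toy", chains=[chain("A", coords), chain("B", coords_b)]
    )


# ---------------------------------------------------------------------------
# motif-planted sequences


@dataclass
class ToySeqSpec:
    """Planted-motif sequence generation.

    The scaffold is either the packaged segment-containing reference
    (``reference``) or a random sequence of the same layout; the motif
    anchors are planted at positions 55/57/59, the 40-residue segment
    occupies 151-190 and ``cterm_truncation`` residues are removed from
    the end.  Substitutions never touch the three anchor columns.
    """

    scaffold: str = "reference"  # reference | random
    motif_class: str = "HxExK"
    n_outside_substitutions: int = 0
    delete_segment40: bool = False
    cterm_truncation: int = 0
    seed: int = 0


_MOTIF_ANCHORS = {
    "HxExK": ("H", "E", "K"),
    "HxTxE": ("H", "T", "E"),
    "HxTxQ": ("H", "T", "Q"),
}
_MOTIF_START = 55       # 1-based anchor position in the scaffold
_SEGMENT40 = (151, 190)


def make_motif_sequences(
    spec: ToySeqSpec, n: int = 1
) -> Tuple[List[ProteinSequence], pd.DataFrame]:
    """Generate ``n`` sequences with a planted fingerprint motif.

    Returns the sequences and a truth table (id, motif class, segment
    state, truncation).  Deterministic under ``spec.seed``.
    """
    from .refdata import get_reference

    if n < 1:
        raise InputError("n must be >= 1")
    if spec.motif_class not in _MOTIF_ANCHORS:
        raise GenerationError(f"cannot plant motif class {spec.motif_class!r}")
    rng = np.random.default_rng(spec.seed)
    if spec.scaffold == "reference":
        base = get_reference("bacterial").ref_sequence.residues
    elif spec.scaffold == "random":
        base = "".join(_AA20[i] for i in rng.integers(0, 20, size=469))
    else:
        raise GenerationError(f"unknown scaffold {spec.scaffold!r}")
    if spec.cterm_truncation >= len(base):
        raise GenerationError("C-terminal truncation longer than scaffold")
    if spec.cterm_truncation < 0 or spec.n_outside_substitutions < 0:
        raise InputError("counts must be non-negative")

    anchors = {_MOTIF_START - 1 + 2 * i: aa
               for i, aa in enumerate(_MOTIF_ANCHORS[spec.motif_class])}
    seqs: List[ProteinSequence] = []
    truth_rows = []
    for k in range(n):
        res = list(base)
        for pos0, aa in anchors.items():
            res[pos0] = aa
        candidates = [i for i in range(len(res)) if i not in anchors]
        subs = rng.choice(len(candidates), size=spec.n_outside_substitutions,
                          replace=False)
        for ci in subs:
            pos0 = candidates[ci]
            res[pos0] = _AA20[rng.integers(0, 20)]
        if spec.delete_segment40:
            s, e = _SEGMENT40
            del res[s - 1:e]
        if spec.cterm_truncation:
            res = res[: len(res) - spec.cterm_truncation]
        sid = f"planted_{spec.motif_class}_{spec.seed}_{k}"
        seqs.append(ProteinSequence(sid, "".join(res)))
        truth_rows.append({
            "id": sid,
            "motif_class": spec.motif_class,
            "segment40_present": not spec.delete_segment40,
            "cterm_truncation": spec.cterm_truncation,
        })
    return seqs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# peak tables

_RT_MIN = {
    "SAH": 11.8, "SIH": 10.2, "adenosine": 6.5, "inosine": 5.1,
    "adenine": 4.2, "hypoxanthine": 3.3,
}
_SIDE_FRACTION = 0.15  # of converted substrate ends up as the nucleobase


def make_peak_table(
    true_conversion_pct: float,
    response_factors: Optional[Dict[str, float]] = None,
    noise_sigma_pct: float = 0.0,
    seed: int = 0,
    direction: str = "cleavage",
    substrate: str = "SAH",
    assay_id: Optional[str] = None,
) -> Tuple[PeakTable, Dict]:
    """A peak table whose noise-free conversion equals the target exactly.

    Amounts: substrate 100-c, product 0.85c, nucleobase side product
    0.15c; areas are amounts times the analyte response factor, with
    optional relative Gaussian noise (``noise_sigma_pct`` percent).
    """
    if not 0.0 <= true_conversion_pct <= 100.0:
        raise InputError("true conversion must be in [0, 100]")
    if noise_sigma_pct < 0:
        raise InputError("noise sigma must be non-negative")
    from .assay import DEFAULT_ROLES

    key = (direction, substrate)
    if key not in DEFAULT_ROLES:
        raise InputError(f"no analyte roles for {key}")
    roles = DEFAULT_ROLES[key]
    by_role = {role: analyte for analyte, role in roles.items()}
    response_factors = dict(response_factors or {})
    rng = np.random.default_rng(seed)
    c = true_conversion_pct
    amounts = {
        by_role["substrate"]: 100.0 - c,
        by_role["product"]: (1.0 - _SIDE_FRACTION) * c,
        by_role["side_product"]: _SIDE_FRACTION * c,
    }
    rows = []
    for analyte, amount in amounts.items():
        area = amount * response_factors.get(analyte, 1.0)
        if noise_sigma_pct > 0:
            area = max(0.0, area * (1.0 + rng.normal(0.0, noise_sigma_pct / 100.0)))
        rows.append({"analyte": analyte, "rt_min": _RT_MIN[analyte], "area": area})
    table = PeakTable(
        assay_id=assay_id or f"synthetic_{direction}_{substrate}_{seed}",
        direction=direction,
        substrate=substrate,
        rows=pd.DataFrame(rows),
        response_factors=response_factors,
    )
    truth = {
        "true_conversion_pct": true_conversion_pct,
        "noise_sigma_pct": noise_sigma_pct,
        "seed": seed,
        "direction": direction,
        "substrate": substrate,
    }
    return table, truth
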