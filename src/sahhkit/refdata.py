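"""Packaged reference data.

Real SAHH/SIHH sequences are hundreds of residues that the package does
not redistribute; instead the reference set consists of *synthetic*
scaffold sequences, generated deterministically, that carry the published
landmark numbering of the study enzymes:

* ``pfu`` (PfuSAHH-like, 404 aa): fingerprint motif at 55-59 (His55,
  Glu57, Lys59 = HxExK), molecular gate His298/Phe299, catalytic Asp128,
  His-OUT partner Glu302, C6 main-chain partner Asp348.
* ``sac`` (SacSAHH-like): derived from the Pfu scaffold by removing four
  N-terminal residues, so the motif sits at 51-55 with Thr53 (HxTxE) and
  the adenine N6 partners are Glu342/His344.
* ``mma`` (MmaSAHH-like): the Pfu scaffold behind a 15-residue N-terminal
  extension with one internal deletion, so the motif Lys lands at 74 and
  the C6 partner Asp at 362.
* ``bacterial`` (mesophile-like, 469 aa): the Pfu scaffold with an extra
  40-residue catalytic-domain segment (151-190), an HxTxQ motif and a
  25-residue C-terminal extension; it is the segment-containing,
  long-C-terminus reference used for architecture detection.

The homologue-scan references (``DadD``, ``MTAN``) are synthetic stand-in
sequences as well.  The study table (enzyme, phylum, motif class, assay
symbols, DadD/MTAN presence) is the published Table of tested enzymes and
ships as plain text.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sequences import ProteinSequence, ReferenceAnnotation

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_SCAFFOLD_SEED = 730514  # fixed: reference scaffolds are versioned data


def _random_residues(n: int, rng: np.random.Generator) -> List[str]:
    return [_AA20[i] for i in rng.integers(0, 20, size=n)]


def _pfu_scaffold() -> str:
    rng = np.random.default_rng(_SCAFFOLD_SEED)
    res = _random_residues(404, rng)
    # planted landmarks, 1-based published numbering
    res[54] = "H"   # motif position 1, His55
    res[55] = "S"
    res[56] = "E"   # Glu57
    res[57] = "M"
    res[58] = "K"   # Lys59
    res[127] = "D"  # catalytic Asp128
    res[297] = "H"  # gate His298
    res[298] = "F"  # gate Phe299
    res[301] = "E"  # His-OUT partner Glu302
    res[347] = "D"  # C6 main-chain partner Asp348
    return "".join(res)


_DOMAIN_RANGES_PFU = {
    "substrate_binding": (5, 215),
    "cofactor_binding": (226, 354),
    "dimerisation": (371, 404),
    "hinge": [(216, 225), (355, 370)],
}


def _shift_ranges(ranges: Dict, offset: int, n: int) -> Dict:
    out = {}
    for name, rng in ranges.items():
        if isinstance(rng, list):
            out[name] = [
                (max(1, s + offset), min(n, e + offset)) for s, e in rng
            ]
        else:
            s, e = rng
            out[name] = (max(1, s + offset), min(n, e + offset))
    return out


@functools.lru_cache(maxsize=None)
def get_reference(name: str = "pfu") -> ReferenceAnnotation:
    """Return a packaged (synthetic-scaffold) reference annotation."""
    pfu = _pfu_scaffold()
    if name == "pfu":
        return ReferenceAnnotation(
            ref_id="pfu_synthetic_ref",
            ref_sequence=ProteinSequence("pfu_synthetic_ref", pfu),
            motif_start=55,
            gate_his=298,
            gate_phe=299,
            catalytic_asp=128,
            out_partner_glu=302,
            c6_partner=348,
            domain_ranges=_DOMAIN_RANGES_PFU,
        )
    if name == "sac":
        res = list(pfu[4:])  # drop 4 N-terminal residues: Glu57 -> position 53
        res[50] = "H"   # His51
        res[52] = "T"   # Thr53 (HxTxE)
        res[54] = "E"   # Glu55
        res[341] = "E"  # Glu342, adenine N6 main-chain partner
        res[343] = "H"  # His344
        seq = "".join(res)
        return ReferenceAnnotation(
            ref_id="sac_synthetic_ref",
            ref_sequence=ProteinSequence("sac_synthetic_ref", seq),
            motif_start=51,
            gate_his=294,
            gate_phe=295,
            catalytic_asp=124,
            out_partner_glu=298,
            c6_partner=342,
            domain_ranges=_shift_ranges(_DOMAIN_RANGES_PFU, -4, len(seq)),
        )
    if name == "mma":
        rng = np.random.default_rng(_SCAFFOLD_SEED + 1)
        prefix = "".join(_random_residues(15, rng))
        # one internal deletion (Pfu 331) puts the C6 partner Asp at 362
        seq = prefix + pfu[:330] + pfu[331:]
        return ReferenceAnnotation(
            ref_id="mma_synthetic_ref",
            ref_sequence=ProteinSequence("mma_synthetic_ref", seq),
            motif_start=70,   # His70 .. Lys74
            gate_his=313,
            gate_phe=314,
            catalytic_asp=143,
            out_partner_glu=317,
            c6_partner=362,   # Asp362
            domain_ranges=_shift_ranges(_DOMAIN_RANGES_PFU, 15, len(seq)),
        )
    if name == "bacterial":
        rng = np.random.default_rng(_SCAFFOLD_SEED + 2)
        segment = "".join(_random_residues(40, rng))
        tail = "".join(_random_residues(25, rng))
        res = list(pfu[:150] + segment + pfu[150:] + tail)
        res[56] = "T"  # HxTxQ motif
        res[58] = "Q"
        seq = "".join(res)
        return ReferenceAnnotation(
            ref_id="bacterial_synthetic_ref",
            ref_sequence=ProteinSequence("bacterial_synthetic_ref", seq),
            motif_start=55,
            gate_his=338,
            gate_phe=339,
            catalytic_asp=128,
            out_partner_glu=342,
            c6_partner=388,
            domain_ranges={
                "substrate_binding": (5, 255),
                "cofactor_binding": (266, 394),
                "dimerisation": (411, 469),
                "hinge": [(256, 265), (395, 410)],
            },
            segment40=(151, 190),
        )
    raise ConfigurationError(f"unknown reference {name!r}")


REFERENCE_NAMES = ("pfu", "sac", "mma", "bacterial")


@functools.lru_cache(maxsize=None)
def get_homolog_reference(name: str) -> ProteinSequence:
    """Synthetic stand-in reference for the DadD / MTAN homologue scan."""
    if name == "DadD":
        rng = np.random.default_rng(_SCAFFOLD_SEED + 10)
        return ProteinSequence(
            "MjDadD_synthetic_ref", "".join(_random_residues(440, rng)),
            organism="Methanocaldococcus jannaschii",
        )
    if name == "MTAN":
        rng = np.random.default_rng(_SCAFFOLD_SEED + 11)
        return ProteinSequence(
            "EcMTAN_synthetic_ref", "".join(_random_residues(232, rng)),
            organism="Escherichia coli",
        )
    raise ConfigurationError(f"unknown homologue reference {name!r}")


def load_study_table() -> pd.DataFrame:
    """The published study table of 18 biochemically tested enzymes."""
    with resources.files("sahhkit.data").joinpath("study_set.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def study_sequences(seed: int = 0) -> Tuple[List[ProteinSequence], pd.DataFrame]:
    """Synthetic study-set sequences matching the published feature table.

    For every enzyme in the study table a scaffold sequence is generated
    (from the segment-containing mesophile reference) with that enzyme's
    motif class planted, the 40-residue segment deleted where the table
    marks it absent, and the C-terminus truncated for short-C-terminus
    (thermophile-like) entries.  Returns the sequences and the table.
    """
    from .synthetic import ToySeqSpec, make_motif_sequences

    table = load_study_table()
    seqs: List[ProteinSequence] = []
    for i, row in table.iterrows():
        spec = ToySeqSpec(
            motif_class=row["motif_class"],
            delete_segment40=row["segment40"] == "absent",
            cterm_truncation=25 if row["cterm"] == "short" else 0,
            n_outside_substitutions=8,
            seed=seed + i,
        )
        recs, _ = make_motif_sequences(spec, n=1)
        seqs.append(
            ProteinSequence(
                row["enzyme"],
                recs[0].residues,
                organism=row["organism"],
                phylum=row["phylum"],
            )
        )
    return seqs, table
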