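"""FASTA reading/writing and report emitters (TSV/JSON)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError
from .sequences import ProteinSequence


def read_fasta(path) -> List[ProteinSequence]:
    """Read a multi-record FASTA file (wrapped or single-line)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise InputError(f"FASTA {path} contains no records")
    return [ProteinSequence(rec.id, str(rec.seq)) for rec in records]


def write_fasta(sequences: Iterable[ProteinSequence], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.organism or "")
        for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_tsv(rows: Sequence[Mapping], path) -> None:
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
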