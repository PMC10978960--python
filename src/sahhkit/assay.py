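"""Semi-quantitative HPLC assay scoring.

Enzyme activity is followed by HPLC peak areas: the substrate peak
shrinks as the product (adenosine/inosine in the cleavage direction,
SAH/SIH in the synthesis direction) and the nucleobase side product
(adenine/hypoxanthine) appear.  Conversion is scored from
response-corrected areas and binned into the published categories:
+++ (>70%), ++ (30-70%), + (<30%) and - (below the noise floor).
Per-enzyme substrate preference is called from the four records
(two substrates x two directions) by ordinal comparison, and the calls
are compared against the motif-based sequence predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import FormatError, InputError, MeasurementError

ANALYTE_VOCABULARY = frozenset({
    "SAH", "SIH", "adenosine", "inosine", "adenine", "hypoxanthine",
    "Hcy", "Hcy-disulfide", "methionine", "S-methylmethionine",
})

CATEGORY_ORDER = {"-": 0, "+": 1, "++": 2, "+++": 3}

#: default analyte roles per (direction, substrate); Hcy-derived species
#: are excluded from the denominator (their UV response is not comparable)
DEFAULT_ROLES: Dict[Tuple[str, str], Dict[str, str]] = {
    ("cleavage", "SAH"): {
        "SAH": "substrate", "adenosine": "product", "adenine": "side_product",
    },
    ("cleavage", "SIH"): {
        "SIH": "substrate", "inosine": "product", "hypoxanthine": "side_product",
    },
    ("synthesis", "SAH"): {
        "adenosine": "substrate", "SAH": "product", "adenine": "side_product",
    },
    ("synthesis", "SIH"): {
        "inosine": "substrate", "SIH": "product", "hypoxanthine": "side_product",
    },
}


@dataclass
class PeakTable:
    """One assay's peak areas: rows of (analyte, retention time, area)."""

    assay_id: str
    direction: str  # cleavage | synthesis
    substrate: str  # SAH | SIH
    rows: pd.DataFrame  # columns: analyte, rt_min, area
    response_factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("cleavage", "synthesis"):
            raise InputError(f"unknown direction {self.direction!r}")
        required = {"analyte", "rt_min", "area"}
        if not required.issubset(self.rows.columns):
            raise FormatError(f"peak table needs columns {sorted(required)}")
        if (self.rows["area"] < 0).any():
            raise InputError("peak areas must be non-negative")
        unknown = set(self.rows["analyte"]) - ANALYTE_VOCABULARY
        if unknown:
            raise InputError(f"unknown analytes {sorted(unknown)}")


@dataclass(frozen=True)
class ConversionRecord:
    enzyme_id: str
    substrate: str
    direction: str
    conversion_pct: float
    category: str


@dataclass(frozen=True)
class PreferenceCallAssay:
    enzyme_id: str
    label: str
    records: Tuple[ConversionRecord, ...]


def categorize(conversion_pct: float, noise_floor_pct: float = 1.0) -> str:
    """Published conversion categories; the 30-70 band is closed on both
    ends (the printed thresholds are strict >70% and <30%)."""
    if not 0.0 <= conversion_pct <= 100.0:
        raise InputError(f"conversion {conversion_pct} outside [0, 100]")
    if conversion_pct <= noise_floor_pct:
        return "-"
    if conversion_pct < 30.0:
        return "+"
    if conversion_pct <= 70.0:
        return "++"
    return "+++"


def score_conversion(
    peaks: PeakTable,
    roles: Optional[Mapping[str, str]] = None,
    enzyme_id: Optional[str] = None,
    noise_floor_pct: float = 1.0,
) -> ConversionRecord:
    """Conversion percentage from response-corrected peak areas.

    conversion = 100 * sum(product + side-product amounts) /
    sum(substrate + product + side-product amounts), where amount =
    area / response factor (default 1.0).  Analytes with role
    ``excluded`` are ignored.
    """
    if roles is None:
        key = (peaks.direction, peaks.substrate)
        if key not in DEFAULT_ROLES:
            raise InputError(f"no default analyte roles for {key}")
        roles = DEFAULT_ROLES[key]
    amounts = {"substrate": 0.0, "product": 0.0, "side_product": 0.0}
    substrate_seen = False
    for _, row in peaks.rows.iterrows():
        role = roles.get(row["analyte"], "excluded")
        if role == "excluded":
            continue
        rf = float(peaks.response_factors.get(row["analyte"], 1.0))
        amounts[role] += float(row["area"]) / rf
        if role == "substrate":
            substrate_seen = True
    if not substrate_seen:
        raise InputError(
            f"substrate analyte missing from peak table {peaks.assay_id}"
        )
    total = sum(amounts.values())
    if total <= 0:
        raise MeasurementError(f"all peak areas zero in {peaks.assay_id}")
    conversion = 100.0 * (amounts["product"] + amounts["side_product"]) / total
    return ConversionRecord(
        enzyme_id=enzyme_id or peaks.assay_id,
        substrate=peaks.substrate,
        direction=peaks.direction,
        conversion_pct=conversion,
        category=categorize(conversion, noise_floor_pct),
    )


def records_from_symbols(
    enzyme_id: str, symbols: Mapping[Tuple[str, str], str]
) -> List[ConversionRecord]:
    """Build categorical records directly from published symbols.

    ``symbols`` maps (substrate, direction) to one of -/+/++/+++; the
    numeric conversion is set to a category-representative value.
    """
    representative = {"-": 0.0, "+": 15.0, "++": 50.0, "+++": 85.0}
    out = []
    for (substrate, direction), sym in symbols.items():
        if sym not in CATEGORY_ORDER:
            raise InputError(f"unknown category symbol {sym!r}")
        out.append(ConversionRecord(
            enzyme_id=enzyme_id, substrate=substrate, direction=direction,
            conversion_pct=representative[sym], category=sym,
        ))
    return out


def call_assay_preference(
    records: Sequence[ConversionRecord],
) -> PreferenceCallAssay:
    """Per-enzyme substrate preference from the four assay records.

    Categories are compared ordinally (- < + < ++ < +++): a substrate
    strictly greater in at least one direction and not smaller in the
    other is preferred; if the other substrate shows no conversion in
    either direction the call upgrades to SAH-only/SIH-only; all - means
    inactive; anything else is both/no-preference.
    """
    by_key: Dict[Tuple[str, str], ConversionRecord] = {}
    enzyme_ids = set()
    for r in records:
        by_key[(r.substrate, r.direction)] = r
        enzyme_ids.add(r.enzyme_id)
    needed = [(s, d) for s in ("SAH", "SIH") for d in ("cleavage", "synthesis")]
    missing = [k for k in needed if k not in by_key]
    if missing:
        raise InputError(f"missing assay records for {missing}")
    if len(enzyme_ids) != 1:
        raise InputError(f"records mix enzymes: {sorted(enzyme_ids)}")
    enzyme_id = enzyme_ids.pop()
    sah = tuple(CATEGORY_ORDER[by_key[("SAH", d)].category] for d in ("cleavage", "synthesis"))
    sih = tuple(CATEGORY_ORDER[by_key[("SIH", d)].category] for d in ("cleavage", "synthesis"))
    if max(sah) == 0 and max(sih) == 0:
        label = "inactive"
    elif all(a >= b for a, b in zip(sah, sih)) and any(a > b for a, b in zip(sah, sih)):
        label = "SAH-only" if max(sih) == 0 else "SAH-preferring"
    elif all(b >= a for a, b in zip(sah, sih)) and any(b > a for a, b in zip(sah, sih)):
        label = "SIH-only" if max(sah) == 0 else "SIH-preferring"
    else:
        label = "both/no-preference"
    ordered = tuple(by_key[k] for k in needed)
    return PreferenceCallAssay(enzyme_id=enzyme_id, label=label, records=ordered)


_CONCORDANT = {
    "SIH-preferring": {"SIH-preferring", "SIH-only"},
    "SAH-preferring": {"SAH-preferring", "SAH-only"},
}


def concordance_report(
    predictions: Mapping[str, str], assay_calls: Mapping[str, str]
) -> Tuple[pd.DataFrame, float]:
    """Compare motif-based predictions against assay preference calls.

    Returns the per-enzyme table (with a note on discordant rows) and the
    overall concordant fraction over the shared enzyme ids.
    """
    shared = sorted(set(predictions) & set(assay_calls))
    if not shared:
        raise InputError("no shared enzyme ids between predictions and calls")
    rows = []
    n_conc = 0
    for enzyme in shared:
        pred = predictions[enzyme]
        call = assay_calls[enzyme]
        concordant = call in _CONCORDANT.get(pred, set())
        n_conc += concordant
        note = ""
        if not concordant:
            if pred == "unknown":
                note = "no motif-based prediction"
            else:
                note = (
                    f"assay call {call} not explained by motif class; "
                    "substrate recognition beyond the fingerprint motif"
                )
        rows.append({
            "enzyme": enzyme, "predicted": pred, "assay": call,
            "concordant": concordant, "note": note,
        })
    table = pd.DataFrame(rows)
    return table, n_conc / len(shared)


# ---------------------------------------------------------------------------
# delimited-text IO

def read_peak_table(path, sep: Optional[str] = None) -> List[PeakTable]:
    """Read peak tables from delimited text.

    Expected header: assay, direction, substrate, analyte, rt_min, area
    and optionally response_factor.  Multiple assays may share one file.
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse peak table {path}: {exc}") from exc
    required = {"assay", "direction", "substrate", "analyte", "rt_min", "area"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"peak table {path} missing columns {sorted(required - set(df.columns))}"
        )
    tables = []
    for assay_id, grp in df.groupby("assay", sort=False):
        rf = {}
        if "response_factor" in grp.columns:
            rf = {
                row["analyte"]: float(row["response_factor"])
                for _, row in grp.iterrows()
                if pd.notna(row.get("response_factor"))
            }
        tables.append(PeakTable(
            assay_id=str(assay_id),
            direction=str(grp["direction"].iloc[0]),
            substrate=str(grp["substrate"].iloc[0]),
            rows=grp[["analyte", "rt_min", "area"]].reset_index(drop=True),
            response_factors=rf,
        ))
    return tables


def write_peak_table(tables: Iterable[PeakTable], path, sep: str = ",") -> None:
    frames = []
    for t in tables:
        df = t.rows.copy()
        df.insert(0, "assay", t.assay_id)
        df.insert(1, "direction", t.direction)
        df.insert(2, "substrate", t.substrate)
        if t.response_factors:
            df["response_factor"] = [
                t.response_factors.get(a, 1.0) for a in df["analyte"]
            ]
        frames.append(df)
    pd.concat(frames).to_csv(path, sep=sep, index=False)


def render_preference_table(calls: Sequence[PreferenceCallAssay]) -> str:
    """Study-table-style text rendering with the +++/++/+/- symbols."""
    lines = ["enzyme\tSAH cleavage/synthesis\tSIH cleavage/synthesis\tcall"]
    for call in calls:
        by = {(r.substrate, r.direction): r.category for r in call.records}
        lines.append(
            f"{call.enzyme_id}\t"
            f"{by[('SAH', 'cleavage')]}/{by[('SAH', 'synthesis')]}\t"
            f"{by[('SIH', 'cleavage')]}/{by[('SIH', 'synthesis')]}\t"
            f"{call.label}"
        )
    return "\n".join(lines) + "\n"
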