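"""Packaged published screening-value tables and validation against them.

The package ships the published 119-API table (name, CASRN, LTD, total
UF/AF, sRfD, WSV) and the five-API comparison against health-based
guidance values from full in-depth reviews. The published numbers are
ground truth and are never recomputed in place; validation is
one-directional — recompute with this package's arithmetic, compare, and
report. Rows that do not reproduce under the derivation equations as
printed are frozen in ``known_discrepancies.json`` with the recomputed
value, rather than silently corrected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .derivation import compute_srfd, compute_wsv
from .rounding import round_sig, to_decimal

__all__ = [
    "PublishedRecord",
    "load_table3",
    "load_table4",
    "load_known_discrepancies",
    "Mismatch",
    "ValidationReport",
    "validate_published",
    "aggregate_stats",
    "protection_ratio",
    "contextualize_detections",
]

_LATTICE_MIN, _LATTICE_MAX = 100, 30_000


def _on_half_log_lattice(value: int) -> bool:
    e = math.log10(value)
    if abs(e - round(e)) < 1e-9:
        return True
    f = math.log10(value / 3)
    return abs(f - round(f)) < 1e-9


@dataclass(frozen=True)
class PublishedRecord:
    """One published row; numeric fields kept as decimals of the printed text."""

    api_name: str
    casrn: Optional[str]
    ltd_mg_kg_d: Decimal
    total_uf: int
    srfd_mg_kg_d: Decimal
    wsv_ug_L: Decimal
    rsc: Decimal
    source: str  # "table3" | "table4"
    inconsistent_as_printed: bool = False
    hbg_ug_L: Optional[Decimal] = None


def _resource(name: str):
    return resources.files("rxscreen.data").joinpath(name)


def load_table3() -> list[PublishedRecord]:
    """The 119-API published table."""
    with _resource("table3_wsv.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    records = []
    for i, row in df.iterrows():
        try:
            rec = PublishedRecord(
                api_name=row["api_name"],
                casrn=None if row["casrn"] == "-" else row["casrn"],
                ltd_mg_kg_d=Decimal(row["ltd_mg_kg_d"]),
                total_uf=int(row["total_uf"]),
                srfd_mg_kg_d=Decimal(row["srfd_mg_kg_d"]),
                wsv_ug_L=Decimal(row["wsv_ug_L"]),
                rsc=Decimal(row["rsc"]),
                source="table3",
            )
        except (KeyError, ValueError, ArithmeticError) as exc:
            raise ValueError(f"table3 row {i} ({row.get('api_name')}): {exc}") from exc
        if not _LATTICE_MIN <= rec.total_uf <= _LATTICE_MAX or not _on_half_log_lattice(
            rec.total_uf
        ):
            raise ValueError(
                f"table3 row {i} ({rec.api_name}): total UF/AF {rec.total_uf} is off "
                f"the half-log lattice [{_LATTICE_MIN}, {_LATTICE_MAX}]"
            )
        records.append(rec)
    if len(records) != 119:
        raise ValueError(f"expected 119 published records, found {len(records)}")
    return records


def load_table4() -> pd.DataFrame:
    """Published WSV vs health-based guidance comparison (five APIs).

    The acetaminophen, 17a-ethinylestradiol and venlafaxine rows carry an
    ``inconsistent_as_printed`` flag: the WSVs printed for them cannot be
    reproduced from the inputs printed beside them, and the package keeps
    them as published rather than resolving the conflict.
    """
    with _resource("table4_hbg.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"total_uf": int})
    df["inconsistent_as_printed"] = df["inconsistent_as_printed"].astype(bool)
    return df


def load_known_discrepancies() -> dict:
    with _resource("known_discrepancies.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class Mismatch:
    api_name: str
    quantity: str  # "srfd" | "wsv"
    printed: Decimal
    recomputed: Decimal

    @property
    def magnitude(self) -> float:
        return float(self.recomputed / self.printed)


@dataclass(frozen=True)
class ValidationReport:
    frame: pd.DataFrame
    mismatches: tuple[Mismatch, ...]
    n_records: int

    @property
    def n_matching(self) -> int:
        return self.n_records - len({m.api_name for m in self.mismatches})

    def unexpected(self, known: Mapping | None = None) -> list[Mismatch]:
        """Mismatches not covered by the frozen known-discrepancy file."""
        known = load_known_discrepancies() if known is None else known
        keys = {(d["api_name"], d["quantity"]) for d in known.get("table3", [])}
        return [m for m in self.mismatches if (m.api_name, m.quantity) not in keys]


def validate_published(
    records: list[PublishedRecord], config: RunConfig = DEFAULT_CONFIG
) -> ValidationReport:
    """Recompute every published row and flag divergences.

    The sRfD is recomputed from the printed LTD and total UF/AF; the WSV is
    recomputed from the PRINTED sRfD and RSC, so the two checks are
    independent and a transcription slip in one column cannot hide in the
    other. Comparison is exact numeric equality of decimals.
    """
    rows = []
    mismatches: list[Mismatch] = []
    for rec in records:
        srfd = compute_srfd(rec.ltd_mg_kg_d, rec.total_uf, config)
        wsv = compute_wsv(rec.srfd_mg_kg_d, float(rec.rsc), config)
        srfd_ok = srfd == rec.srfd_mg_kg_d
        wsv_ok = wsv == rec.wsv_ug_L
        if not srfd_ok:
            mismatches.append(Mismatch(rec.api_name, "srfd", rec.srfd_mg_kg_d, srfd))
        if not wsv_ok:
            mismatches.append(Mismatch(rec.api_name, "wsv", rec.wsv_ug_L, wsv))
        rows.append(
            {
                "api_name": rec.api_name,
                "casrn": rec.casrn,
                "ltd_mg_kg_d": float(rec.ltd_mg_kg_d),
                "total_uf": rec.total_uf,
                "srfd_printed": format(rec.srfd_mg_kg_d, "f"),
                "srfd_recomputed": format(srfd, "f"),
                "srfd_match": srfd_ok,
                "wsv_printed": format(rec.wsv_ug_L, "f"),
                "wsv_recomputed": format(wsv, "f"),
                "wsv_match": wsv_ok,
            }
        )
    return ValidationReport(pd.DataFrame(rows), tuple(mismatches), len(records))


def aggregate_stats(records: list[PublishedRecord]) -> dict:
    """Order statistics over the published columns."""
    if not records:
        return {}
    ltds = [r.ltd_mg_kg_d for r in records]
    wsvs = [r.wsv_ug_L for r in records]
    srfds = [r.srfd_mg_kg_d for r in records]
    totals = [r.total_uf for r in records]
    return {
        "n": len(records),
        "ltd_min_mg_kg_d": float(min(ltds)),
        "ltd_max_mg_kg_d": float(max(ltds)),
        "srfd_min_mg_kg_d": float(min(srfds)),
        "srfd_max_mg_kg_d": float(max(srfds)),
        "wsv_min_ug_L": float(min(wsvs)),
        "wsv_max_ug_L": float(max(wsvs)),
        "total_uf_min": min(totals),
        "total_uf_max": max(totals),
    }


def protection_ratio(hbg_ug_L, wsv_ug_L) -> Decimal:
    """Fold difference HBG / WSV, to 2 significant figures.

    Values above 1 mean the screening value is the more conservative of
    the pair; below 1 would flag a screening value less protective than
    the in-depth guidance.
    """
    hbg, wsv = to_decimal(hbg_ug_L), to_decimal(wsv_ug_L)
    if hbg <= 0 or wsv <= 0:
        raise ValueError("protection_ratio requires positive concentrations")
    return round_sig(hbg / wsv, 2)


def contextualize_detections(
    detections: pd.DataFrame, records: list[PublishedRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen monitoring detections against WSVs.

    ``detections`` needs columns ``analyte``, ``concentration_ug_L`` and
    optionally ``casrn``. Matching is by CASRN when present, else
    case-insensitive name. A concentration strictly above the WSV flags an
    exceedance; equality does not. Returns (screened, unmatched) — no
    input row is dropped.
    """
    if "analyte" not in detections or "concentration_ug_L" not in detections:
        raise ValueError("detections need 'analyte' and 'concentration_ug_L' columns")
    by_name = {r.api_name.lower(): r for r in records}
    by_cas = {r.casrn: r for r in records if r.casrn}

    screened_rows, unmatched_rows = [], []
    for i, row in detections.iterrows():
        conc = row["concentration_ug_L"]
        if conc is None or float(conc) < 0:
            raise ValueError(f"detections row {i} ({row['analyte']}): bad concentration {conc}")
        rec = None
        if "casrn" in detections and isinstance(row.get("casrn"), str):
            rec = by_cas.get(row["casrn"])
        if rec is None:
            rec = by_name.get(str(row["analyte"]).lower())
        if rec is None:
            unmatched_rows.append({"analyte": row["analyte"], "concentration_ug_L": conc})
            continue
        wsv = rec.wsv_ug_L
        conc_d = to_decimal(conc)
        screened_rows.append(
            {
                "analyte": row["analyte"],
                "api_name": rec.api_name,
                "casrn": rec.casrn,
                "concentration_ug_L": float(conc),
                "wsv_ug_L": float(wsv),
                "ratio": float(conc_d / wsv),
                "exceeds_wsv": conc_d > wsv,
            }
        )
    return pd.DataFrame(screened_rows), pd.DataFrame(unmatched_rows)
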