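"""Reading and writing evidence profiles (CSV and JSON).

The JSON form is a list of nested profile objects, exactly the package's
JSON schema. The CSV form is flat — one column per scalar field, with the
carcinogenicity/endocrine sub-objects flattened under ``cancer_*`` /
``endocrine_finding`` prefixes and the dosing regimens as a nested JSON
column — so that curators can maintain profiles in a spreadsheet.

Parsing aggregates errors per line instead of failing on the first bad
row: a file with one malformed record among ten still yields nine
profiles plus one error naming the row and field.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import ValidationError

from .evidence import EvidenceProfile

__all__ = ["LoadError", "LoadResult", "read_profiles", "write_profiles"]

log = logging.getLogger(__name__)

_CANCER_PREFIX = "cancer_"
_SCALAR_BOOLS = {
    "discontinued_override",
    "category_c_ltd_near_reprotox_dose",
    "black_box_warning_relevant",
    "life_threatening_indication",
    "not_tested_in_children_or_different_pediatric_profile",
    "serious_effects_at_ltd",
    "otc_pediatric_use",
}

_CSV_COLUMNS = [
    "api_name",
    "casrn",
    "route",
    "product_status",
    "discontinued_override",
    "cancer_finding",
    "cancer_hed_mg_per_kg_day",
    "cancer_mrhd_mg_per_kg_day",
    "endocrine_finding",
    "pregnancy_category",
    "category_c_ltd_near_reprotox_dose",
    "black_box_warning_relevant",
    "life_threatening_indication",
    "not_tested_in_children_or_different_pediatric_profile",
    "serious_effects_at_ltd",
    "database_completeness",
    "duration_profile",
    "otc_pediatric_use",
    "label_source",
    "regimens",
]


@dataclass(frozen=True)
class LoadError:
    row: int
    message: str


@dataclass(frozen=True)
class LoadResult:
    profiles: list[EvidenceProfile]
    errors: list[LoadError] = field(default_factory=list)

    def raise_on_errors(self) -> list[EvidenceProfile]:
        if self.errors:
            detail = "; ".join(f"row {e.row}: {e.message}" for e in self.errors)
            raise ValueError(f"{len(self.errors)} invalid profile record(s): {detail}")
        return self.profiles


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        msg = err["msg"]
        ctx = err.get("ctx") or {}
        if "expected" in ctx:  # enum errors: name the allowed set
            msg = f"{msg} (allowed: {ctx['expected']})"
        parts.append(f"field '{loc}': {msg}")
    return "; ".join(parts)


def _profile_from_flat(flat: dict) -> EvidenceProfile:
    data: dict = {}
    cancer: dict = {}
    for key, value in flat.items():
        if value is None or value == "":
            continue
        if key.startswith(_CANCER_PREFIX):
            cancer[key[len(_CANCER_PREFIX):]] = value
        elif key == "endocrine_finding":
            data["endocrine"] = {"finding": value}
        elif key == "regimens":
            data["regimens"] = json.loads(value) if isinstance(value, str) else value
        elif key in _SCALAR_BOOLS and isinstance(value, str):
            data[key] = value.strip().lower() in ("true", "1", "yes")
        else:
            data[key] = value
    if cancer:
        data["carcinogenicity"] = cancer
    return EvidenceProfile.model_validate(data)


def read_profiles(path, format: str | None = None) -> LoadResult:
    """Load profiles from a CSV or JSON file (format inferred from suffix)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    profiles: list[EvidenceProfile] = []
    errors: list[LoadError] = []

    if fmt == "json":
        text = path.read_text()
        if not text.strip():
            log.warning("%s: empty profile file", path)
            return LoadResult([], [])
        raw = json.loads(text)
        for i, item in enumerate(raw):
            try:
                profiles.append(EvidenceProfile.model_validate(item))
            except ValidationError as exc:
                errors.append(LoadError(i, _format_validation_error(exc)))
        return LoadResult(profiles, errors)

    if fmt != "csv":
        raise ValueError(f"unknown profile format {fmt!r} (expected csv or json)")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    if not rows:
        log.warning("%s: empty profile file", path)
        return LoadResult([], [])
    for i, row in enumerate(rows):
        try:
            profiles.append(_profile_from_flat(row))
        except ValidationError as exc:
            errors.append(LoadError(i, _format_validation_error(exc)))
        except (json.JSONDecodeError, ValueError) as exc:
            errors.append(LoadError(i, str(exc)))
    return LoadResult(profiles, errors)


def write_profiles(profiles: list[EvidenceProfile], path, format: str | None = None) -> None:
    """Write profiles to CSV or JSON; CSV round-trips through read_profiles."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")

    if fmt == "json":
        payload = [p.model_dump(mode="json") for p in profiles]
        path.write_text(json.dumps(payload, indent=2))
        return
    if fmt != "csv":
        raise ValueError(f"unknown profile format {fmt!r} (expected csv or json)")

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        for p in profiles:
            d = p.model_dump(mode="json")
            row = {
                key: d.get(key, "")
                for key in _CSV_COLUMNS
                if key not in ("cancer_finding", "cancer_hed_mg_per_kg_day",
                               "cancer_mrhd_mg_per_kg_day", "endocrine_finding", "regimens")
            }
            row["cancer_finding"] = d["carcinogenicity"]["finding"]
            row["cancer_hed_mg_per_kg_day"] = d["carcinogenicity"]["hed_mg_per_kg_day"]
            row["cancer_mrhd_mg_per_kg_day"] = d["carcinogenicity"]["mrhd_mg_per_kg_day"]
            row["endocrine_finding"] = d["endocrine"]["finding"]
            row["regimens"] = json.dumps(d["regimens"])
            for key in list(row):
                if row[key] is None:
                    row[key] = ""
            writer.writerow(row)
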