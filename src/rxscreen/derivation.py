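"""Screening reference dose (sRfD) and water screening value (WSV).

    sRfD (mg/kg-d) = LTD / [(AF_C or AF_E) x UF_Human x UF_L_N x UF_DB x UF_S_C]
    WSV  (ug/L)    = sRfD x RSC x 1000 (ug/mg) / 0.289 (L/kg-d)

The intake rate 0.289 L/kg-d is the 95th-percentile consumption of a
bottle-fed infant aged 1-3 months, the most highly exposed life stage per
unit body weight. The relative source contribution (RSC) caps the share of
the reference dose allocable to drinking water: 0.8 by default, 0.2 for
APIs that also appear in numerous over-the-counter children's products
(acetaminophen/ibuprofen pattern), where other exposure routes dominate.

Rounding is two-stage: the sRfD is rounded to 2 significant figures first
and the WSV is computed FROM that rounded value, then rounded to 1
significant figure. The order matters on boundary cases (an LTD/total of
0.0125 rounds to 0.013 and yields a WSV of 40, where the unrounded chain
would give 30) and is the convention that reproduces the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional

from .config import DEFAULT_CONFIG, RunConfig
from .evidence import EvidenceProfile
from .factors import FactorSet, TotalFactor, assign_all
from .ltd import BodyWeightTable, LTDResult, compute_ltd
from .rounding import round_sig, to_decimal
from .evidence import screen_eligibility

__all__ = [
    "compute_srfd",
    "select_rsc",
    "compute_wsv",
    "derive",
    "ScreeningResult",
]


def compute_srfd(
    ltd_mg_kg_d, total: TotalFactor | int, config: RunConfig = DEFAULT_CONFIG
) -> Decimal:
    """LTD divided by the combined factor, rounded to 2 significant figures."""
    ltd = to_decimal(ltd_mg_kg_d)
    if ltd <= 0:
        raise ValueError("LTD must be positive")
    divisor = total.display_value if isinstance(total, TotalFactor) else int(total)
    return round_sig(ltd / divisor, config.srfd_sig_figs)


def select_rsc(profile: EvidenceProfile, config: RunConfig = DEFAULT_CONFIG) -> float:
    """Relative source contribution: 0.2 for pediatric-OTC APIs, else 0.8."""
    return config.rsc_otc if profile.otc_pediatric_use else config.rsc_default


def compute_wsv(srfd_mg_kg_d, rsc: float, config: RunConfig = DEFAULT_CONFIG) -> Decimal:
    """WSV in ug/L from an ALREADY-ROUNDED sRfD (two-stage convention)."""
    srfd = to_decimal(srfd_mg_kg_d)
    if srfd <= 0:
        raise ValueError("sRfD must be positive")
    wsv = (
        srfd
        * to_decimal(rsc)
        * to_decimal(config.conversion_ug_per_mg)
        / to_decimal(config.intake_L_kg_d)
    )
    return round_sig(wsv, config.wsv_sig_figs)


@dataclass(frozen=True)
class ScreeningResult:
    """Full derivation record for one API."""

    api_name: str
    casrn: Optional[str]
    ltd_mg_kg_d: Decimal
    factors: FactorSet
    srfd_mg_kg_d: Decimal
    rsc: float
    wsv_ug_L: Decimal
    config: RunConfig
    trace: tuple[dict, ...] = field(default_factory=tuple)

    @property
    def total_uf(self) -> int:
        return self.factors.total.display_value

    def to_row(self) -> dict:
        """Flat CSV row (plain-decimal formatting, no scientific notation)."""
        return {
            "api_name": self.api_name,
            "casrn": self.casrn or "",
            "ltd_mg_kg_d": format(self.ltd_mg_kg_d, "f"),
            "total_uf": self.total_uf,
            "srfd_mg_kg_d": format(self.srfd_mg_kg_d, "f"),
            "rsc": self.rsc,
            "wsv_ug_L": format(self.wsv_ug_L, "f"),
        }

    def to_dict(self) -> dict:
        """JSON-serializable record including the full rule trace."""
        row = self.to_row()
        row["factors"] = [
            {
                "factor_id": a.factor_id.value,
                "value": a.value,
                "applied": a.applied,
                "rationale_codes": list(a.rationale_codes),
            }
            for a in self.factors.assignments
        ]
        row["trace"] = [dict(t) for t in self.trace]
        row["provenance"] = self.config.provenance()
        return row


def derive(
    profile: EvidenceProfile,
    config: RunConfig = DEFAULT_CONFIG,
    body_weights: BodyWeightTable | None = None,
) -> ScreeningResult:
    """End-to-end derivation: eligibility → LTD → factors → sRfD → RSC → WSV."""
    decision = screen_eligibility(profile)
    if not decision.eligible:
        raise ValueError(
            f"{profile.api_name}: profile is excluded ({decision.reason.value}); "
            "no screening value can be derived"
        )
    if not profile.regimens:
        raise ValueError(f"{profile.api_name}: an eligible profile needs dosing regimens")

    ltd: LTDResult = compute_ltd(profile.regimens, table=body_weights)
    factors = assign_all(profile)
    srfd = compute_srfd(ltd.ltd_mg_kg_d, factors.total, config)
    rsc = select_rsc(profile, config)
    wsv = compute_wsv(srfd, rsc, config)

    trace = [
        {"step": "eligibility", "decision": "eligible"},
        {
            "step": "ltd",
            "ltd_mg_kg_d": format(ltd.ltd_mg_kg_d, "f"),
            "regimen_index": ltd.regimen_index,
            "age_bracket": ltd.age_bracket,
        },
    ]
    for a in factors.assignments:
        trace.append(
            {
                "step": "factor",
                "factor_id": a.factor_id.value,
                "value": a.value,
                "applied": a.applied,
                "rationale_codes": list(a.rationale_codes),
            }
        )
    trace += [
        {"step": "total_uf", "display": factors.total.display_value},
        {"step": "srfd", "srfd_mg_kg_d": format(srfd, "f")},
        {
            "step": "rsc",
            "rsc": rsc,
            "rule": "otc_pediatric_use" if profile.otc_pediatric_use else "default",
        },
        {"step": "wsv", "wsv_ug_L": format(wsv, "f")},
    ]

    return ScreeningResult(
        api_name=profile.api_name,
        casrn=profile.casrn,
        ltd_mg_kg_d=ltd.ltd_mg_kg_d,
        factors=factors,
        srfd_mg_kg_d=srfd,
        rsc=rsc,
        wsv_ug_L=wsv,
        config=config,
        trace=tuple(trace),
    )
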