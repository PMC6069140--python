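# rxscreen

Rapid screening-level drinking-water guidance for active pharmaceutical
ingredients (APIs).

Hundreds of prescription drugs are detected in ambient and source waters,
but very few have health-based guidance values. `rxscreen` implements a
rapid-assessment framework that derives a **screening reference dose
(sRfD)** and a **water screening value (WSV)** for an API from structured
evidence curated off its FDA-approved drug label — no toxicity literature
review required. It is aimed at state/regional risk assessors and
environmental-monitoring programs who need to put detections in health
context and prioritize APIs for in-depth review.

## Method

The point of departure is the **lowest therapeutic dose (LTD)**, the
smallest labeled daily dose producing a clinical effect, treated as
analogous to a LOAEL:

```
LTD (mg/kg-d) = lowest labeled dose (mg/day) / body weight by age (kg)
```

Doses are normalised by mean body weight per one-year age bracket
(22.5 kg at ages 6–7 up to 80 kg for adults ≥18); a label covering an age
span is evaluated bracket by bracket and the minimum quotient is kept.
Doses already labeled in mg/kg-day pass through unchanged.

A decision tree assigns six uncertainty/adjustment factors, each 1, 3
or 10: a threshold-carcinogenicity adjustment AF_C, an endocrine-activity
adjustment AF_E (noted but not applied when AF_C fires — the two never
multiply together), an intraspecies UF_Human fixed at 10, a LOAEL→NOAEL
factor UF_L-N (default 3, raised to 10 by severity signals such as
pregnancy category D/X or a relevant boxed warning), a database factor
UF_DB, and a duration-of-use factor UF_S-C. Factors combine on a
**half-log scale** — 3 counts as 10^0.5, so 3 × 10 = 30 and
3 × 3 = 10 — giving totals on the lattice {30, 100, 300, …, 100,000}.

```
sRfD (mg/kg-d) = LTD / [(AF_C or AF_E) × UF_Human × UF_L-N × UF_DB × UF_S-C]
WSV  (µg/L)    = sRfD × RSC × 1000 (µg/mg) / 0.289 (L/kg-d)
```

The intake rate 0.289 L/kg-d is the 95th-percentile consumption of a
bottle-fed infant aged 1–3 months; the relative source contribution (RSC)
is 0.8 by default and 0.2 for APIs with widespread pediatric
over-the-counter use (the acetaminophen/ibuprofen pattern). The sRfD is
reported at 2 significant figures and the WSV at 1, with the WSV computed
from the *rounded* sRfD — the convention that reproduces the published
119-API screening table shipped with the package.

A water concentration below the WSV is unlikely to be a human-health
concern via ingestion; a concentration above it flags the API for a more
thorough assessment, not a definitive risk finding.

## Worked example

Sulfamethoxazole, curated from its label: LTD 4.57 mg/kg-d, a class-wide
thyroid effect in the warnings section (AF_E 10), a relevant boxed warning
(UF_L-N 10), no multigenerational reproductive study (UF_DB 3), and
short-term antibiotic use (UF_S-C 10):

```python
from rxscreen import DoseRegimen, EvidenceProfile, EndocrineEvidence, derive

profile = EvidenceProfile(
    api_name="Sulfamethoxazole",
    casrn="723-46-6",
    regimens=[DoseRegimen(amount_mg=4.57, units="mg_per_kg_day",
                          age_min_years=0, age_max_years=99)],
    endocrine=EndocrineEvidence(finding="warnings_or_pharmacodynamics_section"),
    black_box_warning_relevant=True,
    database_completeness="missing_key_study",
    duration_profile="short_term_use",
)
result = derive(profile)
print(result.to_row())
```

prints

```
{'api_name': 'Sulfamethoxazole', 'casrn': '723-46-6', 'ltd_mg_kg_d': '4.57',
 'total_uf': 30000, 'srfd_mg_kg_d': '0.00015', 'rsc': 0.8, 'wsv_ug_L': '0.4'}
```

i.e. the factors combine to 10 × 10 × 10 × 3 × 10 = 30,000 on the
half-log scale, the sRfD is 4.57/30,000 ≈ 0.00015 mg/kg-d, and the water
screening value is 0.4 µg/L. Every fired rule is retained in
`result.trace` with a stable rationale code (e.g. `UF_L_N.blackbox`).

The same pipeline is scriptable from the shell:

```
rxscreen derive profiles.csv --out values.csv   # derive sRfD/WSV per profile
rxscreen validate                               # recompute the packaged table
rxscreen context detections.csv                 # screen monitoring detections
rxscreen stats                                  # aggregate table statistics
rxscreen fixtures --seed 1 -n 50 -o p.json      # synthetic test profiles
```

`rxscreen stats` reports, over the packaged 119-API table, LTDs from
0.0013 to 25 mg/kg-d, sRfDs from 0.00000016 to 0.11 mg/kg-d, WSVs from
0.0004 to 300 µg/L, and total UF/AFs from 100 to 30,000.

## Packaged data

* `table3_wsv.csv` — the published 119-API screening table (name, CASRN,
  LTD, total UF/AF, sRfD, WSV, RSC), kept as printed and never mutated.
* `table2_bodyweights.csv` — mean body weight per age bracket.
* `table4_hbg.csv` — five APIs with both a WSV and a health-based guidance
  value from a full in-depth review, for conservatism comparison.
* `known_discrepancies.json` — the frozen list of published rows that do
  not reproduce under the derivation equations as printed (2 of 119),
  each with the recomputed value.

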