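# Methods

## Scope and model

`rxscreen` derives screening-level, not definitive, guidance: a screening
reference dose (sRfD, mg/kg-d) and a water screening value (WSV, µg/L)
per active pharmaceutical ingredient (API), from a curated
`EvidenceProfile` of drug-label facts. The framework deliberately trades
refinement for speed and coverage — conservative defaults everywhere —
so a WSV exceedance means "look closer", never "risk established".

The chain is:

1. **Eligibility screen.** Seven exclusion criteria, applied in a fixed
   precedence order (non-oral route, nutritional supplement, OTC-only,
   illicit, discontinued/unapproved, veterinary-only, genotoxic or
   non-threshold carcinogen). The first match is the reported reason;
   all matches are logged. Linear carcinogens are excluded because a
   point of departure divided by uncertainty factors is the wrong model
   for a no-threshold mode of action — they need slope factors the
   labels do not carry. A curator override keeps recently discontinued
   APIs assessable from archived labels, mirroring actual screening
   practice.
2. **Lowest therapeutic dose (LTD).** The lowest labeled clinically
   effective dose over a full 24-h day, divided by mean body weight for
   every one-year age bracket the label covers; the minimum quotient is
   the LTD, reported at 3 significant figures. Doses already in
   mg/kg-day pass through bit-identically. Special-population regimens
   (renal/hepatic, titrated) never set the LTD. The LTD is treated as
   analogous to a LOAEL: by design a therapeutic dose is biologically
   active, and effects below it are typically untested.
3. **Factor decision tree.** Six factors valued 1/3/10 (see the README
   for their meanings). `UF_Human` is unconditionally 10; `UF_L_N` is
   never below 3. AF_C takes precedence over AF_E: when both fire, the
   endocrine assignment is retained in the record with `applied=False`
   and contributes nothing to the total — the two factors read
   overlapping evidence and multiplying them would double-count
   conservatism. This is equivalent to `max(AF_C, AF_E)` for every
   reachable combination, asserted as a test property.
4. **Half-log combination.** Factor products use the risk-assessment
   convention that 3 ≈ 10^0.5: totals are stored as an integer count of
   half-logs, so combination is exact integer arithmetic with no
   floating drift, and a half-integral exponent displays with a leading
   3 (3×10^n, e.g. 30,000), not 3.16×10^n. A full factor set is bounded
   to [30, 100,000]; reaching the 100,000 ceiling emits a warning, since
   a profile that maximal signals too little data even for screening.
5. **sRfD and WSV.** sRfD = LTD / total, rounded to 2 significant
   figures. WSV = sRfD × RSC × 1000 / 0.289, rounded to 1 significant
   figure, computed **from the rounded sRfD** (see Rounding below).

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| intake | 0.289 L/kg-d | 95th-percentile water intake, bottle-fed infant aged 1–3 months — the most exposed life stage per kg |
| RSC | 0.8 / 0.2 | fraction of the sRfD allocable to drinking water; 0.2 only for APIs with numerous pediatric OTC uses, where non-water exposure dominates |
| adult body weight | 80 kg | current US adult mean; higher than the historical 70 kg, hence lower (more conservative) LTDs |
| sRfD / WSV precision | 2 / 1 sig. figs | the precision of the published screening table |

All of these live in `RunConfig`; overrides exist for sensitivity
analysis only and are echoed into output provenance, because a value
derived with a non-default intake is not a WSV in the defined sense.

## Numerical choices

* **Decimal arithmetic.** All rounding runs through `decimal` with
  half-away-from-zero ties. Published values are decimal literals;
  binary floats misplace exactly the tie cases that matter
  (12.5/1000 = 0.0125 must round to 0.013, not 0.012).
* **Two-stage rounding.** The WSV is computed from the already-rounded
  sRfD. The order is observable: an LTD/total of 0.0125 gives
  0.013 → 36.0 → 40 µg/L two-stage but 34.6 → 30 µg/L single-stage.
  Validation of the packaged table certifies the two-stage order.
* **Age brackets.** A regimen age range covers brackets
  a = max(6, ⌊age_min⌋) … min(17, ⌊age_max⌋); the adult 80 kg row is
  used only for regimens with age_min ≥ 18. Ages under 6 must be dosed
  in mg/kg-day (labels do this), and the converter refuses otherwise.
* **Ties.** Equal-LTD regimens keep the first in label order; all
  candidate quotients are retained in the result for audit.
* **Exceedance.** Detection screening uses strict inequality
  (concentration > WSV); a detection exactly at the WSV is not flagged.

## Packaged published data and validation

The published 119-API table is shipped as a versioned CSV and treated as
ground truth: validation recomputes the sRfD from the printed LTD and
total UF/AF, and the WSV from the printed sRfD and RSC (two independent
checks), comparing decimals exactly. 117 of 119 rows reproduce; the two
that do not — doxepin's sRfD (printed 0.00032 vs 0.94/3000 = 0.00031 at
2 significant figures) and norfloxacin's WSV (printed 10 vs
0.0033×800/0.289 = 9.13 → 9) — are frozen in
`known_discrepancies.json` with the recomputed values rather than
silently corrected. Three rows of the five-API guidance comparison
(acetaminophen, 17α-ethinylestradiol, venlafaxine) are internally
inconsistent as printed (the WSV cannot be recovered from the inputs
beside it); they are packaged with an `inconsistent_as_printed` flag.
The source narrative also quotes slightly different extreme values
(WSV up to 400 µg/L, sRfD up to 0.12 mg/kg-d) than its own table
maxima (300, 0.11); aggregate statistics report the tabulated values.

## Synthetic profiles

The fixture generator draws profiles uniformly over the closed evidence
vocabulary (with log-uniform dose amounts spanning the potency range of
real labels, 10⁻³–10^1.5 mg). That uniformity is the point: it reaches
rule combinations no marketed drug exhibits, which is what the bulk
invariants need (totals bounded to [30, 100,000] and on the half-log
lattice; AF_C/AF_E never jointly multiplied; monotonicity — strengthening
any single evidence field never lowers a factor or raises the WSV). It
does **not** emulate the joint distribution of real label evidence:
passing property tests demonstrate the rule engine is total,
deterministic and bounded, not that any real API's curation is correct.
Correctness against reality is carried instead by the published-table
validation and the exact reproduction of the benchmark derivations.
Bulk invariant checks run on 10,000 generated profiles; ladder-style
monotonicity checks on 40 base profiles per evidence field.

## Limitations

* Curation quality is out of scope: the package consumes structured
  evidence and cannot detect a mis-read label.
* Non-oral routes, genotoxic/non-threshold carcinogens, OTC-only
  products and nutritional supplements are excluded by design, however
  often they are detected in water.
* The RSC is a two-valued rule (0.8/0.2), not a full exposure-decision
  tree; the two values are the only ones the framework uses.
* WSVs protect human ingestion only — no ecological receptors, and no
  route-to-route extrapolation.
* Pregnancy letter categories (A–X) drive one UF_L-N criterion; labels
  migrated to the newer pregnancy/lactation narrative format need the
  curator to map narrative text onto the same flags.
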