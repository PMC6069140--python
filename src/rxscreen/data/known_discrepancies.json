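{
  "comment": "Published rows that do not reproduce under the derivation equations with the package's rounding convention (sRfD = 2 s.f. of LTD/totalUF; WSV = 1 s.f. of rounded-sRfD x RSC x 1000 / 0.289). The printed value is kept as ground truth; the recomputed value is recorded here. Frozen after a full validation pass over all 119 rows.",
  "table3": [
    {
      "api_name": "Doxepin",
      "quantity": "srfd",
      "printed": "0.00032",
      "recomputed": "0.00031",
      "note": "0.94/3000 = 0.0003133; rounds to 0.00031 at 2 significant figures under any tie rule."
    },
    {
      "api_name": "Norfloxacin",
      "quantity": "wsv",
      "printed": "10",
      "recomputed": "9",
      "note": "0.0033 x 0.8 x 1000 / 0.289 = 9.13; rounds to 9 at 1 significant figure."
    }
  ],
  "table4": [
    {
      "api_name": "Acetaminophen",
      "note": "Printed WSVs 9 and 50 ug/L do not follow from the printed LTDs (3.75, 22.5 mg/kg-d), total UF/AF 3000 and RSC 0.2, which give 0.9 and 5 ug/L."
    },
    {
      "api_name": "17a-Ethinylestradiol",
      "note": "Printed WSV 0.0001 ug/L does not follow from LTD 0.00044 mg/kg-d with the stated RSC 0.8 (gives 0.0004); the printed factor list (10,10,10,3,3) also combines to 10,000 on the half-log lattice, not the printed 3000."
    },
    {
      "api_name": "Venlafaxine",
      "note": "Printed LTD 25 mg/kg-d with total UF/AF 3000 gives a WSV of 20 ug/L, not the printed 0.3."
    }
  ],
  "text_vs_table": [
    "Narrative WSV range quotes an upper end of 400 ug/L; the tabulated maximum is 300 ug/L (gabapentin).",
    "Narrative sRfD range quotes an upper end of 0.12 mg/kg-d; the tabulated maximum is 0.11 mg/kg-d (gabapentin)."
  ]
}
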