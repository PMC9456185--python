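{
 "description": "Published MM/PBSA component means (kcal/mol) for the aurisin A / DM-beta-cyclodextrin complex, used as generator settings and identity-check inputs.",
 "means": {
  "e_vdw": -35.12,
  "e_ele": -17.05,
  "g_solv_polar": 29.69,
  "g_solv_nonpolar": -5.51
 },
 "t_delta_s": -24.12,
 "g_exp": -3.24
}
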