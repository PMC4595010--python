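{
  "comment": "Nearest-neighbor RNA energy parameters (kcal/mol, 37C). Stacks are keyed p1:p2 where p1=(s[i],s[j]) and p2=(s[i+1],s[j-1]) read 5'->3' on the top strand. Loop penalties are indexed by loop size; sizes beyond the table extrapolate with the Jacobson-Stockmayer term js_coef*ln(n/n_max).",
  "stacks": {
    "au:au": -0.9, "au:cg": -2.2, "au:gc": -2.1, "au:ua": -1.1, "au:gu": -0.6, "au:ug": -1.4,
    "cg:au": -2.1, "cg:cg": -3.3, "cg:gc": -2.4, "cg:ua": -2.1, "cg:gu": -1.4, "cg:ug": -2.1,
    "gc:au": -2.4, "gc:cg": -3.4, "gc:gc": -3.3, "gc:ua": -2.2, "gc:gu": -1.5, "gc:ug": -2.5,
    "ua:au": -1.3, "ua:cg": -2.4, "ua:gc": -2.1, "ua:ua": -0.9, "ua:gu": -1.0, "ua:ug": -1.3,
    "gu:au": -1.3, "gu:cg": -2.5, "gu:gc": -2.1, "gu:ua": -1.4, "gu:gu": -0.5, "gu:ug": 1.3,
    "ug:au": -1.0, "ug:cg": -1.5, "ug:gc": -1.4, "ug:ua": -0.6, "ug:gu": 0.3, "ug:ug": -0.5
  },
  "hairpin": {"3": 5.4, "4": 5.6, "5": 5.7, "6": 5.4, "7": 6.0, "8": 5.5, "9": 6.4},
  "bulge": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal": {"2": 1.5, "3": 1.6, "4": 1.7, "5": 2.0, "6": 2.0, "7": 2.2, "8": 2.3},
  "internal_asymmetry": 0.5,
  "internal_asymmetry_max": 3.0,
  "multiloop_init": 3.4,
  "multiloop_branch": 0.4,
  "multiloop_unpaired": 0.0,
  "terminal_au": 0.5,
  "duplex_init": 4.1,
  "js_coef": 1.07,
  "min_loop": 3,
  "max_interior_loop": 30
}
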