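{
  "version": "1.0",
  "comment": "Pinned simplified nearest-neighbor folding parameters at 37 C (kcal/mol). Stacking free energies for the six canonical pair types follow the classic Freier/Turner table; loop penalties are logarithmic in loop size; no dangles, no coaxial stacking. stack[p][q] is the energy of inner pair q stacked on closing pair p, pairs written 5'base+3'base of the closing position.",
  "pair_order": ["AU", "CG", "GC", "UA", "GU", "UG"],
  "stack": {
    "AU": {"AU": -0.9, "CG": -2.1, "GC": -1.7, "UA": -0.9, "GU": -0.5, "UG": -1.0},
    "CG": {"AU": -1.8, "CG": -2.9, "GC": -2.0, "UA": -1.7, "GU": -1.2, "UG": -1.9},
    "GC": {"AU": -2.3, "CG": -3.4, "GC": -2.9, "UA": -2.1, "GU": -1.4, "UG": -2.1},
    "UA": {"AU": -1.1, "CG": -2.3, "GC": -1.8, "UA": -0.9, "GU": -0.8, "UG": -1.1},
    "GU": {"AU": -1.1, "CG": -2.1, "GC": -1.9, "UA": -1.0, "GU": -0.4, "UG": -1.5},
    "UG": {"AU": -0.8, "CG": -1.4, "GC": -1.2, "UA": -0.5, "GU": -0.2, "UG": -0.4}
  },
  "hairpin_base": 4.5,
  "bulge_base": 3.8,
  "internal_base": 4.1,
  "loop_log_coeff": 1.0786,
  "min_hairpin_loop": 3,
  "max_interior_loop": 30,
  "multiloop_closing": 4.6,
  "multiloop_branch": 0.4,
  "multiloop_unpaired": 0.1
}
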