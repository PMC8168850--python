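# Reflex wiring table, version 1.
#
# One entry wires a pathway (C feedforward, L stretch, V velocity, F force,
# PD trunk balance) into a muscle over a set of gait phases; the same named
# parameter is shared by every phase listed (the phase-group notation used
# in parameter names, e.g. KFSOL_MS-PS).  `source` is the proprioceptive
# source muscle; negative `sign` wires an inhibitory projection.  Parameter
# defaults are the hand baseline; optimization replaces them.
#
# Categories for analysis/freezing are implied by pathway: L/V/F entries
# are "reflex" parameters, C entries "feedforward", the PD block "balance"
# and the state-machine thresholds "state".
version: 1
tau_activation: 0.01
stimulation_clamp: [0.01, 1.0]
delays_ms: {hip: 5, knee: 10, ankle: 20}
muscle_delay_group:
  GMAX: hip
  HAMS: hip
  ILPSO: hip
  RF: knee
  VAS: knee
  BFSH: knee
  GAS: ankle
  SOL: ankle
  TA: ankle

balance:
  # PD trunk-lean controller, applied to hip muscles during stance;
  # its positive output drives the extensors, negative the flexors.
  KP_BAL:  {default: 1.9,  bounds: [0.0, 10.0], std: 0.15}
  KV_BAL:  {default: 0.4,  bounds: [0.0, 10.0], std: 0.05}
  THETA0:  {default: 0.10, bounds: [-0.3, 0.3], std: 0.02}

state:
  LOAD_THR: {default: 0.15, bounds: [0.02, 0.6], std: 0.02}
  D_ES_MS:  {default: 0.03, bounds: [-0.2, 0.2], std: 0.02}
  D_S_LP:   {default: -0.15, bounds: [-0.35, 0.4], std: 0.03}

entries:
  # --- gluteus maximus ---------------------------------------------
  - {muscle: GMAX, pathway: C, phases: [ES, MS, PS],
     param: {name: KCGMAX_ST, default: 0.05, bounds: [0.0, 0.5], std: 0.02}}
  - {muscle: GMAX, pathway: PD, sign: 1, phases: [ES, MS, PS]}
  - {muscle: GMAX, pathway: F, source: GMAX, sign: 1, phases: [ES, MS],
     param: {name: KFGMAX_ES-MS, default: 0.4, bounds: [0.0, 10.0], std: 0.15}}
  - {muscle: GMAX, pathway: L, source: GMAX, sign: 1, phases: [LP],
     gain:   {name: KLGMAX_LP, default: 0.40, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0GMAX_LP, default: 0.95, bounds: [0.4, 1.4], std: 0.05}}
  # --- hamstrings ---------------------------------------------------
  - {muscle: HAMS, pathway: PD, sign: 1, phases: [ES, MS, PS]}
  - {muscle: HAMS, pathway: L, source: HAMS, sign: 1, phases: [ES, MS],
     gain:   {name: KLHAMS_ES-MS, default: 0.60, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0HAMS_ES-MS, default: 0.95, bounds: [0.4, 1.4], std: 0.05}}
  - {muscle: HAMS, pathway: L, source: HAMS, sign: 1, phases: [LP],
     gain:   {name: KLHAMS_LP, default: 0.70, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0HAMS_LP, default: 0.90, bounds: [0.4, 1.4], std: 0.05}}
  # --- iliopsoas ----------------------------------------------------
  - {muscle: ILPSO, pathway: PD, sign: -1, phases: [ES, MS, PS]}
  - {muscle: ILPSO, pathway: L, source: ILPSO, sign: 1, phases: [PS],
     gain:   {name: KLILPSO_PS, default: 1.50, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0ILPSO_PS, default: 0.85, bounds: [0.4, 1.4], std: 0.05}}
  - {muscle: ILPSO, pathway: L, source: ILPSO, sign: 1, phases: [S],
     gain:   {name: KLILPSO_S, default: 2.00, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0ILPSO_S, default: 0.75, bounds: [0.4, 1.4], std: 0.05}}
  - {muscle: ILPSO, pathway: C, phases: [S],
     param: {name: KCILPSO_S, default: 0.15, bounds: [0.0, 0.5], std: 0.02}}
  - {muscle: ILPSO, pathway: L, source: HAMS, sign: -1, phases: [S],
     gain:   {name: KLHAMSILPSO_S, default: 0.30, bounds: [0.0, 10.0], std: 0.1},
     offset: {name: L0HAMSILPSO_S, default: 1.00, bounds: [0.4, 1.4], std: 0.05}}
  # --- rectus femoris ----------------------------------------------
  - {muscle: RF, pathway: C, phases: [PS],
     param: {name: KCRF_PS, default: 0.15, bounds: [0.0, 0.5], std: 0.02}}
  - {muscle: RF, pathway: L, source: RF, sign: 1, phases: [S, LP],
     gain:   {name: KLRF_S-LP, default: 0.80, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0RF_S-LP, default: 1.05, bounds: [0.4, 1.4], std: 0.05}}
  # --- vasti --------------------------------------------------------
  - {muscle: VAS, pathway: C, phases: [ES, MS],
     param: {name: KCVAS_ST, default: 0.10, bounds: [0.0, 0.5], std: 0.02}}
  - {muscle: VAS, pathway: F, source: VAS, sign: 1, phases: [ES, MS],
     param: {name: KFVAS_ES-MS, default: 1.0, bounds: [0.0, 10.0], std: 0.15}}
  - {muscle: VAS, pathway: L, source: BFSH, sign: -1, phases: [ES, MS],
     gain:   {name: KLBFSHVAS_ES-MS, default: 2.0, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0BFSHVAS_ES-MS, default: 1.05, bounds: [0.4, 1.4], std: 0.05}}
  - {muscle: VAS, pathway: C, phases: [LP],
     param: {name: KCVAS_LP, default: 0.20, bounds: [0.0, 0.5], std: 0.02}}
  # --- biceps femoris short head -----------------------------------
  - {muscle: BFSH, pathway: L, source: BFSH, sign: 1, phases: [PS, S],
     gain:   {name: KLBFSH_PS-S, default: 0.50, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0BFSH_PS-S, default: 0.95, bounds: [0.4, 1.4], std: 0.05}}
  - {muscle: BFSH, pathway: C, phases: [PS],
     param: {name: KCBFSH_PS, default: 0.10, bounds: [0.0, 0.5], std: 0.02}}
  # --- gastrocnemius -----------------------------------------------
  - {muscle: GAS, pathway: F, source: GAS, sign: 1, phases: [MS, PS],
     param: {name: KFGAS_MS-PS, default: 1.1, bounds: [0.0, 10.0], std: 0.15}}
  - {muscle: GAS, pathway: F, source: GAS, sign: 1, phases: [ES],
     param: {name: KFGAS_ES, default: 0.6, bounds: [0.0, 10.0], std: 0.15}}
  # --- soleus -------------------------------------------------------
  - {muscle: SOL, pathway: F, source: SOL, sign: 1, phases: [MS, PS],
     param: {name: KFSOL_MS-PS, default: 1.2, bounds: [0.0, 10.0], std: 0.15}}
  - {muscle: SOL, pathway: F, source: SOL, sign: 1, phases: [ES],
     param: {name: KFSOL_ES, default: 0.8, bounds: [0.0, 10.0], std: 0.15}}
  # --- tibialis anterior -------------------------------------------
  # Stretch excitation in every phase (phase-specific parameters) with
  # inhibition from soleus force during stance.
  - {muscle: TA, pathway: L, source: TA, sign: 1, phases: [ES, MS, PS],
     gain:   {name: KLTA_ST, default: 0.80, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0TA_ST, default: 0.70, bounds: [0.4, 1.4], std: 0.05}}
  - {muscle: TA, pathway: L, source: TA, sign: 1, phases: [S],
     gain:   {name: KLTA_S, default: 1.20, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0TA_S, default: 0.70, bounds: [0.4, 1.4], std: 0.05}}
  - {muscle: TA, pathway: L, source: TA, sign: 1, phases: [LP],
     gain:   {name: KLTA_LP, default: 0.80, bounds: [0.0, 10.0], std: 0.15},
     offset: {name: L0TA_LP, default: 0.75, bounds: [0.4, 1.4], std: 0.05}}
  - {muscle: TA, pathway: F, source: SOL, sign: -1, phases: [ES, MS, PS],
     param: {name: KFSOLTA_ST, default: 0.4, bounds: [0.0, 10.0], std: 0.1}}
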