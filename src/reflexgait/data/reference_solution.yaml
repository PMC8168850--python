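# Bundled mid-range reference solution: reflex parameter values of the
# best speed-protocol (set 1) gait near 1.0 m/s found by the package's
# own CMA-ES runs.  Walks the full 15 s simulation with converged joint
# cycles; used to seed the step-length/step-duration protocol sets and
# the scaled-down validation runs.  Values are hex floats (bit-exact).
format: hexfloat
values:
  D_ES_MS: -0x1.3e367d0b87067p-5
  D_S_LP: -0x1.1aca97bafb17cp-4
  KCBFSH_PS: 0x1.44aee46679d73p-3
  KCGMAX_ST: 0x1.37f8c3fbe0adcp-6
  KCILPSO_S: 0x1.c2e394d061ab0p-3
  KCRF_PS: 0x1.cb3ba0ed1caeep-8
  KCVAS_LP: 0x1.1b320a3af62fep-7
  KCVAS_ST: 0x1.657d180338608p-7
  KFGAS_ES: 0x1.214c02d002c51p+1
  KFGAS_MS-PS: 0x1.93951333622ecp+1
  KFGMAX_ES-MS: 0x1.6f248255000c5p-1
  KFSOLTA_ST: 0x1.ee9c41e6038abp-2
  KFSOL_ES: 0x1.224b6a79eb295p-1
  KFSOL_MS-PS: 0x1.9116d68e9c53bp-2
  KFVAS_ES-MS: 0x1.80335def4f4bbp+0
  KLBFSHVAS_ES-MS: 0x1.d74c2aacc26b3p-1
  KLBFSH_PS-S: 0x1.0c847fc2f8dfcp+0
  KLGMAX_LP: 0x1.f533690cdb205p-2
  KLHAMSILPSO_S: 0x1.38ee14b0b7b70p-1
  KLHAMS_ES-MS: 0x1.438a686c825cfp-1
  KLHAMS_LP: 0x1.f01c76c5d0da6p+0
  KLILPSO_PS: 0x1.bf700fe88cfcdp-1
  KLILPSO_S: 0x1.317fa769edd03p-1
  KLRF_S-LP: 0x1.05d52e28a004cp+0
  KLTA_LP: 0x1.c9acde27848f3p-1
  KLTA_S: 0x1.0a10a0c0969acp+1
  KLTA_ST: 0x1.cc2361e5f2c5dp-5
  KP_BAL: 0x1.9c9e381e8e830p+1
  KV_BAL: 0x1.96ffc6945dcbfp-2
  L0BFSHVAS_ES-MS: 0x1.af582e35718f5p-2
  L0BFSH_PS-S: 0x1.4c6123d9ee51fp+0
  L0GMAX_LP: 0x1.5945e7847cd95p+0
  L0HAMSILPSO_S: 0x1.3acf4352685acp+0
  L0HAMS_ES-MS: 0x1.5964a4d3bc0aap+0
  L0HAMS_LP: 0x1.57dada4006d7fp+0
  L0ILPSO_PS: 0x1.981716f8c9bdfp-1
  L0ILPSO_S: 0x1.270f5bbd357eep+0
  L0RF_S-LP: 0x1.39cbd0981a347p-1
  L0TA_LP: 0x1.1c88335a6e1e6p+0
  L0TA_S: 0x1.b40613756cdf4p-1
  L0TA_ST: 0x1.8a82d45cd1492p-1
  LOAD_THR: 0x1.2cdf234c20f21p-3
  THETA0: 0x1.06ff5598591c9p-2
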