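# SYNTHETIC rosuvastatin-like victim model (surrogate).
#
# An openly parameterised stand-in for a proprietary rosuvastatin PBPK
# model, built from literature-typical values: slow absorption, low oral
# availability with OATP2B1-mediated intestinal uptake and BCRP apical
# efflux, moderate hepatic extraction with sinusoidal OATP uptake (split
# OATP1B1 0.55 / OATP1B3 0.25 / OATP2B1 0.10 / passive 0.10) that is only
# partially rate-limiting for elimination, renal clearance ~28% of systemic
# clearance, and a long terminal half-life (~20 h) from slow peripheral
# redistribution. Intended for qualitative DDI simulations, not for
# quantitative prediction of rosuvastatin exposure.
name: rosuvastatin_surrogate
mw: 481.54
fu_p: 0.115
rb: 0.69
ka: 0.3           # 1/h
fa: 0.5
fg: 1.0
model: full
vc_l: 21.0
vp_l: 113.0
cl_distribution: 4.0
cl_renal: 13.0    # L/h
hepatic_uptake_clint: 340.0
hepatic_uptake_fractions:
  OATP1B1: 0.55
  OATP1B3: 0.25
  OATP2B1: 0.10
  passive: 0.10
cl_met_int: 60.0
intestinal_efflux_clint: 10.0
intestinal_efflux_fractions:
  BCRP: 1.0
gut_uptake_oatp2b1_fraction: 0.4
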