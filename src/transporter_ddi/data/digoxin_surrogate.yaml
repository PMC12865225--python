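# SYNTHETIC digoxin-like victim model (surrogate).
#
# Stand-in for a proprietary digoxin model: good oral absorption moderated
# by intestinal P-gp efflux, very large distribution volume, predominantly
# renal elimination with a minor hepatic component. Qualitative use only.
name: digoxin_surrogate
mw: 780.94
fu_p: 0.71
rb: 1.0
ka: 1.0           # 1/h
fa: 0.85
fg: 1.0
model: full
vc_l: 50.0
vp_l: 430.0
cl_distribution: 60.0
cl_renal: 7.2     # L/h
hepatic_uptake_clint: 10.0
hepatic_uptake_fractions:
  passive: 1.0
cl_met_int: 3.0
intestinal_efflux_clint: 15.0
intestinal_efflux_fractions:
  P-gp: 1.0
gut_uptake_oatp2b1_fraction: 0.0
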