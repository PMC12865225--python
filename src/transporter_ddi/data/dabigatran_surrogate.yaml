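# SYNTHETIC dabigatran-like victim model (surrogate).
#
# Stand-in for a proprietary dabigatran etexilate model. The dose is given
# as the etexilate prodrug (mw 627.73); conversion to the active dabigatran
# is treated as instantaneous, so the systemic compartments track the active
# moiety. Oral availability is low (~6-7%) and limited by intestinal P-gp
# efflux, which is the interaction site of interest; elimination is mostly
# renal. Qualitative use only.
name: dabigatran_surrogate
mw: 627.73
fu_p: 0.65
rb: 1.0
ka: 1.0           # 1/h
fa: 0.12
fg: 1.0
model: full
vc_l: 20.0
vp_l: 50.0
cl_distribution: 40.0
cl_renal: 9.0     # L/h
hepatic_uptake_clint: 12.0
hepatic_uptake_fractions:
  passive: 1.0
cl_met_int: 4.0
intestinal_efflux_clint: 30.0
intestinal_efflux_fractions:
  P-gp: 1.0
gut_uptake_oatp2b1_fraction: 0.0
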