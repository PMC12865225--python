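# Flucloxacillin precipitant model.
#
# One-compartment oral disposition calibrated to published clinical anchors
# for a 1000 mg oral dose (total Cmax ~46 uM, terminal half-life ~1 h, oral
# availability ~0.6). Ki values (uM, unbound) from in vitro IC50s; the P-gp
# entry is a lower-bound IC50 (>= 833 uM) used at its bound, which makes the
# simulated P-gp inhibition an upper bound.
name: flucloxacillin
mw: 453.87
fu_p: 0.06
rb: 0.65
ka: 1.4          # 1/h
fa: 0.6
fg: 1.0
model: one_compartment
vc_l: 14.0
cl_plasma: 9.7   # L/h
ki_map:
  OATP1B1: 30.7
  OATP1B3: 20.7
  OATP2B1: 64.2
  OAT3: 26.6
  OAT4: 32.7
  BCRP: 379.0
  P-gp: 833.0
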