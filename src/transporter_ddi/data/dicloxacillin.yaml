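# Dicloxacillin precipitant model.
#
# Disposition is represented by a one-compartment oral model calibrated to
# published clinical anchors for a 1000 mg oral dose (total Cmax ~67 uM,
# terminal half-life ~0.8 h, oral availability ~0.7); the gut-lumen and
# systemic states of the model drive the dynamic inhibition of a
# co-simulated victim drug. Ki values (uM, unbound) are taken from in vitro
# inhibition experiments: the measured competitive Ki for OATP1B1, IC50
# values elsewhere (unbound incubation assumed).
name: dicloxacillin
mw: 470.33
fu_p: 0.02
rb: 0.65
ka: 1.6          # 1/h
fa: 0.7
fg: 1.0
model: one_compartment
vc_l: 10.0
cl_plasma: 8.7   # L/h
ki_map:
  OATP1B1: 3.65
  OATP1B3: 6.68
  OATP2B1: 35.5
  OAT3: 19.5
  OAT4: 7.23
  BCRP: 166.0
  P-gp: 258.0
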