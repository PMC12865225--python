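"""FDA static R-value risk assessment for two penicillin inhibitors.

Builds the exposure metrics (liver inlet, systemic unbound, gut lumen) for
1000 mg oral doses of dicloxacillin and flucloxacillin and screens their in
vitro IC50s against the FDA cut-offs. Flagged rows (R at or above the
threshold) indicate that a clinical DDI cannot be excluded.
"""

from transporter_ddi import PrecipitantProfile, build_report

profiles = {
    "dicloxacillin": PrecipitantProfile(
        name="dicloxacillin", fu_p=0.02, cmax_total=67.0, dose_mg=1000.0,
        mw=470.33, fa=1.0, fg=1.0, ka=0.1, qh=1.62, rb=0.65),
    "flucloxacillin": PrecipitantProfile(
        name="flucloxacillin", fu_p=0.06, cmax_total=46.0, dose_mg=1000.0,
        mw=453.87, fa=1.0, fg=1.0, ka=0.1, qh=1.62, rb=0.65),
}
ic50s = {
    "dicloxacillin": {"OATP1B1": 3.86, "OATP1B3": 6.68, "OATP2B1": 35.5,
                      "OAT3": 19.5, "OAT4": 7.23, "BCRP": 166.0, "P-gp": 258.0},
    # the P-gp IC50 is a lower bound, so its R-value is an upper bound
    "flucloxacillin": {"OATP1B1": 30.7, "OATP1B3": 20.7, "OATP2B1": 64.2,
                       "OAT3": 26.6, "OAT4": 32.7, "BCRP": 379.0,
                       "P-gp": (833.0, "lower_bound")},
}

for name, profile in profiles.items():
    report = build_report(profile, ic50s[name])
    print(f"\n=== {name} ===")
    print({k: round(v, 2) for k, v in report.exposures.items()}, "(uM)")
    cols = ["transporter", "mechanism", "ic50_uM", "r_value_2sf",
            "r_is_upper_bound", "threshold", "flagged"]
    print(report.table[cols].to_string(index=False))
    print("flagged:", ", ".join(report.flagged_transporters()))
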