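"""End-to-end pipeline: synthetic assays -> IC50 fits -> risk table -> PBPK DDI.

Runs the whole workflow from one seeded configuration and writes a
fitted-parameter table, the static risk report, a PBPK DDI summary, and a
manifest (seed + config hash) to ``pipeline_out/``. Re-running with the same
seed reproduces every output byte for byte.
"""

from transporter_ddi.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig.model_validate({
    "seed": 42,
    "out_dir": "pipeline_out",
    "precipitant": {"name": "dicloxacillin", "fu_p": 0.02, "cmax_total": 67.0,
                    "dose_mg": 1000.0, "mw": 470.33},
    "assays": [
        {"transporter": "OATP1B1", "true_ic50": 3.86},
        {"transporter": "OATP1B3", "true_ic50": 6.68},
        {"transporter": "BCRP", "kind": "vesicle", "true_ic50": 166.0,
         "concs": [4.1, 12.3, 37.0, 111.0, 333.0, 1000.0, 3000.0]},
    ],
    "pbpk": {"victim": "rosuvastatin_surrogate", "precipitant": "dicloxacillin",
             "victim_dose_mg": 20.0, "t_end_h": 48.0},
})

outputs = run_pipeline(config)
print("\nwritten outputs:")
for name, path in outputs.items():
    print(f"  {name}: {path}")
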