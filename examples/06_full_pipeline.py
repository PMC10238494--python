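"""Run the complete pipeline end to end and inspect the candidate funnel.

Chains proteome simulation, library construction, quantifiability
screening, two-stage marker discovery, analytical QC and hold-out
classification from a single seeded configuration, writing every stage's
outputs (FASTA, transition list, screening calls, marker table, QC
report, metrics) to ./scratch/pipeline_demo.
"""

from pathlib import Path

from mrmkit import load_config, run_pipeline

cfg = load_config(Path(__file__).parent / "demo_config.yaml")
summary = run_pipeline(cfg, "scratch/pipeline_demo")

print("candidate funnel:")
print(f"  proteins simulated      {summary['n_proteins']}")
print(f"  surrogates selected     {summary['n_selected']}")
print(f"  quantifiable (SNR>3)    {summary['n_quantifiable']}")
print(f"  passed discovery        {summary['n_discovery']}")
print(f"  passed validation       {summary['n_validated_markers']}")
print(f"  passed analytical QC    {summary['n_qc_validated']}")
print()
print("hold-out metrics (last row = average over random states):")
print(summary["metrics"].to_string(index=False,
                                   float_format=lambda v: f"{v:.4f}"))
print()
print("Outputs and the run log are under scratch/pipeline_demo/;")
print("re-running with the same seed reproduces them byte for byte.")
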