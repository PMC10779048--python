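"""Run the complete pipeline on a seeded synthetic experiment.

Executes simulate -> DEG -> enrichment -> clustering -> biomarker ->
BMC/tPOD -> potency ranking and prints the run report plus the potency
chains, writing all artifacts under ./pipeline_demo/.
"""

from pathlib import Path

from toxpod import PipelineConfig, run_pipeline

config = PipelineConfig(
    mode="synthetic", seed=11, outdir="pipeline_demo",
    n_genes=150, n_sets=5, hub_size=30, replicates=3,
    timepoints=(24,), bmc_timepoints=(24,),
    deg_n_perm=300, n_boot=40, dose_metric="compound",
)
report = run_pipeline(config)
print(report.to_json())
print(Path("pipeline_demo/potency.txt").read_text())
# Potency chains order compounds from most to least potent; '~' joins
# compounds whose BMC confidence intervals overlap (equivalent potency).
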