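"""Run every stage end to end and print the machine-readable run report.

Equivalent to the CLI call
    dioica run-all --counts ... --samples ... --fasta ... --vcf ... --out ...
but driven from Python.
"""

import json

from dioica.pipeline import PipelineConfig, run_all
from dioica.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1), outdir="example_output/dataset")

config = PipelineConfig(
    counts=ds.paths["counts"],
    samples=ds.paths["samples"],
    fasta=ds.paths["fasta"],
    vcf=ds.paths["vcf"],
    out_dir="example_output/run",
)
report = run_all(config)

print(f"DEGs: {report.deg_counts}  percentages: {report.deg_percentages()}")
print(f"putative sex-associated genes: {len(report.sex_associated_genes)}")
print(f"samples cluster by sex: {report.samples_cluster_by_sex}")
print("SNP spectrum:")
print(report.snp_summary.to_string(index=False))
print("\nfull report written to example_output/run/report.json; provenance:")
print(json.dumps(report.provenance, indent=2))
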