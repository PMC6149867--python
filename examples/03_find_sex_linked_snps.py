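"""Filter multi-sample genotype calls for SNPs that segregate by sex.

Applies the three-criterion filter (depth >= 5 in every individual; site
polymorphic; one allele fixed per sex) to the synthetic VCF and checks the
result against the planted truth.  Also prints the chance that a random
polymorphic site passes by luck with 3 males + 3 females.
"""

from dioica import sex_association as sa
from dioica.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1), outdir="example_output/dataset")

calls = sa.load_genotypes(ds.paths["vcf"], ds.design)
sites, genes = sa.run_filter(calls, ds.design, min_depth=5)

print(f"genotype calls loaded: {len(calls)} "
      f"({ds.config.n_snp_sites} sites x {len(ds.design.samples)} individuals)")
print(f"sex-segregating sites found: {len(sites)}")
print(f"putative sex-associated genes: {len(genes)}")
print(sites[["gene", "pos", "female_allele", "male_allele"]].to_string(index=False))

planted = set(zip(ds.manifest.seg_sites["gene"], ds.manifest.seg_sites["pos"]))
found = set(zip(sites["gene"], sites["pos"]))
print(f"exactly the planted set recovered: {found == planted}")

rate = sa.segregation_null_rate(3, 3)
print(f"null pass rate for a random polymorphic site (3M/3F): {rate:.4f} "
      f"(= 2/62; so decoys are rejected by structure, not chance)")
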