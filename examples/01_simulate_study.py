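"""Generate a synthetic two-time-point study dataset.

The 'speciesA' preset emulates a colonial, kin-structured rodent
population sampled before and after an abrupt ~40% decline, plus a second
population sampled only afterwards: 17 pre / 31 post focal individuals and
9 from the second deme, genotyped at 531 biallelic SNPs scattered over
~2,000 target regions.
"""

from eruptpop import emulate_study

matrix, metadata = emulate_study("speciesA", seed=7, out_dir="example_output")

print(f"samples: {matrix.n_samples}, SNPs: {matrix.n_sites}")
print(metadata.table.groupby(["population", "period"]).size())
print("files written: example_output/speciesA.vcf, example_output/speciesA.meta.tsv")
# Each row of the metadata carries the population, sampling period (pre or
# post event), sex, age class and burrow (social group) of one individual.
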