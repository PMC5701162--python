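"""One-call pipeline: filter -> stats -> structure -> resample -> demography.

Equivalent to `eruptpop run --config run.yaml`; everything lands in a
single deterministic report.json keyed by population x period.
"""

import json

from eruptpop import RunConfig, emulate_study, run_compare

emulate_study("speciesA", seed=7, out_dir="example_output")

config = RunConfig(
    vcf="example_output/speciesA.vcf",
    metadata="example_output/speciesA.meta.tsv",
    out_dir="example_output/run",
    seed=7,
    outlier_sims=5000,   # envelope size; 50,000 is the full-study default
    reps=100,
    admixture_k=(2,),
)
report = run_compare(config)

comp = report["pre_post"]["RinconGrande"]
print(json.dumps({
    "sites kept": report["n_sites_final"],
    "het pre": round(comp["het_pre"], 5),
    "het post": round(comp["het_post"], 5),
    "temporal FST": round(report["fst_pairwise"]["RinconGrande:post|RinconGrande:pre"], 5),
    "survivor-sim het": round(comp["survivor_drift"]["post_mean_het"], 5),
}, indent=2))
print("full report: example_output/run/report.json")
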