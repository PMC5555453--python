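"""The full comparative run: two synthetic regions through every stage.

Generates a repeat-dense, low-GC region and a repeat-sparse, high-GC
reference, writes a run config, and executes the pipeline: repeat
densities, gene metrics, codon bias, Tm/LLR metagenes, and the
Kruskal-Wallis + Dunn comparisons across regions.  All outputs are TSV
tables plus a manifest recording stages, skips and the config hash.
"""

import os
import tempfile

import pandas as pd
import yaml

from domainscape import run_compare, validate_config
from domainscape.simulate import SimulationConfig, make_reference_counts, simulate_region

base = tempfile.mkdtemp(prefix="domainscape_demo_")
simulate_region(SimulationConfig(seed=21, region_length=120_000, gene_count=8,
                                 gene_gc3=0.30,
                                 class_densities={"LTR": 0.40, "LINE": 0.20}),
                os.path.join(base, "dense"))
simulate_region(SimulationConfig(seed=22, region_length=120_000, gene_count=8,
                                 gene_gc3=0.65,
                                 class_densities={"LTR": 0.05, "LINE": 0.04}),
                os.path.join(base, "sparse"))
ref, _ = make_reference_counts()
pd.DataFrame({"codon": list(ref.counts), "count": list(ref.counts.values())}
             ).to_csv(os.path.join(base, "reference.tsv"), sep="\t", index=False)

config = {
    "out_dir": "report", "seed": 7, "reference_counts": "reference.tsv",
    "regions": [
        {"name": "dense", "bed": "dense/region.bed", "genome": "dense/region.fasta",
         "annotation": "dense/genes.gff3", "repeats": "dense/repeats.out",
         "treatment": "dense/signal_active.bedgraph",
         "control": "dense/signal_silencing.bedgraph"},
        {"name": "sparse", "bed": "sparse/region.bed", "genome": "sparse/region.fasta",
         "annotation": "sparse/genes.gff3", "repeats": "sparse/repeats.out"},
    ],
}
cfg_path = os.path.join(base, "run.yaml")
with open(cfg_path, "w") as fh:
    yaml.safe_dump(config, fh)

bundle = run_compare(validate_config(cfg_path))
print(f"report written to {bundle.out_dir}")
print("tables:", ", ".join(sorted(bundle.tables)))
dens = bundle.tables["repeat_density"]
print("\ntotal repeat density by region (dense first):")
print(dens[dens["class"] == "TOTAL"].to_string(index=False))
print("\nKruskal-Wallis results across regions:")
print(bundle.tables["kw_tests"].to_string(index=False))
# The dense region leads the density ranking.  CAI and GC3 separate the
# two gene groups (they were planted with different codon GC), while the
# intron metrics do not: both regions draw from the same intron mixture.
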