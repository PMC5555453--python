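"""Repeat-density accounting on a synthetic repeat-dense region.

Plants transposon fragments at known per-class densities, then recovers
those densities with class-aware merging (overlap bases of conflicting
classes become "Overlapping") and ranks the most common repeats by
cumulative fragment size — the dense/sparse contrast mirrors an
F-element versus euchromatic-reference comparison.
"""

from domainscape import AnalysisRegion, class_density, merge_by_class, top_repeat_table
from domainscape.simulate import SimulationConfig, simulate_region

cfg = SimulationConfig(seed=1, region_length=300_000, gene_count=10,
                       class_densities={"LTR": 0.40, "LINE": 0.20, "DNA": 0.05})
sim = simulate_region(cfg)
region = AnalysisRegion("dense", [("sim_region", 0, cfg.region_length)])

segments = merge_by_class(sim.visible_fragments)
report = class_density(segments, region)
print("planted vs recovered per-class density (fraction of region bp):")
for cls, target in sorted(cfg.class_densities.items()):
    print(f"  {cls:12s} planted {target:.3f}  recovered {report.per_class[cls]:.4f}")
print(f"  total transposon density: {report.total:.4f}")

print("\ntop repeats by cumulative fragment size:")
print(top_repeat_table(sim.visible_fragments, region, 5).to_string(index=False))
# Recovered densities match the planted truth because the annotation
# reflects exactly the fragment bases visible after nested insertion.
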