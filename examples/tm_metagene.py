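"""Melting-temperature metagenes of low-GC versus high-GC gene groups.

Computes 9-bp sliding-window nearest-neighbor Tm over two synthetic
regions whose genes differ in codon GC, rescales each coding span to
3 kb with 2-kb flanks, and aggregates the per-position median.  The
low-GC group should show the lower span Tm — the profile shape used to
argue that gene bodies of repeat-dense domains melt more easily.
"""

import numpy as np

from domainscape import TmParams, build_metagene, signal_profile, window_tm
from domainscape.io import SignalTrack
from domainscape.simulate import SimulationConfig, simulate_region

for label, gc3, seed in (("low-GC genes", 0.30, 11), ("high-GC genes", 0.65, 12)):
    sim = simulate_region(SimulationConfig(seed=seed, region_length=80_000,
                                           gene_count=8, gene_gc3=gc3,
                                           class_densities={"LINE": 0.1}))
    tm = window_tm(sim.sequence, TmParams())  # deg C per window start
    profiles = []
    for iso in sim.isoforms:
        track = SignalTrack(iso.seq_id, [0], [len(tm)], [0.0])
        up, span, down = signal_profile(track, iso, flank=2000,
                                        seq_length=len(tm), dense=tm)
        profiles.append((up, span, down))
    mg = build_metagene(profiles, span_length=3000, flank=2000).smooth()
    in_span = (mg.positions >= 0) & (mg.positions <= 3000)
    print(f"{label}: median span Tm {np.nanmedian(mg.median[in_span]):6.2f} C, "
          f"median flank Tm {np.nanmedian(mg.median[~in_span]):6.2f} C")
# The span median tracks codon GC: the low-GC group sits several degrees
# below the high-GC group, while the background flanks are similar.
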