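"""Simulate a small BAC project and assemble its physical map.

Generates a 3 Mb, 7-chromosome genome, draws 300 clones from two
libraries (144.6 kb and 110.9 kb mean inserts), fingerprints them with
realistic noise (~81 bands/clone), and runs the full assembly schedule:
initial build at 1e-50, DQer, stepped merges to 1e-35, manual merges at
1e-20.  Prints the map summary table.
"""

import dataclasses
import json

from bacmap import ScoreParams, assembly_stats, dqer, initial_build, manual_merge, stepped_merge
from bacmap import simdata as sd

SEED = 1
genome = sd.simulate_genome(3_000_000, n_linkage_groups=7, seed=SEED)
noise = sd.NoiseModel(seed=SEED)  # 5% sizing error, 2% dropout, 1 spurious band
clones = []
for k, spec in enumerate((sd.AF_BB, sd.AF_BC)):
    spec = dataclasses.replace(spec, n_clones=150)
    clones += sd.simulate_library(genome, spec, seed=SEED * 2 + k + 1)
profiles = sd.simulate_fingerprints(clones, genome, noise)

params = ScoreParams()  # tolerance 3, cutoff 1e-50
pid = {p.clone_id: p for p in profiles if p.status == "ok"}
build, table = initial_build(profiles, params)
build = dqer(build, table, pid)
build = stepped_merge(build, table)  # 1e-45, 1e-40, 1e-35
build = manual_merge(build, table)  # 1e-20, 41-band matched clones

stats = assembly_stats(build, genome_size_mb=3.0, n_fingerprinted=len(profiles))
print(json.dumps(stats, indent=2))
print(
    "-> clones grouped into contigs per chromosome; total_length_mb is the"
    " CB-map span estimate, length_vs_genome its multiple of the 3 Mb genome"
)
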