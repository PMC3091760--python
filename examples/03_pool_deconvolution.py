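"""Design a 5x5x5 overgo pool experiment and deconvolute the signals.

125 probes occupy unique cube coordinates; each probe sits in exactly 3
of 15 pools.  A clone is a hit for a probe only when all three of its
pools light up.  The example simulates a filter hybridization with
widely spaced probes (the published regime: probe spacing much larger
than an insert) and recovers every probe->clone assignment.
"""

import numpy as np

from bacmap import deconvolve, design_pools, evaluate_deconvolution
from bacmap import simdata as sd

SEED = 7
design = design_pools(125, (5, 5, 5))
print(f"{len(design.probes)} probes in {len(design.pool_ids())} pools;"
      f" probe P017 sits in pools {design.pools_of('P017')}")

genome = sd.simulate_genome(40_000_000, 1, n_markers=0, seed=SEED)
positions = {p: 150_000 + i * 310_000 for i, p in enumerate(design.probes)}
rng = np.random.default_rng(SEED)
clones = []
for k in range(400):
    start = int(rng.integers(0, genome.length - 150_000))
    clones.append(sd.SimClone(f"c{k:03d}", "L", start, start + 130_000))

hyb, _truth = sd.simulate_hybridization(design, clones, genome, sd.NOISELESS, positions)
decon = deconvolve(design, hyb)
truth = {
    c.clone_id: {p for p, x in positions.items() if c.start <= x < c.end} for c in clones
}
metrics = evaluate_deconvolution(decon, {c: ps for c, ps in truth.items() if ps})

unique = sum(1 for a in decon.assignments if a.status == "unique")
print(f"{unique} unique assignments, {metrics['ambiguous_total']} ambiguous clones")
print(f"precision {metrics['precision']:.3f}, recall {metrics['recall']:.3f}")
print("-> with noiseless signals and single-probe clones the 3D design"
      " recovers probe->clone assignments without error")
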