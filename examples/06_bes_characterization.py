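"""Quality-filter BAC-end reads and mine microsatellites.

Simulates a few end reads (567 b average, 37.6% GC, some with planted
SSRs), applies the QC rules (>= 100 contiguous bases at phred >= 20,
<= 5% N after trimming), reports GC content and all perfect SSRs
meeting the motif thresholds (di >= 5, tri >= 4, tetra/penta >= 3
copies).
"""

from bacmap import find_ssrs, gc_content, trim_and_filter
from bacmap import simdata as sd
from bacmap.bes import bes_summary

reads = sd.simulate_bes_records([f"AF_Bb_{i:03d}" for i in range(6)], seed=5, ssr_prob=0.8)
# one deliberately bad read: too short after quality trimming
reads.append(("AF_Bc_999f", "ACGT" * 20))

records = [trim_and_filter(bid, seq) for bid, seq in reads]
passing = [r for r in records if r.status == "pass"]
calls = [c for r in passing for c in find_ssrs(r.bes_id, r.sequence)]
_per, gc = gc_content(passing)

print(f"{len(records)} reads, {len(passing)} pass QC, aggregate GC {100 * gc:.1f}%")
for c in calls:
    print(f"  {c.bes_id}: ({c.motif})x{c.copies} at [{c.start}, {c.end})")
print(bes_summary(records, calls))
print("-> SSR positions are 0-based half-open; motifs are canonical"
      " (lexicographically smallest rotation)")
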