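"""Select a minimal tiling path from a contig layout.

A contig's clones carry consensus-band (CB) offsets; the MTP is the
smallest chain of clones covering the span with confirmed overlaps,
chosen greedily by furthest extension.  These are the clones one would
re-array for end sequencing.
"""

from bacmap import Contig, mtp_stats, select_mtp

# a staircase of 7 clones, each ~80 CB wide, starts every 30 CB
clones = [f"AF_Bb_{i:03d}" for i in range(7)]
offsets = [0, 30, 60, 90, 120, 150, 180]
widths = {c: 80 for c in clones}
contig = Contig("ctg0042", clones, offsets)

path = select_mtp(contig, widths, min_overlap_cb=3)
print(f"contig of {len(clones)} clones, span {max(offsets) + 80} CB units")
print("tiling path:", " -> ".join(path.clones))
print("adjacent overlaps (CB):", path.overlaps_cb, "| weak joins:", path.weak_joins)
print("stats:", mtp_stats([path]))
print(f"-> {len(path.clones)} of {len(clones)} clones suffice to cover the"
      " contig; each junction keeps >= 3 CB units of overlap as confirmation")
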