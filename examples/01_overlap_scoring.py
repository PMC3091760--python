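"""Score the overlap of two BAC fingerprints with the Sulston statistic.

Builds two band lists that share part of a genomic region, counts
matching bands at tolerance 3, and prints the probability of seeing
that many matches by chance.  Scores below the assembly cutoff (1e-50)
would place the two clones in one contig.
"""

from bacmap import ScoreParams, match_bands, sulston_log10_score

# two clones tiling the same region: 81-band profiles sharing 50 sites
shared = [137 * i % 29989 + 1 for i in range(1, 51)]
only_a = [211 * i % 29989 + 1 for i in range(1, 32)]
only_b = [389 * i % 29989 + 1 for i in range(1, 32)]
bands_a = sorted(shared + only_a)
bands_b = sorted(shared + only_b)

params = ScoreParams()  # tolerance 3, band space 30000, cutoff 1e-50
m = match_bands(bands_a, bands_b, params.tolerance_t)
log10_score = sulston_log10_score(len(bands_a), len(bands_b), m, params)

print(f"clone A: {len(bands_a)} bands, clone B: {len(bands_b)} bands")
print(f"matched bands (tolerance {params.tolerance_t}): {m}")
print(f"Sulston score: 1e{log10_score:.1f}")
print(
    "-> the chance of this many shared bands between unrelated clones;"
    f" {'below' if log10_score <= -50 else 'above'} the 1e-50 assembly cutoff"
)
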