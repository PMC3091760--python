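# Methods

## Overlap statistic

Bands are integers in `[1, G]`; two bands match when they differ by at
most the tolerance `t` (default 3, matching the published assembly
parameters). Matching between two band lists is a greedy two-pointer
scan over the sorted lists that pairs heads within tolerance and
otherwise advances the smaller head; for sorted lists this equals the
maximum bipartite matching (asserted against an augmenting-path oracle
in the tests, not assumed).

The Sulston score is the binomial tail `P(X ≥ m)` with
`X ~ Bin(nL, p)`, `nL = min(nA, nB)`, and per-band coincidence
probability `p = 1 − (1 − (2t+1)/G)^nH`, `nH = max(nA, nB)`. It is
computed in log space (gammaln + logsumexp); probabilities below 1e-300
are clamped and all comparisons use log10 scores.

**Choice of G.** The band-value space defaults to `G = 30000`,
representing the sizing resolution of capillary HICF profiles. This is
a deliberate calibration: with ~81 bands per clone and tolerance 3, the
per-band coincidence probability must be small enough that genuinely
overlapping clones can reach the 1e-50 … 1e-20 stringency window at
all. At `G = 30000` two identical 81-band clones score ~1e-140, a pair
sharing 43 bands sits right at 1e-50, and 41 shared bands — the
matched-clone threshold used by the manual-merge rules — corresponds to
~1e-48, so the published cutoffs and the 41-band rule are mutually
coherent. A much smaller band space (say, a few hundred values) makes
p ≈ 0.7 and the same cutoffs unreachable even for identical clones.

**Validity regime of the formula.** The binomial tail treats per-band
coincidences as independent. That is exact for "at least one match"
(up to `O(nA·nB·(2t+1)/G)` sampling corrections) but deliberately
approximate deeper in the tail: for `m ≥ 2` the one-to-one matching
constraint and value collisions give a relative error of order `1/nB`
(for distinct-valued lists the exact law is hypergeometric-like). The
Monte-Carlo agreement suite therefore probes the `m = 1` regime across
20 parameter configurations; deep-tail behaviour is pinned by the
closed-form two-band example and by monotonicity properties. For
assembly this distinction is immaterial — decisions happen at scores of
1e-20 and below, where the ranking of pairs, not the absolute tail
mass, drives the build.

## Assembly

The initial build takes single-linkage connected components of the
overlap graph at the 1e-50 cutoff; size-1 components are singletons.
All pair scores are computed once (vectorised two-pointer over all
pairs, identical to the scalar path) and retained down to 1e-20, the
loosest stringency any later stage queries.

**Layout (CB map).** Within a contig, clones receive integer offsets in
consensus-band units by greedy placement: seed with the lowest-score
pair, then repeatedly place the unplaced clone with the strongest
overlap to any placed clone. The new offset is the best neighbour's
offset shifted by the unmatched band count, on the left or right of the
neighbour; the side is chosen by a consistency score — how well the
implied interval explains the observed matched-band counts against
*every* placed clone — with ties broken rightward, then
lexicographically. A support-only side rule (without the consistency
score) mis-places clones whenever the seed lies mid-contig and the
errors compound; with it, noiseless single-region layouts reproduce the
true clone order (up to global reversal) and span estimates land within
a few percent of truth. Contig length is `CB span × kb_per_band`,
default `128/81.1 ≈ 1.578 kb` (mean insert over mean band count),
overridable in configuration.

**Q clones and DQer.** A clone is questionable when fewer than half of
its bands match, at tolerance, the multiset union of bands of clones
whose layout intervals overlap its own. This is a published-behaviour
stand-in: the original fingerprint-assembly software does not document
its Q logic at implementable detail, so the definition here is
validated by simulation, not against that software's output. Contigs
with more than 10% Q clones are re-assembled from their own clones at a
cutoff tightened ×1e-5 per round (up to 3 rounds) until they comply or
disperse. A consequence of the definition worth knowing: a bridge clone
strong enough to pass 1e-50 is, by construction, at least 50%
band-consistent with its neighbours, so false joins that trip the DQer
arise from forced (manual-merge-style) contigs rather than from the
automatic build — the test fixtures reflect that.

**Merges.** Stepped merges relax the cutoff ×1e5 per pass
(1e-45, 1e-40, 1e-35). End-End passes merge contig pairs whose
end-window clones (5 from each end) score at or below the cutoff;
Single-End passes attach singletons to end windows. Merges apply one at
a time in ascending score order with layouts recomputed after each, so
the result is deterministic. Manual merges at 1e-20 use matched-clone
counts: a clone is matched into the other contig when it shares ≥41
bands with one of its clones at or below the cutoff; a pair merges with
3 matched clones on one side and 2 on the other, or 2+2 when the
contigs share an anchored genetic marker. The 3-versus-2 asymmetry is
implemented exactly as published (max side ≥ 3, min side ≥ 2).

## Pooling and anchoring

Probes fill an r×c×l cube (default 5×5×5) in row-major order; each pool
collects the probes sharing one coordinate. Deconvolution intersects
the Cartesian product of a clone's positive row/column/layer pools with
the occupied coordinates; a clone with any silent dimension gets no
assignment (the all-three-pools hit rule), a singleton candidate set is
a unique call, larger sets are reported as ambiguous, never dropped.
Anchoring classifies markers by the contigs their positive clones
occupy, assigns each contig the linkage group of its mapped markers
(conflicting groups flag the contig: counted as anchored per group,
excluded from the unique mapped count and from anchored length), and
sums anchored length over uniquely mapped contigs. Singleton hits are
reported separately — a singleton is not a contig and does not anchor.

## Minimal tiling path

Greedy furthest-extension interval cover over CB coordinates: from the
current chain end, take the overlapping clone reaching furthest right
(ties: sufficient overlap first, then the wider clone, then the id).
Junction overlaps below `min_overlap_cb = 3` are taken only when
nothing better overlaps and are logged as weak joins; choosing by reach
rather than by overlap size keeps the greedy path a true minimum cover
(equal to brute force on every tested contig). Layout gaps are jumped
with a weak join so the path always spans the contig.

## BES characterization

Quality trimming keeps the longest run of bases at or above phred 20
(a deliberate simplification of multi-tool base-calling/vector
pipelines); trimmed reads shorter than 100 bp or with more than 5% N
are removed. GC content excludes ambiguity codes from numerator and
denominator. SSR mining reports every maximal perfect tandem of a 2-5
bp motif meeting the copy thresholds (di ≥ 5, tri ≥ 4, tetra ≥ 3,
penta ≥ 3); motifs that are powers of a shorter unit are reported at
the shortest unit only, motifs are canonicalised to the smallest
rotation, and coordinates are 0-based half-open on the given strand.
Shifted variants of the same physical run (an odd-length tail) are
distinct maximal runs and are all reported — the exhaustive oracle and
the scanner agree on this by construction. The organelle screen flags a
read sharing at least half of its 31-mers with any single reference;
it is a containment heuristic standing in for alignment search, and
its thresholds are configuration, not claims.

## Synthetic data

The simulator generates what the pipeline needs and nothing more:
fingerprint-generating sites as a Poisson process (default rate
81.1/128000 per bp, so clones at the published 128 kb mean insert carry
~81 bands), one fixed uniform band value per site, clones drawn
uniformly within a chromosome (a clone never spans linkage groups),
insert lengths truncated-normal at the published library means/ranges
(144.6 kb and 110.9 kb), empty-clone rates 4.8% and 0.5%, and pool
signals from probe containment. Noise defaults — 5% band sizing error,
2% dropout, one spurious band per clone, configurable pool flip rates —
are plausible settings, not published values (none are printed for the
source project), and are configuration. Ground truth (clone
coordinates, probe positions) travels separately and is read only by
tests and evaluation code.

What the simulator does *not* model: sequence-level realism (real
restriction sites, GC structure in fingerprints), chimeric or
rearranged clones, vector sequence, or hybridization intensity. BES
reads are composition-only (length, GC, planted SSRs). Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to every artefact of real libraries.

**Scale.** Demo and test runs use a 3 Mb, 7-linkage-group genome with
300-500 clones (~12-21× coverage) and 20 probes. These sizes keep full
runs in seconds while preserving the published per-clone statistics
(band counts, insert sizes, coverage depth). One visible consequence:
20 probes on 3 Mb is a far denser marker spacing relative to insert
size than 125 probes on 300 Mb, so multi-probe clones — and hence
ambiguous deconvolution calls — are common in the demo, whereas the
published regime yields almost exclusively unique calls. The
deconvolution-exactness tests use wide probe spacing to emulate that
regime explicitly.

## Determinism

Every operation is a pure function of its inputs and a seed; per-clone
noise streams are keyed by a CRC of the clone id so results are
independent of iteration order and process hash randomisation. Ties are
broken lexicographically throughout (pair selection, merge order,
contig renumbering). A pipeline rerun with the same seed is
byte-identical, and the suite asserts it.
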