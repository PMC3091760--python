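# bacmap

A toolkit for constructing BAC-based physical maps from
high-information-content fingerprints (HICF), in the style used for the
*Aquilegia formosa* genome project: clone-overlap detection with the
Sulston score, FPC-style contig assembly with a stepped stringency
schedule, three-dimensional overgo-pool deconvolution, genetic-marker
anchoring, minimal-tiling-path selection, and BAC-end-sequence (BES)
characterization. A ground-truthed synthetic genome/clone/fingerprint
simulator makes every stage testable without any external data.

It is written for people who work with clone-based physical maps:
band-list files in, contig tables, anchoring summaries, tiling paths
and SSR calls out — as an importable Python library first
(`import bacmap`), with a thin `bacmap` command-line wrapper.

## The model

A HICF fingerprint reduces a BAC clone to a sorted list of integer band
values. Two bands *match* when they differ by at most a tolerance *t*
(default 3). For clones with `nA ≥ nB` bands sharing `m` matches, the
overlap statistic is the classic Sulston coincidence probability — the
chance of at least `m` matches arising between unrelated clones:

```
p = 1 − (1 − (2t+1)/G)^nA          per-band coincidence probability
S = Σ_{k=m}^{nB} C(nB, k) p^k (1 − p)^(nB−k)
```

where `G` is the number of distinguishable band values (default
30 000). Low scores mean real overlap. Assembly follows the published
schedule: single-linkage build at cutoff 1e-50; DQer breakup of contigs
with >10% questionable (Q) clones; End-End and Single-End merges with
the cutoff relaxed ×1e5 per step down to 1e-35; marker-aware manual
merges at 1e-20 requiring 3+2 matched clones (2+2 with a shared genetic
marker), where a matched clone shares ≥41 bands. Contig layouts are
greedy consensus-band (CB) placements; physical length is CB units ×
128/81.1 kb (mean insert over mean band count).

Marker integration uses a 5×5×5 pooling design: 125 probes, 15 pools,
each probe in exactly 3 pools, and a clone counts as a hit for a probe
only when all three of its pools are positive.

## A worked example

```bash
python examples/01_overlap_scoring.py
```

```
clone A: 81 bands, clone B: 81 bands
matched bands (tolerance 3): 50
Sulston score: 1e-64.3
-> the chance of this many shared bands between unrelated clones; below the 1e-50 assembly cutoff
```

Two 81-band fingerprints sharing 50 bands have a coincidence
probability of 1e-64 — far below the 1e-50 cutoff, so the clones would
be placed in the same contig. The other examples walk through the full
demo assembly (`02`), pool deconvolution (`03`), linkage-group
anchoring (`04`), tiling-path selection (`05`) and BES/SSR mining
(`06`), each printing the numbers it computes and what they mean.

The full pipeline on a synthetic 3 Mb project:

```bash
bacmap run --seed 1 --outdir demo_out
```

writes band/marker/hybridization inputs, the contig table, anchoring
and map summaries, the MTP and BES outputs, plus a manifest with the
seed and parameter hash; a rerun with the same seed is byte-identical.

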