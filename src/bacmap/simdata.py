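"""Synthetic genome / BAC library / fingerprint / hybridization simulator.

Provides ground-truthed inputs for every downstream stage.  The model:
a genome of ``n_linkage_groups`` chromosomes carries fingerprint-generating
sites as a Poisson process; each site has a fixed integer band value, so
overlapping clones share exactly the band values of their shared sites
(before noise and value coincidences).  Defaults are calibrated to the
mapping project this toolkit emulates: two BAC libraries with 144.6 kb /
110.9 kb mean inserts, ~81 bands per clone, a 5x5x5 overgo pool design,
and 7 linkage groups.

Chemistry is deliberately abstract: a band is an integer in [1, G], not a
restriction fragment of a concrete enzyme set, because band lists are all
the assembly mathematics consumes.  Ground truth (clone coordinates,
probe positions) travels in separate structures/files that the pipeline
stages never read — only tests and evaluation do.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .fingerprint import FingerprintProfile
from .pooling import HybMatrix, PoolDesign

__all__ = [
    "SyntheticGenome",
    "LibrarySpec",
    "SimClone",
    "NoiseModel",
    "AF_BB",
    "AF_BC",
    "simulate_genome",
    "simulate_library",
    "simulate_fingerprint",
    "simulate_fingerprints",
    "simulate_hybridization",
    "simulate_bes_records",
]

#: bands per clone / mean insert (kb), the empirical HICF site density
DEFAULT_SITE_RATE = 81.1 / 128_000.0


@dataclass
class SyntheticGenome:
    length: int
    n_linkage_groups: int
    site_positions: np.ndarray  # sorted ints in [0, length)
    site_band_values: np.ndarray  # ints in [1, G], one per site
    markers: list[tuple[str, int, int, float]]  # (marker_id, lg, position bp, cM)
    band_range_G: int

    def __post_init__(self) -> None:
        if len(self.site_positions) != len(self.site_band_values):
            raise ValueError("one band value per site required")
        if len(self.site_positions) and (
            np.any(np.diff(self.site_positions) <= 0)
            or self.site_positions[0] < 0
            or self.site_positions[-1] >= self.length
        ):
            raise ValueError("site positions must be strictly increasing in [0, length)")

    @property
    def lg_boundaries(self) -> np.ndarray:
        """Linkage groups partition [0, length) into equal contiguous blocks."""
        return np.linspace(0, self.length, self.n_linkage_groups + 1).astype(np.int64)

    def linkage_group_of(self, pos: int) -> int:
        """1-based linkage group containing a position."""
        b = self.lg_boundaries
        return int(np.searchsorted(b, pos, side="right"))


@dataclass(frozen=True)
class LibrarySpec:
    name: str
    n_clones: int
    insert_mean_kb: float
    insert_min_kb: float
    insert_max_kb: float
    empty_rate: float = 0.0
    fingerprint_fail_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (self.insert_min_kb <= self.insert_mean_kb <= self.insert_max_kb):
            raise ValueError("insert sizes must satisfy min <= mean <= max")
        for r in (self.empty_rate, self.fingerprint_fail_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")


# Library specifications mirroring the two source HindIII/MboI libraries
# (mean insert 144.6/110.9 kb; 4.8%/0.5% empty-vector clones).  Clone
# counts here are desk-scale defaults; override n_clones for larger runs.
AF_BB = LibrarySpec("AF_Bb", 1000, 144.6, 60.0, 300.0, empty_rate=0.048)
AF_BC = LibrarySpec("AF_Bc", 1000, 110.9, 35.0, 290.0, empty_rate=0.005)


@dataclass(frozen=True)
class SimClone:
    clone_id: str
    library: str
    start: int
    end: int  # half-open
    is_empty: bool = False
    fingerprint_failed: bool = False

    def __post_init__(self) -> None:
        if not self.is_empty and self.end <= self.start:
            raise ValueError("end must exceed start for non-empty clones")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NoiseModel:
    """Fingerprint and hybridization noise.

    sizing_error_prob: per-band probability of a +/-1..tolerance value shift
    band_dropout_prob: per-band probability of disappearing
    spurious_band_rate: expected extra (uniform-value) bands per clone
    pool_false_pos / pool_false_neg: per-cell flip rates in the pool matrix
    """

    sizing_error_prob: float = 0.05
    band_dropout_prob: float = 0.02
    spurious_band_rate: float = 1.0
    pool_false_pos: float = 0.0
    pool_false_neg: float = 0.0
    seed: int = 0
    sizing_tolerance: int = 3

    def __post_init__(self) -> None:
        for r in (
            self.sizing_error_prob,
            self.band_dropout_prob,
            self.pool_false_pos,
            self.pool_false_neg,
        ):
            if not (0.0 <= r <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.spurious_band_rate < 0:
            raise ValueError("spurious_band_rate must be >= 0")


NOISELESS = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0, seed=0)


def simulate_genome(
    length: int,
    n_linkage_groups: int = 7,
    site_rate: float = DEFAULT_SITE_RATE,
    n_markers: int = 0,
    band_range_G: int = 30000,
    seed: int = 0,
) -> SyntheticGenome:
    """Draw fingerprint sites as a Poisson process and place markers.

    Each site's band value is drawn uniformly on [1, G] from the seeded
    stream, so the value is a deterministic function of (seed, site
    index).  Markers are placed uniformly; cM positions are proportional
    to bp within each linkage group (100 cM per group).
    """
    if length <= 0 or site_rate <= 0:
        raise ValueError("length and site_rate must be positive")
    if band_range_G < 2:
        raise ValueError("band_range_G must be >= 2")
    rng = np.random.default_rng(seed)
    n_sites = rng.poisson(length * site_rate)
    positions = np.sort(rng.choice(length, size=min(n_sites, length), replace=False))
    values = rng.integers(1, band_range_G + 1, size=len(positions))
    genome = SyntheticGenome(
        length=length,
        n_linkage_groups=n_linkage_groups,
        site_positions=positions.astype(np.int64),
        site_band_values=values.astype(np.int64),
        markers=[],
        band_range_G=band_range_G,
    )
    bounds = genome.lg_boundaries
    markers = []
    for k in range(n_markers):
        pos = int(rng.integers(0, length))
        lg = genome.linkage_group_of(pos)
        lg_start, lg_end = bounds[lg - 1], bounds[lg]
        cm = 100.0 * (pos - lg_start) / max(lg_end - lg_start, 1)
        markers.append((f"M{k:04d}", lg, pos, round(float(cm), 3)))
    genome.markers = markers
    return genome


def simulate_library(genome: SyntheticGenome, spec: LibrarySpec, seed: int = 0) -> list[SimClone]:
    """Draw clones from the genome under a library specification.

    Insert length ~ Normal(mean, (max-min)/6) truncated to [min, max].
    A clone never spans a linkage-group (chromosome) boundary: the group
    is chosen proportional to its length, the start uniform within it.
    Empty and fingerprint-failure flags are drawn independently at the
    spec rates.
    """
    ins_min = int(spec.insert_min_kb * 1000)
    ins_max = int(spec.insert_max_kb * 1000)
    bounds = genome.lg_boundaries
    lg_lengths = np.diff(bounds)
    if np.any(lg_lengths < ins_max):
        raise ValueError("every linkage group must be longer than insert_max")
    rng = np.random.default_rng(seed)
    sd = (spec.insert_max_kb - spec.insert_min_kb) * 1000 / 6.0
    clones = []
    for k in range(spec.n_clones):
        length = int(np.clip(rng.normal(spec.insert_mean_kb * 1000, sd), ins_min, ins_max))
        lg = rng.choice(len(lg_lengths), p=lg_lengths / lg_lengths.sum())
        start = int(rng.integers(bounds[lg], bounds[lg + 1] - length))
        clones.append(
            SimClone(
                clone_id=f"{spec.name}_{k:05d}",
                library=spec.name,
                start=start,
                end=start + length,
                is_empty=bool(rng.random() < spec.empty_rate),
                fingerprint_failed=bool(rng.random() < spec.fingerprint_fail_rate),
            )
        )
    return clones


def simulate_fingerprint(
    clone: SimClone, genome: SyntheticGenome, noise: NoiseModel = NOISELESS
) -> FingerprintProfile:
    """Band profile of one clone: site values inside [start, end) with
    dropout, sizing shifts and spurious bands applied.

    Empty or fingerprint-failed clones return a band-less profile with
    status ``no_fingerprint``.
    """
    if clone.is_empty or clone.fingerprint_failed:
        return FingerprintProfile(clone.clone_id, clone.library, [], status="no_fingerprint")
    rng = np.random.default_rng([noise.seed, zlib.crc32(clone.clone_id.encode()) & 0x7FFFFFFF])
    lo = np.searchsorted(genome.site_positions, clone.start, side="left")
    hi = np.searchsorted(genome.site_positions, clone.end, side="left")
    bands = genome.site_band_values[lo:hi].astype(np.int64)
    if noise.band_dropout_prob > 0 and len(bands):
        bands = bands[rng.random(len(bands)) >= noise.band_dropout_prob]
    if noise.sizing_error_prob > 0 and len(bands):
        shift_mask = rng.random(len(bands)) < noise.sizing_error_prob
        shifts = rng.integers(1, noise.sizing_tolerance + 1, size=len(bands))
        signs = rng.choice([-1, 1], size=len(bands))
        bands = bands + shift_mask * shifts * signs
        bands = np.clip(bands, 1, genome.band_range_G)
    n_spurious = rng.poisson(noise.spurious_band_rate) if noise.spurious_band_rate > 0 else 0
    if n_spurious:
        bands = np.concatenate([bands, rng.integers(1, genome.band_range_G + 1, size=n_spurious)])
    return FingerprintProfile(
        clone.clone_id, clone.library, sorted(int(b) for b in bands), status="ok"
    )


def simulate_fingerprints(clones, genome, noise: NoiseModel = NOISELESS):
    """Fingerprint every clone; duplicates retained, order preserved."""
    return [simulate_fingerprint(c, genome, noise) for c in clones]


def simulate_hybridization(
    design: PoolDesign,
    clones: list[SimClone],
    genome: SyntheticGenome,
    noise: NoiseModel = NOISELESS,
    probe_positions: dict[str, int] | None = None,
) -> tuple[HybMatrix, HybMatrix]:
    """Pool-level hybridization signals plus the noise-free truth matrix.

    A pool x clone cell is truly positive iff some probe of the pool lies
    inside the clone interval.  Positives flip to negative at
    ``pool_false_neg``; negatives flip to positive at ``pool_false_pos``.
    Probe positions default to the genome's marker positions keyed by
    marker id.
    """
    if probe_positions is None:
        probe_positions = {mid: pos for (mid, _lg, pos, _cm) in genome.markers}
    for probe in design.probes:
        if probe not in probe_positions:
            raise ValueError(f"probe {probe!r} has no genome position")
    rng = np.random.default_rng([noise.seed, 2911])
    pool_ids = design.pool_ids()
    truth_pos: set[tuple[str, str]] = set()
    for clone in clones:
        if clone.is_empty:
            continue
        for probe, pos in probe_positions.items():
            if clone.start <= pos < clone.end:
                for pool in design.pools_of(probe):
                    truth_pos.add((pool, clone.clone_id))
    observed: set[tuple[str, str]] = set()
    for pool in pool_ids:
        for clone in clones:
            key = (pool, clone.clone_id)
            positive = key in truth_pos
            if positive and noise.pool_false_neg > 0 and rng.random() < noise.pool_false_neg:
                positive = False
            elif not positive and noise.pool_false_pos > 0 and rng.random() < noise.pool_false_pos:
                positive = True
            if positive:
                observed.add(key)
    clone_ids = [c.clone_id for c in clones]
    return (
        HybMatrix(positives=observed, pool_universe=set(pool_ids), clone_universe=set(clone_ids)),
        HybMatrix(positives=truth_pos, pool_universe=set(pool_ids), clone_universe=set(clone_ids)),
    )


_BES_ALPHABET = np.array(list("ACGT"))


def simulate_bes_records(clone_ids, seed: int = 0, length_mean: int = 567, gc: float = 0.376,
                         ssr_prob: float = 0.15):
    """Synthetic BAC-end reads for a set of clones (plumbing for demos).

    Composition-only realism: read length ~ Normal(567, 80), base
    composition at the target GC fraction, and a planted perfect SSR in a
    fraction of reads so the SSR scanner has work to do.  Returns
    ``(bes_id, sequence)`` pairs with ids ``<clone>f`` / ``<clone>r``.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for cid in clone_ids:
        for direction in ("f", "r"):
            n = int(np.clip(rng.normal(length_mean, 80), 120, 900))
            seq = rng.choice(_BES_ALPHABET, size=n, p=p)
            if rng.random() < ssr_prob:
                unit = rng.integers(2, 6)
                motif = rng.choice(_BES_ALPHABET, size=unit)
                copies = int(rng.integers(5, 9))
                ins = motif.tolist() * copies
                at = int(rng.integers(0, max(n - len(ins), 1)))
                seq = np.concatenate([seq[:at], np.array(ins), seq[at + len(ins):]])[:n]
            out.append((f"{cid}{direction}", "".join(seq)))
    return out
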