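"""Three-dimensional overgo pooling and deconvolution.

Probes are arranged in an r x c x l cube (default 5x5x5 = 125 probes);
each pool collects the probes sharing one coordinate value, giving
r + c + l pools (15) with each probe present in exactly three pools, one
per dimension.  A clone is a *hit* for a probe only when all three of
that probe's pools give a positive signal — the rule that suppresses
false positives in pooled hybridization.  Clones containing several
probes can produce combinatorial ambiguity (the positive-pool product
set exceeds the true probes); candidates are always reported with an
explicit unique/ambiguous status, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "PoolDesign",
    "HybMatrix",
    "Assignment",
    "Deconvolution",
    "design_pools",
    "deconvolve",
    "evaluate_deconvolution",
]

log = logging.getLogger(__name__)

_DIM_PREFIX = ("R", "C", "L")


@dataclass
class PoolDesign:
    dims: tuple[int, int, int]
    coordinates: dict[str, tuple[int, int, int]]  # probe_id -> (r, c, l)

    def __post_init__(self) -> None:
        r, c, l = self.dims
        if len(self.coordinates) > r * c * l:
            raise ValueError("more probes than cube capacity")
        for probe, (pr, pc, pl) in self.coordinates.items():
            if not (0 <= pr < r and 0 <= pc < c and 0 <= pl < l):
                raise ValueError(f"probe {probe} coordinate outside cube")

    @property
    def probes(self) -> list[str]:
        return list(self.coordinates)

    def pool_ids(self) -> list[str]:
        out = []
        for axis, n in enumerate(self.dims):
            out += [f"{_DIM_PREFIX[axis]}{k}" for k in range(n)]
        return out

    def pools_of(self, probe: str) -> tuple[str, str, str]:
        coord = self.coordinates[probe]
        return tuple(f"{_DIM_PREFIX[axis]}{coord[axis]}" for axis in range(3))

    def members(self, pool_id: str) -> list[str]:
        axis = _DIM_PREFIX.index(pool_id[0])
        value = int(pool_id[1:])
        return [p for p, coord in self.coordinates.items() if coord[axis] == value]

    def occupied(self) -> dict[tuple[int, int, int], str]:
        return {coord: probe for probe, coord in self.coordinates.items()}


@dataclass
class HybMatrix:
    """Observed pool x clone positivity calls (the input boundary after
    filter imaging and scoring)."""

    positives: set[tuple[str, str]]  # (pool_id, clone_id)
    pool_universe: set[str]
    clone_universe: set[str]

    def __post_init__(self) -> None:
        bad = {p for (p, _c) in self.positives} - self.pool_universe
        if bad:
            raise ValueError(f"positives reference unknown pools: {sorted(bad)[:5]}")

    def positive_pools(self, clone_id: str) -> set[str]:
        return {p for (p, c) in self.positives if c == clone_id}


def design_pools(n_probes: int, dims: tuple[int, int, int] = (5, 5, 5),
                 probe_ids: list[str] | None = None) -> PoolDesign:
    """Fill probes into the cube in row-major order; deterministic.

    Probe ids default to ``P000, P001, ...``; supply real marker ids to
    pool actual probes.
    """
    r, c, l = dims
    if n_probes > r * c * l:
        raise ValueError(f"{n_probes} probes exceed cube capacity {r * c * l}")
    if probe_ids is None:
        probe_ids = [f"P{k:03d}" for k in range(n_probes)]
    elif len(probe_ids) != n_probes:
        raise ValueError("probe_ids length must equal n_probes")
    coords = {}
    for k, probe in enumerate(probe_ids):
        coords[probe] = (k // (c * l), (k // l) % c, k % l)
    return PoolDesign(dims=dims, coordinates=coords)


@dataclass(frozen=True)
class Assignment:
    probe_id: str
    clone_id: str
    status: str  # unique | ambiguous


@dataclass
class Deconvolution:
    assignments: list[Assignment]
    candidate_sets: dict[str, set[tuple[int, int, int]]] = field(default_factory=dict)

    def hits(self, include_ambiguous: bool = False) -> list[Assignment]:
        if include_ambiguous:
            return list(self.assignments)
        return [a for a in self.assignments if a.status == "unique"]

    def by_probe(self, include_ambiguous: bool = False) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a in self.hits(include_ambiguous):
            out.setdefault(a.probe_id, []).append(a.clone_id)
        return out


def deconvolve(design: PoolDesign, hyb: HybMatrix) -> Deconvolution:
    """Resolve pool signals into probe -> clone assignments.

    Per clone: take the positive row/column/layer pools; the candidate
    coordinates are their Cartesian product intersected with occupied
    probe positions.  One assignment is emitted per candidate probe,
    ``unique`` iff the candidate set is a singleton.  A clone with any
    all-negative dimension yields no assignment (the all-three-pools hit
    rule).  Pools in the results absent from the design are an error;
    design pools absent from the results are treated all-negative with a
    warning.
    """
    known = set(design.pool_ids())
    unknown = hyb.pool_universe - known
    if unknown:
        raise ValueError(f"unknown pool ids in results: {sorted(unknown)}")
    missing = known - hyb.pool_universe
    if missing:
        log.warning("pools missing from results, treated all-negative: %s", sorted(missing))

    by_clone: dict[str, list[set[int]]] = {}
    for pool, clone in hyb.positives:
        axis = _DIM_PREFIX.index(pool[0])
        by_clone.setdefault(clone, [set(), set(), set()])[axis].add(int(pool[1:]))

    occupied = design.occupied()
    assignments: list[Assignment] = []
    candidate_sets: dict[str, set[tuple[int, int, int]]] = {}
    for clone in sorted(by_clone):
        rr, cc, ll = by_clone[clone]
        if not (rr and cc and ll):
            continue
        candidates = {
            (r, c, l)
            for r in rr
            for c in cc
            for l in ll
            if (r, c, l) in occupied
        }
        if not candidates:
            continue
        candidate_sets[clone] = candidates
        status = "unique" if len(candidates) == 1 else "ambiguous"
        for coord in sorted(candidates):
            assignments.append(Assignment(occupied[coord], clone, status))
    return Deconvolution(assignments=assignments, candidate_sets=candidate_sets)


def evaluate_deconvolution(decon: Deconvolution, truth: dict[str, set[str]]) -> dict:
    """Confusion metrics against ground truth.

    ``truth`` maps clone_id -> set of probe ids truly contained in the
    clone.  Unique assignments are the calls; ambiguous candidates are
    scored separately (a clone is candidate-sound when all its true
    probes appear among its candidates).
    """
    unique_calls = {(a.probe_id, a.clone_id) for a in decon.assignments if a.status == "unique"}
    true_pairs = {(p, c) for c, probes in truth.items() for p in probes}
    tp = len(unique_calls & true_pairs)
    fp = len(unique_calls - true_pairs)
    fn = len(true_pairs - unique_calls)
    ambiguous_clones = {a.clone_id for a in decon.assignments if a.status == "ambiguous"}
    sound = sum(
        1
        for c in ambiguous_clones
        if truth.get(c, set())
        <= {a.probe_id for a in decon.assignments if a.clone_id == c}
    )
    n_called = len({a.clone_id for a in decon.assignments})
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
        "ambiguity_rate": len(ambiguous_clones) / n_called if n_called else 0.0,
        "ambiguous_sound": sound,
        "ambiguous_total": len(ambiguous_clones),
    }
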