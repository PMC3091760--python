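"""Contig assembly from fingerprint overlaps.

The build follows the FPC-style schedule used for the source physical
map: an initial single-linkage build at high stringency (cutoff 1e-50,
tolerance 3), DQer splitting of contigs with more than 10% questionable
clones, stepped End-End / Single-End merges with stringency relaxed by
1e5 per step down to 1e-35, and finally marker-aware manual merges at
1e-20 governed by matched-clone counts (a matched clone shares at least
41 bands with a clone of the partner contig; 3+2 matched clones merge a
pair, 2+2 suffice when the contigs share a genetic marker).

Clone layout inside a contig is a deterministic greedy placement in
consensus-band (CB) units; contig length is CB count times kb-per-band
(default 128/81.1 kb, mean insert over mean band count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .fingerprint import OverlapTable, ScoreParams, match_bands

__all__ = [
    "Contig",
    "ContigBuild",
    "MergeRuleParams",
    "initial_build",
    "order_clones",
    "flag_q_clones",
    "dqer",
    "stepped_merge",
    "manual_merge",
    "assembly_stats",
    "physical_map_summary",
]

KB_PER_BAND_DEFAULT = 128.0 / 81.1

SIZE_BINS = ((2, 2), (3, 9), (10, 24), (25, 49), (50, 99), (100, 199), (200, 399), (400, None))


@dataclass
class Contig:
    contig_id: str
    clones: list[str]  # ordered by layout
    offsets: list[int]  # CB units, non-decreasing, min 0
    q_flags: list[bool] = field(default_factory=list)
    consensus_band_count: int = 0
    length_kb: float = 0.0

    def __post_init__(self) -> None:
        if len(self.clones) < 2:
            raise ValueError("a contig needs at least 2 clones")
        if any(b < a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be non-decreasing along the clone order")

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def q_fraction(self) -> float:
        return sum(self.q_flags) / len(self.clones) if self.q_flags else 0.0


@dataclass
class ContigBuild:
    contigs: list[Contig]
    singletons: list[str]
    params_history: list[tuple[str, float, int]]  # (stage, cutoff, tolerance)
    kb_per_band: float = KB_PER_BAND_DEFAULT

    def clone_ids(self) -> set[str]:
        out = set(self.singletons)
        for ctg in self.contigs:
            out.update(ctg.clones)
        return out

    def contig_of(self) -> dict[str, str]:
        return {c: ctg.contig_id for ctg in self.contigs for c in ctg.clones}

    @property
    def current_cutoff(self) -> float:
        return self.params_history[-1][1]

    def total_length_mb(self) -> float:
        return sum(c.length_kb for c in self.contigs) / 1000.0


@dataclass(frozen=True)
class MergeRuleParams:
    manual_cutoff: float = 1e-20
    tolerance: int = 3
    min_shared_bands: int = 41
    min_matched_clones_first: int = 3
    min_matched_clones_second: int = 2
    min_matched_with_marker: int = 2
    end_window: int = 5

    def __post_init__(self) -> None:
        for v in (
            self.min_shared_bands,
            self.min_matched_clones_first,
            self.min_matched_clones_second,
            self.min_matched_with_marker,
            self.end_window,
        ):
            if v < 1:
                raise ValueError("counts must be >= 1")


# ---------------------------------------------------------------- layout


def order_clones(clone_ids, table: OverlapTable):
    """Greedy CB-unit layout of a connected clone set.

    Seeds with the lowest-score pair, then repeatedly places the unplaced
    clone with the strongest overlap to any placed clone.  The new
    clone's offset is its best neighbour's offset shifted by the
    unmatched band count, placed on the side (left/right of the
    neighbour) with the greater matched-band support among already-placed
    clones; ties go to the emptier side, then rightward.  All ties among
    candidates break lexicographically, so the layout is deterministic.

    Returns ``(ordered_clones, offsets, consensus_band_count)``.
    """
    ids = sorted(clone_ids)
    if len(ids) == 1:
        return ids, [0], table.n_bands[ids[0]]
    edges = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            hit = table.lookup(a, b)
            if hit is not None:
                edges[(a, b)] = hit
    if not edges:
        raise ValueError("clone set is not connected in the overlap graph")
    seed = min(edges, key=lambda k: (edges[k][1], k))
    a, b = seed
    m_ab = edges[seed][0]
    offsets = {a: 0, b: table.n_bands[a] - m_ab}
    placed = [a, b]
    unplaced = [c for c in ids if c not in offsets]
    neigh: dict[str, list[tuple[str, int, float]]] = {c: [] for c in ids}
    for (x, y), (m, lg) in edges.items():
        neigh[x].append((y, m, lg))
        neigh[y].append((x, m, lg))

    while unplaced:
        best = None  # (score, candidate, neighbor, m)
        for cand in unplaced:
            for other, m, lg in neigh[cand]:
                if other in offsets and (best is None or (lg, cand, other) < (best[0], best[1], best[2])):
                    best = (lg, cand, other, m)
        if best is None:
            raise ValueError("clone set is not connected in the overlap graph")
        _, cand, nb, m = best
        off_nb = offsets[nb]
        n_cand = table.n_bands[cand]
        x_right = off_nb + (table.n_bands[nb] - m)
        x_left = off_nb - (n_cand - m)
        m_with = {other: mm for other, mm, _lg in neigh[cand]}

        def inconsistency(x: int) -> int:
            # how badly the implied interval [x, x+n_cand) explains the
            # observed matched-band counts against every placed clone
            cost = 0
            for other in placed:
                expected = min(x + n_cand, offsets[other] + table.n_bands[other]) - max(
                    x, offsets[other]
                )
                cost += abs(max(expected, 0) - m_with.get(other, 0))
            return cost

        # ties toward rightward placement
        offsets[cand] = x_left if inconsistency(x_left) < inconsistency(x_right) else x_right
        placed.append(cand)
        unplaced.remove(cand)

    base = min(offsets.values())
    offsets = {c: off - base for c, off in offsets.items()}
    ordered = sorted(ids, key=lambda c: (offsets[c], c))
    cb = max(offsets[c] + table.n_bands[c] for c in ids)
    return ordered, [offsets[c] for c in ordered], cb


def _make_contig(cid, clone_ids, table, kb_per_band) -> Contig:
    ordered, offsets, cb = order_clones(clone_ids, table)
    return Contig(
        contig_id=cid,
        clones=ordered,
        offsets=offsets,
        consensus_band_count=cb,
        length_kb=cb * kb_per_band,
    )


def _renumber(contigs: list[Contig]) -> list[Contig]:
    contigs = sorted(contigs, key=lambda c: c.clones[0])
    width = max(4, len(str(len(contigs))))
    for k, c in enumerate(contigs, start=1):
        c.contig_id = f"ctg{k:0{width}d}"
    return contigs


# ------------------------------------------------------------ initial build


def initial_build(
    profiles,
    params: ScoreParams,
    table: OverlapTable | None = None,
    kb_per_band: float = KB_PER_BAND_DEFAULT,
    exclude: set[str] | None = None,
) -> tuple[ContigBuild, OverlapTable]:
    """Single-linkage components of the overlap graph at the cutoff.

    Components of size one become singletons.  Supply ``exclude`` to drop
    clones (e.g. a manual poor-fingerprint removal list) before building.
    Returns the build together with the overlap table (retained down to
    the loosest later stringency) for reuse by later stages.
    """
    ok = [p for p in profiles if p.status == "ok" and (not exclude or p.clone_id not in exclude)]
    if table is None:
        table = OverlapTable(ok, params, keep_cutoff=max(params.cutoff, 1e-20))
    graph = nx.Graph()
    graph.add_nodes_from(p.clone_id for p in ok)
    for edge in table.edges(params.cutoff):
        graph.add_edge(edge.clone_a, edge.clone_b)
    contigs, singles = [], []
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            singles.extend(comp)
        else:
            contigs.append(_make_contig("tmp", comp, table, kb_per_band))
    build = ContigBuild(
        contigs=_renumber(contigs),
        singletons=sorted(singles),
        params_history=[("initial_build", params.cutoff, params.tolerance_t)],
        kb_per_band=kb_per_band,
    )
    return build, table


# ---------------------------------------------------------------- Q clones


def flag_q_clones(contig: Contig, profiles_by_id, tolerance: int = 3) -> list[bool]:
    """Flag questionable clones: a clone is Q when fewer than half of its
    bands match (at tolerance) the multiset union of bands of the clones
    whose layout intervals overlap its own."""
    flags = []
    n = {c: len(profiles_by_id[c].bands) for c in contig.clones}
    for idx, clone in enumerate(contig.clones):
        lo = contig.offsets[idx]
        hi = lo + n[clone]
        union: list[int] = []
        for jdx, other in enumerate(contig.clones):
            if other == clone:
                continue
            olo = contig.offsets[jdx]
            ohi = olo + n[other]
            if olo < hi and lo < ohi:
                union.extend(profiles_by_id[other].bands)
        if n[clone] == 0:
            flags.append(False)
            continue
        matched = match_bands(profiles_by_id[clone].bands, sorted(union), tolerance)
        flags.append(matched < 0.5 * n[clone])
    contig.q_flags = flags
    return flags


def dqer(
    build: ContigBuild,
    table: OverlapTable,
    profiles_by_id,
    q_fraction_threshold: float = 0.10,
    max_rounds: int = 3,
    step_factor: float = 1e-5,
) -> ContigBuild:
    """Break up contigs whose Q-clone fraction exceeds the threshold.

    Each offending contig is re-assembled from its own clones at a
    cutoff tightened by ``step_factor`` per round (up to ``max_rounds``),
    until no offender remains or its clones have dispersed to smaller
    contigs / singletons.  Never merges anything.
    """
    tolerance = build.params_history[-1][2]
    base_cutoff = build.current_cutoff
    contigs = list(build.contigs)
    singles = list(build.singletons)
    for ctg in contigs:
        if not ctg.q_flags:
            flag_q_clones(ctg, profiles_by_id, tolerance)

    for round_no in range(1, max_rounds + 1):
        cutoff = base_cutoff * (step_factor**round_no)
        offenders = [c for c in contigs if c.q_fraction > q_fraction_threshold]
        if not offenders:
            break
        for ctg in offenders:
            contigs.remove(ctg)
            graph = nx.Graph()
            graph.add_nodes_from(ctg.clones)
            for i, a in enumerate(ctg.clones):
                for b in ctg.clones[i + 1 :]:
                    hit = table.lookup(a, b)
                    if hit is not None and hit[1] <= math.log10(cutoff):
                        graph.add_edge(a, b)
            for comp in nx.connected_components(graph):
                if len(comp) == 1:
                    singles.extend(comp)
                else:
                    piece = _make_contig("tmp", comp, table, build.kb_per_band)
                    flag_q_clones(piece, profiles_by_id, tolerance)
                    piece.contig_id = f"tmp{len(contigs)}"
                    contigs.append(piece)

    out = ContigBuild(
        contigs=_renumber(contigs),
        singletons=sorted(singles),
        params_history=build.params_history + [("dqer", base_cutoff, tolerance)],
        kb_per_band=build.kb_per_band,
    )
    return out


# ------------------------------------------------------------ stepped merge


def _end_clones(contig: Contig, window: int) -> set[str]:
    if contig.n_clones <= 2 * window:
        return set(contig.clones)
    return set(contig.clones[:window]) | set(contig.clones[-window:])


def stepped_merge(
    build: ContigBuild,
    table: OverlapTable,
    start_cutoff: float = 1e-50,
    end_cutoff: float = 1e-35,
    step_factor: float = 1e-5,
    end_window: int = 5,
) -> ContigBuild:
    """End-End and Single-End merges under stepped stringency relaxation.

    For each cutoff (start/step, ..., end): merge contig pairs whose
    end-window clones overlap at or below the cutoff, then attach
    singletons scoring at or below the cutoff against an end-window
    clone.  Merges apply greedily in ascending score order, one at a
    time, with layouts recomputed after each merge.  Never splits.
    """
    contigs = {c.contig_id: c for c in build.contigs}
    singles = set(build.singletons)
    tolerance = build.params_history[-1][2]

    cutoffs = []
    c = start_cutoff
    while c < end_cutoff * (1 - 1e-9):
        c = c / step_factor
        cutoffs.append(min(c, end_cutoff))
    next_id = [0]

    def fresh_id() -> str:
        next_id[0] += 1
        return f"mrg{next_id[0]:05d}"

    for cutoff in cutoffs:
        lg_cut = math.log10(cutoff)
        # --- End-End passes
        while True:
            clone_to_ctg = {c: cid for cid, ctg in contigs.items() for c in ctg.clones}
            ends = {cid: _end_clones(ctg, end_window) for cid, ctg in contigs.items()}
            best = None  # (lg, ctgA, ctgB)
            for (a, b), (m, lg) in sorted(table._pairs.items(), key=lambda kv: (kv[1][1], kv[0])):
                if lg > lg_cut:
                    continue
                ca, cb = clone_to_ctg.get(a), clone_to_ctg.get(b)
                if ca is None or cb is None or ca == cb:
                    continue
                if a in ends[ca] and b in ends[cb]:
                    best = (lg, *sorted((ca, cb)))
                    break
            if best is None:
                break
            _, ca, cb = best
            merged_clones = set(contigs[ca].clones) | set(contigs[cb].clones)
            del contigs[ca], contigs[cb]
            ctg = _make_contig(fresh_id(), merged_clones, table, build.kb_per_band)
            contigs[ctg.contig_id] = ctg
        # --- Single-End passes
        while True:
            ends_all = {}
            for cid, ctg in contigs.items():
                for cl in _end_clones(ctg, end_window):
                    ends_all[cl] = cid
            best = None
            for (a, b), (m, lg) in sorted(table._pairs.items(), key=lambda kv: (kv[1][1], kv[0])):
                if lg > lg_cut:
                    continue
                for single, endc in ((a, b), (b, a)):
                    if single in singles and endc in ends_all:
                        best = (lg, single, ends_all[endc])
                        break
                if best:
                    break
            if best is None:
                break
            _, single, cid = best
            singles.remove(single)
            merged = set(contigs[cid].clones) | {single}
            del contigs[cid]
            ctg = _make_contig(fresh_id(), merged, table, build.kb_per_band)
            contigs[ctg.contig_id] = ctg

    return ContigBuild(
        contigs=_renumber(list(contigs.values())),
        singletons=sorted(singles),
        params_history=build.params_history + [("stepped_merge", end_cutoff, tolerance)],
        kb_per_band=build.kb_per_band,
    )


# ------------------------------------------------------------- manual merge


def _matched_clone_sets(contigs: dict[str, Contig], table, rules: MergeRuleParams):
    """Per contig pair, the clones of each side 'matched' into the other:
    sharing at least ``min_shared_bands`` bands with some partner clone
    at or below the manual cutoff.  One pass over the overlap table."""
    lg_cut = math.log10(rules.manual_cutoff)
    clone_to_ctg = {c: cid for cid, ctg in contigs.items() for c in ctg.clones}
    out: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    for (a, b), (m, lg) in table._pairs.items():
        if m < rules.min_shared_bands or lg > lg_cut:
            continue
        ca, cb = clone_to_ctg.get(a), clone_to_ctg.get(b)
        if ca is None or cb is None or ca == cb:
            continue
        if ca > cb:
            ca, cb, a, b = cb, ca, b, a
        sets = out.setdefault((ca, cb), (set(), set()))
        sets[0].add(a)
        sets[1].add(b)
    return out


def manual_merge(
    build: ContigBuild,
    table: OverlapTable,
    rules: MergeRuleParams = MergeRuleParams(),
    marker_pairs: set[tuple[str, str]] | None = None,
) -> ContigBuild:
    """Marker-aware manual merges at low stringency.

    A contig pair merges when one side has at least 3 matched clones and
    the other at least 2, or when both sides have at least 2 matched
    clones and the contigs share a genetic marker.  Candidates are
    applied greedily by descending total matched clones (ties by contig
    id); the pass repeats until no pair qualifies.
    """
    marker_pairs = marker_pairs or set()
    contigs = {c.contig_id: c for c in build.contigs}
    tolerance = build.params_history[-1][2]
    merged_marker_pairs = {tuple(sorted(p)) for p in marker_pairs}
    next_id = [0]

    while True:
        candidates = []
        for (ca, cb), (set_a, set_b) in sorted(_matched_clone_sets(contigs, table, rules).items()):
            na, nb = len(set_a), len(set_b)
            hi, lo = max(na, nb), min(na, nb)
            by_count = hi >= rules.min_matched_clones_first and lo >= rules.min_matched_clones_second
            by_marker = (
                (ca, cb) in merged_marker_pairs
                and hi >= rules.min_matched_with_marker
                and lo >= rules.min_matched_with_marker
            )
            if by_count or by_marker:
                candidates.append((-(na + nb), ca, cb))
        if not candidates:
            break
        candidates.sort()
        _, ca, cb = candidates[0]
        merged_clones = set(contigs[ca].clones) | set(contigs[cb].clones)
        del contigs[ca], contigs[cb]
        next_id[0] += 1
        ctg = _make_contig(f"man{next_id[0]:05d}", merged_clones, table, build.kb_per_band)
        contigs[ctg.contig_id] = ctg
        # marker sharing transfers to the merged contig
        renamed = set()
        for x, y in merged_marker_pairs:
            x2 = ctg.contig_id if x in (ca, cb) else x
            y2 = ctg.contig_id if y in (ca, cb) else y
            if x2 != y2:
                renamed.add(tuple(sorted((x2, y2))))
        merged_marker_pairs = renamed

    return ContigBuild(
        contigs=_renumber(list(contigs.values())),
        singletons=sorted(build.singletons),
        params_history=build.params_history + [("manual_merge", rules.manual_cutoff, tolerance)],
        kb_per_band=build.kb_per_band,
    )


# -------------------------------------------------------------------- stats


def physical_map_summary(
    n_in_map: int,
    n_in_contigs: int,
    n_singletons: int,
    n_contigs: int,
    total_length_mb: float,
    genome_size_mb: float,
    n_fingerprinted: int | None = None,
    mean_insert_kb: float | None = None,
) -> dict:
    """Derived map statistics from raw counts (pure arithmetic).

    Computes the percentage of map clones placed in contigs, the genome
    coverage in X (clones x mean insert / genome) and the contig span as
    a multiple of the genome size.
    """
    out = {
        "clones_in_map": n_in_map,
        "clones_in_contigs": n_in_contigs,
        "pct_clones_in_contigs": round(100.0 * n_in_contigs / n_in_map, 1) if n_in_map else 0.0,
        "singletons": n_singletons,
        "n_contigs": n_contigs,
        "total_length_mb": round(total_length_mb, 1),
        "length_vs_genome": round(total_length_mb / genome_size_mb, 1) if genome_size_mb else 0.0,
    }
    if n_fingerprinted is not None:
        out["clones_fingerprinted"] = n_fingerprinted
    if mean_insert_kb is not None and genome_size_mb:
        out["genome_coverage_x"] = round(n_in_map * mean_insert_kb / 1000.0 / genome_size_mb, 1)
    return out


def assembly_stats(
    build: ContigBuild,
    genome_size_mb: float = 300.0,
    n_fingerprinted: int | None = None,
    mean_insert_kb: float | None = None,
) -> dict:
    """Summary table of a build: counts, contig-size histogram over the
    standard bins, total physical length and genome multiples."""
    n_in_contigs = sum(c.n_clones for c in build.contigs)
    n_in_map = n_in_contigs + len(build.singletons)
    hist = {}
    for lo, hi in SIZE_BINS:
        label = f"{lo}" if lo == hi else (f">{lo - 1}" if hi is None else f"{lo}-{hi}")
        hist[label] = sum(
            1 for c in build.contigs if c.n_clones >= lo and (hi is None or c.n_clones <= hi)
        )
    out = physical_map_summary(
        n_in_map,
        n_in_contigs,
        len(build.singletons),
        len(build.contigs),
        build.total_length_mb(),
        genome_size_mb,
        n_fingerprinted=n_fingerprinted,
        mean_insert_kb=mean_insert_kb,
    )
    out["contig_size_histogram"] = hist
    return out
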