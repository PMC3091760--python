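"""Minimal tiling path selection.

Given a contig's CB-unit layout, pick the fewest clones whose layout
intervals cover the contig span, walking left to right and always
extending as far as possible (greedy furthest-extension, the optimal
strategy for covering a segment with intervals).  Consecutive MTP
clones are required to overlap by at least ``min_overlap_cb`` band
units as confirmation; when no candidate meets that, the join is
relaxed (still choosing the furthest-reaching overlapping clone) and
logged as weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .assembly import Contig, ContigBuild

__all__ = ["TilingPath", "select_mtp", "select_all_mtps", "mtp_stats", "minimum_cover_size"]

log = logging.getLogger(__name__)


@dataclass
class TilingPath:
    contig_id: str
    clones: list[str]
    overlaps_cb: list[int]  # per adjacent pair, len(clones) - 1
    weak_joins: int = 0


def _intervals(contig: Contig, n_bands: dict[str, int]):
    return {
        c: (off, off + n_bands[c]) for c, off in zip(contig.clones, contig.offsets)
    }


def select_mtp(contig: Contig, n_bands: dict[str, int], min_overlap_cb: int = 3) -> TilingPath:
    """Greedy furthest-extension cover of the contig span.

    ``n_bands`` maps clone id -> band count (the clone's CB-unit width).
    Starts from a clone at the minimal offset (ties: widest, then
    lexicographic), then repeatedly picks, among clones overlapping the
    chain end by at least ``min_overlap_cb``, the one reaching furthest
    right (ties: wider clone, then lexicographic id).  If none overlaps
    sufficiently the requirement relaxes to any positive overlap (weak
    join, logged); a true layout gap falls back to the next clone by
    offset.
    """
    if not contig.clones or len(contig.clones) != len(contig.offsets):
        raise ValueError("contig must carry an ordered layout")
    missing = [c for c in contig.clones if c not in n_bands]
    if missing:
        raise ValueError(f"no band counts for clones: {missing[:5]}")
    iv = _intervals(contig, n_bands)
    span_end = max(e for _s, e in iv.values())
    start_clone = min(iv, key=lambda c: (iv[c][0], -(iv[c][1] - iv[c][0]), c))
    chain = [start_clone]
    overlaps: list[int] = []
    weak = 0
    cur_end = iv[start_clone][1]
    remaining = set(iv) - {start_clone}
    while cur_end < span_end:
        def reach_key(c):
            # furthest reach; ties: sufficient overlap first, then wider, then id
            strong = iv[c][0] <= cur_end - min_overlap_cb
            return (-iv[c][1], not strong, -(iv[c][1] - iv[c][0]), c)

        # touching (start == cur_end) keeps contiguous coverage, zero overlap
        overlapping = [c for c in remaining if iv[c][0] <= cur_end and iv[c][1] > cur_end]
        if overlapping:
            nxt = min(overlapping, key=reach_key)
            if iv[nxt][0] > cur_end - min_overlap_cb:
                weak += 1
                log.debug("weak join in %s at CB %d -> %s", contig.contig_id, cur_end, nxt)
        else:
            # layout gap: jump to the next interval by offset
            ahead = [c for c in remaining if iv[c][1] > cur_end]
            if not ahead:
                break
            nxt = min(ahead, key=lambda c: (iv[c][0], reach_key(c)))
            weak += 1
            log.debug("gap jump in %s at CB %d -> %s", contig.contig_id, cur_end, nxt)
        overlaps.append(max(0, cur_end - iv[nxt][0]))
        chain.append(nxt)
        cur_end = iv[nxt][1]
        remaining.discard(nxt)
    return TilingPath(contig.contig_id, chain, overlaps, weak_joins=weak)


def minimum_cover_size(contig: Contig, n_bands: dict[str, int]) -> int:
    """Brute-force minimum number of clones whose intervals contiguously
    cover the contig span (oracle; intended for contigs of <= ~10 clones)."""
    iv = _intervals(contig, n_bands)
    span_start = min(s for s, _e in iv.values())
    span_end = max(e for _s, e in iv.values())
    ids = sorted(iv)
    for k in range(1, len(ids) + 1):
        for subset in combinations(ids, k):
            ivs = sorted(iv[c] for c in subset)
            if ivs[0][0] != span_start:
                continue
            reach = ivs[0][1]
            for s, e in ivs[1:]:
                if s > reach:
                    reach = -1
                    break
                reach = max(reach, e)
            if reach >= span_end:
                return k
    return len(ids)


def select_all_mtps(build: ContigBuild, n_bands: dict[str, int], min_overlap_cb: int = 3):
    return [select_mtp(c, n_bands, min_overlap_cb) for c in build.contigs]


def mtp_stats(paths: list[TilingPath]) -> dict:
    """Totals over all tiling paths."""
    n_clones = sum(len(p.clones) for p in paths)
    all_ov = [o for p in paths for o in p.overlaps_cb]
    return {
        "n_contigs": len(paths),
        "mtp_clones": n_clones,
        "mean_overlap_cb": round(sum(all_ov) / len(all_ov), 2) if all_ov else 0.0,
        "weak_joins": sum(p.weak_joins for p in paths),
    }
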