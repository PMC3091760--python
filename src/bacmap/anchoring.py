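"""Marker integration: probe hits -> contigs -> linkage groups.

After pool deconvolution each marker (overgo probe) has a set of
positive clones; those clones' contig memberships classify the marker
(single contig / two / three-or-more / failed) and, for genetically
mapped markers, anchor contigs to linkage-group positions.  Anchored
length sums contig length estimates per linkage group; a contig hit by
markers from two different groups is a conflict — it is counted as
*anchored* for each group it touches but excluded from the unique
*mapped* contig count and from anchored length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .assembly import ContigBuild

__all__ = [
    "MarkerRecord",
    "MarkerAnchorRow",
    "MarkerAnchorTable",
    "anchor_markers",
    "anchor_linkage_groups",
    "merge_support",
]

log = logging.getLogger(__name__)

MARKER_CLASSES = ("drought", "mapped", "anthocyanin", "floral", "snp")


@dataclass(frozen=True)
class MarkerRecord:
    marker_id: str
    marker_class: str = "drought"
    linkage_group: int | None = None
    cM: float | None = None

    def __post_init__(self) -> None:
        if self.marker_class == "mapped" and (self.linkage_group is None or self.cM is None):
            raise ValueError(f"mapped marker {self.marker_id} needs linkage_group and cM")


@dataclass
class MarkerAnchorRow:
    marker_id: str
    contig_ids: list[str]
    singleton_hits: list[str] = field(default_factory=list)
    unplaced_hits: list[str] = field(default_factory=list)

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)


@dataclass
class MarkerAnchorTable:
    rows: list[MarkerAnchorRow]
    contig_lg: dict[str, tuple[int | None, list[str]]] = field(default_factory=dict)
    conflicts: dict[str, list[int]] = field(default_factory=dict)
    anchored_per_lg: dict[int, dict] = field(default_factory=dict)
    anchored_length_mb: float = 0.0
    genome_fraction: float = 0.0

    def classification(self, attempted: int | None = None) -> dict:
        """Marker counts by contigs hit; buckets sum to markers attempted."""
        single = sum(1 for r in self.rows if r.n_contigs == 1)
        two = sum(1 for r in self.rows if r.n_contigs == 2)
        multi = sum(1 for r in self.rows if r.n_contigs >= 3)
        placed = single + two + multi
        n_attempted = attempted if attempted is not None else len(self.rows)
        return {
            "attempted": n_attempted,
            "failed": n_attempted - placed,
            "single_contig": single,
            "two_contigs": two,
            "multi_contig": multi,
        }


def anchor_markers(hits_by_marker: dict[str, list[str]], build: ContigBuild) -> MarkerAnchorTable:
    """Map each marker's positive clones onto contigs.

    ``hits_by_marker`` maps marker/probe id -> positive clone ids (the
    unique deconvolution calls).  Clones that are singletons or absent
    from the build are recorded separately — they do not anchor.
    """
    contig_of = build.contig_of()
    singles = set(build.singletons)
    rows = []
    for marker in sorted(hits_by_marker):
        contigs: list[str] = []
        single_hits, unplaced = [], []
        for clone in sorted(hits_by_marker[marker]):
            if clone in contig_of:
                if contig_of[clone] not in contigs:
                    contigs.append(contig_of[clone])
            elif clone in singles:
                single_hits.append(clone)
            else:
                unplaced.append(clone)
        if unplaced:
            log.info("marker %s: %d hits not in build", marker, len(unplaced))
        rows.append(MarkerAnchorRow(marker, sorted(contigs), single_hits, unplaced))
    return MarkerAnchorTable(rows=rows)


def anchor_linkage_groups(
    table: MarkerAnchorTable,
    markers: list[MarkerRecord],
    build: ContigBuild,
    genome_size_mb: float = 300.0,
) -> MarkerAnchorTable:
    """Assign contigs to linkage groups via their mapped markers.

    A contig takes the linkage group of the mapped markers hitting it;
    markers from two or more groups flag a conflict (the contig counts
    as anchored per group but is excluded from the unique mapped count
    and from anchored length).  Anchored length per group sums the
    length estimates of uniquely mapped contigs.
    """
    by_id = {m.marker_id: m for m in markers}
    length_kb = {c.contig_id: c.length_kb for c in build.contigs}
    support: dict[str, dict[int, list[str]]] = {}
    for row in table.rows:
        rec = by_id.get(row.marker_id)
        if rec is None or rec.marker_class != "mapped" or rec.linkage_group is None:
            continue
        for cid in row.contig_ids:
            support.setdefault(cid, {}).setdefault(rec.linkage_group, []).append(row.marker_id)

    contig_lg: dict[str, tuple[int | None, list[str]]] = {}
    conflicts: dict[str, list[int]] = {}
    per_lg: dict[int, dict] = {}
    for cid in sorted(support):
        lgs = sorted(support[cid])
        marker_ids = sorted(mid for ms in support[cid].values() for mid in ms)
        if len(lgs) == 1:
            contig_lg[cid] = (lgs[0], marker_ids)
        else:
            contig_lg[cid] = (None, marker_ids)
            conflicts[cid] = lgs
        for lg in lgs:
            entry = per_lg.setdefault(
                lg, {"markers": set(), "anchored_contigs": set(), "mapped_contigs": set(), "length_mb": 0.0}
            )
            entry["markers"].update(support[cid][lg])
            entry["anchored_contigs"].add(cid)
            if len(lgs) == 1:
                entry["mapped_contigs"].add(cid)
                entry["length_mb"] += length_kb.get(cid, 0.0) / 1000.0

    total_mb = sum(e["length_mb"] for e in per_lg.values())
    table.contig_lg = contig_lg
    table.conflicts = conflicts
    table.anchored_per_lg = {
        lg: {
            "genetic_markers": len(e["markers"]),
            "anchored_contigs": len(e["anchored_contigs"]),
            "mapped_contigs": len(e["mapped_contigs"]),
            "length_mb": round(e["length_mb"], 1),
        }
        for lg, e in sorted(per_lg.items())
    }
    table.anchored_length_mb = round(total_mb, 1)
    table.genome_fraction = total_mb / genome_size_mb if genome_size_mb else 0.0
    return table


def merge_support(table: MarkerAnchorTable) -> set[tuple[str, str]]:
    """Contig pairs sharing at least one marker (evidence for the
    2+2-matched-clone manual merge rule)."""
    pairs: set[tuple[str, str]] = set()
    for row in table.rows:
        for i, a in enumerate(row.contig_ids):
            for b in row.contig_ids[i + 1 :]:
                pairs.add(tuple(sorted((a, b))))
    return pairs
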