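"""BAC-end-sequence characterization.

Quality trimming keeps the longest run of bases at or above phred 20 and
discards reads shorter than 100 bp after trimming or with more than 5% N
bases.  Surviving reads are profiled for GC content and mined for
perfect microsatellites (SSRs): maximal exact tandem repeats of 2-5 bp
motifs with at least 5 (di), 4 (tri), 3 (tetra) or 3 (penta) copies in a
row.  A k-mer sharing screen flags reads of likely organelle origin
against user-supplied chloroplast/mitochondrial references.

Coordinates are 0-based half-open throughout; SSR motifs are reported as
the lexicographically smallest rotation, with positions on the given
strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = [
    "BESRecord",
    "SSRCall",
    "SSR_MIN_COPIES",
    "trim_and_filter",
    "gc_content",
    "find_ssrs",
    "find_ssrs_brute_force",
    "organelle_screen",
    "bes_summary",
]

log = logging.getLogger(__name__)

#: minimum copy number per motif unit length (di, tri, tetra, penta)
SSR_MIN_COPIES = {2: 5, 3: 4, 4: 3, 5: 3}


@dataclass
class BESRecord:
    bes_id: str
    sequence: str
    qualities: list[int] | None = None
    status: str = "pass"  # pass | too_short | too_many_n | organelle

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.bes_id}: qualities/sequence length mismatch")


@dataclass(frozen=True)
class SSRCall:
    bes_id: str
    motif: str  # canonical (smallest rotation), length 2-5
    unit_length: int
    copies: int
    start: int  # 0-based half-open on the given strand
    end: int


def trim_and_filter(
    bes_id: str,
    sequence: str,
    qualities: list[int] | None = None,
    phred_min: int = 20,
    window_len: int = 100,
    max_n_frac: float = 0.05,
) -> BESRecord:
    """Quality-trim one read and apply the length / N-content filters.

    With qualities: keep the longest contiguous run of bases with
    quality >= ``phred_min``.  The trimmed read fails ``too_short``
    below ``window_len`` bases, then ``too_many_n`` above ``max_n_frac``
    N content.  Without qualities only the length and N rules apply.
    Idempotent: re-filtering a pass record changes nothing.
    """
    sequence = sequence.upper()
    if qualities is not None:
        if len(qualities) != len(sequence):
            raise ValueError(f"{bes_id}: qualities/sequence length mismatch")
        best = (0, 0)
        run_start = None
        for i, q in enumerate(list(qualities) + [-1]):
            if q >= phred_min:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                if i - run_start > best[1] - best[0]:
                    best = (run_start, i)
                run_start = None
        sequence = sequence[best[0] : best[1]]
    if len(sequence) < window_len:
        return BESRecord(bes_id, sequence, None, status="too_short")
    n_frac = sequence.count("N") / len(sequence)
    if n_frac > max_n_frac:
        return BESRecord(bes_id, sequence, None, status="too_many_n")
    return BESRecord(bes_id, sequence, None, status="pass")


def gc_content(records: list[BESRecord]) -> tuple[dict[str, float], float]:
    """Per-record and aggregate GC fraction over pass records.

    GC = (G+C)/(A+C+G+T); ambiguity codes are excluded from both
    numerator and denominator.  The aggregate pools all counted bases
    (the base-weighted mean).
    """
    per = {}
    tot_gc = tot_acgt = 0
    for rec in records:
        if rec.status != "pass":
            continue
        s = rec.sequence
        gc = s.count("G") + s.count("C")
        acgt = gc + s.count("A") + s.count("T")
        if acgt == 0:
            log.warning("%s: no unambiguous bases, GC undefined — skipped", rec.bes_id)
            continue
        per[rec.bes_id] = gc / acgt
        tot_gc += gc
        tot_acgt += acgt
    return per, (tot_gc / tot_acgt if tot_acgt else float("nan"))


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_power(motif: str) -> bool:
    """True when the motif is itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return True
    return False


def find_ssrs(bes_id: str, sequence: str) -> list[SSRCall]:
    """All maximal perfect tandem repeats of unit length 2-5 meeting the
    per-unit copy thresholds.

    A run whose motif is a power of a shorter unit (e.g. ATAT as a
    4-mer) is reported only at the shortest unit; overlapping calls of
    different unit lengths are all reported.  Deterministic left-to-right
    scan.
    """
    seq = sequence.upper()
    n = len(seq)
    calls = []
    for unit in (2, 3, 4, 5):
        min_copies = SSR_MIN_COPIES[unit]
        i = 0
        while i + unit * min_copies <= n:
            motif = seq[i : i + unit]
            if "N" in motif or _is_power(motif):
                i += 1
                continue
            if i >= unit and seq[i - unit : i] == motif:
                i += 1  # left-extendable: not the start of a maximal run
                continue
            j = i + unit
            while j + unit <= n and seq[j : j + unit] == motif:
                j += unit
            copies = (j - i) // unit
            if copies >= min_copies:
                calls.append(
                    SSRCall(bes_id, _canonical_rotation(motif), unit, copies, i, i + copies * unit)
                )
            i += 1
    return sorted(calls, key=lambda c: (c.start, c.unit_length))


def find_ssrs_brute_force(bes_id: str, sequence: str) -> list[SSRCall]:
    """Oracle: test every (start, unit, copies) triple; keep maximal runs."""
    seq = sequence.upper()
    n = len(seq)
    calls = set()
    for unit in (2, 3, 4, 5):
        min_copies = SSR_MIN_COPIES[unit]
        for start in range(n - unit * min_copies + 1):
            motif = seq[start : start + unit]
            if "N" in motif or _is_power(motif):
                continue
            copies = 1
            while seq[start + copies * unit : start + (copies + 1) * unit] == motif:
                copies += 1
            if copies < min_copies:
                continue
            # maximal: no extra copy to the left
            if start >= unit and seq[start - unit : start] == motif:
                continue
            calls.add(
                SSRCall(bes_id, _canonical_rotation(motif), unit, copies, start, start + copies * unit)
            )
    return sorted(calls, key=lambda c: (c.start, c.unit_length))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def organelle_screen(
    records: list[BESRecord],
    organelle_refs: dict[str, str],
    k: int = 31,
    min_shared_frac: float = 0.5,
) -> list[BESRecord]:
    """Flag reads sharing >= ``min_shared_frac`` of their k-mers with any
    single organelle reference.  Empty reference set skips the screen.
    A k-mer containment screen stands in for alignment-based search; the
    threshold is configuration.
    """
    if not organelle_refs:
        log.warning("no organelle references supplied — screen skipped")
        return records
    ref_sets = {name: _kmers(seq.upper(), k) for name, seq in organelle_refs.items()}
    for rec in records:
        if rec.status != "pass":
            continue
        mers = _kmers(rec.sequence, k)
        if not mers:
            continue
        for name in sorted(ref_sets):
            if len(mers & ref_sets[name]) / len(mers) >= min_shared_frac:
                rec.status = "organelle"
                log.info("%s flagged organelle (%s)", rec.bes_id, name)
                break
    return records


def bes_summary(records: list[BESRecord], ssr_calls: list[SSRCall]) -> dict:
    by_status: dict[str, int] = {}
    for rec in records:
        by_status[rec.status] = by_status.get(rec.status, 0) + 1
    _per, aggregate_gc = gc_content(records)
    passing = [r for r in records if r.status == "pass"]
    by_unit = {u: sum(1 for c in ssr_calls if c.unit_length == u) for u in (2, 3, 4, 5)}
    return {
        "n_records": len(records),
        "status_counts": dict(sorted(by_status.items())),
        "mean_length": round(sum(len(r.sequence) for r in passing) / len(passing), 1)
        if passing
        else 0.0,
        "aggregate_gc": round(aggregate_gc, 4) if passing else None,
        "n_ssr_calls": len(ssr_calls),
        "ssr_by_unit": by_unit,
        "reads_with_ssr": len({c.bes_id for c in ssr_calls}),
    }
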