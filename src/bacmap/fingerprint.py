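"""Fingerprint band handling and clone-overlap scoring.

A HICF fingerprint reduces a BAC clone to a sorted list of integer band
values (sized restriction fragments).  Two clones overlap physically when
their fingerprints share many bands; the Sulston score quantifies the
probability of seeing at least the observed number of band matches by
chance, so *low* scores indicate true overlap.  The score drives every
assembly stage: the initial build (cutoff 1e-50), the stepped merges
(down to 1e-35) and the marker-guided manual merges (1e-20).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "FingerprintProfile",
    "ScoreParams",
    "Overlap",
    "match_bands",
    "sulston_score",
    "sulston_log10_score",
    "pairwise_overlaps",
    "OverlapTable",
]

#: probabilities below this are clamped; comparisons use log10 scores
SCORE_FLOOR = 1e-300
LOG10_FLOOR = -300.0


@dataclass
class FingerprintProfile:
    """One clone's electronic fingerprint.

    ``bands`` is a sorted ascending list of integer band values in
    ``[1, G]``; ``status`` is ``ok`` for usable fingerprints,
    ``no_fingerprint`` for empty/failed clones and ``removed`` for clones
    excluded from the project (e.g. manual removals for poor data).
    """

    clone_id: str
    library: str
    bands: list[int] = field(default_factory=list)
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status != "ok" and self.bands:
            raise ValueError(
                f"clone {self.clone_id}: status {self.status!r} requires empty bands"
            )
        if any(b > a for a, b in zip(self.bands[1:], self.bands)):
            raise ValueError(f"clone {self.clone_id}: bands must be sorted ascending")

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the overlap statistic.

    tolerance_t : band-units window; values x, y match when ``|x-y| <= t``.
    gellen_G    : size of the band-value space (number of distinguishable
                  band values the sizing method can produce).
    cutoff      : emit a clone pair as overlapping when score <= cutoff.
    """

    tolerance_t: int = 3
    gellen_G: int = 30000
    cutoff: float = 1e-50

    def __post_init__(self) -> None:
        if self.tolerance_t < 0:
            raise ValueError("tolerance must be >= 0")
        if self.gellen_G <= 2 * self.tolerance_t + 1:
            raise ValueError("gellen_G must exceed 2t+1")
        if not (0 < self.cutoff <= 1):
            raise ValueError("cutoff must be in (0, 1]")

    def replace(self, **kw) -> "ScoreParams":
        d = {"tolerance_t": self.tolerance_t, "gellen_G": self.gellen_G, "cutoff": self.cutoff}
        d.update(kw)
        return ScoreParams(**d)


def match_bands(a, b, tolerance_t: int) -> int:
    """Count one-to-one band matches between two sorted band lists.

    Greedy two-pointer scan: heads x, y pair when ``|x-y| <= t`` (both
    advance); otherwise the smaller head advances.  For sorted lists this
    equals the maximum bipartite matching size (asserted against brute
    force in the test suite).
    """
    if any(y < x for x, y in zip(a, a[1:])) or any(y < x for x, y in zip(b, b[1:])):
        raise ValueError("band lists must be sorted ascending")
    i = j = m = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        d = a[i] - b[j]
        if -tolerance_t <= d <= tolerance_t:
            m += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return m


def match_bands_brute_force(a, b, tolerance_t: int) -> int:
    """Maximum bipartite matching size via augmenting paths (oracle:
    independent of the greedy scan, exact for any input order)."""
    na, nb = len(a), len(b)
    adj = [[j for j in range(nb) if abs(a[i] - b[j]) <= tolerance_t] for i in range(na)]
    match_of_b = [-1] * nb

    def augment(i, seen):
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if match_of_b[j] == -1 or augment(match_of_b[j], seen):
                match_of_b[j] = i
                return True
        return False

    return sum(augment(i, set()) for i in range(na))


def coincidence_probability(n_high: int, tolerance_t: int, gellen_G: int) -> float:
    """Probability a single band of the smaller clone matches *some* band
    of the larger clone by chance: ``1 - (1 - (2t+1)/G)^nH``."""
    w = (2 * tolerance_t + 1) / gellen_G
    return -np.expm1(n_high * np.log1p(-w))


@lru_cache(maxsize=200_000)
def _log10_tail(n_low: int, n_high: int, m: int, tolerance_t: int, gellen_G: int) -> float:
    if m == 0:
        return 0.0
    p = coincidence_probability(n_high, tolerance_t, gellen_G)
    k = np.arange(m, n_low + 1)
    log_terms = (
        gammaln(n_low + 1)
        - gammaln(k + 1)
        - gammaln(n_low - k + 1)
        + k * np.log(p)
        + (n_low - k) * np.log1p(-p)
    )
    return float(logsumexp(log_terms) / np.log(10))


def sulston_log10_score(nA: int, nB: int, m: int, params: ScoreParams) -> float:
    """log10 of the Sulston score (clamped at -300 to avoid underflow)."""
    if nA < 0 or nB < 0:
        raise ValueError("band counts must be non-negative")
    nL, nH = min(nA, nB), max(nA, nB)
    if m > nL or m < 0:
        raise ValueError(f"matched count m={m} outside [0, min(nA,nB)={nL}]")
    if nL == 0:
        return 0.0
    return max(_log10_tail(nL, nH, m, params.tolerance_t, params.gellen_G), LOG10_FLOOR)


def sulston_score(nA: int, nB: int, m: int, params: ScoreParams) -> float:
    """Probability that two random clones of nA and nB bands share at
    least m matching bands: a binomial tail ``P(X >= m)`` with
    ``X ~ Bin(min(nA,nB), p)`` and per-band coincidence probability
    ``p = 1 - (1 - (2t+1)/G)^max(nA,nB)``.  Computed in log space;
    results below 1e-300 are clamped.
    """
    return float(10.0 ** sulston_log10_score(nA, nB, m, params))


@dataclass(frozen=True)
class Overlap:
    clone_a: str
    clone_b: str
    m: int
    log10_score: float

    @property
    def score(self) -> float:
        return 10.0**self.log10_score


def _match_counts_block(bands_a, na, bands_b, nb, tolerance_t):
    """Vectorised greedy two-pointer over many pairs at once.

    bands_* are int arrays (n_pairs, width) padded with a huge sentinel;
    na/nb the true band counts.  Returns matched counts per pair.
    """
    n_pairs = bands_a.shape[0]
    i = np.zeros(n_pairs, dtype=np.int64)
    j = np.zeros(n_pairs, dtype=np.int64)
    m = np.zeros(n_pairs, dtype=np.int64)
    rows = np.arange(n_pairs)
    wa, wb = bands_a.shape[1], bands_b.shape[1]
    for _ in range(wa + wb):
        active = (i < na) & (j < nb)
        if not active.any():
            break
        x = bands_a[rows, np.minimum(i, wa - 1)]
        y = bands_b[rows, np.minimum(j, wb - 1)]
        hit = active & (np.abs(x - y) <= tolerance_t)
        m += hit
        adv_i = hit | (active & ~hit & (x < y))
        adv_j = hit | (active & ~hit & (x >= y))
        i += adv_i
        j += adv_j
    return m


class OverlapTable:
    """All-pairs matched-band counts and scores for a set of profiles.

    Scored once at a *retention* cutoff (the loosest stringency any stage
    will ask for); stages then query at their own cutoff.  Pair keys are
    unordered (stored sorted).
    """

    def __init__(self, profiles, params: ScoreParams, keep_cutoff: float | None = None):
        self.params = params
        keep = keep_cutoff if keep_cutoff is not None else params.cutoff
        self._keep_log10 = np.log10(keep)
        self.n_bands = {p.clone_id: p.n_bands for p in profiles}
        self._pairs: dict[tuple[str, str], tuple[int, float]] = {}
        self._build(profiles)

    def _build(self, profiles) -> None:
        profiles = [p for p in profiles if p.status == "ok"]
        n = len(profiles)
        if n < 2:
            return
        width = max(p.n_bands for p in profiles) or 1
        sentinel = np.iinfo(np.int64).max // 4
        arr = np.full((n, width), sentinel, dtype=np.int64)
        counts = np.zeros(n, dtype=np.int64)
        for k, p in enumerate(profiles):
            counts[k] = p.n_bands
            if p.n_bands:
                arr[k, : p.n_bands] = p.bands
        ia, ib = np.triu_indices(n, k=1)
        t = self.params.tolerance_t
        block = 200_000
        for s in range(0, len(ia), block):
            sa, sb = ia[s : s + block], ib[s : s + block]
            ms = _match_counts_block(arr[sa], counts[sa], arr[sb], counts[sb], t)
            for k in np.nonzero(ms > 0)[0]:
                pa, pb = profiles[sa[k]], profiles[sb[k]]
                lg = sulston_log10_score(pa.n_bands, pb.n_bands, int(ms[k]), self.params)
                if lg <= self._keep_log10:
                    key = (pa.clone_id, pb.clone_id) if pa.clone_id < pb.clone_id else (pb.clone_id, pa.clone_id)
                    self._pairs[key] = (int(ms[k]), lg)

    def lookup(self, a: str, b: str) -> tuple[int, float] | None:
        key = (a, b) if a < b else (b, a)
        return self._pairs.get(key)

    def edges(self, cutoff: float):
        """Yield Overlap records with score <= cutoff, deterministic order."""
        lg_cut = np.log10(cutoff)
        for (a, b), (m, lg) in sorted(self._pairs.items()):
            if lg <= lg_cut:
                yield Overlap(a, b, m, lg)

    def __len__(self) -> int:
        return len(self._pairs)


def pairwise_overlaps(profiles, params: ScoreParams) -> list[Overlap]:
    """Score all unordered profile pairs; emit those at or below the cutoff.

    Equals the all-pairs computation exactly (the internal blocking is a
    speed device only).
    """
    for p in profiles:
        if p.status != "ok":
            raise ValueError(f"profile {p.clone_id} has status {p.status!r}")
    table = OverlapTable(profiles, params)
    return list(table.edges(params.cutoff))
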