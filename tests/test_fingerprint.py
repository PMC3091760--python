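"""Band matching and Sulston scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacmap import ScoreParams, match_bands, pairwise_overlaps, sulston_log10_score, sulston_score
from bacmap.fingerprint import (
    FingerprintProfile,
    OverlapTable,
    _match_counts_block,
    coincidence_probability,
    match_bands_brute_force,
)

band_lists = st.lists(st.integers(1, 60), min_size=0, max_size=8).map(sorted)


class TestMatchBands:
    @pytest.mark.parametrize(
        "a,b,t,expected",
        [
            ([10, 20, 30], [10, 20, 30], 0, 3),
            ([100], [104], 3, 0),
            ([100, 103], [101, 200], 3, 1),
            ([], [1, 2], 3, 0),
            ([5, 5, 5], [5, 5], 0, 2),  # duplicates: one-to-one pairing
        ],
    )
    def test_examples(self, a, b, t, expected):
        assert match_bands(a, b, t) == expected
        assert match_bands(b, a, t) == expected  # symmetry

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            match_bands([3, 1], [1, 2], 1)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(band_lists, band_lists, st.integers(0, 5))
    def test_greedy_equals_maximum_matching(self, a, b, t):
        """The greedy two-pointer count equals the true maximum bipartite
        matching size on sorted lists."""
        assert match_bands(a, b, t) == match_bands_brute_force(a, b, t)

    def test_vectorised_matcher_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        sentinel = np.iinfo(np.int64).max // 4
        for _ in range(50):
            na, nb = rng.integers(0, 30, size=2)
            a = np.sort(rng.integers(1, 200, size=na))
            b = np.sort(rng.integers(1, 200, size=nb))
            arr_a = np.full((1, max(na, 1)), sentinel)
            arr_b = np.full((1, max(nb, 1)), sentinel)
            arr_a[0, :na] = a
            arr_b[0, :nb] = b
            got = _match_counts_block(arr_a, np.array([na]), arr_b, np.array([nb]), 3)[0]
            assert got == match_bands(list(a), list(b), 3)


class TestSulstonScore:
    def test_zero_matches_gives_one(self, default_params):
        for nA, nB in [(0, 0), (5, 9), (81, 120)]:
            assert sulston_score(nA, nB, 0, default_params) == 1.0

    def test_two_band_closed_form(self):
        """nA=nB=2, m=1, t=0, G=1000: score = 1-(1-p)^2, p = 1-0.999^2."""
        params = ScoreParams(tolerance_t=0, gellen_G=1000, cutoff=1.0)
        p = 1 - 0.999**2
        expected = 1 - (1 - p) ** 2
        assert sulston_score(2, 2, 1, params) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(3.99e-3, rel=1e-2)

    def test_monotone_in_m(self, default_params):
        scores = [sulston_score(81, 81, m, default_params) for m in range(0, 82)]
        assert all(b <= a for a, b in zip(scores, scores[1:]))

    def test_increases_with_tolerance_and_nh(self):
        base = ScoreParams(tolerance_t=1, gellen_G=5000, cutoff=1.0)
        wide = ScoreParams(tolerance_t=3, gellen_G=5000, cutoff=1.0)
        assert sulston_score(40, 40, 10, wide) > sulston_score(40, 40, 10, base)
        assert sulston_score(40, 80, 10, base) > sulston_score(40, 40, 10, base)

    def test_m_above_nl_rejected(self, default_params):
        with pytest.raises(ValueError):
            sulston_score(3, 10, 4, default_params)

    def test_log_floor(self, default_params):
        assert sulston_log10_score(81, 81, 81, default_params) >= -300.0

    def test_in_unit_interval(self, default_params):
        rng = np.random.default_rng(0)
        for _ in range(100):
            nA, nB = rng.integers(1, 150, size=2)
            m = rng.integers(0, min(nA, nB) + 1)
            s = sulston_score(int(nA), int(nB), int(m), default_params)
            assert 0.0 <= s <= 1.0


def _mc_exceedance(nA, nB, m0, t, G, trials, rng):
    """Empirical P(matches >= m0) over random band lists, using an
    independent vectorised two-pointer (oracle for the analytic tail)."""
    sentinel = np.iinfo(np.int64).max // 4
    a = np.sort(rng.integers(1, G + 1, size=(trials, nA)), axis=1)
    b = np.sort(rng.integers(1, G + 1, size=(trials, nB)), axis=1)
    counts = _match_counts_block(
        a, np.full(trials, nA), b, np.full(trials, nB), t
    )
    return float(np.mean(counts >= m0))


class TestMonteCarloAgreement:
    @pytest.mark.parametrize(
        "nA,nB,m0,t,G",
        [
            (2, 2, 1, 0, 1000),
            (5, 5, 1, 1, 2000),
            (8, 6, 2, 2, 5000),
            (10, 10, 2, 3, 10000),
        ],
    )
    def test_analytic_matches_simulation(self, nA, nB, m0, t, G):
        """The binomial-tail score equals the chance-match exceedance
        frequency of genuinely random band lists (3 SE tolerance)."""
        rng = np.random.default_rng(42)
        trials = 200_000
        emp = _mc_exceedance(nA, nB, m0, t, G, trials, rng)
        ana = sulston_score(nA, nB, m0, ScoreParams(t, G, 1.0))
        se = np.sqrt(max(ana * (1 - ana), 1e-12) / trials)
        assert abs(emp - ana) <= 3 * se + 1e-9


class TestPairwiseOverlaps:
    def test_identical_profiles_emitted(self, default_params):
        bands = sorted(np.random.default_rng(1).integers(1, 30000, size=80).tolist())
        profs = [
            FingerprintProfile("a", "L", bands),
            FingerprintProfile("b", "L", bands),
        ]
        out = pairwise_overlaps(profs, default_params)
        assert len(out) == 1 and out[0].score < 1e-50

    def test_disjoint_profiles_not_emitted(self, default_params):
        profs = [
            FingerprintProfile("a", "L", [1, 2, 3]),
            FingerprintProfile("b", "L", [20000, 20005, 20010]),
        ]
        assert pairwise_overlaps(profs, default_params) == []

    def test_non_ok_status_rejected(self, default_params):
        profs = [FingerprintProfile("a", "L", [], status="no_fingerprint")]
        with pytest.raises(ValueError):
            pairwise_overlaps(profs, default_params)

    def test_simulation_recovers_true_overlaps(self, small_noiseless_sim, default_params):
        """On a noiseless simulation, emitted pairs are exactly the truly
        overlapping pairs with enough shared sites (truth-file check)."""
        genome, clones, profiles = small_noiseless_sim
        sub = profiles[:50]
        ids = {p.clone_id for p in sub}
        by = {c.clone_id: c for c in clones if c.clone_id in ids}
        pos = genome.site_positions
        emitted = {(o.clone_a, o.clone_b) for o in pairwise_overlaps(sub, default_params)}

        def shared_sites(x, y):
            lo = max(by[x].start, by[y].start)
            hi = min(by[x].end, by[y].end)
            return int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo)) if hi > lo else 0

        # every emitted pair truly overlaps strongly ...
        for a, b in emitted:
            assert shared_sites(a, b) >= 20
        # ... and pairs sharing >= 60 sites are always emitted
        names = sorted(ids)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if shared_sites(a, b) >= 60:
                    key = (a, b) if a < b else (b, a)
                    assert key in emitted


def test_overlap_table_matches_pairwise(small_noiseless_sim, default_params):
    """OverlapTable bucketing/blocking equals the simple all-pairs path."""
    _g, _c, profiles = small_noiseless_sim
    sub = profiles[:30]
    table = OverlapTable(sub, default_params)
    via_table = {(o.clone_a, o.clone_b): (o.m, round(o.log10_score, 9)) for o in table.edges(default_params.cutoff)}
    direct = {}
    for i, a in enumerate(sub):
        for b in sub[i + 1 :]:
            m = match_bands(a.bands, b.bands, default_params.tolerance_t)
            if m:
                lg = sulston_log10_score(a.n_bands, b.n_bands, m, default_params)
                if lg <= np.log10(default_params.cutoff):
                    key = tuple(sorted((a.clone_id, b.clone_id)))
                    direct[key] = (m, round(lg, 9))
    assert via_table == direct


def test_coincidence_probability_bounds():
    p = coincidence_probability(81, 3, 30000)
    assert 0 < p < 0.05
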