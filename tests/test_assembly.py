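"""Contig assembly: build, layout, Q clones, DQer, merges, statistics."""

import numpy as np
import pytest

from bacmap import (
    Contig,
    ContigBuild,
    MergeRuleParams,
    ScoreParams,
    assembly_stats,
    dqer,
    flag_q_clones,
    initial_build,
    manual_merge,
    order_clones,
    physical_map_summary,
    stepped_merge,
)
from bacmap.fingerprint import FingerprintProfile, OverlapTable
from bacmap import simdata as sd


def prof(clone_id, values):
    return FingerprintProfile(clone_id, "L", sorted(values))


def vals(start, n, step=10):
    """n distinct band values spaced beyond tolerance."""
    return [start + step * i for i in range(n)]


PARAMS = ScoreParams()  # tolerance 3, G 30000, cutoff 1e-50


def make_table(profiles, keep=1e-20):
    return OverlapTable(profiles, PARAMS, keep_cutoff=keep)


class TestInitialBuild:
    def test_no_overlaps_all_singletons(self):
        profiles = [prof(f"c{i}", vals(1 + 3000 * i, 30)) for i in range(4)]
        build, _ = initial_build(profiles, PARAMS)
        assert build.contigs == [] and len(build.singletons) == 4

    def test_three_tiling_clones_one_contig(self):
        base = vals(10, 120)
        profiles = [
            prof("a", base[:80]),
            prof("b", base[20:100]),
            prof("c", base[40:120]),
        ]
        build, _ = initial_build(profiles, PARAMS)
        assert len(build.contigs) == 1 and build.contigs[0].n_clones == 3

    def test_exclusion_list_applied(self):
        base = vals(10, 80)
        profiles = [prof("a", base), prof("b", base), prof("x", base)]
        build, _ = initial_build(profiles, PARAMS, exclude={"x"})
        assert "x" not in build.clone_ids()

    def test_simulation_co_assignment(self, multi_lg_sim):
        """Noiseless multi-coverage simulation: truly overlapping pairs
        (>= 20 shared sites) co-assigned at high rate already at 1e-50."""
        genome, clones, profiles = multi_lg_sim
        build, _ = initial_build(profiles, PARAMS)
        by = {c.clone_id: c for c in clones}
        pos = genome.site_positions
        cof = build.contig_of()
        tot = hit = 0
        ids = sorted(by)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                lo = max(by[a].start, by[b].start)
                hi = min(by[a].end, by[b].end)
                if hi <= lo:
                    continue
                if np.searchsorted(pos, hi) - np.searchsorted(pos, lo) >= 20:
                    tot += 1
                    hit += cof.get(a) is not None and cof.get(a) == cof.get(b)
        assert tot > 500 and hit / tot >= 0.95


class TestOrderClones:
    def test_identical_pair(self):
        p = [prof("a", vals(10, 80)), prof("b", vals(10, 80))]
        table = make_table(p)
        ordered, offsets, cb = order_clones({"a", "b"}, table)
        assert offsets == [0, 0] and cb == 80

    def test_chain_end_offsets_increase(self):
        va = vals(10, 80)
        vc = vals(5000, 80)
        vb = va[35:] + vc[:35]  # shares 45 with each end
        p = [prof("a", va), prof("b", vb), prof("c", vc)]
        table = make_table(p)
        ordered, offsets, _cb = order_clones({"a", "b", "c"}, table)
        off = dict(zip(ordered, offsets))
        assert off["a"] < off["b"] < off["c"] or off["c"] < off["b"] < off["a"]

    def test_disconnected_set_rejected(self):
        p = [prof("a", vals(10, 30)), prof("b", vals(5000, 30))]
        with pytest.raises(ValueError):
            order_clones({"a", "b"}, make_table(p))

    def test_noiseless_tiling_recovers_true_order(self):
        """5-clone staircase: layout order equals genomic start order or
        its exact reversal."""
        genome = sd.simulate_genome(500_000, 1, n_markers=0, seed=21)
        starts = [0, 60_000, 120_000, 180_000, 240_000]
        clones = [sd.SimClone(f"t{i}", "L", s, s + 130_000) for i, s in enumerate(starts)]
        profiles = [sd.simulate_fingerprint(c, genome) for c in clones]
        table = make_table(profiles)
        ordered, offsets, _ = order_clones({c.clone_id for c in clones}, table)
        expected = [f"t{i}" for i in range(5)]
        assert ordered == expected or ordered == expected[::-1]

    def test_layout_span_tracks_true_length(self, small_build, small_noiseless_sim):
        """Single-region noiseless build: CB-length estimate within 15%
        of the true covered span."""
        _genome, clones, _profiles = small_noiseless_sim
        build, _table, _p = small_build
        assert len(build.contigs) == 1
        ctg = build.contigs[0]
        ids = set(ctg.clones)
        span_kb = (
            max(c.end for c in clones if c.clone_id in ids)
            - min(c.start for c in clones if c.clone_id in ids)
        ) / 1000.0
        assert abs(ctg.length_kb - span_kb) / span_kb < 0.15


class TestQClones:
    def test_noiseless_contig_no_q(self, small_build):
        build, _table, profiles = small_build
        pid = {p.clone_id: p for p in profiles}
        for ctg in build.contigs:
            assert sum(flag_q_clones(ctg, pid)) == 0

    def test_two_identical_clones_not_flagged(self):
        p = [prof("a", vals(10, 80)), prof("b", vals(10, 80))]
        ctg = Contig("c1", ["a", "b"], [0, 0])
        assert flag_q_clones(ctg, {x.clone_id: x for x in p}) == [False, False]

    def test_grafted_outlier_flagged(self):
        """An unrelated clone forced into a contig's layout is Q."""
        good = [prof(f"g{i}", vals(10, 80)) for i in range(3)]
        outlier = prof("zz", vals(9000, 80))
        pid = {p.clone_id: p for p in good + [outlier]}
        ctg = Contig("c1", ["g0", "g1", "g2", "zz"], [0, 0, 0, 5])
        assert flag_q_clones(ctg, pid) == [False, False, False, True]


def _dqer_fixture():
    """Two true 4-clone groups plus one forced-in chimeric outlier, as a
    single hand-merged contig whose layout makes the outlier Q."""
    vx = vals(10, 150)
    vy = vals(5000, 150)
    outlier_bands = vx[:60] + vy[:60] + vals(12000, 30)
    xs = [prof(f"x{i}", vx) for i in range(4)]
    ys = [prof(f"y{i}", vy) for i in range(4)]
    bb = prof("bb", outlier_bands)
    profiles = xs + ys + [bb]
    pid = {p.clone_id: p for p in profiles}
    table = make_table(profiles)
    ctg = Contig(
        "mix",
        ["x0", "x1", "x2", "x3", "bb", "y0", "y1", "y2", "y3"],
        [0, 0, 0, 0, 10, 400, 400, 400, 400],
    )
    build = ContigBuild([ctg], [], [("initial_build", 1e-50, 3)])
    return build, table, pid


class TestDQer:
    def test_clean_build_unchanged(self, small_build):
        build, table, profiles = small_build
        pid = {p.clone_id: p for p in profiles}
        out = dqer(build, table, pid)
        assert {tuple(c.clones) for c in out.contigs} == {
            tuple(c.clones) for c in build.contigs
        }
        assert out.singletons == build.singletons

    def test_bridged_contig_split_exactly(self):
        """A forced two-region contig bridged by an outlier splits into
        the two true groups; the outlier disperses to a singleton."""
        build, table, pid = _dqer_fixture()
        ctg = build.contigs[0]
        flag_q_clones(ctg, pid)
        assert ctg.q_flags == [False] * 4 + [True] + [False] * 4
        assert ctg.q_fraction > 0.10
        out = dqer(build, table, pid)
        groups = sorted(tuple(c.clones) for c in out.contigs)
        assert groups == [
            ("x0", "x1", "x2", "x3"),
            ("y0", "y1", "y2", "y3"),
        ]
        assert out.singletons == ["bb"]

    def test_never_merges_and_conserves_clones(self):
        build, table, pid = _dqer_fixture()
        before = build.clone_ids()
        out = dqer(build, table, pid)
        assert out.clone_ids() == before
        # every output contig is a subset of some input contig
        for ctg in out.contigs:
            assert set(ctg.clones) <= set(build.contigs[0].clones)


class TestSteppedMerge:
    def _split_pair(self, shared):
        va = vals(10, 80)
        vb = vals(9000, 80)
        bridge_a = va[:shared] + vb[-(80 - shared):]
        a = [prof("a1", va), prof("a2", va), prof("a3", bridge_a)]
        b = [prof("b1", vb), prof("b2", vb)]
        profiles = a + b
        table = make_table(profiles)
        build, _ = initial_build(profiles, PARAMS, table=table)
        return build, table

    def test_moderate_end_overlap_merged_by_final_cutoff(self):
        # bridge shares 42 bands with the b-group: ~1e-49 < s < 1e-35... no:
        # 42 of 80 scores just above 1e-50, below 1e-35 -> merged in steps
        build, table = self._split_pair(42)
        assert len(build.contigs) == 2
        out = stepped_merge(build, table)
        assert len(out.contigs) == 1 and out.contigs[0].n_clones == 5

    def test_weak_overlap_not_merged(self):
        build, table = self._split_pair(70)  # bridge shares only 10 with b
        build2 = stepped_merge(build, table)
        assert len(build2.contigs) == len(build.contigs)

    def test_singleton_attached_first_step(self):
        va = vals(10, 80)
        profiles = [prof("a1", va), prof("a2", va), prof("s1", va)]
        table = make_table(profiles)
        # force s1 out: build from the other two only, then declare singleton
        build, _ = initial_build(profiles[:2], PARAMS, table=make_table(profiles[:2]))
        build.singletons.append("s1")
        out = stepped_merge(build, table)
        assert out.singletons == [] and out.contigs[0].n_clones == 3

    def test_merging_is_monotone(self, multi_lg_sim):
        """stepped_merge never splits existing contigs."""
        _g, _c, profiles = multi_lg_sim
        build, table = initial_build(profiles, PARAMS)
        out = stepped_merge(build, table)
        cof = out.contig_of()
        for ctg in build.contigs:
            assert len({cof[c] for c in ctg.clones}) == 1


class TestManualMerge:
    def _two_contigs(self, shared, n_a=3, n_b=2):
        va = vals(10, 80)
        vb = va[:shared] + vals(9000, 80 - shared)
        a = [prof(f"a{i}", va) for i in range(n_a)]
        b = [prof(f"b{i}", vb) for i in range(n_b)]
        profiles = a + b
        table = make_table(profiles)
        build, _ = initial_build(profiles, PARAMS, table=table)
        assert len(build.contigs) == 2  # 41 shared bands is above 1e-50
        return build, table

    def test_three_two_matched_clones_merge(self):
        build, table = self._two_contigs(41)
        out = manual_merge(build, table)
        assert len(out.contigs) == 1

    def test_forty_shared_bands_no_merge(self):
        build, table = self._two_contigs(40)
        out = manual_merge(build, table)
        assert len(out.contigs) == 2

    def test_two_plus_two_requires_marker(self):
        build, table = self._two_contigs(41, n_a=2, n_b=2)
        assert len(manual_merge(build, table).contigs) == 2
        ids = {c.contig_id for c in build.contigs}
        pair = {tuple(sorted(ids))}
        out = manual_merge(build, table, marker_pairs=pair)
        assert len(out.contigs) == 1

    def test_conserves_clones(self):
        build, table = self._two_contigs(41)
        out = manual_merge(build, table)
        assert out.clone_ids() == build.clone_ids()


class TestStats:
    def test_published_scale_percentages(self):
        """The map-level arithmetic on full-project counts: 46,216 of
        50,155 clones in contigs is 92.1%; 689.8 Mb over a 300 Mb genome
        is 2.3x; 50,155 x 128 kb is ~21x coverage."""
        s = physical_map_summary(
            n_in_map=50_155,
            n_in_contigs=46_216,
            n_singletons=3_939,
            n_contigs=832,
            total_length_mb=689.8,
            genome_size_mb=300.0,
            n_fingerprinted=57_121,
            mean_insert_kb=128.0,
        )
        assert s["pct_clones_in_contigs"] == 92.1
        assert s["length_vs_genome"] == 2.3
        assert s["genome_coverage_x"] == 21.4

    def test_empty_build_all_zero(self):
        build = ContigBuild([], [], [("initial_build", 1e-50, 3)])
        s = assembly_stats(build, 300.0)
        assert s["clones_in_map"] == 0 and s["n_contigs"] == 0
        assert s["total_length_mb"] == 0.0
        assert all(v == 0 for v in s["contig_size_histogram"].values())

    def test_histogram_bins(self):
        contigs = []
        for k, n in enumerate([2, 5, 12, 430]):
            ids = [f"c{k}_{i}" for i in range(n)]
            contigs.append(Contig(f"ctg{k}", ids, [0] * n))
        build = ContigBuild(contigs, ["s1"], [("initial_build", 1e-50, 3)])
        h = assembly_stats(build, 300.0)["contig_size_histogram"]
        assert h["2"] == 1 and h["3-9"] == 1 and h["10-24"] == 1 and h[">399"] == 1


class TestCloneConservation:
    def test_partition_preserved_through_stages(self, multi_lg_sim):
        _g, _c, profiles = multi_lg_sim
        ok_ids = {p.clone_id for p in profiles if p.status == "ok"}
        pid = {p.clone_id: p for p in profiles}
        build, table = initial_build(profiles, PARAMS)
        for stage in (
            lambda b: dqer(b, table, pid),
            lambda b: stepped_merge(b, table),
            lambda b: manual_merge(b, table),
        ):
            build = stage(build)
            ids = [c for ctg in build.contigs for c in ctg.clones] + build.singletons
            assert sorted(ids) == sorted(ok_ids)  # no loss, no duplication
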