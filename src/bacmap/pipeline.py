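"""Umbrella pipeline: simulate -> fingerprint -> assemble -> pools ->
anchor -> manual merge -> stats -> MTP -> BES.

Every stage writes its artifacts under the output directory with a
header naming the stage and the configuration hash; a ``manifest.json``
records the package version, the seed and the full parameter set.  All
randomness flows from the single configuration seed, and reruns with
the same seed produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__, anchoring, assembly, bes, io, mtp, pooling, simdata
from .config import PipelineConfig
from .fingerprint import OverlapTable, ScoreParams

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "assemble",
    "pools",
    "anchor",
    "manual_merge",
    "stats",
    "mtp",
    "bes",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    outdir,
    simulate: bool = True,
    bands_path=None,
    markers_path=None,
    skip: set[str] | None = None,
) -> dict:
    """Execute the full physical-mapping pipeline.

    With ``simulate=True`` the synthetic-data module generates the
    inputs; otherwise ``bands_path`` (and optionally ``markers_path``)
    supply real data.  ``skip`` names stages to omit (recorded in the
    manifest).  Returns the summary dictionary.
    """
    skip = skip or set()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phash = config.params_hash()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params_hash": phash,
        "config": config.to_dict(),
        "skipped": sorted(skip),
        "stages_run": [],
    }
    summary: dict = {}
    genome = None
    clones = None
    truth_probe_positions = None

    def _run(stage, fn):
        if stage in skip:
            log.info("stage %s skipped", stage)
            return None
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - abort with stage name and cause
            raise StageError(stage, exc) from exc
        manifest["stages_run"].append(stage)
        return result

    # ---- simulate ------------------------------------------------------
    if simulate:
        def do_simulate():
            nonlocal genome, clones
            genome = simdata.simulate_genome(
                length=config.sim_genome_length,
                n_linkage_groups=config.sim_n_linkage_groups,
                site_rate=config.sim_site_rate,
                n_markers=config.sim_n_markers,
                band_range_G=config.gellen_G,
                seed=config.seed,
            )
            noise = simdata.NoiseModel(
                sizing_error_prob=config.sim_sizing_error,
                band_dropout_prob=config.sim_band_dropout,
                spurious_band_rate=config.sim_spurious_rate,
                pool_false_pos=config.sim_pool_false_pos,
                pool_false_neg=config.sim_pool_false_neg,
                seed=config.seed,
                sizing_tolerance=config.tolerance,
            )
            import dataclasses

            clones = []
            for k, spec in enumerate((simdata.AF_BB, simdata.AF_BC)):
                spec = dataclasses.replace(spec, n_clones=config.sim_clones_per_library)
                clones += simdata.simulate_library(genome, spec, seed=config.seed * 2 + k + 1)
            profiles = simdata.simulate_fingerprints(clones, genome, noise)
            io.write_band_file(outdir / "bands.tsv", profiles, "simulate", phash)
            with open(outdir / "truth.tsv", "w") as fh:
                fh.write("# ground truth - not read by pipeline stages\n")
                fh.write("clone_id\tstart\tend\n")
                for c in clones:
                    fh.write(f"{c.clone_id}\t{c.start}\t{c.end}\n")
            markers = [
                anchoring.MarkerRecord(mid, "mapped", lg, cm)
                for (mid, lg, _pos, cm) in genome.markers
            ]
            io.write_marker_file(outdir / "markers.tsv", markers, "simulate", phash)
            return profiles, markers, noise

        sim = _run("simulate", do_simulate)
        profiles, markers, noise = sim
    else:
        profiles = io.read_band_file(bands_path)
        markers = io.read_marker_file(markers_path) if markers_path else []
        noise = None

    # ---- assemble ------------------------------------------------------
    params = ScoreParams(config.tolerance, config.gellen_G, config.cutoff_initial)
    profiles_by_id = {p.clone_id: p for p in profiles if p.status == "ok"}

    def do_assemble():
        build, table = assembly.initial_build(
            profiles,
            params,
            kb_per_band=config.kb_per_band,
            exclude=set(config.exclude_clones),
        )
        summary["initial"] = assembly.assembly_stats(build, config.genome_size_mb)
        build = assembly.dqer(
            build, table, profiles_by_id, q_fraction_threshold=config.dq_threshold
        )
        build = assembly.stepped_merge(
            build,
            table,
            start_cutoff=config.cutoff_initial,
            end_cutoff=config.cutoff_final,
            step_factor=config.step_factor,
            end_window=config.end_window,
        )
        return build, table

    build, table = _run("assemble", do_assemble)

    # ---- pools ---------------------------------------------------------
    decon = None
    if simulate and "pools" not in skip:
        def do_pools():
            n_probes = len(genome.markers)
            design = pooling.design_pools(
                n_probes, config.pool_dims, probe_ids=[m[0] for m in genome.markers]
            )
            hyb, truth_hyb = simdata.simulate_hybridization(design, clones, genome, noise)
            io.write_pool_design(outdir / "pool_design.tsv", design, "pools", phash)
            io.write_hyb_file(outdir / "hyb.tsv", hyb, "pools", phash)
            result = pooling.deconvolve(design, hyb)
            io.write_hits_file(outdir / "hits.tsv", result, "pools", phash)
            return result

        decon = _run("pools", do_pools)

    # ---- anchor --------------------------------------------------------
    anchor_table = None
    marker_pairs = set()
    if decon is not None and "anchor" not in skip:
        def do_anchor():
            hits = decon.by_probe()
            tbl = anchoring.anchor_markers(hits, build)
            anchoring.anchor_linkage_groups(
                tbl, markers, build, genome_size_mb=config.sim_genome_length / 1e6
            )
            io.write_json(
                outdir / "anchoring.json",
                {
                    "classification": tbl.classification(),
                    "per_linkage_group": tbl.anchored_per_lg,
                    "anchored_length_mb": tbl.anchored_length_mb,
                    "genome_fraction": round(tbl.genome_fraction, 4),
                },
                "anchor",
                phash,
            )
            return tbl

        anchor_table = _run("anchor", do_anchor)
        if anchor_table is not None:
            marker_pairs = anchoring.merge_support(anchor_table)

    # ---- manual merge --------------------------------------------------
    def do_manual():
        rules = assembly.MergeRuleParams(
            manual_cutoff=config.cutoff_manual,
            tolerance=config.tolerance,
            min_shared_bands=config.min_shared_bands,
            min_matched_clones_first=config.min_matched_clones_first,
            min_matched_clones_second=config.min_matched_clones_second,
            min_matched_with_marker=config.min_matched_with_marker,
            end_window=config.end_window,
        )
        return assembly.manual_merge(build, table, rules, marker_pairs)

    merged = _run("manual_merge", do_manual)
    if merged is not None:
        build = merged
    for ctg in build.contigs:
        assembly.flag_q_clones(ctg, profiles_by_id, config.tolerance)
    io.write_contig_file(outdir / "contigs.tsv", build, "assemble", phash)

    # ---- stats ---------------------------------------------------------
    def do_stats():
        genome_mb = config.sim_genome_length / 1e6 if simulate else config.genome_size_mb
        stats = assembly.assembly_stats(
            build, genome_mb, n_fingerprinted=len(profiles), mean_insert_kb=128.0
        )
        summary["final"] = stats
        io.write_json(outdir / "summary.json", summary, "stats", phash)
        _write_report(outdir / "report.txt", build, stats, phash)
        return stats

    _run("stats", do_stats)

    # ---- mtp -----------------------------------------------------------
    paths = None

    def do_mtp():
        n_bands = {p.clone_id: len(p.bands) for p in profiles}
        out_paths = mtp.select_all_mtps(build, n_bands, config.mtp_min_overlap_cb)
        io.write_mtp_file(outdir / "mtp.tsv", out_paths, "mtp", phash)
        summary["mtp"] = mtp.mtp_stats(out_paths)
        return out_paths

    paths = _run("mtp", do_mtp)

    # ---- bes -----------------------------------------------------------
    if simulate and "bes" not in skip and paths is not None:
        def do_bes():
            mtp_clones = sorted({c for p in paths for c in p.clones})
            raw = simdata.simulate_bes_records(mtp_clones, seed=config.seed + 77)
            records = [
                bes.trim_and_filter(
                    bid,
                    seq,
                    phred_min=config.bes_phred_min,
                    window_len=config.bes_window_len,
                    max_n_frac=config.bes_max_n_frac,
                )
                for bid, seq in raw
            ]
            passing = [r for r in records if r.status == "pass"]
            calls = [c for r in passing for c in bes.find_ssrs(r.bes_id, r.sequence)]
            io.write_fasta(outdir / "bes_pass.fasta", [(r.bes_id, r.sequence) for r in passing])
            io.write_ssr_bed(outdir / "ssrs.bed", calls, "bes", phash)
            summary["bes"] = bes.bes_summary(records, calls)
            return summary["bes"]

        _run("bes", do_bes)

    io.write_json(outdir / "summary.json", summary, "stats", phash)
    io.write_json(outdir / "manifest.json", manifest, "manifest", phash)
    return summary


def _write_report(path, build, stats, phash) -> None:
    lines = [f"# stage=stats params={phash}", "Physical map summary", "=" * 40]
    for key, val in stats.items():
        if key == "contig_size_histogram":
            lines.append("contig size histogram:")
            for label, count in val.items():
                lines.append(f"  {label:>8} clones : {count}")
        else:
            lines.append(f"{key}: {val}")
    lines.append("")
    lines.append(f"{'contig':<12}{'clones':>8}{'CB len':>10}{'kb':>12}")
    for ctg in build.contigs:
        lines.append(
            f"{ctg.contig_id:<12}{ctg.n_clones:>8}{ctg.consensus_band_count:>10}{ctg.length_kb:>12.1f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
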