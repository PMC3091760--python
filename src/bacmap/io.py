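"""File formats: band TSV, marker TSV, hybridization/hits TSV, contig
membership TSV, MTP TSV, FASTA and BED, JSON summaries.

Every output file starts with comment lines naming the producing stage
and a parameter hash, so any artifact can be traced to the run that
made it.  All writers are byte-deterministic for a fixed input.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .anchoring import MarkerRecord
from .assembly import ContigBuild
from .fingerprint import FingerprintProfile
from .pooling import HybMatrix, PoolDesign

__all__ = [
    "write_band_file",
    "read_band_file",
    "write_marker_file",
    "read_marker_file",
    "write_hyb_file",
    "read_hyb_file",
    "write_contig_file",
    "write_mtp_file",
    "write_hits_file",
    "write_pool_design",
    "write_json",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_ssr_bed",
]

log = logging.getLogger(__name__)

BAND_FORMAT_VERSION = "bacmap-bands/1"


def _header(stage: str, params_hash: str = "-") -> str:
    return f"# stage={stage} params={params_hash}\n"


def write_band_file(path, profiles, stage: str = "simulate", params_hash: str = "-") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params_hash))
        fh.write(f"# format={BAND_FORMAT_VERSION}\n")
        fh.write("clone_id\tlibrary\tstatus\tbands\n")
        for p in profiles:
            bands = ",".join(str(b) for b in p.bands)
            fh.write(f"{p.clone_id}\t{p.library}\t{p.status}\t{bands}\n")


def read_band_file(path) -> list[FingerprintProfile]:
    """Parse a band TSV; malformed rows are rejected with their line
    number, duplicate clone ids are a hard error, unsorted bands are
    auto-sorted with a warning."""
    profiles = []
    seen: set[str] = set()
    with open(path) as fh:
        header_ok = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_ok:
                if not line.startswith("clone_id\t"):
                    raise ValueError(f"{path}:{lineno}: missing band-file header")
                header_ok = True
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                log.warning("%s:%d: malformed row rejected", path, lineno)
                continue
            clone_id, library, status, band_str = parts
            if clone_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate clone_id {clone_id!r}")
            seen.add(clone_id)
            try:
                bands = [int(b) for b in band_str.split(",")] if band_str else []
            except ValueError:
                log.warning("%s:%d: non-integer band value, row rejected", path, lineno)
                continue
            if any(y < x for x, y in zip(bands, bands[1:])):
                log.warning("%s:%d: unsorted bands auto-sorted", path, lineno)
                bands.sort()
            if status != "ok":
                bands = []
            profiles.append(FingerprintProfile(clone_id, library, bands, status=status))
    return profiles


def write_marker_file(path, markers: list[MarkerRecord], stage="simulate", params_hash="-") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params_hash))
        fh.write("marker_id\tclass\tlinkage_group\tcM\n")
        for m in markers:
            lg = "" if m.linkage_group is None else str(m.linkage_group)
            cm = "" if m.cM is None else f"{m.cM:g}"
            fh.write(f"{m.marker_id}\t{m.marker_class}\t{lg}\t{cm}\n")


def read_marker_file(path) -> list[MarkerRecord]:
    markers = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("marker_id\t"):
                continue
            mid, mclass, lg, cm = line.split("\t")
            markers.append(
                MarkerRecord(
                    mid,
                    mclass,
                    int(lg) if lg else None,
                    float(cm) if cm else None,
                )
            )
    return markers


def write_hyb_file(path, hyb: HybMatrix, stage="simulate", params_hash="-") -> None:
    """Positive pool x clone calls, one row each."""
    with open(path, "w") as fh:
        fh.write(_header(stage, params_hash))
        fh.write("pool_id\tclone_id\n")
        for pool, clone in sorted(hyb.positives):
            fh.write(f"{pool}\t{clone}\n")


def read_hyb_file(path, pool_universe, clone_universe) -> HybMatrix:
    positives = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("pool_id\t"):
                continue
            pool, clone = line.split("\t")
            positives.add((pool, clone))
    return HybMatrix(positives, set(pool_universe), set(clone_universe))


def write_pool_design(path, design: PoolDesign, stage="pools", params_hash="-") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params_hash))
        fh.write("probe_id\trow\tcol\tlayer\tpool_ids\n")
        for probe in sorted(design.coordinates):
            r, c, l = design.coordinates[probe]
            pools = ",".join(design.pools_of(probe))
            fh.write(f"{probe}\t{r}\t{c}\t{l}\t{pools}\n")


def write_contig_file(path, build: ContigBuild, stage="assemble", params_hash="-") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params_hash))
        fh.write("clone_id\tcontig_id\torder_index\toffset_cb\tq_flag\n")
        for ctg in build.contigs:
            flags = ctg.q_flags or [False] * ctg.n_clones
            for k, (clone, off, q) in enumerate(zip(ctg.clones, ctg.offsets, flags)):
                fh.write(f"{clone}\t{ctg.contig_id}\t{k}\t{off}\t{int(q)}\n")
        for clone in build.singletons:
            fh.write(f"{clone}\tsingleton\t0\t0\t0\n")


def write_mtp_file(path, paths, stage="mtp", params_hash="-") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params_hash))
        fh.write("contig_id\trank\tclone_id\toverlap_cb\n")
        for p in paths:
            for k, clone in enumerate(p.clones):
                ov = p.overlaps_cb[k - 1] if k else ""
                fh.write(f"{p.contig_id}\t{k}\t{clone}\t{ov}\n")


def write_hits_file(path, decon, stage="pools", params_hash="-") -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params_hash))
        fh.write("probe_id\tclone_id\tstatus\n")
        for a in sorted(decon.assignments, key=lambda a: (a.probe_id, a.clone_id)):
            fh.write(f"{a.probe_id}\t{a.clone_id}\t{a.status}\n")


def write_json(path, obj, stage="stats", params_hash="-") -> None:
    payload = {"stage": stage, "params": params_hash, "data": obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    return [
        (rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fasta(path, records) -> None:
    """records: iterable of (id, sequence)."""
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seq_records, str(path), "fasta")


def write_ssr_bed(path, calls, stage="bes", params_hash="-") -> None:
    """SSR calls as BED (0-based half-open; name = motif:copies)."""
    with open(path, "w") as fh:
        fh.write(_header(stage, params_hash))
        for c in sorted(calls, key=lambda c: (c.bes_id, c.start, c.unit_length)):
            fh.write(f"{c.bes_id}\t{c.start}\t{c.end}\t{c.motif}:{c.copies}\n")
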