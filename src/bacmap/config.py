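"""Pipeline configuration.

Defaults are the published mapping parameters: tolerance 3, cutoffs
1e-50 (initial) / 1e-35 (stepped-merge endpoint) / 1e-20 (manual),
DQer threshold 10%, 41 shared bands for a matched clone, 5x5x5 pools,
kb-per-band 128/81.1 and a 300 Mb genome.  The ``sim_*`` block sizes
the bundled synthetic demo (a 3 Mb, 7-linkage-group genome).  Any
override against the defaults is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import yaml

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome_size_mb: float = 300.0
    tolerance: int = 3
    gellen_G: int = 30000
    cutoff_initial: float = 1e-50
    cutoff_final: float = 1e-35
    cutoff_manual: float = 1e-20
    step_factor: float = 1e-5
    dq_threshold: float = 0.10
    min_shared_bands: int = 41
    min_matched_clones_first: int = 3
    min_matched_clones_second: int = 2
    min_matched_with_marker: int = 2
    end_window: int = 5
    kb_per_band: float = 128.0 / 81.1
    pool_dims: tuple[int, int, int] = (5, 5, 5)
    mtp_min_overlap_cb: int = 3
    ssr_min_copies: dict = field(default_factory=lambda: {2: 5, 3: 4, 4: 3, 5: 3})
    bes_phred_min: int = 20
    bes_window_len: int = 100
    bes_max_n_frac: float = 0.05
    exclude_clones: list = field(default_factory=list)
    seed: int = 0
    # synthetic demo block
    sim_genome_length: int = 3_000_000
    sim_n_linkage_groups: int = 7
    sim_site_rate: float = 81.1 / 128_000.0
    sim_n_markers: int = 20
    sim_clones_per_library: int = 250
    sim_sizing_error: float = 0.05
    sim_band_dropout: float = 0.02
    sim_spurious_rate: float = 1.0
    sim_pool_false_pos: float = 0.0
    sim_pool_false_neg: float = 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pool_dims"] = list(self.pool_dims)
        d["ssr_min_copies"] = {str(k): v for k, v in self.ssr_min_copies.items()}
        return d

    def params_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        defaults = cls()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                value = data[f.name]
                if f.name == "pool_dims":
                    value = tuple(value)
                if f.name == "ssr_min_copies":
                    value = {int(k): v for k, v in value.items()}
                if value != getattr(defaults, f.name):
                    log.info("config override: %s = %r", f.name, value)
                kwargs[f.name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
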