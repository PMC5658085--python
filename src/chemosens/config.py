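"""Pipeline configuration with defaults matching the published procedure:
75/25 stratified split, +/-0.5 SD indeterminate band, 100-feature elimination
blocks, and a 10-feature floor."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class PipelineConfig:
    drug: str = ""
    C: float = 1.0
    split_fraction: float = 0.75
    split_seed: int = 0
    band_sd: float = 0.5
    feature_floor: int = 10
    block_size: int = 100
    probe_filter: tuple[str, ...] | None = None
    gene_collapse: str = "off"  # off | mean
    reference_mode: str = "rank-mean"  # rank-mean | probe-mean
    allow_nonpaper: bool = False

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.band_sd < 0:
            raise ValueError("band_sd must be non-negative")
        if self.gene_collapse not in ("off", "mean"):
            raise ValueError("gene_collapse must be 'off' or 'mean'")
        if self.reference_mode not in ("rank-mean", "probe-mean"):
            raise ValueError("reference_mode must be 'rank-mean' or 'probe-mean'")
        if not self.allow_nonpaper:
            # guard the published procedure's constants against silent drift
            if self.feature_floor < 10:
                raise ValueError(
                    "feature_floor < 10 departs from the published procedure; "
                    "pass allow_nonpaper=True to override"
                )
            if self.block_size < 1:
                raise ValueError("block_size must be at least 1")
        if self.probe_filter is not None:
            object.__setattr__(self, "probe_filter", tuple(map(str, self.probe_filter)))

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["probe_filter"] is not None:
            d["probe_filter"] = list(d["probe_filter"])
        return d

    def fingerprint(self) -> str:
        """Short stable digest of the configuration, stored in model files."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
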