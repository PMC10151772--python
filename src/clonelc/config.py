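"""Analysis configuration.

All thresholds used by the clonality classification, identical-clone merge,
germline assignment and clinical concordance steps live here, with the
defaults the pipeline was designed around. Values can be overridden from a
YAML mapping (flat key: value pairs).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger("clonelc")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds for the light-chain clonality pipeline.

    Fractions are of combined IGK+IGL ("LC") counts unless noted.
    """

    # clonality categories
    cat1_min_fraction: float = 0.95    # Category 1: major clone >= this (inclusive)
    cat3_max_second: float = 0.05      # Category 3: second clone < this (strict)
    major_min_fraction: float = 0.50   # a "major" clone: fraction > this (strict)
    biclonal_min_share: float = 0.10   # biclonal flag: top two each > this (strict)

    # identical-clone merge (Category 2)
    merge_secondary_min_count: int = 100     # secondary eligibility (inclusive)
    merge_secondary_min_share: float = 0.01  # secondary share of LC counts (strict)
    merge_min_overlap: int = 200             # nt, 100% identity required
    merge_min_combined_fraction: float = 0.95
    min_reportable_overlap: int = 16         # below this, "no overlap"

    # germline best-hit local alignment
    align_match: int = 1
    align_mismatch: int = -2
    align_gap_open: int = -4
    align_gap_extend: int = -1
    v_min_aligned: int = 100        # nt aligned for a V call
    v_min_identity: float = 0.85

    # support / clinical
    low_support_count: int = 1000   # advisory: major clone counts below this
    flc_ratio_low: float = 0.26     # kappa/lambda FLC reference range
    flc_ratio_high: float = 1.65

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


DEFAULT_CONFIG = AnalysisConfig()
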