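"""Run configuration: seeds, paths and the statistical convention switches.

Every convention flag defaults to the choice under which the package's
reference analyses reproduce from the printed summary tables; each is
documented at its point of use in the stats/scoring modules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "taphomark_out"
    # input paths (populated by the simulate stage when absent)
    profiles_path: str | None = None
    responses_path: str | None = None
    answer_key_path: str | None = None
    indentations_path: str | None = None
    # convention flags
    mann_whitney_continuity: bool = True
    wilcoxon_continuity: bool = False
    cv_ddof: int = 1                    # sample sd in measures 5-7
    pca_standardize: bool = True        # correlation-matrix PCA
    vickers_variant: str = "paper"      # F/D^2; "standard" adds the 1.8544 factor
    round_percent: bool = True          # integer percentages in table tests
    # simulation sizes
    n_marks_per_group: int = 40
    transects_per_mark: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
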