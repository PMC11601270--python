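"""YAML configuration for the command-line pipeline.

One file holds every tunable: scan window caps, Monte Carlo settings,
epoch geometry, levels and age strata, thresholds and seeds.  Keys not
present fall back to package defaults.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .geo import AGE_GROUPS, LEVELS
from .scan import ScanParams
from .synthetic import BaselineSpec, GeographySpec


@dataclass
class SurveillanceConfig:
    scan: ScanParams = field(default_factory=ScanParams)
    geography: GeographySpec = field(default_factory=GeographySpec)
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    levels: tuple[str, ...] = LEVELS
    age_groups: tuple[str, ...] = AGE_GROUPS
    epoch_len: int = 24
    step: int = 1
    study_start: str = "2015-01"
    n_months: int = 90
    jaccard_threshold: float = 0.5
    suppression_threshold: int = 5
    seed: int = 0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["levels"] = list(self.levels)
        d["age_groups"] = list(self.age_groups)
        return yaml.safe_dump(d, sort_keys=True)


def load_config(path) -> SurveillanceConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SurveillanceConfig()
    if "scan" in raw:
        cfg.scan = ScanParams(**raw["scan"])
    if "geography" in raw:
        cfg.geography = GeographySpec(**raw["geography"])
    if "baseline" in raw:
        cfg.baseline = BaselineSpec(**raw["baseline"])
    for key in ("epoch_len", "step", "study_start", "n_months",
                "jaccard_threshold", "suppression_threshold", "seed"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "levels" in raw:
        cfg.levels = tuple(raw["levels"])
    if "age_groups" in raw:
        cfg.age_groups = tuple(raw["age_groups"])
    return cfg
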