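"""Run configuration: every constant that enters a formula, in one place.

The config is echoed (with its hash) into every report so a run is fully
reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cutpoints import CountParams
from .forest import ForestConfig


@dataclass
class RunConfig:
    n_subjects: int = 31
    train_fraction: float = 21 / 31
    duration_min: float = 20.0
    rate_hz: float = 100.0
    epoch_s: float = 15.0
    seed: int = 1
    # CARS banding thresholds: score < sed_upper -> SED, >= mvpa_lower -> MVPA
    cars_sed_upper: float = 2.0
    cars_mvpa_lower: float = 3.0
    max_out_of_view_s: float = 0.0
    kappa_weights: str = "linear"        # linear | quadratic
    equivalence_alpha: float = 0.05
    bound_sd_multiplier: float = 0.5
    cutpoint_names: tuple[str, ...] = ()  # empty = all eight
    forest: ForestConfig = field(default_factory=ForestConfig)
    counts: CountParams = field(default_factory=CountParams)
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cutpoint_names"] = list(self.cutpoint_names)
        d["forest"]["labels"] = list(self.forest.labels)
        d["counts"] = self.counts.as_dict()
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "forest" in d:
            f = dict(d["forest"])
            if "labels" in f:
                f["labels"] = tuple(f["labels"])
            d["forest"] = ForestConfig(**f)
        if "counts" in d:
            c = dict(d["counts"])
            if "passband_hz" in c:
                c["passband_hz"] = tuple(c["passband_hz"])
            d["counts"] = CountParams(**c)
        if "cutpoint_names" in d:
            d["cutpoint_names"] = tuple(d["cutpoint_names"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
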