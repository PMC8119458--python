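"""YAML configuration mirroring the tunable constants.

Every named constant of the energy model and the annealing protocol is
an overridable key with its standard value as default; a config file
only needs the keys it changes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .energy_bb import ScalingConfig
from .energy_local import ClashParams, InternalParams
from .nutree import AnnealSchedule


@dataclass
class BriqConfig:
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    clash: ClashParams = field(default_factory=ClashParams)
    internal: InternalParams = field(default_factory=InternalParams)
    schedule: AnnealSchedule = field(
        default_factory=AnnealSchedule.refinement
    )
    codebook_size: int = 2000
    n_clusters: int = 80

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "scaling": asdict(self.scaling),
            "clash": asdict(self.clash),
            "internal": asdict(self.internal),
            "schedule": asdict(self.schedule),
            "codebook_size": self.codebook_size,
            "n_clusters": self.n_clusters,
        }, sort_keys=False)


def load_config(path=None, mode: str = "refine") -> BriqConfig:
    base_schedule = (AnnealSchedule.refinement() if mode == "refine"
                     else AnnealSchedule.prediction())
    cfg = BriqConfig(schedule=base_schedule)
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "scaling" in data:
        cfg.scaling = ScalingConfig(**{**asdict(cfg.scaling),
                                       **data["scaling"]})
    if "clash" in data:
        cfg.clash = ClashParams(**{**asdict(cfg.clash), **data["clash"]})
    if "internal" in data:
        cfg.internal = InternalParams(**{**asdict(cfg.internal),
                                         **data["internal"]})
    if "schedule" in data:
        cfg.schedule = AnnealSchedule(**{**asdict(cfg.schedule),
                                         **data["schedule"]})
    cfg.codebook_size = data.get("codebook_size", cfg.codebook_size)
    cfg.n_clusters = data.get("n_clusters", cfg.n_clusters)
    return cfg
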