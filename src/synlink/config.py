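"""Single run configuration shared by every pipeline stage.

Defaults encode the analysis constants: dead-plate threshold at a 90th
percentile of 2000 RFU, CI cap 5, CI class cutoffs {0.3, 0.85, 1}, LOD
peak threshold 3, plus the generator's desk-scale defaults (40 nuclear
families of 2–4 children, 4 chromosomes x 60 markers at 2 cM).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int

    # plate QC
    cv_threshold: float = 0.3
    plate_rfu_threshold: float = 2000.0
    resid_threshold: float = 3.0
    max_iter: int = 10
    eps: float = 0.005

    # synergy
    ci_cap: float = 5.0
    ci_strong_max: float = 0.3
    ci_weak_min: float = 0.85
    ci_additive: float = 1.0

    # linkage
    grid_step_cM: float = 1.0
    lod_threshold: float = 3.0
    min_sib_pairs: int = 20

    # generator
    n_families: int = 40
    children_low: int = 2
    children_high: int = 4
    n_chromosomes: int = 4
    markers_per_chromosome: int = 60
    marker_spacing_cM: float = 2.0
    n_doses: int = 6
    n_quadruplicate: int = 4
    n_runs: int = 2
    drug1: str = "drugA"
    drug2: str = "drugB"
    dm1: float = 4.0
    m1: float = 1.5
    dm2: float = 1.0
    m2: float = 2.0
    dm_cv: float = 0.3
    vehicle_level: float = 10000.0
    negative_level: float = 500.0
    noise_sd: float = 150.0
    deviant_rate: float = 0.02
    dead_plate_rate: float = 0.02
    target_h2: float = 0.3
    qtl_fraction: float = 1.0
    qtl_chromosome: int = 2
    qtl_position_cM: float = 60.0
    ci_range_low: float = 0.3
    ci_range_high: float = 2.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory in the run configuration")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in data:
            raise ValueError(f"{path}: config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
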