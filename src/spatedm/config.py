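"""Run configuration: the analysis constants in one validated place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Tunable constants of the full pipeline.

    Defaults follow the survey analysis this package operationalises:
    embedding dimensions 1..10 scanned by simplex projection, S-map
    nonlinearity theta tuned over 0..8, CCM lags 0..8 biquarterly steps
    (0..4 on the yearly grid), 200 CCM replicates with the 95% pass rule at
    alpha 0.05, S-map significance gate at alpha 0.10, and at least 10
    surveyed grid cells per retained quarter.
    """

    E_max: int = 10
    theta_grid: tuple = (0, 1, 2, 3, 4, 5, 6, 7, 8)
    lag_max_quarterly: int = 8
    lag_max_yearly: int = 4
    n_ccm_replicates: int = 200
    ccm_pass_fraction: float = 0.95
    alpha_ccm: float = 0.05
    alpha_smap: float = 0.10
    alpha_trend: float = 0.05
    min_grids: int = 10
    L_grid_size: int = 15
    max_sensitivity_models: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.E_max < 2:
            raise ValidationError("E_max must be >= 2")
        if self.n_ccm_replicates < 1:
            raise ValidationError("n_ccm_replicates must be >= 1")
        for name in ("ccm_pass_fraction", "alpha_ccm", "alpha_smap", "alpha_trend"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.L_grid_size < 3:
            raise ValidationError("L_grid_size must be >= 3")
        if any(t < 0 for t in self.theta_grid):
            raise ValidationError("theta values must be >= 0")
        if self.lag_max_quarterly < 0 or self.lag_max_yearly < 0:
            raise ValidationError("lag maxima must be >= 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["theta_grid"] = list(d["theta_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "theta_grid" in raw:
            raw["theta_grid"] = tuple(raw["theta_grid"])
        return cls(**raw)
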