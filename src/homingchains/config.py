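"""Run configuration for the end-to-end synthetic reproduction pipeline.

All defaults mirror the study constants: an 8.4 km beeline, 1 Hz sampling,
800 m / 200 m exclusion radii, a 250 m pairing proximity threshold, weight
grids in steps of 0.01, five generations, and 10,000 bootstrap runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geo import SiteGeometry
from .strategies import STRATEGY_NAMES
from .synth import SyntheticConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproduction run needs, explicit seeds included."""

    seed: int = 1
    n_birds: int = 9
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    strategies: tuple[str, ...] = STRATEGY_NAMES
    reference_strategy: str = "averaging"
    chain_mode: str = "sample"           # "exhaustive" or "sample"
    n_chains: int = 500                  # per strategy, sample mode
    fit_n_chains: int = 300              # chains used while fitting weights
    grid_step: float = 0.01
    max_flock_n: int | None = None       # defaults to n_birds
    n_boot: int = 10_000
    release_excl_m: float = 800.0
    home_excl_m: float = 200.0

    def __post_init__(self) -> None:
        unknown = set(self.strategies) - set(STRATEGY_NAMES)
        if unknown:
            raise ValueError(
                f"unknown strategy name(s) {sorted(unknown)}; "
                f"valid names: {list(STRATEGY_NAMES)}"
            )
        if self.reference_strategy not in self.strategies:
            raise ValueError("reference_strategy must be among strategies")
        if self.chain_mode not in ("exhaustive", "sample"):
            raise ValueError("chain_mode must be 'exhaustive' or 'sample'")

    def geometry(self) -> SiteGeometry:
        return SiteGeometry(
            release=(0.0, self.synthetic.beeline_m),
            home=(0.0, 0.0),
            release_excl_m=self.release_excl_m,
            home_excl_m=self.home_excl_m,
        )

    def with_seed(self, seed: int) -> "RunConfig":
        from dataclasses import replace

        return replace(
            self, seed=seed, synthetic=SyntheticConfig(
                **{**asdict(self.synthetic), "seed": seed}
            )
        )

    # -- plain-text round trip -------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["strategies"] = list(self.strategies)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "strategies" in d:
            d["strategies"] = tuple(d["strategies"])
        return cls(**d)
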