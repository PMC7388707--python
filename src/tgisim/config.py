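"""Run configuration: a JSON-serializable record sufficient to reproduce a run."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import PopulationParams
from .pk import PKParams
from .tumor import DEMO_DELAY, DEMO_TRANSIT, DelayParams, TumorParams

__all__ = ["RunConfig", "load_config", "tumor_params_from_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on.

    A run directory's config echo (``config.json``) plus the seed reproduce
    the run bit-exactly.
    """

    model: str = "transit"  # "transit" | "dde"
    half_life_days: float = 6.9
    concentration_scale: float = 1.0
    tumor: dict = field(default_factory=lambda: DEMO_TRANSIT.to_dict())
    regimens: tuple[str, ...] = ()  # empty = all seven
    horizons: tuple[float, ...] = (20.0, 50.0)
    t_end: float = 50.0
    anchor: float = 2.433
    omega: dict = field(default_factory=lambda: {"lambda0": 0.2, "k2": 0.2, "w0": 0.2})
    sigma_add: float = 5.0
    sigma_prop: float = 0.1
    n_control: int = 21
    n_treated: int = 19
    n_replicates: int = 20
    seed: int = 0
    out_dir: str = "tgisim_out"
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.model not in ("transit", "dde"):
            raise ValueError(f"model must be 'transit' or 'dde', got {self.model!r}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["regimens"] = list(self.regimens)
        d["horizons"] = list(self.horizons)
        return json.dumps(d, indent=2, sort_keys=True) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "regimens" in d:
            d["regimens"] = tuple(d["regimens"])
        if "horizons" in d:
            d["horizons"] = tuple(float(h) for h in d["horizons"])
        return cls(**d)

    @property
    def pk(self) -> PKParams:
        return PKParams(self.half_life_days, self.concentration_scale)

    @property
    def population(self) -> PopulationParams:
        return PopulationParams(
            theta=tumor_params_from_config(self),
            omega=dict(self.omega),
            sigma_add=self.sigma_add,
            sigma_prop=self.sigma_prop,
            seed=self.seed,
        )


def tumor_params_from_config(config: RunConfig) -> TumorParams | DelayParams:
    base = dict((DEMO_TRANSIT if config.model == "transit" else DEMO_DELAY).to_dict())
    base.update(config.tumor or {})
    if config.model == "transit":
        base.pop("tau", None)
        return TumorParams(**base)
    base.pop("k1", None)
    base.pop("n_transit", None)
    return DelayParams(**base)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(json.loads(Path(path).read_text()))
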