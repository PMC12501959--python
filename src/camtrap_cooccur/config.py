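"""Run configuration shared by the CLI subcommands and analysis drivers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from camtrap_cooccur.data_model import DEFAULT_PRIORITY, FOCAL_SPECIES


@dataclass
class RunConfig:
    """One config drives all pipeline stages; CLI flags override fields."""

    events_path: str = "events.csv"
    stations_path: str = "stations.csv"
    output_dir: str = "results"
    species: list[str] = field(default_factory=lambda: list(FOCAL_SPECIES))
    window_minutes: float = 30.0
    min_detections: int = 11
    occasion_days: int = 10
    grazing_season: tuple[tuple[int, int], tuple[int, int]] = ((5, 1), (9, 30))
    candidate_covariates: list[str] | None = None   # None: all screened survivors
    priority: list[str] = field(default_factory=lambda: list(DEFAULT_PRIORITY))
    n_starts: int = 5
    n_sim: int = 1000
    n_boot: int = 1000
    n_perm: int = 999
    estimator: str = "dhat4"
    conditioning_mode: str = "pairwise"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("occasion_days", "n_starts", "n_sim", "n_boot", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grazing_season" in raw:
            raw["grazing_season"] = tuple(tuple(x) for x in raw["grazing_season"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["grazing_season"] = [list(x) for x in self.grazing_season]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def write_table(df: pd.DataFrame, path, config: RunConfig, index: bool = False) -> None:
    """Write a result CSV with a provenance header comment (config hash and
    seed); read back with ``pd.read_csv(path, comment='#')``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.hash()} seed={config.seed}\n")
        df.to_csv(fh, index=index, na_rep="")
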