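"""Structured run configuration (JSON canonical, YAML accepted).

A config file holds blocks: ``rates``, ``init``, ``sim``, ``dose_sweep``,
``rate_sweep``, ``microcolony``, ``assay``.  Two profiles are shipped:
``paper`` (200,000 s horizon, 10 replicates, 58 colonies — the study
conditions) and ``desk`` (reduced horizon and replication for quick runs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .engine import SimConfig
from .microcolony import MicrocolonyParams
from .network import ConfigurationError, InitConfig, RateSet
from .sweeps import default_init_config, default_rates

__all__ = ["RunConfig", "load_config", "save_config", "PROFILES"]

PROFILES = {
    "paper": {
        "sim": {"t_end": 200_000.0, "burn_in": 10_000.0, "record_mode": "grid",
                "grid_step": 5.0},
        "dose_sweep": {"levels": [0.003, 0.3, 3.0], "replicates": 10},
        "rate_sweep": {"factor": 10.0, "replicates": 10},
        "microcolony": {"n_colonies": 58},
        "assay": {"cells_per_rep": 500, "replicates": 5},
    },
    "desk": {
        "sim": {"t_end": 50_000.0, "burn_in": 5_000.0, "record_mode": "grid",
                "grid_step": 5.0},
        "dose_sweep": {"levels": [0.003, 0.3, 3.0], "replicates": 3},
        "rate_sweep": {"factor": 10.0, "replicates": 3},
        "microcolony": {"n_colonies": 20},
        "assay": {"cells_per_rep": 500, "replicates": 5},
    },
}


@dataclass
class RunConfig:
    rates: RateSet
    init: InitConfig
    sim: SimConfig
    dose_levels: list
    dose_replicates: int
    sweep_factor: float
    sweep_replicates: int
    microcolony: MicrocolonyParams
    n_colonies: int
    assay_cells: int
    assay_replicates: int

    @classmethod
    def from_profile(cls, profile: str = "desk", seed: int = 0) -> "RunConfig":
        if profile not in PROFILES:
            raise ConfigurationError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        p = PROFILES[profile]
        return cls(
            rates=default_rates(),
            init=default_init_config(),
            sim=SimConfig(seed=seed, **p["sim"]),
            dose_levels=list(p["dose_sweep"]["levels"]),
            dose_replicates=p["dose_sweep"]["replicates"],
            sweep_factor=p["rate_sweep"]["factor"],
            sweep_replicates=p["rate_sweep"]["replicates"],
            microcolony=MicrocolonyParams(),
            n_colonies=p["microcolony"]["n_colonies"],
            assay_cells=p["assay"]["cells_per_rep"],
            assay_replicates=p["assay"]["replicates"],
        )

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(),
            "init": self.init.to_dict(),
            "sim": self.sim.to_dict(),
            "dose_sweep": {"levels": self.dose_levels,
                           "replicates": self.dose_replicates},
            "rate_sweep": {"factor": self.sweep_factor,
                           "replicates": self.sweep_replicates},
            "microcolony": {**asdict(self.microcolony),
                            "n_colonies": self.n_colonies},
            "assay": {"cells_per_rep": self.assay_cells,
                      "replicates": self.assay_replicates},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        mc = dict(d.get("microcolony", {}))
        n_colonies = mc.pop("n_colonies", 58)
        base = cls.from_profile("paper")
        return cls(
            rates=RateSet.from_dict(d["rates"]) if "rates" in d else base.rates,
            init=InitConfig.from_dict(d["init"]) if "init" in d else base.init,
            sim=SimConfig.from_dict(d["sim"]) if "sim" in d else base.sim,
            dose_levels=list(d.get("dose_sweep", {}).get("levels", base.dose_levels)),
            dose_replicates=d.get("dose_sweep", {}).get("replicates",
                                                        base.dose_replicates),
            sweep_factor=d.get("rate_sweep", {}).get("factor", base.sweep_factor),
            sweep_replicates=d.get("rate_sweep", {}).get("replicates",
                                                         base.sweep_replicates),
            microcolony=MicrocolonyParams(**mc) if mc else MicrocolonyParams(),
            n_colonies=n_colonies,
            assay_cells=d.get("assay", {}).get("cells_per_rep", 500),
            assay_replicates=d.get("assay", {}).get("replicates", 5),
        )


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return RunConfig.from_dict(yaml.safe_load(text))
    return RunConfig.from_dict(json.loads(text))


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))
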