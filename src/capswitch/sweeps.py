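"""In-silico experiments over the growth-capsulation network.

Two sweeps mirror the model analyses:

* the UXP dose sweep — simulate CAP trajectories at UXP production rates
  spanning a 1,000-fold range (defaults 0.003 / 0.3 / 3 molecules/s:
  switcher, intermediate, ancestor-like conditions);
* the one-at-a-time rate sensitivity sweep — each of the 23 rate constants
  is multiplied and divided by 10 (plus the baseline: 47 conditions), with
  several replicate simulations per condition, summarised as the fraction
  of time in the Cap- state and per-condition mean cumulative occupancy
  curves.

Seed policy: every (condition, replicate) derives its simulation and
initial-condition streams from the master seed through
``numpy.random.SeedSequence(master, spawn_key=(condition, replicate))``, so
conditions are independent but the whole table is reproducible.

``calibrate_defaults`` certifies (or searches for) a rate set meeting the
qualitative regime targets the model is built around; the shipped default
rates in ``data/default_rates.json`` are one certified set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import SimConfig, Trajectory, simulate
from .network import (ConfigurationError, InitConfig, RATE_NAMES, RateSet,
                      build_growth_capsulation_network, initialize_state,
                      perturb_rate)
from .phenotype import (classify_states, cumulative_occupancy_curve,
                        occupancy_summary)

__all__ = [
    "default_rates",
    "default_init_config",
    "DoseSweepConfig",
    "SweepTable",
    "CalibrationTargets",
    "CalibrationError",
    "run_dose_sweep",
    "run_sensitivity_sweep",
    "calibrate_defaults",
    "condition_seed",
]


def _load_default_blob() -> dict:
    with resources.files("capswitch.data").joinpath("default_rates.json").open() as fh:
        return json.load(fh)


def default_rates() -> RateSet:
    """The shipped calibrated default rate constants."""
    return RateSet.from_dict(_load_default_blob()["rates"])


def default_init_config() -> InitConfig:
    return InitConfig.from_dict(_load_default_blob()["init"])


def condition_seed(master_seed: int, condition: int, replicate: int
                   ) -> Tuple[int, np.random.Generator]:
    """Derived (simulation seed, init-state generator) for one run."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(condition, replicate))
    sim_ss, init_ss = ss.spawn(2)
    sim_seed = int(sim_ss.generate_state(1, np.uint32)[0])
    return sim_seed, np.random.default_rng(init_ss)


@dataclass
class SweepTable:
    """Per-run rows plus per-condition aggregates and occupancy curves."""

    runs: pd.DataFrame
    aggregated: pd.DataFrame
    curves: Dict[str, np.ndarray] = field(default_factory=dict)
    failures: List[Tuple[str, str]] = field(default_factory=list)

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(f"{prefix}_runs.tsv", sep="\t", index=False)
        self.aggregated.to_csv(f"{prefix}_conditions.tsv", sep="\t", index=False)
        for label, curve in self.curves.items():
            safe = label.replace("/", "_")
            np.savetxt(f"{prefix}_curve_{safe}.tsv", curve, delimiter="\t",
                       header="level\tcumulative_seconds", comments="")
        manifest = {
            "conditions": self.aggregated["condition"].tolist(),
            "n_runs": int(len(self.runs)),
            "failures": self.failures,
        }
        Path(f"{prefix}_manifest.json").write_text(json.dumps(manifest, indent=1))


def _run_one(rates: RateSet, sim: SimConfig, init_cfg: InitConfig,
             master_seed: int, condition: int, replicate: int):
    sim_seed, init_rng = condition_seed(master_seed, condition, replicate)
    init = initialize_state(init_cfg, init_rng)
    net = build_growth_capsulation_network(rates)
    traj = simulate(net, init, replace(sim, seed=sim_seed))
    segs = classify_states(traj)
    summ = occupancy_summary(segs, traj)
    return traj, segs, summ, sim_seed


def _row(label: str, rate_name: str, factor: float, replicate: int,
         sim_seed: int, summ) -> dict:
    return {
        "condition": label,
        "rate_name": rate_name,
        "factor": factor,
        "replicate": replicate,
        "seed": sim_seed,
        "fraction_cap_low": summ.fraction_cap_low,
        "n_switches": summ.n_switches,
        "mean_dwell_low_s": summ.mean_dwell_low_s,
        "mean_dwell_high_s": summ.mean_dwell_high_s,
        "mean_cap_low": summ.mean_cap_low,
        "mean_cap_high": summ.mean_cap_high,
        "threshold": summ.threshold,
    }


def _aggregate(runs: pd.DataFrame) -> pd.DataFrame:
    # mean is the primary replicate aggregate; medians reported for robustness
    g = runs.groupby("condition", sort=False)
    agg = g.agg(
        rate_name=("rate_name", "first"),
        factor=("factor", "first"),
        n_replicates=("replicate", "count"),
        mean_fraction_cap_low=("fraction_cap_low", "mean"),
        median_fraction_cap_low=("fraction_cap_low", "median"),
        mean_n_switches=("n_switches", "mean"),
        median_n_switches=("n_switches", "median"),
        two_state_fraction=("fraction_cap_low",
                            lambda s: float(np.mean((s > 0) & (s < 1)))),
    ).reset_index()
    return agg


# ---------------------------------------------------------------------------
# dose sweep
# ---------------------------------------------------------------------------


@dataclass
class DoseSweepConfig:
    """UXP dose-response sweep settings (defaults: the 1,000-fold triple)."""

    levels: Sequence[float] = (0.003, 0.3, 3.0)
    replicates: int = 3
    base_rates: Optional[RateSet] = None
    sim: SimConfig = field(default_factory=SimConfig)
    init: Optional[InitConfig] = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not all(l > 0 for l in self.levels):
            raise ConfigurationError("UXP levels must be positive")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.base_rates is None:
            self.base_rates = default_rates()
        if self.init is None:
            self.init = default_init_config()


def run_dose_sweep(config: DoseSweepConfig) -> SweepTable:
    """Simulate, classify and summarise at each UXP production level."""
    rows = []
    failures: List[Tuple[str, str]] = []
    curves: Dict[str, np.ndarray] = {}
    for ci, level in enumerate(config.levels):
        label = f"uxp_{level:g}"
        rates = config.base_rates.replace(k_uxp_prod=float(level))
        per_rep_curves = []
        for rep in range(config.replicates):
            try:
                traj, segs, summ, sim_seed = _run_one(
                    rates, config.sim, config.init, config.master_seed, ci, rep)
            except Exception as exc:  # pragma: no cover - propagated context
                raise type(exc)(f"[condition {label} replicate {rep}] {exc}") from exc
            rows.append(_row(label, "k_uxp_prod", float(level), rep, sim_seed, summ))
            per_rep_curves.append(traj)
        curves[label] = _mean_curve(per_rep_curves)
    runs = pd.DataFrame(rows)
    return SweepTable(runs=runs, aggregated=_aggregate(runs), curves=curves,
                      failures=failures)


def _mean_curve(trajs: Sequence[Trajectory], n_levels: int = 201) -> np.ndarray:
    """Mean cumulative-occupancy curve over replicate trajectories."""
    cap_max = max(int(t.series("CA").max()) for t in trajs)
    levels = np.unique(np.round(np.linspace(0, max(cap_max, 1), n_levels)))
    stacked = np.stack([
        cumulative_occupancy_curve(t, levels)[:, 1] for t in trajs])
    return np.column_stack([levels, stacked.mean(axis=0)])


# ---------------------------------------------------------------------------
# sensitivity sweep
# ---------------------------------------------------------------------------


def sensitivity_conditions(factor: float = 10.0
                           ) -> List[Tuple[str, Optional[str], float]]:
    """The 47 one-at-a-time conditions: baseline + each rate x10 and /10."""
    conds: List[Tuple[str, Optional[str], float]] = [("baseline", None, 1.0)]
    for name in RATE_NAMES:
        conds.append((f"{name}_x{factor:g}", name, factor))
        conds.append((f"{name}_x{1 / factor:g}", name, 1.0 / factor))
    return conds


def run_sensitivity_sweep(base: Optional[RateSet] = None, factor: float = 10.0,
                          replicates: int = 10,
                          sim: Optional[SimConfig] = None,
                          init: Optional[InitConfig] = None,
                          master_seed: int = 0,
                          with_curves: bool = True) -> SweepTable:
    """One-at-a-time +/-10x sensitivity sweep over all 23 rate constants.

    47 conditions x *replicates* simulations.  Per-condition failures are
    recorded in ``SweepTable.failures`` and the sweep continues.
    """
    base = base if base is not None else default_rates()
    sim = sim if sim is not None else SimConfig()
    init = init if init is not None else default_init_config()
    conds = sensitivity_conditions(factor)
    rows = []
    curves: Dict[str, np.ndarray] = {}
    failures: List[Tuple[str, str]] = []
    for ci, (label, name, f) in enumerate(conds):
        rates = base if name is None else perturb_rate(base, name, f)
        trajs = []
        for rep in range(replicates):
            try:
                traj, segs, summ, sim_seed = _run_one(
                    rates, sim, init, master_seed, ci, rep)
            except Exception as exc:
                failures.append((label, f"replicate {rep}: {exc}"))
                continue
            rows.append(_row(label, name or "baseline", f, rep, sim_seed, summ))
            trajs.append(traj)
        if with_curves and trajs:
            curves[label] = _mean_curve(trajs)
    runs = pd.DataFrame(rows)
    return SweepTable(runs=runs, aggregated=_aggregate(runs), curves=curves,
                      failures=failures)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class CalibrationError(RuntimeError):
    def __init__(self, message: str, report: Optional[dict] = None):
        super().__init__(message)
        self.report = report


@dataclass
class CalibrationTargets:
    """Qualitative regime targets a default rate set must meet.

    At the low UXP dose the network must be genuinely bimodal (both states
    occupied, multi-hour heritable dwells); at the high dose CAP must stay
    basal (at most one threshold crossing per window).  Medians are taken
    over ``n_seeds`` independent runs.
    """

    low_dose: float = 0.003
    high_dose: float = 3.0
    min_state_occupancy: float = 0.10
    min_mean_dwell_s: float = 7200.0     # 2 h ~ 2 division-equivalents
    max_switches_high: float = 1.0
    min_switches_low: float = 2.0
    n_seeds: int = 5


def _regime_metrics(rates: RateSet, dose: float, sim: SimConfig,
                    init_cfg: InitConfig, master_seed: int, n_seeds: int,
                    condition: int) -> dict:
    doses = rates.replace(k_uxp_prod=dose)
    occ_low, occ_high, dwl, dwh, sw = [], [], [], [], []
    for rep in range(n_seeds):
        _, _, summ, _ = _run_one(doses, sim, init_cfg, master_seed, condition, rep)
        occ_low.append(summ.fraction_cap_low)
        occ_high.append(summ.fraction_cap_high)
        dwl.append(summ.mean_dwell_low_s)
        dwh.append(summ.mean_dwell_high_s)
        sw.append(summ.n_switches)
    def med(x):
        arr = np.asarray(x, dtype=float)
        arr = arr[~np.isnan(arr)]
        return float(np.median(arr)) if arr.size else float("nan")
    return {
        "dose": dose,
        "median_fraction_cap_low": med(occ_low),
        "median_fraction_cap_high": med(occ_high),
        "median_mean_dwell_low_s": med(dwl),
        "median_mean_dwell_high_s": med(dwh),
        "median_n_switches": med(sw),
    }


def check_targets(rates: RateSet, targets: CalibrationTargets,
                  sim: Optional[SimConfig] = None,
                  init_cfg: Optional[InitConfig] = None,
                  master_seed: int = 20_000) -> Tuple[bool, dict]:
    """Evaluate *rates* against *targets*; returns (passed, report)."""
    sim = sim if sim is not None else SimConfig()
    init_cfg = init_cfg if init_cfg is not None else default_init_config()
    low = _regime_metrics(rates, targets.low_dose, sim, init_cfg, master_seed,
                          targets.n_seeds, condition=0)
    high = _regime_metrics(rates, targets.high_dose, sim, init_cfg, master_seed,
                           targets.n_seeds, condition=1)
    checks = {
        "low_both_states_occupied":
            low["median_fraction_cap_low"] >= targets.min_state_occupancy and
            low["median_fraction_cap_high"] >= targets.min_state_occupancy,
        "low_dwell_low": not targets.min_mean_dwell_s or
            low["median_mean_dwell_low_s"] >= targets.min_mean_dwell_s,
        "low_dwell_high": not targets.min_mean_dwell_s or
            low["median_mean_dwell_high_s"] >= targets.min_mean_dwell_s,
        "low_switching": low["median_n_switches"] >= targets.min_switches_low,
        "high_basal": high["median_n_switches"] <= targets.max_switches_high,
    }
    report = {"low": low, "high": high, "checks": checks}
    return all(checks.values()), report


def calibrate_defaults(targets: Optional[CalibrationTargets] = None,
                       base_guess: Optional[RateSet] = None,
                       budget: int = 20, seed: int = 0,
                       sim: Optional[SimConfig] = None) -> Tuple[RateSet, dict]:
    """Find (or certify) a rate set meeting the regime targets.

    The base guess (shipped defaults unless given) is checked first and
    accepted if it passes.  Otherwise a budgeted random search perturbs the
    guess with log-uniform factors, accepting the first passing set.
    Raises :class:`CalibrationError` with best-found diagnostics when the
    budget is exhausted.
    """
    targets = targets if targets is not None else CalibrationTargets()
    base_guess = base_guess if base_guess is not None else default_rates()
    ok, report = check_targets(base_guess, targets, sim=sim, master_seed=20_000)
    if ok:
        return base_guess, report
    rng = np.random.default_rng(seed)
    best_report = report
    for trial in range(budget):
        factors = np.exp(rng.uniform(math.log(0.25), math.log(4.0),
                                     size=len(RATE_NAMES)))
        cand = RateSet(tuple(v * f for v, f in zip(base_guess.values, factors)))
        ok, report = check_targets(cand, targets, sim=sim,
                                   master_seed=20_000 + trial + 1)
        if ok:
            return cand, report
        n_ok = sum(report["checks"].values())
        if n_ok > sum(best_report["checks"].values()):
            best_report = report
    raise CalibrationError(
        f"calibration budget ({budget} trials) exhausted without meeting targets",
        report=best_report,
    )
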