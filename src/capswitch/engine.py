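"""Exact stochastic simulation (Gillespie direct method) for mass-action networks.

The direct method simulates the continuous-time Markov jump process defined
by the network's propensities: waiting times are exponential with rate equal
to the total propensity, and the firing channel is chosen with probability
proportional to its propensity.

All randomness comes from one PCG64 uniform stream, pre-generated in blocks
and consumed two numbers per event (waiting time, channel choice) by a
resumable inner kernel.  The kernel is JIT-compiled with numba when
available and falls back to the identical pure-Python code path otherwise;
both paths consume the same uniforms, so trajectories are bit-identical for
a given seed either way.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .network import SPECIES, ConfigurationError, RateSet, ReactionNetwork, SpeciesState

__all__ = [
    "SimConfig",
    "Trajectory",
    "SimulationError",
    "Absorbed",
    "draw_next_event",
    "simulate",
    "to_grid",
    "write_trajectory",
    "read_trajectory",
]

_U_BLOCK = 1 << 20          # uniforms generated per refill
_EVENT_CHUNK = 1 << 17      # rows per event-record buffer chunk

# kernel status codes
_DONE = 0
_NEED_UNIFORMS = 1
_BUFFER_FULL = 2
_ABSORBED = 3
_MAX_EVENTS = 4


class SimulationError(RuntimeError):
    """Simulation failed (event cap exceeded, inconsistent propensities...)."""

    def __init__(self, message: str, trajectory: Optional["Trajectory"] = None):
        super().__init__(message)
        self.trajectory = trajectory


class Absorbed:
    """Sentinel returned by :func:`draw_next_event` when no channel can fire."""

    waiting_time = math.inf
    reaction_index = -1

    def __repr__(self) -> str:  # pragma: no cover
        return "Absorbed()"


@dataclass(frozen=True)
class SimConfig:
    """Simulation horizon, burn-in, seeding and recording policy.

    Defaults mirror the study conditions: 200,000 simulated seconds with the
    first 10,000 s discarded as burn-in (the state prevailing at burn-in
    seeds the reported path).  ``record_mode`` is ``"event"`` (every jump)
    or ``"grid"`` (sample-and-hold at ``grid_step`` intervals).
    """

    t_end: float = 200_000.0
    burn_in: float = 10_000.0
    seed: int = 0
    record_mode: str = "event"
    grid_step: float = 5.0
    max_events: int = 50_000_000

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.t_end):
            raise ConfigurationError(
                f"need 0 <= burn_in < t_end, got burn_in={self.burn_in}, t_end={self.t_end}"
            )
        if self.record_mode not in ("event", "grid"):
            raise ConfigurationError(f"unknown record_mode {self.record_mode!r}")
        if self.record_mode == "grid":
            if not self.grid_step > 0:
                raise ConfigurationError("grid_step must be > 0")
            if self.grid_step > self.t_end - self.burn_in:
                raise ConfigurationError("grid_step larger than the analysis window")
        if self.max_events <= 0:
            raise ConfigurationError("max_events must be positive")

    def to_dict(self) -> dict:
        return {
            "t_end": self.t_end,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "record_mode": self.record_mode,
            "grid_step": self.grid_step,
            "max_events": self.max_events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**{k: d[k] for k in
                      ("t_end", "burn_in", "seed", "record_mode", "grid_step",
                       "max_events") if k in d})


@dataclass
class Trajectory:
    """Piecewise-constant species counts over simulated time.

    ``times`` are strictly increasing, starting at the burn-in boundary; the
    count row at ``times[i]`` holds on ``[times[i], times[i+1])`` and the
    final row holds to ``config.t_end``.
    """

    times: np.ndarray
    counts: np.ndarray
    config: SimConfig
    rates: RateSet
    initial_state: SpeciesState
    species: Tuple[str, ...] = SPECIES
    n_events: int = 0
    absorbed: bool = False
    traj_id: str = ""

    def __post_init__(self) -> None:
        if not self.traj_id:
            self.traj_id = f"seed{self.config.seed}-n{len(self.times)}"

    @property
    def window(self) -> Tuple[float, float]:
        return (self.config.burn_in, self.config.t_end)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def series(self, name: str) -> np.ndarray:
        return self.counts[:, self.species_index(name)]

    def state_at(self, t: float) -> np.ndarray:
        """Sample-and-hold state at time t within the analysis window."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.counts[max(i, 0)]


def draw_next_event(state: SpeciesState, network: ReactionNetwork, rng):
    """One direct-method draw: (exponential waiting time, channel index).

    Returns an :class:`Absorbed` sentinel when the total propensity is zero.
    Raises :class:`SimulationError` on NaN/negative propensities (never
    silently clamps).
    """
    props = network.propensities(state)
    if np.any(~np.isfinite(props)) or np.any(props < 0):
        raise SimulationError(f"invalid propensities: {props}")
    a0 = float(props.sum())
    if a0 == 0.0:
        return Absorbed()
    u1 = rng.random()
    u2 = rng.random()
    wait = -math.log(u1) / a0
    target = u2 * a0
    acc = 0.0
    idx = len(props) - 1
    for j, a in enumerate(props):
        acc += a
        if target < acc:
            idx = j
            break
    return wait, idx


# ---------------------------------------------------------------------------
# inner kernel (numba-jitted when available; same code runs in pure Python)
# ---------------------------------------------------------------------------


def _ssa_chunk(counts, t, t_end, burn_in, react_sp, react_st, net, k,
               u, u_pos, rec_times, rec_counts, rec_n, next_grid, grid_step,
               grid_mode, events_done, max_events, burned):
    """Advance the SSA until done / out of uniforms / record buffer full.

    Returns (t, u_pos, rec_n, next_grid, events_done, burned, status).
    """
    n_r = react_sp.shape[0]
    max_terms = react_sp.shape[1]
    n_u = u.shape[0]
    rec_cap = rec_times.shape[0]
    while True:
        # total propensity
        a0 = 0.0
        for i in range(n_r):
            a = k[i]
            for j in range(max_terms):
                sp = react_sp[i, j]
                if sp < 0:
                    break
                s = react_st[i, j]
                n = counts[sp]
                for q in range(s):
                    a *= (n - q) / (q + 1.0)
            if a > 0.0:
                a0 += a
        if a0 <= 0.0:
            return t, u_pos, rec_n, next_grid, events_done, burned, _ABSORBED
        if u_pos + 2 > n_u:
            return t, u_pos, rec_n, next_grid, events_done, burned, _NEED_UNIFORMS
        u1 = u[u_pos]
        u2 = u[u_pos + 1]
        u_pos += 2
        t_new = t - math.log(u1) / a0
        if t_new >= t_end:
            return t_end, u_pos, rec_n, next_grid, events_done, burned, _DONE
        # channel choice
        target = u2 * a0
        acc = 0.0
        chosen = n_r - 1
        for i in range(n_r):
            a = k[i]
            for j in range(max_terms):
                sp = react_sp[i, j]
                if sp < 0:
                    break
                s = react_st[i, j]
                n = counts[sp]
                for q in range(s):
                    a *= (n - q) / (q + 1.0)
            if a > 0.0:
                acc += a
                if target < acc:
                    chosen = i
                    break
        if grid_mode == 1:
            # fill grid points covered by the prevailing state
            while next_grid < t_new and next_grid <= t_end:
                if rec_n >= rec_cap:
                    return t, u_pos - 2, rec_n, next_grid, events_done, burned, _BUFFER_FULL
                rec_times[rec_n] = next_grid
                for sidx in range(counts.shape[0]):
                    rec_counts[rec_n, sidx] = counts[sidx]
                rec_n += 1
                next_grid += grid_step
        elif t_new > burn_in and not burned:
            # event mode: state prevailing at burn-in seeds the reported path
            if rec_n >= rec_cap:
                return t, u_pos - 2, rec_n, next_grid, events_done, burned, _BUFFER_FULL
            rec_times[rec_n] = burn_in
            for sidx in range(counts.shape[0]):
                rec_counts[rec_n, sidx] = counts[sidx]
            rec_n += 1
            burned = True
        # apply stoichiometry
        for sidx in range(counts.shape[0]):
            counts[sidx] += net[chosen, sidx]
        t = t_new
        events_done += 1
        if grid_mode == 0 and t >= burn_in:
            if rec_n >= rec_cap:
                # roll back the event so the caller can re-run it
                for sidx in range(counts.shape[0]):
                    counts[sidx] -= net[chosen, sidx]
                return t, u_pos - 2, rec_n, next_grid, events_done - 1, burned, _BUFFER_FULL
            rec_times[rec_n] = t
            for sidx in range(counts.shape[0]):
                rec_counts[rec_n, sidx] = counts[sidx]
            rec_n += 1
        if events_done >= max_events:
            return t, u_pos, rec_n, next_grid, events_done, burned, _MAX_EVENTS


_py_ssa_chunk = _ssa_chunk
try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _ssa_chunk = njit(cache=True, fastmath=False)(_ssa_chunk)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def simulate(network: ReactionNetwork, init: SpeciesState,
             config: SimConfig) -> Trajectory:
    """Run one exact SSA path of *network* from *init* under *config*.

    The path runs from t=0 to ``t_end``; records before ``burn_in`` are
    discarded except the state prevailing at the burn-in boundary, which
    becomes the first reported record.  Identical (network, init, seed)
    give bit-identical trajectories.
    """
    counts = init.counts.astype(np.int64).copy()
    n_sp = counts.shape[0]
    rng = np.random.Generator(np.random.PCG64(config.seed))
    grid_mode = 1 if config.record_mode == "grid" else 0

    if grid_mode:
        n_grid = int(math.floor((config.t_end - config.burn_in) / config.grid_step)) + 1
        rec_times = np.empty(n_grid, dtype=np.float64)
        rec_counts = np.empty((n_grid, n_sp), dtype=np.int64)
    else:
        rec_times = np.empty(_EVENT_CHUNK, dtype=np.float64)
        rec_counts = np.empty((_EVENT_CHUNK, n_sp), dtype=np.int64)
    done_times: List[np.ndarray] = []
    done_counts: List[np.ndarray] = []

    t = 0.0
    u = rng.random(_U_BLOCK)
    u_pos = 0
    rec_n = 0
    next_grid = config.burn_in
    events_done = 0
    burned = False
    absorbed = False

    while True:
        (t, u_pos, rec_n, next_grid, events_done, burned, status) = _ssa_chunk(
            counts, t, config.t_end, config.burn_in,
            network.reactant_species, network.reactant_stoich, network.net,
            network.rate_array, u, u_pos, rec_times, rec_counts, rec_n,
            next_grid, config.grid_step, grid_mode, events_done,
            config.max_events, burned,
        )
        if status == _NEED_UNIFORMS:
            u = rng.random(_U_BLOCK)
            u_pos = 0
            continue
        if status == _BUFFER_FULL:
            done_times.append(rec_times[:rec_n].copy())
            done_counts.append(rec_counts[:rec_n].copy())
            rec_n = 0
            continue
        if status == _ABSORBED:
            absorbed = True
            break
        if status == _DONE:
            break
        if status == _MAX_EVENTS:
            done_times.append(rec_times[:rec_n].copy())
            done_counts.append(rec_counts[:rec_n].copy())
            partial = _assemble(done_times, done_counts, counts, config,
                                network.rates, init, events_done, False)
            raise SimulationError(
                f"max_events={config.max_events} exceeded at t={t:.1f}s "
                f"(t_end={config.t_end}); partial trajectory attached",
                trajectory=partial,
            )

    done_times.append(rec_times[:rec_n].copy())
    done_counts.append(rec_counts[:rec_n].copy())
    if grid_mode:
        # the final state holds to t_end: fill the remaining grid points
        remaining = []
        g = next_grid
        while g <= config.t_end + 1e-9:
            remaining.append(g)
            g += config.grid_step
        if remaining:
            done_times.append(np.asarray(remaining, dtype=np.float64))
            done_counts.append(np.tile(counts, (len(remaining), 1)))
    return _assemble(done_times, done_counts, counts, config, network.rates,
                     init, events_done, absorbed)


def _assemble(done_times, done_counts, counts, config, rates, init,
              events_done, absorbed) -> Trajectory:
    chunks_t = [a for a in done_times if len(a)]
    chunks_c = [a for a in done_counts if len(a)]
    if chunks_t:
        times = np.concatenate(chunks_t)
        cmat = np.concatenate(chunks_c)
    else:
        times = np.empty(0, dtype=np.float64)
        cmat = np.empty((0, counts.shape[0]), dtype=np.int64)
    if times.size == 0 or times[0] > config.burn_in:
        # no record at the burn-in boundary: report the prevailing state there
        times = np.concatenate([[config.burn_in], times])
        cmat = np.concatenate([counts[None, :], cmat]) if cmat.size else counts[None, :]
    return Trajectory(times=times, counts=cmat.astype(np.int64), config=config,
                      rates=rates, initial_state=init, n_events=events_done,
                      absorbed=absorbed)


def to_grid(traj: Trajectory, step: float) -> Trajectory:
    """Sample-and-hold resampling of *traj* onto a fixed grid of *step* seconds."""
    t0, t1 = traj.window
    if not step > 0:
        raise ConfigurationError("step must be > 0")
    if step > t1 - t0:
        raise ConfigurationError("step larger than the analysis window")
    grid = np.arange(t0, t1, step)  # half-open: the state at t1 has no duration
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    idx = np.clip(idx, 0, len(traj.times) - 1)
    cfg = SimConfig(t_end=traj.config.t_end, burn_in=traj.config.burn_in,
                    seed=traj.config.seed, record_mode="grid", grid_step=step,
                    max_events=traj.config.max_events)
    return Trajectory(times=grid, counts=traj.counts[idx], config=cfg,
                      rates=traj.rates, initial_state=traj.initial_state,
                      n_events=traj.n_events, absorbed=traj.absorbed,
                      traj_id=traj.traj_id + f"-grid{step}")


# ---------------------------------------------------------------------------
# I/O: TSV trajectory + JSON sidecar, lossless round-trip
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, prefix) -> Tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (time_s + species columns) and ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = Path(str(prefix) + ".tsv")
    with open(tsv, "w") as fh:
        fh.write("time_s\t" + "\t".join(traj.species) + "\n")
        for t, row in zip(traj.times, traj.counts):
            fh.write(f"{float(t)!r}\t" + "\t".join(str(int(v)) for v in row) + "\n")
    meta = {
        "config": traj.config.to_dict(),
        "rates": traj.rates.to_dict(),
        "initial_state": traj.initial_state.to_dict(),
        "species": list(traj.species),
        "n_events": traj.n_events,
        "absorbed": traj.absorbed,
        "traj_id": traj.traj_id,
    }
    side = Path(str(prefix) + ".json")
    side.write_text(json.dumps(meta, indent=1))
    return tsv, side


def read_trajectory(prefix) -> Trajectory:
    prefix = Path(prefix)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    data = np.loadtxt(Path(str(prefix) + ".tsv"), skiprows=1, ndmin=2)
    times = data[:, 0]
    counts = data[:, 1:].astype(np.int64)
    return Trajectory(
        times=times, counts=counts, config=SimConfig.from_dict(meta["config"]),
        rates=RateSet.from_dict(meta["rates"]),
        initial_state=SpeciesState.from_dict(meta["initial_state"]),
        species=tuple(meta["species"]), n_events=meta["n_events"],
        absorbed=meta["absorbed"], traj_id=meta["traj_id"],
    )
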