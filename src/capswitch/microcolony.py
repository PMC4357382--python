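"""Synthetic microcolony generator.

Emulates time-lapse observations of single cells growing into
microcolonies with a fluorescent capsule reporter:

* Markov branching growth — each cell divides after an exponential waiting
  time whose rate is the phenotype's Malthusian growth rate (defaults
  0.0116 min^-1 for Cap- and 0.0113 min^-1 for Cap+, i.e. doubling every
  ~59.8 and ~61.3 min; capsulation is costly).
* A per-colony Gaussian population-size threshold (default 1870 +/- 660
  cells) below which no Cap- -> Cap+ switch can occur; once the colony
  exceeds its threshold, Cap- cells switch stochastically at a constant
  per-cell rate.  With the default high switch rate the first switch
  happens essentially at the drawn threshold, so first-switch sizes are
  Gaussian across colonies.
* Rapid reversion of Cap+ founders: cells of a Cap+ founder lineage revert
  to Cap- on a fast exponential clock (mean 30 min by default); phenotypes
  are otherwise heritable along lineages.
* A capsule-counting assay emulator: independent binomial replicates
  (default 500 cells scored x 5 replicates) at a given true Cap+ proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "MicrocolonyParams",
    "Cell",
    "LineageTree",
    "AssayCounts",
    "generate_microcolony",
    "generate_microcolonies",
    "first_switch_size",
    "generate_assay",
]

CAP_LOW = "CAP_LOW"
CAP_HIGH = "CAP_HIGH"


@dataclass(frozen=True)
class MicrocolonyParams:
    """Generator parameters; defaults are the observed study conditions."""

    growth_rate_cap_low: float = 0.0116     # min^-1 (Cap- Malthusian rate)
    growth_rate_cap_high: float = 0.0113    # min^-1 (Cap+; slower: cost)
    switch_threshold_mean: float = 1870.0   # cells
    switch_threshold_sd: float = 660.0      # cells
    per_cell_switch_rate: float = 1.0       # events/cell/min once above threshold
    founder_phenotype: str = CAP_LOW
    founder_reversion_rate: float = 1.0 / 30.0  # min^-1 (fast reversion)
    total_time: float = 1000.0              # min (censoring rare by then)
    stop_after_first_switch: bool = False

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError("total_time must be > 0")
        for name in ("growth_rate_cap_low", "growth_rate_cap_high",
                     "per_cell_switch_rate", "founder_reversion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.growth_rate_cap_high > self.growth_rate_cap_low:
            raise ValueError(
                "capsulation is costly: growth_rate_cap_high must not exceed "
                "growth_rate_cap_low"
            )
        if self.switch_threshold_sd < 0:
            raise ValueError("switch_threshold_sd must be >= 0")
        if self.founder_phenotype not in (CAP_LOW, CAP_HIGH):
            raise ValueError(f"unknown founder phenotype {self.founder_phenotype!r}")


@dataclass
class Cell:
    cell_id: int
    parent_id: int                      # -1 for the founder
    birth_min: float
    division_min: Optional[float]       # None = alive (censored) at end
    phenotype_segments: List[Tuple[str, float]]  # (state, start time)

    def phenotype_at(self, t: float) -> str:
        state = self.phenotype_segments[0][0]
        for s, start in self.phenotype_segments:
            if start <= t:
                state = s
            else:
                break
        return state


@dataclass
class LineageTree:
    """One simulated microcolony: cells, divisions, phenotypes, switches."""

    cells: List[Cell]
    params: MicrocolonyParams
    seed: int
    threshold: float                                   # the drawn Gaussian threshold
    switch_events: List[Tuple[float, int, int, str, str]]  # (t, cell, pop, from, to)
    end_time: float

    @property
    def founder(self) -> Cell:
        return self.cells[0]

    def population_curve(self) -> Tuple[np.ndarray, np.ndarray]:
        """(times, alive-cell counts) at every birth/division event."""
        divisions = sorted(c.division_min for c in self.cells
                           if c.division_min is not None)
        # each division removes the parent and adds two children at the same
        # instant: net +1 per division event
        times = np.array(divisions)
        pops = 1 + np.arange(1, len(divisions) + 1)
        times = np.concatenate([[self.cells[0].birth_min], times])
        pops = np.concatenate([[1], pops])
        return times, pops

    def population_at(self, t: float) -> int:
        return sum(1 for c in self.cells
                   if c.birth_min <= t and (c.division_min is None or c.division_min > t))

    def phenotype_population_curve(self, phenotype: str
                                   ) -> Tuple[np.ndarray, np.ndarray]:
        """(times, counts) of alive cells holding *phenotype*, at change points."""
        deltas: Dict[float, int] = {}
        for c in self.cells:
            end = c.division_min if c.division_min is not None else self.end_time
            segs = c.phenotype_segments + [("_end", end)]
            for (s, start), (_, stop) in zip(segs[:-1], segs[1:]):
                if s == phenotype and stop > start:
                    deltas[start] = deltas.get(start, 0) + 1
                    deltas[stop] = deltas.get(stop, 0) - 1
        if not deltas:
            return np.empty(0), np.empty(0, dtype=int)
        times = np.array(sorted(deltas))
        counts = np.cumsum([deltas[t] for t in times])
        return times, counts

    def write_tsv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\tthreshold={self.threshold!r}\t"
                     f"end_time={self.end_time!r}\n")
            fh.write("cell_id\tparent_id\tbirth_min\tdivision_min\tphenotypes\n")
            for c in self.cells:
                div = "" if c.division_min is None else repr(c.division_min)
                ph = ";".join(f"{s}@{t!r}" for s, t in c.phenotype_segments)
                fh.write(f"{c.cell_id}\t{c.parent_id}\t{c.birth_min!r}\t{div}\t{ph}\n")


def generate_microcolony(params: MicrocolonyParams, seed) -> LineageTree:
    """Simulate one microcolony from a single founder cell.

    Event-driven exact simulation: division, threshold-gated Cap- -> Cap+
    switching and Cap+ founder-lineage reversion compete as exponential
    channels (Gillespie over exchangeable cells within a class).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_label = seed if isinstance(seed, int) else -1
    p = params
    threshold = float(rng.normal(p.switch_threshold_mean, p.switch_threshold_sd)) \
        if p.switch_threshold_sd > 0 else float(p.switch_threshold_mean)

    founder = Cell(0, -1, 0.0, None, [(p.founder_phenotype, 0.0)])
    cells = [founder]
    # class membership by current phenotype; founder-lineage Cap+ cells are
    # tracked separately because only they carry the fast reversion clock
    low: List[int] = []
    high: List[int] = []          # post-switch Cap+ (heritable, stable)
    high_founder: List[int] = []  # Cap+ founder lineage (reverts quickly)
    (low if p.founder_phenotype == CAP_LOW else high_founder).append(0)

    switch_events: List[Tuple[float, int, int, str, str]] = []
    t = 0.0
    end_time = p.total_time
    while True:
        n_low, n_high, n_hf = len(low), len(high), len(high_founder)
        pop = n_low + n_high + n_hf
        a_div_low = p.growth_rate_cap_low * n_low
        a_div_high = p.growth_rate_cap_high * (n_high + n_hf)
        a_switch = p.per_cell_switch_rate * n_low if pop >= threshold else 0.0
        a_revert = p.founder_reversion_rate * n_hf
        a0 = a_div_low + a_div_high + a_switch + a_revert
        if a0 == 0.0:
            break
        t_new = t + rng.exponential(1.0 / a0)
        if t_new >= p.total_time:
            break
        t = t_new
        u = rng.random() * a0
        if u < a_div_low or u < a_div_low + a_div_high:
            # division: pick the dividing cell uniformly within its class
            if u < a_div_low:
                cls = low
            else:
                # split Cap+ divisions between stable and founder-lineage pools
                # proportionally to their sizes
                u2 = rng.random() * (n_high + n_hf)
                cls = high if u2 < n_high else high_founder
            i = int(rng.integers(len(cls)))
            cid = cls[i]
            parent = cells[cid]
            parent.division_min = t
            state = parent.phenotype_at(t)
            # remove the parent from its class (O(1) swap-pop), add children
            cls[i] = cls[-1]
            cls.pop()
            for _ in range(2):
                child = Cell(len(cells), cid, t, None, [(state, t)])
                cells.append(child)
                cls.append(child.cell_id)
        elif u < a_div_low + a_div_high + a_switch:
            i = int(rng.integers(len(low)))
            cid = low.pop(i)
            cells[cid].phenotype_segments.append((CAP_HIGH, t))
            high.append(cid)
            pop_now = len(low) + len(high) + len(high_founder)
            switch_events.append((t, cid, pop_now, CAP_LOW, CAP_HIGH))
            if p.stop_after_first_switch:
                end_time = t
                break
        else:
            i = int(rng.integers(len(high_founder)))
            cid = high_founder.pop(i)
            cells[cid].phenotype_segments.append((CAP_LOW, t))
            low.append(cid)
            switch_events.append(
                (t, cid, len(low) + len(high) + len(high_founder), CAP_HIGH, CAP_LOW))

    return LineageTree(cells=cells, params=p,
                       seed=seed_label, threshold=threshold,
                       switch_events=switch_events, end_time=end_time)


def generate_microcolonies(params: MicrocolonyParams, n: int, seed
                           ) -> List[LineageTree]:
    """Generate *n* independent colonies from one master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    return [generate_microcolony(params, np.random.default_rng(c)) for c in children]


def first_switch_size(tree: LineageTree) -> Optional[int]:
    """Population size at the first Cap- -> Cap+ switch; None if censored.

    Defined only for Cap- founded colonies (the statistic mirrors watching
    a noncapsulated cell grow into a microcolony until a capsulated cell
    first appears).
    """
    if tree.params.founder_phenotype != CAP_LOW:
        raise ValueError("first_switch_size is undefined for Cap+ founded colonies")
    for t, cid, pop, frm, to in tree.switch_events:
        if frm == CAP_LOW and to == CAP_HIGH:
            return int(pop)
    return None


@dataclass
class AssayCounts:
    """Capsule-counting assay replicates: Cap+ counts out of cells scored."""

    counts: np.ndarray          # capsulated cells per replicate
    cells_per_replicate: int
    proportion: float           # generating proportion
    seed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) < 3:
            raise ValueError("at least 3 replicates are required")
        if np.any(self.counts < 0) or np.any(self.counts > self.cells_per_replicate):
            raise ValueError("counts must lie in [0, cells_per_replicate]")

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.cells_per_replicate

    def write_tsv(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"# generating_proportion={self.proportion!r}\tseed={self.seed}\n")
            fh.write("replicate\tcells_scored\tcapsulated\n")
            for i, c in enumerate(self.counts):
                fh.write(f"{i + 1}\t{self.cells_per_replicate}\t{int(c)}\n")


def generate_assay(p: float, cells_per_rep: int = 500, replicates: int = 5,
                   seed=0) -> AssayCounts:
    """Binomial emulation of the capsule-counting assay (500 cells x 3-5 reps)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    if cells_per_rep <= 0:
        raise ValueError("cells_per_rep must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.binomial(cells_per_rep, p, size=replicates)
    return AssayCounts(counts=counts, cells_per_replicate=cells_per_rep,
                       proportion=float(p), seed=seed if isinstance(seed, int) else -1)
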