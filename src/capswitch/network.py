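"""Growth-capsulation reaction network.

The model couples the fate of an abstract pyrimidine signal molecule (UXP,
proportional to UTP) to capsular polymer (CAP, species ``CA``) synthesis.
UXP is produced at a constant rate and drained either by nucleotide
metabolism (the PyrG branch, folded into a first-order constant) or by CAP
synthesis itself (positive feedback: committing to capsule production keeps
UXP low, giving the Cap+ state its memory).  UXP sequesters a
transcriptional activator of the CAP biosynthetic genes, so low UXP frees
the activator and drives high CAP expression.  Return to Cap- is provided
by a repressor whose transcription is triggered by CAP: the repressor
dimerises (cooperativity) and the dimer occupies the CAP promoter; the
Cap- episode ends when the repressor pool decays and the promoter is
released.

Thirteen molecular species, 23 mass-action reactions, one rate constant per
reaction.  DNA polymerase and PyrG are treated as constant catalysts and
folded into the corresponding rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "SPECIES",
    "RATE_NAMES",
    "ConfigurationError",
    "SpeciesState",
    "RateSet",
    "Reaction",
    "ReactionNetwork",
    "InitConfig",
    "build_growth_capsulation_network",
    "initialize_state",
    "perturb_rate",
]

#: Canonical species ordering used by every array in the package.
SPECIES: Tuple[str, ...] = (
    "UXP",        # signal molecule (proportional to UTP), molecules
    "CA",         # capsular polymer units (CAP), molecules
    "A",          # free transcriptional activator
    "A_UXP",      # activator sequestered by UXP
    "DNAca_free",  # CAP biosynthetic gene promoter, unoccupied
    "DNAca_act",   # promoter bound by activator (transcribing)
    "DNAca_rep",   # promoter bound by repressor dimer (silenced)
    "mRNAca",     # CAP biosynthetic transcript
    "DNAr_free",  # repressor gene promoter, unoccupied
    "DNAr_act",   # repressor promoter bound by CAP (transcribing)
    "mRNAr",      # repressor transcript
    "R",          # repressor monomer
    "R2",         # repressor dimer
)

#: Canonical rate-constant ordering; indices are stable and used by sweeps.
RATE_NAMES: Tuple[str, ...] = (
    "k_uxp_prod",
    "k_cap_feedback",
    "k_pyrg_drain",
    "k_seq_on",
    "k_seq_off",
    "k_act_bind",
    "k_act_unbind",
    "k_tx_active",
    "k_tx_basal",
    "k_tl_ca",
    "k_capDNAr_bind",
    "k_capDNAr_unbind",
    "k_tx_rep",
    "k_tl_rep",
    "k_dim_on",
    "k_dim_off",
    "k_rep_bind",
    "k_rep_unbind",
    "k_deg_mRNAca",
    "k_deg_mRNAr",
    "k_deg_CA",
    "k_deg_R",
    "k_deg_R2",
)

_SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}
_RATE_INDEX = {name: i for i, name in enumerate(RATE_NAMES)}


class ConfigurationError(ValueError):
    """A rate set, initial state or config block is invalid."""


# ---------------------------------------------------------------------------
# species state
# ---------------------------------------------------------------------------


@dataclass
class SpeciesState:
    """Integer molecule counts for the 13 network species.

    Degradation by-products are a conceptual sink and are not stored.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (len(SPECIES),):
            raise ConfigurationError(
                f"state must have {len(SPECIES)} entries, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ConfigurationError("species counts must be integers")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ConfigurationError("species counts must be non-negative")
        self.counts = arr.astype(np.int64)

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "SpeciesState":
        unknown = set(d) - set(SPECIES)
        if unknown:
            raise ConfigurationError(f"unknown species: {sorted(unknown)}")
        counts = np.zeros(len(SPECIES), dtype=np.int64)
        for name, value in d.items():
            counts[_SPECIES_INDEX[name]] = value
        return cls(counts)

    def to_dict(self) -> Dict[str, int]:
        return {name: int(self.counts[i]) for i, name in enumerate(SPECIES)}

    def __getitem__(self, species: str) -> int:
        return int(self.counts[_SPECIES_INDEX[species]])

    @property
    def total_activator(self) -> int:
        """Conserved activator total: free + UXP-sequestered + promoter-bound."""
        return self["A"] + self["A_UXP"] + self["DNAca_act"]

    @property
    def dnaca_total(self) -> int:
        return self["DNAca_free"] + self["DNAca_act"] + self["DNAca_rep"]

    @property
    def dnar_total(self) -> int:
        return self["DNAr_free"] + self["DNAr_act"]

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.counts.copy())


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSet:
    """The 23 named, non-negative rate constants of the network.

    Units: seconds; zeroth-order constants are molecules/s, first-order 1/s,
    second-order 1/(molecule*s).  ``k_uxp_prod`` is the tunable UXP
    production rate, so the dose settings 0.003 / 0.3 / 3 molecules/s are
    used directly as its value.
    """

    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(RATE_NAMES):
            raise ConfigurationError(
                f"expected {len(RATE_NAMES)} rates, got {len(self.values)}"
            )
        for name, v in zip(RATE_NAMES, self.values):
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(
                    f"rate constant {name!r} must be finite and >= 0, got {v}"
                )
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RateSet":
        missing = set(RATE_NAMES) - set(d)
        if missing:
            raise ConfigurationError(f"missing rate constants: {sorted(missing)}")
        unknown = set(d) - set(RATE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown rate constants: {sorted(unknown)}")
        return cls(tuple(float(d[name]) for name in RATE_NAMES))

    def to_dict(self) -> Dict[str, float]:
        return dict(zip(RATE_NAMES, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)

    def __getitem__(self, key) -> float:
        if isinstance(key, str):
            if key not in _RATE_INDEX:
                raise KeyError(
                    f"unknown rate {key!r}; valid names: {', '.join(RATE_NAMES)}"
                )
            return self.values[_RATE_INDEX[key]]
        return self.values[key]

    def __iter__(self) -> Iterator[Tuple[str, float]]:
        return iter(zip(RATE_NAMES, self.values))

    def replace(self, **updates: float) -> "RateSet":
        d = self.to_dict()
        unknown = set(updates) - set(RATE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown rate constants: {sorted(unknown)}")
        d.update(updates)
        return RateSet.from_dict(d)


def perturb_rate(rates: RateSet, name: str, factor: float) -> RateSet:
    """Return a copy of *rates* with the named constant multiplied by *factor*.

    This is the one-at-a-time perturbation used by the sensitivity sweep
    (factors 10 and 0.1).
    """
    if name not in _RATE_INDEX:
        raise KeyError(
            f"unknown rate {name!r}; valid names: {', '.join(RATE_NAMES)}"
        )
    if not (factor > 0) or not np.isfinite(factor):
        raise ConfigurationError(f"factor must be positive and finite, got {factor}")
    values = list(rates.values)
    values[_RATE_INDEX[name]] = values[_RATE_INDEX[name]] * factor
    return RateSet(tuple(values))


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction channel.

    Propensity follows stochastic mass-action combinatorics:
    ``k * prod_i C(n_i, s_i)`` over reactant species i with stoichiometry
    s_i (so a homodimerisation 2R -> R2 has propensity k*R*(R-1)/2).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_name: str
    label: str
    block: str  # equation-block tag: A (UXP), B (CAP transcription), C (switch), D (turnover)

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for sp, s in side.items():
                if sp not in _SPECIES_INDEX:
                    raise ConfigurationError(f"unknown species {sp!r} in {self.label}")
                if s < 0 or s != int(s):
                    raise ConfigurationError(
                        f"stoichiometry must be a non-negative integer in {self.label}"
                    )
        if not self.reactants and not self.products:
            raise ConfigurationError(f"empty reaction {self.label}")
        if self.rate_name not in _RATE_INDEX:
            raise ConfigurationError(f"unknown rate name {self.rate_name!r}")

    def propensity(self, state: SpeciesState, rates: RateSet) -> float:
        a = rates[self.rate_name]
        for sp, s in self.reactants.items():
            n = state[sp]
            for j in range(s):
                a *= (n - j) / (j + 1)
        return max(a, 0.0)

    def net_change(self) -> np.ndarray:
        delta = np.zeros(len(SPECIES), dtype=np.int64)
        for sp, s in self.reactants.items():
            delta[_SPECIES_INDEX[sp]] -= s
        for sp, s in self.products.items():
            delta[_SPECIES_INDEX[sp]] += s
        return delta

    def __str__(self) -> str:
        def side(m: Mapping[str, int]) -> str:
            if not m:
                return "0"
            return " + ".join(
                (f"{s} {sp}" if s != 1 else sp) for sp, s in sorted(m.items())
            )

        return f"{side(self.reactants)} -> {side(self.products)} @ {self.rate_name}"


# canonical reaction list: one reaction per rate constant, realizing the
# verbal network description with exactly 23 channels.
_CANONICAL = [
    # block A: processes affecting the signal molecule UXP
    ({}, {"UXP": 1}, "k_uxp_prod", "constant UXP production", "A"),
    ({"UXP": 1, "CA": 1}, {"CA": 2}, "k_cap_feedback",
     "CAP synthesis draws UXP into capsule production (positive feedback)", "A"),
    ({"UXP": 1}, {}, "k_pyrg_drain", "UXP drained to nucleotide metabolism (PyrG branch)", "A"),
    ({"A": 1, "UXP": 1}, {"A_UXP": 1}, "k_seq_on", "UXP sequesters the activator", "A"),
    ({"A_UXP": 1}, {"A": 1, "UXP": 1}, "k_seq_off", "sequestered activator released", "A"),
    # block B: transcription of the CAP biosynthetic genes
    ({"A": 1, "DNAca_free": 1}, {"DNAca_act": 1}, "k_act_bind",
     "activator binds the CAP promoter", "B"),
    ({"DNAca_act": 1}, {"A": 1, "DNAca_free": 1}, "k_act_unbind",
     "activator leaves the CAP promoter", "B"),
    ({"DNAca_act": 1}, {"DNAca_act": 1, "mRNAca": 1}, "k_tx_active",
     "activated transcription of CAP genes", "B"),
    ({"DNAca_free": 1}, {"DNAca_free": 1, "mRNAca": 1}, "k_tx_basal",
     "basal transcription of CAP genes", "B"),
    ({"mRNAca": 1}, {"mRNAca": 1, "CA": 1}, "k_tl_ca", "translation / CAP synthesis", "B"),
    # block C: the Cap+ -> Cap- switch (CAP-triggered repressor)
    ({"CA": 1, "DNAr_free": 1}, {"DNAr_act": 1}, "k_capDNAr_bind",
     "CAP activates the repressor gene promoter", "C"),
    ({"DNAr_act": 1}, {"CA": 1, "DNAr_free": 1}, "k_capDNAr_unbind",
     "CAP leaves the repressor promoter", "C"),
    ({"DNAr_act": 1}, {"DNAr_act": 1, "mRNAr": 1}, "k_tx_rep",
     "repressor transcription", "C"),
    ({"mRNAr": 1}, {"mRNAr": 1, "R": 1}, "k_tl_rep", "repressor translation", "C"),
    ({"R": 2}, {"R2": 1}, "k_dim_on", "repressor dimerisation (cooperativity)", "C"),
    ({"R2": 1}, {"R": 2}, "k_dim_off", "repressor dimer dissociation", "C"),
    ({"R2": 1, "DNAca_free": 1}, {"DNAca_rep": 1}, "k_rep_bind",
     "repressor dimer silences the CAP promoter", "C"),
    ({"DNAca_rep": 1}, {"R2": 1, "DNAca_free": 1}, "k_rep_unbind",
     "repressor dimer leaves the CAP promoter", "C"),
    # block D: turnover of mRNA and protein
    ({"mRNAca": 1}, {}, "k_deg_mRNAca", "CAP mRNA degradation", "D"),
    ({"mRNAr": 1}, {}, "k_deg_mRNAr", "repressor mRNA degradation", "D"),
    ({"CA": 1}, {}, "k_deg_CA", "CAP degradation", "D"),
    ({"R": 1}, {}, "k_deg_R", "repressor monomer degradation", "D"),
    ({"R2": 1}, {}, "k_deg_R2", "repressor dimer degradation", "D"),
]


@dataclass
class ReactionNetwork:
    """A concrete mass-action network: reactions plus their rate constants.

    Precompiles the index/stoichiometry arrays consumed by the simulation
    kernel.
    """

    reactions: Sequence[Reaction]
    rates: RateSet
    species: Tuple[str, ...] = SPECIES

    # compiled arrays, built in __post_init__
    reactant_species: np.ndarray = field(init=False, repr=False)
    reactant_stoich: np.ndarray = field(init=False, repr=False)
    net: np.ndarray = field(init=False, repr=False)
    rate_array: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n_r = len(self.reactions)
        max_terms = max((len(r.reactants) for r in self.reactions), default=1)
        max_terms = max(max_terms, 1)
        self.reactant_species = np.full((n_r, max_terms), -1, dtype=np.int64)
        self.reactant_stoich = np.zeros((n_r, max_terms), dtype=np.int64)
        self.net = np.zeros((n_r, len(self.species)), dtype=np.int64)
        for i, rxn in enumerate(self.reactions):
            for j, (sp, s) in enumerate(sorted(rxn.reactants.items())):
                self.reactant_species[i, j] = _SPECIES_INDEX[sp]
                self.reactant_stoich[i, j] = s
            self.net[i] = rxn.net_change()
        self.rate_array = np.array(
            [self.rates[r.rate_name] for r in self.reactions], dtype=np.float64
        )

    def propensities(self, state: SpeciesState) -> np.ndarray:
        """Mass-action propensity of every channel in *state* (pure-Python
        reference path; the kernel recomputes these internally)."""
        return np.array(
            [r.propensity(state, self.rates) for r in self.reactions], dtype=np.float64
        )

    def with_rates(self, rates: RateSet) -> "ReactionNetwork":
        return ReactionNetwork(self.reactions, rates, self.species)

    def to_text(self) -> str:
        """Human-readable one-reaction-per-line dump, for docs and diffing."""
        width = max(len(str(r)) for r in self.reactions)
        lines = [f"{str(r):<{width}}  # [{r.block}] {r.label}" for r in self.reactions]
        return "\n".join(lines) + "\n"

    def __len__(self) -> int:
        return len(self.reactions)


def build_growth_capsulation_network(rates: RateSet) -> ReactionNetwork:
    """Build the canonical 23-reaction growth-capsulation network.

    One reaction per rate constant; raises :class:`ConfigurationError` if
    the rate set is malformed (missing or negative constants are rejected
    by :class:`RateSet` itself, naming the offending constant).
    """
    if not isinstance(rates, RateSet):
        rates = RateSet.from_dict(rates)
    reactions = [Reaction(*args) for args in _CANONICAL]
    assert len(reactions) == len(RATE_NAMES)
    assert [r.rate_name for r in reactions] == list(RATE_NAMES)
    return ReactionNetwork(reactions, rates)


# ---------------------------------------------------------------------------
# initial state
# ---------------------------------------------------------------------------


@dataclass
class InitConfig:
    """Sampling ranges for the randomised initial condition.

    Ranges are inclusive integer intervals ``(lo, hi)``.  The initial UXP
    count is drawn conditional on strictly exceeding the total activator
    count (free + sequestered), reflecting that UTP outnumbers activator
    molecules at the start of every run.  Promoter copy numbers are fixed
    (default one copy of each promoter).
    """

    uxp_range: Tuple[int, int] = (20, 100)
    activator_range: Tuple[int, int] = (10, 10)
    ca_range: Tuple[int, int] = (0, 0)
    mrna_ca_range: Tuple[int, int] = (0, 0)
    mrna_r_range: Tuple[int, int] = (0, 0)
    r_range: Tuple[int, int] = (0, 0)
    dnaca_copies: int = 1
    dnar_copies: int = 1

    def __post_init__(self) -> None:
        for name in ("uxp_range", "activator_range", "ca_range",
                     "mrna_ca_range", "mrna_r_range", "r_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"bad range {name}=({lo}, {hi})")
            setattr(self, name, (int(lo), int(hi)))
        if self.dnaca_copies < 0 or self.dnar_copies < 0:
            raise ConfigurationError("promoter copy numbers must be >= 0")
        if self.uxp_range[1] <= self.activator_range[0]:
            raise ConfigurationError(
                "uxp_range cannot satisfy UXP > activator total "
                f"(max UXP {self.uxp_range[1]} <= min activator {self.activator_range[0]})"
            )

    def to_dict(self) -> Dict[str, object]:
        return {
            "uxp_range": list(self.uxp_range),
            "activator_range": list(self.activator_range),
            "ca_range": list(self.ca_range),
            "mrna_ca_range": list(self.mrna_ca_range),
            "mrna_r_range": list(self.mrna_r_range),
            "r_range": list(self.r_range),
            "dnaca_copies": self.dnaca_copies,
            "dnar_copies": self.dnar_copies,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "InitConfig":
        kwargs = {}
        for key in ("uxp_range", "activator_range", "ca_range",
                    "mrna_ca_range", "mrna_r_range", "r_range"):
            if key in d:
                kwargs[key] = tuple(d[key])  # type: ignore[arg-type]
        for key in ("dnaca_copies", "dnar_copies"):
            if key in d:
                kwargs[key] = int(d[key])  # type: ignore[arg-type]
        return cls(**kwargs)


def initialize_state(config: InitConfig, seed) -> SpeciesState:
    """Draw a random initial state with UXP strictly above the activator total.

    *seed* may be an int, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`; the result is reproducible for a fixed
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(lo_hi: Tuple[int, int]) -> int:
        lo, hi = lo_hi
        return int(rng.integers(lo, hi + 1))

    a_total = draw(config.activator_range)
    uxp_lo = max(config.uxp_range[0], a_total + 1)
    if uxp_lo > config.uxp_range[1]:
        raise ConfigurationError(
            f"cannot draw UXP > activator total {a_total} within "
            f"uxp_range {config.uxp_range}"
        )
    uxp = int(rng.integers(uxp_lo, config.uxp_range[1] + 1))
    state = SpeciesState.from_dict(
        {
            "UXP": uxp,
            "A": a_total,
            "CA": draw(config.ca_range),
            "mRNAca": draw(config.mrna_ca_range),
            "mRNAr": draw(config.mrna_r_range),
            "R": draw(config.r_range),
            "DNAca_free": config.dnaca_copies,
            "DNAr_free": config.dnar_copies,
        }
    )
    assert state["UXP"] > state["A"] + state["A_UXP"]
    return state
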