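# Methods

## The growth–capsulation model

The model couples capsule (CAP) gene expression to the state of the
pyrimidine nucleotide pool through a single abstract signal molecule, UXP,
whose copy number stands in for UTP at the pathway bifurcation. Thirteen
molecular species interact through 23 irreversible mass-action reactions,
one named rate constant per reaction, grouped into four blocks:

* **A — UXP economy.** UXP is produced at a constant rate `k_uxp_prod`
  (the dose knob), drained to nucleotide metabolism by a first-order
  channel (`k_pyrg_drain`; the PyrG branch, with PyrG folded into the
  constant as a constant catalyst), and consumed by CAP synthesis itself
  (`k_cap_feedback`, UXP + CA → 2 CA): once a cell commits to capsule
  production, that commitment draws UXP down, which is the positive
  feedback giving the Cap⁺ state its memory. UXP also reversibly
  sequesters the transcriptional activator A (`k_seq_on`/`k_seq_off`), so
  abundant UXP keeps the CAP genes off.
* **B — CAP transcription.** Free activator binds the CAP promoter
  (`k_act_bind`/`k_act_unbind`); the bound promoter transcribes at
  `k_tx_active`, the free promoter leaks at `k_tx_basal` (this basal
  channel produces the low constant CAP level seen at high UXP), and
  transcripts are translated into CAP at `k_tl_ca` (polymerase folded into
  the constants).
* **C — the return switch.** CAP binds a dedicated repressor-gene promoter
  (`k_capDNAr_bind`/`k_capDNAr_unbind`), driving repressor transcription
  and translation; monomers dimerise (`k_dim_on`/`k_dim_off`,
  cooperativity), and the dimer silences the CAP promoter
  (`k_rep_bind`/`k_rep_unbind`). A repressed promoter transcribes nothing;
  bound mRNA is not actively degraded — baseline turnover continues.
* **D — turnover.** First-order degradation of both transcripts and of
  CAP, repressor monomer and dimer. Repressor decay is what ends the Cap⁻
  episode.

A separate repressor-gene promoter species (`DNAr`) is introduced as the
minimal realisation of a repressor *triggered by* Cap⁺; the CAP promoter
copy number and repressor promoter copy number default to one (single
locus in a single cell). Three invariants hold by construction and are
property-tested: both promoter totals and the activator total are
conserved, no applicable reaction drives a count negative, and each
propensity is linear in its rate constant (homodimerisation uses the
stochastic combinatorial form k·R(R−1)/2).

Initial conditions are randomised per run — activator total 10, UXP
uniform on [20, 100] conditioned to strictly exceed the activator total,
everything else zero — and the first 10,000 s of each 200,000 s simulation
are discarded, so results do not depend on the start state.

## Default rate constants

The published description fixes the network topology and the dose settings
(0.003/0.3/3 molecules·s⁻¹ spanning switcher → ancestor conditions) but
not the 23 rate values. The shipped defaults
(`capswitch/data/default_rates.json`) were therefore chosen to realise the
stated regime targets, and `sweeps.calibrate_defaults` re-certifies them:

* at `k_uxp_prod = 0.003`, both phenotype states occupy ≥ 10 % of the
  window and mean dwells exceed two division-equivalents (2 h), i.e.
  switching is heritable over several divisions;
* at `k_uxp_prod = 3`, CAP stays basal (≤ 1 threshold crossing per 48-h
  window, median over seeds).

Design rationale for the key choices: promoter binding kinetics are fast
relative to mRNA lifetime (`k_act_bind = 0.1`, `k_act_unbind = 0.5` s⁻¹),
so at high UXP the rare moments of activator release are far too short to
transcribe — this is what keeps the ancestor-like regime basal rather than
burst-prone. The CAP module carries ≈ 5 transcripts and ≈ 130 CAP
molecules in the ON state, making the ON/OFF separation (≈ 130 vs ≈ 2)
many standard deviations wide so that Poisson noise cannot flicker the
state call. The Cap⁺ episode ends when the first repressor dimer forms and
captures the promoter: with a slowly accumulating ~20-monomer pool and a
small dimerisation constant (1.5×10⁻⁷), the capture hazard grows ∝ t³,
giving multi-hour dwells with modest dispersion instead of an exponential
race. The Cap⁻ episode is the repressed-promoter hold (1/`k_rep_unbind` ≈
3.5 h) plus pool decay. The UXP feedback constant is kept small
(10⁻⁶) because the CAP pool is only stable when `k_cap_feedback · UXP`
stays below `k_deg_CA`; larger values convert the high-dose UXP influx
into unbounded CAP accumulation.

Because these values are calibrated stand-ins, the published sweep
endpoints (Cap⁻ between 11.6 % and 90.4 % of the time) are matched only
qualitatively: the analysis asserts a wide occupancy span (≥ 0.5) and a
retained two-state structure in ≥ 80 % of the 47 sweep conditions, not the
printed endpoints. At the ±10× extremes a handful of repressor-limited
conditions (e.g. repressor translation ÷10, repressor degradation ×10)
genuinely lose bistability within the simulated window.

## Simulation engine

Gillespie's direct method, exact and event-driven. All randomness comes
from one PCG64 uniform stream consumed two numbers per event (waiting
time, channel), pre-generated in blocks and fed to a resumable kernel; the
kernel is numba-JIT-compiled when numba is importable and otherwise runs
as the identical pure-Python code, so a given seed yields bit-identical
trajectories on both paths. Recording is either event-resolved (canonical)
or sample-and-hold on a fixed grid; occupancy statistics on a grid differ
from exact values by at most one grid step per state change (5 s default
against multi-hour dwells). The state prevailing at the burn-in boundary
seeds the reported path. Zero total propensity is reported as absorption
(the state holds to the horizon); NaN or negative propensities raise
rather than clamp, and an event-count safety cap raises with the partial
trajectory attached.

## Phenotype calls

A cell is Cap⁺ while CAP exceeds a threshold. No threshold is published,
so the default rule is data-driven: build the time-weighted histogram of
CAP copy number, smooth it lightly, and if it is bimodal (two modes ≥ 10
molecules apart separated by a real valley) take the midpoint of the two
heaviest modes; otherwise fall back to a fixed 20 molecules (well below
the ~100-molecule ON state). The threshold used is recorded in every
output, since occupancy numbers are only interpretable relative to it. No
hysteresis or debouncing is applied by default. Dwell times divided by a
3600 s division time (matching the ~60 min observed doubling times)
express heritability in division-equivalents.

## Synthetic microcolony generator

The generator emulates time-lapse microscopy of single founder cells
growing into microcolonies, with phenotype read directly (standing in for
a perfectly correlated fluorescent reporter). It is a continuous-time
Markov branching process: each cell divides after an exponential waiting
time with rate 0.0116 min⁻¹ (Cap⁻) or 0.0113 min⁻¹ (Cap⁺) — growth
"rates" are interpreted as Malthusian parameters, so ln 2/rate reproduces
the observed ~59.8 and ~61.3 min division times, and capsulation is
costly by construction. Phenotype is inherited at division. Each colony
draws a switching threshold from 𝒩(1870, 660²) cells once at birth;
Cap⁻ → Cap⁺ switching occurs at a constant per-cell rate (default
1 min⁻¹) only while the population is at or above the threshold, so in
this threshold-dominated default the first switch fires essentially at
the drawn threshold and first-switch sizes are Gaussian across colonies.
The generator realises the *observation* (Gaussian first-switch sizes)
without asserting a mechanism; whether cells sense population size or
density is left open. Cap⁺ founder-lineage cells revert to Cap⁻ on a fast
exponential clock (mean 30 min — "very short" is not quantified in the
source observations; configurable); post-threshold Cap⁺ cells do not
revert. Colonies run to 1000 min by default (by which time non-switching
colonies are rare) and non-switchers are reported as censored. What the
generator does **not** emulate: spatial colony geometry, cell-size or
age-dependent division, imaging noise, and any coupling between the
intracellular network and division timing — so passing the inference
tests shows estimator correctness under the stated stochastic model, not
robustness to those real-data complications.

The capsule-counting assay is emulated as independent binomial draws
(default 500 cells scored × 5 replicates) at a given true Cap⁺ proportion
(0.0016 ancestor-like, 0.084 switcher-like).

## Inference

* **Growth rates** — OLS slope of ln(population) vs time at division
  events, restricted to epochs where the whole colony holds one phenotype.
  Simultaneous divisions collapse to the final count, and sizes below 8
  cells are excluded because E[ln N(t)] is curved at small N and biases
  the slope. The reported SE is conditional on the realised path; batch
  tests use the spread across independent colonies. The analysis driver
  resolving the ~3 % cost fits only the near-deterministic N ≥ 100 regime
  over 40 colonies per phenotype.
* **Capsulation cost** — 100·(1 − rate₊/rate₋), delta-method SE.
* **Threshold model comparison** — maximum likelihood for (a) a Gaussian
  in first-switch population size (closed form without censoring,
  Nelder–Mead on (μ, log σ) with right-censored survival terms otherwise)
  against (b) a memoryless alternative: a constant per-division switch
  probability gives a geometric law in colony size, p(1−p)^(n−1), with
  censored colonies contributing (1−p)^c — the formalisation of "a random
  process independent of population size". Preference by AIC (k = 2 vs 1).
  Fits are on raw sizes, not log sizes (configurable by transforming the
  input).
* **Proportions** — mean of per-replicate proportions, SE = SD/√reps.
* **Two-sample policy** — Shapiro normality per sample at α = 0.05
  (constant samples count as non-normal); both normal → Levene chooses
  pooled-t vs Welch; otherwise Wilcoxon rank-sum. The branch taken is
  always reported.

## Problem sizes and numerical choices

Simulation-level analyses run at the full 200,000 s horizon with 10,000 s
burn-in and a 5 s recording grid; the dose response uses 10 replicates per
level and the sensitivity sweep 47 × 10 runs (the engine makes the full
sweep a ~1-minute computation with numba). Microcolony batches use 58
colonies (matching the observed sample size) with early stopping after the
first switch where only first-switch sizes are needed; growth-rate batches
use 20–40 colonies to 700–800 min. Monte-Carlo assertions use 3-standard-
error bands; goodness-of-fit checks use α = 0.01 with an allowance for the
expected false-rejection count. Seeds propagate from a single master seed
through `numpy.random.SeedSequence(master, spawn_key=(condition,
replicate))`, so any single run is reproducible in isolation.

## Known limitations

* The 23 default rate constants are calibrated to the qualitative regime
  targets, not fitted to data; quantities that depend on their exact
  values (sweep endpoints, absolute dwell times) are model illustrations.
* The intermediate dose (0.3 molecules·s⁻¹) produces mostly-basal
  trajectories with brief Cap⁺ excursions rather than sustained three-level
  switching.
* A single cell is simulated; division, partitioning noise and
  cell-to-cell variation are outside the chemical model (they appear only
  in the branching-process generator, which is deliberately independent of
  it).
* The phenotype threshold rule is an operationalisation; occupancy figures
  are reported together with the threshold used and change smoothly with
  it.
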