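#!/usr/bin/env python
"""One-at-a-time rate sensitivity: tuning the stochastic switch.

Each of the 23 rate constants is increased and decreased tenfold (plus the
baseline: 47 conditions), ten simulations per condition at the low-flux
default.  The per-condition mean fraction of time in the Cap- state and
mean cumulative occupancy curves quantify how widely the switch can be
tuned; a two-humped curve indicates that both phenotype states remain
accessible.
"""

import argparse
from pathlib import Path

from capswitch.engine import SimConfig
from capswitch.sweeps import run_sensitivity_sweep


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replicates", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sim = SimConfig(t_end=200_000, burn_in=10_000, record_mode="grid",
                    grid_step=5.0)
    table = run_sensitivity_sweep(factor=10.0, replicates=args.replicates,
                                  sim=sim, master_seed=args.seed)
    table.write(args.out / "sensitivity")

    agg = table.aggregated
    frac = agg["mean_fraction_cap_low"]
    two = (agg["two_state_fraction"] >= 0.5)
    print(f"{agg.shape[0]} conditions x {args.replicates} runs "
          f"({len(table.runs)} simulations).")
    print(f"Mean Cap- occupancy spans {frac.min():.3f} .. {frac.max():.3f} "
          "across conditions: stochasticity is tunable over a wide range.")
    print(f"{two.sum()}/{agg.shape[0]} conditions retain a two-state "
          "(two-humped) occupancy structure.")
    lost = agg.loc[~two, "condition"].tolist()
    if lost:
        print("Conditions losing bistability (repressor-limited):", lost)


if __name__ == "__main__":
    main()
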