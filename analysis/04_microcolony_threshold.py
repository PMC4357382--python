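#!/usr/bin/env python
"""Single-cell microcolony analyses: growth cost and switching threshold.

Generates 58 synthetic microcolonies from noncapsulated founders, extracts
the population size at each colony's first Cap- -> Cap+ switch, and fits
the Gaussian-threshold model against the memoryless (constant per-division
hazard) alternative.  Also estimates the two phenotype growth rates from
pure-phenotype colonies and the implied capsulation cost, and demonstrates
rapid reversion of capsulated founders.
"""

import argparse
import json
import math
from pathlib import Path

import numpy as np

from capswitch.colony_stats import (capsulation_cost, estimate_growth_rate,
                                    fit_threshold_models)
from capswitch.microcolony import (CAP_HIGH, CAP_LOW, MicrocolonyParams,
                                   first_switch_size, generate_microcolonies,
                                   generate_microcolony)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-colonies", type=int, default=58)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # first-switch sizes over n colonies
    trees = generate_microcolonies(
        MicrocolonyParams(stop_after_first_switch=True), args.n_colonies,
        args.seed)
    sizes = [first_switch_size(t) for t in trees]
    observed = [s for s in sizes if s is not None]
    censored = [t.population_at(t.end_time)
                for t, s in zip(trees, sizes) if s is None]
    with open(args.out / "first_switch_sizes.tsv", "w") as fh:
        fh.write("colony\tfirst_switch_size\tcensored\n")
        for i, s in enumerate(sizes):
            fh.write(f"{i}\t{'' if s is None else s}\t{int(s is None)}\n")
    g, m, preferred = fit_threshold_models(observed, censored)

    # phenotype growth rates from pure-phenotype colonies; the slope is fit
    # over the near-deterministic large-colony regime (N >= 100) so the
    # ~3% rate difference is resolvable from tens of colonies
    fits = {}
    for phen, founder in ((CAP_LOW, CAP_LOW), (CAP_HIGH, CAP_HIGH)):
        p = MicrocolonyParams(per_cell_switch_rate=0.0,
                              founder_phenotype=founder,
                              founder_reversion_rate=0.0, total_time=800.0)
        rates = []
        for s in range(40):
            tree = generate_microcolony(p, args.seed * 1000 + 77 + s)
            try:  # a rare slow colony may never reach the fitting size
                rates.append(estimate_growth_rate(
                    tree, phen, min_population=100).rate)
            except ValueError:
                continue
        fits[phen] = (float(np.mean(rates)),
                      float(np.std(rates, ddof=1) / math.sqrt(len(rates))),
                      len(rates))
    from capswitch.colony_stats import GrowthFit
    fit_low = GrowthFit(*fits[CAP_LOW], CAP_LOW)
    fit_high = GrowthFit(*fits[CAP_HIGH], CAP_HIGH)
    cost = capsulation_cost(fit_low, fit_high)

    report = {
        "n_colonies": args.n_colonies,
        "n_observed": len(observed),
        "n_censored": len(censored),
        "mean_first_switch_size": float(np.mean(observed)),
        "gaussian_fit": {"mean": g.params[0], "sd": g.params[1], "aic": g.aic},
        "memoryless_fit": {"per_division_hazard": m.params[0], "aic": m.aic},
        "preferred_model": preferred,
        "growth_rate_cap_low": fits[CAP_LOW],
        "growth_rate_cap_high": fits[CAP_HIGH],
        "capsulation_cost_percent": cost.percent,
    }
    (args.out / "microcolony_report.json").write_text(json.dumps(report, indent=1))

    print(f"{len(observed)}/{args.n_colonies} colonies switched; "
          f"mean first-switch size {np.mean(observed):.0f} cells "
          f"(generating Gaussian 1870 +/- 660).")
    print(f"Model comparison: gaussian AIC {g.aic:.1f} vs memoryless AIC "
          f"{m.aic:.1f} -> {preferred} preferred: switching depends on "
          "population size, not a size-independent random process.")
    print(f"Growth rates: Cap- {fit_low.rate:.5f}/min, Cap+ {fit_high.rate:.5f}/min "
          f"-> capsulation cost {cost.percent:.1f}% "
          f"(doubling {fit_low.doubling_time_min:.1f} vs "
          f"{fit_high.doubling_time_min:.1f} min).")


if __name__ == "__main__":
    main()
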