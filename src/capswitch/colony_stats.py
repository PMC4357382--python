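"""Inference on microcolony and capsule-assay data.

Covers the single-cell analyses: phenotype-specific growth-rate estimation
(log-linear fit of population size against time within same-phenotype
epochs), the capsulation growth cost, maximum-likelihood comparison of a
Gaussian population-size threshold against a memoryless (constant
per-division hazard) alternative for first-switch sizes, replicate
proportion estimates with standard errors, and the two-sample testing
policy (t/Welch when both samples look normal, Wilcoxon rank-sum
otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .microcolony import AssayCounts, CAP_LOW, LineageTree

__all__ = [
    "GrowthFit",
    "ThresholdFit",
    "CostEstimate",
    "TestResult",
    "estimate_growth_rate",
    "capsulation_cost",
    "fit_threshold_models",
    "proportion_capsulated",
    "two_sample_compare",
]


@dataclass(frozen=True)
class GrowthFit:
    """Estimated Malthusian growth rate for one phenotype."""

    rate: float            # min^-1
    se: float              # standard error of the slope
    n: int                 # population-size observations used
    phenotype: str

    @property
    def doubling_time_min(self) -> float:
        return math.log(2.0) / self.rate


@dataclass(frozen=True)
class ThresholdFit:
    """Maximum-likelihood fit of one first-switch-size model."""

    model: str                     # "gaussian" | "memoryless"
    params: Tuple[float, ...]      # (mean, sd) or (per_division_hazard,)
    loglik: float
    n_events: int
    n_censored: int

    @property
    def aic(self) -> float:
        return 2.0 * len(self.params) - 2.0 * self.loglik


@dataclass(frozen=True)
class CostEstimate:
    percent: float
    se_percent: float


@dataclass(frozen=True)
class TestResult:
    test: str              # "t", "welch" or "wilcoxon"
    statistic: float
    pvalue: float
    normality_pvalues: Tuple[float, float]


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def _pure_epochs(tree: LineageTree, phenotype: str
                 ) -> List[Tuple[float, float]]:
    """Intervals during which every alive cell holds *phenotype*."""
    t_all, n_all = tree.population_curve()
    t_ph, n_ph = tree.phenotype_population_curve(phenotype)
    if t_ph.size == 0:
        return []
    # merge change points; an epoch is pure while counts coincide and > 0
    points = np.unique(np.concatenate([t_all, t_ph, [tree.end_time]]))
    epochs: List[Tuple[float, float]] = []
    start = None
    for a, b in zip(points[:-1], points[1:]):
        mid = 0.5 * (a + b)
        total = n_all[np.searchsorted(t_all, mid, side="right") - 1] if t_all.size else 0
        k = n_ph[np.searchsorted(t_ph, mid, side="right") - 1] if \
            (t_ph.size and mid >= t_ph[0]) else 0
        if total > 0 and k == total:
            if start is None:
                start = a
        else:
            if start is not None:
                epochs.append((start, a))
                start = None
    if start is not None:
        epochs.append((start, points[-1]))
    return epochs


def estimate_growth_rate(tree: LineageTree, phenotype: str = CAP_LOW,
                         min_population: int = 8) -> GrowthFit:
    """Least-squares slope of ln(population) vs time over pure epochs.

    Observations are the population sizes at division events falling inside
    epochs where the whole colony holds *phenotype*.  Simultaneous divisions
    collapse to the final count at that instant, and sizes below
    *min_population* are dropped: at very small sizes ln N(t) is curved in
    expectation and would bias the slope of a Markov branching process.
    Requires at least three observations.  The reported SE is the OLS slope
    error, conditional on the realised path.
    """
    epochs = _pure_epochs(tree, phenotype)
    t_all, n_all = tree.population_curve()
    # keep the last population value at each unique time (simultaneous events)
    _, last_idx = np.unique(t_all[::-1], return_index=True)
    keep = len(t_all) - 1 - last_idx
    t_all, n_all = t_all[np.sort(keep)], n_all[np.sort(keep)]
    ts: List[float] = []
    ns: List[float] = []
    for a, b in epochs:
        mask = (t_all >= a) & (t_all <= b) & (n_all >= min_population)
        ts.extend(t_all[mask])
        ns.extend(n_all[mask])
    if len(ts) < 3:
        raise ValueError(
            f"need >= 3 population observations for {phenotype}, got {len(ts)}"
        )
    res = stats.linregress(np.asarray(ts), np.log(np.asarray(ns, dtype=float)))
    return GrowthFit(rate=float(res.slope), se=float(res.stderr),
                     n=len(ts), phenotype=phenotype)


def capsulation_cost(fit_low: GrowthFit, fit_high: GrowthFit) -> CostEstimate:
    """Percent growth cost of capsulation: 100*(1 - rate_high/rate_low).

    The standard error is propagated from the two slope SEs by the delta
    method.
    """
    if fit_low.rate <= 0:
        raise ValueError("Cap- growth rate must be positive")
    ratio = fit_high.rate / fit_low.rate
    var = (fit_high.se / fit_low.rate) ** 2 + \
          (fit_high.rate * fit_low.se / fit_low.rate ** 2) ** 2
    return CostEstimate(percent=100.0 * (1.0 - ratio),
                        se_percent=100.0 * math.sqrt(var))


# ---------------------------------------------------------------------------
# first-switch-size models
# ---------------------------------------------------------------------------


def _gaussian_fit(sizes: np.ndarray, censored: np.ndarray) -> ThresholdFit:
    n_ev, n_cen = len(sizes), len(censored)
    if n_cen == 0:
        mu = float(sizes.mean())
        sd = float(sizes.std(ddof=0))
        sd = max(sd, 1e-9)
        ll = float(stats.norm.logpdf(sizes, mu, sd).sum())
        return ThresholdFit("gaussian", (mu, sd), ll, n_ev, 0)

    def nll(theta):
        mu, log_sd = theta
        sd = math.exp(log_sd)
        ll = stats.norm.logpdf(sizes, mu, sd).sum()
        ll += stats.norm.logsf(censored, mu, sd).sum()
        return -ll

    x0 = np.array([sizes.mean(), math.log(max(sizes.std(ddof=0), 1.0))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    mu, sd = float(res.x[0]), float(math.exp(res.x[1]))
    return ThresholdFit("gaussian", (mu, sd), float(-res.fun), n_ev, n_cen)


def _memoryless_fit(sizes: np.ndarray, censored: np.ndarray) -> ThresholdFit:
    # constant per-division switch probability p: first switch at colony
    # size n has geometric likelihood p*(1-p)^(n-1); a colony censored at
    # size c contributes (1-p)^c.  Closed-form MLE.
    d = len(sizes)
    denom = float(sizes.sum() + censored.sum())
    p = d / denom
    q = 1.0 - p
    ll = d * math.log(p) + float((sizes - 1).sum()) * math.log(q) \
        + float(censored.sum()) * math.log(q)
    return ThresholdFit("memoryless", (p,), ll, d, len(censored))


def fit_threshold_models(sizes: Sequence[float],
                         censored: Optional[Sequence[float]] = None
                         ) -> Tuple[ThresholdFit, ThresholdFit, str]:
    """Fit Gaussian and memoryless models to first-switch population sizes.

    *sizes* are observed first-switch sizes; *censored* are final colony
    sizes of colonies that never switched (right-censoring).  Returns the
    two fits and the AIC-preferred model name.  A Gaussian preference
    supports a population-size threshold; a memoryless preference supports
    switching as a size-independent random process.
    """
    sizes = np.asarray([s for s in sizes], dtype=float)
    censored_arr = np.asarray(list(censored) if censored else [], dtype=float)
    if sizes.size == 0:
        raise ValueError("all colonies censored: no observed switch events")
    if sizes.size < 5:
        raise ValueError(f"need >= 5 uncensored switch events, got {sizes.size}")
    if np.any(sizes < 1) or np.any(censored_arr < 0):
        raise ValueError("sizes must be positive")
    g = _gaussian_fit(sizes, censored_arr)
    m = _memoryless_fit(sizes, censored_arr)
    preferred = "gaussian" if g.aic < m.aic else "memoryless"
    return g, m, preferred


# ---------------------------------------------------------------------------
# assay proportions and the two-sample policy
# ---------------------------------------------------------------------------


def proportion_capsulated(assay: AssayCounts) -> Tuple[float, float]:
    """Mean per-replicate Cap+ proportion and its standard error.

    SE is the sample standard deviation of the replicate proportions over
    sqrt(number of replicates).
    """
    props = assay.proportions
    if len(props) < 2:
        raise ValueError("need >= 2 replicates for a standard error")
    mean = float(props.mean())
    se = float(props.std(ddof=1) / math.sqrt(len(props)))
    return mean, se


def _normality_p(x: np.ndarray) -> float:
    # constant samples violate normality trivially (Shapiro is undefined)
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def two_sample_compare(x: Iterable[float], y: Iterable[float],
                       alpha: float = 0.05) -> TestResult:
    """Two-sample comparison under the stated testing policy.

    Shapiro normality check per sample at *alpha*; if both pass, Levene's
    test chooses between the pooled-variance t test and Welch's t test;
    otherwise the Wilcoxon rank-sum test is applied.  The branch taken is
    recorded in the result.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs >= 3 observations")
    px, py = _normality_p(x), _normality_p(y)
    if px > alpha and py > alpha:
        equal_var = stats.levene(x, y).pvalue > alpha
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        name = "t" if equal_var else "welch"
        return TestResult(name, float(res.statistic), float(res.pvalue), (px, py))
    res = stats.ranksums(x, y)
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue), (px, py))
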