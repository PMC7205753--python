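"""Operating characteristics of the adaptive design by Monte Carlo replication.

Each replicate simulates one full trial (optionally drawing its linkage
parameters from the posterior of the historical model, so that uncertainty in
the surrogate-primary relationship propagates into the design's operating
characteristics), runs the closed combination test on the realized data, and
aggregates: per-arm selection probabilities, carry-forward and futility
probabilities, overall and conditional power, the false-stopping
("flip-flop") probability, and expected sample size.  Sample-size searches
for both the adaptive design and a traditional single-stage Dunnett design
use bisection with common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SearchError, ValidationError
from .historical import PosteriorDraws
from .testing import analyze_trial, dunnett_critical_value, logrank_uv
from .trial import (
    THREE_YEARS_WEEKS,
    DesignConfig,
    event_rate_to_hazard,
    sample_size_accounting,
    simulate_trial,
)

__all__ = [
    "OCConfig",
    "OCResult",
    "run_oc",
    "threshold_sweep",
    "false_stopping_probability",
    "find_stage2_n",
    "traditional_design_n",
    "traditional_design_power",
    "type_one_error_scan",
]


@dataclass(frozen=True)
class OCConfig:
    """Replication settings for an operating-characteristics run."""

    n_replicates: int = 5000
    parameter_mode: str = "fixed"  # "fixed" | "posterior_draws"
    fixed_params: tuple = (0.16, -1.37, 1.53)  # (a, b, sigma)
    master_seed: int = 0
    compute_counterfactual: bool = False
    compute_tests: bool = True  # skip per-replicate testing for decision-only summaries

    def __post_init__(self):
        problems = []
        if self.n_replicates < 100:
            problems.append("n_replicates: must be >= 100")
        if self.parameter_mode not in ("fixed", "posterior_draws"):
            problems.append("parameter_mode: must be 'fixed' or 'posterior_draws'")
        if self.parameter_mode == "fixed" and len(self.fixed_params) != 3:
            problems.append("fixed_params: need (a, b, sigma)")
        if problems:
            raise ConfigurationError(problems)


@dataclass(frozen=True)
class OCResult:
    """Aggregated operating characteristics over replicates.

    Probabilities are proportions of replicates; ``mc_se`` holds binomial
    Monte-Carlo standard errors.  ``false_stopping`` is the JOINT probability
    of stopping at IA and the counterfactual continuation reaching
    significance (NaN unless the counterfactual was computed).
    """

    p_select: np.ndarray  # per active arm
    p_carry_forward: float
    p_futility: float
    overall_power: float
    conditional_power: float
    false_stopping: float
    expected_n: float
    mean_analysed_n: float
    n_replicates: int
    mc_se: dict = field(default_factory=dict)
    threshold_delta: float = np.nan

    def to_dict(self) -> dict:
        d = {
            "threshold_delta": self.threshold_delta,
            "n_replicates": self.n_replicates,
            "p_carry_forward": self.p_carry_forward,
            "p_futility": self.p_futility,
            "overall_power": self.overall_power,
            "conditional_power": self.conditional_power,
            "false_stopping": self.false_stopping,
            "expected_n": self.expected_n,
            "mean_analysed_n": self.mean_analysed_n,
        }
        for i, p in enumerate(self.p_select, start=1):
            d[f"p_select_arm{i}"] = p
        for key, se in self.mc_se.items():
            d[f"se_{key}"] = se
        return d


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1.0 - p), 0.0) / n))


def _replicate_params(oc: OCConfig, draws_or_params):
    """Resolve per-replicate (a, b, sigma) triples."""
    n = oc.n_replicates
    if oc.parameter_mode == "fixed":
        params = tuple(float(v) for v in (draws_or_params or oc.fixed_params))
        return [params] * n
    if not isinstance(draws_or_params, PosteriorDraws):
        raise ValidationError("posterior_draws mode requires a PosteriorDraws object")
    if len(draws_or_params) < n:
        raise ValidationError(
            f"need >= {n} posterior draws for {n} replicates, got {len(draws_or_params)}"
        )
    return list(
        zip(
            draws_or_params.a_draws[:n],
            draws_or_params.b_draws[:n],
            draws_or_params.sigma_draws[:n],
        )
    )


def _rep_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(rep,))


def run_oc(design: DesignConfig, oc: OCConfig, draws_or_params=None) -> OCResult:
    """Estimate operating characteristics over ``oc.n_replicates`` trials.

    Power is the probability of rejecting at least one elementary hypothesis
    in the closed combination test; a futility stop counts as a failure.
    Replicate r uses the seed stream (master_seed, r), so identical seeds
    give bitwise-identical results and design variants sharing a master seed
    share trial realizations (common random numbers).
    """
    params = _replicate_params(oc, draws_or_params)
    n = oc.n_replicates
    k = design.n_active

    select_counts = np.zeros(k)
    n_stop = 0
    n_reject = 0
    n_false_stop = 0
    tot_enrolled = 0.0
    tot_analysed = 0.0

    for rep in range(n):
        a, b, sigma = params[rep]
        seed = _rep_seed(oc.master_seed, rep)
        trial = simulate_trial(design, a, b, sigma, seed=seed)
        acc = sample_size_accounting(trial, design)
        tot_enrolled += acc.enrolled
        tot_analysed += acc.analysed
        if trial.decision.futility_stop:
            n_stop += 1
            if oc.compute_counterfactual and oc.compute_tests:
                cf = simulate_trial(design, a, b, sigma, seed=seed, force_continue=True)
                if analyze_trial(cf, design).any_rejected():
                    n_false_stop += 1
        else:
            (sel,) = trial.decision.selected_arms
            select_counts[sel - 1] += 1
            if oc.compute_tests and analyze_trial(trial, design).any_rejected():
                n_reject += 1

    p_stop = n_stop / n
    p_carry = 1.0 - p_stop
    power = n_reject / n if oc.compute_tests else np.nan
    cond_power = power / p_carry if (oc.compute_tests and p_carry > 0) else np.nan
    false_stop = (
        n_false_stop / n if (oc.compute_counterfactual and oc.compute_tests) else np.nan
    )
    mc_se = {
        "p_carry_forward": _binom_se(p_carry, n),
        "overall_power": _binom_se(power, n) if oc.compute_tests else np.nan,
        "false_stopping": _binom_se(false_stop, n) if np.isfinite(false_stop) else np.nan,
    }
    return OCResult(
        p_select=select_counts / n,
        p_carry_forward=p_carry,
        p_futility=p_stop,
        overall_power=power,
        conditional_power=cond_power,
        false_stopping=false_stop,
        expected_n=tot_enrolled / n,
        mean_analysed_n=tot_analysed / n,
        n_replicates=n,
        mc_se=mc_se,
        threshold_delta=design.threshold_delta,
    )


def threshold_sweep(design: DesignConfig, thresholds, oc: OCConfig, draws_or_params=None):
    """One OCResult per interim threshold, common random numbers throughout.

    Returns a tidy DataFrame, one row per threshold.  Because every variant
    shares the master seed, the same stage-1 realizations are re-decided at
    each threshold and carry-forward probability is non-increasing in Delta
    replicate-wise.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValidationError("thresholds must be non-empty")
    rows = []
    for delta in thresholds:
        res = run_oc(replace(design, threshold_delta=float(delta)), oc, draws_or_params)
        rows.append(res.to_dict())
    return pd.DataFrame(rows)


def false_stopping_probability(design: DesignConfig, oc: OCConfig, draws_or_params=None) -> float:
    """Joint probability that a trial stops at IA AND its counterfactual
    continuation (observed-best arm carried forward) reaches significance."""
    if not oc.compute_counterfactual:
        oc = replace(oc, compute_counterfactual=True)
    return run_oc(design, oc, draws_or_params).false_stopping


def _bisect_smallest(grid, predicate):
    """Smallest grid value whose monotone predicate holds, by bisection."""
    lo, hi = 0, len(grid) - 1
    if not predicate(grid[hi]):
        raise SearchError(f"target not reachable on grid (max tried: {grid[hi]})")
    if predicate(grid[lo]):
        return grid[lo]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if predicate(grid[mid]):
            hi = mid
        else:
            lo = mid
    return grid[hi]


def find_stage2_n(
    design: DesignConfig,
    target_power: float,
    oc: OCConfig,
    draws_or_params=None,
    n_grid=None,
) -> int:
    """Smallest stage-2 per-arm size on the grid with overall power >= target.

    Bisection with common random numbers (shared master seed) so estimated
    power is non-decreasing in n2 replicate-wise up to stage-2 sampling noise.
    """
    if n_grid is None:
        n_grid = list(range(design.n_stage1_per_arm, 301, 2))
    n_grid = sorted(int(v) for v in n_grid)

    cache = {}

    def power_at(n2):
        if n2 not in cache:
            cache[n2] = run_oc(replace(design, n_stage2_per_arm=n2), oc, draws_or_params)
        return cache[n2].overall_power

    return int(_bisect_smallest(n_grid, lambda n2: power_at(n2) >= target_power))


def _simulate_single_stage_z(rng, n_per_arm, event_rates, followup, dropout_3yr):
    """Stage-less comparator trial: per-comparison log-rank Z at full follow-up."""
    k_all = len(event_rates)
    hazards = np.array([event_rate_to_hazard(r, THREE_YEARS_WEEKS) for r in event_rates])
    drop_rate = (
        event_rate_to_hazard(dropout_3yr, THREE_YEARS_WEEKS) if dropout_3yr > 0 else 0.0
    )
    latent = rng.exponential(1.0, size=(k_all, n_per_arm)) / hazards[:, None]
    if drop_rate > 0:
        dropout = rng.exponential(1.0 / drop_rate, size=(k_all, n_per_arm))
    else:
        dropout = np.full((k_all, n_per_arm), np.inf)
    obs = np.minimum.reduce([latent, dropout, np.full((k_all, n_per_arm), followup)])
    ev = latent <= np.minimum(dropout, followup)
    zs = np.empty(k_all - 1)
    for i in range(1, k_all):
        times = np.concatenate([obs[0], obs[i]])
        events = np.concatenate([ev[0], ev[i]])
        grp = np.concatenate([np.zeros(n_per_arm, bool), np.ones(n_per_arm, bool)])
        zs[i - 1] = logrank_uv(times, events, grp).z
    return zs


def traditional_design_power(
    n_per_arm: int,
    event_rates,
    alpha: float = 0.025,
    followup_weeks: float = THREE_YEARS_WEEKS,
    dropout_3yr: float = 0.05,
    n_replicates: int = 5000,
    master_seed: int = 0,
) -> float:
    """Simulated power of the single-stage Dunnett design (reject >= 1 arm)."""
    k = len(event_rates) - 1
    crit = dunnett_critical_value(k, alpha)
    n_hit = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(_rep_seed(master_seed, rep))
        zs = _simulate_single_stage_z(rng, n_per_arm, event_rates, followup_weeks, dropout_3yr)
        if zs.max() > crit:
            n_hit += 1
    return n_hit / n_replicates


def traditional_design_n(
    event_rates,
    alpha: float = 0.025,
    target_power: float = 0.90,
    followup_weeks: float = THREE_YEARS_WEEKS,
    dropout_3yr: float = 0.05,
    oc: OCConfig | None = None,
    n_grid=None,
) -> int:
    """Per-arm n for the traditional 4-arm single-stage Dunnett design.

    Smallest n on the grid (default 10..250) whose simulated probability of
    claiming significance on at least one active arm reaches the target,
    found by bisection with common random numbers.
    """
    oc = oc or OCConfig()
    if n_grid is None:
        n_grid = list(range(10, 251))
    n_grid = sorted(int(v) for v in n_grid)
    cache = {}

    def power_at(n):
        if n not in cache:
            cache[n] = traditional_design_power(
                n,
                event_rates,
                alpha=alpha,
                followup_weeks=followup_weeks,
                dropout_3yr=dropout_3yr,
                n_replicates=oc.n_replicates,
                master_seed=oc.master_seed,
            )
        return cache[n]

    return int(_bisect_smallest(n_grid, lambda n: power_at(n) >= target_power))


def type_one_error_scan(
    null_rates, thresholds, design: DesignConfig, oc: OCConfig, draws_or_params=None
):
    """FWER of the full adaptive pipeline over a grid of global nulls.

    For each (rate, Delta) all arms share the 3-year event rate ``rate``;
    the reported cell is the probability of rejecting at least one (true)
    elementary hypothesis.
    """
    rows = []
    for rate in null_rates:
        arms = tuple(
            replace(armspec, event_rate_3yr=float(rate)) for armspec in design.arms
        )
        base = replace(design, arms=arms)
        for delta in thresholds:
            res = run_oc(replace(base, threshold_delta=float(delta)), oc, draws_or_params)
            rows.append(
                {
                    "event_rate_3yr": float(rate),
                    "threshold_delta": float(delta),
                    "fwer": res.overall_power,
                    "se_fwer": res.mc_se["overall_power"],
                    "n_replicates": res.n_replicates,
                }
            )
    return pd.DataFrame(rows)
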