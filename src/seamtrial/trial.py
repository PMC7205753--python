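"""End-to-end simulation of one two-stage adaptive dose-selection trial.

Stage 1 randomizes subjects over all arms (control + k active doses) under a
constant deterministic enrollment rate.  When the preplanned number of
subjects per arm has carried the surrogate through its maturation window, an
interim analysis (IA) either selects the observed-best active arm — if its
surrogate-mean margin over control reaches the threshold Delta — or stops the
trial for futility.  Stage 2 continues enrollment into the control and the
selected arm only, up to the preplanned per-arm quota.

Event times are exponential, calibrated so that the probability of an event
by 3 years (156 weeks) equals the per-arm design rate; the direction of
benefit is a SHORTER time to event (time to confirmed improvement), so higher
event rates are better.  Surrogate values are generated by inverting the
log-normal linkage model: X = (log T - a)/b + eps', eps' ~ N(0, (sigma/b)^2),
driven by the latent (uncensored) event time.  Dropout is an independent
exponential censoring process calibrated to the design's 3-year dropout
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateSlopeError, ValidationError

__all__ = [
    "ArmSpec",
    "DesignConfig",
    "InterimDecision",
    "TrialDataset",
    "SampleSizeAccounting",
    "event_rate_to_hazard",
    "simulate_surrogate",
    "apply_decision_rule",
    "simulate_trial",
    "sample_size_accounting",
]

THREE_YEARS_WEEKS = 156.0
_MIN_ABS_SLOPE = 1e-6


@dataclass(frozen=True)
class ArmSpec:
    name: str
    role: str  # "control" | "active"
    event_rate_3yr: float

    def __post_init__(self):
        if self.role not in ("control", "active"):
            raise ValidationError(f"arm role must be control/active, got {self.role!r}")
        if not 0.0 < self.event_rate_3yr < 1.0:
            raise ValidationError(f"event_rate_3yr must be in (0,1), got {self.event_rate_3yr}")


@dataclass(frozen=True)
class DesignConfig:
    """All design constants of the two-stage adaptive trial.

    Defaults reproduce the worked design example: 4 arms, 20/arm in stage 1
    with a 26-week surrogate maturation window, enrollment at 80 subjects per
    26 weeks (so the IA lands at week 52), 124/arm preplanned in stage 2
    (including the pre-IA immature enrollees of the continuing arms),
    3-year follow-up, 5% 3-year dropout, one-sided alpha 2.5%.
    """

    arms: tuple
    n_stage1_per_arm: int = 20
    n_stage2_per_arm: int = 124
    threshold_delta: float = 0.3
    surrogate_maturation_weeks: float = 26.0
    followup_weeks: float = THREE_YEARS_WEEKS
    enrollment_rate: float | None = None  # subjects/week; default n_arms*n_stage1/maturation
    dropout_3yr: float = 0.05
    alpha_one_sided: float = 0.025
    n_select: int = 1
    weight_convention: str = "sqrt-sample-fraction"
    weights: tuple | None = None  # explicit (w1, w2) override

    def __post_init__(self):
        problems = []
        arms = tuple(self.arms)
        object.__setattr__(self, "arms", arms)
        if sum(1 for a in arms if a.role == "control") != 1:
            problems.append("arms: exactly one control arm required")
        elif arms[0].role != "control":
            problems.append("arms: control arm must come first")
        if len(arms) < 2:
            problems.append("arms: need at least one active arm")
        if self.n_stage1_per_arm < 2:
            problems.append("n_stage1_per_arm: must be >= 2")
        if self.n_stage2_per_arm < self.n_stage1_per_arm:
            problems.append(
                "n_stage2_per_arm: must be >= n_stage1_per_arm "
                "(stage-2 quota includes pre-IA immature enrollees)"
            )
        if np.isnan(self.threshold_delta):
            problems.append("threshold_delta: must not be NaN")
        if self.followup_weeks < self.surrogate_maturation_weeks:
            problems.append("followup_weeks: must be >= surrogate_maturation_weeks")
        if not 0.0 <= self.dropout_3yr < 1.0:
            problems.append("dropout_3yr: must be in [0,1)")
        if not 0.0 < self.alpha_one_sided < 0.5:
            problems.append("alpha_one_sided: must be in (0, 0.5)")
        if self.n_select != 1:
            problems.append("n_select: only single-arm selection is supported")
        if self.enrollment_rate is not None and self.enrollment_rate <= 0:
            problems.append("enrollment_rate: must be > 0")
        if self.weights is not None:
            w1, w2 = self.weights
            if w1 < 0 or w2 < 0 or abs(w1**2 + w2**2 - 1.0) > 1e-9:
                problems.append("weights: need w1,w2 >= 0 with w1^2 + w2^2 = 1")
        if problems:
            raise ConfigurationError(problems)

    @classmethod
    def from_event_rates(cls, event_rates, arm_names=None, **kwargs) -> "DesignConfig":
        """Build a design from 3-year event rates, control first."""
        rates = list(event_rates)
        if arm_names is None:
            arm_names = ["control"] + [f"dose_{i}" for i in range(1, len(rates))]
        arms = tuple(
            ArmSpec(name, "control" if i == 0 else "active", r)
            for i, (name, r) in enumerate(zip(arm_names, rates))
        )
        return cls(arms=arms, **kwargs)

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def n_active(self) -> int:
        return self.n_arms - 1

    @property
    def rate(self) -> float:
        """Enrollment rate in subjects/week."""
        if self.enrollment_rate is not None:
            return float(self.enrollment_rate)
        return self.n_arms * self.n_stage1_per_arm / self.surrogate_maturation_weeks

    @property
    def event_rates(self) -> np.ndarray:
        return np.array([a.event_rate_3yr for a in self.arms])

    def stage_weights(self) -> tuple:
        """Inverse-normal combination weights with w1^2+w2^2=1.

        Square-root of the per-comparison information fraction of the
        preplanned sample sizes: n1 = 2*n_stage1 and n2 = 2*n_stage2 subjects
        enter each treatment-vs-control comparison in stages 1 and 2.
        """
        if self.weights is not None:
            return tuple(self.weights)
        n1 = 2.0 * self.n_stage1_per_arm
        n2 = 2.0 * self.n_stage2_per_arm
        return (np.sqrt(n1 / (n1 + n2)), np.sqrt(n2 / (n1 + n2)))


@dataclass(frozen=True)
class InterimDecision:
    selected_arms: tuple  # active-arm indices (1-based over the arm list)
    futility_stop: bool
    observed_means: np.ndarray  # per-arm surrogate means at IA, control first
    forced: bool = False

    def __post_init__(self):
        if self.futility_stop and self.selected_arms:
            raise ValidationError("a futility stop cannot select arms")


@dataclass
class TrialDataset:
    """One simulated trial, stored column-wise (one entry per subject)."""

    arm: np.ndarray  # arm index, 0 = control
    enroll_week: np.ndarray
    latent_event_week: np.ndarray  # weeks since enrollment, uncensored
    dropout_week: np.ndarray  # weeks since enrollment, inf when no dropout
    surrogate: np.ndarray
    surrogate_mature_at_ia: np.ndarray  # bool
    in_analysis_set: np.ndarray  # bool
    ia_calendar_week: float
    final_calendar_week: float
    decision: InterimDecision

    @property
    def n_subjects(self) -> int:
        return self.arm.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_subjects),
                "arm": self.arm,
                "enroll_week": self.enroll_week,
                "latent_event_week": self.latent_event_week,
                "dropout_week": self.dropout_week,
                "surrogate": self.surrogate,
                "surrogate_mature_at_ia": self.surrogate_mature_at_ia,
                "in_analysis_set": self.in_analysis_set,
            }
        )


@dataclass(frozen=True)
class SampleSizeAccounting:
    enrolled: int
    analysed: int
    excluded: int
    enrolled_at_ia: int


def event_rate_to_hazard(rate_3yr: float, horizon_weeks: float = THREE_YEARS_WEEKS) -> float:
    """Exponential hazard/week such that P(event <= horizon) = rate_3yr."""
    if not 0.0 < rate_3yr < 1.0:
        raise ValidationError(f"event rate must be in (0,1), got {rate_3yr}")
    return -np.log1p(-rate_3yr) / horizon_weeks


def simulate_surrogate(latent_event_week, a, b, sigma, rng) -> np.ndarray:
    """Invert the linkage model: X = (log T - a)/b + N(0, (sigma/|b|)^2).

    Driven by the *latent* event time: the linkage ties the surrogate to the
    event process itself, censoring being a separate observation process.
    """
    if abs(b) < _MIN_ABS_SLOPE:
        raise DegenerateSlopeError(f"|b| = {abs(b)} too small to invert the linkage model")
    t = np.asarray(latent_event_week, float)
    if np.any(t <= 0):
        raise ValidationError("latent event times must be > 0")
    noise = rng.standard_normal(t.shape) * (sigma / abs(b)) if sigma > 0 else 0.0
    return (np.log(t) - a) / b + noise


def apply_decision_rule(means, control_mean, delta, rng=None) -> InterimDecision:
    """Interim rule: pick the best active arm iff its margin over control >= delta.

    ``means`` are the per-active-arm surrogate means at IA (arm order
    preserved, index i corresponds to active arm i+1).  Exact ties for the
    maximum are broken uniformly at random.
    """
    means = np.asarray(means, float)
    if means.size == 0:
        raise ValidationError("need at least one active-arm mean")
    rng = rng or np.random.default_rng()
    best = np.flatnonzero(means == means.max())
    pick = int(best[0] if best.size == 1 else rng.choice(best))
    observed = np.concatenate([[control_mean], means])
    if means[pick] - control_mean >= delta:
        return InterimDecision((pick + 1,), False, observed)
    return InterimDecision((), True, observed)


def _child_rng(seed, *key) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        ss = np.random.SeedSequence(entropy=seed.entropy, spawn_key=tuple(seed.spawn_key) + key)
    else:
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return np.random.default_rng(ss)


def _permuted_blocks(rng, open_arms, n_assign):
    """Permuted-block randomization over ``open_arms``; partial last block."""
    out = np.empty(n_assign, int)
    k = len(open_arms)
    pos = 0
    while pos < n_assign:
        block = rng.permutation(open_arms)
        take = min(k, n_assign - pos)
        out[pos : pos + take] = block[:take]
        pos += take
    return out


def _draw_subject_outcomes(rng, arm_idx, hazards, dropout_rate, a, b, sigma):
    lam = hazards[arm_idx]
    latent = rng.exponential(1.0 / lam)
    if dropout_rate > 0:
        dropout = rng.exponential(1.0 / dropout_rate, size=arm_idx.size)
    else:
        dropout = np.full(arm_idx.size, np.inf)
    surr = simulate_surrogate(latent, a, b, sigma, rng)
    return latent, dropout, surr


def simulate_trial(
    config: DesignConfig,
    a: float,
    b: float,
    sigma: float,
    seed=0,
    force_continue: bool = False,
) -> TrialDataset:
    """Simulate one adaptive trial under linkage parameters (a, b, sigma).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  Three
    independent streams are derived from it: stage-1 enrollment/outcomes, the
    tie-break draw, and stage-2 enrollment/outcomes.  The stage-2 stream is
    additionally keyed by the selected arm, so re-deciding the same stage-1
    data at a different threshold reuses identical stage-2 data whenever the
    same arm is selected (common random numbers across design variants).

    ``force_continue=True`` carries the observed-best arm forward even when
    it misses the threshold — the counterfactual continuation used for the
    false-stopping ("flip-flop") probability.
    """
    if abs(b) < _MIN_ABS_SLOPE:
        raise DegenerateSlopeError(f"|b| = {abs(b)} too small to invert the linkage model")
    rate = config.rate
    k_all = config.n_arms
    n1 = config.n_stage1_per_arm
    hazards = np.array([event_rate_to_hazard(r, THREE_YEARS_WEEKS) for r in config.event_rates])
    dropout_rate = (
        event_rate_to_hazard(config.dropout_3yr, THREE_YEARS_WEEKS)
        if config.dropout_3yr > 0
        else 0.0
    )

    rng1 = _child_rng(seed, 11)
    rng_tie = _child_rng(seed, 13)

    # deterministic arrivals at j/rate; IA when every arm has n1 mature subjects
    n_mature_total = k_all * n1
    ia_week = config.surrogate_maturation_weeks + n_mature_total / rate
    n_pre_ia = int(np.floor(ia_week * rate + 1e-9))
    enroll1 = (np.arange(1, n_pre_ia + 1)) / rate
    arm1 = _permuted_blocks(rng1, np.arange(k_all), n_pre_ia)
    latent1, dropout1, surr1 = _draw_subject_outcomes(
        rng1, arm1, hazards, dropout_rate, a, b, sigma
    )
    mature1 = enroll1 + config.surrogate_maturation_weeks <= ia_week + 1e-9

    # interim decision on mature subjects only
    act_means = np.array(
        [surr1[mature1 & (arm1 == i)].mean() for i in range(1, k_all)]
    )
    control_mean = float(surr1[mature1 & (arm1 == 0)].mean())
    decision = apply_decision_rule(act_means, control_mean, config.threshold_delta, rng_tie)
    if decision.futility_stop and force_continue:
        forced = apply_decision_rule(act_means, control_mean, -np.inf, _child_rng(seed, 19))
        decision = InterimDecision(
            forced.selected_arms, False, forced.observed_means, forced=True
        )

    if decision.futility_stop:
        in_set = mature1.copy()  # no final analysis; only mature data were used
        return TrialDataset(
            arm=arm1,
            enroll_week=enroll1,
            latent_event_week=latent1,
            dropout_week=dropout1,
            surrogate=surr1,
            surrogate_mature_at_ia=mature1,
            in_analysis_set=in_set,
            ia_calendar_week=ia_week,
            final_calendar_week=ia_week,
            decision=decision,
        )

    # stage 2: top up control + selected arm(s) to n_stage1 + n_stage2 subjects
    continuing = np.array([0] + sorted(decision.selected_arms))
    target = n1 + config.n_stage2_per_arm
    counts_ia = np.bincount(arm1, minlength=k_all)
    needed = {int(i): target - int(counts_ia[i]) for i in continuing}
    if any(v < 0 for v in needed.values()):
        raise ConfigurationError(
            ["n_stage2_per_arm: stage-2 quota already exceeded at IA (unreachable)"]
        )
    rng2 = _child_rng(seed, 17, int(continuing[-1]))
    total_new = sum(needed.values())
    arm2 = np.empty(total_new, int)
    pos = 0
    while pos < total_new:
        open_arms = [i for i in continuing if needed[int(i)] > 0]
        for i in rng2.permutation(open_arms):
            if needed[int(i)] > 0 and pos < total_new:
                arm2[pos] = i
                needed[int(i)] -= 1
                pos += 1
    enroll2 = (np.arange(n_pre_ia + 1, n_pre_ia + total_new + 1)) / rate
    latent2, dropout2, surr2 = _draw_subject_outcomes(
        rng2, arm2, hazards, dropout_rate, a, b, sigma
    )

    arm = np.concatenate([arm1, arm2])
    enroll = np.concatenate([enroll1, enroll2])
    latent = np.concatenate([latent1, latent2])
    dropout = np.concatenate([dropout1, dropout2])
    surr = np.concatenate([surr1, surr2])
    mature = np.concatenate([mature1, np.zeros(total_new, bool)])

    dropped = ~np.isin(arm, continuing)
    in_set = ~(dropped & ~mature)  # pre-IA immature subjects of dropped arms are excluded

    final_week = float(enroll[in_set].max() + config.followup_weeks)
    return TrialDataset(
        arm=arm,
        enroll_week=enroll,
        latent_event_week=latent,
        dropout_week=dropout,
        surrogate=surr,
        surrogate_mature_at_ia=mature,
        in_analysis_set=in_set,
        ia_calendar_week=ia_week,
        final_calendar_week=final_week,
        decision=decision,
    )


def sample_size_accounting(trial: TrialDataset, config: DesignConfig) -> SampleSizeAccounting:
    """Enrolled / analysed / excluded subject counts for one trial.

    A stopped trial reports everyone on study at IA as enrolled (they were
    randomized before the stop); a continued trial excludes the pre-IA
    immature subjects of the dropped arms from the analysis set.
    """
    enrolled = trial.n_subjects
    if trial.decision.futility_stop:
        return SampleSizeAccounting(enrolled, enrolled, 0, enrolled)
    excluded = int((~trial.in_analysis_set).sum())
    at_ia = int((trial.enroll_week <= trial.ia_calendar_week + 1e-9).sum())
    return SampleSizeAccounting(enrolled, enrolled - excluded, excluded, at_ia)
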