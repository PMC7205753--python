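"""Final-analysis machinery: log-rank statistics, Dunnett adjustment, and the
closed weighted inverse-normal combination test.

Per treatment-vs-control comparison the unstandardized log-rank statistic
``U`` (observed minus expected events in the active arm, hypergeometric
variance ``V``) is computed at the interim cut and at the final analysis.
The stagewise statistics

    Z1 = U1 / sqrt(V1),      Z2 = (U2 - U1) / sqrt(V2 - V1)

are asymptotically independent (independent-increments property of log-rank
scores), so stagewise p-values may be combined through the prespecified
weighted inverse-normal combination function

    C(p1, p2) = 1 - Phi[w1 * Phi^-1(1-p1) + w2 * Phi^-1(1-p2)],  w1^2+w2^2=1.

Within each stage the many-to-one multiplicity over the k dose arms is
addressed by Dunnett's test; across the arm-selection adaptation the closure
principle over all non-empty subsets of elementary hypotheses gives strong
familywise error control.  For intersections containing dropped arms the
stage-2 p-value only reflects the arms actually carried forward
(p2_S = p2_{S & S2}; the empty intersection contributes p2 = 1).

Benefit orientation: the primary endpoint is time to confirmed improvement,
so MORE events / shorter times in the active arm indicate benefit and the
one-sided tests reject for large positive Z.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

from .exceptions import MonotoneInformationError, ValidationError

__all__ = [
    "LogrankStat",
    "StagewiseStats",
    "IntersectionPValues",
    "ClosedTestResult",
    "logrank_uv",
    "stagewise_z",
    "dunnett_adjusted_p",
    "dunnett_critical_value",
    "inverse_normal_combination",
    "closed_testing",
    "single_stage_dunnett_test",
    "analyze_trial",
]

_P_EPS = 1e-15
_V_EPS = 1e-12


@dataclass(frozen=True)
class LogrankStat:
    """Unstandardized log-rank numerator and its hypergeometric variance."""

    u: float
    v: float

    def __post_init__(self):
        if self.v < 0:
            raise ValidationError("log-rank variance must be >= 0")

    @property
    def z(self) -> float:
        return self.u / np.sqrt(self.v) if self.v > 0 else 0.0


@dataclass(frozen=True)
class StagewiseStats:
    z1: float
    z2: float
    u1: float
    v1: float
    u2: float
    v2: float


@dataclass(frozen=True)
class IntersectionPValues:
    subset: frozenset
    p1: float
    p2: float
    combined: float


@dataclass(frozen=True)
class ClosedTestResult:
    rejected: np.ndarray  # per elementary hypothesis, index 0 <-> active arm 1
    details: tuple  # IntersectionPValues for every non-empty subset

    def any_rejected(self) -> bool:
        return bool(np.any(self.rejected))


def logrank_uv(times, events, group) -> LogrankStat:
    """Log-rank (observed - expected) statistic for active vs control.

    ``group`` is truthy for active-arm subjects.  Positive ``u`` means the
    active arm accrued more events than expected under the null — the
    benefit direction for a time-to-improvement endpoint.  Ties are handled
    by the standard hypergeometric moments at each distinct event time.
    """
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    group = np.asarray(group).astype(bool)
    if times.size == 0 or group.all() or (~group).all():
        raise ValidationError("need at least one subject in each group")
    if not events.any():
        return LogrankStat(0.0, 0.0)

    et = np.unique(times[events])
    times_sorted = np.sort(times)
    times_sorted_a = np.sort(times[group])
    # at-risk counts just before each event time (risk set: follow-up >= t)
    n_at = times.size - np.searchsorted(times_sorted, et, side="left")
    n1_at = group.sum() - np.searchsorted(times_sorted_a, et, side="left")
    # event counts at each distinct event time
    idx = np.searchsorted(et, times[events])
    d_at = np.bincount(idx, minlength=et.size)
    d1_at = np.bincount(idx[group[events]], minlength=et.size)

    frac = n1_at / n_at
    u = float(np.sum(d1_at - d_at * frac))
    ok = n_at > 1
    v = float(
        np.sum(
            d_at[ok]
            * frac[ok]
            * (1.0 - frac[ok])
            * (n_at[ok] - d_at[ok])
            / (n_at[ok] - 1.0)
        )
    )
    return LogrankStat(u, max(v, 0.0))


def stagewise_z(interim: LogrankStat, final: LogrankStat) -> StagewiseStats:
    """Independent-increment stagewise statistics from interim and final log-ranks."""
    dv = final.v - interim.v
    if dv < -1e-9:
        raise MonotoneInformationError(
            f"final variance {final.v} smaller than interim variance {interim.v}"
        )
    z1 = interim.u / np.sqrt(interim.v) if interim.v > 0 else 0.0
    z2 = (final.u - interim.u) / np.sqrt(dv) if dv > _V_EPS else 0.0
    return StagewiseStats(float(z1), float(z2), interim.u, interim.v, final.u, final.v)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(96)


def _pmax_equicorrelated(t: float, k: int, rho: float) -> float:
    """P(max of k equicorrelated standard normals < t), exact 1-d quadrature.

    Factor model Z_i = sqrt(rho) X0 + sqrt(1-rho) X_i reduces the orthant
    probability to a single Gauss-Hermite integral.
    """
    if k == 1 or rho == 0.0:
        return float(ndtr(t)) ** k
    x = np.sqrt(2.0) * _GH_NODES
    inner = ndtr((t - np.sqrt(rho) * x) / np.sqrt(1.0 - rho))
    return float(np.sum(_GH_WEIGHTS * inner**k) / np.sqrt(np.pi))


def _is_equicorrelated(corr: np.ndarray) -> float | None:
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    if off.size == 0:
        return 0.0
    rho = float(off[0])
    if np.allclose(off, rho, atol=1e-12) and 0.0 <= rho < 1.0:
        return rho
    return None


def dunnett_adjusted_p(z_values, correlation=None) -> float:
    """One-sided Dunnett-adjusted p-value for the maximum of the k statistics.

    p = 1 - P(max of a zero-mean multivariate normal with the given
    correlation < max observed z).  ``correlation`` defaults to the
    equal-allocation many-to-one structure (equicorrelation 0.5).
    Equicorrelated matrices use an exact one-dimensional quadrature; general
    matrices fall back to the multivariate normal CDF (abs. tol <= 1e-6).
    """
    z = np.atleast_1d(np.asarray(z_values, float))
    k = z.size
    if correlation is None:
        correlation = np.full((k, k), 0.5)
        np.fill_diagonal(correlation, 1.0)
    corr = np.asarray(correlation, float)
    if corr.shape != (k, k):
        raise ValidationError(f"correlation must be {k}x{k}, got {corr.shape}")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValidationError("correlation matrix must have unit diagonal")
    zmax = float(z.max())
    rho = _is_equicorrelated(corr)
    if rho is not None:
        pmax = _pmax_equicorrelated(zmax, k, rho)
    else:
        pmax = float(
            multivariate_normal.cdf(
                np.full(k, zmax), mean=np.zeros(k), cov=corr, abseps=1e-7, allow_singular=True
            )
        )
    return float(np.clip(1.0 - pmax, 0.0, 1.0))


def dunnett_critical_value(k: int, alpha: float, rho: float = 0.5) -> float:
    """Critical value c with P(max of k equicorrelated normals >= c) = alpha."""
    return brentq(lambda t: _pmax_equicorrelated(t, k, rho) - (1.0 - alpha), -10.0, 10.0)


def inverse_normal_combination(p1: float, p2: float, w1: float, w2: float) -> float:
    """Weighted inverse-normal combination C(p1,p2)=1-Phi[w1 z(p1) + w2 z(p2)]."""
    if w1 < 0 or w2 < 0 or abs(w1**2 + w2**2 - 1.0) > 1e-9:
        raise ValidationError("weights must satisfy w1,w2 >= 0 and w1^2 + w2^2 = 1")
    p1 = float(np.clip(p1, _P_EPS, 1.0 - _P_EPS))
    p2 = float(np.clip(p2, _P_EPS, 1.0 - _P_EPS))
    stat = w1 * ndtri(1.0 - p1) + w2 * ndtri(1.0 - p2)
    return float(np.clip(1.0 - ndtr(stat), _P_EPS, 1.0 - _P_EPS))


def _p_from_z(z: float) -> float:
    return float(np.clip(1.0 - ndtr(z), _P_EPS, 1.0 - _P_EPS))


def _nonempty_subsets(k):
    return chain.from_iterable(combinations(range(1, k + 1), r) for r in range(1, k + 1))


def closed_testing(
    stage1_z,
    stage2_z,
    selected,
    alpha: float = 0.025,
    weights=(0.5**0.5, 0.5**0.5),
    correlation_stage1=None,
) -> ClosedTestResult:
    """Closure over all intersections of the k elementary hypotheses.

    ``stage1_z``: length-k stage-1 statistics (one per active arm, in arm
    order).  ``stage2_z``: length-k array of stage-2 increment statistics;
    only entries of selected arms are used.  ``selected``: iterable of
    selected active-arm indices in 1..k (empty = futility stop, in which
    case no final test is performed and nothing is rejected).

    For each non-empty subset S the stage-1 p-value is Dunnett-adjusted over
    S; the stage-2 p-value is the unadjusted p of the selected arm when
    S contains it and 1 otherwise.  H_i is rejected iff every S containing i
    has C(p1_S, p2_S) < alpha.
    """
    z1 = np.atleast_1d(np.asarray(stage1_z, float))
    k = z1.size
    selected = frozenset(int(i) for i in selected)
    if any(i < 1 or i > k for i in selected):
        raise ValidationError(f"selected arms must be in 1..{k}")
    if len(selected) > 1:
        raise ValidationError("only single-arm selection is supported")
    if not selected:
        return ClosedTestResult(np.zeros(k, bool), ())
    z2 = np.atleast_1d(np.asarray(stage2_z, float))
    w1, w2 = weights
    (sel,) = selected
    p2_sel = _p_from_z(float(z2[sel - 1]))

    details = []
    reject_all = np.ones(k, bool)
    for S in _nonempty_subsets(k):
        idx = np.array(S) - 1
        if correlation_stage1 is None:
            p1 = dunnett_adjusted_p(z1[idx])
        else:
            sub = np.asarray(correlation_stage1)[np.ix_(idx, idx)]
            p1 = dunnett_adjusted_p(z1[idx], sub)
        p2 = p2_sel if sel in S else 1.0
        comb = inverse_normal_combination(p1, p2, w1, w2)
        details.append(IntersectionPValues(frozenset(S), p1, p2, comb))
        if comb >= alpha:
            reject_all[idx] = False
    return ClosedTestResult(reject_all, tuple(details))


def single_stage_dunnett_test(z_values, alpha: float = 0.025, correlation=None) -> np.ndarray:
    """Traditional single-look Dunnett test: reject H_i iff its adjusted p < alpha."""
    z = np.atleast_1d(np.asarray(z_values, float))
    k = z.size
    out = np.zeros(k, bool)
    for i in range(k):
        zi = np.full(k, z[i])
        # adjusted p of z_i over the full family
        if correlation is None:
            p = dunnett_adjusted_p(zi)
        else:
            p = dunnett_adjusted_p(zi, correlation)
        out[i] = p < alpha
    return out


def _comparison_logrank(trial, arm_i, cut, mask):
    """Log-rank for control vs active arm ``arm_i`` on ``mask`` subjects.

    Follow-up of each subject is truncated at ``cut`` calendar weeks (and at
    the per-design administrative follow-up handled by the caller via
    ``cut``); dropout censors the event.
    """
    pick = mask & ((trial.arm == 0) | (trial.arm == arm_i))
    arm = trial.arm[pick]
    if isinstance(cut, np.ndarray):
        horizon = cut[pick]
    else:
        horizon = np.asarray(cut - trial.enroll_week[pick])
    obs = np.minimum.reduce([trial.latent_event_week[pick], trial.dropout_week[pick], horizon])
    ev = trial.latent_event_week[pick] <= np.minimum(trial.dropout_week[pick], horizon)
    return logrank_uv(obs, ev, arm == arm_i)


def analyze_trial(trial, config) -> ClosedTestResult:
    """Run the preplanned final analysis on a simulated trial.

    Stage-1 statistics use, per comparison, the mature stage-1 subjects of
    the control and the given active arm with follow-up censored at the IA
    calendar week.  The stage-2 increment uses the full analysis set of the
    continuing arms (every analysed subject followed the full preplanned
    follow-up window).  A stopped trial performs no final test.
    """
    if trial.decision.futility_stop:
        return ClosedTestResult(np.zeros(config.n_active, bool), ())

    k = config.n_active
    z1 = np.zeros(k)
    interim_stats = []
    for i in range(1, k + 1):
        st = _comparison_logrank(trial, i, trial.ia_calendar_week, trial.surrogate_mature_at_ia)
        interim_stats.append(st)
        z1[i - 1] = st.z

    (sel,) = trial.decision.selected_arms
    followup = np.full(trial.n_subjects, config.followup_weeks)
    final_stat = _comparison_logrank(trial, sel, followup, trial.in_analysis_set)
    sw = stagewise_z(interim_stats[sel - 1], final_stat)
    z2 = np.zeros(k)
    z2[sel - 1] = sw.z2

    return closed_testing(
        z1,
        z2,
        {sel},
        alpha=config.alpha_one_sided,
        weights=config.stage_weights(),
    )
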