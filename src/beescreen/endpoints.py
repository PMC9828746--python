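"""Dose-response endpoint statistics for honey-bee toxicity tests.

Estimates the endpoints a tier-1 pollinator assessment consumes:

* ``tsk_ld50`` — trimmed Spearman-Kärber LD50 with a delta-method 95% CI
  from quantal (dead / exposed) acute data;
* ``williams_noed`` — Williams-type no-observed-effect dose for
  replicated continuous responses under an assumed monotone dose effect,
  with critical values calibrated by seeded Monte-Carlo simulation of
  the null rather than transcribed tables;
* ``stepdown_trend_noed`` — Cochran-Armitage step-down trend NOED for
  monotone quantal data;
* ``fisher_holm_noed`` — per-dose one-sided Fisher's exact tests against
  the negative control with Holm step-down adjustment, for non-monotone
  quantal data;
* ``decide_test`` / ``compare_controls`` — the test-selection and
  solvent-control screens that choose among them.

All tests are one-sided (mortality can only be adverse) at α = 0.05 by
default.  Replicate structure is collapsed to totals for quantal tests;
replicate-level variance is used only by the Williams procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import isotonic_regression

from .errors import InsufficientDataError

__all__ = [
    "QuantalDoseResponse",
    "EndpointEstimate",
    "tsk_ld50",
    "williams_noed",
    "stepdown_trend_noed",
    "cochran_armitage_p",
    "fisher_holm_noed",
    "holm_adjust",
    "decide_test",
    "compare_controls",
]


@dataclass(frozen=True)
class QuantalDoseResponse:
    """Quantal mortality data: dead out of exposed at ascending doses.

    ``control`` and ``solvent_control`` are (n_exposed, n_dead) pairs.
    """

    doses: tuple[float, ...]
    n_exposed: tuple[int, ...]
    n_dead: tuple[int, ...]
    control: tuple[int, int] | None = None
    solvent_control: tuple[int, int] | None = None

    def __post_init__(self):
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "n_exposed", tuple(int(n) for n in self.n_exposed))
        object.__setattr__(self, "n_dead", tuple(int(d) for d in self.n_dead))
        if not (len(doses) == len(self.n_exposed) == len(self.n_dead)):
            raise ValueError("doses, n_exposed, n_dead must have equal length")
        if any(d <= 0 for d in doses) or any(
            b <= a for a, b in zip(doses, doses[1:])
        ):
            raise ValueError("doses must be positive and strictly increasing")
        for n, d in zip(self.n_exposed, self.n_dead):
            if not 0 <= d <= n:
                raise ValueError("need 0 <= n_dead <= n_exposed")

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.n_dead, float) / np.asarray(self.n_exposed, float)


@dataclass(frozen=True)
class EndpointEstimate:
    """A toxicity endpoint with provenance of the statistical method.

    ``unbounded`` flags estimates only known to exceed the highest dose
    tested (the face value is still the highest dose); ``below_lowest``
    flags NOEDs where even the lowest dose showed a significant effect.
    """

    kind: str  # ld50 | noed
    value: float
    method: str  # tsk | williams | cochran_armitage_stepdown | fisher_holm
    ci_low: float | None = None
    ci_high: float | None = None
    unbounded: bool = False
    below_lowest: bool = False
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.value <= self.ci_high:
                raise ValueError("need ci_low <= value <= ci_high")


def _pava(y: np.ndarray, weights: np.ndarray, increasing: bool = True) -> np.ndarray:
    """Pool-adjacent-violators monotone regression."""
    return isotonic_regression(y, weights=weights, increasing=increasing).x


# ---------------------------------------------------------------------------
# Trimmed Spearman-Kärber


def _tsk_mean(x: np.ndarray, p: np.ndarray, trim: float) -> float:
    """Mean log10-dose of the trimmed, monotonized tolerance distribution.

    The monotone empirical curve through (x_i, p_i) is extended by one
    dose-spacing below the lowest dose (to p = 0) and above the highest
    (to p = 1), the central 1 - 2·trim probability mass is kept, and the
    mean of the implied log-dose distribution is integrated segment by
    segment.
    """
    spacing = float(np.mean(np.diff(x))) if x.size > 1 else np.log10(2.0)
    xs = np.concatenate(([x[0] - spacing], x, [x[-1] + spacing]))
    ps = np.concatenate(([0.0], p, [1.0]))
    a, b = trim, 1.0 - trim
    total = 0.0
    for x0, x1, p0, p1 in zip(xs[:-1], xs[1:], ps[:-1], ps[1:]):
        if p1 <= p0:
            continue
        lo, hi = max(p0, a), min(p1, b)
        if hi <= lo:
            continue
        xl = x0 + (lo - p0) / (p1 - p0) * (x1 - x0)
        xh = x0 + (hi - p0) / (p1 - p0) * (x1 - x0)
        total += (hi - lo) * 0.5 * (xl + xh)
    return total / (b - a)


def tsk_ld50(
    data: QuantalDoseResponse, trim: float = 0.0, alpha: float = 0.05
) -> EndpointEstimate:
    """Trimmed Spearman-Kärber LD50 with a delta-method 95% CI.

    Mortality proportions are monotonized on log dose by PAVA before
    trimming.  If no dose reaches 50% mortality the LD50 is only known to
    exceed the highest dose tested and is returned unbounded at that
    value.  The variance of the log10 estimate is obtained by the delta
    method, propagating the per-dose binomial variances of the
    monotonized proportions through a finite-difference gradient of the
    trimmed estimator.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    x = np.log10(np.asarray(data.doses, float))
    n = np.asarray(data.n_exposed, float)
    p_obs = data.proportions
    p_mono = _pava(p_obs, n, increasing=True)

    if p_mono.max() < 0.5:
        return EndpointEstimate(
            kind="ld50", value=float(data.doses[-1]), method="tsk", unbounded=True,
            details={"reason": "no dose reached 50% mortality"},
        )
    if p_mono.min() >= 1.0 - 1e-12:
        raise InsufficientDataError(
            "complete mortality at every dose: LD50 is below the lowest dose "
            "and the response curve carries no information"
        )

    mu = _tsk_mean(x, p_mono, trim)

    # delta method: numerical gradient of the full estimator wrt observed p
    grad = np.zeros_like(p_obs)
    h = 1e-4
    for i in range(p_obs.size):
        for sign in (+1.0, -1.0):
            pp = p_obs.copy()
            pp[i] = np.clip(pp[i] + sign * h, 0.0, 1.0)
            grad[i] += sign * _tsk_mean(x, _pava(pp, n, increasing=True), trim)
        grad[i] /= 2.0 * h
    denom = np.maximum(n - 1.0, 1.0)
    var = float(np.sum(grad**2 * p_mono * (1.0 - p_mono) / denom))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return EndpointEstimate(
        kind="ld50",
        value=float(10.0**mu),
        ci_low=float(10.0 ** (mu - half)),
        ci_high=float(10.0 ** (mu + half)),
        method="tsk",
        details={"log10_ld50": mu, "log10_se": float(np.sqrt(var)), "trim": trim},
    )


# ---------------------------------------------------------------------------
# Williams-type NOED (continuous responses, Monte-Carlo critical values)

_WILLIAMS_CRIT_CACHE: dict[tuple, np.ndarray] = {}


def _williams_t(
    means: np.ndarray,
    ns: np.ndarray,
    m0: float,
    n0: int,
    s: float,
    direction: str,
) -> tuple[np.ndarray, str]:
    """Williams statistics for every dose under monotone amalgamation.

    ``direction='auto'`` resolves the adverse direction from the sign of
    the highest-dose effect; the same rule is replayed inside the null
    calibration so the critical values account for it.
    """
    if direction == "auto":
        direction = "less" if means[-1] <= m0 else "greater"
    amalg = _pava(means, ns, increasing=(direction == "greater"))
    if s <= 0:
        s = np.finfo(float).tiny
    se = s * np.sqrt(1.0 / ns + 1.0 / n0)
    t = (m0 - amalg) / se if direction == "less" else (amalg - m0) / se
    return t, direction


def _williams_crit(
    ns: tuple[int, ...], n0: int, alpha: float, n_null: int, seed: int
) -> np.ndarray:
    """Per-step one-sided critical values by seeded null simulation."""
    key = (ns, n0, round(alpha, 6), n_null, seed)
    if key in _WILLIAMS_CRIT_CACHE:
        return _WILLIAMS_CRIT_CACHE[key]
    rng = np.random.default_rng(seed)
    k = len(ns)
    sizes = (n0,) + ns
    tstats = np.empty((n_null, k))
    for r in range(n_null):
        groups = [rng.standard_normal(m) for m in sizes]
        m0 = groups[0].mean()
        means = np.array([g.mean() for g in groups[1:]])
        df = sum(m - 1 for m in sizes)
        s = np.sqrt(sum(((g - g.mean()) ** 2).sum() for g in groups) / df)
        tstats[r], _ = _williams_t(
            means, np.asarray(ns, float), m0, n0, s, "auto"
        )
    crit = np.quantile(tstats, 1.0 - alpha, axis=0)
    _WILLIAMS_CRIT_CACHE[key] = crit
    return crit


def williams_noed(
    dose_groups: Mapping[float, Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
    direction: str = "auto",
    n_null: int = 10_000,
    seed: int = 20260,
) -> EndpointEstimate:
    """Williams-type NOED on replicate-level continuous responses.

    Dose means are amalgamated by PAVA under the monotone-effect
    assumption and compared with the (pooled) control sequentially from
    the highest dose downward at one-sided ``alpha``.  Critical values
    come from ``n_null`` seeded Monte-Carlo draws of the null for the
    same design (group sizes and the direction-resolution rule), so the
    procedure carries no transcribed tables.  The NOED is the highest
    dose with no significant effect.
    """
    doses = sorted(dose_groups)
    if len(doses) < 2:
        raise InsufficientDataError("Williams NOED needs >= 2 dose groups")
    groups = [np.asarray(dose_groups[d], float) for d in doses]
    ctrl = np.asarray(control, float)
    if ctrl.size < 2 or any(g.size < 2 for g in groups):
        raise InsufficientDataError("need >= 2 replicates per group")

    ns = np.array([g.size for g in groups], float)
    means = np.array([g.mean() for g in groups])
    m0 = float(ctrl.mean())
    df = (ctrl.size - 1) + sum(g.size - 1 for g in groups)
    s = float(
        np.sqrt(
            (((ctrl - m0) ** 2).sum() + sum(((g - g.mean()) ** 2).sum() for g in groups))
            / df
        )
    )
    t, resolved = _williams_t(means, ns, m0, ctrl.size, s, direction)
    crit = _williams_crit(
        tuple(int(m) for m in ns), ctrl.size, alpha, n_null, seed
    )

    details = {
        "t": t.tolist(),
        "critical_values": crit.tolist(),
        "direction": resolved,
        "pooled_sd": s,
    }
    noed_idx: int | None = None
    for k in range(len(doses) - 1, -1, -1):
        if t[k] <= crit[k]:
            noed_idx = k
            break
    if noed_idx == len(doses) - 1:
        return EndpointEstimate(
            kind="noed", value=float(doses[-1]), method="williams",
            unbounded=True, details=details,
        )
    if noed_idx is None:
        return EndpointEstimate(
            kind="noed", value=float(doses[0]), method="williams",
            below_lowest=True, details=details,
        )
    return EndpointEstimate(
        kind="noed", value=float(doses[noed_idx]), method="williams", details=details
    )


# ---------------------------------------------------------------------------
# Cochran-Armitage step-down trend NOED (monotone quantal data)


def cochran_armitage_p(
    n: Sequence[int], r: Sequence[int], scores: Sequence[float] | None = None
) -> float:
    """One-sided (increasing mortality) Cochran-Armitage trend p-value.

    Uses the conditional (permutation) variance of the score-weighted
    death count; ``scores`` default to group index 0..k.
    """
    n = np.asarray(n, float)
    r = np.asarray(r, float)
    s = np.arange(n.size, dtype=float) if scores is None else np.asarray(scores, float)
    N, R = n.sum(), r.sum()
    if R == 0 or R == N:
        return 1.0
    pbar = R / N
    t_obs = float((s * r).sum())
    e = pbar * float((s * n).sum())
    var = (
        pbar * (1.0 - pbar) * N / (N - 1.0)
        * (float((n * s**2).sum()) - float((n * s).sum()) ** 2 / N)
    )
    z = (t_obs - e) / np.sqrt(var)
    return float(stats.norm.sf(z))


def stepdown_trend_noed(
    data: QuantalDoseResponse,
    alpha: float = 0.05,
    scores: Sequence[float] | None = None,
) -> EndpointEstimate:
    """Cochran-Armitage step-down NOED for monotone quantal data.

    The one-sided trend test is run on control plus all doses; while it
    is significant the highest dose is dropped and the test repeated.
    The NOED is the highest dose of the first non-significant
    configuration.
    """
    if data.control is None:
        raise InsufficientDataError("step-down trend test requires a control group")
    if len(data.doses) < 2:
        raise InsufficientDataError("step-down trend test needs >= 2 dose groups")
    n0, d0 = data.control
    pvals = []
    k = len(data.doses)
    while k >= 1:
        n = (n0,) + data.n_exposed[:k]
        r = (d0,) + data.n_dead[:k]
        sc = None if scores is None else (scores[0],) + tuple(scores[1 : k + 1])
        p = cochran_armitage_p(n, r, sc)
        pvals.append(p)
        if p >= alpha:
            break
        k -= 1
    details = {"p_values_stepdown": pvals, "alpha": alpha}
    if k == len(data.doses):
        return EndpointEstimate(
            kind="noed", value=float(data.doses[-1]),
            method="cochran_armitage_stepdown", unbounded=True, details=details,
        )
    if k == 0:
        return EndpointEstimate(
            kind="noed", value=float(data.doses[0]),
            method="cochran_armitage_stepdown", below_lowest=True, details=details,
        )
    return EndpointEstimate(
        kind="noed", value=float(data.doses[k - 1]),
        method="cochran_armitage_stepdown", details=details,
    )


# ---------------------------------------------------------------------------
# Fisher's exact with Holm adjustment (non-monotone quantal data)


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone non-decreasing in the
    step-down order)."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def fisher_holm_noed(data: QuantalDoseResponse, alpha: float = 0.05) -> EndpointEstimate:
    """Per-dose one-sided Fisher's exact tests vs the negative control,
    Holm-adjusted across doses.

    The NOED is the highest dose whose adjusted p ≥ alpha with no
    significant dose below it.
    """
    if data.control is None:
        raise InsufficientDataError("Fisher's exact NOED requires a negative control")
    n0, d0 = data.control
    raw = [
        float(
            stats.fisher_exact(
                [[d, n - d], [d0, n0 - d0]], alternative="greater"
            ).pvalue
        )
        for n, d in zip(data.n_exposed, data.n_dead)
    ]
    adj = holm_adjust(raw)
    details = {"p_raw": raw, "p_holm": adj.tolist(), "alpha": alpha}
    sig = adj < alpha
    if not sig.any():
        return EndpointEstimate(
            kind="noed", value=float(data.doses[-1]), method="fisher_holm",
            unbounded=True, details=details,
        )
    lowest_sig = int(np.argmax(sig))
    if lowest_sig == 0:
        return EndpointEstimate(
            kind="noed", value=float(data.doses[0]), method="fisher_holm",
            below_lowest=True, details=details,
        )
    return EndpointEstimate(
        kind="noed", value=float(data.doses[lowest_sig - 1]),
        method="fisher_holm", details=details,
    )


# ---------------------------------------------------------------------------
# Test selection and control comparison


def decide_test(data) -> str:
    """Choose the NOED procedure for a data set.

    Continuous replicate-level data (a mapping dose -> replicate values)
    goes to the Williams procedure.  Quantal data is screened for
    monotonicity: the per-dose mortality proportions are monotone when
    all nonzero adjacent differences share one sign and the Spearman rank
    correlation of proportion against dose agrees with that sign;
    monotone data goes to the step-down trend test, non-monotone to
    Fisher-Holm.
    """
    if isinstance(data, Mapping):
        return "williams"
    p = data.proportions
    diffs = np.diff(p)
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return "cochran_armitage_stepdown"  # flat response is trivially monotone
    same_sign = bool(np.all(nonzero > 0) or np.all(nonzero < 0))
    rho = stats.spearmanr(data.doses, p).statistic
    consistent = np.isnan(rho) or np.sign(rho) == np.sign(nonzero[0])
    if same_sign and consistent:
        return "cochran_armitage_stepdown"
    return "fisher_holm"


def compare_controls(negative, solvent, alpha: float = 0.05) -> str:
    """Screen the solvent control against the negative control.

    Quantal controls are (n, dead) pairs compared by two-sided Fisher's
    exact test; continuous controls are replicate arrays compared by a
    two-sided Welch t test.  With no detectable difference (or no solvent
    control at all) the negative control is used downstream.
    """
    if solvent is None:
        return "pool_with_negative"
    if isinstance(negative, tuple) and len(negative) == 2 and np.isscalar(negative[0]):
        n0, d0 = negative
        n1, d1 = solvent
        p = float(
            stats.fisher_exact([[d0, n0 - d0], [d1, n1 - d1]]).pvalue
        )
    else:
        a = np.asarray(negative, float)
        b = np.asarray(solvent, float)
        if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return "pool_with_negative" if p >= alpha else "use_solvent"
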