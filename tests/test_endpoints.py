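"""Tests for LD50 and NOED estimation against independent oracles."""

from itertools import product
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beescreen.endpoints import (
    EndpointEstimate,
    QuantalDoseResponse,
    cochran_armitage_p,
    compare_controls,
    decide_test,
    fisher_holm_noed,
    holm_adjust,
    stepdown_trend_noed,
    tsk_ld50,
    williams_noed,
)
from beescreen.errors import InsufficientDataError
from beescreen.simulate import SimConfig, gen_dose_response

# ---------------------------------------------------------------------------
# independent oracles


def pava_oracle(p, w):
    """Plain-loop pool-adjacent-violators, non-decreasing."""
    blocks = [[pi, wi] for pi, wi in zip(p, w)]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            m = (
                blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1]
            ) / (blocks[i][1] + blocks[i + 1][1])
            blocks[i : i + 2] = [[m, blocks[i][1] + blocks[i + 1][1]]]
            i = max(i - 1, 0)
        else:
            i += 1
    # expand pooled blocks back to one value per original point
    res = []
    it = iter(blocks)
    val, remaining = next(it)
    for wi in w:
        while remaining < wi - 1e-12:
            val, wt2 = next(it)
            remaining += wt2
        res.append(val)
        remaining -= wi
    return np.array(res)


def sk_closed_form(doses, p_monotone):
    """Untrimmed Spearman-Kärber mean of a monotone curve, with the
    one-spacing extension to 0 below and 1 above the tested range."""
    x = np.log10(np.asarray(doses, float))
    spacing = np.mean(np.diff(x)) if x.size > 1 else np.log10(2.0)
    xs = np.concatenate(([x[0] - spacing], x, [x[-1] + spacing]))
    ps = np.concatenate(([0.0], p_monotone, [1.0]))
    mu = sum(
        (ps[i + 1] - ps[i]) * 0.5 * (xs[i] + xs[i + 1]) for i in range(len(xs) - 1)
    )
    return 10.0**mu


def sk_dense_integration(doses, p_monotone, trim=0.0):
    """Direct numerical integration of the monotonized empirical curve."""
    x = np.log10(np.asarray(doses, float))
    spacing = np.mean(np.diff(x)) if x.size > 1 else np.log10(2.0)
    xs = np.concatenate(([x[0] - spacing], x, [x[-1] + spacing]))
    ps = np.concatenate(([0.0], p_monotone, [1.0]))
    grid = np.linspace(xs[0], xs[-1], 200_001)
    q = np.clip(np.interp(grid, xs, ps), trim, 1.0 - trim)
    q = (q - trim) / (1.0 - 2.0 * trim)
    mu = np.trapezoid(grid, q)  # ∫ x dq by integrating along q
    return 10.0**mu


def exact_ca_p(n, r, scores):
    """Exact one-sided permutation mid-p of the trend statistic, conditional
    on the total death count (multivariate hypergeometric enumeration).
    The mid-p convention (half the point mass at the observed statistic)
    is the discrete analogue of the continuous normal approximation."""
    n, r = list(n), list(r)
    total = sum(r)
    t_obs = sum(s * ri for s, ri in zip(scores, r))
    num = num_eq = den = 0
    for vec in product(*[range(ni + 1) for ni in n]):
        if sum(vec) != total:
            continue
        w = 1
        for ni, vi in zip(n, vec):
            w *= comb(ni, vi)
        den += w
        t = sum(s * v for s, v in zip(scores, vec))
        if t >= t_obs:
            num += w
            if t == t_obs:
                num_eq += w
    return (num - 0.5 * num_eq) / den


# ---------------------------------------------------------------------------
# trimmed Spearman-Kärber


class TestTSK:
    def test_two_dose_step_is_geometric_mean(self):
        data = QuantalDoseResponse((10, 40), (10, 10), (0, 10))
        est = tsk_ld50(data)
        assert est.value == pytest.approx((10 * 40) ** 0.5, rel=1e-12)

    def test_trimming_a_single_step_keeps_the_midpoint(self):
        data = QuantalDoseResponse((10, 40), (10, 10), (0, 10))
        assert tsk_ld50(data, trim=0.2).value == pytest.approx(20.0, rel=1e-12)

    def test_matches_untrimmed_closed_form_on_monotone_curve(self):
        data = QuantalDoseResponse(
            (6.25, 12.5, 25, 50, 100), (10,) * 5, (0, 1, 4, 8, 10)
        )
        est = tsk_ld50(data, trim=0.0)
        expected = sk_closed_form(data.doses, data.proportions)
        assert est.value == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_integration_oracle_after_monotonization(self):
        data = QuantalDoseResponse(
            (6.25, 12.5, 25, 50, 100), (10,) * 5, (1, 0, 5, 4, 10)
        )
        p_mono = pava_oracle(data.proportions, np.asarray(data.n_exposed, float))
        for trim in (0.0, 0.1):
            est = tsk_ld50(data, trim=trim)
            oracle = sk_dense_integration(data.doses, p_mono, trim)
            assert est.value == pytest.approx(oracle, rel=1e-4)

    def test_unbounded_when_no_dose_reaches_half_mortality(self):
        data = QuantalDoseResponse((10, 100), (10, 10), (0, 3))
        est = tsk_ld50(data)
        assert est.unbounded and est.value == 100.0

    def test_complete_mortality_everywhere_rejected(self):
        with pytest.raises(InsufficientDataError):
            tsk_ld50(QuantalDoseResponse((1, 10), (10, 10), (10, 10)))

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_scale_invariance(self, c):
        """Rescaling all doses by c rescales the LD50 (and CI) by c."""
        base = QuantalDoseResponse(
            (6.25, 12.5, 25, 50, 100), (10,) * 5, (0, 2, 5, 8, 10)
        )
        scaled = QuantalDoseResponse(
            tuple(c * d for d in base.doses), base.n_exposed, base.n_dead
        )
        a, b = tsk_ld50(base), tsk_ld50(scaled)
        assert b.value == pytest.approx(c * a.value, rel=1e-10)
        assert b.ci_low == pytest.approx(c * a.ci_low, rel=1e-10)
        assert b.ci_high == pytest.approx(c * a.ci_high, rel=1e-10)

    def test_ci_brackets_estimate(self):
        est = tsk_ld50(gen_dose_response(SimConfig(seed=4)))
        assert est.ci_low <= est.value <= est.ci_high

    def test_invalid_trim_rejected(self):
        data = QuantalDoseResponse((10, 40), (10, 10), (0, 10))
        with pytest.raises(ValueError):
            tsk_ld50(data, trim=0.5)


# ---------------------------------------------------------------------------
# Williams-type NOED


class TestWilliams:
    def test_pure_null_noed_is_highest_dose(self):
        rng = np.random.default_rng(5)
        groups = {d: rng.normal(10, 1, 3) for d in (1, 2, 4, 8, 16)}
        ctrl = rng.normal(10, 1, 9)
        est = williams_noed(groups, ctrl, n_null=4000, seed=1)
        assert est.value == 16.0 and est.unbounded

    def test_threshold_between_third_and_fourth_dose(self):
        """A monotone decline whose effect becomes detectable at the 4th
        dose leaves the 3rd dose as the NOED."""
        spread = np.array([-0.4, 0.0, 0.4])
        ctrl = 10.0 + spread
        groups = {
            1: 10.0 + spread,
            2: 10.0 + spread,
            4: 10.0 + spread,
            8: 5.0 + spread,
            16: 3.0 + spread,
        }
        est = williams_noed(groups, ctrl, n_null=4000, seed=1)
        assert est.value == 4.0 and not est.unbounded

    def test_huge_effect_everywhere_flags_below_lowest(self):
        rng = np.random.default_rng(8)
        ctrl = rng.normal(10, 0.5, 9)
        groups = {d: rng.normal(10 - 5 * i - 5, 0.5, 3)
                  for i, d in enumerate((1, 2, 4))}
        est = williams_noed(groups, ctrl, n_null=4000, seed=1)
        assert est.below_lowest and est.value == 1.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(InsufficientDataError):
            williams_noed({1: [1.0, 2.0], 2: [3.0]}, [1.0, 2.0])

    def test_ci_invariant_on_estimate(self):
        with pytest.raises(ValueError):
            EndpointEstimate(kind="ld50", value=5.0, method="tsk",
                             ci_low=6.0, ci_high=7.0)


# ---------------------------------------------------------------------------
# Cochran-Armitage step-down


class TestTrendStepdown:
    @pytest.mark.parametrize(
        "deaths",
        [(0, 1, 5, 10), (1, 1, 1, 1), (2, 2, 3, 6), (10, 5, 2, 0)],
    )
    def test_normal_approximation_tracks_exact_permutation(self, deaths):
        n = (10, 10, 10, 10)
        scores = list(range(4))
        p_norm = cochran_armitage_p(n, deaths)
        p_exact = exact_ca_p(n, deaths, scores)
        assert p_norm == pytest.approx(p_exact, abs=0.03)
        assert (p_norm < 0.05) == (p_exact < 0.05)

    def test_obvious_trend_is_significant_then_steps_down(self):
        data = QuantalDoseResponse(
            (1, 2, 3), (10, 10, 10), (1, 5, 10), control=(10, 0)
        )
        est = stepdown_trend_noed(data)
        steps = est.details["p_values_stepdown"]
        assert steps[0] < 0.05  # full configuration significant
        assert est.value == 1.0 and not est.below_lowest

    def test_null_data_noed_is_highest_dose(self):
        data = QuantalDoseResponse(
            (1, 2, 3), (10, 10, 10), (1, 1, 1), control=(10, 1)
        )
        est = stepdown_trend_noed(data)
        assert est.value == 3.0 and est.unbounded

    def test_reversed_trend_not_significant_one_sided(self):
        assert cochran_armitage_p((10,) * 4, (10, 5, 2, 0)) > 0.95

    def test_single_dose_rejected(self):
        data = QuantalDoseResponse((1,), (10,), (5,), control=(10, 0))
        with pytest.raises(InsufficientDataError):
            stepdown_trend_noed(data)


# ---------------------------------------------------------------------------
# Fisher's exact with Holm adjustment


class TestFisherHolm:
    def test_single_table_one_sided_p_from_enumeration(self):
        # dead/alive 9/1 vs 1/9: P(X >= 9) = 101 / 184756
        data = QuantalDoseResponse((1.0,), (10,), (9,), control=(10, 1))
        est = fisher_holm_noed(data)
        assert est.details["p_raw"][0] == pytest.approx(101 / 184756, rel=1e-9)

    def test_all_groups_at_control_rate(self):
        data = QuantalDoseResponse(
            (1, 2, 3), (10, 10, 10), (1, 1, 1), control=(10, 1)
        )
        est = fisher_holm_noed(data)
        assert est.details["p_holm"] == [1.0, 1.0, 1.0]
        assert est.value == 3.0 and est.unbounded

    def test_identical_significant_groups_scale_by_k(self):
        k = 3
        data = QuantalDoseResponse(
            (1, 2, 3), (10,) * k, (9,) * k, control=(10, 0)
        )
        est = fisher_holm_noed(data)
        raw = est.details["p_raw"]
        assert est.details["p_holm"][0] == pytest.approx(k * raw[0])
        assert est.below_lowest

    def test_noed_is_highest_clean_dose(self):
        data = QuantalDoseResponse(
            (1, 2, 3), (10, 10, 10), (1, 1, 10), control=(10, 1)
        )
        est = fisher_holm_noed(data)
        assert est.value == 2.0

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=8)
    )
    @settings(deadline=None, max_examples=100)
    def test_holm_adjusted_p_monotone_in_stepdown_order(self, pvals):
        adj = holm_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)


# ---------------------------------------------------------------------------
# test selection and control screening


class TestSelection:
    def test_strictly_increasing_mortality_goes_to_trend(self):
        data = QuantalDoseResponse((1, 2, 3), (10,) * 3, (1, 5, 9))
        assert decide_test(data) == "cochran_armitage_stepdown"

    def test_u_shaped_mortality_goes_to_fisher(self):
        data = QuantalDoseResponse((1, 2, 3), (10,) * 3, (5, 1, 6))
        assert decide_test(data) == "fisher_holm"

    def test_continuous_replicates_go_to_williams(self):
        assert decide_test({1: [0.9, 1.0], 2: [0.7, 0.8]}) == "williams"

    def test_identical_controls_pool(self):
        assert compare_controls((10, 1), (10, 1)) == "pool_with_negative"

    def test_divergent_solvent_control_flagged(self):
        # 8/10 vs 0/10 dead: exact p < 0.05
        assert compare_controls((10, 0), (10, 8)) == "use_solvent"

    def test_missing_solvent_pools_by_construction(self):
        assert compare_controls((10, 1), None) == "pool_with_negative"

    def test_continuous_controls(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 12)
        assert compare_controls(a, a + 0.01) == "pool_with_negative"
        assert compare_controls(a, a - 8.0) == "use_solvent"
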