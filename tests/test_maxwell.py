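"""Prony-series fitting, order selection, RI, element taxonomy and QC."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelrelax import (
    FitOptions,
    MaxwellElement,
    MaxwellFit,
    RelaxationCurve,
    chi_squared,
    classify_elements,
    fit_fixed_order,
    prony_predict,
    qc_flag_collapse,
    relative_importance,
    select_order,
)
from gelrelax.errors import GelRelaxError, UndefinedRIError


def _fit_of(elements, e_inf=0.0):
    return MaxwellFit(elements=elements, E_inf_kpa=e_inf, chi2=0.0,
                      n_elements=len(elements), relative_importance=[],
                      converged=True, selection_trace=[], seed=0)


def _curve(elements, e_inf=0.0, noise=0.0, n=1001, t_end=100.0, seed=0):
    t = np.linspace(0, t_end, n)
    et = prony_predict(elements, e_inf, t)
    if noise > 0:
        et = et + np.random.default_rng(seed).normal(0, noise, n)
    return RelaxationCurve(t, et, 0.2)


class TestPronyPredict:
    def test_t_zero_is_sum_of_stiffnesses(self):
        els = [MaxwellElement(2.0, 5.0), MaxwellElement(1.0, 0.3)]
        assert prony_predict(els, 0.7, np.array([0.0]))[0] == 2.0 + 1.0 + 0.7

    def test_single_element_closed_form(self):
        els = [MaxwellElement(2.0, 5.0)]
        assert prony_predict(els, 0.0, np.array([5.0]))[0] == pytest.approx(
            2.0 * np.exp(-1.0), rel=1e-12
        )

    def test_long_time_asymptote_is_equilibrium(self):
        els = [MaxwellElement(2.0, 10.0)]
        assert prony_predict(els, 0.3, np.array([1000.0]))[0] == pytest.approx(
            0.3, abs=1e-12
        )

    def test_invalid_tau_rejected(self):
        with pytest.raises(GelRelaxError):
            MaxwellElement(1.0, -2.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0.0, 10.0), st.floats(0.01, 100.0)), min_size=1, max_size=4
        )
    )
    def test_monotone_nonincreasing_for_nonnegative_stiffness(self, pairs):
        els = [MaxwellElement(e, tau) for e, tau in pairs]
        y = prony_predict(els, 0.1, np.linspace(0, 50, 200))
        assert np.all(np.diff(y) <= 1e-12)


class TestChiSquared:
    def test_perfect_fit_is_zero(self):
        els = [MaxwellElement(1.5, 3.0)]
        assert chi_squared(_fit_of(els), _curve(els)) == 0.0

    def test_constant_residual(self):
        els = [MaxwellElement(1.5, 3.0)]
        curve = _curve(els, n=11)
        shifted = RelaxationCurve(curve.t_s, curve.Et_kpa + 0.2, 0.2)
        assert chi_squared(_fit_of(els), shifted) == pytest.approx(11 * 0.04, rel=1e-9)

    def test_against_brute_force_loop(self, rng):
        et = rng.normal(1.0, 0.3, 37)
        curve = RelaxationCurve(np.linspace(0, 100, 37), et, 0.2)
        zero_model = _fit_of([MaxwellElement(0.0, 1.0)])
        expected = sum(float(v) ** 2 for v in et)  # independent loop
        assert chi_squared(zero_model, curve) == pytest.approx(expected, rel=1e-12)


class TestFixedOrderFit:
    def test_recovers_single_element_exactly(self):
        curve = _curve([MaxwellElement(1.81, 5.0)])
        fit = fit_fixed_order(curve, 1, seed=1)
        assert fit.converged
        assert fit.elements[0].E_kpa == pytest.approx(1.81, rel=1e-6)
        assert fit.elements[0].tau_s == pytest.approx(5.0, rel=1e-6)

    def test_recovers_two_elements(self):
        curve = _curve([MaxwellElement(1.2, 0.5), MaxwellElement(0.6, 20.0)])
        fit = fit_fixed_order(curve, 2, seed=1)
        e = fit.elements
        assert e[0].E_kpa == pytest.approx(1.2, rel=1e-4)
        assert e[0].tau_s == pytest.approx(0.5, rel=1e-4)
        assert e[1].E_kpa == pytest.approx(0.6, rel=1e-4)
        assert e[1].tau_s == pytest.approx(20.0, rel=1e-4)

    def test_recovers_equilibrium_term(self):
        curve = _curve([MaxwellElement(1.0, 2.0)], e_inf=0.4, noise=0.005, seed=5)
        fit = fit_fixed_order(curve, 1, seed=2)
        assert fit.E_inf_kpa == pytest.approx(0.4, abs=0.02)

    def test_deterministic_given_seed(self):
        curve = _curve([MaxwellElement(1.2, 0.5), MaxwellElement(0.6, 20.0)], noise=0.02)
        a = fit_fixed_order(curve, 2, seed=7)
        b = fit_fixed_order(curve, 2, seed=7)
        assert a.chi2 == b.chi2
        assert [(e.E_kpa, e.tau_s) for e in a.elements] == [
            (e.E_kpa, e.tau_s) for e in b.elements
        ]

    def test_matches_grid_search_oracle(self):
        """Single-element fit agrees with an exhaustive 400x400 log-grid search."""
        curve = _curve([MaxwellElement(1.81, 5.0)], noise=0.018, n=201, seed=11)
        fit = fit_fixed_order(curve, 1, FitOptions(fit_e_inf=False), seed=3)
        e_grid = np.geomspace(0.18, 18.0, 400)
        tau_grid = np.geomspace(0.05, 200.0, 400)
        t, y = curve.t_s, curve.Et_kpa
        best = (np.inf, None, None)
        for tau in tau_grid:
            d = np.exp(-t / tau)
            ssr = np.sum(y**2) - 2 * e_grid * (d @ y) + e_grid**2 * (d @ d)
            k = int(np.argmin(ssr))
            if ssr[k] < best[0]:
                best = (ssr[k], e_grid[k], tau)
        log_step_e = np.log(e_grid[1] / e_grid[0])
        log_step_tau = np.log(tau_grid[1] / tau_grid[0])
        assert abs(np.log(fit.elements[0].E_kpa / best[1])) <= log_step_e
        assert abs(np.log(fit.elements[0].tau_s / best[2])) <= log_step_tau


class TestOrderSelection:
    def test_noiseless_two_element_curve_selects_two(self):
        curve = _curve([MaxwellElement(1.2, 0.5), MaxwellElement(0.6, 20.0)])
        fit = select_order(curve, seed=1)
        assert fit.n_elements == 2

    def test_noiseless_single_element_curve_selects_one(self):
        curve = _curve([MaxwellElement(1.81, 5.0)])
        fit = select_order(curve, seed=1)
        assert fit.n_elements == 1

    def test_chi2_non_increasing_along_trace(self):
        curve = _curve(
            [MaxwellElement(1.2, 0.4), MaxwellElement(0.5, 4.0)], noise=0.017, seed=9
        )
        fit = select_order(curve, max_n=4, epsilon=-1.0, seed=2,
                           options=FitOptions(n_starts=4))
        chis = [c for _, c in fit.selection_trace]
        assert len(chis) == 4
        assert all(a >= b for a, b in zip(chis, chis[1:]))

    def test_typical_gel_regime_needs_two_or_three_elements(self):
        """Fast fluid element + 1-10 s ECM element (+ slow mode) -> n in {2, 3}."""
        for seed in range(3):
            els = [MaxwellElement(1.2, 0.4), MaxwellElement(0.5, 4.0)]
            if seed == 2:
                els.append(MaxwellElement(0.25, 30.0))
            curve = _curve(els, noise=0.017, seed=100 + seed)
            fit = select_order(curve, seed=seed)
            assert fit.n_elements in (2, 3)


class TestRelativeImportance:
    @pytest.mark.parametrize(
        "e,expected",
        [([3.0, 1.0], [75.0, 25.0]), ([2.0], [100.0]), ([1.0, 1.0, 2.0], [25.0, 25.0, 50.0])],
    )
    def test_formula(self, e, expected):
        fit = _fit_of([MaxwellElement(v, 10.0 ** i) for i, v in enumerate(e)])
        assert relative_importance(fit) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_stiffness_undefined(self):
        with pytest.raises(UndefinedRIError):
            relative_importance(_fit_of([MaxwellElement(0.0, 1.0)]))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 100.0), min_size=1, max_size=4))
    def test_sums_to_100(self, stiffnesses):
        fit = _fit_of([MaxwellElement(e, 1.0 + i) for i, e in enumerate(stiffnesses)])
        assert sum(relative_importance(fit)) == pytest.approx(100.0, abs=1e-9)


class TestElementTaxonomy:
    @pytest.mark.parametrize(
        "tau,label",
        [
            (0.4, "sub_second_fluid"),
            (5.0, "ecm_1_10s"),
            (1.0, "ecm_1_10s"),  # left-closed bin
            (10.0, "slow_10_100s"),
            (100.0, "slow_10_100s"),
            (250.0, "out_of_range"),
        ],
    )
    def test_tau_bins(self, tau, label):
        assert classify_elements(_fit_of([MaxwellElement(1.0, tau)])) == [label]


class TestCollapseQC:
    def test_stress_forced_to_zero_is_flagged(self):
        t = np.linspace(0, 100, 1001)
        et = prony_predict([MaxwellElement(1.2, 0.5), MaxwellElement(0.6, 20.0)], 0.0, t)
        et[t >= 3.0] = 0.0  # gel gives way 3 s into the hold
        qc = qc_flag_collapse(RelaxationCurve(t, et, 0.2))
        assert qc.collapsed

    def test_clean_two_element_curve_not_flagged(self):
        curve = _curve(
            [MaxwellElement(1.2, 0.5), MaxwellElement(0.6, 20.0)], noise=0.018, seed=4
        )
        assert not qc_flag_collapse(curve).collapsed

    def test_all_zero_curve_flagged(self):
        t = np.linspace(0, 100, 101)
        qc = qc_flag_collapse(RelaxationCurve(t, np.zeros(101), 0.2))
        assert qc.collapsed

    def test_nonconverged_fit_flagged(self):
        curve = _curve([MaxwellElement(1.0, 5.0)], noise=0.01, seed=2)
        bad = dataclasses.replace(_fit_of([MaxwellElement(1.0, 5.0)]), converged=False)
        qc = qc_flag_collapse(curve, bad)
        assert qc.collapsed and "converge" in qc.reasons[0]
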