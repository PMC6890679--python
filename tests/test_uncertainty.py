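"""Delta-method propagation and one-at-a-time decomposition."""

import numpy as np
import pytest

import allergenrisk as ar
from allergenrisk.uncertainty import REPORT_UNIT


def _ln(loc, scale, n):
    return ar.LognormalParams(loc, scale, n, scale / np.sqrt(n),
                              scale**2 * np.sqrt(2 / (n - 1)))


CASE_B_X = _ln(-3.719, 0.747, 350)
CASE_B_Y = _ln(3.496, 1.283, 24)
CASE_B_Z = _ln(4.088, 2.987, 158)


class TestDeltaMethod:
    def test_centered_configuration_kills_variance_term(self):
        """mu_z = mu_x + mu_y makes the K2 (variance-uncertainty) factor
        vanish, leaving only the location contributions."""
        x, y, z = _ln(1.0, 1.0, 50), _ln(2.0, 1.0, 50), _ln(3.0, 1.0, 50)
        dec = ar.delta_method_variance(x, y, z)
        phi0 = 1 / np.sqrt(2 * np.pi)
        k1 = (phi0 / np.sqrt(3.0)) ** 2
        assert dec.var_consumption == pytest.approx(k1 * 1.0 / 50)
        assert dec.sum_individual == pytest.approx(3 * k1 / 50)

    def test_reproduces_published_risk_sd(self):
        """Total SD of the case B risk ~ 2.2 percentage points."""
        dec = ar.delta_method_variance(CASE_B_X, CASE_B_Y, CASE_B_Z)
        assert 100 * np.sqrt(dec.var_joint) == pytest.approx(2.20, rel=0.15)

    def test_components_are_exactly_additive(self):
        dec = ar.delta_method_variance(CASE_B_X, CASE_B_Y, CASE_B_Z)
        assert dec.var_joint == pytest.approx(dec.sum_individual, rel=1e-12)

    def test_variance_vanishes_with_infinite_samples(self):
        big = [_ln(p.location, p.scale, 10**12)
               for p in (CASE_B_X, CASE_B_Y, CASE_B_Z)]
        dec = ar.delta_method_variance(*big)
        assert dec.var_joint < 1e-13

    def test_restricted_to_triple_lognormal(self):
        with pytest.raises(ar.InvalidParameterError):
            ar.delta_method_variance(
                CASE_B_X, ar.ExponentialParams(0.013, 24, 0.003, 1848.0),
                CASE_B_Z,
            )

    def test_rank_order_threshold_then_contamination_then_consumption(self):
        dec = ar.delta_method_variance(CASE_B_X, CASE_B_Y, CASE_B_Z)
        assert dec.var_threshold > dec.var_contamination > dec.var_consumption


class TestOATDecomposition:
    def test_no_active_uncertainty_leaves_only_mc_noise(self):
        """With all parameter draws off every component sits at the
        binomial noise floor p(1-p)/n, far below the case B components."""
        spec = ar.case_a(K=60, n=4000, seed=21)
        dec = ar.oat_decomposition(spec)
        floor = 0.1 * 0.9 / 4000
        for v in (dec.var_consumption, dec.var_contamination,
                  dec.var_threshold, dec.var_joint):
            assert v < 5 * floor
        assert dec.var_joint < ar.delta_method_variance(
            CASE_B_X, CASE_B_Y, CASE_B_Z
        ).var_contamination

    def test_component_shrinks_as_its_sample_size_grows(self):
        """The contamination component is monotone decreasing in n_Y
        (closed-form mode: no inner-loop noise)."""
        vars_ = []
        for n_y in (24, 240, 2400):
            params = {
                "x": (-3.719, 0.747, 350),
                "y": (3.496, 1.283, n_y),
                "z": (4.088, 2.987, 158),
            }
            spec = ar.case_b(params=params, mode="calculated", K=3000, seed=22)
            dec = ar.oat_decomposition(spec)
            vars_.append(dec.var_contamination)
        assert vars_[0] > vars_[1] > vars_[2]

    def test_calculated_mode_components_match_delta_method(self):
        """Simulation decomposition in closed-form mode agrees with the
        delta method component-wise (no MC floor to inflate it)."""
        spec = ar.case_b(mode="calculated", K=8000, seed=23)
        sim = ar.oat_decomposition(spec)
        delta = ar.delta_method_variance(CASE_B_X, CASE_B_Y, CASE_B_Z)
        assert sim.var_contamination == pytest.approx(
            delta.var_contamination, rel=0.2
        )
        assert sim.var_threshold == pytest.approx(delta.var_threshold, rel=0.2)
        assert abs(sim.sum_individual - sim.var_joint) / sim.var_joint < 0.2

    def test_scale_overrides_are_applied(self):
        spec = ar.case_b(K=999, n=99999, seed=24)
        dec = ar.oat_decomposition(spec, K=40, n=500, seed=25)
        assert dec.method == "simulation"
        assert dec.var_joint >= 0


class TestDecompositionReport:
    def test_sum_row_is_exact_and_units_scale(self):
        dec = ar.UncertaintyDecomposition(1e-4, 2e-4, 3e-4, 6e-4, "delta")
        table = ar.decomposition_report(delta=dec)
        col = table["Calculation"]
        assert col["Sum of individual parameters"] == pytest.approx(
            col.iloc[:3].sum()
        )
        assert col["Consumption (X)"] == pytest.approx(1e-4 / REPORT_UNIT)

    def test_delta_only_table_has_single_column(self):
        dec = ar.UncertaintyDecomposition(1e-4, 2e-4, 3e-4, 6e-4, "delta")
        table = ar.decomposition_report(delta=dec, sim=None)
        assert list(table.columns) == ["Calculation"]

    def test_both_methods_render_side_by_side(self):
        d = ar.UncertaintyDecomposition(1e-4, 2e-4, 3e-4, 6e-4, "delta")
        s = ar.UncertaintyDecomposition(2e-4, 2e-4, 3e-4, 7e-4, "simulation")
        table = ar.decomposition_report(delta=d, sim=s)
        assert list(table.columns) == ["Calculation", "Simulation"]
        assert table.shape == (5, 2)

    def test_empty_report_rejected(self):
        with pytest.raises(ar.InvalidParameterError):
            ar.decomposition_report(None, None)
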