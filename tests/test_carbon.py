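import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batchphys.carbon import (
    instantaneous_theta,
    propagate_theta_error,
    sink_decomposition,
)
from batchphys.core import CarbonParams
from batchphys.datasets import anaplerosis_panel


def round_half_even(x: float, decimals: int = 2) -> float:
    return float(np.round(x, decimals))


class TestTheta:
    def test_wild_type_value(self):
        cb = instantaneous_theta(0.45, 4.82, 6.94)
        assert round_half_even(cb.theta) == 0.82

    def test_evolved_double_deletion_value(self):
        cb = instantaneous_theta(0.27, 3.74, 7.40)
        assert round_half_even(cb.theta) == 0.78

    def test_zero_sinks_give_zero(self):
        assert instantaneous_theta(0.0, 5.0, 0.0).theta == 0.0

    def test_nonpositive_uptake_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_theta(0.4, 0.0, 5.0)

    # strains whose published Θ is reproduced exactly at 2 decimals from
    # the published (2-decimal) rates; for the rest the rounding of the
    # printed inputs shifts the second decimal by one
    EXACT = ("WT", "dpyc", "dpyc_dodx", "dppc_dmalE", "dppc_dpyc_evo")

    def test_panel_thetas_reproduce_reported_values(self):
        """Recomputing Θ from the published rates reproduces the
        published Θ: exactly at 2 decimals where the printed precision
        allows it, within 0.015 everywhere."""
        panel = anaplerosis_panel()
        for strain, row in panel.iterrows():
            cb = instantaneous_theta(row.mu, row.pi_glc, row.pi_co2)
            if strain in self.EXACT:
                assert round_half_even(cb.theta) == pytest.approx(
                    row.theta_reported, abs=1e-12
                ), strain
            else:
                assert cb.theta == pytest.approx(
                    row.theta_reported, abs=0.015
                ), strain

    def test_mean_panel_theta_near_eighty_percent_closure(self):
        panel = anaplerosis_panel()
        thetas = [
            instantaneous_theta(r.mu, r.pi_glc, r.pi_co2).theta
            for _, r in panel.iterrows()
        ]
        assert 0.78 <= np.mean(thetas) <= 0.83

    @given(
        mu=st.floats(0.05, 1.0),
        pi_glc=st.floats(0.5, 10.0),
        pi_co2=st.floats(0.0, 20.0),
        k=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_monotonicity(self, mu, pi_glc, pi_co2, k):
        cb = instantaneous_theta(mu, pi_glc, pi_co2)
        # homogeneous of degree 0 in the three carbon rates
        scaled = instantaneous_theta(k * mu, k * pi_glc, k * pi_co2)
        assert scaled.theta == pytest.approx(cb.theta, rel=1e-9)
        # strictly increasing in pi_co2 and mu, decreasing in pi_glc
        assert instantaneous_theta(mu, pi_glc, pi_co2 + 0.5).theta > cb.theta
        assert instantaneous_theta(mu + 0.01, pi_glc, pi_co2).theta > cb.theta
        assert instantaneous_theta(mu, pi_glc * 1.1, pi_co2).theta < cb.theta

    def test_invariant_theta_equals_sinks_over_uptake(self):
        cb = instantaneous_theta(0.4, 4.5, 7.0)
        assert cb.theta == (cb.biomass_carbon_rate + cb.co2_carbon_rate) / cb.uptake_carbon_rate


class TestErrorPropagation:
    def test_exact_inputs_give_zero_error(self):
        cp = CarbonParams(sd_omega_c=0.0)
        assert propagate_theta_error(0.45, 4.82, 6.94, 0, 0, 0, cp) == 0.0

    def test_single_term_omega_c_partial(self):
        # only sd(omega_c)=0.05 active: sd = mu/(M_c*6*pi_glc) * 0.05
        sd = propagate_theta_error(0.45, 4.82, 6.94, 0.0, 0.0, 0.0)
        expect = 0.45 / (0.012011 * 6 * 4.82) * 0.05
        assert sd == pytest.approx(expect, rel=1e-9)
        assert sd == pytest.approx(0.0648, abs=2e-4)

    def test_full_wild_type_quadrature_sum(self):
        """Independent first-order propagation at the wild-type point:
        the quadrature sum gives ~0.097 (the published 0.089 presumably
        includes parameter covariances; both are reported, not forced)."""
        sd = propagate_theta_error(0.45, 4.82, 6.94, 0.04, 0.25, 0.71)
        assert sd == pytest.approx(0.097, abs=0.001)

    def test_matches_numerical_differentiation(self):
        cp = CarbonParams()
        args = (0.41, 5.0, 7.2)
        sds = (0.03, 0.2, 0.6)
        analytic = propagate_theta_error(*args, *sds, cp)

        def theta(mu, pg, pc, wc):
            return (mu * wc / cp.M_c + pc) / (6 * pg)

        h = 1e-7
        x = (*args, cp.omega_c)
        all_sds = (*sds, cp.sd_omega_c)
        var = 0.0
        for i in range(4):
            xp, xm = list(x), list(x)
            xp[i] += h
            xm[i] -= h
            d = (theta(*xp) - theta(*xm)) / (2 * h)
            var += (d * all_sds[i]) ** 2
        assert analytic == pytest.approx(np.sqrt(var), rel=1e-6)


class TestSinkDecomposition:
    def test_full_closure_has_zero_gap(self):
        cp = CarbonParams()
        pi_co2 = 6 * 5.0 - 0.4 * cp.omega_c / cp.M_c
        cb = instantaneous_theta(0.4, 5.0, pi_co2, cp)
        bio, co2, gap = sink_decomposition(cb)
        assert gap == pytest.approx(0.0, abs=1e-12)
        assert bio + co2 == pytest.approx(1.0, rel=1e-12)

    def test_fractions_sum_to_one_with_gap(self):
        cb = instantaneous_theta(0.45, 4.82, 6.94)
        bio, co2, gap = sink_decomposition(cb)
        assert bio + co2 + gap == pytest.approx(1.0, abs=1e-12)
        assert bio + co2 == pytest.approx(cb.theta, abs=1e-12)

    def test_retention_creates_gap_equal_to_withheld_co2_share(self):
        """Starting from a closed balance, retaining a fraction rho of
        the CO2 opens a gap of exactly rho times the CO2 carbon share."""
        cp = CarbonParams()
        mu, pi_glc = 0.45, 4.82
        pi_co2_true = 6 * pi_glc - mu * cp.omega_c / cp.M_c
        rho = 0.2
        cb = instantaneous_theta(mu, pi_glc, (1 - rho) * pi_co2_true, cp)
        _, _, gap = sink_decomposition(cb)
        assert gap == pytest.approx(rho * pi_co2_true / (6 * pi_glc), rel=1e-9)
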