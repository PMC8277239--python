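"""Exact mean-field reduction: fixed points, cycles, adjoint PRC."""

import numpy as np
import pytest

from gammaprc.meanfield import (
    DivergentError,
    MFParams,
    NonOscillatoryError,
    adjoint_imprc,
    emft_fmprc,
    find_limit_cycle,
    fixed_point,
    fixed_point_eigenvalues,
    mf_rhs,
    regime_and_response_maps,
)


class TestFixedPoint:
    @pytest.mark.parametrize("p", [MFParams.ing(), MFParams.ping()])
    def test_residual_vanishes(self, p):
        fp = fixed_point(p)
        assert np.max(np.abs(mf_rhs(0.0, fp, p))) < 1e-10
        assert fp[0] >= 0  # rates non-negative

    def test_quiescent_limit(self):
        # eta < 0, no coupling, delta -> 0: V -> -sqrt(-eta), r -> 0
        p = MFParams.ing(eta_i=-4.0, delta_i=1e-8, J_ii=0.0)
        fp = fixed_point(p)
        assert fp[1] == pytest.approx(-2.0, abs=1e-3)
        assert fp[0] < 1e-4


class TestLimitCycle:
    def test_standard_ing_oscillates(self, ing_mft):
        _, lc, _ = ing_mft
        assert 8.0 < lc.T < 12.0
        # orbit is periodic: endpoints of the sampled period agree
        assert np.allclose(lc.spline(0.0), lc.spline(lc.T), atol=1e-6)
        # anchor is the synaptic-variable peak
        s0 = lc.s_of(0.0)
        assert s0 == pytest.approx(lc.s_of(np.linspace(0, lc.T, 500)).max(), rel=1e-3)

    def test_large_heterogeneity_is_stationary(self):
        with pytest.raises(NonOscillatoryError):
            find_limit_cycle(MFParams.ing(delta_i=10.0))

    def test_period_robust_to_tolerance(self):
        p = MFParams.ing(delta_i=3.0)
        a = find_limit_cycle(p, rtol=1e-10)
        b = find_limit_cycle(p, rtol=5e-11)
        assert abs(a.T - b.T) < 1e-4 * a.T

    def test_hopf_side_matches_eigenvalues(self):
        for d in (3.0, 10.0):
            ev = np.max(np.real(fixed_point_eigenvalues(MFParams.ing(delta_i=d))))
            try:
                find_limit_cycle(MFParams.ing(delta_i=d), t_settle=300.0)
                oscillatory = True
            except (NonOscillatoryError, DivergentError):
                oscillatory = False
            assert oscillatory == (ev > 0)


class TestAdjoint:
    def test_normalization_identity(self, ing_mft):
        _, lc, z = ing_mft
        assert z.normalization_residual(lc) < 1e-6

    def test_type_two_with_paradoxical_component(self, ing_mft):
        _, lc, z = ing_mft
        v = z.v_component("I")
        assert v.min() < 0 < v.max()

    def test_linear_response_matches_finite_pulse(self, ing_mft):
        # small deflection: finite response within 10% of imPRC * dV
        p, lc, z = ing_mft
        ph, d = emft_fmprc(lc, p, dV=0.05, phases=12)
        lin = 0.05 * np.interp(ph, z.phases, z.v_component("I"))
        good = np.isfinite(d)
        assert np.max(np.abs(d[good] - lin[good])) < 0.1 * np.max(np.abs(lin))

    def test_finite_difference_richardson(self, ing_mft):
        """(dphi(+dV) - dphi(-dV)) / (2 dV) converges to the imPRC."""
        p, lc, z = ing_mft
        ph = np.array([0.15, 0.45, 0.75])
        zi = np.interp(ph, z.phases, z.v_component("I"))
        errs = []
        for dV in (0.2, 0.05):
            _, dp = emft_fmprc(lc, p, dV=+dV, phases=ph)
            _, dn = emft_fmprc(lc, p, dV=-dV, phases=ph)
            errs.append(np.max(np.abs((dp - dn) / (2 * dV) - zi)))
        assert errs[-1] <= errs[0] + 1e-5
        assert errs[-1] < 0.05 * np.max(np.abs(zi))

    def test_paradox_grows_with_heterogeneity(self):
        amps = []
        for d in (0.5, 1.5, 3.0):
            lc = find_limit_cycle(MFParams.ing(delta_i=d))
            z = adjoint_imprc(lc)
            amps.append(-z.v_component("I").min())
        assert amps[0] < amps[1] < amps[2]
        assert amps[0] > 0  # present even for weak heterogeneity

    def test_ping_paradox_in_all_four_scenarios(self):
        """Excitation can delay and inhibition can advance the PING
        rhythm through either population, in the weak-pulse regime where
        the response follows the adjoint's sign-changing V-component."""
        p = MFParams.ping(delta_e=1.0, delta_i=1.0)
        lc = find_limit_cycle(p)
        z = adjoint_imprc(lc)
        for tgt in ("E", "I"):
            v = z.v_component(tgt)
            assert v.min() < 0 < v.max()
            # probe the paradoxical lobe directly
            lobe = z.phases[v < 0.5 * v.min()]
            ph = np.linspace(lobe.min(), lobe.max(), 5)
            for dV in (+0.05, -0.05):
                _, d = emft_fmprc(lc, p, dV=dV, target=tgt, phases=ph)
                good = np.isfinite(d)
                assert good.any()
                if dV > 0:  # excitation: paradoxical = delay
                    assert np.nanmin(d[good]) < 0
                else:  # inhibition: paradoxical = advance
                    assert np.nanmax(d[good]) > 0


class TestMechanism:
    def test_external_input_shifts_within_network_inhibition(self, ing_mft):
        p, lc, _ = ing_mft
        _, _, inh_p, inh_ref = emft_fmprc(
            lc, p, dV=+3.0, phases=6, return_inhibition=True
        )
        _, _, inh_n, _ = emft_fmprc(
            lc, p, dV=-3.0, phases=6, return_inhibition=True
        )
        assert np.nanmean(inh_p) > inh_ref > np.nanmean(inh_n)


def test_regime_map_labels():
    tab = regime_and_response_maps(
        {"delta_i": np.array([3.0, 10.0])}, MFParams.ing(), n_phases=8
    )
    lab = tab.set_index("delta_i")["label"]
    assert lab[3.0] == "oscillatory"
    assert lab[10.0] == "stationary"
    assert tab[tab.label == "oscillatory"]["paradox_inh_I"].iloc[0] > 0
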