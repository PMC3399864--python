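"""ODE core: rate expressions, steady-state relaxation, event simulation."""

import numpy as np
import pytest

from nfkbuv.model import (
    STATE_NAMES,
    initial_state,
    relax_to_steady_state,
    rhs,
    simulate,
)
from nfkbuv.protocols import Event, StimulationProtocol

I = {n: i for i, n in enumerate(STATE_NAMES)}


def random_state(rng, params):
    y = rng.uniform(0.0, 1.0, len(STATE_NAMES))
    y[I["NFkB_n"]] = rng.uniform(0.0, params.nfkb_tot * params.k_v)
    return y


class TestRateExpressions:
    def test_pp2a_decays_first_order_under_uv(self, params):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = random_state(rng, params)
            d = rhs(y, 0.0, params, {"uv": 1.0})
            assert d[I["PP2A"]] == pytest.approx(-params.k_uv * y[I["PP2A"]],
                                                 rel=1e-12)
        # and is exactly constant without UV
        d0 = rhs(y, 0.0, params, {})
        assert d0[I["PP2A"]] == 0.0

    def test_total_ikba_conserved_under_mg_and_chx(self, params):
        """With synthesis (CHX) and proteasomal degradation (MG132) both
        blocked, total IκBα = free + nuclear/k_v + complexed cannot change."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = random_state(rng, params)
            d = rhs(y, 0.0, params, {"mg": 1.0, "chx": 1.0})
            # d(complex)/dt = -d(NFkB_n)/dt / k_v by the conservation law
            d_total = (d[I["IkBa"]] + d[I["IkBa_n"]] / params.k_v
                       - d[I["NFkB_n"]] / params.k_v)
            assert abs(d_total) < 1e-15

    def test_ikkp_gain_loss_structure(self, params):
        y = np.zeros(len(STATE_NAMES))
        y[I["ILRc"]], y[I["PP2A"]], y[I["IKKp"]] = 0.5, 1.0, 0.4
        d = rhs(y, 0.0, params, {})
        gain = (params.k_p * 0.5 + params.k_pconst) * 0.6
        loss = params.k_dp * 1.0 * 0.4 / (params.km + 0.4)
        assert d[I["IKKp"]] == pytest.approx(gain - loss, rel=1e-12)

    def test_zero_km_reduces_to_mass_action_in_pp2a(self, params):
        p = params.replace(km=0.0)
        y = np.zeros(len(STATE_NAMES))
        y[I["PP2A"]], y[I["IKKp"]] = 0.7, 0.3
        d = rhs(y, 0.0, p, {})
        assert d[I["IKKp"]] == pytest.approx(
            p.k_pconst * 0.7 - p.k_dp * 0.7, rel=1e-12
        )
        # degenerate 0/0 corner: no substrate, no flux
        y[I["IKKp"]] = 0.0
        assert np.isfinite(rhs(y, 0.0, p, {})[I["IKKp"]])

    def test_nonfinite_state_rejected_with_component_name(self, params):
        y = initial_state(params)
        y[I["IkBa_t"]] = np.nan
        with pytest.raises(ValueError, match="IkBa_t"):
            rhs(y, 0.0, params, {})
        with pytest.raises(ValueError, match="uv"):
            rhs(initial_state(params), 0.0, params, {"uv": np.inf})


class TestRelaxation:
    def test_steady_state_is_a_fixed_point(self, params, steady_state):
        """Direct evaluation of the vector field at the relaxed state."""
        resid = np.abs(rhs(steady_state, 0.0, params, {}))
        assert resid.max() < 1e-10

    def test_resting_ikk_is_almost_unphosphorylated(self, steady_state):
        assert steady_state[I["IKKp"]] < 0.01

    def test_nfkb_almost_exclusively_complexed_at_rest(self, params,
                                                       steady_state):
        complexed = params.nfkb_tot - steady_state[I["NFkB_n"]] / params.k_v
        assert complexed / params.nfkb_tot > 0.97

    def test_zero_flux_limit_keeps_initial_condition(self, params):
        p = params.replace(c_5a=0.0, c_6a=0.0, k_pconst=0.0)
        out = relax_to_steady_state(p)
        assert out == pytest.approx(initial_state(p), abs=1e-12)

    def test_nonstationary_end_state_warns(self, params):
        slow = params.replace(c_6a=1e-7, c_5a=6e-4)
        import nfkbuv.model as m

        m._relax_cache.clear()
        with pytest.warns(RuntimeWarning, match="not stationary"):
            relax_to_steady_state(slow, stationarity_tol=1e-30)
        m._relax_cache.clear()


class TestSimulate:
    def test_unstimulated_trajectory_is_flat(self, params, protocols, grid16):
        tr = simulate(params, protocols["UNSTIMULATED"], t_grid_h=grid16)
        for name in STATE_NAMES:
            v = tr.state(name)
            ref = max(abs(v[0]), 1e-12)
            assert np.all(np.abs(v - v[0]) <= 1e-3 * ref + 1e-14), name

    def test_steady_state_idempotence_over_further_120h(self, params,
                                                        protocols):
        grid = np.linspace(0.0, 120.0, 121)
        tr = simulate(params, protocols["UNSTIMULATED"], t_grid_h=grid)
        y0, yT = tr.states[0], tr.states[-1]
        assert np.all(np.abs(yT - y0) <= 1e-3 * np.maximum(np.abs(y0), 1e-12))

    @pytest.mark.parametrize("variant,forced", [("p", "k_uv"), ("t", "uvinh")])
    def test_variants_equal_manual_override(self, params, protocols, grid16,
                                            variant, forced):
        tr_variant = simulate(params, protocols["IL1_UVB"], variant=variant,
                              t_grid_h=grid16)
        tr_manual = simulate(params.replace(**{forced: 0.0}),
                             protocols["IL1_UVB"], t_grid_h=grid16)
        assert np.array_equal(tr_variant.states, tr_manual.states)

    def test_pp2a_matches_closed_form_under_uv(self, params, protocols,
                                               grid16):
        tr = simulate(params, protocols["UVB"], t_grid_h=grid16)
        p0 = tr.state("PP2A")[0]
        expected = p0 * np.exp(-params.k_uv * grid16 * 3600.0)
        rel = np.abs(tr.state("PP2A") - expected) / np.maximum(expected, 1e-300)
        assert rel[expected > 1e-3].max() < 1e-6

    def test_il1_ikkp_transient_shape(self, params, protocols):
        """Fast phosphorylation peak, near-complete dephosphorylation."""
        grid = np.linspace(0.0, 2.0, 241)
        tr = simulate(params, protocols["IL1"], t_grid_h=grid)
        ikkp = tr.state("IKKp")
        i_peak = int(np.argmax(ikkp))
        assert grid[i_peak] <= 0.5  # peak within 30 min
        assert ikkp[-1] < 0.1 * ikkp[i_peak]  # <10% of peak at 2 h

    @pytest.mark.parametrize(
        "proto_name", ["IL1", "UVB", "IL1_UVB", "IL1_UVB_MG_minus1h",
                       "IL1_UVB_MG_plus15", "CHX"]
    )
    def test_nonnegativity_and_conservation(self, params, protocols, grid16,
                                            proto_name):
        tr = simulate(params, protocols[proto_name], t_grid_h=grid16)
        assert tr.states.min() >= -1e-9
        # conservation-derived states stay in range
        nfkb_n = tr.state("NFkB_n")
        assert np.all(nfkb_n <= params.k_v * params.nfkb_tot + 1e-9)
        complexed = tr.state("IkBaNFkB")
        assert np.all(complexed >= -1e-9)
        assert np.all(complexed <= params.nfkb_tot + 1e-9)
        # IKK + IKKp == 1 identically (definition)
        assert np.array_equal(tr.state("IKK"), 1.0 - tr.state("IKKp"))

    def test_tolerance_refinement_changes_little(self, params, protocols):
        grid = np.linspace(0.0, 8.0, 97)
        a = simulate(params, protocols["IL1_UVB"], t_grid_h=grid)
        b = simulate(params, protocols["IL1_UVB"], t_grid_h=grid,
                     rtol=5e-9, atol=5e-11)
        for tot_a, tot_b in [(a.total_ikba(), b.total_ikba())]:
            assert np.max(np.abs(tot_a - tot_b)) < 1e-4 * tot_a[0]

    def test_unsorted_grid_rejected(self, params, protocols):
        with pytest.raises(ValueError, match="sorted"):
            simulate(params, protocols["IL1"], t_grid_h=[0.0, 2.0, 1.0])

    def test_event_after_grid_end_rejected(self, params):
        proto = StimulationProtocol("late", (Event(10.0, "mg", 1.0),))
        with pytest.raises(ValueError, match="outside"):
            simulate(params, proto, t_grid_h=np.linspace(0, 4, 5))

    def test_trajectory_frame_is_tidy(self, params, protocols):
        tr = simulate(params, protocols["IL1"], t_grid_h=[0.0, 1.0, 2.0])
        df = tr.to_frame()
        assert set(df.columns) == {"stimulation", "variant", "time_h",
                                   "state", "value"}
        assert set(df["state"]) == set(STATE_NAMES) | {"IKK", "IkBaNFkB"}
        assert len(df) == 3 * (len(STATE_NAMES) + 2)
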