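"""Reaction-network construction, steady-state solvers and perturbation scans."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from akdyn.kinetics import (
    isolate_effect,
    kc_scan,
    stationary_distribution,
    steady_state_turnover,
    velocity_curve,
)
from akdyn.params import Conditions, ConformationalRates, LIGATION_STATES, ModelParameters
from akdyn.states import N_STATES, build_generator, state_index

from conftest import random_model


def test_generator_is_conservative_without_catalysis(wt_params):
    # small-rate network: column sums vanish to 1e-12 absolute
    small = ModelParameters(
        k_cat=0.0, k_r_T=4.2, k_r_M=0.37, Kd_ATP=5e-5, Kd_AMP=3.3e-4, k_on=1e4,
        conformational_rates=ConformationalRates.from_kc(0.16, 1.28, relaxation_rate=40.0),
    )
    G = build_generator(small, Conditions(atp=1e-3, amp=5e-3))
    assert np.abs(G.sum(axis=0)).max() < 1e-12
    # full-scale rates: conservation holds to rounding ulp of the largest rate
    params = wt_params.with_updates(k_cat=0.0)
    G = build_generator(params, Conditions(atp=1e-3, amp=5e-3))
    assert np.abs(G.sum(axis=0)).max() < 1e-15 * np.abs(G).max()


def test_generator_conservative_with_recycling_drain(wt_params):
    # catalysis recycles enzyme to E(open), so columns still sum to zero
    G = build_generator(wt_params, Conditions(atp=1e-3, amp=5e-3))
    assert np.abs(G.sum(axis=0)).max() < 1e-9


def test_absent_amp_leaves_amp_species_unpopulated(wt_params):
    G = build_generator(wt_params, Conditions(atp=1e-3, amp=0.0))
    p = stationary_distribution(G)
    for lig in ("EM", "EMTi"):
        for conf in ("open", "closed"):
            assert p[state_index(lig, conf)] < 1e-15


def test_stationary_matches_eigendecomposition_oracle():
    """Null-space solve agrees with an independent eigen-decomposition, and the
    closed/open occupancy ratio of each ligation state reproduces its K_C when
    catalysis is off."""
    rng = np.random.default_rng(42)
    params, cond = random_model(rng)
    params = params.with_updates(k_cat=0.0)
    G = build_generator(params, cond)
    p = stationary_distribution(G)
    ns = null_space(G)
    assert ns.shape[1] == 1
    p_oracle = np.abs(ns[:, 0]) / np.abs(ns[:, 0]).sum()
    np.testing.assert_allclose(p, p_oracle, atol=1e-10)
    for lig in LIGATION_STATES:
        po = p[state_index(lig, "open")]
        pc = p[state_index(lig, "closed")]
        if po > 1e-12:
            assert pc / po == pytest.approx(params.conformational_rates.kc(lig), rel=1e-6)


def test_no_atp_means_no_turnover(wt_params):
    v, flux = steady_state_turnover(wt_params, Conditions(atp=0.0, amp=5e-3))
    assert v == pytest.approx(0.0, abs=1e-12)
    assert flux.total == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_ode_and_nullspace_steady_states_agree(seed):
    rng = np.random.default_rng(1000 + seed)
    params, cond = random_model(rng)
    v, _ = steady_state_turnover(params, cond, method="nullspace", cross_check=True)
    assert v >= 0.0


def test_probability_conserved_along_trajectory(wt_params):
    params = wt_params.with_updates(k_cat=0.0)
    G = build_generator(params, Conditions(atp=1e-3, amp=5e-3))
    p0 = np.zeros(N_STATES)
    p0[state_index("E", "open")] = 1.0
    sol = solve_ivp(lambda _t, p: G @ p, (0.0, 0.1), p0, method="BDF",
                    jac=lambda _t, _p: G, rtol=1e-8, atol=1e-12, dense_output=True)
    for t in np.linspace(0.0, 0.1, 25):
        assert abs(sol.sol(t).sum() - 1.0) < 1e-9


def test_detailed_balance_in_pure_binding_network(wt_params):
    """With rearrangement and catalysis off, binding equilibria reproduce Kd."""
    from akdyn.kinetics import _ode_steady_state

    params = wt_params.with_updates(k_cat=0.0, k_r_T=0.0, k_r_M=0.0)
    cond = Conditions(atp=2e-4, amp=7e-4)
    p = _ode_steady_state(build_generator(params, cond))
    e_open = p[state_index("E", "open")]
    assert p[state_index("ET", "open")] / e_open == pytest.approx(cond.atp / params.Kd_ATP, rel=1e-6)
    assert p[state_index("EM", "open")] / e_open == pytest.approx(cond.amp / params.Kd_AMP, rel=1e-6)


def test_pathway_fluxes_sum_to_catalytic_flux(wt_params):
    v, flux = steady_state_turnover(wt_params, Conditions(atp=1e-3, amp=2e-3))
    assert flux.via_atp_first + flux.via_amp_first == pytest.approx(flux.total, rel=1e-8)
    assert flux.total == pytest.approx(v, rel=1e-12)


def test_velocity_curve_composes_single_solves(wt_params):
    scan = [1e-4, 1e-3, 1e-2]
    curve = velocity_curve(wt_params, Conditions(atp=1e-3, amp=0.0), scan)
    for conc, v in zip(curve["conc_M"], curve["velocity_per_s"]):
        v_single, _ = steady_state_turnover(wt_params, Conditions(atp=1e-3, amp=conc))
        assert v == pytest.approx(v_single, rel=1e-12)


def test_substrate_inhibition_present_and_removable(wt_params):
    """The wild-type curve has an interior maximum; equalizing the rearrangement
    rates (removing the slow pathway's barrier) abolishes the inhibition."""
    scan = np.logspace(-5, np.log10(5e-2), 25)
    base = Conditions(atp=1e-3, amp=0.0)
    wt = velocity_curve(wt_params, base, scan)["velocity_per_s"].to_numpy()
    imax = int(np.argmax(wt))
    assert 0 < imax < len(wt) - 1
    assert wt[-1] < 0.8 * wt[imax]

    no_barrier = wt_params.with_updates(k_r_M=wt_params.k_r_T)
    v = velocity_curve(no_barrier, base, scan)["velocity_per_s"].to_numpy()
    assert np.all(np.diff(v) > -1e-4 * v.max())


def test_turnover_vanishes_at_low_amp(wt_params):
    v, _ = steady_state_turnover(wt_params, Conditions(atp=1e-3, amp=1e-9))
    assert v < 1.0  # s^-1, far below the hundreds at the optimum


def test_isolate_effect_identity_and_nonadditivity(wt_params, wt_params_urea):
    scan = [1e-4, 1e-3, 1e-2]
    base = Conditions(atp=1e-3, amp=0.0)
    same = isolate_effect(wt_params, wt_params, "affinity_only", base, scan)
    baseline = velocity_curve(wt_params, base, scan)
    np.testing.assert_allclose(same["velocity_per_s"], baseline["velocity_per_s"], rtol=1e-12)

    affinity = isolate_effect(wt_params, wt_params_urea, "affinity_only", base, scan)
    dynamics = isolate_effect(wt_params, wt_params_urea, "dynamics_only", base, scan)
    joint = velocity_curve(wt_params_urea, base, scan)
    single_deltas = (affinity["velocity_per_s"] - baseline["velocity_per_s"]) + (
        dynamics["velocity_per_s"] - baseline["velocity_per_s"])
    joint_delta = joint["velocity_per_s"] - baseline["velocity_per_s"]
    assert not np.allclose(single_deltas, joint_delta, rtol=1e-3)


def test_affinity_swap_hurts_low_amp_helps_intermediate(wt_params, wt_params_urea):
    """Weakening AMP binding alone lowers velocity at low AMP but raises it at
    intermediate AMP, where it diverts flux from the slow pathway."""
    scan = [1e-4, 2e-3]
    base = Conditions(atp=1e-3, amp=0.0)
    baseline = velocity_curve(wt_params, base, scan)["velocity_per_s"].to_numpy()
    affinity = isolate_effect(wt_params, wt_params_urea, "affinity_only", base, scan)[
        "velocity_per_s"].to_numpy()
    assert affinity[0] < baseline[0]
    assert affinity[1] > baseline[1]


def test_kc_scan_identity_and_modes(wt_params):
    cond = Conditions(atp=1e-3, amp=1e-2)
    v_base, _ = steady_state_turnover(wt_params, cond)
    for mode in ("opening", "closing", "both"):
        table = kc_scan(wt_params, cond, [1.0], mode=mode)
        assert table["velocity_per_s"].iloc[0] == pytest.approx(v_base, rel=1e-12)
    with pytest.raises(ValueError):
        kc_scan(wt_params, cond, [0.0])


def test_kc_preserving_scan_has_interior_optimum_at_physiological_conditions(wt_params):
    """At ~5 mM ATP / 300 uM AMP, scanning K_C (opening-rate scaling) shows an
    interior turnover maximum near the experimentally observed equilibrium."""
    cond = Conditions(atp=5e-3, amp=3e-4)
    factors = np.logspace(-2, 2, 17)
    v = kc_scan(wt_params, cond, factors, mode="opening")["velocity_per_s"].to_numpy()
    imax = int(np.argmax(v))
    assert 0 < imax < len(v) - 1


def test_turnover_dependence_on_association_rate_saturates(wt_params):
    """Because binding connects open conformers only, association flux competes
    with conformational exchange: turnover rises monotonically with k_on and
    saturates once binding exchange outruns the conformational relaxation."""
    cond = Conditions(atp=1e-3, amp=2e-3)
    velocities = []
    for factor in (0.1, 1.0, 10.0, 100.0, 1000.0):
        v, _ = steady_state_turnover(
            wt_params.with_updates(k_on=wt_params.k_on * factor), cond)
        velocities.append(v)
    assert all(a < b for a, b in zip(velocities, velocities[1:]))
    # saturation: the last decade of k_on moves turnover by ~1%, the first by >50%
    assert velocities[-1] / velocities[-2] < 1.02
    assert velocities[1] / velocities[0] > 1.5


def test_invalid_inputs_raise(wt_params):
    with pytest.raises(ValueError):
        Conditions(atp=-1e-3, amp=0.0)
    with pytest.raises(ValueError):
        ModelParameters(k_cat=-1, k_r_T=1, k_r_M=1, Kd_ATP=1e-4, Kd_AMP=1e-4,
                        conformational_rates=wt_params.conformational_rates)
    with pytest.raises(ValueError):
        velocity_curve(wt_params, Conditions(atp=1e-3, amp=0.0), [])
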