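"""Markov channel schemes: structure, equilibria, and the binomial algorithm."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import axonoise as ax
from axonoise.kinetics import (ChannelPopulationState, KineticScheme,
                               deterministic_step, equilibrium_distribution,
                               hh_squid_schemes, initial_counts,
                               stochastic_step, wang_buzsaki_schemes)


def n_inf(scheme_k, v):
    """Closed-form stationary open probability of an n⁴ activation chain."""
    a = scheme_k.transitions[0][2](v) / 4.0  # 4α_n on n0→n1
    b = [tr for tr in scheme_k.transitions if tr[0] == "n1" and tr[1] == "n0"][0][2](v)
    return (a / (a + b)) ** 4


@pytest.mark.parametrize("factory", [hh_squid_schemes, wang_buzsaki_schemes])
def test_scheme_structure(factory):
    na, k = factory()
    assert na.n_states == 8  # 3 m-gates x 1 h-gate lattice
    assert k.n_states == 5  # 4 independent n-gates
    assert na.conducting == frozenset({"m3h1"})
    assert k.conducting == frozenset({"n4"})
    # subunit multiplicity: rate out of m0 is 3x the single-subunit rate of m2->m3
    v = -30.0
    r_m0 = [tr[2](v) for tr in na.transitions if tr[0] == "m0h1" and tr[1] == "m1h1"][0]
    r_m2 = [tr[2](v) for tr in na.transitions if tr[0] == "m2h1" and tr[1] == "m3h1"][0]
    assert r_m0 == pytest.approx(3.0 * r_m2, rel=1e-12)


def test_scheme_validation_errors():
    ok = lambda v: np.full_like(np.asarray(v, float), 1.0)
    with pytest.raises(ValueError, match="undeclared"):
        KineticScheme("x", ("a", "b"), (("a", "c", ok),), frozenset({"b"}), 1.0, 0.0)
    with pytest.raises(ValueError, match="conducting"):
        KineticScheme("x", ("a", "b"), (("a", "b", ok),), frozenset(), 1.0, 0.0)
    neg = lambda v: np.full_like(np.asarray(v, float), -1.0)
    with pytest.raises(ValueError, match="negative"):
        KineticScheme("x", ("a", "b"), (("a", "b", neg),), frozenset({"b"}), 1.0, 0.0)


@pytest.mark.parametrize("factory", [hh_squid_schemes, wang_buzsaki_schemes])
@pytest.mark.parametrize("v", [-80.0, -65.0, -40.0, 0.0, 40.0])
def test_equilibrium_matches_closed_form(factory, v):
    """Stationary open mass of the K⁺ chain equals n∞⁴ at any clamp."""
    _, k = factory()
    pi = equilibrium_distribution(k, v)
    assert pi.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(pi >= 0)
    assert pi[-1] == pytest.approx(n_inf(k, v), rel=1e-10)


def test_equilibrium_one_way_chain():
    """All rates zero except closed→open: all stationary mass sits open."""
    fwd = lambda v: np.full_like(np.asarray(v, float), 2.0)
    zero = lambda v: np.zeros_like(np.asarray(v, float))
    sch = KineticScheme("oneway", ("c", "o"), (("c", "o", fwd), ("o", "c", zero)),
                        frozenset({"o"}), 1.0, 0.0)
    pi = equilibrium_distribution(sch, -60.0)
    assert pi == pytest.approx([0.0, 1.0], abs=1e-12)


def test_equilibrium_singular_chain_fails():
    """A chain with no transitions at all has no unique stationary state."""
    zero = lambda v: np.zeros_like(np.asarray(v, float))
    sch = KineticScheme("dead", ("c", "o"), (("c", "o", zero), ("o", "c", zero)),
                        frozenset({"o"}), 1.0, 0.0)
    with pytest.raises((np.linalg.LinAlgError, ValueError)):
        equilibrium_distribution(sch, -60.0)


def test_stochastic_step_zero_rates_noop(rng):
    zero = lambda v: np.zeros_like(np.asarray(v, float))
    sch = KineticScheme("frozen", ("c", "o"), (("c", "o", zero), ("o", "c", zero)),
                        frozenset({"o"}), 1.0, 0.0)
    state = ChannelPopulationState(np.array([[40, 10]]), np.array([50]))
    out = stochastic_step(state, sch, -60.0, 0.001, rng)
    assert np.array_equal(out.counts, state.counts)


def test_stochastic_step_mean_exit_rate(rng):
    """One state, one exit at rate r: mean leavers ≈ N·r·dt (binomial mean)."""
    r, dt, n_ch, n_rep = 0.2, 0.01, 200, 100_000
    fwd = lambda v: np.full_like(np.asarray(v, float), r)
    zero = lambda v: np.zeros_like(np.asarray(v, float))
    sch = KineticScheme("exit", ("c", "o"), (("c", "o", fwd), ("o", "c", zero)),
                        frozenset({"o"}), 1.0, 0.0)
    state = ChannelPopulationState(
        np.tile([n_ch, 0], (n_rep, 1)), np.full(n_rep, n_ch))
    out = stochastic_step(state, sch, -60.0, dt, rng)
    leavers = out.counts[:, 1]
    p = r * dt
    se = np.sqrt(n_ch * p * (1 - p) / n_rep)
    assert abs(leavers.mean() - n_ch * p) < 3 * se


def test_stochastic_step_dt_guard():
    fast = lambda v: np.full_like(np.asarray(v, float), 600.0)
    sch = KineticScheme("fast", ("c", "o"), (("c", "o", fast),),
                        frozenset({"o"}), 1.0, 0.0)
    state = ChannelPopulationState(np.array([[10, 0]]), np.array([10]))
    with pytest.raises(ValueError, match="escape probability"):
        stochastic_step(state, sch, -60.0, 0.001, np.random.default_rng(0))


@settings(derandomize=True, max_examples=20, deadline=None)
@given(v=st.floats(-90.0, 50.0), seed=st.integers(0, 2**31 - 1),
       n_ch=st.integers(1, 500))
def test_channel_count_conservation(v, seed, n_ch):
    """Totals are an exact integer identity through repeated binomial steps."""
    na, _ = wang_buzsaki_schemes()
    rng = np.random.default_rng(seed)
    counts = np.tile(initial_counts(na, -65.0, n_ch), (4, 1))
    state = ChannelPopulationState(counts, np.full(4, n_ch))
    for _ in range(5):
        state = stochastic_step(state, na, v, 0.001, rng)
    assert np.array_equal(state.counts.sum(axis=1), np.full(4, n_ch))
    assert np.all(state.counts >= 0)


CLAMP_N_CH = 50
CLAMP_N_REP = 2000
CLAMP_V = -30.0


@pytest.fixture(scope="module")
def clamp_samples():
    """Long clamp of the K⁺ chain at −30 mV: 2000 independent compartments
    of 50 channels burnt in for 10 gating time constants and read out once,
    giving 1e5 independent channel-state observations."""
    dt = 0.005
    _, k = hh_squid_schemes()
    rng = np.random.default_rng(424242)
    pi = equilibrium_distribution(k, CLAMP_V)
    tau = 1.0 / (k.transitions[0][2](CLAMP_V) / 4.0
                 + k.transitions[1][2](CLAMP_V))
    burn = int(10 * tau / dt)
    counts = np.tile(initial_counts(k, -65.0, CLAMP_N_CH), (CLAMP_N_REP, 1))
    state = ChannelPopulationState(counts, np.full(CLAMP_N_REP, CLAMP_N_CH))
    for _ in range(burn):
        state = stochastic_step(state, k, CLAMP_V, dt, rng)
    return k, pi, state.counts.copy()


class TestVoltageClampStationarity:
    """Stationary state distribution and open-count variance under clamp."""

    N_CH = CLAMP_N_CH
    N_REP = CLAMP_N_REP

    def test_state_distribution_matches_equilibrium(self, clamp_samples):
        """χ² goodness-of-fit of 1e5 channel-state draws vs the stationary
        law (not rejected at α = 0.01)."""
        k, pi, counts = clamp_samples
        observed = counts.sum(axis=0).astype(float)
        total = observed.sum()
        assert total == self.N_CH * self.N_REP
        chi2, p = stats.chisquare(observed, pi * total)
        assert p > 0.01, f"chi2={chi2:.1f}, p={p:.2e}"

    def test_open_count_variance_is_binomial(self, clamp_samples):
        """Var(open) ≈ N·p(1−p) across independent compartments: channel
        noise is binomial at stationarity."""
        k, pi, counts = clamp_samples
        n_open = counts[:, -1]
        p_open = pi[-1]
        expected = self.N_CH * p_open * (1 - p_open)
        # SE of a variance over 2000 independent draws is ~4.5 %
        assert n_open.var(ddof=0) == pytest.approx(expected, rel=0.15)
        assert n_open.mean() == pytest.approx(self.N_CH * p_open, rel=0.05)


def test_deterministic_step_fixed_point():
    """The discrete map settles at the clamped equilibrium to within its
    first-order integration tolerance, converging linearly in dt."""
    na, _ = wang_buzsaki_schemes()
    pi = equilibrium_distribution(na, -50.0)
    gaps = {}
    for dt in (0.001, 0.00025):
        out = pi.copy()
        for _ in range(int(0.5 / dt)):
            out = deterministic_step(out, na, -50.0, dt)
        gaps[dt] = np.abs(out - pi).max()
    assert gaps[0.001] < 1e-3
    assert gaps[0.001] / gaps[0.00025] == pytest.approx(4.0, rel=0.25)


def test_deterministic_step_bit_identical():
    na, _ = wang_buzsaki_schemes()
    x = equilibrium_distribution(na, -65.0)
    a = deterministic_step(x, na, -20.0, 0.001)
    b = deterministic_step(x, na, -20.0, 0.001)
    assert np.array_equal(a, b)


def test_deterministic_matches_stochastic_mean():
    """1 ms clamp step: master-equation mean vs 10⁴ binomial replicates."""
    na, _ = wang_buzsaki_schemes()
    rng = np.random.default_rng(77)
    n_ch, n_rep, dt, v = 100, 10_000, 0.002, -30.0
    c0 = initial_counts(na, -65.0, n_ch)
    state = ChannelPopulationState(np.tile(c0, (n_rep, 1)), np.full(n_rep, n_ch))
    frac = c0 / n_ch
    for _ in range(int(1.0 / dt)):
        state = stochastic_step(state, na, v, dt, rng)
        frac = deterministic_step(frac, na, v, dt)
    mc_mean = state.counts.mean(axis=0) / n_ch
    mc_se = state.counts.std(axis=0, ddof=0) / n_ch / np.sqrt(n_rep)
    assert np.all(np.abs(mc_mean - frac) <= 3 * mc_se + 1e-12)


def test_rate_table_matches_direct_evaluation():
    """0.01 mV tabulation agrees with direct rate evaluation to 1e-6 relative."""
    na, k = hh_squid_schemes()
    vgrid = np.arange(-130.0, 90.0 + 0.005, 0.01)
    v_test = np.linspace(-99.5, 59.5, 997)
    for sch in (na, k):
        tab = sch.rate_table(vgrid)
        for t, (_, _, fn) in enumerate(sch.transitions):
            interp = np.interp(v_test, vgrid, tab[t])
            direct = np.asarray(fn(v_test))
            denom = np.maximum(np.abs(direct), 1e-12)
            assert np.max(np.abs(interp - direct) / denom) < 1e-6


def test_scheme_declared_from_config_mapping():
    """A scheme declared with textual rate expressions of V matches the
    equivalent programmatic scheme."""
    from axonoise.kinetics import scheme_from_dict

    decl = {
        "name": "K_decl",
        "states": ["n0", "n1", "n2", "n3", "n4"],
        "transitions": (
            [[f"n{i}", f"n{i+1}", f"{4-i} * 0.01 * exp_trap(V + 55, 10)"]
             for i in range(4)]
            + [[f"n{i+1}", f"n{i}", f"{i+1} * 0.125 * exp(-(V + 65) / 80)"]
               for i in range(4)]
        ),
        "conducting": ["n4"],
        "single_channel_conductance": 20.0,
        "reversal_potential": -77.0,
    }
    sch = scheme_from_dict(decl)
    _, k_ref = hh_squid_schemes()
    for v in (-95.0, -65.0, -30.0, 10.0, 55.0):
        assert np.allclose(sch.rate_matrix(v), k_ref.rate_matrix(v),
                           rtol=1e-12)
    assert sch.conducting_indices.tolist() == [4]
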