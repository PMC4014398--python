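"""Voltage-dependent Markov kinetic schemes for ion-channel populations.

A channel type is described by a :class:`KineticScheme`: a finite set of
states, voltage-dependent transition rates between them (ms⁻¹), and a set of
conducting states that carry the single-channel conductance.  Populations of
such channels are advanced either stochastically — drawing the number of
channels making each transition per time step from a binomial distribution
(the "binomial algorithm") — or deterministically, by propagating expected
occupancies through the master equation.

All voltages are in mV, all times in ms, all rates in ms⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "KineticScheme",
    "ChannelPopulationState",
    "scheme_from_dict",
    "hh_squid_schemes",
    "wang_buzsaki_schemes",
    "equilibrium_distribution",
    "stochastic_step",
    "deterministic_step",
]

RATE_VALID_RANGE = (-100.0, 60.0)


def _exp_trap(x, k):
    """x / (1 - exp(-x/k)), with the removable singularity at x = 0 filled in.

    This is the standard form of the Hodgkin–Huxley opening-rate functions.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x / k) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, k * (1.0 + x / (2.0 * k)), safe / (1.0 - np.exp(-safe / k)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KineticScheme:
    """A voltage-dependent Markov chain for one channel type.

    Parameters
    ----------
    name
        Identifier (used in recordings and run metadata).
    states
        Ordered state labels.
    transitions
        ``(from_state, to_state, rate_fn)`` triples; ``rate_fn(V_mV) -> ms⁻¹``
        must be vectorizable and non-negative on [-100, 60] mV.
    conducting
        Labels of the states that carry ``single_channel_conductance``.
    single_channel_conductance
        Conductance of one open channel, pS.
    reversal_potential
        Reversal potential of the carried current, mV.
    """

    name: str
    states: tuple
    transitions: tuple
    conducting: frozenset
    single_channel_conductance: float  # pS
    reversal_potential: float  # mV

    def __post_init__(self):
        labels = set(self.states)
        if len(labels) != len(self.states):
            raise ValueError(f"{self.name}: duplicate state labels")
        for src, dst, _ in self.transitions:
            if src not in labels or dst not in labels:
                raise ValueError(
                    f"{self.name}: transition {src}->{dst} uses undeclared state"
                )
        if not self.conducting:
            raise ValueError(f"{self.name}: at least one conducting state required")
        if not set(self.conducting) <= labels:
            raise ValueError(f"{self.name}: conducting set contains unknown state")
        vv = np.linspace(*RATE_VALID_RANGE, 321)
        for src, dst, fn in self.transitions:
            r = np.asarray(fn(vv), dtype=float)
            if not np.all(np.isfinite(r)) or np.any(r < 0):
                raise ValueError(
                    f"{self.name}: rate {src}->{dst} negative or non-finite "
                    f"on [{RATE_VALID_RANGE[0]}, {RATE_VALID_RANGE[1]}] mV"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label) -> int:
        return self.states.index(label)

    @property
    def conducting_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.states) if s in self.conducting], dtype=int
        )

    def rate_matrix(self, v: float) -> np.ndarray:
        """Generator matrix Q at clamped potential ``v``; Q[i, j] = rate i→j
        for i ≠ j, rows sum to zero."""
        n = self.n_states
        q = np.zeros((n, n))
        for src, dst, fn in self.transitions:
            q[self.state_index(src), self.state_index(dst)] += float(fn(v))
        q[np.diag_indices(n)] -= q.sum(axis=1)
        return q

    def transition_arrays(self):
        """(src_idx, dst_idx) integer arrays in declared order."""
        src = np.array([self.state_index(s) for s, _, _ in self.transitions], dtype=np.int64)
        dst = np.array([self.state_index(d) for _, d, _ in self.transitions], dtype=np.int64)
        return src, dst

    def rate_table(self, v_grid: np.ndarray) -> np.ndarray:
        """Tabulated rates, shape (n_transitions, len(v_grid))."""
        return np.array([np.asarray(fn(v_grid), dtype=float) for _, _, fn in self.transitions])

    def escape_probability(self, v, dt: float) -> np.ndarray:
        """Summed per-state probability of leaving each state in one step dt."""
        out = np.zeros(self.n_states)
        for src, _, fn in self.transitions:
            out[self.state_index(src)] += float(fn(v)) * dt
        return out


@dataclass
class ChannelPopulationState:
    """Integer occupancies of one channel population, one row per compartment."""

    counts: np.ndarray  # (n_compartments, n_states) int64
    total: np.ndarray  # (n_compartments,) int64

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=np.int64))
        self.total = np.atleast_1d(np.asarray(self.total, dtype=np.int64))
        self.validate()

    def validate(self):
        if np.any(self.counts < 0):
            raise ValueError("negative channel occupancy")
        if np.any(self.counts.sum(axis=1) != self.total):
            raise ValueError("occupancies do not sum to the per-compartment total")


# rate-expression namespace for schemes declared in configuration files
_EXPR_NS = {
    "exp": np.exp, "expm1": np.expm1, "log": np.log, "sqrt": np.sqrt,
    "where": np.where, "abs": np.abs, "exp_trap": _exp_trap,
}


def scheme_from_dict(d: dict) -> KineticScheme:
    """Build a scheme from a declarative (e.g. YAML-loaded) mapping.

    Expected keys: ``name``, ``states`` (list), ``transitions`` (list of
    ``[from, to, expr]`` where ``expr`` is an arithmetic expression of the
    membrane potential ``V`` in mV, e.g. ``"0.1 * exp_trap(V + 40, 10)"``),
    ``conducting`` (list), ``single_channel_conductance`` (pS) and
    ``reversal_potential`` (mV).  Available functions: exp, expm1, log,
    sqrt, where, abs and exp_trap(x, k) = x/(1−e^(−x/k)).
    """
    transitions = []
    for src, dst, expr in d["transitions"]:
        code = compile(expr, f"<rate {src}->{dst}>", "eval")

        def rate(v, code=code):
            out = eval(code, {"__builtins__": {}},
                       {**_EXPR_NS, "V": np.asarray(v, dtype=float)})
            return np.broadcast_to(np.asarray(out, dtype=float),
                                   np.shape(np.asarray(v, dtype=float)))
        transitions.append((src, dst, rate))
    return KineticScheme(
        name=d["name"],
        states=tuple(d["states"]),
        transitions=tuple(transitions),
        conducting=frozenset(d["conducting"]),
        single_channel_conductance=float(d["single_channel_conductance"]),
        reversal_potential=float(d["reversal_potential"]),
    )


# ---------------------------------------------------------------------------
# Canonical schemes
# ---------------------------------------------------------------------------

def _subunit_lattice_na(alpha_m, beta_m, alpha_h, beta_h, gamma_pS, e_rev, name):
    """m³h activation/inactivation lattice: 8 states m0h0..m3h1, open = m3h1."""
    states = tuple(f"m{i}h{j}" for j in (0, 1) for i in range(4))

    def mk(fn, mult):
        return lambda v, fn=fn, mult=mult: mult * np.asarray(fn(v), dtype=float)

    transitions = []
    for j in (0, 1):
        for i in range(3):
            transitions.append((f"m{i}h{j}", f"m{i+1}h{j}", mk(alpha_m, 3 - i)))
            transitions.append((f"m{i+1}h{j}", f"m{i}h{j}", mk(beta_m, i + 1)))
    for i in range(4):
        transitions.append((f"m{i}h0", f"m{i}h1", mk(alpha_h, 1)))
        transitions.append((f"m{i}h1", f"m{i}h0", mk(beta_h, 1)))
    return KineticScheme(
        name=name,
        states=states,
        transitions=tuple(transitions),
        conducting=frozenset({"m3h1"}),
        single_channel_conductance=gamma_pS,
        reversal_potential=e_rev,
    )


def _subunit_chain_k(alpha_n, beta_n, gamma_pS, e_rev, name):
    """n⁴ activation chain: 5 states n0..n4, open = n4."""
    states = tuple(f"n{i}" for i in range(5))

    def mk(fn, mult):
        return lambda v, fn=fn, mult=mult: mult * np.asarray(fn(v), dtype=float)

    transitions = []
    for i in range(4):
        transitions.append((f"n{i}", f"n{i+1}", mk(alpha_n, 4 - i)))
        transitions.append((f"n{i+1}", f"n{i}", mk(beta_n, i + 1)))
    return KineticScheme(
        name=name,
        states=states,
        transitions=tuple(transitions),
        conducting=frozenset({"n4"}),
        single_channel_conductance=gamma_pS,
        reversal_potential=e_rev,
    )


def hh_squid_schemes():
    """The original squid giant axon Na⁺ (8-state m³h lattice) and K⁺ (5-state
    n⁴ chain) Markov schemes at 6.3 °C.

    Rates are the canonical Hodgkin–Huxley α/β functions (absolute membrane
    potential, resting level −65 mV), multiplied by subunit multiplicities,
    e.g. 3α_m from m0 to m1.  Single-channel conductances (20 pS) and
    reversals (+50 / −77 mV) follow the squid giant axon parameter set.
    """
    a_m = lambda v: 0.1 * _exp_trap(np.asarray(v, float) + 40.0, 10.0)
    b_m = lambda v: 4.0 * np.exp(-(np.asarray(v, float) + 65.0) / 18.0)
    a_h = lambda v: 0.07 * np.exp(-(np.asarray(v, float) + 65.0) / 20.0)
    b_h = lambda v: 1.0 / (1.0 + np.exp(-(np.asarray(v, float) + 35.0) / 10.0))
    a_n = lambda v: 0.01 * _exp_trap(np.asarray(v, float) + 55.0, 10.0)
    b_n = lambda v: 0.125 * np.exp(-(np.asarray(v, float) + 65.0) / 80.0)
    na = _subunit_lattice_na(a_m, b_m, a_h, b_h, 20.0, 50.0, "Na_HH")
    k = _subunit_chain_k(a_n, b_n, 20.0, -77.0, "K_HH")
    return na, k


def wang_buzsaki_schemes(phi_m: float = 5.0):
    """Rodent hippocampal interneuron Na⁺/K⁺ Markov schemes (35 °C).

    Rate functions follow the canonical fast-spiking interneuron model with
    temperature factor φ = 5 on the h and n gates.  The source model treats
    the m gate as instantaneous (m = m∞(V)), which a discrete Markov channel
    cannot be; ``phi_m`` scales the m-gate rates toward that limit and
    defaults to the same factor φ = 5.  Conductances and reversals use the
    interneuron axon parameter set (15 pS / +55 mV Na⁺; 14 pS / −90 mV K⁺).
    """
    a_m = lambda v: phi_m * 0.1 * _exp_trap(np.asarray(v, float) + 35.0, 10.0)
    b_m = lambda v: phi_m * 4.0 * np.exp(-(np.asarray(v, float) + 60.0) / 18.0)
    a_h = lambda v: 5.0 * 0.07 * np.exp(-(np.asarray(v, float) + 58.0) / 20.0)
    b_h = lambda v: 5.0 / (1.0 + np.exp(-(np.asarray(v, float) + 28.0) / 10.0))
    a_n = lambda v: 5.0 * 0.01 * _exp_trap(np.asarray(v, float) + 34.0, 10.0)
    b_n = lambda v: 5.0 * 0.125 * np.exp(-(np.asarray(v, float) + 44.0) / 80.0)
    na = _subunit_lattice_na(a_m, b_m, a_h, b_h, 15.0, 55.0, "Na_RHI")
    k = _subunit_chain_k(a_n, b_n, 14.0, -90.0, "K_RHI")
    return na, k


# ---------------------------------------------------------------------------
# State advancement
# ---------------------------------------------------------------------------

def equilibrium_distribution(scheme: KineticScheme, v: float) -> np.ndarray:
    """Stationary occupancy distribution of the chain at clamped potential.

    Solves πQ = 0 with Σπ = 1.  Raises ``np.linalg.LinAlgError`` for a
    singular system and ``ValueError`` if the solve is ill-conditioned enough
    to produce significantly negative probabilities.
    """
    q = scheme.rate_matrix(v)
    if not np.all(np.isfinite(q)):
        raise ValueError(f"{scheme.name}: non-finite rates at V={v} mV")
    n = scheme.n_states
    a = q.T.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)  # raises LinAlgError if singular
    if np.any(pi < -1e-9):
        raise ValueError(f"{scheme.name}: ill-conditioned stationary solve at V={v}")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _check_dt(scheme: KineticScheme, v: np.ndarray, dt: float):
    vv = np.atleast_1d(np.asarray(v, dtype=float))
    per_state = np.zeros((scheme.n_states, vv.size))
    for src, _, fn in scheme.transitions:
        per_state[scheme.state_index(src)] += np.broadcast_to(
            np.asarray(fn(vv), dtype=float), vv.shape) * dt
    esc = per_state.max()
    if esc >= 1.0:
        raise ValueError(
            f"{scheme.name}: per-step escape probability {esc:.3g} >= 1 at dt={dt} ms; "
            "reduce dt"
        )
    if esc > 0.5:
        raise ValueError(
            f"{scheme.name}: per-step escape probability {esc:.3g} exceeds the 0.5 "
            f"guard at dt={dt} ms; reduce dt"
        )


def stochastic_step(
    state: ChannelPopulationState,
    scheme: KineticScheme,
    v,
    dt: float,
    rng: np.random.Generator,
) -> ChannelPopulationState:
    """Advance a channel population one step with the binomial algorithm.

    For each state the number of channels taking each outgoing transition is
    drawn binomially with probability rate·dt, sequentially over that state's
    transitions (in declared order) from the remaining occupancy, which makes
    channel-count conservation an exact integer identity.

    ``v`` is the membrane potential per compartment (scalar or array matching
    the number of compartments).
    """
    counts = state.counts
    n_comp = counts.shape[0]
    vv = np.broadcast_to(np.atleast_1d(np.asarray(v, dtype=float)), (n_comp,))
    _check_dt(scheme, vv, dt)
    src, dst = scheme.transition_arrays()
    remaining = counts.copy()
    moved = np.zeros_like(counts)
    for t, (_, _, fn) in enumerate(scheme.transitions):
        s, d = src[t], dst[t]
        p = np.minimum(np.broadcast_to(np.asarray(fn(vv), float), (n_comp,)) * dt,
                       1.0)
        n_move = rng.binomial(remaining[:, s], p)
        remaining[:, s] -= n_move
        moved[:, d] += n_move
        moved[:, s] -= n_move
    return ChannelPopulationState(counts=counts + moved, total=state.total.copy())


def deterministic_step(fractions, scheme: KineticScheme, v, dt: float) -> np.ndarray:
    """Expected-value limit of :func:`stochastic_step`.

    Advances fractional occupancies with the same sequential-depletion update
    so that it is exactly the ensemble mean of the binomial update.  Repeated
    identical calls are bit-identical.
    """
    frac = np.atleast_2d(np.asarray(fractions, dtype=float))
    n_comp = frac.shape[0]
    vv = np.broadcast_to(np.atleast_1d(np.asarray(v, dtype=float)), (n_comp,))
    _check_dt(scheme, vv, dt)
    src, dst = scheme.transition_arrays()
    rates = np.stack([np.broadcast_to(np.asarray(fn(vv), float), (n_comp,))
                      for _, _, fn in scheme.transitions])
    remaining = frac.copy()
    moved = np.zeros_like(frac)
    for t in range(len(src)):
        s, d = src[t], dst[t]
        flow = remaining[:, s] * np.minimum(rates[t] * dt, 1.0)
        remaining[:, s] -= flow
        moved[:, d] += flow
        moved[:, s] -= flow
    out = frac + moved
    if np.asarray(fractions).ndim == 1:
        return out[0]
    return out


def initial_counts(scheme: KineticScheme, v_rest: float, total: int) -> np.ndarray:
    """Deterministic integer occupancies closest to the resting equilibrium.

    Largest-remainder rounding of total·π(V_rest); identical across trials so
    stochastic repeats differ only through their RNG streams.
    """
    pi = equilibrium_distribution(scheme, v_rest)
    raw = pi * total
    base = np.floor(raw).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(raw - base)[::-1]
        base[order[:short]] += 1
    return base
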