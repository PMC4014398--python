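"""Compartmental cable model of an unmyelinated axon.

An :class:`AxonSpec` collects geometry, passive membrane properties and the
channel populations (kinetic scheme + areal density) of a cylindrical axon.
:func:`build_cable` discretizes it into compartments with sealed ends;
:func:`integrate` advances it under a stimulus in stochastic or deterministic
mode and returns time-stamped recordings at requested positions.

Internal unit system: mV, ms, µm, µS, nA, nF.  Spec-level fields use the
conventional physiological units noted on each field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _engine
from .kinetics import KineticScheme, equilibrium_distribution, initial_counts

__all__ = [
    "AxonSpec",
    "RecordingSet",
    "Recording",
    "Cable",
    "build_cable",
    "integrate",
]

ENGINE_GRID = (-130.0, 90.0, 0.01)  # v0, v1, dv for tabulated rates


@dataclass(frozen=True)
class AxonSpec:
    """Geometry, passive membrane and channel complement of one axon."""

    diameter: float  # µm
    axon_length: float  # µm
    compartment_length: float  # µm
    membrane_capacitance: float  # µF/cm²
    axial_resistivity: float  # Ω·cm
    leak_conductance: float  # mS/cm²
    leak_reversal: float  # mV
    resting_potential: float  # mV
    channel_populations: tuple  # ((KineticScheme, density per µm²), ...)
    temperature: float  # °C, metadata (kinetics carry their own temperature)
    name: str = "axon"

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.axon_length <= 0 or self.compartment_length <= 0:
            raise ValueError("lengths must be positive")
        lam = self.length_constant
        if self.compartment_length > 0.1 * lam:
            raise ValueError(
                f"compartment_length {self.compartment_length} µm exceeds λ/10 = "
                f"{0.1 * lam:.1f} µm (λ = {lam:.1f} µm)"
            )

    @property
    def length_constant(self) -> float:
        """Passive length constant λ in µm: sqrt(R_m·d / (4·R_a))."""
        r_m = 1.0 / (self.leak_conductance * 1e-3)  # Ω·cm²
        d_cm = self.diameter * 1e-4
        lam_cm = math.sqrt(r_m * d_cm / (4.0 * self.axial_resistivity))
        return lam_cm * 1e4

    @property
    def n_compartments(self) -> int:
        return max(1, round(self.axon_length / self.compartment_length))

    @property
    def compartment_area(self) -> float:
        """Membrane area of one compartment, µm²."""
        return math.pi * self.diameter * self.compartment_length

    def channels_per_compartment(self, density: float) -> int:
        return max(0, round(density * self.compartment_area))

    def with_passive(self, axial_resistivity=None, leak_conductance=None,
                     **overrides) -> "AxonSpec":
        kw = dict(overrides)
        if axial_resistivity is not None:
            kw["axial_resistivity"] = axial_resistivity
        if leak_conductance is not None:
            kw["leak_conductance"] = leak_conductance
        return replace(self, **kw)


@dataclass(frozen=True)
class RecordingSet:
    """Where and how often to record."""

    positions: tuple = tuple(np.round(np.arange(0.05, 0.96, 0.10), 2))
    sampling_interval: float = 0.01  # ms
    record_currents: bool = True

    def __post_init__(self):
        for p in self.positions:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"recording position {p} outside the axon")


@dataclass
class Recording:
    """Columnar trace record from one integration run."""

    t: np.ndarray  # ms, absolute
    positions: tuple  # fractions of axon length
    v: np.ndarray  # (n_samples, n_positions) mV
    open_counts: np.ndarray  # (n_samples, n_positions, n_pop)
    pop_names: tuple
    gamma_uS: np.ndarray  # per-channel conductance per population
    erev: np.ndarray
    g_leak_uS: float  # per recorded compartment (uniform cable)
    e_leak: float
    mode: str
    meta: dict = field(default_factory=dict)

    def currents(self) -> dict:
        """Per-species membrane currents (nA, outward positive) and net
        ionic+leak current at each recorded position."""
        out = {}
        net = self.g_leak_uS * (self.v - self.e_leak)
        out["leak"] = self.g_leak_uS * (self.v - self.e_leak)
        for p, nm in enumerate(self.pop_names):
            ip = self.gamma_uS[p] * self.open_counts[:, :, p] * (self.v - self.erev[p])
            out[nm] = ip
            net = net + ip
        out["net"] = net
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, position, V, per-species current, open counts."""
        cur = self.currents()
        frames = []
        for j, pos in enumerate(self.positions):
            d = {"t_ms": self.t, "position": pos, "v_mV": self.v[:, j]}
            for nm in self.pop_names:
                d[f"i_{nm}_nA"] = cur[nm][:, j]
            d["i_leak_nA"] = cur["leak"][:, j]
            d["i_net_nA"] = cur["net"][:, j]
            for p, nm in enumerate(self.pop_names):
                d[f"open_{nm}"] = self.open_counts[:, j, p]
            frames.append(pd.DataFrame(d))
        return pd.concat(frames, ignore_index=True)


class Cable:
    """Discretized axon with mutable electrical and channel state."""

    def __init__(self, spec: AxonSpec):
        self.spec = spec
        n = spec.n_compartments
        area = spec.compartment_area
        self.n_comp = n
        self.cm = np.full(n, spec.membrane_capacitance * 1e-5 * area)  # nF
        self.g_leak = np.full(n, spec.leak_conductance * 1e-5 * area)  # µS
        a_cross = math.pi * spec.diameter**2 / 4.0
        g_ax = 100.0 * a_cross / (spec.axial_resistivity * spec.compartment_length)
        self.g_ax = np.full(n - 1, g_ax)  # µS, sealed ends

        # flatten channel populations for the engine
        schemes = [s for s, _ in spec.channel_populations]
        self.schemes = schemes
        self.densities = [d for _, d in spec.channel_populations]
        self.pop_totals = np.array(
            [spec.channels_per_compartment(d) for d in self.densities], dtype=np.int64
        )
        offsets = np.concatenate([[0], np.cumsum([s.n_states for s in schemes])])
        self.state_offsets = offsets
        n_states = int(offsets[-1])

        v0, v1, dv = ENGINE_GRID
        vgrid = np.arange(v0, v1 + dv / 2, dv)
        self._vgrid0, self._dv = v0, dv

        ptr = [0]
        dst_all, tab_all = [], []
        cond_idx, cond_pop = [], []
        self._esc_rate = []  # per-population per-state total escape rate on vgrid
        for p, sch in enumerate(schemes):
            src, dst = sch.transition_arrays()
            tab = sch.rate_table(vgrid)
            order = np.argsort(src, kind="stable")
            src, dst, tab = src[order], dst[order], tab[order]
            esc = np.zeros((sch.n_states, vgrid.size))
            for t in range(len(src)):
                esc[src[t]] += tab[t]
            self._esc_rate.append(esc)
            for s in range(sch.n_states):
                sel = np.where(src == s)[0]
                for t in sel:
                    dst_all.append(dst[t] + offsets[p])
                    tab_all.append(tab[t])
                ptr.append(ptr[-1] + len(sel))
            for ci in sch.conducting_indices:
                cond_idx.append(ci + offsets[p])
                cond_pop.append(p)

        self.state_ptr = np.array(ptr, dtype=np.int64)
        self.esc_tab = np.ascontiguousarray(np.vstack(self._esc_rate))
        self.trans_dst = np.array(dst_all, dtype=np.int64)
        self.rate_tab = np.ascontiguousarray(np.array(tab_all))
        self.cond_idx = np.array(cond_idx, dtype=np.int64)
        self.cond_pop = np.array(cond_pop, dtype=np.int64)
        self.gamma = np.array([s.single_channel_conductance * 1e-6 for s in schemes])
        self.erev = np.array([s.reversal_potential for s in schemes])
        self.totals_mat = np.tile(self.pop_totals.astype(float), (n, 1))

        self.t = 0.0
        self.v = None
        self.counts = None
        self.fracs = None
        self.reset()

    # -- state ---------------------------------------------------------------
    def reset(self):
        """Return every compartment to rest: V = resting potential, channels
        at the resting-potential equilibrium distribution (deterministically
        rounded, so repeated stochastic trials start identically)."""
        spec = self.spec
        self.t = 0.0
        self.v = np.full(self.n_comp, spec.resting_potential)
        n_states = int(self.state_offsets[-1])
        counts = np.zeros((self.n_comp, n_states), dtype=np.int64)
        fracs = np.zeros((self.n_comp, n_states))
        for p, sch in enumerate(self.schemes):
            o = self.state_offsets[p]
            c0 = initial_counts(sch, spec.resting_potential, int(self.pop_totals[p]))
            pi = equilibrium_distribution(sch, spec.resting_potential)
            counts[:, o : o + sch.n_states] = c0
            fracs[:, o : o + sch.n_states] = pi
        self.counts = counts
        self.fracs = fracs

    def compartment_index(self, position: float) -> int:
        return min(self.n_comp - 1, max(0, int(position * self.n_comp)))

    # -- dt guard ------------------------------------------------------------
    def check_dt(self, dt: float, v_lo: float, v_hi: float):
        """Refuse dt if any state's summed escape probability exceeds 0.5
        anywhere on the voltage window [v_lo, v_hi].

        The engine additionally enforces the same guard per step at the
        actual compartment voltages, restricted to occupied states (an empty
        state loses no channels); this method gives an a-priori check over an
        explicit envelope."""
        i_lo = max(0, int((v_lo - self._vgrid0) / self._dv))
        i_hi = int((v_hi - self._vgrid0) / self._dv) + 1
        for sch, esc in zip(self.schemes, self._esc_rate):
            worst = esc[:, i_lo:i_hi].max() * dt
            if worst > 0.5:
                raise ValueError(
                    f"{sch.name}: max per-state escape probability {worst:.3g} "
                    f"exceeds 0.5 on [{v_lo:.0f}, {v_hi:.0f}] mV at dt={dt} ms; "
                    "reduce dt"
                )

    # -- integration ---------------------------------------------------------
    def run(self, stim: np.ndarray, dt: float, mode: str, seed: int = 0,
            record_positions: Sequence[float] = (0.5,), record_every: int = 1
            ) -> Recording:
        """Advance the cable by ``len(stim)`` steps, continuing from the
        current state.  ``stim`` is the injected current (nA) per step at the
        proximal compartment."""
        stim = np.ascontiguousarray(stim, dtype=np.float64)
        n_steps = stim.size
        rec_idx = np.array([self.compartment_index(p) for p in record_positions],
                           dtype=np.int64)
        n_samp = n_steps // record_every
        out_v = np.empty((n_samp, rec_idx.size))
        out_open = np.empty((n_samp, rec_idx.size, len(self.schemes)))
        if mode == "stochastic":
            status = _engine.run_cable_stochastic(
                self.v, self.counts,
                self.state_ptr, self.trans_dst, self.rate_tab, self.esc_tab,
                self._vgrid0, self._dv,
                self.cond_idx, self.cond_pop, self.gamma, self.erev,
                self.cm, self.g_ax, self.g_leak, self.spec.leak_reversal,
                stim, 0, dt,
                rec_idx, record_every, out_v, out_open,
                int(seed) % 2**31,
            )
        elif mode == "deterministic":
            status = _engine.run_cable_deterministic(
                self.v, self.fracs, self.totals_mat,
                self.state_ptr, self.trans_dst, self.rate_tab, self.esc_tab,
                self._vgrid0, self._dv,
                self.cond_idx, self.cond_pop, self.gamma, self.erev,
                self.cm, self.g_ax, self.g_leak, self.spec.leak_reversal,
                stim, 0, dt,
                rec_idx, record_every, out_v, out_open,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if status == _engine.STATUS_BLOWUP:
            raise RuntimeError(
                f"membrane potential exceeded ±{_engine.V_ABORT} mV — numerical "
                f"blow-up (mode={mode}, dt={dt} ms, n_comp={self.n_comp})"
            )
        if status == _engine.STATUS_DT_GUARD:
            raise ValueError(
                f"per-state escape probability too large even with "
                f"{_engine.MAX_SUBSTEPS}-fold local substepping at dt={dt} ms — "
                "dt grossly too large for these kinetics; reduce dt"
            )
        t = self.t + dt * record_every * np.arange(1, n_samp + 1)
        self.t += dt * n_steps
        return Recording(
            t=t,
            positions=tuple(record_positions),
            v=out_v,
            open_counts=out_open,
            pop_names=tuple(s.name for s in self.schemes),
            gamma_uS=self.gamma,
            erev=self.erev,
            g_leak_uS=float(self.g_leak[0]),
            e_leak=self.spec.leak_reversal,
            mode=mode,
            meta={"dt": dt, "seed": seed, "axon": self.spec.name},
        )


def build_cable(spec: AxonSpec) -> Cable:
    """Discretize ``spec`` into a sealed-end compartmental cable with channel
    populations initialized at the resting-potential equilibrium."""
    return Cable(spec)


def integrate(cable: Cable, stimulus, recording: RecordingSet, dt: float,
              t_end: float, mode: str = "stochastic",
              rng: np.random.Generator | int | None = None) -> Recording:
    """Run ``cable`` for ``t_end`` ms under ``stimulus``.

    ``stimulus`` may be a pre-sampled current array (nA per step) or a
    :class:`axonoise.stimulus.StimulusProtocol`.
    """
    from .stimulus import StimulusProtocol, realize_stimulus

    n_steps = int(round(t_end / dt))
    if isinstance(stimulus, StimulusProtocol):
        stim, _ = realize_stimulus(stimulus, dt, t_end)
    else:
        stim = np.asarray(stimulus, dtype=float)
        if stim.size < n_steps:
            stim = np.concatenate([stim, np.zeros(n_steps - stim.size)])
    if rng is None:
        seed = 0
    elif isinstance(rng, (int, np.integer)):
        seed = int(rng)
    else:
        seed = int(rng.integers(2**31))
    every = max(1, int(round(recording.sampling_interval / dt)))
    return cable.run(stim[:n_steps], dt, mode, seed=seed,
                     record_positions=recording.positions, record_every=every)
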