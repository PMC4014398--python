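"""End-to-end stimulation protocols.

Two frameworks are provided, mirroring the two ways thin axons are probed in
simulation studies of channel noise:

* **single spike per trial** — a brief suprathreshold pulse (auto-tuned to
  1.5× the deterministic threshold) elicits exactly one AP per trial;
  repeated stochastic trials share initial conditions and stimulus and differ
  only in their RNG streams.
* **spike train** — a long run driven by zero-mean low-pass-filtered noise
  current; APs are collected where they arrive near the distal end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cable import AxonSpec, Cable, build_cable
from .stimulus import make_filtered_noise, make_pulse
from .waveform import detect_aps

__all__ = [
    "tune_pulse_amplitude",
    "run_single_ap_protocol",
    "run_spike_train_protocol",
    "SingleAPResult",
    "SpikeTrainResult",
]

log = logging.getLogger("axonoise")

AP_WINDOW = (-1.0, 4.0)  # ms around the alignment point kept with each event


@dataclass
class SingleAPResult:
    events_by_position: dict  # position -> [APEvent] (valid trials only)
    n_trials: int
    n_excluded: int
    amplitude: float  # nA, tuned pulse amplitude
    t_end: float  # ms per trial
    dt: float
    seed: int


@dataclass
class SpikeTrainResult:
    events_by_position: dict
    duration: float  # ms of analysed (post-settle) simulated time
    firing_rate: float  # Hz at the distal site
    isi_mean: float  # ms
    isi_sd: float  # ms
    dt: float
    seed: int
    mode: str
    meta: dict = field(default_factory=dict)


def _detect_positions(rec, v_rest, trial, window=AP_WINDOW):
    out = {}
    for j, pos in enumerate(rec.positions):
        out[pos] = detect_aps(rec.t, rec.v[:, j], v_rest, trial=trial,
                              position=pos, window=window)
    return out


def tune_pulse_amplitude(spec: AxonSpec, dt: float = 0.005,
                         pulse_duration: float = 0.5, detect_at: float = 0.95,
                         t_end: float = 30.0, safety_factor: float = 1.5,
                         tol: float = 0.02) -> float:
    """Pulse amplitude (nA) reliably eliciting one propagated AP.

    Bisects the deterministic model's threshold for a ``pulse_duration`` ms
    rectangular pulse at the proximal end (detection at ``detect_at`` of the
    axon length) and returns ``safety_factor`` times that threshold.
    """
    cable = build_cable(spec)

    def fires(amp):
        cable.reset()
        stim = make_pulse(amp, pulse_duration, dt, t_end)
        rec = cable.run(stim, dt, "deterministic",
                        record_positions=(detect_at,), record_every=2)
        return len(detect_aps(rec.t, rec.v[:, 0], spec.resting_potential)) >= 1

    lo, hi = 0.0, 0.01
    for _ in range(20):
        if fires(hi):
            break
        lo, hi = hi, hi * 2.0
    else:
        raise RuntimeError("could not elicit an AP with pulses up to "
                           f"{hi / 2:.3g} nA")
    while (hi - lo) / hi > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    log.info("tuned pulse threshold %.4g nA (x%.1f applied)", hi, safety_factor)
    return safety_factor * hi


def run_single_ap_protocol(spec: AxonSpec, n_trials: int, seed: int = 0,
                           dt: float = 0.005,
                           positions=(0.45, 0.95),
                           pulse_duration: float = 0.5,
                           amplitude: float | None = None,
                           t_end: float | None = None,
                           record_every: int = 2) -> SingleAPResult:
    """Independent stochastic trials, one pulse-triggered AP each.

    All trials start from the identical resting state and receive the
    identical stimulus; only the RNG stream differs.  Trials in which any
    recorded position does not show exactly one AP are excluded from the
    returned ensembles (their count is reported).
    """
    if amplitude is None:
        amplitude = tune_pulse_amplitude(spec, dt=dt,
                                         pulse_duration=pulse_duration)
    cable = build_cable(spec)
    if t_end is None:
        cable.reset()
        cable.t = 0.0
        stim = make_pulse(amplitude, pulse_duration, dt, 40.0)
        rec = cable.run(stim, dt, "deterministic",
                        record_positions=(max(positions),), record_every=2)
        evs = detect_aps(rec.t, rec.v[:, 0], spec.resting_potential)
        if not evs:
            raise RuntimeError("tuned pulse failed to elicit a deterministic AP")
        t_end = float(evs[0].t_align + 8.0)

    seeds = np.random.SeedSequence(seed).generate_state(n_trials) % 2**31
    stim = make_pulse(amplitude, pulse_duration, dt, t_end)
    events_by_position = {p: [] for p in positions}
    n_excluded = 0
    for trial in range(n_trials):
        cable.reset()
        cable.t = 0.0
        rec = cable.run(stim, dt, "stochastic", seed=int(seeds[trial]),
                        record_positions=positions, record_every=record_every)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_pos = _detect_positions(rec, spec.resting_potential, trial)
        if any(len(v) != 1 for v in per_pos.values()):
            n_excluded += 1
            continue
        for p in positions:
            events_by_position[p].extend(per_pos[p])
    log.info("single-AP protocol: %d/%d valid trials", n_trials - n_excluded,
             n_trials)
    return SingleAPResult(events_by_position=events_by_position,
                          n_trials=n_trials, n_excluded=n_excluded,
                          amplitude=amplitude, t_end=t_end, dt=dt, seed=seed)


def run_spike_train_protocol(spec: AxonSpec, duration: float = 10_000.0,
                             seed: int = 0, dt: float = 0.005,
                             positions=(0.45, 0.95),
                             noise_sd: float = 0.01, corner: float = 1.0,
                             mode: str = "stochastic",
                             target_aps: int | None = None,
                             max_duration: float = 60_000.0,
                             settle: float = 200.0,
                             chunk: float = 1_000.0,
                             record_every: int = 2) -> SpikeTrainResult:
    """Continuous noise-driven run; APs collected along the axon.

    The axon is driven by zero-mean filtered white-noise current
    (``noise_sd`` nA, ``corner`` kHz) at the proximal end.  The run proceeds
    in chunks with a seamless noise stream and channel state; an initial
    ``settle`` ms is simulated but excluded from all statistics.  If
    ``target_aps`` is given the run continues until that many APs have
    arrived at the most distal recorded position or ``max_duration`` ms of
    analysed time is reached.
    """
    cable = build_cable(spec)
    rng = np.random.default_rng(seed)
    kernel_seeds = np.random.SeedSequence(
        (seed, 0x5eed)).generate_state(4096) % 2**31
    distal = max(positions)
    events_by_position = {p: [] for p in positions}
    carry_ms = 12.0
    edge = AP_WINDOW[1] + 1.0  # defer APs this close to the chunk end
    noise_state = None
    carry_t = carry_v = None
    accept_from = settle
    analysed = 0.0
    sim_t = 0.0
    n_chunk = 0
    while True:
        this_chunk = min(chunk, max_duration + settle - sim_t)
        if this_chunk <= 0:
            break
        stim, noise_state = make_filtered_noise(noise_sd, corner, dt,
                                                this_chunk, rng,
                                                state=noise_state)
        rec = cable.run(stim, dt, mode, seed=int(kernel_seeds[n_chunk % 4096]),
                        record_positions=positions, record_every=record_every)
        n_chunk += 1
        chunk_end = rec.t[-1]
        cutoff = chunk_end - edge
        for j, pos in enumerate(positions):
            if carry_t is not None:
                tt = np.concatenate([carry_t, rec.t])
                vv = np.concatenate([carry_v[:, j], rec.v[:, j]])
            else:
                tt, vv = rec.t, rec.v[:, j]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                evs = detect_aps(tt, vv, spec.resting_potential, trial=n_chunk,
                                 position=pos, window=AP_WINDOW)
            for e in evs:
                if accept_from <= e.t_align < cutoff and not e.truncated:
                    events_by_position[pos].append(e)
        n_keep = int(carry_ms / (dt * record_every))
        carry_t = rec.t[-n_keep:]
        carry_v = rec.v[-n_keep:, :]
        accept_from = cutoff
        sim_t = cable.t
        analysed = max(0.0, sim_t - settle - edge)
        n_distal = len(events_by_position[distal])
        log.info("spike train: t=%.1f s, %d APs at distal site",
                 sim_t / 1000.0, n_distal)
        if target_aps is not None:
            if ((n_distal >= target_aps and analysed >= duration)
                    or analysed >= max_duration):
                break
        elif sim_t >= duration + settle:
            break
    t_distal = np.array(sorted(e.t_align for e in events_by_position[distal]))
    isi = np.diff(t_distal)
    rate = len(t_distal) / (analysed / 1000.0) if analysed > 0 else np.nan
    return SpikeTrainResult(
        events_by_position=events_by_position,
        duration=analysed, firing_rate=rate,
        isi_mean=float(isi.mean()) if isi.size else np.nan,
        isi_sd=float(isi.std(ddof=0)) if isi.size else np.nan,
        dt=dt, seed=seed, mode=mode,
        meta={"noise_sd": noise_sd, "corner_kHz": corner, "settle_ms": settle},
    )
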