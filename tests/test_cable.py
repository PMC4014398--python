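"""Cable discretization, integration accuracy, stimuli and reproducibility."""

import numpy as np
import pytest
from scipy import signal
from scipy.integrate import solve_ivp

import axonoise as ax
from axonoise.cable import AxonSpec, build_cable
from axonoise.stimulus import StimulusProtocol, make_filtered_noise, make_pulse
from axonoise.waveform import detect_aps


def passive_spec(diameter=0.2, length=2000.0, dx=10.0):
    na, k = ax.hh_squid_schemes()
    return AxonSpec(
        diameter=diameter, axon_length=length, compartment_length=dx,
        membrane_capacitance=1.0, axial_resistivity=35.4,
        leak_conductance=0.3, leak_reversal=-65.0, resting_potential=-65.0,
        channel_populations=((na, 0.0), (k, 0.0)), temperature=6.3)


def test_compartment_and_channel_arithmetic():
    """0.2 µm × 2000 µm axon at 1 µm compartments: 2000 compartments with
    round(60·π·0.2·1) = 38 Na⁺ channels each at squid density."""
    spec = ax.preset("squid_hh", diameter=0.2, axon_length=2000.0,
                     compartment_length=1.0)
    assert spec.n_compartments == 2000
    assert spec.channels_per_compartment(60.0) == 38
    cable = build_cable(spec)
    assert cable.pop_totals[0] == 38  # Na⁺
    assert cable.pop_totals[1] == round(18.0 * np.pi * 0.2 * 1.0)  # K⁺


def test_lambda_rule_refused_with_diagnostic():
    with pytest.raises(ValueError, match="λ"):
        passive_spec(dx=50.0)  # λ(0.2 µm, squid passive) ≈ 217 µm


def test_passive_cable_steady_state_decay():
    """Constant current at the sealed end: V(x) ∝ cosh((L−x)/λ)/sinh(L/λ)."""
    spec = passive_spec()
    cable = build_cable(spec)
    dt = 0.01
    stim = np.full(int(40.0 / dt), 0.01)  # nA, far beyond 5 membrane τ
    positions = (0.05, 0.25, 0.45, 0.65, 0.85)
    rec = cable.run(stim, dt, "deterministic", record_positions=positions,
                    record_every=10)
    dv = rec.v[-1, :] - spec.resting_potential
    lam = spec.length_constant
    L = spec.axon_length
    x = np.array(positions) * L
    analytic = np.cosh((L - x) / lam)
    # compare decay profiles normalized at the first position
    ratio = (dv / dv[0]) / (analytic / analytic[0])
    assert np.max(np.abs(ratio - 1.0)) < 0.01


def test_charge_bookkeeping_space_clamp():
    """Single deterministic compartment: C·dV/dt + I_ion + I_leak = I_stim
    at every recorded step (exact for the implicit update)."""
    na, k = ax.hh_squid_schemes()
    spec = AxonSpec(
        diameter=1.0, axon_length=30.0, compartment_length=30.0,
        membrane_capacitance=1.0, axial_resistivity=35.4,
        leak_conductance=0.3, leak_reversal=-54.4, resting_potential=-65.0,
        channel_populations=((na, 60.0), (k, 18.0)), temperature=6.3)
    cable = build_cable(spec)
    assert cable.n_comp == 1
    dt = 0.005
    stim = make_pulse(0.05, 0.5, dt, 10.0)
    rec = cable.run(stim, dt, "deterministic", record_positions=(0.5,),
                    record_every=1)
    v = np.concatenate([[spec.resting_potential], rec.v[:, 0]])
    cm = cable.cm[0]
    cur = rec.currents()
    i_mem = cur["net"][:, 0]
    residual = cm * np.diff(v) / dt + i_mem - stim
    assert np.max(np.abs(residual)) < 1e-9


def test_deterministic_point_membrane_matches_ode_oracle():
    """The squid schemes integrated on one compartment reproduce an
    independent ODE solution of the classic point-membrane equations."""
    na, k = ax.hh_squid_schemes()
    spec = AxonSpec(
        diameter=1.0, axon_length=30.0, compartment_length=30.0,
        membrane_capacitance=1.0, axial_resistivity=35.4,
        leak_conductance=0.3, leak_reversal=-54.4, resting_potential=-65.0,
        channel_populations=((na, 60.0), (k, 18.0)), temperature=6.3)
    cable = build_cable(spec)
    dt = 0.001
    amp = 0.02  # nA
    stim = make_pulse(amp, 0.5, dt, 15.0)
    rec = cable.run(stim, dt, "deterministic", record_positions=(0.5,),
                    record_every=1)

    area_cm2 = spec.compartment_area * 1e-8
    i_density = amp * 1e-3 / area_cm2  # µA/cm²

    def trap(x, kk):
        return np.where(np.abs(x / kk) < 1e-7, kk,
                        x / (1.0 - np.exp(-x / kk)))

    def hh(t, y):
        v, m, h, n = y
        am = 0.1 * trap(v + 40.0, 10.0); bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
        an = 0.01 * trap(v + 55.0, 10.0)
        bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
        ina = 120.0 * m**3 * h * (v - 50.0)
        ik = 36.0 * n**4 * (v + 77.0)
        il = 0.3 * (v + 54.4)
        i_inj = i_density if t <= 0.5 else 0.0
        return [-(ina + ik + il) + i_inj,
                am * (1 - m) - bm * m, ah * (1 - h) - bh * h,
                an * (1 - n) - bn * n]

    m0 = 0.1 * trap(-25.0, 10.0) / (0.1 * trap(-25.0, 10.0) + 4.0 * np.exp(0.0))
    h0 = 0.07 / (0.07 + 1.0 / (1.0 + np.exp(3.0)))
    n0 = 0.01 * trap(-10.0, 10.0) / (0.01 * trap(-10.0, 10.0) + 0.125)
    sol = solve_ivp(hh, [0, 15.0], [-65.0, m0, h0, n0], max_step=0.01,
                    dense_output=True, rtol=1e-8, atol=1e-8)
    v_ode = sol.sol(rec.t)[0]

    ap_cable = detect_aps(rec.t, rec.v[:, 0], -65.0)[0]
    ap_ode = detect_aps(rec.t, v_ode, -65.0)[0]
    assert ap_cable.peak > 0.0  # overshoot
    assert ap_cable.peak == pytest.approx(ap_ode.peak, abs=1.0)
    assert ap_cable.width == pytest.approx(ap_ode.width, rel=0.02)
    assert abs(ap_cable.t_align - ap_ode.t_align) < 0.05


def test_refinement_convergence_under_1_percent():
    """Halving dt or compartment length moves deterministic AP width and
    height by < 1 %."""
    def ap(dx, dt):
        spec = ax.preset("squid_hh", diameter=0.2, axon_length=2000.0,
                         compartment_length=dx)
        cable = build_cable(spec)
        stim = make_pulse(0.05, 0.5, dt, 20.0)
        rec = cable.run(stim, dt, "deterministic", record_positions=(0.95,),
                        record_every=1)
        return detect_aps(rec.t, rec.v[:, 0], -65.0)[0]

    base = ap(10.0, 0.005)
    half_dx = ap(5.0, 0.005)
    half_dt = ap(10.0, 0.0025)
    for ref in (half_dx, half_dt):
        assert abs(ref.height - base.height) / base.height < 0.01
        assert abs(ref.width - base.width) / base.width < 0.01


def test_deterministic_runs_bit_identical():
    spec = ax.preset("squid_hh", diameter=0.5, axon_length=1000.0,
                     compartment_length=20.0)
    stim = make_pulse(0.05, 0.5, 0.005, 10.0)
    recs = []
    for _ in range(2):
        cable = build_cable(spec)
        recs.append(cable.run(stim, 0.005, "deterministic",
                              record_positions=(0.5, 0.95), record_every=2))
    assert np.array_equal(recs[0].v, recs[1].v)


def test_stochastic_seed_reproducibility():
    spec = ax.preset("squid_hh", diameter=0.5, axon_length=1000.0,
                     compartment_length=20.0)
    stim = make_pulse(0.05, 0.5, 0.005, 10.0)

    def run(seed):
        cable = build_cable(spec)
        return cable.run(stim, 0.005, "stochastic", seed=seed,
                         record_positions=(0.95,), record_every=2)

    assert np.array_equal(run(9).v, run(9).v)
    assert not np.array_equal(run(9).v, run(10).v)


def test_resting_fluctuations_grow_as_diameter_shrinks():
    """Channel noise at rest: membrane-potential variance is larger in a
    0.2 µm axon than in a 1.0 µm axon (fewer channels per length)."""
    sds = {}
    for d in (0.2, 1.0):
        spec = ax.preset("squid_hh", diameter=d, axon_length=1000.0,
                         compartment_length=20.0)
        cable = build_cable(spec)
        stim = np.zeros(int(200.0 / 0.005))
        rec = cable.run(stim, 0.005, "stochastic", seed=31,
                        record_positions=(0.5,), record_every=10)
        v = rec.v[rec.t > 50.0, 0]  # discard settling
        sds[d] = v.std(ddof=0)
    assert sds[0.2] > sds[1.0] > 0.0


def test_upstroke_steepens_with_distance():
    """A just-suprathreshold AP rises faster after propagating a few length
    constants than at the initiation site, where the resting membrane's time
    constant limits the response; the effect is confined to roughly the
    first length constant (λ ≈ 270 µm here)."""
    from axonoise.protocols import tune_pulse_amplitude

    spec = ax.preset("rat_interneuron", diameter=0.2, axon_length=2000.0,
                     compartment_length=20.0)
    dt = 0.005
    amp = tune_pulse_amplitude(spec, dt=dt, safety_factor=1.2)
    cable = build_cable(spec)
    stim = make_pulse(amp, 0.5, dt, 15.0)
    rec = cable.run(stim, dt, "deterministic",
                    record_positions=(0.01, 0.5), record_every=1)
    slopes = {pos: np.max(np.diff(rec.v[:, j])) / dt
              for j, pos in enumerate(rec.positions)}
    assert slopes[0.5] > slopes[0.01]


def test_numerical_blowup_reported():
    spec = passive_spec(length=500.0)
    cable = build_cable(spec)
    stim = np.full(2000, 1e6)  # absurd current
    with pytest.raises(RuntimeError, match="blow-up"):
        cable.run(stim, 0.01, "deterministic", record_positions=(0.5,))


NOISE_SD, NOISE_CORNER, NOISE_DT, NOISE_DUR = 0.01, 1.0, 0.005, 10_000.0


@pytest.fixture(scope="module")
def series():
    y, _ = make_filtered_noise(NOISE_SD, NOISE_CORNER, NOISE_DT, NOISE_DUR,
                               np.random.default_rng(8))
    return y


class TestFilteredNoise:
    SD, CORNER, DT, DUR = NOISE_SD, NOISE_CORNER, NOISE_DT, NOISE_DUR

    def test_realized_sd_within_2_percent(self, series):
        assert series.std(ddof=0) == pytest.approx(self.SD, rel=0.02)

    def test_zero_mean_within_3_se(self, series):
        n_eff = self.DUR / 1000.0 * 2 * self.CORNER * 1000  # ~2·f_c·T
        se = self.SD / np.sqrt(n_eff)
        assert abs(series.mean()) < 3 * se

    def test_stopband_attenuation(self, series):
        """PSD at 2 kHz at least 3 dB below the passband level."""
        fs_khz = 1.0 / self.DT
        f, pxx = signal.welch(series, fs=fs_khz, nperseg=1 << 14)
        passband = pxx[(f > 0.02) & (f < 0.2)].mean()
        at_2k = pxx[np.argmin(np.abs(f - 2.0))]
        assert 10 * np.log10(at_2k / passband) < -3.0

    def test_chunked_stream_is_continuous(self):
        rng = np.random.default_rng(99)
        a, st = make_filtered_noise(self.SD, self.CORNER, self.DT, 50.0, rng)
        b, _ = make_filtered_noise(self.SD, self.CORNER, self.DT, 50.0, rng,
                                   state=st)
        # no jump at the seam beyond typical one-step increments
        steps = np.abs(np.diff(np.concatenate([a, b])))
        assert abs(b[0] - a[-1]) < 10 * np.median(steps) + 1e-6

    def test_corner_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_filtered_noise(0.01, 200.0, 0.005, 10.0,
                                np.random.default_rng(0))


def test_stimulus_protocol_validation():
    with pytest.raises(ValueError, match="kind"):
        StimulusProtocol(kind="sawtooth", amplitude=0.1, duration=1.0)
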