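"""Declarative run configurations and canned reproduction experiments.

A :class:`RunConfig` captures everything needed to re-run a protocol — axon
preset and geometry, protocol kind and scale, dt, seeds — and round-trips
losslessly through YAML.  :func:`run_experiment` executes one and writes the
trace/feature tables, the exact config used, and a JSON metadata record
(versions, seeds, RNG algorithm, exclusion counts) to an output directory.
:func:`reproduce` re-runs the study's canned analyses (waveform variability,
diameter scaling, spike trains, the synaptic cascade) at a configurable
scale and emits their summary numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .presets import SPIKE_TRAIN_PASSIVE, preset
from .protocols import run_single_ap_protocol, run_spike_train_protocol
from .synapse import cascade_statistics
from .waveform import (events_frame, feature_statistics, fit_power_law,
                       pairwise_feature_change)

__all__ = ["RunConfig", "run_experiment", "reproduce", "scaling_experiment"]

log = logging.getLogger("axonoise")


@dataclass
class RunConfig:
    """Serializable description of one protocol run."""

    preset: str = "rat_interneuron"
    protocol: str = "spike_train"  # {"spike_train", "single_ap"}
    diameter: float = 0.2  # µm
    axon_length: float = 2000.0  # µm
    compartment_length: float = 20.0  # µm
    dt: float = 0.005  # ms
    seed: int = 0
    duration: float = 10_000.0  # ms, spike-train protocol
    n_trials: int = 100  # single-AP protocol
    noise_sd: float = 0.01  # nA
    corner: float = 1.0  # kHz
    positions: tuple = (0.45, 0.95)
    mode: str = "stochastic"
    spike_train_passive: bool = True  # R_a=70 Ωcm, R_m=20000 Ωcm² for trains
    overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["positions"] = list(self.positions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["positions"] = tuple(d.get("positions", (0.45, 0.95)))
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def build_spec(self):
        kw = dict(self.overrides)
        if self.protocol == "spike_train" and self.spike_train_passive:
            kw.update(SPIKE_TRAIN_PASSIVE)
        return preset(self.preset, diameter=self.diameter,
                      axon_length=self.axon_length,
                      compartment_length=self.compartment_length, **kw)


def _write_meta(outdir: Path, config: RunConfig, extra: dict):
    meta = {
        "axonoise_version": __version__,
        "python": platform.python_version(),
        "rng": "numpy MT19937 (numba kernel) / PCG64 (stimulus)",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    config.to_yaml(outdir / "config.yaml")


def run_experiment(config: RunConfig, outdir) -> Path:
    """Execute ``config`` and write events, summaries and metadata.

    The output directory contains ``config.yaml`` (round-trips losslessly),
    ``events.csv`` (one row per AP and position), ``features.csv`` (summary
    statistics) and ``run_meta.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.build_spec()
    t0 = time.time()
    if config.protocol == "spike_train":
        res = run_spike_train_protocol(
            spec, duration=config.duration, seed=config.seed, dt=config.dt,
            positions=config.positions, noise_sd=config.noise_sd,
            corner=config.corner, mode=config.mode)
        extra = {"firing_rate_hz": res.firing_rate, "duration_ms": res.duration,
                 "isi_mean_ms": res.isi_mean, "isi_sd_ms": res.isi_sd,
                 "seed": config.seed}
    elif config.protocol == "single_ap":
        res = run_single_ap_protocol(
            spec, n_trials=config.n_trials, seed=config.seed, dt=config.dt,
            positions=config.positions)
        extra = {"n_trials": config.n_trials, "n_excluded": res.n_excluded,
                 "pulse_amplitude_nA": res.amplitude, "seed": config.seed}
    else:
        raise ValueError(f"unknown protocol {config.protocol!r}")
    extra["wall_seconds"] = time.time() - t0
    all_events = [e for evs in res.events_by_position.values() for e in evs]
    events_frame(all_events).to_csv(outdir / "events.csv", index=False)
    distal = res.events_by_position[max(config.positions)]
    if len(distal) >= 2:
        feature_statistics(distal).to_csv(outdir / "features.csv", index=False)
    _write_meta(outdir, config, extra)
    log.info("experiment written to %s", outdir)
    return outdir


def scaling_experiment(diameters=(0.2, 0.5, 1.0), n_trials: int = 60,
                       seed: int = 0, preset_name: str = "squid_hh",
                       axon_length: float = 2000.0,
                       compartment_length: float = 10.0, dt: float = 0.005,
                       feature: str = "height_mV"):
    """CV of distal AP features vs diameter plus the log–log power-law fit.

    Returns ``(table, fit)`` where the table has one row per diameter with
    width/height CVs at the distal site and ``fit`` is the
    :class:`~axonoise.waveform.ScalingFit` on ``feature``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(diameters))
    rows = []
    for d, s in zip(diameters, seeds):
        spec = preset(preset_name, diameter=d, axon_length=axon_length,
                      compartment_length=compartment_length)
        res = run_single_ap_protocol(spec, n_trials=n_trials, seed=int(s), dt=dt)
        evs = res.events_by_position[max(res.events_by_position)]
        stats = feature_statistics(evs).set_index("feature")
        rows.append({
            "diameter_um": d,
            "n_aps": len(evs),
            "cv_width": stats.loc["width_ms", "cv"],
            "cv_height": stats.loc["height_mV", "cv"],
        })
    table = pd.DataFrame(rows)
    col = "cv_height" if feature == "height_mV" else "cv_width"
    fit = fit_power_law(table["diameter_um"], table[col])
    return table, fit


def reproduce(name: str, scale: float = 1.0, seed: int = 0, outdir=None) -> dict:
    """Re-run one of the study's analyses at reduced scale.

    ``name`` ∈ {fig3, fig4, fig5, fig7, fig8, table1}; ``scale`` ∈ (0, 1]
    multiplies trial counts / durations relative to the desk-scale defaults
    (10 s trains, 100–250 trials).  Returns the summary numbers as a dict
    (and writes them to ``outdir`` when given).
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    out: dict = {"name": name, "scale": scale, "seed": seed}

    if name in ("fig3", "fig4"):
        # single-AP waveform variability, thin interneuron axon
        spec = preset("rat_interneuron", diameter=0.2, compartment_length=20.0)
        res = run_single_ap_protocol(spec, n_trials=max(10, round(250 * scale)),
                                     seed=seed)
        distal = res.events_by_position[0.95]
        stats = feature_statistics(distal).set_index("feature")
        ch = pairwise_feature_change(res.events_by_position[0.45], distal,
                                     by="trial")
        from .waveform import align_and_profile
        prof = align_and_profile(distal)
        out.update({
            "n_aps": len(distal), "n_excluded": res.n_excluded,
            "width_ms_mean": stats.loc["width_ms", "mean"],
            "width_cv": stats.loc["width_ms", "cv"],
            "height_mV_mean": stats.loc["height_mV", "mean"],
            "height_cv": stats.loc["height_mV", "cv"],
            "sd_dheight_mV_1mm": ch["sd_dheight_mV"],
            "sd_dwidth_ms_1mm": ch["sd_dwidth_ms"],
            "max_3sd_envelope_mV": float(prof.envelope.max()),
        })
    elif name == "fig5":
        table, fit = scaling_experiment(n_trials=max(10, round(250 * scale)),
                                        seed=seed)
        out["cv_vs_diameter"] = table.to_dict(orient="records")
        out["exponent_height"] = fit.exponent
        out["r_squared"] = fit.r_squared
    elif name in ("fig7", "fig8", "table1"):
        spec = preset("rat_interneuron", diameter=0.2,
                      compartment_length=20.0, **SPIKE_TRAIN_PASSIVE)
        res = run_spike_train_protocol(
            spec, duration=max(2_000.0, 600_000.0 * scale), seed=seed,
            target_aps=300, max_duration=60_000.0)
        distal = [e for e in res.events_by_position[0.95] if not e.truncated]
        out["n_aps"] = len(distal)
        out["firing_rate_hz"] = res.firing_rate
        if name == "fig7":
            stats = feature_statistics(distal).set_index("feature")
            out.update({
                "width_ms_mean": stats.loc["width_ms", "mean"],
                "width_cv": stats.loc["width_ms", "cv"],
                "height_mV_mean": stats.loc["height_mV", "mean"],
                "height_cv": stats.loc["height_mV", "cv"],
            })
        else:
            wf = np.stack([e.waveform_v for e in distal])
            t = distal[0].waveform_t
            widths = [e.width for e in distal]
            table = cascade_statistics(wf, t, spec.resting_potential,
                                       widths=widths)
            out["cascade"] = table.to_dict(orient="records")
            if name == "fig8":
                rel = table.set_index("stage")
                out["released_mean"] = rel.loc["vesicles released", "mean"]
                out["released_sd"] = rel.loc["vesicles released", "sd"]
                out["released_cv"] = rel.loc["vesicles released", "cv"]
    else:
        raise KeyError(
            f"unknown reproduction {name!r}; choose from fig3, fig4, fig5, "
            "fig7, fig8, table1")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{name}.json").write_text(
            json.dumps(out, indent=2, default=str))
    return out
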