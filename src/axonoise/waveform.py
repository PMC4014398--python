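"""Action-potential detection, alignment and variability statistics.

APs are detected with a threshold discriminator and aligned at the time the
rising phase crosses the half-height level (resting potential plus half of
peak-minus-rest), located by linear interpolation between samples.  Width is
the interval between the rising and falling half-height crossings; height is
reported both as the absolute peak potential and as peak minus resting
potential.

All ensemble statistics use the population standard deviation (ddof = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "APEvent",
    "VariabilityProfile",
    "ScalingFit",
    "detect_aps",
    "events_frame",
    "align_and_profile",
    "feature_statistics",
    "match_events",
    "pairwise_feature_change",
    "correlation_vs_distance",
    "fit_power_law",
]


@dataclass
class APEvent:
    """One detected action potential at one recording position."""

    trial: int
    position: float  # fraction of axon length
    t_align: float  # ms, rising half-height crossing (absolute time)
    peak: float  # mV, maximum membrane potential
    height: float  # mV, peak − resting potential
    width: float  # ms, between rising and falling half-height crossings
    waveform_t: np.ndarray = field(repr=False, default=None)  # ms rel. to t_align
    waveform_v: np.ndarray = field(repr=False, default=None)  # mV
    truncated: bool = False

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("AP width must be positive")
        if self.height <= 0:
            raise ValueError("AP height must be positive")


@dataclass
class VariabilityProfile:
    """Mean waveform and its point-wise spread on an alignment-relative grid."""

    t: np.ndarray  # ms relative to alignment
    mean: np.ndarray
    sd: np.ndarray
    envelope: np.ndarray  # 3×SD
    q_low: np.ndarray  # 1% quantile
    q_high: np.ndarray  # 99% quantile
    n: int


@dataclass
class ScalingFit:
    """Least-squares power law CV = c·d^exponent fitted in log–log space."""

    diameters: np.ndarray
    cvs: np.ndarray
    exponent: float
    intercept: float
    r_squared: float


def _cross_time(t0, t1, v0, v1, level):
    """Linear-interpolated crossing time of `level` between two samples."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_aps(t, v, v_rest, threshold=None, lockout=2.0, trial=0, position=0.5,
               window=(-1.0, 4.0), align_frac=0.5):
    """Threshold-discriminate APs in a uniformly sampled trace.

    Parameters
    ----------
    t, v
        Time (ms) and membrane potential (mV), uniform sampling.
    v_rest
        Nominal resting potential; heights and half-height levels are
        measured from it.
    threshold
        Detection level, default ``v_rest + 40`` mV.
    lockout
        Refractory lockout (ms) preventing double counts.
    window
        Alignment-relative window stored with each event, ms.
    align_frac
        Fraction of the rest-to-peak amplitude whose rising crossing defines
        the alignment time (0.5 = half-height; 0.2 checks alignment-level
        robustness).  Width is always measured at half-height.

    Returns one :class:`APEvent` per suprathreshold excursion that rises
    through and falls back below its half-height level; excursions that never
    return below half-height before the trace ends are discarded with a
    warning.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if threshold is None:
        threshold = v_rest + 40.0
    dt = t[1] - t[0] if t.size > 1 else 1.0
    above = v >= threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)) == 1) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    events = []
    last_t = -np.inf
    for start in edges:
        if t[start] - last_t < lockout:
            continue
        # end of this suprathreshold segment
        rel_end = np.argmax(~above[start:])
        end = start + rel_end if rel_end > 0 or not above[start:].all() else t.size
        seg = slice(start, min(end, t.size))
        ipk = start + int(np.argmax(v[seg]))
        peak = float(v[ipk])
        half = v_rest + 0.5 * (peak - v_rest)
        # rising half-height crossing: search backwards from the peak
        i = ipk
        while i > 0 and v[i - 1] >= half:
            i -= 1
        if i == 0 and v[0] >= half:
            warnings.warn("AP at trace start has no rising half-height crossing; discarded")
            last_t = t[ipk]
            continue
        t_rise = _cross_time(t[i - 1], t[i], v[i - 1], v[i], half)
        # falling crossing: search forwards from the peak
        j = ipk
        while j < v.size - 1 and v[j + 1] >= half:
            j += 1
        if j >= v.size - 1 and v[-1] >= half:
            warnings.warn("AP does not return below half-height before trace end; discarded")
            last_t = t[ipk]
            continue
        t_fall = _cross_time(t[j], t[j + 1], v[j], v[j + 1], half)
        width = t_fall - t_rise
        if align_frac == 0.5:
            t_align = t_rise
        else:
            level = v_rest + align_frac * (peak - v_rest)
            i = ipk
            while i > 0 and v[i - 1] >= level:
                i -= 1
            t_align = _cross_time(t[i - 1], t[i], v[i - 1], v[i], level) \
                if i > 0 else t[0]
        last_t = t[ipk]
        # alignment-relative waveform window
        wt = np.arange(window[0], window[1] + dt / 2, dt)
        truncated = (t_align + window[0] < t[0]) or (t_align + window[1] > t[-1])
        wv = np.interp(wt + t_align, t, v, left=np.nan, right=np.nan)
        events.append(APEvent(
            trial=trial, position=position, t_align=float(t_align),
            peak=peak, height=peak - v_rest, width=float(width),
            waveform_t=wt, waveform_v=wv, truncated=bool(truncated),
        ))
    return events


def events_frame(events) -> pd.DataFrame:
    """One row per APEvent (waveforms omitted)."""
    return pd.DataFrame(
        [{"trial": e.trial, "position": e.position, "t_align": e.t_align,
          "peak_mV": e.peak, "height_mV": e.height, "width_ms": e.width,
          "truncated": e.truncated} for e in events]
    )


def align_and_profile(events, window=None) -> VariabilityProfile:
    """Stack aligned waveforms and compute mean, SD, 3×SD and 1–99% bands.

    Events flagged as truncated (their stored window ran past the trace) are
    dropped with a warning.
    """
    usable = [e for e in events if not e.truncated]
    if len(usable) < len(events):
        warnings.warn(f"dropped {len(events) - len(usable)} truncated waveform(s)")
    if len(usable) < 2:
        raise ValueError("need at least 2 complete events to profile variability")
    tgrid = usable[0].waveform_t
    if window is not None:
        sel = (tgrid >= window[0]) & (tgrid <= window[1])
        tgrid = tgrid[sel]
    mat = np.stack([
        e.waveform_v if window is None else e.waveform_v[sel] for e in usable
    ])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    return VariabilityProfile(
        t=tgrid, mean=mean, sd=sd, envelope=3.0 * sd,
        q_low=np.quantile(mat, 0.01, axis=0),
        q_high=np.quantile(mat, 0.99, axis=0),
        n=len(usable),
    )


def feature_statistics(events) -> pd.DataFrame:
    """Mean, population SD and CV of width and height over an AP ensemble."""
    if len(events) < 2:
        raise ValueError("need at least 2 events")
    df = events_frame(events)
    rows = []
    for feat, col in (("width_ms", "width_ms"), ("height_mV", "height_mV"),
                      ("peak_mV", "peak_mV")):
        x = df[col].to_numpy()
        mu = x.mean()
        sd = x.std(ddof=0)
        rows.append({"feature": feat, "mean": mu, "sd": sd,
                     "cv": sd / mu if mu != 0 else np.nan, "n": len(x)})
    return pd.DataFrame(rows)


def match_events(events_a, events_b, max_delay=10.0):
    """Pair APs recorded at two positions by propagation order.

    For each event at A the first event at B whose alignment time falls in
    (t_A, t_A + max_delay] is taken; pairing is injective and unmatched
    events are dropped (count available from the lengths).
    """
    pairs = []
    bs = sorted(events_b, key=lambda e: e.t_align)
    j = 0
    for ea in sorted(events_a, key=lambda e: e.t_align):
        while j < len(bs) and bs[j].t_align <= ea.t_align:
            j += 1
        if j < len(bs) and bs[j].t_align - ea.t_align <= max_delay:
            pairs.append((ea, bs[j]))
            j += 1
    return pairs


def pairwise_feature_change(events_a, events_b, by="trial", max_delay=10.0):
    """Per-AP feature differences between two positions.

    ``by='trial'`` matches events by trial id (single-AP protocol);
    ``by='time'`` matches consecutive events by arrival order (spike trains).

    Returns a dict with per-pair height/width differences (B − A), their
    population SDs, and Pearson correlations of the A vs B features.
    """
    if by == "trial":
        bmap = {e.trial: e for e in events_b}
        pairs = [(e, bmap[e.trial]) for e in events_a if e.trial in bmap]
    else:
        pairs = match_events(events_a, events_b, max_delay=max_delay)
    n_dropped = len(events_a) + len(events_b) - 2 * len(pairs)
    if len(pairs) < 2:
        raise ValueError("fewer than 2 matched AP pairs")
    ha = np.array([a.height for a, _ in pairs])
    hb = np.array([b.height for _, b in pairs])
    wa = np.array([a.width for a, _ in pairs])
    wb = np.array([b.width for _, b in pairs])
    out = {
        "n_pairs": len(pairs),
        "n_dropped": n_dropped,
        "dheight_mV": hb - ha,
        "dwidth_ms": wb - wa,
        "sd_dheight_mV": float((hb - ha).std(ddof=0)),
        "sd_dwidth_ms": float((wb - wa).std(ddof=0)),
        "r_height": float(stats.pearsonr(ha, hb)[0]) if np.std(ha) > 0 and np.std(hb) > 0 else np.nan,
        "r_width": float(stats.pearsonr(wa, wb)[0]) if np.std(wa) > 0 and np.std(wb) > 0 else np.nan,
    }
    return out


def correlation_vs_distance(events_by_position: dict, axon_length: float = 1.0,
                            max_delay: float = 10.0) -> pd.DataFrame:
    """Correlation of waveform deviations between position pairs vs distance.

    ``events_by_position`` maps position (fraction of axon length) to that
    position's AP list; events are matched across positions by propagation
    order.  For every pair of positions the per-AP deviations from the local
    mean waveform are flattened and correlated.  A deterministic ensemble has
    zero variance everywhere; its correlation is reported as NaN.

    Returns a frame with columns distance, correlation, n plus a Spearman
    trend statistic (attrs['trend_rho'], attrs['trend_p']) testing a
    monotone-decreasing correlation–distance relationship.
    """
    positions = sorted(events_by_position)
    if len(positions) < 3:
        raise ValueError("need at least 3 recording positions")
    rows = []
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            pa, pb = positions[i], positions[j]
            pairs = match_events(events_by_position[pa], events_by_position[pb],
                                 max_delay=max_delay)
            pairs = [(a, b) for a, b in pairs if not (a.truncated or b.truncated)]
            if len(pairs) < 3:
                continue
            ma = np.stack([a.waveform_v for a, _ in pairs])
            mb = np.stack([b.waveform_v for _, b in pairs])
            da = (ma - ma.mean(axis=0)).ravel()
            db = (mb - mb.mean(axis=0)).ravel()
            # zero-variance (deterministic) ensembles: correlation undefined;
            # the threshold is relative to the waveform scale so that pure
            # rounding residue does not masquerade as variability
            tol = 1e-9 * max(np.ptp(ma), 1.0)
            if da.std() < tol or db.std() < tol:
                r = np.nan
            else:
                r = float(np.corrcoef(da, db)[0, 1])
            rows.append({"distance": (pb - pa) * axon_length, "correlation": r,
                         "n": len(pairs)})
    df = pd.DataFrame(rows)
    ok = df.dropna(subset=["correlation"])
    if len(ok) >= 3:
        rho, p = stats.spearmanr(ok["distance"], ok["correlation"])
        df.attrs["trend_rho"], df.attrs["trend_p"] = float(rho), float(p)
    else:
        df.attrs["trend_rho"] = df.attrs["trend_p"] = np.nan
    return df


def fit_power_law(diameters, cvs) -> ScalingFit:
    """Least-squares line in log–log coordinates; the exponent is the slope.

    Non-positive CVs are excluded with a warning (they have no logarithm).
    """
    d = np.asarray(diameters, dtype=float)
    c = np.asarray(cvs, dtype=float)
    good = c > 0
    if not good.all():
        warnings.warn(f"excluded {np.sum(~good)} non-positive CV value(s)")
    d, c = d[good], c[good]
    if d.size < 3:
        raise ValueError("need at least 3 diameters with positive CV")
    res = stats.linregress(np.log10(d), np.log10(c))
    return ScalingFit(
        diameters=d, cvs=c, exponent=float(res.slope),
        intercept=float(res.intercept), r_squared=float(res.rvalue**2),
    )
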