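"""Synthetic behavioral cohorts and calcium traces.

The behavioral generator inverts the network model's readout: bout times
follow a renewal (Poisson) process at ~2 bouts/s, optionally modulated by
total multifeature drive, and each turn's direction is a Bernoulli draw
from the model's momentary left-swim probability.  Emitted bout tables
carry every field the filtering rules inspect, so clean synthetic cohorts
pass the filters with essentially no removals.

The calcium generator follows the benchmark recipe: min-max-normalized
node activity plus Poisson spikes, convolved with a causal GCaMP kernel
(exponential decay, 2.4 s), plus i.i.d. Gaussian noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stimulus import BatteryEntry, StimulusTimeSeries, render_timeseries
from .model import ModelParams, NodeActivities, simulate
from . import behavior

GCAMP_TAU = 2.4  # s, GCaMP response kernel time constant
IMAGING_DT = 0.5  # s


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings of a synthetic behavioral cohort.

    ``param_jitter`` is the relative (lognormal sigma) per-fish scatter
    applied to every weight and time constant.  ``bout_rate`` is the base
    renewal rate (~2 bouts/s as in free-swimming larvae); ``drive_gain``
    g > 0 modulates it as rate = base (1 + g (MF_L + MF_R)), emulating
    convergent control of swim initiation.  Turns have magnitude
    |N(20, 10)| deg (clipped to stay turns) and a ``forward_fraction`` of
    bouts are straight (|delta| <= 2 deg).
    """

    n_fish: int = 15
    trials_per_stim: int = 4
    params: ModelParams = field(default_factory=ModelParams)
    param_jitter: float = 0.1
    bout_rate: float = 2.0
    drive_gain: float = 0.0
    forward_fraction: float = 0.25
    turn_mag_mean: float = 20.0
    turn_mag_sd: float = 10.0
    dt: float = 0.1
    seed: int = 0


def _jittered(params: ModelParams, sigma: float, rng: np.random.Generator) -> ModelParams:
    if sigma <= 0:
        return params
    kw = {}
    for name in ("w_m", "w_ll", "w_lc", "tau_m", "tau_ll", "tau_lc", "tau_mf"):
        v = getattr(params, name)
        kw[name] = v * rng.lognormal(0.0, sigma) if v > 0 else v
    return replace(params, **kw)


def simulate_bout_train(
    ts: StimulusTimeSeries,
    params: ModelParams,
    spec: CohortSpec,
    rng: np.random.Generator,
    fish_id: str = "f0",
    trial_id: int = 0,
    stimulus_id: str = "s00",
    activities: NodeActivities | None = None,
) -> pd.DataFrame:
    """One trial's bout table drawn from the model's swim-ratio readout."""
    act = activities if activities is not None else simulate(ts, params)
    dt = ts.dt
    # convergent initiation: the converged multifeature unit that wins the
    # competition reaches the swim-initiation threshold; its drive (not the
    # bilateral sum, which is identical for congruent and conflicting cues)
    # modulates the bout rate
    drive = np.maximum(act.mf_left, act.mf_right)
    rate = spec.bout_rate * (1.0 + spec.drive_gain * drive)
    # instantaneous readout: the 2 s rolling mean exists to match the
    # windowed bout analysis and must not enter the generative draw twice
    return bout_train_from_prob(act.ratio_left, dt, spec, rng,
                                rate=rate, fish_id=fish_id,
                                trial_id=trial_id, stimulus_id=stimulus_id)


def bout_train_from_prob(
    p_left: np.ndarray,
    dt: float,
    spec: CohortSpec,
    rng: np.random.Generator,
    rate: np.ndarray | float | None = None,
    fish_id: str = "f0",
    trial_id: int = 0,
    stimulus_id: str = "s00",
) -> pd.DataFrame:
    """One trial's bout table from an explicit left-turn probability
    timecourse (renewal bout times, Bernoulli directions)."""
    p_left = np.asarray(p_left, dtype=float)
    rate = np.broadcast_to(
        spec.bout_rate if rate is None else np.asarray(rate, float), p_left.shape)
    p_bout = 1.0 - np.exp(-rate * dt)
    bout_bins = np.flatnonzero(rng.random(len(p_bout)) < p_bout)

    n = len(bout_bins)
    t_start = bout_bins * dt + rng.uniform(0, dt, n)
    order = np.argsort(t_start)
    t_start = t_start[order]
    p_at_bout = p_left[bout_bins][order]

    is_forward = rng.random(n) < spec.forward_fraction
    go_left = rng.random(n) < p_at_bout
    mag = np.abs(rng.normal(spec.turn_mag_mean, spec.turn_mag_sd, n))
    mag = np.clip(mag, behavior.TURN_THRESHOLD_DEG + 0.5, 120.0)
    delta = np.where(go_left, mag, -mag)
    delta[is_forward] = rng.uniform(-behavior.TURN_THRESHOLD_DEG,
                                    behavior.TURN_THRESHOLD_DEG, is_forward.sum())

    dur = rng.uniform(0.1, 0.2, n)
    dist = rng.uniform(0.03, 0.09, n)  # keeps average speed < 1 cm/s
    # positions: slow angular drift near the arena center, away from edges
    ang = np.cumsum(rng.normal(0, 0.3, n))
    r = 1.0 + 0.5 * np.sin(ang)
    x, y = r * np.cos(ang), r * np.sin(ang)

    df = pd.DataFrame({
        "fish_id": fish_id, "trial_id": trial_id, "stimulus_id": stimulus_id,
        "t_start": t_start, "t_end": t_start + dur,
        "x_start": x, "y_start": y,
        "x_end": x + dist * np.cos(ang), "y_end": y + dist * np.sin(ang),
        "orientation_start": 0.0, "orientation_end": delta,
        "delta_theta": delta,
        "interbout_interval": np.concatenate(([np.nan], np.diff(t_start))),
        "distance": dist, "speed": dist / dur,
        "contour_area": rng.normal(800.0, 80.0, n),
        "edge_distance": 6.0 - np.hypot(x, y),
    })
    return df[behavior.BOUT_COLUMNS]


@dataclass
class Cohort:
    """A generated cohort: battery entries, the pooled bout table, and the
    per-fish generative parameters (the recovery targets)."""

    entries: list[BatteryEntry]
    bouts: pd.DataFrame
    fish_params: dict[str, ModelParams]
    spec: CohortSpec

    @property
    def fish_ids(self) -> list[str]:
        return sorted(self.fish_params)


def generate_cohort(spec: CohortSpec, entries: list[BatteryEntry]) -> Cohort:
    """Generate a full cohort over a stimulus battery, deterministically
    from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    rendered = {e.stimulus_id: render_timeseries(e.spec, spec.dt) for e in entries}
    tables = []
    fish_params: dict[str, ModelParams] = {}
    for i in range(spec.n_fish):
        fid = f"f{i:03d}"
        p = _jittered(spec.params, spec.param_jitter, rng)
        fish_params[fid] = p
        for e in entries:
            ts = rendered[e.stimulus_id]
            act = simulate(ts, p)
            for trial in range(spec.trials_per_stim):
                tables.append(simulate_bout_train(
                    ts, p, spec, rng, fish_id=fid, trial_id=trial,
                    stimulus_id=e.stimulus_id, activities=act))
    bouts = (pd.concat(tables, ignore_index=True) if tables
             else pd.DataFrame(columns=behavior.BOUT_COLUMNS))
    return Cohort(entries=list(entries), bouts=bouts, fish_params=fish_params,
                  spec=spec)


# ---------------------------------------------------------------------------
# calcium traces


def gcamp_kernel(tau: float = GCAMP_TAU, dt: float = IMAGING_DT) -> np.ndarray:
    """Causal exponential GCaMP response kernel, normalized to unit sum so
    sustained signals keep their amplitude."""
    t = np.arange(0.0, 6.0 * tau, dt)
    k = np.exp(-t / tau)
    return k / k.sum()


def convolve_gcamp(x: np.ndarray, tau: float = GCAMP_TAU, dt: float = IMAGING_DT) -> np.ndarray:
    """Causal convolution with the GCaMP kernel (same length as input)."""
    x = np.asarray(x, dtype=float)
    return np.convolve(x, gcamp_kernel(tau, dt))[: len(x)]


def minmax(x: np.ndarray) -> np.ndarray:
    """Unity-based normalization to [0, 1]; constant input maps to zeros."""
    x = np.asarray(x, dtype=float)
    span = np.ptp(x)
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


@dataclass(frozen=True)
class CalciumSimSpec:
    """Settings of the synthetic calcium benchmark traces."""

    spike_rate: float = 0.05       # Poisson events per 0.5 s bin
    spike_amplitude: float = 1.0
    gcamp_tau: float = GCAMP_TAU
    noise_scales: tuple[float, ...] = (0.3, 0.65, 1.0, 1.35, 1.7, 2.0)
    n_neurons: int = 100
    n_repeats: int = 5             # trials per neuron and stimulus
    dt: float = IMAGING_DT


def simulate_calcium(
    activity: np.ndarray,
    spec: CalciumSimSpec,
    noise_scale: float,
    rng: np.random.Generator,
    n_neurons: int | None = None,
) -> np.ndarray:
    """Synthetic traces for one ground-truth node.

    ``activity`` is the node's concatenated activity on the imaging grid.
    Each neuron/trial receives the min-max-normalized activity plus an
    independent Poisson spike train, GCaMP-convolved, plus Gaussian noise
    of scale ``noise_scale``.  Returns (n_neurons, n_repeats, len(activity)).
    """
    n_neurons = spec.n_neurons if n_neurons is None else n_neurons
    base = minmax(activity)
    T = len(base)
    shape = (n_neurons, spec.n_repeats, T)
    drive = base[None, None, :] + spec.spike_amplitude * rng.poisson(
        spec.spike_rate, size=shape)
    k = gcamp_kernel(spec.gcamp_tau, spec.dt)
    # causal convolution along time for the whole stack
    from scipy.signal import fftconvolve
    conv = fftconvolve(drive, k[None, None, :], mode="full", axes=2)[:, :, :T]
    if noise_scale < 0:
        raise ValueError("noise scale must be >= 0")
    if noise_scale > 0:
        conv = conv + rng.normal(0.0, noise_scale, size=shape)
    return conv
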