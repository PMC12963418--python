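"""Additive three-pathway network model of visuomotor decision-making.

Stimulus channels feed three parallel pathways, each a leaky integrator
realized as convolution with a truncated exponential decay kernel:

* motion pathway: per-side leaky integration of the motion channels
  (time constant ``tau_m``), attractive;
* luminance-level pathway: per-side leaky integration of the luminance
  channels (``tau_ll``), attractive;
* luminance-change pathway: the rectified difference between the momentary
  luminance and its leaky integral (``tau_lc``) yields increase and decrease
  detectors whose sum is the change detector, repulsive and therefore wired
  to the *contralateral* multifeature integrator.

The per-side weighted sums (weights ``w_m``, ``w_ll``, ``w_lc``) are
integrated once more (``tau_mf``) into the multifeature nodes MF_L / MF_R,
and the left-swim probability is the normalized difference
``1/2 ((MF_L - MF_R)/(MF_L + MF_R) + 1)`` smoothed with a trailing 2 s
rolling mean to match the behavioral windowing.
"""
from __future__ import annotations

from dataclasses import dataclass, replace, asdict, field
import numpy as np
import pandas as pd

from .stimulus import StimulusTimeSeries

KERNEL_DUR = 30.0  # s, total kernel support
KERNEL_SHIFT = 15.0  # s, kernel is zero for t <= 15 (causal half)
ROLL_WINDOW = 2.0  # s, trailing smoothing window of the swim ratio
MF_FLOOR = 1e-12  # multifeature values below this count as exactly 0

PATHWAYS = ("motion", "lum_level", "lum_change")

#: free parameters of the full model, in canonical order
FREE_PARAM_NAMES = ("w_m", "w_ll", "w_lc", "tau_m", "tau_ll", "tau_lc", "tau_mf")

_PATHWAY_FIELDS = {
    "motion": ("w_m", "tau_m"),
    "lum_level": ("w_ll", "tau_ll"),
    "lum_change": ("w_lc", "tau_lc"),
}


@dataclass(frozen=True)
class ModelParams:
    """The seven free parameters plus fixed auxiliaries.

    ``sensitivity`` scales all four input channels (clutch-specific
    sensitivity factor, default 1).  ``cross_inhibition`` adds an optional
    subtractive mutual inhibition between the side-paired motion
    integrators; it is off (0) by default and did not improve fits.
    """

    w_m: float = 1.0
    w_ll: float = 0.15
    w_lc: float = 0.7
    tau_m: float = 4.0
    tau_ll: float = 4.0
    tau_lc: float = 5.0
    tau_mf: float = 2.0
    sensitivity: float = 1.0
    cross_inhibition: float = 0.0

    def __post_init__(self) -> None:
        for w in ("w_m", "w_ll", "w_lc", "cross_inhibition"):
            if getattr(self, w) < 0:
                raise ValueError(f"{w} must be >= 0")
        for tau in ("tau_m", "tau_ll", "tau_lc", "tau_mf"):
            if getattr(self, tau) <= 0:
                raise ValueError(f"{tau} must be > 0")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")

    def free_names(self) -> tuple[str, ...]:
        """Free parameters: a silenced pathway (weight exactly 0) also drops
        its time constant from the free set."""
        names = []
        for name in FREE_PARAM_NAMES:
            pathway = next((p for p, (w, tau) in _PATHWAY_FIELDS.items()
                            if tau == name), None)
            if pathway is not None and getattr(self, _PATHWAY_FIELDS[pathway][0]) == 0:
                continue
            if name.startswith("w_") and getattr(self, name) == 0:
                continue
            names.append(name)
        return tuple(names)

    def with_values(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def silence_pathway(params: ModelParams, pathway: str) -> ModelParams:
    """Return a copy with the named pathway's weight set to 0 (idempotent).

    The paired time constant is thereby removed from ``free_names()``.
    """
    if pathway not in _PATHWAY_FIELDS:
        raise ValueError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    w_name, _ = _PATHWAY_FIELDS[pathway]
    return replace(params, **{w_name: 0.0})


def decay_kernel(tau: float, dt: float) -> np.ndarray:
    """The 30 s exponential decay kernel K(t) = (1/tau) e^{-(t-15)/tau} for
    t > 15, else 0, sampled at step ``dt`` (length round(30/dt)+1).

    The zero first half makes a centered ("same"-length) convolution with
    this kernel strictly causal.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if dt <= 0 or dt > KERNEL_SHIFT:
        raise ValueError("dt must be in (0, 15]")
    t = np.arange(int(round(KERNEL_DUR / dt)) + 1) * dt
    k = np.where(t > KERNEL_SHIFT, np.exp(-(t - KERNEL_SHIFT) / tau) / tau, 0.0)
    return k


def leaky_convolve(signal: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Leaky integration: causal convolution of ``signal`` with the decay
    kernel, Riemann-weighted by ``dt``.  Output has the signal's length and
    at time t depends only on the signal at times <= t.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    causal = _causal_weights(tau, dt)
    return np.convolve(signal, causal)[: len(signal)] * dt


def _causal_weights(tau: float, dt: float) -> np.ndarray:
    """Causal half of the decay kernel, rescaled so its discrete integral
    equals the continuous one (1 - e^{-15/tau}); removes the Riemann-sum
    gain bias that is otherwise ~dt/(2 tau)."""
    k = decay_kernel(tau, dt)
    shift = int(round(KERNEL_SHIFT / dt))
    causal = k[shift:]
    target = 1.0 - np.exp(-KERNEL_SHIFT / tau)
    return causal * (target / (causal.sum() * dt))


def change_pathway(
    lum_channel: np.ndarray, tau_lc: float, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Luminance increase / decrease / change detectors for one hemifield.

    The channel is compared against its own leaky integral: increases above
    it drive the increase detector, drops below it the decrease detector;
    their sum is the change detector.  All three are nonnegative and decay
    to ~0 for a channel held constant.
    """
    lum = np.asarray(lum_channel, dtype=float)
    lint = leaky_convolve(lum, tau_lc, dt)
    li = np.maximum(lum - lint, 0.0)
    ld = np.maximum(lint - lum, 0.0)
    return li, ld, li + ld


def trailing_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Trailing rolling mean over the last ``n`` samples (window holds the
    past), partial windows averaged over what exists."""
    c = np.cumsum(np.concatenate(([0.0], x)))
    out = np.empty_like(x, dtype=float)
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - n, 0)
    out[:] = (c[idx] - c[lo]) / (idx - lo)
    return out


#: node kinds exposed by :meth:`NodeActivities.node`
NODE_TYPES = (
    "motion_integrator",
    "luminance_integrator",
    "multifeature_integrator",
    "luminance_change",
    "luminance_increase",
    "luminance_decrease",
)


@dataclass
class NodeActivities:
    """All node timecourses of one simulation plus the left-swim ratio.

    ``lint_*`` is the change pathway's internal leaky luminance integral
    (the quantity the rectified detectors compare against); ``lc_*`` is the
    summed change detector.
    """

    dt: float
    t: np.ndarray
    m_left: np.ndarray
    m_right: np.ndarray
    ll_left: np.ndarray
    ll_right: np.ndarray
    lint_left: np.ndarray
    lint_right: np.ndarray
    li_left: np.ndarray
    li_right: np.ndarray
    ld_left: np.ndarray
    ld_right: np.ndarray
    lc_left: np.ndarray
    lc_right: np.ndarray
    mf_left: np.ndarray
    mf_right: np.ndarray
    ratio_left: np.ndarray
    swims_left: np.ndarray

    _FIELD_BY_TYPE = {
        "motion_integrator": "m",
        "luminance_integrator": "ll",
        "multifeature_integrator": "mf",
        "luminance_change": "lc",
        "luminance_increase": "li",
        "luminance_decrease": "ld",
    }

    def node(self, node_type: str, side: str) -> np.ndarray:
        """Activity of one node.

        For the integrator nodes ``side`` is the node's own side.  The
        change-family nodes are repulsive and wired contralaterally, so the
        node *driving behavior toward* ``side`` is the one monitoring the
        opposite hemifield; ``node(type, side)`` follows that drive-side
        convention throughout the package.
        """
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        prefix = self._FIELD_BY_TYPE[node_type]
        if node_type in ("luminance_change", "luminance_increase", "luminance_decrease"):
            side = "right" if side == "left" else "left"
        return getattr(self, f"{prefix}_{side}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (time, node, side, value)."""
        rows = []
        for name in ("m", "ll", "lint", "li", "ld", "lc", "mf"):
            for side in ("left", "right"):
                rows.append(pd.DataFrame({
                    "time": self.t, "node": name, "side": side,
                    "value": getattr(self, f"{name}_{side}"),
                }))
        rows.append(pd.DataFrame({
            "time": self.t, "node": "swims", "side": "left",
            "value": self.swims_left,
        }))
        return pd.concat(rows, ignore_index=True)


def swims_left_batch(
    motion_left: np.ndarray,
    motion_right: np.ndarray,
    luminance_left: np.ndarray,
    luminance_right: np.ndarray,
    dt: float,
    params: ModelParams,
) -> np.ndarray:
    """Left-swim probability timecourses for a stack of stimuli.

    Same computation as :func:`simulate` restricted to the behavioral
    readout, vectorized over the leading axis of the (n_stim, T) channel
    arrays.  Used by the fitting protocol, where only ``swims_left``
    enters the loss.
    """
    from scipy.signal import fftconvolve

    chans = {
        "motion_left": np.atleast_2d(np.asarray(motion_left, float)) * params.sensitivity,
        "motion_right": np.atleast_2d(np.asarray(motion_right, float)) * params.sensitivity,
        "luminance_left": np.atleast_2d(np.asarray(luminance_left, float)) * params.sensitivity,
        "luminance_right": np.atleast_2d(np.asarray(luminance_right, float)) * params.sensitivity,
    }
    n, T = chans["motion_left"].shape
    npad = int(round(KERNEL_SHIFT / dt))

    def conv(x: np.ndarray, tau: float) -> np.ndarray:
        pad = np.concatenate([np.repeat(x[:, :1], npad, axis=1), x], axis=1)
        k = _causal_weights(tau, dt)
        out = fftconvolve(pad, k[None, :], mode="full", axes=1)[:, : T + npad] * dt
        return out[:, npad:]

    m_l = conv(chans["motion_left"], params.tau_m)
    m_r = conv(chans["motion_right"], params.tau_m)
    ll_l = conv(chans["luminance_left"], params.tau_ll)
    ll_r = conv(chans["luminance_right"], params.tau_ll)
    lint_l = conv(chans["luminance_left"], params.tau_lc)
    lint_r = conv(chans["luminance_right"], params.tau_lc)
    lc_l = np.abs(chans["luminance_left"] - lint_l)
    lc_r = np.abs(chans["luminance_right"] - lint_r)
    if params.cross_inhibition > 0:
        c = params.cross_inhibition
        m_l, m_r = (np.maximum(m_l - c * m_r, 0.0),
                    np.maximum(m_r - c * m_l, 0.0))
    multi_l = params.w_m * m_l + params.w_ll * ll_l + params.w_lc * lc_r
    multi_r = params.w_m * m_r + params.w_ll * ll_r + params.w_lc * lc_l
    mf_l = conv(multi_l, params.tau_mf)
    mf_r = conv(multi_r, params.tau_mf)
    mf_l = np.where(mf_l < MF_FLOOR, 0.0, mf_l)
    mf_r = np.where(mf_r < MF_FLOOR, 0.0, mf_r)
    total = mf_l + mf_r
    ratio = np.where(total > 0, (mf_l - mf_r) / np.where(total > 0, total, 1.0), 0.0)

    nwin = max(1, int(round(ROLL_WINDOW / dt)))
    x = 0.5 * (ratio + 1.0)
    c = np.concatenate([np.zeros((n, 1)), np.cumsum(x, axis=1)], axis=1)
    idx = np.arange(1, T + 1)
    lo = np.maximum(idx - nwin, 0)
    return (c[:, idx] - c[:, lo]) / (idx - lo)


def simulate(ts: StimulusTimeSeries, params: ModelParams) -> NodeActivities:
    """Run the full model on a rendered stimulus.

    Channels are first scaled by the sensitivity factor.  Each channel is
    padded at the front with one kernel memory (15 s) of its initial value —
    the pre-stimulus background is treated as stationary history — so the
    integrator baselines are settled at t = 0.  Where both multifeature
    nodes are (numerically) zero the ratio is defined as chance (0.5).
    """
    dt = ts.dt
    ch = {k: np.asarray(v, dtype=float) * params.sensitivity
          for k, v in ts.channels().items()}
    for v in ch.values():
        if not np.all(np.isfinite(v)):
            raise ValueError("stimulus channels contain non-finite values")

    npad = int(round(KERNEL_SHIFT / dt))
    padded = {k: np.concatenate([np.full(npad, v[0]), v]) for k, v in ch.items()}

    def conv(key: str, tau: float) -> np.ndarray:
        return leaky_convolve(padded[key], tau, dt)[npad:]

    m = {s: conv(f"motion_{s}", params.tau_m) for s in ("left", "right")}
    ll = {s: conv(f"luminance_{s}", params.tau_ll) for s in ("left", "right")}
    lint = {s: conv(f"luminance_{s}", params.tau_lc) for s in ("left", "right")}
    li, ld, lc = {}, {}, {}
    for s in ("left", "right"):
        lum = ch[f"luminance_{s}"]
        li[s] = np.maximum(lum - lint[s], 0.0)
        ld[s] = np.maximum(lint[s] - lum, 0.0)
        lc[s] = li[s] + ld[s]

    if params.cross_inhibition > 0:
        c = params.cross_inhibition
        m_l = np.maximum(m["left"] - c * m["right"], 0.0)
        m_r = np.maximum(m["right"] - c * m["left"], 0.0)
        m = {"left": m_l, "right": m_r}

    multi = {
        "left": params.w_m * m["left"] + params.w_ll * ll["left"] + params.w_lc * lc["right"],
        "right": params.w_m * m["right"] + params.w_ll * ll["right"] + params.w_lc * lc["left"],
    }
    mf = {}
    for s in ("left", "right"):
        pad = np.concatenate([np.full(npad, multi[s][0]), multi[s]])
        mf[s] = leaky_convolve(pad, params.tau_mf, dt)[npad:]

    mf_l = np.where(mf["left"] < MF_FLOOR, 0.0, mf["left"])
    mf_r = np.where(mf["right"] < MF_FLOOR, 0.0, mf["right"])
    total = mf_l + mf_r
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, (mf_l - mf_r) / np.where(total > 0, total, 1.0), 0.0)
    ratio_left = 0.5 * (ratio + 1.0)
    swims = trailing_mean(ratio_left, max(1, int(round(ROLL_WINDOW / dt))))

    return NodeActivities(
        dt=dt, t=ts.t.copy(),
        m_left=m["left"], m_right=m["right"],
        ll_left=ll["left"], ll_right=ll["right"],
        lint_left=lint["left"], lint_right=lint["right"],
        li_left=li["left"], li_right=li["right"],
        ld_left=ld["left"], ld_right=ld["right"],
        lc_left=lc["left"], lc_right=lc["right"],
        mf_left=mf["left"], mf_right=mf["right"],
        ratio_left=ratio_left, swims_left=swims,
    )
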