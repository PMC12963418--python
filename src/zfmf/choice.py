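"""Steady-state choice models and the threshold-width psychometric curve.

The additive model predicts the probability of a rightward swim from the
motion coherences presented on either side (M_r, M_l in [0, 1]), binary
lateral-luminance indicators (L_r, L_l in {0, 1}) and a bias:

    p(R) = sigma(m_r M_r^gamma - m_l M_l^gamma + l_r L_r - l_l L_l + b)

The winner-takes-all (WTA) variant zeroes the weaker feature — the one
whose absolute contribution to the sigmoid argument is smaller — before
evaluation.  MOT and LUMI are the single-feature restrictions.  Model
comparison uses the mean squared error between fit and data (lower wins).

The threshold-width reparametrization describes tuning rather than
decisions:

    p(R) = sigma(-2 log(1/0.8 - 1) (M - t) / w)

with signed coherence M in [-1, 1]; the curve crosses 0.5 at the threshold
t and reaches 0.8 at M = t + w/2 by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit

MODEL_KINDS = ("ADD", "WTA", "MOT", "LUMI")

#: initial guesses used both for fitting and for model-hypothesis curves
INIT_GUESS = dict(m_r=-1.0, m_l=-1.0, l_r=0.5, l_l=0.5, b=0.0, gamma=0.6)

#: scale constant of the threshold-width curve; anchors p = 0.8 at t + w/2
TW_SCALE = -2.0 * np.log(1.0 / 0.8 - 1.0)


@dataclass(frozen=True)
class ChoiceModelParams:
    m_r: float
    m_l: float
    l_r: float
    l_l: float
    b: float
    gamma: float
    kind: str = "ADD"

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        if self.kind == "MOT" and (self.l_r != 0 or self.l_l != 0):
            raise ValueError("MOT fixes l_r = l_l = 0")
        if self.kind == "LUMI" and (self.m_r != 0 or self.m_l != 0):
            raise ValueError("LUMI fixes m_r = m_l = 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PsychometricTW:
    """Threshold (inflection point) and width of the psychometric curve."""

    t: float
    w: float

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("width w must be > 0")


def _pow(m: np.ndarray, gamma: float) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.where(m > 0, np.power(np.where(m > 0, m, 1.0), gamma), 0.0)


def _argument(m_r, m_l, l_r, l_l, b, gamma, M_r, M_l, L_r, L_l, wta: bool):
    motion = m_r * _pow(M_r, gamma) - m_l * _pow(M_l, gamma)
    lum = l_r * np.asarray(L_r, float) - l_l * np.asarray(L_l, float)
    if wta:
        keep_motion = np.abs(motion) >= np.abs(lum)
        motion = np.where(keep_motion, motion, 0.0)
        lum = np.where(keep_motion, 0.0, lum)
    return motion + lum + b


def predict_choice(
    params: ChoiceModelParams,
    M_r, M_l, L_r, L_l,
) -> np.ndarray | float:
    """Probability of a rightward swim under the given model."""
    M_r, M_l = np.asarray(M_r, float), np.asarray(M_l, float)
    L_r, L_l = np.asarray(L_r, float), np.asarray(L_l, float)
    for name, v, hi in (("M_r", M_r, 1), ("M_l", M_l, 1)):
        if np.any(v < 0) or np.any(v > hi):
            raise ValueError(f"{name} must be in [0, 1]")
    for name, v in (("L_r", L_r), ("L_l", L_l)):
        if not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError(f"{name} must be 0 or 1")
    if np.any((M_r > 0) & (M_l > 0)) or np.any((L_r > 0) & (L_l > 0)):
        raise ValueError("at most one side of each feature may be nonzero")
    arg = _argument(params.m_r, params.m_l, params.l_r, params.l_l,
                    params.b, params.gamma, M_r, M_l, L_r, L_l,
                    wta=params.kind == "WTA")
    out = expit(arg)
    return float(out) if np.ndim(out) == 0 else out


def conditions_from_table(data: pd.DataFrame) -> tuple[np.ndarray, ...]:
    """Design arrays (M_r, M_l, L_r, L_l, frac_right) from a tidy table.

    Expected columns: ``coherence_signed`` in [-1, 1] (positive = rightward
    motion), ``lum_condition`` in {none, left, right} and either
    ``frac_right`` or counts ``n_left``/``n_right``.
    """
    c = data["coherence_signed"].to_numpy(dtype=float)
    M_r = np.where(c > 0, c, 0.0)
    M_l = np.where(c < 0, -c, 0.0)
    lum = data["lum_condition"].astype(str).to_numpy()
    L_r = (lum == "right").astype(float)
    L_l = (lum == "left").astype(float)
    if "frac_right" in data.columns:
        y = data["frac_right"].to_numpy(dtype=float)
    else:
        n_r = data["n_right"].to_numpy(dtype=float)
        n_l = data["n_left"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            y = n_r / (n_r + n_l)
    return M_r, M_l, L_r, L_l, y


def fit_choice(data: pd.DataFrame, kind: str = "ADD") -> tuple[ChoiceModelParams, float]:
    """Nonlinear least-squares fit of one model kind from the canonical
    initial guess; returns fitted parameters and the MSE against the data.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"kind must be one of {MODEL_KINDS}")
    M_r, M_l, L_r, L_l, y = conditions_from_table(data)
    ok = np.isfinite(y)
    M_r, M_l, L_r, L_l, y = M_r[ok], M_l[ok], L_r[ok], L_l[ok], y[ok]

    if kind == "LUMI" and not np.any((L_r > 0) | (L_l > 0)):
        raise ValueError("LUMI fit is degenerate: no luminance conditions")
    if kind == "MOT" and not np.any((M_r > 0) | (M_l > 0)):
        raise ValueError("MOT fit is degenerate: no motion conditions")

    g = INIT_GUESS
    if kind in ("ADD", "WTA"):
        names = ("m_r", "m_l", "l_r", "l_l", "b", "gamma")
    elif kind == "MOT":
        names = ("m_r", "m_l", "b", "gamma")
    else:  # LUMI: gamma unidentifiable without motion, held at its guess
        names = ("l_r", "l_l", "b")
    if len(y) < len(names):
        raise ValueError("fewer observations than free parameters")

    def model(_x, *theta):
        p = dict(m_r=0.0, m_l=0.0, l_r=0.0, l_l=0.0, b=0.0, gamma=g["gamma"])
        p.update(dict(zip(names, theta)))
        return expit(_argument(p["m_r"], p["m_l"], p["l_r"], p["l_l"],
                               p["b"], p["gamma"], M_r, M_l, L_r, L_l,
                               wta=kind == "WTA"))

    p0 = [g[n] for n in names]
    import warnings
    from scipy.optimize import OptimizeWarning
    with warnings.catch_warnings():
        # the WTA argmax switch makes the jacobian piecewise; covariance
        # estimation is irrelevant here
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(model, np.zeros_like(y), y, p0=p0, maxfev=20000)
    fitted = dict(m_r=0.0, m_l=0.0, l_r=0.0, l_l=0.0, b=0.0, gamma=g["gamma"])
    fitted.update(dict(zip(names, popt)))
    params = ChoiceModelParams(kind=kind, **fitted)
    pred = model(None, *popt)
    mse = float(np.mean((pred - y) ** 2))
    return params, mse


def compare_models(data: pd.DataFrame) -> pd.DataFrame:
    """Fit all four model kinds and rank them by MSE (lower is better).

    Degenerate fits (e.g. LUMI with no luminance conditions) are flagged
    and ranked last with infinite MSE.
    """
    rows = []
    for kind in MODEL_KINDS:
        try:
            params, mse = fit_choice(data, kind)
            rows.append({"kind": kind, "mse": mse, "degenerate": False,
                         "params": params})
        except ValueError:
            rows.append({"kind": kind, "mse": np.inf, "degenerate": True,
                         "params": None})
    df = pd.DataFrame(rows).sort_values("mse", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def predict_tw(params: PsychometricTW, M) -> np.ndarray | float:
    """Threshold-width psychometric curve: p(rightward swim) at signed
    coherence M.  Crosses 0.5 at M = t and 0.8 at M = t + w/2."""
    if params.w <= 0:
        raise ValueError("width w must be > 0")
    out = expit(TW_SCALE * (np.asarray(M, float) - params.t) / params.w)
    return float(out) if np.ndim(out) == 0 else out


def fit_tw(data: pd.DataFrame) -> tuple[PsychometricTW, float]:
    """Fit (t, w) to fraction-rightward over signed coherence from the
    canonical initial guess (t = 0, w = 0.4)."""
    M = data["coherence_signed"].to_numpy(dtype=float)
    if "frac_right" in data.columns:
        y = data["frac_right"].to_numpy(dtype=float)
    else:
        n_r = data["n_right"].to_numpy(dtype=float)
        n_l = data["n_left"].to_numpy(dtype=float)
        y = n_r / (n_r + n_l)
    ok = np.isfinite(y)
    M, y = M[ok], y[ok]
    if len(y) < 2:
        raise ValueError("need at least two observations")

    def model(m, t, w):
        return expit(TW_SCALE * (m - t) / w)

    import warnings
    from scipy.optimize import OptimizeWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(model, M, y, p0=[0.0, 0.4], maxfev=20000)
    t, w = float(popt[0]), float(abs(popt[1]))
    mse = float(np.mean((model(M, t, w) - y) ** 2))
    return PsychometricTW(t=t, w=w), mse
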