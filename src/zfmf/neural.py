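"""Functional classification of calcium traces against the model's nodes.

Two complementary classifiers operate on trial-averaged responses to the
nine imaging stimuli (motion {left, right, off} x luminance {left, right,
off}, labels a-i, 60 s each on a 0.5 s grid):

* the *logical-statement* classifier summarizes each stimulus response
  into five window means (A: 0-10 s pre, B: 12.5-17.5 s initial stimulus,
  C: 20-40 s stimulus, D: 42.5-47.5 s initial post, E: 50-60 s post) and
  evaluates a conjunction of inequality statements per functional type,
  under both hemispheric hypotheses (ipsi = left and ipsi = right);
* the *regression* classifier correlates the unity-normalized average
  trace with GCaMP-convolved model-node regressors and thresholds the
  Pearson r (0.85 for integrator nodes, 0.65 for detector nodes).

Statements are pure data (:class:`Atom` rows in a rule table); rerunning
with modified rules or thresholds needs no code change.  Side labels
follow the drive-side convention of :meth:`zfmf.model.NodeActivities.node`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .model import ModelParams, NODE_TYPES, simulate
from .stimulus import IMAGING_LABELS, imaging_set, imaging_sides, render_timeseries
from .synth import GCAMP_TAU, IMAGING_DT, convolve_gcamp, minmax

WINDOWS = {"A": (0.0, 10.0), "B": (12.5, 17.5), "C": (20.0, 40.0),
           "D": (42.5, 47.5), "E": (50.0, 60.0)}
WINDOW_NAMES = tuple(WINDOWS)

INTEGRATOR_TYPES = ("motion_integrator", "luminance_integrator",
                    "multifeature_integrator")
DETECTOR_TYPES = ("luminance_change", "luminance_increase", "luminance_decrease")
WTA_TYPES = ("wta_motion_integrator", "wta_luminance_integrator")

REGRESSION_R_THRESHOLDS = {**{t: 0.85 for t in INTEGRATOR_TYPES},
                           **{t: 0.65 for t in DETECTOR_TYPES}}


@dataclass(frozen=True)
class ClassifierThresholds:
    """Statement constants, anchored to the overall data noise level."""

    T_activity: float = 0.2
    T_minimum: float = 0.1
    T_peaksLC: float = 1.25
    T_peaks: float = 1.5
    T_below: float = 0.9

    def value(self, ref) -> float:
        return getattr(self, ref) if isinstance(ref, str) else float(ref)


ANY = ("ipsi", "contra", "off")


@dataclass(frozen=True)
class Atom:
    """One inequality statement over window means of selected stimuli.

    The statement must hold for *every* stimulus matched by the selector,
    every left-hand window and every right-hand window (conjunction over
    the expanded set).  When ``rhs`` is empty the left side is compared
    against the constant ``offset`` alone; otherwise against
    ``factor * rhs_window + offset``.  ``factor``/``offset`` may name a
    threshold constant.  An ``rhs_m_sel``/``rhs_l_sel`` lets the right
    side reference a different stimulus (all lhs x rhs pairs); by default
    both sides read the same stimulus.
    """

    m_sel: tuple[str, ...]
    l_sel: tuple[str, ...]
    lhs: tuple[str, ...]
    op: str
    rhs: tuple[str, ...] = ()
    factor: float | str = 1.0
    offset: float | str = 0.0
    rhs_m_sel: tuple[str, ...] | None = None
    rhs_l_sel: tuple[str, ...] | None = None


def default_rules() -> dict[str, tuple[Atom, ...]]:
    """The statement table for the eight functional types."""
    A = Atom
    return {
        "motion_integrator": (
            A(("ipsi",), ANY, ("C",), ">", offset="T_activity"),
            A(("ipsi",), ANY, ("C",), ">", ("A", "B", "E")),
            A(("off", "contra"), ("ipsi", "contra"), ("C",), "<", ("A", "E"),
              offset="T_minimum"),
            A(("off", "contra"), ("ipsi", "contra"), ("D",), "<", ("E",),
              offset="T_minimum"),
        ),
        "multifeature_integrator": (
            A(("ipsi",), ANY, ("C",), ">", offset="T_activity"),
            A(("ipsi",), ANY, ("C",), ">", ("A", "E")),
            A(("off", "contra"), ("contra",), ("B", "D"), ">", ("C",)),
            A(("off",), ("ipsi",), ("C",), ">", ("A", "E")),
            A(("off",), ("contra",), ("B",), ">", ("A",)),
            A(("off",), ("contra",), ("D",), ">", ("E",)),
        ),
        "luminance_integrator": (
            A(ANY, ("ipsi",), ("C",), ">", offset="T_activity"),
            A(ANY, ("ipsi",), ("C",), ">", ("A", "B", "E")),
            A(("ipsi", "contra"), ("off",), ("C",), "<", ("A", "E"),
              offset="T_minimum"),
            A(ANY, ("contra",), ("C",), "<", ("A", "E"), factor="T_below"),
        ),
        "luminance_change": (
            A(ANY, ("contra",), ("B",), ">", offset="T_activity"),
            A(ANY, ("contra",), ("B", "D"), ">", ("A", "C", "E")),
            A(ANY, ("ipsi",), ("B", "D"), ">", ("A", "C")),
            A(("off",), ("contra",), ("B",), ">", ("B",), factor="T_peaksLC",
              rhs_m_sel=("off",), rhs_l_sel=("ipsi",)),
        ),
        "luminance_increase": (
            A(ANY, ("contra",), ("B",), ">", offset="T_activity"),
            A(ANY, ("contra",), ("B",), ">", ("A", "C", "D", "E")),
            A(ANY, ("ipsi",), ("D",), ">", ("C",)),
            A(ANY, ("ipsi",), ("B",), "<", ("A",), offset="T_minimum"),
            A(("off",), ("contra",), ("B",), ">", ("D",), factor="T_peaks",
              rhs_m_sel=("off",), rhs_l_sel=("ipsi",)),
            A(("off",), ("contra",), ("D",), "<", ("A",), offset="T_minimum"),
        ),
        "luminance_decrease": (
            A(ANY, ("contra",), ("D",), ">", offset="T_activity"),
            A(ANY, ("contra",), ("D",), ">", ("A", "B", "C", "E")),
            A(ANY, ("ipsi",), ("B",), ">", ("A",)),
            A(ANY, ("ipsi",), ("D",), "<", ("A",), offset="T_minimum"),
            A(("off",), ("contra",), ("D",), ">", ("B",), factor="T_peaks",
              rhs_m_sel=("off",), rhs_l_sel=("ipsi",)),
            A(("off",), ("contra",), ("B",), "<", ("A",), offset="T_minimum"),
        ),
        "wta_motion_integrator": (
            A(("ipsi",), ("off", "ipsi"), ("C",), ">", offset="T_activity"),
            A(("ipsi",), ("off", "ipsi"), ("C",), ">", ("A", "B", "E")),
            A(("off", "contra"), ("ipsi", "contra"), ("C",), "<", ("A", "E"),
              offset="T_minimum"),
            A(("ipsi",), ("contra",), ("C",), "<", ("A", "E"),
              offset="T_minimum"),
            A(("off", "contra"), ("ipsi", "contra"), ("D",), "<", ("E",),
              offset="T_minimum"),
        ),
        "wta_luminance_integrator": (
            A(("off", "ipsi"), ("ipsi",), ("C",), ">", offset="T_activity"),
            A(("off", "ipsi"), ("ipsi",), ("C",), ">", ("A", "B", "E")),
            A(("ipsi", "contra"), ("off",), ("C",), "<", ("A", "E"),
              offset="T_minimum"),
            A(("ipsi",), ("contra",), ("C",), "<", ("A", "E"),
              offset="T_minimum"),
            A(("contra",), ("ipsi",), ("C",), "<", ("A", "E"),
              offset="T_minimum"),
            A(ANY, ("contra",), ("C",), "<", ("A", "E"), factor="T_below"),
        ),
    }


def dff0(raw: np.ndarray, dt: float = IMAGING_DT, baseline_s: float = 10.0) -> np.ndarray:
    """dF/F0 with F0 the mean fluorescence of the pre-stimulus period.

    Raises ``ValueError`` for F0 <= 0 (the neuron is flagged and excluded
    by callers)."""
    raw = np.asarray(raw, dtype=float)
    n0 = int(round(baseline_s / dt))
    f0 = float(np.mean(raw[:n0]))
    if f0 <= 0:
        raise ValueError("non-positive baseline fluorescence F0")
    return (raw - f0) / f0


def summarize_windows(
    traces: dict[str, np.ndarray] | pd.DataFrame, dt: float = IMAGING_DT
) -> pd.DataFrame:
    """Five window means per stimulus from trial-averaged 60 s traces.

    ``traces`` maps stimulus label -> trace array (or a DataFrame with one
    column per label).  Returns a DataFrame indexed by stimulus label with
    columns A-E.
    """
    if isinstance(traces, pd.DataFrame):
        traces = {c: traces[c].to_numpy() for c in traces.columns}
    rows = {}
    for label, tr in traces.items():
        tr = np.asarray(tr, dtype=float)
        rows[label] = {
            w: float(np.mean(tr[int(round(lo / dt)): int(round(hi / dt))]))
            for w, (lo, hi) in WINDOWS.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(WINDOW_NAMES)]


def _resolve(sel: tuple[str, ...], hypo: str) -> set[str]:
    contra = "right" if hypo == "left" else "left"
    out = set()
    for token in sel:
        out.add({"ipsi": hypo, "contra": contra, "off": "off"}[token])
    return out


def _select(sides: dict[str, tuple[str, str]],
            m_set: set[str], l_set: set[str]) -> list[str]:
    return [lab for lab, (m, l) in sides.items() if m in m_set and l in l_set]


def _atom_holds(atom: Atom, summary: pd.DataFrame, hypo: str,
                thresholds: ClassifierThresholds,
                sides: dict[str, tuple[str, str]]) -> bool:
    lhs_stims = _select(sides, _resolve(atom.m_sel, hypo), _resolve(atom.l_sel, hypo))
    if not lhs_stims:
        raise ValueError("atom selector matches no stimulus")
    factor = thresholds.value(atom.factor)
    offset = thresholds.value(atom.offset)

    same_stim = atom.rhs_m_sel is None and atom.rhs_l_sel is None
    if atom.rhs and not same_stim:
        rhs_stims = _select(sides,
                            _resolve(atom.rhs_m_sel or atom.m_sel, hypo),
                            _resolve(atom.rhs_l_sel or atom.l_sel, hypo))
        if not rhs_stims:
            raise ValueError("atom rhs selector matches no stimulus")

    for s in lhs_stims:
        for wl in atom.lhs:
            lhs_val = summary.at[s, wl]
            if not atom.rhs:
                rhs_vals = [offset]
            elif same_stim:
                rhs_vals = [factor * summary.at[s, wr] + offset for wr in atom.rhs]
            else:
                rhs_vals = [factor * summary.at[s2, wr] + offset
                            for s2 in rhs_stims for wr in atom.rhs]
            for rv in rhs_vals:
                ok = lhs_val > rv if atom.op == ">" else lhs_val < rv
                if not ok:
                    return False
    return True


def classify_logical(
    summary: pd.DataFrame,
    thresholds: ClassifierThresholds | None = None,
    rules: dict[str, tuple[Atom, ...]] | None = None,
    sides: dict[str, tuple[str, str]] | None = None,
) -> set[tuple[str, str]]:
    """All (type, side) labels whose statement conjunction holds.

    ``summary`` is the A-E window table over the nine stimuli.  Each type
    is evaluated under both hemispheric hypotheses; a type passing under
    both is ambiguous and callers may exclude it downstream.
    """
    thresholds = thresholds or ClassifierThresholds()
    rules = rules or default_rules()
    sides = sides or imaging_sides()
    missing = [lab for lab in sides if lab not in summary.index]
    if missing:
        raise ValueError(f"summary is missing stimuli: {missing}")
    labels = set()
    for type_name, atoms in rules.items():
        for hypo in ("left", "right"):
            if all(_atom_holds(a, summary, hypo, thresholds, sides) for a in atoms):
                labels.add((type_name, hypo))
    return labels


# ---------------------------------------------------------------------------
# model-derived reference traces and regressors

_SIM_DT = 0.1  # model simulated finely, then resampled to the imaging grid


def node_activity_concat(
    params: ModelParams, node_type: str, side: str, dt: float = IMAGING_DT
) -> np.ndarray:
    """A node's raw activity concatenated over the nine imaging stimuli in
    canonical a-i order, on the imaging grid."""
    step = int(round(dt / _SIM_DT))
    segs = []
    for label, spec in imaging_set().items():
        act = simulate(render_timeseries(spec, _SIM_DT), params)
        segs.append(act.node(node_type, side)[::step])
    return np.concatenate(segs)


def reference_trace(
    params: ModelParams, node_type: str, side: str, dt: float = IMAGING_DT
) -> np.ndarray:
    """Noiseless synthetic neuron: min-max-normalized node activity
    convolved with the GCaMP kernel (concatenated a-i)."""
    return convolve_gcamp(minmax(node_activity_concat(params, node_type, side, dt)),
                          GCAMP_TAU, dt)


def build_regressors(
    params: ModelParams, dt: float = IMAGING_DT
) -> tuple[dict[tuple[str, str], np.ndarray], list[tuple[str, str]]]:
    """GCaMP-convolved, unity-normalized model regressors for the six node
    types x both sides, concatenated over the nine stimuli.

    Returns (regressors, flagged) where flagged lists degenerate (constant)
    node/side combinations, excluded from the regressor dict.
    """
    regs: dict[tuple[str, str], np.ndarray] = {}
    flagged: list[tuple[str, str]] = []
    for node_type in NODE_TYPES:
        for side in ("left", "right"):
            raw = node_activity_concat(params, node_type, side, dt)
            conv = convolve_gcamp(raw, GCAMP_TAU, dt)
            if np.ptp(conv) < 1e-9:
                flagged.append((node_type, side))
                continue
            regs[(node_type, side)] = minmax(conv)
    return regs, flagged


def classify_regression(
    trace: np.ndarray,
    regressors: dict[tuple[str, str], np.ndarray],
    thresholds: dict[str, float] | None = None,
) -> set[tuple[str, str]]:
    """Labels whose regressor correlates with the unity-normalized average
    trace above the node-class threshold (one-sided)."""
    thresholds = thresholds or REGRESSION_R_THRESHOLDS
    trace = np.asarray(trace, dtype=float)
    if np.ptp(trace) == 0:
        return set()
    norm = minmax(trace)
    labels = set()
    for (node_type, side), reg in regressors.items():
        r = pearsonr(norm, reg).statistic
        if r > thresholds.get(node_type, np.inf):
            labels.add((node_type, side))
    return labels


# ---------------------------------------------------------------------------
# SNR benchmark

BENCHMARK_TYPES = ("luminance_change", "luminance_integrator")


def snr_benchmark(
    params: ModelParams | None = None,
    sim_spec=None,
    n_rounds: int = 5,
    seed: int = 0,
    thresholds: ClassifierThresholds | None = None,
) -> pd.DataFrame:
    """Percent correctly labeled synthetic neurons per method, ground-truth
    type, noise scale and round.

    Ground truth covers leftward and rightward luminance change detectors
    and luminance integrators.  A neuron counts as correct when its true
    (type, side) is among the labels the classifier returns for its
    trial-averaged trace.
    """
    from .synth import CalciumSimSpec, simulate_calcium

    params = params or ModelParams()
    spec = sim_spec or CalciumSimSpec()
    rng = np.random.default_rng(seed)
    regressors, _ = build_regressors(params, spec.dt)
    sides_map = imaging_sides()
    n_bins = int(round(60.0 / spec.dt))

    activities = {
        (t, s): node_activity_concat(params, t, s, spec.dt)
        for t in BENCHMARK_TYPES for s in ("left", "right")
    }
    rows = []
    for noise in spec.noise_scales:
        for rnd in range(n_rounds):
            hits = {(m, t): 0 for m in ("logical", "regression")
                    for t in BENCHMARK_TYPES}
            totals = {t: 0 for t in BENCHMARK_TYPES}
            for (true_type, true_side), act in activities.items():
                traces = simulate_calcium(act, spec, noise, rng)
                avg = traces.mean(axis=1)  # over repeats
                totals[true_type] += len(avg)
                for tr in avg:
                    per_stim = {lab: tr[i * n_bins:(i + 1) * n_bins]
                                for i, lab in enumerate(IMAGING_LABELS)}
                    summ = summarize_windows(per_stim, spec.dt)
                    logical = classify_logical(summ, thresholds, sides=sides_map)
                    if (true_type, true_side) in logical:
                        hits[("logical", true_type)] += 1
                    regression = classify_regression(tr, regressors)
                    if (true_type, true_side) in regression:
                        hits[("regression", true_type)] += 1
            for method in ("logical", "regression"):
                for t in BENCHMARK_TYPES:
                    rows.append({
                        "method": method, "node_type": t,
                        "noise_scale": noise, "round": rnd,
                        "accuracy": 100.0 * hits[(method, t)] / totals[t],
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exponential rise fitting and condition distances

@dataclass(frozen=True)
class ExpFit:
    a: float
    tau: float
    b: float
    converged: bool = True


def fit_exponential(t: np.ndarray, y: np.ndarray) -> ExpFit:
    """Bounded fit of the saturating exponential a (1 - e^{-t/tau}) + b,
    from the canonical initial guess (1, 1, 0); a in [0, 100], tau in
    [0, 60], b in [-10, 10]."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)

    def f(tt, a, tau, b):
        return a * (1.0 - np.exp(-tt / max(tau, 1e-9))) + b

    try:
        popt, _ = curve_fit(f, t, y, p0=[1.0, 1.0, 0.0],
                            bounds=([0.0, 0.0, -10.0], [100.0, 60.0, 10.0]),
                            maxfev=20000)
    except RuntimeError:
        return ExpFit(np.nan, np.nan, np.nan, converged=False)
    return ExpFit(float(popt[0]), float(popt[1]), float(popt[2]), True)


TYPE_PAIRS = {
    "motion": ("c", "f"),
    "luminance": ("g", "h"),
    "congruent": ("a", "e"),
    "conflicting": ("b", "d"),
}


def condition_distance(
    trials: dict[str, np.ndarray],
    n_components: int = 3,
) -> pd.DataFrame:
    """Euclidean population distance between left and right trials of the
    same stimulus type in a shared 3D principal-component space.

    ``trials`` maps stimulus label -> array (n_neurons, n_trials, T).
    The PCA basis is fitted on trial-averaged population vectors across
    all stimuli and timepoints.  For each type, the left-right distance is
    the mean pairwise distance between left- and right-stimulus trial
    embeddings per timepoint; the control is the mean within-stimulus
    (same direction) pairwise distance.
    """
    from sklearn.decomposition import PCA

    for lab, arr in trials.items():
        if arr.shape[1] < 2:
            raise ValueError(f"stimulus {lab}: need >= 2 trials")
    labels = list(trials)
    avg = {lab: trials[lab].mean(axis=1) for lab in labels}  # (neurons, T)
    X = np.concatenate([avg[lab].T for lab in labels], axis=0)
    pca = PCA(n_components=n_components)
    pca.fit(X)

    def embed(arr: np.ndarray) -> np.ndarray:  # (trials, T, 3)
        n_neurons, n_trials, T = arr.shape
        flat = arr.transpose(1, 2, 0).reshape(n_trials * T, n_neurons)
        return pca.transform(flat).reshape(n_trials, T, -1)

    rows = []
    for type_name, (left_lab, right_lab) in TYPE_PAIRS.items():
        if left_lab not in trials or right_lab not in trials:
            continue
        e_l, e_r = embed(trials[left_lab]), embed(trials[right_lab])
        T = e_l.shape[1]
        d_lr = np.mean(
            [np.linalg.norm(e_l[i] - e_r[j], axis=1)
             for i in range(len(e_l)) for j in range(len(e_r))], axis=0)
        ctrl = []
        for e in (e_l, e_r):
            for i in range(len(e)):
                for j in range(i + 1, len(e)):
                    ctrl.append(np.linalg.norm(e[i] - e[j], axis=1))
        d_ctrl = np.mean(ctrl, axis=0)
        t = np.arange(T) * IMAGING_DT
        rows.append(pd.DataFrame({
            "type": type_name, "time": t,
            "distance_lr": d_lr, "distance_control": d_ctrl,
        }))
    return pd.concat(rows, ignore_index=True)
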