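"""Bout detection, filtering, binarization and choice metrics.

Bout tables are plain :class:`pandas.DataFrame` objects with one row per
bout and the columns listed in :data:`BOUT_COLUMNS`.  Times are seconds
relative to trial start; orientations are degrees; positions centimeters
(arena-centered).  The sign convention is fixed once for the whole package:
a positive orientation change is a leftward turn.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: column dictionary of a bout table (one row per bout)
BOUT_COLUMNS = [
    "fish_id",        # str/int fish identifier
    "trial_id",       # int trial index within fish
    "stimulus_id",    # str battery stimulus id
    "t_start",        # s, bout start (trial-relative)
    "t_end",          # s, bout end
    "x_start", "y_start", "x_end", "y_end",      # cm
    "orientation_start", "orientation_end",       # deg
    "delta_theta",    # deg, wrapped to (-180, 180]; positive = left turn
    "interbout_interval",  # s, start-to-start; NaN for a trial's first bout
    "distance",       # cm traveled during the bout
    "speed",          # cm/s, distance / bout duration
    "contour_area",   # px, max fish contour area during the bout
    "edge_distance",  # cm, distance from the dish edge at bout start
]

TURN_THRESHOLD_DEG = 2.0   # |delta| <= 2 deg is a forward bout, excluded
WINDOW_S = 2.0             # rolling choice window (trailing)
STEP_S = 0.1               # rolling window step

# bout-level exclusion rules (rule number -> description)
FILTER_RULES = {
    1: "interbout_interval > 10 s",
    2: "contour_area > 2000 px",
    3: "average speed > 1 cm/s",
    4: "|orientation change| > 150 deg",
    5: "within 0.25 cm of the dish edge",
}
#: rules counted as tracking errors for the trial-level drop (edge
#: proximity is an analysis exclusion, not a tracking error)
TRACKING_ERROR_RULES = (1, 2, 3, 4)
TRIAL_DROP_FRACTION = 0.05


def wrap_angle(deg: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(deg, float) + 180.0) % 360.0 - 180.0)


@dataclass
class OrientationTrace:
    """Raw tracking output for one trial (~90 Hz)."""

    time: np.ndarray          # s, strictly increasing
    orientation: np.ndarray   # deg
    x: np.ndarray             # cm
    y: np.ndarray             # cm
    contour_area: np.ndarray | None = None  # px
    arena_radius: float = 6.0  # cm

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for arr in (self.time, self.orientation, self.x, self.y):
            if not np.all(np.isfinite(arr)):
                raise ValueError("trace values must be finite")


def detect_bouts(
    trace: OrientationTrace,
    var_window_s: float = 0.05,
    start_threshold: float = 1.0,   # deg^2
    end_threshold: float = 0.5,     # deg^2
    start_dwell_s: float = 0.02,
    end_dwell_s: float = 0.05,
) -> pd.DataFrame:
    """Detect swim bouts from the orientation trace.

    A 50 ms rolling variance of orientation is thresholded with hysteresis:
    a bout starts once the variance has exceeded ``start_threshold`` for at
    least ``start_dwell_s`` and ends once it has stayed below
    ``end_threshold`` for at least ``end_dwell_s``.
    """
    t = trace.time
    fs = 1.0 / float(np.median(np.diff(t)))
    if fs < 50:
        raise ValueError("trace must be sampled at >= 50 Hz")
    nw = max(2, int(round(var_window_s * fs)))
    var = pd.Series(trace.orientation).rolling(nw, min_periods=nw).var().to_numpy()
    if len(t) < nw + 1:
        return pd.DataFrame(columns=BOUT_COLUMNS)

    n_start = max(1, int(round(start_dwell_s * fs)))
    n_end = max(1, int(round(end_dwell_s * fs)))
    above = var > start_threshold
    below = var < end_threshold

    bouts = []
    in_bout = False
    start_idx = 0
    run_above = 0
    run_below = 0
    for i in range(len(t)):
        if not in_bout:
            run_above = run_above + 1 if above[i] else 0
            if run_above >= n_start:
                in_bout = True
                # bout starts where the variance first exceeded threshold;
                # shift back by the variance window to the motion onset
                start_idx = max(0, i - run_above - nw + 2)
                run_below = 0
        else:
            run_below = run_below + 1 if below[i] else 0
            if run_below >= n_end:
                end_idx = max(start_idx + 1, i - run_below + 1)
                bouts.append((start_idx, end_idx))
                in_bout = False
                run_above = 0
    if in_bout:
        bouts.append((start_idx, len(t) - 1))

    rows = []
    prev_start_t = np.nan
    for s, e in bouts:
        dist = float(np.hypot(trace.x[e] - trace.x[s], trace.y[e] - trace.y[s]))
        dur = float(t[e] - t[s])
        r_start = float(np.hypot(trace.x[s], trace.y[s]))
        area = (float(np.max(trace.contour_area[s:e + 1]))
                if trace.contour_area is not None else np.nan)
        rows.append({
            "t_start": float(t[s]), "t_end": float(t[e]),
            "x_start": float(trace.x[s]), "y_start": float(trace.y[s]),
            "x_end": float(trace.x[e]), "y_end": float(trace.y[e]),
            "orientation_start": float(trace.orientation[s]),
            "orientation_end": float(trace.orientation[e]),
            "delta_theta": float(wrap_angle(trace.orientation[e] - trace.orientation[s])),
            "interbout_interval": float(t[s] - prev_start_t) if np.isfinite(prev_start_t) else np.nan,
            "distance": dist,
            "speed": dist / dur if dur > 0 else np.nan,
            "contour_area": area,
            "edge_distance": trace.arena_radius - r_start,
        })
        prev_start_t = t[s]
    df = pd.DataFrame(rows)
    for col in BOUT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[BOUT_COLUMNS]


def flag_bouts(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with one boolean column per exclusion rule."""
    out = table.copy()
    out["rule1"] = out["interbout_interval"] > 10.0
    out["rule2"] = out["contour_area"] > 2000.0
    out["rule3"] = out["speed"] > 1.0
    out["rule4"] = out["delta_theta"].abs() > 150.0
    out["rule5"] = out["edge_distance"] <= 0.25
    return out


def filter_bouts(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the five bout exclusion rules and the trial-level drop.

    A whole trial is dropped when more than 5 % of its bouts carry a
    tracking-error flag (rules 1-4).  Returns (kept bouts, dropped bouts
    annotated with the rule(s) that removed them, report dict).
    """
    if table.empty:
        return table.copy(), table.copy(), {
            "n_bouts": 0, "n_removed": 0, "n_trials": 0, "n_trials_dropped": 0,
            "removed_fraction": 0.0, "per_rule": {r: 0 for r in FILTER_RULES},
        }
    flagged = flag_bouts(table)
    rule_cols = [f"rule{r}" for r in FILTER_RULES]
    err_cols = [f"rule{r}" for r in TRACKING_ERROR_RULES]
    any_rule = flagged[rule_cols].any(axis=1)
    any_err = flagged[err_cols].any(axis=1)

    trial_keys = ["fish_id", "trial_id"]
    err_frac = flagged.assign(_err=any_err).groupby(trial_keys)["_err"].mean()
    dropped_trials = set(err_frac[err_frac > TRIAL_DROP_FRACTION].index)
    in_dropped = flagged.set_index(trial_keys).index.isin(dropped_trials)

    removed_mask = any_rule.to_numpy() | in_dropped
    removed = flagged.loc[removed_mask].copy()
    removed["removed_by"] = [
        ",".join([f"rule{r}" for r in FILTER_RULES if row[f"rule{r}"]]) or "trial_drop"
        for _, row in removed.iterrows()
    ]
    kept = flagged.loc[~removed_mask, table.columns].copy()

    report = {
        "n_bouts": int(len(table)),
        "n_removed": int(removed_mask.sum()),
        "removed_fraction": float(removed_mask.mean()),
        "n_trials": int(err_frac.size),
        "n_trials_dropped": int(len(dropped_trials)),
        "per_rule": {r: int(flagged[f"rule{r}"].sum()) for r in FILTER_RULES},
    }
    return kept, removed, report


def binarize(table: pd.DataFrame) -> pd.DataFrame:
    """Label each bout left / right / excluded from its orientation change.

    Positive orientation change (> 2 deg) is a left turn, negative below
    -2 deg a right turn; forward bouts in between are excluded.
    """
    out = table.copy()
    d = out["delta_theta"]
    out["turn"] = np.select(
        [d > TURN_THRESHOLD_DEG, d < -TURN_THRESHOLD_DEG],
        ["left", "right"], default="excluded",
    )
    return out


def _flip_turns(table: pd.DataFrame, flip_ids: set | None) -> pd.DataFrame:
    if not flip_ids:
        return table
    out = table.copy()
    m = out["stimulus_id"].isin(flip_ids)
    out.loc[m, "turn"] = out.loc[m, "turn"].map(
        {"left": "right", "right": "left", "excluded": "excluded"})
    return out


def percent_left_timecourse(
    table: pd.DataFrame,
    duration: float,
    flip_ids: set | None = None,
    window: float = WINDOW_S,
    step: float = STEP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage of leftward bouts in a trailing rolling window.

    Bouts from all trials/fish in ``table`` are pooled by trial-relative
    bout start time.  ``flip_ids`` lists stimulus ids whose left/right
    labels are mirrored first (rightward stimuli folded onto leftward
    ones).  Windows containing no binarized bout yield NaN.
    """
    left, total = window_counts(table, duration, flip_ids, window, step)
    t = np.arange(len(total)) * step
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * left / np.where(total > 0, total, 1), np.nan)
    return t, pct


def window_counts(
    table: pd.DataFrame,
    duration: float,
    flip_ids: set | None = None,
    window: float = WINDOW_S,
    step: float = STEP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window counts of leftward and of all binarized bouts on the
    rolling grid; building block of the percent-left timecourse that also
    lets callers pool counts across groups before taking the ratio."""
    tab = _flip_turns(table, flip_ids)
    tab = tab[tab["turn"].isin(["left", "right"])]
    n_steps = int(round(duration / step)) + 1
    nwin = max(1, int(round(window / step)))
    edges = (np.arange(n_steps + 1) - 0.5) * step
    counts_l = np.histogram(tab.loc[tab["turn"] == "left", "t_start"], bins=edges)[0]
    counts_a = np.histogram(tab["t_start"], bins=edges)[0]

    def trail(c):
        cs = np.concatenate(([0], np.cumsum(c)))
        idx = np.arange(1, n_steps + 1)
        lo = np.maximum(idx - nwin, 0)
        return cs[idx] - cs[lo]

    return trail(counts_l).astype(float), trail(counts_a).astype(float)


def steady_state_percent(
    table: pd.DataFrame,
    stim_end: float,
    flip_ids: set | None = None,
    window: float = 10.0,
) -> pd.Series:
    """Per-fish percentage of leftward bouts in the last ``window`` seconds
    of the stimulus ([stim_end - window, stim_end)).  Fish without
    binarized bouts in the window are NaN (missing, not 0)."""
    tab = _flip_turns(table, flip_ids)
    tab = tab[tab["turn"].isin(["left", "right"])]
    tab = tab[(tab["t_start"] >= stim_end - window) & (tab["t_start"] < stim_end)]
    if tab.empty:
        return pd.Series(dtype=float, name="percent_left")
    g = tab.groupby("fish_id")["turn"]
    out = 100.0 * g.apply(lambda s: (s == "left").mean())
    out.name = "percent_left"
    return out


def category_metrics(
    table: pd.DataFrame,
    categories: dict,
    flip_ids: set | None = None,
    stim_window: tuple[float, float] = (10.0, 40.0),
    steady_window: float = 10.0,
) -> pd.DataFrame:
    """Per-fish following percentage and relative interbout interval per
    stimulus category (M, L, M=L, M!=L).

    ``categories`` maps stimulus_id -> category.  Following percentage is
    the percent of bouts toward the stimulus (after mirroring the
    rightward stimuli listed in ``flip_ids``) in the last ``steady_window``
    seconds of the stimulus.  The relative IBI is the mean interbout
    interval of stimulus-phase bouts per category minus the across-category
    mean per fish; with a single category it is 0 by construction.
    """
    tab = _flip_turns(binarize(table) if "turn" not in table.columns else table,
                      flip_ids)
    tab = tab[tab["stimulus_id"].isin(categories)]
    tab = tab.assign(category=tab["stimulus_id"].map(categories))
    t0, t1 = stim_window

    rows = []
    for (fish, cat), grp in tab.groupby(["fish_id", "category"]):
        steady = grp[(grp["t_start"] >= t1 - steady_window) & (grp["t_start"] < t1)]
        steady = steady[steady["turn"].isin(["left", "right"])]
        pct = 100.0 * (steady["turn"] == "left").mean() if len(steady) else np.nan
        stim_bouts = grp[(grp["t_start"] >= t0) & (grp["t_start"] < t1)]
        ibi = stim_bouts["interbout_interval"].dropna()
        rows.append({"fish_id": fish, "category": cat,
                     "percent_following": pct,
                     "mean_ibi": float(ibi.mean()) if len(ibi) else np.nan})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["relative_ibi"] = out["mean_ibi"] - out.groupby("fish_id")["mean_ibi"].transform("mean")
    out["n_categories"] = out.groupby("fish_id")["category"].transform("nunique")
    out["flagged_single_category"] = out["n_categories"] == 1
    return out.drop(columns="n_categories")
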