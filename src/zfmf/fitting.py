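"""Cross-validated fitting of the seven network-model parameters.

The protocol fits the model's left-swim timecourse (x100, percent scale)
to observed percent-left rolling timecourses pooled over fish, per
stimulus.  The data are first split 50/50 into training and validation
groups — either all single-feature stimuli train and all combinations
validate ("unifeature" mode), or half the fish train across all stimulus
types ("multifeature" mode).  Each of the (default 25) training rounds
splits the training group's fish 2/3 train : 1/3 test, draws (default 5)
random restarts — each restart subsamples (default 20) stimuli as the
fitting target and a uniform-random initial guess inside the bounds
(tau in [0.1, 100] s, w in [0.1, 25]) — runs bounded least squares, and
keeps the restart with the best test MSE.  Validating the resulting
parameter sets on the validation group gives one MSE per round.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import behavior
from .model import ModelParams, swims_left_batch
from .stimulus import render_timeseries, CLASS_M, CLASS_L
from .synth import Cohort


@dataclass(frozen=True)
class FitProtocol:
    n_rounds: int = 25
    n_restarts: int = 5
    n_combo_draws: int = 20
    tau_bounds: tuple[float, float] = (0.1, 100.0)
    w_bounds: tuple[float, float] = (0.1, 25.0)
    split_mode: str = "multifeature"  # or "unifeature"
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    max_nfev: int = 60  # residual-evaluation budget per restart

    def __post_init__(self) -> None:
        if min(self.n_rounds, self.n_restarts, self.n_combo_draws) < 1:
            raise ValueError("counts must be >= 1")
        if self.tau_bounds[0] <= 0 or self.w_bounds[0] <= 0:
            raise ValueError("bounds must be positive")
        if self.split_mode not in ("multifeature", "unifeature"):
            raise ValueError("split_mode must be multifeature or unifeature")


@dataclass
class FitResult:
    """One parameter set per round (best-of-restarts), with MSE scores."""

    params_per_round: list[ModelParams]
    test_mses: list[float]
    free_names: tuple[str, ...]
    flagged_rounds: list[int] = field(default_factory=list)
    validation_mses: list[float] | None = None

    @property
    def median_params(self) -> ModelParams:
        ok = [p for i, p in enumerate(self.params_per_round)
              if i not in self.flagged_rounds]
        base = ok[0]
        med = {name: float(np.median([getattr(p, name) for p in ok]))
               for name in self.free_names}
        return replace(base, **med)

    def to_dict(self) -> dict:
        return {
            "free_names": list(self.free_names),
            "params_per_round": [p.to_dict() for p in self.params_per_round],
            "test_mses": self.test_mses,
            "validation_mses": self.validation_mses,
            "flagged_rounds": self.flagged_rounds,
            "median_params": self.median_params.to_dict(),
        }


class CohortDataset:
    """Fitting view of a cohort: per-(fish, stimulus) rolling window counts
    and rendered stimulus channels, precomputed once.

    Pooled observed timecourses are ratios of summed counts, so pooling
    over any fish subset is cheap inside the protocol's inner loops.
    """

    def __init__(self, cohort: Cohort, dt: float = 0.1):
        self.dt = dt
        self.entries = {e.stimulus_id: e for e in cohort.entries}
        self.fish_ids = cohort.fish_ids
        self.stimulus_ids = [e.stimulus_id for e in cohort.entries]
        self._channels: dict[str, dict[str, np.ndarray]] = {}
        self._n_steps: dict[str, int] = {}
        self._counts: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

        bouts = behavior.binarize(cohort.bouts)
        for sid, e in self.entries.items():
            ts = render_timeseries(e.spec, dt)
            self._channels[sid] = ts.channels()
            self._n_steps[sid] = len(ts.t)
        for (fid, sid), grp in bouts.groupby(["fish_id", "stimulus_id"]):
            dur = (self._n_steps[sid] - 1) * dt
            left, tot = behavior.window_counts(
                grp, duration=dur, window=behavior.WINDOW_S, step=dt)
            self._counts[(fid, sid)] = (left[: self._n_steps[sid]],
                                        tot[: self._n_steps[sid]])

    def observed_percent(self, fish_ids, stimulus_ids) -> dict[str, np.ndarray]:
        """Pooled percent-left timecourse per stimulus (NaN where empty)."""
        out = {}
        for sid in stimulus_ids:
            n = self._n_steps[sid]
            left = np.zeros(n)
            tot = np.zeros(n)
            for fid in fish_ids:
                lc, tc = self._counts.get((fid, sid), (None, None))
                if lc is not None:
                    left += lc
                    tot += tc
            with np.errstate(invalid="ignore", divide="ignore"):
                out[sid] = np.where(tot > 0, 100.0 * left / np.where(tot > 0, tot, 1),
                                    np.nan)
        return out

    def predict_percent(self, params: ModelParams, stimulus_ids) -> dict[str, np.ndarray]:
        """Model percent-left per stimulus, batched by grid length."""
        by_len: dict[int, list[str]] = {}
        for sid in stimulus_ids:
            by_len.setdefault(self._n_steps[sid], []).append(sid)
        out: dict[str, np.ndarray] = {}
        for T, sids in by_len.items():
            stacks = {k: np.stack([self._channels[s][k] for s in sids])
                      for k in ("motion_left", "motion_right",
                                "luminance_left", "luminance_right")}
            swims = swims_left_batch(
                stacks["motion_left"], stacks["motion_right"],
                stacks["luminance_left"], stacks["luminance_right"],
                self.dt, params)
            for i, s in enumerate(sids):
                out[s] = 100.0 * swims[i]
        return out

    def mse(self, params: ModelParams, fish_ids, stimulus_ids) -> float:
        obs = self.observed_percent(fish_ids, stimulus_ids)
        pred = self.predict_percent(params, stimulus_ids)
        errs = []
        for sid in stimulus_ids:
            d = pred[sid] - obs[sid]
            d = d[np.isfinite(d)]
            if len(d):
                errs.append(np.mean(d ** 2))
        return float(np.mean(errs)) if errs else np.nan


def split_dataset(
    dataset: CohortDataset, mode: str, seed: int = 0
) -> tuple[tuple[list, list], tuple[list, list]]:
    """50/50 training/validation split as (fish_ids, stimulus_ids) views.

    ``unifeature``: all single-feature stimuli (classes M and L) train,
    all combination stimuli validate; every fish appears in both.
    ``multifeature``: fish split in half at random, all stimuli in both.
    """
    rng = np.random.default_rng(seed)
    if mode == "unifeature":
        uni = [s for s in dataset.stimulus_ids
               if dataset.entries[s].class_label in (CLASS_M, CLASS_L)]
        multi = [s for s in dataset.stimulus_ids if s not in set(uni)]
        if not uni or not multi:
            raise ValueError("unifeature split needs both single-feature and "
                             "combination stimuli")
        return (list(dataset.fish_ids), uni), (list(dataset.fish_ids), multi)
    if mode == "multifeature":
        fish = list(dataset.fish_ids)
        order = rng.permutation(len(fish))
        half = len(fish) // 2
        train = [fish[i] for i in order[:half]]
        val = [fish[i] for i in order[half:]]
        return (train, list(dataset.stimulus_ids)), (val, list(dataset.stimulus_ids))
    raise ValueError("mode must be 'unifeature' or 'multifeature'")


def _bounds_for(names, protocol: FitProtocol) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for n in names:
        b = protocol.w_bounds if n.startswith("w_") else protocol.tau_bounds
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


def _fit_once(
    dataset: CohortDataset,
    base: ModelParams,
    names,
    x0: np.ndarray,
    fish_ids,
    stimulus_ids,
    protocol: FitProtocol,
) -> ModelParams:
    obs = dataset.observed_percent(fish_ids, stimulus_ids)
    masks = {s: np.isfinite(obs[s]) for s in stimulus_ids}
    target = np.concatenate([obs[s][masks[s]] for s in stimulus_ids])
    lo, hi = _bounds_for(names, protocol)

    def residual(x):
        p = replace(base, **dict(zip(names, x)))
        pred = dataset.predict_percent(p, stimulus_ids)
        return np.concatenate([pred[s][masks[s]] for s in stimulus_ids]) - target

    res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                        max_nfev=protocol.max_nfev)
    return replace(base, **dict(zip(names, res.x)))


def run_protocol(
    dataset: CohortDataset,
    fish_ids,
    stimulus_ids,
    protocol: FitProtocol,
    base_params: ModelParams | None = None,
) -> FitResult:
    """The cross-validated training rounds on one training group.

    ``base_params`` fixes non-free parameters (e.g. a silenced pathway's
    weight at 0, which also removes its time constant from the free set).
    """
    base = base_params if base_params is not None else ModelParams()
    names = base.free_names()
    rng = np.random.default_rng(protocol.seed)
    fish_ids = list(fish_ids)
    stimulus_ids = list(stimulus_ids)

    params_rounds: list[ModelParams] = []
    test_mses: list[float] = []
    flagged: list[int] = []
    lo, hi = _bounds_for(names, protocol)
    for r in range(protocol.n_rounds):
        order = rng.permutation(len(fish_ids))
        n_train = max(1, int(round(protocol.train_fraction * len(fish_ids))))
        train = [fish_ids[i] for i in order[:n_train]]
        test = [fish_ids[i] for i in order[n_train:]] or train

        best: tuple[float, ModelParams] | None = None
        for _ in range(protocol.n_restarts):
            k = min(protocol.n_combo_draws, len(stimulus_ids))
            combo = list(rng.choice(stimulus_ids, size=k, replace=False))
            x0 = rng.uniform(lo, hi)
            try:
                fitted = _fit_once(dataset, base, names, x0, train, combo, protocol)
            except Exception:
                continue
            mse = dataset.mse(fitted, test, stimulus_ids)
            if np.isfinite(mse) and (best is None or mse < best[0]):
                best = (mse, fitted)
        if best is None:
            flagged.append(r)
            params_rounds.append(base)
            test_mses.append(np.nan)
        else:
            params_rounds.append(best[1])
            test_mses.append(best[0])
    return FitResult(params_per_round=params_rounds, test_mses=test_mses,
                     free_names=names, flagged_rounds=flagged)


def validate(result: FitResult, dataset: CohortDataset, fish_ids, stimulus_ids) -> list[float]:
    """Per-round MSE of the fitted parameter sets on the validation group."""
    mses = [dataset.mse(p, fish_ids, stimulus_ids)
            for p in result.params_per_round]
    result.validation_mses = mses
    return mses


ABLATION_CONDITIONS = ("full", "no_lum_change", "no_lum_level", "no_motion")
_ABLATION_PATHWAY = {"no_lum_change": "lum_change", "no_lum_level": "lum_level",
                     "no_motion": "motion"}


def ablation_eval(
    dataset: CohortDataset, protocol: FitProtocol
) -> dict[str, dict]:
    """Refit with each pathway silenced and compare validation MSEs.

    Each condition fixes the silenced weight at 0 (removing its time
    constant from the free set), reruns the full protocol on the training
    group, and reports the validation MSE distribution.
    """
    from .model import silence_pathway

    (train_f, train_s), (val_f, val_s) = split_dataset(
        dataset, protocol.split_mode, protocol.seed)
    out = {}
    for cond in ABLATION_CONDITIONS:
        base = ModelParams()
        if cond != "full":
            base = silence_pathway(base, _ABLATION_PATHWAY[cond])
        result = run_protocol(dataset, train_f, train_s, protocol, base_params=base)
        mses = validate(result, dataset, val_f, val_s)
        ok = [m for i, m in enumerate(mses) if i not in result.flagged_rounds]
        out[cond] = {
            "validation_mses": mses,
            "median_mse": float(np.median(ok)) if ok else np.nan,
            "result": result,
        }
    return out
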