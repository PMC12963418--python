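"""End-to-end pipeline orchestration from one YAML configuration.

A run config lists stages (``battery``, ``cohort``, ``fit``, ``ablation``,
``benchmark``, ``report``) with their settings, a global seed and an output
directory.  Stages execute in dependency order; every artifact is written
with a content hash into a manifest, and a completed stage whose inputs are
unchanged is skipped on re-run (hash-checked idempotence).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior
from .model import ModelParams
from .stimulus import (BatteryConfig, behavior_battery, battery_to_manifest,
                       battery_from_manifest)
from .synth import CohortSpec, CalciumSimSpec, generate_cohort
from .fitting import (CohortDataset, FitProtocol, run_protocol, split_dataset,
                      validate, ablation_eval)

STAGES = ("battery", "cohort", "fit", "ablation", "benchmark", "report")


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage executes)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _filter_kwargs(cls, d: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    bad = set(d) - names
    if bad:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(bad)}")
    return d


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    stages = cfg.get("stages")
    if not stages or not isinstance(stages, list):
        raise ConfigError("config must list 'stages'")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    order = [s for s in STAGES if s in stages]
    needs = {"cohort": "battery", "fit": "cohort", "ablation": "cohort"}
    for s in order:
        dep = needs.get(s)
        if dep and dep not in order:
            raise ConfigError(f"stage '{s}' requires stage '{dep}'")
    cfg["stages"] = order
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "zfmf_run")
    return cfg


class Runner:
    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.out = Path(cfg["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(cfg["seed"])
        self.manifest_path = self.out / "manifest.json"
        self.manifest = {"config": cfg, "artifacts": {}, "failures": {}}
        if self.manifest_path.exists():
            try:
                prev = json.loads(self.manifest_path.read_text())
                if prev.get("config") == cfg:
                    self.manifest = prev
            except json.JSONDecodeError:
                pass

    def _record(self, stage: str, path: Path) -> None:
        self.manifest["artifacts"][path.name] = {
            "stage": stage, "path": str(path), "sha256": _sha256(path),
        }

    def _done(self, *names: str) -> bool:
        arts = self.manifest["artifacts"]
        return all(
            n in arts and Path(arts[n]["path"]).exists()
            and _sha256(Path(arts[n]["path"])) == arts[n]["sha256"]
            for n in names
        )

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def run(self) -> dict:
        import sys
        for stage in self.cfg["stages"]:
            t0 = time.time()
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:  # record and stop: later stages depend on it
                self.manifest["failures"][stage] = repr(exc)
                self._save_manifest()
                raise
            print(f"[zfmf] stage {stage}: {time.time() - t0:.1f} s "
                  f"(seed {self.seed})", file=sys.stderr)
            self._save_manifest()
        return self.manifest

    # -- stages -----------------------------------------------------------

    def stage_battery(self) -> None:
        if self._done("battery.csv"):
            return
        kw = _filter_kwargs(BatteryConfig, dict(self.cfg.get("battery", {})))
        kw.setdefault("seed", self.seed)
        entries = behavior_battery(BatteryConfig(**kw))
        path = self.out / "battery.csv"
        battery_to_manifest(entries).to_csv(path, index=False)
        self._record("battery", path)

    def stage_cohort(self) -> None:
        if self._done("cohort_bouts.csv", "cohort_truth.json"):
            return
        entries = battery_from_manifest(
            pd.read_csv(self.manifest["artifacts"]["battery.csv"]["path"]))
        kw = dict(self.cfg.get("cohort", {}))
        params = ModelParams(**kw.pop("params", {}))
        kw = _filter_kwargs(CohortSpec, kw)
        kw.setdefault("seed", self.seed + 1)
        cohort = generate_cohort(CohortSpec(params=params, **kw), entries)
        bouts_path = self.out / "cohort_bouts.csv"
        cohort.bouts.to_csv(bouts_path, index=False)
        truth_path = self.out / "cohort_truth.json"
        truth_path.write_text(json.dumps(
            {f: p.to_dict() for f, p in cohort.fish_params.items()}, indent=2))
        self._record("cohort", bouts_path)
        self._record("cohort", truth_path)
        self._cohort = cohort

    def _dataset(self) -> CohortDataset:
        if not hasattr(self, "_cohort"):
            entries = battery_from_manifest(
                pd.read_csv(self.manifest["artifacts"]["battery.csv"]["path"]))
            bouts = pd.read_csv(self.manifest["artifacts"]["cohort_bouts.csv"]["path"])
            truth = json.loads(
                Path(self.manifest["artifacts"]["cohort_truth.json"]["path"]).read_text())
            from .synth import Cohort
            self._cohort = Cohort(
                entries=entries, bouts=bouts,
                fish_params={f: ModelParams(**d) for f, d in truth.items()},
                spec=CohortSpec())
        return CohortDataset(self._cohort)

    def stage_fit(self) -> None:
        if self._done("fit.json"):
            return
        kw = _filter_kwargs(FitProtocol, dict(self.cfg.get("fit", {})))
        kw.setdefault("seed", self.seed + 2)
        protocol = FitProtocol(**kw)
        ds = self._dataset()
        (tf, ts), (vf, vs) = split_dataset(ds, protocol.split_mode, protocol.seed)
        result = run_protocol(ds, tf, ts, protocol)
        validate(result, ds, vf, vs)
        path = self.out / "fit.json"
        path.write_text(json.dumps(result.to_dict(), indent=2))
        self._record("fit", path)

    def stage_ablation(self) -> None:
        if self._done("ablation.json"):
            return
        kw = _filter_kwargs(FitProtocol, dict(self.cfg.get("ablation", {})))
        kw.setdefault("seed", self.seed + 3)
        out = ablation_eval(self._dataset(), FitProtocol(**kw))
        path = self.out / "ablation.json"
        path.write_text(json.dumps(
            {c: {"median_mse": v["median_mse"],
                 "validation_mses": v["validation_mses"]}
             for c, v in out.items()}, indent=2))
        self._record("ablation", path)

    def stage_benchmark(self) -> None:
        if self._done("benchmark.csv"):
            return
        from .neural import snr_benchmark
        kw = dict(self.cfg.get("benchmark", {}))
        n_rounds = int(kw.pop("n_rounds", 5))
        if "noise_scales" in kw:
            kw["noise_scales"] = tuple(kw["noise_scales"])
        kw = _filter_kwargs(CalciumSimSpec, kw)
        spec = CalciumSimSpec(**kw)
        df = snr_benchmark(sim_spec=spec, n_rounds=n_rounds, seed=self.seed + 4)
        path = self.out / "benchmark.csv"
        df.to_csv(path, index=False)
        self._record("benchmark", path)

    def stage_report(self) -> None:
        path = self.out / "report.txt"
        path.write_text(report(self.manifest))
        self._record("report", path)


def run(config_path: str | Path) -> dict:
    """Execute a run config; returns the artifact manifest."""
    return Runner(load_config(config_path)).run()


def report(manifest: dict) -> str:
    """Deterministic human-readable summary of a run's artifacts."""
    lines = ["zfmf run report", "=" * 40]
    arts = manifest.get("artifacts", {})
    if not arts:
        lines.append("warning: no artifacts in manifest")
    if "fit.json" in arts:
        fit = json.loads(Path(arts["fit.json"]["path"]).read_text())
        lines.append("\nFitted parameters (median over rounds; spread = IQR):")
        per_round = fit["params_per_round"]
        for name in fit["free_names"]:
            vals = np.array([p[name] for p in per_round])
            q1, q3 = np.percentile(vals, [25, 75])
            lines.append(f"  {name:8s} median={np.median(vals):8.3f} "
                         f"IQR=[{q1:.3f}, {q3:.3f}]")
        if fit.get("validation_mses"):
            lines.append(f"  validation MSE median="
                         f"{np.median(fit['validation_mses']):.2f}")
    else:
        lines.append("fit results: absent")
    if "ablation.json" in arts:
        abl = json.loads(Path(arts["ablation.json"]["path"]).read_text())
        lines.append("\nAblation validation MSEs (median):")
        for cond, v in abl.items():
            lines.append(f"  {cond:15s} {v['median_mse']:8.2f}")
    else:
        lines.append("ablation results: absent")
    if "benchmark.csv" in arts:
        df = pd.read_csv(arts["benchmark.csv"]["path"])
        lines.append("\nClassifier accuracy vs noise (mean over rounds, %):")
        tab = (df.groupby(["method", "node_type", "noise_scale"])["accuracy"]
                 .mean().round(1))
        lines.append(tab.to_string())
    else:
        lines.append("benchmark results: absent")
    return "\n".join(lines) + "\n"
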