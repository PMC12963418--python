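"""Abstract visual stimuli as four-channel time series.

A stimulus is described by a :class:`StimulusSpec` (which side moves, at what
coherence; which side is bright; background brightness; phase durations) and
rendered onto a uniform time grid as a :class:`StimulusTimeSeries` with four
channels: ``motion_left``, ``motion_right``, ``luminance_left`` and
``luminance_right``, all fractions in [0, 1].  These channels are the only
sensory input the network model sees.

Conventions
-----------
* Left/right are fish-centric.  Downstream mirroring of behavioral data
  happens in the behavior module, never here.
* A lateral luminance cue sets the bright hemifield's channel to
  ``bright_level`` and the dark hemifield's to ``dark_level``; a homogeneous
  background sets both channels to ``background_level``.
* The two motion channels are mutually exclusive: at most one is nonzero at
  any time.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Iterable

import numpy as np
import pandas as pd

SIDES = ("left", "right", "off")

CLASS_M = "M"
CLASS_L = "L"
CLASS_CONGRUENT = "M=L"
CLASS_CONFLICT = "M!=L"
CLASS_CONTROL = "control"
CLASSES = (CLASS_M, CLASS_L, CLASS_CONGRUENT, CLASS_CONFLICT)

#: canonical labels of the 3x3 imaging stimulus grid, row-major
#: motion {left, right, off} x luminance {left, right, off}
IMAGING_LABELS = tuple("abcdefghi")


def _opposite(side: str) -> str:
    return {"left": "right", "right": "left", "off": "off"}[side]


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus: phases pre / stim / post, a motion cue and a luminance cue.

    ``coherence`` is the fraction of coherently moving dots (motion strength);
    ``background_level`` the normalized homogeneous background brightness
    (0 = black, 0.5 = gray, 1 = white).  ``bright_level``/``dark_level`` give
    the normalized brightness of the two hemifields while a lateral cue is on.
    """

    motion_side: str = "off"
    coherence: float = 0.0
    lum_side: str = "off"
    background_level: float = 0.5
    pre_dur: float = 10.0
    stim_dur: float = 30.0
    post_dur: float = 10.0
    bright_level: float = 1.0
    dark_level: float = 0.0

    def __post_init__(self) -> None:
        if self.motion_side not in SIDES or self.lum_side not in SIDES:
            raise ValueError(f"sides must be in {SIDES}")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must be in [0, 1]")
        if self.motion_side == "off" and self.coherence != 0.0:
            raise ValueError("coherence must be 0 when motion is off")
        for name in ("background_level", "bright_level", "dark_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("pre_dur", "stim_dur", "post_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def class_label(self) -> str:
        has_m = self.motion_side != "off" and self.coherence > 0
        has_l = self.lum_side != "off"
        if has_m and has_l:
            return CLASS_CONGRUENT if self.motion_side == self.lum_side else CLASS_CONFLICT
        if has_m:
            return CLASS_M
        if has_l:
            return CLASS_L
        return CLASS_CONTROL

    @property
    def total_dur(self) -> float:
        return self.pre_dur + self.stim_dur + self.post_dur

    def mirrored(self) -> "StimulusSpec":
        """Swap left and right for both cues."""
        return replace(
            self,
            motion_side=_opposite(self.motion_side),
            lum_side=_opposite(self.lum_side),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "StimulusSpec":
        return cls(**json.loads(s))


@dataclass
class StimulusTimeSeries:
    """The four stimulus channels on a uniform time grid with step ``dt``."""

    dt: float
    t: np.ndarray
    motion_left: np.ndarray
    motion_right: np.ndarray
    luminance_left: np.ndarray
    luminance_right: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for ch in self.channels().values():
            if len(ch) != n:
                raise ValueError("all channels must share the time grid")
            if np.any(ch < -1e-12) or np.any(ch > 1 + 1e-12):
                raise ValueError("channel values must lie in [0, 1]")
        if np.any(self.motion_left * self.motion_right != 0):
            raise ValueError("motion channels must be mutually exclusive")

    def channels(self) -> dict[str, np.ndarray]:
        return {
            "motion_left": self.motion_left,
            "motion_right": self.motion_right,
            "luminance_left": self.luminance_left,
            "luminance_right": self.luminance_right,
        }

    def mirrored(self) -> "StimulusTimeSeries":
        return StimulusTimeSeries(
            dt=self.dt,
            t=self.t,
            motion_left=self.motion_right.copy(),
            motion_right=self.motion_left.copy(),
            luminance_left=self.luminance_right.copy(),
            luminance_right=self.luminance_left.copy(),
        )


def render_timeseries(spec: StimulusSpec, dt: float) -> StimulusTimeSeries:
    """Render a spec onto a uniform grid of step ``dt`` covering [0, total).

    The stimulus window is [pre, pre + stim).  Motion channels are zero
    outside the window and equal to the coherence on the moving side inside
    it.  Luminance channels sit at the background level outside the window;
    inside it, the bright side carries ``bright_level`` and the dark side
    ``dark_level`` (both stay at background when the luminance cue is off).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = int(round(spec.total_dur / dt))
    t = np.arange(n) * dt
    in_stim = (t >= spec.pre_dur - 1e-9) & (t < spec.pre_dur + spec.stim_dur - 1e-9)

    motion = {"left": np.zeros(n), "right": np.zeros(n)}
    if spec.motion_side != "off":
        motion[spec.motion_side][in_stim] = spec.coherence

    lum = {
        "left": np.full(n, spec.background_level),
        "right": np.full(n, spec.background_level),
    }
    if spec.lum_side != "off":
        lum[spec.lum_side][in_stim] = spec.bright_level
        lum[_opposite(spec.lum_side)][in_stim] = spec.dark_level

    return StimulusTimeSeries(
        dt=dt,
        t=t,
        motion_left=motion["left"],
        motion_right=motion["right"],
        luminance_left=lum["left"],
        luminance_right=lum["right"],
    )


@dataclass(frozen=True)
class BatteryConfig:
    """Composition of the 40-stimulus behavioral battery.

    The main text fixes the total (40) and the four-class structure; the
    per-class variants (coherence levels, background levels) are
    configurable.  Defaults give 10 stimuli per class: both sides crossed
    with three coherence levels on gray background plus black/white
    background variants at the reference 25 % coherence.
    """

    n_per_class: int = 10
    coherences: tuple[float, ...] = (0.25, 0.5, 1.0)
    backgrounds: tuple[float, ...] = (0.0, 1.0)
    pre_dur: float = 10.0
    stim_dur: float = 30.0
    post_dur: float = 10.0
    seed: int = 0

    @property
    def total(self) -> int:
        return 4 * self.n_per_class


@dataclass(frozen=True)
class BatteryEntry:
    """A battery member: id, spec and its train/test tags for both splits."""

    stimulus_id: str
    spec: StimulusSpec
    split_multifeature: str  # "train" | "test"
    split_unifeature: str

    @property
    def class_label(self) -> str:
        return self.spec.class_label


#: lateral-cue semicircle pairs as (bright_level, dark_level, background):
#: black-and-white on gray, gray-and-white on white, black-and-gray on
#: black, plus black-and-white cues breaking a white or black background
LUM_VARIANTS = (
    (1.0, 0.0, 0.5),
    (1.0, 0.6, 1.0),
    (0.6, 0.0, 0.0),
    (1.0, 0.0, 1.0),
    (1.0, 0.0, 0.0),
)


def _class_variants(config: BatteryConfig, cls: str) -> list[StimulusSpec]:
    """Per-class stimulus variants; exactly ``n_per_class`` members."""
    base = dict(pre_dur=config.pre_dur, stim_dur=config.stim_dur, post_dur=config.post_dur)
    specs: list[StimulusSpec] = []
    ref_coh = config.coherences[0]
    for side in ("left", "right"):
        other = _opposite(side)
        if cls == CLASS_M:
            for c in config.coherences:
                specs.append(StimulusSpec(motion_side=side, coherence=c,
                                          background_level=0.5, **base))
            for bg in config.backgrounds:
                specs.append(StimulusSpec(motion_side=side, coherence=ref_coh,
                                          background_level=bg, **base))
        elif cls == CLASS_L:
            for bright, dark, bg in LUM_VARIANTS:
                specs.append(StimulusSpec(lum_side=side, background_level=bg,
                                          bright_level=bright, dark_level=dark,
                                          **base))
        else:
            lum_side = side if cls == CLASS_CONGRUENT else other
            bw = LUM_VARIANTS[0]
            for c in config.coherences:
                specs.append(StimulusSpec(motion_side=side, coherence=c,
                                          lum_side=lum_side,
                                          background_level=bw[2],
                                          bright_level=bw[0], dark_level=bw[1],
                                          **base))
            for bright, dark, bg in LUM_VARIANTS[1:3]:
                specs.append(StimulusSpec(motion_side=side, coherence=ref_coh,
                                          lum_side=lum_side,
                                          background_level=bg,
                                          bright_level=bright, dark_level=dark,
                                          **base))
    if len(specs) != config.n_per_class:
        raise ValueError(
            f"class {cls}: {len(specs)} variants != n_per_class={config.n_per_class}"
        )
    return specs


def behavior_battery(config: BatteryConfig | None = None) -> list[BatteryEntry]:
    """The behavioral stimulus battery with train/test tags for both splits.

    The multifeature split assigns half of every class to training and half
    to testing (20/20 by default).  The unifeature split puts all
    single-feature stimuli (classes M and L) in training and all
    combinations in testing.  Assignment within a class is a seeded shuffle,
    reproducible bit-for-bit.
    """
    config = config or BatteryConfig()
    rng = np.random.default_rng(config.seed)
    entries: list[BatteryEntry] = []
    count = 0
    for cls in CLASSES:
        specs = _class_variants(config, cls)
        order = rng.permutation(len(specs))
        half = len(specs) // 2
        for rank, idx in enumerate(order):
            uni = "train" if cls in (CLASS_M, CLASS_L) else "test"
            entries.append(BatteryEntry(
                stimulus_id=f"s{count + idx:02d}",
                spec=specs[idx],
                split_multifeature="train" if rank < half else "test",
                split_unifeature=uni,
            ))
        count += len(specs)
    entries.sort(key=lambda e: e.stimulus_id)
    if len(entries) != config.total:
        raise ValueError("battery size mismatch")
    return entries


def imaging_set() -> dict[str, StimulusSpec]:
    """The nine imaging stimuli a-i: motion {left, right, off} x luminance
    {left, right, off}, each 10 s pre / 30 s stim / 20 s post.

    Brightness encoding follows the measured projector levels of the imaging
    setup (bright : background : dark = 4 : 2 : 1 in lux), normalized to
    bright = 1.0, background = 0.5, dark = 0.25.  Stimulus ``i`` (motion off,
    luminance off) is the control: flat background, 0 % coherence.
    """
    out: dict[str, StimulusSpec] = {}
    labels = iter(IMAGING_LABELS)
    for m_side in ("left", "right", "off"):
        for l_side in ("left", "right", "off"):
            out[next(labels)] = StimulusSpec(
                motion_side=m_side,
                coherence=1.0 if m_side != "off" else 0.0,
                lum_side=l_side,
                background_level=0.5,
                bright_level=1.0,
                dark_level=0.25,
                pre_dur=10.0,
                stim_dur=30.0,
                post_dur=20.0,
            )
    return out


def imaging_sides() -> dict[str, tuple[str, str]]:
    """Map imaging label -> (motion_side, lum_side), for the classifiers."""
    return {k: (v.motion_side, v.lum_side) for k, v in imaging_set().items()}


MANIFEST_COLUMNS = [
    "stimulus_id", "class", "motion_side", "coherence", "lum_side",
    "background", "bright_level", "dark_level", "pre", "stim", "post",
    "split_multifeature", "split_unifeature",
]


def battery_to_manifest(entries: Iterable[BatteryEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        s = e.spec
        rows.append({
            "stimulus_id": e.stimulus_id, "class": s.class_label,
            "motion_side": s.motion_side, "coherence": s.coherence,
            "lum_side": s.lum_side, "background": s.background_level,
            "bright_level": s.bright_level, "dark_level": s.dark_level,
            "pre": s.pre_dur, "stim": s.stim_dur, "post": s.post_dur,
            "split_multifeature": e.split_multifeature,
            "split_unifeature": e.split_unifeature,
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def battery_from_manifest(df: pd.DataFrame) -> list[BatteryEntry]:
    entries = []
    for _, r in df.iterrows():
        spec = StimulusSpec(
            motion_side=r["motion_side"], coherence=float(r["coherence"]),
            lum_side=r["lum_side"], background_level=float(r["background"]),
            bright_level=float(r.get("bright_level", 1.0)),
            dark_level=float(r.get("dark_level", 0.0)),
            pre_dur=float(r["pre"]), stim_dur=float(r["stim"]),
            post_dur=float(r["post"]),
        )
        entries.append(BatteryEntry(
            stimulus_id=str(r["stimulus_id"]), spec=spec,
            split_multifeature=str(r["split_multifeature"]),
            split_unifeature=str(r["split_unifeature"]),
        ))
    return entries
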