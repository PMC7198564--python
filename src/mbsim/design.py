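"""Stimulus schedules and their convolution into volume-sampled regressors.

Three schedule families are provided: the fast alternating two-condition
design (switch every 2 s), the rapid event-related schedule (48 stimuli of
0.5 s + 2.5 s ISI with 30 interleaved null trials per run), and the block
design (32 s ON / 16 s OFF). ``convolve_schedule`` turns a schedule plus an
impulse-response function into the regressor sampled once per imaging
volume.

Conventions: condition label -1 marks null/blank trials; the fine
convolution grid uses the IRF's dt; volumes are sampled at the END of each
TR (t = tr, 2*tr, ...); schedules are padded with trailing blank up to a
whole number of volumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .irf import GridMismatchError, ImpulseResponse, InvalidParameterError

NULL = -1  # condition label for null/blank trials


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    condition: int


@dataclass(frozen=True)
class EventSchedule:
    """Timed, labelled stimulus/null events plus the volume grid."""

    events: tuple[Event, ...]
    tr: float
    total_duration: float

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise InvalidParameterError("tr must be positive")
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        n_vol = self.total_duration / self.tr
        if abs(n_vol - round(n_vol)) > 1e-9:
            raise InvalidParameterError(
                f"total_duration {self.total_duration} not a multiple of tr {self.tr}"
            )
        prev_end = None
        for ev in events:
            if ev.onset < 0 or ev.onset + ev.duration > self.total_duration + 1e-9:
                raise InvalidParameterError(f"event outside run: {ev}")
            if prev_end is not None and ev.onset < prev_end - 1e-9:
                raise InvalidParameterError(f"overlapping/unsorted events at {ev}")
            prev_end = ev.onset + ev.duration

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration / self.tr))

    @property
    def conditions(self) -> list[int]:
        """Sorted distinct stimulus condition labels (nulls excluded)."""
        return sorted({ev.condition for ev in self.events if ev.condition != NULL})

    def events_for(self, condition: int) -> list[Event]:
        return [ev for ev in self.events if ev.condition == condition]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# tr={self.tr!r}, total_duration={self.total_duration!r}\n")
            fh.write("onset_s,duration_s,condition\n")
            for ev in self.events:
                fh.write(
                    f"{float(ev.onset)!r},{float(ev.duration)!r},{int(ev.condition)}\n"
                )

    @classmethod
    def from_csv(cls, path) -> "EventSchedule":
        with open(path) as fh:
            header = fh.readline().strip()
            body = fh.read()
        meta = dict(
            part.partition("=")[::2] for part in header.lstrip("# ").split(", ")
        )
        events = []
        for line in body.splitlines()[1:]:
            onset, duration, condition = line.split(",")
            events.append(Event(float(onset), float(duration), int(condition)))
        return cls(tuple(events), float(meta["tr"]), float(meta["total_duration"]))


@dataclass(frozen=True)
class SampledRegressor:
    """One amplitude per imaging volume, plus its sampling TR."""

    values: np.ndarray = field(repr=False)
    tr: float
    condition: str = ""

    def __post_init__(self) -> None:
        values = np.array(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("regressor values must be finite")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# tr={self.tr!r}, condition={self.condition}\n")
            fh.write("volume_index,time_s,value\n")
            for i, v in enumerate(self.values):
                fh.write(f"{i},{float((i + 1) * self.tr)!r},{float(v)!r}\n")

    @classmethod
    def from_csv(cls, path) -> "SampledRegressor":
        with open(path) as fh:
            header = fh.readline().strip()
            body = fh.read()
        meta = dict(
            part.partition("=")[::2] for part in header.lstrip("# ").split(", ")
        )
        arr = np.loadtxt(io.StringIO(body), delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 2], float(meta["tr"]), meta.get("condition", ""))


def _pad_to_tr(duration: float, tr: float) -> float:
    n = int(np.ceil(duration / tr - 1e-9))
    return n * tr


def alternating_design(
    switch_every: float = 2.0, total_duration: float = 480.0, tr: float = 2.0
) -> EventSchedule:
    """Two conditions presented in strict alternation (fast-switch design).

    Conditions 0 and 1 alternate, each shown for ``switch_every`` seconds
    with no gaps; the fundamental period is 2*switch_every (0.25 Hz for the
    default 2 s switch).
    """
    if switch_every <= 0:
        raise InvalidParameterError("switch_every must be positive")
    n_events = total_duration / switch_every
    if abs(n_events / 2 - round(n_events / 2)) > 1e-9:
        raise InvalidParameterError(
            "total_duration must be a multiple of 2*switch_every"
        )
    events = tuple(
        Event(i * switch_every, switch_every, i % 2) for i in range(int(round(n_events)))
    )
    return EventSchedule(events, tr, _pad_to_tr(total_duration, tr))


def rapid_er_schedule(
    n_stimuli: int = 48,
    stim_duration: float = 0.5,
    isi: float = 2.5,
    n_null: int = 30,
    null_slot: float = 3.0,
    tr: float = 2.0,
    seed: int | None = None,
) -> EventSchedule:
    """Rapid event-related run: each stimulus once, nulls interleaved at random.

    Slots are laid back to back in a seeded random permutation: a stimulus
    slot is ``stim_duration`` of stimulus followed by ``isi`` of blank; a
    null slot is ``null_slot`` seconds of blank (condition -1). Each
    condition label 0..n_stimuli-1 appears exactly once per run. At the
    defaults (48 x 3 s + 30 x 3 s at TR 2 s) a run spans 117 volumes.
    """
    if seed is None:
        raise InvalidParameterError("a seed is required for reproducible schedules")
    if n_stimuli < 1:
        raise InvalidParameterError("n_stimuli must be >= 1")
    if stim_duration + isi <= 0:
        raise InvalidParameterError("stim_duration + isi must be positive")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.arange(n_stimuli), np.full(n_null, NULL)])
    labels = rng.permutation(labels)
    events = []
    t = 0.0
    for lab in labels:
        if lab == NULL:
            events.append(Event(t, null_slot, NULL))
            t += null_slot
        else:
            events.append(Event(t, stim_duration, int(lab)))
            t += stim_duration + isi
    return EventSchedule(tuple(events), tr, _pad_to_tr(t, tr))


def block_schedule(
    on_duration: float = 32.0,
    off_duration: float = 16.0,
    stim_duration: float = 0.4,
    isi: float = 0.5,
    n_cycles: int = 5,
    tr: float = 2.0,
) -> EventSchedule:
    """Alternating ON/OFF block design.

    Within each ON block, stimulus events (all condition 0) are packed as
    full (stim_duration + isi) cycles while they fit, plus one final
    stimulus if the stimulus alone still fits. OFF blocks carry no events.
    """
    for name, dur in (("on_duration", on_duration), ("off_duration", off_duration)):
        if abs(dur / tr - round(dur / tr)) > 1e-9:
            raise InvalidParameterError(f"{name} must be a multiple of tr")
    cycle = stim_duration + isi
    if cycle > on_duration:
        raise InvalidParameterError("stim_duration + isi exceeds the ON block")
    n_full = int(np.floor(on_duration / cycle + 1e-9))
    extra = n_full * cycle + stim_duration <= on_duration + 1e-9
    events = []
    for c in range(n_cycles):
        block_start = c * (on_duration + off_duration)
        for i in range(n_full + (1 if extra else 0)):
            events.append(Event(block_start + i * cycle, stim_duration, 0))
    total = n_cycles * (on_duration + off_duration)
    return EventSchedule(tuple(events), tr, _pad_to_tr(total, tr))


def _boxcar(
    schedule: EventSchedule,
    dt: float,
    weights: dict[int, float],
) -> np.ndarray:
    """Fine-grid indicator with per-condition weights on [0, total_duration]."""
    n_fine = int(round(schedule.total_duration / dt)) + 1
    box = np.zeros(n_fine)
    for ev in schedule.events:
        w = weights.get(ev.condition)
        if w is None:
            continue
        start = int(np.ceil(ev.onset / dt - 1e-9))
        stop = int(np.ceil((ev.onset + ev.duration) / dt - 1e-9))
        box[start:stop] = w
    return box


def convolve_schedule(
    schedule: EventSchedule,
    irf: ImpulseResponse,
    condition: int | str | None = None,
    contrast: tuple[int, int] | None = None,
) -> SampledRegressor:
    """Convolve a schedule's boxcar with an IRF and sample once per volume.

    Exactly one of ``condition`` (an integer label, or ``"all"`` for the
    all-events indicator) or ``contrast`` (a pair (a, b) weighted +1/-1)
    selects the boxcar. Discrete convolution on the IRF's dt grid; volume
    samples are taken at t = tr, 2*tr, ... so a single event of duration dt
    at t = 0 reproduces the IRF itself at volume times.
    """
    if not schedule.events:
        raise InvalidParameterError("schedule has no events")
    ratio = schedule.tr / irf.dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise GridMismatchError(f"irf.dt {irf.dt} does not divide tr {schedule.tr}")
    if (condition is None) == (contrast is None):
        raise InvalidParameterError("pass exactly one of condition or contrast")
    if contrast is not None:
        weights = {contrast[0]: 1.0, contrast[1]: -1.0}
        desc = f"contrast({contrast[0]}-{contrast[1]})"
    elif condition == "all":
        weights = {c: 1.0 for c in schedule.conditions}
        desc = "all"
    else:
        weights = {int(condition): 1.0}
        desc = f"condition {condition}"
    box = _boxcar(schedule, irf.dt, weights)
    conv = np.convolve(box, irf.samples)[: box.size]
    step = int(round(ratio))
    idx = np.arange(1, schedule.n_volumes + 1) * step
    return SampledRegressor(conv[idx], schedule.tr, desc)
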