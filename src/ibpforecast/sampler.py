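"""Windowed sample generation: observation / delay / class-observation.

A candidate sample is three contiguous spans laid over the recording: a 20 s
observation window (features are computed here), a 5 min delay (the
forecasting horizon), and a 1 min class-observation window (where the event
is assessed). Candidates start every ``windowing_interval_s`` seconds.

Labeling uses the 2 s trailing moving average (the MAP proxy):

* hypotension — the MAP proxy stays below 65 mmHg for the whole class window
  (its maximum is below threshold);
* normal — it stays above 65 mmHg for the whole class window;
* a class window that crosses the threshold fits neither strict definition
  and is excluded as ambiguous.

Exclusions, in precedence order:

1. ``partial_window`` — the moving average is not yet defined somewhere in
   the sample's spans (recording edge);
2. ``artifact_obs`` / ``artifact_class`` — the artifact screen fires on the
   observation or class window (raw values);
3. ``event_in_obs_or_delay`` — a full hypotensive event (a contiguous
   below-threshold stretch at least one class-observation long) lies inside
   observation+delay: hypotension is already ongoing, so forecasting it is
   pointless. A shorter sub-threshold stretch does not fire this rule —
   necessarily so, because the threshold crossing of the very event being
   forecast always falls in the delay tail of its own sample (the class
   window starts where the MAP proxy is already below threshold);
4. ``ambiguous_class`` — threshold-crossing class window;
5. ``duplicate_event`` — a hypotension sample whose class window overlaps the
   same below-threshold run as an earlier hypotension sample: for a
   consecutive event only the first alarm matters.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from ibpforecast.signal_core import Recording, WindowSpan, artifact_check, moving_average

__all__ = [
    "Label",
    "ExclusionReason",
    "SamplerConfig",
    "SampleWindow",
    "label_class_window",
    "event_in_span",
    "generate_samples",
    "exclusion_tally",
]


class Label(str, enum.Enum):
    NORMAL = "normal"
    HYPOTENSION = "hypotension"
    EXCLUDED = "excluded"


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    ARTIFACT_OBS = "artifact_obs"
    ARTIFACT_CLASS = "artifact_class"
    EVENT_IN_OBS_OR_DELAY = "event_in_obs_or_delay"
    AMBIGUOUS_CLASS = "ambiguous_class"
    PARTIAL_WINDOW = "partial_window"
    DUPLICATE_EVENT = "duplicate_event"


@dataclass(frozen=True)
class SamplerConfig:
    """Windowing geometry and labeling threshold.

    Defaults: 20 s observation, 5 min delay, 1 min class observation,
    65 mmHg threshold on a 2 s moving average, 30 s stride.
    """

    observation_s: float = 20.0
    delay_s: float = 300.0
    class_obs_s: float = 60.0
    windowing_interval_s: float = 30.0
    hypo_threshold: float = 65.0
    ma_width_s: float = 2.0
    flat_threshold: float = 30.0
    jump_threshold: float = 30.0

    def __post_init__(self) -> None:
        for name in ("observation_s", "delay_s", "class_obs_s", "windowing_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.windowing_interval_s > self.observation_s + self.delay_s + self.class_obs_s:
            raise ValueError("windowing interval exceeds the total sample span")

    @property
    def total_s(self) -> float:
        return self.observation_s + self.delay_s + self.class_obs_s


@dataclass(frozen=True)
class SampleWindow:
    """One candidate sample: three contiguous spans plus its label."""

    obs: WindowSpan
    delay: WindowSpan
    class_obs: WindowSpan
    label: Label
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if self.obs.end != self.delay.start or self.delay.end != self.class_obs.start:
            raise ValueError("obs, delay, class_obs must be contiguous")
        excluded = self.label is Label.EXCLUDED
        if excluded != (self.exclusion_reason is not ExclusionReason.NONE):
            raise ValueError("label=excluded iff exclusion_reason != none")


def label_class_window(
    ma: NDArray[np.float64], span: WindowSpan, threshold: float
) -> Label:
    """Label one class-observation window from the smoothed series.

    Hypotension if the window maximum of the MAP proxy is below threshold;
    normal if the window minimum is above it; otherwise the window crosses
    the threshold and is excluded as ambiguous (returned as EXCLUDED).
    """
    seg = ma[span.start : span.end]
    if np.isnan(seg).any():
        raise ValueError("moving average invalid inside class window")
    if float(np.max(seg)) < threshold:
        return Label.HYPOTENSION
    if float(np.min(seg)) > threshold:
        return Label.NORMAL
    return Label.EXCLUDED


def event_in_span(
    ma: NDArray[np.float64],
    span: WindowSpan,
    threshold: float,
    min_event_samples: int = 1,
) -> bool:
    """Is there a hypotensive event inside the span?

    With the default ``min_event_samples=1`` this is the instantaneous test
    (any MAP-proxy value below threshold). The sample generator passes the
    class-observation length instead, so only a contiguous below-threshold
    stretch at least one event long counts — the reading under which
    first-minute forecasting samples can exist at all.
    """
    seg = ma[span.start : span.end]
    if np.isnan(seg).any():
        raise ValueError("moving average invalid inside span")
    below = seg < threshold
    if min_event_samples <= 1:
        return bool(below.any())
    if not below.any():
        return False
    # longest run of consecutive True
    padded = np.concatenate(([False], below, [False])).astype(np.int8)
    d = np.diff(padded)
    run_lengths = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
    return bool(np.max(run_lengths) >= min_event_samples)


def _run_id_map(ma: NDArray[np.float64], threshold: float) -> NDArray[np.int64]:
    """Label each sample with the index of its below-threshold run (-1 elsewhere)."""
    below = ma < threshold
    if not below.any():
        return np.full(ma.size, -1, dtype=np.int64)
    starts = np.flatnonzero(np.diff(np.concatenate(([False], below)).astype(np.int8)) == 1)
    d = np.zeros(ma.size, dtype=np.int64)
    d[starts] = 1
    return np.where(below, np.cumsum(d) - 1, -1)


def generate_samples(recording: Recording, config: SamplerConfig) -> list[SampleWindow]:
    """Slide the three-span template over the recording and label every stop.

    Returns all candidates, excluded ones included, so exclusion tallies can
    be audited; filter on ``label`` for modeling.
    """
    fs = recording.fs
    n = recording.n_samples
    obs_n = int(round(config.observation_s * fs))
    delay_n = int(round(config.delay_s * fs))
    class_n = int(round(config.class_obs_s * fs))
    step = int(round(config.windowing_interval_s * fs))
    total = obs_n + delay_n + class_n
    if n <= total:
        raise ValueError("recording shorter than one observation+delay+class span")

    ma = moving_average(recording.values, config.ma_width_s, fs)
    run_ids = _run_id_map(ma, config.hypo_threshold)
    seen_runs: set[int] = set()

    out: list[SampleWindow] = []
    for start in range(0, n - total + 1, step):
        obs = WindowSpan(start, start + obs_n)
        delay = WindowSpan(obs.end, obs.end + delay_n)
        cls = WindowSpan(delay.end, delay.end + class_n)

        def emit(label: Label, reason: ExclusionReason = ExclusionReason.NONE) -> None:
            out.append(SampleWindow(obs, delay, cls, label, reason))

        if np.isnan(ma[obs.start : cls.end]).any():
            emit(Label.EXCLUDED, ExclusionReason.PARTIAL_WINDOW)
            continue
        if artifact_check(
            recording.values[obs.start : obs.end], config.flat_threshold, config.jump_threshold
        ).any:
            emit(Label.EXCLUDED, ExclusionReason.ARTIFACT_OBS)
            continue
        if artifact_check(
            recording.values[cls.start : cls.end], config.flat_threshold, config.jump_threshold
        ).any:
            emit(Label.EXCLUDED, ExclusionReason.ARTIFACT_CLASS)
            continue
        # any sub-threshold MA inside the observation means hypotension has
        # already reached the feature window; in the delay only a full
        # class-observation-length event counts (the forecast event's own
        # crossing always lies in the delay tail)
        if event_in_span(ma, obs, config.hypo_threshold) or event_in_span(
            ma, WindowSpan(obs.start, delay.end), config.hypo_threshold, min_event_samples=class_n
        ):
            emit(Label.EXCLUDED, ExclusionReason.EVENT_IN_OBS_OR_DELAY)
            continue
        label = label_class_window(ma, cls, config.hypo_threshold)
        if label is Label.EXCLUDED:
            emit(Label.EXCLUDED, ExclusionReason.AMBIGUOUS_CLASS)
            continue
        if label is Label.HYPOTENSION:
            runs = set(run_ids[cls.start : cls.end]) - {-1}
            if runs & seen_runs:
                emit(Label.EXCLUDED, ExclusionReason.DUPLICATE_EVENT)
                continue
            seen_runs |= runs
        emit(label)
    return out


def exclusion_tally(samples: list[SampleWindow]) -> dict[str, int]:
    """Count samples per label/exclusion reason — the main debugging surface."""
    tally: Counter[str] = Counter()
    for s in samples:
        if s.label is Label.EXCLUDED:
            tally[s.exclusion_reason.value] += 1
        else:
            tally[s.label.value] += 1
    return dict(tally)
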