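"""Waveform data model, causal smoothing, and artifact predicates.

Everything downstream — sample generation, labeling, feature extraction —
operates on a :class:`Recording`: a uniformly sampled invasive-blood-pressure
series in mmHg. The 2 s trailing moving average defined here is the package's
working proxy for mean arterial pressure (MAP); the hypotension criterion
everywhere is that proxy falling below 65 mmHg.

Artifact screening follows the usual intraoperative rules: pressures above
200 mmHg or below 20 mmHg are non-physiological, a window whose total range is
under 30 mmHg is a flatline/damped trace (typically external cuff pressure),
and a sample-to-sample jump above 30 mmHg is a transducer event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "Recording",
    "WindowSpan",
    "ArtifactReport",
    "moving_average",
    "artifact_check",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_annotations",
    "write_annotations",
]

#: annotation kinds carried by a Recording
ANNOTATION_KINDS = ("hypotension_episode", "artifact")


@dataclass(frozen=True)
class WindowSpan:
    """Half-open span of sample indices, ``[start, end)``, 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "WindowSpan") -> bool:
        return self.start < other.end and other.start < self.end

    @classmethod
    def from_seconds(cls, start_s: float, end_s: float, fs: float) -> "WindowSpan":
        return cls(int(round(start_s * fs)), int(round(end_s * fs)))


@dataclass
class Recording:
    """A uniformly sampled arterial-pressure trace.

    Parameters
    ----------
    values
        Pressure samples in mmHg.
    fs
        Sampling rate in Hz (clinical monitors export 100 Hz).
    t0
        Start time in seconds; only used for CSV round-trips.
    annotations
        Ground-truth intervals as ``(WindowSpan, kind)`` with kind in
        ``{"hypotension_episode", "artifact"}``; spans are sample indices.
    """

    values: NDArray[np.float64]
    fs: float = 100.0
    t0: float = 0.0
    annotations: list[tuple[WindowSpan, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D series")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        for span, kind in self.annotations:
            if kind not in ANNOTATION_KINDS:
                raise ValueError(f"unknown annotation kind {kind!r}")
            if span.end > self.values.size:
                raise ValueError("annotation span outside recording")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def intervals(self, kind: str) -> list[WindowSpan]:
        """All annotation spans of one kind, in recording order."""
        return [s for s, k in self.annotations if k == kind]


@dataclass(frozen=True)
class ArtifactReport:
    """Outcome of the four artifact predicates on one window."""

    over_200: bool
    under_20: bool
    flat_range: bool
    jump: bool

    @property
    def any(self) -> bool:
        return self.over_200 or self.under_20 or self.flat_range or self.jump


def moving_average(values: ArrayLike, width_s: float, fs: float) -> NDArray[np.float64]:
    """Trailing (causal) moving average; the MAP proxy.

    Element ``i`` of the output is the mean of the ``round(width_s * fs)``
    samples ending at raw index ``i`` inclusive. The first ``w - 1`` elements,
    where no full window exists yet, are NaN — partial windows are never
    shortened, because a real-time consumer has no future samples to borrow.

    Raises
    ------
    ValueError
        If the series is shorter than one window.
    """
    x = np.asarray(values, dtype=np.float64)
    w = int(round(width_s * fs))
    if w < 1:
        raise ValueError("window must span at least one sample")
    if x.size < w:
        raise ValueError("window longer than series")
    # cumulative-sum trailing mean; float64 cumsum is adequate at mmHg scale
    c = np.cumsum(np.insert(x, 0, 0.0))
    out = np.full(x.size, np.nan)
    out[w - 1 :] = (c[w:] - c[:-w]) / w
    return out


def artifact_check(
    window_values: ArrayLike,
    flat_threshold: float = 30.0,
    jump_threshold: float = 30.0,
    *,
    check_flat: bool = True,
    check_jump: bool = True,
) -> ArtifactReport:
    """Screen one window for the four artifact conditions.

    ``over_200`` / ``under_20`` flag non-physiological pressures; ``flat_range``
    flags a window whose max-min range is below ``flat_threshold`` (a damped or
    cuff-compressed trace); ``jump`` flags any consecutive-sample difference
    exceeding ``jump_threshold``. The flat-range and jump predicates are two
    readings of the same clinical screening rule and can be toggled
    independently; both are on by default.
    """
    x = np.asarray(window_values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty window")
    mx = float(np.max(x))
    mn = float(np.min(x))
    jump = False
    if check_jump and x.size > 1:
        jump = bool(np.max(np.abs(np.diff(x))) > jump_threshold)
    return ArtifactReport(
        over_200=mx > 200.0,
        under_20=mn < 20.0,
        flat_range=check_flat and (mx - mn) < flat_threshold,
        jump=jump,
    )


# ---------------------------------------------------------------------------
# waveform CSV + annotation sidecar I/O
# ---------------------------------------------------------------------------

_CSV_HEADER = "time_s,ibp_mmHg"


def write_waveform_csv(recording: Recording, path: str | Path) -> None:
    """Write ``time_s,ibp_mmHg`` rows at the recording's sampling grid."""
    t = recording.t0 + np.arange(recording.n_samples) / recording.fs
    arr = np.column_stack([t, recording.values])
    np.savetxt(path, arr, delimiter=",", header=_CSV_HEADER, comments="", fmt="%.6f")


def read_waveform_csv(path: str | Path, uniformity_tol_s: float = 1e-6) -> Recording:
    """Read a waveform CSV; sampling rate is inferred from the time column.

    The grid must be uniform to within ``uniformity_tol_s`` seconds.
    """
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[0] < 2:
        raise ValueError("waveform CSV needs at least two samples")
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > uniformity_tol_s:
        raise ValueError("non-uniform sampling grid in waveform CSV")
    return Recording(values=v, fs=1.0 / float(dt[0]), t0=float(t[0]))


def write_annotations(recording: Recording, path: str | Path) -> None:
    """Write the annotation sidecar: JSON list of {start_s, end_s, kind}."""
    items = [
        {"start_s": span.start / recording.fs, "end_s": span.end / recording.fs, "kind": kind}
        for span, kind in recording.annotations
    ]
    Path(path).write_text(json.dumps(items, indent=1))


def read_annotations(path: str | Path, fs: float) -> list[tuple[WindowSpan, str]]:
    items = json.loads(Path(path).read_text())
    return [
        (WindowSpan.from_seconds(d["start_s"], d["end_s"], fs), d["kind"]) for d in items
    ]


def attach_annotations(recording: Recording, path: str | Path) -> Recording:
    """Load a sidecar next to a waveform and attach its intervals."""
    recording.annotations = read_annotations(path, recording.fs)
    return recording
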