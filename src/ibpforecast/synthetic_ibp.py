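"""Seeded generator of 100 Hz arterial-pressure recordings with ground truth.

Clinical arterial traces are a pulsatile beat train riding on a slowly
drifting mean arterial pressure (MAP). The simulator reproduces exactly the
properties the downstream pipeline contracts on:

* a fixed analytic beat morphology (fast systolic upstroke, slower decay,
  dicrotic bump), zero-mean and normalized to unit peak-to-trough, scaled by
  the pulse pressure and added to MAP;
* MAP = baseline + Ornstein–Uhlenbeck drift (mean-reverting, stationary
  standard deviation ``map_noise_sd``, relaxation time ``drift_tau_s``);
* hypotensive episodes as trapezoidal MAP depressions (ramp / plateau /
  recovery) toward a plateau MAP, optionally preceded by a shallow
  "precursor" MAP dip timed to fall inside the observation window of the
  sample that should forecast the episode;
* artifacts (high spikes > 200 mmHg, low drops < 20 mmHg, flatline segments)
  that overwrite the clean signal.

Ground-truth annotations use the same criterion the labeler uses: a
hypotension interval is a maximal run where the 2 s trailing moving average
of the generated waveform is below 65 mmHg (runs touching artifacts are
attributed to the artifact, not to hypotension).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from ibpforecast.signal_core import Recording, WindowSpan, moving_average

__all__ = [
    "SimConfig",
    "EpisodeSpec",
    "ArtifactSpec",
    "simulate",
    "default_study_config",
    "learnable_study_config",
    "EPISODES_PER_HOUR",
    "ARTIFACTS_PER_HOUR",
]

#: expected episode / artifact counts per hour of recording in the default
#: multi-patient study generator (Poisson rates)
EPISODES_PER_HOUR = 2.0
ARTIFACTS_PER_HOUR = 3.0

HYPO_THRESHOLD_MMHG = 65.0


@dataclass(frozen=True)
class EpisodeSpec:
    """One trapezoidal hypotensive episode.

    MAP descends linearly from baseline to ``plateau_map`` over ``ramp_s``,
    holds for ``plateau_s``, and recovers over ``recovery_s``. If
    ``precursor_drop`` is positive, a raised-cosine MAP dip of that depth
    (mmHg) and width ``precursor_width_s`` is centered ``precursor_lead_s``
    seconds before the episode's nominal 65 mmHg crossing — a detectable
    early-warning signature for the forecasting task.
    """

    onset_s: float
    ramp_s: float
    plateau_s: float
    recovery_s: float
    plateau_map: float
    precursor_drop: float = 0.0
    precursor_lead_s: float = 290.0
    precursor_width_s: float = 120.0

    def __post_init__(self) -> None:
        if min(self.ramp_s, self.plateau_s, self.recovery_s) < 0:
            raise ValueError("episode durations must be non-negative")
        if self.precursor_drop < 0:
            raise ValueError("precursor_drop must be non-negative")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.ramp_s + self.plateau_s + self.recovery_s

    def crossing_s(self, baseline: float, threshold: float = HYPO_THRESHOLD_MMHG) -> float:
        """Nominal first time MAP crosses `threshold` on the down-ramp."""
        if self.plateau_map >= threshold or baseline <= threshold:
            return self.onset_s
        frac = (baseline - threshold) / (baseline - self.plateau_map)
        return self.onset_s + self.ramp_s * frac


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact interval overwriting the clean waveform."""

    start_s: float
    duration_s: float
    kind: str  # spike_high | drop_low | flatline

    KINDS = ("spike_high", "drop_low", "flatline")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("artifact duration must be positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated recording.

    Defaults mirror a stable adult intraoperative trace: MAP 85 mmHg, pulse
    pressure 45 mmHg, heart rate 1.27 Hz (~76 bpm), slow MAP drift with a
    60 s relaxation time and 2 mmHg stationary spread.
    """

    duration_s: float
    fs: float = 100.0
    map_baseline: float = 85.0
    pulse_pressure: float = 45.0
    heart_rate_hz: float = 1.27
    map_noise_sd: float = 2.0
    drift_tau_s: float = 60.0
    episodes: tuple[EpisodeSpec, ...] = ()
    artifacts: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.pulse_pressure < 30:
            raise ValueError("pulse_pressure must be >= 30 mmHg (flat-range screen)")
        if not (0.5 < self.heart_rate_hz < 3.5):
            raise ValueError("heart rate outside physiological band (0.5, 3.5) Hz")
        for ep in self.episodes:
            if ep.end_s > self.duration_s or ep.onset_s < 0:
                raise ValueError("episode does not fit within the recording")
        for a in self.artifacts:
            if a.end_s > self.duration_s or a.start_s < 0:
                raise ValueError("artifact does not fit within the recording")


def _pulse_shape(phase: NDArray[np.float64]) -> NDArray[np.float64]:
    """Zero-mean beat morphology with unit peak-to-trough amplitude.

    Two raised bumps per period: a dominant systolic wave and a smaller
    dicrotic wave. Widths are chosen so the fundamental carries the largest
    harmonic amplitude (so periodogram/wavelet features recover the heart
    rate rather than a harmonic).
    """
    ph = np.mod(phase, 1.0)
    s = np.exp(-0.5 * ((ph - 0.22) / 0.11) ** 2)
    s = s + 0.30 * np.exp(-0.5 * ((ph - 0.55) / 0.055) ** 2)
    return (s - _SHAPE_MEAN) / _SHAPE_SPAN


# normalization constants computed once on a fine phase grid
_g = np.linspace(0.0, 1.0, 20001)[:-1]
_raw = np.exp(-0.5 * ((_g - 0.22) / 0.11) ** 2) + 0.30 * np.exp(
    -0.5 * ((_g - 0.55) / 0.055) ** 2
)
_SHAPE_MEAN = float(_raw.mean())
_SHAPE_SPAN = float(_raw.max() - _raw.min())
del _g, _raw


def _trapezoid_deficit(t: NDArray[np.float64], ep: EpisodeSpec) -> NDArray[np.float64]:
    """Fractional MAP deficit (0..1) of one episode at times ``t``."""
    f = np.zeros_like(t)
    up_end = ep.onset_s + ep.ramp_s
    plat_end = up_end + ep.plateau_s
    if ep.ramp_s > 0:
        m = (t >= ep.onset_s) & (t < up_end)
        f[m] = (t[m] - ep.onset_s) / ep.ramp_s
    f[(t >= up_end) & (t < plat_end)] = 1.0
    if ep.recovery_s > 0:
        m = (t >= plat_end) & (t < ep.end_s)
        f[m] = 1.0 - (t[m] - plat_end) / ep.recovery_s
    return f


def _precursor_dip(
    t: NDArray[np.float64], ep: EpisodeSpec, baseline: float
) -> NDArray[np.float64]:
    if ep.precursor_drop <= 0:
        return np.zeros_like(t)
    center = ep.crossing_s(baseline) - ep.precursor_lead_s
    half = ep.precursor_width_s / 2.0
    dip = np.zeros_like(t)
    m = np.abs(t - center) < half
    dip[m] = ep.precursor_drop * 0.5 * (1.0 + np.cos(np.pi * (t[m] - center) / half))
    return dip


def _ou_drift(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> NDArray:
    """Ornstein–Uhlenbeck drift with stationary sd ``sd`` and time constant ``tau``."""
    if sd <= 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i - 1]
    return x


def _hypotension_runs(
    ma: NDArray[np.float64],
    artifact_spans: list[WindowSpan],
    guard: int,
    threshold: float = HYPO_THRESHOLD_MMHG,
) -> list[WindowSpan]:
    """Maximal below-threshold runs of the MAP proxy, excluding artifact fallout.

    Runs that touch an artifact interval (padded by ``guard`` samples, the
    moving-average memory) are caused by the artifact, not by hypotension.
    """
    below = ma < threshold  # NaN compares False
    if not below.any():
        return []
    d = np.diff(below.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size)
    # merge runs separated by less than one averaging window: edge ripple of
    # the same episode, not distinct events
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < guard:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    runs = []
    for s, e in merged:
        run = WindowSpan(s, e)
        padded_hits = any(
            run.start < a.end + guard and a.start - guard < run.end for a in artifact_spans
        )
        if not padded_hits:
            runs.append(run)
    return runs


def simulate(config: SimConfig) -> Recording:
    """Generate one annotated recording; identical config ⇒ identical output.

    Raises on overlapping episodes; an artifact overlapping an episode only
    warns (the artifact overwrites the waveform there).
    """
    eps = sorted(config.episodes, key=lambda e: e.onset_s)
    for a, b in zip(eps, eps[1:]):
        if b.onset_s < a.end_s:
            raise ValueError("overlapping episodes")
    for art in config.artifacts:
        for ep in eps:
            if art.start_s < ep.end_s and ep.onset_s < art.end_s:
                warnings.warn(
                    "artifact overlaps an episode; artifact overwrites the waveform",
                    stacklevel=2,
                )

    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    rng = np.random.default_rng(config.seed)

    map_t = config.map_baseline + _ou_drift(
        n, 1.0 / config.fs, config.map_noise_sd, config.drift_tau_s, rng
    )
    for ep in eps:
        map_t -= _trapezoid_deficit(t, ep) * (config.map_baseline - ep.plateau_map)
        map_t -= _precursor_dip(t, ep, config.map_baseline)

    pressure = map_t + config.pulse_pressure * _pulse_shape(config.heart_rate_hz * t)

    artifact_spans: list[WindowSpan] = []
    for art in config.artifacts:
        span = WindowSpan.from_seconds(art.start_s, art.end_s, config.fs)
        span = WindowSpan(span.start, min(span.end, n))
        seg = np.arange(len(span))
        if art.kind == "spike_high":
            # triangular spike peaking at 240 mmHg
            peak = len(seg) // 2
            tri = 1.0 - np.abs(seg - peak) / max(peak, 1)
            pressure[span.start : span.end] = 210.0 + 30.0 * tri
        elif art.kind == "drop_low":
            pressure[span.start : span.end] = 5.0
        else:  # flatline at the local mean, range < 30 by construction
            pressure[span.start : span.end] = float(map_t[span.start])
        artifact_spans.append(span)

    ma_guard = int(round(2.0 * config.fs))
    ma = moving_average(pressure, 2.0, config.fs) if n >= ma_guard else np.full(n, np.nan)
    hypo_spans = _hypotension_runs(ma, artifact_spans, ma_guard)

    annotations = [(s, "hypotension_episode") for s in hypo_spans]
    annotations += [(s, "artifact") for s in artifact_spans]
    annotations.sort(key=lambda item: item[0].start)
    return Recording(values=pressure, fs=config.fs, annotations=annotations)


# ---------------------------------------------------------------------------
# multi-patient study generators
# ---------------------------------------------------------------------------


def _place_episodes(
    rng: np.random.Generator,
    n_episodes: int,
    duration_s: float,
    min_onset_s: float,
    precursor_drop: float,
    pre_onset_clear_s: float = 0.0,
    recovery_range_s: tuple[float, float] = (30.0, 60.0),
) -> tuple[EpisodeSpec, ...]:
    """Draw non-overlapping trapezoids by rejection sampling.

    ``pre_onset_clear_s`` additionally keeps that many seconds before each
    onset free of other episodes, so the observation windows that forecast
    an episode never see the tail of an earlier one.
    """
    placed: list[EpisodeSpec] = []

    def footprint(ep: EpisodeSpec) -> tuple[float, float]:
        # full span the episode occupies, including precursor / kept-clear lead
        lead = ep.precursor_lead_s + ep.precursor_width_s if ep.precursor_drop > 0 else 0.0
        return ep.onset_s - max(lead, pre_onset_clear_s), ep.end_s

    for _ in range(n_episodes):
        for _try in range(200):
            ramp = rng.uniform(30.0, 60.0)
            plateau = rng.uniform(90.0, 180.0)
            recovery = rng.uniform(*recovery_range_s)
            total = ramp + plateau + recovery
            hi = duration_s - total - 30.0
            if hi <= min_onset_s:
                break
            onset = rng.uniform(min_onset_s, hi)
            cand = EpisodeSpec(
                onset_s=onset,
                ramp_s=ramp,
                plateau_s=plateau,
                recovery_s=recovery,
                plateau_map=rng.uniform(50.0, 58.0),
                precursor_drop=precursor_drop,
            )
            lo_c, hi_c = footprint(cand)
            clear = True
            for other in placed:
                lo_o, hi_o = footprint(other)
                if not (hi_c + 60.0 < lo_o or hi_o + 60.0 < lo_c):
                    clear = False
                    break
            if clear:
                placed.append(cand)
                break
    return tuple(sorted(placed, key=lambda e: e.onset_s))


def _place_artifacts(
    rng: np.random.Generator,
    n_artifacts: int,
    duration_s: float,
    episodes: tuple[EpisodeSpec, ...],
) -> tuple[ArtifactSpec, ...]:
    placed: list[ArtifactSpec] = []
    for _ in range(n_artifacts):
        for _try in range(200):
            dur = rng.uniform(1.0, 5.0)
            start = rng.uniform(5.0, duration_s - dur - 5.0)
            kind = rng.choice(ArtifactSpec.KINDS)
            # avoid episodes (and their precursor windows) so artifacts never
            # silently destroy the ground-truth events
            clear = all(
                not (start < ep.end_s + 30.0 and ep.onset_s - 460.0 < start + dur)
                for ep in episodes
            )
            if clear and all(
                not (start < a.end_s + 10.0 and a.start_s - 10.0 < start + dur) for a in placed
            ):
                placed.append(ArtifactSpec(start_s=start, duration_s=dur, kind=str(kind)))
                break
    return tuple(sorted(placed, key=lambda a: a.start_s))


def default_study_config(
    n_patients: int,
    seed: int,
    duration_s: float = 1800.0,
) -> list[SimConfig]:
    """Per-patient configs for a generic simulated study.

    Baselines U(75, 95) mmHg, heart rates U(0.9, 1.6) Hz; episode and
    artifact counts are Poisson with rates ``EPISODES_PER_HOUR`` and
    ``ARTIFACTS_PER_HOUR``. Deterministic given ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    configs = []
    hours = duration_s / 3600.0
    for _ in range(n_patients):
        baseline = rng.uniform(75.0, 95.0)
        hr = rng.uniform(0.9, 1.6)
        n_ep = int(rng.poisson(EPISODES_PER_HOUR * hours))
        n_art = int(rng.poisson(ARTIFACTS_PER_HOUR * hours))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        episodes = _place_episodes(rng, n_ep, duration_s, 90.0, precursor_drop=0.0)
        artifacts = _place_artifacts(rng, n_art, duration_s, episodes)
        configs.append(
            SimConfig(
                duration_s=duration_s,
                map_baseline=baseline,
                heart_rate_hz=hr,
                episodes=episodes,
                artifacts=artifacts,
                seed=sub_seed,
            )
        )
    return configs


def learnable_study_config(
    n_patients: int,
    seed: int,
    duration_s: float = 1800.0,
    precursor_drop: float = 12.0,
    episodes_per_patient: int = 2,
    map_noise_sd: float = 1.0,
) -> list[SimConfig]:
    """Study configs with (or without) a forecastable precursor signature.

    Each episode is preceded by a ``precursor_drop`` mmHg MAP dip timed to
    fall inside the 20 s observation window of the sample that targets the
    episode's first hypotensive minute (5 min lead + windowing slack). With
    ``precursor_drop=0`` the pre-episode waveform carries no information
    about the upcoming event — the negative control for the learning test.

    Baselines are drawn U(82, 92) mmHg so the dipped MAP stays well above the
    65 mmHg criterion (the precursor must warn, not itself be hypotension).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(n_patients):
        baseline = rng.uniform(82.0, 92.0)
        hr = rng.uniform(0.9, 1.6)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        episodes = _place_episodes(
            rng,
            episodes_per_patient,
            duration_s,
            480.0,
            precursor_drop=precursor_drop,
            pre_onset_clear_s=420.0,
            # treated intraoperative hypotension resolves promptly; fast
            # recovery also keeps recovery-phase windows out of the normal
            # class, so the no-precursor arm is a clean null
            recovery_range_s=(8.0, 15.0),
        )
        artifacts = _place_artifacts(rng, 1, duration_s, episodes)
        configs.append(
            SimConfig(
                duration_s=duration_s,
                map_baseline=baseline,
                heart_rate_hz=hr,
                map_noise_sd=map_noise_sd,
                episodes=episodes,
                artifacts=artifacts,
                seed=sub_seed,
            )
        )
    return configs
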