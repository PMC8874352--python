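"""Synthetic continuous EOG/frontal recordings with ground-truth events.

Blink timing follows a modulated renewal process: baseline inter-blink
intervals are uniform on 3-5 s (the physiological spontaneous range of
roughly 12-20 blinks/min), and each candidate blink time is accepted by
thinning against a bounded modulation

    g(t) = cyclic_gain(phase of t in the 750-ms tone cycle; kappa)
           * exp(beta * (position - 2))   inside pre-stimulus windows,

so that kappa in [0, 1] concentrates blinks at a preferred phase of the tone
cycle (entrainment) and beta <= 0 progressively suppresses blinks in the
300 ms before potential target onsets at positions 2, 3, 4 (the hazard-rate
inhibition structure). With kappa = 0 and beta = 0 every candidate is
accepted and the process is exactly the uniform renewal process.

Blink waveforms are a linear up-stroke (default 90 ms, < 100 ms) followed by
a gentle exponential down-stroke (default 200 ms), smoothed by a short
raised-cosine kernel; the inner 80 % of each stroke is close to linear so a
stereotype-fitting detector sees R^2 > 0.98 on clean renderings. Saccades
are step displacements with exponential settling on the lateral channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .protocol import Protocol, TARGET_POSITIONS

EOG_CHANNELS = ("upperV", "lowerV", "Fp1", "Fp2", "Fz", "F3", "F4",
                "leftLateral", "rightLateral")

#: channel gain for the blink template (sign = polarity)
BLINK_GAIN = {
    "upperV": 1.0, "lowerV": -0.8,
    "Fp1": 0.45, "Fp2": 0.45, "Fz": 0.35, "F3": 0.3, "F4": 0.3,
    "leftLateral": 0.08, "rightLateral": 0.08,
}
SACCADE_GAIN = {
    "leftLateral": 1.0, "rightLateral": -1.0,
    "upperV": 0.1, "lowerV": 0.1,
    "Fp1": 0.05, "Fp2": 0.05, "Fz": 0.03, "F3": 0.08, "F4": 0.08,
}

REFRACTORY_MS = 400.0  # smallest physiologically plausible IBI is ~422 ms


@dataclass(frozen=True)
class BlinkShape:
    """Stereotyped blink waveform template parameters."""

    up_duration_ms: float = 90.0
    down_duration_ms: float = 200.0
    amplitude: float = 100.0  # microvolt-scale units on upperV
    smooth_ms: float = 16.0   # raised-cosine smoothing kernel width

    def __post_init__(self):
        if self.up_duration_ms >= 100.0:
            raise ValueError("blink up-stroke must be < 100 ms")

    def render(self, fs: float) -> np.ndarray:
        """Unit-amplitude template sampled at ``fs``; peak at index
        ``round(up_duration_ms * fs / 1000)``."""
        n_up = int(round(self.up_duration_ms * fs / 1000.0))
        n_down = int(round(self.down_duration_ms * fs / 1000.0))
        up = np.linspace(0.0, 1.0, n_up, endpoint=False)
        t = np.arange(n_down + 1) / n_down
        tau = 1.0  # gentle decay: inner 80% of the stroke stays near-linear
        down = (np.exp(-t / tau) - np.exp(-1.0 / tau)) / \
            (1.0 - np.exp(-1.0 / tau))
        wave = np.concatenate([up, down])
        n_k = max(3, int(round(self.smooth_ms * fs / 1000.0)) | 1)
        k = np.hanning(n_k)
        k /= k.sum()
        pad = n_k // 2
        wave = np.convolve(np.pad(wave, pad), k, mode="same")[pad:-pad]
        m = wave.max()
        return wave / m if m > 0 else wave

    def peak_offset_samples(self, fs: float) -> int:
        return int(np.argmax(self.render(fs)))


@dataclass(frozen=True)
class TimingModel:
    """Blink point-process parameters (baseline, entrainment, suppression)."""

    base_interval_s: tuple[float, float] = (3.0, 5.0)
    kappa: float = 0.8            # entrainment strength in [0, 1]
    beta: float = -0.8            # log-decrement per position step, <= 0
    prestim_window_ms: float = 300.0
    preferred_phase_ms: float = 375.0  # blinks gravitate to mid-interval
    kappa_concentration: float = 4.0   # von-Mises-like gain sharpness at kappa=1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.beta > 0:
            raise ValueError("beta must be <= 0")


@dataclass
class ContinuousRecording:
    """Named multichannel traces at a common sampling rate."""

    channels: dict[str, np.ndarray]
    fs: float = 500.0

    @property
    def duration_s(self) -> float:
        n = len(next(iter(self.channels.values()))) if self.channels else 0
        return n / self.fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.channels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.4f")

    @classmethod
    def from_tsv(cls, path, fs: float = 500.0) -> "ContinuousRecording":
        df = pd.read_csv(path, sep="\t")
        return cls({c: df[c].to_numpy(float) for c in df.columns}, fs=fs)


@dataclass
class GroundTruthLog:
    """Injected-event truth for recovery experiments."""

    blink_peaks_ms: np.ndarray
    blink_amplitudes: np.ndarray
    saccade_onsets_ms: np.ndarray = field(
        default_factory=lambda: np.array([]))
    saccade_durations_ms: np.ndarray = field(
        default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        blinks = pd.DataFrame({
            "event": "blink",
            "time_ms": self.blink_peaks_ms,
            "amplitude": self.blink_amplitudes,
            "duration_ms": np.nan,
        })
        sacc = pd.DataFrame({
            "event": "saccade",
            "time_ms": self.saccade_onsets_ms,
            "amplitude": np.nan,
            "duration_ms": self.saccade_durations_ms,
        })
        return pd.concat([blinks, sacc], ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _cyclic_gain(t_ms: np.ndarray, model: TimingModel,
                 soa_ms: float) -> np.ndarray:
    """Phase gain in (0, 1], maximal at the preferred phase; identically 1
    when kappa = 0."""
    phase = 2.0 * np.pi * ((t_ms - model.preferred_phase_ms) % soa_ms) / soa_ms
    conc = model.kappa * model.kappa_concentration
    return np.exp(conc * (np.cos(phase) - 1.0))


def _suppression_gain(t_ms: np.ndarray, model: TimingModel,
                      seq_ms: float, soa_ms: float) -> np.ndarray:
    """exp(beta * (position - 2)) inside the pre-stimulus window of each
    potential target position; 1 elsewhere."""
    gain = np.ones_like(t_ms, dtype=float)
    s = np.asarray(t_ms) % seq_ms
    for pos in TARGET_POSITIONS:
        onset = (pos - 1) * soa_ms
        inside = (s >= onset - model.prestim_window_ms) & (s < onset)
        gain[inside] = np.exp(model.beta * (pos - 2))
    return gain


def modulation(t_ms: np.ndarray, model: TimingModel,
               soa_ms: float = 750.0, seq_ms: float = 3750.0) -> np.ndarray:
    """Full bounded modulation g(t) in (0, 1]."""
    t_ms = np.atleast_1d(np.asarray(t_ms, dtype=float))
    g = _cyclic_gain(t_ms, model, soa_ms) * \
        _suppression_gain(t_ms, model, seq_ms, soa_ms)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite blink intensity")
    return g


def sample_blink_times(model: TimingModel, protocol: Protocol,
                       rng: Optional[np.random.Generator] = None,
                       max_tries: int = 200) -> np.ndarray:
    """Sample blink peak times (ms) over the protocol duration.

    Renewal-with-thinning: from each accepted blink the next candidate is
    drawn at a uniform baseline interval and accepted with probability
    g(candidate); rejected candidates are redrawn from the same blink
    (Lewis-Shedler-style acceptance against the bounded modulation).
    """
    if not protocol.tones:
        raise ValueError("protocol is empty")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    lo, hi = (v * 1000.0 for v in model.base_interval_s)
    dur = protocol.duration_ms
    soa, seq = protocol.soa_ms, protocol.sequence_duration_ms

    times: list[float] = []
    t = rng.uniform(0.0, hi)  # burn-in start
    while t < dur:
        times.append(t)
        nxt = None
        for _ in range(max_tries):
            cand = t + rng.uniform(lo, hi)
            if cand >= dur:
                nxt = cand
                break
            if rng.uniform() < modulation(cand, model, soa, seq)[0]:
                nxt = cand
                break
        if nxt is None:  # pathological modulation; take the last candidate
            nxt = cand
        t = nxt
    return np.asarray(times)


def sample_saccade_times(duration_ms: float, rate_hz: float,
                         rng: np.random.Generator,
                         duration_range_ms: tuple[float, float] = (20., 60.)
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson saccade onsets with uniform durations."""
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    onsets = np.sort(rng.uniform(0.0, duration_ms, size=n))
    durs = rng.uniform(*duration_range_ms, size=n)
    return onsets, durs


def _saccade_wave(duration_ms: float, fs: float,
                  settle_ms: float = 400.0) -> np.ndarray:
    """Step displacement reached during ``duration_ms`` then slow
    exponential settling back toward baseline (the return to fixation is
    much slower than the saccadic step itself)."""
    n_rise = max(2, int(round(duration_ms * fs / 1000.0)))
    n_settle = int(round(settle_ms * fs / 1000.0))
    rise = np.linspace(0.0, 1.0, n_rise)
    settle = np.exp(-np.arange(1, n_settle + 1) / (n_settle / 3.0))
    return np.concatenate([rise, settle])


def render_recording(blink_times_ms: np.ndarray,
                     shape: BlinkShape = BlinkShape(),
                     noise_sd: float = 5.0,
                     fs: float = 500.0,
                     duration_ms: Optional[float] = None,
                     saccade_onsets_ms: Optional[np.ndarray] = None,
                     saccade_durations_ms: Optional[np.ndarray] = None,
                     saccade_amplitude: float = 40.0,
                     amplitude_jitter: float = 0.15,
                     rng: Optional[np.random.Generator] = None,
                     channels: tuple[str, ...] = EOG_CHANNELS,
                     ) -> tuple[ContinuousRecording, GroundTruthLog]:
    """Render blink and saccade events into a multichannel recording.

    Blink templates are placed so the waveform *peak* falls at the logged
    time, with channel-appropriate polarity (upperV positive, lowerV
    negative, attenuated frontal copies). Gaussian noise is added per
    channel. Returns the recording together with the ground-truth log.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    blink_times_ms = np.sort(np.asarray(blink_times_ms, dtype=float))
    if saccade_onsets_ms is None:
        saccade_onsets_ms = np.array([])
        saccade_durations_ms = np.array([])
    if duration_ms is None:
        tail = shape.down_duration_ms + 100.0
        last = max(blink_times_ms.max() if len(blink_times_ms) else 0.0,
                   saccade_onsets_ms.max() if len(saccade_onsets_ms) else 0.0)
        duration_ms = last + tail
    n = int(round(duration_ms * fs / 1000.0))
    if len(blink_times_ms) and blink_times_ms.max() * fs / 1000.0 >= n:
        raise ValueError("event times beyond recording duration")
    if len(blink_times_ms) > 1 and \
            np.min(np.diff(blink_times_ms)) < REFRACTORY_MS + 22.0:
        warnings.warn("blinks closer than 422 ms: below the physiological "
                      "inter-blink range", stacklevel=2)

    template = shape.render(fs)
    peak_off = int(np.argmax(template))

    clean = np.zeros(n)
    amps = shape.amplitude * (
        1.0 + amplitude_jitter * rng.standard_normal(len(blink_times_ms)))
    amps = np.clip(amps, 0.3 * shape.amplitude, None)
    for t_ms, a in zip(blink_times_ms, amps):
        i0 = int(round(t_ms * fs / 1000.0)) - peak_off
        lo, hi = max(i0, 0), min(i0 + len(template), n)
        clean[lo:hi] += a * template[lo - i0:hi - i0]

    sacc = np.zeros(n)
    for t_ms, d_ms in zip(saccade_onsets_ms, saccade_durations_ms):
        w = _saccade_wave(d_ms, fs) * saccade_amplitude * \
            rng.choice([-1.0, 1.0])
        i0 = int(round(t_ms * fs / 1000.0))
        lo, hi = max(i0, 0), min(i0 + len(w), n)
        sacc[lo:hi] += w[lo - i0:hi - i0]

    data = {}
    for ch in channels:
        trace = BLINK_GAIN.get(ch, 0.0) * clean \
            + SACCADE_GAIN.get(ch, 0.0) * sacc \
            + noise_sd * rng.standard_normal(n)
        data[ch] = trace
    rec = ContinuousRecording(data, fs=fs)
    log = GroundTruthLog(blink_peaks_ms=blink_times_ms,
                         blink_amplitudes=amps,
                         saccade_onsets_ms=np.asarray(saccade_onsets_ms),
                         saccade_durations_ms=np.asarray(saccade_durations_ms))
    return rec, log


#: PD-like group preset: fewer blinks (longer baseline intervals), weaker
#: entrainment, and more variable saccading; suppression beta is shared with
#: the control preset since hazard-rate inhibition is present in both groups.
PD_LIKE_OVERRIDES = {
    "base_interval_s": (3.8, 6.2),
    "kappa": 0.4,
}
HC_LIKE_OVERRIDES: dict = {}


@dataclass
class SyntheticParticipant:
    participant_id: str
    group: str
    model: TimingModel
    blink_times_ms: np.ndarray
    recording: Optional[ContinuousRecording]
    truth: GroundTruthLog
    age: float = np.nan


def generate_cohort(n_participants: int,
                    protocol: Protocol,
                    seed: int,
                    group: str = "HC-like",
                    model_overrides: Optional[dict] = None,
                    base_model: TimingModel = TimingModel(),
                    render: bool = True,
                    noise_sd: float = 5.0,
                    saccade_rate_hz: float = 0.15,
                    saccade_rate_sd: float = 0.0,
                    shape: BlinkShape = BlinkShape(),
                    ages: Optional[np.ndarray] = None,
                    ) -> list[SyntheticParticipant]:
    """Generate a cohort of synthetic participants with per-participant
    seeds derived reproducibly from the master seed."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if model_overrides is None:
        model_overrides = (PD_LIKE_OVERRIDES if group.lower().startswith("pd")
                           else HC_LIKE_OVERRIDES)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        model = replace(base_model, **model_overrides)
        blinks = sample_blink_times(model, protocol, rng=rng)
        rate = max(0.0, saccade_rate_hz
                   + saccade_rate_sd * rng.standard_normal())
        sacc_on, sacc_dur = sample_saccade_times(
            protocol.duration_ms, rate, rng)
        if render:
            rec, truth = render_recording(
                blinks, shape=shape, noise_sd=noise_sd,
                duration_ms=protocol.duration_ms,
                saccade_onsets_ms=sacc_on, saccade_durations_ms=sacc_dur,
                rng=rng)
        else:
            rec = None
            truth = GroundTruthLog(blinks, np.full(len(blinks), np.nan),
                                   sacc_on, sacc_dur)
        age = float(ages[i]) if ages is not None else float(rng.uniform(55, 75))
        out.append(SyntheticParticipant(
            participant_id=f"{group}-{i + 1:02d}", group=group, model=model,
            blink_times_ms=blinks, recording=rec, truth=truth, age=age))
    return out
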