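"""Spectral entrainment of blink point processes to the tone stream.

Blink peaks from non-target sequences are marked as unit impulses on a
500-Hz grid, the per-sequence epochs are concatenated into one vector per
participant, and an 8192-point FFT (magnitude normalized by N, averaged over
consecutive non-overlapping windows) quantifies power at the sequence rate
(0.267 Hz), the stimulus rate (1.34 Hz) and its first harmonic (2.67 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .blink_detect import BlinkCatalog
from .protocol import Protocol

EPOCH_MS = 3500.0
NFFT = 8192
PROBE_FREQS_HZ = (0.267, 1.34, 2.67)
#: reference band half-width (bins) and probe exclusion half-width (bins)
REF_HALFWIDTH = 10
REF_EXCLUDE = 1


@dataclass
class EpochSet:
    """Blink peak latencies per non-target sequence epoch [0, 3500) ms."""

    participant_id: str
    epoch_onsets_ms: np.ndarray      # sequence onsets of retained epochs
    latencies_ms: list[np.ndarray]   # per-epoch latencies relative to onset

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_onsets_ms)

    @property
    def n_blinks(self) -> int:
        return int(sum(len(v) for v in self.latencies_ms))

    def all_latencies(self) -> np.ndarray:
        if not self.latencies_ms:
            return np.array([])
        return np.concatenate(self.latencies_ms)


#: band inspected for entrainment peaks (sequence rate through the first
#: harmonic); point-process spectra do not decay with frequency, so a peak
#: search is only meaningful within the analysis band
ANALYSIS_BAND_HZ = (0.0, 3.0)


@dataclass
class SpectrumResult:
    freqs_hz: np.ndarray
    power: np.ndarray
    peak_power: dict[float, float]
    reference_power: dict[float, float]
    n_windows: int

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def peak_frequency(self, fmin: float = ANALYSIS_BAND_HZ[0],
                       fmax: float = ANALYSIS_BAND_HZ[1]) -> float:
        """Frequency of the maximal-power bin in (fmin, fmax] (DC excluded
        whenever fmin >= 0)."""
        band = (self.freqs_hz > fmin) & (self.freqs_hz <= fmax)
        if not band.any():
            raise ValueError("empty frequency band")
        return float(self.freqs_hz[band][np.argmax(self.power[band])])


def extract_epochs(catalog: BlinkCatalog, protocol: Protocol) -> EpochSet:
    """One epoch per non-target sequence; blinks assigned to the half-open
    window [sequence onset, onset + 3500 ms)."""
    seq_ms = protocol.sequence_duration_ms
    assert EPOCH_MS <= seq_ms, "epoch window must fit inside a sequence"
    onsets = protocol.nontarget_sequence_indices() * seq_ms
    peaks = catalog.peak_times_ms()
    lat = [peaks[(peaks >= o) & (peaks < o + EPOCH_MS)] - o for o in onsets]
    return EpochSet(participant_id=catalog.participant_id,
                    epoch_onsets_ms=onsets, latencies_ms=lat)


def concatenate(epochs: EpochSet, fs: float = 500.0) -> np.ndarray:
    """Abut epochs into one impulse vector: 1 at blink-peak samples."""
    n_per = int(round(EPOCH_MS * fs / 1000.0))
    vec = np.zeros(epochs.n_epochs * n_per)
    for i, lat in enumerate(epochs.latencies_ms):
        idx = i * n_per + np.round(np.asarray(lat) * fs / 1000.0).astype(int)
        idx = idx[idx < (i + 1) * n_per]
        vec[idx] = 1.0
    return vec


def timeline_vector(epochs: EpochSet, fs: float = 500.0,
                    duration_ms: float | None = None) -> np.ndarray:
    """Impulse vector on the original session timeline: 1 at blink-peak
    samples of retained epochs, 0 everywhere else (excluded stretches are
    zeroed out rather than cut).

    Unlike :func:`concatenate`, this preserves the phase of the 750-ms tone
    cycle across epochs: abutting 3500-ms windows skips one third of a tone
    cycle per epoch, which scrambles phase-locked structure at the
    stimulus rate. The pipeline therefore uses this form for entrainment
    spectra.
    """
    if duration_ms is None:
        if epochs.n_epochs == 0:
            return np.array([])
        duration_ms = float(epochs.epoch_onsets_ms.max()) + EPOCH_MS
    n = int(round(duration_ms * fs / 1000.0))
    vec = np.zeros(n)
    for onset, lat in zip(epochs.epoch_onsets_ms, epochs.latencies_ms):
        idx = np.round((onset + np.asarray(lat)) * fs / 1000.0).astype(int)
        vec[idx[idx < n]] = 1.0
    return vec


def _probe_bin(freqs: np.ndarray, f: float) -> int:
    """Nearest grid bin; ties broken toward the lower frequency."""
    d = np.abs(freqs - f)
    lo = int(np.argmin(d))
    # argmin returns the first (lower-frequency) minimizer, which is the tie rule
    return lo


def fft_power(vector: np.ndarray, nfft: int = NFFT, fs: float = 500.0,
              probe_freqs: tuple[float, ...] = PROBE_FREQS_HZ,
              mode: str = "windowed") -> SpectrumResult:
    """Average |FFT|/N over consecutive non-overlapping N-sample windows.

    ``mode='single'`` analyzes only the first window. Vectors shorter than
    N are zero-padded with a warning; empty vectors give a flat zero
    spectrum.
    """
    vector = np.asarray(vector, dtype=float)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    if vector.size == 0:
        warnings.warn("empty vector: flat zero spectrum", stacklevel=2)
        power = np.zeros(len(freqs))
        n_windows = 0
    else:
        if len(vector) < nfft:
            warnings.warn("vector shorter than FFT size; zero-padding",
                          stacklevel=2)
            vector = np.pad(vector, (0, nfft - len(vector)))
        n_windows = len(vector) // nfft
        if mode == "single":
            n_windows = 1
        segs = vector[:n_windows * nfft].reshape(n_windows, nfft)
        power = np.mean(np.abs(np.fft.rfft(segs, axis=1)) / nfft, axis=0)

    peak, ref = {}, {}
    for f in probe_freqs:
        b = _probe_bin(freqs, f)
        peak[f] = float(power[b])
        lo, hi = max(0, b - REF_HALFWIDTH), min(len(power), b + REF_HALFWIDTH + 1)
        neigh = [i for i in range(lo, hi) if abs(i - b) > REF_EXCLUDE]
        ref[f] = float(np.median(power[neigh])) if neigh else np.nan
    return SpectrumResult(freqs_hz=freqs, power=power, peak_power=peak,
                          reference_power=ref, n_windows=n_windows)


def _effect_size_r(z: float, n_total: int, conventional: bool = False) -> float:
    return z / np.sqrt(n_total) if conventional else z / n_total


def entrainment_stats(group_a: list[SpectrumResult],
                      group_b: list[SpectrumResult],
                      probe_freqs: tuple[float, ...] = PROBE_FREQS_HZ,
                      conventional_r: bool = False) -> dict:
    """Within-group signed-rank tests of peak vs. reference power, and
    one-sided rank-sum tests of peak power between groups (A > B).

    Effect sizes follow r = Z / n (paired) and r = Z / (n1 + n2)
    (independent); set ``conventional_r`` for the Z/sqrt(n) variant.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 participants per group")
    report: dict = {}
    for f in probe_freqs:
        entry: dict = {}
        for name, grp in (("group_a", group_a), ("group_b", group_b)):
            pk = np.array([s.peak_power[f] for s in grp])
            rf = np.array([s.reference_power[f] for s in grp])
            d = pk - rf
            if np.allclose(d, 0):
                entry[name] = {"z": 0.0, "p": 1.0, "r": 0.0}
            else:
                res = stats.wilcoxon(pk, rf, alternative="greater",
                                     method="approx")
                z = float(res.zstatistic)
                entry[name] = {
                    "z": z, "p": float(res.pvalue),
                    "r": _effect_size_r(z, len(grp), conventional_r),
                }
        pa = np.array([s.peak_power[f] for s in group_a])
        pb = np.array([s.peak_power[f] for s in group_b])
        res = stats.ranksums(pa, pb, alternative="greater")
        z = float(res.statistic)
        entry["between"] = {
            "z": z, "p": float(res.pvalue),
            "r": _effect_size_r(z, len(pa) + len(pb), conventional_r),
        }
        report[f] = entry
    return report
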