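"""Probabilistic saccade detection from bipolar horizontal EOG.

Candidate events are velocity-magnitude peaks of the horizontal derivation.
Their features (peak velocity, displacement amplitude, duration) are
modeled by a two-component Gaussian mixture learned by EM on an
unsupervised training stretch of 50-200 s; the component with the larger
mean velocity is taken as the saccade class, and each event receives the
posterior probability of belonging to it. Events overlapping detected
blink intervals are excluded by default, separating genuine saccades from
peri-blink saccadic movements. This is a deliberately compact probabilistic
detector, not eye-tracking-grade metrology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sstats
from sklearn.mixture import GaussianMixture

from .blink_detect import BlinkCatalog

MIN_TRAIN_EVENTS = 10
TRAIN_WINDOW_RANGE_S = (50.0, 200.0)
#: adaptive candidate threshold: multiples of the robust SD of the velocity
VEL_THRESHOLD_ROBUST_SD = 4.0
SMOOTH_MS = 10.0


@dataclass
class SaccadeEvent:
    onset_ms: float
    duration_ms: float
    probability: float


@dataclass
class FeatureModel:
    mixture: GaussianMixture
    saccade_class: int
    feature_means: np.ndarray
    feature_sds: np.ndarray
    degenerate: bool


def horizontal_trace(channels: dict[str, np.ndarray]) -> np.ndarray:
    """Bipolar horizontal derivation leftLateral - rightLateral."""
    return channels["leftLateral"] - channels["rightLateral"]


def _velocity(trace: np.ndarray, fs: float) -> np.ndarray:
    n = max(3, int(round(SMOOTH_MS * fs / 1000.0)) | 1)
    k = np.ones(n) / n
    sm = np.convolve(trace, k, mode="same")
    return np.gradient(sm)


def _candidate_events(trace: np.ndarray, fs: float) -> list[dict]:
    """Velocity peaks above an adaptive robust threshold, with duration
    from half-peak velocity crossings and amplitude from the displacement
    across the event."""
    v = _velocity(trace, fs)
    av = np.abs(v)
    med = np.median(av)
    robust_sd = 1.48 * np.median(np.abs(av - med))
    thr = med + VEL_THRESHOLD_ROBUST_SD * max(robust_sd, 1e-12)

    above = av > thr
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    events = []
    for a, b in zip(starts, stops):
        pk = a + int(np.argmax(av[a:b]))
        # duration: same-velocity-sign run around the peak above a 10% floor
        sgn = np.sign(v[pk])
        floor = 0.1 * av[pk]
        lo = pk
        while lo > 0 and np.sign(v[lo - 1]) == sgn and av[lo - 1] > floor:
            lo -= 1
        hi = pk
        while hi < len(av) - 1 and np.sign(v[hi + 1]) == sgn \
                and av[hi + 1] > floor:
            hi += 1
        dur_ms = (hi - lo + 1) * 1000.0 / fs
        amp = abs(trace[min(hi + 2, len(trace) - 1)] - trace[max(lo - 2, 0)])
        events.append({
            "onset_ms": lo * 1000.0 / fs,
            "duration_ms": dur_ms,
            "peak_velocity": float(av[pk]),
            "amplitude": float(amp),
        })
    return events


def _feature_matrix(events: list[dict]) -> np.ndarray:
    return np.array([[e["peak_velocity"], e["amplitude"], e["duration_ms"]]
                     for e in events])


def train_feature_model(trace: np.ndarray, fs: float,
                        train_window_s: float = 120.0,
                        seed: int = 0) -> FeatureModel:
    """Fit the two-class Gaussian feature mixture on the training stretch."""
    if not TRAIN_WINDOW_RANGE_S[0] <= train_window_s <= TRAIN_WINDOW_RANGE_S[1]:
        raise ValueError("training window must lie in [50, 200] s")
    n_train = int(round(train_window_s * fs))
    if len(trace) < n_train:
        raise ValueError("trace shorter than the training window")
    events = _candidate_events(trace[:n_train], fs)
    if len(events) < MIN_TRAIN_EVENTS:
        raise ValueError(
            f"only {len(events)} candidate events in the training window; "
            f"need >= {MIN_TRAIN_EVENTS}")
    X = _feature_matrix(events)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         random_state=seed, n_init=5, reg_covar=1e-4)
    gm.fit(Z)
    sacc = int(np.argmax(gm.means_[:, 0]))  # larger mean velocity
    sep = abs(gm.means_[1, 0] - gm.means_[0, 0])
    degenerate = bool(sep < 0.5)  # components barely separated in velocity
    return FeatureModel(mixture=gm, saccade_class=sacc, feature_means=mu,
                        feature_sds=sd, degenerate=degenerate)


def score_events(trace: np.ndarray, model: FeatureModel, fs: float,
                 blink_catalog: Optional[BlinkCatalog] = None,
                 exclude_blinks: bool = True,
                 blink_pad_ms: float = 150.0) -> list[SaccadeEvent]:
    """Posterior saccade probability for every candidate event in the
    trace; events overlapping blink intervals are excluded by default."""
    events = _candidate_events(trace, fs)
    if not events:
        return []
    if exclude_blinks and blink_catalog is not None:
        windows = [(b.left_zero * 1000.0 / blink_catalog.fs - blink_pad_ms,
                    b.right_zero * 1000.0 / blink_catalog.fs + blink_pad_ms)
                   for b in blink_catalog.used]
        events = [e for e in events
                  if not any(lo <= e["onset_ms"] <= hi for lo, hi in windows)]
        if not events:
            return []
    Z = (_feature_matrix(events) - model.feature_means) / model.feature_sds
    post = model.mixture.predict_proba(Z)[:, model.saccade_class]
    return [SaccadeEvent(onset_ms=e["onset_ms"],
                         duration_ms=e["duration_ms"],
                         probability=float(p))
            for e, p in zip(events, post)]


def variance_compare(group_a: list[list[SaccadeEvent]],
                     group_b: list[list[SaccadeEvent]],
                     attribute: str = "probability") -> dict:
    """Rank-sum test on per-participant variances of an event attribute
    (saccade probability by default; duration with attribute='duration_ms');
    effect size r = Z / (n1 + n2)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 participants per group")

    def per_participant_var(group):
        return np.array([
            np.var([getattr(e, attribute) for e in evs]) if len(evs) > 1
            else 0.0 for evs in group])

    va, vb = per_participant_var(group_a), per_participant_var(group_b)
    degenerate = bool(np.all(va == va[0]) and np.all(vb == vb[0])
                      and va[0] == vb[0])
    res = sstats.ranksums(va, vb)
    z = float(res.statistic)
    return {
        "attribute": attribute,
        "variances_a": va.tolist(),
        "variances_b": vb.tolist(),
        "z": z,
        "p": float(res.pvalue),
        "r": z / (len(va) + len(vb)),
        "degenerate": degenerate,
    }
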