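"""Peri-stimulus hazard-rate slopes and cluster permutation inference.

For each participant, blink frequency is binned in 20-ms half-open bins
covering -300 to +300 ms around the potential target onsets at positions 2,
3 and 4 (onsets at 750, 1500, 2250 ms within the sequence window; one bin
edge coincides with onset). Regressing frequency on the centered position
codes (-1, 0, 1) with a Tukey-bisquare robust fit gives, per time bin, the
change in blink frequency per position step; a negative slope is
oculomotor inhibition growing with the target's hazard. Group-level
inference uses a one-sample cluster permutation test with sign-flipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distfit import BIN_MS
from .protocol import TARGET_POSITIONS
from .spectral import EpochSet, EPOCH_MS

PERISTIM_MS = 300.0
N_PERI_BINS = int(2 * PERISTIM_MS / BIN_MS)  # 30: 15 pre, 15 post
SOA_MS = 750.0
POSITION_ONSETS_MS = tuple((p - 1) * SOA_MS for p in TARGET_POSITIONS)
POSITION_CODES = np.array([-1.0, 0.0, 1.0])

BISQUARE_C = 4.685
#: bin left edges relative to target onset (ms)
PERI_BIN_EDGES_MS = np.arange(-PERISTIM_MS, PERISTIM_MS + BIN_MS, BIN_MS)


@dataclass
class PeristimMatrix:
    """positions (2,3,4) x peri-stimulus bins of blink frequency."""

    participant_id: str
    freq: np.ndarray  # shape (3, N_PERI_BINS)
    n_blinks: int


@dataclass
class Cluster:
    start_bin: int
    stop_bin: int  # exclusive
    mass: float
    p_value: float

    @property
    def start_ms(self) -> float:
        return float(PERI_BIN_EDGES_MS[self.start_bin])

    @property
    def stop_ms(self) -> float:
        return float(PERI_BIN_EDGES_MS[self.stop_bin])


@dataclass
class ClusterResult:
    t_per_bin: np.ndarray
    threshold: float
    clusters: list[Cluster]
    n_permutations: int
    exhaustive: bool

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]


def build_peristim(epochs: EpochSet) -> PeristimMatrix:
    """Blink frequency (counts normalized by total blinks, pre-smoothing)
    per 20-ms bin in the +/-300-ms windows around each position onset."""
    assert POSITION_ONSETS_MS[0] - PERISTIM_MS >= 0
    assert POSITION_ONSETS_MS[-1] + PERISTIM_MS <= EPOCH_MS
    lat = epochs.all_latencies()
    total = max(len(lat), 1)
    freq = np.zeros((len(POSITION_ONSETS_MS), N_PERI_BINS))
    for i, onset in enumerate(POSITION_ONSETS_MS):
        edges = onset + PERI_BIN_EDGES_MS
        counts, _ = np.histogram(lat, bins=edges)
        freq[i] = counts / total
    return PeristimMatrix(participant_id=epochs.participant_id, freq=freq,
                          n_blinks=len(lat))


def robust_slope(y: np.ndarray, max_iter: int = 50,
                 tol: float = 1e-12) -> float:
    """Tukey-bisquare IRLS slope of y against the centered position codes.

    Scale is 1.48 x MAD of the residuals; when the residual scale collapses
    (perfect line or all-equal values) the ordinary least-squares slope is
    returned, which the bisquare fit reduces to in the absence of outliers.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != 3:
        raise ValueError("expected one value per position (3)")
    if y[0] == y[1] == y[2]:
        return 0.0
    x = POSITION_CODES
    X = np.column_stack([np.ones(3), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(max_iter):
        resid = y - X @ beta
        scale = 1.48 * np.median(np.abs(resid - np.median(resid)))
        if scale < 1e-14:
            return float(beta[1])
        u = resid / (BISQUARE_C * scale)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        if w.sum() < 2 or np.count_nonzero(w) < 2:
            return float(beta[1])  # degenerate weighting: fall back to OLS
        W = np.diag(w)
        new = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return float(beta[1])


def slope_map(matrices: list[PeristimMatrix]) -> np.ndarray:
    """Per-participant x per-bin robust slopes across positions."""
    out = np.empty((len(matrices), N_PERI_BINS))
    for i, m in enumerate(matrices):
        for b in range(N_PERI_BINS):
            out[i, b] = robust_slope(m.freq[:, b])
    return out


def _per_bin_t(slopes: np.ndarray) -> np.ndarray:
    # moment form, shared with the permutation null so that the identity
    # sign pattern reproduces the observed t exactly
    n = slopes.shape[0]
    mean = slopes.mean(axis=0)
    var = (np.sum(slopes ** 2, axis=0) - n * mean ** 2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
    return t


def _find_clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    below = t < threshold
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def cluster_permutation_test(slopes: np.ndarray, alpha: float = 0.05,
                             n_perm: int = 2000, seed: int = 0,
                             method: str = "mass") -> ClusterResult:
    """One-sample cluster permutation test for negative slopes.

    Per-bin one-sample t statistics are thresholded at the one-sided
    critical t(alpha, n-1); contiguous sub-threshold bins form clusters
    whose mass (summed t) is compared against a sign-flipping null: each
    permutation flips the sign of every slope in a participant's vector and
    records the most negative cluster mass (``method='mass'``) or the most
    negative single-bin t (``method='tmax'``). Exhaustive enumeration is
    used when 2^n <= n_perm.
    """
    slopes = np.atleast_2d(np.asarray(slopes, dtype=float))
    n, n_bins = slopes.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse",
                      stacklevel=2)
    t_obs = _per_bin_t(slopes)
    t_crit = stats.t.ppf(alpha, df=n - 1)  # negative threshold

    exhaustive = 2 ** n <= n_perm
    if exhaustive:
        bits = np.arange(2 ** n)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)) & 1)  # (2^n, n)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n))
    signs = signs.astype(float)

    # sign flips leave per-bin second moments unchanged
    sumsq = np.sum(slopes ** 2, axis=0)
    means = signs @ slopes / n  # (P, n_bins)
    var = (sumsq - n * means ** 2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_null = np.where(var > 0, means / np.sqrt(var / n), 0.0)

    if method == "tmax":
        null_stat = t_null.min(axis=1)
    else:
        null_stat = np.zeros(t_null.shape[0])
        for i in range(t_null.shape[0]):
            masses = [t_null[i, a:b].sum()
                      for a, b in _find_clusters(t_null[i], t_crit)]
            null_stat[i] = min(masses) if masses else 0.0

    n_eff = len(null_stat)
    clusters = []
    for a, b in _find_clusters(t_obs, t_crit):
        mass = float(t_obs[a:b].sum())
        obs_stat = float(t_obs[a:b].min()) if method == "tmax" else mass
        p = (1.0 + np.sum(null_stat <= obs_stat)) / (n_eff + 1.0)
        clusters.append(Cluster(start_bin=int(a), stop_bin=int(b),
                                mass=mass, p_value=float(p)))
    return ClusterResult(t_per_bin=t_obs, threshold=float(t_crit),
                         clusters=clusters, n_permutations=n_eff,
                         exhaustive=exhaustive)
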