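"""Isochronous five-tone sequence protocol and its hazard-rate model.

The stimulus stream repeats five-tone sequences at a fixed 750-ms SOA: four
standard tones (440 Hz) followed by a sequence-final non-target deviant
(494 Hz). A rare target (349 Hz) replaces the standard at position 2, 3 or 4
in a subset of sequences, equiprobably across the three positions. Because a
listener knows the target has not yet occurred, its conditional (hazard)
probability rises with position: h_k = f_k / (1 - F_{k-1}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STANDARD_HZ = 440
DEVIANT_HZ = 494
TARGET_HZ = 349

TONES_PER_SEQUENCE = 5
TARGET_POSITIONS = (2, 3, 4)
#: Minimum number of target-free sequences immediately preceding a target
#: sequence (the first target sequence of the stream is exempt).
MIN_CLEAN_BEFORE_TARGET = 2


@dataclass(frozen=True)
class ToneEvent:
    """A single tone in the stream."""

    onset_ms: float
    pitch_hz: int
    role: str  # "standard" | "deviant" | "target"
    sequence_index: int
    position: int  # 1-based within the sequence (1..5)
    block: int  # 1..3


@dataclass
class Protocol:
    """An ordered tone stream plus the design parameters that produced it."""

    tones: list[ToneEvent]
    soa_ms: float
    n_sequences: int
    n_target_sequences: int
    seed: int

    @property
    def sequence_duration_ms(self) -> float:
        return TONES_PER_SEQUENCE * self.soa_ms

    @property
    def duration_ms(self) -> float:
        return self.n_sequences * self.sequence_duration_ms

    def target_sequence_indices(self) -> np.ndarray:
        return np.unique(
            [t.sequence_index for t in self.tones if t.role == "target"]
        )

    def nontarget_sequence_indices(self) -> np.ndarray:
        targets = set(self.target_sequence_indices().tolist())
        return np.array(
            [i for i in range(self.n_sequences) if i not in targets], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_ms": [t.onset_ms for t in self.tones],
                "pitch_hz": [t.pitch_hz for t in self.tones],
                "role": [t.role for t in self.tones],
                "sequence_index": [t.sequence_index for t in self.tones],
                "position": [t.position for t in self.tones],
                "block": [t.block for t in self.tones],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, soa_ms: float = 750.0,
                   seed: int = -1) -> "Protocol":
        tones = [
            ToneEvent(
                onset_ms=float(r.onset_ms),
                pitch_hz=int(r.pitch_hz),
                role=str(r.role),
                sequence_index=int(r.sequence_index),
                position=int(r.position),
                block=int(r.block),
            )
            for r in df.itertuples()
        ]
        n_seq = int(df["sequence_index"].max()) + 1 if len(df) else 0
        n_targ = int((df["role"] == "target").sum())
        return cls(tones=tones, soa_ms=soa_ms, n_sequences=n_seq,
                   n_target_sequences=n_targ, seed=seed)

    @classmethod
    def from_tsv(cls, path, soa_ms: float = 750.0) -> "Protocol":
        return cls.from_frame(pd.read_csv(path, sep="\t"), soa_ms=soa_ms)


@dataclass
class HazardTable:
    """Per-position target probability mass and the derived hazard.

    ``h[k] = f[k] / (1 - F[k-1])`` where ``F`` is the cumulative mass and the
    denominator is the survival probability evaluated just before position k.
    Positions with zero remaining mass and zero local mass get ``h = nan``
    (not applicable: the target can no longer occur there).
    """

    positions: tuple[int, ...]
    f: np.ndarray
    F: np.ndarray
    survival: np.ndarray  # 1 - F evaluated *before* each position
    h: np.ndarray


def hazard(f: Sequence[float], positions: tuple[int, ...] = TARGET_POSITIONS
           ) -> HazardTable:
    """Compute the hazard table for a per-position probability mass ``f``."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or len(f) != len(positions):
        raise ValueError("f must be one value per position")
    if np.any(f < 0):
        raise ValueError("probability mass must be non-negative")
    if not np.isclose(f.sum(), 1.0):
        raise ValueError("probability mass must sum to 1")

    F = np.cumsum(f)
    survival = 1.0 - np.concatenate([[0.0], F[:-1]])
    h = np.full_like(f, np.nan)
    for k in range(len(f)):
        if survival[k] > 1e-12:
            h[k] = f[k] / survival[k]
        elif f[k] > 0:
            raise ValueError(
                f"impossible mass: f[{k}] > 0 but survival is 0"
            )
        # survival 0 and f 0 -> nan (not applicable)
    return HazardTable(positions=tuple(positions), f=f, F=F,
                       survival=survival, h=h)


def _sample_spaced_indices(n: int, k: int, min_gap: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample k sorted indices in [0, n) with consecutive gaps
    >= min_gap (bijection onto unconstrained sorted subsets)."""
    m = n - (min_gap - 1) * (k - 1)
    if m < k:
        raise ValueError(
            f"cannot place {k} target sequences with gap >= {min_gap} "
            f"in {n} sequences"
        )
    base = np.sort(rng.choice(m, size=k, replace=False))
    return base + (min_gap - 1) * np.arange(k)


def generate_protocol(n_sequences: int = 240, n_target_sequences: int = 60,
                      soa_ms: float = 750.0, seed: int = 0) -> Protocol:
    """Generate a randomized protocol satisfying the design constraints.

    Target-containing sequences are separated by at least two target-free
    sequences, target positions are balanced across 2/3/4 (exactly when
    ``n_target_sequences`` is divisible by 3, maximally otherwise), and the
    stream is deterministic given ``seed``.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if not (0 <= n_target_sequences <= n_sequences):
        raise ValueError("n_target_sequences out of range")
    min_gap = MIN_CLEAN_BEFORE_TARGET + 1
    if n_target_sequences > 0 and \
            n_target_sequences * min_gap - MIN_CLEAN_BEFORE_TARGET > n_sequences:
        raise ValueError(
            "spacing constraint infeasible: need "
            f"{n_target_sequences * min_gap - MIN_CLEAN_BEFORE_TARGET} "
            f"sequences, have {n_sequences}"
        )

    rng = np.random.default_rng(seed)
    if n_target_sequences > 0:
        target_seqs = _sample_spaced_indices(
            n_sequences, n_target_sequences, min_gap, rng)
    else:
        target_seqs = np.array([], dtype=int)

    # balanced positions, shuffled across target sequences
    k = n_target_sequences
    if k % 3 != 0 and k > 0:
        warnings.warn(
            "n_target_sequences not divisible by 3; using maximal balance",
            stacklevel=2,
        )
    per = k // 3
    extra = k - 3 * per
    pos_pool = list(TARGET_POSITIONS) * per + list(
        rng.choice(TARGET_POSITIONS, size=extra, replace=False))
    pos_pool = np.array(pos_pool, dtype=int)
    rng.shuffle(pos_pool)
    target_pos = dict(zip(target_seqs.tolist(), pos_pool.tolist()))

    block_len = int(np.ceil(n_sequences / 3))
    tones: list[ToneEvent] = []
    for s in range(n_sequences):
        block = min(s // block_len, 2) + 1
        tpos = target_pos.get(s)
        for p in range(1, TONES_PER_SEQUENCE + 1):
            idx = s * TONES_PER_SEQUENCE + (p - 1)
            if p == TONES_PER_SEQUENCE:
                role, pitch = "deviant", DEVIANT_HZ
            elif p == tpos:
                role, pitch = "target", TARGET_HZ
            else:
                role, pitch = "standard", STANDARD_HZ
            tones.append(ToneEvent(onset_ms=idx * soa_ms, pitch_hz=pitch,
                                   role=role, sequence_index=s, position=p,
                                   block=block))
    return Protocol(tones=tones, soa_ms=soa_ms, n_sequences=n_sequences,
                    n_target_sequences=n_target_sequences, seed=seed)


@dataclass
class ValidationReport:
    role_counts: dict
    per_position_target_counts: dict
    global_probabilities: dict
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_protocol(p: Protocol) -> ValidationReport:
    """Check every protocol invariant; reports violations, never raises."""
    df = p.to_frame()
    violations: list[str] = []

    role_counts = df["role"].value_counts().to_dict()
    n_tones = len(df)
    global_probs = {r: c / n_tones for r, c in role_counts.items()} \
        if n_tones else {}

    # one deviant per sequence, always at position 5
    for s, grp in df.groupby("sequence_index"):
        dev = grp[grp["role"] == "deviant"]
        if len(dev) != 1 or (len(dev) and int(dev["position"].iloc[0]) != 5):
            violations.append(f"sequence {s}: deviant count/position wrong")
        tg = grp[grp["role"] == "target"]
        if len(tg) > 1:
            violations.append(f"sequence {s}: multiple targets")
        if len(tg) and int(tg["position"].iloc[0]) not in TARGET_POSITIONS:
            violations.append(f"sequence {s}: target at invalid position")

    # spacing: >=2 clean sequences before every target sequence but the first
    tseqs = np.sort(df.loc[df["role"] == "target", "sequence_index"].unique())
    for a, b in zip(tseqs[:-1], tseqs[1:]):
        if b - a < MIN_CLEAN_BEFORE_TARGET + 1:
            violations.append(f"spacing < {MIN_CLEAN_BEFORE_TARGET} between "
                              f"target sequences {a} and {b}")

    # onset grid
    expect = np.arange(len(df)) * p.soa_ms
    if len(df) and not np.allclose(df["onset_ms"].to_numpy(), expect):
        violations.append("onsets not on the SOA grid")

    per_pos = df.loc[df["role"] == "target", "position"] \
        .value_counts().to_dict()
    return ValidationReport(
        role_counts=role_counts,
        per_position_target_counts={int(k): int(v) for k, v in per_pos.items()},
        global_probabilities=global_probs,
        violations=violations,
    )


def derived_rates(soa_ms: float = 750.0,
                  tones_per_sequence: int = TONES_PER_SEQUENCE) -> dict:
    """Stimulation rates implied by the SOA: stimulus rate, its first
    harmonic, and the repeating-sequence rate (Hz)."""
    stim = 1000.0 / soa_ms
    return {
        "stimulus_rate_hz": stim,
        "first_harmonic_hz": 2.0 * stim,
        "sequence_rate_hz": stim / tones_per_sequence,
    }


def block_duration_s(n_sequences: int, soa_ms: float = 750.0,
                     tones_per_sequence: int = TONES_PER_SEQUENCE) -> float:
    """Duration of a block of ``n_sequences`` repeating sequences."""
    return n_sequences * tones_per_sequence * soa_ms / 1000.0
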