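"""Digit-triplet scheduling, stimulus timing, and response scoring.

The test presents triplets of spoken digits drawn from the nine
monosyllabic digits ("oh"=0, 1-6, 8-9; 7 is disyllabic and excluded).
Within a triplet no digit repeats, and within one test run no ordered
triplet is presented twice. Digit onsets are isochronous: the inter-onset
interval equals the duration of the longer of the first two digits plus a
fixed pad, which preserves a natural prosody while keeping rhythm constant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The nine monosyllabic digit labels used by the test. 7 is never a member.
DIGIT_SET: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 8, 9)

#: Number of ordered distinct-digit triplets available (9 * 8 * 7).
N_ORDERED_TRIPLETS = 9 * 8 * 7


class ExhaustedTripletsError(RuntimeError):
    """All 504 ordered triplets have already been presented."""


@dataclass(frozen=True)
class DigitSet:
    """Ordered set of digit labels available to the scheduler."""

    digits: tuple[int, ...] = DIGIT_SET

    def __post_init__(self) -> None:
        if tuple(sorted(self.digits)) != tuple(sorted(DIGIT_SET)):
            raise ValueError(f"digit set must be exactly {DIGIT_SET}")


@dataclass(frozen=True)
class Triplet:
    """One presented digit triplet with per-digit timing.

    ``onset_times`` are milliseconds from the onset of the first digit;
    ``durations`` are exemplar durations in ms. Timing fields may be empty
    when only the digit identities matter (e.g., scoring).
    """

    d1: int
    d2: int
    d3: int
    onset_times: tuple[float, float, float] | None = None
    durations: tuple[float, float, float] | None = None

    @property
    def digits(self) -> tuple[int, int, int]:
        return (self.d1, self.d2, self.d3)

    def __post_init__(self) -> None:
        ds = self.digits
        if len(set(ds)) != 3:
            raise ValueError(f"triplet digits must be distinct, got {ds}")
        for d in ds:
            if d not in DIGIT_SET:
                raise ValueError(f"digit {d} not in the nine-digit set")
        if self.onset_times is not None:
            o = self.onset_times
            if not (o[0] < o[1] < o[2]):
                raise ValueError("onset times must be strictly increasing")


@dataclass(frozen=True)
class TimingConfig:
    """Stimulus timing and level constants.

    All durations in milliseconds. The target level is fixed; SNR is varied
    by moving the masker level (masker = target - SNR).
    """

    inter_onset_pad_ms: float = 140.0
    babble_lead_ms: float = 600.0
    babble_lag_ms: float = 600.0
    cue_light_ms: float = 400.0
    target_level_dba: float = 62.0

    def __post_init__(self) -> None:
        for name in ("inter_onset_pad_ms", "babble_lead_ms", "babble_lag_ms",
                     "cue_light_ms", "target_level_dba"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TripletTiming:
    """Onset schedule for one triplet plus the babble masker window (ms)."""

    onsets_ms: tuple[float, float, float]
    inter_onset_ms: float
    babble_start_ms: float
    babble_end_ms: float


def compute_timing(d1_dur: float, d2_dur: float, d3_dur: float,
                   cfg: TimingConfig = TimingConfig()) -> TripletTiming:
    """Compute digit onsets and the babble window for one triplet.

    The inter-onset interval is identical between digits 1->2 and 2->3 and
    equals ``max(d1_dur, d2_dur) + inter_onset_pad_ms``. Babble starts
    ``babble_lead_ms`` before the first onset and ends ``babble_lag_ms``
    after the offset of the third digit.
    """
    if min(d1_dur, d2_dur, d3_dur) <= 0:
        raise ValueError("digit durations must be positive")
    ioi = max(d1_dur, d2_dur) + cfg.inter_onset_pad_ms
    onsets = (0.0, ioi, 2.0 * ioi)
    return TripletTiming(
        onsets_ms=onsets,
        inter_onset_ms=ioi,
        babble_start_ms=-cfg.babble_lead_ms,
        babble_end_ms=onsets[2] + d3_dur + cfg.babble_lag_ms,
    )


def score_response(target: Triplet | Sequence[int], response: Sequence[int]) -> bool:
    """A trial is correct iff all three digits match in order."""
    tgt = target.digits if isinstance(target, Triplet) else tuple(target)
    if len(response) != 3:
        raise ValueError("response must have exactly three entries")
    return tuple(response) == tuple(tgt)


def generate_triplet(rng: np.random.Generator,
                     history: Iterable[Triplet | tuple[int, int, int]] = ()) -> Triplet:
    """Draw a uniformly random ordered triplet not previously presented.

    Digits are sampled without replacement from the nine-digit set; any
    digit may occur in any position. Uniqueness is over the ordered digit
    sequence within ``history``.
    """
    used = {t.digits if isinstance(t, Triplet) else tuple(t) for t in history}
    if len(used) >= N_ORDERED_TRIPLETS:
        raise ExhaustedTripletsError(
            f"all {N_ORDERED_TRIPLETS} ordered triplets already presented")
    # Rejection sampling keeps the draw uniform over unused sequences; at
    # realistic run lengths (~25 trials) rejections are vanishingly rare.
    # Fall back to enumeration if the unused pool is tiny.
    for _ in range(1000):
        cand = tuple(rng.choice(len(DIGIT_SET), size=3, replace=False))
        digits = tuple(DIGIT_SET[i] for i in cand)
        if digits not in used:
            return Triplet(*digits)
    remaining = [t for t in itertools.permutations(DIGIT_SET, 3) if t not in used]
    digits = remaining[rng.integers(len(remaining))]
    return Triplet(*digits)


@dataclass
class TripletScheduler:
    """Stateful no-repeat triplet source for one test run."""

    rng: np.random.Generator
    history: list[Triplet] = field(default_factory=list)

    def next(self) -> Triplet:
        t = generate_triplet(self.rng, self.history)
        self.history.append(t)
        return t
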