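"""Three-phase adaptive SNR staircase and SRT computation.

The track opens with a one-up/one-down descent in 6 dB steps from a
starting SNR well above threshold (+14 dB colocated, +11 dB separated).
The first incorrect response is the first reversal: the step drops to
3 dB and SNR rises until the next correct response (second reversal).
From there a two-down/one-up rule in 3 dB steps tracks the SNR at which
the triplet is reported correctly 70.7% of the time (the sqrt(0.5) fixed
point of the 2-down/1-up rule). The track stops at the sixth reversal
recorded during this final phase, and the SRT is the arithmetic mean of
the SNRs at those six reversals. The two phase-transition reversals are
not among the six averaged.

A reversal's SNR is the SNR presented on the trial at which the movement
direction flips -- the track extremum, the standard transformed up-down
convention. On entry to the tracking phase the correct response that
triggered the transition counts as the first of a down-pair and the
nominal direction is "down", so the first tracked down-step does not
register as a reversal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .listener import ListenerProfile, respond
from .triplets import TimingConfig, Triplet, TripletScheduler


class Phase(str, enum.Enum):
    DESCEND_1U1D = "DESCEND_1U1D"
    RECOVER = "RECOVER"
    TRACK_2D1U = "TRACK_2D1U"
    DONE = "DONE"


class TrackStateError(RuntimeError):
    """Raised on contract violations (advancing a finished track, etc.)."""


@dataclass(frozen=True)
class TrackConfig:
    """Staircase parameters.

    ``start_snr_db`` defaults to the colocated (0 deg) start; use +11 for
    the separated (90 deg) condition. ``max_trials`` is a safety bound for
    non-converging tracks; no SNR ceiling or floor is imposed.
    """

    start_snr_db: float = 14.0
    big_step_db: float = 6.0
    small_step_db: float = 3.0
    reversals_to_stop: int = 6
    max_trials: int = 60

    def __post_init__(self) -> None:
        if not (self.big_step_db > self.small_step_db > 0):
            raise ValueError("need big_step_db > small_step_db > 0")
        if self.reversals_to_stop < 2:
            raise ValueError("reversals_to_stop must be >= 2")

    @classmethod
    def for_condition(cls, condition: str, **kw) -> "TrackConfig":
        """Condition defaults: '0'/'colocated' -> +14 dB, '90'/'separated' -> +11 dB."""
        cond = str(condition).lower()
        if cond in ("0", "colocated"):
            return cls(start_snr_db=kw.pop("start_snr_db", 14.0), **kw)
        if cond in ("90", "separated"):
            return cls(start_snr_db=kw.pop("start_snr_db", 11.0), **kw)
        raise ValueError(f"unknown condition {condition!r}")


@dataclass
class TrialRecord:
    trial_index: int
    snr_db: float
    digits: tuple[int, int, int] | None
    response: tuple[int, int, int] | None
    correct: bool
    phase: str
    reversal_flag: bool

    def to_json_dict(self) -> dict:
        return {
            "trial_index": self.trial_index,
            "snr_db": round(self.snr_db, 2),
            "digits": list(self.digits) if self.digits else None,
            "response": list(self.response) if self.response else None,
            "correct": self.correct,
            "phase": self.phase,
            "reversal_flag": self.reversal_flag,
        }


@dataclass
class TrackState:
    """Complete state of one adaptive run."""

    cfg: TrackConfig
    phase: Phase = Phase.DESCEND_1U1D
    current_snr_db: float = field(default=None)  # type: ignore[assignment]
    consecutive_correct: int = 0
    reversal_snrs: list[float] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)
    last_direction: str = "none"  # {"down", "up", "none"}
    converged: bool = False

    def __post_init__(self) -> None:
        if self.current_snr_db is None:
            self.current_snr_db = self.cfg.start_snr_db

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class SrtResult:
    """Outcome of one adaptive track."""

    srt_db: float | None
    n_trials: int
    reversal_snrs: tuple[float, ...]
    converged: bool


def advance(state: TrackState, correct: bool, *,
            digits: tuple[int, int, int] | None = None,
            response: tuple[int, int, int] | None = None) -> TrackState:
    """Record one trial outcome at the current SNR and update the track.

    Mutates and returns ``state``. The trial is scored at
    ``state.current_snr_db``; the SNR for the *next* trial is set according
    to the phase rules described in the module docstring.
    """
    if state.phase is Phase.DONE:
        raise TrackStateError("cannot advance a finished track")
    cfg = state.cfg
    snr = state.current_snr_db
    reversal = False

    if state.phase is Phase.DESCEND_1U1D:
        if correct:
            state.current_snr_db = snr - cfg.big_step_db
            state.last_direction = "down"
        else:
            # first reversal of the whole track: shrink step, start recovery
            state.phase = Phase.RECOVER
            state.current_snr_db = snr + cfg.small_step_db
            state.last_direction = "up"
    elif state.phase is Phase.RECOVER:
        if correct:
            # second transition reversal: enter 2-down/1-up; this correct
            # counts as the first of a down-pair and SNR does not move
            state.phase = Phase.TRACK_2D1U
            state.consecutive_correct = 1
            state.last_direction = "down"
        else:
            state.current_snr_db = snr + cfg.small_step_db
            state.last_direction = "up"
    elif state.phase is Phase.TRACK_2D1U:
        if correct:
            state.consecutive_correct += 1
            if state.consecutive_correct >= 2:
                state.consecutive_correct = 0
                if state.last_direction == "up":
                    reversal = True
                    state.reversal_snrs.append(snr)
                state.current_snr_db = snr - cfg.small_step_db
                state.last_direction = "down"
        else:
            state.consecutive_correct = 0
            if state.last_direction == "down":
                reversal = True
                state.reversal_snrs.append(snr)
            state.current_snr_db = snr + cfg.small_step_db
            state.last_direction = "up"

    state.trials.append(TrialRecord(
        trial_index=len(state.trials), snr_db=snr, digits=digits,
        response=response, correct=correct, phase=state.phase.value,
        reversal_flag=reversal))

    if len(state.reversal_snrs) >= cfg.reversals_to_stop:
        state.phase = Phase.DONE
        state.converged = True
    elif len(state.trials) >= cfg.max_trials:
        state.phase = Phase.DONE
        state.converged = False
    return state


def compute_srt(state: TrackState) -> SrtResult:
    """Mean of the final-phase reversal SNRs; only valid once DONE."""
    if state.phase is not Phase.DONE:
        raise TrackStateError("SRT requested before the track finished")
    if state.converged:
        srt = float(np.mean(state.reversal_snrs))
    else:
        srt = None
    return SrtResult(srt_db=srt, n_trials=state.n_trials,
                     reversal_snrs=tuple(state.reversal_snrs),
                     converged=state.converged)


def run_scripted(script: Sequence[bool], cfg: TrackConfig) -> tuple[SrtResult, TrackState]:
    """Run the staircase against a fixed correct/incorrect response script.

    Stops at convergence, at ``max_trials``, or when the script is
    exhausted (the latter marks the track unconverged unless already DONE).
    """
    state = TrackState(cfg=cfg)
    for correct in script:
        if state.phase is Phase.DONE:
            break
        advance(state, bool(correct))
    if state.phase is not Phase.DONE:
        state.phase = Phase.DONE
        state.converged = len(state.reversal_snrs) >= cfg.reversals_to_stop
    return compute_srt(state), state


def run_track(listener: ListenerProfile, cfg: TrackConfig,
              condition: str = "colocated",
              rng: np.random.Generator | None = None,
              respond_fn: Callable[..., tuple[tuple[int, int, int], bool]] | None = None,
              ) -> tuple[SrtResult, TrackState]:
    """Run one full adaptive track on a simulated listener.

    Composes the no-repeat triplet scheduler, the listener's stochastic
    response model, and the staircase rules. Returns the SRT result and the
    final track state (whose ``trials`` list is the session log).
    """
    rng = np.random.default_rng() if rng is None else rng
    sched = TripletScheduler(rng=rng)
    state = TrackState(cfg=cfg)
    do_respond = respond_fn or respond
    while state.phase is not Phase.DONE:
        triplet = sched.next()
        resp, correct = do_respond(listener, triplet, state.current_snr_db,
                                   condition=condition, rng=rng)
        advance(state, correct, digits=triplet.digits, response=resp)
    return compute_srt(state), state
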