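"""Simulated listener producing stochastic digit responses.

Per-digit recognition follows a guessing-corrected Boltzmann (logistic)
psychometric function

    Pc(snr) = 0.11 + (1 - 0.11) / (1 + exp(-beta * (snr - srt50)))

where 0.11 is chance for a closed set of nine digits, beta the slope
(per dB) and srt50 the midpoint, at which Pc = 0.555. Digits within a
triplet are recognized independently (the test pools over positions), so
the triplet-level probability is the product of the three per-digit
probabilities. In the spatially separated condition the listener gains a
fixed SNR advantage -- spatial release from masking (SRM) -- modelled as a
shift of the effective SNR.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .triplets import DIGIT_SET, Triplet

#: Chance performance for a closed set of nine response alternatives
#: (1/9 rounded to two decimals, as the scoring model defines it).
GUESS_RATE = 0.11

#: Triplet-level proportion correct tracked by the 2-down/1-up rule.
TRACKED_P_TRIPLET = math.sqrt(0.5)  # ~0.7071

#: Per-digit proportion corresponding to the tracked triplet level.
TRACKED_P_DIGIT = TRACKED_P_TRIPLET ** (1.0 / 3.0)  # ~0.8909

#: Default psychometric slope (per dB) for simulated adults; children's
#: slopes are shallower and default to 0.75x this value.
DEFAULT_BETA_ADULT = 0.7
CHILD_BETA_FACTOR = 0.75


@dataclass(frozen=True)
class BoltzmannParams:
    """Parameters of one guessing-corrected Boltzmann function."""

    beta: float
    srt50_db: float
    guess_rate: float = GUESS_RATE

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 < self.guess_rate < 1):
            raise ValueError("guess_rate must be in (0, 1)")


def p_digit(params: BoltzmannParams, snr: float) -> float:
    """Probability of reporting one digit correctly at the given SNR."""
    g = params.guess_rate
    z = params.beta * (np.asarray(snr, dtype=float) - params.srt50_db)
    p = g + (1.0 - g) / (1.0 + np.exp(-z))
    return float(p) if np.ndim(snr) == 0 else p


def digit_srt50_for_triplet_srt(triplet_srt_db: float, beta: float,
                                guess_rate: float = GUESS_RATE) -> float:
    """Per-digit midpoint placing the triplet 70.7% point at ``triplet_srt_db``.

    The staircase converges where the triplet probability is sqrt(0.5),
    i.e., per-digit p = 0.5^(1/6) ~ 0.891. Solving the Boltzmann function
    for that probability gives the offset between a listener's triplet SRT
    and the per-digit srt50.
    """
    p = TRACKED_P_DIGIT
    core = (p - guess_rate) / (1.0 - guess_rate)
    return triplet_srt_db - math.log(core / (1.0 - core)) / beta


@dataclass(frozen=True)
class ListenerProfile:
    """Simulated participant.

    ``digit_params`` maps each of the nine digits to its Boltzmann
    function (shared slope, per-digit midpoint offsets). ``srm_db`` is the
    SNR advantage applied in the separated condition.
    """

    digit_params: dict[int, BoltzmannParams]
    srm_db: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.digit_params) != set(DIGIT_SET):
            raise ValueError("digit_params must cover exactly the nine digits")

    @classmethod
    def from_triplet_srt(cls, triplet_srt_db: float, beta: float = DEFAULT_BETA_ADULT,
                         srm_db: float = 0.0, digit_offsets_db: dict[int, float] | None = None,
                         label: str = "") -> "ListenerProfile":
        """Build a listener whose colocated triplet SRT is ``triplet_srt_db``.

        ``digit_offsets_db`` adds per-digit midpoint deviations (dB) around
        the common midpoint, emulating residual intelligibility differences.
        """
        base = digit_srt50_for_triplet_srt(triplet_srt_db, beta)
        offs = digit_offsets_db or {}
        params = {d: BoltzmannParams(beta=beta, srt50_db=base + offs.get(d, 0.0))
                  for d in DIGIT_SET}
        return cls(digit_params=params, srm_db=srm_db, label=label)

    def effective_snr(self, snr_db: float, condition: str) -> float:
        cond = str(condition).lower()
        if cond in ("90", "separated"):
            return snr_db + self.srm_db
        if cond in ("0", "colocated"):
            return snr_db
        raise ValueError(f"unknown condition {condition!r}")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "label": self.label,
            "srm_db": self.srm_db,
            "digits": {str(d): {"beta": p.beta, "srt50_db": p.srt50_db,
                                "guess_rate": p.guess_rate}
                       for d, p in self.digit_params.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ListenerProfile":
        obj = json.loads(Path(path).read_text())
        params = {int(d): BoltzmannParams(**v) for d, v in obj["digits"].items()}
        return cls(digit_params=params, srm_db=obj.get("srm_db", 0.0),
                   label=obj.get("label", ""))


def p_triplet(listener: ListenerProfile, triplet: Triplet, snr_db: float,
              condition: str = "colocated") -> float:
    """Probability the whole triplet is reported correctly (in order)."""
    eff = listener.effective_snr(snr_db, condition)
    p = 1.0
    for d in triplet.digits:
        p *= p_digit(listener.digit_params[d], eff)
    return p


def respond(listener: ListenerProfile, triplet: Triplet, snr_db: float,
            condition: str = "colocated",
            rng: np.random.Generator | None = None,
            ) -> tuple[tuple[int, int, int], bool]:
    """Draw one stochastic response to a presented triplet.

    Each digit is independently correct with its Boltzmann probability at
    the effective SNR; a missed digit is replaced by a uniform draw from
    the other eight digits (confusions are not modelled). The trial is
    correct iff all three reported digits match in order.
    """
    rng = np.random.default_rng() if rng is None else rng
    eff = listener.effective_snr(snr_db, condition)
    out = []
    for d in triplet.digits:
        if rng.random() < p_digit(listener.digit_params[d], eff):
            out.append(d)
        else:
            others = [x for x in DIGIT_SET if x != d]
            out.append(others[rng.integers(8)])
    resp = (out[0], out[1], out[2])
    return resp, resp == triplet.digits
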