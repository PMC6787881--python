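"""Test-retest agreement via Bland-Altman 95% limits of agreement.

The paired difference d = Run 1 SRT - Run 2 SRT is summarized by its mean
(the average practice/learning effect), its sample SD (time-related
individual variation), and the normal-theory interval
mean +/- 1.96 * SD, expected to contain 95% of test-retest differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def limits_of_agreement(run1: Sequence[float], run2: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement between paired Run 1 / Run 2 SRTs (dB)."""
    a = np.asarray(run1, dtype=float)
    b = np.asarray(run2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("run1 and run2 must be 1-D and the same length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired measurements")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        mean_diff=mean, sd_diff=sd,
        loa_low=mean - LOA_MULTIPLIER * sd,
        loa_high=mean + LOA_MULTIPLIER * sd,
        n=len(d))
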