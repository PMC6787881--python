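"""Synthetic study cohort emulating the normative sample.

Generates tables of {participant, age, condition, run, SRT} that follow
the child age regressions and adult means of the normative model, with a
between-subject true component, an independent per-run measurement noise,
a practice (learning) improvement between runs in the colocated
condition, and an age-constant spatial release from masking (SRM).

The printed residual SDs of the norms describe *observed* first-run
scatter, which already contains measurement noise; the generator
therefore decomposes each norm SD into a between-subject component
sqrt(norm_sd^2 - run_noise_sd^2) plus the per-run noise, so that refitted
norms and test-retest statistics are simultaneously consistent with the
normative model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .listener import CHILD_BETA_FACTOR, DEFAULT_BETA_ADULT, ListenerProfile
from .norms import DEFAULT_NORMS, NormSet


@dataclass(frozen=True)
class CohortSpec:
    """Study-sample generator parameters.

    Defaults mirror the normative study: 100 children aged 4.08-13.0 y
    (uniform), 23 adults; practice improvements of 0.6 dB (children) and
    1.0 dB (adults) in the colocated condition only; per-run measurement
    noise of 1.6 dB SD. SRM is age-constant with mean 6.0 dB (children)
    and 6.8 dB (adults, the difference of the adult condition means);
    ``srm_age_slope_db_per_yr`` (default 0) exposes the alternative
    hypothesis of age-growing SRM.
    """

    n_children: int = 100
    n_adults: int = 23
    age_min: float = 4.08
    age_max: float = 13.0
    norms: NormSet = field(default_factory=NormSet)
    srm_mean_child_db: float = 6.0
    srm_sd_child_db: float = 1.4
    srm_mean_adult_db: float = 6.8
    srm_sd_adult_db: float = 0.8
    srm_age_slope_db_per_yr: float = 0.0
    practice_child_0_db: float = 0.6
    practice_child_90_db: float = 0.0
    practice_adult_0_db: float = 1.0
    practice_adult_90_db: float = 0.0
    run_noise_sd_db: float = 1.6

    def __post_init__(self) -> None:
        for name in ("srm_sd_child_db", "srm_sd_adult_db", "run_noise_sd_db"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _between_sd(norm_sd: float, run_noise_sd: float) -> float:
    """Between-subject SD once per-run noise is removed from the norm SD."""
    v = norm_sd ** 2 - run_noise_sd ** 2
    if v < 0:
        raise ValueError(
            f"run noise SD {run_noise_sd} exceeds norm SD {norm_sd}; "
            "the norm scatter cannot be decomposed")
    return math.sqrt(v)


def generate_cohort(spec: CohortSpec, rng: np.random.Generator,
                    return_listeners: bool = False):
    """Draw one synthetic cohort.

    Returns a long-format DataFrame with columns ``id``, ``group``,
    ``age_years`` (NaN for adults), ``condition`` ('0'/'90'), ``run``
    (1/2), ``srt_db``. With ``return_listeners=True`` also returns a list
    of :class:`ListenerProfile` (one per participant, built from the true
    colocated SRT and true SRM, child slopes shallower than adults').
    """
    rows = []
    listeners = []
    noise = spec.run_noise_sd_db
    between_c0 = _between_sd(spec.norms.child_0.residual_sd_db, noise)
    between_a0 = _between_sd(spec.norms.adult_0.sd_db, noise)

    def emit(pid, group, age, true_0, srm_true, practice_0, practice_90):
        true_90 = true_0 - srm_true
        for cond, true_srt, practice in (("0", true_0, practice_0),
                                         ("90", true_90, practice_90)):
            for run in (1, 2):
                obs = true_srt + rng.normal(0.0, noise)
                if run == 2:
                    obs -= practice
                rows.append({"id": pid, "group": group,
                             "age_years": age, "condition": cond,
                             "run": run, "srt_db": obs})
        if return_listeners:
            beta = DEFAULT_BETA_ADULT * (CHILD_BETA_FACTOR if group == "child" else 1.0)
            listeners.append(ListenerProfile.from_triplet_srt(
                true_0, beta=beta, srm_db=srm_true, label=pid))

    for i in range(spec.n_children):
        age = float(rng.uniform(spec.age_min, spec.age_max))
        true_0 = spec.norms.child_0.mean_srt(age) + rng.normal(0.0, between_c0)
        srm_true = (spec.srm_mean_child_db
                    + spec.srm_age_slope_db_per_yr * (age - 8.5)
                    + rng.normal(0.0, spec.srm_sd_child_db))
        emit(f"C{i:03d}", "child", age, true_0, srm_true,
             spec.practice_child_0_db, spec.practice_child_90_db)

    for i in range(spec.n_adults):
        true_0 = spec.norms.adult_0.mean_db + rng.normal(0.0, between_a0)
        srm_true = spec.srm_mean_adult_db + rng.normal(0.0, spec.srm_sd_adult_db)
        emit(f"A{i:03d}", "adult", float("nan"), true_0, srm_true,
             spec.practice_adult_0_db, spec.practice_adult_90_db)

    df = pd.DataFrame(rows)
    if return_listeners:
        return df, listeners
    return df


def sample_child_listeners(n: int, rng: np.random.Generator,
                           condition: str = "0",
                           norms: NormSet = DEFAULT_NORMS,
                           beta: float = DEFAULT_BETA_ADULT * CHILD_BETA_FACTOR,
                           age_min: float = 4.0, age_max: float = 13.0,
                           ) -> list[ListenerProfile]:
    """Child listeners with triplet SRTs drawn from a printed child norm.

    Ages are uniform on [age_min, age_max]; each listener's true triplet
    SRT in the requested condition is the norm regression mean at their
    age plus Gaussian residual with the norm's residual SD. Used for
    trial-count and convergence simulations, where the listener's
    threshold in the tested condition is what matters, so the profile is
    built directly at that SRT with srm_db = 0.
    """
    norm = norms.child(condition)
    out = []
    for i in range(n):
        age = float(rng.uniform(age_min, age_max))
        srt = norm.mean_srt(age) + rng.normal(0.0, norm.residual_sd_db)
        out.append(ListenerProfile.from_triplet_srt(srt, beta=beta,
                                                    label=f"sim{i:04d}"))
    return out
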