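"""Boltzmann psychometric fitting and digit homogenization.

After data collection, each digit's relative intelligibility is estimated
by pooling every presentation of that digit -- across test and retest,
across the colocated and separated conditions, and across the three
triplet positions -- on an SNR axis *relative to the SRT of the track in
which it was presented*. A guessing-corrected Boltzmann function with
floor 0.11 is fitted per digit by Bernoulli maximum likelihood. Digits
whose data never span the transition region cannot constrain the slope;
they are refitted with the slope fixed to the mean slope of the
well-defined digits, leaving the midpoint as the only free parameter.
The per-digit level adjustments that would equate intelligibility are the
deviations of each midpoint from the mean midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar, minimize

from .listener import GUESS_RATE, BoltzmannParams
from .triplets import DIGIT_SET

#: Upper bound on the fitted slope; a fit pinned here is ill-defined.
BETA_MAX = 5.0
BETA_MIN = 1e-3


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted psychometric parameters with diagnostics."""

    params: BoltzmannParams
    slope_fixed: bool
    n_trials: int
    log_likelihood: float
    ill_defined: bool


def _nll(beta: float, srt50: float, snr: np.ndarray, correct: np.ndarray,
         guess: float) -> float:
    z = beta * (snr - srt50)
    p = guess + (1.0 - guess) / (1.0 + np.exp(-z))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(correct, np.log(p), np.log1p(-p))))


def _is_ill_defined(snr: np.ndarray, correct: np.ndarray, beta_hat: float,
                    min_low_obs: int = 10, low_acc: float = 0.70) -> bool:
    """Data cannot constrain the slope.

    Criterion: fewer than ``min_low_obs`` observations falling in 1 dB bins
    whose empirical accuracy is below ``low_acc`` (performance rarely dips
    into the transition region), or the fitted slope pinned at its bound.
    """
    if beta_hat >= BETA_MAX * (1 - 1e-6):
        return True
    bins = np.floor(snr).astype(int)
    n_low = 0
    for b in np.unique(bins):
        m = bins == b
        if correct[m].mean() < low_acc:
            n_low += int(m.sum())
    return n_low < min_low_obs


def fit_boltzmann(data: Sequence[tuple[float, bool]] | np.ndarray,
                  fixed_beta: float | None = None,
                  guess_rate: float = GUESS_RATE) -> BoltzmannFit:
    """Maximum-likelihood Boltzmann fit to Bernoulli (SNR, correct) trials.

    The guessing floor is fixed. With ``fixed_beta`` supplied only the
    midpoint is free (the fixed-slope refit for ill-defined digits);
    otherwise both slope and midpoint are estimated.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("data must be (n, 2): (relative SNR, correct)")
    if arr.shape[0] < 20:
        raise FitError(f"need >= 20 observations, got {arr.shape[0]}")
    snr = arr[:, 0]
    correct = arr[:, 1].astype(bool)
    n = len(snr)

    if fixed_beta is not None:
        if fixed_beta <= 0:
            raise ValueError("fixed_beta must be positive")
        res = minimize_scalar(
            lambda m: _nll(fixed_beta, m, snr, correct, guess_rate),
            bounds=(snr.min() - 30.0, snr.max() + 30.0), method="bounded")
        params = BoltzmannParams(beta=fixed_beta, srt50_db=float(res.x),
                                 guess_rate=guess_rate)
        return BoltzmannFit(params=params, slope_fixed=True, n_trials=n,
                            log_likelihood=-float(res.fun), ill_defined=False)

    best = None
    for beta0, mid0 in [(0.7, float(np.median(snr))), (0.2, 0.0), (2.0, 0.0)]:
        res = minimize(lambda th: _nll(th[0], th[1], snr, correct, guess_rate),
                       x0=[beta0, mid0], method="L-BFGS-B",
                       bounds=[(BETA_MIN, BETA_MAX),
                               (snr.min() - 30.0, snr.max() + 30.0)])
        if best is None or res.fun < best.fun:
            best = res
    beta_hat, mid_hat = float(best.x[0]), float(best.x[1])
    ill = (not best.success) or _is_ill_defined(snr, correct, beta_hat)
    params = BoltzmannParams(beta=beta_hat, srt50_db=mid_hat, guess_rate=guess_rate)
    return BoltzmannFit(params=params, slope_fixed=False, n_trials=n,
                        log_likelihood=-float(best.fun), ill_defined=ill)


def relative_snr_dataset(logs: Iterable) -> dict[int, list[tuple[float, bool]]]:
    """Pool per-digit Bernoulli observations on a track-relative SNR axis.

    ``logs`` is an iterable of finished tracks: objects with a converged
    ``SrtResult`` (``.srt_db``) and a trial list carrying ``snr_db``,
    ``digits`` and ``response``. Each presented digit contributes one
    observation at (trial SNR - track SRT); the digit is scored correct
    iff the response matches at its position. Non-converged tracks are
    skipped with a warning.
    """
    import warnings

    out: dict[int, list[tuple[float, bool]]] = {d: [] for d in DIGIT_SET}
    for result, state in logs:
        if not result.converged or result.srt_db is None:
            warnings.warn("skipping non-converged track in pooling", stacklevel=2)
            continue
        for tr in state.trials:
            if tr.digits is None or tr.response is None:
                continue
            rel = tr.snr_db - result.srt_db
            for pos in range(3):
                out[tr.digits[pos]].append((rel, tr.digits[pos] == tr.response[pos]))
    return out


def fit_digit_set(per_digit: Mapping[int, Sequence[tuple[float, bool]]],
                  guess_rate: float = GUESS_RATE) -> dict[int, BoltzmannFit]:
    """Fit all nine digits; refit ill-defined ones with the common slope.

    The common slope is the unweighted mean of the free-fit slopes of the
    well-defined digits.
    """
    first = {d: fit_boltzmann(per_digit[d], guess_rate=guess_rate) for d in DIGIT_SET}
    good = [f.params.beta for f in first.values() if not f.ill_defined]
    if not good:
        raise FitError("no digit yielded a well-defined slope")
    common = float(np.mean(good))
    out = {}
    for d, f in first.items():
        if f.ill_defined:
            out[d] = fit_boltzmann(per_digit[d], fixed_beta=common,
                                   guess_rate=guess_rate)
        else:
            out[d] = f
    return out


@dataclass(frozen=True)
class HomogenizationTable:
    """Per-digit dB adjustments equating intelligibility.

    ``adjustment(d) = mean(srt50) - srt50(d)``: positive for digits easier
    than average (midpoint below the mean). Defined as deviations from the
    mean midpoint, the adjustments sum to ~0.
    """

    adjustments_db: dict[int, float]

    @property
    def range_db(self) -> tuple[float, float]:
        vals = list(self.adjustments_db.values())
        return (min(vals), max(vals))


def homogenize(fits: Mapping[int, BoltzmannFit | BoltzmannParams]) -> HomogenizationTable:
    """Level adjustments that equate the nine digits' intelligibility."""
    mids = {}
    for d, f in fits.items():
        p = f.params if isinstance(f, BoltzmannFit) else f
        mids[d] = p.srt50_db
    if set(mids) != set(DIGIT_SET) and len(mids) < 2:
        raise ValueError("need fits for at least two digits")
    mean_mid = float(np.mean(list(mids.values())))
    return HomogenizationTable(
        adjustments_db={d: mean_mid - m for d, m in mids.items()})
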