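"""Adaptive staircase: worked traces, contracts, and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dintest.listener import BoltzmannParams, ListenerProfile
from dintest.staircase import (
    Phase, SrtResult, TrackConfig, TrackState, TrackStateError, advance,
    compute_srt, run_scripted, run_track,
)
from dintest.triplets import DIGIT_SET


# --------------------------------------------------------------- oracle
# Straight-line re-statement of the tracking rules, kept deliberately
# separate from the engine: one flat loop over the response script.

def oracle_trace(script, start=14.0, big=6.0, small=3.0, n_rev=6, max_trials=60):
    """Return (presented SNRs, final-phase reversal SNRs, srt-or-None)."""
    snr = start
    phase = "descend"
    last = None     # 'd' or 'u'
    pair = 0
    presented, revs = [], []
    for resp in script:
        if len(revs) >= n_rev or len(presented) >= max_trials:
            break
        presented.append(snr)
        if phase == "descend":
            if resp:
                snr -= big
                last = "d"
            else:
                phase = "recover"
                snr += small
                last = "u"
        elif phase == "recover":
            if resp:
                phase = "track"
                pair = 1
                last = "d"
            else:
                snr += small
                last = "u"
        else:
            if resp:
                pair += 1
                if pair == 2:
                    pair = 0
                    if last == "u":
                        revs.append(presented[-1])
                    snr -= small
                    last = "d"
            else:
                pair = 0
                if last == "d":
                    revs.append(presented[-1])
                snr += small
                last = "u"
    srt = sum(revs) / len(revs) if len(revs) >= n_rev else None
    return presented, revs, srt


WORKED_SCRIPT = [c == "C" for c in "CCCWCCWCCWCCWCC"]


class TestWorkedTrace:
    def test_snr_path_reversals_and_srt(self):
        """The canonical 15-trial script descends 14->-4, then alternates
        between -1 and -4 in the tracking phase, yielding SRT -2.5 dB."""
        res, state = run_scripted(WORKED_SCRIPT, TrackConfig(start_snr_db=14))
        assert [t.snr_db for t in state.trials] == [
            14, 8, 2, -4, -1, -1, -4, -1, -1, -4, -1, -1, -4, -1, -1]
        assert res.reversal_snrs == (-4, -1, -4, -1, -4, -1)
        assert res.srt_db == -2.5
        assert res.n_trials == 15
        assert res.converged

    def test_oracle_agrees_on_worked_trace(self):
        presented, revs, srt = oracle_trace(WORKED_SCRIPT)
        assert presented == [14, 8, 2, -4, -1, -1, -4, -1, -1, -4, -1, -1, -4, -1, -1]
        assert srt == -2.5

    def test_all_correct_descends_monotonically(self):
        res, state = run_scripted([True] * 60, TrackConfig(start_snr_db=14))
        snrs = [t.snr_db for t in state.trials]
        assert snrs == [14 - 6 * i for i in range(60)]
        assert res.reversal_snrs == ()
        assert not res.converged
        assert res.srt_db is None


class TestContracts:
    def test_advance_after_done_raises(self):
        state = TrackState(cfg=TrackConfig(max_trials=3))
        for _ in range(3):
            advance(state, True)
        assert state.phase is Phase.DONE
        with pytest.raises(TrackStateError):
            advance(state, True)

    def test_srt_before_done_raises(self):
        state = TrackState(cfg=TrackConfig())
        advance(state, True)
        with pytest.raises(TrackStateError):
            compute_srt(state)

    def test_max_trials_flags_nonconvergence(self):
        res, _ = run_scripted([True] * 200, TrackConfig(max_trials=20))
        assert res.n_trials == 20
        assert not res.converged

    def test_condition_start_snrs(self):
        assert TrackConfig.for_condition("0").start_snr_db == 14
        assert TrackConfig.for_condition("colocated").start_snr_db == 14
        assert TrackConfig.for_condition("90").start_snr_db == 11
        assert TrackConfig.for_condition("separated").start_snr_db == 11

    def test_equal_reversals_average_to_themselves(self):
        state = TrackState(cfg=TrackConfig())
        state.reversal_snrs = [-3.0] * 6
        state.phase = Phase.DONE
        state.converged = True
        assert compute_srt(state).srt_db == -3.0


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.lists(st.booleans(), min_size=1, max_size=80))
def test_engine_matches_oracle_on_random_scripts(script):
    """For any scripted response sequence the engine's presented SNRs,
    reversal SNRs and SRT equal the straight-line oracle's."""
    res, state = run_scripted(script, TrackConfig(start_snr_db=14))
    presented, revs, srt = oracle_trace(script)
    assert [t.snr_db for t in state.trials] == presented
    assert list(res.reversal_snrs) == revs
    assert res.srt_db == srt


class TestRunTrack:
    @staticmethod
    def _flat_listener(srt50: float, beta: float = 0.7) -> ListenerProfile:
        params = {d: BoltzmannParams(beta=beta, srt50_db=srt50) for d in DIGIT_SET}
        return ListenerProfile(digit_params=params)

    def test_fixed_seed_reproduces_log_bit_identically(self):
        lst = self._flat_listener(-4.0)
        runs = []
        for _ in range(2):
            res, state = run_track(lst, TrackConfig(), rng=np.random.default_rng(99))
            runs.append((res, [(t.snr_db, t.digits, t.response, t.correct)
                               for t in state.trials]))
        assert runs[0] == runs[1]

    def test_deterministic_listener_srt_near_threshold(self):
        """A listener correct iff SNR >= -2.5 yields SRT within one small
        step of -2.5 dB (here exactly, by the alternation of the track)."""
        def respond_fn(listener, triplet, snr, condition, rng):
            ok = snr >= -2.5
            return (triplet.digits if ok else (0, 1, 2)), ok

        res, _ = run_track(None, TrackConfig(start_snr_db=14),
                           rng=np.random.default_rng(1), respond_fn=respond_fn)
        assert res.converged
        assert abs(res.srt_db - (-2.5)) <= 3.0
        assert res.srt_db == -2.5

    def test_srt_invariant_under_uniform_shift(self):
        """Shifting listener threshold and start SNR by +k shifts the SRT
        by exactly +k under matched response randomness."""
        k = 4.0
        base = self._flat_listener(-4.0)
        shifted = self._flat_listener(-4.0 + k)
        r0, _ = run_track(base, TrackConfig(start_snr_db=14),
                          rng=np.random.default_rng(17))
        r1, _ = run_track(shifted, TrackConfig(start_snr_db=14 + k),
                          rng=np.random.default_rng(17))
        assert r1.srt_db == r0.srt_db + k

    def test_session_log_has_no_repeated_triplet(self):
        lst = self._flat_listener(-4.0)
        _, state = run_track(lst, TrackConfig(), rng=np.random.default_rng(3))
        seen = [t.digits for t in state.trials]
        assert len(set(seen)) == len(seen)
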