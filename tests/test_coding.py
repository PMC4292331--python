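import numpy as np
import pandas as pd
import pytest

from rangeplan.coding import (AlignmentError, UndefinedGradientError,
                              align_trial, apply_exclusions, classify_errors,
                              code_trial, contrast_value, correct_tone_table,
                              error_rate, error_rates_by_accent,
                              intensity_by_accent, mean_range,
                              movement_gradient, similar_proportion)
from rangeplan.score import ErrorRecord, Performance, Score

IOI = 225.0

# one-hand test score: 17 events, excerpt at positions 4..11
_PITCHES = np.array([60, 64, 62, 65, 64, 60, 62, 64, 67, 60, 64, 65,
                     62, 60, 67, 64, 62])


def one_hand_score():
    return Score(pitches={"R": _PITCHES.copy()}, context_label="short",
                 pre_len=4, excerpt_len=8)


def perform(score, hand="R", ioi=IOI, velocity=64, edits=None,
            extra=None, drop=None, **meta):
    """Build a clean performance of a score, with optional tampering.

    ``edits`` maps position -> produced pitch; ``extra`` is a list of
    (onset_ms, pitch) additions; ``drop`` is a set of deleted positions.
    """
    edits, extra, drop = edits or {}, extra or [], set(drop or ())
    rows = []
    for hand_label, seq in score.pitches.items():
        for i, p in enumerate(seq):
            if (hand_label, i) in {(hand, d) for d in drop}:
                continue
            pitch = edits.get(i, int(p)) if hand_label == hand else int(p)
            rows.append(dict(onset_ms=i * ioi, pitch=pitch,
                             velocity=velocity, hand=hand_label))
    for onset, pitch in extra:
        rows.append(dict(onset_ms=onset, pitch=pitch, velocity=velocity,
                         hand=hand))
    ks = pd.DataFrame(rows).sort_values("onset_ms", kind="stable")
    return Performance(keystrokes=ks.reset_index(drop=True),
                       ioi_nominal_ms=ioi, **meta)


class TestAlignment:
    def test_error_free_performance_aligns_perfectly(self):
        score = one_hand_score()
        al = align_trial(score, perform(score))
        ha = al.hands["R"]
        assert len(ha.matches) == score.n_positions
        assert not ha.deletions and not ha.insertions
        assert classify_errors(al) == []

    def test_truncated_performance_raises(self):
        score = one_hand_score()
        perf = perform(score)
        short = Performance(keystrokes=perf.keystrokes.head(5),
                            ioi_nominal_ms=IOI)
        with pytest.raises(AlignmentError):
            align_trial(score, short)

    def test_empty_performance_raises(self):
        score = one_hand_score()
        with pytest.raises(AlignmentError):
            align_trial(score, Performance(
                keystrokes=pd.DataFrame(columns=["onset_ms", "pitch",
                                                 "velocity", "hand"])))

    def test_conservation_of_events(self):
        score = one_hand_score()
        perf = perform(score, edits={6: 59}, drop={9},
                       extra=[(3.5 * IOI, 58)])
        al = align_trial(score, perf)
        ha = al.hands["R"]
        assert len(ha.matches) + len(ha.deletions) == score.n_positions
        assert len(ha.matches) + len(ha.insertions) == len(perf.by_hand("R"))

    def test_produced_ioi_estimate(self):
        score = one_hand_score()
        al = align_trial(score, perform(score, ioi=230.0))
        assert al.produced_ioi_ms() == pytest.approx(230.0)


class TestClassification:
    def test_contextual_substitution_distance_and_direction(self):
        score = one_hand_score()
        # position 6 (62) replaced by 65, whose nearest occurrence is position 3
        recs = code_trial(score, perform(score, edits={6: 65}))
        assert len(recs) == 1
        r = recs[0]
        assert r.error_type == "substitution" and r.contextual
        assert r.signed_source_distance == -3
        assert r.direction == "perseveratory"
        assert r.target_pitch == 62 and r.intruder_pitch == 65

    def test_anticipatory_tie_preference(self):
        # position 5 (60) -> 64: sources at 4 and 7; nearest is -1
        score = one_hand_score()
        recs = code_trial(score, perform(score, edits={5: 64}))
        assert recs[0].signed_source_distance == -1
        # position 12 (62) -> 64: sources at 10 and 15, exact +-2/+3 tie? (10->-2)
        recs = code_trial(score, perform(score, edits={12: 64}))
        assert recs[0].signed_source_distance == -2

    def test_exchange_coded_as_single_error(self):
        # intended A-E-D-C produced A-D-E-C (positions 0..3 of a toy score)
        score = Score(pitches={"R": np.array([69, 76, 74, 72, 69, 74, 76, 72,
                                              69, 74, 76, 72, 74, 72, 76, 74,
                                              69])},
                      context_label="short", pre_len=4, excerpt_len=8)
        recs = code_trial(score, perform(score, edits={1: 74, 2: 76}))
        assert len(recs) == 1
        r = recs[0]
        assert r.error_type == "exchange"
        assert r.target_position == 1
        assert r.signed_source_distance == 1
        assert r.contextual

    def test_chord_error_is_single_record(self):
        score = one_hand_score()
        # two wrong keystrokes 40 ms apart replacing position 8
        perf = perform(score, drop={8},
                       extra=[(8 * IOI, 59), (8 * IOI + 40, 66)])
        recs = code_trial(score, perform_sorted(perf))
        chords = [r for r in recs if r.error_type == "chord_error"]
        assert len(chords) == 1 and len(recs) == 1
        assert chords[0].chord_pitches == (59, 66)
        # representative intruder is nearest in pitch height to the target (67)
        assert chords[0].intruder_pitch == 66

    def test_noncontextual_intruder(self):
        score = one_hand_score()
        recs = code_trial(score, perform(score, edits={6: 59}))
        assert not recs[0].contextual
        assert recs[0].signed_source_distance is None

    def test_deletion_and_addition(self):
        score = one_hand_score()
        recs = code_trial(score, perform(score, drop={9}))
        assert [r.error_type for r in recs] == ["deletion"]
        recs = code_trial(score, perform(
            score, extra=[(5.55 * IOI, 59)]))
        assert [r.error_type for r in recs] == ["addition"]
        assert recs[0].target_position == 6

    def test_key_and_chord_flags(self):
        score = one_hand_score()  # C major; triad {0, 4, 7}
        recs = code_trial(score, perform(score, edits={6: 59}))  # B: in key
        assert recs[0].in_key and not recs[0].in_chord
        recs = code_trial(score, perform(score, edits={6: 61}))  # C#: neither
        assert not recs[0].in_key and not recs[0].in_chord
        recs = code_trial(score, perform(score, edits={6: 72}))  # C: both
        assert recs[0].in_key and recs[0].in_chord
        assert recs[0].semitone_distance == 10


def perform_sorted(perf):
    ks = perf.keystrokes.sort_values("onset_ms", kind="stable")
    return Performance(keystrokes=ks.reset_index(drop=True),
                       ioi_nominal_ms=perf.ioi_nominal_ms)


class TestExclusions:
    def _records(self, n_trials, positions, learning_positions=()):
        recs = []
        for trial in range(n_trials):
            block, rep = trial // 2 + 1, trial % 2 + 1
            for pos in positions[trial]:
                recs.append(ErrorRecord(
                    error_type="substitution", contextual=True, hand="R",
                    target_position=pos, target_pitch=60, intruder_pitch=62,
                    signed_source_distance=2, block=block, repetition=rep))
        learn = [ErrorRecord(error_type="substitution", contextual=True,
                             hand="R", target_position=pos, target_pitch=60,
                             intruder_pitch=62, block=0)
                 for pos in learning_positions]
        return recs, learn

    def test_learned_error_excluded(self):
        recs, learn = self._records(8, [[5]] * 5 + [[], [], []],
                                    learning_positions=[5])
        apply_exclusions(recs, learn)
        assert all(r.excluded and r.exclusion_reason == "learned"
                   for r in recs)

    def test_frequent_error_with_clean_learning_retained(self):
        recs, learn = self._records(8, [[5]] * 5 + [[], [], []])
        apply_exclusions(recs, learn)
        assert not any(r.excluded for r in recs)

    def test_rare_error_with_learning_error_retained(self):
        recs, learn = self._records(8, [[5], [5], [5], [], [], [], [], []],
                                    learning_positions=[5])
        apply_exclusions(recs, learn)
        assert not any(r.excluded for r in recs)

    def test_missing_learning_data_warns(self):
        recs, _ = self._records(8, [[5]] * 8)
        with pytest.warns(UserWarning):
            apply_exclusions(recs, None)

    def test_corrected_error_excluded(self):
        score = one_hand_score()
        # wrong key at position 7's slot, correct pitch re-struck 100 ms later
        perf = perform(score, drop={7},
                       extra=[(7 * IOI, 59), (7 * IOI + 100, 64)])
        recs = code_trial(score, perform_sorted(perf))
        apply_exclusions(recs, [])
        errors = [r for r in recs if r.error_type != "deletion"]
        assert len(errors) == 1
        assert errors[0].excluded
        assert errors[0].exclusion_reason == "corrected"

    def test_plain_addition_is_not_a_correction(self):
        score = one_hand_score()
        recs = code_trial(score, perform(score, extra=[(5.55 * IOI, 59)]))
        apply_exclusions(recs, [])
        assert not recs[0].excluded


class TestSummaries:
    def _recs(self, distances):
        return [ErrorRecord(error_type="substitution", contextual=True,
                            hand="R", target_position=5, target_pitch=60,
                            intruder_pitch=62, signed_source_distance=d,
                            in_excerpt=True)
                for d in distances]

    def test_all_distance_one(self):
        recs = self._recs([1, -1, 1])
        g = movement_gradient(recs)
        assert g.proportions.tolist() == [1, 0, 0, 0, 0, 0, 0, 0]
        assert mean_range(recs) == 1.0

    def test_mixed_distances(self):
        recs = self._recs([2, -2, 4])
        assert similar_proportion(recs) == 1.0
        assert mean_range(recs) == pytest.approx(8 / 3)
        assert movement_gradient(recs).n_errors == 3

    def test_empty_signals_undefined(self):
        with pytest.raises(UndefinedGradientError):
            movement_gradient([])
        with pytest.raises(UndefinedGradientError):
            mean_range(self._recs([None]))

    def test_excluded_records_do_not_enter(self):
        recs = self._recs([1, 3])
        recs[1].excluded = True
        assert movement_gradient(recs).proportions[0] == 1.0

    def test_exchange_counts_once(self):
        score = one_hand_score()
        recs = code_trial(score, perform(score, edits={5: 62, 6: 60}))
        assert len(recs) == 1
        g = movement_gradient(recs)
        assert g.n_errors == 1


class TestAccentRates:
    def test_uniform_errors_give_equal_rates(self, short_score):
        recs = []
        counts = short_score.accent_counts()
        for pos in short_score.excerpt_positions:
            recs.append(ErrorRecord(
                error_type="substitution", contextual=True, hand="R",
                target_position=int(pos), target_pitch=60, intruder_pitch=62,
                accent_at_target=int(counts[pos]), in_excerpt=True))
        rates = error_rates_by_accent(recs, short_score, n_trials=1)
        # one error per position; opportunity adjustment equalises levels
        assert np.allclose(rates, rates[0])
        assert contrast_value(rates) == pytest.approx(0.0, abs=1e-12)

    def test_decreasing_rates_give_negative_contrast(self):
        assert contrast_value(np.array([0.12, 0.09, 0.07, 0.06])) < 0
        assert contrast_value(np.array([0.06, 0.07, 0.09, 0.12])) > 0

    def test_error_rate_denominator(self):
        recs = [ErrorRecord(error_type="deletion", contextual=False, hand="R",
                            target_position=1, target_pitch=60,
                            intruder_pitch=None)] * 2
        assert error_rate(recs, 16) == pytest.approx(2 / 16)
        assert error_rate(recs, 16, include_deletions=False) == 0.0


class TestIntensities:
    def test_velocity_table_and_accent_means(self):
        score = one_hand_score()
        perf = perform(score)
        al = align_trial(score, perf)
        table = correct_tone_table(al)
        assert len(table) == score.n_positions
        means = intensity_by_accent(table)
        assert (means == 64).all()
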