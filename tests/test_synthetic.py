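import numpy as np
import pytest

from rangeplan.coding import code_trial
from rangeplan.synthetic import (KEYS, GenerativeTruth, generate_design,
                                 generate_performance, generate_stimulus_pair,
                                 mean_recurrence_distance, trial_tables)


class TestStimuli:
    def test_layout_lengths(self, stimulus_pair):
        long_s, short_s = stimulus_pair
        assert long_s.n_positions == 33 and long_s.pre_len == 12
        assert short_s.n_positions == 17 and short_s.pre_len == 4
        assert long_s.post_len == 13 and short_s.post_len == 5

    def test_excerpt_and_flanks_shared(self, stimulus_pair):
        long_s, short_s = stimulus_pair
        for hand in ("R", "L"):
            # the whole short layout is embedded in the long one
            assert np.array_equal(long_s.pitches[hand][8:25],
                                  short_s.pitches[hand])

    def test_no_successive_repeats_many_seeds(self):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            long_s, short_s = generate_stimulus_pair(
                KEYS[seed % 8], excerpt_id=seed % 8 + 1, rng=rng)
            for s in (long_s, short_s):
                for seq in s.pitches.values():
                    assert np.all(np.diff(seq) != 0)

    def test_recurrence_band_100_seeds(self):
        dists = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            long_s, _ = generate_stimulus_pair(KEYS[seed % 8], rng=rng)
            dists.append(mean_recurrence_distance(long_s.pitches["R"]))
        dists = np.array(dists)
        assert np.all((dists >= 5.0) & (dists <= 7.0))

    def test_diatonic_material(self, stimulus_pair):
        long_s, _ = stimulus_pair
        scale = long_s.scale_pcs()
        for seq in long_s.pitches.values():
            assert all(p % 12 in scale for p in seq)

    def test_excerpt_accent_composition(self, long_score):
        counts = long_score.accent_counts()[long_score.excerpt_positions]
        assert sorted(counts.tolist()) == [1, 1, 1, 1, 2, 2, 3, 4]


class TestDesign:
    def test_trial_counts(self):
        design = generate_design(26)
        assert len(design) == 26 * 64
        per = design.groupby("participant").size()
        assert (per == 64).all()

    def test_condition_balance(self):
        design = generate_design(4)
        cells = design.groupby(["participant", "context_label",
                                "tempo_label"]).size()
        assert (cells == 16).all()

    def test_context_order_counterbalanced(self):
        design = generate_design(2)
        first = design[design.trial == 1].set_index("participant")
        assert set(first["context_label"]) == {"long", "short"}

    def test_tempo_alternates_every_trial(self):
        design = generate_design(3)
        for _, sub in design.groupby("participant"):
            labels = sub.sort_values("trial")["tempo_label"].tolist()
            assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_each_piece_twice_per_block(self):
        design = generate_design(1)
        reps = design.groupby(["block", "excerpt_id"]).size()
        assert (reps == 2).all()


class TestGeneratePerformance:
    def test_zero_error_rate_is_score_up_to_jitter(self, long_score):
        truth = GenerativeTruth(base_error_rate=0.0, timing_jitter_sd_ms=0.0)
        perf, gt = generate_performance(long_score, truth, 225.0, seed=0)
        assert gt == []
        for hand in ("R", "L"):
            ks = perf.by_hand(hand)
            assert np.array_equal(ks["pitch"].to_numpy(),
                                  long_score.pitches[hand])
            assert np.allclose(ks["onset_ms"].to_numpy(),
                               np.arange(33) * 225.0)

    def test_hand_velocity_means(self, long_score):
        truth = GenerativeTruth(base_error_rate=0.0, velocity_sd=0.0)
        rng = np.random.default_rng(1)
        perf, _ = generate_performance(long_score, truth, 225.0, rng=rng)
        vr = perf.by_hand("R")["velocity"].mean()
        vl = perf.by_hand("L")["velocity"].mean()
        # accent term averages near zero over the grid; hand offsets dominate
        assert vr == pytest.approx(74.7, abs=1.5)
        assert vl == pytest.approx(58.8, abs=1.5)
        assert vr - vl == pytest.approx(74.7 - 58.8, abs=1.0)

    def test_velocity_scales_with_accent(self, long_score):
        truth = GenerativeTruth(base_error_rate=0.0, velocity_sd=0.0)
        perf, _ = generate_performance(long_score, truth, 225.0, seed=2)
        ks = perf.by_hand("R")
        counts = long_score.accent_counts()
        strong = ks["velocity"][counts == 4].mean()
        weak = ks["velocity"][counts == 1].mean()
        # integer MIDI velocities: the 3-level accent span, up to rounding
        assert strong - weak == pytest.approx(3.5 * 3, abs=0.6)

    def test_contextual_sources_respect_nearest_coding(self, long_score,
                                                       clean_truth):
        tables = trial_tables(long_score, clean_truth, 225.0)
        for hand in ("R", "L"):
            seq = long_score.pitches[hand]
            for i, cand in enumerate(tables[hand].candidates):
                if cand is None:
                    continue
                xs, probs = cand
                assert probs.sum() == pytest.approx(1.0)
                for x in xs:
                    q = seq[i + x]
                    occ = np.flatnonzero(seq == q)
                    assert np.min(np.abs(occ - i)) == abs(x)

    def test_planted_error_rate_near_truth(self, stimulus_pair, clean_truth):
        long_s, short_s = stimulus_pair
        n_events = n_errors = 0
        for seed in range(60):
            sc = long_s if seed % 2 else short_s
            perf, gt = generate_performance(sc, clean_truth, 225.0,
                                            seed=1000 + seed)
            n_events += 2 * sc.n_positions
            n_errors += len(gt)
        rate = n_errors / n_events
        assert 0.06 < rate < 0.16

    def test_meter_on_favours_even_distances(self, long_score):
        def even_share(truth, base_seed):
            dist = []
            for s in range(80):
                _, gt = generate_performance(long_score, truth, 225.0,
                                             seed=base_seed + s)
                dist += [abs(r.signed_source_distance) for r in gt
                         if r.signed_source_distance is not None]
            dist = np.array(dist)
            return (dist % 2 == 0).mean()

        on = GenerativeTruth(w2_true=0.5, w2_short_true=0.5,
                             timing_jitter_sd_ms=0.0, correction_prob=0.0)
        off = GenerativeTruth(use_meter=False, timing_jitter_sd_ms=0.0,
                              correction_prob=0.0)
        assert even_share(on, 0) > even_share(off, 0)

    def test_corrections_marked_excluded_in_truth(self, long_score):
        truth = GenerativeTruth(correction_prob=1.0, timing_jitter_sd_ms=0.0)
        excluded = total = 0
        for s in range(30):
            _, gt = generate_performance(long_score, truth, 225.0, seed=s)
            for r in gt:
                if r.error_type == "substitution" and r.contextual:
                    total += 1
                    excluded += r.excluded and r.exclusion_reason == "corrected"
        assert total > 0 and excluded == total


class TestCohortRoundTrip:
    def test_planted_errors_recode_exactly(self, stimulus_pair, clean_truth):
        """Coded records equal planted ground truth with no jitter/corrections."""
        long_s, short_s = stimulus_pair
        checked = 0
        for seed in range(150):
            sc = long_s if seed % 2 else short_s
            ioi = 187.5 if seed % 3 else 225.0
            perf, gt = generate_performance(sc, clean_truth, ioi,
                                            seed=5000 + seed)
            recs = code_trial(sc, perf)
            assert sorted(r.key() for r in recs) == sorted(r.key() for r in gt)
            checked += len(gt)
        assert checked > 300

    def test_jittered_trials_agree_above_99_percent(self, stimulus_pair):
        truth = GenerativeTruth(timing_jitter_sd_ms=20.0, correction_prob=0.0)
        long_s, short_s = stimulus_pair
        agree = total = 0
        for seed in range(150):
            sc = long_s if seed % 2 else short_s
            perf, gt = generate_performance(sc, truth, 187.5 if seed % 3
                                            else 225.0, seed=7000 + seed)
            recs = code_trial(sc, perf)
            planted = {r.key() for r in gt}
            coded = {r.key() for r in recs}
            total += len(planted)
            agree += len(planted & coded)
        assert agree / total >= 0.99

    def test_cohort_structure(self, small_cohort):
        assert len(small_cohort.trials) == 4 * 64
        assert len(small_cohort.stimuli) == 16
        assert len(small_cohort.learning_trials) == 4 * 8 * 2
        # per-trial substreams: regenerating one trial reproduces it
        tr = small_cohort.trials[17]
        row = small_cohort.design.iloc[17]
        score = small_cohort.stimuli[(row.excerpt_id, row.context_label)]
        rng = np.random.default_rng((7, int(row.participant), int(row.trial)))
        perf, _ = generate_performance(
            score, small_cohort.truth, row.tempo_ioi_ms, rng=rng,
            meta=dict(participant=int(row.participant), block=int(row.block),
                      repetition=int(row.repetition),
                      tempo_label=row.tempo_label))
        assert np.array_equal(perf.keystrokes["pitch"],
                              tr.performance.keystrokes["pitch"])
        assert np.allclose(perf.keystrokes["onset_ms"],
                           tr.performance.keystrokes["onset_ms"])
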