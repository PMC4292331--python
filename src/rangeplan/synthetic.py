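"""Synthetic study generator: stimuli, cohort design, and performances.

Emulates the study design this package analyses at desk scale: 8 composed
excerpts of 8 per-hand sixteenth-note events, each embedded in a long
(12+8+13) and a short (4+8+5) per-hand context sharing the excerpt and its
immediate flanks; 26 pianists; 64 test trials each (pieces crossed with two
tempi over 4 blocks x 2 repetitions, tempo alternating every trial, context
order counterbalanced across blocks and participants).

Performances are generated from the range model itself: each event errs
with a probability modulated by the condition's mean event activation
(tempo and context effects) and by the event's metrical accent strength;
contextual intruders are drawn from the surrounding context in proportion
to serial proximity x metrical similarity; keystroke velocities scale with
accent and differ by hand; onsets carry Gaussian jitter.  Full ground truth
is returned so the error coder can be validated by exact round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrical import accent_strengths, build_grid, make_weights
from .model import RangeParams, event_activation, predicted_gradient
from .score import LAYOUTS, ErrorRecord, Performance, Score

__all__ = [
    "KEYS",
    "TEMPI_MS",
    "GenerativeTruth",
    "StimulusGenerationError",
    "mean_recurrence_distance",
    "generate_stimulus_pair",
    "generate_design",
    "trial_tables",
    "generate_performance",
    "Cohort",
    "Trial",
    "generate_cohort",
    "condition_profile",
    "reference_activation",
]

#: keys of the 8 excerpts: half major, half harmonic minor
KEYS = [("C", "major"), ("C", "major"), ("G", "major"), ("F", "major"),
        ("C", "minor"), ("G", "minor"), ("D", "minor"), ("A", "minor")]

TEMPI_MS = {"fast": 187.5, "medium": 225.0, "slow": 429.0}

MEAN_ACCENT = 1.875  # cycle mean of the 4-level accent counts [4,1,2,1,3,1,2,1]
_RECURRENCE_BAND = (5.0, 7.0)
_RH_OCTAVE = 60  # C4; right hand plays in 60..71
_LH_OCTAVE = 36  # C2; left hand plays in 36..47 (registers never overlap)


class StimulusGenerationError(RuntimeError):
    """Constraint satisfaction failed after bounded retries."""


@dataclass(frozen=True)
class GenerativeTruth:
    """Ground-truth parameters of the synthetic performer.

    Error probabilities follow ``p_err(i) = base_error_rate *
    exp(-lambda_rate * (E_cond - E_ref)) * exp(-beta_accent * (c_i - c_bar))``
    where ``E_cond`` is the condition's mean current-event activation (so
    slower tempi and longer contexts lower the rate, as the model's
    activation account implies) and ``c_i`` the accent count at the event
    (so strongly accented events err less, the observed accent effect).
    The tactus weight of the generating process is context-dependent
    (``w2_true`` for long, ``w2_short_true`` for short layouts): longer
    contexts give the metrical hierarchy more time to instantiate, which
    is the model's account of why planning reaches further in them.
    """

    a_true: float = 0.85
    w2_true: float = 0.48
    w2_short_true: float = 0.40
    base_error_rate: float = 0.115
    lambda_rate: float = 0.5
    beta_accent: float = 0.23
    p_contextual: float = 0.81
    p_deletion: float = 0.60  # noncontextual mix: deletions dominate
    p_nc_substitution: float = 0.25
    p_nc_addition: float = 0.15
    right_hand_velocity: float = 74.7
    left_hand_velocity: float = 58.8
    accent_slope: float = 3.5  # MIDI velocity units per accent level
    velocity_sd: float = 4.0
    timing_jitter_sd_ms: float = 8.0
    correction_prob: float = 0.04
    exchange_prob: float = 0.3
    use_meter: bool = True
    window: int = 8

    def __post_init__(self) -> None:
        if not 0.8 < self.a_true <= 1.0:
            raise ValueError("a_true outside (0.8, 1.0]")
        if not 0.25 <= self.w2_true <= 0.99:
            raise ValueError("w2_true outside [0.25, 0.99]")
        if not 0.25 <= self.w2_short_true <= 0.99:
            raise ValueError("w2_short_true outside [0.25, 0.99]")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate outside [0, 0.5)")
        mix = self.p_deletion + self.p_nc_substitution + self.p_nc_addition
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("noncontextual mix must sum to 1")

    def w2_for(self, context_label: str) -> float:
        """Tactus weight of the generating process for a context layout.

        Longer contexts instantiate the metrical hierarchy more strongly,
        so the tactus carries more weight in the long layout than in the
        short one; the defaults are the study's fitted condition means.
        """
        return self.w2_true if context_label == "long" else self.w2_short_true

    def weights(self, context_label: str = "long"):
        return make_weights(4, 2, self.w2_for(context_label))

    def params(self, t: float, context_label: str = "long") -> RangeParams:
        return RangeParams(a=self.a_true, t=t,
                           weights=self.weights(context_label),
                           window=self.window, use_meter=self.use_meter)

    def with_(self, **kw) -> "GenerativeTruth":
        return replace(self, **kw)


def mean_recurrence_distance(pitches) -> float:
    """Mean distance to the nearest previous occurrence of the same pitch."""
    seq = np.asarray(pitches)
    last: dict = {}
    dists = []
    for i, p in enumerate(seq):
        p = int(p)
        if p in last:
            dists.append(i - last[p])
        last[p] = i
    if not dists:
        return float("inf")
    return float(np.mean(dists))


def _diatonic_pitches(tonic: str, mode: str, octave_base: int) -> np.ndarray:
    from .score import scale_pitch_classes

    pcs = scale_pitch_classes(tonic, mode)
    return np.array(sorted(octave_base + pc for pc in pcs))


def _sample_hand(rng, n, alphabet, first_banned=None):
    """Diatonic sequence with no successive pitch repeats."""
    seq = np.empty(n, dtype=int)
    prev = first_banned
    for i in range(n):
        choices = alphabet[alphabet != prev] if prev is not None else alphabet
        seq[i] = rng.choice(choices)
        prev = seq[i]
    return seq


def _sample_hand_in_band(rng, n, alphabet, band=_RECURRENCE_BAND,
                         max_tries=400, first_banned=None, last_banned=None):
    for _ in range(max_tries):
        seq = _sample_hand(rng, n, alphabet, first_banned)
        if last_banned is not None and seq[-1] == last_banned:
            continue
        if band[0] <= mean_recurrence_distance(seq) <= band[1]:
            return seq
    raise StimulusGenerationError(
        f"could not satisfy the recurrence-distance band {band} in {max_tries} tries")


def generate_stimulus_pair(
    key=("C", "major"), excerpt_id: int = 1, seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[Score, Score]:
    """One excerpt embedded in its long and short contexts.

    The short layout (4+8+5 per hand) is generated first under the
    recurrence constraints; the long layout extends it by 8 events on each
    side, so the excerpt and its surrounding events are identical across
    the pair by construction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tonic, mode = key
    pitches_long, pitches_short, fingers_long, fingers_short = {}, {}, {}, {}
    for hand, base in (("R", _RH_OCTAVE), ("L", _LH_OCTAVE)):
        alphabet = _diatonic_pitches(tonic, mode, base)
        pre_s, exc, post_s = LAYOUTS["short"]
        n_short = pre_s + exc + post_s
        short = _sample_hand_in_band(rng, n_short, alphabet)
        for _ in range(400):
            head = _sample_hand_in_band(rng, 8, alphabet, band=(0, np.inf),
                                        last_banned=short[0])
            tail = _sample_hand_in_band(rng, 8, alphabet, band=(0, np.inf),
                                        first_banned=short[-1])
            long = np.concatenate([head, short, tail])
            if _RECURRENCE_BAND[0] <= mean_recurrence_distance(long) <= _RECURRENCE_BAND[1]:
                break
        else:
            raise StimulusGenerationError(
                f"long-context flanks failed the recurrence band (seed-dependent); "
                f"excerpt {excerpt_id}, hand {hand}")
        pitches_short[hand] = short
        pitches_long[hand] = long
        # notated fingering: scale degree cycled over fingers 1..5
        def _fingers(seq):
            order = {p: k for k, p in enumerate(alphabet)}
            return [str(1 + order[int(p)] % 5) for p in seq]

        fingers_short[hand] = _fingers(short)
        fingers_long[hand] = _fingers(long)
    tonic_notes = {"R": int(_diatonic_pitches(tonic, mode, _RH_OCTAVE)[0]),
                   "L": int(_diatonic_pitches(tonic, mode, _LH_OCTAVE)[0])}
    common = dict(key_tonic=tonic, key_mode=mode, excerpt_id=excerpt_id,
                  final_notes=tonic_notes)
    long_score = Score(pitches=pitches_long, context_label="long",
                       pre_len=LAYOUTS["long"][0], fingers=fingers_long, **common)
    short_score = Score(pitches=pitches_short, context_label="short",
                        pre_len=LAYOUTS["short"][0], fingers=fingers_short, **common)
    return long_score, short_score


def generate_design(n_participants: int = 26) -> pd.DataFrame:
    """Trial roster: 64 test trials per participant.

    Context assignment (which excerpts appear long), tempo assignment and
    the within-block order of the two context groups are counterbalanced by
    participant and block parity; medium and fast tempi alternate every
    trial; each piece is performed twice per block.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rows = []
    for p in range(1, n_participants + 1):
        long_ids = [1, 2, 3, 4] if p % 2 == 1 else [5, 6, 7, 8]
        short_ids = [e for e in range(1, 9) if e not in long_ids]
        groups = {"long": long_ids, "short": short_ids}
        tempo_of = {e: ("medium" if (e + p) % 2 == 0 else "fast")
                    for e in range(1, 9)}
        trial = 0
        for b in range(1, 5):
            order = ["long", "short"] if (p + b) % 2 == 0 else ["short", "long"]
            for ctx in order:
                ids = groups[ctx]
                med = [e for e in ids if tempo_of[e] == "medium"]
                fast = [e for e in ids if tempo_of[e] == "fast"]
                seq = []
                for m_id, f_id in zip(med, fast):
                    seq += [(m_id, 1), (f_id, 1), (m_id, 2), (f_id, 2)]
                for e, rep in seq:
                    trial += 1
                    rows.append(dict(
                        participant=p, block=b, trial=trial, excerpt_id=e,
                        context_label=ctx, tempo_label=tempo_of[e],
                        tempo_ioi_ms=TEMPI_MS[tempo_of[e]], repetition=rep))
    return pd.DataFrame(rows)


def condition_profile(context_label: str, tactus_weight: float = 0.25,
                      grid_offset: int = 0):
    """(grid, accent profile, excerpt positions) of a context layout."""
    pre, exc, post = LAYOUTS[context_label]
    n = pre + exc + post
    grid = build_grid(8, 4, n, offset=grid_offset)
    profile = accent_strengths(grid, make_weights(4, 2, tactus_weight))
    return grid, profile, np.arange(pre, pre + exc)


_REF_CACHE: dict = {}


def reference_activation(truth: GenerativeTruth) -> float:
    """Grand-mean excerpt Event(0) over the four context x tempo cells."""
    key = (truth.a_true, truth.w2_true, truth.w2_short_true,
           truth.use_meter, truth.window)
    if key not in _REF_CACHE:
        vals = []
        for ctx in ("long", "short"):
            _, profile, excerpt = condition_profile(ctx, truth.w2_for(ctx))
            for tempo in ("fast", "medium"):
                params = truth.params(TEMPI_MS[tempo] / 1000.0, ctx)
                vals.append(np.mean([event_activation(profile, int(i), params)
                                     for i in excerpt]))
        _REF_CACHE[key] = float(np.mean(vals))
    return _REF_CACHE[key]


@dataclass
class _HandTables:
    p_err: np.ndarray
    candidates: list  # per position: (signed distances, probabilities) or None


def trial_tables(score: Score, truth: GenerativeTruth,
                 tempo_ioi_ms: float) -> dict:
    """Precomputed per-position error probabilities and source distributions.

    Contextual source candidates at position *i* are the signed distances
    ``x`` (within the window, inside the sequence) whose pitch would be
    coded back to exactly ``x`` by nearest-source coding: the pitch at
    ``i+x`` must not occur closer to *i*, and on an exact two-sided tie
    only the anticipatory side is a candidate.  Probabilities are
    proportional to ``S_x * M_x(i)``.
    """
    t = tempo_ioi_ms / 1000.0
    params = truth.params(t, score.context_label)
    profile = score.accent_profile(truth.w2_for(score.context_label))
    counts = score.accent_counts()
    n = score.n_positions
    e_mean = float(np.mean([event_activation(profile, int(i), params)
                            for i in score.excerpt_positions]))
    e_ref = reference_activation(truth)
    base = (truth.base_error_rate
            * np.exp(-truth.lambda_rate * (e_mean - e_ref)))
    p_err = base * np.exp(-truth.beta_accent * (counts - MEAN_ACCENT))
    p_err = np.clip(p_err, 0.0, 0.5)

    from .model import metrical_similarity, serial_component

    tables = {}
    for hand, seq in score.pitches.items():
        seq = np.asarray(seq)
        occ: dict = {}
        for j, q in enumerate(seq):
            occ.setdefault(int(q), []).append(j)
        cand = []
        for i in range(n):
            xs, ws = [], []
            for x in range(-truth.window, truth.window + 1):
                j = i + x
                if x == 0 or not 0 <= j < n:
                    continue
                q = int(seq[j])
                if q == int(seq[i]):
                    continue
                dmin = min(abs(s - i) for s in occ[q])
                if abs(x) != dmin:
                    continue
                if x < 0 and i + abs(x) < n and int(seq[i + abs(x)]) == q:
                    continue  # two-sided tie is coded anticipatory
                w = serial_component(x, params.a, params.t)
                if truth.use_meter:
                    w *= metrical_similarity(profile.strengths[i],
                                             profile.strengths[j])
                xs.append(x)
                ws.append(float(w))
            if xs:
                ws = np.asarray(ws)
                cand.append((np.asarray(xs), ws / ws.sum()))
            else:
                cand.append(None)
        tables[hand] = _HandTables(p_err=p_err, candidates=cand)
    return tables


def _out_of_stimulus_pitch(target: int, stimulus_pitches: set, rng) -> int:
    first = int(rng.choice([1, -1]))
    for mag in range(1, 12):
        for sign in (first, -first):
            q = target + sign * mag
            if 0 < q < 128 and q not in stimulus_pitches:
                return q
    raise RuntimeError("no out-of-stimulus pitch found")  # pragma: no cover


def generate_performance(
    score: Score, truth: GenerativeTruth, tempo_ioi_ms: float,
    seed=None, rng: np.random.Generator | None = None, tables: dict | None = None,
    meta: dict | None = None,
) -> tuple[Performance, list[ErrorRecord]]:
    """One performed trial plus its planted ground-truth error records."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if tables is None:
        tables = trial_tables(score, truth, tempo_ioi_ms)
    meta = meta or {}
    tempo_label = meta.get("tempo_label",
                           {v: k for k, v in TEMPI_MS.items()}.get(tempo_ioi_ms, "medium"))
    rec_meta = dict(participant=meta.get("participant", 0),
                    excerpt_id=score.excerpt_id,
                    context_label=score.context_label,
                    tempo_label=tempo_label,
                    block=meta.get("block", 1),
                    repetition=meta.get("repetition", 1))
    counts = score.accent_counts()
    stim_pitches = score.pitch_set()
    ioi = tempo_ioi_ms
    rows, records = [], []
    for hand, seq in score.pitches.items():
        seq = np.asarray(seq)
        n = len(seq)
        tab = tables[hand]
        base_vel = (truth.right_hand_velocity if hand == "R"
                    else truth.left_hand_velocity)

        def vel(i=None):
            accent_term = 0.0 if i is None else truth.accent_slope * (counts[i] - MEAN_ACCENT)
            v = base_vel + accent_term + rng.normal(0.0, truth.velocity_sd)
            return int(np.clip(round(v), 1, 127))

        produced = seq.astype(int).copy()
        deleted = np.zeros(n, dtype=bool)
        extras = []  # (position offset in IOIs, pitch, accent position or None)
        errs = rng.random(n) < tab.p_err
        skip = set()
        errored = set()
        last_deletion = last_addition = last_exchange = -10
        planted = []  # (position, kind, signed distance) per hand, in order

        def _shift_safe(j: int, i: int, free_d: int) -> bool:
            # A deletion/addition pair at (i, j) re-codes as a run of
            # substitutions iff the shifted alignment over (i, j) is cheaper
            # than one deletion plus one insertion.  Substitutions at the
            # pair-ward unit distance and exchanged pairs give the shifted
            # register free matches; everything else mismatches (no pitch
            # repeats successively).  Only plant the pair when the planted
            # description is strictly cheaper.
            if j - i > 14:
                return True
            span = [e for e in planted if i < e[0] < j]
            subs = sum(1 for e in span if e[1] == "substitution")
            frees = sum(1 for e in span
                        if e[1] == "substitution" and e[2] == free_d)
            exch = sum(1 for e in span if e[1] == "exchange")
            return (j - i) - frees - 3 * exch > 2.9 + subs + 2 * exch
        for i in range(n):
            if i in skip or not errs[i]:
                continue
            # adjacent errors interact (a swap next to a deletion re-codes as
            # a shorter edit), so the error process is refractory for one event
            if i - 1 in errored or i - 1 in skip:
                errs[i] = False
                continue
            errored.add(i)
            contextual = rng.random() < truth.p_contextual and tab.candidates[i] is not None
            if contextual:
                xs, probs = tab.candidates[i]
                x = int(rng.choice(xs, p=probs))
                # a swap within four positions of another swap, deletion or
                # addition also re-codes as a shorter edit (the transposed
                # pair gives a shifted alignment free matches), so exchanges
                # keep a wider spacing from all count-changing errors
                if (x == 1 and i + 1 < n and not errs[i + 1]
                        and i - last_exchange >= 5
                        and i - last_deletion >= 5
                        and i - last_addition >= 5
                        and rng.random() < truth.exchange_prob):
                    last_exchange = i
                    planted.append((i, "exchange", 1))
                    produced[i], produced[i + 1] = int(seq[i + 1]), int(seq[i])
                    skip.add(i + 1)
                    records.append(ErrorRecord(
                        error_type="exchange", contextual=True, hand=hand,
                        target_position=i, target_pitch=int(seq[i]),
                        intruder_pitch=int(seq[i + 1]),
                        signed_source_distance=1, direction="none",
                        accent_at_target=int(counts[i]),
                        accent_at_source=int(counts[i + 1]),
                        in_excerpt=bool(score.excerpt_mask[i]), **rec_meta))
                    continue
                produced[i] = int(seq[i + x])
                planted.append((i, "substitution", x))
                rec = ErrorRecord(
                    error_type="substitution", contextual=True, hand=hand,
                    target_position=i, target_pitch=int(seq[i]),
                    intruder_pitch=int(seq[i + x]),
                    signed_source_distance=x,
                    direction="anticipatory" if x > 0 else "perseveratory",
                    accent_at_target=int(counts[i]),
                    accent_at_source=int(counts[i + x]),
                    in_excerpt=bool(score.excerpt_mask[i]), **rec_meta)
                if rng.random() < truth.correction_prob:
                    extras.append((i + 0.5, int(seq[i]), i))
                    rec.excluded = True
                    rec.exclusion_reason = "corrected"
                records.append(rec)
            else:
                u = rng.random()
                kind = ("deletion" if u < truth.p_deletion else
                        "substitution" if u < truth.p_deletion + truth.p_nc_substitution
                        else "addition")
                # a deletion/addition pair whose shifted alignment would be
                # the cheaper edit must not be planted as such; keep both
                # clear of the wider exchange interaction range too
                if kind == "addition" and (not _shift_safe(i, last_deletion, -1)
                                           or i - last_exchange < 5):
                    kind = "substitution"
                if kind == "deletion" and (not _shift_safe(i, last_addition, 1)
                                           or i - last_exchange < 5):
                    kind = "substitution"
                if kind == "deletion":
                    deleted[i] = True
                    last_deletion = i
                    planted.append((i, "deletion", None))
                    records.append(ErrorRecord(
                        error_type="deletion", contextual=False, hand=hand,
                        target_position=i, target_pitch=int(seq[i]),
                        intruder_pitch=None, accent_at_target=int(counts[i]),
                        in_excerpt=bool(score.excerpt_mask[i]), **rec_meta))
                elif kind == "substitution":
                    q = _out_of_stimulus_pitch(int(seq[i]), stim_pitches, rng)
                    produced[i] = q
                    planted.append((i, "substitution", None))
                    records.append(ErrorRecord(
                        error_type="substitution", contextual=False, hand=hand,
                        target_position=i, target_pitch=int(seq[i]),
                        intruder_pitch=q, accent_at_target=int(counts[i]),
                        in_excerpt=bool(score.excerpt_mask[i]), **rec_meta))
                else:
                    q = _out_of_stimulus_pitch(int(seq[i]), stim_pitches, rng)
                    extras.append((i - 0.45, q, None))
                    last_addition = i
                    planted.append((i, "addition", None))
                    records.append(ErrorRecord(
                        error_type="addition", contextual=False, hand=hand,
                        target_position=i, target_pitch=None, intruder_pitch=q,
                        accent_at_target=int(counts[i]),
                        in_excerpt=bool(score.excerpt_mask[i]), **rec_meta))
        for i in range(n):
            if deleted[i]:
                continue
            onset = i * ioi + rng.normal(0.0, truth.timing_jitter_sd_ms)
            rows.append(dict(onset_ms=onset, pitch=int(produced[i]),
                             velocity=vel(i), hand=hand))
        for frac, pitch, acc_pos in extras:
            onset = frac * ioi + rng.normal(0.0, truth.timing_jitter_sd_ms)
            rows.append(dict(onset_ms=onset, pitch=int(pitch),
                             velocity=vel(acc_pos), hand=hand))
    ks = pd.DataFrame(rows, columns=["onset_ms", "pitch", "velocity", "hand"])
    ks = ks.sort_values("onset_ms", kind="stable").reset_index(drop=True)
    perf = Performance(keystrokes=ks, ioi_nominal_ms=tempo_ioi_ms,
                       tempo_label=tempo_label, **{k: v for k, v in rec_meta.items()
                                                   if k not in ("tempo_label",)})
    records.sort(key=lambda r: (r.hand, r.target_position))
    return perf, records


@dataclass
class Trial:
    meta: dict
    performance: Performance
    truth: list


@dataclass
class Cohort:
    """A full synthetic study: stimuli, roster, and generated trials."""

    truth: GenerativeTruth
    seed: int
    stimuli: dict  # (excerpt_id, context_label) -> Score
    design: pd.DataFrame
    trials: list = field(repr=False, default_factory=list)
    learning_trials: list = field(repr=False, default_factory=list)

    def all_truth_records(self) -> list:
        return [r for tr in self.trials for r in tr.truth]


def generate_cohort(
    truth: GenerativeTruth | None = None,
    n_participants: int = 26,
    seed: int = 0,
    include_learning: bool = True,
    n_learning: int = 3,
) -> Cohort:
    """Generate the full study.

    All randomness flows from the cohort seed through documented per-trial
    substreams (``(seed, participant, trial)``), so any single trial can be
    regenerated in isolation.
    """
    truth = truth or GenerativeTruth()
    stimuli = {}
    for e in range(1, 9):
        rng = np.random.default_rng((seed, 1000 + e))
        long_s, short_s = generate_stimulus_pair(KEYS[e - 1], excerpt_id=e, rng=rng)
        stimuli[(e, "long")] = long_s
        stimuli[(e, "short")] = short_s
    design = generate_design(n_participants)
    tables_cache: dict = {}
    cohort = Cohort(truth=truth, seed=seed, stimuli=stimuli, design=design)
    for row in design.itertuples(index=False):
        score = stimuli[(row.excerpt_id, row.context_label)]
        key = (row.excerpt_id, row.context_label, row.tempo_ioi_ms)
        if key not in tables_cache:
            tables_cache[key] = trial_tables(score, truth, row.tempo_ioi_ms)
        rng = np.random.default_rng((seed, row.participant, row.trial))
        meta = dict(participant=row.participant, block=row.block,
                    repetition=row.repetition, tempo_label=row.tempo_label)
        perf, recs = generate_performance(score, truth, row.tempo_ioi_ms,
                                          rng=rng, tables=tables_cache[key],
                                          meta=meta)
        cohort.trials.append(Trial(meta=dict(row._asdict()), performance=perf,
                                   truth=recs))
    if include_learning:
        slow = TEMPI_MS["slow"]
        for p in range(1, n_participants + 1):
            for (e, ctx), score in stimuli.items():
                if _performs(design, p, e, ctx):
                    key = (e, ctx, slow)
                    if key not in tables_cache:
                        tables_cache[key] = trial_tables(score, truth, slow)
                    for rep in range(1, n_learning + 1):
                        rng = np.random.default_rng((seed, p, 9000 + 10 * e + rep))
                        meta = dict(participant=p, block=0, repetition=rep,
                                    tempo_label="slow")
                        perf, recs = generate_performance(
                            score, truth, slow, rng=rng,
                            tables=tables_cache[key], meta=meta)
                        cohort.learning_trials.append(
                            Trial(meta=dict(participant=p, excerpt_id=e,
                                            context_label=ctx, block=0,
                                            tempo_label="slow", repetition=rep),
                                  performance=perf, truth=recs))
    return cohort


def _performs(design: pd.DataFrame, participant: int, excerpt_id: int,
              context: str) -> bool:
    sub = design[(design.participant == participant)
                 & (design.excerpt_id == excerpt_id)
                 & (design.context_label == context)]
    return len(sub) > 0


def simulate_gradient_cohort(
    truth: GenerativeTruth, seed: int = 0, n_participants: int = 26,
    mean_errors_per_cell: float = 20.0, grid_offset: int = 0,
) -> dict:
    """Condition-pooled observed gradients drawn from the model itself.

    For each context x tempo cell, every participant contributes a
    Poisson-distributed number of contextual errors whose source distances
    follow the model's predicted gradient for that cell; the pooled
    multinomial counts become the observed gradient.  Used for parameter
    recovery of the fitting machinery under pure sampling noise.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for ctx in ("long", "short"):
        grid, profile, excerpt = condition_profile(ctx, truth.w2_for(ctx),
                                                   grid_offset)
        for tempo in ("fast", "medium"):
            t = TEMPI_MS[tempo] / 1000.0
            pred = predicted_gradient(profile, excerpt, truth.params(t, ctx))
            n_err = rng.poisson(mean_errors_per_cell, size=n_participants)
            total = max(int(n_err.sum()), 1)
            counts = rng.multinomial(total, pred.proportions)
            out[(ctx, tempo)] = dict(
                observed=counts / counts.sum(), n_errors=total,
                grid=build_grid(8, 4, profile.n_positions, offset=grid_offset),
                positions=excerpt, t=t)
    return out
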