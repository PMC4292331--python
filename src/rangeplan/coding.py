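"""Error coding of keyboard performances against a score.

The coder aligns each performed trial to the intended note sequence with a
per-hand dynamic-programming alignment (match cost 0 for octave-specific
pitch identity, substitution cheaper than an insertion/deletion pair, ties
broken by temporal proximity to the nominal onset), then codes the
discrepancies into the standard serial-ordering taxonomy:

* contextual substitution — the intruding pitch occurs elsewhere in the
  stimulus; coded with the signed distance to its nearest source
  (anticipatory when the source lies ahead of the error);
* exchange — two adjacent events produced in swapped order, one error;
* chord error — multiple incorrect pitches within one short temporal
  window (94 ms), one error;
* noncontextual substitutions, additions and deletions.

Exclusion filters mark (never delete) errors attributable to mislearning
(same position erred in the learning phase and in at least half of the
eight test performances of the stimulus) and immediately corrected errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MovementGradient
from .score import ErrorRecord, Performance, Score

__all__ = [
    "AlignmentError",
    "UndefinedGradientError",
    "HandAlignment",
    "Alignment",
    "align_trial",
    "classify_errors",
    "code_trial",
    "apply_exclusions",
    "movement_gradient",
    "mean_range",
    "similar_proportion",
    "anticipatory_proportion",
    "error_rates_by_accent",
    "contrast_value",
    "correct_tone_table",
    "intensity_by_accent",
    "error_rate",
]

CHORD_WINDOW_MS = 94.0
WINDOW = 8
SUB_COST = 1.0
INDEL_COST = 1.45
TIME_COST = 0.02  # per nominal IOI of onset deviation; breaks ties only
#: a correcting keystroke must be at least this late (in IOIs) to count as
#: a correction rather than the position's own on-time event
CORRECTION_MIN_LATE = 0.25


class AlignmentError(RuntimeError):
    """Performance too degraded to align (fewer than half the positions match)."""


class UndefinedGradientError(RuntimeError):
    """No qualifying contextual errors: the movement gradient is undefined."""


@dataclass
class HandAlignment:
    hand: str
    matches: list  # (position, keystroke row index) pairs, both ascending
    deletions: list  # unmatched score positions
    insertions: list  # unmatched keystroke row indices
    anchor_ms: float  # estimated onset of position 0


@dataclass
class Alignment:
    score: Score
    performance: Performance
    hands: dict = field(default_factory=dict)  # hand -> HandAlignment
    chord_window_ms: float = CHORD_WINDOW_MS

    def produced_ioi_ms(self) -> float:
        """Mean produced IOI across matched events of both hands."""
        span, events = 0.0, 0
        for h, ha in self.hands.items():
            if len(ha.matches) >= 2:
                ks = self.performance.by_hand(h)
                (p0, k0), (p1, k1) = ha.matches[0], ha.matches[-1]
                span += ks["onset_ms"].iat[k1] - ks["onset_ms"].iat[k0]
                events += p1 - p0
        if events == 0:
            return self.performance.ioi_nominal_ms
        return span / events


def _dp_align(target: np.ndarray, pitches: np.ndarray, onsets: np.ndarray,
              ioi: float, anchor: float, time_cost: float) -> tuple:
    """One Needleman-Wunsch pass; returns (matches, deletions, insertions)."""
    n, m = len(target), len(pitches)
    # substitution/match cost per (position, keystroke), temporal tie-break in
    nominal_col = anchor + np.arange(n)[:, None] * ioi
    diag_cost = (SUB_COST * (pitches[None, :] != target[:, None])
                 + time_cost * np.abs(onsets[None, :] - nominal_col) / ioi)
    D = np.empty((n + 1, m + 1))
    D[0, :] = np.arange(m + 1) * INDEL_COST
    D[:, 0] = np.arange(n + 1) * INDEL_COST
    steps = np.arange(m + 1) * INDEL_COST
    for i in range(1, n + 1):
        prev = D[i - 1]
        cand = np.minimum(prev[:-1] + diag_cost[i - 1], prev[1:] + INDEL_COST)
        # fold in the horizontal (insertion) chain via a prefix minimum
        chain = np.concatenate(([i * INDEL_COST], cand)) - steps
        D[i] = np.minimum.accumulate(chain) + steps
    # backtrack; prefer diagonal, then score-deletion, then insertion
    matches, deletions, insertions = [], [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            nominal = anchor + (i - 1) * ioi
            tp = time_cost * abs(onsets[j - 1] - nominal) / ioi
            diag = SUB_COST * (pitches[j - 1] != target[i - 1]) + tp
            if np.isclose(D[i, j], D[i - 1, j - 1] + diag):
                matches.append((i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if i > 0 and np.isclose(D[i, j], D[i - 1, j] + INDEL_COST):
            deletions.append(i - 1)
            i -= 1
            continue
        insertions.append(j - 1)
        j -= 1
    matches.reverse()
    deletions.reverse()
    insertions.reverse()
    return matches, deletions, insertions


def _align_hand(
    target: np.ndarray, ks: pd.DataFrame, ioi: float, hand: str
) -> HandAlignment:
    """Two-pass alignment of one hand's score against its keystrokes.

    Pass one aligns on pitch alone to estimate the trial's time anchor
    (robust to insertions/deletions, which shift raw onset offsets by whole
    IOIs); pass two adds the temporal-proximity tie-break around that
    anchor.
    """
    n, m = len(target), len(ks)
    onsets = ks["onset_ms"].to_numpy() if m else np.empty(0)
    pitches = ks["pitch"].to_numpy() if m else np.empty(0, dtype=int)
    if m == 0:
        return HandAlignment(hand=hand, matches=[], deletions=list(range(n)),
                             insertions=[], anchor_ms=0.0)
    matches, _, _ = _dp_align(target, pitches, onsets, ioi, 0.0, 0.0)
    if matches:
        anchor = float(np.median([onsets[j] - pos * ioi for pos, j in matches]))
    else:
        anchor = float(onsets[0])
    matches, deletions, insertions = _dp_align(
        target, pitches, onsets, ioi, anchor, TIME_COST)
    return HandAlignment(hand=hand, matches=matches, deletions=deletions,
                         insertions=insertions, anchor_ms=anchor)


def align_trial(
    score: Score, performance: Performance, chord_window_ms: float = CHORD_WINDOW_MS
) -> Alignment:
    """Align one performed trial to its score, hand by hand.

    Raises
    ------
    AlignmentError
        If fewer than half of all score positions receive a keystroke.
    """
    if len(performance.keystrokes) == 0:
        raise AlignmentError("empty performance")
    ioi = performance.ioi_nominal_ms
    al = Alignment(score=score, performance=performance,
                   chord_window_ms=chord_window_ms)
    total_matched = 0
    for hand, target in score.pitches.items():
        ks = performance.by_hand(hand)
        al.hands[hand] = _align_hand(np.asarray(target), ks, ioi, hand)
        total_matched += len(al.hands[hand].matches)
    n_positions = score.n_positions * len(score.pitches)
    if total_matched < 0.5 * n_positions:
        raise AlignmentError(
            f"only {total_matched}/{n_positions} positions matchable "
            f"(participant={performance.participant}, "
            f"excerpt={performance.excerpt_id}, block={performance.block})"
        )
    return al


def _nearest_source(score: Score, hand: str, pos: int, pitch: int,
                    window: int) -> tuple:
    """Nearest octave-specific occurrence of ``pitch`` in the full stimulus.

    Returns ``(contextual, signed_distance_or_None, source_hand, tie)``.
    Sources may lie anywhere in the stimulus (either hand); the signed
    distance is ``source - pos`` in sixteenth-note positions.  Exact
    distance ties prefer the anticipatory (future) source and are flagged.
    """
    best, tie, best_hand = None, False, None
    for h, seq in score.pitches.items():
        hits = np.flatnonzero(np.asarray(seq) == pitch)
        for s in hits:
            if h == hand and s == pos:
                continue
            d = int(s - pos)
            if best is None or abs(d) < abs(best):
                best, tie, best_hand = d, False, h
            elif abs(d) == abs(best) and d != best:
                tie = True
                if d > best:  # prefer anticipatory on exact tie
                    best, best_hand = d, h
    if best is None:
        return False, None, None, False
    if abs(best) > window:
        return True, None, best_hand, tie
    return True, best, best_hand, tie


def _finalize(rec: ErrorRecord, score: Score, window: int) -> ErrorRecord:
    """Fill source, direction, accent, key/chord flags of a coded error."""
    counts = score.accent_counts()
    rec.accent_at_target = int(counts[rec.target_position])
    rec.in_excerpt = bool(score.excerpt_mask[rec.target_position])
    if rec.error_type == "exchange":
        # the source is the swapped neighbour by construction
        rec.contextual = True
        rec.signed_source_distance = 1
        rec.accent_at_source = int(counts[rec.target_position + 1])
        pc = rec.intruder_pitch % 12
        rec.in_key = pc in score.scale_pcs()
        rec.in_chord = pc in score.triad_pcs()
        rec.semitone_distance = abs(rec.intruder_pitch - rec.target_pitch)
        return rec
    if rec.intruder_pitch is not None:
        contextual, d, src_hand, tie = _nearest_source(
            score, rec.hand, rec.target_position, rec.intruder_pitch, window)
        rec.contextual = contextual
        rec.signed_source_distance = d
        rec.source_tie = tie
        if d is not None:
            rec.direction = "anticipatory" if d > 0 else "perseveratory"
            rec.accent_at_source = int(counts[rec.target_position + d])
            if (score.fingers is not None and src_hand == rec.hand):
                fingers = score.fingers[rec.hand]
                rec.same_finger = (
                    fingers[rec.target_position + d] == fingers[rec.target_position])
        pc = rec.intruder_pitch % 12
        rec.in_key = pc in score.scale_pcs()
        rec.in_chord = pc in score.triad_pcs()
        if rec.target_pitch is not None:
            rec.semitone_distance = abs(rec.intruder_pitch - rec.target_pitch)
    else:
        rec.contextual = False
    return rec


def classify_errors(
    alignment: Alignment, window: int = WINDOW
) -> list[ErrorRecord]:
    """Produce the full error taxonomy from an aligned trial.

    Adjacent substitutions whose intruders are each other's targets collapse
    to a single exchange; incorrect keystrokes within the chord window
    collapse to a single chord error whose representative intruder is the
    pitch nearest in height to the target.
    """
    score, perf = alignment.score, alignment.performance
    ioi = perf.ioi_nominal_ms
    meta = dict(participant=perf.participant, excerpt_id=perf.excerpt_id,
                context_label=perf.context_label, tempo_label=perf.tempo_label,
                block=perf.block, repetition=perf.repetition)
    records: list[ErrorRecord] = []
    for hand, ha in alignment.hands.items():
        target = np.asarray(score.pitches[hand])
        ks = perf.by_hand(hand)
        subs = {}  # position -> keystroke idx with wrong pitch
        for pos, k in ha.matches:
            if ks["pitch"].iat[k] != target[pos]:
                subs[pos] = k
        # exchange collapse: produced(i) == score(i+1) and produced(i+1) == score(i)
        consumed = set()
        positions = sorted(subs)
        for pos in positions:
            if pos in consumed or pos + 1 not in subs:
                continue
            pi, pj = ks["pitch"].iat[subs[pos]], ks["pitch"].iat[subs[pos + 1]]
            if pi == target[pos + 1] and pj == target[pos]:
                k = subs[pos]
                records.append(ErrorRecord(
                    error_type="exchange", contextual=True, hand=hand,
                    target_position=pos, target_pitch=int(target[pos]),
                    intruder_pitch=int(pi),
                    velocity=int(ks["velocity"].iat[k]),
                    onset_ms=float(ks["onset_ms"].iat[k]), **meta))
                consumed.update({pos, pos + 1})
        # remaining substitutions and additions, as raw error keystrokes
        raw = []  # (onset, kind, pos_or_None, ks_idx)
        for pos, k in subs.items():
            if pos not in consumed:
                raw.append((float(ks["onset_ms"].iat[k]), "substitution", pos, k))
        for k in ha.insertions:
            raw.append((float(ks["onset_ms"].iat[k]), "addition", None, k))
        raw.sort()
        # chord merge: incorrect keystrokes within the chord window are one error
        groups, cur = [], []
        for ev in raw:
            if cur and ev[0] - cur[-1][0] < alignment.chord_window_ms:
                cur.append(ev)
            else:
                if cur:
                    groups.append(cur)
                cur = [ev]
        if cur:
            groups.append(cur)
        anchor = ha.anchor_ms
        for g in groups:
            sub_members = [ev for ev in g if ev[1] == "substitution"]
            if sub_members:
                pos = sub_members[0][2]
                tp = int(target[pos])
            else:
                # addition: serves the position nearest in nominal time
                pos = int(np.clip(round((g[0][0] - anchor) / ioi), 0,
                                  score.n_positions - 1))
                tp = None
            pitches = [int(ks["pitch"].iat[ev[3]]) for ev in g]
            if len(g) == 1:
                etype = g[0][1]
                intruder = pitches[0]
                k = g[0][3]
            else:
                etype = "chord_error"
                ref = tp if tp is not None else pitches[0]
                which = min(range(len(g)),
                            key=lambda idx: (abs(pitches[idx] - ref), pitches[idx]))
                intruder = pitches[which]
                k = g[which][3]
            rec = ErrorRecord(
                error_type=etype, contextual=False, hand=hand,
                target_position=int(pos), target_pitch=tp,
                intruder_pitch=intruder,
                velocity=int(ks["velocity"].iat[k]),
                onset_ms=float(g[0][0]),
                chord_pitches=tuple(pitches) if len(g) > 1 else None, **meta)
            records.append(rec)
        for pos in ha.deletions:
            records.append(ErrorRecord(
                error_type="deletion", contextual=False, hand=hand,
                target_position=int(pos), target_pitch=int(target[pos]),
                intruder_pitch=None, **meta))
    for rec in records:
        _finalize(rec, score, window)
    # correction candidates: a later keystroke re-serves the error's position
    _flag_correction_latency(records, alignment)
    records.sort(key=lambda r: (r.hand, r.target_position, r.onset_ms or 0))
    return records


def _flag_correction_latency(records, alignment: Alignment) -> None:
    """Attach the latency to a correct-pitch re-strike, where one exists.

    A correction is a correct-pitch keystroke serving the error's position
    within one nominal IOI of the erroneous keystroke, arriving late
    relative to the position's nominal onset (an on-time correct keystroke
    next to a plain addition is not a correction).
    """
    score, perf = alignment.score, alignment.performance
    ioi = perf.ioi_nominal_ms
    for rec in records:
        rec._correction_latency_ms = None
        if rec.onset_ms is None or rec.error_type == "deletion":
            continue
        ks = perf.by_hand(rec.hand)
        correct_pitch = int(score.pitches[rec.hand][rec.target_position])
        nominal = alignment.hands[rec.hand].anchor_ms + rec.target_position * ioi
        onsets = ks["onset_ms"].to_numpy()
        hits = np.flatnonzero(
            (ks["pitch"].to_numpy() == correct_pitch)
            & (onsets > rec.onset_ms)
            & (onsets <= rec.onset_ms + ioi)
            & (onsets >= nominal + CORRECTION_MIN_LATE * ioi))
        if hits.size:
            rec._correction_latency_ms = float(onsets[hits[0]] - rec.onset_ms)


def code_trial(score: Score, performance: Performance,
               chord_window_ms: float = CHORD_WINDOW_MS,
               window: int = WINDOW) -> list[ErrorRecord]:
    """Align and classify one trial in one call."""
    return classify_errors(align_trial(score, performance, chord_window_ms),
                           window=window)


def apply_exclusions(
    records: list[ErrorRecord],
    learning_records: list[ErrorRecord] | None = None,
    n_test_trials: int = 8,
) -> list[ErrorRecord]:
    """Mark (never delete) excluded error records.

    Two filters: (a) errors at a position that also erred in the learning
    phase of the same stimulus and in at least half of its test
    performances; (b) immediately corrected errors (correct-pitch re-strike
    serving the same position within one nominal IOI).  Records are returned
    with ``excluded``/``exclusion_reason`` set.
    """
    for rec in records:
        if getattr(rec, "_correction_latency_ms", None) is not None:
            rec.excluded = True
            rec.exclusion_reason = "corrected"
    if learning_records is None:
        warnings.warn("no learning-phase data: mislearning exclusion skipped",
                      stacklevel=2)
        return records
    learned = {(r.participant, r.excerpt_id, r.context_label, r.hand,
                r.target_position) for r in learning_records}
    by_pos: dict = {}
    for r in records:
        key = (r.participant, r.excerpt_id, r.context_label, r.hand,
               r.target_position)
        by_pos.setdefault(key, set()).add((r.block, r.repetition))
    for r in records:
        key = (r.participant, r.excerpt_id, r.context_label, r.hand,
               r.target_position)
        if key in learned and len(by_pos[key]) >= n_test_trials / 2:
            r.excluded = True
            if r.exclusion_reason:
                r.exclusion_reason += "+learned"
            else:
                r.exclusion_reason = "learned"
    return records


def _qualifying(records, window: int):
    return [r for r in records
            if r.contextual and not r.excluded
            and r.signed_source_distance is not None
            and 1 <= abs(r.signed_source_distance) <= window]


def movement_gradient(records, window: int = WINDOW) -> MovementGradient:
    """Observed movement gradient over absolute source distances 1..window."""
    q = _qualifying(records, window)
    if not q:
        raise UndefinedGradientError("no contextual errors with identified source")
    counts = np.zeros(window)
    for r in q:
        counts[abs(r.signed_source_distance) - 1] += 1
    return MovementGradient(proportions=counts / counts.sum(), n_errors=len(q))


def mean_range(records, window: int = WINDOW) -> float:
    """Mean absolute source distance of contextual errors (range of planning)."""
    q = _qualifying(records, window)
    if not q:
        raise UndefinedGradientError("no contextual errors with identified source")
    return float(np.mean([abs(r.signed_source_distance) for r in q]))


def similar_proportion(records, window: int = WINDOW) -> float:
    """Share of contextual errors arising from metrically similar (even) distances."""
    q = _qualifying(records, window)
    if not q:
        raise UndefinedGradientError("no contextual errors with identified source")
    even = sum(1 for r in q if abs(r.signed_source_distance) % 2 == 0)
    return even / len(q)


def anticipatory_proportion(records, window: int = WINDOW) -> float:
    q = [r for r in _qualifying(records, window) if r.error_type != "exchange"]
    if not q:
        raise UndefinedGradientError("no directional contextual errors")
    return sum(1 for r in q if r.signed_source_distance > 0) / len(q)


def error_rates_by_accent(
    records, score: Score, n_trials: int, include_deletions: bool = True
) -> np.ndarray:
    """Excerpt error rates per metrical accent level 1..k.

    Each rate is adjusted for the number of opportunities for an error to
    receive that accent strength: ``rate(l) = errors at level l /
    (excerpt positions at level l x hands x n_trials)``.
    """
    counts = score.accent_counts()[score.excerpt_positions]
    k = score.n_levels
    opportunities = np.array([(counts == l).sum() for l in range(1, k + 1)])
    opportunities = opportunities * len(score.pitches)
    errs = np.zeros(k)
    for r in records:
        if r.excluded or not r.in_excerpt:
            continue
        if not include_deletions and r.error_type == "deletion":
            continue
        errs[r.accent_at_target - 1] += 1
    rates = np.full(k, np.nan)
    ok = opportunities > 0
    rates[ok] = errs[ok] / (opportunities[ok] * n_trials)
    return rates


def contrast_value(rates: np.ndarray) -> float:
    """Linear metrical-accent contrast of error rates.

    Mean-zero, unit-spaced weights over accent levels; negative values mean
    error probability falls as accent strength rises.
    """
    rates = np.asarray(rates, dtype=float)
    k = rates.shape[0]
    weights = np.arange(k) - (k - 1) / 2
    return float(np.nansum(rates * weights))


def correct_tone_table(alignment: Alignment) -> pd.DataFrame:
    """Velocities of correctly produced tones with their accent levels."""
    score = alignment.score
    counts = score.accent_counts()
    mask = score.excerpt_mask
    rows = []
    for hand, ha in alignment.hands.items():
        target = np.asarray(score.pitches[hand])
        ks = alignment.performance.by_hand(hand)
        for pos, k in ha.matches:
            if ks["pitch"].iat[k] == target[pos]:
                rows.append(dict(hand=hand, position=pos,
                                 accent=int(counts[pos]),
                                 velocity=int(ks["velocity"].iat[k]),
                                 in_excerpt=bool(mask[pos])))
    return pd.DataFrame(rows, columns=["hand", "position", "accent",
                                       "velocity", "in_excerpt"])


def intensity_by_accent(events: pd.DataFrame, excerpt_only: bool = True) -> pd.Series:
    """Mean keystroke velocity per metrical accent level."""
    df = events
    if excerpt_only and "in_excerpt" in df.columns:
        df = df[df["in_excerpt"]]
    return df.groupby("accent")["velocity"].mean()


def error_rate(records, n_scored_events: int,
               include_deletions: bool = True) -> float:
    """Errors per scored event in the analysis region."""
    n = sum(1 for r in records if not r.excluded
            and (include_deletions or r.error_type != "deletion"))
    return n / n_scored_events
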