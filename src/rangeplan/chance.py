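"""Chance estimates for error patterns under a meter-blind random process.

A Monte-Carlo baseline for the movement gradient: error events are planted
on excerpt positions with a fixed probability, intruder pitches are drawn
at random from the stimulus's own pitches, and the distance to the nearest
same pitch is tallied exactly as in the observed-gradient coding.  Because
the sampler knows nothing about meter, the resulting gradient shows only
the mild decreasing trend induced by pitch-recurrence structure — no
even/odd alternation — and so anchors what the metrical effects are
measured against.  Analytic chance values for key/chord/hand membership
are exposed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MovementGradient
from .score import Score, scale_pitch_classes, triad_pitch_classes

__all__ = ["ChanceGradient", "simulate_chance", "chance_memberships"]


@dataclass(frozen=True)
class ChanceGradient:
    """Mean chance proportions over distances 1..window, with provenance."""

    proportions: np.ndarray = field(repr=False)
    n_sims: int = 1000
    p_error: float = 0.10
    seed: int | None = None
    bin_se: np.ndarray | None = field(default=None, repr=False)

    def as_gradient(self) -> MovementGradient:
        return MovementGradient(proportions=self.proportions, n_errors=None)


def _nearest_distance_table(score: Score, window: int) -> tuple:
    """Per excerpt slot and stimulus pitch, distance to the nearest source.

    Slots are (hand, excerpt position) pairs.  An entry is the absolute
    distance to the nearest same-pitch event anywhere in the stimulus,
    excluding the erring event itself (a draw equal to the target still
    counts as an error, sourced from the pitch's nearest other occurrence,
    mirroring the random-sampling procedure); 0 means only a simultaneous
    other-hand event matches; -1 means no occurrence within the window.
    """
    pool = score.all_pitches()
    uniq = np.unique(pool)
    positions = score.excerpt_positions
    hands = sorted(score.pitches)
    occ = {int(p): [] for p in uniq}
    for hand, seq in score.pitches.items():
        for pos, p in enumerate(np.asarray(seq)):
            occ[int(p)].append((pos, hand))
    table = np.full((len(hands) * len(positions), len(uniq)), -1, dtype=int)
    for hi, hand in enumerate(hands):
        for pi, pos in enumerate(positions):
            for qi, p in enumerate(uniq):
                dists = [abs(s - pos) for s, h in occ[int(p)]
                         if not (s == pos and h == hand)]
                if dists:
                    d = min(dists)
                    if d <= window:
                        table[hi * len(positions) + pi, qi] = d
    return table, uniq, pool


def simulate_chance(
    score: Score,
    p_error: float = 0.10,
    n_sims: int = 1000,
    seed: int | None = None,
    window: int = 8,
    rng: np.random.Generator | None = None,
    multiset: bool = True,
) -> ChanceGradient:
    """Monte-Carlo chance movement gradient for one stimulus.

    Per simulation, every excerpt event (both hands) errs with probability
    ``p_error``; the intruder pitch is drawn uniformly from the multiset of
    all stimulus pitches (set ``multiset=False`` to draw from the distinct
    pitch set); the distance to the nearest same pitch is recorded and
    errors with no source within the window are dropped.  Per-simulation
    proportions are averaged across simulations.
    """
    if not 0 < p_error <= 1:
        raise ValueError(f"p_error must lie in (0, 1], got {p_error}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    table, uniq, pool = _nearest_distance_table(score, window)
    n_slots = len(score.excerpt_positions) * len(score.pitches)
    slot_rows = np.arange(n_slots)  # one table row per (hand, position) slot
    if multiset:
        draw_pool = np.searchsorted(uniq, pool)  # index into uniq per event
    else:
        draw_pool = np.arange(len(uniq))

    props = np.zeros((n_sims, window))
    valid = np.zeros(n_sims, dtype=bool)
    err = rng.random((n_sims, n_slots)) < p_error
    pick = rng.integers(0, len(draw_pool), size=(n_sims, n_slots))
    dist = table[slot_rows[None, :], draw_pool[pick]]
    dist = np.where(err, dist, -1)
    for s in range(n_sims):
        d = dist[s]
        d = d[(d >= 1) & (d <= window)]
        if d.size:
            counts = np.bincount(d - 1, minlength=window).astype(float)
            props[s] = counts / counts.sum()
            valid[s] = True
    if not valid.any():
        raise RuntimeError("no simulation produced a qualifying error")
    mean = props[valid].mean(axis=0)
    se = props[valid].std(axis=0, ddof=1) / np.sqrt(valid.sum())
    return ChanceGradient(proportions=mean, n_sims=n_sims, p_error=p_error,
                          seed=seed, bin_se=se)


def chance_memberships(key_tonic: str = "C", key_mode: str = "major") -> dict:
    """Analytic chance rates for uniform random intrusions over the chromatic set.

    A random chromatic pitch lands in the 7-tone key with probability 7/12,
    in the 3-tone triad with probability 3/12, and in either hand with
    probability 1/2.
    """
    scale = scale_pitch_classes(key_tonic, key_mode)
    triad = triad_pitch_classes(key_tonic, key_mode)
    if len(scale) != 7:
        raise ValueError("key must have 7 scale tones")
    if len(triad) != 3:
        raise ValueError("triad must have 3 tones")
    return {"in_key": len(scale) / 12, "in_chord": len(triad) / 12, "hand": 0.5}
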