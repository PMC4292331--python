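"""Metrical grids, level weights, and per-position accent strengths.

A metrical hierarchy for isochronous binary-meter music is a stack of *k*
nested periodic accent levels.  Level 1 is the fastest pulse (here the
sixteenth note, period 1); each higher level doubles the period, up to the
full metrical cycle (period ``2**(k-1)`` sixteenths).  A position carries an
accent at level *j* when its index is a multiple of that level's period, so
the number of active levels ("number of Xs" in a metrical grid drawing)
alternates strictly between strong and weak positions.

The accent *strength* of position *i* is the weighted count of active
levels::

    m_i = sum_j  w_j * g_ji

where ``g_ji`` is the binary presence indicator and the level weights
``w_j`` sum to 1.  One level — the tactus, the beat listeners clap to — may
be weighted more heavily than the rest; the remaining levels then share the
complement equally, ``(1 - w_tactus) / (k - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricalGrid",
    "MetricalWeights",
    "AccentProfile",
    "build_grid",
    "make_weights",
    "accent_strengths",
]


class UnsupportedMeterError(ValueError):
    """Raised for meters the binary-grid constructor cannot represent."""


@dataclass(frozen=True)
class MetricalGrid:
    """Binary accent-presence matrix for a nested binary hierarchy.

    Attributes
    ----------
    n_levels : int
        Number of hierarchy tiers *k* (level 1 = sixteenth-note level).
    periods : tuple of int
        Per-level period in sixteenth-note units, ``(1, 2, 4, ...)``.
    presence : np.ndarray
        Boolean array of shape ``(n_levels, n_positions)``; ``presence[j-1, i]``
        is ``g_ji``.
    tactus_level : int
        1-based index of the tactus level.
    offset : int
        Phase of the grid: position 0 of the sequence falls ``offset``
        sixteenths after a downbeat.  Default 0 (sequence starts on the
        strongest accent).
    """

    n_levels: int
    periods: tuple[int, ...]
    presence: np.ndarray = field(repr=False)
    tactus_level: int = 2
    offset: int = 0

    @property
    def cycle_length(self) -> int:
        return self.periods[-1]

    @property
    def n_positions(self) -> int:
        return self.presence.shape[1]

    def accent_counts(self) -> np.ndarray:
        """Integer count of active levels per position (number of Xs)."""
        return self.presence.sum(axis=0)


@dataclass(frozen=True)
class MetricalWeights:
    """Per-level weights ``w_j`` summing to 1, with an elevated tactus."""

    weights: tuple[float, ...]
    tactus_level: int = 2

    @property
    def n_levels(self) -> int:
        return len(self.weights)

    @property
    def tactus_weight(self) -> float:
        return self.weights[self.tactus_level - 1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class AccentProfile:
    """Per-position accent strengths ``m_i`` and raw accent counts."""

    strengths: np.ndarray = field(repr=False)
    accent_counts: np.ndarray = field(repr=False)
    cycle_length: int = 8

    @property
    def n_positions(self) -> int:
        return self.strengths.shape[0]

    def __len__(self) -> int:
        return self.n_positions


def build_grid(
    meter_cycle: int,
    n_levels: int,
    n_positions: int,
    tactus_level: int | None = None,
    offset: int = 0,
) -> MetricalGrid:
    """Build a nested binary metrical grid.

    Parameters
    ----------
    meter_cycle : int
        Positions per full metrical cycle; must equal ``2**(n_levels-1)``.
    n_levels : int
        Number of hierarchy tiers.
    n_positions : int
        Length of the sequence the grid covers.
    tactus_level : int, optional
        1-based tactus level (default 2, the eighth-note level).
    offset : int, optional
        Phase shift: position 0 falls this many sixteenths after a downbeat.

    Raises
    ------
    UnsupportedMeterError
        If ``meter_cycle`` is not the power-of-two implied by ``n_levels``
        (ternary and mixed meters are not represented).
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if n_positions < 1:
        raise ValueError(f"n_positions must be >= 1, got {n_positions}")
    if tactus_level is None:
        tactus_level = min(2, n_levels)
    if meter_cycle != 2 ** (n_levels - 1):
        raise UnsupportedMeterError(
            f"binary hierarchy with {n_levels} levels requires a cycle of "
            f"{2 ** (n_levels - 1)} positions, got {meter_cycle}"
        )
    if not 1 <= tactus_level <= n_levels:
        raise ValueError(f"tactus_level {tactus_level} outside 1..{n_levels}")
    periods = tuple(2**j for j in range(n_levels))
    idx = np.arange(n_positions) + offset
    presence = np.stack([idx % p == 0 for p in periods])
    return MetricalGrid(
        n_levels=n_levels,
        periods=periods,
        presence=presence,
        tactus_level=tactus_level,
        offset=offset,
    )


def make_weights(
    n_levels: int, tactus_level: int = 2, tactus_weight: float = 0.25
) -> MetricalWeights:
    """Build level weights with an elevated tactus.

    Non-tactus levels share ``(1 - tactus_weight) / (n_levels - 1)`` equally,
    so the vector sums to 1.  ``tactus_weight`` must lie in [0.25, 0.99]
    (0.25 = all four levels equal; the tactus may only be enhanced, never
    suppressed below the flat weighting).
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if n_levels == 1:
        return MetricalWeights(weights=(1.0,), tactus_level=1)
    if not 1 <= tactus_level <= n_levels:
        raise ValueError(f"tactus_level {tactus_level} outside 1..{n_levels}")
    if not 0.25 <= tactus_weight <= 0.99:
        raise ValueError(
            f"tactus_weight must lie in [0.25, 0.99], got {tactus_weight}"
        )
    other = (1.0 - tactus_weight) / (n_levels - 1)
    weights = tuple(
        tactus_weight if j == tactus_level else other
        for j in range(1, n_levels + 1)
    )
    return MetricalWeights(weights=weights, tactus_level=tactus_level)


def accent_strengths(grid: MetricalGrid, weights: MetricalWeights) -> AccentProfile:
    """Per-position accent strength ``m_i = sum_j w_j * g_ji``."""
    if weights.n_levels != grid.n_levels:
        raise ValueError(
            f"weight vector has {weights.n_levels} levels, grid has {grid.n_levels}"
        )
    m = weights.as_array() @ grid.presence
    return AccentProfile(
        strengths=m,
        accent_counts=grid.accent_counts().astype(int),
        cycle_length=grid.cycle_length,
    )
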