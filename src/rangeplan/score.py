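"""Scores, performances and coded error records.

A :class:`Score` is the intended event sequence for one stimulus: two hands
of isochronous sixteenth notes (an 8-event excerpt per hand embedded in a
longer context), with meter, key and fingering.  A :class:`Performance` is
the produced keystroke stream of one trial — timestamped MIDI-style note
events.  An :class:`ErrorRecord` is one coded discrepancy between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .metrical import AccentProfile, MetricalGrid, accent_strengths, build_grid, make_weights

__all__ = [
    "Score",
    "Performance",
    "ErrorRecord",
    "records_to_frame",
    "scale_pitch_classes",
    "triad_pitch_classes",
]

HANDS = ("R", "L")
EXCERPT_LEN = 8
#: per-hand (pre, excerpt, post) event counts for the two context layouts
LAYOUTS = {"long": (12, EXCERPT_LEN, 13), "short": (4, EXCERPT_LEN, 5)}

_MAJOR = (0, 2, 4, 5, 7, 9, 11)
_HARMONIC_MINOR = (0, 2, 3, 5, 7, 8, 11)
_TONIC_PC = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


def scale_pitch_classes(tonic: str, mode: str) -> tuple[int, ...]:
    """The 7 pitch classes of the stimulus key (harmonic minor for minor)."""
    if tonic not in _TONIC_PC:
        raise ValueError(f"unknown tonic {tonic!r}")
    if mode == "major":
        ivs = _MAJOR
    elif mode == "minor":
        ivs = _HARMONIC_MINOR
    else:
        raise ValueError(f"mode must be 'major' or 'minor', got {mode!r}")
    root = _TONIC_PC[tonic]
    return tuple(sorted((root + iv) % 12 for iv in ivs))


def triad_pitch_classes(tonic: str, mode: str) -> tuple[int, ...]:
    """The 3 pitch classes of the tonic triad."""
    root = _TONIC_PC[tonic]
    third = 4 if mode == "major" else 3
    if mode not in ("major", "minor"):
        raise ValueError(f"mode must be 'major' or 'minor', got {mode!r}")
    return tuple(sorted({(root) % 12, (root + third) % 12, (root + 7) % 12}))


@dataclass(frozen=True)
class Score:
    """Intended two-hand note sequence for one stimulus.

    ``pitches`` maps hand ("R"/"L") to an integer MIDI note-number array of
    equal length; hands sound together on every sixteenth-note position.
    The excerpt occupies positions ``pre_len .. pre_len + excerpt_len - 1``.
    """

    pitches: dict  # hand -> np.ndarray[int]
    context_label: str
    key_tonic: str = "C"
    key_mode: str = "major"
    excerpt_id: int = 1
    pre_len: int = 12
    excerpt_len: int = EXCERPT_LEN
    fingers: Optional[dict] = None  # hand -> list[str]
    grid_offset: int = 0
    n_levels: int = 4
    tactus_level: int = 2
    final_notes: Optional[dict] = None  # trailing whole note per hand

    def __post_init__(self) -> None:
        lens = {h: len(p) for h, p in self.pitches.items()}
        if len(set(lens.values())) != 1:
            raise ValueError(f"hands have unequal lengths: {lens}")
        if self.context_label in LAYOUTS:
            pre, exc, post = LAYOUTS[self.context_label]
            if (self.pre_len, self.excerpt_len) != (pre, exc):
                raise ValueError(
                    f"{self.context_label} layout requires pre={pre}, excerpt={exc}"
                )
            if self.n_positions != pre + exc + post:
                raise ValueError(
                    f"{self.context_label} layout requires {pre + exc + post} "
                    f"events per hand, got {self.n_positions}"
                )

    @property
    def n_positions(self) -> int:
        return len(next(iter(self.pitches.values())))

    @property
    def post_len(self) -> int:
        return self.n_positions - self.pre_len - self.excerpt_len

    @property
    def excerpt_positions(self) -> np.ndarray:
        return np.arange(self.pre_len, self.pre_len + self.excerpt_len)

    @property
    def excerpt_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_positions, dtype=bool)
        mask[self.excerpt_positions] = True
        return mask

    def grid(self) -> MetricalGrid:
        return build_grid(
            2 ** (self.n_levels - 1),
            self.n_levels,
            self.n_positions,
            tactus_level=self.tactus_level,
            offset=self.grid_offset,
        )

    def accent_profile(self, tactus_weight: float = 0.25) -> AccentProfile:
        w = make_weights(self.n_levels, self.tactus_level, tactus_weight)
        return accent_strengths(self.grid(), w)

    def accent_counts(self) -> np.ndarray:
        return self.grid().accent_counts()

    def all_pitches(self) -> np.ndarray:
        """Multiset of every pitch in the stimulus (both hands, in order)."""
        return np.concatenate([self.pitches[h] for h in sorted(self.pitches)])

    def pitch_set(self) -> set:
        return set(int(p) for p in self.all_pitches())

    def scale_pcs(self) -> tuple[int, ...]:
        return scale_pitch_classes(self.key_tonic, self.key_mode)

    def triad_pcs(self) -> tuple[int, ...]:
        return triad_pitch_classes(self.key_tonic, self.key_mode)

    def with_(self, **kw) -> "Score":
        return replace(self, **kw)


@dataclass(frozen=True)
class Performance:
    """Produced keystroke stream of one trial.

    ``keystrokes`` is a DataFrame with columns ``onset_ms`` (float,
    non-decreasing), ``pitch`` (int MIDI note number), ``velocity``
    (int 0-127) and ``hand`` ("R"/"L", or empty when unknown).
    """

    keystrokes: pd.DataFrame = field(repr=False)
    ioi_nominal_ms: float = 225.0
    tempo_label: str = "medium"
    participant: int = 0
    excerpt_id: int = 1
    context_label: str = "long"
    block: int = 1
    repetition: int = 1

    def __post_init__(self) -> None:
        ks = self.keystrokes
        required = {"onset_ms", "pitch", "velocity", "hand"}
        if not required.issubset(ks.columns):
            raise ValueError(f"keystrokes must have columns {sorted(required)}")
        if len(ks) and (np.diff(ks["onset_ms"].to_numpy()) < 0).any():
            raise ValueError("keystroke onsets must be non-decreasing")
        if len(ks) and not ks["velocity"].between(0, 127).all():
            raise ValueError("velocities must lie in 0..127")

    def by_hand(self, hand: str) -> pd.DataFrame:
        return self.keystrokes[self.keystrokes["hand"] == hand].reset_index(drop=True)

    @property
    def condition(self) -> tuple[str, str]:
        return (self.context_label, self.tempo_label)


@dataclass
class ErrorRecord:
    """One coded pitch error.

    ``signed_source_distance`` is ``source position - error position`` in
    events (positive = anticipatory source, ahead of the error), or ``None``
    when the error is noncontextual or has no identifiable source within the
    coding window.
    """

    error_type: str  # substitution | exchange | addition | deletion | chord_error
    contextual: bool
    hand: str
    target_position: int
    target_pitch: Optional[int]
    intruder_pitch: Optional[int]
    signed_source_distance: Optional[int] = None
    direction: str = "none"  # anticipatory | perseveratory | none
    accent_at_target: Optional[int] = None
    accent_at_source: Optional[int] = None
    velocity: Optional[int] = None
    onset_ms: Optional[float] = None
    in_key: Optional[bool] = None
    in_chord: Optional[bool] = None
    semitone_distance: Optional[int] = None
    same_finger: Optional[bool] = None
    in_excerpt: bool = False
    source_tie: bool = False
    chord_pitches: Optional[tuple] = None
    excluded: bool = False
    exclusion_reason: str = ""
    # trial metadata
    participant: int = 0
    excerpt_id: int = 1
    context_label: str = "long"
    tempo_label: str = "medium"
    block: int = 1
    repetition: int = 1

    def key(self) -> tuple:
        """Identity for round-trip comparisons against planted ground truth."""
        return (
            self.hand,
            self.target_position,
            self.error_type,
            self.intruder_pitch,
            self.signed_source_distance,
        )


_FRAME_COLS = [
    "participant", "excerpt_id", "context_label", "tempo_label", "block",
    "repetition", "hand", "error_type", "contextual", "target_position",
    "target_pitch", "intruder_pitch", "signed_source_distance", "direction",
    "accent_at_target", "accent_at_source", "velocity", "onset_ms", "in_key",
    "in_chord", "semitone_distance", "same_finger", "in_excerpt",
    "source_tie", "excluded", "exclusion_reason",
]


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate error records with the stable column contract."""
    rows = [{c: getattr(r, c) for c in _FRAME_COLS} for r in records]
    df = pd.DataFrame(rows, columns=_FRAME_COLS)
    return df
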