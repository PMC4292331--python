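"""Core range-model computations.

The range model describes incremental planning in sequence production as
graded memory activation of the events surrounding the one currently being
produced.  Two components multiply:

* serial proximity ``S_x = a**(|x|/t)`` — activation decays with event
  distance *x*, faster at fast tempi (small *t*, the interonset interval in
  seconds) or under tighter working-memory constraints (small *a*);
* metrical similarity ``M_x(i) = 1 - |m_i - m_{i+x}| / (m_i + m_{i+x})`` —
  a Weber-law similarity between the accent strengths of the current and
  the contextual position.

The absolute activation of the current event is the squared sum of its
contextual activations, ``Event(0) = B * (sum_{x!=0} S_x * M_x(i))**2``:
the more active the surrounding context, the easier the current event is to
retrieve.  Normalising ``S_x * M_x`` over a window of distances yields the
predicted *movement gradient* — the conditional probability that a serial
ordering error arises from each source distance, given that an error occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrical import AccentProfile, MetricalWeights, make_weights

__all__ = [
    "RangeParams",
    "ActivationField",
    "MovementGradient",
    "serial_component",
    "metrical_similarity",
    "contextual_activations",
    "event_activation",
    "predicted_gradient",
]

A_BOUNDS = (0.8, 1.0)  # open below, closed above
T_BOUNDS = (0.1, 2.0)
W2_BOUNDS = (0.25, 0.99)
DEFAULT_WINDOW = 8


class ParameterDomainError(ValueError):
    """A model parameter lies outside its admissible range."""


def _check_params(a: float, t: float) -> None:
    if not A_BOUNDS[0] < a <= A_BOUNDS[1]:
        raise ParameterDomainError(f"a must satisfy 0.8 < a <= 1.0, got {a}")
    if not T_BOUNDS[0] < t <= T_BOUNDS[1]:
        raise ParameterDomainError(f"t must satisfy 0.1 < t <= 2.0 s, got {t}")


@dataclass(frozen=True)
class RangeParams:
    """Parameter set of the range model.

    Attributes
    ----------
    a : float
        Memory parameter, 0.8 < a <= 1.0.  Larger values mean slower decay
        of contextual activation with serial distance.
    t : float
        Event duration (IOI) in seconds, 0.1 < t <= 2.0.
    weights : MetricalWeights
        Metrical level weights (tactus weight ``w2`` when the tactus is
        level 2).
    window : int
        Maximum source distance in events (default 8, one metrical cycle).
    activation_scale : float
        Non-negative output scale *B* on the absolute activation (default 1).
    use_meter : bool
        If False the metrical component is dropped (``M == 1`` everywhere):
        the meter-free serial-only variant used in model comparison.
    """

    a: float = 0.85
    t: float = 0.225
    weights: MetricalWeights = field(default_factory=lambda: make_weights(4, 2, 0.25))
    window: int = DEFAULT_WINDOW
    activation_scale: float = 1.0
    use_meter: bool = True

    def __post_init__(self) -> None:
        _check_params(self.a, self.t)
        if self.window < 1:
            raise ParameterDomainError(f"window must be >= 1, got {self.window}")
        if self.activation_scale < 0:
            raise ParameterDomainError(
                f"activation_scale must be >= 0, got {self.activation_scale}"
            )

    def with_(self, **kw) -> "RangeParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ActivationField:
    """Contextual activations of one current position over signed distances."""

    position: int
    signed_distances: np.ndarray = field(repr=False)
    contextual: np.ndarray = field(repr=False)

    @property
    def current(self) -> float:
        """Absolute activation of the current event (unit scale)."""
        return float(self.contextual.sum() ** 2)


@dataclass(frozen=True)
class MovementGradient:
    """Error proportions over absolute source distances ``1..window``.

    ``n_errors`` is the error count behind an observed gradient, or ``None``
    for a model-predicted gradient.
    """

    proportions: np.ndarray = field(repr=False)
    n_errors: int | None = None

    @property
    def window(self) -> int:
        return self.proportions.shape[0]

    @property
    def distances(self) -> np.ndarray:
        return np.arange(1, self.window + 1)

    def mean_distance(self) -> float:
        return float(self.proportions @ self.distances)

    def similar_proportion(self) -> float:
        """Share of errors at metrically similar (even) distances."""
        return float(self.proportions[1::2].sum())


def serial_component(x, a: float, t: float):
    """Serial proximity activation ``S_x = a**(|x|/t)``.

    Symmetric in the sign of ``x``; equals 1 at ``x = 0``.  Accepts scalars
    or arrays of distances.
    """
    _check_params(a, t)
    return a ** (np.abs(x) / t)


def metrical_similarity(m_current, m_other):
    """Weber-law metrical similarity ``1 - |mi - mj| / (mi + mj)``.

    Both accent strengths must be positive; the result lies in (0, 1],
    reaching 1 exactly when the accents are equal.
    """
    mi = np.asarray(m_current, dtype=float)
    mj = np.asarray(m_other, dtype=float)
    if np.any(mi <= 0) or np.any(mj <= 0):
        raise ValueError("accent strengths must be positive")
    out = 1.0 - np.abs(mi - mj) / (mi + mj)
    return out if out.ndim else float(out)


def _field_arrays(
    profile: AccentProfile, i: int, params: RangeParams
) -> tuple[np.ndarray, np.ndarray]:
    """Signed distances within the window/sequence and their S*M values."""
    n = profile.n_positions
    if not 0 <= i < n:
        raise IndexError(f"position {i} outside sequence of length {n}")
    lo = max(-params.window, -i)
    hi = min(params.window, n - 1 - i)
    x = np.concatenate([np.arange(lo, 0), np.arange(1, hi + 1)])
    s = serial_component(x, params.a, params.t)
    if params.use_meter:
        m = metrical_similarity(profile.strengths[i], profile.strengths[i + x])
        return x, s * m
    return x, s


def contextual_activations(
    profile: AccentProfile, i: int, params: RangeParams
) -> ActivationField:
    """Contextual activations ``S_x * M_x(i)`` of position ``i``.

    The window is clipped at the sequence edges: positions beyond the
    sequence contribute nothing (no phantom events).
    """
    x, v = _field_arrays(profile, i, params)
    return ActivationField(position=i, signed_distances=x, contextual=v)


def event_activation(profile: AccentProfile, i: int, params: RangeParams) -> float:
    """Absolute activation ``Event(0) = B * (sum_{x!=0} S_x * M_x(i))**2``."""
    _, v = _field_arrays(profile, i, params)
    return float(params.activation_scale * v.sum() ** 2)


def predicted_gradient(
    profile: AccentProfile,
    positions,
    params: RangeParams,
    interior_only: bool = False,
) -> MovementGradient:
    """Model-predicted movement gradient over distances ``1..window``.

    For each evaluation position, ``S_x * M_x`` over signed distances is
    folded into absolute bins (the ±x contributions add), the bins are
    averaged across positions, and the result is normalised to sum to 1.

    Parameters
    ----------
    positions : sequence of int
        Evaluation positions (typically the excerpt positions).
    interior_only : bool, optional
        If True, positions whose ±window crosses a sequence boundary are
        dropped before averaging.
    """
    positions = np.atleast_1d(np.asarray(positions, dtype=int))
    n = profile.n_positions
    w = params.window
    if interior_only:
        positions = positions[(positions >= w) & (positions <= n - 1 - w)]
        if positions.size == 0:
            raise ValueError("no interior evaluation positions remain")
    bins = np.zeros(w)
    for i in positions:
        x, v = _field_arrays(profile, int(i), params)
        np.add.at(bins, np.abs(x) - 1, v)
    bins /= positions.size
    total = bins.sum()
    if total <= 0:
        raise ZeroDivisionError("activation field is identically zero")
    return MovementGradient(proportions=bins / total, n_errors=None)
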