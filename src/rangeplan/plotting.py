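"""Plotting hooks: movement gradients and activation-by-rate curves."""

from __future__ import annotations

import numpy as np

from .metrical import AccentProfile
from .model import MovementGradient, RangeParams, event_activation

__all__ = ["plot_gradients", "plot_activation_by_rate"]


def plot_gradients(gradients: dict, chance: dict | None = None, ax=None):
    """Observed/predicted gradients by condition, with optional chance lines.

    ``gradients`` maps a label to a :class:`MovementGradient`; ``chance``
    maps a label to a chance gradient drawn as a dashed line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, g in gradients.items():
        ax.plot(g.distances, g.proportions, marker="o", label=str(label))
    if chance:
        for label, g in chance.items():
            props = getattr(g, "proportions", g)
            ax.plot(np.arange(1, len(props) + 1), props, linestyle="--",
                    color="gray", label=f"chance {label}")
    ax.set_xlabel("absolute source distance (events)")
    ax.set_ylabel("error proportion")
    ax.legend(fontsize=8)
    return ax


def plot_activation_by_rate(
    profiles: dict, positions: dict, a: float = 0.85,
    iois=np.arange(0.125, 1.01, 0.025), ax=None,
):
    """Mean current-event activation against production rate per layout.

    ``profiles`` maps a context label to an :class:`AccentProfile`;
    ``positions`` maps the same labels to evaluation positions.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, profile in profiles.items():
        pos = positions[label]
        means = []
        for t in iois:
            params = RangeParams(a=a, t=float(t))
            means.append(np.mean([event_activation(profile, int(i), params)
                                  for i in pos]))
        ax.plot(iois, means, label=str(label))
    ax.set_xlabel("interonset interval (s)")
    ax.set_ylabel("mean Event(0) activation")
    ax.legend(fontsize=8)
    return ax
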