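"""Fitting the range model to observed movement gradients.

The estimation problem: given an observed 8-bin movement gradient (error
proportions over absolute source distances 1..8), find the model parameters
that minimise the sum of squared errors between observed and predicted
bins.  Fits follow a two-step procedure: the memory parameter *a* is fitted
first with all metrical levels weighted equally; the tactus weight *w2* is
then fitted with *a* held at its (participant-) averaged step-one value.

Three model variants are compared: serial-only (S, one free parameter),
serial x metrical with equal weights (S x M fixed, one free parameter), and
serial x metrical with the tactus weight free (S x M + w2, two free
parameters).  Goodness of fit is the variance accounted for (VAF, the
squared Pearson correlation between observed and predicted bins; critical
value 0.50 for an 8-point gradient at alpha = .05) and the Gaussian-SSE
Akaike information criterion ``AIC = n ln(SSE/n) + 2p`` (lower is better).

The optimiser is a deterministic exhaustive grid (step 1e-3) with
golden-section refinement inside the winning grid cell; identical inputs
always give identical fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .metrical import MetricalGrid, make_weights
from .model import A_BOUNDS, MovementGradient, W2_BOUNDS

__all__ = [
    "CRITICAL_VAF",
    "GradientModel",
    "GradientFitResults",
    "fit_a",
    "fit_w2",
    "vaf",
    "aic",
    "compare_models",
    "two_step_fit",
    "NoFitError",
]

CRITICAL_VAF = 0.50  # r^2 significance threshold for an 8-point gradient
GRID_STEP = 1e-3
MODEL_TAGS = ("s", "sxm_fixed", "sxm_w2")
_EQUAL_W2 = 0.25


class NoFitError(RuntimeError):
    """The observed gradient is undefined or unusable for fitting."""


def vaf(observed, predicted) -> float:
    """Variance accounted for: squared Pearson correlation of the bins."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted gradients differ in length")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise NoFitError("zero-variance gradient: VAF undefined")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def aic(sse: float, n: int, p: int) -> float:
    """Gaussian-SSE Akaike information criterion ``n ln(SSE/n) + 2p``."""
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    return float(n * math.log(max(sse, 1e-300) / n) + 2 * p)


def _golden(f, lo: float, hi: float, tol: float = 1e-7) -> float:
    """Golden-section minimisation of a unimodal scalar function."""
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


@dataclass
class GradientFitResults:
    """Fitted parameters, goodness of fit and diagnostics of one gradient fit.

    Produced by :meth:`GradientModel.fit`; carries enough provenance
    (``t_used``, bounds, objective) to reproduce the fit exactly.
    """

    model: "GradientModel"
    model_tag: str
    a_hat: float
    w2_hat: Optional[float]
    t_used: float
    sse: float
    n_points: int
    n_free_params: int
    at_bound: bool = False

    @property
    def params(self) -> dict:
        out = {"a": self.a_hat}
        if self.w2_hat is not None:
            out["w2"] = self.w2_hat
        return out

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.a_hat, w2=self.w2_hat,
                                  use_meter=self.model_tag != "s")

    @property
    def vaf(self) -> float:
        return vaf(self.model.observed, self.fittedvalues)

    @property
    def significant(self) -> bool:
        """Whether the fit clears the critical VAF of 0.50."""
        return self.vaf >= CRITICAL_VAF

    @property
    def aic(self) -> float:
        return aic(self.sse, self.n_points, self.n_free_params)

    def summary(self) -> str:
        lines = [
            "Range model gradient fit",
            "=" * 44,
            f"model:            {self.model_tag}",
            f"n gradient bins:  {self.n_points}",
            f"free parameters:  {self.n_free_params}",
            f"t (IOI, s):       {self.t_used:.4f}",
            f"a_hat:            {self.a_hat:.4f}",
        ]
        if self.w2_hat is not None:
            lines.append(f"w2_hat:           {self.w2_hat:.4f}")
        lines += [
            f"SSE:              {self.sse:.6f}",
            f"VAF (r^2):        {self.vaf:.4f}"
            f"  [{'significant' if self.significant else 'n.s.'}"
            f" at critical {CRITICAL_VAF}]",
            f"AIC:              {self.aic:.2f}",
        ]
        if self.at_bound:
            lines.append("warning: estimate pinned at a parameter bound")
        return "\n".join(lines)


class GradientModel:
    """Observed movement gradient paired with its stimulus structure.

    Parameters
    ----------
    observed : MovementGradient or array
        Observed error proportions over distances ``1..window``.
    grid : MetricalGrid
        Metrical grid of the stimulus layout the errors came from.
    positions : sequence of int
        Evaluation positions for the predicted gradient (the excerpt).
    t : float
        Event IOI in seconds (mean produced IOI of the fitted trials).
    """

    def __init__(self, observed, grid: MetricalGrid, positions, t: float):
        if isinstance(observed, MovementGradient):
            observed = observed.proportions
        self.observed = np.asarray(observed, dtype=float)
        self.window = self.observed.shape[0]
        self.grid = grid
        self.positions = np.atleast_1d(np.asarray(positions, dtype=int))
        self.t = float(t)
        self._build_pairs()
        self._coef_cache: dict = {}

    @classmethod
    def from_score(cls, observed, score, t: float,
                   tactus_weight: float = _EQUAL_W2) -> "GradientModel":
        return cls(observed, score.grid(), score.excerpt_positions, t)

    @classmethod
    def from_records(cls, records, score, t: float) -> "GradientModel":
        from .coding import movement_gradient

        return cls.from_score(movement_gradient(records), score, t)

    def _build_pairs(self) -> None:
        n = self.grid.n_positions
        i_idx, j_idx, absd = [], [], []
        for i in self.positions:
            for x in range(-self.window, self.window + 1):
                if x == 0:
                    continue
                j = i + x
                if 0 <= j < n:
                    i_idx.append(i)
                    j_idx.append(j)
                    absd.append(abs(x))
        self._i = np.asarray(i_idx)
        self._j = np.asarray(j_idx)
        self._d = np.asarray(absd)
        # indicator matrix folding pairs into absolute-distance bins
        self._fold = np.zeros((len(self._d), self.window))
        self._fold[np.arange(len(self._d)), self._d - 1] = 1.0

    def _similarity(self, w2: float) -> np.ndarray:
        w = make_weights(self.grid.n_levels, self.grid.tactus_level, w2)
        m = w.as_array() @ self.grid.presence
        mi, mj = m[self._i], m[self._j]
        return 1.0 - np.abs(mi - mj) / (mi + mj)

    def _coef(self, w2: Optional[float], use_meter: bool) -> np.ndarray:
        """Per-bin metrical coefficients c_d = sum over pairs of M at distance d."""
        key = (None if not use_meter else round(float(w2), 12))
        if key not in self._coef_cache:
            mvals = self._similarity(w2) if use_meter else np.ones(len(self._d))
            self._coef_cache[key] = mvals @ self._fold
        return self._coef_cache[key]

    def predict(self, a: float, w2: Optional[float] = None,
                use_meter: bool = True) -> np.ndarray:
        """Predicted gradient bins for the given parameters."""
        c = self._coef(_EQUAL_W2 if w2 is None else w2, use_meter)
        bins = c * a ** (np.arange(1, self.window + 1) / self.t)
        return bins / bins.sum()

    def _sse_a(self, a_values: np.ndarray, c: np.ndarray) -> np.ndarray:
        expo = np.arange(1, self.window + 1) / self.t
        bins = c * a_values[:, None] ** expo
        bins /= bins.sum(axis=1, keepdims=True)
        return ((bins - self.observed) ** 2).sum(axis=1)

    def fit(self, model_tag: str = "sxm_fixed", a: Optional[float] = None,
            w2: Optional[float] = None) -> GradientFitResults:
        """Fit one model variant to the observed gradient.

        ``model_tag`` is one of ``"s"`` (serial only, *a* free),
        ``"sxm_fixed"`` (serial x metrical, equal weights, *a* free) or
        ``"sxm_w2"`` (serial x metrical, *w2* free; *a* must be supplied,
        typically the participant's step-one average).
        """
        if model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model_tag {model_tag!r}")
        use_meter = model_tag != "s"
        if model_tag in ("s", "sxm_fixed"):
            c = self._coef(_EQUAL_W2, use_meter)
            lo, hi = A_BOUNDS[0] + GRID_STEP, A_BOUNDS[1]
            grid = np.minimum(np.arange(lo, hi + GRID_STEP / 2, GRID_STEP), hi)
            sse = self._sse_a(grid, c)
            k = int(np.argmin(sse))
            glo = max(lo, grid[k] - GRID_STEP)
            ghi = min(hi, grid[k] + GRID_STEP)
            a_hat = _golden(lambda av: self._sse_a(np.array([av]), c)[0], glo, ghi)
            sse_hat = float(self._sse_a(np.array([a_hat]), c)[0])
            at_bound = a_hat <= lo + 1e-6 or a_hat >= hi - 1e-6
            return GradientFitResults(
                model=self, model_tag=model_tag, a_hat=float(a_hat),
                w2_hat=None, t_used=self.t, sse=sse_hat,
                n_points=self.window, n_free_params=1, at_bound=at_bound)
        # sxm_w2: w2 free with a fixed
        if a is None:
            raise ValueError("sxm_w2 requires the step-one `a` estimate")

        def sse_w2(w2v: float) -> float:
            c = self._coef(w2v, True)
            return float(self._sse_a(np.array([a]), c)[0])

        lo, hi = W2_BOUNDS
        grid = np.minimum(np.arange(lo, hi + GRID_STEP / 2, GRID_STEP), hi)
        sses = np.array([sse_w2(v) for v in grid])
        k = int(np.argmin(sses))
        glo = max(lo, grid[k] - GRID_STEP)
        ghi = min(hi, grid[k] + GRID_STEP)
        w2_hat = _golden(sse_w2, glo, ghi)
        if sse_w2(w2_hat) > sses[k]:
            w2_hat = float(grid[k])
        at_bound = w2_hat <= lo + 1e-6 or w2_hat >= hi - 1e-6
        return GradientFitResults(
            model=self, model_tag="sxm_w2", a_hat=float(a),
            w2_hat=float(w2_hat), t_used=self.t, sse=float(sse_w2(w2_hat)),
            n_points=self.window, n_free_params=2, at_bound=at_bound)


def fit_a(gradient, grid, positions, t: float,
          use_meter: bool = True) -> GradientFitResults:
    """Step one: fit the memory parameter *a* with equal metrical weights."""
    model = GradientModel(gradient, grid, positions, t)
    return model.fit("sxm_fixed" if use_meter else "s")


def fit_w2(gradient, grid, positions, t: float, a: float) -> GradientFitResults:
    """Step two: fit the tactus weight *w2* with *a* held fixed."""
    model = GradientModel(gradient, grid, positions, t)
    return model.fit("sxm_w2", a=a)


def compare_models(gradient, grid, positions, t: float) -> pd.DataFrame:
    """Fit S, S x M (fixed weights) and S x M (+w2) to one gradient.

    The w2 fit reuses the fixed-weights fit's *a* (so its SSE can never
    exceed the fixed fit's).  Returns a table with VAF (percent), AIC and a
    best-model flag by AIC.
    """
    model = GradientModel(gradient, grid, positions, t)
    res_s = model.fit("s")
    res_f = model.fit("sxm_fixed")
    res_w = model.fit("sxm_w2", a=res_f.a_hat)
    rows = []
    for res in (res_s, res_f, res_w):
        rows.append(dict(model_tag=res.model_tag, a_hat=res.a_hat,
                         w2_hat=res.w2_hat, vaf_pct=100 * res.vaf,
                         aic=res.aic, sse=res.sse,
                         n_free_params=res.n_free_params,
                         significant=res.significant))
    table = pd.DataFrame(rows)
    table["best"] = table["aic"] == table["aic"].min()
    return table


def two_step_fit(items) -> dict:
    """Two-step fit across one participant's conditions.

    ``items`` maps a condition key to ``(gradient, grid, positions, t)``.
    Step one fits *a* per condition (equal weights); *a* is then averaged
    over the conditions that produced errors, and step two fits *w2* per
    condition at that average.  Returns ``{key: (a_results, w2_results)}``.
    """
    models, step1 = {}, {}
    for key, (gradient, grid, positions, t) in items.items():
        models[key] = GradientModel(gradient, grid, positions, t)
        step1[key] = models[key].fit("sxm_fixed")
    a_bar = float(np.mean([r.a_hat for r in step1.values()]))
    return {key: (step1[key], models[key].fit("sxm_w2", a=a_bar))
            for key in models}
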