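"""Summation analysis: how simultaneously evoked responses relate to the
arithmetic sum of the single-input responses.

The simultaneous (DUO) response is fitted by a single scale factor applied
to the sum of the two single-pathway responses::

    DUO(t) ~= alpha * (AiP(t) + LA(t))

with residuals weighted by a decaying exponential (time constant 20 ms by
default) so the early response — where synaptic interaction matters —
dominates the fit. The scale factor is constrained non-negative by default
(the original analysis used a non-negative least-squares routine):

    alpha = argmin_{a >= 0}  sum_t w(t)^2 (DUO(t) - a * S(t))^2,
    S = AiP + LA,  w(t) = exp(-t / tau) inside the fit window, 0 outside,

which has the closed form ``alpha = max(0, sum w^2 S D / sum w^2 S^2)``.
``alpha > 1`` means super-linear summation, ``alpha = 1`` linear,
``alpha < 1`` sub-linear. The same fit applies to conductance traces
(G_exc, G_inh) and to synaptic currents recorded at the inhibitory
reversal potential.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core_io import TimeBase
from .errors import DegenerateFitError, InsufficientDataError, ParameterError
from .stats import pearson_skewness


class SummationClass(str, enum.Enum):
    SUBLINEAR = "sublinear"
    LINEAR = "linear"
    SUPERLINEAR = "superlinear"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class SummationConfig:
    """Parameters of the scale-factor fit.

    tau_ms
        Exponential weighting time constant (default 20 ms; makes the first
        ~40 ms dominate).
    fit_window_ms
        Window of the fit, default the full [0, 100] ms analysis span.
    nonnegative
        Constrain alpha >= 0 (default True, matching the original
        non-negative least-squares fit).
    """

    tau_ms: float = 20.0
    fit_window_ms: tuple[float, float] = (0.0, 100.0)
    nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ParameterError("tau_ms must be positive")


@dataclass
class SummationResult:
    alpha: float
    weighted_rss: float
    classification: SummationClass
    n_points: int
    tau_ms: float = 20.0


def exponential_weights(timebase: TimeBase, tau_ms: float = 20.0,
                        fit_window_ms: tuple[float, float] = (0.0, 100.0),
                        ) -> np.ndarray:
    """``w(t) = exp(-t/tau)`` for t in the fit window (t >= 0), 0 outside."""
    if tau_ms <= 0:
        raise ParameterError("tau_ms must be positive")
    t = timebase.times()
    w = np.exp(-t / tau_ms)
    lo = max(fit_window_ms[0], 0.0)
    w[(t < lo) | (t > fit_window_ms[1])] = 0.0
    return w


def fit_scale_factor(duo: np.ndarray, aip: np.ndarray, la: np.ndarray,
                     timebase: TimeBase,
                     cfg: SummationConfig = SummationConfig(),
                     tol: float = 0.0) -> SummationResult:
    """Weighted (non-negative) least-squares fit of DUO = alpha * (AiP + LA).

    Raises
    ------
    DegenerateFitError
        If the summed single responses are identically zero in the window.
    """
    duo, aip, la = (np.asarray(x, dtype=float) for x in (duo, aip, la))
    if not (duo.shape == aip.shape == la.shape == (timebase.n_samples,)):
        raise InsufficientDataError("traces must share the given timebase")
    w = exponential_weights(timebase, cfg.tau_ms, cfg.fit_window_ms)
    s = aip + la
    w2 = w * w
    denom = float(w2 @ (s * s))
    if denom == 0.0:
        raise DegenerateFitError(
            "summed single responses are identically zero in the fit window"
        )
    alpha = float(w2 @ (s * duo)) / denom
    if cfg.nonnegative:
        alpha = max(alpha, 0.0)
    resid = duo - alpha * s
    rss = float(w2 @ (resid * resid))
    n_points = int(np.count_nonzero(w))
    return SummationResult(alpha, rss, classify_summation(alpha, tol),
                           n_points, cfg.tau_ms)


def classify_summation(alpha: float, tol: float = 0.0) -> SummationClass:
    """Classify a scale factor: >1+tol super-linear, <1-tol sub-linear,
    otherwise linear."""
    if tol < 0:
        raise ParameterError("tol must be >= 0")
    if alpha > 1.0 + tol:
        return SummationClass.SUPERLINEAR
    if alpha < 1.0 - tol:
        return SummationClass.SUBLINEAR
    return SummationClass.LINEAR


def population_scale_summary(alphas) -> tuple[float, float, float, float]:
    """Population summary of per-cell scale factors.

    Returns ``(mean, SEM, SD, skewness)`` with SD the n-1 sample standard
    deviation, SEM = SD/sqrt(n), and skewness the Fisher-Pearson moment
    coefficient g1.
    """
    x = np.asarray(alphas, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 scale factors")
    sd = float(np.std(x, ddof=1))
    return (float(x.mean()), sd / np.sqrt(x.size), sd,
            pearson_skewness(x) if x.size >= 3 and sd > 0 else 0.0)
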