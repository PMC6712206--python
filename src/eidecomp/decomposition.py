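"""Linear decomposition of synaptic currents into excitatory and inhibitory
conductances.

The evoked membrane current at holding potential ``V`` is, after background
subtraction and assuming only glutamatergic and GABA_A-ergic synapses with
time-invariant reversal potentials::

    I_m(t) = G_exc(t) * (V - E_exc) + G_inh(t) * (V - E_inh)
           = [G_exc(t) + G_inh(t)] * V - [G_exc(t)*E_exc + G_inh(t)*E_inh]

i.e. at each moment in time the current/voltage relation across holding
potentials is linear, ``I_m = a(t) * V + b(t)``. Fitting that line at every
timepoint (ordinary least squares over the clamped potentials, typically the
five levels from -90 to -50 mV) gives the total synaptic conductance
``a(t) = G_exc + G_inh`` [nS] and intercept ``b(t)`` [pA], from which::

    G_inh(t) = (b(t) + a(t) * E_exc) / (E_exc - E_inh)
    G_exc(t) = a(t) - G_inh(t)

The excitability ratio ``(G_exc + G_m) / (G_inh + G_m)`` regularizes the
pointwise excitation/inhibition balance by the passive membrane (leak)
conductance ``G_m``, which also prevents division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Sweep, SweepSet, TimeBase
from .errors import DataError, InsufficientDataError, ParameterError

DEFAULT_HOLDING_POTENTIALS = (-90.0, -80.0, -70.0, -60.0, -50.0)


@dataclass(frozen=True)
class ReversalPotentials:
    """Reversal potentials of the two synaptic components (mV).

    Defaults: 0 mV for glutamatergic excitation, -70 mV for GABA_A
    inhibition (the chloride reversal under the recording solutions
    this analysis was designed for).
    """

    E_exc_mV: float = 0.0
    E_inh_mV: float = -70.0

    def __post_init__(self) -> None:
        if self.E_exc_mV == self.E_inh_mV:
            raise ParameterError("E_exc and E_inh must differ")


@dataclass
class IVFit:
    """Per-timepoint linear I/V fit across holding potentials.

    ``a_nS`` is the slope (total conductance), ``b_pA`` the intercept.
    ``r2`` is the coefficient of determination; where the current is
    identical across potentials a flat line fits perfectly and r2 is
    recorded as 1 by convention.
    """

    timebase: TimeBase
    a_nS: np.ndarray
    b_pA: np.ndarray
    r2: np.ndarray
    n_potentials: int


@dataclass
class ConductanceTrace:
    """Reconstructed excitatory and inhibitory conductance time courses."""

    timebase: TimeBase
    G_exc_nS: np.ndarray
    G_inh_nS: np.ndarray
    clipped: bool = False


@dataclass
class ExcitabilityTrace:
    """Leak-regularized excitation/inhibition balance over time."""

    timebase: TimeBase
    ratio: np.ndarray
    G_m_nS: float


def fit_iv_per_timepoint(sweepset: SweepSet) -> IVFit:
    """OLS fit of I against V across holding potentials, at each timepoint.

    The set must be background-subtracted and repeat-averaged (one sweep per
    potential) with >= 2 distinct holding potentials.
    """
    potentials = sweepset.holding_potentials_mV
    if len(potentials) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct holding potentials, got {len(potentials)}"
        )
    rows = []
    for v in potentials:
        sweeps = sweepset.at_potential(v)
        if len(sweeps) != 1:
            raise InsufficientDataError(
                f"expected one averaged sweep at {v} mV, got {len(sweeps)}; "
                "run average_repeats first"
            )
        rows.append(sweeps[0].values)
    I = np.stack(rows)                      # (n_potentials, n_t)
    if not np.all(np.isfinite(I)):
        raise DataError("non-finite samples in sweepset")
    V = np.asarray(potentials, dtype=float)

    vbar = V.mean()
    dv = V - vbar
    ss_v = float(dv @ dv)
    ibar = I.mean(axis=0)
    a = (dv @ (I - ibar)) / ss_v            # nS (pA/mV)
    b = ibar - a * vbar                     # pA

    resid = I - (np.outer(V, a) + b)
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((I - ibar) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot <= 1e-300, 1.0, r2)   # flat I/V: perfect flat line
    r2 = np.clip(r2, 0.0, 1.0)
    return IVFit(sweepset.timebase, a, b, r2, len(potentials))


def decompose(
    ivfit: IVFit,
    reversals: ReversalPotentials = ReversalPotentials(),
    clip_negative: bool = False,
) -> ConductanceTrace:
    """Convert the per-timepoint I/V line into G_exc(t) and G_inh(t).

    Negative estimates (possible under noise) are reported as-is by default;
    with ``clip_negative`` they are set to 0 and the trace flagged.
    """
    e_exc, e_inh = reversals.E_exc_mV, reversals.E_inh_mV
    if not (np.all(np.isfinite(ivfit.a_nS)) and np.all(np.isfinite(ivfit.b_pA))):
        raise DataError("non-finite I/V fit")
    g_inh = (ivfit.b_pA + ivfit.a_nS * e_exc) / (e_exc - e_inh)
    g_exc = ivfit.a_nS - g_inh
    clipped = False
    if clip_negative:
        clipped = bool(np.any(g_inh < 0) or np.any(g_exc < 0))
        g_inh = np.maximum(g_inh, 0.0)
        g_exc = np.maximum(g_exc, 0.0)
    return ConductanceTrace(ivfit.timebase, g_exc, g_inh, clipped)


def measure_gm(
    step_sweep: Sweep,
    step_amplitude_mV: float,
    baseline_window_ms: tuple[float, float] = (-50.0, 0.0),
    steady_window_ms: tuple[float, float] | None = None,
) -> float:
    """Passive membrane conductance from a small voltage-clamp step.

    ``G_m = dI_steady / dV`` in nS, with the steady-state current taken as
    the plateau mean late in the step (by default the last quarter of the
    post-stimulus span) minus the pre-step plateau mean.
    """
    if step_amplitude_mV == 0:
        raise ParameterError("step amplitude must be nonzero")
    tb = step_sweep.timebase
    if steady_window_ms is None:
        span = tb.end_ms
        steady_window_ms = (0.75 * span, span)
    pre = step_sweep.values[tb.window_slice(*baseline_window_ms)]
    post = step_sweep.values[tb.window_slice(*steady_window_ms)]
    return float((post.mean() - pre.mean()) / step_amplitude_mV)


def excitability_ratio(ct: ConductanceTrace, G_m_nS: float) -> ExcitabilityTrace:
    """Pointwise ``(G_exc + G_m) / (G_inh + G_m)``; requires ``G_m > 0``."""
    if G_m_nS <= 0:
        raise ParameterError("G_m must be positive")
    ratio = (ct.G_exc_nS + G_m_nS) / (ct.G_inh_nS + G_m_nS)
    return ExcitabilityTrace(ct.timebase, ratio, G_m_nS)


def qc_linearity(ivfit: IVFit, r2_min: float = 0.9,
                 window_ms: tuple[float, float] = (0.0, 100.0)) -> bool:
    """Sweepset-level linearity screen: median r2 over the response window.

    Mirrors the inclusion rule that only neurons with a linear I/V relation
    enter the conductance analysis.
    """
    sl = ivfit.timebase.window_slice(*window_ms)
    return bool(np.median(ivfit.r2[sl]) >= r2_min)
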