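"""Seeded generators for every input the pipeline consumes.

The generators emulate the recordings the analysis was designed for:

* difference-of-exponentials synaptic conductance transients with the
  measured latencies and peak amplitudes (excitation ~3 nS at ~6 ms,
  inhibition ~9 nS at ~7.7 ms for neocortical stimulation; smaller for
  amygdalar stimulation),
* ideal voltage-clamp sweep sets at several holding potentials with a
  passive leak and additive Gaussian current noise, in the standard
  3-repeat structure,
* leaky integrate-and-fire (LIF) current-clamp traces with an internal
  ground-truth spike log,
* simultaneous-stimulation (DUO) traces built with a controllable true
  summation factor,
* a 464-diode hexagonally packed photodiode array sampled at 1 kHz.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Condition, Sweep, SweepSet, TimeBase
from .decomposition import DEFAULT_HOLDING_POTENTIALS, ReversalPotentials
from .detection import SpikeTrain
from .errors import ParameterError
from .vsd import DiodeArrayRecording

# Ground-truth kernel defaults: peak conductances and latencies measured for
# the two pathways (mean values over the recorded principal neurons);
# rise/decay kinetics are not reported and are package defaults.
AIP_EXC = dict(latency_ms=5.95, peak_nS=2.94)
AIP_INH = dict(latency_ms=7.67, peak_nS=8.89)
LA_EXC = dict(latency_ms=5.55, peak_nS=0.75)
LA_INH = dict(latency_ms=6.72, peak_nS=3.22)

DEFAULT_TAU_RISE_MS = 1.0
DEFAULT_TAU_DECAY_MS = 10.0

# Excitatory drive onto fast-spiking (PV) interneurons, derived from the
# measured synaptic current peaks at the -70 mV inhibitory reversal
# (AiP 1416 pA, LA 322 pA; 70 mV driving force) and response latencies.
PV_AIP_EXC = dict(latency_ms=7.1, peak_nS=1416.0 / 70.0)
PV_LA_EXC = dict(latency_ms=6.6, peak_nS=322.0 / 70.0)


@dataclass(frozen=True)
class ConductanceKernel:
    """Difference-of-exponentials synaptic conductance transient."""

    latency_ms: float
    peak_nS: float
    tau_rise_ms: float = DEFAULT_TAU_RISE_MS
    tau_decay_ms: float = DEFAULT_TAU_DECAY_MS
    kind: str = "exc"

    def __post_init__(self) -> None:
        if not (self.tau_decay_ms > self.tau_rise_ms > 0):
            raise ParameterError("need tau_decay > tau_rise > 0")
        if self.peak_nS < 0 or self.latency_ms < 0:
            raise ParameterError("peak and latency must be >= 0")

    @property
    def time_to_peak_ms(self) -> float:
        """Closed-form time of the kernel maximum, relative to the stimulus."""
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return self.latency_ms + tr * td / (td - tr) * np.log(td / tr)

    def scaled(self, factor: float) -> "ConductanceKernel":
        return ConductanceKernel(self.latency_ms, self.peak_nS * factor,
                                 self.tau_rise_ms, self.tau_decay_ms,
                                 self.kind)


def default_kernels(condition: Condition | str = Condition.AIP,
                    ) -> tuple[ConductanceKernel, ConductanceKernel]:
    """(excitatory, inhibitory) ground-truth kernels for a pathway."""
    cond = Condition(condition)
    if cond == Condition.AIP:
        exc, inh = AIP_EXC, AIP_INH
    elif cond == Condition.LA:
        exc, inh = LA_EXC, LA_INH
    else:
        raise ParameterError(f"no default kernels for condition {cond}")
    return (ConductanceKernel(kind="exc", **exc),
            ConductanceKernel(kind="inh", **inh))


@dataclass(frozen=True)
class MembraneModel:
    """Passive membrane plus LIF spiking parameters.

    Defaults are the measured intrinsic properties of principal neurons:
    input resistance 111 MOhm, resting potential -62.8 mV, spike threshold
    -37.3 mV, capacitance 21.4 pF. ``pv_interneuron()`` gives the
    fast-spiking interneuron set (104 MOhm, -65.9 mV, -36.1 mV, 14.3 pF).
    """

    C_pF: float = 21.4
    R_MOhm: float = 111.0
    E_rest_mV: float = -62.8
    V_thresh_mV: float = -37.3
    V_reset_mV: float = -62.8
    refractory_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.C_pF <= 0 or self.R_MOhm <= 0:
            raise ParameterError("C and R must be positive")
        if self.V_reset_mV >= self.V_thresh_mV:
            raise ParameterError("V_reset must be below V_thresh")

    @property
    def G_m_nS(self) -> float:
        """Leak conductance, 1/R (1000/MOhm = nS)."""
        return 1000.0 / self.R_MOhm

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant R*C (MOhm * pF = ns -> /1000 ms)."""
        return self.R_MOhm * self.C_pF / 1000.0

    @staticmethod
    def pv_interneuron() -> "MembraneModel":
        return MembraneModel(C_pF=14.3, R_MOhm=104.0, E_rest_mV=-65.9,
                             V_thresh_mV=-36.1, V_reset_mV=-65.9)


@dataclass(frozen=True)
class NoiseModel:
    """Additive recording noise levels."""

    current_sd_pA: float = 10.0
    vsd_sd_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.current_sd_pA < 0 or self.vsd_sd_fraction < 0:
            raise ParameterError("noise SDs must be >= 0")


DEFAULT_TIMEBASE = TimeBase(t0_ms=-100.0, dt_ms=0.1, n_samples=2001)


def kernel_waveform(k: ConductanceKernel, timebase: TimeBase) -> np.ndarray:
    """Evaluate the kernel on a grid, normalized so the grid maximum equals
    the requested peak exactly.

    ``g(t) = peak * N * (exp(-(t-L)/tau_d) - exp(-(t-L)/tau_r))`` for
    ``t >= L``, 0 before.
    """
    t = timebase.times()
    dt = np.maximum(t - k.latency_ms, 0.0)
    shape = np.exp(-dt / k.tau_decay_ms) - np.exp(-dt / k.tau_rise_ms)
    shape[t < k.latency_ms] = 0.0
    m = shape.max()
    if m <= 0 or k.peak_nS == 0:
        return np.zeros_like(shape)
    return k.peak_nS * shape / m


def saturating_scale(stimulus_uA: float, s50_uA: float = 400.0,
                     hill: float = 2.0) -> float:
    """Stimulus-intensity input/output scaling: ``(s/s50)^h / (1+(s/s50)^h)``.

    Used only to build input/output-curve fixtures; at ``s = s50`` the
    response is half-maximal.
    """
    x = (stimulus_uA / s50_uA) ** hill
    return x / (1.0 + x)


def simulate_voltage_clamp(
    gexc: np.ndarray,
    ginh: np.ndarray,
    timebase: TimeBase = DEFAULT_TIMEBASE,
    m: MembraneModel = MembraneModel(),
    potentials_mV=DEFAULT_HOLDING_POTENTIALS,
    reversals: ReversalPotentials = ReversalPotentials(),
    noise: NoiseModel = NoiseModel(),
    n_repeats: int = 3,
    condition: Condition = Condition.AIP,
    excitation_blocked: bool = False,
) -> SweepSet:
    """Ideal-clamp sweep set from known conductance traces.

    At each holding potential ``V_h`` (the clamp is ideal, ``V_m == V_h``)::

        I(t) = gexc(t) (V_h - E_exc) + ginh(t) (V_h - E_inh)
             + G_m (V_h - E_rest) + eps(t),  eps ~ N(0, current_sd^2)

    Repeats differ only in noise. ``excitation_blocked`` zeroes both
    conductances (the glutamatergic-block control: feedforward inhibition
    disappears with excitation).
    """
    potentials = sorted(set(float(v) for v in potentials_mV))
    if len(potentials) < 2:
        raise ParameterError("need >= 2 distinct holding potentials")
    gexc = np.zeros(timebase.n_samples) if excitation_blocked else np.asarray(gexc, float)
    ginh = np.zeros(timebase.n_samples) if excitation_blocked else np.asarray(ginh, float)
    rng = np.random.default_rng(noise.seed)
    sweeps = []
    for v in potentials:
        i_clean = (gexc * (v - reversals.E_exc_mV)
                   + ginh * (v - reversals.E_inh_mV)
                   + m.G_m_nS * (v - m.E_rest_mV))
        for rep in range(n_repeats):
            eps = (rng.normal(0.0, noise.current_sd_pA, timebase.n_samples)
                   if noise.current_sd_pA > 0 else 0.0)
            sweeps.append(Sweep(timebase, i_clean + eps, v, condition, rep))
    return SweepSet(sweeps, condition,
                    {"junction_corrected": True, "ground_truth": True})


def simulate_current_clamp(
    gexc: np.ndarray,
    ginh: np.ndarray,
    timebase: TimeBase | None = None,
    m: MembraneModel = MembraneModel(),
    reversals: ReversalPotentials = ReversalPotentials(),
    noise_sd_pA: float = 0.0,
    seed: int = 0,
    spike_peak_mV: float = 30.0,
    condition: Condition = Condition.AIP,
) -> tuple[Sweep, SpikeTrain]:
    """LIF current-clamp simulation driven by conductance traces.

    Forward-Euler integration of::

        C dV/dt = -(V - E_rest)/R - gexc (V - E_exc) - ginh (V - E_inh) + eps

    with threshold-reset spiking and an absolute refractory period. Returns
    the voltage trace — with stylized spike peaks rendered at ``spike_peak_mV``
    so peak detectors have something to find — and the internal spike log as
    ground truth. Requires ``dt <= 0.1 tau_m`` for stability.
    """
    if timebase is None:
        timebase = TimeBase(t0_ms=-10.0, dt_ms=0.01,
                            n_samples=int(round(110.0 / 0.01)) + 1)
    dt = timebase.dt_ms
    if dt > 0.1 * m.tau_m_ms:
        raise ParameterError(
            f"dt = {dt} ms too large for stability (tau_m = {m.tau_m_ms:.3g} ms)"
        )
    gexc = np.asarray(gexc, dtype=float)
    ginh = np.asarray(ginh, dtype=float)
    n = timebase.n_samples
    if gexc.shape != (n,) or ginh.shape != (n,):
        raise ParameterError("conductance traces must match the timebase")
    rng = np.random.default_rng(seed)
    eps = (rng.normal(0.0, noise_sd_pA, n) if noise_sd_pA > 0
           else np.zeros(n))

    gm = m.G_m_nS
    v = np.empty(n)
    v[0] = m.E_rest_mV
    t = timebase.times()
    spike_idx: list[int] = []
    refr_until = -np.inf
    for i in range(1, n):
        if t[i] < refr_until:
            v[i] = m.V_reset_mV
            continue
        i_pA = (-gm * (v[i - 1] - m.E_rest_mV)
                - gexc[i - 1] * (v[i - 1] - reversals.E_exc_mV)
                - ginh[i - 1] * (v[i - 1] - reversals.E_inh_mV)
                + eps[i - 1])
        v[i] = v[i - 1] + dt * i_pA / m.C_pF
        if v[i] >= m.V_thresh_mV:
            spike_idx.append(i)
            v[i] = m.V_reset_mV
            refr_until = t[i] + m.refractory_ms
    rendered = v.copy()
    rendered[spike_idx] = spike_peak_mV
    train = SpikeTrain(t[spike_idx], np.full(len(spike_idx), spike_peak_mV))
    return (Sweep(timebase, rendered, None, condition, 0), train)


def make_duo(aip_g, la_g, true_alpha: float = 1.0,
             saturation: float | None = None):
    """Construct a simultaneous-stimulation trace (or pair of traces) as
    ``true_alpha * (aip + la)``, optionally passed through a soft-saturating
    nonlinearity ``s * tanh(x / s)`` for robustness fixtures.
    """
    def one(a, b):
        d = true_alpha * (np.asarray(a, float) + np.asarray(b, float))
        if saturation is not None:
            d = saturation * np.tanh(d / saturation)
        return d

    if isinstance(aip_g, (tuple, list)):
        return tuple(one(a, b) for a, b in zip(aip_g, la_g))
    return one(aip_g, la_g)


# ---------------------------------------------------------------------------
# diode array
# ---------------------------------------------------------------------------

def hexagonal_layout(n_diodes: int = 464, pitch_um: float = 150.0,
                     ) -> np.ndarray:
    """Coordinates of a hexagonally packed array, center outward."""
    pts = [(0.0, 0.0)]
    ring = 1
    while len(pts) < n_diodes:
        # walk the hexagonal ring at radius `ring`
        x, y = ring * pitch_um, 0.0
        directions = [(-0.5, np.sqrt(3) / 2), (-1.0, 0.0),
                      (-0.5, -np.sqrt(3) / 2), (0.5, -np.sqrt(3) / 2),
                      (1.0, 0.0), (0.5, np.sqrt(3) / 2)]
        for dx, dy in directions:
            for _ in range(ring):
                pts.append((x, y))
                x += dx * pitch_um
                y += dy * pitch_um
        ring += 1
    return np.asarray(pts[:n_diodes])


def simulate_vsd(
    n_diodes: int = 464,
    pitch_um: float = 150.0,
    center_um: tuple[float, float] = (0.0, 0.0),
    spread_um: float = 1500.0,
    amplitude_fraction: float = 0.0741,
    onset_ms: float = 10.0,
    rise_ms: float = 8.0,
    decay_ms: float = 60.0,
    noise: NoiseModel = NoiseModel(),
    n_repeats: int = 3,
    timebase: TimeBase = TimeBase(-100.0, 1.0, 400),
    seed: int | None = None,
) -> DiodeArrayRecording:
    """Synthetic diode-array recording of a spreading depolarization wave.

    The fractional signal on diode ``d`` is a spatial Gaussian around the
    wave center times a difference-of-exponentials time course, plus white
    noise of SD ``vsd_sd_fraction``; frames are returned un-normalized
    (ΔA = fraction * Amax) so the normalization step is exercised. Amax is
    drawn uniformly per diode (arbitrary positive light levels).

    The default spread (1.5 mm) makes the wave broad relative to the diode
    pitch, as the depolarization covering the deep-layer band is in the
    recordings this emulates; a 150 µm spatial filter then attenuates the
    ROI peak by only a few percent.
    """
    if amplitude_fraction < 0:
        raise ParameterError("amplitude_fraction must be >= 0")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    coords = hexagonal_layout(n_diodes, pitch_um)
    amax = rng.uniform(800.0, 1200.0, n_diodes)

    d2 = ((coords - np.asarray(center_um)) ** 2).sum(axis=1)
    spatial = np.exp(-d2 / (2.0 * spread_um**2))
    kernel = ConductanceKernel(onset_ms, 1.0, rise_ms, decay_ms, "exc")
    temporal = kernel_waveform(kernel, timebase)

    clean = amplitude_fraction * spatial[:, None] * temporal[None, :]
    frames = np.empty((n_repeats, n_diodes, timebase.n_samples))
    for r in range(n_repeats):
        eps = (rng.normal(0.0, noise.vsd_sd_fraction, clean.shape)
               if noise.vsd_sd_fraction > 0 else 0.0)
        frames[r] = (clean + eps) * amax[:, None]
    return DiodeArrayRecording(frames, amax, coords, timebase)


def population_scenario(
    n_cells: int = 18,
    alpha_mean: float = 0.77,
    alpha_sd: float = 0.1786,
    seed: int = 0,
    timebase: TimeBase = DEFAULT_TIMEBASE,
    peak_lognorm_sigma: float = 0.3,
    latency_jitter_sd_ms: float = 0.5,
):
    """Per-cell (AiP, LA, DUO) conductance-trace triplets with known alphas.

    Each cell's kernels are the pathway defaults with lognormal peak jitter
    and Gaussian latency jitter; the cell's true summation factor is drawn
    from N(alpha_mean, alpha_sd). Returns ``(cells, true_alphas)`` where each
    cell is a dict with keys 'AIP', 'LA', 'DUO' mapping to
    ``(gexc_trace, ginh_trace)`` pairs.
    """
    if n_cells < 2:
        raise ParameterError("need n_cells >= 2")
    rng = np.random.default_rng(seed)
    cells = []
    alphas = np.maximum(rng.normal(alpha_mean, alpha_sd, n_cells), 0.0)
    for c in range(n_cells):
        cell = {}
        per_path = {}
        for cond in (Condition.AIP, Condition.LA):
            exc, inh = default_kernels(cond)
            jittered = []
            for k in (exc, inh):
                peak = k.peak_nS * rng.lognormal(0.0, peak_lognorm_sigma)
                lat = max(k.latency_ms + rng.normal(0.0, latency_jitter_sd_ms),
                          0.5)
                kj = ConductanceKernel(lat, peak, k.tau_rise_ms,
                                       k.tau_decay_ms, k.kind)
                jittered.append(kernel_waveform(kj, timebase))
            per_path[cond.value] = tuple(jittered)
        cell["AIP"] = per_path["AIP"]
        cell["LA"] = per_path["LA"]
        cell["DUO"] = make_duo(cell["AIP"], cell["LA"],
                               true_alpha=float(alphas[c]))
        cells.append(cell)
    return cells, alphas
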