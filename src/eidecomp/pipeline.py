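"""End-to-end orchestration: simulate -> decompose -> summate -> detect ->
stats -> report.

The default scenario reproduces the structure of the study's main analyses
on synthetic data:

* a population of principal cells whose excitatory conductances summate
  sub-linearly (true scale factor ~0.77) and whose inhibitory conductances
  summate linearly (~0.94), each recorded as noisy voltage-clamp sweep sets
  at five holding potentials with three repeats;
* a population of fast-spiking interneurons driven by both pathways in a
  LIF current-clamp simulation, where the simultaneous stimulus shifts the
  first spike forward.

Every stage is a pure function of its inputs plus the seed, so a rerun with
the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core_io import (BaselineWindow, Condition, SweepSet, average_repeats,
                      crop, subtract_background)
from .decomposition import (ReversalPotentials, decompose,
                            fit_iv_per_timepoint)
from .detection import first_spike_latency, spike_density
from .errors import ParameterError
from .stats import one_sample_z_test
from .summation import (SummationConfig, classify_summation, fit_scale_factor,
                        population_scale_summary)
from .synthetic_data import (DEFAULT_TIMEBASE, PV_AIP_EXC, PV_LA_EXC,
                             ConductanceKernel, MembraneModel, NoiseModel,
                             default_kernels, kernel_waveform, make_duo,
                             simulate_current_clamp, simulate_voltage_clamp)


@dataclass
class PipelineConfig:
    """Everything the default synthetic run needs; YAML-serializable."""

    seed: int = 0
    # principal-neuron population
    n_cells: int = 18
    alpha_exc_mean: float = 0.77
    alpha_exc_sd: float = 0.1786
    alpha_inh_mean: float = 0.94
    alpha_inh_sd: float = 0.2785
    current_noise_sd_pA: float = 10.0
    holding_potentials_mV: tuple = (-90.0, -80.0, -70.0, -60.0, -50.0)
    n_repeats: int = 3
    e_exc_mV: float = 0.0
    e_inh_mV: float = -70.0
    # summation fit
    tau_ms: float = 20.0
    fit_window_ms: tuple = (0.0, 100.0)
    # PV / spike-latency scenario
    n_pv_cells: int = 19
    pv_noise_sd_pA: float = 20.0
    # stage toggles
    run_conductance_stage: bool = True
    run_spike_stage: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _derive_seed(seed: int, *tags: int) -> int:
    """Stable child seed below 2**31 from a master seed and stage tags."""
    h = hashlib.sha256(np.array([seed, *tags], dtype=np.int64).tobytes())
    return int.from_bytes(h.digest()[:4], "little") % (2**31)


def _analyze_sweepset(ss: SweepSet, reversals: ReversalPotentials):
    """Standard whole-cell chain: background -> average -> per-timepoint
    I/V fit -> conductances, restricted to the post-stimulus window."""
    subtracted = SweepSet(
        [subtract_background(s, BaselineWindow()) for s in ss.sweeps],
        ss.condition, dict(ss.metadata),
    )
    averaged = average_repeats(subtracted)
    windowed = crop(averaged, 0.0, 100.0)
    return decompose(fit_iv_per_timepoint(windowed), reversals)


def run_conductance_stage(config: PipelineConfig,
                          reversals: ReversalPotentials) -> dict:
    """Simulate and analyze the principal-neuron population."""
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    true_a_exc = np.maximum(
        rng.normal(config.alpha_exc_mean, config.alpha_exc_sd, config.n_cells),
        0.0)
    true_a_inh = np.maximum(
        rng.normal(config.alpha_inh_mean, config.alpha_inh_sd, config.n_cells),
        0.0)

    tb = DEFAULT_TIMEBASE
    cfg = SummationConfig(tau_ms=config.tau_ms,
                          fit_window_ms=tuple(config.fit_window_ms))
    membrane = MembraneModel()
    cells = []
    for c in range(config.n_cells):
        truth = {}
        for cond in (Condition.AIP, Condition.LA):
            exc, inh = default_kernels(cond)
            truth[cond.value] = (kernel_waveform(exc, tb),
                                 kernel_waveform(inh, tb))
        truth["DUO"] = (
            make_duo(truth["AIP"][0], truth["LA"][0], float(true_a_exc[c])),
            make_duo(truth["AIP"][1], truth["LA"][1], float(true_a_inh[c])),
        )
        recovered = {}
        for j, cond in enumerate((Condition.AIP, Condition.LA, Condition.DUO)):
            gexc, ginh = truth[cond.value]
            ss = simulate_voltage_clamp(
                gexc, ginh, tb, membrane, config.holding_potentials_mV,
                reversals,
                NoiseModel(current_sd_pA=config.current_noise_sd_pA,
                           seed=_derive_seed(config.seed, 1, c, j)),
                n_repeats=config.n_repeats, condition=cond)
            recovered[cond.value] = _analyze_sweepset(ss, reversals)

        tb_fit = recovered["AIP"].timebase
        fit_exc = fit_scale_factor(recovered["DUO"].G_exc_nS,
                                   recovered["AIP"].G_exc_nS,
                                   recovered["LA"].G_exc_nS, tb_fit, cfg)
        fit_inh = fit_scale_factor(recovered["DUO"].G_inh_nS,
                                   recovered["AIP"].G_inh_nS,
                                   recovered["LA"].G_inh_nS, tb_fit, cfg)
        cells.append({"conductances": recovered,
                      "alpha_exc": fit_exc, "alpha_inh": fit_inh})

    summary = {}
    for name, fits, true_vals in (
        ("G_exc", [c["alpha_exc"] for c in cells], true_a_exc),
        ("G_inh", [c["alpha_inh"] for c in cells], true_a_inh),
    ):
        alphas = [f.alpha for f in fits]
        mean, sem, sd, skew = population_scale_summary(alphas)
        z = one_sample_z_test(mean, sd, len(alphas), mu0=1.0)
        summary[name] = {
            "alphas": alphas,
            "true_alphas": list(map(float, true_vals)),
            "mean": mean, "sem": sem, "sd": sd, "skewness": skew,
            "z": z.statistic, "p": z.p_value,
            "classification": str(classify_summation(mean)),
            "population_linear": z.p_value >= 0.05,
        }
    return {"cells": cells, "summary": summary}


def run_spike_stage(config: PipelineConfig,
                    reversals: ReversalPotentials) -> dict:
    """LIF spike-latency scenario: simultaneous input shifts the first
    spike of fast-spiking interneurons forward."""
    from .core_io import TimeBase

    tb = TimeBase(t0_ms=-10.0, dt_ms=0.01, n_samples=11001)
    membrane = MembraneModel.pv_interneuron()
    rng = np.random.default_rng(_derive_seed(config.seed, 2))
    rows = []
    for c in range(config.n_pv_cells):
        lat_aip = max(PV_AIP_EXC["latency_ms"] + rng.normal(0, 0.5), 1.0)
        lat_la = max(PV_LA_EXC["latency_ms"] + rng.normal(0, 0.5), 1.0)
        peak_aip = PV_AIP_EXC["peak_nS"] * rng.lognormal(0, 0.2)
        peak_la = PV_LA_EXC["peak_nS"] * rng.lognormal(0, 0.2)
        g_aip = kernel_waveform(ConductanceKernel(lat_aip, peak_aip), tb)
        g_la = kernel_waveform(ConductanceKernel(lat_la, peak_la), tb)
        g_duo = make_duo(g_aip, g_la, true_alpha=1.0)
        zeros = np.zeros(tb.n_samples)
        lat = {}
        trains = {}
        for name, g in (("AIP", g_aip), ("LA", g_la), ("DUO", g_duo)):
            _, train = simulate_current_clamp(
                g, zeros, tb, membrane, reversals,
                noise_sd_pA=config.pv_noise_sd_pA,
                seed=_derive_seed(config.seed, 2, c))
            lat[name] = first_spike_latency(train)
            trains[name] = train
        rows.append({"latency": lat, "trains": trains})

    out = {"cells": rows}
    for name in ("AIP", "LA", "DUO"):
        lats = [r["latency"][name] for r in rows
                if r["latency"][name] is not None]
        counts, edges = spike_density([r["trains"][name] for r in rows],
                                      bin_ms=1.0, window_ms=(0.0, 50.0))
        out[name] = {
            "n_spiking": len(lats),
            "first_spike_mean_ms": float(np.mean(lats)) if lats else None,
            "first_spike_sem_ms": (float(np.std(lats, ddof=1)
                                         / np.sqrt(len(lats)))
                                   if len(lats) > 1 else None),
            "density_counts": counts.tolist(),
            "density_edges": edges.tolist(),
        }
    paired = [
        (r["latency"]["DUO"], r["latency"]["AIP"]) for r in rows
        if r["latency"]["DUO"] is not None and r["latency"]["AIP"] is not None
    ]
    out["duo_forward_shift"] = bool(
        paired and all(d <= a for d, a in paired)
    )
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 ) -> dict:
    """Run the configured stages and return (optionally write) the bundle.

    The bundle carries per-cell conductance traces, per-cell summation
    results, spike detections, population summaries with Z tests against 1,
    and a manifest with version, seed and config hash. Identical
    config + seed produce an identical bundle.
    """
    reversals = ReversalPotentials(config.e_exc_mV, config.e_inh_mV)  # validates
    if config.n_cells < 2:
        raise ParameterError("n_cells must be >= 2")

    bundle: dict = {
        "manifest": {
            "package_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.digest(),
        }
    }
    if config.run_conductance_stage:
        bundle["conductance"] = run_conductance_stage(config, reversals)
    if config.run_spike_stage:
        bundle["spikes"] = run_spike_stage(config, reversals)
    bundle["report"] = make_report(bundle)

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _scalar_bundle(bundle: dict) -> dict:
    """JSON-serializable view of the bundle (traces dropped)."""
    out = {"manifest": bundle["manifest"]}
    if "conductance" in bundle:
        out["summation"] = bundle["conductance"]["summary"]
    if "spikes" in bundle:
        out["spikes"] = {
            k: v for k, v in bundle["spikes"].items() if k != "cells"
        }
    return out


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    import h5py

    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "results.json", "w") as f:
        json.dump(_scalar_bundle(bundle), f, indent=2, sort_keys=True)
    with open(out_dir / "report.md", "w") as f:
        f.write(bundle["report"])
    if "conductance" in bundle:
        with h5py.File(out_dir / "conductances.h5", "w") as f:
            for i, cell in enumerate(bundle["conductance"]["cells"]):
                for cond, ct in cell["conductances"].items():
                    g = f.create_group(f"cell{i:03d}/{cond}")
                    g.create_dataset("Gexc", data=ct.G_exc_nS)
                    g.create_dataset("Ginh", data=ct.G_inh_nS)
                    g.attrs["dt_ms"] = ct.timebase.dt_ms
                    g.attrs["t0_ms"] = ct.timebase.t0_ms


def _alpha_histogram(alphas, bin_width: float = 0.1):
    """Scale-factor histogram in 0.1 bins (the reporting convention)."""
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0:
        return np.zeros(0, dtype=int), np.zeros(1)
    lo = np.floor(alphas.min() / bin_width) * bin_width
    hi = np.ceil(alphas.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(alphas, bins=edges)
    return counts, edges


def make_report(bundle: dict) -> str:
    """Human-readable markdown summary of a bundle (mean +/- SEM tables,
    0.1-bin scale-factor histograms, Z-test lines)."""
    lines = ["# Synthetic pipeline report", ""]
    man = bundle.get("manifest", {})
    lines.append(f"seed: {man.get('seed')}  |  config hash: "
                 f"{man.get('config_hash')}  |  version: "
                 f"{man.get('package_version')}")
    lines.append("")

    cond = bundle.get("conductance")
    lines.append("## Summation of synaptic conductances")
    if not cond or not cond["summary"]["G_exc"]["alphas"]:
        lines.append("no cells")
    else:
        for name, s in cond["summary"].items():
            lines.append(f"### {name}")
            lines.append(
                f"scale factor: {s['mean']:.2f} +/- {s['sem']:.2f} "
                f"(SD = {s['sd']:.4f}, n = {len(s['alphas'])}); "
                f"skewness = {s['skewness']:.4f}"
            )
            p_txt = "p < 0.0001" if s["p"] < 1e-4 else f"p = {s['p']:.4f}"
            verdict = ("n.s. (linear summation)" if s["p"] >= 0.05
                       else s["classification"])
            lines.append(f"Z test vs 1: z = {s['z']:.3f}, {p_txt} -> {verdict}")
            counts, edges = _alpha_histogram(s["alphas"])
            hist = ", ".join(
                f"[{edges[i]:.1f},{edges[i+1]:.1f}): {counts[i]}"
                for i in range(len(counts))
            )
            lines.append(f"histogram (0.1 bins): {hist}")
            lines.append("")

    spk = bundle.get("spikes")
    lines.append("## Interneuron spike latency")
    if not spk:
        lines.append("no cells")
    else:
        for name in ("AIP", "LA", "DUO"):
            s = spk[name]
            if s["first_spike_mean_ms"] is None:
                lines.append(f"{name}: no spikes")
            else:
                sem = s["first_spike_sem_ms"]
                lines.append(
                    f"{name}: first spike {s['first_spike_mean_ms']:.1f}"
                    + (f" +/- {sem:.1f}" if sem is not None else "")
                    + f" ms (n = {s['n_spiking']} spiking cells)"
                )
        lines.append(
            "simultaneous-stimulation forward shift in every cell: "
            + ("yes" if spk.get("duo_forward_shift") else "no")
        )
    lines.append("")
    return "\n".join(lines)
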