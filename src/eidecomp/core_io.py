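"""Data model and I/O for whole-cell recordings.

Conventions used throughout the package:

* the stimulus defines ``t = 0``; all stored data are stimulus-aligned,
* units are fixed to mV / pA / nS / ms, so that ``nS * mV = pA`` exactly,
* stored voltages are assumed already corrected for the junction potential
  (a metadata boolean records this; no arithmetic is applied here).

On-disk formats:

* HDF5 — ``/sweeps/{condition}/{V_mV}/{repeat}`` 1-D float64 datasets with
  root attributes ``dt_ms``, ``t0_ms``, ``units_current``, ``units_voltage``
  and ``junction_corrected``,
* CSV — first column ``time_ms``, remaining columns named
  ``{condition}_{V_mV}mV_r{repeat}``; header mandatory, UTF-8, '.' decimal.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .errors import InsufficientDataError, RangeError, SchemaError, ShapeError


class Condition(str, enum.Enum):
    """Stimulus condition of a sweep."""

    AIP = "AIP"      # neocortical (agranular insular cortex) stimulation
    LA = "LA"        # lateral amygdala stimulation
    DUO = "DUO"      # simultaneous AiP + LA stimulation
    STEP = "STEP"    # voltage step for passive-membrane measurement
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TimeBase:
    """Uniform sampling grid, stimulus-aligned (stimulus at t = 0).

    Parameters
    ----------
    t0_ms : float
        Time of the first sample relative to the stimulus.
    dt_ms : float
        Sample interval in ms (0.1 ms is the analysis grid; raw acquisition
        at 100 kHz corresponds to ``dt_ms=0.01``).
    n_samples : int
        Number of samples (>= 2).
    """

    t0_ms: float
    dt_ms: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ShapeError("dt_ms must be positive")
        if self.n_samples < 2:
            raise ShapeError("a timebase needs at least 2 samples")

    def times(self) -> np.ndarray:
        """Sample times in ms: ``t0_ms + k * dt_ms``."""
        return self.t0_ms + self.dt_ms * np.arange(self.n_samples)

    @property
    def end_ms(self) -> float:
        return self.t0_ms + self.dt_ms * (self.n_samples - 1)

    def index_of(self, t_ms: float) -> int:
        """Nearest sample index for a time (no bounds check)."""
        return int(round((t_ms - self.t0_ms) / self.dt_ms))

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        """Slice of samples with ``start_ms <= t <= end_ms``.

        Raises
        ------
        RangeError
            If the window does not overlap the recorded span or is empty.
        """
        if start_ms > end_ms:
            raise RangeError(f"empty window [{start_ms}, {end_ms}]")
        eps = 1e-9 * self.dt_ms
        if end_ms < self.t0_ms - eps or start_ms > self.end_ms + eps:
            raise RangeError(
                f"window [{start_ms}, {end_ms}] ms outside recorded span "
                f"[{self.t0_ms}, {self.end_ms}] ms"
            )
        lo = int(np.ceil((start_ms - self.t0_ms) / self.dt_ms - 1e-9))
        hi = int(np.floor((end_ms - self.t0_ms) / self.dt_ms + 1e-9))
        lo = max(lo, 0)
        hi = min(hi, self.n_samples - 1)
        if hi < lo:
            raise RangeError(
                f"window [{start_ms}, {end_ms}] ms contains no samples"
            )
        return slice(lo, hi + 1)


@dataclass(frozen=True)
class BaselineWindow:
    """Pre-stimulus window used for background/offset estimation.

    Both bounds are relative to the stimulus and must satisfy
    ``start_ms < end_ms <= 0``. The default [-100, 0] ms mirrors the
    100 ms pre-stimulus offset window of the optical recordings.
    """

    start_ms: float = -100.0
    end_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start_ms < self.end_ms <= 0):
            raise RangeError(
                "baseline window must satisfy start_ms < end_ms <= 0, got "
                f"[{self.start_ms}, {self.end_ms}]"
            )


@dataclass
class Sweep:
    """One recorded trace.

    ``values`` are pA in voltage clamp, mV in current clamp, dimensionless
    for optical signals. ``holding_potential_mV`` is None for current-clamp
    sweeps.
    """

    timebase: TimeBase
    values: np.ndarray
    holding_potential_mV: float | None = None
    condition: Condition = Condition.OTHER
    repeat_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.timebase.n_samples:
            raise ShapeError(
                f"sweep has {self.values.size} samples, timebase expects "
                f"{self.timebase.n_samples}"
            )
        if self.holding_potential_mV is not None and not np.isfinite(
            self.holding_potential_mV
        ):
            raise ShapeError("holding potential must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.timebase.times()


@dataclass
class SweepSet:
    """Sweeps sharing one timebase and condition, across holding potentials
    and repeats. At least 2 distinct holding potentials are required for
    conductance decomposition."""

    sweeps: list[Sweep]
    condition: Condition
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise InsufficientDataError("SweepSet needs at least one sweep")
        tb = self.sweeps[0].timebase
        for s in self.sweeps:
            if s.timebase != tb:
                raise ShapeError("all sweeps in a SweepSet must share a timebase")
            if s.condition != self.condition:
                raise ShapeError("all sweeps must share the set's condition")

    @property
    def timebase(self) -> TimeBase:
        return self.sweeps[0].timebase

    @property
    def holding_potentials_mV(self) -> list[float]:
        vs = {s.holding_potential_mV for s in self.sweeps
              if s.holding_potential_mV is not None}
        return sorted(vs)

    @property
    def n_repeats(self) -> int:
        return len({s.repeat_index for s in self.sweeps})

    def at_potential(self, v_mV: float) -> list[Sweep]:
        return [s for s in self.sweeps
                if s.holding_potential_mV is not None
                and np.isclose(s.holding_potential_mV, v_mV)]


# ---------------------------------------------------------------------------
# baseline handling and repeat averaging
# ---------------------------------------------------------------------------

def subtract_background(sweep: Sweep, window: BaselineWindow | None = None) -> Sweep:
    """Remove the stimulus-independent background (mean over a pre-stimulus
    window) from a sweep.

    The mean of the result over the window is 0 to numerical precision. This
    is a linear operation: ``f(a + b) = f(a) + f(b)`` for a shared window.
    """
    window = window or BaselineWindow()
    sl = sweep.timebase.window_slice(window.start_ms, window.end_ms)
    baseline = float(np.mean(sweep.values[sl]))
    return replace(sweep, values=sweep.values - baseline)


def average_repeats(sweepset: SweepSet) -> SweepSet:
    """Pointwise mean across repeats, one output sweep per holding potential.

    The original repeat count is recorded in ``metadata['n_repeats']``.
    Current-clamp sweeps (holding potential None) are averaged as one group.
    """
    groups: dict[float | None, list[Sweep]] = {}
    for s in sweepset.sweeps:
        groups.setdefault(s.holding_potential_mV, []).append(s)

    out: list[Sweep] = []
    n_reps: set[int] = set()
    for v, sweeps in sorted(
        groups.items(), key=lambda kv: (kv[0] is None, kv[0] or 0.0)
    ):
        stack = np.stack([s.values for s in sweeps])
        n_reps.add(len(sweeps))
        out.append(
            Sweep(
                timebase=sweepset.timebase,
                values=stack.mean(axis=0),
                holding_potential_mV=v,
                condition=sweepset.condition,
                repeat_index=0,
            )
        )
    meta = dict(sweepset.metadata)
    meta["n_repeats"] = max(n_reps)
    return SweepSet(sweeps=out, condition=sweepset.condition, metadata=meta)


def decimate(sweepset: SweepSet, target_dt_ms: float = 0.1) -> SweepSet:
    """Boxcar-mean decimation of raw sweeps onto the analysis grid.

    Raw acquisition may be at 0.01 ms; analysis runs at 0.1 ms. The factor
    must be an integer; trailing samples that do not fill a full boxcar are
    dropped. A no-op when the set is already on the target grid.
    """
    tb = sweepset.timebase
    factor = target_dt_ms / tb.dt_ms
    if abs(factor - round(factor)) > 1e-9:
        raise ShapeError(
            f"target dt {target_dt_ms} is not an integer multiple of {tb.dt_ms}"
        )
    factor = int(round(factor))
    if factor == 1:
        return sweepset
    n_out = tb.n_samples // factor
    new_tb = TimeBase(
        t0_ms=tb.t0_ms + (factor - 1) * tb.dt_ms / 2.0,
        dt_ms=target_dt_ms,
        n_samples=n_out,
    )
    out = [
        Sweep(
            timebase=new_tb,
            values=s.values[: n_out * factor].reshape(n_out, factor).mean(axis=1),
            holding_potential_mV=s.holding_potential_mV,
            condition=s.condition,
            repeat_index=s.repeat_index,
        )
        for s in sweepset.sweeps
    ]
    return SweepSet(out, sweepset.condition, dict(sweepset.metadata))


def crop(sweepset: SweepSet, start_ms: float, end_ms: float) -> SweepSet:
    """Restrict all sweeps to samples with ``start_ms <= t <= end_ms``."""
    sl = sweepset.timebase.window_slice(start_ms, end_ms)
    n = sl.stop - sl.start
    if n < 2:
        raise RangeError("cropped window contains fewer than 2 samples")
    new_tb = TimeBase(
        t0_ms=sweepset.timebase.t0_ms + sl.start * sweepset.timebase.dt_ms,
        dt_ms=sweepset.timebase.dt_ms,
        n_samples=n,
    )
    out = [
        Sweep(new_tb, s.values[sl], s.holding_potential_mV, s.condition,
              s.repeat_index)
        for s in sweepset.sweeps
    ]
    return SweepSet(out, sweepset.condition, dict(sweepset.metadata))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_REQUIRED_ATTRS = ("dt_ms", "t0_ms")
_COLUMN_RE = re.compile(r"^(?P<cond>[A-Z]+)_(?P<v>-?\d+(?:\.\d+)?)mV_r(?P<rep>\d+)$")


def save_sweepset(sweepset: SweepSet, path: str, format: str = "hdf5") -> None:
    """Write a SweepSet to disk (``hdf5`` or ``csv``)."""
    tb = sweepset.timebase
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["dt_ms"] = tb.dt_ms
            f.attrs["t0_ms"] = tb.t0_ms
            f.attrs["units_current"] = "pA"
            f.attrs["units_voltage"] = "mV"
            f.attrs["junction_corrected"] = bool(
                sweepset.metadata.get("junction_corrected", True)
            )
            grp = f.create_group(f"sweeps/{sweepset.condition.value}")
            for s in sweepset.sweeps:
                v = s.holding_potential_mV
                vkey = "cc" if v is None else f"{v:g}"
                grp.require_group(vkey).create_dataset(
                    str(s.repeat_index), data=s.values, dtype="float64"
                )
    elif format == "csv":
        cols = {"time_ms": tb.times()}
        for s in sweepset.sweeps:
            v = s.holding_potential_mV
            vtxt = "cc" if v is None else f"{v:g}"
            cols[f"{s.condition.value}_{vtxt}mV_r{s.repeat_index}"] = s.values
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    else:
        raise SchemaError(f"unknown format {format!r}")


def load_sweepset(path: str, format: str = "hdf5",
                  condition: Condition | str | None = None) -> SweepSet:
    """Load a SweepSet written by :func:`save_sweepset`.

    Raises
    ------
    SchemaError
        Missing metadata keys or malformed column names.
    ShapeError
        Mismatched trace lengths.
    """
    if format == "hdf5":
        return _load_hdf5(path, condition)
    if format == "csv":
        return _load_csv(path, condition)
    raise SchemaError(f"unknown format {format!r}")


def _load_hdf5(path: str, condition) -> SweepSet:
    with h5py.File(path, "r") as f:
        for key in _REQUIRED_ATTRS:
            if key not in f.attrs:
                raise SchemaError(f"missing required root attribute {key!r}")
        if "sweeps" not in f:
            raise SchemaError("missing /sweeps group")
        conds = list(f["sweeps"].keys())
        cname = (str(Condition(condition).value) if condition is not None
                 else conds[0])
        if cname not in f["sweeps"]:
            raise SchemaError(f"condition {cname!r} not in file ({conds})")
        cgrp = f["sweeps"][cname]
        sweeps: list[Sweep] = []
        lengths: set[int] = set()
        raw = []
        for vkey in cgrp:
            v = None if vkey == "cc" else float(vkey)
            for rep in cgrp[vkey]:
                data = np.asarray(cgrp[vkey][rep], dtype=float)
                lengths.add(data.size)
                raw.append((v, int(rep), data))
        if len(lengths) != 1:
            raise ShapeError(f"mismatched trace lengths: {sorted(lengths)}")
        tb = TimeBase(float(f.attrs["t0_ms"]), float(f.attrs["dt_ms"]),
                      lengths.pop())
        cond = Condition(cname)
        for v, rep, data in raw:
            sweeps.append(Sweep(tb, data, v, cond, rep))
        meta = {"junction_corrected": bool(f.attrs.get("junction_corrected",
                                                       True))}
    return SweepSet(sweeps, cond, meta)


def _load_csv(path: str, condition) -> SweepSet:
    df = pd.read_csv(path)
    if "time_ms" not in df.columns:
        raise SchemaError("CSV must have a 'time_ms' first column")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ShapeError("need at least 2 samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise SchemaError("time_ms column is not uniformly sampled")
    tb = TimeBase(float(t[0]), float(dts.mean()), len(t))
    sweeps: list[Sweep] = []
    conds: set[Condition] = set()
    for col in df.columns:
        if col == "time_ms":
            continue
        m = _COLUMN_RE.match(col)
        if m is None:
            raise SchemaError(f"column {col!r} does not match "
                              "'{{condition}}_{{V_mV}}mV_r{{repeat}}'")
        cond = Condition(m.group("cond"))
        if condition is not None and cond != Condition(condition):
            continue
        conds.add(cond)
        sweeps.append(Sweep(tb, df[col].to_numpy(dtype=float),
                            float(m.group("v")), cond, int(m.group("rep"))))
    if len(conds) != 1:
        raise SchemaError(f"expected exactly one condition, found {conds}")
    return SweepSet(sweeps, conds.pop(), {"junction_corrected": True})
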