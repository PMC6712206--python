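"""Statistical procedures used by the pipeline: one-sample Z test against a
reference mean, Student's t tests, Pearson skewness, and a pointwise
(per-timepoint) paired comparison of trace populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError, ShapeError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    test_name: str
    two_sided: bool = True
    degenerate: bool = False


def one_sample_z_test(mean: float, sd: float, n: int, mu0: float = 1.0,
                      ) -> TestResult:
    """Z test of a sample mean against ``mu0`` using the sample SD.

    ``z = (mean - mu0) / (sd / sqrt(n))``, two-sided p from the standard
    normal. This is the test applied to per-cell scale factors against 1
    (linear summation).
    """
    if sd <= 0:
        raise ParameterError("sd must be positive")
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    z = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(p), int(n), "one-sample Z")


def t_tests(x, y, paired: bool = False) -> TestResult:
    """Student's t test, paired or two-sample (classic pooled-variance).

    Degenerate paired cases: all differences zero gives t=0, p=1; constant
    nonzero differences give p=0 with the ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ShapeError("paired test needs equal-length samples")
        if x.size < 2:
            raise InsufficientDataError("need n >= 2")
        d = x - y
        if np.std(d, ddof=1) == 0:
            if np.allclose(d, 0):
                return TestResult(0.0, 1.0, x.size, "paired t",
                                  degenerate=True)
            return TestResult(np.inf if d.mean() > 0 else -np.inf, 0.0,
                              x.size, "paired t", degenerate=True)
        t, p = sps.ttest_rel(x, y)
        return TestResult(float(t), float(p), x.size, "paired t")
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need n >= 2 in both samples")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(t), float(p), x.size + y.size, "two-sample t")


def pearson_skewness(x, variant: str = "moment") -> float:
    """Skewness of a sample.

    variant="moment"
        Fisher-Pearson moment coefficient ``g1 = m3 / m2^{3/2}`` with
        population moments (biased form) — the default.
    variant="median"
        Pearson's second skewness coefficient ``3 (mean - median) / sd``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need n >= 3")
    xc = x - x.mean()
    m2 = float(np.mean(xc**2))
    if m2 == 0:
        raise ParameterError("zero variance: skewness undefined")
    if variant == "moment":
        return float(np.mean(xc**3) / m2**1.5)
    if variant == "median":
        sd = float(np.std(x, ddof=1))
        return float(3.0 * (x.mean() - np.median(x)) / sd)
    raise ParameterError(f"unknown skewness variant {variant!r}")


def pointwise_comparison(traces_a, traces_b, alpha: float = 0.05,
                         ) -> np.ndarray:
    """Per-timepoint paired t test between two trace populations.

    ``traces_a`` and ``traces_b`` are (n_cells, n_t) arrays with matched
    rows (same cells). Returns a boolean mask over time where the paired
    difference is significant at ``alpha`` (uncorrected, as in the figure
    captions this reproduces).
    """
    a = np.asarray(traces_a, dtype=float)
    b = np.asarray(traces_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ShapeError("trace sets must be matched (n_cells, n_t) arrays")
    if a.shape[0] < 2:
        raise InsufficientDataError("need >= 2 cells per set")
    d = a - b
    # vectorized paired t along cells; zero-variance timepoints:
    # all-zero differences -> not significant, constant nonzero -> significant
    n = d.shape[0]
    dm = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = dm / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    p = np.where(zero_var & (dm != 0), 0.0, p)
    p = np.where(zero_var & (dm == 0), 1.0, p)
    return p < alpha
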