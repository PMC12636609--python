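"""Turbidity-trace processing for LLPS inhibition, reversal and
disaggregation assays, plus sedimentation fractions.

Traces are absorbance at 395 nm sampled in 1-minute cycles. Inhibition
assays are buffer-subtracted and normalized to the maximum of the 0 uM RNA
control; reversal assays are normalized to each trace's own pre-RNA
absorbance. The summary statistic is the trapezoidal area under the curve
(AUC), optionally normalized to the matched zero-RNA control AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TurbidityTrace", "AUCResult", "preprocess_inhibition",
           "preprocess_reversal", "auc", "sedimentation_fractions"]


@dataclass(frozen=True)
class TurbidityTrace:
    """A single turbidity time course (minutes vs A395) with metadata."""

    time: np.ndarray
    a395: np.ndarray
    rna_name: str = ""
    rna_concentration: float = 0.0
    buffer: str = ""
    rna_add_time: float | None = None
    role: str = "sample"   # sample | buffer_blank | zero_rna_control

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.a395, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("time and a395 must be 1-D arrays of equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("time must be nondecreasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("a395 must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "a395", a)

    def with_values(self, a395: np.ndarray) -> "TurbidityTrace":
        return TurbidityTrace(self.time, a395, self.rna_name,
                              self.rna_concentration, self.buffer,
                              self.rna_add_time, self.role)


@dataclass(frozen=True)
class AUCResult:
    raw_auc: float
    window: tuple[float, float]
    normalized_auc: float | None = None


def preprocess_inhibition(traces: Sequence[TurbidityTrace],
                          buffer_traces: Sequence[TurbidityTrace]
                          ) -> list[TurbidityTrace]:
    """Buffer-subtract and control-normalize a trial of inhibition traces.

    The pointwise mean of the buffer blanks is subtracted from every trace,
    then all traces are divided by the maximum absorbance of the trial's
    zero-RNA control (which therefore peaks at exactly 1.0).
    """
    if not buffer_traces:
        raise ValueError("at least one buffer trace is required")
    controls = [t for t in traces if t.role == "zero_rna_control"]
    if len(controls) != 1:
        raise ValueError("exactly one zero-RNA control per trial is required")
    grid = traces[0].time
    for t in list(traces) + list(buffer_traces):
        if t.time.shape != grid.shape or not np.allclose(t.time, grid):
            raise ValueError("all traces must share one time grid")
    buffer_mean = np.mean([t.a395 for t in buffer_traces], axis=0)
    control_max = float((controls[0].a395 - buffer_mean).max())
    if control_max <= 0:
        raise ValueError("zero-RNA control has non-positive maximum")
    return [t.with_values((t.a395 - buffer_mean) / control_max) for t in traces]


def preprocess_reversal(trace: TurbidityTrace,
                        rna_add_time: float | None = None,
                        k_pre: int = 5) -> TurbidityTrace:
    """Normalize a reversal trace to its own pre-RNA absorbance.

    The anchor is the mean of the last ``k_pre`` points before RNA addition,
    making the trace ~1.0 at the moment RNA is added; the normalized trace is
    invariant to overall scaling.
    """
    t_add = rna_add_time if rna_add_time is not None else trace.rna_add_time
    if t_add is None:
        raise ValueError("rna_add_time is required")
    pre = trace.a395[trace.time < t_add]
    if len(pre) < k_pre:
        raise ValueError(
            f"need at least {k_pre} points before RNA addition"
        )
    anchor = float(pre[-k_pre:].mean())
    if anchor <= 0:
        raise ValueError("pre-RNA mean absorbance is non-positive")
    return trace.with_values(trace.a395 / anchor)


def auc(trace: TurbidityTrace, t0: float, t1: float,
        control_auc: float | None = None) -> AUCResult:
    """Trapezoidal area under the trace over [t0, t1] (absorbance*min).

    Window endpoints falling between samples are handled by linear
    interpolation. When a matched zero-RNA control AUC is supplied the
    normalized AUC (raw/control) is reported alongside.
    """
    t, a = trace.time, trace.a395
    if not (t0 < t1):
        raise ValueError("require t0 < t1")
    if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
        raise ValueError("integration window outside trace span")
    inside = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inside], [t1]))
    aa = np.concatenate(([np.interp(t0, t, a)], a[inside],
                         [np.interp(t1, t, a)]))
    raw = float(np.trapezoid(aa, tt))
    norm = raw / control_auc if control_auc is not None else None
    return AUCResult(raw, (t0, t1), norm)


def sedimentation_fractions(pellet_intensity: float,
                            supernatant_intensity: float
                            ) -> tuple[float, float]:
    """Relative abundance of protein in pellet vs supernatant.

    Returns (fraction_pellet, fraction_supernatant); they sum to 1 exactly.
    """
    if pellet_intensity < 0 or supernatant_intensity < 0:
        raise ValueError("intensities must be non-negative")
    total = pellet_intensity + supernatant_intensity
    if total == 0:
        raise ValueError("both fractions are zero")
    return pellet_intensity / total, supernatant_intensity / total
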