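"""Reduce kinetic Ellman traces to percent inhibition of AChE.

The assay records four pre-enzyme absorbance reads (0/3/6/9 min) that track
spontaneous, non-enzymatic signal, then a single read after enzyme addition.
The enzymatic signal of a well is its post-enzyme increment over the
drift-extrapolated baseline; percent inhibition ratios that increment to the
mean negative-control increment on the same plate:

    inhibition = 100 * (1 - signal_sample / signal_control)

Values outside [0, 100] are kept and flagged, never clipped — clipping is a
presentation choice and would bias downstream curve fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import KineticPlate, KineticRecord

__all__ = [
    "DriftFit",
    "spontaneous_drift",
    "enzymatic_signal",
    "percent_inhibition",
    "reduce_plate",
    "aggregate_inhibition",
    "DRIFT_NONLINEAR",
    "NEGATIVE_RATE",
]

DRIFT_NONLINEAR = "drift_nonlinear"
NEGATIVE_RATE = "negative_rate"


@dataclass(frozen=True)
class DriftFit:
    """Least-squares linear fit to the pre-enzyme reads."""

    slope: float  # AU / min
    intercept: float  # AU at t=0
    max_residual: float  # linearity diagnostic, AU


def spontaneous_drift(record: KineticRecord, nonlinear_threshold: float = 0.02) -> DriftFit:
    """Fit the spontaneous (pre-enzyme) drift of a well.

    Returns the least-squares slope of absorbance vs time over the pre-enzyme
    reads together with the maximum absolute residual as a linearity
    diagnostic.  Callers flag the well ``drift_nonlinear`` when the residual
    exceeds ``nonlinear_threshold`` (AU).
    """
    if len(record.pre_reads) < 2:
        raise ValueError(f"well {record.well}: need >= 2 pre-enzyme reads to fit drift")
    t = np.array([p[0] for p in record.pre_reads])
    a = np.array([p[1] for p in record.pre_reads])
    slope, intercept = np.polyfit(t, a, 1)
    resid = a - (slope * t + intercept)
    return DriftFit(float(slope), float(intercept), float(np.max(np.abs(resid))))


def enzymatic_signal(record: KineticRecord, drift: DriftFit) -> float:
    """Drift-corrected post-enzyme absorbance increment of a well.

    ``post - (last_pre + slope * (t_post - t_last_pre))``: the part of the
    final read not explained by extrapolating the spontaneous drift forward
    from the last pre-enzyme read.
    """
    t_last, a_last = record.pre_reads[-1]
    t_post, a_post = record.post_read
    return a_post - (a_last + drift.slope * (t_post - t_last))


def percent_inhibition(sample_signal: float, control_signal: float) -> float:
    """Percent inhibition of a well relative to the negative-control signal."""
    if not control_signal > 0:
        raise ValueError(
            f"control signal must be > 0 (got {control_signal}); "
            "plate-level failure, inhibition undefined"
        )
    return 100.0 * (1.0 - sample_signal / control_signal)


def reduce_plate(
    plate: KineticPlate,
    nonlinear_threshold: float = 0.02,
) -> pd.DataFrame:
    """Reduce a parsed kinetic plate to per-well percent inhibition.

    The control signal is the mean enzymatic increment over all
    negative-control wells of the plate (no per-column controls are modelled).
    Returns a tidy frame ``well, sample, role, dose, replicate, signal,
    inhibition, qc_flags`` where ``qc_flags`` is a semicolon-joined set drawn
    from ``{drift_nonlinear, negative_rate}``.
    """
    controls = [w for w in plate.layout.wells if w.role == "negative_control"]
    if not controls:
        raise ValueError("plate has no negative_control wells; inhibition undefined")

    signals: dict[str, tuple[float, set[str]]] = {}
    for well_id, record in plate.records.items():
        drift = spontaneous_drift(record, nonlinear_threshold)
        flags: set[str] = set()
        if drift.max_residual > nonlinear_threshold:
            flags.add(DRIFT_NONLINEAR)
        sig = enzymatic_signal(record, drift)
        if sig < 0:
            flags.add(NEGATIVE_RATE)
        signals[well_id] = (sig, flags)

    ctrl_signals = [signals[w.well][0] for w in controls if w.well in signals]
    if not ctrl_signals:
        raise ValueError("all negative_control wells were flagged; inhibition undefined")
    control_signal = float(np.mean(ctrl_signals))

    rows = []
    for w in plate.layout.wells:
        if w.well not in signals:
            continue
        sig, flags = signals[w.well]
        rows.append(
            {
                "well": w.well,
                "sample": w.sample,
                "role": w.role,
                "dose": w.dose,
                "replicate": w.replicate,
                "signal": sig,
                "inhibition": percent_inhibition(sig, control_signal),
                "qc_flags": ";".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)


def aggregate_inhibition(reduced: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to mean inhibition per (sample, dose).

    Keeps the replicate values as a list column so the summary remains
    auditable; the summary inhibition is the arithmetic mean of replicates.
    """
    samples = reduced[reduced["role"] == "sample"]
    out = (
        samples.groupby(["sample", "dose"], sort=True)["inhibition"]
        .agg(inhibition="mean", n="size", replicates=list)
        .reset_index()
    )
    return out
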