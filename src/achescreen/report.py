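"""Aggregate per-sample results into screen summary artifacts.

Covers the cytotoxicity side (MTT viability percentages, selectivity
ratios between the cytotoxic and on-target IC50s), replicate summaries
(mean ± sample SD), and the wide screen tables with the inactivity rule
applied.  Display rounding mirrors the conventions of the screen's summary
tables — ratios to 2 significant figures, CI to 3 — and is presentation
only: unrounded values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

from .dose_response import activity_call

__all__ = [
    "SelectivityResult",
    "viability_percent",
    "selectivity_ratio",
    "round_sigfigs",
    "summarize_replicates",
    "build_screen_table",
    "build_actives_table",
]


def round_sigfigs(x: float, n: int) -> float:
    """Round to ``n`` significant figures, half to even."""
    if n < 1:
        raise ValueError("need n >= 1 significant figures")
    x = float(x)
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(exponent - n + 1)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_EVEN))


def viability_percent(od_sample: float, od_control: float) -> float:
    """Percent viable cells relative to the untreated control OD."""
    if not od_control > 0:
        raise ValueError(f"control OD must be > 0, got {od_control}")
    return 100.0 * od_sample / od_control


@dataclass(frozen=True)
class SelectivityResult:
    """Cytotoxic vs on-target IC50 quotient for one sample.

    ``ratio`` is exact; ``ratio_display`` is rounded to 2 significant figures
    for tabulation.  High ratios indicate a wide window between enzyme
    inhibition and cell toxicity.
    """

    sample: str
    ic50_toxicity: float
    ic50_inhibition: float
    ratio: float
    ratio_display: float


def selectivity_ratio(
    ic50_toxicity: float, ic50_inhibition: float, sample: str = ""
) -> SelectivityResult:
    """Selectivity index: cytotoxic IC50 divided by inhibitory IC50."""
    if not ic50_toxicity > 0 or not ic50_inhibition > 0:
        raise ValueError("both IC50s must be > 0")
    ratio = ic50_toxicity / ic50_inhibition
    return SelectivityResult(
        sample=sample,
        ic50_toxicity=ic50_toxicity,
        ic50_inhibition=ic50_inhibition,
        ratio=ratio,
        ratio_display=round_sigfigs(ratio, 2),
    )


def summarize_replicates(values) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of replicate values.

    SD is NaN for a single value; an empty list is an error.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values to summarize")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else float("nan")
    return mean, sd


def build_screen_table(
    fits: pd.DataFrame,
    *,
    ceiling: float = 1250.0,
    threshold: float = 80.0,
) -> pd.DataFrame:
    """Wide screen summary: one row per species, one IC50 cell per solvent.

    ``fits`` is long-form with columns ``family, species, solvent, ic50, sd,
    max_tested_dose, inhibition_at_max`` (``ic50``/``sd`` may be NaN when the
    extract was not analysed).  Cells render as ``mean ± sd``; samples failing
    the activity rule (< ``threshold`` % inhibition at the ``ceiling`` dose)
    render ``NA``; missing extracts render ``n/a``.  Rows are ordered by
    family then species; conflicting duplicate rows are an error.  The
    rendering is idempotent: re-running on its own output changes nothing.
    """
    required = {"family", "species", "solvent", "ic50", "sd", "max_tested_dose", "inhibition_at_max"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing column(s): {sorted(missing)}")
    dup = fits.duplicated(subset=["species", "solvent"], keep=False)
    if dup.any():
        conflicts = fits.loc[dup].drop_duplicates(subset=["species", "solvent", "ic50"])
        if conflicts.duplicated(subset=["species", "solvent"], keep=False).any():
            bad = sorted(conflicts.loc[
                conflicts.duplicated(subset=["species", "solvent"], keep=False), "species"
            ].unique())
            raise ValueError(f"conflicting duplicate rows for sample(s): {bad}")
        fits = fits.drop_duplicates(subset=["species", "solvent"])

    def render(row) -> str:
        if pd.isna(row["ic50"]):
            return "n/a"
        call = activity_call(
            row["max_tested_dose"], row["inhibition_at_max"],
            ceiling=ceiling, threshold=threshold,
        )
        if call == "inactive":
            return "NA"
        sd = "" if pd.isna(row["sd"]) else f" ± {row['sd']:g}"
        return f"{row['ic50']:g}{sd}"

    fits = fits.assign(cell=fits.apply(render, axis=1))
    wide = fits.pivot_table(
        index=["family", "species"], columns="solvent", values="cell", aggfunc="first"
    ).fillna("n/a")
    wide = wide.sort_index().reset_index()
    wide.columns.name = None
    return wide


def build_actives_table(
    fits: pd.DataFrame, toxicity: pd.DataFrame
) -> pd.DataFrame:
    """Actives summary: inhibition IC50, cytotoxic IC50, and selectivity ratio.

    ``fits`` needs ``sample, ic50, sd``; ``toxicity`` needs ``sample, ic50,
    sd``.  Samples without toxicity data get NaN ratios.  The stored ``ratio``
    column is unrounded; ``ratio_display`` carries the 2-significant-figure
    presentation value.
    """
    merged = fits.merge(toxicity, on="sample", how="left", suffixes=("_ache", "_tox"))
    ratios, displays = [], []
    for _, row in merged.iterrows():
        if pd.isna(row.get("ic50_tox")):
            ratios.append(float("nan"))
            displays.append(float("nan"))
        else:
            res = selectivity_ratio(row["ic50_tox"], row["ic50_ache"], row["sample"])
            ratios.append(res.ratio)
            displays.append(res.ratio_display)
    merged["ratio"] = ratios
    merged["ratio_display"] = displays
    return merged
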