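"""Seeded synthetic plate data with the statistical structure the analysis assumes.

The generator produces the three kinds of raw input the pipeline consumes:

* kinetic absorbance plates (pre-enzyme drift reads plus one post-enzyme read),
* single-agent dose–response series, and
* fixed-partner combination series under a Loewe-additivity response model
  with a tunable interaction index.

Every stochastic function takes an explicit seed or :class:`numpy.random.Generator`;
there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .plate_io import PlateLayout, Well

__all__ = [
    "AgentModel",
    "InteractionModel",
    "NoiseModel",
    "CombinationEffect",
    "simulate_effect",
    "simulate_combination_effect",
    "combination_dose_for_effect",
    "simulate_inhibition_series",
    "simulate_checkerboard",
    "simulate_kinetic_plate",
    "serial_dilution_layout",
]


@dataclass(frozen=True)
class AgentModel:
    """Ground-truth four-parameter logistic inhibition model for one agent.

    ``effect(d) = bottom + (top - bottom) * d^h / (d^h + ic50^h)`` with
    inhibition rising from ``bottom`` (at dose 0) to ``top``.  Concentrations
    are µg/mL throughout; effects are percent inhibition.
    """

    name: str
    ic50: float
    hill: float
    bottom: float = 0.0
    top: float = 100.0

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError(f"agent {self.name!r}: ic50 must be > 0, got {self.ic50}")
        if not self.hill > 0:
            raise ValueError(f"agent {self.name!r}: hill must be > 0, got {self.hill}")
        if not (0 <= self.bottom < self.top <= 100):
            raise ValueError(
                f"agent {self.name!r}: need 0 <= bottom < top <= 100, "
                f"got bottom={self.bottom}, top={self.top}"
            )

    def effect(self, dose: float) -> float:
        """Percent inhibition at ``dose`` (µg/mL)."""
        d = float(dose)
        if d == 0.0:
            return self.bottom
        frac = d**self.hill / (d**self.hill + self.ic50**self.hill)
        return self.bottom + (self.top - self.bottom) * frac

    def dose_for_effect(self, effect: float) -> float:
        """Closed-form inverse: the dose producing ``effect`` percent inhibition.

        Only defined strictly inside ``(bottom, top)``.
        """
        if not (self.bottom < effect < self.top):
            raise ValueError(
                f"agent {self.name!r}: effect {effect} outside achievable open "
                f"range ({self.bottom}, {self.top})"
            )
        frac = (effect - self.bottom) / (self.top - effect)
        return self.ic50 * frac ** (1.0 / self.hill)


@dataclass(frozen=True)
class InteractionModel:
    """Loewe interaction index ``tau``: 1 additive, <1 synergy, >1 antagonism."""

    tau: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class NoiseModel:
    """Instrument-level read noise and replicate structure.

    ``sd_abs``
        additive Gaussian SD on each absorbance read (AU).
    ``sd_rel``
        multiplicative Gaussian SD on enzymatic rates (fraction).
    ``n_replicates``
        wells per (sample, dose) condition.
    ``seed``
        base seed; identical seeds give bit-identical output.
    """

    sd_abs: float = 0.01
    sd_rel: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_abs < 0 or self.sd_rel < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class CombinationEffect(NamedTuple):
    effect: float
    below_detection: bool


def simulate_effect(agent: AgentModel, dose: float, well: str | None = None) -> float:
    """Noise-free percent inhibition of ``agent`` at ``dose``.

    Monotone nondecreasing in dose; rejects negative doses with a message
    naming the offending well when one is given.
    """
    if dose < 0:
        where = f" (well {well})" if well else ""
        raise ValueError(f"negative dose {dose} for agent {agent.name!r}{where}")
    return agent.effect(dose)


def _loewe_dose_sum(
    effect: float,
    agents: Sequence[AgentModel],
    doses: Sequence[float],
) -> float:
    """Sum of dose fractions d_i / D_i(E); strictly decreasing in E."""
    return sum(d / a.dose_for_effect(effect) for a, d in zip(agents, doses) if d > 0)


def simulate_combination_effect(
    varied: AgentModel,
    fixed: Sequence[tuple[AgentModel, float]],
    dose: float,
    interaction: InteractionModel = InteractionModel(),
    *,
    tol: float = 1e-9,
    full_output: bool = False,
) -> float | CombinationEffect:
    """Combined percent inhibition of ``varied`` at ``dose`` plus fixed partners.

    The response is the effect level ``E`` solving the generalised Loewe
    relation ``sum_i d_i / D_i(E) = tau``, where ``D_i(E)`` is agent *i*'s
    single-agent dose producing ``E``.  The dose-fraction sum is strictly
    decreasing in ``E``, so the root is unique and found by bisection to an
    absolute effect tolerance of ``tol``.

    With ``tau = 1`` and no fixed partners this reduces exactly to
    :func:`simulate_effect`.  A total dose too small to lift the effect off
    the shared bottom asymptote has no root in the open interval; the bottom
    is returned and, with ``full_output=True``, flagged ``below_detection``.
    """
    agents = [varied] + [a for a, _ in fixed]
    doses = [dose] + [d for _, d in fixed]
    for a, d in zip(agents, doses):
        if d < 0:
            raise ValueError(f"negative dose {d} for agent {a.name!r}")
        if a.bottom != agents[0].bottom or a.top != agents[0].top:
            raise ValueError("all agents in a combination must share bottom and top")

    bottom, top = varied.bottom, varied.top
    total = sum(doses)
    if total == 0:
        out = CombinationEffect(bottom, True)
        return out if full_output else out.effect

    lo, hi = bottom, top
    # shrink away from the asymptotes where D_i(E) is undefined
    eps = (top - bottom) * 1e-12
    lo_e, hi_e = bottom + eps, top - eps
    tau = interaction.tau
    if _loewe_dose_sum(lo_e, agents, doses) < tau:
        # even just above bottom the dose sum falls short: undetectable
        out = CombinationEffect(bottom, True)
        return out if full_output else out.effect
    a, b = lo_e, hi_e
    while b - a > tol:
        mid = 0.5 * (a + b)
        if _loewe_dose_sum(mid, agents, doses) > tau:
            a = mid
        else:
            b = mid
    out = CombinationEffect(0.5 * (a + b), False)
    return out if full_output else out.effect


def combination_dose_for_effect(
    varied: AgentModel,
    fixed: Sequence[tuple[AgentModel, float]],
    effect: float,
    interaction: InteractionModel = InteractionModel(),
    *,
    tol: float = 1e-10,
) -> float:
    """Dose of the varied agent at which the combination reaches ``effect``.

    Inverse of :func:`simulate_combination_effect` in its first dose argument,
    solved by bisection on the dose (the combined effect is strictly
    increasing in the varied dose).
    """
    if not (varied.bottom < effect < varied.top):
        raise ValueError(f"effect {effect} outside ({varied.bottom}, {varied.top})")
    baseline = simulate_combination_effect(varied, fixed, 0.0, interaction)
    if baseline >= effect:
        raise ValueError(
            f"fixed partners alone already produce effect {baseline:.3g} "
            f">= requested level {effect}; no varied dose can titrate down to it"
        )
    lo, hi = 0.0, varied.dose_for_effect(effect)
    # the combination is at least as potent as sub-additivity tau allows;
    # expand upper bracket until the effect is reached
    while simulate_combination_effect(varied, fixed, hi, interaction) < effect:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket combination dose")
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if simulate_combination_effect(varied, fixed, mid, interaction) < effect:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_inhibition_series(
    agent: AgentModel,
    doses: Sequence[float],
    noise: NoiseModel = NoiseModel(sd_abs=0.0, n_replicates=1),
    *,
    fixed: Sequence[tuple[AgentModel, float]] = (),
    interaction: InteractionModel = InteractionModel(),
    control_increment: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate-structured percent-inhibition table for a dilution series.

    Noise is applied in the absorbance domain: the noise-free enzymatic
    increment ``control_increment * (1 - E/100)`` and the control increment
    each receive multiplicative ``sd_rel`` and additive ``sd_abs`` noise
    before inhibition is recomputed, mimicking how read noise propagates
    through the plate reduction.

    Returns a tidy frame with columns ``sample, dose, replicate, inhibition,
    true_inhibition``.
    """
    if rng is None:
        rng = noise.rng()
    rows = []
    for dose in doses:
        if fixed:
            e = simulate_combination_effect(agent, fixed, dose, interaction)
        else:
            e = simulate_effect(agent, dose)
        for rep in range(noise.n_replicates):
            ctrl = control_increment * (1 + rng.normal(0, noise.sd_rel)) + rng.normal(
                0, noise.sd_abs
            )
            sig = control_increment * (1 - e / 100.0)
            sig = sig * (1 + rng.normal(0, noise.sd_rel)) + rng.normal(0, noise.sd_abs)
            rows.append(
                {
                    "sample": agent.name,
                    "dose": float(dose),
                    "replicate": rep + 1,
                    "inhibition": 100.0 * (1.0 - sig / ctrl),
                    "true_inhibition": e,
                }
            )
    return pd.DataFrame(rows)


def simulate_checkerboard(
    varied: AgentModel,
    partner: AgentModel,
    varied_doses: Sequence[float],
    partner_doses: Sequence[float],
    interaction: InteractionModel = InteractionModel(),
) -> pd.DataFrame:
    """Noise-free combination response surface over a dose grid.

    Columns: ``dose_varied, dose_partner, effect, below_detection``.
    """
    rows = []
    for dv in varied_doses:
        for dp in partner_doses:
            eff = simulate_combination_effect(
                varied, [(partner, dp)], dv, interaction, full_output=True
            )
            rows.append(
                {
                    "dose_varied": float(dv),
                    "dose_partner": float(dp),
                    "effect": eff.effect,
                    "below_detection": eff.below_detection,
                }
            )
    return pd.DataFrame(rows)


def serial_dilution_layout(
    agents: Sequence[AgentModel],
    start_dose: float,
    n_steps: int,
    n_replicates: int = 3,
    n_controls: int = 3,
) -> PlateLayout:
    """96-well-style layout: 1:1 serial dilutions per agent plus solvent controls."""
    wells: list[Well] = []
    idx = 0
    for agent in agents:
        for k in range(n_steps):
            dose = start_dose / 2**k
            for rep in range(1, n_replicates + 1):
                idx += 1
                wells.append(
                    Well(
                        well=f"W{idx:03d}",
                        sample=agent.name,
                        role="sample",
                        dose=dose,
                        replicate=rep,
                    )
                )
    for rep in range(1, n_controls + 1):
        idx += 1
        wells.append(
            Well(well=f"W{idx:03d}", sample="DMSO", role="negative_control", dose=0.0, replicate=rep)
        )
    return PlateLayout(wells=wells)


def simulate_kinetic_plate(
    layout: PlateLayout,
    agents: dict[str, AgentModel],
    noise: NoiseModel = NoiseModel(),
    *,
    combinations: dict[str, Sequence[tuple[AgentModel, float]]] | None = None,
    interaction: InteractionModel = InteractionModel(),
    drift: float = 0.002,
    baseline: float = 0.10,
    control_increment: float = 0.5,
    post_time: float = 12.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a kinetic Ellman plate for ``layout``.

    Each well receives pre-enzyme reads at 0/3/6/9 min following a linear
    spontaneous drift (``drift`` AU/min) from ``baseline``, then a single
    post-enzyme read at ``post_time`` whose increment over the
    drift-extrapolated baseline is ``control_increment * (100 - I)/100`` for
    a well with true inhibition ``I`` percent.  Gaussian read noise
    (``noise.sd_abs``) lands on every absorbance; rate noise (``noise.sd_rel``)
    multiplies the enzymatic increment.  Negative absorbances after noise are
    clipped to zero (the clipping rule is echoed in the ground-truth table's
    attrs).

    Returns ``(kinetic, truth)``: the long-form kinetic table understood by
    :mod:`achescreen.plate_io` and a noiseless ground-truth table with columns
    ``well, sample, dose, true_inhibition, true_tau``.
    """
    if not any(w.role == "negative_control" for w in layout.wells):
        raise ValueError("layout has no negative_control well; percent inhibition undefined")
    combinations = combinations or {}
    if rng is None:
        rng = noise.rng()

    pre_times = (0.0, 3.0, 6.0, 9.0)
    kin_rows, truth_rows = [], []
    for w in layout.wells:
        if w.role in ("negative_control", "blank"):
            inh = 0.0 if w.role == "negative_control" else None
        else:
            agent = agents[w.sample]
            if w.sample in combinations:
                inh = simulate_combination_effect(
                    agent, combinations[w.sample], w.dose, interaction
                )
            else:
                inh = simulate_effect(agent, w.dose, well=w.well)
        for t in pre_times:
            a = baseline + drift * t + rng.normal(0, noise.sd_abs)
            kin_rows.append(
                {
                    "well": w.well,
                    "sample": w.sample,
                    "role": w.role,
                    "dose": w.dose,
                    "replicate": w.replicate,
                    "time_min": t,
                    "phase": "pre",
                    "absorbance": max(a, 0.0),
                }
            )
        if w.role == "blank":
            increment = 0.0
        else:
            increment = control_increment * (100.0 - inh) / 100.0
            increment *= 1 + rng.normal(0, noise.sd_rel)
        a = baseline + drift * post_time + increment + rng.normal(0, noise.sd_abs)
        kin_rows.append(
            {
                "well": w.well,
                "sample": w.sample,
                "role": w.role,
                "dose": w.dose,
                "replicate": w.replicate,
                "time_min": post_time,
                "phase": "post",
                "absorbance": max(a, 0.0),
            }
        )
        truth_rows.append(
            {
                "well": w.well,
                "sample": w.sample,
                "dose": w.dose,
                "true_inhibition": np.nan if inh is None else inh,
                "true_tau": interaction.tau if w.sample in combinations else np.nan,
            }
        )
    kinetic = pd.DataFrame(kin_rows)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["clipping"] = "absorbance clipped at 0 after noise"
    truth.attrs["seed"] = noise.seed
    return kinetic, truth
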