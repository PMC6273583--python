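"""Fixed-partner combination designs and FIC/CI synergy scoring.

The experimental design this scores: one agent (the "varied" agent) is
serially diluted 1:1 while each partner is held at a constant dose equal to
that partner's single-agent IC30.  Both the combination series and the
single-agent series are fitted and inverted to IC ladders, and at each effect
level x a combination index is formed from fractional-effect (FE) terms:

    FE_varied = IC_x(combination) / IC_x(varied alone)
    FE_fixed  = IC_x(combination) / fixed partner dose
    CI        = FE_varied + sum(FE_fixed)

The fixed-dose denominator for partners is the operational convention of the
fixed-partner design (the partner has no varying concentration to invert);
the literal iso-effect variant — partner denominators taken as the partner's
own IC_x — is available via ``convention="isoeffect"``.  The classical Loewe
FIC (``sum d_i / D_i`` at one effect level) is provided separately for
simulation validation; on Loewe-generated data it recovers the generator's
interaction index exactly.

Classification schemes map CI values to interaction labels.  Shipped schemes:

``schelz``
    CI ≤ 0.5 synergy; 0.5 < CI ≤ 1.0 additive; 1.0 < CI < 4.0 indifferent;
    CI ≥ 4.0 antagonism.
``berenbaum``
    CI < 1 synergy; CI = 1 additive; CI > 1 antagonism.
``table_bold``
    CI < 1.0 synergy, else no_synergy (the convention that bolds synergistic
    cells in a combination table).

Interval boundaries are explicit because published threshold wordings
overlap at the boundaries; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .dose_response import ICLadder

__all__ = [
    "CombinationDesign",
    "FICResult",
    "ClassificationScheme",
    "SCHEMES",
    "build_design",
    "compute_ci",
    "compute_classical_fic",
    "classify",
    "ci_table",
    "isobologram_points",
    "plot_isobologram",
]


@dataclass(frozen=True)
class CombinationDesign:
    """One varied agent's serial dilution plus partners fixed at their IC30s."""

    varied: str
    dilution: tuple[float, ...]
    fixed_partners: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        steps = self.dilution
        for a, b in zip(steps, steps[1:]):
            if not b < a:
                raise ValueError("dilution must be strictly decreasing")
            if abs(b - a / 2.0) > 1e-9 * a:
                raise ValueError("dilution must proceed in 1:1 (halving) steps")
        for name, dose in self.fixed_partners:
            if not dose > 0:
                raise ValueError(f"fixed partner {name!r} needs dose > 0, got {dose}")


def build_design(
    varied_ladder: ICLadder,
    partner_ladders: Sequence[ICLadder],
    start_dose: float,
    n_steps: int,
    partner_level: int = 30,
) -> CombinationDesign:
    """Build the fixed-partner design from single-agent ladders.

    The varied agent is diluted 1:1 from ``start_dose`` for ``n_steps`` wells;
    each partner is pinned at its ladder's IC30 (or ``partner_level``).
    A partner ladder lacking the pin level is an error.
    """
    if not start_dose > 0 or n_steps < 1:
        raise ValueError("need start_dose > 0 and n_steps >= 1")
    fixed = []
    for ladder in partner_ladders:
        if partner_level not in ladder.levels:
            raise ValueError(
                f"partner ladder {ladder.agent!r} has no IC{partner_level}; "
                f"available levels: {sorted(ladder.levels)}"
            )
        fixed.append((ladder.agent, ladder[partner_level]))
    dilution = tuple(start_dose / 2**k for k in range(n_steps))
    return CombinationDesign(
        varied=varied_ladder.agent, dilution=dilution, fixed_partners=tuple(fixed)
    )


@dataclass(frozen=True)
class FICResult:
    """Combination index at one effect level, with per-term breakdown."""

    level: float
    ic_combo: float
    fe_varied: float
    fe_fixed: tuple[float, ...]
    ci: float
    classification: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered half-open intervals over (0, inf) mapping CI to a label.

    ``bins`` is a sequence of ``(upper_bound, upper_inclusive, label)``
    scanned left to right; the final bin must have an infinite upper bound so
    every positive CI receives exactly one label.
    """

    name: str
    bins: tuple[tuple[float, bool, str], ...]

    def __post_init__(self) -> None:
        if self.bins[-1][0] != float("inf"):
            raise ValueError(f"scheme {self.name!r}: last bin must extend to infinity")
        uppers = [b[0] for b in self.bins]
        if any(b < a for a, b in zip(uppers, uppers[1:])):
            raise ValueError(f"scheme {self.name!r}: bins must be ordered")

    def label(self, ci: float) -> str:
        if not ci > 0:
            raise ValueError(f"CI must be > 0, got {ci}")
        for upper, inclusive, lab in self.bins:
            if ci < upper or (inclusive and ci == upper):
                return lab
        raise AssertionError("unreachable: final bin is unbounded")


SCHEMES: dict[str, ClassificationScheme] = {
    "schelz": ClassificationScheme(
        "schelz",
        (
            (0.5, True, "synergy"),
            (1.0, True, "additive"),
            (4.0, False, "indifferent"),
            (float("inf"), False, "antagonism"),
        ),
    ),
    "berenbaum": ClassificationScheme(
        "berenbaum",
        (
            (1.0, False, "synergy"),
            (1.0, True, "additive"),
            (float("inf"), False, "antagonism"),
        ),
    ),
    "table_bold": ClassificationScheme(
        "table_bold",
        (
            (1.0, False, "synergy"),
            (float("inf"), False, "no_synergy"),
        ),
    ),
}


def classify(ci: float, scheme: str | ClassificationScheme = "schelz") -> str:
    """Interaction label for a combination index under a named scheme."""
    if isinstance(scheme, str):
        try:
            scheme = SCHEMES[scheme]
        except KeyError:
            raise ValueError(
                f"unknown scheme {scheme!r}; available: {sorted(SCHEMES)}"
            ) from None
    return scheme.label(ci)


def compute_ci(
    ic_combo: float,
    ic_alone_varied: float,
    fixed_doses: Sequence[float],
    *,
    level: float = float("nan"),
    fixed_ic_alone: Sequence[float] | None = None,
    convention: str = "fixed_dose",
    schemes: Sequence[str] = ("schelz", "berenbaum", "table_bold"),
) -> FICResult:
    """Combination index at one effect level of a fixed-partner design.

    ``ic_combo`` is the varied agent's concentration at which the combination
    reaches the effect level; ``ic_alone_varied`` the varied agent's own IC at
    that level.  Under the default ``fixed_dose`` convention each partner term
    divides ``ic_combo`` by the partner's constant dose.  Under ``isoeffect``
    the partner denominators are the partners' own single-agent ICs at the
    same level (pass ``fixed_ic_alone``); with no partners at all the two
    conventions coincide and reduce to the classical single-ratio FIC.
    """
    if not ic_combo > 0 or not ic_alone_varied > 0:
        raise ValueError("ic_combo and ic_alone_varied must be > 0")
    if convention == "fixed_dose":
        denominators = list(fixed_doses)
    elif convention == "isoeffect":
        if fixed_ic_alone is None:
            if fixed_doses:
                raise ValueError("isoeffect convention requires fixed_ic_alone")
            denominators = []
        else:
            denominators = list(fixed_ic_alone)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if any(not d > 0 for d in denominators):
        raise ValueError("all partner denominators must be > 0")

    fe_varied = ic_combo / ic_alone_varied
    fe_fixed = tuple(ic_combo / d for d in denominators)
    ci = fe_varied + sum(fe_fixed)
    return FICResult(
        level=level,
        ic_combo=ic_combo,
        fe_varied=fe_varied,
        fe_fixed=fe_fixed,
        ci=ci,
        classification={s: classify(ci, s) for s in schemes},
    )


def compute_classical_fic(
    d_varied: float,
    d_fixed: Sequence[float] | float,
    D_varied: float,
    D_fixed: Sequence[float] | float,
) -> float:
    """Classical Loewe FIC at one effect level: ``sum_i d_i / D_i``.

    ``d_i`` are the doses present in the combination when it reaches the
    level, ``D_i`` the single-agent doses reaching the same level alone.
    A sham combination (an agent split against itself) scores exactly 1.
    """
    d_fixed = [d_fixed] if isinstance(d_fixed, (int, float)) else list(d_fixed)
    D_fixed = [D_fixed] if isinstance(D_fixed, (int, float)) else list(D_fixed)
    if len(d_fixed) != len(D_fixed):
        raise ValueError("d_fixed and D_fixed must have equal length")
    for v in [d_varied, D_varied, *d_fixed, *D_fixed]:
        if not v > 0:
            raise ValueError(f"all doses must be > 0, got {v}")
    return d_varied / D_varied + sum(d / D for d, D in zip(d_fixed, D_fixed))


def ci_table(
    varied_ladder: ICLadder,
    combo_ladder: ICLadder,
    fixed_partners: Sequence[tuple[str, float]],
    *,
    levels: Sequence[int] | None = None,
    schemes: Sequence[str] = ("schelz", "berenbaum", "table_bold"),
) -> pd.DataFrame:
    """Per-level CI table for one combination (the combination-table row pair).

    ``combo_ladder`` holds the varied agent's concentrations in the
    combination at each effect level.  Levels default to those present in
    both ladders.
    """
    if levels is None:
        levels = sorted(set(varied_ladder.levels) & set(combo_ladder.levels))
    rows = []
    for x in levels:
        res = compute_ci(
            combo_ladder[x],
            varied_ladder[x],
            [dose for _, dose in fixed_partners],
            level=x,
            schemes=schemes,
        )
        row = {
            "varied": varied_ladder.agent,
            "partners": "+".join(name for name, _ in fixed_partners),
            "level": x,
            "ic_combo": res.ic_combo,
            "fe_varied": res.fe_varied,
            "ci": res.ci,
        }
        for s in schemes:
            row[f"class_{s}"] = res.classification[s]
        rows.append(row)
    return pd.DataFrame(rows)


def isobologram_points(
    results: Sequence[FICResult],
    varied_ladder: ICLadder,
    fixed_partners: Sequence[tuple[str, float]],
    partner_ladders: Sequence[ICLadder] = (),
) -> pd.DataFrame:
    """Normalised isobologram coordinates for two-agent combinations.

    For each result at level x, the abscissa is the varied agent's dose
    fraction ``ic_combo / IC_x(varied alone)`` and the ordinate the partner's
    dose fraction ``fixed_dose / IC_x(partner alone)``; the additivity line is
    ``x + y = 1`` and a point lies below it iff the classical Loewe FIC < 1.
    With no partners the output degenerates to the single axis and is flagged.
    """
    if not results:
        raise ValueError("need at least one FICResult")
    rows = []
    degenerate = len(fixed_partners) == 0
    ladder_by_name = {lad.agent: lad for lad in partner_ladders}
    for res in results:
        fa = res.ic_combo / varied_ladder[int(res.level)]
        if degenerate:
            rows.append({"level": res.level, "fa": fa, "fb": 0.0, "degenerate": True})
            continue
        name, dose = fixed_partners[0]
        lad = ladder_by_name.get(name)
        if lad is None:
            raise ValueError(f"no single-agent ladder supplied for partner {name!r}")
        rows.append(
            {
                "level": res.level,
                "fa": fa,
                "fb": dose / lad[int(res.level)],
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)


def plot_isobologram(points: pd.DataFrame, path=None, ax=None):
    """Plot normalised isoeffective dose fractions with the unit additivity line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [1, 0], "k--", lw=1, label="Loewe additivity")
    ax.scatter(points["fa"], points["fb"], c=points["level"], cmap="viridis")
    ax.set_xlabel("dose fraction, varied agent")
    ax.set_ylabel("dose fraction, fixed partner")
    ax.set_xlim(left=0)
    ax.set_ylim(bottom=0)
    ax.legend(loc="upper right", frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
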