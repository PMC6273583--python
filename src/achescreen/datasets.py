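"""Bundled reference measurements used in worked examples and validation.

The data describe an AChE-inhibition screen of isoquinoline alkaloids
(berberine, coptisine, palmatine): single-agent IC ladders, fixed-partner
combination ladders with their reported combination indices, and an
IC50/cytotoxicity summary for the most active plant extracts and reference
inhibitors.  Concentrations are µg/mL; effects are percent inhibition.

These tables serve as desk-scale inputs: the analysis functions recompute
CI values, ladder consistency and selectivity ratios from them at run time.
One combination row (palmatine varied against fixed coptisine) carries
reported CI values that no single denominator convention reproduces from its
IC entries; it is retained verbatim but excluded from consistency checks
(``CI_INCONSISTENT_ROWS``).
"""

from __future__ import annotations

import pandas as pd

from .dose_response import ICLadder

__all__ = [
    "LEVELS",
    "alkaloid_ladders",
    "partner_ic30",
    "combination_ladders",
    "reported_ci",
    "screen_summary",
    "CI_INCONSISTENT_ROWS",
]

LEVELS = tuple(range(10, 100, 10))

# single-agent IC10..IC90 ladders (µg/mL)
_SINGLE = {
    "berberine": (0.27, 0.51, 0.76, 1.08, 1.48, 2.02, 2.85, 4.32, 8.09),
    "coptisine": (0.6, 0.79, 0.95, 1.11, 1.27, 1.46, 1.69, 2.04, 2.68),
    "palmatine": (1.73, 2.6, 3.4, 4.25, 5.21, 6.39, 7.97, 10.4, 15.7),
}

# combination rows: varied agent's concentration in the mixture at each level,
# partners held at their single-agent IC30s
_COMBO = {
    ("berberine", ("coptisine",)): (0.051, 0.11, 0.18, 0.28, 0.4, 0.59, 0.9, 1.5, 3.22),
    ("berberine", ("palmatine",)): (0.031, 0.08, 0.15, 0.24, 0.37, 0.59, 0.96, 1.75, 4.33),
    ("berberine", ("coptisine", "palmatine")): (
        0.027, 0.066, 0.12, 0.19, 0.31, 0.48, 0.78, 1.42, 3.47,
    ),
    ("coptisine", ("berberine",)): (0.12, 0.26, 0.44, 0.67, 1.0, 1.49, 2.3, 3.91, 8.67),
    ("coptisine", ("palmatine",)): (0.13, 0.3, 0.52, 0.82, 1.23, 1.86, 2.9, 5.01, 11.4),
    ("coptisine", ("berberine", "palmatine")): (
        0.13, 0.29, 0.47, 0.73, 1.08, 1.6, 2.44, 4.11, 8.97,
    ),
    ("palmatine", ("berberine",)): (0.25, 0.67, 1.28, 2.18, 3.54, 5.77, 9.81, 18.7, 49.6),
    ("palmatine", ("coptisine",)): (0.37, 0.96, 1.82, 3.08, 5.0, 8.11, 13.7, 26.1, 68.8),
    ("palmatine", ("berberine", "coptisine")): (
        0.43, 1.06, 1.95, 3.2, 5.05, 7.97, 13.1, 24.0, 59.8,
    ),
}

# reported combination indices for the same rows
_CI = {
    ("berberine", ("coptisine",)): (0.24, 0.33, 0.43, 0.55, 0.7, 0.91, 1.26, 1.92, 3.79),
    ("berberine", ("palmatine",)): (0.12, 0.18, 0.24, 0.29, 0.36, 0.47, 0.62, 0.92, 1.81),
    ("berberine", ("coptisine", "palmatine")): (
        0.14, 0.22, 0.32, 0.43, 0.62, 0.88, 1.32, 2.24, 5.1,
    ),
    ("coptisine", ("berberine",)): (0.36, 0.67, 1.04, 1.49, 2.11, 2.98, 4.39, 7.06, 14.6),
    ("coptisine", ("palmatine",)): (0.25, 0.47, 0.7, 0.98, 1.33, 1.82, 2.57, 3.93, 7.6),
    ("coptisine", ("berberine", "palmatine")): (
        0.43, 0.83, 1.25, 1.83, 2.59, 3.67, 5.37, 8.63, 17.8,
    ),
    ("palmatine", ("berberine",)): (0.47, 1.14, 2.06, 3.38, 5.34, 8.49, 14.1, 26.4, 68.5),
    ("palmatine", ("coptisine",)): (0.44, 0.76, 1.1, 1.49, 1.97, 2.6, 3.54, 5.13, 8.99),
    ("palmatine", ("berberine", "coptisine")): (
        1.27, 2.92, 5.19, 8.33, 12.9, 20.12, 32.7, 59.2, 145.0,
    ),
}

#: combination rows whose reported CI cannot be recomputed from their IC
#: entries under any single denominator convention (kept verbatim, excluded
#: from consistency checks)
CI_INCONSISTENT_ROWS = (("palmatine", ("coptisine",)),)

# screen summary: inhibition IC50 ± SD, cytotoxic IC50 ± SD (COS7), µg/mL
_SCREEN = [
    ("Berberis bealei MeOH", 34.10, 4.89, 35.37, 4.21),
    ("Berberis bealei CH2Cl2", 9.99, 1.18, 13.36, 1.76),
    ("Berberis bealei H2O", 87.77, 4.11, 270.0, 13.5),
    ("Coptis chinensis MeOH", 0.031, 0.002, 3.72, 0.74),
    ("Coptis chinensis CH2Cl2", 8.13, 0.90, 39.57, 4.87),
    ("Coptis chinensis H2O", 2.5, 0.61, 118.3, 7.4),
    ("Phellodendron chinense MeOH", 8.03, 0.98, 85.52, 11.90),
    ("Phellodendron chinense CH2Cl2", 6.34, 1.37, 71.33, 6.87),
    ("Phellodendron chinense H2O", 84.83, 1.84, 282.9, 15.3),
    ("Berberine", 1.48, 0.07, None, None),
    ("Coptisine", 1.27, 0.06, None, None),
    ("Palmatine", 5.21, 0.48, None, None),
    ("Physostigmine", 2.24, 0.27, None, None),
    ("Galantamine", 4.33, 0.21, None, None),
]


def alkaloid_ladders() -> dict[str, ICLadder]:
    """Single-agent IC10…IC90 ladders for the three alkaloids."""
    return {
        name: ICLadder(agent=name, levels=dict(zip(LEVELS, concs)))
        for name, concs in _SINGLE.items()
    }


def partner_ic30(name: str) -> float:
    """A partner's fixed dose in combination designs: its single-agent IC30."""
    return alkaloid_ladders()[name][30]


def combination_ladders() -> dict[tuple[str, tuple[str, ...]], ICLadder]:
    """Varied-agent IC ladders measured in each fixed-partner combination."""
    return {
        (varied, partners): ICLadder(
            agent=f"{varied}+" + "+".join(partners), levels=dict(zip(LEVELS, concs))
        )
        for (varied, partners), concs in _COMBO.items()
    }


def reported_ci() -> pd.DataFrame:
    """Long-form reported combination indices: varied, partners, level, ci."""
    rows = []
    for (varied, partners), cis in _CI.items():
        for level, ci in zip(LEVELS, cis):
            rows.append(
                {
                    "varied": varied,
                    "partners": "+".join(partners),
                    "partner_tuple": partners,
                    "level": level,
                    "ci": ci,
                }
            )
    return pd.DataFrame(rows)


def screen_summary() -> pd.DataFrame:
    """Inhibition and cytotoxicity IC50 summary of the most active samples."""
    return pd.DataFrame(
        _SCREEN,
        columns=["sample", "ic50_ache", "sd_ache", "ic50_cos7", "sd_cos7"],
    ).astype({"ic50_cos7": float, "sd_cos7": float})
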