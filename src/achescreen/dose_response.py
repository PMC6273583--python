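"""Four-parameter logistic dose–response fitting and IC ladder construction.

The model is the standard Hill/4PL form with inhibition rising with dose:

    r(d) = bottom + (top - bottom) * d^h / (d^h + ic50^h)

For screen samples the asymptotes default to fixed bottom = 0 and top = 100,
leaving (ic50, h) free; both asymptotes can be freed.  Inversion to IC_x is
closed-form, and a pair of printed IC levels determines the curve exactly
(``fit_from_ic_pair``), which is how ladder tables are checked for internal
consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FourPLFit",
    "ICLadder",
    "four_pl",
    "fit_4pl",
    "ic_at_level",
    "build_ladder",
    "hill_from_ic_pair",
    "fit_from_ic_pair",
    "activity_call",
]

DEFAULT_LEVELS = tuple(range(10, 100, 10))


def four_pl(dose, bottom: float, top: float, ic50: float, hill: float):
    """Evaluate the four-parameter logistic at ``dose`` (scalar or array)."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        frac = 1.0 / (1.0 + (ic50 / np.where(d > 0, d, np.nan)) ** hill)
    frac = np.where(d > 0, frac, 0.0)
    out = bottom + (top - bottom) * frac
    return float(out) if np.isscalar(dose) else out


@dataclass(frozen=True)
class FourPLFit:
    """Fitted dose–response parameters with diagnostics.

    ``ic50`` is the curve midpoint (µg/mL); ``se_ic50`` its standard error
    from the Jacobian at the optimum (NaN when unavailable).
    """

    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float = float("nan")
    converged: bool = True
    se_ic50: float = float("nan")

    def __post_init__(self) -> None:
        if not self.bottom < self.top:
            raise ValueError(f"bottom ({self.bottom}) must be < top ({self.top})")
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be > 0, got {self.ic50}")
        if not self.hill > 0:
            raise ValueError(f"hill must be > 0, got {self.hill}")

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ic50, self.hill)


@dataclass(frozen=True)
class ICLadder:
    """Concentrations producing each effect level (percent) for one agent."""

    agent: str
    levels: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        xs = sorted(self.levels)
        concs = [self.levels[x] for x in xs]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError(
                f"ladder for {self.agent!r}: concentrations must increase with level"
            )

    def __getitem__(self, level: int) -> float:
        try:
            return self.levels[level]
        except KeyError:
            raise KeyError(
                f"ladder for {self.agent!r} has no level {level}; "
                f"available: {sorted(self.levels)}"
            ) from None


_HILL_STARTS = (0.5, 1.0, 2.0, 4.0)


def fit_4pl(
    doses,
    responses,
    *,
    fix_bottom: float | None = 0.0,
    fix_top: float | None = 100.0,
    descending: bool = False,
) -> FourPLFit:
    """Least-squares 4PL fit of percent response vs dose.

    By default the asymptotes are fixed at 0 and 100 (pass ``None`` to free
    them).  Initialisation is multi-start: the midpoint is seeded at the dose
    bracketing 50% response and the slope at each of {0.5, 1, 2, 4}; the start
    with the lowest residual sum of squares wins, ties broken by the smallest
    slope.  A stalled optimiser is reported via ``converged=False`` rather
    than raised.

    ``descending=True`` fits a response falling with dose (viability curves)
    by fitting the reflected response; the returned midpoint/slope describe
    the same curve.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape:
        raise ValueError("doses and responses must have the same length")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    if len(np.unique(d)) < 4:
        raise ValueError(f"need >= 4 distinct doses, got {len(np.unique(d))}")
    if np.allclose(r, r[0]):
        raise ValueError("all responses equal; curve unidentifiable")

    if descending:
        lo = fix_bottom if fix_bottom is not None else float(np.min(r))
        hi = fix_top if fix_top is not None else float(np.max(r))
        fit = fit_4pl(
            d, (lo + hi) - r, fix_bottom=fix_bottom, fix_top=fix_top, descending=False
        )
        return fit

    free_asym = fix_bottom is None or fix_top is None

    def unpack(theta):
        ic50, hill = math.exp(theta[0]), math.exp(theta[1])
        if free_asym:
            bottom = theta[2] if fix_bottom is None else fix_bottom
            top = theta[3 if fix_bottom is None else 2] if fix_top is None else fix_top
        else:
            bottom, top = fix_bottom, fix_top
        return bottom, top, ic50, hill

    def resid(theta):
        bottom, top, ic50, hill = unpack(theta)
        return four_pl(d, bottom, top, ic50, hill) - r

    # seed ic50 at the dose bracketing half-maximal response
    lo_r = fix_bottom if fix_bottom is not None else float(np.min(r))
    hi_r = fix_top if fix_top is not None else float(np.max(r))
    half = 0.5 * (lo_r + hi_r)
    pos = d[d > 0]
    order = np.argsort(d)
    ds, rs = d[order], r[order]
    above = np.nonzero(rs >= half)[0]
    if len(above) and above[0] > 0 and ds[above[0] - 1] > 0:
        ic50_seed = math.sqrt(ds[above[0]] * ds[above[0] - 1])
    elif len(above) and ds[above[0]] > 0:
        ic50_seed = ds[above[0]]
    else:
        ic50_seed = float(np.median(pos)) if len(pos) else 1.0

    best = None
    for h0 in _HILL_STARTS:
        theta0 = [math.log(ic50_seed), math.log(h0)]
        if fix_bottom is None:
            theta0.append(float(np.min(r)))
        if fix_top is None:
            theta0.append(float(np.max(r)))
        try:
            sol = least_squares(resid, theta0, method="lm", max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-12 or (
            abs(rss - best[0]) <= 1e-12 and h0 < best[2]
        ):
            best = (rss, sol, h0)
    if best is None:
        raise RuntimeError("4PL optimisation failed from every start")

    rss, sol, _ = best
    bottom, top, ic50, hill = unpack(sol.x)

    se_ic50 = float("nan")
    dof = len(r) - len(sol.x)
    if dof > 0:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (rss / dof)
            se_ic50 = ic50 * math.sqrt(max(cov[0, 0], 0.0))  # delta method on log ic50
        except np.linalg.LinAlgError:
            pass

    return FourPLFit(
        bottom=float(bottom),
        top=float(top),
        ic50=float(ic50),
        hill=float(hill),
        rss=rss,
        converged=bool(sol.success),
        se_ic50=se_ic50,
    )


def ic_at_level(fit: FourPLFit, x: float) -> float:
    """Concentration producing effect level ``x`` percent (closed form).

    ``ic50 * ((x - bottom)/(top - x))^(1/hill)``; strictly increasing in x.
    """
    if not (fit.bottom < x < fit.top):
        raise ValueError(
            f"effect level {x} outside achievable open range ({fit.bottom}, {fit.top})"
        )
    return fit.ic50 * ((x - fit.bottom) / (fit.top - x)) ** (1.0 / fit.hill)


def build_ladder(fit: FourPLFit, levels=DEFAULT_LEVELS, agent: str = "") -> ICLadder:
    """IC ladder (default IC10…IC90 in steps of 10) from a fitted curve."""
    unreachable = [x for x in levels if not (fit.bottom < x < fit.top)]
    if unreachable:
        raise ValueError(
            f"cannot build ladder at level(s) {unreachable}: outside the "
            f"achievable open range ({fit.bottom}, {fit.top})"
        )
    return ICLadder(agent=agent, levels={int(x): ic_at_level(fit, x) for x in levels})


def hill_from_ic_pair(
    ic_lo: float, ic_hi: float, level_lo: float = 10.0, level_hi: float = 90.0
) -> float:
    """Slope of the 0–100 logistic passing through two IC levels.

    For the default IC10/IC90 pair this is ``ln(81) / ln(IC90/IC10)``.
    """
    if not (0 < ic_lo < ic_hi):
        raise ValueError("need 0 < ic_lo < ic_hi")
    if not (0 < level_lo < level_hi < 100):
        raise ValueError("levels must satisfy 0 < lo < hi < 100")
    odds = (level_hi / (100.0 - level_hi)) / (level_lo / (100.0 - level_lo))
    return math.log(odds) / math.log(ic_hi / ic_lo)


def fit_from_ic_pair(
    ic_lo: float, ic_hi: float, level_lo: float = 10.0, level_hi: float = 90.0
) -> FourPLFit:
    """Exact 0–100 logistic through two printed IC levels.

    Solves the slope from the level pair, then inverts to the midpoint:
    with the default pair, ``IC50 = IC10 * 9^(1/h)``.  Used to check printed
    IC ladders for internal consistency.
    """
    hill = hill_from_ic_pair(ic_lo, ic_hi, level_lo, level_hi)
    odds_lo = level_lo / (100.0 - level_lo)
    ic50 = ic_lo * odds_lo ** (-1.0 / hill)
    return FourPLFit(bottom=0.0, top=100.0, ic50=ic50, hill=hill, rss=0.0)


def activity_call(
    max_tested_dose: float,
    inhibition_at_max: float,
    *,
    ceiling: float = 1250.0,
    threshold: float = 80.0,
) -> str:
    """Screen triage: ``inactive`` iff inhibition at the screen ceiling is
    below ``threshold`` percent; the boundary value counts as active.

    The default ceiling of 1250 µg/mL and 80% cutoff are the screen's
    inactivity rule; a sample not tested up to the ceiling cannot be called
    inactive and is returned as ``active``.
    """
    if max_tested_dose >= ceiling and inhibition_at_max < threshold:
        return "inactive"
    return "active"
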