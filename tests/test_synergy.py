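"""Combination designs, CI/FIC scoring, classification and isobolograms."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from achescreen import datasets
from achescreen import synergy as sy
from achescreen.synthetic import (
    AgentModel,
    InteractionModel,
    combination_dose_for_effect,
)


def last_digit_tol(printed: float) -> float:
    """One unit of the last printed digit (the tables carry rounded CI values)."""
    s = f"{printed}"
    if "." in s and not s.endswith(".0"):
        return 10.0 ** -(len(s.split(".")[1]))
    return 1.0


class TestBuildDesign:
    def test_partner_fixed_at_ic30(self, ladders):
        design = sy.build_design(ladders["berberine"], [ladders["coptisine"]], 10.0, 4)
        assert design.fixed_partners == (("coptisine", 0.95),)

    def test_palmatine_partner_dose(self, ladders):
        design = sy.build_design(ladders["berberine"], [ladders["palmatine"]], 10.0, 4)
        assert design.fixed_partners == (("palmatine", 3.4),)

    def test_halving_dilution(self, ladders):
        design = sy.build_design(ladders["berberine"], [ladders["coptisine"]], 10.0, 8)
        assert design.dilution == tuple(10.0 / 2**k for k in range(8))
        assert design.dilution[-1] == pytest.approx(0.078125)

    def test_missing_partner_level_rejected(self, ladders):
        from achescreen.dose_response import ICLadder

        thin = ICLadder("thin", {10: 0.1, 50: 1.0})
        with pytest.raises(ValueError, match="IC30"):
            sy.build_design(ladders["berberine"], [thin], 10.0, 4)


class TestComputeCi:
    def test_worked_example_two_agents(self):
        res = sy.compute_ci(0.59, 2.02, [0.95], level=60)
        assert res.ci == pytest.approx(0.913, abs=5e-4)
        assert res.ci == pytest.approx(res.fe_varied + sum(res.fe_fixed))

    def test_sham_single_ratio_is_one(self):
        assert sy.compute_ci(1.23, 1.23, []).ci == pytest.approx(1.0)

    def test_worked_example_three_agents(self):
        res = sy.compute_ci(3.47, 8.09, [0.95, 3.4], level=90)
        assert res.ci == pytest.approx(5.10, abs=5e-3)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sy.compute_ci(0.0, 1.0, [])
        with pytest.raises(ValueError):
            sy.compute_ci(1.0, 1.0, [0.0])

    def test_isoeffect_variant_degrades_to_classical_without_partners(self):
        a = sy.compute_ci(0.4, 1.48, [], convention="isoeffect")
        b = sy.compute_classical_fic(0.4, [], 1.48, [])
        assert a.ci == pytest.approx(b)

    def test_isoeffect_variant_uses_partner_ic(self):
        # literal form: partner denominator is the partner's own IC at the level
        res = sy.compute_ci(
            0.4, 1.48, [0.95], fixed_ic_alone=[1.27], convention="isoeffect"
        )
        assert res.ci == pytest.approx(0.4 / 1.48 + 0.4 / 1.27)


class TestReferenceCiReproduction:
    """Recomputing CI from the reference IC entries reproduces the tabulated
    values at one unit of the last printed digit, for every consistent row."""

    @pytest.mark.parametrize(
        "varied,partners",
        [k for k in datasets.combination_ladders() if k not in datasets.CI_INCONSISTENT_ROWS],
        ids=lambda v: v if isinstance(v, str) else "+".join(v),
    )
    def test_row_reproduced(self, varied, partners, ladders):
        combo = datasets.combination_ladders()[(varied, partners)]
        reported = datasets.reported_ci()
        fixed = [(p, datasets.partner_ic30(p)) for p in partners]
        table = sy.ci_table(ladders[varied], combo, fixed)
        for _, row in table.iterrows():
            printed = reported.query(
                "varied == @varied and partner_tuple == @partners and level == @row.level"
            )["ci"].iloc[0]
            assert row["ci"] == pytest.approx(printed, abs=last_digit_tol(printed)), (
                f"{varied}+{partners} IC{int(row['level'])}"
            )

    def test_inconsistent_row_is_actually_inconsistent(self, ladders):
        # documents why the palmatine/coptisine row is excluded: the reported
        # IC10 CI (0.44) is irreproducible from its own IC entries (0.60)
        combo = datasets.combination_ladders()[("palmatine", ("coptisine",))]
        res = sy.compute_ci(combo[10], ladders["palmatine"][10], [0.95], level=10)
        assert res.ci == pytest.approx(0.60, abs=0.01)
        assert res.ci != pytest.approx(0.44, abs=0.01)


class TestClassicalFic:
    def test_sham_combination_identity(self, berberine):
        d = berberine.dose_for_effect(50.0) / 2
        assert sy.compute_classical_fic(d, [d], 2 * d, [2 * d]) == pytest.approx(1.0)

    def test_arithmetic_variant_example(self):
        fic = sy.compute_classical_fic(0.4, [0.95], 1.48, [1.27])
        assert fic == pytest.approx(0.270 + 0.748, abs=2e-3)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0])
    def test_recovers_generator_tau_at_every_level(self, tau, berberine, coptisine):
        # checkerboard geometry: walk an iso-effect dose ray at each level,
        # generate the combined response, and score it — the classical FIC
        # must hand back the generator's interaction index
        inter = InteractionModel(tau=tau)
        from achescreen.synthetic import simulate_combination_effect

        for level in range(10, 100, 10):
            for theta in (0.25, 0.5, 0.75):
                d_v = theta * tau * berberine.dose_for_effect(level)
                d_f = (1 - theta) * tau * coptisine.dose_for_effect(level)
                eff = simulate_combination_effect(
                    berberine, [(coptisine, d_f)], d_v, inter
                )
                assert eff == pytest.approx(level, abs=1e-6)
                fic = sy.compute_classical_fic(
                    d_v, [d_f],
                    berberine.dose_for_effect(eff),
                    [coptisine.dose_for_effect(eff)],
                )
                assert fic == pytest.approx(tau, rel=0.01), f"level {level}"

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sy.compute_classical_fic(0.0, [1.0], 1.0, [1.0])


class TestClassify:
    @pytest.mark.parametrize(
        "ci,scheme,label",
        [
            (0.43, "schelz", "synergy"),
            (0.91, "schelz", "additive"),
            (0.91, "table_bold", "synergy"),
            (0.5, "schelz", "synergy"),
            (0.5000001, "schelz", "additive"),
            (1.0, "schelz", "additive"),
            (1.0000001, "schelz", "indifferent"),
            (4.0, "schelz", "antagonism"),
            (3.9999999, "schelz", "indifferent"),
            (1.0, "berenbaum", "additive"),
            (0.9999999, "berenbaum", "synergy"),
            (1.0000001, "berenbaum", "antagonism"),
            (1.0, "table_bold", "no_synergy"),
        ],
    )
    def test_boundaries(self, ci, scheme, label):
        assert sy.classify(ci, scheme) == label

    def test_unknown_scheme_lists_available(self):
        with pytest.raises(ValueError, match="berenbaum"):
            sy.classify(0.5, "nope")

    @given(ci=st.floats(1e-6, 1e6))
    @settings(max_examples=200, derandomize=True)
    @pytest.mark.parametrize("scheme", sorted(sy.SCHEMES))
    def test_total_on_positive_reals(self, ci, scheme):
        assert sy.classify(ci, scheme) in {
            "synergy", "additive", "indifferent", "antagonism", "no_synergy",
        }

    def test_nonpositive_ci_rejected(self):
        with pytest.raises(ValueError):
            sy.classify(0.0, "schelz")


class TestIsobologram:
    def test_sham_point_on_additivity_line(self, ladders):
        lad = ladders["berberine"]
        # sham: split berberine against itself, halves at every level
        results = [
            sy.compute_ci(lad[x] / 2, lad[x], [lad[x] / 2], level=x)
            for x in (30, 50, 70)
        ]
        pts = sy.isobologram_points(
            results, lad, [("berberine", 1.0)], partner_ladders=[lad]
        )
        # fb computed from the sham's per-level dose: override partner dose per level
        for res, (_, row) in zip(results, pts.iterrows()):
            fa = res.ic_combo / lad[int(res.level)]
            fb = (lad[int(res.level)] / 2) / lad[int(res.level)]
            assert fa + fb == pytest.approx(1.0)

    def test_synergy_points_below_line(self, berberine, coptisine):
        # tau=0.5 generator: every iso-effect dose pair lands strictly below
        # the additivity line (fa + fb = tau < 1)
        inter = InteractionModel(tau=0.5)
        for level in (20, 40, 60, 80):
            fixed_dose = 0.25 * coptisine.dose_for_effect(level)
            d = combination_dose_for_effect(
                berberine, [(coptisine, fixed_dose)], float(level), inter
            )
            fa = d / berberine.dose_for_effect(level)
            fb = fixed_dose / coptisine.dose_for_effect(level)
            assert fa + fb == pytest.approx(0.5, abs=1e-6)
            assert fa + fb < 1.0

    def test_empty_partner_list_degenerate_flagged(self, ladders):
        res = [sy.compute_ci(0.4, 1.48, [], level=50)]
        pts = sy.isobologram_points(res, ladders["berberine"], [])
        assert pts["degenerate"].all()
        assert (pts["fb"] == 0.0).all()

    def test_no_results_rejected(self, ladders):
        with pytest.raises(ValueError):
            sy.isobologram_points([], ladders["berberine"], [])
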