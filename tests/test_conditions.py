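"""WT/MUT condition construction: medium, biomass, forcing, KO/KD."""

import numpy as np
import pytest

from fluxshift import (
    ConditionSpec,
    apply_biomass_constraint,
    apply_medium_bounds,
    build_condition_pair,
    build_mut,
    build_wt,
    gene_to_reactions,
)
from fluxshift.model import MetabolicModel


def _spec(**kw):
    base = dict(name="t", perturbation_targets=["g1"], target_kind="genes")
    base.update(kw)
    return ConditionSpec(**base)


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------


def test_knockdown_requires_fraction():
    with pytest.raises(ValueError, match="knockdown_fraction"):
        _spec(mode="knockdown")


@pytest.mark.parametrize("kw", [
    {"medium_uptake_X": -1.0},
    {"forcing_fraction": 0.0},
    {"forcing_fraction": 1.5},
    {"biomass_fraction": 2.0},
    {"mode": "knockdown", "knockdown_fraction": 1.0},
])
def test_invalid_spec_rejected(kw):
    with pytest.raises(ValueError):
        _spec(**kw)


# ---------------------------------------------------------------------------
# medium bounds
# ---------------------------------------------------------------------------


def test_medium_bounds_default_X(toy):
    out = apply_medium_bounds(toy, 1.0)
    for rid in out.exchange_ids:
        j = out.reaction_index(rid)
        assert (out.lb[j], out.ub[j]) == (-1.0, 1000.0)
    # internal reactions untouched
    j = out.reaction_index("R_AB")
    assert (out.lb[j], out.ub[j]) == (toy.lb[j], toy.ub[j])


def test_medium_X_zero_forbids_uptake(toy):
    out = apply_medium_bounds(toy, 0.0)
    j = out.reaction_index("EX_A")
    assert (out.lb[j], out.ub[j]) == (0.0, 1000.0)


def test_medium_pass_through(toy):
    out = apply_medium_bounds(toy, None)
    np.testing.assert_array_equal(out.lb, toy.lb)
    np.testing.assert_array_equal(out.ub, toy.ub)


# ---------------------------------------------------------------------------
# gene -> reaction resolution
# ---------------------------------------------------------------------------


def test_single_gene_knocks_reaction(toy):
    assert gene_to_reactions(toy, {"g1"}) == {"R_BC"}


def test_isozyme_compensates():
    model = MetabolicModel(
        ["A", "B"], ["R1"], np.array([[-1.0], [1.0]]),
        np.array([0.0]), np.array([10.0]),
        gpr=[__import__("fluxshift").parse_gpr("g1 or g2")],
    )
    assert gene_to_reactions(model, {"g1"}) == set()


def test_shared_complex_subunit_hits_all_reactions():
    from fluxshift import parse_gpr

    model = MetabolicModel(
        ["A", "B"],
        ["R1", "R2", "R3"],
        np.array([[-1.0, -1.0, -1.0], [1.0, 1.0, 1.0]]),
        np.zeros(3),
        np.full(3, 10.0),
        gpr=[parse_gpr("gA and gB")] * 3,
    )
    # brute-force oracle: every rule is False once gA is knocked
    assert gene_to_reactions(model, {"gA"}) == {"R1", "R2", "R3"}


def test_unknown_gene_warns_not_errors(toy):
    with pytest.warns(UserWarning, match="ghost"):
        assert gene_to_reactions(toy, {"ghost"}) == set()


# ---------------------------------------------------------------------------
# MUT construction
# ---------------------------------------------------------------------------


def test_knockout_zeroes_bounds(toy):
    mut = build_mut(toy, _spec())
    j = mut.reaction_index("R_BC")
    assert (mut.lb[j], mut.ub[j]) == (0.0, 0.0)


def test_knockdown_scales_permitted_side(toy):
    mut = build_mut(toy, _spec(mode="knockdown", knockdown_fraction=0.3))
    j = mut.reaction_index("R_BC")
    assert (mut.lb[j], mut.ub[j]) == (0.0, pytest.approx(300.0))


def test_knockdown_reversible_scales_both_sides():
    model = MetabolicModel(
        ["A"], ["EX1", "EX2"], np.array([[-1.0, 1.0]]),
        np.array([-10.0, -10.0]), np.array([10.0, 10.0]),
        gpr=[__import__("fluxshift").parse_gpr("g1"),
             __import__("fluxshift").parse_gpr("")],
    )
    mut = build_mut(model, _spec(mode="knockdown", knockdown_fraction=0.5))
    j = mut.reaction_index("EX1")
    assert (mut.lb[j], mut.ub[j]) == (-5.0, 5.0)


def test_unresolvable_target_is_hard_error(toy):
    with pytest.raises(ValueError, match="no reactions"):
        with pytest.warns(UserWarning):
            build_mut(toy, _spec(perturbation_targets=["ghost"]))


# ---------------------------------------------------------------------------
# WT forcing
# ---------------------------------------------------------------------------


def test_forcing_sets_lb_to_fraction_of_max(toy):
    """vmax through R_BC under the X=1 medium is 2 (A + B uptake), so the
    forced lower bound is 0.05 * 2."""
    base = apply_medium_bounds(toy, 1.0)
    wt = build_wt(base, _spec())
    j = wt.reaction_index("R_BC")
    assert wt.lb[j] == pytest.approx(0.1, abs=1e-9)


def test_forcing_reverse_only_target():
    """A target that can only run backwards gets ub = fraction * vmin.

    Mass balance couples the two reactions (EX_A flux = R_rev flux), so
    R_rev can only run in reverse, down to -8; the forcing rule then caps
    its upper bound at 5% of that extreme.
    """
    from fluxshift import parse_gpr

    model = MetabolicModel(
        ["A"], ["EX_A", "R_rev"], np.array([[-1.0, 1.0]]),
        np.array([-10.0, -8.0]), np.array([0.0, 0.0]),
        gpr=[parse_gpr(""), parse_gpr("g1")],
    )
    wt = build_wt(model, _spec(medium_uptake_X=None))
    j = wt.reaction_index("R_rev")
    assert wt.ub[j] == pytest.approx(-0.4, abs=1e-9)  # 0.05 * (-8)
    assert wt.lb[j] == -8.0


def test_blocked_target_left_unforced_with_warning(toy):
    model = toy.copy()
    j = model.reaction_index("R_BC")
    model.lb[j] = model.ub[j] = 0.0  # block it
    with pytest.warns(UserWarning, match="blocked"):
        wt = build_wt(model, _spec())
    assert (wt.lb[j], wt.ub[j]) == (0.0, 0.0)
    assert wt._unforceable == ["R_BC"]


def test_build_wt_idempotent(toy):
    base = apply_medium_bounds(toy, 1.0)
    wt1 = build_wt(base, _spec())
    wt2 = build_wt(base, _spec())
    np.testing.assert_array_equal(wt1.lb, wt2.lb)
    np.testing.assert_array_equal(wt1.ub, wt2.ub)


# ---------------------------------------------------------------------------
# biomass constraint
# ---------------------------------------------------------------------------


def test_biomass_fraction_zero_keeps_lb(chain_model):
    out = apply_biomass_constraint(chain_model, "EXPORT_B", 0.0)
    j = out.reaction_index("EXPORT_B")
    assert out.lb[j] == 0.0


@pytest.mark.parametrize("fraction, expected", [(1.0, 5.0), (0.5, 2.5)])
def test_biomass_fraction_pins_lb(chain_model, fraction, expected):
    out = apply_biomass_constraint(chain_model, "EXPORT_B", fraction)
    j = out.reaction_index("EXPORT_B")
    assert out.lb[j] == pytest.approx(expected, abs=1e-8)


# ---------------------------------------------------------------------------
# the pair
# ---------------------------------------------------------------------------


def test_condition_pair_invariants(toy_pair):
    wt, mut = toy_pair.wt, toy_pair.mut
    assert toy_pair.affected_reactions == ["R_BC"]
    # structure identical
    np.testing.assert_array_equal(wt.S, mut.S)
    assert wt.reaction_ids == mut.reaction_ids
    # bounds differ only on affected reactions
    diff = np.nonzero((wt.lb != mut.lb) | (wt.ub != mut.ub))[0]
    assert {wt.reaction_ids[j] for j in diff} <= set(toy_pair.affected_reactions)
    # knockout: [0, 0] in MUT
    j = mut.reaction_index("R_BC")
    assert (mut.lb[j], mut.ub[j]) == (0.0, 0.0)
    # provenance recorded every change
    assert all(p["reaction"] == "R_BC" for p in toy_pair.provenance)
    assert len(toy_pair.provenance) >= 3  # wt lb + mut lb + mut ub
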