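"""Difference distributions, z-scores, ranking, and auxiliary metrics."""

import itertools

import numpy as np
import pytest

from fluxshift import (
    ExchangeScore,
    MetabolicProfile,
    alt_metrics,
    difference_distribution,
    rank_by_abs_z,
    run_fva,
    sample_fluxes,
    score_exchanges,
    z_score,
)
from fluxshift.scoring import Z_SENTINEL, DifferenceDistribution

pytestmark = pytest.mark.filterwarnings("ignore:warm-up produced")


# ---------------------------------------------------------------------------
# difference distribution
# ---------------------------------------------------------------------------


def test_constant_columns_constant_difference():
    dd = difference_distribution([1.0], [3.0], n_pairs=5, seed=0)
    assert np.all(dd.values == 2.0)


def test_identical_columns_mean_near_zero():
    rng = np.random.default_rng(1)
    col = rng.uniform(0, 10, size=200)
    dd = difference_distribution(col, col, n_pairs=50_000, seed=2)
    se = col.std() * np.sqrt(2 / 50_000)
    assert abs(dd.values.mean()) <= 3 * se


def test_empty_column_rejected():
    with pytest.raises(ValueError):
        difference_distribution([], [1.0], n_pairs=1)


def test_default_n_pairs_is_sample_count():
    dd = difference_distribution(np.arange(7), np.arange(7), seed=0)
    assert len(dd) == 7


# ---------------------------------------------------------------------------
# z-score against the exhaustive-pairing oracle
# ---------------------------------------------------------------------------

WT_ORACLE = np.array([0.0, 1.0, 2.0, 3.0])
MUT_ORACLE = np.array([10.0, 11.0, 12.0, 13.0])
# frozen from the 16-pair Cartesian enumeration: mean 10, population sd
# sqrt(2.5) = 1.5811..., z = 10 / sqrt(2.5) = 6.3245...
CART = np.array([m - w for w in WT_ORACLE for m in MUT_ORACLE])
ORACLE_MEAN, ORACLE_SD = 10.0, 1.5811388300841898
ORACLE_Z = 6.324555320336759


def test_cartesian_enumeration_frozen_values():
    assert CART.mean() == pytest.approx(ORACLE_MEAN)
    assert CART.std() == pytest.approx(ORACLE_SD)
    assert z_score(DifferenceDistribution(CART)) == pytest.approx(ORACLE_Z)


def test_random_pairing_converges_to_cartesian_oracle():
    n_pairs = 100_000
    dd = difference_distribution(WT_ORACLE, MUT_ORACLE, n_pairs=n_pairs, seed=3)
    se_mean = ORACLE_SD / np.sqrt(n_pairs)
    assert abs(dd.values.mean() - ORACLE_MEAN) <= 3 * se_mean
    z = z_score(dd)
    # z's standard error is approximately 1/sqrt(n) at fixed sd
    assert abs(z - ORACLE_Z) <= 3 * np.sqrt((1 + ORACLE_Z**2 / 2) / n_pairs)


@pytest.mark.parametrize(
    "values, expected",
    [
        ([0.0, 0.0], 0.0),
        ([2.0, 2.0], Z_SENTINEL),
        ([-2.0, -2.0], -Z_SENTINEL),
    ],
)
def test_degenerate_distributions_use_sentinel(values, expected):
    assert z_score(DifferenceDistribution(np.array(values))) == expected


def test_zero_mean_gives_zero_z():
    assert z_score(DifferenceDistribution(np.array([-1.0, 1.0]))) == 0.0


def test_scale_equivariance_exact():
    """Multiplying all fluxes by c > 0 leaves z unchanged (same seed)."""
    for c in (0.5, 3.0, 1e4):
        z1 = z_score(difference_distribution(WT_ORACLE, MUT_ORACLE,
                                             n_pairs=5000, seed=9))
        z2 = z_score(difference_distribution(c * WT_ORACLE, c * MUT_ORACLE,
                                             n_pairs=5000, seed=9))
        assert z2 == pytest.approx(z1, abs=1e-9)


def test_antisymmetry_monte_carlo():
    """Swapping the conditions flips the z sign within Monte-Carlo noise."""
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 1, size=64)
    b = rng.uniform(0.5, 1.5, size=64)
    n_pairs = 10_000
    z_ab = z_score(difference_distribution(a, b, n_pairs=n_pairs, seed=1))
    z_ba = z_score(difference_distribution(b, a, n_pairs=n_pairs, seed=2))
    assert abs(z_ab + z_ba) <= 3 * np.sqrt(2 * (1 + z_ab**2 / 2) / n_pairs)


# ---------------------------------------------------------------------------
# auxiliary metrics
# ---------------------------------------------------------------------------


def test_alt_metrics_basic():
    mean_diff, median_diff, fold = alt_metrics([1.0, 3.0], [4.0, 6.0])
    assert mean_diff == pytest.approx(3.0)
    assert median_diff == pytest.approx(3.0)
    assert fold == pytest.approx(2.5)


def test_alt_metrics_identical_columns():
    assert alt_metrics([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0, 1.0)


def test_alt_metrics_zero_denominator_sentinel():
    _, _, fold = alt_metrics([-1.0, 1.0], [0.0, 2.0])
    assert fold == 1e9
    _, _, fold = alt_metrics([-1.0, 1.0], [0.0, 0.0])
    assert fold is None


# ---------------------------------------------------------------------------
# profile scoring and ranking
# ---------------------------------------------------------------------------


def _profile(zs):
    scores = [
        ExchangeScore(f"M{r}", r, z=z, status="scored") for r, z in zs.items()
    ]
    return MetabolicProfile("t", scores)


def test_rank_by_abs_z_ordering():
    profile = rank_by_abs_z(_profile({"A": -2.0, "B": 0.5, "C": 1.0}))
    ranks = {s.exchange_reaction_id: s.rank for s in profile.scores}
    assert ranks == {"A": 1, "C": 2, "B": 3}


def test_rank_ties_break_on_reaction_id():
    profile = rank_by_abs_z(_profile({"B": 1.0, "A": -1.0, "C": 1.0}))
    ranks = {s.exchange_reaction_id: s.rank for s in profile.scores}
    assert ranks == {"A": 1, "B": 2, "C": 3}


def test_ranks_form_permutation(toy_pair):
    wt = sample_fluxes(toy_pair.wt, 500, thinning=5, seed=1)
    mut = sample_fluxes(toy_pair.mut, 500, thinning=5, seed=1)
    profile = score_exchanges(wt, mut, toy_pair.wt, seed=1)
    ranks = sorted(s.rank for s in profile.scores if s.status == "scored")
    assert ranks == list(range(1, profile.n_scored + 1))


def test_score_exchanges_full(toy_pair):
    wt_fva = run_fva(toy_pair.wt)
    mut_fva = run_fva(toy_pair.mut)
    wt = sample_fluxes(toy_pair.wt, 1500, thinning=5, seed=2)
    mut = sample_fluxes(toy_pair.mut, 1500, thinning=5, seed=2)
    profile = score_exchanges(
        wt, mut, toy_pair.wt, wt_fva, mut_fva, seed=2,
        requested_metabolites=["C", "UNOBTAINIUM"],
    )
    # the planted KO collapses the E export: largest |z|, direction decrease
    top = next(s for s in profile.scores if s.rank == 1)
    assert top.exchange_reaction_id == "EX_E"
    assert top.direction == "decrease"
    # requested-metabolite statuses
    assert profile.score_for("C").status == "no_exchange"
    assert profile.score_for("UNOBTAINIUM").status == "absent"
    # unscored entries carry no z and no rank
    for s in profile.scores:
        if s.status != "scored":
            assert s.z is None and s.rank is None


def test_identical_conditions_z_near_zero(toy_pair):
    wt = sample_fluxes(toy_pair.wt, 2000, thinning=5, seed=3)
    profile = score_exchanges(wt, wt, toy_pair.wt, seed=3)
    for s in profile.scores:
        if s.status == "scored":
            assert abs(s.z) <= 0.05


def test_blocked_exchange_status(toy):
    """An exchange blocked in both conditions is reported unscored."""
    model = toy.copy()
    j = model.reaction_index("R_CE")
    model.lb[j] = model.ub[j] = 0.0  # E can never be produced
    wt_fva = run_fva(model)
    s = sample_fluxes(model, 300, thinning=5, seed=4)
    profile = score_exchanges(s, s, model, wt_fva, wt_fva, seed=4)
    assert profile.score_for("E").status == "blocked"
    assert profile.score_for("E").z is None


def test_profile_frame_shape(toy_pair):
    wt = sample_fluxes(toy_pair.wt, 300, thinning=5, seed=5)
    mut = sample_fluxes(toy_pair.mut, 300, thinning=5, seed=5)
    df = score_exchanges(wt, mut, toy_pair.wt, seed=5).to_frame()
    assert list(df.columns[:7]) == [
        "metabolite_id", "exchange_reaction_id", "z_score", "abs_z",
        "rank", "direction", "status",
    ]
    assert len(df) == 4
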