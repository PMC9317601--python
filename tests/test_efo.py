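"""The incremental EF-optimizing consensus search."""

import numpy as np
import pytest

from efoscreen import (ConsensusModel, ConsensusTerm, DataError, EFOConsensus,
                       Ranking, SearchConfig,
                       aggregate_poses, best_single_channel,
                       incremental_search, optimize_coefficients,
                       rank_ligands, score_ligands)
from efoscreen.metrics import quality

from conftest import make_matrix


def one_term(matrix, j, coef=1.0):
    return ConsensusModel(terms=(ConsensusTerm(coef, matrix.channels[j]),))


def test_single_term_reproduces_channel_ranking(rng):
    values = rng.normal(size=(50, 3))
    m = make_matrix(values, [True] * 5 + [False] * 45)
    model = one_term(m, 1)
    r = rank_ligands(model, m)
    direct = Ranking.from_scores(values[:, 1], m.ligand_ids)
    assert (r.order == direct.order).all()


def test_negated_term_reverses_ranking(rng):
    values = rng.normal(size=(30, 2))  # continuous: no ties
    m = make_matrix(values, [True] * 3 + [False] * 27)
    fwd = rank_ligands(one_term(m, 0, 1.0), m)
    rev = rank_ligands(one_term(m, 0, -1.0), m)
    assert (fwd.order == rev.order[::-1]).all()


def test_two_term_model_matches_hand_expanded_sum():
    values = np.array([[1.0, 10.0], [2.0, 5.0], [3.0, 0.0],
                       [4.0, -5.0], [5.0, -10.0]])
    m = make_matrix(values, [True, False, False, False, True])
    model = ConsensusModel(terms=(
        ConsensusTerm(1.0, m.channels[0]),
        ConsensusTerm(-2.5, m.channels[1])))
    expected = values[:, 0] * 1.0 + values[:, 1] * (-2.5)
    assert score_ligands(model, m) == pytest.approx(expected, abs=1e-12)


def test_unknown_channel_rejected(rng):
    m = make_matrix(rng.normal(size=(10, 2)), [True] + [False] * 9)
    other = make_matrix(rng.normal(size=(10, 6)), [True] + [False] * 9)
    model = one_term(other, 5)
    with pytest.raises(DataError, match="unknown channel"):
        score_ligands(model, m)


def test_best_single_channel_finds_planted_column(rng):
    """One informative channel among 23 noise channels."""
    n, n_act = 200, 8
    is_active = np.zeros(n, dtype=bool)
    is_active[rng.choice(n, n_act, replace=False)] = True
    values = rng.normal(size=(n, 24))
    planted = 7
    values[is_active, planted] += 4.0
    m = make_matrix(values, is_active)
    model = best_single_channel(m)
    assert model.terms[0].channel == m.channels[planted]
    assert model.terms[0].coefficient == 1.0


def test_best_single_channel_sign_flip_symmetry(rng):
    n, n_act = 150, 6
    is_active = np.zeros(n, dtype=bool)
    is_active[rng.choice(n, n_act, replace=False)] = True
    values = rng.normal(size=(n, 8))
    values[is_active, 3] += 4.0
    m1 = make_matrix(values, is_active)
    flipped = values.copy()
    flipped[:, 3] *= -1.0
    m2 = make_matrix(flipped, is_active)
    b1 = best_single_channel(m1)
    b2 = best_single_channel(m2)
    assert b1.terms[0].channel == b2.terms[0].channel
    assert b2.terms[0].coefficient == -b1.terms[0].coefficient
    assert b1.training_quality == b2.training_quality


def test_perfect_separator_reaches_ef_ceiling(rng):
    n, n_act = 1000, 20
    is_active = np.zeros(n, dtype=bool)
    is_active[rng.choice(n, n_act, replace=False)] = True
    values = rng.normal(size=(n, 4))
    values[:, 2] = np.where(is_active, 100.0, 0.0) + rng.normal(size=n)
    m = make_matrix(values, is_active)
    model = best_single_channel(m)
    assert model.training_ef == pytest.approx(50.0)


def test_tiny_separable_fixture_channel_recovered(tiny_separable):
    matrix = aggregate_poses(tiny_separable.raw, tiny_separable.labels)
    model = best_single_channel(matrix)
    ch = model.terms[0].channel
    assert (ch.score_type, ch.monomer) == ("CS", "B")


def test_optimize_single_channel_returns_unit_coefficient(rng):
    m = make_matrix(rng.normal(size=(40, 3)), [True] * 4 + [False] * 36)
    coefs, _ = optimize_coefficients(m.channels[:1], m)
    assert abs(coefs[0]) == 1.0


def test_optimize_never_below_single_channel_quality(rng):
    """Adding an exactly anti-correlated channel cannot hurt."""
    n = 100
    is_active = np.array([True] * 5 + [False] * 95)
    base = rng.normal(size=n)
    base[is_active] += 3.0
    values = np.column_stack([base, -base])
    m = make_matrix(values, is_active)
    single = best_single_channel(m)
    _, q2 = optimize_coefficients(m.channels, m,
                                  lead_sign=single.terms[0].coefficient)
    assert q2 >= single.training_quality


def test_grid_search_matches_exhaustive_enumeration(rng):
    """On a coarse grid, the fitted second coefficient attains the same
    quality as brute-force enumeration over that grid."""
    n = 20
    is_active = np.array([True] * 4 + [False] * 16)
    values = rng.normal(size=(n, 2))
    values[is_active, 0] += 1.0
    values[is_active, 1] += 1.5
    m = make_matrix(values, is_active)
    config = SearchConfig(grid_points=11, refine_budget=0)
    coefs, q = optimize_coefficients(m.channels, m, config=config,
                                     lead_sign=1.0)
    # brute-force oracle over the identical grid
    ids = m.ligand_ids
    best = None
    for g in config.grid():
        scores = values[:, 0] + g * values[:, 1]
        qq = quality(Ranking.from_scores(scores, ids), is_active)
        best = qq if best is None or qq > best else best
    assert q == best


def test_incremental_stops_at_ceiling(rng):
    n, n_act = 500, 10
    is_active = np.zeros(n, dtype=bool)
    is_active[rng.choice(n, n_act, replace=False)] = True
    values = rng.normal(size=(n, 6))
    values[:, 0] = np.where(is_active, 1000.0, 0.0) + rng.normal(size=n)
    m = make_matrix(values, is_active)
    out = incremental_search(m)
    assert len(out.frontier) == 1


def test_complementary_channels_combined(complementary):
    matrix = aggregate_poses(complementary.raw, complementary.labels)
    out = incremental_search(matrix)
    best = out.best
    types = {t.channel.score_type for t in best.terms}
    assert {"CS", "CSOPT"} <= types
    singles = [m for m in out.candidates if len(m) == 1]
    assert best.training_quality > max(m.training_quality for m in singles)


def test_training_quality_nondecreasing_along_frontier(small_campaign):
    matrix = aggregate_poses(small_campaign.raw.slice(frame_ns=900),
                             small_campaign.labels)
    out = incremental_search(matrix)
    qualities = [m.training_quality for m in out.frontier]
    assert qualities == sorted(qualities)


def test_quality_invariant_under_channel_rescaling(rng):
    """Positively rescaling an input channel leaves the searched
    training quality unchanged (coefficients adapt on the grid)."""
    n = 120
    is_active = np.array([True] * 6 + [False] * (n - 6))
    values = rng.normal(size=(n, 4))
    values[is_active, 0] += 1.2
    values[is_active, 2] += 1.2
    m1 = make_matrix(values, is_active)
    scaled = values.copy()
    scaled[:, 2] *= 10.0
    m2 = make_matrix(scaled, is_active)
    q1 = incremental_search(m1).best.training_quality
    q2 = incremental_search(m2).best.training_quality
    assert q1[0] == pytest.approx(q2[0], abs=1e-9)


def test_model_invariants_enforced():
    from efoscreen.channels import ChannelKey
    ch = ChannelKey(100, "A", "CS", "BEST")
    with pytest.raises(ValueError, match="±1.00"):
        ConsensusModel(terms=(ConsensusTerm(0.5, ch),))
    with pytest.raises(ValueError, match="non-zero"):
        ConsensusTerm(0.0, ch)


def test_model_json_round_trip(small_campaign):
    """to_dict/from_dict preserve terms, channels and validation."""
    import json
    matrix = aggregate_poses(small_campaign.raw.slice(frame_ns=700),
                             small_campaign.labels)
    from efoscreen import ValidationPlan
    res = EFOConsensus(matrix, config=SearchConfig(grid_points=7,
                                                   refine_budget=20)).fit(
        validation=ValidationPlan(repetitions=2), n_validate=3)
    payload = json.loads(json.dumps(res.best.to_dict()))
    back = ConsensusModel.from_dict(payload)
    assert back.terms == res.best.terms
    assert back.validated_ef == res.best.validated_ef


def test_results_summary_mentions_best_equation(small_campaign):
    matrix = aggregate_poses(small_campaign.raw.slice(frame_ns=900),
                             small_campaign.labels)
    res = EFOConsensus(matrix).fit()
    text = res.summary()
    assert res.best.equation().split()[-1] in text
    assert "candidates evaluated" in text
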