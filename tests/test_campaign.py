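"""Suitability filters, validation, y-scrambling, multi-frame consensus."""

import numpy as np
import pandas as pd
import pytest

from efoscreen import (DataError, SearchConfig, ValidationPlan,
                       aggregate_poses, best_single_channel, filter_frame,
                       filter_monomer, incremental_search,
                       multiframe_consensus, run_frame_campaign,
                       validate_models, y_scramble)
from efoscreen.campaign import MonomerVerdict
from efoscreen.channels import PoseScoreTable
from efoscreen.efo import EFOConsensus

from conftest import make_matrix

FAST = SearchConfig(max_vars=2, grid_points=7, refine_budget=20)
PLAN2 = ValidationPlan(repetitions=2, base_seed=0)


def failure_table(n_failed_actives, n_actives=20, n_decoys=30):
    """One (frame, monomer) slice where the first ``n_failed_actives``
    actives have no poses at all."""
    ids = [f"A{i:02d}" for i in range(n_actives)] + \
          [f"D{i:02d}" for i in range(n_decoys)]
    labels = pd.DataFrame({"ligand_id": ids,
                           "active": [1] * n_actives + [0] * n_decoys})
    rows = [(lig, 100, "A", "CS", 1, 0.5) for lig in ids[n_failed_actives:]]
    return PoseScoreTable(df=pd.DataFrame(
        rows, columns=["ligand_id", "frame_ns", "monomer", "score_type",
                       "pose", "value"])), labels


@pytest.mark.parametrize("n_failed,discarded", [
    (0, False), (3, False), (4, True), (20, True)])
def test_monomer_discard_boundary(n_failed, discarded):
    """More than three unaccommodated actives discard the monomer."""
    table, labels = failure_table(n_failed)
    v = filter_monomer(table, labels, 100, "A")
    assert v.discarded is discarded
    assert v.accommodated_actives == 20 - n_failed


def verdicts(n_discarded):
    return [MonomerVerdict(100, m, 20 - 5 * d, 20, bool(d))
            for m, d in zip("ABCD", [1] * n_discarded +
                            [0] * (4 - n_discarded))]


@pytest.mark.parametrize("n_discarded,frame_gone", [
    (0, False), (2, False), (3, True), (4, True)])
def test_frame_discard_rule(n_discarded, frame_gone):
    assert filter_frame(verdicts(n_discarded)) is frame_gone


def test_frame_rule_requires_four_verdicts():
    with pytest.raises(DataError):
        filter_frame(verdicts(0)[:3])


def test_filter_idempotence(heavy_failures):
    """Re-running the filters on the filtered campaign changes nothing."""
    data = heavy_failures
    first = {(f, m): filter_monomer(data.raw, data.labels, f, m)
             for f in (50, 100) for m in "ABCD"}
    kept = {k for k, v in first.items() if not v.discarded}
    filtered_df = data.raw.df[[
        (f, m) in kept for f, m in zip(data.raw.df["frame_ns"],
                                       data.raw.df["monomer"])]]
    filtered = PoseScoreTable(df=filtered_df.reset_index(drop=True))
    again = {k: filter_monomer(filtered, data.labels, *k) for k in kept}
    assert all(not v.discarded for v in again.values())
    assert {k: first[k].accommodated_actives for k in kept} == \
        {k: v.accommodated_actives for k, v in again.items()}


def test_heavy_failures_fixture_verdicts(heavy_failures):
    """Planted failures reproduce the documented discard pattern."""
    data = heavy_failures
    discarded = {(f, m)
                 for f in (50, 100) for m in "ABCD"
                 if filter_monomer(data.raw, data.labels, f, m).discarded}
    assert discarded == {(50, "A"), (50, "C"), (50, "D"), (100, "D")}
    frame50 = [filter_monomer(data.raw, data.labels, 50, m) for m in "ABCD"]
    frame100 = [filter_monomer(data.raw, data.labels, 100, m)
                for m in "ABCD"]
    assert filter_frame(frame50) is True
    assert filter_frame(frame100) is False


def test_verdicts_match_planted_failure_list(small_campaign):
    """Filter verdicts agree with the generator's failure ground truth."""
    data = small_campaign
    actives = set(data.labels.loc[data.labels["active"] == 1, "ligand_id"])
    for f in (100, 300):
        for m in "ABCD":
            v = filter_monomer(data.raw, data.labels, f, m)
            planted = {lig for (var, ff, mm, lig) in data.truth.failures
                       if var == "RAW" and ff == f and mm == m
                       and lig in actives}
            assert v.accommodated_actives == len(actives) - len(planted)
            assert v.discarded is (len(planted) > 3)


def test_validation_perfect_separator_hits_test_ceiling(rng):
    n = 200
    is_active = np.zeros(n, dtype=bool)
    is_active[rng.choice(n, 10, replace=False)] = True
    values = rng.normal(size=(n, 3))
    values[:, 1] = np.where(is_active, 50.0, 0.0) + rng.normal(size=n)
    m = make_matrix(values, is_active)
    cand = [best_single_channel(m, config=FAST)]
    out = validate_models(cand, m, plan=ValidationPlan(repetitions=3),
                          config=FAST)
    # test sets: 60 ligands, 3 actives, n_top=1 -> EF ceiling 20
    assert out[0].validation.ef_values == (20.0, 20.0, 20.0)


def test_validation_deterministic_given_seed(small_campaign):
    data = small_campaign
    matrix = aggregate_poses(data.raw.slice(frame_ns=900), data.labels)
    r1 = EFOConsensus(matrix, config=FAST).fit(validation=PLAN2,
                                               n_validate=5)
    r2 = EFOConsensus(matrix, config=FAST).fit(validation=PLAN2,
                                               n_validate=5)
    assert [m.equation() for m in r1.validated] == \
        [m.equation() for m in r2.validated]
    assert r1.best.validated_ef == r2.best.validated_ef


def test_run_frame_campaign_discarded_frame_has_no_model(heavy_failures):
    data = heavy_failures
    res = run_frame_campaign(data.raw, data.labels, 50,
                             search_config=FAST, plan=PLAN2)
    assert res.frame_discarded and res.best_model is None
    assert res.report_row()["equation"] == "The frame was fully discarded"


def test_discarded_monomer_never_in_equation(heavy_failures):
    data = heavy_failures
    res = run_frame_campaign(data.raw, data.labels, 100,
                             search_config=FAST, plan=PLAN2)
    assert not res.frame_discarded
    assert all(t.channel.monomer != "D" for t in res.best_model.terms)


def test_planted_quality_orders_frame_performance(small_campaign):
    """A high-equilibration frame outperforms a low-quality one from the
    same campaign."""
    data = small_campaign
    lo = run_frame_campaign(data.raw, data.labels, 100,
                            search_config=FAST, plan=PLAN2)
    hi = run_frame_campaign(data.raw, data.labels, 900,
                            search_config=FAST, plan=PLAN2)
    assert data.truth.frame_quality[900] > data.truth.frame_quality[100]
    assert hi.validated_ef > lo.validated_ef


def test_y_scramble_repetition_matches_manual_rerun(small_campaign):
    """Each scrambling repetition equals an independent rerun with that
    permutation (K=1 semantics); an identity permutation would
    reproduce the unscrambled result by the same construction."""
    data = small_campaign
    matrix = aggregate_poses(data.raw.slice(frame_ns=900), data.labels)
    out = y_scramble(matrix, repetitions=1, seed=42, search_config=FAST,
                     plan=PLAN2, n_validate=5)
    rng = np.random.default_rng(42)
    permuted = matrix.is_active[rng.permutation(matrix.n_ligands)]
    manual = EFOConsensus(matrix, config=FAST, labels=permuted).fit(
        validation=PLAN2, n_validate=5)
    assert out["ef_values"] == [manual.best.validated_ef]
    identity = EFOConsensus(matrix, config=FAST,
                            labels=matrix.is_active).fit(
        validation=PLAN2, n_validate=5)
    assert identity.best.validated_ef == out["unscrambled_ef"]


def test_multiframe_threshold_selects_frames(small_campaign):
    data = small_campaign
    results = [run_frame_campaign(data.raw, data.labels, f,
                                  search_config=FAST, plan=PLAN2)
               for f in (100, 900)]
    matrix = aggregate_poses(data.raw, data.labels)
    threshold = (results[0].validated_ef + results[1].validated_ef) / 2
    rep = multiframe_consensus(results, matrix, ef_threshold=threshold,
                               search_config=FAST, plan=PLAN2,
                               n_validate=10)
    assert rep.selected_frames == (900,)
    assert set(rep.frame_occurrence) == {900}
    with pytest.raises(DataError, match="threshold"):
        multiframe_consensus(results, matrix, ef_threshold=1000.0,
                             search_config=FAST, plan=PLAN2)


def test_multiframe_subset_restriction(small_campaign):
    data = small_campaign
    results = [run_frame_campaign(data.raw, data.labels, f,
                                  search_config=FAST, plan=PLAN2)
               for f in (700, 900)]
    matrix = aggregate_poses(data.raw, data.labels)
    rep = multiframe_consensus(results, matrix, ef_threshold=0.0,
                               monomer="B", search_config=FAST,
                               plan=PLAN2, n_validate=10)
    assert all(t.channel.monomer == "B"
               for m in rep.top_models for t in m.terms)
    rep2 = multiframe_consensus(results, matrix, ef_threshold=0.0,
                                aggregation="MEAN", search_config=FAST,
                                plan=PLAN2, n_validate=10)
    assert all(t.channel.aggregation == "MEAN"
               for m in rep2.top_models for t in m.terms)


def test_pool_inclusion_monotonicity(rng):
    """Enlarging the variable pool never lowers best training quality."""
    n = 150
    is_active = np.zeros(n, dtype=bool)
    is_active[rng.choice(n, 6, replace=False)] = True
    values = rng.normal(size=(n, 12))
    values[is_active, 2] += 1.5
    values[is_active, 9] += 1.0
    m_all = make_matrix(values, is_active)
    m_small = m_all.restrict(keys=m_all.channels[:6])
    q_small = incremental_search(m_small, config=FAST).best.training_quality
    q_all = incremental_search(m_all, config=FAST).best.training_quality
    assert q_all >= q_small
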