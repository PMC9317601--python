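"""Per-frame virtual-screening campaigns and multi-frame consensus.

A campaign walks every MD frame of a preparation variant through:
suitability filters (a monomer is dropped when docking failed to place
more than three actives; a frame is dropped when more than two monomers
are unsuitable), the incremental consensus search restricted to the
surviving channels, repeated stratified 70/30 validation that re-ranks
the candidate models by mean test EF1%, and optional y-scrambling.  A
multi-frame consensus pools the channels of the frames whose validated
EF1% clears a threshold and searches over the pooled variable set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .channels import (DataError, MONOMERS, PoseScoreTable, ScreeningMatrix,
                       aggregate_poses, _normalize_labels)
from .efo import (ConsensusModel, ConsensusTerm, EFOConsensus, SearchConfig,
                  ValidationSummary, optimize_coefficients, rank_ligands)
from .metrics import ef_at


@dataclass(frozen=True)
class MonomerVerdict:
    """Suitability of one monomer of one frame for model building."""

    frame_ns: int
    monomer: str
    accommodated_actives: int
    n_actives: int
    discarded: bool


@dataclass(frozen=True)
class ValidationPlan:
    """Repeated stratified train/test validation settings."""

    train_fraction: float = 0.70
    repetitions: int = 5
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    def splits(self, is_active: np.ndarray):
        """Yield (train_idx, test_idx) pairs, identical across calls."""
        n = len(is_active)
        if self.stratified:
            splitter = StratifiedShuffleSplit(
                n_splits=self.repetitions,
                train_size=self.train_fraction,
                random_state=self.base_seed)
            yield from splitter.split(np.zeros(n), is_active.astype(int))
        else:
            rng = np.random.default_rng(self.base_seed)
            n_train = int(round(self.train_fraction * n))
            for _ in range(self.repetitions):
                perm = rng.permutation(n)
                yield perm[:n_train], perm[n_train:]


@dataclass
class FrameCampaignResult:
    """Outcome of one frame's screening campaign."""

    frame_ns: int
    variant: str
    verdicts: tuple
    frame_discarded: bool
    best_model: ConsensusModel | None = None
    validated_ef: float | None = None
    candidates: list = field(default_factory=list)

    @property
    def equation(self) -> str | None:
        return None if self.best_model is None else self.best_model.equation()

    def report_row(self) -> dict:
        if self.frame_discarded:
            return {"frame_ns": self.frame_ns, "status": "discarded",
                    "ef1": None, "equation": "The frame was fully discarded"}
        return {"frame_ns": self.frame_ns, "status": "accepted",
                "ef1": self.validated_ef, "equation": self.equation}


def filter_monomer(table: PoseScoreTable, labels, frame_ns: int,
                   monomer: str, failure_threshold: int = 3) -> MonomerVerdict:
    """Verdict for one (frame, monomer).

    An active is "not accommodated" when it has zero poses on that
    monomer across all score types; the monomer is discarded when the
    number of such actives exceeds ``failure_threshold`` (default 3, so
    4 failures discard, 3 keep).
    """
    lab = _normalize_labels(labels)
    actives = set(lab.loc[lab["active"], "ligand_id"])
    df = table.df
    sel = (df["frame_ns"] == frame_ns) & (df["monomer"] == monomer)
    docked = set(df.loc[sel, "ligand_id"].astype(str))
    accommodated = len(actives & docked)
    failures = len(actives) - accommodated
    return MonomerVerdict(
        frame_ns=frame_ns, monomer=monomer,
        accommodated_actives=accommodated, n_actives=len(actives),
        discarded=failures > failure_threshold)


def filter_frame(verdicts: Sequence[MonomerVerdict]) -> bool:
    """True (frame discarded) iff more than two monomers are unsuitable."""
    if len(verdicts) != len(MONOMERS):
        raise DataError(f"expected {len(MONOMERS)} monomer verdicts, "
                        f"got {len(verdicts)}")
    return sum(v.discarded for v in verdicts) > 2


def validate_models(candidates: Sequence[ConsensusModel],
                    matrix: ScreeningMatrix, labels=None,
                    plan: ValidationPlan | None = None,
                    config: SearchConfig | None = None) -> list:
    """Re-rank candidate models by mean test EF over repeated splits.

    The variable set (and the leading sign) chosen on the full data is
    frozen; the free coefficients are re-fit on each training split and
    EF is measured on the corresponding test split.  The same splits are
    shared by all candidates.  Ties break by training quality, then by
    model size ascending.
    """
    if not candidates:
        raise DataError("no candidate models to validate")
    plan = plan or ValidationPlan()
    config = config or SearchConfig()
    is_active = (matrix.is_active if labels is None
                 else np.asarray(labels, dtype=bool))
    splits = list(plan.splits(is_active))
    for train, test in splits:
        if is_active[test].sum() == 0:
            raise DataError("validation split has no actives in the test set")

    def subset(idx):
        return ScreeningMatrix(
            ligand_ids=matrix.ligand_ids[idx],
            is_active=is_active[idx],
            channels=matrix.channels,
            values=matrix.values[idx],
            higher_is_better=dict(matrix.higher_is_better),
            provenance=dict(matrix.provenance), strict=False)

    alpha = config.quality.alpha
    validated = []
    train_mats = [subset(tr) for tr, _ in splits]
    test_mats = [subset(te) for _, te in splits]
    for model in candidates:
        efs = []
        for train_m, test_m in zip(train_mats, test_mats):
            coefs, _ = optimize_coefficients(
                model.channels, train_m, config=config,
                lead_sign=model.terms[0].coefficient,
                init=model.coefficients)
            refit = ConsensusModel(
                terms=tuple(ConsensusTerm(float(c), ch)
                            for c, ch in zip(coefs, model.channels)),
                training_quality=model.training_quality)
            ranking = rank_ligands(refit, test_m)
            efs.append(ef_at(ranking, test_m.is_active, alpha))
        summary = ValidationSummary(ef_values=tuple(efs),
                                    mean_ef=float(np.mean(efs)), plan=plan)
        validated.append(replace(model, validation=summary))
    validated.sort(key=lambda m: (m.validation.mean_ef,
                                  m.training_quality, -len(m)),
                   reverse=True)
    return validated


def run_frame_campaign(table: PoseScoreTable, labels, frame_ns: int,
                       search_config: SearchConfig | None = None,
                       plan: ValidationPlan | None = None,
                       failure_threshold: int = 3,
                       n_validate: int | None = 10) -> FrameCampaignResult:
    """Filters -> matrix restriction -> incremental search -> validation
    for a single frame of one variant."""
    search_config = search_config or SearchConfig()
    plan = plan or ValidationPlan()
    verdicts = tuple(
        filter_monomer(table, labels, frame_ns, m, failure_threshold)
        for m in MONOMERS)
    if filter_frame(verdicts):
        return FrameCampaignResult(frame_ns=frame_ns, variant=table.variant,
                                   verdicts=verdicts, frame_discarded=True)
    kept = {v.monomer for v in verdicts if not v.discarded}
    frame_table = table.slice(frame_ns=frame_ns)
    frame_table = replace(
        frame_table,
        df=frame_table.df[frame_table.df["monomer"].isin(kept)]
        .reset_index(drop=True))
    matrix = aggregate_poses(frame_table, labels)
    results = EFOConsensus(matrix, config=search_config).fit(
        validation=plan, n_validate=n_validate)
    best = results.best
    return FrameCampaignResult(
        frame_ns=frame_ns, variant=table.variant, verdicts=verdicts,
        frame_discarded=False, best_model=best,
        validated_ef=best.validated_ef,
        candidates=results.validated or results.candidates)


def run_campaign(table: PoseScoreTable, labels,
                 search_config: SearchConfig | None = None,
                 plan: ValidationPlan | None = None,
                 failure_threshold: int = 3,
                 n_validate: int | None = 10,
                 progress=None) -> list:
    """Per-frame campaigns for every frame of one variant's pose table."""
    results = []
    for frame_ns in table.frame_times:
        res = run_frame_campaign(table, labels, int(frame_ns),
                                 search_config=search_config, plan=plan,
                                 failure_threshold=failure_threshold,
                                 n_validate=n_validate)
        results.append(res)
        if progress is not None:
            progress(res)
    return results


def campaign_report(results: Sequence[FrameCampaignResult]) -> pd.DataFrame:
    """Table-shaped report: one row per frame (frame_ns, status, ef1,
    equation)."""
    return pd.DataFrame([r.report_row() for r in results])


def y_scramble(matrix: ScreeningMatrix, labels=None, repetitions: int = 20,
               seed: int = 0, search_config: SearchConfig | None = None,
               plan: ValidationPlan | None = None,
               n_validate: int | None = 10) -> dict:
    """Chance-level baseline: permute activity labels, rerun search +
    validation, record the best validated EF per repetition.

    Returns {"mean_ef", "ef_values", "unscrambled_ef"}.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    search_config = search_config or SearchConfig()
    plan = plan or ValidationPlan()
    base = (matrix.is_active if labels is None
            else np.asarray(labels, dtype=bool))
    rng = np.random.default_rng(seed)
    efs = []
    for _ in range(repetitions):
        permuted = base[rng.permutation(len(base))]
        res = EFOConsensus(matrix, config=search_config,
                           labels=permuted).fit(validation=plan,
                                                n_validate=n_validate)
        efs.append(res.best.validated_ef)
    res_true = EFOConsensus(matrix, config=search_config,
                            labels=base).fit(validation=plan,
                                             n_validate=n_validate)
    return {"mean_ef": float(np.mean(efs)), "ef_values": efs,
            "unscrambled_ef": res_true.best.validated_ef}


@dataclass
class MultiFrameReport:
    """Multi-frame consensus outcome for one channel-subset selector."""

    subset: str
    selected_frames: tuple
    best_model: ConsensusModel
    best_ef: float
    top_models: list
    top_mean_ef: float
    n_top: int
    frame_occurrence: dict


def multiframe_consensus(frame_results: Sequence[FrameCampaignResult],
                         matrix: ScreeningMatrix, labels=None,
                         ef_threshold: float = 30.0,
                         monomer: str | None = None,
                         aggregation: str | None = None,
                         search_config: SearchConfig | None = None,
                         plan: ValidationPlan | None = None,
                         n_top_models: int = 20,
                         n_validate: int | None = 40) -> MultiFrameReport:
    """Consensus over the channels of the high-performing frames.

    Frames with validated EF1% strictly above ``ef_threshold`` define
    the variable pool, optionally restricted to one monomer or to
    BEST-/MEAN-only channels.  Reports the best validated EF1%, the
    mean over the best ``n_top_models`` validated models, and how often
    each selected frame occurs in those top models.
    """
    search_config = search_config or SearchConfig()
    plan = plan or ValidationPlan()
    selected = tuple(r.frame_ns for r in frame_results
                     if not r.frame_discarded
                     and r.validated_ef is not None
                     and r.validated_ef > ef_threshold)
    if not selected:
        raise DataError(
            f"no frame passes the EF threshold {ef_threshold}")
    kept_monomers = {
        r.frame_ns: {v.monomer for v in r.verdicts if not v.discarded}
        for r in frame_results}

    def keep(c):
        if c.frame_ns not in selected:
            return False
        if c.monomer not in kept_monomers.get(c.frame_ns, set(MONOMERS)):
            return False
        if monomer is not None and c.monomer != monomer:
            return False
        if aggregation is not None and c.aggregation != aggregation:
            return False
        return True

    try:
        pool = matrix.restrict(predicate=keep)
    except DataError:
        raise DataError(
            f"channel pool empty after restriction "
            f"(monomer={monomer}, aggregation={aggregation})") from None
    results = EFOConsensus(pool, config=search_config,
                           labels=labels).fit(validation=plan,
                                              n_validate=n_validate)
    validated = results.validated
    top = validated[:n_top_models]
    occurrence = {}
    for f in selected:
        occurrence[f] = sum(
            1 for m in top if any(t.channel.frame_ns == f for t in m.terms))
    label = "all"
    if monomer is not None:
        label = f"monomer {monomer}"
    elif aggregation is not None:
        label = f"{aggregation.lower()} scores"
    return MultiFrameReport(
        subset=label, selected_frames=selected,
        best_model=validated[0], best_ef=validated[0].validated_ef,
        top_models=top, top_mean_ef=float(np.mean(
            [m.validated_ef for m in top])),
        n_top=len(top), frame_occurrence=occurrence)


def multiframe_report_table(reports: Sequence[MultiFrameReport]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subset": r.subset, "best_ef1": r.best_ef,
         "top_mean_ef1": r.top_mean_ef, "n_models": r.n_top}
        for r in reports])
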