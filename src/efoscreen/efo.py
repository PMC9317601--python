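"""Incremental enrichment-factor-optimizing (EFO) consensus search.

A consensus model is an ordered signed linear combination of score
channels, at most ``max_vars`` of them, whose leading coefficient is
fixed at ±1.00 (rankings are scale-invariant, so one degree of freedom
is removable).  The search grows models greedily: start from the best
single channel, then repeatedly try every remaining channel as the next
variable, optimizing its coefficient on a signed log-spaced grid
followed by derivative-free coordinate refinement, and stop as soon as
no candidate strictly improves the quality key.  The quality function is
piecewise constant in the coefficients (it depends on the ranking only),
which rules out gradient methods by construction.

The module surface follows the Model/Results idiom: ``EFOConsensus`` is
built from a ScreeningMatrix and fitted with :meth:`EFOConsensus.fit`,
which returns an :class:`EFOResults` carrying the candidate models, the
greedy frontier, optional validation summaries and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .channels import ChannelKey, DataError, ScreeningMatrix
from .equations import format_equation
from .metrics import QualityConfig, Ranking, fast_quality, top_set_size


@dataclass(frozen=True)
class ConsensusTerm:
    """A signed coefficient attached to one score channel."""

    coefficient: float
    channel: ChannelKey

    def __post_init__(self) -> None:
        if self.coefficient == 0:
            raise ValueError("consensus term coefficient must be non-zero")


@dataclass(frozen=True)
class ValidationSummary:
    """Mean test-set EF over repeated stratified splits."""

    ef_values: tuple
    mean_ef: float
    plan: object = None


@dataclass(frozen=True)
class ConsensusModel:
    """An ordered signed linear combination of score channels.

    The first term's coefficient is ±1.00 exactly; channels are
    distinct.  ``training_quality`` is the quality tuple on the data the
    model was searched on; ``validation`` (if present) holds the
    per-split and mean test EF from repeated 70/30 validation.
    """

    terms: tuple
    training_quality: tuple = ()
    validation: ValidationSummary | None = None
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a consensus model needs at least one term")
        if abs(abs(self.terms[0].coefficient) - 1.0) > 1e-12:
            raise ValueError("leading coefficient must be ±1.00")
        chans = [t.channel for t in self.terms]
        if len(set(chans)) != len(chans):
            raise ValueError("model channels must be distinct")

    @property
    def channels(self) -> tuple:
        return tuple(t.channel for t in self.terms)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([t.coefficient for t in self.terms])

    @property
    def training_ef(self) -> float:
        return float(self.training_quality[0]) if self.training_quality else float("nan")

    @property
    def validated_ef(self) -> float | None:
        return None if self.validation is None else self.validation.mean_ef

    def equation(self) -> str:
        return format_equation(self)

    def to_dict(self) -> dict:
        """JSON-ready representation (terms, metrics, provenance)."""
        return {
            "terms": [{"coefficient": t.coefficient,
                       "channel": t.channel.to_string()}
                      for t in self.terms],
            "equation": self.equation(),
            "training_quality": list(self.training_quality),
            "validated_ef": self.validated_ef,
            "validation_ef_values": (list(self.validation.ef_values)
                                     if self.validation else None),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ConsensusModel":
        terms = tuple(
            ConsensusTerm(coefficient=float(t["coefficient"]),
                          channel=ChannelKey.from_string(t["channel"]))
            for t in payload["terms"])
        validation = None
        if payload.get("validation_ef_values") is not None:
            validation = ValidationSummary(
                ef_values=tuple(payload["validation_ef_values"]),
                mean_ef=float(payload["validated_ef"]))
        return cls(terms=terms,
                   training_quality=tuple(payload.get("training_quality",
                                                      ())),
                   validation=validation,
                   provenance=dict(payload.get("provenance", {})))

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class SearchConfig:
    """Tunables of the incremental search.

    The coefficient grid spans signed log-spaced magnitudes
    [grid_min, grid_max] with grid_points per sign; refinement is a
    deterministic multiplicative pattern search capped at refine_budget
    quality evaluations per model.
    """

    max_vars: int = 3
    grid_min: float = 0.01
    grid_max: float = 100.0
    grid_points: int = 25
    refine_budget: int = 200
    #: off-grid multiplicative pattern search after the on-grid
    #: coordinate descent; disable to keep every coefficient on the grid
    off_grid_refine: bool = True
    seed: int = 0
    quality: QualityConfig = field(default_factory=QualityConfig)

    def __post_init__(self) -> None:
        if self.max_vars < 1:
            raise ValueError("max_vars must be >= 1")
        if self.grid_points < 1 or self.grid_min <= 0 or \
                self.grid_max < self.grid_min:
            raise ValueError("invalid coefficient grid specification")

    def grid(self) -> np.ndarray:
        mags = np.geomspace(self.grid_min, self.grid_max, self.grid_points)
        return np.concatenate([mags, -mags])


def score_ligands(model: ConsensusModel,
                  matrix: ScreeningMatrix) -> np.ndarray:
    """Consensus score per ligand (aligned with matrix.ligand_ids),
    missing channel values imputed by the matrix policy."""
    idx = [matrix.channel_index(t.channel) for t in model.terms]
    X = matrix.imputed()
    return X[:, idx] @ model.coefficients


def rank_ligands(model: ConsensusModel, matrix: ScreeningMatrix) -> Ranking:
    return Ranking.from_scores(score_ligands(model, matrix),
                               matrix.ligand_ids)


class _Evaluator:
    """Shared state for fast quality evaluation during a search."""

    def __init__(self, matrix: ScreeningMatrix, labels=None,
                 quality: QualityConfig | None = None):
        self.matrix = matrix
        self.X = matrix.imputed()
        self.is_active = (np.asarray(labels, dtype=bool)
                          if labels is not None else matrix.is_active)
        if len(self.is_active) != matrix.n_ligands:
            raise DataError("labels length does not match matrix")
        self.quality = quality or QualityConfig()
        self.id_sorter = np.argsort(matrix.ligand_ids, kind="stable")
        self.n_top = top_set_size(matrix.n_ligands, self.quality.alpha)
        self.a_total = int(self.is_active.sum())
        self.n_evals = 0

    def evaluate(self, cols: Sequence[int], coefs: np.ndarray) -> tuple:
        self.n_evals += 1
        scores = self.X[:, list(cols)] @ np.asarray(coefs, dtype=float)
        return fast_quality(scores, self.is_active, self.id_sorter,
                            self.n_top, self.a_total,
                            self.quality.skew_weight)


def best_single_channel(matrix: ScreeningMatrix, labels=None,
                        config: SearchConfig | None = None) -> ConsensusModel:
    """The single channel and sign (±1.00) maximizing the quality key;
    ties broken by canonical ChannelKey order (sign + before -)."""
    config = config or SearchConfig()
    ev = _Evaluator(matrix, labels, config.quality)
    best = None
    for j, key in enumerate(matrix.channels):
        for sign in (1.0, -1.0):
            q = ev.evaluate([j], np.array([sign]))
            tiebreak = (-sign, key.sort_key())
            if best is None or q > best[0] or \
                    (q == best[0] and tiebreak < best[3]):
                best = (q, j, sign, tiebreak)
    q, j, sign, _ = best
    return ConsensusModel(
        terms=(ConsensusTerm(coefficient=sign,
                             channel=matrix.channels[j]),),
        training_quality=q,
        provenance={"pool_size": len(matrix.channels)})


def _refine(ev: _Evaluator, cols: list, coefs: np.ndarray,
            best_q: tuple, config: SearchConfig):
    """Polish the free coefficients (all but the leading ±1).

    First joint coordinate descent over the signed grid (sweeps until
    stable), then an optional deterministic multiplicative pattern
    search off the grid; both capped by the shared evaluation budget.
    """
    budget = config.refine_budget
    used = 0
    if len(cols) > 1 and budget > 0:
        grid = config.grid()
        moved = True
        while moved and used < budget:
            moved = False
            for j in range(1, len(cols)):
                trial = coefs.copy()
                for g in grid:
                    if used >= budget:
                        break
                    trial[j] = g
                    q = ev.evaluate(cols, trial)
                    used += 1
                    if q > best_q:
                        best_q = q
                        coefs = trial.copy()
                        moved = True
    if not config.off_grid_refine:
        return coefs, best_q
    factors = (1.6, 1.25, 1.1)
    improved = True
    while improved and used < budget:
        improved = False
        for f in factors:
            for j in range(1, len(cols)):
                for mult in (f, 1.0 / f):
                    if used >= budget:
                        return coefs, best_q
                    trial = coefs.copy()
                    trial[j] *= mult
                    q = ev.evaluate(cols, trial)
                    used += 1
                    if q > best_q:
                        best_q, coefs = q, trial
                        improved = True
    return coefs, best_q


def optimize_coefficients(channels: Sequence[ChannelKey],
                          matrix: ScreeningMatrix, labels=None,
                          config: SearchConfig | None = None,
                          lead_sign: float | None = None,
                          init: Sequence[float] | None = None):
    """Fit coefficients for a fixed ordered channel set.

    The leading coefficient is pinned to ±1.00 (sign from the best
    single-channel orientation unless given); each further coefficient
    is seeded by a signed log-spaced grid search with the others held
    fixed, then all free coefficients are polished by pattern search.
    Returns (coefficients, quality).
    """
    config = config or SearchConfig()
    if not 1 <= len(channels) <= config.max_vars:
        raise ValueError(
            f"need 1..{config.max_vars} channels, got {len(channels)}")
    ev = _Evaluator(matrix, labels, config.quality)
    cols = [matrix.channel_index(c) for c in channels]
    if lead_sign is None:
        q_plus = ev.evaluate(cols[:1], np.array([1.0]))
        q_minus = ev.evaluate(cols[:1], np.array([-1.0]))
        lead_sign = 1.0 if q_plus >= q_minus else -1.0
    coefs = np.zeros(len(cols))
    coefs[0] = lead_sign
    if len(cols) == 1:
        return coefs, ev.evaluate(cols, coefs)
    grid = config.grid()
    if init is not None:
        coefs[1:] = np.asarray(init, dtype=float)[1:]
        best_q = ev.evaluate(cols, coefs)
    else:
        best_q = None
        for j in range(1, len(cols)):
            probe = coefs.copy()
            sub = cols[: j + 1]
            best_c, best_sub_q = None, None
            for g in grid:
                probe[j] = g
                q = ev.evaluate(sub, probe[: j + 1])
                if best_sub_q is None or q > best_sub_q:
                    best_sub_q, best_c = q, g
            coefs[j] = best_c
            best_q = best_sub_q
    coefs, best_q = _refine(ev, cols, coefs, best_q, config)
    return coefs, best_q


@dataclass
class SearchOutcome:
    """Everything the incremental search evaluated.

    ``frontier`` holds the best model at each size along the greedy
    path; ``candidates`` holds the best model found for every distinct
    channel set that was tried, sorted by training quality (descending).
    """

    frontier: list
    candidates: list

    @property
    def best(self) -> ConsensusModel:
        return max(self.frontier, key=lambda m: m.training_quality)


def incremental_search(matrix: ScreeningMatrix, labels=None,
                       config: SearchConfig | None = None) -> SearchOutcome:
    """Greedy incremental consensus-model generation.

    Grows the current best model one variable at a time, re-optimizing
    the new coefficient for every remaining channel on the grid (the
    winning candidate also gets full pattern-search refinement), and
    stops when no candidate strictly improves the quality key or
    ``max_vars`` is reached.
    """
    config = config or SearchConfig()
    ev = _Evaluator(matrix, labels, config.quality)
    grid = config.grid()

    candidates: dict[frozenset, ConsensusModel] = {}

    def record(cols: tuple, coefs: np.ndarray, q: tuple) -> ConsensusModel:
        model = ConsensusModel(
            terms=tuple(ConsensusTerm(float(c), matrix.channels[j])
                        for c, j in zip(coefs, cols)),
            training_quality=q,
            provenance={"pool_size": len(matrix.channels)})
        key = frozenset(cols)
        prev = candidates.get(key)
        if prev is None or q > prev.training_quality:
            candidates[key] = model
        return model

    # size 1: every (channel, sign); ties prefer +1, then ChannelKey order
    best1 = None
    for j, key in enumerate(matrix.channels):
        for sign in (1.0, -1.0):
            q = ev.evaluate([j], np.array([sign]))
            record((j,), np.array([sign]), q)
            tiebreak = (-sign, key.sort_key())
            if best1 is None or q > best1[0] or \
                    (q == best1[0] and tiebreak < best1[3]):
                best1 = (q, j, sign, tiebreak)
    q_best, j_best, sign_best, _ = best1
    frontier_cols = [j_best]
    frontier_coefs = np.array([sign_best])
    frontier_q = q_best
    frontier = [candidates[frozenset(frontier_cols)]]

    while len(frontier_cols) < config.max_vars:
        best_cand = None
        for j in range(len(matrix.channels)):
            if j in frontier_cols:
                continue
            cols = frontier_cols + [j]
            best_c, best_cq = None, None
            probe = np.append(frontier_coefs, 0.0)
            for g in grid:
                probe[-1] = g
                q = ev.evaluate(cols, probe)
                if best_cq is None or q > best_cq:
                    best_cq, best_c = q, g
            coefs = np.append(frontier_coefs, best_c)
            record(tuple(cols), coefs, best_cq)
            if best_cand is None or best_cq > best_cand[0]:
                best_cand = (best_cq, j, coefs)
        if best_cand is None:
            break
        cq, j, coefs = best_cand
        cols = frontier_cols + [j]
        coefs, cq = _refine(ev, cols, coefs.copy(), cq, config)
        record(tuple(cols), coefs, cq)
        if cq <= frontier_q:
            break  # stop rule: no strict improvement
        frontier_cols, frontier_coefs, frontier_q = cols, coefs, cq
        frontier.append(candidates[frozenset(cols)])

    ranked = sorted(candidates.values(),
                    key=lambda m: (m.training_quality, -len(m)),
                    reverse=True)
    return SearchOutcome(frontier=frontier, candidates=ranked)


class EFOConsensus:
    """Consensus-scoring model over a screening matrix.

    Parameters
    ----------
    matrix : ScreeningMatrix
        Ligands x channels matrix; its activity labels are used unless
        ``labels`` overrides them (e.g. for y-scrambling).
    config : SearchConfig, optional
    labels : array-like of bool, optional
    """

    def __init__(self, matrix: ScreeningMatrix,
                 config: SearchConfig | None = None, labels=None):
        self.matrix = matrix
        self.config = config or SearchConfig()
        self.labels = (matrix.is_active if labels is None
                       else np.asarray(labels, dtype=bool))

    @classmethod
    def from_pose_tables(cls, tables, labels,
                         config: SearchConfig | None = None):
        from .channels import build_matrix
        return cls(build_matrix(tables, labels), config=config)

    def fit(self, validation=None, n_validate: int | None = None,
            seed: int | None = None) -> "EFOResults":
        """Run the incremental search; optionally validate candidates.

        ``validation`` is a campaign.ValidationPlan; when given, the top
        ``n_validate`` candidates by training quality (default: all) are
        re-fit on repeated stratified 70/30 splits and re-ranked by mean
        test EF.
        """
        config = self.config
        if seed is not None:
            config = replace(config, seed=seed)
        outcome = incremental_search(self.matrix, self.labels, config)
        validated = None
        if validation is not None:
            from .campaign import validate_models
            pool = outcome.candidates
            if n_validate is not None:
                pool = pool[:n_validate]
            validated = validate_models(pool, self.matrix, self.labels,
                                        validation, config=config)
        return EFOResults(model=self, outcome=outcome, validated=validated)


class EFOResults:
    """Fit results: candidate consensus models and their diagnostics."""

    def __init__(self, model: EFOConsensus, outcome: SearchOutcome,
                 validated=None):
        self.model = model
        self.outcome = outcome
        self.validated = validated

    @property
    def frontier(self) -> list:
        return self.outcome.frontier

    @property
    def candidates(self) -> list:
        return self.outcome.candidates

    @property
    def best(self) -> ConsensusModel:
        if self.validated:
            return self.validated[0]
        return self.outcome.best

    def ranking(self, model: ConsensusModel | None = None) -> Ranking:
        return rank_ligands(model or self.best, self.model.matrix)

    def summary(self, top: int = 10) -> str:
        lines = [
            "EFO consensus search results",
            "=" * 64,
            f"ligands: {self.model.matrix.n_ligands}   "
            f"actives: {int(np.asarray(self.model.labels).sum())}   "
            f"channels: {len(self.model.matrix.channels)}",
            f"max_vars: {self.model.config.max_vars}   "
            f"candidates evaluated: {len(self.candidates)}",
            "-" * 64,
        ]
        shown = self.validated if self.validated else self.candidates
        header = f"{'rank':>4}  {'EF(train)':>9}  {'EF(valid)':>9}  equation"
        lines.append(header)
        for i, m in enumerate(shown[:top], 1):
            vef = f"{m.validated_ef:9.2f}" if m.validation else " " * 9
            lines.append(
                f"{i:>4}  {m.training_ef:9.2f}  {vef}  {m.equation()}")
        lines.append("=" * 64)
        return "\n".join(lines)
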