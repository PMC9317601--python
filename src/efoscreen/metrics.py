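"""Early-recognition and classification metrics over ligand rankings.

The central quantity is the enrichment factor at a top fraction alpha
(EF1% for alpha = 0.01): the active rate inside the top alpha·N of a
ranking divided by the active rate in the whole library.  A composite
quality — EF first, a rank-skewness statistic of the actives' positions
as tie-breaker — is the objective maximized by the consensus search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. no actives)."""


@dataclass(frozen=True)
class Ranking:
    """A deterministic ordering of the ligand set, best first.

    ``ligand_ids`` is the canonical (sorted) ligand array; ``order``
    indexes into it.  Ties in the score vector are broken by ligand_id
    via a stable sort on the pre-sorted array, so a ranking is a pure
    function of (scores, ligand_ids).
    """

    ligand_ids: np.ndarray
    order: np.ndarray
    scores: np.ndarray
    tie_break: str = "stable-ligand-id"

    @classmethod
    def from_scores(cls, scores, ligand_ids) -> "Ranking":
        scores = np.asarray(scores, dtype=float)
        ligand_ids = np.asarray(ligand_ids, dtype=object)
        if np.isnan(scores).any():
            raise UndefinedMetricError("scores contain NaN; impute first")
        sort_idx = np.argsort(ligand_ids, kind="stable")
        # stable sort of -score over the id-sorted array => ties by id
        order = sort_idx[np.argsort(-scores[sort_idx], kind="stable")]
        return cls(ligand_ids=ligand_ids, order=order, scores=scores)

    @property
    def ordered_ids(self) -> np.ndarray:
        return self.ligand_ids[self.order]

    def __len__(self) -> int:
        return len(self.order)


@dataclass(frozen=True)
class QualityConfig:
    """Configuration of the search objective.

    alpha is the top fraction for the EF term (default 1%).  With
    skew_weight 0 the quality is the lexicographic pair (EF, skew); a
    positive weight switches to the scalar EF + skew_weight * skew.
    """

    alpha: float = 0.01
    skew_weight: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.skew_weight < 0:
            raise ValueError("skew_weight must be >= 0")


def top_set_size(n: int, alpha: float) -> int:
    """Half-up rounding of alpha*n, minimum 1 (1000 at 1% -> 10)."""
    return max(1, int(np.floor(alpha * n + 0.5)))


def _as_active(labels) -> np.ndarray:
    return np.asarray(labels, dtype=bool)


def ef_at(ranking: Ranking, labels, alpha: float = 0.01) -> float:
    """Enrichment factor at the top ``alpha`` fraction.

    EF = (a_top/n_top) / (A/N) with a_top the actives among the first
    n_top = round(alpha*N) ligands; bounded by min(1/alpha, N/A).
    """
    act = _as_active(labels)
    n = len(act)
    a_total = int(act.sum())
    if a_total == 0:
        raise UndefinedMetricError("EF undefined: no actives in labels")
    n_top = top_set_size(n, alpha)
    a_top = int(act[ranking.order[:n_top]].sum())
    return (a_top / n_top) / (a_total / n)


def actives_in_top_fraction(ranking: Ranking, labels,
                            alpha: float = 0.01) -> float:
    """Percentage of the top-alpha set that is active (Table-7 style)."""
    act = _as_active(labels)
    if act.sum() == 0:
        raise UndefinedMetricError("metric undefined: no actives")
    n_top = top_set_size(len(act), alpha)
    a_top = int(act[ranking.order[:n_top]].sum())
    return 100.0 * a_top / n_top


def classification_metrics(ranking: Ranking, labels,
                           cutoff_k: int) -> dict:
    """Confusion-matrix metrics with the top ``cutoff_k`` ligands
    predicted positive.

    Returns MCC (0 when a denominator factor vanishes), sensitivity and
    accuracy.
    """
    act = _as_active(labels)
    n = len(act)
    if not 1 <= cutoff_k < n:
        raise ValueError(f"cutoff_k must lie in [1, {n - 1}]")
    predicted = np.zeros(n, dtype=bool)
    predicted[ranking.order[:cutoff_k]] = True
    tp = int((predicted & act).sum())
    fp = int((predicted & ~act).sum())
    fn = int((~predicted & act).sum())
    tn = int((~predicted & ~act).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    acc = (tp + tn) / n
    return {"MCC": float(mcc), "sensitivity": float(sens),
            "accuracy": float(acc), "TP": tp, "FP": fp, "FN": fn, "TN": tn}


#: variance of normalized ranks under the uniform null
_NULL_M2 = 1.0 / 12.0


def rank_skewness(ranking: Ranking, labels) -> float:
    """Asymmetry of the actives' positions about the ranking midpoint.

    With normalized ranks x_i = r_i/N in (0, 1], the statistic is the
    third moment of (0.5 - x_i) standardized by the dispersion of the
    uniform null, (1/12)^(3/2).  Positive values mean actives
    concentrated near the top (maximal when all actives head the
    ranking), a uniform spread gives ~0, and reversing the ranking
    negates the value.  Standardizing by the fixed null dispersion —
    rather than the sample moment — keeps the statistic monotone toward
    top-concentration, which is what a ranking tie-breaker needs.
    """
    act = _as_active(labels)
    if act.sum() < 2:
        raise UndefinedMetricError("skewness needs at least 2 actives")
    n = len(act)
    ranks = np.nonzero(act[ranking.order])[0] + 1  # 1-based positions
    d = 0.5 - ranks / n
    m3 = float(np.mean(d ** 3))
    return m3 / _NULL_M2 ** 1.5


def quality(ranking: Ranking, labels,
            config: QualityConfig | None = None) -> tuple:
    """Composite search objective as a comparable tuple.

    With skew_weight 0 (default): (EF_alpha, skew) compared
    lexicographically.  Otherwise the single-element tuple
    (EF_alpha + skew_weight * skew,).
    """
    config = config or QualityConfig()
    ef = ef_at(ranking, labels, config.alpha)
    skew = rank_skewness(ranking, labels)
    if config.skew_weight == 0:
        return (ef, skew)
    return (ef + config.skew_weight * skew,)


# ---------------------------------------------------------------------------
# Fast path used inside search loops: operate on a pre-imputed value
# matrix and a boolean label vector without constructing Ranking objects.
# Semantics are identical to the public functions above (tested).

def fast_order(scores: np.ndarray, id_sorter: np.ndarray) -> np.ndarray:
    return id_sorter[np.argsort(-scores[id_sorter], kind="stable")]


def fast_quality(scores: np.ndarray, is_active: np.ndarray,
                 id_sorter: np.ndarray, n_top: int, a_total: int,
                 skew_weight: float = 0.0) -> tuple:
    order = fast_order(scores, id_sorter)
    act = is_active[order]
    n = len(act)
    a_top = int(act[:n_top].sum())
    ef = (a_top / n_top) / (a_total / n)
    ranks = np.nonzero(act)[0] + 1
    d = 0.5 - ranks / n
    skew = float(np.mean(d ** 3)) / _NULL_M2 ** 1.5
    if skew_weight == 0:
        return (ef, skew)
    return (ef + skew_weight * skew,)
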