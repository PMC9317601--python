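"""Domain data model for ensemble-docking score tables.

A virtual-screening campaign over an MD trajectory produces, for every
ligand, a stack of docking poses against each (frame, monomer) receptor
conformation, scored by several scoring functions.  This module defines
the keyed containers for those scores and the aggregation of pose stacks
into per-ligand score *channels* (best pose and mean over poses), which
are the input variables of the consensus-model search.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCORE_TYPES = ("PS", "CS", "CSOPT")
AGGREGATIONS = ("BEST", "MEAN")
VARIANTS = ("RAW", "OPTIMIZED")
MONOMERS = ("A", "B", "C", "D")

#: Default score orientation: all three docking scores are treated as
#: "larger is better".  The consensus layer is sign-agnostic, so results
#: do not depend on this convention; it only fixes which pose is "best"
#: and which direction a missing value is pushed towards.
DEFAULT_ORIENTATION: Mapping[str, bool] = {t: True for t in SCORE_TYPES}

_SCORE_PRINT = {"PS": "PS", "CS": "CS", "CSOPT": "Csopt"}
_VARIANT_PRINT = {"RAW": "raw", "OPTIMIZED": "opt"}
_VARIANT_PARSE = {"raw": "RAW", "opt": "OPTIMIZED",
                  "optimized": "OPTIMIZED"}

_CHANNEL_RE = re.compile(
    r"^(?P<score>csopt|cs|ps)(?P<agg>best|mean)(?P<mono>[a-d])"
    r"@(?P<frame>\d+)ns/(?P<variant>raw|opt|optimized)$"
)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class LigandRecord:
    """A screened compound and its activity label."""

    ligand_id: str
    is_active: bool


@dataclass(frozen=True, order=False)
class ChannelKey:
    """Identity of one aggregated score channel.

    A channel is one column of the screening matrix: the (best | mean)
    value of one score type on one monomer of one MD frame, for one
    protein-preparation variant.
    """

    frame_ns: int
    monomer: str
    score_type: str
    aggregation: str
    variant: str = "RAW"

    def __post_init__(self) -> None:
        if self.frame_ns <= 0:
            raise DataError(f"frame_ns must be positive, got {self.frame_ns}")
        if self.monomer not in MONOMERS:
            raise DataError(f"unknown monomer {self.monomer!r}")
        if self.score_type not in SCORE_TYPES:
            raise DataError(f"unknown score_type {self.score_type!r}")
        if self.aggregation not in AGGREGATIONS:
            raise DataError(f"unknown aggregation {self.aggregation!r}")
        if self.variant not in VARIANTS:
            raise DataError(f"unknown variant {self.variant!r}")

    def sort_key(self) -> tuple:
        return (
            VARIANTS.index(self.variant),
            self.frame_ns,
            MONOMERS.index(self.monomer),
            SCORE_TYPES.index(self.score_type),
            AGGREGATIONS.index(self.aggregation),
        )

    def __lt__(self, other: "ChannelKey") -> bool:
        return self.sort_key() < other.sort_key()

    def __le__(self, other: "ChannelKey") -> bool:
        return self.sort_key() <= other.sort_key()

    def __gt__(self, other: "ChannelKey") -> bool:
        return self.sort_key() > other.sort_key()

    def __ge__(self, other: "ChannelKey") -> bool:
        return self.sort_key() >= other.sort_key()

    def to_string(self) -> str:
        """Canonical rendering, e.g. ``CsoptmeanC@575ns/raw``."""
        return (
            f"{_SCORE_PRINT[self.score_type]}{self.aggregation.lower()}"
            f"{self.monomer}@{self.frame_ns}ns/{_VARIANT_PRINT[self.variant]}"
        )

    @classmethod
    def from_string(cls, text: str) -> "ChannelKey":
        m = _CHANNEL_RE.match(text.strip().lower())
        if m is None:
            raise DataError(f"unparseable channel key {text!r}")
        score = m.group("score")
        score_type = "CSOPT" if score == "csopt" else score.upper()
        return cls(
            frame_ns=int(m.group("frame")),
            monomer=m.group("mono").upper(),
            score_type=score_type,
            aggregation=m.group("agg").upper(),
            variant=_VARIANT_PARSE[m.group("variant")],
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _normalize_labels(labels) -> pd.DataFrame:
    """Accept a labels DataFrame or LigandRecord iterable; return a frame
    with string ligand_id and boolean active, sorted by ligand_id."""
    if isinstance(labels, pd.DataFrame):
        if not {"ligand_id", "active"}.issubset(labels.columns):
            raise DataError("labels need 'ligand_id' and 'active' columns")
        df = labels[["ligand_id", "active"]].copy()
    else:
        df = pd.DataFrame(
            [(r.ligand_id, r.is_active) for r in labels],
            columns=["ligand_id", "active"],
        )
    df["ligand_id"] = df["ligand_id"].astype(str)
    df["active"] = df["active"].astype(int).astype(bool)
    if df["ligand_id"].duplicated().any():
        dup = df.loc[df["ligand_id"].duplicated(), "ligand_id"].iloc[0]
        raise DataError(f"duplicate ligand_id {dup!r} in labels")
    df = df.sort_values("ligand_id", kind="stable").reset_index(drop=True)
    n_active = int(df["active"].sum())
    if n_active == 0 or n_active == len(df):
        raise DataError("labels must contain at least one active and one decoy")
    return df


REQUIRED_POSE_COLUMNS = ("ligand_id", "frame_ns", "monomer",
                         "score_type", "pose", "value")


@dataclass
class PoseScoreTable:
    """Long-form pose-level docking scores for one preparation variant.

    ``df`` has columns ligand_id, frame_ns, monomer, score_type, pose,
    value.  A (ligand, frame, monomer, score_type) group may be empty —
    that is a docking failure — but never holds duplicate pose indices.
    """

    df: pd.DataFrame
    variant: str = "RAW"
    pose_budget: int = 10
    higher_is_better: Mapping[str, bool] = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATION))

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise DataError(f"unknown variant {self.variant!r}")
        missing = set(REQUIRED_POSE_COLUMNS) - set(self.df.columns)
        if missing:
            raise DataError(f"pose table missing columns {sorted(missing)}")
        df = self.df
        bad_type = ~df["score_type"].isin(SCORE_TYPES)
        if bad_type.any():
            row = df[bad_type].iloc[0]
            raise DataError(
                f"unknown score_type {row['score_type']!r} for ligand "
                f"{row['ligand_id']!r} at frame {row['frame_ns']}")
        bad_mono = ~df["monomer"].isin(MONOMERS)
        if bad_mono.any():
            row = df[bad_mono].iloc[0]
            raise DataError(
                f"unknown monomer {row['monomer']!r} for ligand "
                f"{row['ligand_id']!r} at frame {row['frame_ns']}")
        if len(df) and (df["pose"].min() < 1 or
                        df["pose"].max() > self.pose_budget):
            raise DataError(
                f"pose index outside 1..{self.pose_budget}")
        group_cols = ["ligand_id", "frame_ns", "monomer", "score_type", "pose"]
        if df.duplicated(subset=group_cols).any():
            row = df[df.duplicated(subset=group_cols)].iloc[0]
            raise DataError(
                f"duplicate pose {row['pose']} for ligand {row['ligand_id']!r}"
                f" ({row['score_type']}, monomer {row['monomer']},"
                f" frame {row['frame_ns']})")

    @property
    def frame_times(self) -> np.ndarray:
        return np.sort(self.df["frame_ns"].unique())

    @property
    def ligand_ids(self) -> np.ndarray:
        return np.sort(self.df["ligand_id"].astype(str).unique())

    def slice(self, frame_ns: int | None = None,
              monomer: str | None = None) -> "PoseScoreTable":
        """Restrict to one frame and/or monomer (shares validation)."""
        df = self.df
        if frame_ns is not None:
            df = df[df["frame_ns"] == frame_ns]
        if monomer is not None:
            df = df[df["monomer"] == monomer]
        return replace(self, df=df.reset_index(drop=True))


@dataclass
class ScreeningMatrix:
    """Ligands x channels matrix of aggregated scores with activity labels.

    Missing entries (docking failures) are NaN.  Ligands are kept sorted
    by ligand_id so that every ranking derived from the matrix has a
    deterministic tie-break.
    """

    ligand_ids: np.ndarray
    is_active: np.ndarray
    channels: tuple
    values: np.ndarray
    higher_is_better: Mapping[str, bool] = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATION))
    provenance: dict = field(default_factory=dict)
    #: strict=False tolerates entirely-missing channels (used for row
    #: subsets taken during validation; a full matrix is always strict).
    strict: bool = True

    def __post_init__(self) -> None:
        self.ligand_ids = np.asarray(self.ligand_ids, dtype=object)
        self.is_active = np.asarray(self.is_active, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        self.channels = tuple(self.channels)
        n, c = self.values.shape
        if n != len(self.ligand_ids) or c != len(self.channels):
            raise DataError("matrix dimensions do not match ligands/channels")
        if len(np.unique(self.ligand_ids)) != n:
            raise DataError("ligand_ids must be unique")
        if not (self.is_active.any() and (~self.is_active).any()):
            raise DataError("need at least one active and one decoy")
        if self.strict:
            all_missing = np.isnan(self.values).all(axis=0)
            if all_missing.any():
                names = [self.channels[i].to_string()
                         for i in np.nonzero(all_missing)[0]]
                raise DataError(f"channels entirely missing: {names}")

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_actives(self) -> int:
        return int(self.is_active.sum())

    def channel_index(self, key: ChannelKey) -> int:
        try:
            return self.channels.index(key)
        except ValueError:
            raise DataError(f"unknown channel {key.to_string()}") from None

    def restrict(self, keys: Iterable[ChannelKey] | None = None,
                 predicate=None) -> "ScreeningMatrix":
        """Matrix restricted to a channel subset (order preserved by
        canonical ChannelKey ordering)."""
        if keys is not None:
            keep = sorted(set(keys), key=ChannelKey.sort_key)
            idx = [self.channel_index(k) for k in keep]
        else:
            keep = [c for c in self.channels if predicate(c)]
            idx = [i for i, c in enumerate(self.channels) if predicate(c)]
        if not idx:
            raise DataError("channel restriction leaves an empty matrix")
        return ScreeningMatrix(
            ligand_ids=self.ligand_ids,
            is_active=self.is_active,
            channels=keep if keys is not None else keep,
            values=self.values[:, idx],
            higher_is_better=dict(self.higher_is_better),
            provenance=dict(self.provenance),
        )

    def imputed(self) -> np.ndarray:
        """Values with NaN replaced per channel by the worst observed value
        pushed one scale epsilon further, so failures never rank on top."""
        out = self.values.copy()
        for j, key in enumerate(self.channels):
            col = out[:, j]
            mask = np.isnan(col)
            if not mask.any():
                continue
            finite = col[~mask]
            if len(finite) == 0:
                col[mask] = 0.0
                continue
            span = float(finite.max() - finite.min())
            eps = 1e-9 + 1e-6 * span
            if self.higher_is_better.get(key.score_type, True):
                col[mask] = finite.min() - eps
            else:
                col[mask] = finite.max() + eps
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.ligand_ids, name="ligand_id"),
            columns=[c.to_string() for c in self.channels],
        )
        df.insert(0, "active", self.is_active.astype(int))
        return df


def aggregate_poses(table: PoseScoreTable, labels,
                    method: str | None = None) -> ScreeningMatrix:
    """Collapse pose stacks into per-ligand score channels.

    ``method`` is "BEST" (extremum over available poses in the direction
    of the score orientation), "MEAN" (arithmetic mean), or None to emit
    both aggregations as separate channels.  Groups with zero poses are
    missing (NaN).  Ligands appearing in the table but absent from the
    labels are rejected.
    """
    if table.df.empty:
        raise DataError("pose table is empty")
    if method is not None and method not in AGGREGATIONS:
        raise DataError(f"unknown aggregation {method!r}")
    methods = AGGREGATIONS if method is None else (method,)

    lab = _normalize_labels(labels)
    known = set(lab["ligand_id"])
    in_table = set(table.df["ligand_id"].astype(str))
    orphans = sorted(in_table - known)
    if orphans:
        raise DataError(f"ligands missing from labels: {orphans}")

    df = table.df.copy()
    df["ligand_id"] = df["ligand_id"].astype(str)
    grouped = (
        df.groupby(["frame_ns", "monomer", "score_type", "ligand_id"],
                   observed=True)["value"]
        .agg(["mean", "max", "min"])
        .reset_index()
    )
    hib = grouped["score_type"].map(
        lambda t: table.higher_is_better.get(t, True))
    grouped["BEST"] = np.where(hib, grouped["max"], grouped["min"])
    grouped["MEAN"] = grouped["mean"]

    ligand_ids = lab["ligand_id"].to_numpy(dtype=object)
    lig_pos = {lid: i for i, lid in enumerate(ligand_ids)}

    combos = (
        grouped[["frame_ns", "monomer", "score_type"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    channels = []
    for frame_ns, monomer, score_type in combos:
        for agg in methods:
            channels.append(ChannelKey(
                frame_ns=int(frame_ns), monomer=monomer,
                score_type=score_type, aggregation=agg,
                variant=table.variant))
    channels.sort(key=ChannelKey.sort_key)
    col_pos = {c: j for j, c in enumerate(channels)}

    values = np.full((len(ligand_ids), len(channels)), np.nan)
    rows = grouped["ligand_id"].map(lig_pos).to_numpy()
    for agg in methods:
        cols = np.fromiter(
            (col_pos[ChannelKey(int(f), m, t, agg, table.variant)]
             for f, m, t in zip(grouped["frame_ns"], grouped["monomer"],
                                grouped["score_type"])),
            dtype=int, count=len(grouped))
        values[rows, cols] = grouped[agg].to_numpy()

    return ScreeningMatrix(
        ligand_ids=ligand_ids,
        is_active=lab["active"].to_numpy(),
        channels=channels,
        values=values,
        higher_is_better=dict(table.higher_is_better),
        provenance={"variant": table.variant,
                    "aggregations": list(methods)},
    )


def build_matrix(tables: Mapping[str, PoseScoreTable] | Sequence[PoseScoreTable],
                 labels) -> ScreeningMatrix:
    """Assemble the full screening matrix across preparation variants.

    One channel per (frame, monomer, score_type, aggregation, variant)
    present in the input; columns in canonical ChannelKey order.
    """
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    else:
        tables = list(tables)
    if not tables:
        raise DataError("no pose tables given")
    parts = [aggregate_poses(t, labels) for t in tables]
    base = parts[0]
    channels = [c for p in parts for c in p.channels]
    if len(set(channels)) != len(channels):
        raise DataError("duplicate channels across pose tables")
    values = np.hstack([p.values for p in parts])
    order = sorted(range(len(channels)), key=lambda i: channels[i].sort_key())
    hib = {}
    for t in tables:
        hib.update(t.higher_is_better)
    return ScreeningMatrix(
        ligand_ids=base.ligand_ids,
        is_active=base.is_active,
        channels=[channels[i] for i in order],
        values=values[:, order],
        higher_is_better=hib,
        provenance={"variants": [t.variant for t in tables]},
    )
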