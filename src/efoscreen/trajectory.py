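"""Trend and correlation analyses over per-frame results and pocket volumes.

Works on two inputs: a per-frame metric series (validated EF1% or a
pocket-volume average, with an acceptance mask for discarded frames) and
a pocket-volume table keyed by (frame, monomer, variant).  Provides the
cumulative and fixed-window segment means used to describe how screening
performance evolves along an MD run, per-monomer volume averages, the
Pearson correlations between volume and performance, and term-frequency
cross-tabs over collections of consensus equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .channels import DataError, MONOMERS
from .equations import parse_equation
from .metrics import UndefinedMetricError

EN_DASH = "–"  # used in segment labels like "25–250"


@dataclass
class VolumeTable:
    """Pocket volumes (Å³) per (frame, monomer, variant)."""

    df: pd.DataFrame  # columns frame_ns, monomer, variant, volume

    def __post_init__(self) -> None:
        required = {"frame_ns", "monomer", "variant", "volume"}
        missing = required - set(self.df.columns)
        if missing:
            raise DataError(f"volume table missing columns {sorted(missing)}")
        if (self.df["volume"] < 0).any():
            raise DataError("volumes must be non-negative")
        if self.df.duplicated(["frame_ns", "monomer", "variant"]).any():
            raise DataError("duplicate (frame, monomer, variant) volume rows")


@dataclass
class FrameSeries:
    """Ordered (frame_time, value) pairs with an acceptance mask."""

    frame_ns: np.ndarray
    values: np.ndarray
    accepted: np.ndarray = None

    def __post_init__(self) -> None:
        self.frame_ns = np.asarray(self.frame_ns, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.accepted is None:
            self.accepted = ~np.isnan(self.values)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if not (len(self.frame_ns) == len(self.values) == len(self.accepted)):
            raise DataError("frame series arrays must be equally long")
        if (np.diff(self.frame_ns) <= 0).any():
            raise DataError("frame times must be strictly increasing")

    @property
    def sampling_interval(self) -> int:
        if len(self.frame_ns) > 1:
            return int(np.gcd.reduce(np.diff(self.frame_ns)))
        return int(self.frame_ns[0])

    def accepted_values(self) -> tuple[np.ndarray, np.ndarray]:
        return self.frame_ns[self.accepted], self.values[self.accepted]


def cumulative_means(series: FrameSeries) -> FrameSeries:
    """Running mean over the accepted values, emitted at accepted frames."""
    t, v = series.accepted_values()
    if len(v) == 0:
        raise DataError("no accepted points in series")
    cm = np.cumsum(v) / np.arange(1, len(v) + 1)
    return FrameSeries(frame_ns=t, values=cm,
                       accepted=np.ones(len(t), dtype=bool))


def segment_means(series: FrameSeries, segment_ns: int = 250) -> pd.Series:
    """Mean of accepted values per consecutive trajectory window.

    Windows are label-inclusive, e.g. at a 25 ns sampling interval and
    250 ns windows: 25–250, 275–500, ...  Empty windows yield NaN.
    """
    step = series.sampling_interval
    if segment_ns <= 0 or (len(series.frame_ns) > 1
                           and segment_ns % step != 0):
        raise DataError(
            f"segment_ns must be a positive multiple of the sampling "
            f"interval ({step} ns)")
    if len(series.frame_ns) == 1:
        step = min(step, segment_ns)
    idx = (np.ceil(series.frame_ns / segment_ns) - 1).astype(int)
    n_seg = int(idx.max()) + 1
    out = {}
    for seg in range(n_seg):
        lo, hi = seg * segment_ns + step, (seg + 1) * segment_ns
        mask = (idx == seg) & series.accepted
        label = f"{lo}{EN_DASH}{hi}"
        out[label] = float(np.mean(series.values[mask])) if mask.any() \
            else float("nan")
    return pd.Series(out, name="segment_mean")


def volume_averages(volumes: VolumeTable, variant: str = "RAW") -> pd.Series:
    """Per-monomer volume means over frames plus the overall mean
    (the unweighted mean of the four per-monomer means)."""
    df = volumes.df[volumes.df["variant"] == variant]
    means = {}
    for m in MONOMERS:
        sub = df.loc[df["monomer"] == m, "volume"]
        if sub.empty:
            raise DataError(f"no volume rows for monomer {m} "
                            f"(variant {variant})")
        means[m] = float(sub.mean())
    means["overall"] = float(np.mean([means[m] for m in MONOMERS]))
    return pd.Series(means, name="mean_volume")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; undefined for n < 3 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedMetricError(
            "pearson_r needs equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("pearson_r undefined at zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class TermFrequency:
    """Occurrence counts of equation terms.

    ``cross_tab`` is aggregation x monomer (with Total margins),
    ``by_score_type`` the PS/CS/CSopt marginals, ``half_split`` the
    per-aggregation counts in the first vs second half of the run.
    """

    cross_tab: pd.DataFrame
    by_score_type: pd.Series
    total: int
    half_split: pd.DataFrame = None
    parse_warnings: tuple = ()


def term_frequency(equations: Iterable,
                   half_boundary_ns: float | None = None) -> TermFrequency:
    """Count term occurrences in a collection of consensus equations.

    ``equations`` holds strings or (frame_ns, string) pairs; frame times
    enable the first-half/second-half split (boundary defaults to the
    midpoint of the observed frame range).
    """
    rows = []
    warnings_seen = []
    times = []
    for item in equations:
        if isinstance(item, tuple):
            frame_ns, text = item
        else:
            frame_ns, text = None, item
        try:
            parsed = parse_equation(text)
        except Exception as exc:
            raise DataError(f"cannot parse equation {text!r}: {exc}") from exc
        warnings_seen.extend(parsed.warnings)
        for term in parsed.terms:
            rows.append((frame_ns, term.score_type, term.aggregation,
                         term.monomer))
        times.append(frame_ns)
    if not rows:
        raise DataError("no terms found in equations")
    df = pd.DataFrame(rows, columns=["frame_ns", "score_type",
                                     "aggregation", "monomer"])

    cross = pd.crosstab(df["aggregation"], df["monomer"])
    cross = cross.reindex(index=["BEST", "MEAN"], columns=list(MONOMERS),
                          fill_value=0)
    cross["Total"] = cross.sum(axis=1)
    cross.loc["Total"] = cross.sum(axis=0)

    by_type = df["score_type"].value_counts().reindex(
        ["PS", "CS", "CSOPT"], fill_value=0)

    half = None
    if df["frame_ns"].notna().any():
        t = df["frame_ns"].astype(float)
        if half_boundary_ns is None:
            known = [x for x in times if x is not None]
            half_boundary_ns = (min(known) + max(known)) / 2
        df = df.assign(half=np.where(t < half_boundary_ns,
                                     "first", "second"))
        half = pd.crosstab(df["aggregation"], df["half"]).reindex(
            index=["BEST", "MEAN"], columns=["first", "second"],
            fill_value=0)

    return TermFrequency(cross_tab=cross, by_score_type=by_type,
                         total=len(rows), half_split=half,
                         parse_warnings=tuple(warnings_seen))


def frequency_volume_correlation(freq: TermFrequency,
                                 volumes: pd.Series) -> float:
    """Pearson r between per-monomer total term frequency and mean
    pocket volume, over the four monomers."""
    f = [float(freq.cross_tab.loc["Total", m]) for m in MONOMERS]
    v = [float(volumes[m]) for m in MONOMERS]
    x, y = np.asarray(f), np.asarray(v)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError(
            "frequency-volume correlation undefined at zero variance")
    return float(stats.pearsonr(x, y).statistic)
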