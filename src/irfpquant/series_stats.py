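"""Longitudinal and replicate statistics: fold change, coefficient of
variance, dilution-series linearity, limit of detection and detection
heat-tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError
from .quantification import IntensityMeasurement

__all__ = [
    "TimeSeries",
    "DilutionSeries",
    "DetectionTable",
    "DilutionLinearity",
    "fold_change",
    "fold_change_per_mouse",
    "coefficient_of_variance",
    "dilution_linearity",
    "limit_of_detection",
    "detection_table",
]

NEVER = "never"


@dataclass(frozen=True)
class TimeSeries:
    """Intensity measurements keyed by (mouse_id, day)."""

    entries: tuple[IntensityMeasurement, ...]

    def __post_init__(self) -> None:
        keys = [(m.mouse_id, m.day) for m in self.entries]
        if len(set(keys)) != len(keys):
            raise DomainError("duplicate (mouse_id, day) keys in time series")
        if not keys:
            raise DegenerateInputError("time series is empty")
        object.__setattr__(self, "entries", tuple(self.entries))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": [m.mouse_id for m in self.entries],
                "day": [m.day for m in self.entries],
                "net_total": [m.net_total for m in self.entries],
                "mean_net": [m.mean_net for m in self.entries],
                "total_raw": [m.total_raw for m in self.entries],
                "area_px": [m.area_px for m in self.entries],
            }
        )

    def values_at(self, day: int, value: str = "net_total") -> pd.Series:
        df = self.to_frame()
        sel = df[df["day"] == day].set_index("mouse_id")[value]
        if sel.empty:
            raise DomainError(f"no measurements at day {day}")
        return sel


@dataclass(frozen=True)
class DilutionSeries:
    """Replicate signals along a decreasing dilution-factor ladder.

    ``dilution_factors`` are the surviving fractions of the top
    concentration (1, 0.1, 0.01, ... for a tenfold ladder);
    ``replicate_signals[i]`` are the raw well signals at factor ``i``;
    ``background_wells`` are blank (agarose-only) wells.
    """

    dilution_factors: tuple[float, ...]
    replicate_signals: tuple[tuple[float, ...], ...]
    background_wells: tuple[float, ...]

    def __post_init__(self) -> None:
        factors = tuple(float(f) for f in self.dilution_factors)
        if len(factors) < 2:
            raise DomainError("need at least 2 dilutions")
        if any(f <= 0 for f in factors):
            raise DomainError("dilution factors must be positive")
        if any(a <= b for a, b in zip(factors, factors[1:])):
            raise DomainError("dilution factors must be strictly decreasing")
        signals = tuple(tuple(float(v) for v in row) for row in self.replicate_signals)
        if len(signals) != len(factors):
            raise DomainError("one replicate list required per dilution")
        if any(len(row) < 1 for row in signals):
            raise DomainError("each dilution needs at least 1 replicate")
        object.__setattr__(self, "dilution_factors", factors)
        object.__setattr__(self, "replicate_signals", signals)
        object.__setattr__(
            self, "background_wells", tuple(float(v) for v in self.background_wells)
        )


@dataclass(frozen=True)
class DilutionLinearity:
    """Per-dilution summary plus log-log linearity over the detectable
    range."""

    dilution_factors: tuple[float, ...]
    normalized_means: tuple[float, ...]
    normalized_sds: tuple[float, ...]
    detectable: tuple[bool, ...]
    slope: float          # log10(signal - bg) vs log10(dilution); NaN if < 2 points
    linear_range_extent: int  # number of detectable dilutions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dilution_factor": self.dilution_factors,
                "normalized_mean": self.normalized_means,
                "normalized_sd": self.normalized_sds,
                "detectable": self.detectable,
            }
        )


@dataclass(frozen=True)
class DetectionTable:
    """Earliest detection day per (lesion, platform); ``"never"`` marks
    lesions a platform missed entirely."""

    grid: pd.DataFrame  # index: lesion, columns: platform

    def to_csv(self, path: str | Path) -> None:
        self.grid.to_csv(path, index_label="lesion")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DetectionTable":
        df = pd.read_csv(path, index_col="lesion")
        for col in df.columns:
            df[col] = pd.Series(
                [NEVER if v == NEVER else int(float(v))
                 for v in df[col].astype(str)],
                index=df.index,
                dtype=object,
            )
        return cls(grid=df)


def fold_change(
    series: TimeSeries, day_a: int, day_b: int, value: str = "net_total"
) -> float:
    """Ratio of group means: mean over mice at ``day_b`` divided by
    mean at ``day_a``.

    Uses the group-average convention (mean of day-b values over mean of
    day-a values), not the mean of per-mouse ratios; see
    :func:`fold_change_per_mouse` for the latter.
    """
    mean_a = float(series.values_at(day_a, value).mean())
    mean_b = float(series.values_at(day_b, value).mean())
    if mean_a <= 0:
        raise DomainError(f"day {day_a} mean is {mean_a}; fold change undefined")
    return mean_b / mean_a


def fold_change_per_mouse(
    series: TimeSeries, day_a: int, day_b: int, value: str = "net_total"
) -> pd.Series:
    """Per-mouse day_b / day_a ratios for mice measured on both days."""
    a = series.values_at(day_a, value)
    b = series.values_at(day_b, value)
    common = a.index.intersection(b.index)
    if common.empty:
        raise DomainError("no mouse measured on both days")
    a = a.loc[common]
    if (a <= 0).any():
        raise DomainError("non-positive baseline measurement")
    return b.loc[common] / a


def coefficient_of_variance(values: Sequence[float]) -> float:
    """Sample sd divided by mean, as a percentage.

    Scale-free measure of repeatability; invariant to multiplying all
    values by a positive constant.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size < 2:
        raise DomainError("need at least 2 values for a CV")
    mean = arr.mean()
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return 100.0 * float(np.std(arr, ddof=1)) / float(mean)


def _background_threshold(series: DilutionSeries, k: float) -> float:
    bg = np.asarray(series.background_wells, dtype=np.float64)
    if bg.size == 0:
        raise DomainError("need at least one background well")
    sd = float(np.std(bg, ddof=1)) if bg.size > 1 else 0.0
    return float(bg.mean()) + k * sd


def limit_of_detection(series: DilutionSeries, k: float = 3.0) -> float | None:
    """Smallest dilution factor whose replicate mean exceeds
    background mean + k * background sd, or None if nothing is
    detectable.

    A statistical stand-in for the by-eye "last visible dilution" call;
    with a single background well the sd term is taken as 0.  The rule
    walks down the ladder from the most concentrated well and stops at
    the first undetectable dilution: an isolated deeper well that
    clears the threshold by chance (the background sd is estimated from
    few blanks) is treated as spurious rather than as detection.
    """
    if k < 0:
        raise DomainError("k must be non-negative")
    threshold = _background_threshold(series, k)
    lod = None
    for f, row in zip(series.dilution_factors, series.replicate_signals):
        if np.mean(row) > threshold:
            lod = f
        else:
            break
    return lod


def dilution_linearity(
    series: DilutionSeries, k: float = 3.0, subtract_background: bool = True
) -> DilutionLinearity:
    """Normalized dilution curve and log-log slope over the detectable
    range.

    Replicate means (optionally background-subtracted) are scaled so the
    top dilution maps to 1.  The slope of log10(signal - background)
    against log10(dilution factor) is fitted over dilutions above the
    limit of detection; a perfectly linear instrument gives slope 1.
    An all-undetectable series yields an empty range, not an error.
    """
    bg_mean = float(np.mean(series.background_wells)) if series.background_wells else 0.0
    threshold = _background_threshold(series, k)
    means = np.array([np.mean(r) for r in series.replicate_signals])
    sds = np.array(
        [np.std(r, ddof=1) if len(r) > 1 else 0.0 for r in series.replicate_signals]
    )
    net = means - bg_mean if subtract_background else means
    top = net[0]
    if top <= 0:
        raise DomainError("top dilution has no signal above background")
    detectable = means > threshold
    n_det = int(detectable.sum())
    if n_det >= 2:
        x = np.log10(np.asarray(series.dilution_factors)[detectable])
        with np.errstate(invalid="ignore"):
            y = np.log10(means[detectable] - bg_mean)
        keep = np.isfinite(y)
        slope = (
            float(np.polyfit(x[keep], y[keep], 1)[0]) if keep.sum() >= 2 else float("nan")
        )
    else:
        slope = float("nan")
    return DilutionLinearity(
        dilution_factors=series.dilution_factors,
        normalized_means=tuple(net / top),
        normalized_sds=tuple(sds / top),
        detectable=tuple(bool(d) for d in detectable),
        slope=slope,
        linear_range_extent=n_det,
    )


def detection_table(
    calls: Iterable[tuple[str, str, int, bool]]
) -> DetectionTable:
    """Assemble earliest-detection days from per-day presence calls.

    ``calls`` holds (lesion, platform, day, detected) tuples; the table
    records the earliest day each platform detected each lesion, or
    ``"never"``.
    """
    calls = list(calls)
    keys = [(l, p, d) for l, p, d, _ in calls]
    if len(set(keys)) != len(keys):
        raise DomainError("duplicate (lesion, platform, day) entries")
    if not calls:
        raise DegenerateInputError("no detection calls provided")
    lesions = sorted({l for l, _, _, _ in calls})
    platforms = sorted({p for _, p, _, _ in calls})
    grid = pd.DataFrame(NEVER, index=lesions, columns=platforms, dtype=object)
    for lesion in lesions:
        for platform in platforms:
            days = [
                d
                for l, p, d, det in calls
                if l == lesion and p == platform and det
            ]
            if days:
                grid.loc[lesion, platform] = int(min(days))
    grid.index.name = "lesion"
    return DetectionTable(grid=grid)
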