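"""Behavioral and imaging summary statistics.

Count-based indices for larval/adult assays:

* preference index ``(n_odor - n_blank) / n_total`` — animals in the middle
  zone count toward the total but toward neither side;
* learning index ``(pref_paired - pref_unpaired) / 2`` from a reciprocal
  odor-reward training design;
* performance index ``(n_cs_plus - n_cs_minus) / n_total`` for T-maze
  odor-shock conditioning, optionally averaged over the reciprocal trial in
  which the two odors swap CS+ roles;
* rolling fraction (escape-response contingency) with a Wilson 95% CI.

Continuous summaries:

* per-animal locomotion (mean centroid velocity, cumulative absolute bending
  angle) over the first part of a tracked recording;
* fluorescence fold-change ΔF/F with a pre-stimulus baseline mean F0 and the
  post-stimulus maximum ΔF_max.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

#: Default number of baseline frames for confocal cAMP/calcium imaging.
CONFOCAL_BASELINE_FRAMES = 95
#: Baseline frames for the intact-larva two-photon protocol.
INTACT_LARVA_BASELINE_FRAMES = 50

DEFAULT_FRAME_RATE_HZ = 10.0


class BehaviorError(ValueError):
    """Raised for invalid counts, tracks, or traces."""


@dataclass(frozen=True)
class BehaviorCounts:
    """Animal counts from one trial of a two-choice or contingency assay.

    Exactly one family of fields is used per assay: ``n_odor``/``n_blank``
    (larval two-side preference), ``n_cs_plus``/``n_cs_minus`` (adult
    T-maze), or ``n_rolling`` (escape contingency).
    """

    n_total: int
    n_odor: Optional[int] = None
    n_blank: Optional[int] = None
    n_cs_plus: Optional[int] = None
    n_cs_minus: Optional[int] = None
    n_rolling: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise BehaviorError("n_total must be non-negative")
        for name in ("n_odor", "n_blank", "n_cs_plus", "n_cs_minus", "n_rolling"):
            value = getattr(self, name)
            if value is None:
                continue
            if value < 0:
                raise BehaviorError(f"{name} must be non-negative")
            if value > self.n_total:
                raise BehaviorError(f"{name} ({value}) exceeds n_total ({self.n_total})")
        for a, b in (("n_odor", "n_blank"), ("n_cs_plus", "n_cs_minus")):
            va, vb = getattr(self, a), getattr(self, b)
            if va is not None and vb is not None and va + vb > self.n_total:
                raise BehaviorError(f"{a} + {b} exceeds n_total")


def preference_index(c: BehaviorCounts) -> float:
    """Two-side odor preference in [-1, 1]."""
    if c.n_odor is None or c.n_blank is None:
        raise BehaviorError("preference_index requires n_odor and n_blank")
    if c.n_total == 0:
        raise BehaviorError("n_total must be positive")
    return (c.n_odor - c.n_blank) / c.n_total


@dataclass(frozen=True)
class PairedPreferences:
    """Odor preferences of the paired and unpaired (reciprocal) groups."""

    pref_paired: float
    pref_unpaired: float

    def __post_init__(self) -> None:
        for name in ("pref_paired", "pref_unpaired"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise BehaviorError(f"{name} = {v} outside [-1, 1]")


def learning_index(p: PairedPreferences) -> float:
    """Half the paired-minus-unpaired preference difference, in [-1, 1]."""
    return (p.pref_paired - p.pref_unpaired) / 2.0


def performance_index(
    c: BehaviorCounts, reciprocal: Optional[BehaviorCounts] = None
) -> float:
    """T-maze performance index, optionally averaged with the reciprocal trial."""
    if c.n_cs_plus is None or c.n_cs_minus is None:
        raise BehaviorError("performance_index requires n_cs_plus and n_cs_minus")
    if c.n_total == 0:
        raise BehaviorError("n_total must be positive")
    pi = (c.n_cs_plus - c.n_cs_minus) / c.n_total
    if reciprocal is None:
        return pi
    return (pi + performance_index(reciprocal)) / 2.0


@dataclass(frozen=True)
class RollingFraction:
    fraction: float
    ci_low: float
    ci_high: float
    n_rolling: int
    n_total: int


def rolling_fraction(c: BehaviorCounts, alpha: float = 0.05) -> RollingFraction:
    """Escape (rolling) response fraction with a Wilson score interval."""
    if c.n_rolling is None:
        raise BehaviorError("rolling_fraction requires n_rolling")
    if c.n_total < 1:
        raise BehaviorError("n_total must be at least 1")
    low, high = proportion_confint(c.n_rolling, c.n_total, alpha=alpha,
                                   method="wilson")
    return RollingFraction(
        fraction=c.n_rolling / c.n_total,
        ci_low=float(low),
        ci_high=float(high),
        n_rolling=c.n_rolling,
        n_total=c.n_total,
    )


# ---------------------------------------------------------------------------
# Locomotion


@dataclass
class TrackTable:
    """Per-frame centroid tracks (one row per animal per frame).

    Columns: ``animal_id, frame, time_s, x_mm, y_mm, bending_deg``.  Frames
    must be strictly increasing per animal and consistent with the frame
    rate (``time_s == frame / frame_rate_hz``).
    """

    frames: pd.DataFrame
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ

    REQUIRED = ("animal_id", "frame", "x_mm", "y_mm", "bending_deg")

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise BehaviorError("frame_rate_hz must be positive")
        missing = set(self.REQUIRED) - set(self.frames.columns)
        if missing:
            raise BehaviorError(f"track table missing columns {sorted(missing)}")
        if "time_s" not in self.frames.columns:
            self.frames = self.frames.assign(
                time_s=self.frames["frame"] / self.frame_rate_hz
            )
        for animal, group in self.frames.groupby("animal_id"):
            frames = group["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise BehaviorError(f"animal {animal}: frames not strictly increasing")
            expected = frames / self.frame_rate_hz
            if np.max(np.abs(group["time_s"].to_numpy() - expected)) > 1e-6:
                raise BehaviorError(
                    f"animal {animal}: time_s inconsistent with frame rate"
                )

    @classmethod
    def from_csv(cls, path: str | Path,
                 frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> "TrackTable":
        return cls(frames=pd.read_csv(path), frame_rate_hz=frame_rate_hz)


def locomotion_summary(t: TrackTable, window_s: float = 30.0) -> pd.DataFrame:
    """Per-animal mean velocity (mm/s) and cumulative bending angle (deg).

    Uses the first ``window_s`` seconds of each animal's track (relative to
    its first frame).  Velocity is the mean consecutive-frame centroid
    displacement times the frame rate; no smoothing is applied.  Bending is
    summed as absolute values.
    """
    rows = []
    for animal, group in t.frames.groupby("animal_id"):
        group = group.sort_values("frame")
        rel_t = group["time_s"].to_numpy() - group["time_s"].to_numpy()[0]
        in_window = group[rel_t < window_s]
        if len(in_window) < 2:
            raise BehaviorError(
                f"animal {animal}: fewer than 2 frames inside the window"
            )
        dx = np.diff(in_window["x_mm"].to_numpy())
        dy = np.diff(in_window["y_mm"].to_numpy())
        step = np.hypot(dx, dy)
        rows.append(
            {
                "animal_id": animal,
                "mean_velocity_mm_s": float(np.mean(step) * t.frame_rate_hz),
                "cumulative_bending_deg": float(
                    np.sum(np.abs(in_window["bending_deg"].to_numpy()))
                ),
                "n_frames": len(in_window),
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")


# ---------------------------------------------------------------------------
# Fluorescence fold-change


@dataclass
class FluorescenceTrace:
    """A fluorescence time series with a pre-stimulus baseline window."""

    frames: np.ndarray
    baseline_frames: int = CONFOCAL_BASELINE_FRAMES
    stimulus_start: Optional[int] = None  # frame index of first post-stimulus frame
    stimulus_end: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.baseline_frames < 1:
            raise BehaviorError("baseline_frames must be positive")
        if self.baseline_frames >= len(self.frames):
            raise BehaviorError("baseline_frames must be shorter than the trace")
        if self.stimulus_start is None:
            self.stimulus_start = self.baseline_frames
        if self.stimulus_end is None:
            self.stimulus_end = len(self.frames)
        if not (self.baseline_frames <= self.stimulus_start < self.stimulus_end
                <= len(self.frames)):
            raise BehaviorError("invalid stimulus window")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "FluorescenceTrace":
        df = pd.read_csv(path)
        if "F" not in df.columns:
            raise BehaviorError("fluorescence CSV must contain a column 'F'")
        return cls(frames=df.sort_values("frame")["F"].to_numpy()
                   if "frame" in df.columns else df["F"].to_numpy(), **kwargs)


@dataclass(frozen=True)
class DffResult:
    dff: np.ndarray
    dff_max: float
    f0: float


def dff_trace(f: FluorescenceTrace) -> DffResult:
    """Baseline-normalized fluorescence change.

    ``F0`` is the mean of the first ``baseline_frames`` values; ``dff[i] =
    (F[i] - F0) / F0``; ``dff_max`` is the maximum over the post-stimulus
    window.
    """
    f0 = float(np.mean(f.frames[: f.baseline_frames]))
    if f0 <= 0:
        raise BehaviorError("baseline mean must be positive")
    dff = (f.frames - f0) / f0
    dff_max = float(np.max(dff[f.stimulus_start : f.stimulus_end]))
    return DffResult(dff=dff, dff_max=dff_max, f0=f0)


# ---------------------------------------------------------------------------
# CSV helpers for counts tables


def read_counts_csv(path: str | Path) -> list[BehaviorCounts]:
    """Read a counts table; recognized columns map onto BehaviorCounts fields."""
    df = pd.read_csv(path)
    if "n_total" not in df.columns:
        raise BehaviorError("counts CSV must contain column 'n_total'")
    fields = ("n_odor", "n_blank", "n_cs_plus", "n_cs_minus", "n_rolling")
    out = []
    for _, row in df.iterrows():
        kwargs = {"n_total": int(row["n_total"])}
        for name in fields:
            if name in df.columns and not pd.isna(row[name]):
                kwargs[name] = int(row[name])
        out.append(BehaviorCounts(**kwargs))
    return out
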