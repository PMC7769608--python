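"""Immunofluorescence line-profile quantification.

Works on per-axon RGB line scans extracted along stained axons: channel R is
the paranodal marker (Caspr1), channel G the channel being tested for
dislocation (Kv1.2 or pan-Nav).  Two computations are provided:

* overlap detection — a position belongs to an overlapping region when the
  absolute difference between the two channel intensities falls below a
  threshold T while both signals sit above a background floor B;
* paranode length — the extent of the contiguous region of a single-channel
  profile above half of its peak-above-background intensity (FWHM rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BACKGROUND_FLOOR = 20.0
DEFAULT_GRID_STEP_UM = 0.05
INTENSITY_MAX = 255.0


class ProfileFormatError(ValueError):
    pass


class NoParanodeError(ValueError):
    """Raised when no region of the profile rises above the length rule level."""


@dataclass(frozen=True)
class IntensityProfile:
    """Aligned two-channel line scan of one axon."""

    axon_id: str
    positions_um: np.ndarray
    red: np.ndarray
    green: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        r = np.asarray(self.red, dtype=float)
        g = np.asarray(self.green, dtype=float)
        if not (len(pos) == len(r) == len(g)):
            raise ProfileFormatError(
                f"axon {self.axon_id}: position/intensity arrays differ in length"
            )
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise ProfileFormatError("positions must be strictly increasing")
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "red", r)
        object.__setattr__(self, "green", g)

    def swapped(self) -> "IntensityProfile":
        return IntensityProfile(self.axon_id, self.positions_um, self.green, self.red)


@dataclass(frozen=True)
class OverlapResult:
    axon_id: str
    threshold: float
    overlapping_indices: tuple[int, ...]

    @property
    def has_overlap(self) -> bool:
        return len(self.overlapping_indices) > 0


@dataclass(frozen=True)
class ParanodeMeasurement:
    axon_id: str
    length_um: float
    rule: str = "half-max"


def regrid_channels(
    positions_r: np.ndarray,
    red: np.ndarray,
    positions_g: np.ndarray,
    green: np.ndarray,
    axon_id: str = "",
    step_um: float = DEFAULT_GRID_STEP_UM,
) -> IntensityProfile:
    """Interpolate separately-sampled channels onto a common grid."""
    lo = max(positions_r[0], positions_g[0])
    hi = min(positions_r[-1], positions_g[-1])
    if hi <= lo:
        raise ProfileFormatError("channel position ranges do not overlap")
    grid = np.arange(lo, hi + step_um / 2, step_um)
    return IntensityProfile(
        axon_id,
        grid,
        np.interp(grid, positions_r, red),
        np.interp(grid, positions_g, green),
    )


def overlap_points(
    profile: IntensityProfile,
    threshold: float,
    background_floor: float = DEFAULT_BACKGROUND_FLOOR,
) -> OverlapResult:
    """Positions where the two channels overlap.

    Position i overlaps iff |R_i - G_i| < T and min(R_i, G_i) >= B.  With
    B = 0 this is the bare subtraction rule (which also marks mutual
    background as overlap).
    """
    if threshold <= 0 and threshold != 0:
        raise ValueError("threshold must be >= 0")
    diff_ok = np.abs(profile.red - profile.green) < threshold
    fg_ok = np.minimum(profile.red, profile.green) >= background_floor
    idx = np.nonzero(diff_ok & fg_ok)[0]
    return OverlapResult(profile.axon_id, threshold, tuple(int(i) for i in idx))


def proportion_overlapping_axons(
    profiles: list[IntensityProfile],
    threshold: float,
    background_floor: float = DEFAULT_BACKGROUND_FLOOR,
) -> float:
    """Fraction of axons whose profile has at least one overlapping position."""
    if not profiles:
        raise ValueError("need at least one profile")
    n_overlap = sum(
        overlap_points(p, threshold, background_floor).has_overlap for p in profiles
    )
    return n_overlap / len(profiles)


def threshold_sweep(
    profiles: list[IntensityProfile],
    thresholds,
    background_floor: float = DEFAULT_BACKGROUND_FLOOR,
) -> pd.DataFrame:
    """Proportion of overlapping axons at each threshold (non-decreasing in T)."""
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("threshold grid must ascend")
    props = [
        proportion_overlapping_axons(profiles, t, background_floor)
        for t in thresholds
    ]
    return pd.DataFrame({"threshold": thresholds, "proportion_overlapping": props})


def paranode_length_from_profile(
    positions_um: np.ndarray,
    intensity,
    axon_id: str = "",
    rule: str = "half-max",
    fixed_level: float | None = None,
    background_percentile: float = 10.0,
) -> ParanodeMeasurement:
    """Length of the stained band from a single-channel profile, um.

    Default rule: the contiguous region around the global peak where the
    intensity is at least background + half the peak-above-background, with
    the two boundary positions linearly interpolated between samples.  A
    ``fixed`` rule uses ``fixed_level`` directly.
    """
    pos = np.asarray(positions_um, dtype=float)
    v = np.asarray(intensity, dtype=float)
    if len(pos) != len(v):
        raise ProfileFormatError("position/intensity arrays differ in length")
    if rule == "half-max":
        background = float(np.percentile(v, background_percentile))
        peak = float(np.max(v))
        if peak <= background:
            raise NoParanodeError(f"axon {axon_id}: no region above background")
        level = background + (peak - background) / 2.0
    elif rule == "fixed":
        if fixed_level is None:
            raise ValueError("fixed rule requires fixed_level")
        level = fixed_level
    else:
        raise ValueError(f"unknown measurement rule {rule!r}")

    above = v >= level
    if not np.any(above):
        raise NoParanodeError(f"axon {axon_id}: no region above level {level}")
    i_peak = int(np.argmax(v))
    if not above[i_peak]:
        raise NoParanodeError(f"axon {axon_id}: peak below measurement level")
    i_lo = i_peak
    while i_lo > 0 and above[i_lo - 1]:
        i_lo -= 1
    i_hi = i_peak
    while i_hi < len(v) - 1 and above[i_hi + 1]:
        i_hi += 1

    if i_lo > 0:
        frac = (level - v[i_lo - 1]) / (v[i_lo] - v[i_lo - 1])
        x_lo = pos[i_lo - 1] + frac * (pos[i_lo] - pos[i_lo - 1])
    else:
        x_lo = pos[0]
    if i_hi < len(v) - 1:
        frac = (level - v[i_hi]) / (v[i_hi + 1] - v[i_hi])
        x_hi = pos[i_hi] + frac * (pos[i_hi + 1] - pos[i_hi])
    else:
        x_hi = pos[-1]
    length = x_hi - x_lo
    if length <= 0:
        raise NoParanodeError(f"axon {axon_id}: degenerate band")
    return ParanodeMeasurement(axon_id, float(length), rule)


def read_profiles_csv(path) -> list[IntensityProfile]:
    """Read per-axon profiles from CSV (axon_id, position_um, R, G)."""
    df = pd.read_csv(path)
    required = {"axon_id", "position_um", "R", "G"}
    if not required.issubset(df.columns):
        raise ProfileFormatError(
            f"profile CSV must have columns {sorted(required)}"
        )
    out = []
    for axon_id, sub in df.groupby("axon_id", sort=False):
        sub = sub.sort_values("position_um")
        out.append(
            IntensityProfile(
                str(axon_id),
                sub["position_um"].to_numpy(float),
                sub["R"].to_numpy(float),
                sub["G"].to_numpy(float),
            )
        )
    return out


def write_profiles_csv(profiles: list[IntensityProfile], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "axon_id": p.axon_id,
                "position_um": p.positions_um,
                "R": p.red,
                "G": p.green,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
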