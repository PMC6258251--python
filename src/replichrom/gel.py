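"""Densitometry of electrophoresis lane traces.

A lane scan is reduced upstream to a 1-D trace of intensity against migration
position. Migration distance is linear in log10(fragment size), the standard
approximation for agarose/PAGE gels, so a ladder of known sizes calibrates the
position axis and band areas can be integrated over size windows.

The mono-nucleosomal fraction of a lane (mono band area over total lane area)
is the quantity used to compare MNase sensitivity of nascent chromatin between
strains; its ratio between two lanes is the reported fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .errors import InputError

#: default integration windows in bp, chosen as conventions for budding-yeast
#: chromatin (mono ~147+linker, di ~2x repeat)
DEFAULT_MONO_WINDOW = (120.0, 220.0)
DEFAULT_DI_WINDOW = (280.0, 420.0)
DEFAULT_TOTAL_WINDOW = (50.0, 1000.0)


@dataclass
class LaneTrace:
    """Intensity against migration position for one gel lane.

    ``ladder`` holds (position, size bp) pairs for the size standard run
    alongside; positions are in the same coordinate as ``positions``.
    """

    positions: np.ndarray
    intensities: np.ndarray
    ladder: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise InputError("positions and intensities differ in length")
        if len(self.intensities) and np.any(self.intensities < 0):
            raise InputError("negative intensities")


@dataclass(frozen=True)
class SizeMap:
    """Invertible monotone map between migration position and fragment size.

    position = intercept + slope * log10(size); slope is negative when larger
    fragments migrate less (the usual orientation) but either sign is allowed.
    """

    slope: float
    intercept: float
    position_range: tuple[float, float]

    def size_to_position(self, size: float | np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.log10(np.asarray(size, dtype=float))

    def position_to_size(self, position: float | np.ndarray) -> np.ndarray:
        return 10.0 ** ((np.asarray(position, dtype=float) - self.intercept) / self.slope)


@dataclass
class BandQuant:
    """Integrated band areas of one lane and the derived mono fraction."""

    band_areas: dict[str, float]
    mono_fraction: float
    windows: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.mono_fraction <= 1.0 + 1e-9:
            raise InputError(f"mono_fraction {self.mono_fraction} outside [0, 1]")


def calibrate(ladder: list[tuple[float, float]]) -> SizeMap:
    """Least-squares fit of migration position against log10(size).

    Requires at least two ladder points with distinct sizes; sizes must be
    strictly monotone in position (either orientation), otherwise the lane is
    not interpretable as a single migration axis.
    """
    if len(ladder) < 2:
        raise InputError("ladder needs at least 2 points")
    pos = np.array([p for p, _ in ladder], dtype=float)
    size = np.array([s for _, s in ladder], dtype=float)
    if np.any(size <= 0):
        raise InputError("ladder sizes must be positive")
    if len(set(size.tolist())) != len(size):
        raise InputError("ladder sizes must be distinct")
    order = np.argsort(pos)
    s_sorted = size[order]
    diffs = np.diff(s_sorted)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise InputError("ladder is not monotone in position")
    slope, intercept = np.polyfit(np.log10(size), pos, 1)
    return SizeMap(float(slope), float(intercept), (float(pos.min()), float(pos.max())))


def detect_bands(
    trace: LaneTrace, prominence: float, min_separation: int = 1
) -> list[tuple[float, float]]:
    """Local maxima of the trace exceeding ``prominence``, at least
    ``min_separation`` points apart. Returns (position, height) pairs."""
    if prominence <= 0:
        raise InputError("prominence must be positive")
    idx, _ = find_peaks(
        trace.intensities, prominence=prominence, distance=max(1, int(min_separation))
    )
    return [(float(trace.positions[i]), float(trace.intensities[i])) for i in idx]


def subtract_baseline(intensities: np.ndarray, window: int) -> np.ndarray:
    """Rolling baseline subtraction for lane traces.

    The baseline at each point is the larger of a rolling minimum and a
    rolling median of a lightly pre-smoothed copy of the trace, so it hugs
    both a drifting offset and the floor of zero-clipped scanner noise while
    staying below bands narrower than half the window. The signed residual
    is returned (not floored), so that symmetric noise integrates to ~zero
    over a quantification window instead of inflating it.
    """
    w = max(3, int(window))
    smoothed = uniform_filter1d(intensities, size=max(3, w // 5), mode="nearest")
    floor = minimum_filter1d(smoothed, size=w, mode="nearest")
    # the median window is twice the minimum window so that bands occupying
    # up to half of it do not lift the estimated level
    level = median_filter(smoothed, size=2 * w + 1, mode="nearest")
    return intensities - np.maximum(floor, level)


def _integrate_window(
    positions: np.ndarray,
    corrected: np.ndarray,
    size_map: SizeMap,
    size_window: tuple[float, float],
) -> float:
    lo_p, hi_p = sorted(float(p) for p in size_map.size_to_position(np.array(size_window)))
    pmin, pmax = positions.min(), positions.max()
    if lo_p < pmin - 1e-9 or hi_p > pmax + 1e-9:
        raise InputError(
            f"size window {size_window} maps to positions ({lo_p:.1f}, {hi_p:.1f}) "
            f"outside the trace range ({pmin:.1f}, {pmax:.1f})"
        )
    mask = (positions >= lo_p) & (positions <= hi_p)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(corrected[mask], positions[mask]))


def quantify_mono_fraction(
    trace: LaneTrace,
    size_map: SizeMap,
    mono_window: tuple[float, float] = DEFAULT_MONO_WINDOW,
    di_window: tuple[float, float] = DEFAULT_DI_WINDOW,
    total_window: tuple[float, float] = DEFAULT_TOTAL_WINDOW,
    baseline_frac: float = 0.1,
) -> BandQuant:
    """Integrate background-subtracted intensity over size windows.

    ``mono_window`` must lie inside ``total_window``; the mono fraction is the
    mono area divided by the total-lane area, matching the 'proportion of
    mono-nucleosomal to total nascent DNA' readout of blot densitometry.
    """
    if not (total_window[0] <= mono_window[0] and mono_window[1] <= total_window[1]):
        raise InputError("mono_window must be contained in total_window")
    corrected = subtract_baseline(
        trace.intensities, int(baseline_frac * len(trace.intensities))
    )
    areas = {
        "mono": _integrate_window(trace.positions, corrected, size_map, mono_window),
        "di": _integrate_window(trace.positions, corrected, size_map, di_window),
        "total": _integrate_window(trace.positions, corrected, size_map, total_window),
    }
    total = areas["total"]
    mono_fraction = areas["mono"] / total if total > 0 else 0.0
    return BandQuant(
        band_areas=areas,
        mono_fraction=min(1.0, mono_fraction),
        windows={"mono": mono_window, "di": di_window, "total": total_window},
    )


def fold_change(a: BandQuant, b: BandQuant) -> float:
    """Ratio of mono fractions a/b (e.g. mutant over wild type)."""
    if b.mono_fraction <= 0:
        raise InputError("denominator lane has zero mono fraction")
    return a.mono_fraction / b.mono_fraction
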