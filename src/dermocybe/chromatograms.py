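"""HPLC-DAD chromatogram processing: channel summation, peak calling,
retention-time annotation and semi-quantitative profile construction.

Processing follows the study protocol for pigment profiling: the three
detector channels (428, 478 and 519 nm, covering the yellow-to-red colour
range of the anthraquinones) are summed into one trace; peaks are detected
against a 5% relative-height threshold; each peak's height is expressed as a
percentage of the tallest peak (set to 100%); peaks below 10% of the tallest
are classified as trace pigments, the rest as main pigments; and peaks are
assigned to library compounds by retention-time proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks

from .pigments import PigmentLibrary, SpeciesPigmentProfile


@dataclass
class Chromatogram:
    """Multi-channel absorbance trace on a common, strictly increasing time grid."""

    time: np.ndarray
    absorbance_428: np.ndarray
    absorbance_478: np.ndarray
    absorbance_519: np.ndarray
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance_428 = np.asarray(self.absorbance_428, dtype=float)
        self.absorbance_478 = np.asarray(self.absorbance_478, dtype=float)
        self.absorbance_519 = np.asarray(self.absorbance_519, dtype=float)
        n = len(self.time)
        if n < 2:
            raise ValueError("chromatogram needs at least 2 time points")
        for name in ("absorbance_428", "absorbance_478", "absorbance_519"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length differs from time grid")
        if not (np.diff(self.time) > 0).all():
            bad = int(np.flatnonzero(np.diff(self.time) <= 0)[0]) + 1
            raise ValueError(f"time grid not strictly increasing at row {bad}")

    @property
    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.absorbance_428, self.absorbance_478, self.absorbance_519


@dataclass
class PeakCall:
    """One called chromatogram peak.

    ``relative_height`` is in percent of the tallest called peak (the tallest
    peak itself is 100 and always a main pigment); ``pigment_id`` is None
    until annotation, or stays None for peaks matching no library compound.
    """

    apex_time: float
    height: float
    relative_height: float
    pigment_id: int | None = None
    level: str | None = None


@dataclass
class PeakCallingConfig:
    """Tunable processing parameters.

    detection_threshold
        Minimum peak height in percent of the tallest peak (study default 5).
    trace_main_boundary
        Relative height (percent) separating trace from main pigments
        (study default 10; the boundary value itself counts as main).
    rt_match_tolerance
        Maximum |apex - reference| retention-time difference (minutes) for a
        peak to be assigned to a library compound.
    min_prominence
        Required topographic prominence in percent of the global maximum.
    baseline_window
        Width, in samples, of the rolling-minimum baseline estimator.
    forced_apices
        Retention times (minutes) whose nearest grid point is always reported
        as a peak - the programmatic stand-in for manual peak addition.
    """

    detection_threshold: float = 5.0
    trace_main_boundary: float = 10.0
    rt_match_tolerance: float = 0.1
    min_prominence: float = 1.0
    baseline_window: int = 20
    forced_apices: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0 < self.detection_threshold < self.trace_main_boundary <= 100:
            raise ValueError(
                "need 0 < detection_threshold < trace_main_boundary <= 100"
            )
        if self.rt_match_tolerance <= 0 or self.min_prominence < 0:
            raise ValueError("invalid tolerance/prominence")


def sum_channels(c: Chromatogram) -> np.ndarray:
    """Pointwise sum of the three detector channels on the shared time grid."""
    a, b, d = c.channels
    return a + b + d


def subtract_baseline(trace: np.ndarray, window: int) -> np.ndarray:
    """Rolling-minimum baseline subtraction (window in samples)."""
    if window <= 1:
        return trace - trace.min()
    baseline = minimum_filter1d(trace, size=window, mode="nearest")
    return trace - baseline


def call_peaks(
    time: np.ndarray, trace: np.ndarray, config: PeakCallingConfig | None = None
) -> list[PeakCall]:
    """Detect peaks in a single (summed) trace.

    Local maxima of the baseline-subtracted trace with prominence of at least
    ``min_prominence`` percent of the global maximum are kept when their
    height reaches ``detection_threshold`` percent of the tallest such peak.
    A flat or empty trace yields an empty list.  Calls are sorted by apex time
    and carry relative heights normalised to the tallest peak (= 100).
    """
    config = config or PeakCallingConfig()
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 3:
        raise ValueError("trace needs at least 3 points for peak detection")
    y = subtract_baseline(trace, config.baseline_window)
    ymax = y.max()
    if ymax <= 0:
        return []
    idx, _ = find_peaks(y, prominence=config.min_prominence / 100.0 * ymax)
    idx = set(idx.tolist())
    for rt in config.forced_apices:
        idx.add(int(np.argmin(np.abs(time - rt))))
    if not idx:
        return []
    indices = sorted(idx)
    heights = y[indices]
    max_height = heights.max()
    calls = [
        PeakCall(
            apex_time=float(time[i]),
            height=float(h),
            # divide first so the tallest peak is exactly 100
            relative_height=float(100.0 * (h / max_height)),
        )
        for i, h in zip(indices, heights)
        if 100.0 * (h / max_height) >= config.detection_threshold
    ]
    return calls


def classify_levels(
    calls: list[PeakCall], config: PeakCallingConfig | None = None
) -> list[PeakCall]:
    """Set each call's level: trace below the boundary, main at or above it."""
    config = config or PeakCallingConfig()
    for call in calls:
        if not 0 < call.relative_height <= 100:
            raise ValueError("relative heights must be populated and in (0, 100]")
        call.level = (
            "main" if call.relative_height >= config.trace_main_boundary else "trace"
        )
    return calls


def annotate_peaks(
    calls: list[PeakCall],
    library: PigmentLibrary,
    config: PeakCallingConfig | None = None,
) -> list[PeakCall]:
    """Assign peaks to library compounds by retention time.

    Each call is matched to the library compound whose reference retention
    time lies within ``rt_match_tolerance``; a compound claims at most one
    call (the nearest apex wins, remaining calls stay unassigned).  Libraries
    whose compounds are closer together than twice the tolerance are rejected
    as unresolvable.
    """
    config = config or PeakCallingConfig()
    if library.min_rt_spacing() <= 2 * config.rt_match_tolerance:
        raise ValueError(
            "library retention times closer than twice the match tolerance"
        )
    pairs = []
    for ci, call in enumerate(calls):
        for compound in library:
            delta = abs(call.apex_time - compound.reference_rt)
            if delta <= config.rt_match_tolerance:
                pairs.append((delta, ci, compound.id))
    taken_calls: set[int] = set()
    taken_pigments: set[int] = set()
    for call in calls:
        call.pigment_id = None
    for delta, ci, pid in sorted(pairs):
        if ci in taken_calls or pid in taken_pigments:
            continue
        calls[ci].pigment_id = pid
        taken_calls.add(ci)
        taken_pigments.add(pid)
    return calls


def profile_from_peaks(calls: list[PeakCall], species: str = "") -> SpeciesPigmentProfile:
    """Collapse annotated, level-classified calls into a species profile.

    Unassigned calls are reported as unknown peaks (apex times) rather than
    silently dropped; duplicate pigment assignments are an error upstream.
    """
    levels: dict[int, str] = {}
    quantities: dict[int, float] = {}
    unknown: list[float] = []
    for call in calls:
        if call.level is None:
            raise ValueError("calls must be level-classified before profiling")
        if call.pigment_id is None:
            unknown.append(call.apex_time)
            continue
        if call.pigment_id in levels:
            raise ValueError(f"duplicate pigment id {call.pigment_id} among calls")
        levels[call.pigment_id] = call.level
        quantities[call.pigment_id] = call.relative_height
    return SpeciesPigmentProfile(
        species=species,
        levels=levels,
        quantities=quantities or None,
        unknown_peaks=unknown,
    )


def process_chromatogram(
    c: Chromatogram,
    library: PigmentLibrary,
    config: PeakCallingConfig | None = None,
) -> tuple[SpeciesPigmentProfile, list[PeakCall]]:
    """Full pipeline: sum channels, call, classify, annotate, profile."""
    config = config or PeakCallingConfig()
    trace = sum_channels(c)
    calls = call_peaks(c.time, trace, config)
    classify_levels(calls, config)
    annotate_peaks(calls, library, config)
    return profile_from_peaks(calls, species=c.sample_label), calls
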