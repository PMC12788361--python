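"""Cycle detection and four-phase segmentation from plantar pressure.

The slideboard cycle is delimited by pressure onset (first foot-board
contact) and pressure disappearance (end of push-off). Within the cycle,
the multi-source feature rules are:

* b1 (initial -> double support): end of the loading ramp, i.e. start of
  the first sustained low-slope pressure segment (the plateau),
* b2 (double -> single support): first local pressure peak after the
  plateau with sufficient prominence,
* b3 (single support -> push-off): last local pressure minimum (the
  distinct trough) before the global pressure maximum; push-off contains
  the global maximum.

All thresholds are specified relative to the cycle's pressure peak and
peak slope, so segmentation is invariant to uniform pressure rescaling.
Joint-angle features (hip-abduction minimum inside single support,
maximal knee-extension rate inside push-off) confirm the boundaries but
are advisory only: failures are reported, not fatal, because the study's
hard arbiter (motion video) is outside this package's scope.

Segmentation expects Kalman-smoothed signals; the pressure derivative can
be taken from the filter's velocity state (preferred) or falls back to
central differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .errors import (
    ConfigurationError,
    DataError,
    DegeneratePressureError,
    IncompleteCycleError,
    NoCycleError,
    PlateauNotFoundError,
)
from .synthetic import PHASES

__all__ = [
    "SegmentationParams",
    "PhaseSegmentation",
    "detect_cycle",
    "detect_all_cycles",
    "segment_phases",
]


@dataclass(frozen=True)
class SegmentationParams:
    sampling_rate: float = 100.0
    onset_floor: float = 5.0  # newtons; onset threshold = max(floor, onset_frac * peak)
    onset_frac: float = 0.02
    hold: int = 5  # hysteresis: samples a crossing must persist
    plateau_slope_frac: float = 0.10  # of the cycle's peak |dF/dt|
    plateau_min_duration: float = 0.15  # seconds
    peak_prominence_frac: float = 0.10  # of the cycle's pressure peak
    # centered median window (samples) applied to dF/dt before thresholding;
    # odd window w leaves a clean step boundary exactly in place while
    # suppressing noise spikes that would fragment the plateau run
    slope_median_window: int = 9

    def onset_threshold(self, peak: float) -> float:
        return max(self.onset_floor, self.onset_frac * peak)


@dataclass
class PhaseSegmentation:
    """Cycle bounds plus the three interior boundaries (all 0-based sample
    indices; intervals are half-open)."""

    cycle_start: int
    cycle_end: int
    boundaries: tuple[int, int, int]
    sampling_rate: float
    feature_evidence: dict = field(default_factory=dict)
    confirmations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        b1, b2, b3 = self.boundaries
        if not (self.cycle_start < b1 < b2 < b3 < self.cycle_end):
            raise DataError(
                "phase boundaries must satisfy start < b1 < b2 < b3 < end, got "
                f"{self.cycle_start} {self.boundaries} {self.cycle_end}"
            )

    def intervals(self) -> dict[str, tuple[int, int]]:
        """Contiguous, exhaustive half-open phase intervals."""
        edges = [self.cycle_start, *self.boundaries, self.cycle_end]
        return {ph: (edges[i], edges[i + 1]) for i, ph in enumerate(PHASES)}

    def interval_times(self) -> dict[str, tuple[float, float]]:
        fs = self.sampling_rate
        return {ph: (lo / fs, hi / fs) for ph, (lo, hi) in self.intervals().items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cycle_start": int(self.cycle_start),
            "cycle_end": int(self.cycle_end),
            "boundaries": [int(b) for b in self.boundaries],
            "sampling_rate": self.sampling_rate,
            "intervals": {p: [int(a), int(b)] for p, (a, b) in self.intervals().items()},
            "interval_times_s": {p: [a, b] for p, (a, b) in self.interval_times().items()},
            "feature_evidence": self.feature_evidence,
            "confirmations": self.confirmations,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_bed(self, path: str | Path) -> None:
        """BED-like interval export (cycle-relative sample coordinates)."""
        lines = [
            f"{lo - self.cycle_start}\t{hi - self.cycle_start}\t{ph}"
            for ph, (lo, hi) in self.intervals().items()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _bursts(above: np.ndarray, hold: int) -> list[tuple[int, int | None]]:
    """Sustained threshold crossings as (start, end|None) half-open pairs."""
    n = len(above)
    out: list[tuple[int, int | None]] = []
    i = 0
    while i < n:
        if above[i] and (i == 0 or not above[i - 1]):
            seg = above[i : i + hold]
            if seg.all():  # truncated window at array end counts as sustained
                # find sustained fall-off
                j = i + 1
                end = None
                while j < n:
                    if not above[j] and not above[j : j + hold].any():
                        end = j
                        break
                    j += 1
                out.append((i, end))
                if end is None:
                    break
                i = end
                continue
        i += 1
    return out


def detect_cycle(
    pressure: np.ndarray,
    onset_threshold: float | None = None,
    hold: int = 5,
    cycle_index: int = 0,
    params: SegmentationParams | None = None,
) -> tuple[int, int]:
    """Locate the ``cycle_index``-th complete loading burst.

    Returns the half-open sample interval ``[start, end)``: ``start`` is
    the first index at which pressure rises to and holds above the onset
    threshold, ``end`` the first subsequent index where it falls and stays
    below.
    """
    p = np.asarray(pressure, dtype=float)
    if len(p) < 10:
        raise DataError("pressure series too short (need >= 10 samples)")
    if not np.all(np.isfinite(p)):
        raise DataError("pressure series contains non-finite samples")
    if onset_threshold is None:
        onset_threshold = (params or SegmentationParams()).onset_threshold(p.max())
    if onset_threshold <= 0:
        raise ConfigurationError("onset threshold must be > 0")

    bursts = _bursts(p >= onset_threshold, hold)
    if not bursts:
        raise NoCycleError("no cycle found: pressure never crosses the onset threshold")
    if cycle_index >= len(bursts):
        raise NoCycleError(f"only {len(bursts)} cycle(s) present, asked for index {cycle_index}")
    start, end = bursts[cycle_index]
    if end is None:
        raise IncompleteCycleError(
            "incomplete cycle: pressure crosses the onset threshold but never returns below it"
        )
    return start, end


def detect_all_cycles(
    pressure: np.ndarray,
    onset_threshold: float | None = None,
    hold: int = 5,
    params: SegmentationParams | None = None,
) -> list[tuple[int, int]]:
    """All complete loading bursts, in temporal order (incomplete trailing
    bursts are dropped). In multi-burst training recordings the middle
    burst is the steady-state cycle of interest."""
    p = np.asarray(pressure, dtype=float)
    if len(p) < 10:
        raise DataError("pressure series too short (need >= 10 samples)")
    if onset_threshold is None:
        onset_threshold = (params or SegmentationParams()).onset_threshold(p.max())
    bursts = [(a, b) for a, b in _bursts(p >= onset_threshold, hold) if b is not None]
    if not bursts:
        raise NoCycleError("no complete cycle found")
    return bursts


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def segment_phases(
    pressure: np.ndarray,
    angles: Mapping[str, np.ndarray] | None = None,
    params: SegmentationParams | None = None,
    pressure_velocity: np.ndarray | None = None,
    cycle: tuple[int, int] | None = None,
) -> PhaseSegmentation:
    """Partition one cycle into the four ordered phases.

    ``pressure`` (and ``angles``) should be Kalman-smoothed full-length
    series; ``pressure_velocity`` may supply the filter's dF/dt state
    estimate, otherwise central differences are used. ``cycle`` overrides
    cycle detection.
    """
    params = params or SegmentationParams()
    p = np.asarray(pressure, dtype=float)
    if cycle is None:
        cycle = detect_cycle(p, hold=params.hold, params=params)
    start, end = cycle
    seg = p[start:end]
    if len(seg) < 10:
        raise DataError("detected cycle too short to segment")
    peak_val = seg.max()

    if pressure_velocity is not None:
        dp = np.asarray(pressure_velocity, dtype=float)[start:end]
    else:
        dp = np.gradient(seg, 1.0 / params.sampling_rate)
    if params.slope_median_window > 1:
        dp = median_filter(dp, size=params.slope_median_window, mode="nearest")
    slope_thr = params.plateau_slope_frac * np.abs(dp).max()
    min_len = max(2, int(round(params.plateau_min_duration * params.sampling_rate)))

    low = np.abs(dp) < slope_thr
    plateau = next(((a, b) for a, b in _runs(low) if b - a >= min_len), None)
    if plateau is None:
        raise PlateauNotFoundError(
            "plateau not detected: no |dF/dt| run below "
            f"{slope_thr:.3g} lasting >= {min_len} samples"
        )
    b1_rel, plateau_end_rel = plateau

    m_rel = int(np.argmax(seg))
    if b1_rel <= m_rel < plateau_end_rel:
        raise DegeneratePressureError("degenerate pressure profile: global maximum inside the plateau")

    prominence = params.peak_prominence_frac * peak_val
    peaks, _ = find_peaks(seg, prominence=prominence)
    peaks = peaks[peaks >= plateau_end_rel]
    if len(peaks) == 0:
        raise DegeneratePressureError("degenerate pressure profile: no prominent peak after the plateau")
    b2_rel = int(peaks[0])
    b2_evidence = "first pressure peak"
    if b2_rel == m_rel:
        # single first peak coincides with the global maximum: fall back to
        # the preceding local minimum (the pre-push-off trough)
        troughs, _ = find_peaks(-seg[:m_rel])
        troughs = troughs[troughs > b1_rel]
        if len(troughs) == 0:
            raise DegeneratePressureError(
                "degenerate pressure profile: single peak with no preceding trough"
            )
        b2_rel = int(troughs[-1])
        b2_evidence = "local minimum preceding the single prominent peak"

    troughs, _ = find_peaks(-seg[b2_rel:m_rel + 1])
    troughs = troughs + b2_rel
    if len(troughs) == 0:
        raise DegeneratePressureError(
            "degenerate pressure profile: no trough between the first peak and the global maximum"
        )
    b3_rel = int(troughs[-1])

    segmentation = PhaseSegmentation(
        cycle_start=start,
        cycle_end=end,
        boundaries=(start + b1_rel, start + b2_rel, start + b3_rel),
        sampling_rate=params.sampling_rate,
        feature_evidence={
            "b1": "onset of the first pressure plateau (sustained low |dF/dt|)",
            "b2": b2_evidence,
            "b3": "last pressure trough before the global maximum",
            "global_max_index": int(start + m_rel),
            "onset_threshold_N": params.onset_threshold(p.max()),
            "plateau_slope_threshold": float(slope_thr),
        },
    )
    if angles is not None:
        segmentation.confirmations = _confirm_with_angles(segmentation, angles, params)
    return segmentation


def _confirm_with_angles(
    seg: PhaseSegmentation,
    angles: Mapping[str, np.ndarray],
    params: SegmentationParams,
) -> list[dict]:
    """Advisory angle-feature checks for each boundary."""
    intervals = seg.intervals()
    reports: list[dict] = []

    if "hip_abd_deg" in angles:
        abd = np.asarray(angles["hip_abd_deg"], dtype=float)
        idx = seg.cycle_start + int(np.argmin(abd[seg.cycle_start : seg.cycle_end]))
        lo, hi = intervals["single_support"]
        reports.append(
            {
                "check": "hip-abduction minimum falls in single support",
                "passed": bool(lo <= idx < hi),
                "index": idx,
            }
        )
    if "knee_flex_deg" in angles:
        knee = np.asarray(angles["knee_flex_deg"], dtype=float)
        rate = np.gradient(knee, 1.0 / params.sampling_rate)
        idx = seg.cycle_start + int(np.argmin(rate[seg.cycle_start : seg.cycle_end]))
        lo, hi = intervals["push_off"]
        reports.append(
            {
                "check": "maximal knee-extension rate falls in push-off",
                "passed": bool(lo <= idx < hi),
                "index": idx,
            }
        )
    return reports
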