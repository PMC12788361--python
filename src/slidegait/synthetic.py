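"""Synthetic bilateral slideboard-cycle generator.

One slideboard speed-skating cycle runs from first foot-board contact
(plantar pressure rising from zero) to the end of push-off (pressure back to
zero) and is divided into four phases: initial loading ramp, double-leg
support gliding (pressure plateau), single-leg support (first pressure
peak), and push-off (maximal pressure peak followed by unloading).

The generator emulates the *signal statistics* of that cycle, not its
physics: per-phase endpoint targets for the four joint-angle channels
(degrees) and the total plantar-pressure channel (newtons) are joined by
monotone cubic (PCHIP) interpolation inside each phase, and i.i.d. Gaussian
sensor noise is added per channel. Default amplitude targets are calibrated
to the published phase-wise values of an elite-youth slideboard session
(e.g. initial-phase left hip/knee/ankle flexion 108.7/95.8/23.1 deg,
push-off pressure peaks 298.9 N left / 332.0 N right). Ground truth (exact
phase-boundary sample indices, the noiseless trajectories, and - when
pressure is co-generated from an angle - the true cubic coefficients) is
returned alongside every recording so downstream stages can be tested
against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError, DataError

__all__ = [
    "ANGLE_CHANNELS",
    "PRESSURE_CHANNEL",
    "CHANNELS",
    "PHASES",
    "PhaseProfile",
    "CouplingSpec",
    "SyntheticConfig",
    "MultimodalRecording",
    "GroundTruth",
    "default_config",
    "generate_cycle",
    "generate_coupled_pressure",
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "config_to_yaml",
    "config_from_yaml",
]

ANGLE_CHANNELS = ("hip_flex_deg", "hip_abd_deg", "knee_flex_deg", "ankle_dorsi_deg")
PRESSURE_CHANNEL = "pressure_N"
CHANNELS = ANGLE_CHANNELS + (PRESSURE_CHANNEL,)
PHASES = ("initial", "double_support", "single_support", "push_off")

Knots = tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class PhaseProfile:
    """Endpoint targets for one phase of the cycle.

    ``angle_targets`` maps each angle channel to a knot sequence
    ``((fraction_within_phase, value_deg), ...)``; ``pressure_targets`` is
    the analogous knot sequence in newtons. Knot fractions must start at 0,
    end at 1 and be strictly increasing; the endpoint knots double as the
    phase's entry/exit targets, interior knots shape peaks and troughs.
    """

    phase_label: str
    duration: float
    angle_targets: Mapping[str, Knots]
    pressure_targets: Knots

    def __post_init__(self) -> None:
        if self.phase_label not in PHASES:
            raise ConfigurationError(f"unknown phase label {self.phase_label!r}")
        if not self.duration > 0:
            raise ConfigurationError(
                f"phase {self.phase_label!r} duration must be > 0, got {self.duration}"
            )
        for name, knots in list(self.angle_targets.items()) + [
            (PRESSURE_CHANNEL, self.pressure_targets)
        ]:
            fracs = [f for f, _ in knots]
            if len(knots) < 2 or fracs[0] != 0.0 or fracs[-1] != 1.0:
                raise ConfigurationError(
                    f"{self.phase_label}/{name}: knots must span fractions 0..1"
                )
            if any(b <= a for a, b in zip(fracs, fracs[1:])):
                raise ConfigurationError(
                    f"{self.phase_label}/{name}: knot fractions must strictly increase"
                )
        if any(v < 0 for _, v in self.pressure_targets):
            raise ConfigurationError("pressure targets must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Co-generate pressure as a cubic in one standardized joint angle."""

    joint: str
    coefficients: tuple[float, float, float]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.joint not in ANGLE_CHANNELS:
            raise ConfigurationError(f"unknown joint channel {self.joint!r}")
        if self.noise_sd < 0:
            raise ConfigurationError("coupling noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    sampling_rate: float = 100.0
    left_profiles: tuple[PhaseProfile, ...] = ()
    right_profiles: tuple[PhaseProfile, ...] = ()
    angle_noise_sd: float = 1.0
    pressure_noise_sd: float = 2.0
    coupling: CouplingSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.angle_noise_sd < 0 or self.pressure_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        for side, profiles in (("left", self.left_profiles), ("right", self.right_profiles)):
            labels = tuple(p.phase_label for p in profiles)
            if labels != PHASES:
                raise ConfigurationError(
                    f"{side}_profiles must contain the four phases in order {PHASES}, got {labels}"
                )
            # cycle starts and ends at zero load
            if profiles[0].pressure_targets[0][1] != 0.0:
                raise ConfigurationError(f"{side}: initial phase must start at 0 N")
            if profiles[-1].pressure_targets[-1][1] != 0.0:
                raise ConfigurationError(f"{side}: push_off phase must end at 0 N")

    def profiles_for(self, side: str) -> tuple[PhaseProfile, ...]:
        if side == "left":
            return self.left_profiles
        if side == "right":
            return self.right_profiles
        raise ConfigurationError(f"side must be 'left' or 'right', got {side!r}")


@dataclass
class MultimodalRecording:
    """Per-limb synchronized time series: 4 angle channels + pressure."""

    side: str
    sampling_rate: float
    data: pd.DataFrame  # columns: time_s + CHANNELS

    @property
    def n(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    @property
    def pressure(self) -> np.ndarray:
        return self.channel(PRESSURE_CHANNEL)


@dataclass
class GroundTruth:
    """Exact generator-side truth for one cycle.

    ``boundaries`` holds ``[0, b1, b2, b3, n]``: half-open sample intervals
    of the four phases partitioning ``[0, n)``.
    """

    boundaries: np.ndarray
    noiseless: pd.DataFrame
    coefficients: tuple[float, float, float] | None
    seed: int

    def phase_interval(self, phase: str) -> tuple[int, int]:
        i = PHASES.index(phase)
        return int(self.boundaries[i]), int(self.boundaries[i + 1])


def _profile(label: str, duration: float, angles: dict[str, Knots], pressure: Knots) -> PhaseProfile:
    return PhaseProfile(label, duration, angles, pressure)


def default_config(seed: int = 0) -> SyntheticConfig:
    """Config calibrated to the published phase-wise amplitude levels.

    Endpoint targets: initial-phase hip/knee/ankle flexion 108.7/95.8/23.1
    deg left and 115.6/95.5/23.7 right, hip abduction -2.4 left / 12.3
    right; plateau bands 90-148 N left and 140-193 N right; first pressure
    peaks 251.9/313.4 N; push-off peaks 298.9/332.0 N; terminal abduction
    51.0/53.3 deg. Noise defaults: 1.0 deg (angles), 2.0 N (pressure).
    Cycle durations 3.25 s / 3.24 s at 100 Hz give 326/325 samples,
    split into four equal-duration phases.
    """
    ql = 3.25 / 4.0
    qr = 3.24 / 4.0
    left = (
        _profile(
            "initial", ql,
            {
                "hip_flex_deg": ((0, 108.7), (1, 112.0)),
                "hip_abd_deg": ((0, -2.4), (1, -2.0)),
                "knee_flex_deg": ((0, 95.8), (1, 94.5)),
                "ankle_dorsi_deg": ((0, 23.1), (1, 22.0)),
            },
            ((0, 0.0), (0.04, 10.0), (0.35, 40.0), (0.7, 67.0), (1, 90.0)),
        ),
        _profile(
            "double_support", ql,
            {
                "hip_flex_deg": ((0, 112.0), (0.4, 121.2), (1, 111.2)),
                "hip_abd_deg": ((0, -2.0), (1, 18.3)),
                "knee_flex_deg": ((0, 94.5), (1, 66.7)),
                "ankle_dorsi_deg": ((0, 22.0), (1, 15.9)),
            },
            ((0, 90.0), (0.3, 98.0), (0.5, 104.0), (0.68, 160.0), (0.85, 215.0), (1, 251.9)),
        ),
        _profile(
            "single_support", ql,
            {
                "hip_flex_deg": ((0, 111.2), (0.55, 120.8), (1, 118.0)),
                "hip_abd_deg": ((0, 18.3), (0.75, -3.0), (1, 2.0)),
                "knee_flex_deg": ((0, 66.7), (0.8, 79.9), (1, 75.1)),
                "ankle_dorsi_deg": ((0, 15.9), (0.9, 22.5), (1, 22.0)),
            },
            ((0, 251.9), (0.5, 215.0), (1, 195.0)),
        ),
        _profile(
            "push_off", ql,
            {
                "hip_flex_deg": ((0, 118.0), (1, 89.7)),
                "hip_abd_deg": ((0, 2.0), (1, 51.0)),
                "knee_flex_deg": ((0, 75.1), (1, 29.5)),
                "ankle_dorsi_deg": ((0, 22.0), (1, -4.2)),
            },
            ((0, 195.0), (0.2, 240.0), (0.4, 298.9), (0.6, 200.0), (0.8, 95.0), (1, 0.0)),
        ),
    )
    right = (
        _profile(
            "initial", qr,
            {
                "hip_flex_deg": ((0, 115.6), (1, 113.0)),
                "hip_abd_deg": ((0, 12.3), (1, 13.0)),
                "knee_flex_deg": ((0, 95.5), (1, 94.0)),
                "ankle_dorsi_deg": ((0, 23.7), (1, 22.5)),
            },
            ((0, 0.0), (0.04, 12.0), (0.35, 60.0), (0.7, 105.0), (1, 140.0)),
        ),
        _profile(
            "double_support", qr,
            {
                "hip_flex_deg": ((0, 113.0), (1, 107.6)),
                "hip_abd_deg": ((0, 13.0), (1, 21.1)),
                "knee_flex_deg": ((0, 94.0), (1, 66.5)),
                "ankle_dorsi_deg": ((0, 22.5), (1, 16.5)),
            },
            ((0, 140.0), (0.3, 148.0), (0.5, 155.0), (0.68, 215.0), (0.85, 275.0), (1, 313.4)),
        ),
        _profile(
            "single_support", qr,
            {
                "hip_flex_deg": ((0, 107.6), (0.6, 121.8), (1, 119.0)),
                "hip_abd_deg": ((0, 21.1), (0.75, -1.6), (1, 2.0)),
                "knee_flex_deg": ((0, 66.5), (0.8, 83.5), (1, 78.0)),
                "ankle_dorsi_deg": ((0, 16.5), (0.9, 27.0), (1, 26.0)),
            },
            ((0, 313.4), (0.5, 270.0), (1, 250.0)),
        ),
        _profile(
            "push_off", qr,
            {
                "hip_flex_deg": ((0, 119.0), (1, 80.8)),
                "hip_abd_deg": ((0, 2.0), (1, 53.3)),
                "knee_flex_deg": ((0, 78.0), (1, 30.7)),
                "ankle_dorsi_deg": ((0, 26.0), (0.6, 3.9), (1, 6.0)),
            },
            ((0, 250.0), (0.2, 295.0), (0.4, 332.0), (0.6, 225.0), (0.8, 105.0), (1, 0.0)),
        ),
    )
    return SyntheticConfig(left_profiles=left, right_profiles=right, seed=seed)


def _phase_boundaries(profiles: Sequence[PhaseProfile], fs: float) -> tuple[np.ndarray, int]:
    """Sample-index boundaries [0, b1, b2, b3, n] for half-open intervals."""
    edges = np.concatenate([[0.0], np.cumsum([p.duration for p in profiles])])
    n = int(round(edges[-1] * fs)) + 1
    idx = np.round(edges * fs).astype(int)
    idx[-1] = n - 1
    if np.any(np.diff(idx) < 2):
        raise ConfigurationError("phase durations too short for the sampling rate")
    bounds = idx.copy()
    bounds[-1] = n  # half-open partition of [0, n)
    return bounds, n


def _interp_channel(profiles: Sequence[PhaseProfile], channel: str, fs: float) -> np.ndarray:
    """Piecewise monotone cubic trajectory; knot times snapped to samples."""
    bounds, n = _phase_boundaries(profiles, fs)
    knot_idx = np.concatenate([[0], np.round(np.cumsum([p.duration for p in profiles]) * fs)]).astype(int)
    knot_idx[-1] = n - 1
    out = np.empty(n)
    for p_i, prof in enumerate(profiles):
        lo, hi = knot_idx[p_i], knot_idx[p_i + 1]
        knots = prof.pressure_targets if channel == PRESSURE_CHANNEL else prof.angle_targets[channel]
        ki = np.array([lo + round(f * (hi - lo)) for f, _ in knots], dtype=float)
        kv = np.array([v for _, v in knots], dtype=float)
        ki, keep = np.unique(ki, return_index=True)
        kv = kv[keep]
        if len(ki) < 2:
            raise ConfigurationError("phase too short for its knot sequence")
        samples = np.arange(lo, hi + 1)
        out[lo : hi + 1] = PchipInterpolator(ki, kv)(samples)
    return out


def generate_cycle(
    config: SyntheticConfig, side: str
) -> tuple[MultimodalRecording, GroundTruth]:
    """Generate one noisy cycle for ``side`` plus its ground truth.

    Identical ``config`` (including seed) reproduces the output
    bit-for-bit. Pressure is clipped to >= 0 after noise, with the first
    and last cycle samples pinned to exactly 0 N (zero load at contact and
    lift-off).
    """
    profiles = config.profiles_for(side)
    fs = config.sampling_rate
    bounds, n = _phase_boundaries(profiles, fs)

    noiseless = pd.DataFrame({"time_s": np.arange(n) / fs})
    for ch in ANGLE_CHANNELS:
        noiseless[ch] = _interp_channel(profiles, ch, fs)
    noiseless[PRESSURE_CHANNEL] = _interp_channel(profiles, PRESSURE_CHANNEL, fs)

    side_key = 0 if side == "left" else 1
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, side_key]))

    data = noiseless.copy()
    coeffs = None
    if config.coupling is not None:
        coeffs = tuple(config.coupling.coefficients)
        joint = noiseless[config.coupling.joint].to_numpy()
        data[PRESSURE_CHANNEL] = generate_coupled_pressure(
            joint, coeffs, config.coupling.noise_sd, rng=rng
        )
        noiseless[PRESSURE_CHANNEL] = generate_coupled_pressure(joint, coeffs, 0.0)
    for ch in ANGLE_CHANNELS:
        data[ch] = data[ch].to_numpy() + rng.normal(0.0, config.angle_noise_sd, n)
    if config.coupling is None:
        p = data[PRESSURE_CHANNEL].to_numpy() + rng.normal(0.0, config.pressure_noise_sd, n)
        p = np.clip(p, 0.0, None)
        p[0] = 0.0
        p[-1] = 0.0
        data[PRESSURE_CHANNEL] = p

    rec = MultimodalRecording(side=side, sampling_rate=fs, data=data)
    gt = GroundTruth(boundaries=bounds, noiseless=noiseless, coefficients=coeffs, seed=config.seed)
    return rec, gt


def generate_coupled_pressure(
    angle: np.ndarray,
    coefficients: tuple[float, float, float],
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pressure-like series b1*z + b2*z^2 + b3*z^3 + N(0, sd), z the
    standardized angle, shifted to a nonnegative range.

    The shift is affine so it leaves the standardized coupling regression
    invariant. Raises if the angle series is constant (standardization
    undefined).
    """
    a = np.asarray(angle, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise DataError("angle series must be 1-D with length >= 2")
    sd = a.std(ddof=1)
    if sd == 0:
        raise DataError("constant angle series: standardization undefined")
    z = (a - a.mean()) / sd
    b1, b2, b3 = coefficients
    y = b1 * z + b2 * z**2 + b3 * z**3
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, len(y))
    return y - y.min()


# ---------------------------------------------------------------------------
# On-disk formats: CSV recording, JSON ground-truth sidecar, YAML config


def write_recording(rec: MultimodalRecording, path: str | Path) -> None:
    rec.data.to_csv(path, index=False, float_format="%.10g")


def read_recording(path: str | Path, side: str = "", sampling_rate: float | None = None) -> MultimodalRecording:
    df = pd.read_csv(path)
    missing = [c for c in ("time_s",) + CHANNELS if c not in df.columns]
    if missing:
        raise DataError(f"recording {path} lacks columns {missing}")
    if sampling_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or not np.allclose(dt, dt[0]):
            raise DataError(f"recording {path} is not uniformly sampled")
        sampling_rate = 1.0 / dt[0]
    return MultimodalRecording(side=side, sampling_rate=float(sampling_rate), data=df)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "boundaries": [int(b) for b in gt.boundaries],
        "phases": list(PHASES),
        "coefficients": list(gt.coefficients) if gt.coefficients else None,
        "seed": int(gt.seed),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _knots_to_list(knots: Knots) -> list[list[float]]:
    return [[float(f), float(v)] for f, v in knots]


def config_to_yaml(config: SyntheticConfig, path: str | Path) -> None:
    def prof(p: PhaseProfile) -> dict:
        return {
            "phase_label": p.phase_label,
            "duration": float(p.duration),
            "angle_targets": {k: _knots_to_list(v) for k, v in p.angle_targets.items()},
            "pressure_targets": _knots_to_list(p.pressure_targets),
        }

    payload = {
        "sampling_rate": float(config.sampling_rate),
        "angle_noise_sd": float(config.angle_noise_sd),
        "pressure_noise_sd": float(config.pressure_noise_sd),
        "seed": int(config.seed),
        "left_profiles": [prof(p) for p in config.left_profiles],
        "right_profiles": [prof(p) for p in config.right_profiles],
        "coupling": None
        if config.coupling is None
        else {
            "joint": config.coupling.joint,
            "coefficients": list(config.coupling.coefficients),
            "noise_sd": float(config.coupling.noise_sd),
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    raw = yaml.safe_load(Path(path).read_text())

    def prof(d: dict) -> PhaseProfile:
        return PhaseProfile(
            d["phase_label"],
            d["duration"],
            {k: tuple((f, v) for f, v in v_) for k, v_ in d["angle_targets"].items()},
            tuple((f, v) for f, v in d["pressure_targets"]),
        )

    coupling = None
    if raw.get("coupling"):
        c = raw["coupling"]
        coupling = CouplingSpec(c["joint"], tuple(c["coefficients"]), c.get("noise_sd", 0.0))
    return SyntheticConfig(
        sampling_rate=raw["sampling_rate"],
        left_profiles=tuple(prof(p) for p in raw["left_profiles"]),
        right_profiles=tuple(prof(p) for p in raw["right_profiles"]),
        angle_noise_sd=raw["angle_noise_sd"],
        pressure_noise_sd=raw["pressure_noise_sd"],
        coupling=coupling,
        seed=raw["seed"],
    )
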