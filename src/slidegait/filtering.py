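"""Multimodal linear Kalman filter for one limb.

A single 10-dimensional constant-velocity state-space model jointly smooths
the four joint-angle channels and the plantar-pressure channel of one limb:

    x_k = [theta_hip_flex, dtheta_hip_flex, theta_hip_abd, dtheta_hip_abd,
           theta_knee_flex, dtheta_knee_flex, theta_ankle_dorsi,
           dtheta_ankle_dorsi, F_foot, dF_foot]

    x_{k+1} = A x_k + w_k,   w_k ~ N(0, Q)
    z_k     = H x_k + v_k,   v_k ~ N(0, R)

A is block-diagonal with five 2x2 blocks [[1, dt], [0, 1]] (each tracked
quantity evolves with locally constant first derivative plus process
noise); H selects the five position entries. The filter is the standard
forward prediction-update recursion (no backward smoothing pass), run
directly on the raw synchronized signals without low-pass pre-filtering.
The state is initialized from the first observation with zero velocities
and P0 = I.

Measurement-noise defaults come from the instrument accuracies (angle SD
2 deg in dynamic conditions, pressure SD 2 N). Process-noise defaults are
set from the acceleration scale of the slideboard cycle so the filter
tracks the fast knee-extension and push-off pressure transients without
lag artifacts; all entries are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .synthetic import CHANNELS, MultimodalRecording

__all__ = [
    "KalmanModel",
    "KalmanState",
    "build_model",
    "initialize",
    "filter_recording",
    "kalman_forward",
    "DEFAULT_Q_DIAG",
    "DEFAULT_R_DIAG",
]

N_CHANNELS = len(CHANNELS)
N_STATES = 2 * N_CHANNELS

# R: (2 deg)^2 per angle channel, (2 N)^2 for pressure.
DEFAULT_R_DIAG = (4.0, 4.0, 4.0, 4.0, 4.0)
# Q: small position noise; velocity noise sized to the per-step derivative
# changes of the calibrated cycle (~deg/s and ~N/s scales respectively).
DEFAULT_Q_DIAG = (1e-4, 25.0, 1e-4, 25.0, 1e-4, 25.0, 1e-4, 25.0, 1e-4, 2500.0)


@dataclass(frozen=True)
class KalmanModel:
    dt: float
    A: np.ndarray  # (10, 10)
    H: np.ndarray  # (5, 10)
    Q: np.ndarray  # (10, 10) diagonal
    R: np.ndarray  # (5, 5) diagonal


@dataclass
class KalmanState:
    x: np.ndarray  # (10,)
    P: np.ndarray  # (10, 10) symmetric PSD


@dataclass
class FilterResult:
    """Forward-pass output: smoothed channels, state/covariance
    trajectories and the innovation sequence z_k - H x_pred."""

    smoothed: pd.DataFrame
    states: np.ndarray  # (n, 10) posterior means
    covariances: np.ndarray  # (n, 10, 10)
    innovations: np.ndarray  # (n, 5); row 0 is z_0 - H x0 = 0 by initialization
    innovation_covs: np.ndarray  # (n, 5, 5)

    def velocity(self, channel: str) -> np.ndarray:
        """Estimated first derivative of ``channel`` (odd state entries)."""
        return self.states[:, 2 * CHANNELS.index(channel) + 1]


def build_model(
    dt: float = 0.01,
    q_diag: np.ndarray | tuple | None = None,
    r_diag: np.ndarray | tuple | None = None,
) -> KalmanModel:
    """Assemble the block-structured constant-velocity model.

    ``dt`` may be 0 (degenerate: A collapses to the identity); negative
    ``dt`` or non-positive variances raise :class:`ConfigurationError`.
    """
    if dt < 0:
        raise ConfigurationError(f"dt must be >= 0, got {dt}")
    q = np.asarray(DEFAULT_Q_DIAG if q_diag is None else q_diag, dtype=float)
    r = np.asarray(DEFAULT_R_DIAG if r_diag is None else r_diag, dtype=float)
    if q.shape != (N_STATES,):
        raise ConfigurationError(f"q_diag must have length {N_STATES}")
    if r.shape != (N_CHANNELS,):
        raise ConfigurationError(f"r_diag must have length {N_CHANNELS}")
    if np.any(q <= 0) or np.any(r <= 0):
        raise ConfigurationError("process/measurement variances must be > 0")
    block = np.array([[1.0, dt], [0.0, 1.0]])
    A = np.kron(np.eye(N_CHANNELS), block)
    H = np.zeros((N_CHANNELS, N_STATES))
    H[np.arange(N_CHANNELS), 2 * np.arange(N_CHANNELS)] = 1.0
    return KalmanModel(dt=dt, A=A, H=H, Q=np.diag(q), R=np.diag(r))


def initialize(first_observation: np.ndarray) -> KalmanState:
    """First-frame initialization: positions from the observation,
    velocities 0, P0 = identity."""
    z = np.asarray(first_observation, dtype=float)
    if z.shape != (N_CHANNELS,) or not np.all(np.isfinite(z)):
        raise DataError(f"observation must be a finite {N_CHANNELS}-vector")
    x = np.zeros(N_STATES)
    x[::2] = z
    return KalmanState(x=x, P=np.eye(N_STATES))


def kalman_forward(
    A: np.ndarray,
    H: np.ndarray,
    Q: np.ndarray,
    R: np.ndarray,
    x0: np.ndarray,
    P0: np.ndarray,
    Z: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generic forward Kalman recursion (any state/observation dimension).

    The first row of ``Z`` is consumed by the update step against the
    initial state. Uses the Joseph-stabilized covariance update so P stays
    symmetric positive semi-definite. Returns (states, covariances,
    innovations, innovation covariances).
    """
    n, m = Z.shape
    d = len(x0)
    xs = np.empty((n, d))
    Ps = np.empty((n, d, d))
    nus = np.empty((n, m))
    Ss = np.empty((n, m, m))
    x, P = np.asarray(x0, dtype=float), np.asarray(P0, dtype=float)
    I = np.eye(d)
    for k in range(n):
        if k > 0:
            x = A @ x
            P = A @ P @ A.T + Q
        S = H @ P @ H.T + R
        nu = Z[k] - H @ x
        K = np.linalg.solve(S.T, (P @ H.T).T).T
        x = x + K @ nu
        IKH = I - K @ H
        P = IKH @ P @ IKH.T + K @ R @ K.T
        P = 0.5 * (P + P.T)
        xs[k], Ps[k], nus[k], Ss[k] = x, P, nu, S
    return xs, Ps, nus, Ss


def filter_recording(
    recording: MultimodalRecording, model: KalmanModel | None = None
) -> FilterResult:
    """Jointly smooth the five channels of one limb.

    Requires complete, aligned, finite channels with n >= 2 (missing
    samples are rejected, not imputed). The smoothed channels are the
    posterior position entries; output length equals input length.
    """
    if model is None:
        model = build_model(dt=1.0 / recording.sampling_rate)
    df = recording.data
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise DataError(f"recording lacks channels {missing}")
    Z = df[list(CHANNELS)].to_numpy(dtype=float)
    if len(Z) < 2:
        raise DataError("recording must contain at least 2 samples")
    if not np.all(np.isfinite(Z)):
        raise DataError("recording contains non-finite samples")

    state0 = initialize(Z[0])
    xs, Ps, nus, Ss = kalman_forward(
        model.A, model.H, model.Q, model.R, state0.x, state0.P, Z
    )
    smoothed = pd.DataFrame({"time_s": df["time_s"].to_numpy()})
    for i, ch in enumerate(CHANNELS):
        smoothed[ch] = xs[:, 2 * i]
    return FilterResult(
        smoothed=smoothed, states=xs, covariances=Ps, innovations=nus, innovation_covs=Ss
    )
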