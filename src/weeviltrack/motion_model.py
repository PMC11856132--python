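"""Constant-velocity Kalman filter over bounding boxes.

The state is the 8-vector (cx, cy, a, h, vcx, vcy, va, vh): box center,
aspect ratio w/h, height, and their per-frame velocities.  The time step is
fixed at one frame.  Process and observation noise standard deviations scale
with the box height (position std = h/20, velocity std = h/160 by default),
the convention established for appearance-based tracking-by-detection, since
no filter parameters are dictated by the tracking problem itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mot_io import BoundingBox

__all__ = ["MotionState", "KalmanBoxTracker", "kalman_correct"]

_COV_SYM_TOL = 1e-9


@dataclass(frozen=True)
class MotionState:
    """Gaussian belief over the 8-dim box state."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (8,) or cov.shape != (8, 8):
            raise ValueError("MotionState requires an 8-vector mean and 8x8 covariance")
        if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(cov)):
            raise ValueError("non-finite motion state")
        if np.max(np.abs(cov - cov.T)) > _COV_SYM_TOL:
            raise ValueError("covariance must be symmetric")
        if np.min(np.diag(cov)) < 0:
            raise ValueError("covariance diagonal must be non-negative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", 0.5 * (cov + cov.T))

    def to_box(self) -> BoundingBox:
        return BoundingBox.from_xyah(self.mean[:4])


def kalman_correct(
    mean: np.ndarray,
    cov: np.ndarray,
    measurement: np.ndarray,
    obs_matrix: np.ndarray,
    obs_cov: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One linear-Gaussian measurement update (Joseph-form covariance).

    Generic over dimensions, e.g. the scalar case with prior variance 1 and
    measurement variance 1 yields the midpoint mean and posterior variance
    1/2 (gain K = 1/(1+1)).
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    z = np.atleast_1d(np.asarray(measurement, dtype=float))
    H = np.atleast_2d(np.asarray(obs_matrix, dtype=float))
    R = np.atleast_2d(np.asarray(obs_cov, dtype=float))
    innovation = z - H @ mean
    if not np.all(np.isfinite(innovation)):
        raise ValueError("non-finite innovation")
    S = H @ cov @ H.T + R
    K = np.linalg.solve(S.T, (cov @ H.T).T).T
    new_mean = mean + K @ innovation
    I_KH = np.eye(len(mean)) - K @ H
    new_cov = I_KH @ cov @ I_KH.T + K @ R @ K.T
    return new_mean, 0.5 * (new_cov + new_cov.T)


@dataclass(frozen=True)
class KalmanBoxTracker:
    """Stateless operations (initiate/predict/update/gating) with fixed noise scales."""

    std_weight_position: float = 1.0 / 20
    std_weight_velocity: float = 1.0 / 160

    _F: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]
    _H: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        F = np.eye(8)
        F[:4, 4:] = np.eye(4)
        H = np.eye(4, 8)
        object.__setattr__(self, "_F", F)
        object.__setattr__(self, "_H", H)

    def initiate(self, measurement: BoundingBox) -> MotionState:
        """New state from an unassociated box: zero velocity, height-scaled spread."""
        mean = np.zeros(8)
        mean[:4] = measurement.to_xyah()
        h = measurement.height
        wp, wv = self.std_weight_position, self.std_weight_velocity
        std = np.array(
            [2 * wp * h, 2 * wp * h, 1e-2, 2 * wp * h,
             10 * wv * h, 10 * wv * h, 1e-5, 10 * wv * h]
        )
        return MotionState(mean, np.diag(std**2))

    def predict(self, state: MotionState) -> MotionState:
        """Advance one frame under constant velocity; inflate by process noise."""
        h = state.mean[3]
        wp, wv = self.std_weight_position, self.std_weight_velocity
        std = np.array(
            [wp * h, wp * h, 1e-2, wp * h, wv * h, wv * h, 1e-5, wv * h]
        )
        Q = np.diag(std**2)
        mean = self._F @ state.mean
        cov = self._F @ state.covariance @ self._F.T + Q
        return MotionState(mean, cov)

    def update(self, state: MotionState, measurement: BoundingBox) -> MotionState:
        """Kalman correction of the 4 observed components by a measured box."""
        R = np.diag(self._measurement_std(state) ** 2)
        mean, cov = kalman_correct(
            state.mean, state.covariance, measurement.to_xyah(), self._H, R
        )
        return MotionState(mean, cov)

    def _measurement_std(self, state: MotionState) -> np.ndarray:
        h = state.mean[3]
        wp = self.std_weight_position
        return np.array([wp * h, wp * h, 1e-1, wp * h])

    def gating_distance(
        self, state: MotionState, measurements: Sequence[BoundingBox]
    ) -> np.ndarray:
        """Squared Mahalanobis distance of each box in the 4-D observation space."""
        R = np.diag(self._measurement_std(state) ** 2)
        S = self._H @ state.covariance @ self._H.T + R
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise ValueError("singular projected covariance in gating") from None
        mu = self._H @ state.mean
        out = np.empty(len(measurements))
        for i, m in enumerate(measurements):
            d = m.to_xyah() - mu
            y = np.linalg.solve(L, d)
            out[i] = float(y @ y)
        return out
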