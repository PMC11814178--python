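"""Constant-velocity Kalman filter over bounding-box state.

The filter tracks an 8-dimensional state

    (cx, cy, a, h, vcx, vcy, va, vh)

where (cx, cy) is the box centroid, ``a`` the aspect ratio w/h, ``h``
the box height, and the second half their per-frame velocities.  The
motion model is constant velocity; the measurement is the first four
components.  Process and measurement noise scale with the box height
(std weights 1/20 for position, 1/160 for velocity), so uncertainty is
proportional to apparent object size — the standard parameterization
for this family of trackers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BoundingBox

__all__ = ["KalmanState", "initiate", "predict", "update", "gating_distance", "CHI2_95_4DOF"]

#: 95% chi-square quantile at 4 degrees of freedom, the default motion gate.
CHI2_95_4DOF = 9.487729036781154

_STD_WEIGHT_POSITION = 1.0 / 20.0
_STD_WEIGHT_VELOCITY = 1.0 / 160.0

# x' = F x  (dt = 1 frame); measurement picks out the first 4 components.
_F = np.eye(8)
_F[:4, 4:] = np.eye(4)
_H = np.eye(4, 8)


@dataclass(frozen=True)
class KalmanState:
    """Gaussian state estimate: 8-vector mean and 8x8 covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (8,) or cov.shape != (8, 8):
            raise ValueError("state must be an 8-vector mean and 8x8 covariance")
        if not np.allclose(cov, cov.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    def to_box(self) -> BoundingBox:
        cx, cy, a, h = self.mean[:4]
        w = a * h
        return BoundingBox(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


def _measurement(box: BoundingBox) -> np.ndarray:
    return np.array(
        [(box.x1 + box.x2) / 2.0, (box.y1 + box.y2) / 2.0, box.width / box.height, box.height]
    )


def initiate(box: BoundingBox) -> KalmanState:
    """New track state from an unmatched detection: zero velocity, broad prior."""
    if box.height <= 0:
        raise ValueError("box height must be positive")
    mean = np.zeros(8)
    mean[:4] = _measurement(box)
    h = box.height
    std = np.array(
        [
            2 * _STD_WEIGHT_POSITION * h,
            2 * _STD_WEIGHT_POSITION * h,
            1e-2,
            2 * _STD_WEIGHT_POSITION * h,
            10 * _STD_WEIGHT_VELOCITY * h,
            10 * _STD_WEIGHT_VELOCITY * h,
            1e-5,
            10 * _STD_WEIGHT_VELOCITY * h,
        ]
    )
    return KalmanState(mean, np.diag(std**2))


def predict(state: KalmanState) -> KalmanState:
    """One-frame constant-velocity prediction."""
    h = state.mean[3]
    std = np.array(
        [
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_POSITION * h,
            1e-2,
            _STD_WEIGHT_POSITION * h,
            _STD_WEIGHT_VELOCITY * h,
            _STD_WEIGHT_VELOCITY * h,
            1e-5,
            _STD_WEIGHT_VELOCITY * h,
        ]
    )
    Q = np.diag(std**2)
    mean = _F @ state.mean
    # coasting with a negative size velocity must not collapse the box
    mean[2] = max(mean[2], 1e-3)
    mean[3] = max(mean[3], 1.0)
    cov = _F @ state.covariance @ _F.T + Q
    return KalmanState(mean, (cov + cov.T) / 2.0)


def _innovation_cov(state: KalmanState) -> np.ndarray:
    h = state.mean[3]
    std = np.array(
        [_STD_WEIGHT_POSITION * h, _STD_WEIGHT_POSITION * h, 1e-1, _STD_WEIGHT_POSITION * h]
    )
    R = np.diag(std**2)
    return _H @ state.covariance @ _H.T + R


def update(state: KalmanState, box: BoundingBox) -> KalmanState:
    """Measurement update with the observed box (cx, cy, a, h)."""
    z = _measurement(box)
    S = _innovation_cov(state)
    PHt = state.covariance @ _H.T
    try:
        chol = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("innovation covariance not positive-definite") from exc
    # K = P H^T S^{-1} via two triangular solves
    K = np.linalg.solve(chol.T, np.linalg.solve(chol, PHt.T)).T
    innovation = z - _H @ state.mean
    mean = state.mean + K @ innovation
    cov = state.covariance - K @ S @ K.T
    if mean[3] <= 0:
        raise ValueError("posterior height must stay positive")
    return KalmanState(mean, (cov + cov.T) / 2.0)


def gating_distance(state: KalmanState, boxes: list[BoundingBox]) -> np.ndarray:
    """Squared Mahalanobis distance of each box from the predicted measurement."""
    if not boxes:
        return np.zeros(0)
    S = _innovation_cov(state)
    try:
        chol = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("innovation covariance not positive-definite") from exc
    z_pred = _H @ state.mean
    d = np.stack([_measurement(b) for b in boxes]) - z_pred
    y = np.linalg.solve(chol, d.T)
    return np.sum(y * y, axis=0)
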