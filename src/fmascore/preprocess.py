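"""Denoising and motion segmentation.

Depth-camera skeleton streams are noisy; the pipeline denoises every
scalar channel with singular spectrum analysis (SSA) before feature
extraction.  SSA embeds the series in an L x (N-L+1) Hankel trajectory
matrix, takes its SVD, keeps the k leading rank-1 components and
reconstructs by anti-diagonal averaging.  With the defaults L=15, k=2 a
30 fps stream keeps trend plus the dominant oscillation and sheds
broadband sensor noise.  A zero-phase Butterworth low-pass is provided
as the comparison filter only.

Motion start/end are detected on the endpoint (wrist) speed profile:
the segment runs from the first to the last frame whose speed exceeds
the trial mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel
from scipy.signal import butter, filtfilt

from .exceptions import ParameterError, ValidationError
from .io import SkeletonSequence, HandSequence


@dataclass(frozen=True)
class SSAConfig:
    """Window length ``L`` (frames) and number of reconstruction
    components ``k`` of the SSA filter."""

    L: int = 15
    k: int = 2

    def __post_init__(self):
        if self.L < 2:
            raise ParameterError(f"SSA window L must be >= 2, got {self.L}")
        if not 1 <= self.k <= self.L:
            raise ParameterError(
                f"SSA components k must be in [1, L={self.L}], got {self.k}")


@dataclass(frozen=True)
class Segment:
    """Inclusive 0-based frame range of the detected motion."""

    start_frame: int
    end_frame: int

    def __post_init__(self):
        if not 0 <= self.start_frame <= self.end_frame:
            raise ValidationError(f"invalid segment {self}")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def slice(self) -> slice:
        return slice(self.start_frame, self.end_frame + 1)


def ssa_filter(series, config: SSAConfig = SSAConfig()) -> np.ndarray:
    """SSA-denoise a 1D series; output has the input's length.

    Components are the ``k`` singular triplets with the largest singular
    values (ties broken by original index order, which is how
    :func:`numpy.linalg.svd` already orders them).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("ssa_filter expects a 1D series")
    if not np.all(np.isfinite(x)):
        raise ValidationError("ssa_filter: non-finite values in series")
    n = len(x)
    L = config.L
    if n <= L:
        raise ParameterError(
            f"series length {n} must exceed SSA window L={L}")
    # L x K Hankel trajectory matrix, K = N - L + 1
    X = hankel(x[:L], x[L - 1:])
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(config.k, len(s))
    Xk = (U[:, :k] * s[:k]) @ Vt[:k]
    # anti-diagonal (Hankel) averaging back to a series
    idx = np.add.outer(np.arange(L), np.arange(X.shape[1]))
    sums = np.bincount(idx.ravel(), weights=Xk.ravel(), minlength=n)
    counts = np.bincount(idx.ravel(), minlength=n)
    return sums / counts


def ssa_filter_skeleton(seq: SkeletonSequence,
                        config: SSAConfig = SSAConfig()) -> SkeletonSequence:
    """Apply :func:`ssa_filter` independently to each of the 54
    coordinate channels."""
    flat = seq.positions.reshape(len(seq), -1)
    out = np.empty_like(flat)
    for c in range(flat.shape[1]):
        out[:, c] = ssa_filter(flat[:, c], config)
    return seq.with_positions(out.reshape(seq.positions.shape))


def ssa_filter_hand(seq: HandSequence,
                    config: SSAConfig = SSAConfig()) -> HandSequence:
    """Apply :func:`ssa_filter` to every hand channel (grab strength is
    clipped back to [0, 1] afterwards)."""
    out = np.empty_like(seq.channels)
    for c in range(seq.channels.shape[1]):
        out[:, c] = ssa_filter(seq.channels[:, c], config)
    out[:, -1] = np.clip(out[:, -1], 0.0, 1.0)
    return seq.with_channels(out)


def lowpass_filter(series, cutoff_hz: float, fps: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (comparison filter only)."""
    x = np.asarray(series, dtype=float)
    if not 0 < cutoff_hz < fps / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fps / 2}) Hz")
    b, a = butter(order, cutoff_hz, btype="low", fs=fps)
    return filtfilt(b, a, x)


def endpoint_speed(seq: SkeletonSequence, joint: str) -> np.ndarray:
    """Speed magnitude (m/s) of one joint by central differences."""
    pos = seq.joint(joint)
    if len(pos) < 2:
        raise ValidationError("endpoint_speed needs at least 2 frames")
    vel = np.gradient(pos, seq.times, axis=0)
    return np.linalg.norm(vel, axis=1)


def segment_motion(speed) -> Segment:
    """First/last frame whose endpoint speed strictly exceeds the trial
    mean; a series that never exceeds its mean (constant) yields the
    full range."""
    v = np.asarray(speed, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValidationError("segment_motion needs a 1D series, length >= 2")
    if v.min() < 0:
        raise ValidationError("segment_motion: speeds must be non-negative")
    above = np.nonzero(v > v.mean())[0]
    if len(above) == 0:
        return Segment(0, len(v) - 1)
    return Segment(int(above[0]), int(above[-1]))


def mean_joint_offset(a: SkeletonSequence, b: SkeletonSequence,
                      joint: str) -> float:
    """Mean per-frame Euclidean distance between one joint in two equal
    -length sequences, in millimeters."""
    pa, pb = a.joint(joint), b.joint(joint)
    if len(pa) != len(pb):
        raise ValidationError(
            f"frame count mismatch: {len(pa)} vs {len(pb)}")
    return float(np.linalg.norm(pa - pb, axis=1).mean() * 1000.0)
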