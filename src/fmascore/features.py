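"""Kinematic feature extraction.

The Shoulder/Elbow feature vector has exactly 36 named entries:

* 6 endpoint features — path length (m), max/mean speed (m/s), speed
  variance ((m/s)^2), spectral arc length (SPARC, unitless) and
  dimensionless jerk (unitless) of the endpoint speed profile;
* 24 angular features — 4 degrees of freedom (shoulder flexion,
  shoulder adduction/abduction, shoulder rotation, elbow flexion) x
  6 statistics (ROM, max angle, min angle, max/mean angular velocity,
  angular velocity variance), degrees and deg/s;
* 6 other features — inter-joint coordination index (IJCI, the Pearson
  correlation between shoulder- and elbow-flexion trajectories),
  movement time (s), max shoulder displacement along X/Y/Z (m) and
  trunk compensation (m).

Wrist/Hand, Grasp and Coordination/Speed items use per-item scalar
features (channel maxima/minima and ranges, grip-force maxima, SPARC of
the wrist speed, minimum wrist-nose distance, movement time).

Numerical conventions: velocities/accelerations by central finite
differences (second-order accurate edges); mean angular velocity is the
mean of the absolute value, its variance that of the signed value;
"mean velocity" is the mean speed magnitude.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .io import SkeletonSequence, HandSequence, GraspRecording
from .preprocess import Segment, endpoint_speed

#: canonical ordering of the 36 Shoulder/Elbow features
ANGLE_DOFS = ("shoulder_flexion", "shoulder_adduction",
              "shoulder_rotation", "elbow_flexion")
ANGLE_STATS = ("rom", "angle_max", "angle_min",
               "angvel_max", "angvel_mean", "angvel_var")
ENDPOINT_FEATURES = ("path_length", "v_max", "v_mean", "v_var",
                     "sparc", "dimensionless_jerk")
OTHER_FEATURES = ("ijci", "time", "shoulder_disp_x", "shoulder_disp_y",
                  "shoulder_disp_z", "trunk_compensation")
SHOULDER_ELBOW_FEATURES = tuple(
    list(ENDPOINT_FEATURES)
    + [f"{dof}_{stat}" for dof in ANGLE_DOFS for stat in ANGLE_STATS]
    + list(OTHER_FEATURES))

assert len(SHOULDER_ELBOW_FEATURES) == 36


# ---------------------------------------------------------------------------
# smoothness metrics

def sparc(speed, fps: float, cutoff_hz: float = 10.0,
          amp_threshold: float = 0.05, min_bins: int = 4096) -> float:
    """Spectral arc length of a speed profile (always <= 0; values
    closer to 0 indicate smoother movement).

    Standard parameterization: magnitude spectrum of the zero-padded
    FFT, normalized to unit peak, restricted to frequencies up to
    ``cutoff_hz`` and then to the band where the normalized amplitude
    exceeds ``amp_threshold`` (adaptive cutoff); the negative arc length
    of that curve over normalized frequency is returned.  Invariant to
    amplitude and duration scaling of the movement.
    """
    v = np.asarray(speed, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValidationError("sparc needs a 1D speed profile, length >= 4")
    if v.min() < 0:
        raise ValidationError("sparc: speeds must be non-negative")
    if v.max() == 0:
        raise DegenerateInputError("sparc undefined for all-zero speed")
    nfft = max(min_bins, 2 ** int(np.ceil(np.log2(len(v))) + 4))
    freqs = np.arange(nfft // 2 + 1) * fps / nfft
    mag = np.abs(np.fft.rfft(v, nfft))
    mag = mag / mag.max()
    sel = freqs <= cutoff_hz
    f_sel, m_sel = freqs[sel], mag[sel]
    above = np.nonzero(m_sel >= amp_threshold)[0]
    band = slice(above[0], above[-1] + 1)
    f_b, m_b = f_sel[band], m_sel[band]
    if len(f_b) < 2:
        raise DegenerateInputError("sparc: spectrum band degenerate")
    df = np.diff(f_b) / (f_b[-1] - f_b[0])
    return float(-np.sum(np.sqrt(df ** 2 + np.diff(m_b) ** 2)))


def dimensionless_jerk(speed, fps: float) -> float:
    """Dimensionless (speed-based) integrated squared jerk, always < 0;
    values closer to 0 indicate smoother movement.

    ``DJ = -(T^3 / v_peak^2) * integral (d2v/dt2)^2 dt`` with the speed
    profile differentiated by second-order central differences and the
    integral by the trapezoid rule; invariant to amplitude and duration
    scaling up to discretization error.
    """
    v = np.asarray(speed, dtype=float)
    if v.ndim != 1 or len(v) < 5:
        raise ValidationError(
            "dimensionless_jerk needs a 1D speed profile, length >= 5")
    v_peak = v.max()
    if v_peak <= 0:
        raise DegenerateInputError(
            "dimensionless_jerk undefined for zero peak speed")
    dt = 1.0 / fps
    duration = (len(v) - 1) * dt
    accel = np.gradient(v, dt, edge_order=2)
    jerk = np.gradient(accel, dt, edge_order=2)
    return float(-(duration ** 3 / v_peak ** 2)
                 * np.trapezoid(jerk ** 2, dx=dt))


# ---------------------------------------------------------------------------
# endpoint kinematics

def endpoint_features(seq: SkeletonSequence, segment: Segment,
                      endpoint_joint: str, *, sparc_cutoff_hz: float = 10.0,
                      sparc_amp_threshold: float = 0.05) -> dict:
    """The 6 endpoint features of one segmented motion."""
    if segment.end_frame >= len(seq):
        raise ValidationError("segment exceeds sequence length")
    if segment.n_frames < 3:
        raise ValidationError("endpoint_features needs >= 3 frames")
    sl = segment.slice()
    pos = seq.joint(endpoint_joint)[sl]
    speed = endpoint_speed(seq, endpoint_joint)[sl]
    path = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
    out = {
        "path_length": path,
        "v_max": float(speed.max()),
        "v_mean": float(speed.mean()),
        "v_var": float(speed.var()),
    }
    out["sparc"] = sparc(speed, seq.fps, cutoff_hz=sparc_cutoff_hz,
                         amp_threshold=sparc_amp_threshold) \
        if speed.max() > 0 else 0.0
    out["dimensionless_jerk"] = dimensionless_jerk(speed, seq.fps) \
        if speed.max() > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# angular kinematics

def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm < 1e-9):
        raise ValidationError(f"degenerate (zero-length) {what} vector")
    return v / norm


def joint_angles(seq: SkeletonSequence, side: str) -> dict:
    """Per-frame shoulder flexion/adduction/rotation and elbow flexion
    (degrees) of one arm.

    Trunk axes are rebuilt every frame: the downward axis points from
    neck to mid-hip, the lateral axis from left to right shoulder, the
    forward axis is their cross product.  Shoulder flexion is the angle
    of the upper arm's sagittal-plane projection versus the downward
    axis (positive forward); adduction/abduction the frontal-plane
    analogue (positive away from the trunk); shoulder rotation the
    rotation of the forearm about the upper-arm axis relative to the
    projected forward axis (0 when the forearm points body-forward).
    Frames where the elbow is (numerically) fully extended leave the
    rotation angle ill-defined; it is reported as 0 there.
    """
    if side not in ("left", "right"):
        raise ValidationError(f"side must be left/right, got {side!r}")
    s = side[0]
    other = "r" if s == "l" else "l"
    shoulder = seq.joint(f"shoulder_{s}")
    elbow = seq.joint(f"elbow_{s}")
    wrist = seq.joint(f"wrist_{s}")
    neck = seq.joint("neck")
    mid_hip = seq.joint("mid_hip")
    shoulder_other = seq.joint(f"shoulder_{other}")

    down = _unit(mid_hip - neck, "trunk")
    lat_lr = _unit(seq.joint("shoulder_r") - seq.joint("shoulder_l"),
                   "shoulder-line")
    forward = _unit(np.cross(lat_lr, down), "trunk-forward")
    out = _unit(shoulder - shoulder_other, "shoulder-out")

    upper = _unit(elbow - shoulder, "upper-arm")
    fore = _unit(wrist - elbow, "forearm")

    # elbow flexion: 0 deg when fully extended
    cos_e = np.clip(np.sum(-upper * fore, axis=1), -1.0, 1.0)
    elbow_flex = 180.0 - np.degrees(np.arccos(cos_e))

    def _plane_angle(axis):
        proj = upper - np.sum(upper * axis, axis=1, keepdims=True) * axis
        return np.degrees(np.arctan2(np.sum(proj * _second, axis=1),
                                     np.sum(proj * down, axis=1)))

    _second = forward
    sh_flex = _plane_angle(lat_lr)
    _second = out
    sh_add = _plane_angle(forward)

    # shoulder rotation: forearm component perpendicular to the upper arm,
    # measured against the projected trunk-forward axis
    f_perp = fore - np.sum(fore * upper, axis=1, keepdims=True) * upper
    r_ref = forward - np.sum(forward * upper, axis=1, keepdims=True) * upper
    n_f = np.linalg.norm(f_perp, axis=1)
    n_r = np.linalg.norm(r_ref, axis=1)
    rot = np.zeros(len(seq))
    ok = (n_f > 1e-9) & (n_r > 1e-9)
    if np.any(ok):
        fp = f_perp[ok] / n_f[ok, None]
        rr = r_ref[ok] / n_r[ok, None]
        rot[ok] = np.degrees(np.arctan2(
            np.sum(np.cross(rr, fp) * upper[ok], axis=1),
            np.sum(rr * fp, axis=1)))
    return {
        "shoulder_flexion": sh_flex,
        "shoulder_adduction": sh_add,
        "shoulder_rotation": rot,
        "elbow_flexion": elbow_flex,
    }


def angular_features(angle_series, segment: Segment, fps: float) -> dict:
    """ROM, extrema and angular-velocity statistics of one DoF."""
    a = np.asarray(angle_series, dtype=float)
    if segment.end_frame >= len(a):
        raise ValidationError("segment exceeds series length")
    if segment.n_frames < 3:
        raise ValidationError("angular_features needs >= 3 frames")
    a = a[segment.slice()]
    vel = np.gradient(a, 1.0 / fps, edge_order=2)
    return {
        "rom": float(a.max() - a.min()),
        "angle_max": float(a.max()),
        "angle_min": float(a.min()),
        "angvel_max": float(np.abs(vel).max()),
        "angvel_mean": float(np.abs(vel).mean()),
        "angvel_var": float(vel.var()),
    }


def ijci(shoulder_flexion_series, elbow_flexion_series) -> float:
    """Inter-joint coordination index: Pearson correlation between the
    shoulder- and elbow-flexion angle trajectories."""
    x = np.asarray(shoulder_flexion_series, dtype=float)
    y = np.asarray(elbow_flexion_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("ijci needs two equal-length series, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("ijci undefined for constant series")
    return float(np.corrcoef(x, y)[0, 1])


def trunk_compensation(seq: SkeletonSequence, segment: Segment,
                       side: str) -> dict:
    """Max per-axis displacement of the moving-side shoulder and the max
    Euclidean excursion of the mid-shoulder point, both relative to the
    segment's first frame (meters)."""
    if side not in ("left", "right"):
        raise ValidationError(f"side must be left/right, got {side!r}")
    if segment.end_frame >= len(seq):
        raise ValidationError("segment exceeds sequence length")
    sl = segment.slice()
    sh = seq.joint(f"shoulder_{side[0]}")[sl]
    mid = 0.5 * (seq.joint("shoulder_l")[sl] + seq.joint("shoulder_r")[sl])
    disp = np.abs(sh - sh[0]).max(axis=0)
    return {
        "shoulder_disp_x": float(disp[0]),
        "shoulder_disp_y": float(disp[1]),
        "shoulder_disp_z": float(disp[2]),
        "trunk_compensation":
            float(np.linalg.norm(mid - mid[0], axis=1).max()),
    }


def movement_time(seq: SkeletonSequence, segment: Segment) -> float:
    """Segment duration in seconds: frame count times the mean frame
    interval (a 60-frame segment at 30 fps lasts 2.0 s)."""
    if len(seq) < 2:
        raise ValidationError("movement_time needs >= 2 frames")
    dt = float(np.diff(seq.times).mean())
    return segment.n_frames * dt


def shoulder_elbow_vector(seq: SkeletonSequence, segment: Segment,
                          side: str, **sparc_kwargs) -> dict:
    """Assemble the full 36-entry Shoulder/Elbow feature vector."""
    endpoint = endpoint_features(seq, segment, f"wrist_{side[0]}",
                                 **sparc_kwargs)
    angles = joint_angles(seq, side)
    out = dict(endpoint)
    for dof in ANGLE_DOFS:
        stats = angular_features(angles[dof], segment, seq.fps)
        for stat, val in stats.items():
            out[f"{dof}_{stat}"] = val
    sl = segment.slice()
    try:
        out["ijci"] = ijci(angles["shoulder_flexion"][sl],
                           angles["elbow_flexion"][sl])
    except DegenerateInputError:
        out["ijci"] = 0.0
    out["time"] = movement_time(seq, segment)
    out.update(trunk_compensation(seq, segment, side))
    assert set(out) == set(SHOULDER_ELBOW_FEATURES)
    return out


# ---------------------------------------------------------------------------
# wrist/hand, grasp, coordination

def hand_features(seq: HandSequence) -> dict:
    """Scalar features of one hand recording: channel extrema, wrist
    ROMs, per-finger flexion peaks and extension excursions (flexion
    peak minus the post-peak minimum) and peak grab strength."""
    theta = seq.channel("wrist_pitch")
    psi = seq.channel("wrist_yaw")
    out = {
        "wrist_pitch_max": float(theta.max()),
        "wrist_pitch_min": float(theta.min()),
        "wrist_pitch_rom": float(theta.max() - theta.min()),
        "wrist_yaw_max": float(psi.max()),
        "wrist_yaw_min": float(psi.min()),
        "wrist_yaw_rom": float(psi.max() - psi.min()),
        "forearm_rotation_max": float(seq.channel("forearm_rotation").max()),
        "elbow_flexion_max": float(seq.channel("elbow_flexion").max()),
        "shoulder_flexion_max": float(seq.channel("shoulder_flexion").max()),
        "grab_strength_max": float(seq.channel("grab_strength").max()),
    }
    for i in range(1, 5):
        eta = seq.channel(f"finger{i}")
        peak = int(np.argmax(eta))
        out[f"finger{i}_flexion_max"] = float(eta[peak])
        out[f"finger{i}_extension_range"] = float(eta[peak] - eta[peak:].min())
    return out


#: which hand features each Wrist/Hand item consumes
WRIST_HAND_ITEM_FEATURES = {
    14: ("elbow_flexion_max", "forearm_rotation_max"),
    17: ("shoulder_flexion_max", "forearm_rotation_max"),
    19: ("wrist_pitch_max", "wrist_pitch_min"),
    20: ("wrist_pitch_max", "wrist_pitch_min", "wrist_pitch_rom"),
    21: ("wrist_pitch_max", "wrist_pitch_min"),
    22: ("wrist_pitch_max", "wrist_pitch_min", "wrist_pitch_rom"),
    23: ("wrist_pitch_max", "wrist_pitch_min", "wrist_pitch_rom",
         "wrist_yaw_max", "wrist_yaw_min", "wrist_yaw_rom"),
    24: ("finger1_flexion_max", "finger2_flexion_max", "finger3_flexion_max",
         "finger4_flexion_max", "grab_strength_max"),
    25: ("finger1_extension_range", "finger2_extension_range",
         "finger3_extension_range", "finger4_extension_range"),
}


def wrist_hand_features(seq: HandSequence, item_id: int) -> dict:
    """The hand features relevant to one Wrist/Hand item."""
    if item_id not in WRIST_HAND_ITEM_FEATURES:
        raise ValidationError(
            f"item {item_id} is not a hand-sensor Wrist/Hand item")
    feats = hand_features(seq)
    return {k: feats[k] for k in WRIST_HAND_ITEM_FEATURES[item_id]}


def grasp_features(rec: GraspRecording) -> dict:
    """Peak voltage (V) and force (N) of one grip-tool recording."""
    if len(rec) == 0:
        raise ValidationError("grasp_features: empty recording")
    return {"voltage_max": float(rec.voltage.max()),
            "force_max": float(rec.force.max())}


def coordination_features(seq: SkeletonSequence, segment: Segment,
                          side: str, **sparc_kwargs) -> dict:
    """Finger-to-nose (motion XV) features: SPARC of the wrist speed,
    the minimum wrist-nose distance (m) and the movement time (s)."""
    if side not in ("left", "right"):
        raise ValidationError(f"side must be left/right, got {side!r}")
    sl = segment.slice()
    speed = endpoint_speed(seq, f"wrist_{side[0]}")[sl]
    wrist = seq.joint(f"wrist_{side[0]}")[sl]
    nose = seq.joint("nose")[sl]
    sal = sparc(speed, seq.fps, **sparc_kwargs)
    return {
        "sparc": sal,
        "sparc_magnitude": -sal,
        "nose_distance_min":
            float(np.linalg.norm(wrist - nose, axis=1).min()),
        "movement_time": movement_time(seq, segment),
    }
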