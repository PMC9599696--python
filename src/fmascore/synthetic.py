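"""Simulated hemiparetic subjects for pipeline development and testing.

Real patient recordings for this assessment are not publicly available,
so the package ships a motion simulator that emulates the statistical
structure the pipeline assumes: per subject, skeleton / hand / grip
recordings for all 17 motion tasks on the paretic and less-affected
side, with planted ground-truth item scores.

Impairment model
----------------
Each item carries an ability level ``a`` in [0, 1] (1 = unimpaired).
The planted reference score follows the same three equal divisions as
the rule engine (a < 1/3 -> 0, a < 2/3 -> 1, else 2) — by design, so
rule-based recovery is exact in the noise-free limit; this is the
intended oracle structure.  The paretic side executes each motion with:

* range of motion and channel amplitudes scaled by ``a`` (so the
  paretic/less-affected performance ratio equals ``a`` up to noise);
* slowed, fragmented velocity profiles (sub-movements) as ``a`` falls;
* forward trunk lean (compensation) growing as ``a`` falls;
* a movement-gated 5 Hz wrist tremor during finger-to-nose whose
  amplitude grows as the tremor item's ability falls;
* a residual wrist-nose distance (dysmetria) inversely tied to ability;
* depth-sensor-like position noise on every skeleton coordinate
  (slowly drifting tracking error plus white per-frame jitter), angle
  noise on hand channels and force noise on grip recordings.

The less-affected side performs near-full movements.  Items that share
one driving recording channel (3-11, 13/16, 19/20, 21/22, 24/25) share
an ability level; abilities of different items scatter around a
subject-level base ability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import ParameterError, ValidationError
from .io import (GraspRecording, HandSequence, JOINT_NAMES, SkeletonSequence,
                 SubjectRecord, HAND_CHANNELS)
from .registry import GRASP_TOOLS, ITEM_IDS, MOTION_KIND, items_for_motion

#: items that must share an ability level because one recording channel
#: drives them all
ABILITY_GROUPS = (
    (3, 4, 5, 6, 7, 8, 9, 10, 11),    # motion I
    (12,), (13, 16), (15,),           # motions II, III, V
    (14,), (17,),
    (19, 20), (21, 22), (23,), (24, 25),
    (26,), (27,), (28,), (29,), (30,),
    (31,), (32,), (33,),
)

#: default sensor-noise levels ("calibrated": raw-vs-truth wrist offset
#: on the order of tens of millimeters, the scale of depth-camera error)
SKELETON_NOISE_SD_M = 0.015
HAND_NOISE_SD_DEG = 1.5
FORCE_NOISE_SD_N = 0.3

SKELETON_FPS = 30.0
HAND_FPS = 100.0
GRASP_FPS = 10.0

#: peak grip force (N) of an unimpaired grasp per tool
TOOL_FORCE_N = {"hook": 40.0, "thumb_adduction": 25.0, "pincer": 20.0,
                "cylinder": 60.0, "sphere": 50.0}

#: (start, full-excursion-end) degrees for (flexion, abduction, elbow)
#: per skeleton motion; the paretic side covers ability x the excursion
_MOTION_ANGLES = {
    "I": ((5.0, 5.0), (8.0, 90.0), (10.0, 80.0)),
    "II": ((5.0, -30.0), (10.0, 10.0), (10.0, 65.0)),
    "III": ((5.0, 175.0), (8.0, 8.0), (12.0, 12.0)),
    "IV": ((5.0, 5.0), (8.0, 8.0), (10.0, 90.0)),
    "V": ((5.0, 5.0), (8.0, 90.0), (12.0, 12.0)),
}

_MOTION_DURATION_S = {"I": 2.5, "II": 2.0, "III": 3.0, "IV": 2.0, "V": 2.5}
_REST_PAD_S = 0.4
_REPEATED_MOTIONS = ("I", "II", "III", "V")   # performed twice per side

_ARM = {"upper": 0.29, "fore": 0.26, "hand": 0.09}


def ability_to_score(a: float) -> int:
    """Planted score by three equal divisions of the ability level."""
    if a < 1 / 3:
        return 0
    if a < 2 / 3:
        return 1
    return 2


@dataclass(frozen=True)
class ImpairmentProfile:
    """Per-item ability levels plus sensor-noise and compensation
    parameters for one simulated subject."""

    abilities: dict                        # item_id -> a in [0, 1]
    noise_sd: float = SKELETON_NOISE_SD_M  # meters, skeleton positions
    hand_noise_deg: float = HAND_NOISE_SD_DEG
    force_noise_n: float = FORCE_NOISE_SD_N
    tremor_hz: float = 5.0
    tremor_amplitude_m: float | None = None   # None: derived from item 31
    trunk_lean_m: float | None = None         # None: derived from ability
    body_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        missing = set(ITEM_IDS) - set(self.abilities)
        if missing:
            raise ValidationError(
                f"profile lacks abilities for items {sorted(missing)}")
        for item, a in self.abilities.items():
            if not 0 <= a <= 1:
                raise ValidationError(
                    f"ability for item {item} outside [0, 1]: {a}")
        if self.noise_sd < 0 or self.hand_noise_deg < 0 \
                or self.force_noise_n < 0:
            raise ValidationError("noise levels must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted reference score per item."""

    scores: dict                      # item_id -> 0/1/2

    @property
    def total(self) -> int:
        return int(sum(self.scores.values()))


def make_profile(base_ability: float, seed: int, *,
                 jitter_sd: float = 0.08, noise_scale: float = 1.0,
                 rng: np.random.Generator | None = None) -> ImpairmentProfile:
    """Scatter per-item abilities around a subject base ability (shared
    within ability groups, clipped jitter) and draw anthropometry."""
    if not 0 <= base_ability <= 1:
        raise ParameterError("base ability must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    abilities = {}
    for group in ABILITY_GROUPS:
        jitter = float(np.clip(rng.normal(0.0, jitter_sd), -0.15, 0.15))
        a = float(np.clip(base_ability + jitter, 0.0, 1.0))
        for item in group:
            abilities[item] = a
    return ImpairmentProfile(
        abilities=abilities,
        noise_sd=SKELETON_NOISE_SD_M * noise_scale,
        hand_noise_deg=HAND_NOISE_SD_DEG * noise_scale,
        force_noise_n=FORCE_NOISE_SD_N * noise_scale,
        body_scale=float(rng.uniform(0.95, 1.05)),
        seed=seed)


# ---------------------------------------------------------------------------
# trajectory primitives

def _skeleton_noise(rng: np.random.Generator, shape: tuple,
                    sd: float, fps: float) -> np.ndarray:
    """Depth-camera tracking error: a slowly drifting component (the
    dominant part of skeleton-tracking offsets, correlation ~0.5 s)
    plus white per-frame jitter, with overall standard deviation ``sd``
    per coordinate."""
    if sd == 0:
        return np.zeros(shape)
    slow = rng.standard_normal(shape)
    sigma_frames = max(0.5 * fps, 1.0)
    slow = gaussian_filter1d(slow, sigma=sigma_frames, axis=0,
                             mode="reflect")
    std = slow.std()
    if std > 0:
        slow = slow / std
    white = rng.standard_normal(shape)
    return sd * (0.8 * slow + 0.6 * white)


def _minjerk(tau: np.ndarray) -> np.ndarray:
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t ** 3 - 15 * t ** 4 + 6 * t ** 5


def min_jerk_trajectory(start, end, duration: float, fps: float) -> np.ndarray:
    """Minimum-jerk point-to-point path: (N, 3) positions with zero
    boundary velocity and acceleration."""
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if fps <= 0:
        raise ParameterError("fps must be > 0")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    n = int(round(duration * fps)) + 1
    tau = np.linspace(0.0, 1.0, n)
    s = _minjerk(tau)
    return start[None, :] + s[:, None] * (end - start)[None, :]


def _n_submovements(a: float) -> int:
    if a >= 0.7:
        return 1
    if a >= 0.4:
        return 2
    return 3


def _staged_curve(tau: np.ndarray, n_sub: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Monotone 0->1 time-scaling built from staggered minimum-jerk
    sub-movements; one sub-movement reduces to the plain profile."""
    if n_sub <= 1:
        return _minjerk(tau)
    width = 1.4 / n_sub
    weights = rng.dirichlet(np.full(n_sub, 5.0))
    out = np.zeros_like(tau)
    for j in range(n_sub):
        onset = j * (1.0 - width) / (n_sub - 1)
        out = out + weights[j] * _minjerk((tau - onset) / width)
    return out


# ---------------------------------------------------------------------------
# skeleton model

def _base_skeleton(scale: float) -> np.ndarray:
    """Static seated pose, camera frame (x right, y up, z toward
    camera); subject faces the camera.  Returns (18, 3)."""
    sw = 0.19 * scale     # half shoulder width
    hw = 0.12 * scale
    pose = {
        "nose": (0.0, 1.12, 0.09),
        "head": (0.0, 1.22, 0.0),
        "neck": (0.0, 1.05, 0.0),
        "mid_hip": (0.0, 0.55, 0.0),
        "shoulder_l": (sw, 1.00, 0.0),
        "shoulder_r": (-sw, 1.00, 0.0),
        "hip_l": (hw, 0.55, 0.0),
        "hip_r": (-hw, 0.55, 0.0),
        "knee_l": (hw, 0.55, 0.45),
        "knee_r": (-hw, 0.55, 0.45),
        "ankle_l": (hw, 0.12, 0.45),
        "ankle_r": (-hw, 0.12, 0.45),
    }
    arr = np.zeros((len(JOINT_NAMES), 3))
    for name, xyz in pose.items():
        arr[JOINT_NAMES.index(name)] = xyz
    return arr


def _arm_chain(shoulder: np.ndarray, side_sign: float, phi: np.ndarray,
               beta: np.ndarray, eps: np.ndarray, scale: float
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elbow/wrist/hand positions from shoulder flexion ``phi``,
    abduction ``beta`` and elbow flexion ``eps`` (degrees, per frame)."""
    phi, beta, eps = (np.radians(np.asarray(x, dtype=float))
                      for x in (phi, beta, eps))
    u = np.stack([side_sign * np.sin(beta) * np.cos(phi),
                  -np.cos(beta) * np.cos(phi),
                  np.sin(phi)], axis=1)
    forward = np.array([0.0, 0.0, 1.0])
    w = np.cross(u, forward)
    wn = np.linalg.norm(w, axis=1, keepdims=True)
    small = wn[:, 0] < 1e-8
    if np.any(small):     # arm pointing straight forward: bend downward
        w[small] = np.cross(u[small], np.array([0.0, -1.0, 0.0]))
        wn = np.linalg.norm(w, axis=1, keepdims=True)
    w = w / wn
    wxu = np.cross(w, u)
    fore = u * np.cos(eps)[:, None] + wxu * np.sin(eps)[:, None]
    elbow = shoulder + _ARM["upper"] * scale * u
    wrist = elbow + _ARM["fore"] * scale * fore
    hand = wrist + _ARM["hand"] * scale * fore
    return elbow, wrist, hand


def _assemble_skeleton(n: int, base: np.ndarray, body_side: str,
                       elbow: np.ndarray, wrist: np.ndarray,
                       hand: np.ndarray, lean: np.ndarray,
                       scale: float) -> np.ndarray:
    """Per-frame joint array: moving arm plus trunk lean (forward shift
    of every upper-body joint); the other arm rests."""
    pos = np.broadcast_to(base, (n, *base.shape)).copy()
    upper = [JOINT_NAMES.index(j) for j in
             ("nose", "head", "neck", "shoulder_l", "shoulder_r")]
    pos[:, upper, 2] += lean[:, None]
    s = body_side[0]
    other = "r" if s == "l" else "l"
    # resting pose for the contralateral arm
    sh_o = pos[:, JOINT_NAMES.index(f"shoulder_{other}")]
    sign_o = 1.0 if other == "l" else -1.0
    rest = (np.full(n, 5.0), np.full(n, 8.0), np.full(n, 10.0))
    e_o, w_o, h_o = _arm_chain(sh_o, sign_o, *rest, scale)
    for name, val in ((f"elbow_{other}", e_o), (f"wrist_{other}", w_o),
                      (f"hand_{other}", h_o)):
        pos[:, JOINT_NAMES.index(name)] = val
    for name, val in ((f"elbow_{s}", elbow), (f"wrist_{s}", wrist),
                      (f"hand_{s}", hand)):
        pos[:, JOINT_NAMES.index(name)] = val
    return pos


def _pad_profile(curve: np.ndarray, pad: int) -> np.ndarray:
    return np.concatenate([np.full(pad, curve[0]), curve,
                           np.full(pad, curve[-1])])


def _skeleton_motion(motion: str, body_side: str, ability: float,
                     is_paretic: bool, profile: ImpairmentProfile,
                     rng: np.random.Generator) -> SkeletonSequence:
    """One angular skeleton motion (I/II/III/IV/V)."""
    fps = SKELETON_FPS
    scale = profile.body_scale
    g = max(ability, 0.03) if is_paretic else 1.0
    duration = _MOTION_DURATION_S[motion]
    if is_paretic:
        duration *= 1.0 + 1.2 * (1.0 - ability)
    n_move = int(round(duration * fps))
    pad = int(round(_REST_PAD_S * fps))
    tau = np.linspace(0.0, 1.0, n_move)
    n_sub = _n_submovements(ability) if is_paretic else 1
    curve = _pad_profile(_staged_curve(tau, n_sub, rng), pad)
    n = len(curve)

    angles = []
    for start, full_end in _MOTION_ANGLES[motion]:
        angles.append(start + (full_end - start) * g * curve)
    phi, beta, eps = angles

    lean_m = profile.trunk_lean_m
    if lean_m is None:
        lean_m = 0.13 * (1.0 - ability) ** 2 if is_paretic else 0.0
    lean = lean_m * curve

    base = _base_skeleton(scale)
    sign = 1.0 if body_side == "left" else -1.0
    shoulder = np.broadcast_to(
        base[JOINT_NAMES.index(f"shoulder_{body_side[0]}")], (n, 3)).copy()
    shoulder[:, 2] += lean
    elbow, wrist, hand = _arm_chain(shoulder, sign, phi, beta, eps, scale)
    pos = _assemble_skeleton(n, base, body_side, elbow, wrist, hand,
                             lean, scale)
    pos = pos + _skeleton_noise(rng, pos.shape, profile.noise_sd, fps)
    times = np.arange(n) / fps
    return SkeletonSequence(times, pos, fps=fps)


def _finger_to_nose_motion(body_side: str, profile: ImpairmentProfile,
                           is_paretic: bool,
                           rng: np.random.Generator) -> SkeletonSequence:
    """Motion XV: reach from near the knee to the nose, hold, return of
    the measurement window; tremor/dysmetria/slowing planted from the
    abilities of items 31/32/33."""
    fps = SKELETON_FPS
    scale = profile.body_scale
    a31 = profile.abilities[31] if is_paretic else 1.0
    a32 = profile.abilities[32] if is_paretic else 1.0
    a33 = profile.abilities[33] if is_paretic else 1.0

    t_move = 1.5 * scale
    if is_paretic:
        t_move = min(t_move / max(a33, 0.15), 8.0)
    # rest/hold scale with the movement so the above-mean-speed
    # detection covers the same fraction of the reach on both sides
    pad = int(round(0.25 * t_move * fps))
    hold = int(round(0.30 * t_move * fps))
    n_move = int(round(t_move * fps))

    base = _base_skeleton(scale)
    nose = base[JOINT_NAMES.index("nose")]
    sign = 1.0 if body_side == "left" else -1.0
    start = np.array([sign * 0.30 * scale, 0.60, 0.30])
    miss_dir = np.array([sign * 0.5, -0.35, 0.75])
    miss_dir = miss_dir / np.linalg.norm(miss_dir)
    # an accurate touch still leaves the wrist about a hand-length from
    # the nose; dysmetria inflates that residual distance
    miss = 0.08 * scale
    if is_paretic:
        miss = min(0.08 * scale / max(a32, 0.18), 0.45)
    target = nose + miss * miss_dir

    tau = np.linspace(0.0, 1.0, n_move)
    n_sub = _n_submovements(a33) if is_paretic else 1
    curve = _staged_curve(tau, n_sub, rng)
    wrist_move = start[None, :] + curve[:, None] * (target - start)[None, :]

    if is_paretic:
        amp = profile.tremor_amplitude_m
        if amp is None:
            amp = 0.05 * (1.0 - a31) ** 1.5
        if amp > 0:
            speed_env = np.abs(np.gradient(curve))
            env = speed_env / speed_env.max() if speed_env.max() > 0 else 0.0
            t = np.arange(n_move) / fps
            trem = amp * np.sin(2 * np.pi * profile.tremor_hz * t) * env
            wrist_move = wrist_move + trem[:, None] * np.array(
                [sign * 0.7, 0.7, 0.0]) / np.hypot(0.7, 0.7)

    wrist = np.concatenate([
        np.broadcast_to(start, (pad, 3)), wrist_move,
        np.broadcast_to(wrist_move[-1], (hold + pad, 3))])
    n = len(wrist)

    shoulder = np.broadcast_to(
        base[JOINT_NAMES.index(f"shoulder_{body_side[0]}")], (n, 3))
    mid = 0.5 * (shoulder + wrist)
    elbow = mid + np.array([sign * 0.06, -0.10, 0.0])
    fore_dir = wrist - elbow
    fore_dir = fore_dir / np.linalg.norm(fore_dir, axis=1, keepdims=True)
    hand = wrist + 0.05 * fore_dir
    lean = np.zeros(n)
    pos = _assemble_skeleton(n, base, body_side, elbow, wrist, hand,
                             lean, scale)
    pos = pos + _skeleton_noise(rng, pos.shape, profile.noise_sd, fps)
    return SkeletonSequence(np.arange(n) / fps, pos, fps=fps)


# ---------------------------------------------------------------------------
# hand and grasp models

def _hand_template(motion: str, t: np.ndarray, pos_scale: float,
                   amp_scale: float) -> np.ndarray:
    """Noise-free hand channels (n, 10) for one motion.  ``pos_scale``
    scales the positioning channel (prerequisite DoF of items 14/17),
    ``amp_scale`` every performance channel."""
    n = len(t)
    ch = {name: np.zeros(n) for name in HAND_CHANNELS}
    ramp = _minjerk(t / 1.0)                     # 1 s positioning ramp
    osc = np.where(t > 1.2, np.sin(2 * np.pi * 0.75 * (t - 1.2)), 0.0)
    if motion == "VI90":
        ch["elbow_flexion"] = 95.0 * pos_scale * ramp
        ch["forearm_rotation"] = 80.0 * amp_scale * np.abs(osc)
    elif motion == "VI0":
        ch["shoulder_flexion"] = 85.0 * pos_scale * ramp
        ch["forearm_rotation"] = 80.0 * amp_scale * np.abs(osc)
    elif motion in ("VII90", "VII0"):
        up = 25.0 * _minjerk(t / 0.8)
        cyc = np.where(t > 1.0,
                       -27.5 + 27.5 * np.cos(2 * np.pi * 0.9 * (t - 1.0)),
                       0.0)
        ch["wrist_pitch"] = amp_scale * (up + cyc)
        ch["elbow_flexion"][:] = 90.0 if motion == "VII90" else 5.0
    elif motion == "VIII":
        w = 2 * np.pi * 0.8
        gate = _minjerk(t / 0.8)
        ch["wrist_pitch"] = 20.0 * amp_scale * gate * np.sin(w * t)
        ch["wrist_yaw"] = 15.0 * amp_scale * gate * np.cos(w * t) \
            - 15.0 * amp_scale * gate
    elif motion == "IX":
        flex = _minjerk((t - 0.3) / 1.2)
        ext = _minjerk((t - 2.0) / 1.2)
        for i, finger_gain in enumerate((1.0, 1.04, 0.98, 0.94), start=1):
            eta = 5.0 + (95.0 * flex - 85.0 * ext) * finger_gain * amp_scale
            ch[f"finger{i}"] = eta
        ch["grab_strength"] = np.clip(
            0.9 * amp_scale * (flex - ext), 0.0, 1.0)
    else:
        raise ValidationError(f"not a hand motion: {motion!r}")
    return np.stack([ch[name] for name in HAND_CHANNELS], axis=1)


def _hand_motion(motion: str, ability: float, is_paretic: bool,
                 profile: ImpairmentProfile,
                 rng: np.random.Generator) -> HandSequence:
    fps = HAND_FPS
    t = np.arange(int(round(3.6 * fps))) / fps
    amp = max(ability, 0.02) * profile.body_scale if is_paretic \
        else profile.body_scale
    # positioning DoF degrades more slowly than the scored DoF, so the
    # "reached the start position" prerequisite flips at ability ~ 1/3
    pos = min(1.0, ability + 1.0 / 3.0) * profile.body_scale if is_paretic \
        else profile.body_scale
    ch = _hand_template(motion, t, pos, amp)
    noise = rng.normal(0.0, profile.hand_noise_deg, ch.shape)
    noise[:, -1] *= 0.01                        # grab strength is unitless
    ch = ch + noise
    ch[:, -1] = np.clip(ch[:, -1], 0.0, 1.0)
    return HandSequence(t, ch, fps=fps)


def _grasp_motion(motion: str, ability: float, is_paretic: bool,
                  profile: ImpairmentProfile,
                  rng: np.random.Generator) -> GraspRecording:
    fps = GRASP_FPS
    tool = GRASP_TOOLS[motion]
    t = np.arange(int(round(5.0 * fps))) / fps
    amp = max(ability, 0.0) * profile.body_scale if is_paretic \
        else profile.body_scale
    envelope = _minjerk((t - 0.5) / 1.0) - _minjerk((t - 3.5) / 1.0)
    force = TOOL_FORCE_N[tool] * amp * envelope
    force = np.clip(force + rng.normal(0.0, profile.force_noise_n, len(t)),
                    0.0, None)
    voltage = np.clip(0.04 * force
                      + rng.normal(0.0, 0.01, len(t)), 0.0, None)
    return GraspRecording(t, voltage, force, tool_id=tool, fps=fps)


# ---------------------------------------------------------------------------
# subjects and cohorts

def _motion_ability(motion: str, profile: ImpairmentProfile) -> float:
    items = [s.item_id for s in items_for_motion(motion)]
    return float(np.mean([profile.abilities[i] for i in items]))


def simulate_subject(profile: ImpairmentProfile,
                     subject_id: str = "S01",
                     paretic_side: str = "left",
                     motions: tuple[str, ...] | None = None
                     ) -> tuple[SubjectRecord, GroundTruth]:
    """Generate one subject's recordings (both sides) plus planted
    scores.  ``motions`` restricts generation to a subset of tasks.
    Deterministic given the profile's seed."""
    rng = np.random.default_rng(np.random.SeedSequence(profile.seed))
    selected = tuple(MOTION_KIND) if motions is None else tuple(motions)
    less_affected_side = "right" if paretic_side == "left" else "left"
    recordings: dict = {}
    # draw in a fixed motion order so the stream is reproducible
    for motion in MOTION_KIND:
        if motion not in selected:
            continue
        kind = MOTION_KIND[motion]
        a = _motion_ability(motion, profile)
        reps = 2 if motion in _REPEATED_MOTIONS else 1
        recordings[motion] = {"paretic": [], "less_affected": []}
        for side_name, body_side, is_paretic in (
                ("paretic", paretic_side, True),
                ("less_affected", less_affected_side, False)):
            for _ in range(reps):
                if kind == "skeleton" and motion == "XV":
                    rec = _finger_to_nose_motion(body_side, profile,
                                                 is_paretic, rng)
                elif kind == "skeleton":
                    rec = _skeleton_motion(motion, body_side, a,
                                           is_paretic, profile, rng)
                elif kind == "hand":
                    rec = _hand_motion(motion, a, is_paretic, profile, rng)
                else:
                    rec = _grasp_motion(motion, a, is_paretic, profile, rng)
                recordings[motion][side_name].append(rec)
    truth = GroundTruth(
        {i: ability_to_score(profile.abilities[i]) for i in ITEM_IDS})
    record = SubjectRecord(subject_id, paretic_side, recordings,
                           reference_scores=dict(truth.scores))
    return record, truth


def simulate_cohort(n: int, seed: int = 0,
                    ability_spectrum=None, *,
                    noise_scale: float = 1.0,
                    motions: tuple[str, ...] | None = None
                    ) -> list[tuple[SubjectRecord, GroundTruth]]:
    """Simulate ``n`` subjects with base abilities spread evenly across
    [0, 1] (or an explicit spectrum); per-subject seeds derive from the
    master seed, so identical seeds give identical cohorts."""
    if n < 2:
        raise ParameterError("cohort needs n >= 2 subjects")
    if ability_spectrum is None:
        ability_spectrum = np.linspace(0.0, 1.0, n)
    ability_spectrum = np.asarray(ability_spectrum, dtype=float)
    if len(ability_spectrum) != n:
        raise ParameterError("ability spectrum length must equal n")
    children = np.random.SeedSequence(seed).spawn(n)
    cohort = []
    for i, (base, child) in enumerate(zip(ability_spectrum, children)):
        rng = np.random.default_rng(child)
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        profile = make_profile(float(base), sub_seed,
                               noise_scale=noise_scale, rng=rng)
        paretic = "left" if rng.random() < 0.7 else "right"
        cohort.append(simulate_subject(
            profile, subject_id=f"S{i + 1:02d}",
            paretic_side=paretic, motions=motions))
    return cohort
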