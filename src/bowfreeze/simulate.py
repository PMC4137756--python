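"""Synthetic bowing trials with controlled inter-joint coordination.

The generator emulates metronome-paced repeated bowing (0.75 s per bow, 20
cycles, 60 Hz) on an abstract but fully articulated right-arm model and
emits the complete 14-marker set, so synthetic trials run through the whole
pipeline exactly like measured ones.

Model geometry.  The arm is a shoulder-elbow-wrist chain (segment lengths
300 / 280 / 80 mm, bow 650 mm held rigidly in the hand) working against a
fixed string axis that runs parallel to the lab Y axis.  Each joint carries
two rotation channels:

* *elevation* — rotation about the lab Y axis, i.e. in the vertical plane
  containing the bowing direction.  Elevation rotations transport the bow
  along its own axis and, by construction, leave the bow-string angle
  untouched (any bow direction in the XZ plane is perpendicular to Y).
* *yaw* — small rotations about the lab Z axis that tilt the bow toward the
  string axis and therefore perturb the bow-string angle.

This separation makes the coordination structure of a profile exactly
interpretable: transport lives in the elevation channel, bow-angle control
lives in the yaw channel.  The wrist can be programmed to counter-rotate
against the proximal transport (``wrist_counter_gain``, the counter-movement
that keeps the hand lever from adding bow displacement) and to cancel
proximal yaw noise (``angle_compensation_gain``, the coordination that
stabilises the bow-string angle).

Marker placement mirrors — and exactly inverts — the analysis' virtual
joint-center constructions: the lateral elbow marker and the wrist marker
pair are positioned by a fixed-point iteration such that the pipeline's
anthropometric offsets land precisely on the generator's true joint
centers.  Together with rigid hand/bow markers this makes chain
decomposition recover the programmed joint rotations exactly (to numerical
precision) on noise-free trials.

Marker noise is i.i.d. Gaussian per coordinate (default SD 0.5 mm,
motion-capture realistic); joint noise is smooth (low-pass filtered at 3 Hz)
to mimic physiological fluctuation.  Soft-tissue artefact is not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import REQUIRED_ROLES, AnthropometricSet, TrialRecording

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# skeleton constants (mm, lab frame: +Z up, string parallel to +Y)
# ---------------------------------------------------------------------------

L_UPPER = 300.0
L_LOWER = 280.0
L_HAND = 80.0
BOW_LENGTH = 650.0
BOW_TIP_FROM_PROXIMAL = 430.0  # proximal marker ~2/3 of the way from tip to frog

SHOULDER = np.array([0.0, 0.0, 0.0])
STERNUM = np.array([-60.0, -90.0, -140.0])
C7 = np.array([-160.0, -70.0, -60.0])

#: mean wrist position defining the base posture (solved by inverse kinematics)
WRIST_MEAN = np.array([150.0, 0.0, -400.0])
HAND_ELEVATION_MEAN = np.radians(-15.0)  # mean hand direction in the XZ plane

WRIST_MARKER_HALF_SPAN = 25.0  # radial/ulnar markers sit +-25 mm along local y
LOWERARM_OFFSET = np.array([140.0, 40.0, 0.0])  # forearm-shaft marker, local
PIP1_OFFSET = np.array([95.0, 18.0, -15.0])  # distal finger marker, hand frame

DEFAULT_ANTHRO = AnthropometricSet()

_ROLES = tuple(REQUIRED_ROLES)


def _ry(alpha: np.ndarray) -> np.ndarray:
    """Rotation mapping +X into the XZ-plane direction (cos a, 0, sin a)."""
    a = np.atleast_1d(np.asarray(alpha, float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = -s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = s
    out[..., 2, 2] = c
    return out


def _rz(psi: np.ndarray) -> np.ndarray:
    p = np.atleast_1d(np.asarray(psi, float))
    c, s = np.cos(p), np.sin(p)
    out = np.zeros(p.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _seg_rot(psi: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Segment orientation: yaw about Z composed with elevation in XZ."""
    return np.einsum("nij,njk->nik", _rz(psi), _ry(alpha))


def _arm_ik(wrist_xz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Planar two-link inverse kinematics for the (x, z) wrist target.

    Returns (alpha1, beta2): upper-arm elevation and relative elbow angle,
    elbow-down branch.  Raises if the target is out of reach.
    """
    x, z = wrist_xz[..., 0], wrist_xz[..., 1]
    r2 = x * x + z * z
    cos_b = (r2 - L_UPPER**2 - L_LOWER**2) / (2 * L_UPPER * L_LOWER)
    if np.any(np.abs(cos_b) >= 1.0 - 1e-9):
        raise ValueError("wrist target out of reach or elbow fully extended")
    beta2 = np.arccos(cos_b)
    lam = np.arctan2(L_LOWER * np.sin(beta2), L_UPPER + L_LOWER * np.cos(beta2))
    alpha1 = np.arctan2(z, x) - lam
    return alpha1, beta2


# base posture, solved once
_A1_0, _B2_0 = _arm_ik(np.array([WRIST_MEAN[0], WRIST_MEAN[2]]))
ALPHA1_MEAN = float(_A1_0)
BETA2_MEAN = float(_B2_0)
ALPHA2_MEAN = ALPHA1_MEAN + BETA2_MEAN
GAMMA3_MEAN = HAND_ELEVATION_MEAN - ALPHA2_MEAN

_R_HAND_MEAN = _ry(np.array([HAND_ELEVATION_MEAN]))[0]
#: bow grip: proximal bow marker offset (hand frame) and bow direction (hand frame)
R_HP = _R_HAND_MEAN.T @ np.array([60.0, 35.0, -35.0])
U_BOW_HAND = _R_HAND_MEAN.T @ np.array([1.0, 0.0, 0.0])

#: string axis: parallel to +Y through (x, z) = (STRING_X, STRING_Z)
_P_BOW_MEAN = WRIST_MEAN + _R_HAND_MEAN @ R_HP
CONTACT_MEAN = 250.0  # mean contact coordinate along the bow, mm from proximal marker
STRING_X = float(_P_BOW_MEAN[0] + CONTACT_MEAN)
STRING_Z = float(_P_BOW_MEAN[2])
CELLO_SCROLL = np.array([STRING_X, 600.0, STRING_Z])
CELLO_TAILPIECE = np.array([STRING_X, -100.0, STRING_Z])
CELLO_BODY = np.array([STRING_X + 60.0, 250.0, STRING_Z - 45.0])


# ---------------------------------------------------------------------------
# coordination profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoordinationProfile:
    """Joint-space program of one simulated participant.

    Transport amplitudes are half-ranges in radians of the elevation channel
    (the waveform spans [-1, 1]); phases are radians of the 1.5 s bowing
    cycle.  ``plateau_fraction`` shapes the bow-velocity profile: 0 gives a
    sinusoidal (bell-shaped) profile, p > 0 a trapezoid whose constant-
    velocity plateau covers the fraction p of each stroke.  The reversal
    ramp time constant is (1 - p) * stroke/2 unless overridden.
    """

    name: str = "custom"
    shoulder_amp: float = 0.3
    elbow_amp: float = 0.3
    wrist_amp: float = 0.0
    shoulder_phase: float = 0.0
    elbow_phase: float = 0.0
    wrist_phase: float = 0.0
    plateau_fraction: float = 0.0
    reversal_sharpness_s: float | None = None
    wrist_counter_gain: float = 0.0
    angle_compensation_gain: float = 0.0
    joint_noise_sd: float = 0.0  # rad, per channel
    marker_noise_sd: float = 0.5  # mm
    noise_bandwidth_hz: float = 3.0
    coupling_mode: str = "independent"

    def __post_init__(self) -> None:
        for name in ("shoulder_amp", "elbow_amp", "wrist_amp", "joint_noise_sd", "marker_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.plateau_fraction < 1.0:
            raise ValueError("plateau_fraction must lie in [0, 1)")
        if self.coupling_mode not in ("independent", "compensatory"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")


def preset(name: str) -> CoordinationProfile:
    """Documented coordination profiles.

    * ``expert_like`` — shoulder and elbow share transport in phase with a
      rectangular (plateau 0.8) velocity profile and sharp reversals; the
      wrist counter-rotates against the proximal transport and cancels 90 %
      of proximal bow-angle noise.
    * ``novice_like`` — shoulder-only transport with a sinusoidal velocity
      profile and no wrist compensation or counter-movement.
    * ``independent_noise`` — shoulder transport plus mutually independent
      smooth noise at every joint: the no-coordination null.
    * ``compensatory`` — as ``independent_noise`` but the wrist yaw cancels
      90 % of the proximal joints' bow-angle noise.
    """
    presets = {
        "expert_like": CoordinationProfile(
            name="expert_like",
            shoulder_amp=0.30,
            elbow_amp=0.35,
            plateau_fraction=0.8,
            wrist_counter_gain=0.95,
            angle_compensation_gain=0.9,
            joint_noise_sd=0.010,
            coupling_mode="compensatory",
        ),
        "novice_like": CoordinationProfile(
            name="novice_like",
            shoulder_amp=0.52,
            elbow_amp=0.0,
            plateau_fraction=0.0,
            joint_noise_sd=0.015,
            coupling_mode="independent",
        ),
        "independent_noise": CoordinationProfile(
            name="independent_noise",
            shoulder_amp=0.45,
            elbow_amp=0.0,
            plateau_fraction=0.0,
            joint_noise_sd=0.020,
            coupling_mode="independent",
        ),
        "compensatory": CoordinationProfile(
            name="compensatory",
            shoulder_amp=0.45,
            elbow_amp=0.0,
            plateau_fraction=0.0,
            angle_compensation_gain=0.9,
            joint_noise_sd=0.020,
            coupling_mode="compensatory",
        ),
    }
    try:
        return presets[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}") from None


# ---------------------------------------------------------------------------
# waveforms and noise
# ---------------------------------------------------------------------------


def transport_waveform(
    t: np.ndarray,
    period_s: float = 1.5,
    plateau_fraction: float = 0.0,
    ramp_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised transport waveform w(t) in [-1, 1] and its derivative.

    Reversals (velocity zero crossings) sit at t = 0 mod period/2.  With
    ``plateau_fraction`` 0 (and no ramp override) the waveform is
    sinusoidal; otherwise velocity is a trapezoid whose reversal ramps last
    ``ramp_s`` seconds on each side of the reversal (default
    (1 - plateau) * period/4).  Peak acceleration at a reversal is
    V / ramp_s with V the plateau speed.
    """
    t = np.asarray(t, float)
    half = period_s / 2.0
    if ramp_s is None:
        if plateau_fraction <= 0.0:
            w = -np.cos(2 * np.pi * t / period_s)
            v = (2 * np.pi / period_s) * np.sin(2 * np.pi * t / period_s)
            return w, v
        ramp_s = (1.0 - plateau_fraction) * half / 2.0
    if not 0 < ramp_s < half / 2:
        raise ValueError(f"ramp_s must lie in (0, {half / 2}), got {ramp_s}")
    vmax = 2.0 / (half - ramp_s)  # so that the position range is [-1, 1]
    u = np.mod(t, period_s)
    # velocity: +vmax on the first half stroke, -vmax on the second,
    # linear ramps of width 2*ramp centred on u = 0 and u = half
    v = np.where(u < half, vmax, -vmax)
    for center, sign in ((0.0, 1.0), (half, -1.0), (period_s, 1.0)):
        m = np.abs(u - center) < ramp_s
        v = np.where(m, sign * vmax * (u - center) / ramp_s, v)
    # position by piecewise integration (quadratic in the ramps)
    w = np.empty_like(u)
    w0 = -1.0 + 0.5 * vmax * ramp_s  # position at u = ramp
    m = u < ramp_s
    w[m] = -1.0 + 0.5 * vmax * u[m] ** 2 / ramp_s
    m = (u >= ramp_s) & (u < half - ramp_s)
    w[m] = w0 + vmax * (u[m] - ramp_s)
    m = (u >= half - ramp_s) & (u < half + ramp_s)
    du = u[m] - (half - ramp_s)
    w[m] = (w0 + vmax * (half - 2 * ramp_s)) + vmax * du - 0.5 * vmax * du**2 / ramp_s
    m = (u >= half + ramp_s) & (u < period_s - ramp_s)
    w[m] = (1.0 - 0.5 * vmax * ramp_s) - vmax * (u[m] - half - ramp_s)
    m = u >= period_s - ramp_s
    du = u[m] - (period_s - ramp_s)
    w[m] = (-1.0 + 0.5 * vmax * ramp_s) - vmax * du + 0.5 * vmax * du**2 / ramp_s
    return w, v


def _smooth_noise(
    rng: np.random.Generator, n: int, rate_hz: float, sd: float, bandwidth_hz: float
) -> np.ndarray:
    """Low-pass filtered Gaussian noise rescaled to the requested SD."""
    if sd <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = signal.butter(2, bandwidth_hz, fs=rate_hz, output="sos")
    smooth = signal.sosfiltfilt(sos, white)
    s = np.std(smooth)
    return smooth * (sd / s) if s > 0 else np.zeros(n)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _fixed_point_elbow_marker(
    elbow: np.ndarray, shoulder_jc: np.ndarray, sternum: np.ndarray, width: float
) -> np.ndarray:
    """Marker position whose medial anthropometric offset lands on ``elbow``."""
    m = elbow.copy()
    for _ in range(25):
        axis = m - shoulder_jc
        axis /= np.linalg.norm(axis, axis=-1, keepdims=True)
        v = sternum - m
        v = v - np.einsum("ni,ni->n", v, axis)[:, None] * axis
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        m = elbow - 0.5 * width * v
    return m


def _fixed_point_wrist_mid(
    wrist: np.ndarray, elbow: np.ndarray, u_wl: np.ndarray, width: float
) -> np.ndarray:
    """Wrist-marker midpoint whose palmar-normal offset lands on ``wrist``."""
    mid = wrist.copy()
    for _ in range(25):
        fore = mid - elbow
        fore /= np.linalg.norm(fore, axis=-1, keepdims=True)
        n = np.cross(fore, u_wl)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        mid = wrist - 0.5 * width * n
    return mid


def _markers_from_angles(
    alpha1: np.ndarray,
    beta2: np.ndarray,
    gamma3: np.ndarray,
    psi1: np.ndarray,
    psi2: np.ndarray,
    psi3: np.ndarray,
    anthro: AnthropometricSet,
) -> dict[str, np.ndarray]:
    """Exact forward model: marker positions (frames, 3) for every role."""
    n = alpha1.shape[0]
    alpha2 = alpha1 + beta2
    alpha3 = alpha2 + gamma3
    r1 = _seg_rot(psi1, alpha1)
    r2 = _seg_rot(psi1 + psi2, alpha2)
    r3 = _seg_rot(psi1 + psi2 + psi3, alpha3)
    elbow = SHOULDER + np.einsum("nij,j->ni", r1, np.array([L_UPPER, 0.0, 0.0]))
    wrist = elbow + np.einsum("nij,j->ni", r2, np.array([L_LOWER, 0.0, 0.0]))
    mcp1 = wrist + np.einsum("nij,j->ni", r3, np.array([L_HAND, 0.0, 0.0]))
    bow_prox = wrist + np.einsum("nij,j->ni", r3, R_HP)
    u_bow = np.einsum("nij,j->ni", r3, U_BOW_HAND)
    static = lambda p: np.broadcast_to(p, (n, 3)).copy()
    u_wl = np.einsum("nij,j->ni", r2, np.array([0.0, 1.0, 0.0]))
    wrist_mid = _fixed_point_wrist_mid(wrist, elbow, u_wl, anthro.wrist_width_mm)
    markers = {
        "sternum": static(STERNUM),
        "c7": static(C7),
        "acromion": static(SHOULDER),
        "elbow_lateral": _fixed_point_elbow_marker(
            elbow, static(SHOULDER), static(STERNUM), anthro.elbow_width_mm
        ),
        "lowerarm": elbow + np.einsum("nij,j->ni", r2, LOWERARM_OFFSET),
        "wrist_radial": wrist_mid - WRIST_MARKER_HALF_SPAN * u_wl,
        "wrist_ulnar": wrist_mid + WRIST_MARKER_HALF_SPAN * u_wl,
        "mcp1": mcp1,
        "pip1": wrist + np.einsum("nij,j->ni", r3, PIP1_OFFSET),
        "cello_scroll": static(CELLO_SCROLL),
        "cello_tailpiece": static(CELLO_TAILPIECE),
        "cello_body": static(CELLO_BODY),
        "bow_tip": bow_prox + BOW_TIP_FROM_PROXIMAL * u_bow,
        "bow_proximal": bow_prox,
    }
    return markers


def _contact_and_angle(
    bow_prox: np.ndarray, u_bow: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form contact coordinate and bow-string angle (degrees)."""
    d2 = np.array([0.0, -1.0, 0.0])  # scroll -> tailpiece
    w0 = bow_prox - CELLO_SCROLL
    b = u_bow @ d2
    d = np.einsum("ni,ni->n", u_bow, w0)
    e = w0 @ d2
    s = (b * e - d) / (1.0 - b * b)
    angle = np.degrees(np.arccos(np.clip(b, -1.0, 1.0)))
    return s, angle


@dataclass
class GroundTruth:
    """Programmed motion underlying a simulated trial (no marker noise)."""

    time: np.ndarray
    elevation: dict[str, np.ndarray]  # realised relative elevation per joint, rad
    yaw: dict[str, np.ndarray]  # realised relative yaw per joint, rad
    contact_position: np.ndarray  # mm along the bow axis
    contact_velocity: np.ndarray  # mm/s
    angle_deg: np.ndarray
    joint_transport_mm: dict[str, float] = field(default_factory=dict)
    profile: CoordinationProfile | None = None


def simulate_trial(
    profile: CoordinationProfile,
    n_cycles: int = 20,
    rate_hz: float = 60.0,
    bow_period_s: float = 1.5,
    seed: int | None = None,
    *,
    pad_s: float = 0.5,
    meta: dict | None = None,
    missing: dict[str, list[int]] | None = None,
    anthro: AnthropometricSet = DEFAULT_ANTHRO,
) -> tuple[TrialRecording, GroundTruth]:
    """Simulate one metronome-paced bowing trial.

    Twenty bowing cycles by default (40 strokes of 0.75 s) with ``pad_s``
    seconds of extra motion at each end so that the first and last reversal
    windows fit inside the trial.  ``missing`` optionally marks samples of
    named roles as missing.  With a fixed seed the output is bit-identical
    across runs.
    """
    rng = np.random.default_rng(seed)
    n = int(round((n_cycles * bow_period_s + 2 * pad_s) * rate_hz))
    t = np.arange(n) / rate_hz - pad_s

    def wave(phase: float) -> np.ndarray:
        shift = phase / (2 * np.pi) * bow_period_s
        return transport_waveform(
            t - shift, bow_period_s, profile.plateau_fraction, profile.reversal_sharpness_s
        )[0]

    d_sh = profile.shoulder_amp * wave(profile.shoulder_phase)
    d_el = profile.elbow_amp * wave(profile.elbow_phase)
    d_wr = profile.wrist_amp * wave(profile.wrist_phase) - profile.wrist_counter_gain * (
        d_sh + d_el
    )
    noise = {
        key: _smooth_noise(rng, n, rate_hz, profile.joint_noise_sd, profile.noise_bandwidth_hz)
        for key in ("sh_e", "el_e", "wr_e", "sh_y", "el_y", "wr_y")
    }
    elev = {
        "shoulder": d_sh + noise["sh_e"],
        "elbow": d_el + noise["el_e"],
        "wrist": d_wr + noise["wr_e"],
    }
    yaw = {
        "shoulder": noise["sh_y"],
        "elbow": noise["el_y"],
        "wrist": -profile.angle_compensation_gain * (noise["sh_y"] + noise["el_y"])
        + noise["wr_y"],
    }
    markers = _markers_from_angles(
        ALPHA1_MEAN + elev["shoulder"],
        BETA2_MEAN + elev["elbow"],
        GAMMA3_MEAN + elev["wrist"],
        yaw["shoulder"],
        yaw["elbow"],
        yaw["wrist"],
        anthro,
    )
    u_bow = (markers["bow_tip"] - markers["bow_proximal"]) / BOW_TIP_FROM_PROXIMAL
    s_true, angle_true = _contact_and_angle(markers["bow_proximal"], u_bow)

    # per-joint transport contribution: forward model with only that joint's
    # deterministic program active
    transport: dict[str, float] = {}
    zeros = np.zeros(n)
    for joint, prog in (("shoulder", d_sh), ("elbow", d_el), ("wrist", d_wr)):
        solo = {"shoulder": zeros, "elbow": zeros, "wrist": zeros, joint: prog}
        mk = _markers_from_angles(
            ALPHA1_MEAN + solo["shoulder"],
            BETA2_MEAN + solo["elbow"],
            GAMMA3_MEAN + solo["wrist"],
            zeros, zeros, zeros, anthro,
        )
        s_j, _ = _contact_and_angle(
            mk["bow_proximal"], (mk["bow_tip"] - mk["bow_proximal"]) / BOW_TIP_FROM_PROXIMAL
        )
        transport[joint] = float(np.ptp(s_j))

    positions = np.stack([markers[r] for r in _ROLES], axis=1)
    if profile.marker_noise_sd > 0:
        positions = positions + rng.normal(0.0, profile.marker_noise_sd, positions.shape)
    mask = np.zeros((n, len(_ROLES)), dtype=bool)
    if missing:
        for role, frames in missing.items():
            mask[np.asarray(frames, int), _ROLES.index(role)] = True
    positions = positions.copy()
    positions[mask] = np.nan

    trial_meta = {
        "participant_id": "sim",
        "group": "expert" if profile.name == "expert_like" else "novice",
        "lab": "A",
        "anthropometrics": {
            "elbow_width_mm": anthro.elbow_width_mm,
            "wrist_width_mm": anthro.wrist_width_mm,
            "hand_thickness_mm": anthro.hand_thickness_mm,
        },
        "simulation": {"preset": profile.name, "seed": seed, "n_cycles": n_cycles},
    }
    if meta:
        trial_meta.update(meta)
    trial = TrialRecording(
        positions=positions,
        rate_hz=rate_hz,
        labels=list(_ROLES),
        roles={r: r for r in _ROLES},
        missing=mask,
        meta=trial_meta,
    ).validate()
    truth = GroundTruth(
        time=t,
        elevation=elev,
        yaw=yaw,
        contact_position=s_true,
        contact_velocity=np.gradient(s_true, 1.0 / rate_hz),
        angle_deg=angle_true,
        joint_transport_mm=transport,
        profile=profile,
    )
    log.info(
        "simulate_trial: preset=%s seed=%s frames=%d transport=%s",
        profile.name, seed,
        n, {k: round(v, 1) for k, v in transport.items()},
    )
    return trial, truth


def simulate_tracking_trial(
    amplitude_mm: float = 260.0,
    n_cycles: int = 20,
    rate_hz: float = 60.0,
    bow_period_s: float = 1.5,
    plateau_fraction: float = 0.8,
    seed: int | None = None,
    *,
    pad_s: float = 0.5,
    marker_noise_sd: float = 0.0,
    anthro: AnthropometricSet = DEFAULT_ANTHRO,
) -> tuple[TrialRecording, GroundTruth]:
    """Simulate a trial whose bow *contact trajectory is programmed exactly*.

    The bow is translated along its own (fixed) axis following the transport
    waveform, with joint angles obtained by inverse kinematics; the
    ground-truth contact position equals the program to machine precision,
    which makes this variant the reference for validating the bowing-
    coordinate geometry.
    """
    rng = np.random.default_rng(seed)
    n = int(round((n_cycles * bow_period_s + 2 * pad_s) * rate_hz))
    t = np.arange(n) / rate_hz - pad_s
    w, _ = transport_waveform(t, bow_period_s, plateau_fraction)
    s = CONTACT_MEAN + 0.5 * amplitude_mm * w
    p_target_x = STRING_X - s
    # wrist target keeps the hand orientation (hence bow pose) constant
    grip = _R_HAND_MEAN @ R_HP
    wx = p_target_x - grip[0]
    wz = np.full(n, WRIST_MEAN[2])
    alpha1, beta2 = _arm_ik(np.stack([wx, wz], axis=-1))
    gamma3 = HAND_ELEVATION_MEAN - (alpha1 + beta2)
    zeros = np.zeros(n)
    markers = _markers_from_angles(alpha1, beta2, gamma3, zeros, zeros, zeros, anthro)
    positions = np.stack([markers[r] for r in _ROLES], axis=1)
    if marker_noise_sd > 0:
        positions = positions + rng.normal(0.0, marker_noise_sd, positions.shape)
    trial = TrialRecording(
        positions=positions,
        rate_hz=rate_hz,
        labels=list(_ROLES),
        roles={r: r for r in _ROLES},
        meta={
            "participant_id": "sim-tracking",
            "group": "expert",
            "lab": "A",
            "anthropometrics": {
                "elbow_width_mm": anthro.elbow_width_mm,
                "wrist_width_mm": anthro.wrist_width_mm,
                "hand_thickness_mm": anthro.hand_thickness_mm,
            },
            "simulation": {"preset": "tracking", "seed": seed},
        },
    ).validate()
    truth = GroundTruth(
        time=t,
        elevation={"shoulder": alpha1 - ALPHA1_MEAN, "elbow": beta2 - BETA2_MEAN,
                   "wrist": gamma3 - GAMMA3_MEAN},
        yaw={"shoulder": zeros, "elbow": zeros, "wrist": zeros},
        contact_position=s,
        contact_velocity=np.gradient(s, 1.0 / rate_hz),
        angle_deg=np.full(n, 90.0),
        joint_transport_mm={},
        profile=None,
    )
    return trial, truth


def simulate_cohort(
    preset_name: str,
    n_participants: int = 10,
    seed: int = 0,
    *,
    group: str | None = None,
    labs: tuple[str, str] = ("A", "B"),
    rate_hz: float = 60.0,
    n_cycles: int = 20,
) -> list[tuple[TrialRecording, GroundTruth]]:
    """Simulate a group of participants sharing one coordination preset.

    Each participant gets an independent noise stream (spawned from ``seed``)
    and a lab assignment alternating between the two labs.
    """
    profile = preset(preset_name)
    if group is None:
        group = "expert" if preset_name == "expert_like" else "novice"
    children = np.random.SeedSequence(seed).spawn(n_participants)
    out = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        meta = {
            "participant_id": f"{group}{i + 1:02d}",
            "group": group,
            "lab": labs[i % len(labs)],
        }
        out.append(
            simulate_trial(
                profile, n_cycles=n_cycles, rate_hz=rate_hz, seed=sub_seed, meta=meta
            )
        )
    return out
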