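"""Kinematic-chain decomposition of marker trajectories.

The right arm and bow are modelled as a chain of body segments — scapula,
upper arm, lower arm, hand, bow — each carrying an orthonormal local
coordinate system (LCS) built from two marker-derived vectors via
Gram-Schmidt.  Neighbouring segments are related by per-frame rigid-body
motions (rotation + translation):

    lab --root--> scapula --shoulder--> upper arm --elbow--> lower arm
        --wrist--> hand --hand_to_bow--> bow

Marker positions are stored as per-frame offsets in their owning segment's
LCS, so reconstructing markers from the (possibly modified) joint motions is
*exact* for the unmodified chain even in the presence of soft-tissue marker
wobble.  That exactness is what allows frozen-joint surrogate trials to
differ from the original data only through the manipulated joint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import REQUIRED_ROLES, VIRTUAL_ROLES, AnthropometricSet, TrialRecording

log = logging.getLogger(__name__)

VERTICAL = np.array([0.0, 0.0, 1.0])  # lab +Z

#: chain segments in proximal -> distal order (lab holds instrument markers)
SEGMENTS = ("scapula", "upper_arm", "lower_arm", "hand", "bow")

JOINTS = ("shoulder", "elbow", "wrist")

SEGMENT_OF_ROLE: dict[str, str] = {
    "sternum": "scapula",
    "c7": "scapula",
    "acromion": "scapula",
    "shoulder_jc": "scapula",
    "elbow_lateral": "upper_arm",
    "elbow_jc": "upper_arm",
    "lowerarm": "lower_arm",
    "wrist_radial": "lower_arm",
    "wrist_ulnar": "lower_arm",
    "wrist_jc": "lower_arm",
    "mcp1": "hand",
    "pip1": "hand",
    "hand_ref": "hand",
    "bow_tip": "bow",
    "bow_proximal": "bow",
    # cello markers live in the lab frame
    "cello_scroll": "lab",
    "cello_tailpiece": "lab",
    "cello_body": "lab",
}


class DegeneracyError(ValueError):
    """Frame construction vectors are (near) collinear."""


# ---------------------------------------------------------------------------
# basic rigid-body algebra (vectorised over frames)
# ---------------------------------------------------------------------------


@dataclass
class RigidMotionSeries:
    """Per-frame rotation (n,3,3) plus translation (n,3), millimetres."""

    rot: np.ndarray
    trans: np.ndarray

    def __post_init__(self) -> None:
        self.rot = np.asarray(self.rot, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if self.rot.shape[-2:] != (3, 3) or self.trans.shape[-1] != 3:
            raise ValueError("rot must be (n,3,3) and trans (n,3)")
        if self.rot.shape[0] != self.trans.shape[0]:
            raise ValueError("rot/trans frame counts differ")

    @property
    def n_frames(self) -> int:
        return self.rot.shape[0]

    @classmethod
    def identity(cls, n: int) -> "RigidMotionSeries":
        return cls(np.broadcast_to(np.eye(3), (n, 3, 3)).copy(), np.zeros((n, 3)))

    def compose(self, other: "RigidMotionSeries") -> "RigidMotionSeries":
        """self ∘ other (apply ``other`` first, then ``self``)."""
        rot = np.einsum("nij,njk->nik", self.rot, other.rot)
        trans = np.einsum("nij,nj->ni", self.rot, other.trans) + self.trans
        return RigidMotionSeries(rot, trans)

    def inverse(self) -> "RigidMotionSeries":
        rot_t = np.swapaxes(self.rot, -1, -2)
        return RigidMotionSeries(rot_t, -np.einsum("nij,nj->ni", rot_t, self.trans))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map local points (n,3) into the parent frame."""
        return np.einsum("nij,nj->ni", self.rot, np.asarray(points, float)) + self.trans

    def pull_back(self, points: np.ndarray) -> np.ndarray:
        """Express parent-frame points (n,3) in the local frame."""
        return np.einsum("nji,nj->ni", self.rot, np.asarray(points, float) - self.trans)

    def frozen_at(self, frame: int) -> "RigidMotionSeries":
        """Constant series holding this motion's value at ``frame``."""
        n = self.n_frames
        return RigidMotionSeries(
            np.broadcast_to(self.rot[frame], (n, 3, 3)).copy(),
            np.broadcast_to(self.trans[frame], (n, 3)).copy(),
        )

    def copy(self) -> "RigidMotionSeries":
        return RigidMotionSeries(self.rot.copy(), self.trans.copy())


def rotation_angles(series: RigidMotionSeries, reference_frame: int = 0) -> np.ndarray:
    """Rotation magnitude (rad) of each frame's rotation relative to a reference."""
    rel = np.einsum("nij,kj->nik", series.rot, series.rot[reference_frame])
    return Rotation.from_matrix(rel).magnitude()


# ---------------------------------------------------------------------------
# Gram-Schmidt frames
# ---------------------------------------------------------------------------


def _gs_batch(
    primary: np.ndarray, secondary: np.ndarray, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Gram-Schmidt basis; returns (bases (n,3,3), valid (n,))."""
    p = np.atleast_2d(np.asarray(primary, float))
    s = np.atleast_2d(np.asarray(secondary, float))
    pn = np.linalg.norm(p, axis=-1)
    sn = np.linalg.norm(s, axis=-1)
    valid = (pn > 0) & (sn > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = p / pn[..., None]
        orth = s - np.einsum("ni,ni->n", s, e1)[..., None] * e1
        on = np.linalg.norm(orth, axis=-1)
        valid &= on >= tol * sn
        e2 = orth / on[..., None]
    e3 = np.cross(e1, e2)
    basis = np.stack([e1, e2, e3], axis=-1)  # columns are the axes
    basis[~valid] = np.nan
    return basis, valid


def gram_schmidt_frame(primary, secondary, tol: float = 1e-6) -> np.ndarray:
    """Right-handed orthonormal basis from two vectors.

    Column 1 is the normalised primary vector, column 2 the normalised
    component of the secondary orthogonal to it, column 3 their cross
    product.  Near-collinear inputs raise :class:`DegeneracyError`.
    """
    basis, valid = _gs_batch(np.asarray(primary, float)[None], np.asarray(secondary, float)[None], tol)
    if not valid[0]:
        raise DegeneracyError("construction vectors are collinear or zero")
    return basis[0]


# ---------------------------------------------------------------------------
# virtual joint centers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return v / n


def _reject(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Component of v orthogonal to the unit vector ``axis``."""
    return v - np.einsum("ni,ni->n", v, axis)[..., None] * axis


def estimate_joint_centers(
    trial: TrialRecording,
    anthro: AnthropometricSet | None = None,
    *,
    elbow_width_mm: float | None = None,
    wrist_width_mm: float | None = None,
    hand_thickness_mm: float | None = None,
    shoulder_offset_mm: float = 0.0,
) -> TrialRecording:
    """Add virtual joint-center markers derived from anthropometrics.

    Constructions (offsets are half the corresponding thickness):

    * ``shoulder_jc`` — acromion shifted down the lab vertical by
      ``shoulder_offset_mm`` (default 0, i.e. the acromion itself).
    * ``elbow_jc`` — lateral epicondyle shifted medially (perpendicular to
      the shoulder→elbow axis, toward the sternum) by half the elbow width.
    * ``wrist_jc`` — wrist-marker midpoint shifted along the palmar-normal
      estimate ``cross(forearm axis, radial→ulnar line)`` by half the wrist
      width.
    * ``hand_ref`` — first MCP marker shifted along the analogous hand
      normal by half the hand thickness (bookkeeping marker only).

    Keyword overrides take precedence over ``anthro`` and may be zero
    (meaning: no offset); the dataclass itself requires positive values.
    """
    present = [r for r in VIRTUAL_ROLES if r in trial.roles]
    if present:
        raise ValueError(f"virtual roles already present: {present}")
    anthro = anthro or AnthropometricSet(**{
        k: v for k, v in (trial.meta.get("anthropometrics") or {}).items()
    })

    def pick(override: float | None, default: float, name: str) -> float:
        v = default if override is None else float(override)
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"{name} must be >= 0, got {v!r}")
        return v

    w_elbow = pick(elbow_width_mm, anthro.elbow_width_mm, "elbow_width_mm")
    w_wrist = pick(wrist_width_mm, anthro.wrist_width_mm, "wrist_width_mm")
    t_hand = pick(hand_thickness_mm, anthro.hand_thickness_mm, "hand_thickness_mm")

    sternum = trial.marker("sternum")
    acromion = trial.marker("acromion")
    elbow_lat = trial.marker("elbow_lateral")
    radial = trial.marker("wrist_radial")
    ulnar = trial.marker("wrist_ulnar")
    mcp1 = trial.marker("mcp1")

    shoulder_jc = acromion - shoulder_offset_mm * VERTICAL

    up_axis = _unit(elbow_lat - shoulder_jc)
    medial = _unit(_reject(sternum - elbow_lat, up_axis))
    elbow_jc = elbow_lat + 0.5 * w_elbow * medial

    mid = 0.5 * (radial + ulnar)
    wrist_line = _unit(ulnar - radial)
    forearm = _unit(mid - elbow_jc)
    palmar = _unit(np.cross(forearm, wrist_line))
    wrist_jc = mid + 0.5 * w_wrist * palmar

    hand_axis = _unit(mcp1 - wrist_jc)
    hand_norm = _unit(np.cross(hand_axis, wrist_line))
    hand_ref = mcp1 + 0.5 * t_hand * hand_norm

    out = trial.copy()
    new = {
        "shoulder_jc": (shoulder_jc, ["acromion"]),
        "elbow_jc": (elbow_jc, ["acromion", "elbow_lateral", "sternum"]),
        "wrist_jc": (wrist_jc, ["wrist_radial", "wrist_ulnar", "elbow_lateral"]),
        "hand_ref": (hand_ref, ["mcp1", "wrist_radial", "wrist_ulnar"]),
    }
    cols = [pos[:, None, :] for pos, _ in new.values()]
    masks = []
    for _, sources in new.values():
        m = np.zeros(trial.n_frames, dtype=bool)
        for s in sources:
            m |= trial.marker_missing(s)
        masks.append(m[:, None])
    out.positions = np.concatenate([out.positions] + cols, axis=1)
    out.missing = np.concatenate([out.missing] + masks, axis=1)
    for role in new:
        out.labels.append(role)
        out.roles[role] = role
    out.positions[out.missing] = np.nan
    log.info(
        "estimate_joint_centers: elbow=%.1f wrist=%.1f hand=%.1f shoulder_offset=%.1f mm",
        w_elbow, w_wrist, t_hand, shoulder_offset_mm,
    )
    return out


# ---------------------------------------------------------------------------
# segment frames
# ---------------------------------------------------------------------------


def build_segment_frames(
    trial: TrialRecording,
) -> tuple[dict[str, RigidMotionSeries], np.ndarray]:
    """Per-frame LCS for scapula, upper arm, lower arm, hand and bow.

    Axis recipes (Gram-Schmidt on primary, secondary):

    ========== ========================== =======================================
    segment    primary                    secondary
    ========== ========================== =======================================
    scapula    sternum -> shoulder_jc      vertical x primary
    upper_arm  shoulder_jc -> elbow_jc     primary x (lower-arm primary)
    lower_arm  elbow_jc -> wrist_jc        primary x (radial -> ulnar)
    hand       wrist_jc -> mcp1            primary x (radial -> ulnar)
    bow        bow_proximal -> bow_tip     bow_proximal -> pip1 (distal finger)
    ========== ========================== =======================================

    Returns the frames as rigid motions (basis + origin) plus a per-frame
    validity mask (False where any construction is degenerate, e.g. a fully
    extended elbow making upper- and lower-arm axes collinear).
    """
    g = trial.marker
    shoulder_jc = g("shoulder_jc")
    elbow_jc = g("elbow_jc")
    wrist_jc = g("wrist_jc")
    wrist_line = g("wrist_ulnar") - g("wrist_radial")
    upper_primary = elbow_jc - shoulder_jc
    lower_primary = wrist_jc - elbow_jc

    n = trial.n_frames
    vertical = np.broadcast_to(VERTICAL, (n, 3))

    def crossed(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cross product plus a validity mask rejecting near-parallel factors."""
        c = np.cross(a, b)
        ok = np.linalg.norm(c, axis=-1) >= 1e-6 * (
            np.linalg.norm(a, axis=-1) * np.linalg.norm(b, axis=-1)
        )
        return c, ok

    hand_primary = g("mcp1") - wrist_jc
    recipes: dict[str, tuple[np.ndarray, tuple[np.ndarray, np.ndarray], np.ndarray]] = {
        "scapula": (shoulder_jc - g("sternum"), crossed(vertical, shoulder_jc - g("sternum")), shoulder_jc),
        "upper_arm": (upper_primary, crossed(upper_primary, lower_primary), shoulder_jc),
        "lower_arm": (lower_primary, crossed(lower_primary, wrist_line), elbow_jc),
        "hand": (hand_primary, crossed(hand_primary, wrist_line), wrist_jc),
        "bow": (
            g("bow_tip") - g("bow_proximal"),
            (g("pip1") - g("bow_proximal"), np.ones(n, dtype=bool)),
            g("bow_proximal"),
        ),
    }
    frames: dict[str, RigidMotionSeries] = {}
    valid = np.ones(n, dtype=bool)
    for name, (primary, (secondary, cross_ok), origin) in recipes.items():
        basis, ok = _gs_batch(primary, secondary)
        ok &= cross_ok
        bad = ~ok & valid
        if bad.any():
            log.warning(
                "build_segment_frames: %d degenerate frames for segment %s (first at %d)",
                int(bad.sum()), name, int(np.argmax(bad)),
            )
        valid &= ok
        frames[name] = RigidMotionSeries(basis, origin)
    return frames, valid


# ---------------------------------------------------------------------------
# decompose / reconstruct
# ---------------------------------------------------------------------------


@dataclass
class ChainTimeSeries:
    """Joint-level representation of a trial.

    ``root_pose`` is the scapula LCS in the lab; ``joints`` maps each joint
    name (shoulder, elbow, wrist, hand_to_bow) to the distal segment's pose
    expressed in its proximal segment's LCS.  ``local_offsets`` holds each
    marker's per-frame coordinates in its owning segment ("lab" markers are
    stored as lab positions directly).  The representation is invertible:
    :func:`reconstruct` reproduces the source markers exactly.
    """

    rate_hz: float
    labels: list[str]
    roles: dict[str, str]
    root_pose: RigidMotionSeries
    joints: dict[str, RigidMotionSeries]
    local_offsets: dict[str, tuple[str, np.ndarray]]
    frame_valid: np.ndarray
    missing: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.root_pose.n_frames

    def segment_poses(self) -> dict[str, RigidMotionSeries]:
        """Lab-frame pose of every segment, composed along the chain."""
        poses = {"scapula": self.root_pose}
        poses["upper_arm"] = poses["scapula"].compose(self.joints["shoulder"])
        poses["lower_arm"] = poses["upper_arm"].compose(self.joints["elbow"])
        poses["hand"] = poses["lower_arm"].compose(self.joints["wrist"])
        poses["bow"] = poses["hand"].compose(self.joints["hand_to_bow"])
        poses["lab"] = RigidMotionSeries.identity(self.n_frames)
        return poses

    def copy(self) -> "ChainTimeSeries":
        return ChainTimeSeries(
            rate_hz=self.rate_hz,
            labels=list(self.labels),
            roles=dict(self.roles),
            root_pose=self.root_pose.copy(),
            joints={k: v.copy() for k, v in self.joints.items()},
            local_offsets={k: (s, o.copy()) for k, (s, o) in self.local_offsets.items()},
            frame_valid=self.frame_valid.copy(),
            missing=self.missing.copy(),
            meta=dict(self.meta),
        )


def decompose(trial: TrialRecording) -> ChainTimeSeries:
    """Express a trial as per-joint rigid-body motions plus marker offsets.

    The trial must already carry the virtual joint-center markers (see
    :func:`estimate_joint_centers`).  Frames where any segment frame is
    degenerate are flagged invalid and excluded from downstream stroke
    selection.
    """
    for role in VIRTUAL_ROLES:
        if role not in trial.roles:
            raise ValueError(
                "trial lacks virtual joint centers; run estimate_joint_centers first"
            )
    seg_frames, valid = build_segment_frames(trial)
    root = seg_frames["scapula"]
    joints = {
        "shoulder": seg_frames["scapula"].inverse().compose(seg_frames["upper_arm"]),
        "elbow": seg_frames["upper_arm"].inverse().compose(seg_frames["lower_arm"]),
        "wrist": seg_frames["lower_arm"].inverse().compose(seg_frames["hand"]),
        "hand_to_bow": seg_frames["hand"].inverse().compose(seg_frames["bow"]),
    }
    label_role = {v: k for k, v in trial.roles.items()}
    offsets: dict[str, tuple[str, np.ndarray]] = {}
    for j, label in enumerate(trial.labels):
        seg = SEGMENT_OF_ROLE.get(label_role.get(label, ""), "lab")
        pos = trial.positions[:, j, :]
        if seg == "lab":
            offsets[label] = (seg, pos.copy())
        else:
            offsets[label] = (seg, seg_frames[seg].pull_back(pos))
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("decompose: %d degenerate frames marked missing", n_bad)
    return ChainTimeSeries(
        rate_hz=trial.rate_hz,
        labels=list(trial.labels),
        roles=dict(trial.roles),
        root_pose=root,
        joints=joints,
        local_offsets=offsets,
        frame_valid=valid,
        missing=trial.missing.copy(),
        meta=dict(trial.meta),
    )


def reconstruct(chain: ChainTimeSeries) -> TrialRecording:
    """Rebuild marker positions from (possibly modified) joint motions.

    For an unmodified chain this reproduces the decomposed trial to
    numerical precision.  Frames flagged invalid in the chain are marked
    missing for all chain-owned markers.
    """
    for name, j in chain.joints.items():
        if j.n_frames != chain.n_frames:
            raise ValueError(f"joint {name!r} frame count differs from root")
    poses = chain.segment_poses()
    n = chain.n_frames
    positions = np.empty((n, len(chain.labels), 3))
    missing = chain.missing.copy()
    for j, label in enumerate(chain.labels):
        seg, local = chain.local_offsets[label]
        if local.shape[0] != n:
            raise ValueError(f"offsets for {label!r} have wrong frame count")
        positions[:, j, :] = local if seg == "lab" else poses[seg].apply(local)
        if seg != "lab":
            missing[:, j] |= ~chain.frame_valid
    positions[missing] = np.nan
    return TrialRecording(
        positions=positions,
        rate_hz=chain.rate_hz,
        labels=list(chain.labels),
        roles=dict(chain.roles),
        missing=missing,
        meta=dict(chain.meta),
    )


# ---------------------------------------------------------------------------
# tabular export of joint poses (audit/replay)
# ---------------------------------------------------------------------------

_POSE_COLS = ("qw", "qx", "qy", "qz", "tx", "ty", "tz")


def chain_to_table(chain: ChainTimeSeries) -> pd.DataFrame:
    """Joint poses as one row per frame (quaternion + translation each)."""
    cols: dict[str, np.ndarray] = {"frame": np.arange(chain.n_frames)}
    series = {"root": chain.root_pose, **chain.joints}
    for name, motion in series.items():
        q = Rotation.from_matrix(motion.rot).as_quat(scalar_first=True)
        for k, c in enumerate(_POSE_COLS[:4]):
            cols[f"{name}_{c}"] = q[:, k]
        for k, c in enumerate(_POSE_COLS[4:]):
            cols[f"{name}_{c}"] = motion.trans[:, k]
    cols["valid"] = chain.frame_valid.astype(int)
    return pd.DataFrame(cols)


def save_chain(chain: ChainTimeSeries, path) -> None:
    chain_to_table(chain).to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_chain_table(path) -> dict[str, RigidMotionSeries]:
    """Load an exported pose table back into rigid-motion series."""
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, RigidMotionSeries] = {}
    for name in ("root", "shoulder", "elbow", "wrist", "hand_to_bow"):
        q = frame[[f"{name}_{c}" for c in _POSE_COLS[:4]]].to_numpy()
        t = frame[[f"{name}_{c}" for c in _POSE_COLS[4:]]].to_numpy()
        out[name] = RigidMotionSeries(
            Rotation.from_quat(q, scalar_first=True).as_matrix(), t
        )
    return out
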