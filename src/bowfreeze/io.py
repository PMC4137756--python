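"""Trial input/output and the marker model.

A trial is a block of 3D marker trajectories (frames x markers x XYZ, in mm)
with a sampling rate, a map from anatomical *roles* to marker labels, and
participant metadata.  The on-disk exchange format is deliberately vendor
neutral: a wide TSV (one row per frame, columns ``<label>_X/_Y/_Z``) plus a
YAML sidecar carrying rate, roles and metadata.  Missing samples are encoded
as empty fields and surface as a boolean mask; they are never interpolated.

Every downstream module consumes :class:`TrialRecording` objects, never raw
files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Anatomical roles every trial must map to a marker label.
REQUIRED_ROLES: tuple[str, ...] = (
    "sternum",
    "c7",
    "acromion",
    "elbow_lateral",
    "lowerarm",
    "wrist_radial",
    "wrist_ulnar",
    "mcp1",
    "pip1",
    "cello_scroll",
    "cello_tailpiece",
    "cello_body",
    "bow_tip",
    "bow_proximal",
)

#: Virtual roles added by joint-center estimation (not present in raw files).
VIRTUAL_ROLES: tuple[str, ...] = ("shoulder_jc", "elbow_jc", "wrist_jc", "hand_ref")


class RoleMappingError(ValueError):
    """A required marker role is absent or mapped to a missing label."""


class FormatError(ValueError):
    """The on-disk trial does not conform to the documented dialect."""


@dataclass(frozen=True)
class MarkerModel:
    """The set of marker roles a trial must provide.

    The default model is the 14-marker setup used for bowing trials: trunk
    (sternum, C7), right arm (acromion, lateral elbow epicondyle, forearm
    shaft, radial/ulnar wrist), hand (first MCP and PIP joints), instrument
    (scroll, tailpiece, body) and bow (tip plus a proximal marker roughly
    two-thirds of the way from tip to frog).

    Note: some descriptions of this setup list a single "wrist" marker while
    the forearm/hand frames require the line between *two* wrist markers; the
    model here requires both (radial and ulnar).
    """

    required: tuple[str, ...] = REQUIRED_ROLES

    def validate(self, roles: dict[str, str], labels: list[str]) -> None:
        missing = [r for r in self.required if r not in roles]
        if missing:
            raise RoleMappingError(f"roles missing required entries: {missing}")
        bad = [r for r in self.required if roles[r] not in labels]
        if bad:
            raise RoleMappingError(
                f"roles map to labels absent from the trial: "
                f"{ {r: roles[r] for r in bad} }"
            )
        mapped = [roles[r] for r in self.required]
        if len(set(mapped)) != len(mapped):
            dupes = {l for l in mapped if mapped.count(l) > 1}
            raise RoleMappingError(f"role labels not distinct: {sorted(dupes)}")


@dataclass(frozen=True)
class AnthropometricSet:
    """Participant thickness measures (mm) used for joint-center offsets."""

    elbow_width_mm: float = 70.0
    wrist_width_mm: float = 55.0
    hand_thickness_mm: float = 25.0

    def __post_init__(self) -> None:
        for name in ("elbow_width_mm", "wrist_width_mm", "hand_thickness_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass
class TrialRecording:
    """Time-indexed marker positions with metadata.

    Attributes
    ----------
    positions
        Array (frames, markers, 3), millimetres, lab frame (right handed,
        +Z vertical). Entries where ``missing`` is True are NaN.
    rate_hz
        Sampling rate in samples/s (typically 60 or 120).
    labels
        Marker labels, one per column of ``positions``.
    roles
        Map role -> label; must cover :data:`REQUIRED_ROLES`.
    missing
        Boolean mask (frames, markers); True marks unusable samples.
    meta
        Free-form metadata (participant_id, group in {expert, novice},
        lab in {A, B}, optionally anthropometrics).
    """

    positions: np.ndarray
    rate_hz: float
    labels: list[str]
    roles: dict[str, str]
    missing: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must be (frames, markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise ValueError("a trial needs at least 2 frames")
        if not np.isfinite(self.rate_hz) or self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz!r}")
        if len(self.labels) != self.positions.shape[1]:
            raise ValueError("labels do not match the marker axis of positions")
        if self.missing is None:
            self.missing = ~np.all(np.isfinite(self.positions), axis=2)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.positions.shape[:2]:
                raise ValueError("missing mask shape must be (frames, markers)")
        valid = ~self.missing
        if not np.all(np.isfinite(self.positions[valid])):
            raise ValueError("positions must be finite wherever missing is False")

    # -- convenience -----------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no marker labelled {label!r}") from None

    def marker(self, role: str) -> np.ndarray:
        """Positions (frames, 3) of the marker filling ``role``."""
        if role not in self.roles:
            raise RoleMappingError(f"role {role!r} not mapped")
        return self.positions[:, self.index_of(self.roles[role]), :]

    def marker_missing(self, role: str) -> np.ndarray:
        return self.missing[:, self.index_of(self.roles[role])]

    def validate(self, model: MarkerModel | None = None) -> "TrialRecording":
        (model or MarkerModel()).validate(self.roles, self.labels)
        return self

    def copy(self) -> "TrialRecording":
        return replace(
            self,
            positions=self.positions.copy(),
            labels=list(self.labels),
            roles=dict(self.roles),
            missing=self.missing.copy(),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# wide TSV + YAML sidecar dialect
# ---------------------------------------------------------------------------

_AXES = ("X", "Y", "Z")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_trial(trial: TrialRecording, path: str | Path) -> Path:
    """Write a trial as wide TSV plus a YAML sidecar.

    Missing samples become empty fields.  The sidecar stores rate, label
    order, roles and metadata so that :func:`read_trial` restores the trial
    bit-compatibly (positions to better than 1e-9 mm via float repr).
    """
    trial.validate()
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    for j, label in enumerate(trial.labels):
        for k, ax in enumerate(_AXES):
            col = trial.positions[:, j, k].astype(object)
            col[trial.missing[:, j]] = None
            cols[f"{label}_{ax}"] = col
    frame = pd.DataFrame(cols)
    frame.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.12g")
    sidecar = {
        "rate_hz": float(trial.rate_hz),
        "labels": list(trial.labels),
        "roles": dict(trial.roles),
        "meta": dict(trial.meta),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    log.info("wrote trial: %s (%d frames, %d markers)", path, trial.n_frames, len(trial.labels))
    return path


def read_trial(
    path: str | Path,
    model: MarkerModel | None = None,
    roles: dict[str, str] | None = None,
    meta: dict | None = None,
) -> TrialRecording:
    """Read a wide-TSV trial (with its YAML sidecar) into a TrialRecording.

    ``roles``/``meta`` override the sidecar when given.  Unparseable
    coordinates are recorded as missing rather than raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_file = _sidecar_path(path)
    sidecar: dict = {}
    if sidecar_file.exists():
        with open(sidecar_file) as fh:
            sidecar = yaml.safe_load(fh) or {}
    frame = pd.read_csv(path, sep="\t")
    labels = sidecar.get("labels")
    if labels is None:
        seen: list[str] = []
        for col in frame.columns:
            if col.endswith(("_X", "_Y", "_Z")):
                base = col[:-2]
                if base not in seen:
                    seen.append(base)
        labels = seen
    expected = [f"{l}_{ax}" for l in labels for ax in _AXES]
    absent = [c for c in expected if c not in frame.columns]
    if absent:
        raise FormatError(f"trial file lacks coordinate columns: {absent[:6]}")
    n = len(frame)
    positions = np.full((n, len(labels), 3), np.nan)
    for j, label in enumerate(labels):
        for k, ax in enumerate(_AXES):
            positions[:, j, k] = pd.to_numeric(frame[f"{label}_{ax}"], errors="coerce")
    missing = ~np.all(np.isfinite(positions), axis=2)
    positions[missing] = np.nan
    trial = TrialRecording(
        positions=positions,
        rate_hz=float(sidecar.get("rate_hz", 60.0)),
        labels=list(labels),
        roles=dict(roles if roles is not None else sidecar.get("roles", {})),
        missing=missing,
        meta=dict(meta if meta is not None else sidecar.get("meta", {})),
    )
    trial.validate(model)
    log.info(
        "read trial: %s (%d frames, %d markers, %.6g Hz, %d missing samples)",
        path, trial.n_frames, len(trial.labels), trial.rate_hz, int(missing.sum()),
    )
    return trial


def read_c3d(path: str | Path, roles: dict[str, str], meta: dict | None = None) -> TrialRecording:
    """Read a C3D capture into the same TrialRecording container.

    Requires the optional ``ezc3d`` package.
    """
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "C3D import requires the optional 'ezc3d' package; "
            "convert to the wide TSV dialect instead"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    pts = np.transpose(c3d["data"]["points"][:3], (2, 1, 0))  # pragma: no cover
    labels = list(c3d["parameters"]["POINT"]["LABELS"]["value"])  # pragma: no cover
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])  # pragma: no cover
    return TrialRecording(  # pragma: no cover
        positions=pts, rate_hz=rate, labels=labels, roles=roles, meta=dict(meta or {})
    ).validate()
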