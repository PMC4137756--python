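"""Bow kinematics: the bowing coordinate, strokes and performance measures.

Task performance lives at the end effector.  The scalar *bowing coordinate*
is the signed arc-length position, along the bow's long axis measured from
the proximal bow marker, of the point on the bow axis closest to the string
axis (the common-perpendicular foot) — the physically bowed coordinate.
Velocity and acceleration are central differences of this coordinate; the
bow-string angle is the angle between bow and string axes (ideally near 90
degrees).

Strokes are segmented at bow-velocity reversals (zero crossings with a small
hysteresis against jitter); only strokes lasting 0.5-1 s count as bowing
movements and the first ten clean up- and down-bows are analysed, together
with 45-sample (0.75 s at 60 Hz) windows around their reversals.

Five performance measures are computed per direction:

* ``amplitude`` — bow movement range (max - min position) over a stroke, mm
* ``angle_sd`` — SD of the bow-string angle over the central 80 %, degrees
* ``within_bow_var`` — variance of velocity over the central 80 %, averaged
  across strokes, (mm/s)^2; low values mean rectangular velocity profiles
* ``between_bow_var`` — variance across strokes of time-normalised velocity,
  averaged over 100 normalised time points of the central 80 %, (mm/s)^2
* ``accel_amp`` — peak |acceleration| inside the reversal window, mm/s^2

Variances and SDs use the population convention (divide by n); the measures
enter the analysis only as surrogate/original ratios, where the convention
cancels, but fixing it keeps results reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import TrialRecording

log = logging.getLogger(__name__)

MOVEMENT_MEASURES = ("amplitude", "angle_sd", "within_bow_var", "between_bow_var")
REVERSAL_MEASURES = ("accel_amp",)
DIRECTIONS = ("up", "down")
REVERSAL_KINDS = ("up-down", "down-up")

#: reversal window duration (s); round(0.75 * rate) samples
REVERSAL_WINDOW_S = 0.75


def reversal_window_samples(rate_hz: float) -> int:
    """Number of samples in a reversal window (45 at 60 Hz)."""
    return int(round(REVERSAL_WINDOW_S * rate_hz))


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


@dataclass
class BowKinematics:
    """Per-frame scalar bow kinematics along the bowing coordinate."""

    position: np.ndarray  # mm
    velocity: np.ndarray  # mm/s
    acceleration: np.ndarray  # mm/s^2
    angle: np.ndarray  # degrees
    rate_hz: float

    @property
    def n_frames(self) -> int:
        return self.position.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.position) & np.isfinite(self.angle)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return v / n


def bowing_coordinate(
    bow_point: np.ndarray,
    bow_dir: np.ndarray,
    string_point: np.ndarray,
    string_dir: np.ndarray,
    rate_hz: float,
    *,
    flip_sign: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed contact-point coordinate along the bow axis and its derivatives.

    For each frame, the coordinate is the arc length from ``bow_point``
    (the proximal bow marker) along the unit ``bow_dir`` to the point of the
    bow axis nearest the string axis.  Frames where the two axes are
    (near) parallel have no defined contact point and yield NaN.
    Derivatives are central differences (one-sided at the trial edges, which
    stroke selection never uses).
    """
    d1 = _unit(np.asarray(bow_dir, float))
    d2 = _unit(np.asarray(string_dir, float))
    w0 = np.asarray(bow_point, float) - np.asarray(string_point, float)
    b = np.einsum("ni,ni->n", d1, d2)
    denom = 1.0 - b * b
    d = np.einsum("ni,ni->n", d1, w0)
    e = np.einsum("ni,ni->n", d2, w0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (b * e - d) / denom
    s = np.where(denom > 1e-12, s, np.nan)
    if flip_sign:
        s = -s
    dt = 1.0 / rate_hz
    velocity = np.gradient(s, dt)
    acceleration = np.gradient(velocity, dt)
    return s, velocity, acceleration


def bow_angle(
    bow_dir: np.ndarray, string_dir: np.ndarray, convention: str = "signed"
) -> np.ndarray:
    """Bow-string angle in degrees.

    ``signed`` (default) keeps the full arccos range [0, 180] so that
    deviations to either side of 90 degrees remain distinguishable;
    ``acute`` folds to [0, 90] via the absolute dot product.
    """
    dot = np.einsum("ni,ni->n", _unit(np.asarray(bow_dir, float)), _unit(np.asarray(string_dir, float)))
    if convention == "acute":
        dot = np.abs(dot)
    elif convention != "signed":
        raise ValueError(f"unknown angle convention {convention!r}")
    return np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))


def bow_kinematics_from_trial(
    trial: TrialRecording,
    *,
    angle_convention: str = "signed",
    flip_sign: bool = False,
) -> BowKinematics:
    """Bow kinematics computed directly from bow and cello markers."""
    bow_prox = trial.marker("bow_proximal")
    bow_dir = trial.marker("bow_tip") - bow_prox
    scroll = trial.marker("cello_scroll")
    string_dir = trial.marker("cello_tailpiece") - scroll
    pos, vel, acc = bowing_coordinate(
        bow_prox, bow_dir, scroll, string_dir, trial.rate_hz, flip_sign=flip_sign
    )
    angle = bow_angle(bow_dir, string_dir, angle_convention)
    return BowKinematics(pos, vel, acc, angle, trial.rate_hz)


# ---------------------------------------------------------------------------
# strokes and reversal windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stroke:
    """Half-open frame interval [start, end) of one bow movement."""

    direction: str  # "up" or "down"
    start: int
    end: int
    rate_hz: float

    @property
    def duration(self) -> float:
        return (self.end - self.start) / self.rate_hz

    @property
    def frames(self) -> slice:
        return slice(self.start, self.end)


@dataclass(frozen=True)
class ReversalWindow:
    """Fixed-length window of samples centred on a velocity zero crossing."""

    center: int
    kind: str  # "up-down" or "down-up"
    rate_hz: float

    @property
    def span(self) -> int:
        return reversal_window_samples(self.rate_hz)

    def bounds(self) -> tuple[int, int]:
        start = self.center - self.span // 2
        return start, start + self.span

    def inside(self, n_frames: int) -> bool:
        start, stop = self.bounds()
        return start >= 0 and stop <= n_frames


@dataclass
class StrokeSet:
    """Validated strokes plus the reversal windows that bound them."""

    strokes: list[Stroke] = field(default_factory=list)
    windows: list[ReversalWindow] = field(default_factory=list)
    rate_hz: float = 60.0

    def by_direction(self, direction: str) -> list[Stroke]:
        return [s for s in self.strokes if s.direction == direction]

    def windows_by_kind(self, kind: str) -> list[ReversalWindow]:
        return [w for w in self.windows if w.kind == kind]

    def __len__(self) -> int:
        return len(self.strokes)


def detect_strokes(
    velocity: np.ndarray,
    rate_hz: float,
    *,
    min_duration_s: float = 0.5,
    max_duration_s: float = 1.0,
    hysteresis_frac: float = 0.05,
) -> StrokeSet:
    """Segment a velocity trace into alternating bow strokes.

    A reversal is a zero crossing of velocity, confirmed only once |velocity|
    subsequently exceeds ``hysteresis_frac`` times the trace's median
    absolute speed (suppresses jitter reversals near zero).  Strokes are the
    intervals between consecutive confirmed reversals; only durations within
    [``min_duration_s``, ``max_duration_s``] are kept.  Positive velocity is
    labelled "down" by convention.
    """
    v = np.asarray(velocity, float)
    finite = np.isfinite(v)
    if not finite.any():
        log.warning("detect_strokes: no finite velocity samples")
        return StrokeSet(rate_hz=rate_hz)
    th = hysteresis_frac * float(np.median(np.abs(v[finite])))

    reversals: list[tuple[int, str]] = []
    state = 0
    state_idx = -1
    for i in range(v.shape[0]):
        vi = v[i]
        if not np.isfinite(vi):
            continue
        if vi > th:
            s = 1
        elif vi < -th:
            s = -1
        else:
            continue
        if state == 0:
            # if the trace emerged from zero, count the initial crossing
            lead = np.abs(v[: i + 1])
            lead = np.where(np.isfinite(lead), lead, np.inf)
            j = int(np.argmin(lead))
            if lead[j] <= th:
                reversals.append((j, "down-up" if s < 0 else "up-down"))
            state, state_idx = s, i
            continue
        if s != state:
            seg = np.abs(v[state_idx : i + 1])
            seg = np.where(np.isfinite(seg), seg, np.inf)
            center = state_idx + int(np.argmin(seg))
            reversals.append((center, "down-up" if s < 0 else "up-down"))
            state = s
        state_idx = i

    # note: kinds above are named for the *preceding -> following* direction;
    # new state positive (down) means the reversal was up->down
    reversals = [
        (c, "up-down" if k == "up-down" else "down-up") for c, k in reversals
    ]
    strokes: list[Stroke] = []
    for (c0, k0), (c1, _) in zip(reversals, reversals[1:]):
        direction = "down" if k0 == "up-down" else "up"
        stroke = Stroke(direction, c0, c1, rate_hz)
        if min_duration_s <= stroke.duration <= max_duration_s:
            strokes.append(stroke)
    windows = [ReversalWindow(c, k, rate_hz) for c, k in reversals]
    if not reversals:
        log.warning("detect_strokes: no reversals found")
    log.info(
        "detect_strokes: %d reversals, %d strokes within [%g, %g] s",
        len(reversals), len(strokes), min_duration_s, max_duration_s,
    )
    return StrokeSet(strokes=strokes, windows=windows, rate_hz=rate_hz)


def select_analyzed(
    detected: StrokeSet,
    missing: np.ndarray,
    n_per_direction: int = 10,
) -> StrokeSet:
    """First N clean up- and down-bows, with their reversal windows.

    ``missing`` is a per-frame boolean mask (True = unusable: a missing
    marker sample or a degenerate/undefined kinematics frame).  A stroke
    qualifies only if its own frames and both bounding reversal windows are
    fully inside the trial and free of missing samples.
    """
    missing = np.asarray(missing, bool)
    n_frames = missing.shape[0]

    def window_clean(w: ReversalWindow) -> bool:
        if not w.inside(n_frames):
            return False
        start, stop = w.bounds()
        return not missing[start:stop].any()

    window_at = {w.center: w for w in detected.windows}
    kept: dict[str, list[Stroke]] = {"up": [], "down": []}
    kept_windows: dict[int, ReversalWindow] = {}
    for stroke in detected.strokes:
        if len(kept[stroke.direction]) >= n_per_direction:
            continue
        if missing[stroke.start : stroke.end + 1].any():
            continue
        bounds = [window_at.get(stroke.start), window_at.get(stroke.end)]
        if any(w is None or not window_clean(w) for w in bounds):
            continue
        kept[stroke.direction].append(stroke)
        for w in bounds:
            kept_windows[w.center] = w
    for direction in DIRECTIONS:
        if len(kept[direction]) < n_per_direction:
            log.warning(
                "select_analyzed: only %d clean %s-bows (wanted %d)",
                len(kept[direction]), direction, n_per_direction,
            )
    strokes = sorted(kept["up"] + kept["down"], key=lambda s: s.start)
    windows = [kept_windows[c] for c in sorted(kept_windows)]
    return StrokeSet(strokes=strokes, windows=windows, rate_hz=detected.rate_hz)


def central_fraction(stroke: Stroke, fraction: float = 0.8) -> tuple[int, int]:
    """Frame range of the central ``fraction`` of a stroke (excludes reversals).

    Trims floor((1-fraction)/2 * n) frames from each end of the half-open
    stroke interval, rounding inward.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = stroke.end - stroke.start
    if n < 5:
        raise ValueError(f"stroke too short for central fraction: {n} frames")
    k = int(np.floor((1.0 - fraction) / 2.0 * n))
    return stroke.start + k, stroke.end - k


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------


def measure_amplitude(position: np.ndarray, stroke: Stroke) -> float:
    """Bow movement amplitude: position range over the full stroke, mm.

    Both bounding reversal samples are included so that the full excursion
    between reversals is captured.
    """
    seg = position[stroke.start : stroke.end + 1]
    return float(np.max(seg) - np.min(seg))


def measure_angle_sd(angle: np.ndarray, stroke: Stroke, fraction: float = 0.8) -> float:
    """SD (population) of the bow-string angle over the central fraction."""
    a, b = central_fraction(stroke, fraction)
    return float(np.std(angle[a:b]))


def measure_within_bow_var(
    velocity: np.ndarray, strokes: list[Stroke], fraction: float = 0.8
) -> float:
    """Average within-stroke variance of bow velocity (central fraction)."""
    if not strokes:
        raise ValueError("no strokes")
    out = []
    for s in strokes:
        a, b = central_fraction(s, fraction)
        out.append(np.var(velocity[a:b]))
    return float(np.mean(out))


def measure_between_bow_var(
    velocity: np.ndarray,
    strokes: list[Stroke],
    fraction: float = 0.8,
    n_points: int = 100,
) -> float:
    """Average across-stroke variance of time-normalised bow velocity.

    Each stroke's central-fraction velocity is linearly resampled to
    ``n_points`` normalised time points; the variance across strokes is
    taken at each point and averaged over points.
    """
    if len(strokes) < 2:
        raise ValueError("between-bow variance needs at least 2 strokes")
    grid = np.linspace(0.0, 1.0, n_points)
    resampled = []
    for s in strokes:
        a, b = central_fraction(s, fraction)
        seg = velocity[a:b]
        t = np.linspace(0.0, 1.0, seg.shape[0])
        resampled.append(np.interp(grid, t, seg))
    return float(np.mean(np.var(np.stack(resampled), axis=0)))


def measure_accel_amplitude(
    acceleration: np.ndarray, window: ReversalWindow, mode: str = "max_abs"
) -> float:
    """Acceleration amplitude within a reversal window.

    ``max_abs`` (default) is the peak absolute acceleration; ``peak_to_peak``
    is available as an alternative operationalisation.
    """
    start, stop = window.bounds()
    seg = acceleration[start:stop]
    if mode == "max_abs":
        return float(np.max(np.abs(seg)))
    if mode == "peak_to_peak":
        return float(np.max(seg) - np.min(seg))
    raise ValueError(f"unknown accel amplitude mode {mode!r}")


def compute_measures(
    kin: BowKinematics,
    analyzed: StrokeSet,
    *,
    fraction: float = 0.8,
    n_points: int = 100,
    accel_mode: str = "max_abs",
) -> dict[tuple[str, str], float]:
    """All five measures, keyed by (measure, direction).

    Movement measures are tagged "up"/"down"; acceleration amplitude is
    tagged by reversal kind ("up-down"/"down-up").  Directions without
    analysable strokes are simply absent from the result.
    """
    out: dict[tuple[str, str], float] = {}
    for direction in DIRECTIONS:
        strokes = analyzed.by_direction(direction)
        if not strokes:
            continue
        out[("amplitude", direction)] = float(
            np.mean([measure_amplitude(kin.position, s) for s in strokes])
        )
        out[("angle_sd", direction)] = float(
            np.mean([measure_angle_sd(kin.angle, s, fraction) for s in strokes])
        )
        out[("within_bow_var", direction)] = measure_within_bow_var(
            kin.velocity, strokes, fraction
        )
        if len(strokes) >= 2:
            out[("between_bow_var", direction)] = measure_between_bow_var(
                kin.velocity, strokes, fraction, n_points
            )
    for kind in REVERSAL_KINDS:
        windows = [w for w in analyzed.windows_by_kind(kind) if w.inside(kin.n_frames)]
        if windows:
            out[("accel_amp", kind)] = float(
                np.mean(
                    [measure_accel_amplitude(kin.acceleration, w, accel_mode) for w in windows]
                )
            )
    return out
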