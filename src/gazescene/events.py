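"""Velocity-based binocular saccade detection and event segmentation.

Saccades are detected per eye from smoothed 2D velocities: a sample is a
saccade candidate when its velocity lies outside an elliptic threshold whose
axes are lambda times a median-based robust SD of the velocity distribution.
Candidate runs lasting at least a minimum number of samples are monocular
saccades; a binocular saccade requires temporally overlapping detections in
both eyes.  Fixations are the intervals between subsequent saccades (and
blinks); blinks are taken from the tracker's per-sample flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GazeRecording

logger = logging.getLogger(__name__)

#: Velocities below this are treated as numerically degenerate (deg/s).
SIGMA_EPSILON = 1e-6


@dataclass
class GazeEvent:
    """One detected or ground-truth oculomotor event.

    Sample indices are inclusive on both ends.  ``amplitude`` is the
    Euclidean start-to-end displacement of the binocular-averaged position
    (saccades); ``within_event_sd`` is the 2D positional SD
    ``sqrt(sd_x^2 + sd_y^2)`` (fixations).
    """

    kind: str                      # "fixation" | "saccade" | "blink"
    onset_index: int
    offset_index: int
    onset_ms: float
    offset_ms: float
    trial_id: str = ""
    centroid_xy: tuple[float, float] | None = None
    amplitude: float | None = None
    peak_velocity: float | None = None
    within_event_sd: float | None = None
    exclusion_flags: set = field(default_factory=set)
    source: str = "detected"

    def __post_init__(self) -> None:
        if self.offset_ms < self.onset_ms:
            raise ValueError("event offset precedes onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def n_samples(self) -> int:
        return self.offset_index - self.onset_index + 1


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the velocity-based detector.

    ``lam`` multiplies the median-based velocity SD to give the elliptic
    threshold.  The defaults follow the published conventions of the velocity
    threshold algorithm family and are configuration, not claimed study
    values.
    """

    lam: float = 5.0
    kernel_halfwidth: int = 2      # fixed +-2-sample difference kernel
    min_saccade_duration: int = 3  # samples
    min_binocular_overlap: int = 1  # samples

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.min_saccade_duration < 1 or self.min_binocular_overlap < 1:
            raise ValueError("durations must be >= 1 sample")


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, stop) index pairs."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def compute_velocity(positions: np.ndarray, dt: float) -> np.ndarray:
    """Smoothed velocity from positions via a +-2-sample difference kernel.

        v_n = (x_{n+2} + x_{n+1} - x_{n-1} - x_{n-2}) / (6 dt)

    ``positions`` is (n,) or (n, 2) in degrees, ``dt`` the sample interval in
    seconds.  Missing (NaN) samples split the series into segments; each
    segment's first and last two samples, and any segment shorter than five
    samples, yield NaN.
    """
    pos = np.asarray(positions, dtype=float)
    squeeze = pos.ndim == 1
    if squeeze:
        pos = pos[:, None]
    vel = np.full_like(pos, np.nan)
    valid = np.isfinite(pos).all(axis=1)
    for start, stop in _valid_runs(valid):
        if stop - start + 1 < 5:
            continue
        seg = pos[start:stop + 1]
        v = (seg[4:] + seg[3:-1] - seg[1:-3] - seg[:-4]) / (6.0 * dt)
        vel[start + 2:stop - 1] = v
    return vel[:, 0] if squeeze else vel


def median_sd(velocities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-based robust SD of velocities, per axis.

        sigma = sqrt( median(v^2) - median(v)^2 )

    For even sample counts the *lower* median is used (the sigma formula is
    sensitive to the tie rule, so it is fixed here).  Axes whose sigma falls
    below ``SIGMA_EPSILON`` are substituted with the epsilon and flagged
    degenerate.

    Returns ``(sigma, degenerate)``, each of shape (n_axes,).
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    n_axes = v.shape[1]
    sigma = np.empty(n_axes)
    degenerate = np.zeros(n_axes, dtype=bool)
    for a in range(n_axes):
        va = v[:, a]
        va = va[np.isfinite(va)]
        if va.size < 2:
            raise ValueError("median_sd needs >= 2 finite velocity samples")
        med = _lower_median(va)
        med_sq = _lower_median(va ** 2)
        var = med_sq - med ** 2
        s = np.sqrt(var) if var > 0 else 0.0
        if s < SIGMA_EPSILON:
            s = SIGMA_EPSILON
            degenerate[a] = True
        sigma[a] = s
    return sigma, degenerate


def _lower_median(x: np.ndarray) -> float:
    """Lower median: element at rank (n-1)//2 of the sorted sample."""
    xs = np.sort(x)
    return float(xs[(xs.size - 1) // 2])


def _monocular_saccades(
    vel: np.ndarray, sigma: np.ndarray, params: DetectionParams
) -> list[tuple[int, int]]:
    """Supra-threshold runs of >= min_saccade_duration samples, one eye."""
    thr_x = params.lam * sigma[0]
    thr_y = params.lam * sigma[1]
    with np.errstate(invalid="ignore"):
        crit = (vel[:, 0] / thr_x) ** 2 + (vel[:, 1] / thr_y) ** 2 > 1.0
    crit = np.where(np.isfinite(vel).all(axis=1), crit, False)
    return [
        (a, b) for a, b in _valid_runs(crit)
        if b - a + 1 >= params.min_saccade_duration
    ]


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [ivals[0]]
    for a, b in ivals[1:]:
        la, lb = merged[-1]
        if a <= lb + 1:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    return merged


def detect_saccades(
    rec: GazeRecording, params: DetectionParams | None = None
) -> list[GazeEvent]:
    """Detect binocular saccades in an image-frame recording.

    Monocular detections must overlap by at least
    ``params.min_binocular_overlap`` samples in both eyes; the event
    boundaries are the union of the overlapping monocular intervals.
    """
    params = params or DetectionParams()
    s = rec.samples
    t = s["t_ms"].to_numpy(dtype=float)
    dt = (t[1] - t[0]) / 1000.0 if len(t) > 1 else 1.0 / 120.0

    mono: dict[str, list[tuple[int, int]]] = {}
    vels = {}
    n_degenerate_eyes = 0
    for eye, (xc, yc) in (("left", ("xl", "yl")), ("right", ("xr", "yr"))):
        pos = np.column_stack([s[xc].to_numpy(dtype=float),
                               s[yc].to_numpy(dtype=float)])
        vel = compute_velocity(pos, dt)
        vels[eye] = vel
        finite = np.isfinite(vel).all(axis=1)
        if finite.sum() < 2:
            mono[eye] = []
            n_degenerate_eyes += 1
            continue
        sigma, degenerate = median_sd(vel[finite])
        if degenerate.all():
            n_degenerate_eyes += 1
            mono[eye] = []
            continue
        mono[eye] = _monocular_saccades(vel, sigma, params)

    if n_degenerate_eyes == 2:
        logger.warning(
            "trial %s: degenerate velocity noise estimate in both eyes, "
            "no saccades detected", rec.trial_id,
        )
        return []

    # binocular pairing: union of each overlapping (left, right) pair
    unions = []
    for la, lb in mono["left"]:
        for ra, rb in mono["right"]:
            overlap = min(lb, rb) - max(la, ra) + 1
            if overlap >= params.min_binocular_overlap:
                unions.append((min(la, ra), max(lb, rb)))
    unions = _merge_intervals(unions)

    bx = (s["xl"].to_numpy(dtype=float) + s["xr"].to_numpy(dtype=float)) / 2.0
    by = (s["yl"].to_numpy(dtype=float) + s["yr"].to_numpy(dtype=float)) / 2.0
    vmean = (vels["left"] + vels["right"]) / 2.0
    speed = np.sqrt(vmean[:, 0] ** 2 + vmean[:, 1] ** 2)

    out = []
    for a, b in unions:
        dx = bx[b] - bx[a]
        dy = by[b] - by[a]
        seg_speed = speed[a:b + 1]
        peak = float(np.nanmax(seg_speed)) if np.isfinite(seg_speed).any() \
            else float("nan")
        out.append(
            GazeEvent(
                kind="saccade",
                onset_index=int(a),
                offset_index=int(b),
                onset_ms=float(t[a]),
                offset_ms=float(t[b]),
                trial_id=rec.trial_id,
                amplitude=float(np.hypot(dx, dy)),
                peak_velocity=peak,
            )
        )
    return out


def label_blinks(rec: GazeRecording) -> list[GazeEvent]:
    """Turn maximal runs of tracker blink flags into blink events."""
    s = rec.samples
    t = s["t_ms"].to_numpy(dtype=float)
    flags = s["blink"].to_numpy() != 0
    return [
        GazeEvent(
            kind="blink",
            onset_index=int(a),
            offset_index=int(b),
            onset_ms=float(t[a]),
            offset_ms=float(t[b]),
            trial_id=rec.trial_id,
        )
        for a, b in _valid_runs(flags)
    ]


def segment_fixations(
    rec: GazeRecording,
    saccades: list[GazeEvent],
    blinks: list[GazeEvent] | None = None,
) -> list[GazeEvent]:
    """Fixations are the sample intervals not covered by saccades or blinks.

    Fixation centroids are the mean binocular-averaged position; the
    within-event SD is ``sqrt(var_x + var_y)`` (population variances).
    Intervals adjacent to the trial boundaries are included.
    """
    s = rec.samples
    n = len(s)
    t = s["t_ms"].to_numpy(dtype=float)
    covered = np.zeros(n, dtype=bool)
    for ev in list(saccades) + list(blinks or []):
        covered[ev.onset_index:ev.offset_index + 1] = True

    bx = (s["xl"].to_numpy(dtype=float) + s["xr"].to_numpy(dtype=float)) / 2.0
    by = (s["yl"].to_numpy(dtype=float) + s["yr"].to_numpy(dtype=float)) / 2.0

    out = []
    for a, b in _valid_runs(~covered):
        seg_x, seg_y = bx[a:b + 1], by[a:b + 1]
        ok = np.isfinite(seg_x) & np.isfinite(seg_y)
        if ok.any():
            cx, cy = float(np.mean(seg_x[ok])), float(np.mean(seg_y[ok]))
            sd = float(np.sqrt(np.var(seg_x[ok]) + np.var(seg_y[ok])))
        else:
            cx = cy = sd = float("nan")
        out.append(
            GazeEvent(
                kind="fixation",
                onset_index=int(a),
                offset_index=int(b),
                onset_ms=float(t[a]),
                offset_ms=float(t[b]),
                trial_id=rec.trial_id,
                centroid_xy=(cx, cy),
                within_event_sd=sd,
            )
        )
    return out


def detect_events(
    rec: GazeRecording, params: DetectionParams | None = None
) -> list[GazeEvent]:
    """Full per-trial event stream: blinks, saccades, fixations, time-ordered."""
    blinks = label_blinks(rec)
    saccades = detect_saccades(rec, params)
    # saccade samples inside blinks belong to the blink
    saccades = [
        sac for sac in saccades
        if not any(
            sac.onset_index <= b.offset_index and b.onset_index <= sac.offset_index
            for b in blinks
        )
    ]
    fixations = segment_fixations(rec, saccades, blinks)
    events = sorted(blinks + saccades + fixations, key=lambda e: e.onset_index)
    return events


def events_to_frame(events: list[GazeEvent]) -> pd.DataFrame:
    """Event table in the interchange layout (one row per event)."""
    rows = []
    for i, ev in enumerate(events):
        cx, cy = ev.centroid_xy if ev.centroid_xy is not None else (np.nan, np.nan)
        rows.append(
            {
                "event_id": i,
                "trial_id": ev.trial_id,
                "kind": ev.kind,
                "onset_ms": ev.onset_ms,
                "offset_ms": ev.offset_ms,
                "duration_ms": ev.duration_ms,
                "x": cx,
                "y": cy,
                "amplitude_deg": ev.amplitude if ev.amplitude is not None else np.nan,
                "peak_vel": ev.peak_velocity if ev.peak_velocity is not None else np.nan,
                "within_sd": ev.within_event_sd if ev.within_event_sd is not None else np.nan,
                "flags": ";".join(sorted(ev.exclusion_flags)),
                "source": ev.source,
            }
        )
    return pd.DataFrame(rows)
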