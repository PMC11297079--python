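"""Synthetic binocular gaze recordings with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: 8 s trials sampled at 120 Hz, alternating fixations and saccades,
log-normal fixation durations (mean ~250 ms), log-normal saccade amplitudes
(mean ~6 deg), a time-decaying central anchor that produces a tunable central
fixation bias, per-eye white measurement noise, tracker-flagged blinks, the
15-position fixation-cross grid, and additive condition effects plus crossed
subject/image random intercepts on the log-duration / log-amplitude scales.

All randomness flows from one root seed through `numpy.random.SeedSequence`
spawn keys, so every trial (and every module test) is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import GazeRecording, TrialDesign, design_table
from .events import GazeEvent
from .mapping import ScreenGeometry

#: Saccade duration (ms) as a function of amplitude (deg): a main-sequence
#: style affine law with a symmetric raised-cosine velocity profile.
SACCADE_DURATION_INTERCEPT_MS = 21.0
SACCADE_DURATION_SLOPE_MS_PER_DEG = 2.2

_EFFECT_KEYS = ("log_duration", "log_amplitude", "anchor")


def saccade_duration_ms(amplitude_deg: float) -> float:
    return SACCADE_DURATION_INTERCEPT_MS + \
        SACCADE_DURATION_SLOPE_MS_PER_DEG * amplitude_deg


@dataclass
class SimulationParams:
    """Data-generating parameters; defaults define the emulated conditions.

    Durations are log-normal with ``mean_log_fixdur``/``sd_log_fixdur`` on
    the log-ms scale (defaults give a ~250 ms mean).  Saccade amplitudes are
    log-normal moment-matched to ``mean_saccade_amp``/``sd_saccade_amp`` in
    degrees.  ``anchor_strength`` is the probability that a saccade re-targets
    a center-anchored Gaussian rather than an amplitude-directed step; it
    decays over the trial from its initial value to ``anchor_floor`` with
    half-life ``anchor_halflife_ms``, yielding the early-strong central
    fixation bias.

    ``condition_effects`` maps a factor level (e.g. ``"Guess_Time"``) to
    additive shifts on ``log_duration`` (log-ms), ``log_amplitude`` (log-deg)
    and ``anchor`` (probability).  ``subject_sd``/``image_sd`` give SDs of
    random intercepts per response scale, drawn once per subject/image in
    :func:`simulate_experiment`.
    """

    sampling_rate: float = 120.0            # Hz
    trial_duration_ms: float = 8000.0
    mean_log_fixdur: float = 5.46           # log-ms; exp(5.46 + .35^2/2) ~ 250
    sd_log_fixdur: float = 0.35
    mean_saccade_amp: float = 6.0           # deg
    sd_saccade_amp: float = 3.0             # deg
    anchor_strength: float = 0.6            # in [0, 1]
    anchor_floor: float = 0.25
    anchor_halflife_ms: float = 1000.0
    anchor_sd_deg: tuple[float, float] = (6.0, 3.5)
    fixation_noise_sd: float = 0.2          # deg, per eye per axis
    blink_rate: float = 0.1                 # events / s
    blink_median_ms: float = 150.0
    blink_sd_log: float = 0.4
    binocular_offset_deg: float = 0.0       # fixed horizontal disparity
    image_extent_deg: tuple[float, float] = (40.6, 20.1)
    condition_effects: dict = field(default_factory=dict)
    subject_sd: dict = field(
        default_factory=lambda: {"log_duration": 0.1, "log_amplitude": 0.05,
                                 "anchor": 0.0})
    image_sd: dict = field(
        default_factory=lambda: {"log_duration": 0.1, "log_amplitude": 0.05,
                                 "anchor": 0.0})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.trial_duration_ms <= 0:
            raise ValueError("sampling_rate and trial_duration must be positive")
        if not 0.0 <= self.anchor_strength <= 1.0:
            raise ValueError("anchor_strength must lie in [0, 1]")
        if not 0.0 <= self.anchor_floor <= 1.0:
            raise ValueError("anchor_floor must lie in [0, 1]")
        for name in ("sd_log_fixdur", "sd_saccade_amp", "fixation_noise_sd",
                     "blink_rate", "blink_sd_log"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in (self.subject_sd, self.image_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("random-effect SDs must be >= 0")

    def anchor_at(self, t_ms: float, shift: float = 0.0) -> float:
        """Anchor probability at trial time ``t_ms`` (clipped to [0, 1])."""
        a = self.anchor_floor + (self.anchor_strength - self.anchor_floor) * \
            2.0 ** (-t_ms / self.anchor_halflife_ms)
        return float(np.clip(a + shift, 0.0, 1.0))


# --------------------------------------------------------------------------
# experimental designs

_START_FRAC_X = (0.20, 0.35, 0.50, 0.65, 0.80)   # of projector width
_START_FRAC_Y = (0.25, 0.50, 0.75)               # of projector height, top-down


def start_position_deg(index: int,
                       geom: ScreenGeometry | None = None
                       ) -> tuple[float, float]:
    """Degrees-from-image-center of fixation-cross start position 1..15.

    The grid is row-major, rows top to bottom at 25/50/75 % of the screen
    height, columns left to right at 20/35/50/65/80 % of the screen width.
    """
    if not 1 <= index <= 15:
        raise ValueError("start position index must be in 1..15")
    geom = geom or ScreenGeometry()
    row, col = divmod(index - 1, 5)
    sw, sh = geom.projector_px
    ppx, ppy = geom.px_per_deg
    x = (_START_FRAC_X[col] * sw - sw / 2.0) / ppx
    y = (sh / 2.0 - _START_FRAC_Y[row] * sh) / ppy
    return (x, y)


def _assign_start(rng: np.random.Generator) -> tuple[int, tuple[float, float]]:
    idx = int(rng.integers(1, 16))
    return idx, start_position_deg(idx)


def make_design(
    experiment_id: int,
    n_subjects: int,
    n_images: int,
    rng_seed: int = 0,
) -> list[TrialDesign]:
    """Generate the full trial list of one experiment.

    Experiment 1 (2x2 Task x Body within-subject): each image is viewed twice
    per subject — once under ``Free_Viewing`` (blocks A/B) and once under
    ``Guess_Time`` (blocks C/D); the two postures ``Chin_Rest``/``Standing``
    are counterbalanced across subjects within each task.  ``n_images`` must
    be even (two blocks per task).

    Experiment 2 (4-level posture between-block): a single ``Count_Animals``
    task; each image is seen once, in one of four equally sized posture
    blocks; the posture-to-block assignment is counterbalanced between
    participants (Latin-square rotation).  ``n_images`` must be divisible by 4.

    Start positions are drawn uniformly at random from the 15-position grid.
    """
    if experiment_id not in (1, 2):
        raise ValueError(f"unknown experiment_id {experiment_id}; valid: 1, 2")
    if n_subjects < 1 or n_images < 1:
        raise ValueError("n_subjects and n_images must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    designs: list[TrialDesign] = []

    if experiment_id == 1:
        if n_images % 2:
            raise ValueError(
                "Experiment 1 splits the image set into two equal blocks per "
                f"task; n_images={n_images} is not divisible by 2"
            )
        postures = ("Chin_Rest", "Standing")
        for subj in range(1, n_subjects + 1):
            for task, blocks in (("Free_Viewing", ("A", "B")),
                                 ("Guess_Time", ("C", "D"))):
                order = rng.permutation(n_images)
                halves = (order[: n_images // 2], order[n_images // 2:])
                # counterbalance posture-to-block across subjects
                flip = (subj - 1) % 2
                for b, block in enumerate(blocks):
                    posture = postures[(b + flip) % 2]
                    for img in halves[b]:
                        idx, xy = _assign_start(rng)
                        designs.append(TrialDesign(
                            subject_id=subj, image_id=int(img) + 1,
                            block_label=block, task_level=task,
                            posture_level=posture,
                            start_position_index=idx, start_position_xy=xy))
    else:
        if n_images % 4:
            raise ValueError(
                "Experiment 2 assigns images to four equal posture blocks; "
                f"n_images={n_images} is not divisible by 4"
            )
        postures = ("Chin_Rest", "Sitting", "Standing", "Balancing")
        for subj in range(1, n_subjects + 1):
            order = rng.permutation(n_images)
            quarter = n_images // 4
            rot = (subj - 1) % 4
            for b, block in enumerate("ABCD"):
                posture = postures[(b + rot) % 4]
                for img in order[b * quarter:(b + 1) * quarter]:
                    idx, xy = _assign_start(rng)
                    designs.append(TrialDesign(
                        subject_id=subj, image_id=int(img) + 1,
                        block_label=block, task_level="Count_Animals",
                        posture_level=posture,
                        start_position_index=idx, start_position_xy=xy))
    return designs


# --------------------------------------------------------------------------
# trial-level simulation


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _raised_cosine_displacement(u: np.ndarray) -> np.ndarray:
    """Fraction of saccade path covered at normalized time u in [0, 1]."""
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _reflect_into(v: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi] (billiard boundary)."""
    width = hi - lo
    if width <= 0:
        return lo
    v = (v - lo) % (2.0 * width)
    return lo + (width - abs(v - width))


def _trial_rng(params: SimulationParams, design: TrialDesign
               ) -> np.random.Generator:
    key = (3, design.subject_id, design.image_id,
           ord(design.block_label) - ord("A"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.rng_seed, spawn_key=key))


def simulate_trial(
    params: SimulationParams,
    design: TrialDesign,
    *,
    log_dur_shift: float = 0.0,
    log_amp_shift: float = 0.0,
    anchor_shift: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[GazeRecording, list[GazeEvent]]:
    """Simulate one trial; returns the recording and ground-truth events.

    The trial starts with a fixation at the design's fixation-cross start
    position.  Ground-truth fixations and saccades tile ``[0, T]`` exactly;
    samples are the ground-truth trajectory plus independent per-eye white
    noise; blink intervals are flagged per sample with missing positions.
    The optional ``*_shift`` arguments add condition/random-effect offsets on
    the respective scale (used by :func:`simulate_experiment`).
    """
    rng = rng or _trial_rng(params, design)
    T = params.trial_duration_ms
    half_w = params.image_extent_deg[0] / 2.0
    half_h = params.image_extent_deg[1] / 2.0

    mu_d = params.mean_log_fixdur + log_dur_shift
    mu_a_base, sig_a = _lognormal_moments(params.mean_saccade_amp,
                                          params.sd_saccade_amp)
    mu_a = mu_a_base + log_amp_shift

    # --- ground-truth event chain -------------------------------------
    fix_specs = []   # (onset, offset, (x, y))
    sac_specs = []   # (onset, offset, (x0, y0), (x1, y1))
    t = 0.0
    pos = tuple(design.start_position_xy)
    while t < T:
        dur = float(rng.lognormal(mu_d, params.sd_log_fixdur))
        dur = max(dur, 1.0)
        fix_specs.append((t, min(t + dur, T), pos))
        t += dur
        if t >= T:
            break
        a = params.anchor_at(t, anchor_shift)
        if rng.random() < a:
            target = (
                float(np.clip(rng.normal(0.0, params.anchor_sd_deg[0]),
                              -half_w, half_w)),
                float(np.clip(rng.normal(0.0, params.anchor_sd_deg[1]),
                              -half_h, half_h)),
            )
        else:
            amp = float(rng.lognormal(mu_a, sig_a))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            target = (
                _reflect_into(pos[0] + amp * np.cos(theta), -half_w, half_w),
                _reflect_into(pos[1] + amp * np.sin(theta), -half_h, half_h),
            )
        amp_eff = float(np.hypot(target[0] - pos[0], target[1] - pos[1]))
        sdur = saccade_duration_ms(amp_eff)
        sac_specs.append((t, min(t + sdur, T), pos, target))
        t += sdur
        pos = target

    # --- sample the trajectory -----------------------------------------
    n = int(round(T * params.sampling_rate / 1000.0))
    t_grid = np.arange(n) * 1000.0 / params.sampling_rate
    x = np.empty(n)
    y = np.empty(n)
    for onset, offset, p in fix_specs:
        m = (t_grid >= onset) & (t_grid < offset)
        x[m], y[m] = p
    for onset, offset, p0, p1 in sac_specs:
        m = (t_grid >= onset) & (t_grid < offset)
        if not m.any():
            continue
        u = (t_grid[m] - onset) / max(offset - onset, 1e-9)
        f = _raised_cosine_displacement(np.clip(u, 0.0, 1.0))
        x[m] = p0[0] + (p1[0] - p0[0]) * f
        y[m] = p0[1] + (p1[1] - p0[1]) * f

    noise = rng.normal(0.0, params.fixation_noise_sd, size=(n, 4)) \
        if params.fixation_noise_sd > 0 else np.zeros((n, 4))
    off = params.binocular_offset_deg / 2.0
    xl = x - off + noise[:, 0]
    yl = y + noise[:, 1]
    xr = x + off + noise[:, 2]
    yr = y + noise[:, 3]

    # --- blinks ---------------------------------------------------------
    blink = np.zeros(n, dtype=int)
    n_blinks = rng.poisson(params.blink_rate * T / 1000.0)
    for _ in range(n_blinks):
        onset = rng.uniform(0.0, T)
        dur = rng.lognormal(np.log(params.blink_median_ms),
                            params.blink_sd_log)
        m = (t_grid >= onset) & (t_grid < onset + dur)
        blink[m] = 1
    nanmask = blink == 1
    xl[nanmask] = yl[nanmask] = xr[nanmask] = yr[nanmask] = np.nan

    samples = pd.DataFrame(
        {"t_ms": t_grid, "xl": xl, "yl": yl, "xr": xr, "yr": yr,
         "blink": blink}
    )
    rec = GazeRecording(samples=samples, design=design, frame="image_deg")

    # --- ground-truth events --------------------------------------------
    events: list[GazeEvent] = []
    for onset, offset, p in fix_specs:
        events.append(_gt_event("fixation", onset, offset, t_grid,
                                rec.trial_id, centroid=p))
    for onset, offset, p0, p1 in sac_specs:
        events.append(_gt_event(
            "saccade", onset, offset, t_grid, rec.trial_id,
            amplitude=float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))))
    events.sort(key=lambda e: e.onset_ms)
    return rec, events


def _gt_event(kind, onset, offset, t_grid, trial_id, centroid=None,
              amplitude=None) -> GazeEvent:
    i0 = int(np.searchsorted(t_grid, onset, side="left"))
    i1 = int(np.searchsorted(t_grid, offset, side="left")) - 1
    return GazeEvent(
        kind=kind, onset_index=i0, offset_index=max(i1, i0 - 1),
        onset_ms=float(onset), offset_ms=float(offset), trial_id=trial_id,
        centroid_xy=centroid, amplitude=amplitude, source="ground_truth",
    )


# --------------------------------------------------------------------------
# experiment-level simulation


@dataclass
class SimulatedDataset:
    """Recordings, ground truth and design of a simulated experiment."""

    recordings: list[GazeRecording]
    ground_truth: dict[str, list[GazeEvent]]
    design: pd.DataFrame
    random_effects: pd.DataFrame   # drawn subject/image intercepts (truth)


def _unit_effects(params: SimulationParams, tag: int, unit_ids: Iterable[int],
                  sds: dict) -> dict[int, dict[str, float]]:
    out = {}
    for uid in sorted(set(unit_ids)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.rng_seed,
                                   spawn_key=(tag, uid)))
        out[uid] = {k: float(rng.normal(0.0, sds.get(k, 0.0)))
                    for k in _EFFECT_KEYS}
    return out


def _condition_shift(params: SimulationParams, design: TrialDesign,
                     key: str) -> float:
    shift = 0.0
    for level in (design.task_level, design.posture_level):
        shift += params.condition_effects.get(level, {}).get(key, 0.0)
    return shift


def simulate_experiment(
    params: SimulationParams,
    designs: list[TrialDesign],
) -> SimulatedDataset:
    """Simulate all trials of a design list with shared random effects.

    Condition effects (``params.condition_effects``) and subject/image random
    intercepts (drawn once per unit from ``subject_sd``/``image_sd``) shift
    the per-trial generating parameters additively on each response scale.

    Raises on duplicated (subject, image, task) triples — within one task a
    subject sees an image only once.
    """
    seen = set()
    for d in designs:
        key = (d.subject_id, d.image_id, d.task_level)
        if key in seen:
            raise ValueError(
                f"duplicated (subject, image, task) = {key}: within a task, "
                "each subject views an image exactly once"
            )
        seen.add(key)

    subj_re = _unit_effects(params, 1, (d.subject_id for d in designs),
                            params.subject_sd)
    img_re = _unit_effects(params, 2, (d.image_id for d in designs),
                           params.image_sd)

    recordings = []
    ground_truth = {}
    for d in designs:
        shifts = {
            k: _condition_shift(params, d, k)
            + subj_re[d.subject_id][k] + img_re[d.image_id][k]
            for k in _EFFECT_KEYS
        }
        rec, events = simulate_trial(
            params, d,
            log_dur_shift=shifts["log_duration"],
            log_amp_shift=shifts["log_amplitude"],
            anchor_shift=shifts["anchor"],
        )
        recordings.append(rec)
        ground_truth[rec.trial_id] = events

    re_rows = [
        {"unit": "subject", "unit_id": uid, **vals}
        for uid, vals in subj_re.items()
    ] + [
        {"unit": "image", "unit_id": uid, **vals}
        for uid, vals in img_re.items()
    ]
    return SimulatedDataset(
        recordings=recordings,
        ground_truth=ground_truth,
        design=design_table(designs),
        random_effects=pd.DataFrame(re_rows),
    )
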