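"""Exclusion criteria with a complete audit ledger.

Mobile eye-tracking signals are noisier than desktop recordings, so detected
events pass through a fixed set of exclusion rules before analysis: blinks,
implausibly short or long fixations, fixations with jittering signals, and
over-large saccades are removed together with their immediate neighbor
events.  Every removal is recorded in a ledger so that
``len(input) == len(kept) + len(ledger)`` always holds.

Semantics are mark-then-sweep: all critical events are marked against the
original event sequence first, then neighbor marks propagate one step; the
rules are therefore order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GazeRecording
from .events import GazeEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExclusionCriteria:
    """Thresholds of the event/trial exclusion rules.

    Fixations shorter than ``min_fixation_ms`` (33 ms spans four samples at
    120 Hz) or lasting ``max_fixation_ms`` or longer are removed; a fixation
    is "jittery" when its 2D positional SD exceeds ``jitter_factor`` times
    the median 2D SD of all fixations in the dataset (computed before any
    removal).  Saccades are removed only when strictly larger than
    ``max_saccade_amplitude_deg``.  Trials fail the pre-image fixation check
    when any valid sample in the final ``fixcheck_window_ms`` before image
    onset lies more than ``fixcheck_radius_deg`` from the cross.
    """

    min_fixation_ms: float = 33.0
    max_fixation_ms: float = 1000.0       # exclusive: removed at >= this
    jitter_factor: float = 15.0
    max_saccade_amplitude_deg: float = 25.0
    neighbor_removal: bool = True
    fixcheck_radius_deg: float = 2.0
    fixcheck_window_ms: float = 200.0

    def __post_init__(self) -> None:
        for name in ("min_fixation_ms", "max_fixation_ms", "jitter_factor",
                     "max_saccade_amplitude_deg", "fixcheck_radius_deg",
                     "fixcheck_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def min_fixation_samples(self, sampling_rate: float) -> int:
        """Number of samples spanned by the minimum fixation duration."""
        return int(np.ceil(self.min_fixation_ms * sampling_rate / 1000.0))


def apply_event_filters(
    events: list[GazeEvent],
    criteria: ExclusionCriteria | None = None,
) -> tuple[list[GazeEvent], pd.DataFrame]:
    """Apply the event-level exclusion rules; return kept events and ledger.

    Events must be time-ordered and non-overlapping within each trial.
    Neighbor propagation is single-step: the events immediately before and
    after a critical event are removed unless already critical themselves;
    neighbors of neighbors survive.  The ledger has one row per removed
    event with its (first) triggering rule, the threshold and the observed
    value.
    """
    criteria = criteria or ExclusionCriteria()
    if not events:
        return [], _empty_ledger()

    # jitter reference: median 2D SD over ALL fixations, pooled, pre-removal
    fix_sds = np.asarray([
        ev.within_event_sd for ev in events
        if ev.kind == "fixation" and ev.within_event_sd is not None
        and np.isfinite(ev.within_event_sd)
    ])
    jitter_threshold = (
        criteria.jitter_factor * float(np.median(fix_sds))
        if fix_sds.size else np.inf
    )

    # group indices per trial, preserving order
    trial_order: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        trial_order.setdefault(ev.trial_id, []).append(i)

    marks: dict[int, tuple[str, float, float]] = {}  # idx -> (rule, thr, obs)

    def _mark(i: int, rule: str, thr: float, obs: float) -> None:
        if i not in marks:
            marks[i] = (rule, thr, obs)

    for i, ev in enumerate(events):
        if ev.kind == "blink":
            _mark(i, "blink", np.nan, ev.duration_ms)
        elif ev.kind == "fixation":
            if ev.duration_ms < criteria.min_fixation_ms:
                _mark(i, "short_fixation", criteria.min_fixation_ms,
                      ev.duration_ms)
            elif ev.duration_ms >= criteria.max_fixation_ms:
                _mark(i, "long_fixation", criteria.max_fixation_ms,
                      ev.duration_ms)
            elif (ev.within_event_sd is not None
                    and np.isfinite(ev.within_event_sd)
                    and ev.within_event_sd > jitter_threshold):
                _mark(i, "jitter_fixation", jitter_threshold,
                      ev.within_event_sd)
        elif ev.kind == "saccade":
            if (ev.amplitude is not None
                    and ev.amplitude > criteria.max_saccade_amplitude_deg):
                _mark(i, "large_saccade",
                      criteria.max_saccade_amplitude_deg, ev.amplitude)

    if criteria.neighbor_removal:
        critical = list(marks.keys())
        for trial_idx in trial_order.values():
            pos_of = {idx: p for p, idx in enumerate(trial_idx)}
            for i in critical:
                if i not in pos_of:
                    continue
                p = pos_of[i]
                for q in (p - 1, p + 1):
                    if 0 <= q < len(trial_idx):
                        _mark(trial_idx[q], "neighbor", np.nan, np.nan)

    kept, rows = [], []
    for i, ev in enumerate(events):
        if i in marks:
            rule, thr, obs = marks[i]
            ev.exclusion_flags.add(rule)
            rows.append({
                "event_id": i,
                "trial_id": ev.trial_id,
                "rule_label": rule,
                "threshold_value": thr,
                "observed_value": obs,
            })
        else:
            kept.append(ev)
    ledger = pd.DataFrame(rows) if rows else _empty_ledger()
    return kept, ledger


def _empty_ledger() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["event_id", "trial_id", "rule_label", "threshold_value",
                 "observed_value"]
    )


def fixation_check(
    rec: GazeRecording,
    cross_xy: tuple[float, float],
    criteria: ExclusionCriteria | None = None,
    image_onset_ms: float = 0.0,
) -> bool:
    """Pre-image fixation check; True = pass, False = discard the trial.

    Fails iff any valid binocular-mean sample within the final window before
    image onset lies farther than the radius from the cross position.
    Blink-missing samples are ignored.
    """
    criteria = criteria or ExclusionCriteria()
    s = rec.samples
    t = s["t_ms"].to_numpy(dtype=float)
    window = (t >= image_onset_ms - criteria.fixcheck_window_ms) \
        & (t < image_onset_ms)
    bx = (s["xl"].to_numpy(dtype=float) + s["xr"].to_numpy(dtype=float)) / 2.0
    by = (s["yl"].to_numpy(dtype=float) + s["yr"].to_numpy(dtype=float)) / 2.0
    valid = window & np.isfinite(bx) & np.isfinite(by)
    if not valid.any():
        return True
    dist = np.hypot(bx[valid] - cross_xy[0], by[valid] - cross_xy[1])
    return bool(np.all(dist <= criteria.fixcheck_radius_deg))


FIRST_FIXATION_MARKER = "first_fixation_excluded"


def exclude_first_fixation(event_table: pd.DataFrame) -> pd.DataFrame:
    """Drop each trial's first fixation (the one on the fixation cross).

    Operates on analysis tables (the raw event record is untouched).  The
    output carries a marker in ``DataFrame.attrs`` so a second application
    is a no-op.
    """
    if event_table.attrs.get(FIRST_FIXATION_MARKER):
        return event_table
    drop = (
        event_table[event_table["kind"] == "fixation"]
        .groupby("trial_id", sort=False)
        .head(1)
        .index
    )
    out = event_table.drop(index=drop).reset_index(drop=True)
    out.attrs[FIRST_FIXATION_MARKER] = True
    return out


def balance_start_positions(
    trial_table: pd.DataFrame,
    rng_seed: int = 0,
    condition_col: str = "condition",
    position_col: str = "start_position_index",
) -> pd.DataFrame:
    """Subsample trials so every start position occurs equally often per condition.

    For each start position the retained count in every condition equals the
    minimum count of that position across conditions; retained trials are
    chosen uniformly at random with the given seed.  A position absent from
    some condition contributes zero trials everywhere (logged).
    """
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    conditions = sorted(trial_table[condition_col].unique())
    kept_idx: list[np.ndarray] = []
    for pos, sub in trial_table.groupby(position_col):
        counts = {c: (sub[condition_col] == c).sum() for c in conditions}
        m = min(counts.values())
        if m == 0:
            logger.info(
                "start position %s absent in some condition; dropped "
                "everywhere", pos,
            )
            continue
        for c in conditions:
            idx = sub.index[sub[condition_col] == c].to_numpy()
            kept_idx.append(rng.choice(idx, size=m, replace=False))
    if not kept_idx:
        return trial_table.iloc[0:0].copy()
    keep = np.sort(np.concatenate(kept_idx))
    return trial_table.loc[keep].copy()
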