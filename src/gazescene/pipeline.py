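"""End-to-end analysis: recordings -> events -> filters -> tables -> LMM.

Glue over the stage modules so that a simulated (or loaded) dataset can be
pushed through detection, exclusion filtering and statistic extraction into
the contrast-coded mixed models in one call.  Each stage remains usable on
its own; this module only sequences them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GazeRecording
from .events import DetectionParams, detect_events, events_to_frame
from .inference import LMMFit, build_contrasts, cfb_covariates, fit_lmm
from .preprocess import (
    ExclusionCriteria,
    apply_event_filters,
    balance_start_positions,
    exclude_first_fixation,
)
from .stats import (
    TimeWindows,
    compute_entropy,
    fixation_distance_table,
    fixation_duration_table,
    saccade_amplitude_table,
)

#: Supported model responses.
RESPONSES = ("log_fixdur", "log_sacamp", "exp_entropy", "cfb")


def detect_and_filter(
    recordings: list[GazeRecording],
    detection: DetectionParams | None = None,
    criteria: ExclusionCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect events in every recording and apply the exclusion filters.

    Returns the kept-event table and the exclusion ledger.
    """
    events = []
    for rec in recordings:
        events.extend(detect_events(rec, detection))
    kept, ledger = apply_event_filters(events, criteria)
    return events_to_frame(kept), ledger


def _merge_design(event_table: pd.DataFrame,
                  design: pd.DataFrame) -> pd.DataFrame:
    cols = ["trial_id", "subject_id", "image_id", "task_level",
            "posture_level", "start_position_index", "start_x_deg",
            "start_y_deg"]
    return event_table.merge(design[cols], on="trial_id", how="left")


def _condition_label(table: pd.DataFrame, experiment: int) -> pd.Series:
    if experiment == 1:
        return table["task_level"] + ":" + table["posture_level"]
    return table["posture_level"]


def fit_response(
    event_table: pd.DataFrame,
    design: pd.DataFrame,
    experiment: int,
    response: str,
    window: tuple[float, float] | None = None,
    rng_seed: int = 0,
) -> tuple[LMMFit, pd.DataFrame]:
    """Build the analysis table for one response and fit its mixed model.

    ``response`` is one of ``log_fixdur`` (log fixation duration, default
    window 0-2000 ms), ``log_sacamp`` (log saccade amplitude, default full
    trial), ``exp_entropy`` (exponential of the per-image fixation-density
    entropy; image random intercept with a condition slope, no subject term)
    or ``cfb`` (per-fixation distance to the image center with the
    start-distance and log-sample covariates, on start-position-balanced
    trials).  Returns the fit and the analysis table it was computed from.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}; valid: {RESPONSES}")
    table = _merge_design(event_table, design)
    table = exclude_first_fixation(table)

    if response == "log_fixdur":
        win = TimeWindows(duration_analysis=window or (0.0, 2000.0))
        tab = fixation_duration_table(table, win)
        contrasts = build_contrasts(experiment, tab)
        fit = fit_lmm(tab["log_duration"].to_numpy(), contrasts,
                      subject_ids=tab["subject_id"].to_numpy(),
                      image_ids=tab["image_id"].to_numpy())
        return fit, tab

    if response == "log_sacamp":
        tab = saccade_amplitude_table(table, window or (0.0, 8000.0))
        contrasts = build_contrasts(experiment, tab)
        fit = fit_lmm(tab["log_amplitude"].to_numpy(), contrasts,
                      subject_ids=tab["subject_id"].to_numpy(),
                      image_ids=tab["image_id"].to_numpy())
        return fit, tab

    if response == "exp_entropy":
        fix = table[table["kind"] == "fixation"]
        rows = []
        group_cols = ["image_id", "task_level", "posture_level"]
        for keys, sub in fix.groupby(group_cols):
            xy = sub[["x", "y"]].to_numpy(dtype=float)
            try:
                grid = compute_entropy(xy)
            except ValueError:
                continue
            rows.append(dict(zip(group_cols, keys),
                             entropy_bits=grid.entropy_bits,
                             exp_entropy=grid.entropy_exp))
        tab = pd.DataFrame(rows)
        contrasts = build_contrasts(experiment, tab)
        slope = "Task" if experiment == 1 else "C3"
        fit = fit_lmm(tab["exp_entropy"].to_numpy(), contrasts,
                      subject_ids=None,
                      image_ids=tab["image_id"].to_numpy(),
                      image_slope=slope)
        return fit, tab

    # cfb
    trials = design.copy()
    trials["condition"] = _condition_label(trials, experiment)
    balanced = balance_start_positions(trials, rng_seed=rng_seed)
    table = table[table["trial_id"].isin(balanced["trial_id"])]
    tab = fixation_distance_table(table)
    if window is not None:
        tab = tab[(tab["onset_ms"] >= window[0])
                  & (tab["onset_ms"] < window[1])]
    tab = tab.copy()
    tab["start_distance_deg"] = np.hypot(tab["start_x_deg"],
                                         tab["start_y_deg"])
    contrasts = build_contrasts(experiment, tab)
    cov = cfb_covariates(tab)
    X = pd.concat([contrasts, cov], axis=1)
    fit = fit_lmm(tab["distance_deg"].to_numpy(), X,
                  subject_ids=tab["subject_id"].to_numpy(),
                  image_ids=tab["image_id"].to_numpy())
    return fit, tab
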