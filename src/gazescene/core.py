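"""Shared containers for gaze recordings and trial metadata.

All modules share one coordinate convention: degrees of visual angle with the
origin at the stimulus-image center, x rightward and y upward.  Pixel
coordinates are 0-based with pixel centers at integer + 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

#: Task factor levels used across both experiments.
TASK_LEVELS = ("Free_Viewing", "Guess_Time", "Count_Animals")

#: Posture factor levels, ordered from most to least restricted.
POSTURE_LEVELS = ("Chin_Rest", "Sitting", "Standing", "Balancing")

#: Column layout of the long sample-table interchange format.
SAMPLE_COLUMNS = ("trial_id", "t_ms", "xl", "yl", "xr", "yr", "blink")


@dataclass(frozen=True)
class TrialDesign:
    """Metadata of one experimental trial.

    ``start_position_index`` addresses one of the 15 fixation-cross start
    positions (3 vertical x 5 horizontal grid on the projection screen);
    ``start_position_xy`` is that position in degrees from the image center.
    """

    subject_id: int
    image_id: int
    block_label: str                 # "A".."D"
    task_level: str
    posture_level: str
    start_position_index: int        # 1..15
    start_position_xy: tuple[float, float]

    def __post_init__(self) -> None:
        if self.task_level not in TASK_LEVELS:
            raise ValueError(
                f"unknown task level {self.task_level!r}; valid: {TASK_LEVELS}"
            )
        if self.posture_level not in POSTURE_LEVELS:
            raise ValueError(
                f"unknown posture level {self.posture_level!r}; "
                f"valid: {POSTURE_LEVELS}"
            )
        if not 1 <= self.start_position_index <= 15:
            raise ValueError("start_position_index must be in 1..15")

    @property
    def trial_id(self) -> str:
        return (
            f"S{self.subject_id:03d}_I{self.image_id:03d}_"
            f"{self.block_label}_{self.task_level}"
        )


@dataclass
class GazeRecording:
    """A binocular sample stream for one trial.

    ``samples`` holds columns ``t_ms, xl, yl, xr, yr, blink`` (and optional
    flags added by mapping).  ``frame`` labels the coordinate frame:
    ``"image_deg"`` (degrees, image-centered) or ``"scene_px"`` (scene-camera
    pixels).  Blink samples carry NaN positions and ``blink == 1``.
    """

    samples: pd.DataFrame
    design: Optional[TrialDesign] = None
    frame: str = "image_deg"

    @property
    def trial_id(self) -> str:
        return self.design.trial_id if self.design is not None else ""

    @property
    def sampling_rate(self) -> float:
        t = self.samples["t_ms"].to_numpy()
        if len(t) < 2:
            raise ValueError("need at least two samples to infer a rate")
        return 1000.0 / float(t[1] - t[0])

    def binocular_mean(self) -> pd.DataFrame:
        """Cyclopean (binocular-average) gaze position per sample."""
        s = self.samples
        return pd.DataFrame(
            {
                "t_ms": s["t_ms"],
                "x": (s["xl"] + s["xr"]) / 2.0,
                "y": (s["yl"] + s["yr"]) / 2.0,
            }
        )


def design_table(designs: list[TrialDesign]) -> pd.DataFrame:
    """Tabulate trial designs (one row per trial, interchange format)."""
    rows = []
    for d in designs:
        rows.append(
            {
                "trial_id": d.trial_id,
                "subject_id": d.subject_id,
                "image_id": d.image_id,
                "block_label": d.block_label,
                "task_level": d.task_level,
                "posture_level": d.posture_level,
                "start_position_index": d.start_position_index,
                "start_x_deg": d.start_position_xy[0],
                "start_y_deg": d.start_position_xy[1],
            }
        )
    return pd.DataFrame(rows)


def write_samples(recordings: list[GazeRecording], path: str | Path) -> None:
    """Write recordings as one long sample table (CSV or TSV by suffix)."""
    frames = []
    for rec in recordings:
        s = rec.samples[list(SAMPLE_COLUMNS[1:])].copy()
        s.insert(0, "trial_id", rec.trial_id)
        frames.append(s)
    table = pd.concat(frames, ignore_index=True)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.to_csv(path, sep=sep, index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)
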