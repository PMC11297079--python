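"""Dependent variables of the scene-viewing analysis.

Covers the temporal and spatial gaze statistics: log fixation durations in
onset-assigned 400 ms bins, log saccade amplitudes with Gaussian-kernel
density summaries, Shannon entropy of the fixation-location density over a
128 x 128 grid (with its exponential transform), the central-fixation-bias
time course (mean distance to the image center per time window), its uniform
reference value, and Cousineau-Morey within-subject confidence intervals.

Time bins are half-open and a fixation belongs to the bin containing its
onset; durations and amplitudes are natural-log transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_IMAGE_EXTENT = (40.6, 20.1)
ENTROPY_GRID_CELLS = 128


@dataclass(frozen=True)
class TimeWindows:
    """Analysis time windows (ms from image onset)."""

    duration_analysis: tuple[float, float] = (0.0, 2000.0)
    duration_bin_ms: float = 400.0
    cfb_early: tuple[tuple[float, float], ...] = (
        (0.0, 400.0), (400.0, 800.0), (800.0, 1200.0))
    cfb_late: tuple[float, float] = (1200.0, 8000.0)
    full: tuple[float, float] = (0.0, 8000.0)

    def cfb_windows(self) -> list[tuple[float, float]]:
        return [*self.cfb_early, self.cfb_late, self.full]


@dataclass
class EntropyGrid:
    """Probability field over the image grid with its Shannon entropy.

    ``p`` is the (n_cells, n_cells) probability per cell (sums to 1),
    ``entropy_bits`` the Shannon entropy S = -sum p_i log2 p_i in bits
    (0..14 for a 128x128 grid) and ``entropy_exp`` its exponential transform
    exp(S), the response scale used for inference.
    """

    p: np.ndarray
    entropy_bits: float
    n_fixations: int

    @property
    def entropy_exp(self) -> float:
        return float(np.exp(self.entropy_bits))

    @property
    def max_entropy_bits(self) -> float:
        return float(np.log2(self.p.size))


def fixation_duration_table(
    fixations: pd.DataFrame,
    windows: TimeWindows | None = None,
) -> pd.DataFrame:
    """Per-fixation natural-log durations with 400 ms onset-bin labels.

    Expects an analysis event table (first fixation already excluded) with
    columns ``trial_id, onset_ms, duration_ms``.  A fixation is included iff
    its onset lies inside the analysis window; one overlapping the window end
    is included when its onset precedes it.
    """
    windows = windows or TimeWindows()
    lo, hi = windows.duration_analysis
    fix = fixations[fixations["kind"] == "fixation"] \
        if "kind" in fixations.columns else fixations
    m = (fix["onset_ms"] >= lo) & (fix["onset_ms"] < hi) \
        & (fix["duration_ms"] > 0)
    out = fix.loc[m].copy()
    out["log_duration"] = np.log(out["duration_ms"].to_numpy(dtype=float))
    edges = np.arange(lo, hi + windows.duration_bin_ms,
                      windows.duration_bin_ms)
    idx = np.digitize(out["onset_ms"].to_numpy(dtype=float), edges) - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    out["bin_ms"] = edges[idx]
    return out.reset_index(drop=True)


def saccade_amplitude_table(
    saccades: pd.DataFrame,
    window: tuple[float, float] = (0.0, 8000.0),
) -> pd.DataFrame:
    """Per-saccade natural-log amplitudes within an onset window."""
    sac = saccades[saccades["kind"] == "saccade"] \
        if "kind" in saccades.columns else saccades
    amp_col = "amplitude_deg" if "amplitude_deg" in sac.columns else "amplitude"
    m = (sac["onset_ms"] >= window[0]) & (sac["onset_ms"] < window[1]) \
        & (sac[amp_col] > 0)
    out = sac.loc[m].copy()
    out["log_amplitude"] = np.log(out[amp_col].to_numpy(dtype=float))
    return out.reset_index(drop=True)


@dataclass
class DensityCurve:
    x: np.ndarray
    density: np.ndarray
    bandwidth: float


def amplitude_density(
    amplitudes: np.ndarray,
    grid: np.ndarray | None = None,
) -> DensityCurve:
    """Gaussian kernel density with bandwidth = half the sample SD.

    A zero-SD (single-point or constant) sample degenerates to a narrow
    Gaussian bump with an epsilon bandwidth.
    """
    a = np.asarray(amplitudes, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no finite amplitudes")
    sd = float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    bw = 0.5 * sd if sd > 0 else 1e-3
    if grid is None:
        lo = a.min() - 4 * bw
        hi = a.max() + 4 * bw
        grid = np.linspace(lo, hi, 512)
    # explicit Gaussian mixture (gaussian_kde cannot take singular data)
    z = (grid[:, None] - a[None, :]) / bw
    dens = np.mean(sps.norm.pdf(z), axis=1) / bw
    return DensityCurve(x=grid, density=dens, bandwidth=bw)


def compute_entropy(
    fixation_xy: np.ndarray,
    image_extent: tuple[float, float] = DEFAULT_IMAGE_EXTENT,
    n_cells: int = ENTROPY_GRID_CELLS,
) -> EntropyGrid:
    """Shannon entropy (bits) of the fixation-location density on a grid.

    ``fixation_xy`` is (n, 2) in degrees from the image center.  The grid
    covers the image extent exactly; the density is the unweighted fixation
    count per cell normalized to probabilities.  Off-image fixations are
    excluded from the grid.  Empty cells contribute zero (0 log 0 := 0).
    """
    xy = np.atleast_2d(np.asarray(fixation_xy, dtype=float))
    half_w, half_h = image_extent[0] / 2.0, image_extent[1] / 2.0
    on = (
        np.isfinite(xy).all(axis=1)
        & (np.abs(xy[:, 0]) <= half_w) & (np.abs(xy[:, 1]) <= half_h)
    )
    xy = xy[on]
    if xy.shape[0] == 0:
        raise ValueError("empty density: no on-image fixations")
    counts, _, _ = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=n_cells,
        range=[[-half_w, half_w], [-half_h, half_h]],
    )
    p = counts / counts.sum()
    nz = p[p > 0]
    S = float(-(nz * np.log2(nz)).sum())
    return EntropyGrid(p=p, entropy_bits=S, n_fixations=int(xy.shape[0]))


def uniform_grid_entropy(n_cells: int = ENTROPY_GRID_CELLS) -> EntropyGrid:
    """The entropy ceiling: equal probability in every grid cell."""
    p = np.full((n_cells, n_cells), 1.0 / n_cells ** 2)
    return EntropyGrid(p=p, entropy_bits=float(np.log2(n_cells ** 2)),
                       n_fixations=0)


def cfb_timecourse(
    fixations: pd.DataFrame,
    windows: TimeWindows | None = None,
    center_xy: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Mean distance-to-center per time window (central fixation bias).

    Expects an analysis fixation table with columns ``onset_ms, x, y`` (first
    fixation excluded; start-position balancing recommended upstream).
    Distances are Euclidean in degrees; a fixation enters every window that
    contains its onset.  Off-image fixations are retained — the distance is
    defined regardless.
    """
    windows = windows or TimeWindows()
    fix = fixations[fixations["kind"] == "fixation"] \
        if "kind" in fixations.columns else fixations
    onset = fix["onset_ms"].to_numpy(dtype=float)
    dist = np.hypot(fix["x"].to_numpy(dtype=float) - center_xy[0],
                    fix["y"].to_numpy(dtype=float) - center_xy[1])
    rows = []
    for lo, hi in windows.cfb_windows():
        m = (onset >= lo) & (onset < hi) & np.isfinite(dist)
        rows.append({
            "window_lo_ms": lo,
            "window_hi_ms": hi,
            "mean_distance_deg": float(dist[m].mean()) if m.any() else np.nan,
            "n_fixations": int(m.sum()),
        })
    return pd.DataFrame(rows)


def fixation_distance_table(
    fixations: pd.DataFrame,
    center_xy: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Per-fixation distance-to-center with the within-trial ordinal.

    Adds ``distance_deg`` and ``sample`` (1-based ordinal of the fixation
    within its trial, counted on the analysis table), the response and
    covariate bases of the central-fixation-bias model.
    """
    fix = fixations[fixations["kind"] == "fixation"] \
        if "kind" in fixations.columns else fixations
    out = fix.copy()
    out["distance_deg"] = np.hypot(
        out["x"].to_numpy(dtype=float) - center_xy[0],
        out["y"].to_numpy(dtype=float) - center_xy[1])
    out["sample"] = out.groupby("trial_id").cumcount() + 1
    return out.reset_index(drop=True)


def expected_uniform_distance(
    width_deg: float,
    height_deg: float,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo mean distance-to-center for uniform placement.

    Returns ``(mean, standard_error)`` in degrees.  This is the reference
    line against which the central fixation bias is read: for the
    40.6 x 20.1 degree image it is ~12 degrees.
    """
    if width_deg < 0 or height_deg < 0:
        raise ValueError("extents must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = rng.uniform(-width_deg / 2.0, width_deg / 2.0, n_samples)
    y = rng.uniform(-height_deg / 2.0, height_deg / 2.0, n_samples)
    d = np.hypot(x, y)
    return float(d.mean()), float(d.std(ddof=1) / np.sqrt(n_samples))


def within_subject_ci(
    condition_means: pd.DataFrame,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Cousineau-Morey within-subject confidence intervals.

    ``condition_means`` is a subjects x conditions table of means.  Data are
    subject-centered (subtract the subject mean, add the grand mean), a
    t-based CI of each condition mean is computed across subjects, and the
    half-width is inflated by sqrt(C / (C - 1)) for C conditions.
    """
    M = condition_means.to_numpy(dtype=float)
    n_subj, n_cond = M.shape
    if n_cond < 2:
        raise ValueError("within-subject correction requires >= 2 conditions")
    if n_subj < 2:
        raise ValueError("need >= 2 subjects for a confidence interval")
    centered = M - M.mean(axis=1, keepdims=True) + M.mean()
    means = centered.mean(axis=0)
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n_subj)
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, df=n_subj - 1)
    morey = np.sqrt(n_cond / (n_cond - 1.0))
    half = tcrit * sem * morey
    return pd.DataFrame({
        "condition": list(condition_means.columns),
        "mean": M.mean(axis=0),
        "ci_half_width": half,
    })
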