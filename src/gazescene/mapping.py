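"""Scene-camera to stimulus-image mapping.

Mobile eye-tracking glasses report gaze in scene-camera pixels; the stimulus
image occupies an (unknown, head-dependent) quadrilateral of that view.  The
marker frame around the stimulus provides point correspondences from which a
plane homography is estimated; gaze samples are then projected onto the
stimulus plane and converted to degrees of visual angle.

Pixel-to-degree conversion is linear per axis (constant px/deg factor), which
matches how stimulus extent is specified; no tangent correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import ProjectiveTransform

from .core import GazeRecording


@dataclass(frozen=True)
class ScreenGeometry:
    """Fixed geometry of the recording setup.

    Defaults reproduce the reference setup: a 1668x828 px stimulus covering
    40.6 x 20.1 degrees, viewed from 270 cm, recorded by a 960x720 px scene
    camera with a 60 x 46 degree field of view, projected on a 1920x1080
    screen.
    """

    image_px: tuple[float, float] = (1668.0, 828.0)
    image_deg: tuple[float, float] = (40.6, 20.1)
    scene_camera_px: tuple[float, float] = (960.0, 720.0)
    scene_camera_deg: tuple[float, float] = (60.0, 46.0)
    projector_px: tuple[float, float] = (1920.0, 1080.0)
    viewing_distance_cm: float = 270.0

    def __post_init__(self) -> None:
        for name in ("image_px", "image_deg", "scene_camera_px",
                     "scene_camera_deg", "projector_px"):
            if min(getattr(self, name)) <= 0:
                raise ValueError(f"{name} extents must be positive")

    @property
    def px_per_deg(self) -> tuple[float, float]:
        return (
            self.image_px[0] / self.image_deg[0],
            self.image_px[1] / self.image_deg[1],
        )

    def image_px_to_deg(self, xy_px: np.ndarray) -> np.ndarray:
        """Image pixels -> degrees from image center (x right, y up)."""
        xy = np.asarray(xy_px, dtype=float)
        ppx, ppy = self.px_per_deg
        w, h = self.image_px
        out = np.empty_like(xy)
        out[..., 0] = (xy[..., 0] - w / 2.0) / ppx
        out[..., 1] = (h / 2.0 - xy[..., 1]) / ppy
        return out

    def deg_to_image_px(self, xy_deg: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy_deg, dtype=float)
        ppx, ppy = self.px_per_deg
        w, h = self.image_px
        out = np.empty_like(xy)
        out[..., 0] = xy[..., 0] * ppx + w / 2.0
        out[..., 1] = h / 2.0 - xy[..., 1] * ppy
        return out


@dataclass
class Homography:
    """A 3x3 projective map between two labelled pixel frames.

    The matrix is normalized so that ``matrix[2, 2] == 1`` whenever that entry
    is nonzero; a homography is only defined up to scale.
    """

    matrix: np.ndarray
    source: str = "scene_px"
    target: str = "image_px"
    residual: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography matrix is singular")
        if abs(m[2, 2]) > 1e-12:
            m = m / m[2, 2]
        self.matrix = m

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Apply to an (n, 2) array; near-zero denominators yield NaN."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ones = np.ones((xy.shape[0], 1))
        hom = np.hstack([xy, ones]) @ self.matrix.T
        w = hom[:, 2]
        out = np.full_like(xy, np.nan)
        ok = np.abs(w) > 1e-12
        out[ok] = hom[ok, :2] / w[ok, None]
        return out

    def inverse(self) -> "Homography":
        return Homography(
            np.linalg.inv(self.matrix),
            source=self.target,
            target=self.source,
            residual=self.residual,
        )


def estimate_homography(
    correspondences: list[tuple[tuple[float, float], tuple[float, float]]],
    source: str = "scene_px",
    target: str = "image_px",
) -> Homography:
    """Estimate a plane homography from >= 4 point correspondences.

    Uses the normalized direct linear transform (total least squares for
    over-determined systems).  The RMS reprojection residual in target
    pixels is stored on the result.

    Raises
    ------
    ValueError
        For fewer than 4 correspondences or a degenerate (e.g. collinear)
        configuration.
    """
    src = np.asarray([c[0] for c in correspondences], dtype=float)
    dst = np.asarray([c[1] for c in correspondences], dtype=float)
    if len(src) < 4:
        raise ValueError(
            f"homography estimation needs >= 4 correspondences, got {len(src)}"
        )
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src, dst)
        ok = bool(tform)
    else:  # older scikit-image
        tform = ProjectiveTransform()
        ok = tform.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tform.params)):
        raise ValueError(
            "degenerate correspondence configuration (collinear or coincident "
            "points) — homography is not identifiable"
        )
    reproj = tform(src)
    residual = float(np.sqrt(np.mean(np.sum((reproj - dst) ** 2, axis=1))))
    return Homography(tform.params, source=source, target=target,
                      residual=residual)


def median_homography(homographies: list[Homography]) -> Homography:
    """Elementwise median of per-frame homographies (static per-trial map).

    Robustly summarizes repeated marker-based estimates from successive
    scene-camera frames into one per-trial transform.
    """
    if not homographies:
        raise ValueError("no homographies to combine")
    stack = np.stack([h.matrix for h in homographies])
    return Homography(
        np.median(stack, axis=0),
        source=homographies[0].source,
        target=homographies[0].target,
        residual=float(np.median([h.residual for h in homographies])),
    )


def map_recording(
    rec: GazeRecording,
    H: Homography,
    geom: ScreenGeometry | None = None,
) -> GazeRecording:
    """Project a scene-camera recording onto the stimulus image, in degrees.

    Samples mapping outside the image are retained but flagged in an
    ``off_image`` column; blink samples (NaN positions) propagate as missing.
    Samples hitting a vanishing homography denominator become NaN and are
    flagged ``off_image`` as well.
    """
    geom = geom or ScreenGeometry()
    if rec.frame != "scene_px":
        warnings.warn(
            f"mapping a recording whose frame is {rec.frame!r}, "
            "expected 'scene_px'",
            stacklevel=2,
        )
    s = rec.samples.copy()
    w, h = geom.image_px
    off = np.zeros(len(s), dtype=bool)
    for xcol, ycol in (("xl", "yl"), ("xr", "yr")):
        px = H.apply(np.column_stack([s[xcol].to_numpy(),
                                      s[ycol].to_numpy()]))
        valid = np.isfinite(px).all(axis=1)
        inside = valid & (px[:, 0] >= 0) & (px[:, 0] <= w) \
            & (px[:, 1] >= 0) & (px[:, 1] <= h)
        had_data = np.isfinite(s[xcol].to_numpy())
        off |= had_data & ~inside
        deg = geom.image_px_to_deg(px)
        s[xcol] = deg[:, 0]
        s[ycol] = deg[:, 1]
    s["off_image"] = off.astype(int)
    return GazeRecording(samples=s, design=rec.design, frame="image_deg")
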