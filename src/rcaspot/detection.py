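"""Candidate RCP spot detection and signal/background-ratio filtering.

A rolling-circle product images as a diffraction-limited, near-isotropic
bright blob, so candidates are local maxima of a lightly smoothed projection.
Each candidate keeps its *raw* peak pixel intensity and the local background
estimate at the same pixel; the inclusion criterion is the peak/background
ratio with a strict ``>`` comparison (ratio 5 for tissue overviews, ratio 2
for detailed quantification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import BackgroundMap

logger = logging.getLogger(__name__)


@dataclass
class Spot:
    """One detected rolling-circle product.

    ``x`` is the column and ``y`` the row of the peak pixel (0-based).
    ``allele`` and ``unspecific`` are filled in by the classification stage;
    ``region`` and ``field`` by quantification.
    """

    x: int
    y: int
    channel: str
    peak: float
    background: float
    sb_ratio: float
    unspecific: bool = False
    allele: str | None = None
    region: int | None = None
    field: int | None = None


@dataclass(frozen=True)
class DetectionParams:
    """Detector knobs.

    min_sb_ratio : strict lower bound on peak/background. 2.0 is the
        quantification profile; 5.0 the overview profile.
    min_separation : Chebyshev radius (px) within which a peak must dominate.
    smoothing_sigma : Gaussian pre-smoothing (px) for peak finding only;
        peak intensities are read from the unsmoothed image.
    """

    min_sb_ratio: float = 2.0
    min_separation: int = 3
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.min_sb_ratio <= 0:
            raise ValueError("min_sb_ratio must be > 0")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


def local_maxima(smoothed: np.ndarray, min_separation: int) -> list[tuple[int, int]]:
    """All pixels that dominate their Chebyshev neighborhood.

    A pixel (r, c) is a peak iff, within the (2s+1)×(2s+1) window clipped at
    the image border: (a) no neighbor exceeds it, (b) at least one neighbor is
    strictly below it (a fully flat window is featureless, not a peak), and
    (c) it is the lexicographically smallest (r, c) among equal-valued window
    pixels — the plateau tie-break. The rule is purely local, so it can be
    checked by exhaustive scan.
    """
    s = min_separation
    size = 2 * s + 1
    win_max = ndimage.maximum_filter(smoothed, size=size, mode="nearest")
    win_min = ndimage.minimum_filter(smoothed, size=size, mode="nearest")
    cand = np.argwhere((smoothed >= win_max) & (win_min < smoothed))
    nrows, ncols = smoothed.shape
    peaks: list[tuple[int, int]] = []
    for r, c in cand:
        v = smoothed[r, c]
        r0, r1 = max(0, r - s), min(nrows, r + s + 1)
        c0, c1 = max(0, c - s), min(ncols, c + s + 1)
        block = smoothed[r0:r1, c0:c1]
        tie_rows, tie_cols = np.nonzero(block == v)
        first = (int(tie_rows[0]) + r0, int(tie_cols[0]) + c0)
        if first == (int(r), int(c)):
            peaks.append((int(r), int(c)))
    peaks.sort()
    return peaks


def detect_spots(
    image: np.ndarray,
    background: BackgroundMap | np.ndarray,
    params: DetectionParams = DetectionParams(),
    channel: str = "",
) -> list[Spot]:
    """Detect spots in a projected plane and keep those with S/B > threshold.

    Returns spots sorted by (y, x). Candidates whose background estimate is
    zero cannot be ratio-scored and are dropped with a warning.
    """
    image = np.asarray(image)
    bg = background.values if isinstance(background, BackgroundMap) else np.asarray(background)
    if image.shape != bg.shape:
        raise ValueError(
            f"image shape {image.shape} != background shape {bg.shape}"
        )
    work = image.astype(np.float64)
    if params.smoothing_sigma > 0:
        work = ndimage.gaussian_filter(work, params.smoothing_sigma, mode="nearest")
    spots: list[Spot] = []
    n_zero_bg = 0
    for r, c in local_maxima(work, params.min_separation):
        peak = float(image[r, c])
        b = float(bg[r, c])
        if b <= 0:
            n_zero_bg += 1
            continue
        ratio = peak / b
        if ratio > params.min_sb_ratio:
            spots.append(
                Spot(x=c, y=r, channel=channel, peak=peak, background=b, sb_ratio=ratio)
            )
    if n_zero_bg:
        logger.warning(
            "%d candidate spot(s) dropped: zero local background", n_zero_bg
        )
    return spots


def filter_spots(spots: list[Spot], min_sb_ratio: float) -> list[Spot]:
    """Subset of spots with sb_ratio strictly greater than the threshold."""
    return [s for s in spots if s.sb_ratio > min_sb_ratio]


def spots_to_records(spots: list[Spot]) -> list[dict]:
    return [
        {
            "x": s.x,
            "y": s.y,
            "channel": s.channel,
            "peak": s.peak,
            "background": s.background,
            "sb_ratio": s.sb_ratio,
            "unspecific": s.unspecific,
            "allele": s.allele if s.allele is not None else "",
            "region": s.region if s.region is not None else -1,
            "field": s.field if s.field is not None else -1,
        }
        for s in spots
    ]


def spots_from_records(records) -> list[Spot]:
    out = []
    for rec in records:
        allele = rec.get("allele", "")
        region = int(rec.get("region", -1))
        fld = int(rec.get("field", -1))
        out.append(
            Spot(
                x=int(rec["x"]),
                y=int(rec["y"]),
                channel=str(rec["channel"]),
                peak=float(rec["peak"]),
                background=float(rec["background"]),
                sb_ratio=float(rec["sb_ratio"]),
                unspecific=bool(rec.get("unspecific", False)),
                allele=allele if allele not in ("", None) and allele == allele else None,
                region=region if region >= 0 else None,
                field=fld if fld >= 0 else None,
            )
        )
    return out


def write_spots_csv(path, spots: list[Spot]) -> None:
    import pandas as pd

    pd.DataFrame(
        spots_to_records(spots),
        columns=[
            "x", "y", "channel", "peak", "background", "sb_ratio",
            "unspecific", "allele", "region", "field",
        ],
    ).to_csv(path, index=False)


def read_spots_csv(path) -> list[Spot]:
    import pandas as pd

    df = pd.read_csv(path, keep_default_na=False)
    return spots_from_records(df.to_dict("records"))
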