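"""Image stack handling: TIFF I/O, maximum-intensity projection, background maps.

The quantities downstream of this module are ratios of raw pixel intensities,
so nothing here rescales, clips or otherwise "enhances" the data: display
adjustments (brightness/contrast) are a presentation concern and must never
enter the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import footprint_rectangle

CHANNEL_CLASSES = ("nuclear", "wildtype", "mutant", "control")


@dataclass
class ChannelStack:
    """One fluorescence channel: a (n_z, rows, cols) stack plus metadata.

    ``channel_class`` says what the fluorophore reports: the nuclear
    counterstain (DAPI), the wild-type or mutant detection probe, or the
    assay-positive control probe.
    """

    name: str
    channel_class: str
    data: np.ndarray  # (n_z, rows, cols); 2-D input is promoted to n_z=1
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(
                f"channel {self.name!r}: expected a 2-D plane or 3-D z-stack, "
                f"got shape {self.data.shape}"
            )
        if self.channel_class not in CHANNEL_CLASSES:
            raise ValueError(
                f"channel class {self.channel_class!r} not in {CHANNEL_CLASSES}"
            )
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError(f"channel {self.name!r}: negative intensities")

    @property
    def n_z(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class BackgroundMap:
    """Per-pixel local background estimate for one projected channel plane."""

    values: np.ndarray
    estimator: str = "windowed_median"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("background map must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("background map has negative values")


def max_intensity_project(stack: ChannelStack | np.ndarray) -> np.ndarray:
    """Collapse a z-stack to one plane by per-pixel maximum (MIP).

    A single-plane stack is returned unchanged (as a 2-D view). Ensures
    every rolling-circle product is represented by its brightest pixel
    regardless of the focal plane it sits in.
    """
    data = stack.data if isinstance(stack, ChannelStack) else np.asarray(stack)
    if data.ndim == 2:
        return data
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError(f"expected a non-empty z-stack, got shape {data.shape}")
    if data.shape[0] == 1:
        return data[0]
    return data.max(axis=0)


def estimate_background(image: np.ndarray, window: int = 31) -> BackgroundMap:
    """Windowed-median background map of a projected plane.

    Each output pixel is the median of the ``window``×``window`` neighborhood
    (reflection-padded at edges). The median is robust to the sparse,
    diffraction-limited spots themselves, so the map tracks tissue
    autofluorescence rather than signal.

    For unsigned-integer images a sliding-histogram rank filter is used; it is
    exact (odd window ⇒ the median is an element of the window) and fast at
    desk-scale windows. Float images go through ``scipy.ndimage.median_filter``.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("background estimation expects a 2-D image")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > min(image.shape):
        raise ValueError(
            f"window {window} exceeds image extent {min(image.shape)}"
        )
    if image.dtype == np.uint8 or image.dtype == np.uint16:
        pad = window // 2
        padded = np.pad(image, pad, mode="reflect")
        fp = footprint_rectangle((window, window))
        med = rank.median(padded, footprint=fp)
        values = med[pad:-pad, pad:-pad]
    else:
        # scipy "mirror" == numpy pad "reflect": edge pixel not repeated
        values = ndimage.median_filter(image, size=window, mode="mirror")
    return BackgroundMap(
        values=values, estimator="windowed_median", params={"window": window}
    )


def write_stack(path, stack: ChannelStack) -> None:
    """Write a channel stack as a (multi-page) TIFF."""
    tifffile.imwrite(path, stack.data, photometric="minisblack")


def read_stack(path, name: str, channel_class: str) -> ChannelStack:
    """Read a 2-D or multi-page TIFF as a ChannelStack."""
    data = tifffile.imread(path)
    return ChannelStack(name=name, channel_class=channel_class, data=data)


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)
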