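"""Image-side data preparation: frame selection, cropping, size filtering.

Raw video frames are reduced to one frame per second by Laplacian-variance
sharpness scoring; head crops arrive as externally supplied bounding
boxes (see :data:`DETECTOR_CONTRACT`) and undersized crops are removed.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Plug-in contract for users who have a wheat-head detector: any callable
#: ``detect(image: ndarray) -> list[CropBox]`` may replace the manifest boxes.
DETECTOR_CONTRACT = "detect(image) -> list[CropBox]"

# Rec. 601 luminance weights for colour -> intensity conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel box [x0, x1) x [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValidationError(f"degenerate crop box {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass
class HeadImage:
    """A cropped head image with its provenance."""

    pixels: np.ndarray
    source_id: str
    capture_date: dt.date | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError("head image must be 2-D or 3-channel")
        if self.width < 1 or self.height < 1:
            raise ValidationError("empty head image")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FrameSet:
    """Ordered video frames and their frame rate."""

    frames: list[np.ndarray]
    fps: int

    def __post_init__(self):
        if self.fps < 1:
            raise ValidationError(f"fps must be >= 1, got {self.fps}")
        if self.frames:
            shape = self.frames[0].shape
            if any(f.shape != shape for f in self.frames):
                raise ValidationError("frames differ in shape")


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of a colour image; 2-D images pass through."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        return image @ _LUMA
    return image


def laplacian_variance(image: np.ndarray) -> float:
    """Sharpness score: variance of the 4-neighbour Laplacian response.

    Kernel [[0,1,0],[1,-4,1],[0,1,0]] applied over valid interior pixels
    only; constant images score 0 and the score is invariant to additive
    intensity shifts.
    """
    img = to_luminance(image)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValidationError(
            f"image {img.shape} smaller than the 3x3 Laplacian kernel"
        )
    lap = (
        img[:-2, 1:-1]
        + img[2:, 1:-1]
        + img[1:-1, :-2]
        + img[1:-1, 2:]
        - 4.0 * img[1:-1, 1:-1]
    )
    return float(lap.var())


def select_clearest_per_second(frames: FrameSet) -> list[np.ndarray]:
    """Keep the sharpest frame of each second (earliest frame wins ties)."""
    if not frames.frames:
        raise ValidationError("empty frame set")
    selected = []
    for start in range(0, len(frames.frames), frames.fps):
        group = frames.frames[start : start + frames.fps]
        scores = [laplacian_variance(f) for f in group]
        selected.append(group[int(np.argmax(scores))])
    return selected


def crop_head(
    image: np.ndarray,
    box: CropBox,
    source_id: str = "",
    capture_date: dt.date | None = None,
) -> HeadImage:
    """Pixel-exact sub-array extraction."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if box.x0 < 0 or box.y0 < 0 or box.x1 > w or box.y1 > h:
        raise ValidationError(f"crop box {box} outside image of size {w}x{h}")
    return HeadImage(
        image[box.y0 : box.y1, box.x0 : box.x1],
        source_id=source_id,
        capture_date=capture_date,
    )


def filter_small_crops(
    crops: list[HeadImage], min_w: int = 20, min_h: int = 50
) -> list[HeadImage]:
    """Drop crops strictly smaller than min_w x min_h on either dimension.

    Equality survives: the rule removes images *smaller than* the
    threshold, so a 20x50 crop is kept.
    """
    kept = [c for c in crops if c.width >= min_w and c.height >= min_h]
    removed = len(crops) - len(kept)
    if removed:
        logger.info("filter_small_crops removed %d of %d crops", removed, len(crops))
    return kept
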