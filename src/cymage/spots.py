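"""First-frame spot detection into fixed 7x7 AOIs and number density.

Detection follows the study's rule: on the background-subtracted first
frame, pixels at or above an intensity threshold (grayscale units) form
8-connected components; components within an area window become areas of
interest (AOIs) — fixed odd-sized square windows centered on the
intensity-weighted centroid rounded to the nearest pixel.  Centroids closer
than a minimum separation are merged keeping the brightest; windows that
would leave the frame are discarded.  Density is the AOI count per µm² of
membrane, aggregated per movie -> per oocyte -> pooled mean +/- s.e.m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from cymage.quantify import MeanSem, mean_sem

#: Detection-threshold presets: midpoints of the per-channel grayscale
#: ranges used on background-subtracted images (Cy3 150-190, Cy5 130-150).
CY3_THRESHOLD = 170.0
CY5_THRESHOLD = 140.0


@dataclass(frozen=True)
class DetectionParams:
    intensity_threshold: float = CY3_THRESHOLD
    area_min: int = 2
    area_max: int = 49
    aoi_size: int = 7
    min_separation: float = 4.0

    def __post_init__(self) -> None:
        if self.intensity_threshold <= 0:
            raise ValueError("intensity_threshold must be > 0")
        if self.aoi_size < 3 or self.aoi_size % 2 == 0:
            raise ValueError("aoi_size must be odd and >= 3")
        if self.area_min > self.area_max:
            raise ValueError("area_min must be <= area_max")


@dataclass(frozen=True)
class AOI:
    """A detected spot: center pixel of a fixed square window."""

    row: int
    col: int
    channel: str = "Cy3"
    id: int = 0
    aoi_size: int = 7
    area: int = 0
    peak_intensity: float = 0.0

    @property
    def half(self) -> int:
        return self.aoi_size // 2

    def slices(self) -> tuple[slice, slice]:
        h = self.half
        return slice(self.row - h, self.row + h + 1), slice(self.col - h, self.col + h + 1)


def detect_spots(
    first_frame: np.ndarray,
    params: DetectionParams = DetectionParams(),
    channel: str = "Cy3",
) -> list[AOI]:
    """Detect spots on a background-subtracted frame.

    Deterministic: AOIs are ordered by (row, col) and ids assigned in that
    order.
    """
    frame = np.asarray(first_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("first_frame must be 2-D")
    mask = frame >= params.intensity_threshold
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndi.sum_labels(mask, labels, idx)
    keep = (areas >= params.area_min) & (areas <= params.area_max)
    cands = []
    for lab, area in zip(idx[keep], areas[keep]):
        ys, xs = np.nonzero(labels == lab)
        wts = frame[ys, xs]
        # floor(x + 0.5), not banker's rounding: keeps detection
        # translation-equivariant when centroids land exactly on .5
        r = int(np.floor(np.average(ys, weights=wts) + 0.5))
        c = int(np.floor(np.average(xs, weights=wts) + 0.5))
        cands.append((r, c, int(area), float(wts.max())))

    # merge candidates closer than min_separation, keeping the brightest
    cands.sort(key=lambda t: -t[3])
    kept: list[tuple[int, int, int, float]] = []
    for cand in cands:
        if all(
            max(abs(cand[0] - k[0]), abs(cand[1] - k[1])) >= params.min_separation
            for k in kept
        ):
            kept.append(cand)

    h = params.aoi_size // 2
    H, W = frame.shape
    kept = [k for k in kept if h <= k[0] < H - h and h <= k[1] < W - h]
    kept.sort(key=lambda t: (t[0], t[1]))
    return [
        AOI(row=r, col=c, channel=channel, id=i, aoi_size=params.aoi_size,
            area=a, peak_intensity=p)
        for i, (r, c, a, p) in enumerate(kept)
    ]


def spot_density(
    aois: Sequence[AOI] | int,
    shape: tuple[int, int],
    pixel_size: float,
    aoi_size: int | None = None,
) -> float:
    """Spots per µm²: count / (H * W * pixel_size^2).

    Passing ``aoi_size`` restricts the denominator to the region where an
    AOI window fits, (H - s + 1)(W - s + 1) pixels: spots nearer than
    s // 2 to the border cannot be counted, so the full-frame denominator
    underestimates the density (edge correction).
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("frame dimensions must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    count = aois if isinstance(aois, int) else len(aois)
    if aoi_size is not None:
        h, w = h - aoi_size + 1, w - aoi_size + 1
        if h <= 0 or w <= 0:
            raise ValueError("aoi_size too large for frame")
    return count / (h * w * pixel_size**2)


def density_summary(per_movie: pd.DataFrame) -> MeanSem:
    """Pool per-movie densities hierarchically by oocyte.

    ``per_movie`` needs columns ``oocyte`` and ``density``; each oocyte's
    movies are averaged first, then pooled across oocytes.
    """
    groups: Iterable = (g["density"].to_numpy() for _, g in per_movie.groupby("oocyte"))
    return mean_sem(groups)


def aois_to_frame(aois: Sequence[AOI]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(id=a.id, channel=a.channel, row=a.row, col=a.col,
                 area=a.area, peak_intensity=a.peak_intensity)
            for a in aois
        ],
        columns=["id", "channel", "row", "col", "area", "peak_intensity"],
    )
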