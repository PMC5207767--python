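"""Two-channel colocalization with a 90-degree-rotation random null.

Cy5 AOIs are mapped onto the Cy3 field by a translation (the inter-channel
registration offset, ~1-2 px); a Cy5 spot counts as colocalized when at
least one Cy3 AOI center lies within a Chebyshev (square-window) distance
tolerance — square windows match the square AOIs, and the default tolerance
of 2 px covers the stated mapping error.  The colocalized fraction is the
proportion of (in-frame) Cy5 spots, aggregated per frame -> per oocyte ->
pooled mean +/- s.e.m.

The random-colocalization null rotates the Cy5 coordinates 90 degrees about
the image center (within the largest centered square for non-square frames)
and re-scores: rotation preserves the point pattern's density and internal
structure while destroying any true cross-channel correspondence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from cymage.quantify import MeanSem, mean_sem


def map_aois(
    coords: np.ndarray,
    registration_offset: tuple[float, float],
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Translate Cy5 coordinates into the Cy3 field.

    Returns ``(mapped, in_frame)``: the translated (n, 2) coordinates and a
    boolean mask of points inside ``shape`` (all True when no shape given).
    Out-of-frame points must be excluded from the colocalization
    denominator.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 2)
    off = np.asarray(registration_offset, dtype=float)
    if not np.isfinite(off).all():
        raise ValueError("registration offset must be finite")
    mapped = pts + off[None, :]
    if shape is None:
        in_frame = np.ones(len(mapped), dtype=bool)
    else:
        h, w = shape
        in_frame = (
            (mapped[:, 0] >= 0) & (mapped[:, 0] < h)
            & (mapped[:, 1] >= 0) & (mapped[:, 1] < w)
        )
    return mapped, in_frame


@dataclass
class FrameColoc:
    n_cy5: int
    n_colocalized: int

    @property
    def fraction(self) -> float:
        if self.n_cy5 == 0:
            return float("nan")
        return self.n_colocalized / self.n_cy5


def colocalized_fraction(
    cy5_coords_mapped: np.ndarray,
    cy3_coords: np.ndarray,
    tolerance: float = 2.0,
) -> FrameColoc:
    """Score one frame: Cy5 spots with a Cy3 center within the tolerance.

    Chebyshev distance; one Cy3 spot may validate several Cy5 spots (no
    exclusive matching).  With no Cy5 spots the fraction is NaN and the
    frame must be excluded from averaging (a warning is emitted).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    cy5 = np.asarray(cy5_coords_mapped, dtype=float).reshape(-1, 2)
    cy3 = np.asarray(cy3_coords, dtype=float).reshape(-1, 2)
    if cy5.shape[0] == 0:
        warnings.warn("no Cy5 spots in frame; fraction undefined", stacklevel=2)
        return FrameColoc(0, 0)
    if cy3.shape[0] == 0:
        return FrameColoc(cy5.shape[0], 0)
    d = np.abs(cy5[:, None, :] - cy3[None, :, :]).max(axis=2)
    hit = (d <= tolerance).any(axis=1)
    return FrameColoc(int(cy5.shape[0]), int(hit.sum()))


def rotation_null(coords: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rotate coordinates 90 degrees about the center of the frame.

    (row, col) -> (col, S-1-row) within the largest centered square of side
    ``S = min(shape)``; points outside that square are dropped (for square
    frames nothing is dropped).  The map is an isometry, so four
    applications return the original points.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 2)
    h, w = shape
    s = min(h, w)
    r0 = (h - s) / 2.0
    c0 = (w - s) / 2.0
    local = pts - np.array([r0, c0])
    inside = (
        (local[:, 0] >= 0) & (local[:, 0] <= s - 1)
        & (local[:, 1] >= 0) & (local[:, 1] <= s - 1)
    )
    local = local[inside]
    rotated = np.column_stack([local[:, 1], (s - 1) - local[:, 0]])
    return rotated + np.array([r0, c0])


@dataclass
class ColocResult:
    """Observed and null colocalization, pooled hierarchically."""

    observed: MeanSem
    null: MeanSem
    n_cy5: int
    n_colocalized: int

    @property
    def corrected(self) -> float:
        """Null-subtracted colocalized fraction."""
        return self.observed.mean - self.null.mean


def score_movies(
    per_movie: list[dict],
    tolerance: float = 2.0,
) -> ColocResult:
    """Score a set of movies and pool per oocyte.

    Each entry needs keys ``oocyte``, ``cy5_coords`` (already mapped into
    the Cy3 field), ``cy3_coords`` and ``shape``.  The observed and the
    rotation-null fractions are computed per movie (frame), averaged per
    oocyte, then pooled.
    """
    obs: dict[object, list[float]] = {}
    nul: dict[object, list[float]] = {}
    tot5 = totc = 0
    for m in per_movie:
        fc = colocalized_fraction(m["cy5_coords"], m["cy3_coords"], tolerance)
        tot5 += fc.n_cy5
        totc += fc.n_colocalized
        rot = rotation_null(m["cy5_coords"], m["shape"])
        fn = colocalized_fraction(rot, m["cy3_coords"], tolerance) if len(rot) else FrameColoc(0, 0)
        if fc.n_cy5 > 0:
            obs.setdefault(m["oocyte"], []).append(fc.fraction)
        if fn.n_cy5 > 0:
            nul.setdefault(m["oocyte"], []).append(fn.fraction)
    if not obs:
        raise ValueError("no movie had Cy5 spots")
    return ColocResult(
        observed=mean_sem(obs.values()),
        null=mean_sem(nul.values()) if nul else MeanSem(float("nan"), float("nan"), 0),
        n_cy5=tot5,
        n_colocalized=totc,
    )


def estimate_registration_offset(
    cy5_coords: np.ndarray,
    cy3_coords: np.ndarray,
    shape: tuple[int, int],
    max_shift: int = 5,
) -> tuple[int, int]:
    """Integer offset mapping Cy5 onto Cy3 by spot-map cross-correlation.

    Bins both point sets into binary images, cross-correlates, and returns
    the (d_row, d_col) within ``max_shift`` maximizing overlap, i.e. the
    shift to add to Cy3 coordinates to land on Cy5 (the generator's
    registration offset convention).
    """
    h, w = shape

    def binmap(coords: np.ndarray) -> np.ndarray:
        img = np.zeros((h, w))
        c = np.asarray(coords, dtype=float).reshape(-1, 2)
        rr = np.clip(np.round(c[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(c[:, 1]).astype(int), 0, w - 1)
        img[rr, cc] = 1.0
        return img

    corr = signal.fftconvolve(binmap(cy5_coords), binmap(cy3_coords)[::-1, ::-1], mode="full")
    center = (h - 1, w - 1)
    window = corr[
        center[0] - max_shift : center[0] + max_shift + 1,
        center[1] - max_shift : center[1] + max_shift + 1,
    ]
    k = np.unravel_index(int(np.argmax(window)), window.shape)
    return (int(k[0] - max_shift), int(k[1] - max_shift))
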