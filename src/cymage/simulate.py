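"""Synthetic two-channel TIRF movies with known ground truth.

Emulates single-molecule imaging of dye-labelled membrane proteins on an
EMCCD: sparse diffraction-limited spots placed by a homogeneous Poisson
process, 1-5 fluorophores per spot bleaching step-wise with memoryless
(single-exponential) kinetics, a smooth planar background, Poisson shot
noise and Gaussian read noise, and two imperfectly registered channels
(Cy3 / Cy5, 1-2 px offset).  Presets mirror the encoded (amber-suppressed)
and mock (wild-type cRNA) experimental conditions.

All randomness flows from one master seed through deterministically spawned
child streams, so every artefact is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

CY3 = "Cy3"
CY5 = "Cy5"

#: Default physical pixel size (µm/px).  A plausible 60x EMCCD scale; the
#: choice is arbitrary and configurable everywhere it is used.
DEFAULT_PIXEL_SIZE = 0.2

#: Default intensity of one fluorophore (integrated AU over its PSF).
#: Chosen so that a single fluorophore's peak pixel (~0.12 of the total at
#: psf_sigma 1.1 px) sits clearly above the Cy3/Cy5 detection thresholds
#: (130-190 grayscale units) after background subtraction, with its
#: 4-neighbour pixels above threshold as well.
DEFAULT_UNIT_INTENSITY = 2400.0


@dataclass(frozen=True)
class Spot:
    """One ground-truth spot: position, label count and bleach schedule."""

    row: float
    col: float
    n_fluorophores: int
    channel: str
    bleach_frames: tuple[int, ...]
    unit_intensity: float = DEFAULT_UNIT_INTENSITY

    def alive_counts(self, n_frames: int) -> np.ndarray:
        """Number of unbleached fluorophores at each frame 0..n_frames-1."""
        frames = np.arange(n_frames)
        b = np.asarray(self.bleach_frames)
        return (frames[:, None] < b[None, :]).sum(axis=1) if b.size else np.zeros(n_frames, int)


@dataclass
class SpotField:
    """Ground-truth spot list for one channel of one movie."""

    spots: list[Spot]
    field_height: int
    field_width: int
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        if self.field_height <= 0 or self.field_width <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for s in self.spots:
            if not (0 <= s.row < self.field_height and 0 <= s.col < self.field_width):
                raise ValueError(f"spot at ({s.row}, {s.col}) outside field")
            if len(s.bleach_frames) != s.n_fluorophores:
                raise ValueError("one bleach time per fluorophore required")

    @property
    def area_um2(self) -> float:
        return self.field_height * self.field_width * self.pixel_size**2

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (row, col) positions."""
        return np.array([[s.row, s.col] for s in self.spots]).reshape(-1, 2)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD-like imaging model: PSF width, background plane and noise.

    The default PSF width (0.65 px = 130 nm at 0.2 µm/px) corresponds to
    the Gaussian approximation of the Airy pattern for a high-NA TIRF
    objective (sigma ~ 0.21 lambda/NA).
    """

    psf_sigma: float = 0.65
    background_offset: float = 100.0
    background_gradient: tuple[float, float] = (0.05, 0.08)
    read_noise_sd: float = 3.0
    gain: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be nonnegative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def background_plane(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        gr, gc = self.background_gradient
        return self.background_offset + gr * rows + gc * cols


@dataclass(frozen=True)
class ConditionSpec:
    """Parameters of one experimental condition.

    Densities are spots/µm²; ``colocalized_fraction`` is the fraction of
    Cy5 spots that share a position with a Cy3 spot (displaced by the
    channel registration offset); ``fluor_count_distribution[k]`` is the
    probability of k+1 fluorophores per spot; ``bleach_rate`` is the
    per-fluorophore exponential bleaching rate (1/s).
    """

    condition: str
    density_cy3: float
    density_cy5: float
    colocalized_fraction: float
    fluor_count_distribution: tuple[float, ...]
    bleach_rate: float = 0.03
    registration_offset: tuple[int, int] = (1, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_cy3 < 0 or self.density_cy5 < 0:
            raise ValueError("densities must be nonnegative")
        if not (0 <= self.colocalized_fraction <= 1):
            raise ValueError("colocalized_fraction must be in [0, 1]")
        p = np.asarray(self.fluor_count_distribution, dtype=float)
        if p.size == 0 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("fluor_count_distribution must be a probability vector")
        if self.bleach_rate <= 0:
            raise ValueError("bleach_rate must be positive")
        if any(abs(d) > 3 for d in self.registration_offset):
            raise ValueError("registration offset components must be <= 3 px")


def encoded_preset(seed: int = 0, **overrides) -> ConditionSpec:
    """Amber-suppressed condition: dense spots, multi-step distribution.

    Densities follow the reported 0.14 (Cy3) and 0.08 (Cy5) spots/µm²; the
    fluorophore-count distribution is shifted towards 2+ with occasional
    4- and 5-label spots; the true dual-colour fraction follows the
    reported ~14% Cy5-with-Cy3 colocalization.
    """
    kw = dict(
        condition="encoded",
        density_cy3=0.14,
        density_cy5=0.08,
        colocalized_fraction=0.14,
        fluor_count_distribution=(0.35, 0.30, 0.20, 0.10, 0.05),
        seed=seed,
    )
    kw.update(overrides)
    return ConditionSpec(**kw)


def mock_preset(seed: int = 0, **overrides) -> ConditionSpec:
    """Wild-type-cRNA control: sparse spots, single-step dominated."""
    kw = dict(
        condition="mock",
        density_cy3=0.03,
        density_cy5=0.02,
        colocalized_fraction=0.0,
        fluor_count_distribution=(0.85, 0.12, 0.03),
        seed=seed,
    )
    kw.update(overrides)
    return ConditionSpec(**kw)


PRESETS = {"encoded": encoded_preset, "mock": mock_preset}


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_bleach_frames(
    rng: np.random.Generator, n: int, bleach_rate: float, frame_interval: float
) -> tuple[int, ...]:
    # Exposure starts the bleaching clock: every fluorophore is alive in
    # frame 0 (the detection frame); the earliest observable step is frame 1.
    t = rng.exponential(1.0 / bleach_rate, size=n)
    return tuple(sorted(1 + int(np.floor(ti / frame_interval)) for ti in t))


def simulate_spot_field(
    spec: ConditionSpec,
    shape: tuple[int, int],
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = 1.0,
    unit_intensity: float = DEFAULT_UNIT_INTENSITY,
    rng: np.random.Generator | None = None,
) -> tuple[SpotField, SpotField, list[tuple[int, int]]]:
    """Draw ground truth for both channels of one movie.

    Spot counts are Poisson(density x area) per channel with uniform
    positions.  A Binomial(n_cy5, colocalized_fraction) subset of Cy5 spots
    is instead placed on distinct Cy3 positions displaced by the
    registration offset (capped at the number of Cy3 spots).  Returns
    ``(cy3_field, cy5_field, pairs)`` where ``pairs`` lists truly
    colocalized ``(cy3_index, cy5_index)``.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("field must have positive area")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(spec.seed))
    area = h * w * pixel_size**2
    p = np.asarray(spec.fluor_count_distribution)

    def draw_spots(n: int, channel: str, positions: np.ndarray) -> list[Spot]:
        counts = rng.choice(np.arange(1, p.size + 1), size=n, p=p)
        return [
            Spot(
                row=float(positions[i, 0]),
                col=float(positions[i, 1]),
                n_fluorophores=int(counts[i]),
                channel=channel,
                bleach_frames=_draw_bleach_frames(
                    rng, int(counts[i]), spec.bleach_rate, frame_interval
                ),
                unit_intensity=unit_intensity,
            )
            for i in range(n)
        ]

    n_cy3 = rng.poisson(spec.density_cy3 * area)
    pos_cy3 = np.column_stack([rng.uniform(0, h, n_cy3), rng.uniform(0, w, n_cy3)])
    cy3_spots = draw_spots(n_cy3, CY3, pos_cy3)

    n_cy5 = rng.poisson(spec.density_cy5 * area)
    n_pair = min(rng.binomial(n_cy5, spec.colocalized_fraction), n_cy3)
    partners = rng.choice(n_cy3, size=n_pair, replace=False) if n_pair else np.array([], int)
    d_row, d_col = spec.registration_offset
    pos_cy5 = np.column_stack([rng.uniform(0, h, n_cy5), rng.uniform(0, w, n_cy5)])
    pairs: list[tuple[int, int]] = []
    for j, i3 in enumerate(partners):
        # Cy5 coordinates live in the Cy5 field: Cy3 position plus the
        # inter-channel registration offset, clipped to stay in bounds.
        r = min(max(pos_cy3[i3, 0] + d_row, 0.0), h - 1e-9)
        c = min(max(pos_cy3[i3, 1] + d_col, 0.0), w - 1e-9)
        pos_cy5[j] = (r, c)
        pairs.append((int(i3), j))
    cy5_spots = draw_spots(n_cy5, CY5, pos_cy5)

    cy3 = SpotField(cy3_spots, h, w, pixel_size)
    cy5 = SpotField(cy5_spots, h, w, pixel_size)
    return cy3, cy5, pairs


def simulate_bleach_trace(
    n_fluorophores: int,
    unit_intensity: float,
    bleach_frames: Sequence[int],
    n_frames: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    blink_prob: float = 0.0,
) -> tuple[np.ndarray, list[int]]:
    """Idealized integrated-intensity trace with known step times.

    The noiseless signal starts at ``n * unit_intensity`` and drops by one
    unit at each bleach frame, reaching 0 after the last.  Additive Gaussian
    noise of ``noise_sd`` is applied.  ``blink_prob`` is the per-frame
    probability that one live fluorophore visits a reversible one-frame dark
    state (a transient down-up excursion); off by default.  Returns
    ``(values, true_steps)`` where ``true_steps`` lists the bleach frames
    that fall inside the trace.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if len(bleach_frames) != n_fluorophores:
        raise ValueError("one bleach frame per fluorophore required")
    frames = np.arange(n_frames)
    b = np.asarray(bleach_frames)
    alive = (frames[:, None] < b[None, :]).sum(axis=1) if b.size else np.zeros(n_frames, int)
    alive = alive.astype(float)
    if blink_prob > 0:
        if rng is None:
            rng = np.random.default_rng()
        dark = (rng.random(n_frames) < blink_prob) & (alive > 0)
        alive = alive - dark
    values = alive * unit_intensity
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0, noise_sd, n_frames)
    true_steps = sorted(int(t) for t in b if 1 <= t <= n_frames - 1)
    return values.astype(float), true_steps


def _psf_patch(psf_sigma: float, radius: int) -> np.ndarray:
    """Pixel-integrated unit-mass Gaussian on a (2r+1)^2 patch."""
    edges = np.arange(-radius, radius + 2) - 0.5
    cdf = 0.5 * (1 + special.erf(edges / (psf_sigma * np.sqrt(2))))
    mass_1d = np.diff(cdf)
    return np.outer(mass_1d, mass_1d)


@dataclass
class RenderedMovie:
    frames: np.ndarray  # T x H x W uint16
    saturated: bool
    expected: np.ndarray  # noiseless expectation, float


def render_movie(
    field: SpotField,
    camera: CameraModel,
    n_frames: int,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> RenderedMovie:
    """Render a spot field into a 16-bit movie.

    Each live fluorophore contributes a pixel-integrated 2-D Gaussian of its
    unit intensity; the background is a planar ramp; per-pixel Poisson shot
    noise (scaled by gain) plus Gaussian read noise is applied when
    ``noise`` is on.  Output values are clipped to the 16-bit range and the
    clipping is flagged.
    """
    h, w = field.field_height, field.field_width
    if camera.psf_sigma >= min(h, w):
        raise ValueError("psf_sigma must be smaller than the field")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    patch_r = max(3, int(np.ceil(4 * camera.psf_sigma)))
    expected = np.tile(camera.background_plane((h, w)), (n_frames, 1, 1))

    for spot in field.spots:
        r0, c0 = int(round(spot.row)), int(round(spot.col))
        frac_r, frac_c = spot.row - r0, spot.col - c0
        # shift the patch grid by the sub-pixel remainder
        edges = np.arange(-patch_r, patch_r + 2) - 0.5
        cdf_r = 0.5 * (1 + special.erf((edges - frac_r) / (camera.psf_sigma * np.sqrt(2))))
        cdf_c = 0.5 * (1 + special.erf((edges - frac_c) / (camera.psf_sigma * np.sqrt(2))))
        patch = np.outer(np.diff(cdf_r), np.diff(cdf_c))
        rlo, rhi = max(0, r0 - patch_r), min(h, r0 + patch_r + 1)
        clo, chi = max(0, c0 - patch_r), min(w, c0 + patch_r + 1)
        sub = patch[rlo - (r0 - patch_r) : rhi - (r0 - patch_r),
                    clo - (c0 - patch_r) : chi - (c0 - patch_r)]
        alive = spot.alive_counts(n_frames).astype(float) * spot.unit_intensity
        expected[:, rlo:rhi, clo:chi] += alive[:, None, None] * sub[None, :, :]

    if noise:
        photons = rng.poisson(expected / camera.gain)
        out = photons * camera.gain + rng.normal(0, camera.read_noise_sd, expected.shape)
    else:
        out = expected.copy()
    saturated = bool((out > 65535).any())
    frames = np.clip(np.round(out), 0, 65535).astype(np.uint16)
    return RenderedMovie(frames, saturated, expected)


def make_condition_dataset(
    spec: ConditionSpec,
    camera: CameraModel = CameraModel(),
    shape: tuple[int, int] = (128, 128),
    n_frames: int = 100,
    out_dir: str | Path = ".",
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> dict[str, Path]:
    """Write a full two-channel synthetic dataset to ``out_dir``.

    Produces ``cy3.tif`` / ``cy5.tif`` stacks plus ground-truth tables:
    ``spots.csv`` (positions, label counts), ``traces.csv`` (per-fluorophore
    bleach frames), ``pairs.csv`` (truly colocalized index pairs) and
    ``metadata.json``.  Identical seeds produce identical files.
    """
    from cymage import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_field, rng_cy3, rng_cy5 = _child_rngs(spec.seed, 3)
    cy3, cy5, pairs = simulate_spot_field(
        spec, shape, pixel_size, camera.frame_interval, rng=rng_field
    )
    paths: dict[str, Path] = {}
    for name, fld, rng in ((CY3, cy3, rng_cy3), (CY5, cy5, rng_cy5)):
        movie = render_movie(fld, camera, n_frames, rng=rng)
        p = out / f"{name.lower()}.tif"
        cio.write_stack(p, movie.frames)
        paths[name] = p

    rows = []
    for name, fld in ((CY3, cy3), (CY5, cy5)):
        for i, s in enumerate(fld.spots):
            rows.append(
                dict(channel=name, index=i, row=s.row, col=s.col,
                     n_fluorophores=s.n_fluorophores, unit_intensity=s.unit_intensity)
            )
    pd.DataFrame(rows).to_csv(out / "spots.csv", index=False)
    paths["spots"] = out / "spots.csv"

    trows = []
    for name, fld in ((CY3, cy3), (CY5, cy5)):
        for i, s in enumerate(fld.spots):
            for b in s.bleach_frames:
                trows.append(dict(channel=name, index=i, bleach_frame=b))
    pd.DataFrame(trows).to_csv(out / "traces.csv", index=False)
    paths["traces"] = out / "traces.csv"

    pd.DataFrame(pairs, columns=["cy3_index", "cy5_index"]).to_csv(
        out / "pairs.csv", index=False
    )
    paths["pairs"] = out / "pairs.csv"

    meta = dict(
        spec=dataclasses.asdict(spec),
        camera=dataclasses.asdict(camera),
        shape=list(shape),
        n_frames=n_frames,
        pixel_size=pixel_size,
    )
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    paths["metadata"] = out / "metadata.json"
    return paths
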