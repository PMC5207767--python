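"""End-to-end analysis: render/subtract/detect/trace/count/colocalize.

Convenience drivers that chain the modules the way the study's analysis
chained ImageJ and CoSMoS tooling: simulate (or load) two-channel movies,
rolling-ball-subtract, detect first-frame AOIs, extract integrated traces,
count bleach steps, and score Cy5-onto-Cy3 colocalization with the
rotation null.  Used by the tests, the acceptance script and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cymage import coloc, preprocess, simulate, spots, traces
from cymage.simulate import CY3, CY5, CameraModel, ConditionSpec


@dataclass
class ChannelAnalysis:
    channel: str
    aois: list[spots.AOI]
    stepfits: list[traces.StepFit]
    density: float
    n_true: int


@dataclass
class MovieAnalysis:
    oocyte: int
    movie: int
    channels: dict[str, ChannelAnalysis]
    cy5_mapped: np.ndarray
    shape: tuple[int, int]
    estimated_offset: tuple[int, int]


def analyze_movie(
    cy3_frames: np.ndarray,
    cy5_frames: np.ndarray,
    pixel_size: float,
    detection: dict[str, spots.DetectionParams] | None = None,
    step_params: traces.StepFitParams = traces.StepFitParams(),
    ball_radius: float = 50,
    oocyte: int = 0,
    movie: int = 0,
    registration_offset: tuple[int, int] | None = None,
) -> MovieAnalysis:
    """Run the full single-movie analysis on raw two-channel stacks.

    ``registration_offset`` is the known Cy3->Cy5 channel mapping (an
    instrument calibration); when None it is estimated per movie by
    cross-correlation of the detected spot maps — appropriate only when
    genuine cross-channel structure exists, since on independent channels
    the maximum over candidate shifts mines chance overlap.
    """
    if detection is None:
        detection = {
            CY3: spots.DetectionParams(spots.CY3_THRESHOLD),
            CY5: spots.DetectionParams(spots.CY5_THRESHOLD),
        }
    shape = cy3_frames.shape[1:]
    channels: dict[str, ChannelAnalysis] = {}
    corrected: dict[str, np.ndarray] = {}
    for name, raw in ((CY3, cy3_frames), (CY5, cy5_frames)):
        # unclipped residuals for quantitative traces; clipped view for the
        # threshold-based detection step
        sub = preprocess.subtract_stack(raw, radius=ball_radius, clip=False)
        corrected[name] = sub
        aois = spots.detect_spots(np.clip(sub[0], 0, None), detection[name], channel=name)
        fits = [
            traces.count_bleach_steps(
                traces.extract_trace(sub, a, local_background=True), params=step_params
            )
            for a in aois
        ]
        channels[name] = ChannelAnalysis(
            channel=name,
            aois=aois,
            stepfits=fits,
            density=spots.spot_density(aois, shape, pixel_size,
                                       aoi_size=detection[name].aoi_size),
            n_true=-1,
        )

    cy3_xy = np.array([[a.row, a.col] for a in channels[CY3].aois]).reshape(-1, 2)
    cy5_xy = np.array([[a.row, a.col] for a in channels[CY5].aois]).reshape(-1, 2)
    if registration_offset is not None:
        est = (int(registration_offset[0]), int(registration_offset[1]))
    elif len(cy3_xy) and len(cy5_xy):
        est = coloc.estimate_registration_offset(cy5_xy, cy3_xy, shape)
    else:
        est = (0, 0)
    mapped, in_frame = coloc.map_aois(cy5_xy, (-est[0], -est[1]), shape)
    return MovieAnalysis(
        oocyte=oocyte,
        movie=movie,
        channels=channels,
        cy5_mapped=mapped[in_frame],
        shape=shape,
        estimated_offset=est,
    )


@dataclass
class ConditionAnalysis:
    condition: str
    movies: list[MovieAnalysis]
    densities: pd.DataFrame  # oocyte, movie, channel, density, n_detected, n_true
    step_records: pd.DataFrame  # oocyte, movie, channel, n_steps (accepted)
    rejected: pd.DataFrame  # oocyte, movie, channel, reason
    coloc_result: coloc.ColocResult | None = None

    def step_histogram(self, channel: str, max_step: int | None = None) -> traces.StepHistogram:
        rec = self.step_records[self.step_records["channel"] == channel]
        return traces.aggregate_step_histogram(rec, self.condition, max_step)


def run_condition(
    spec: ConditionSpec,
    camera: CameraModel = CameraModel(),
    shape: tuple[int, int] = (128, 128),
    n_frames: int = 100,
    n_oocytes: int = 5,
    movies_per_oocyte: int = 2,
    pixel_size: float = simulate.DEFAULT_PIXEL_SIZE,
    detection: dict[str, spots.DetectionParams] | None = None,
    step_params: traces.StepFitParams = traces.StepFitParams(),
    ball_radius: float = 50,
    coloc_tolerance: float = 2.0,
) -> ConditionAnalysis:
    """Simulate and analyze a whole condition.

    Every oocyte contributes the same number of movies (the study used
    equal movie counts per condition).  All randomness derives from
    ``spec.seed``.
    """
    streams = simulate._child_rngs(spec.seed, n_oocytes * movies_per_oocyte * 3)
    movies: list[MovieAnalysis] = []
    drows, srows, rrows = [], [], []
    coloc_movies = []
    k = 0
    for oo in range(n_oocytes):
        for mv in range(movies_per_oocyte):
            rng_field, rng_c3, rng_c5 = streams[k : k + 3]
            k += 3
            cy3f, cy5f, _ = simulate.simulate_spot_field(
                spec, shape, pixel_size, camera.frame_interval, rng=rng_field
            )
            m3 = simulate.render_movie(cy3f, camera, n_frames, rng=rng_c3)
            m5 = simulate.render_movie(cy5f, camera, n_frames, rng=rng_c5)
            ma = analyze_movie(
                m3.frames.astype(float),
                m5.frames.astype(float),
                pixel_size,
                detection=detection,
                step_params=step_params,
                ball_radius=ball_radius,
                oocyte=oo,
                movie=mv,
                registration_offset=spec.registration_offset,
            )
            for name, fld in ((CY3, cy3f), (CY5, cy5f)):
                ch = ma.channels[name]
                ch.n_true = len(fld.spots)
                drows.append(
                    dict(oocyte=oo, movie=mv, channel=name, density=ch.density,
                         n_detected=len(ch.aois), n_true=len(fld.spots))
                )
                for fit in ch.stepfits:
                    if fit.accepted and fit.n_steps >= 1:
                        srows.append(dict(oocyte=oo, movie=mv, channel=name, n_steps=fit.n_steps))
                    elif not fit.accepted:
                        rrows.append(dict(oocyte=oo, movie=mv, channel=name, reason=fit.rejection_reason))
            cy3_xy = np.array([[a.row, a.col] for a in ma.channels[CY3].aois]).reshape(-1, 2)
            coloc_movies.append(dict(oocyte=oo, cy5_coords=ma.cy5_mapped, cy3_coords=cy3_xy, shape=shape))
            movies.append(ma)
    result = coloc.score_movies(coloc_movies, tolerance=coloc_tolerance)
    cols_d = ["oocyte", "movie", "channel", "density", "n_detected", "n_true"]
    cols_s = ["oocyte", "movie", "channel", "n_steps"]
    cols_r = ["oocyte", "movie", "channel", "reason"]
    return ConditionAnalysis(
        condition=spec.condition,
        movies=movies,
        densities=pd.DataFrame(drows, columns=cols_d),
        step_records=pd.DataFrame(srows, columns=cols_s),
        rejected=pd.DataFrame(rrows, columns=cols_r),
        coloc_result=result,
    )
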