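"""Closed-form quantifications and the statistics used throughout.

tRNA ligation (acylation) efficiency from paired absorbance readings,
percent-of-control luminescence, fold-over-background currents with
delta-method errors, decay-time-to-fraction kinetics for voltage-clamp
traces, the two-sample equal-variance t-test, and hierarchical
(per-oocyte) mean +/- s.e.m. aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

# Molar extinction coefficients (M^-1 cm^-1) used for acylation efficiency:
# the THG73 suppressor tRNA at 260 nm and the cyanine dyes at their
# absorbance peaks (550 nm for Cy3, 650 nm for Cy5).  LD550's coefficient is
# vendor-withheld and must be supplied by the caller.
EPS_THG73_RNA = 696_100.0
EPS_CY3 = 150_000.0
EPS_CY5 = 250_000.0

DYE_EXTINCTION = {"Cy3": EPS_CY3, "Cy5": EPS_CY5}
DYE_WAVELENGTH_NM = {"Cy3": 550, "LD550": 550, "Cy5": 650}


@dataclass(frozen=True)
class AbsorbanceMeasurement:
    """Paired absorbance readings of an acylated-tRNA pellet.

    ``A_rna`` is the 260 nm absorbance of the tRNA; ``A_dye`` the absorbance
    at the dye peak (550 nm for Cy3/LD550, 650 nm for Cy5).  Extinction
    coefficients default from the dye label; LD550 requires an explicit
    ``eps_dye``.
    """

    A_rna: float
    A_dye: float
    dye: str = "Cy3"
    eps_rna: float = EPS_THG73_RNA
    eps_dye: float | None = None

    def __post_init__(self) -> None:
        if self.A_rna < 0 or self.A_dye < 0:
            raise ValueError("absorbances must be nonnegative")
        if self.eps_rna <= 0:
            raise ValueError("eps_rna must be positive")
        eps = self.eps_dye
        if eps is None:
            if self.dye not in DYE_EXTINCTION:
                raise ValueError(
                    f"no default extinction coefficient for dye {self.dye!r}; "
                    "supply eps_dye explicitly"
                )
            eps = DYE_EXTINCTION[self.dye]
        if eps <= 0:
            raise ValueError("eps_dye must be positive")
        object.__setattr__(self, "eps_dye", eps)


def ligation_efficiency(m: AbsorbanceMeasurement) -> float:
    """Acylation (ligation) efficiency in percent.

    efficiency = A_dye * eps_RNA / (A_RNA * eps_dye) * 100, i.e. the molar
    ratio of dye to tRNA assuming Lambert-Beer.  Values above 100% are
    possible with measurement noise and are returned as-is.
    """
    if m.A_rna == 0:
        raise ValueError("A_rna must be > 0")
    return float(m.A_dye * m.eps_rna / (m.A_rna * m.eps_dye) * 100.0)


def percent_of_control(
    signal_mean: float, control_mean: float, ndigits: int | None = None
) -> float:
    """Signal as a percentage of a positive-control mean.

    Full precision is returned by default; pass ``ndigits=0`` to round for
    display (e.g. to the nearest percent).
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    pct = 100.0 * signal_mean / control_mean
    if ndigits is not None:
        pct = round(pct, ndigits)
    return float(pct)


@dataclass(frozen=True)
class FoldResult:
    fold: float
    sem: float
    n_test: int
    n_background: int


def fold_over_background(
    test_currents: Sequence[float], background_currents: Sequence[float]
) -> FoldResult:
    """Mean test current as a multiple of the mean background current.

    The standard error of the ratio is propagated by the delta method:
    Var(x/y) ~= (x/y)^2 (sem_x^2/x^2 + sem_y^2/y^2) for independent groups.
    """
    test = np.asarray(test_currents, dtype=float)
    bg = np.asarray(background_currents, dtype=float)
    if test.size == 0 or bg.size == 0:
        raise ValueError("both groups must be non-empty")
    mt, mb = test.mean(), bg.mean()
    if mb <= 0:
        raise ValueError("background mean must be > 0")
    fold = mt / mb
    sem_t = test.std(ddof=1) / math.sqrt(test.size) if test.size > 1 else 0.0
    sem_b = bg.std(ddof=1) / math.sqrt(bg.size) if bg.size > 1 else 0.0
    rel2 = 0.0
    if mt != 0:
        rel2 += (sem_t / mt) ** 2
    rel2 += (sem_b / mb) ** 2
    return FoldResult(float(fold), float(abs(fold) * math.sqrt(rel2)), test.size, bg.size)


@dataclass(frozen=True)
class DecayResult:
    """Time from the peak to the first crossing of ``fraction * |I_peak|``."""

    time_ms: float
    peak_index: int
    peak_current: float
    reached: bool


def decay_time_to_fraction(
    time_ms: Sequence[float],
    current: Sequence[float],
    fraction: float = 0.1,
    onset_index: int = 0,
) -> DecayResult:
    """Time for a current to decay from its peak to a fraction of the peak.

    The peak is the maximum of |I| at or after ``onset_index``.  The crossing
    time is linearly interpolated between the bracketing samples.  If the
    trace never decays to the threshold the result is flagged
    (``reached=False``) with ``time_ms = nan``.
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current, dtype=float)
    if t.shape != i.shape or t.ndim != 1:
        raise ValueError("time and current must be 1-D and equal length")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if not (0 <= onset_index < t.size):
        raise ValueError("onset_index out of range")
    seg = np.abs(i[onset_index:])
    k = int(np.argmax(seg)) + onset_index
    peak = abs(i[k])
    if peak == 0:
        raise ValueError("trace has zero peak current")
    thresh = fraction * peak
    post = np.abs(i[k:])
    below = np.nonzero(post <= thresh)[0]
    if below.size == 0:
        return DecayResult(float("nan"), k, float(i[k]), False)
    j = int(below[0])
    if j <= 1:
        # below threshold at (or before) the very next sample: the decay is
        # faster than the sampling interval, report it as immediate
        return DecayResult(0.0, k, float(i[k]), True)
    # interpolate |I| between samples k+j-1 and k+j
    a, b = post[j - 1], post[j]
    ta, tb = t[k + j - 1], t[k + j]
    frac = (a - thresh) / (a - b) if a != b else 1.0
    t_cross = ta + frac * (tb - ta)
    return DecayResult(float(t_cross - t[k]), k, float(i[k]), True)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Student's t-test: two-tailed, two-sample, equal (pooled) variance.

    Implemented from the closed form; df = n_a + n_b - 2.  With zero pooled
    variance: equal means give t = 0, p = 1; unequal means are flagged
    degenerate (infinite t, p = 0).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    na, nb = x.size, y.size
    df = na + nb - 2
    sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, df)
        return TTestResult(math.copysign(math.inf, diff), 0.0, df, degenerate=True)
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), df)


@dataclass(frozen=True)
class MeanSem:
    mean: float
    sem: float
    n_groups: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.sem)


def mean_sem(groups: Iterable[Sequence[float]]) -> MeanSem:
    """Hierarchical pooled mean +/- s.e.m.

    Each group (an oocyte) is first reduced to its mean; the pooled mean and
    s.e.m. are then taken across group means, matching per-oocyte pooling.
    A single group yields an undefined (NaN) s.e.m.
    """
    means = [float(np.mean(np.asarray(g, dtype=float))) for g in groups]
    if not means:
        raise ValueError("at least one group is required")
    if any(math.isnan(m) for m in means):
        raise ValueError("groups must be non-empty")
    arr = np.array(means)
    if arr.size == 1:
        return MeanSem(float(arr[0]), float("nan"), 1)
    return MeanSem(float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size)), arr.size)
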