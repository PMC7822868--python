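"""Surface-count analyses.

The central quantity is the number of surfaces in a scene sample that an
observer limited by internal colour noise can tell apart — at a single
instant (*distinguishable*) or across a time interval containing an
illumination change (*identifiable*).  Both are obtained as
``N = 2**I`` where ``I`` is the mutual information, in bits, between the
colour code at time t1 and the noisy colour code at time t2 (t1 = t2 for
distinguishability).

Also here: the log-log time-course regression of N against interval,
the strip-wise relative-SD profile of cone-excitation differences, the
Rice successive-difference estimator of irradiance fluctuation SD, and
BCa bootstrap aggregation of mutual information across scenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import colorimetry
from .errors import DomainError, InsufficientDataError, PairingError
from .information import MIEstimate, NoiseModel, mutual_information
from .io import RadianceCube, extract_strip

logger = logging.getLogger(__name__)

__all__ = [
    "ColourSample",
    "SurfaceCountEstimate",
    "TimeCourseFit",
    "AggregateEstimate",
    "n_distinguishable",
    "n_identifiable",
    "time_course_fit",
    "relative_sd_profile",
    "rice_sd",
    "aggregate_ci",
]

#: Intervals (minutes) at which fitted time courses are evaluated.
REFERENCE_INTERVALS = (2.0, 10.0, 60.0)


@dataclass
class ColourSample:
    """3-D colour coordinates of sampled pixels in a named space."""

    values: np.ndarray
    space: str
    coords: np.ndarray | None = None
    timestamp: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise DomainError("colour sample must have shape (n, 3)")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SurfaceCountEstimate:
    """N = 2**I surfaces, with the MI estimate it derives from."""

    n_surfaces: float
    mi: MIEstimate
    interval_dt: float
    colour_space: str
    noise: NoiseModel

    def __post_init__(self):
        expected = 2.0 ** self.mi.bits
        if not np.isclose(self.n_surfaces, expected, rtol=1e-12):
            raise DomainError("n_surfaces must equal 2**bits")


@dataclass(frozen=True)
class TimeCourseFit:
    """OLS fit of log2 N on log2 interval, with reference predictions."""

    slope: float
    intercept: float
    r_squared: float
    predictions: dict

    def predict(self, dt_minutes: float) -> float:
        return 2.0 ** (self.intercept + self.slope * np.log2(dt_minutes))


@dataclass(frozen=True)
class AggregateEstimate:
    """Across-scene mean and 95% BCa limits, on the count scale."""

    mean_n: float
    ci_low: float
    ci_high: float
    n_scenes: int
    bootstrap_reps: int
    seed: int | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.mean_n <= self.ci_high):
            raise DomainError("confidence limits must bracket the mean")


def _check_paired(s1: ColourSample, s2: ColourSample) -> None:
    if len(s1) != len(s2):
        raise PairingError("samples differ in length")
    if s1.coords is not None and s2.coords is not None:
        if not np.array_equal(s1.coords, s2.coords):
            raise PairingError("samples were drawn at different pixel positions")


def n_identifiable(
    sample_t1: ColourSample,
    sample_t2: ColourSample,
    noise: NoiseModel,
    k_neighbour: int = 3,
    n_noise_reps: int = 5,
    interval_dt: float = 0.0,
    seed: int | None = None,
) -> SurfaceCountEstimate:
    """Number of surfaces identifiable across the interval.

    ``N = 2**I(A1; A2 + W)`` with the observer noise W redrawn
    ``n_noise_reps`` times and the MI estimates averaged.  Samples must
    be pixel-paired (same positions at the two times).
    """
    _check_paired(sample_t1, sample_t2)
    mi = mutual_information(
        sample_t1.values,
        sample_t2.values,
        k_neighbour=k_neighbour,
        noise=noise,
        n_noise_reps=n_noise_reps,
        seed=seed,
    )
    return SurfaceCountEstimate(
        n_surfaces=2.0**mi.bits,
        mi=mi,
        interval_dt=interval_dt,
        colour_space=sample_t1.space,
        noise=noise,
    )


def n_distinguishable(
    sample: ColourSample,
    noise: NoiseModel,
    k_neighbour: int = 3,
    n_noise_reps: int = 5,
    seed: int | None = None,
) -> SurfaceCountEstimate:
    """Number of surfaces distinguishable at a single instant.

    The zero-interval special case of :func:`n_identifiable`:
    ``N = 2**I(A; A + W)``.  Delegating makes the zero-interval
    reduction hold bit-exactly under shared seeds.
    """
    return n_identifiable(
        sample, sample, noise,
        k_neighbour=k_neighbour,
        n_noise_reps=n_noise_reps,
        interval_dt=0.0,
        seed=seed,
    )


def time_course_fit(observations) -> TimeCourseFit:
    """Fit log2 N against log2 interval by ordinary least squares.

    ``observations`` is a sequence of ``(dt_minutes, estimate)`` pairs,
    where ``estimate`` is a :class:`SurfaceCountEstimate` or a bare
    count.  At least three distinct positive intervals are required.
    Predictions are evaluated at the 2, 10 and 60 min reference
    intervals.
    """
    dts, counts = [], []
    for dt, est in observations:
        if dt <= 0:
            raise DomainError("intervals must be positive")
        dts.append(float(dt))
        counts.append(est.n_surfaces if isinstance(est, SurfaceCountEstimate) else float(est))
    if len(set(dts)) < 3:
        raise InsufficientDataError("need >= 3 distinct intervals")
    x = np.log2(dts)
    y = np.log2(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else float(max(0.0, 1.0 - np.sum(resid**2) / ss_tot))
    preds = {dt: 2.0 ** (intercept + slope * np.log2(dt)) for dt in REFERENCE_INTERVALS}
    return TimeCourseFit(float(slope), float(intercept), min(r2, 1.0), preds)


def relative_sd_profile(
    cube_t1: RadianceCube,
    cube_t2: RadianceCube,
    strip_height: int = 30,
    strip_width: int | None = None,
    strip_step: int = 10,
):
    """Strip-wise relative SD of cone-excitation differences, in percent.

    For each vertical strip position: convert both strips to LMS cone
    excitations, von Kries-scale each by its own spatial means (which
    makes the values relative and removes global scaling), take the
    per-pixel Euclidean difference norm, and report its SD over the
    strip as a percentage.  Returns ``(top_rows, profile_percent)``.
    """
    if cube_t1.values.shape != cube_t2.values.shape:
        raise PairingError("cubes differ in shape")
    if strip_width is None:
        strip_width = cube_t1.width
    tops = np.arange(0, cube_t1.height - strip_height + 1, strip_step)
    profile = np.empty(tops.size)
    for i, top in enumerate(tops):
        s1 = extract_strip(cube_t1, int(top), strip_height, strip_width)
        s2 = extract_strip(cube_t2, int(top), strip_height, strip_width)
        q1 = colorimetry.von_kries_scale(colorimetry.cone_excitations(s1.spectra, cube_t1.wavelengths))
        q2 = colorimetry.von_kries_scale(colorimetry.cone_excitations(s2.spectra, cube_t2.wavelengths))
        de = colorimetry.delta_e_cones(q1, q2)
        profile[i] = de.std() * 100.0
    return tops, profile


def rice_sd(series: np.ndarray, relative: bool = False) -> float:
    """Rice successive-difference estimate of residual SD.

    ``sigma^2 = sum (y[i+1] - y[i])^2 / (2 (n - 1))`` suppresses slow
    trends and recovers the SD of superimposed white noise.  With
    ``relative=True`` the SD is divided by the series mean (the
    relative-SD form used for irradiance records).
    """
    y = np.asarray(series, dtype=float).ravel()
    if y.size < 3:
        raise DomainError("series must have length >= 3")
    diffs = np.diff(y)
    var = np.sum(diffs**2) / (2.0 * (y.size - 1))
    sd = float(np.sqrt(var))
    if relative:
        m = y.mean()
        if m <= 0:
            raise DomainError("relative SD undefined for non-positive mean")
        return sd / m
    return sd


def aggregate_ci(
    mi_values,
    bootstrap_reps: int = 2000,
    seed: int | None = None,
) -> AggregateEstimate:
    """Across-scene mean and 95% BCa interval, back on the count scale.

    The mean and limits are computed on the bits (log) scale, where the
    distribution over scenes is closer to symmetric, then transformed by
    ``2**x`` — so the reported mean_n behaves like a geometric mean of
    the per-scene counts.
    """
    from scipy.stats import bootstrap

    bits = np.array(
        [m.bits if isinstance(m, MIEstimate) else float(m) for m in mi_values], dtype=float
    )
    if bits.size < 2:
        raise DomainError("need at least 2 scenes to aggregate")
    if bootstrap_reps < 1:
        raise DomainError("bootstrap_reps must be >= 1")
    mean_bits = bits.mean()
    if np.allclose(bits, bits[0]):
        logger.info("all scene MI values equal; interval collapses to a point")
        lo = hi = mean_bits
    else:
        res = bootstrap(
            (bits,),
            np.mean,
            n_resamples=bootstrap_reps,
            confidence_level=0.95,
            method="BCa",
            random_state=np.random.default_rng(seed),
        )
        lo, hi = res.confidence_interval.low, res.confidence_interval.high
    return AggregateEstimate(
        mean_n=float(2.0**mean_bits),
        ci_low=float(2.0 ** min(lo, mean_bits)),
        ci_high=float(2.0 ** max(hi, mean_bits)),
        n_scenes=bits.size,
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )
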