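"""Observer noise models and nonparametric entropy / mutual information.

The observer's internal noise is additive, isotropic in the uniform
colour space, and drawn per coordinate from either a Gaussian or a
uniform density.  Both families are parameterised by a nominal width
``w``: for the uniform family ``w`` is the width of the support, for the
Gaussian family ``w = sqrt(12) * sigma``, so equal ``w`` means equal
variance ``w^2 / 12``.  The width is referred to a hard discrimination
threshold ``delta_e_thr`` (0.5 in CIECAM02 units is roughly one just-
perceptible difference) via a single convention, ``w = 2 * delta_e_thr``
by default, exposed as a parameter so the alternative ``w = delta_e_thr``
mapping can be swept.

Differential entropy is estimated with the Kozachenko-Leonenko
k-nearest-neighbour statistic

    h_hat = psi(n) - psi(k) + log V_d + (d / n) * sum_i log eps_i

(in nats; reported in bits), where ``eps_i`` is the distance from point
``i`` to its k-th neighbour and ``V_d`` the d-dimensional unit-ball
volume.  Mutual information is the three-entropy combination
``I(A;B) = h(A) + h(B) - h(A,B)``, averaged over repeated independent
noise draws, with a deterministic sub-resolution offset jitter applied
before the neighbour search to break exact ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln

from .errors import DegeneracyError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseModel",
    "MIEstimate",
    "noise_width_from_threshold",
    "draw_noise",
    "kl_entropy",
    "mutual_information",
    "histogram_mi",
]

#: Default mapping from a hard threshold to a support width: displacements
#: of up to delta_e_thr per axis, i.e. w = 2 * delta_e_thr.
THRESHOLD_TO_WIDTH = 2.0

_SQRT12 = math.sqrt(12.0)


@dataclass(frozen=True)
class NoiseModel:
    """Observer internal-noise specification.

    ``width_w`` is the nominal width in colour-space units; both
    families share the variance ``width_w**2 / 12``.
    """

    family: str
    width_w: float
    delta_e_thr: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "uniform"):
            raise DomainError(f"unknown noise family {self.family!r}")
        if self.width_w <= 0:
            raise DomainError("noise width must be positive")

    @property
    def sigma(self) -> float:
        """Per-coordinate standard deviation (equal for both families)."""
        return self.width_w / _SQRT12

    @property
    def variance(self) -> float:
        return self.width_w**2 / 12.0


@dataclass(frozen=True)
class MIEstimate:
    """A mutual-information estimate with its estimator settings."""

    bits: float
    k_neighbour: int
    n_points: int
    n_noise_reps: int = 1
    seed: int | None = None

    def __post_init__(self):
        if not np.isfinite(self.bits):
            raise DomainError("mutual information must be finite")
        if self.n_points <= self.k_neighbour or self.k_neighbour < 1:
            raise DomainError("need n_points > k_neighbour >= 1")


def noise_width_from_threshold(
    delta_e_thr: float,
    family: str,
    seed: int | None = None,
    threshold_to_width: float = THRESHOLD_TO_WIDTH,
) -> NoiseModel:
    """Build a noise model whose width is referred to a hard threshold.

    With the default convention the uniform family has per-coordinate
    support ``[-delta_e_thr, +delta_e_thr]``; the Gaussian family gets
    the same width, hence the same variance.
    """
    if delta_e_thr <= 0:
        raise DomainError("discrimination threshold must be positive")
    return NoiseModel(
        family=family,
        width_w=threshold_to_width * delta_e_thr,
        delta_e_thr=delta_e_thr,
        seed=seed,
    )


def draw_noise(
    n: int,
    model: NoiseModel,
    d: int = 3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. d-dimensional displacement vectors."""
    if n < 1:
        raise DomainError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if model.family == "uniform":
        half = model.width_w / 2.0
        return rng.uniform(-half, half, size=(n, d))
    return rng.normal(0.0, model.sigma, size=(n, d))


# ---------------------------------------------------------------------------
# Entropy / MI estimation

_JITTER_SEED = 0x5EED0FF5
_TIE_FRACTION_LIMIT = 0.01


def _prepare(points: np.ndarray, jitter_scale: float) -> np.ndarray:
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise DomainError("points must be a 2-D array (n, d)")
    scale = np.std(x, axis=0).max()
    if scale == 0:
        raise DegeneracyError("all points identical; differential entropy undefined")
    # Deterministic sub-resolution jitter so exact ties do not yield zero
    # neighbour distances; far below any data scale of interest.
    rng = np.random.default_rng(_JITTER_SEED)
    return x + rng.normal(0.0, jitter_scale * scale, size=x.shape)


def kl_entropy(
    points: np.ndarray,
    k_neighbour: int = 3,
    jitter_scale: float = 1e-9,
) -> float:
    """Kozachenko-Leonenko k-NN differential entropy, in bits."""
    x = _prepare(points, jitter_scale)
    n, d = x.shape
    if k_neighbour < 1 or n <= k_neighbour:
        raise DomainError("need n_points > k_neighbour >= 1")
    tree = cKDTree(x)
    dist, _ = tree.query(x, k=k_neighbour + 1, workers=-1)
    eps = dist[:, k_neighbour]
    zero = eps <= 0
    if zero.mean() >= _TIE_FRACTION_LIMIT:
        raise DegeneracyError("sample is tie-heavy even after offset jitter")
    if zero.any():
        eps = np.where(zero, np.finfo(float).tiny, eps)
    log_vd = (d / 2.0) * math.log(math.pi) - gammaln(d / 2.0 + 1.0)
    h_nats = digamma(n) - digamma(k_neighbour) + log_vd + d * np.mean(np.log(eps))
    return float(h_nats / math.log(2.0))


def mutual_information(
    a_points: np.ndarray,
    b_points: np.ndarray,
    k_neighbour: int = 3,
    noise: NoiseModel | None = None,
    n_noise_reps: int = 1,
    seed: int | None = None,
) -> MIEstimate:
    """Mutual information of paired samples via the entropy combination.

    With a ``noise`` model, each observation carries its own
    threshold-matched noise: the estimate of ``I(A + W1; B + W2)`` with
    independent draws ``W1, W2`` is averaged over ``n_noise_reps``
    repetitions.  Noise on both sides keeps the marginal and joint
    densities non-singular even when the underlying point sets are
    discrete (e.g. a scene with a small palette of distinct spectra).
    Without a noise model the points are used as given (``b`` must then
    not duplicate ``a`` exactly, which would make the joint density
    singular).  Negative averages are clamped to zero (and logged),
    since mutual information cannot be negative.
    """
    a = np.asarray(a_points, dtype=float)
    b = np.asarray(b_points, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] != b.shape[0]:
        raise DomainError("a and b must be paired (equal length)")
    n = a.shape[0]
    if n_noise_reps < 1:
        raise DomainError("n_noise_reps must be >= 1")
    if noise is None and np.array_equal(a, b):
        raise DegeneracyError(
            "b is identical to a with no noise model: joint density singular; "
            "supply a NoiseModel"
        )

    if noise is None:
        reps = 1
        rng = None
    else:
        reps = n_noise_reps
        rng = np.random.default_rng(seed if seed is not None else noise.seed)

    totals = []
    for _ in range(reps):
        if noise is None:
            a_obs, b_obs = a, b
        else:
            a_obs = a + draw_noise(n, noise, d=a.shape[1], rng=rng)
            b_obs = b + draw_noise(n, noise, d=b.shape[1], rng=rng)
        h_a = kl_entropy(a_obs, k_neighbour)
        h_b = kl_entropy(b_obs, k_neighbour)
        h_ab = kl_entropy(np.hstack([a_obs, b_obs]), k_neighbour)
        totals.append(h_a + h_b - h_ab)
    bits = float(np.mean(totals))
    if bits < 0:
        logger.warning("clamping negative MI estimate %.4f bits to 0", bits)
        bits = 0.0
    return MIEstimate(
        bits=bits,
        k_neighbour=k_neighbour,
        n_points=n,
        n_noise_reps=reps,
        seed=seed if seed is not None else (noise.seed if noise else None),
    )


def histogram_mi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Plug-in histogram MI in bits (independent cross-check, 1-D pairs).

    Deliberately simple and biased; used only to corroborate the k-NN
    combination estimator on large synthetic samples.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (pa @ pb)[mask])))
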