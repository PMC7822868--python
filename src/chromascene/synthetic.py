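"""Synthetic hyperspectral scene generation.

Every downstream stage — colour transforms, entropy/MI estimation,
surface counting, time-course regression — is exercised on generated
scenes with controlled statistical structure, so the whole pipeline is
testable without the multi-gigabyte deposited imagery.

A scene is a spatially correlated field of smooth spectral reflectances
(mixtures of Gaussian-bump basis spectra), lit by a global illuminant
spectrum and, optionally, a spatially correlated multiplicative gain
field standing in for the geometric redistribution of light (moving
shadows, dappled illumination) whose magnitude grows with the nominal
interval between acquisitions.  Small multiplicative sensor noise can be
added; the real imaging system's noise is negligible next to the
illumination changes, so the default is 0.1%.

All randomness flows from a single seed through ``numpy``'s
``SeedSequence`` spawning, so each stage (reflectance, gain, noise) is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .colorimetry import DEFAULT_WAVELENGTHS, IlluminantSpectrum
from .errors import ConfigurationError, DomainError, FormatError
from .io import RadianceCube

__all__ = [
    "SceneConfig",
    "ReflectanceCube",
    "GainField",
    "generate_reflectance_cube",
    "generate_gain_field",
    "render_radiance_pair",
    "render_radiance_cube",
]

# Stream indices for SeedSequence spawning: one per random stage.
_STREAM_REFLECTANCE = 0
_STREAM_GAIN = 1
_STREAM_NOISE = 2


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene generator.

    ``gain_amplitude`` sets the pixel SD of the multiplicative gain
    field per unit ``log(1 + dt_minutes)``; ``palette_size`` switches to
    a discrete-palette scene of exactly M distinct spectra in M equal
    contiguous blocks (the degenerate mode used by the discrete
    mutual-information oracle).
    """

    width: int = 96
    height: int = 96
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())
    n_basis: int = 6
    spatial_corr_length: float = 6.0
    palette_size: int | None = None
    gain_amplitude: float = 0.05
    gain_corr_length: float = 8.0
    sensor_noise_sd: float = 0.001
    seed: int = 0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if self.width < 8 or self.height < 8:
            raise ConfigurationError("width and height must be >= 8")
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if wl[0] < 400.0 - 1e-9 or wl[-1] > 720.0 + 1e-9:
            raise ConfigurationError("wavelengths must lie within [400, 720] nm")
        if self.n_basis < 1:
            raise ConfigurationError("n_basis must be >= 1")
        if self.spatial_corr_length <= 0 or self.gain_corr_length <= 0:
            raise ConfigurationError("correlation lengths must be positive")
        if self.gain_amplitude < 0 or self.sensor_noise_sd < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if self.palette_size is not None and self.palette_size < 1:
            raise ConfigurationError("palette_size must be >= 1")
        object.__setattr__(self, "wavelengths", wl)

    def spawn_rng(self, stream: int, extra: int = 0) -> np.random.Generator:
        """Child generator for one random stage (documented split scheme)."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream, extra))
        return np.random.default_rng(ss)


@dataclass
class ReflectanceCube:
    """Per-pixel effective spectral reflectance in [0, 1]."""

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise FormatError("reflectance values must be 3-D")
        if np.any(v < 0) or np.any(v > 1):
            raise DomainError("reflectance must lie in [0, 1]")
        self.values = v
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)


@dataclass
class GainField:
    """Spatially correlated multiplicative illumination gain.

    Mean over pixels is 1 (a redistribution of light, no net gain);
    the pixel SD equals ``amplitude * log(1 + nominal_dt)``.
    """

    values: np.ndarray
    corr_length: float
    amplitude: float
    nominal_dt: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0):
            raise DomainError("gain values must be strictly positive")
        if abs(v.mean() - 1.0) > 1e-6:
            raise DomainError("gain field mean must be 1 within 1e-6")
        self.values = v


def _spectral_basis(wavelengths: np.ndarray, n_basis: int, bandwidth: float = 80.0) -> np.ndarray:
    """Gaussian-bump basis spectra, centres evenly spaced on the grid."""
    centres = np.linspace(wavelengths[0], wavelengths[-1], n_basis)
    sigma = bandwidth / 2.355  # bandwidth given as FWHM
    return np.exp(-0.5 * ((wavelengths[None, :] - centres[:, None]) / sigma) ** 2)


def _correlated_field(rng, shape, corr_length: float) -> np.ndarray:
    """Zero-mean unit-SD field whose autocorrelation decays to 1/e at
    ``corr_length`` pixels (Gaussian filter of white noise, sigma =
    corr_length / 2, periodic boundary for stationarity)."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, corr_length / 2.0, mode="wrap")
    f -= f.mean()
    sd = f.std()
    if sd == 0:
        raise DomainError("degenerate correlated field")
    return f / sd


def _mixture_spectra(weights: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Map mixing weights (..., n_basis) to reflectances in [0, 1]."""
    contrast = 0.15
    spectra = 0.5 + contrast * np.tensordot(weights, basis, axes=([-1], [0]))
    return np.clip(spectra, 0.0, 1.0)


def generate_reflectance_cube(config: SceneConfig) -> ReflectanceCube:
    """Generate the reflectance field of a synthetic scene.

    Continuous mode: each basis function's mixing weight is an
    independent spatially correlated Gaussian field, so nearby pixels
    have similar, smooth spectra.  Palette mode (``palette_size = M``):
    M random smooth spectra arranged in M equal contiguous blocks.
    Deterministic given ``config.seed``.
    """
    rng = config.spawn_rng(_STREAM_REFLECTANCE)
    wl = config.wavelengths
    basis = _spectral_basis(wl, config.n_basis)

    if config.palette_size is not None:
        m = config.palette_size
        n_px = config.width * config.height
        if m > n_px:
            raise ConfigurationError("palette_size exceeds pixel count")
        # Draw until all M spectra are distinct (ties are measure-zero but
        # clipping could in principle collapse two draws).
        for _ in range(100):
            w = rng.standard_normal((m, config.n_basis))
            palette = _mixture_spectra(w, basis)
            if np.unique(palette, axis=0).shape[0] == m:
                break
        else:  # pragma: no cover
            raise ConfigurationError("could not draw M distinct palette spectra")
        labels = (np.arange(n_px) * m) // n_px
        values = palette[labels].reshape(config.height, config.width, wl.size)
        return ReflectanceCube(values, wl)

    weights = np.stack(
        [
            _correlated_field(rng, (config.height, config.width), config.spatial_corr_length)
            for _ in range(config.n_basis)
        ],
        axis=-1,
    )
    return ReflectanceCube(_mixture_spectra(weights, basis), wl)


def generate_gain_field(config: SceneConfig, dt_minutes: float, seed: int) -> GainField:
    """Multiplicative gain field for a nominal interval ``dt_minutes``.

    Pixel SD is ``gain_amplitude * log(1 + dt)`` exactly (the field is
    standardised empirically), chosen so that the log of the downstream
    surface count declines approximately linearly in log interval.
    """
    if dt_minutes <= 0:
        raise DomainError("dt_minutes must be positive")
    sd = config.gain_amplitude * np.log1p(dt_minutes)
    shape = (config.height, config.width)
    if sd == 0:
        return GainField(np.ones(shape), config.gain_corr_length, 0.0, dt_minutes)
    rng = config.spawn_rng(_STREAM_GAIN, extra=seed)
    f = _correlated_field(rng, shape, config.gain_corr_length)
    values = 1.0 + sd * f
    # Large amplitudes could drive the field non-positive; floor and
    # re-centre (mean must stay 1: redistribution, not net gain).
    values = np.clip(values, 1e-3, None)
    values /= values.mean()
    return GainField(values, config.gain_corr_length, config.gain_amplitude, dt_minutes)


def _unity_gain(shape) -> np.ndarray:
    return np.ones(shape)


def render_radiance_cube(
    reflectance: ReflectanceCube,
    illuminant: IlluminantSpectrum,
    gain: GainField | None,
    sensor_noise_sd: float,
    rng: np.random.Generator,
    timestamp: float | None = None,
) -> RadianceCube:
    """Render one radiance cube: L = gain * E(lambda) * R, plus noise."""
    wl = reflectance.wavelengths
    e = illuminant.resampled(wl).power if not np.array_equal(illuminant.wavelengths, wl) else illuminant.power
    if e.shape[0] != wl.size:
        raise FormatError("illuminant grid does not match reflectance grid")
    g = gain.values[..., None] if gain is not None else 1.0
    values = g * e[None, None, :] * reflectance.values
    if sensor_noise_sd > 0:
        values = values * (1.0 + sensor_noise_sd * rng.standard_normal(values.shape))
    return RadianceCube(np.clip(values, 0.0, None), wl, timestamp=timestamp)


def render_radiance_pair(
    reflectance: ReflectanceCube,
    illuminant1: IlluminantSpectrum,
    illuminant2: IlluminantSpectrum,
    gain1: GainField | None,
    gain2: GainField | None,
    sensor_noise_sd: float,
    seed: int,
) -> tuple[RadianceCube, RadianceCube]:
    """Render a registered pair of radiance cubes sharing one reflectance.

    Each cube gets an independent sensor-noise draw (split from the one
    seed); gains and illuminants may differ between members to model
    geometric and/or spectral illumination change.
    """
    for ill in (illuminant1, illuminant2):
        if (
            ill.wavelengths.size != reflectance.wavelengths.size
            and (ill.wavelengths[0] > reflectance.wavelengths[0]
                 or ill.wavelengths[-1] < reflectance.wavelengths[-1])
        ):
            raise FormatError("illuminant grid cannot cover the reflectance grid")
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAM_NOISE,))
    rng1, rng2 = (np.random.default_rng(c) for c in ss.spawn(2))
    cube1 = render_radiance_cube(reflectance, illuminant1, gain1, sensor_noise_sd, rng1, timestamp=0.0)
    dt = gain2.nominal_dt if gain2 is not None else None
    cube2 = render_radiance_cube(reflectance, illuminant2, gain2, sensor_noise_sd, rng2, timestamp=dt)
    return cube1, cube2
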