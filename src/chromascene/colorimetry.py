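"""Colour transforms for hyperspectral radiance data.

Radiance spectra on a 400-720 nm, 10-nm grid are converted to

* LMS cone excitations (for the physical strip-variation analysis),
* CIE XYZ tristimulus values,
* CIECAM02 appearance coordinates ``(J, aC, bC)``,
* CIELAB ``(L*, a*, b*)`` and the spatially filtered S-CIELAB variant,

and daylight-series illuminants of a given correlated colour temperature
can be constructed and swapped into a scene.

Colour-matching functions are evaluated from the multi-lobe Gaussian
analytic fit of the CIE 1931 2-degree standard observer (Wyman, Sloan &
Shirley 2013), which is accurate to well under 1% over the visible range.
Cone fundamentals are the Hunt-Pointer-Estevez transform of those CMFs,
i.e. the LMS basis used inside CIECAM02 itself.  The daylight component
vectors S0/S1/S2 ship as a plain-text data asset.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError, FormatError

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "ViewingConditions",
    "IlluminantSpectrum",
    "xyz_cmf",
    "lms_fundamentals",
    "cone_excitations",
    "von_kries_scale",
    "delta_e_cones",
    "tristimulus",
    "cielab_coords",
    "ciecam02_coords",
    "scielab_transform",
    "daylight_spd",
    "reilluminate",
]

#: Native wavelength grid of the hyperspectral scenes: 400-720 nm, 10 nm.
DEFAULT_WAVELENGTHS = np.arange(400.0, 721.0, 10.0)

# Hunt-Pointer-Estevez cone basis (normalised to D65 inside CIECAM02 use).
M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)

# CAT02 chromatic-adaptation matrix of CIECAM02.
M_CAT02 = np.array(
    [
        [0.7328, 0.4296, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)

_SURROUNDS = {
    # surround: (F, c, Nc)
    "average": (1.0, 0.69, 1.0),
    "dim": (0.9, 0.59, 0.9),
    "dark": (0.8, 0.525, 0.8),
}


def _piecewise_gauss(x: np.ndarray, alpha: float, mu: float, s1: float, s2: float) -> np.ndarray:
    t = (x - mu) * np.where(x < mu, s1, s2)
    return alpha * np.exp(-0.5 * t * t)


def xyz_cmf(wavelengths: np.ndarray) -> np.ndarray:
    """CIE 1931 2-degree colour-matching functions, shape ``(n, 3)``.

    Analytic multi-lobe Gaussian fit (Wyman, Sloan & Shirley 2013).
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = (
        _piecewise_gauss(wl, 0.362, 442.0, 0.0624, 0.0374)
        + _piecewise_gauss(wl, 1.056, 599.8, 0.0264, 0.0323)
        + _piecewise_gauss(wl, -0.065, 501.1, 0.0490, 0.0382)
    )
    y = _piecewise_gauss(wl, 0.821, 568.8, 0.0213, 0.0247) + _piecewise_gauss(
        wl, 0.286, 530.9, 0.0613, 0.0322
    )
    z = _piecewise_gauss(wl, 1.217, 437.0, 0.0845, 0.0278) + _piecewise_gauss(
        wl, 0.681, 459.0, 0.0385, 0.0725
    )
    return np.stack([x, y, z], axis=-1)


def lms_fundamentals(wavelengths: np.ndarray) -> np.ndarray:
    """LMS cone spectral sensitivities, shape ``(n, 3)``.

    Hunt-Pointer-Estevez transform of the 2-degree CMFs; tiny negative
    lobes at the spectrum ends are clipped to zero so that cone
    excitations of non-negative radiances are non-negative.
    """
    lms = xyz_cmf(wavelengths) @ M_HPE.T
    return np.clip(lms, 0.0, None)


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 1 or (wl.size > 1 and np.any(np.diff(wl) <= 0)):
        raise FormatError("wavelength grid must be 1-D and strictly increasing")
    return wl


def _delta_lambda(wl: np.ndarray) -> float:
    if wl.size == 1:
        return 1.0
    steps = np.diff(wl)
    if not np.allclose(steps, steps[0]):
        raise FormatError("wavelength grid must be uniformly spaced for integration")
    return float(steps[0])


def cone_excitations(spectra: np.ndarray, wavelengths: np.ndarray = DEFAULT_WAVELENGTHS) -> np.ndarray:
    """Integrate radiance spectra against the cone fundamentals.

    ``spectra`` has shape ``(..., n_wavelengths)``; the result has shape
    ``(..., 3)`` ordered (L, M, S).  The map is linear in radiance and
    evaluated as a 10-nm rectangular quadrature on the native grid.
    """
    wl = _check_grid(wavelengths)
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != wl.size:
        raise FormatError(
            f"spectra have {spectra.shape[-1]} bands but grid has {wl.size}"
        )
    return spectra @ lms_fundamentals(wl) * _delta_lambda(wl)


def von_kries_scale(triplets: np.ndarray) -> np.ndarray:
    """Divide each cone class by its spatial mean over the sample.

    After scaling, each class has mean exactly 1, which makes the
    Euclidean difference norm a relative (fractional) quantity and
    removes any global intensity or colour scaling of the sample.
    """
    q = np.asarray(triplets, dtype=float)
    if q.size == 0:
        raise DomainError("empty cone-excitation sample")
    means = q.reshape(-1, q.shape[-1]).mean(axis=0)
    if np.any(means <= 0):
        raise DegenerateSampleError("a cone class has non-positive mean")
    return q / means


class DegenerateSampleError(DomainError):
    """A cone class with zero mean cannot be von Kries scaled."""


def delta_e_cones(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Unweighted Euclidean norm of the difference of scaled cone triplets."""
    d = np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


def tristimulus(
    spectra: np.ndarray,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    white_spectrum: np.ndarray | None = None,
) -> np.ndarray:
    """CIE XYZ of radiance spectra, shape ``(..., 3)``.

    If ``white_spectrum`` is given the result is normalised so that the
    white has Y = 100 (relative colorimetry for the adopted white);
    otherwise raw integrated values are returned.
    """
    wl = _check_grid(wavelengths)
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != wl.size:
        raise FormatError("spectral band count does not match wavelength grid")
    cmf = xyz_cmf(wl)
    dl = _delta_lambda(wl)
    xyz = spectra @ cmf * dl
    if white_spectrum is not None:
        yw = float(np.asarray(white_spectrum, dtype=float) @ cmf[:, 1] * dl)
        if yw <= 0:
            raise DomainError("white spectrum has non-positive luminance")
        xyz = xyz * (100.0 / yw)
    return xyz


# ---------------------------------------------------------------------------
# CIELAB

def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def cielab_coords(xyz: np.ndarray, white_point: np.ndarray) -> np.ndarray:
    """CIELAB ``(L*, a*, b*)`` including the low-ratio linear segment."""
    white = np.asarray(white_point, dtype=float)
    if np.any(white <= 0):
        raise DomainError("white point must be strictly positive")
    r = np.asarray(xyz, dtype=float) / white
    fx, fy, fz = _lab_f(r[..., 0]), _lab_f(r[..., 1]), _lab_f(r[..., 2])
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


# ---------------------------------------------------------------------------
# CIECAM02

@dataclass(frozen=True)
class ViewingConditions:
    """Viewing-condition parameters of the CIECAM02 appearance model.

    ``white_point`` is the adopted white in XYZ with Y = 100;
    ``adapting_luminance`` is L_A in cd/m^2 (for relative radiance data
    a nominal value; default 20 = 20% of a Y=100 white);
    ``background_relative_luminance`` is Yb/Yw.
    """

    white_point: np.ndarray = field(default_factory=lambda: np.array([95.05, 100.0, 108.88]))
    adapting_luminance: float = 20.0
    background_relative_luminance: float = 0.2
    surround: str = "average"

    def __post_init__(self):
        if self.adapting_luminance <= 0:
            raise ConfigurationError("adapting luminance must be positive")
        if self.surround not in _SURROUNDS:
            raise ConfigurationError(f"unknown surround {self.surround!r}")
        wp = np.asarray(self.white_point, dtype=float)
        if wp.shape != (3,) or np.any(wp <= 0):
            raise ConfigurationError("white point must be a positive XYZ triplet")
        object.__setattr__(self, "white_point", wp)


def _ciecam02_achromatic(xyz: np.ndarray, vc: ViewingConditions):
    """Shared forward machinery; returns post-adaptation responses."""
    F, c, Nc = _SURROUNDS[vc.surround]
    la = vc.adapting_luminance
    xyz = np.asarray(xyz, dtype=float)
    if np.any(xyz < -1e-9):
        raise DomainError("tristimulus values must be non-negative")

    # Relative colorimetry: stimulus and white are interpreted relative to
    # the white's luminance, so jointly rescaling both changes nothing.
    scale = 100.0 / vc.white_point[1]
    xyz = xyz * scale
    white = vc.white_point * scale

    rgb_w = M_CAT02 @ white
    yw = white[1]
    D = np.clip(F * (1.0 - (1.0 / 3.6) * np.exp(-(la + 42.0) / 92.0)), 0.0, 1.0)
    d_factors = D * yw / rgb_w + 1.0 - D

    k = 1.0 / (5.0 * la + 1.0)
    fl = 0.2 * k**4 * (5.0 * la) + 0.1 * (1.0 - k**4) ** 2 * (5.0 * la) ** (1.0 / 3.0)

    n = vc.background_relative_luminance
    z = 1.48 + np.sqrt(n)
    nbb = ncb = 0.725 * n ** (-0.2)

    m = M_HPE @ np.linalg.inv(M_CAT02)

    def compress(rgb_p):
        t = (fl * np.abs(rgb_p) / 100.0) ** 0.42
        return np.sign(rgb_p) * 400.0 * t / (27.13 + t) + 0.1

    rgb_c = xyz @ M_CAT02.T * d_factors
    rgb_a = compress(rgb_c @ m.T)

    rgb_cw = rgb_w * d_factors
    rgb_aw = compress(m @ rgb_cw)

    return rgb_a, rgb_aw, (F, c, Nc, fl, n, z, nbb, ncb)


def ciecam02_coords(xyz: np.ndarray, vc: ViewingConditions) -> np.ndarray:
    """CIECAM02 rectangular coordinates ``(J, aC, bC)``.

    J is the lightness correlate (0-100); aC = C cos h and bC = C sin h
    are the chroma-weighted red-green and yellow-blue axes, giving an
    approximately uniform 3-D space under the Euclidean metric.
    """
    rgb_a, rgb_aw, (F, c, Nc, fl, n, z, nbb, ncb) = _ciecam02_achromatic(xyz, vc)
    ra, ga, ba = rgb_a[..., 0], rgb_a[..., 1], rgb_a[..., 2]

    a = ra - 12.0 * ga / 11.0 + ba / 11.0
    b = (ra + ga - 2.0 * ba) / 9.0
    h = np.degrees(np.arctan2(b, a)) % 360.0

    A = (2.0 * ra + ga + ba / 20.0 - 0.305) * nbb
    Aw = (2.0 * rgb_aw[0] + rgb_aw[1] + rgb_aw[2] / 20.0 - 0.305) * nbb
    J = 100.0 * np.clip(A / Aw, 0.0, None) ** (c * z)

    et = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
    denom = ra + ga + 21.0 * ba / 20.0
    t = (50000.0 / 13.0 * Nc * ncb * et * np.hypot(a, b)) / np.where(
        np.abs(denom) < 1e-12, 1e-12, denom
    )
    C = np.clip(t, 0.0, None) ** 0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**n) ** 0.73

    hr = np.radians(h)
    return np.stack([J, C * np.cos(hr), C * np.sin(hr)], axis=-1)


# ---------------------------------------------------------------------------
# S-CIELAB

# Poirson-Wandell opponent transform (luminance, red-green, blue-yellow).
_M_OPP = np.array(
    [
        [0.279, 0.72, -0.107],
        [-0.449, 0.29, -0.077],
        [0.086, -0.59, 0.501],
    ]
)

# Sum-of-Gaussians spatial kernels: (weights, half-width-at-half-height in
# degrees of visual angle) per opponent channel (Zhang & Wandell 1997).
_SCIELAB_KERNELS = (
    ((0.921, 0.105, -0.108), (0.0283, 0.133, 4.336)),
    ((0.531, 0.330), (0.0392, 0.494)),
    ((0.488, 0.371), (0.0536, 0.386)),
)

_HWHH_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


def scielab_transform(
    xyz_image: np.ndarray,
    pixels_per_degree: float,
    white_point: np.ndarray,
) -> np.ndarray:
    """S-CIELAB: opponent-space spatial filtering, then CIELAB per pixel.

    ``xyz_image`` has shape ``(H, W, 3)``.  Each opponent channel is
    blurred with its pattern-separable sum-of-Gaussians kernel (unit DC
    gain, so a spatially uniform image is unchanged), the result is
    transformed back to XYZ and converted to CIELAB against
    ``white_point``.  Filtering is applied to the whole image before any
    pixel sampling.
    """
    from scipy.ndimage import gaussian_filter

    if pixels_per_degree <= 0:
        raise DomainError("pixels_per_degree must be positive")
    img = np.asarray(xyz_image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise FormatError("xyz_image must have shape (H, W, 3)")

    opp = img @ _M_OPP.T
    out = np.empty_like(opp)
    for ch, (weights, hwhh) in enumerate(_SCIELAB_KERNELS):
        wsum = sum(weights)
        acc = np.zeros(img.shape[:2])
        for w, hw in zip(weights, hwhh):
            sigma = hw * _HWHH_TO_SIGMA * pixels_per_degree
            acc += (w / wsum) * gaussian_filter(opp[..., ch], sigma, mode="nearest")
        out[..., ch] = acc

    xyz_f = out @ np.linalg.inv(_M_OPP).T
    return cielab_coords(np.clip(xyz_f, 0.0, None), white_point)


# ---------------------------------------------------------------------------
# Daylight illuminants

@dataclass(frozen=True)
class IlluminantSpectrum:
    """Relative spectral power distribution of an illuminant."""

    wavelengths: np.ndarray
    power: np.ndarray
    cct: float | None = None

    def __post_init__(self):
        wl = _check_grid(self.wavelengths)
        p = np.asarray(self.power, dtype=float)
        if p.shape != wl.shape:
            raise FormatError("power and wavelength grids differ in length")
        if np.any(p < 0):
            raise DomainError("spectral power must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "power", p)

    def resampled(self, wavelengths: np.ndarray) -> "IlluminantSpectrum":
        """Linear interpolation onto a new grid; extrapolation forbidden."""
        wl = _check_grid(wavelengths)
        if wl[0] < self.wavelengths[0] - 1e-9 or wl[-1] > self.wavelengths[-1] + 1e-9:
            raise DomainError("requested grid extends beyond the tabulated range")
        return IlluminantSpectrum(wl, np.interp(wl, self.wavelengths, self.power), self.cct)


@functools.lru_cache(maxsize=1)
def _daylight_components() -> tuple[np.ndarray, np.ndarray]:
    ref = importlib.resources.files("chromascene.data") / "cie_daylight_components.csv"
    table = np.loadtxt(str(ref), delimiter=",", comments="#")
    return table[:, 0], table[:, 1:4]


def daylight_locus_chromaticity(cct: float) -> tuple[float, float]:
    """Chromaticity (x_D, y_D) on the CIE daylight locus for a CCT in K."""
    if not 4000.0 <= cct <= 25000.0:
        raise DomainError("CCT must lie in [4000, 25000] K")
    t = cct
    if t <= 7000.0:
        xd = -4.6070e9 / t**3 + 2.9678e6 / t**2 + 0.09911e3 / t + 0.244063
    else:
        xd = -2.0064e9 / t**3 + 1.9018e6 / t**2 + 0.24748e3 / t + 0.237040
    yd = -3.000 * xd**2 + 2.870 * xd - 0.275
    return xd, yd


def daylight_spd(
    cct: float, wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
) -> IlluminantSpectrum:
    """CIE daylight-series illuminant of the given correlated colour
    temperature, on the requested grid, normalised to unit mean power.

    The spectrum is S0 + M1*S1 + M2*S2; the mixing weights are solved
    exactly so that the chromaticity of the result *on this grid, under
    this package's CMFs* equals the daylight-locus value for the CCT.
    """
    xd, yd = daylight_locus_chromaticity(cct)
    wl = _check_grid(wavelengths)
    src_wl, comps = _daylight_components()
    if wl[0] < src_wl[0] or wl[-1] > src_wl[-1]:
        raise DomainError("grid outside the tabulated daylight-component range")
    s = np.stack([np.interp(wl, src_wl, comps[:, i]) for i in range(3)], axis=1)

    cmf = xyz_cmf(wl)
    T = cmf.T @ s  # (3 XYZ) x (3 components)
    sums = T.sum(axis=0)
    # x*(X+Y+Z) = X and y*(X+Y+Z) = Y, linear in (M1, M2).
    A = np.array(
        [
            [T[0, 1] - xd * sums[1], T[0, 2] - xd * sums[2]],
            [T[1, 1] - yd * sums[1], T[1, 2] - yd * sums[2]],
        ]
    )
    rhs = np.array([xd * sums[0] - T[0, 0], yd * sums[0] - T[1, 0]])
    m1, m2 = np.linalg.solve(A, rhs)

    power = s[:, 0] + m1 * s[:, 1] + m2 * s[:, 2]
    power = np.clip(power, 0.0, None)
    power = power / power.mean()
    return IlluminantSpectrum(wl, power, cct=float(cct))


def reilluminate(cube, e0: IlluminantSpectrum, e_target: IlluminantSpectrum):
    """Swap the global illuminant of a radiance cube.

    Multiplies every pixel spectrum by ``e_target/e0``, which replaces
    the scene illuminant while leaving the effective reflectance fixed.
    """
    from .io import RadianceCube

    wl = cube.wavelengths
    e0r = e0.resampled(wl)
    etr = e_target.resampled(wl)
    if np.any(e0r.power <= 0):
        raise DomainError("reference illuminant must be strictly positive on the grid")
    ratio = etr.power / e0r.power
    return RadianceCube(
        values=cube.values * ratio,
        wavelengths=wl,
        timestamp=cube.timestamp,
        angular_subtense=cube.angular_subtense,
        units=cube.units,
    )
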