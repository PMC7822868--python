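"""Hyperspectral cube I/O and pixel sampling.

A :class:`RadianceCube` stores spectral radiance as a ``(height, width,
bands)`` array with a strictly increasing wavelength grid (natively
400-720 nm at 10 nm for the scenes this package analyses).  Cubes can be
round-tripped through three on-disk dialects: ENVI (raw + ``.hdr``),
HDF5 (``/radiance`` + ``/wavelengths``), and flat binary with a JSON
sidecar.

Pixel draws for the information estimates are uniform without
replacement; the draw is defined by *positions*, so the same draw can be
applied to both members of a registered image pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, DomainError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "RadianceCube",
    "PixelSample",
    "read_radiance_cube",
    "write_radiance_cube",
    "extract_strip",
    "sample_pixels",
    "sample_at",
]

#: Fraction of negative pixels above which a file is rejected outright.
_NEGATIVE_FRACTION_LIMIT = 0.01


@dataclass
class RadianceCube:
    """Spectral radiance image: ``values[row, col, band]``.

    ``units`` flags whether values are absolute (W m^-2 sr^-1 nm^-1) or
    relative; ``timestamp`` is acquisition time in minutes within the
    session; ``angular_subtense`` is the horizontal field of view in
    degrees, used to convert pixel positions to visual angle.
    """

    values: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: np.arange(400.0, 721.0, 10.0))
    timestamp: float | None = None
    angular_subtense: float | None = None
    units: str = "relative"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        if v.ndim != 3:
            raise FormatError("cube values must be 3-D (height, width, bands)")
        if wl.ndim != 1 or v.shape[2] != wl.size:
            raise FormatError("band count does not match wavelength grid")
        if wl.size > 1 and np.any(np.diff(wl) <= 0):
            raise FormatError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise DataError("cube contains non-finite radiance")
        neg = v < 0
        if neg.any():
            frac = neg.mean()
            if frac > _NEGATIVE_FRACTION_LIMIT:
                raise DataError(
                    f"{frac:.1%} of radiance values are negative (limit 1%)"
                )
            logger.warning("clipping %d small negative radiances to 0", int(neg.sum()))
            v = np.where(neg, 0.0, v)
        self.values = v
        self.wavelengths = wl

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class PixelSample:
    """Per-pixel radiance spectra drawn from one cube.

    ``coords`` holds ``(u, v) = (column, row)`` positions, 0-based with
    the origin at the top-left.
    """

    spectra: np.ndarray
    coords: np.ndarray
    source_timestamp: float | None = None

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.spectra.shape[0] != self.coords.shape[0]:
            raise FormatError("spectra and coords length mismatch")

    def __len__(self) -> int:
        return self.spectra.shape[0]


# ---------------------------------------------------------------------------
# Reading / writing

def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        return "hdf5"
    if suffix == ".raw" or Path(str(path) + ".hdr").exists() or path.with_suffix(".hdr").exists():
        return "envi"
    if Path(str(path) + ".json").exists():
        return "flat-binary"
    raise FormatError(f"cannot autodetect dialect for {path}")


def write_radiance_cube(cube: RadianceCube, path, dialect: str = "envi") -> None:
    """Write a cube losslessly (float64) in the chosen dialect."""
    path = Path(path)
    if dialect == "envi":
        _write_envi(cube, path)
    elif dialect == "hdf5":
        _write_hdf5(cube, path)
    elif dialect == "flat-binary":
        _write_flat(cube, path)
    else:
        raise FormatError(f"unsupported dialect {dialect!r}")


def read_radiance_cube(path, dialect: str | None = None) -> RadianceCube:
    """Read a cube, validating invariants and sorting bands ascending."""
    path = Path(path)
    if not path.exists() and not Path(str(path) + ".hdr").exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        dialect = _detect_dialect(path)
    if dialect == "envi":
        return _read_envi(path)
    if dialect == "hdf5":
        return _read_hdf5(path)
    if dialect == "flat-binary":
        return _read_flat(path)
    raise FormatError(f"unsupported dialect {dialect!r}")


def _make_cube(values, wavelengths, **kw) -> RadianceCube:
    """Build a cube from raw arrays, re-sorting bands ascending first."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    order = np.argsort(wavelengths)
    if np.any(order != np.arange(order.size)):
        logger.info("re-sorting %d bands into ascending wavelength order", order.size)
        values = values[:, :, order]
        wavelengths = wavelengths[order]
    return RadianceCube(values, wavelengths, **kw)


_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _write_envi(cube: RadianceCube, path: Path) -> None:
    data = np.ascontiguousarray(np.transpose(cube.values, (2, 0, 1)))  # BSQ
    hdr = path.with_suffix(path.suffix + ".hdr") if path.suffix != ".hdr" else path
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"samples = {cube.width}",
        f"lines = {cube.height}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[data.dtype]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = { " + wl + " }",
    ]
    if cube.timestamp is not None:
        lines.append(f"acquisition time = {cube.timestamp:g}")
    if cube.angular_subtense is not None:
        lines.append(f"angular subtense = {cube.angular_subtense:g}")
    hdr.write_text("\n".join(lines) + "\n")
    data.tofile(path)


def _read_envi(path: Path) -> RadianceCube:
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"ENVI header not found for {path}")
    fields: dict[str, str] = {}
    pending_key = None
    pending_val: list[str] = []
    for line in hdr_path.read_text().splitlines():
        line = line.strip()
        if pending_key is not None:
            pending_val.append(line)
            if "}" in line:
                fields[pending_key] = " ".join(pending_val)
                pending_key, pending_val = None, []
            continue
        if "=" not in line:
            continue
        key, val = (p.strip() for p in line.split("=", 1))
        if "{" in val and "}" not in val:
            pending_key, pending_val = key.lower(), [val]
        else:
            fields[key.lower()] = val
    try:
        samples = int(fields["samples"])
        nlines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype = _ENVI_DTYPES[int(fields["data type"])]
    except KeyError as exc:
        raise FormatError(f"ENVI header missing key: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header lacks wavelength metadata")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(t) for t in wl_text.replace(",", " ").split()])
    if wavelengths.size != bands:
        raise FormatError("wavelength list length differs from band count")
    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != samples * nlines * bands:
        raise FormatError("file size inconsistent with declared dimensions")
    if interleave == "bsq":
        values = raw.reshape(bands, nlines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(nlines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(nlines, samples, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    ts = float(fields["acquisition time"]) if "acquisition time" in fields else None
    sub = float(fields["angular subtense"]) if "angular subtense" in fields else None
    return _make_cube(values.astype(float), wavelengths, timestamp=ts, angular_subtense=sub)


def _write_hdf5(cube: RadianceCube, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("radiance", data=cube.values)
        f.create_dataset("wavelengths", data=cube.wavelengths)
        if cube.timestamp is not None:
            d.attrs["timestamp"] = cube.timestamp
        if cube.angular_subtense is not None:
            d.attrs["angular_subtense"] = cube.angular_subtense
        d.attrs["units"] = cube.units


def _read_hdf5(path: Path) -> RadianceCube:
    import h5py

    with h5py.File(path, "r") as f:
        if "radiance" not in f or "wavelengths" not in f:
            raise FormatError("HDF5 file lacks /radiance or /wavelengths")
        d = f["radiance"]
        return _make_cube(
            d[()],
            f["wavelengths"][()],
            timestamp=float(d.attrs["timestamp"]) if "timestamp" in d.attrs else None,
            angular_subtense=(
                float(d.attrs["angular_subtense"]) if "angular_subtense" in d.attrs else None
            ),
            units=str(d.attrs.get("units", "relative")),
        )


def _write_flat(cube: RadianceCube, path: Path) -> None:
    sidecar = {
        "shape": list(cube.values.shape),
        "dtype": "float64",
        "order": "C",
        "wavelengths": [float(w) for w in cube.wavelengths],
        "timestamp": cube.timestamp,
        "angular_subtense": cube.angular_subtense,
        "units": cube.units,
    }
    cube.values.astype(np.float64).tofile(path)
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def _read_flat(path: Path) -> RadianceCube:
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    if "wavelengths" not in meta:
        raise FormatError("sidecar lacks wavelength metadata")
    values = np.fromfile(path, dtype=meta.get("dtype", "float64")).reshape(meta["shape"])
    return _make_cube(
        values,
        np.asarray(meta["wavelengths"], dtype=float),
        timestamp=meta.get("timestamp"),
        angular_subtense=meta.get("angular_subtense"),
        units=meta.get("units", "relative"),
    )


# ---------------------------------------------------------------------------
# Sampling

def extract_strip(
    cube: RadianceCube,
    top_row: int,
    strip_height: int,
    strip_width: int,
    left_col: int = 0,
) -> PixelSample:
    """All pixels of a horizontal strip, row-major order."""
    if strip_height < 1 or strip_width < 1:
        raise DomainError("strip dimensions must be positive")
    if top_row < 0 or top_row + strip_height > cube.height:
        raise DomainError("strip rows out of bounds")
    if left_col < 0 or left_col + strip_width > cube.width:
        raise DomainError("strip columns out of bounds")
    block = cube.values[top_row : top_row + strip_height, left_col : left_col + strip_width]
    vv, uu = np.mgrid[top_row : top_row + strip_height, left_col : left_col + strip_width]
    coords = np.stack([uu.ravel(), vv.ravel()], axis=1)
    return PixelSample(block.reshape(-1, cube.n_bands), coords, cube.timestamp)


def sample_pixels(cube: RadianceCube, n: int, seed) -> PixelSample:
    """Draw ``n`` distinct pixels uniformly without replacement.

    The draw is deterministic given the seed, and is defined by pixel
    positions so the identical positions can be read from the partner
    cube of a registered pair via :func:`sample_at`.
    """
    total = cube.height * cube.width
    if n < 1 or n > total:
        raise DomainError(f"sample size {n} outside [1, {total}]")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n, replace=False)
    coords = np.stack([flat % cube.width, flat // cube.width], axis=1)
    return sample_at(cube, coords)


def sample_at(cube: RadianceCube, coords: np.ndarray) -> PixelSample:
    """Read spectra at explicit ``(u, v)`` positions (for paired cubes)."""
    coords = np.asarray(coords, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise FormatError("coords must have shape (n, 2)")
    u, v = coords[:, 0], coords[:, 1]
    if np.any(u < 0) or np.any(u >= cube.width) or np.any(v < 0) or np.any(v >= cube.height):
        raise DomainError("coordinates out of bounds")
    return PixelSample(cube.values[v, u], coords, cube.timestamp)
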