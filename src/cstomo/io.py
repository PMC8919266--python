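"""Domain containers and standard-format I/O for tomographic data.

Conventions used throughout the package
---------------------------------------
* Volumes are indexed ``(z, x)`` in 2D and ``(z, y, x)`` in 3D, where ``y``
  is the tilt axis and ``z`` is the beam direction at 0 deg tilt.
* Projections are indexed ``(y, u)``, with ``u`` the detector coordinate
  perpendicular to the tilt axis.  A tilt series of a 2D object (a single
  sinogram) stores one 1D projection per angle.
* Positive tilt rotates the specimen so that the ``+x`` direction moves
  toward ``+z``.
* All indexing is 0-based; ranges are half-open ``[start, stop)``.

Volumes and image stacks are stored as MRC2014 files (mode 2, float32,
little-endian; modes 0/1/2/6 accepted on read).  Tilt angles use the plain
text one-angle-per-line ".tlt" dialect.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "TiltSeries",
    "TiltGeometry",
    "MrcFormatError",
    "read_volume",
    "write_volume",
    "read_tilt_series",
    "write_tilt_series",
    "read_tilt_angles",
    "write_tilt_angles",
    "read_config",
]

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


class MrcFormatError(ValueError):
    """Raised when an MRC file cannot be interpreted."""


@dataclass
class Volume:
    """A 2D or 3D real-valued reconstruction grid.

    Parameters
    ----------
    data : ndarray
        ``(z, x)`` or ``(z, y, x)`` array of densities.
    pixel_size : float
        Sampling in Angstrom per voxel (> 0).
    origin : tuple of int
        Offset of this grid's first voxel inside a parent volume's index
        frame (used by chunked reconstruction); zeros for a standalone
        volume.
    """

    data: np.ndarray
    pixel_size: float = 1.0
    origin: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"Volume data must be 2D or 3D, got {self.data.ndim}D")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not self.origin:
            self.origin = (0,) * self.data.ndim

    @property
    def shape(self):
        return self.data.shape

    def require_finite(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values (NaN/Inf)")


@dataclass
class TiltSeries:
    """An ordered stack of projection images with one tilt angle each.

    ``images`` has shape ``(n_angles, ny, nu)`` for projections of a 3D
    object, or ``(n_angles, nu)`` for the sinogram of a 2D object.
    Angles are in degrees and strictly increasing.
    """

    images: np.ndarray
    angles: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim not in (2, 3):
            raise ValueError("images must be (n_angles, nu) or (n_angles, ny, nu)")
        if self.angles.ndim != 1 or len(self.angles) != self.images.shape[0]:
            raise ValueError(
                f"{len(self.angles)} angles for {self.images.shape[0]} images"
            )
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("tilt angles must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def n_angles(self):
        return len(self.angles)

    @property
    def projection_shape(self):
        return self.images.shape[1:]

    def geometry(self) -> "TiltGeometry":
        return TiltGeometry(angles=self.angles.copy())


@dataclass
class TiltGeometry:
    """Single-axis parallel-beam acquisition description.

    The tilt axis is the volume ``y`` axis; at 0 deg the beam runs along
    ``z``.  ``angles`` are degrees, positive rotating ``+x`` toward ``+z``.
    """

    angles: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))

    @property
    def n_angles(self):
        return len(self.angles)

    @property
    def angles_rad(self):
        return np.deg2rad(self.angles)


# ---------------------------------------------------------------------------
# MRC2014 I/O
# ---------------------------------------------------------------------------

def _read_header(raw: bytes, path):
    if len(raw) < _HEADER_SIZE:
        raise MrcFormatError(
            f"{path}: file too short for an MRC header "
            f"(need {_HEADER_SIZE} bytes, got {len(raw)} at offset 0)"
        )
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if mode not in _MODE_DTYPES:
        raise MrcFormatError(f"{path}: unsupported MRC mode {mode} at offset 12")
    if min(nx, ny, nz) <= 0 or max(nx, ny, nz) > 100_000:
        raise MrcFormatError(
            f"{path}: implausible dimensions ({nx}, {ny}, {nz}) at offset 0"
        )
    if nsymbt < 0:
        raise MrcFormatError(f"{path}: negative extended header size at offset 92")
    pixel = float(xlen) / mx if mx > 0 and xlen > 0 else 1.0
    return nx, ny, nz, mode, nsymbt, pixel


def _read_mrc(path):
    with open(path, "rb") as fh:
        raw = fh.read()
    nx, ny, nz, mode, nsymbt, pixel = _read_header(raw, path)
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    offset = _HEADER_SIZE + nsymbt
    nbytes = nx * ny * nz * dtype.itemsize
    if len(raw) < offset + nbytes:
        raise MrcFormatError(
            f"{path}: truncated data block (need {nbytes} bytes at offset "
            f"{offset}, file has {len(raw) - offset})"
        )
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz, offset=offset)
    return data.reshape(nz, ny, nx).astype(np.float32), pixel


def _write_mrc(data3d, pixel_size, path):
    data3d = np.ascontiguousarray(data3d, dtype="<f4")
    nz, ny, nx = data3d.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data3d.min()), float(data3d.max()),
        float(data3d.mean()),
    )
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data3d.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data3d.tobytes())


def read_volume(path) -> Volume:
    """Read an MRC volume; 3D data is ordered (sections, rows, columns).

    A single-section file is returned as a 2D volume.
    """
    data, pixel = _read_mrc(path)
    if data.shape[0] == 1:
        data = data[0]
    return Volume(data=data, pixel_size=pixel)


def write_volume(vol: Volume, path) -> None:
    """Write a volume as MRC mode 2 (float32, little-endian)."""
    vol.require_finite()
    data = vol.data
    if data.ndim == 2:
        data = data[None]
    _write_mrc(data, vol.pixel_size, path)


def read_tilt_series(mrc_path, tlt_path) -> TiltSeries:
    """Read a projection stack plus its ".tlt" angle file."""
    data, pixel = _read_mrc(mrc_path)
    angles = read_tilt_angles(tlt_path)
    if data.shape[1] == 1:  # sinogram of a 2D object
        data = data[:, 0, :]
    return TiltSeries(images=data, angles=np.asarray(angles), pixel_size=pixel)


def write_tilt_series(ts: TiltSeries, mrc_path, tlt_path=None) -> None:
    images = ts.images
    if images.ndim == 2:
        images = images[:, None, :]
    if not np.all(np.isfinite(images)):
        raise ValueError("tilt series contains non-finite values")
    _write_mrc(images, ts.pixel_size, mrc_path)
    if tlt_path is not None:
        write_tilt_angles(ts.angles, tlt_path)


def read_tilt_angles(path) -> list:
    """Parse a ".tlt" file: one tilt angle in degrees per non-empty line."""
    angles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip().replace("−", "-")  # tolerate unicode minus
            if not text:
                continue
            try:
                angles.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: not a number: {text!r}"
                ) from None
    if not angles:
        warnings.warn(f"{path}: empty tilt-angle file", stacklevel=2)
    return angles


def write_tilt_angles(angles, path) -> None:
    with open(path, "w") as fh:
        for a in angles:
            fh.write(f"{float(a):.2f}\n")


def read_config(path) -> dict:
    """Read a flat KEY=VALUE (or "KEY value") config file into a dict.

    Lines starting with '#' are comments.  Values are kept as strings; the
    CLI is responsible for type coercion, and CLI flags override config
    entries.
    """
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            if "=" in text:
                key, value = text.split("=", 1)
            else:
                parts = text.split(None, 1)
                if len(parts) != 2:
                    raise ValueError(f"{path}: line {lineno}: expected KEY=VALUE")
                key, value = parts
            out[key.strip().replace("-", "_")] = value.strip()
    return out
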