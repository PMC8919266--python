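"""Tilt-series conditioning ahead of non-negative reconstruction.

Cryo-EM projections record particles as dark (fewer counts) on a bright
background, while the compressed-sensing solver wants density-positive
data with a near-zero background.  This module provides the three
conditioning steps used for that conversion:

* background estimation, either from a particle-free region measured at
  every tilt (``flat``), or extrapolated from a 0-degree measurement with
  the slab path-length rule t(theta) = t0 / cos(theta) for specimens in a
  constant-thickness ice film (``slab``);
* intensity inversion relative to the background and rescaling to a
  global maximum of one;
* geometric, subpixel centering of a chosen particle on the tilt axis so
  each (sub)volume can be reconstructed in a small box around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import TiltSeries

__all__ = [
    "BackgroundModel",
    "ParticleCoordinate",
    "estimate_background_flat",
    "estimate_background_slab",
    "subtract_background",
    "invert_and_scale",
    "center_on_tilt_axis",
    "fourier_shift_image",
]


@dataclass
class BackgroundModel:
    """Per-tilt background intensity: ``flat`` stores a measured value per
    angle; ``slab`` stores the 0-degree level b0 and scales it by
    1 / cos(theta) (path length through a constant-thickness slab) in the
    linearized mass-thickness domain.  ``beer_lambert=True`` instead uses
    b(theta) = b0 ** (1 / cos theta) on normalized counts."""

    kind: str
    angles: np.ndarray
    per_tilt: np.ndarray
    b0: float = 0.0

    def value_at(self, angle_deg):
        idx = np.argmin(np.abs(self.angles - angle_deg))
        if not np.isclose(self.angles[idx], angle_deg):
            raise ValueError(f"no background entry for tilt {angle_deg}")
        return self.per_tilt[idx]


@dataclass
class ParticleCoordinate:
    """Particle position in pixels relative to the tilt-axis origin:
    ``x`` perpendicular to the tilt axis, ``z`` along the beam (at zero
    tilt), ``y`` along the tilt axis."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0

    def projected_u(self, angle_deg):
        """Detector-u position of the particle at the given tilt: the
        (x, z) position rotated into the detector frame.  Under the
        package's rotation convention (positive tilt moves +x toward +z)
        this is x cos(theta) - z sin(theta)."""
        t = np.deg2rad(angle_deg)
        return self.x * np.cos(t) - self.z * np.sin(t)


def _check_region(region, shape):
    y0, x0, y1, x1 = region
    ny, nx = shape
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"region {region} outside image of shape {shape}")
    return y0, x0, y1, x1


def _as_stack(ts: TiltSeries):
    imgs = ts.images
    return imgs[:, None, :] if imgs.ndim == 2 else imgs


def estimate_background_flat(ts: TiltSeries, region) -> BackgroundModel:
    """Mean intensity over a particle-free rectangle, measured per tilt.

    ``region`` is ``(y0, x0, y1, x1)`` in half-open image coordinates and
    must lie inside every image.
    """
    imgs = _as_stack(ts)
    y0, x0, y1, x1 = _check_region(region, imgs.shape[1:])
    per_tilt = imgs[:, y0:y1, x0:x1].mean(axis=(1, 2))
    return BackgroundModel(
        kind="flat", angles=ts.angles.copy(), per_tilt=per_tilt,
        b0=float(per_tilt[np.argmin(np.abs(ts.angles))]),
    )


def estimate_background_slab(ts: TiltSeries, region_at_zero,
                             beer_lambert=False) -> BackgroundModel:
    """Background from a region measured at (or nearest) 0 degrees,
    extrapolated to every tilt with the slab rule.

    In the linearized domain the ice path length grows as 1 / cos(theta),
    so per-tilt background = b0 / cos(theta).  With ``beer_lambert=True``
    normalized counts follow b0 ** (1 / cos theta) instead.
    """
    if np.any(np.abs(ts.angles) >= 90.0):
        raise ValueError("slab model undefined at |tilt| >= 90 degrees")
    imgs = _as_stack(ts)
    y0, x0, y1, x1 = _check_region(region_at_zero, imgs.shape[1:])
    ref = int(np.argmin(np.abs(ts.angles)))
    b0 = float(imgs[ref, y0:y1, x0:x1].mean())
    sec = 1.0 / np.cos(np.deg2rad(ts.angles))
    per_tilt = np.power(b0, sec) if beer_lambert else b0 * sec
    return BackgroundModel(kind="slab", angles=ts.angles.copy(),
                           per_tilt=per_tilt, b0=b0)


def subtract_background(ts: TiltSeries, bg: BackgroundModel) -> TiltSeries:
    """Subtract the per-tilt background level from every image."""
    shift = bg.per_tilt.reshape((-1,) + (1,) * (ts.images.ndim - 1))
    return TiltSeries(images=ts.images - shift, angles=ts.angles,
                      pixel_size=ts.pixel_size)


def invert_and_scale(ts: TiltSeries, bg: BackgroundModel) -> TiltSeries:
    """Invert intensities relative to the background and scale the whole
    series to a global maximum of one.

    Output = (background - input) / max over the series, so background
    regions map to ~0 and denser (darker) objects to positive values,
    compatible with the non-negative projector.  An all-background series
    is returned unscaled with a warning.
    """
    shift = bg.per_tilt.reshape((-1,) + (1,) * (ts.images.ndim - 1))
    inverted = shift - np.asarray(ts.images, dtype=np.float64)
    peak = inverted.max()
    if peak <= 0:
        warnings.warn("series is all background after inversion; not scaled",
                      stacklevel=2)
        return TiltSeries(images=inverted, angles=ts.angles,
                          pixel_size=ts.pixel_size)
    return TiltSeries(images=inverted / peak, angles=ts.angles,
                      pixel_size=ts.pixel_size)


def fourier_shift_image(image, shift):
    """Subpixel shift by Fourier phase ramp (periodic wrap)."""
    return np.fft.ifftn(
        ndimage.fourier_shift(np.fft.fftn(image), shift)
    ).real


def center_on_tilt_axis(ts: TiltSeries, coord: ParticleCoordinate,
                        box=None) -> TiltSeries:
    """Shift each image so the particle's predicted projection sits at the
    detector center at every tilt, then crop to ``box``.

    The image at tilt theta is shifted by
    -(x cos theta + z sin theta) along u and -y along the tilt axis with
    subpixel (Fourier) precision.  Shifted content wraps periodically;
    wrapped pixels must lie outside the retained box.
    """
    is_2d = ts.images.ndim == 2
    imgs = _as_stack(ts).astype(np.float64)
    n_tilt, ny, nu = imgs.shape
    u_shifts = np.array([-coord.projected_u(a) for a in ts.angles])
    y_shift = 0.0 if is_2d else -coord.y

    cy, cu = (ny - 1) / 2.0, (nu - 1) / 2.0
    if box is not None:
        half = box / 2.0
        bad = []
        for i, du in enumerate(u_shifts):
            pu = cu - du  # particle position along u before shifting
            py = cy - y_shift
            ok_u = half - 1 <= pu <= nu - half
            ok_y = is_2d or (half - 1 <= py <= ny - half)
            if not (ok_u and ok_y):
                bad.append(i)
        if bad:
            raise ValueError(
                f"particle track leaves the field of view at tilts {bad}"
            )

    shifted = np.empty_like(imgs, dtype=np.float64)
    for i in range(n_tilt):
        if is_2d:
            shifted[i, 0] = fourier_shift_image(imgs[i, 0], (u_shifts[i],))
        else:
            shifted[i] = fourier_shift_image(imgs[i], (y_shift, u_shifts[i]))

    if box is not None:
        u0 = int(round(cu - (box - 1) / 2.0))
        usel = slice(u0, u0 + box)
        if is_2d:
            shifted = shifted[:, :, usel]
        else:
            y0 = int(round(cy - (box - 1) / 2.0))
            shifted = shifted[:, y0 : y0 + box, usel]
    if is_2d:
        shifted = shifted[:, 0, :]
    return TiltSeries(images=shifted, angles=ts.angles, pixel_size=ts.pixel_size)
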