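"""Weighted back-projection (WBP) baseline reconstruction.

Each projection row along the detector coordinate ``u`` is filtered in
Fourier space with the ramp weight |k| (optionally Hamming-windowed), then
back-projected with the matched adjoint operator and scaled by
pi / (2 * n_angles).  With the ramp expressed in units of the Nyquist
frequency this normalization approximates the inverse Radon transform in
amplitude on densely sampled full-range data.

Filtering acts only along ``u``: the tilt axis direction is untilted and
must not be filtered.
"""

from __future__ import annotations

import numpy as np

from .io import TiltGeometry, TiltSeries, Volume
from .projector import back_project

__all__ = ["ramp_filter_weights", "ramp_filter", "wbp_reconstruct"]


def ramp_filter_weights(n, window="none"):
    """Frequency weights for a length-``n`` projection row.

    |k| normalized to 1 at Nyquist; weight at zero frequency is exactly 0.
    ``window="hamming"`` multiplies by the Hamming taper
    0.54 + 0.46 cos(pi k / k_Nyquist).
    """
    freq = np.fft.fftfreq(n)
    w = np.abs(2.0 * freq)
    if window == "hamming":
        w = w * (0.54 + 0.46 * np.cos(np.pi * np.abs(freq) / 0.5))
    elif window != "none":
        raise ValueError(f"unknown window {window!r} (choose 'none' or 'hamming')")
    return w


def ramp_filter(ts: TiltSeries, window="none") -> TiltSeries:
    """Apply the 1D ramp filter along ``u`` to every projection row."""
    n = ts.images.shape[-1]
    w = ramp_filter_weights(n, window)
    filtered = np.fft.ifft(np.fft.fft(ts.images, axis=-1) * w, axis=-1).real
    return TiltSeries(images=filtered, angles=ts.angles, pixel_size=ts.pixel_size)


def wbp_reconstruct(
    ts: TiltSeries, geom: TiltGeometry, window="none", volume_shape=None
) -> Volume:
    """Ramp-filter then back-project; linear in the tilt series."""
    if geom.n_angles < 2:
        raise ValueError("WBP needs at least 2 tilt angles")
    vol = back_project(ramp_filter(ts, window), geom, volume_shape=volume_shape)
    scale = np.pi / (2.0 * geom.n_angles)
    return Volume(data=scale * vol.data, pixel_size=vol.pixel_size)
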