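"""Quantitative evaluation of reconstructions: radial intensity profiles,
Fourier ring/shell correlation (FRC/FSC), and threshold-based resolution
estimation.

FSC follows the standard single-particle convention: shells are rounded
integer Fourier-voxel radii (DC is shell 0 and excluded from resolution
estimation), the correlation per shell s is

    Re{ sum F_a conj(F_b) } / sqrt( sum |F_a|^2 * sum |F_b|^2 ),

and the resolution is read off at the first downward crossing of the
chosen threshold (0.143 for independent half-maps, 0.5 against a trusted
reference), linearly interpolated between shells.  No masking or
phase-randomization correction is applied, so values are not directly
comparable with masked-FSC numbers from averaging pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Volume

__all__ = [
    "FscCurve",
    "RadialProfile",
    "ResolutionEstimate",
    "radial_average",
    "fsc",
    "frc_area",
    "resolution_at_threshold",
]


@dataclass
class FscCurve:
    """Per-shell spatial frequency (1/Angstrom) and correlation values."""

    shell_freq: np.ndarray
    correlation: np.ndarray
    n_voxels: np.ndarray
    box_size: int
    pixel_size: float


@dataclass
class RadialProfile:
    radius_bins: np.ndarray
    mean_intensity: np.ndarray
    counts: np.ndarray
    normalized: bool = False


@dataclass
class ResolutionEstimate:
    """Resolution in Angstrom plus whether the curve actually crossed the
    threshold (when it never does, the Nyquist resolution is reported and
    ``crossed`` is False; an immediately sub-threshold curve reports the
    lowest-frequency bound with ``below_from_start`` set)."""

    resolution: float
    frequency: float
    crossed: bool
    below_from_start: bool = False


def _radius_grid(shape):
    axes = [np.fft.fftfreq(n) * n for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.rint(np.sqrt(sum(g**2 for g in grids))).astype(np.int64)


def radial_average(vol, center=None, normalized=False) -> RadialProfile:
    """Mean intensity over integer-radius shells about ``center``
    (defaults to the geometric array center)."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if center is None:
        center = tuple((n - 1) / 2.0 for n in data.shape)
    center = tuple(float(c) for c in center)
    if len(center) != data.ndim:
        raise ValueError("center dimensionality does not match volume")
    for c, n in zip(center, data.shape):
        if not 0 <= c <= n - 1:
            raise ValueError(f"center {center} outside volume of shape {data.shape}")
    grids = np.meshgrid(*[np.arange(n) for n in data.shape], indexing="ij")
    r = np.rint(
        np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    ).astype(np.int64)
    counts = np.bincount(r.ravel())
    sums = np.bincount(r.ravel(), weights=data.ravel().astype(np.float64))
    mean = sums / np.maximum(counts, 1)
    if normalized:
        lo, hi = mean.min(), mean.max()
        mean = (mean - lo) / (hi - lo) if hi > lo else np.zeros_like(mean)
    return RadialProfile(
        radius_bins=np.arange(len(counts)),
        mean_intensity=mean,
        counts=counts,
        normalized=normalized,
    )


def fsc(vol_a, vol_b) -> FscCurve:
    """Fourier shell (3D) or ring (2D) correlation between two volumes of
    identical shape and pixel size."""
    a = vol_a.data if isinstance(vol_a, Volume) else np.asarray(vol_a)
    b = vol_b.data if isinstance(vol_b, Volume) else np.asarray(vol_b)
    pixel_a = vol_a.pixel_size if isinstance(vol_a, Volume) else 1.0
    pixel_b = vol_b.pixel_size if isinstance(vol_b, Volume) else 1.0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(pixel_a, pixel_b):
        raise ValueError(f"pixel size mismatch: {pixel_a} vs {pixel_b}")
    if len(set(a.shape)) != 1:
        raise ValueError("FSC requires a square/cubic box")
    n = a.shape[0]
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    r = _radius_grid(a.shape)
    n_shells = n // 2 + 1
    keep = r < n_shells
    rk = r[keep]
    num = np.bincount(rk.ravel(), weights=(fa[keep] * np.conj(fb[keep])).real.ravel(),
                      minlength=n_shells)
    pa = np.bincount(rk.ravel(), weights=(np.abs(fa[keep]) ** 2).ravel(),
                     minlength=n_shells)
    pb = np.bincount(rk.ravel(), weights=(np.abs(fb[keep]) ** 2).ravel(),
                     minlength=n_shells)
    nvox = np.bincount(rk.ravel(), minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(pa * pb)
    corr[nvox == 0] = np.nan  # empty shell: correlation undefined
    shells = np.arange(n_shells)
    return FscCurve(
        shell_freq=shells / (n * pixel_a),
        correlation=corr,
        n_voxels=nvox,
        box_size=n,
        pixel_size=pixel_a,
    )


def frc_area(curve: FscCurve, shell_lo=1, shell_hi=None) -> float:
    """Area under the correlation curve over a shell range (trapezoid)."""
    hi = curve.box_size // 2 if shell_hi is None else shell_hi
    c = curve.correlation[shell_lo : hi + 1]
    c = np.nan_to_num(c, nan=0.0)
    return float(np.trapezoid(c))


def resolution_at_threshold(curve: FscCurve, threshold, pixel_size=None
                            ) -> ResolutionEstimate:
    """Resolution at the first downward threshold crossing.

    The crossing shell is linearly interpolated between the last shell at
    or above the threshold and the first below it; resolution is
    1 / frequency in Angstrom.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    px = pixel_size if pixel_size is not None else curve.pixel_size
    n = curve.box_size
    corr = np.nan_to_num(curve.correlation, nan=0.0)
    nyq_freq = (n // 2) / (n * px)
    if corr[1] < threshold:
        freq = 1.0 / (n * px)
        return ResolutionEstimate(1.0 / freq, freq, False, below_from_start=True)
    for i in range(2, len(corr)):
        if corr[i] < threshold <= corr[i - 1]:
            shell = (i - 1) + (corr[i - 1] - threshold) / (corr[i - 1] - corr[i])
            freq = shell / (n * px)
            return ResolutionEstimate(1.0 / freq, freq, True)
    return ResolutionEstimate(1.0 / nyq_freq, nyq_freq, False)
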