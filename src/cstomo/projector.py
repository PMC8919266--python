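"""Matched real-space projection operators for single-axis parallel-beam
tomography.

The forward projector is ray-driven (Joseph-style): for each tilt angle and
detector bin, the line integral is approximated by sampling the volume at
unit-spaced points along the beam direction with bilinear interpolation.
The sampling weights are assembled once into a sparse matrix, so the
back-projector is the literal transpose of the forward operator — the
adjoint identity <P f, g> = <f, P^T g> holds to floating-point rounding,
which is what the primal-dual solver's convergence theory assumes.

A 3D single-axis acquisition decomposes into independent 2D problems per
tilt-axis row ``y``; the 2D ``(z, x) -> (angle, u)`` matrix is built once
and applied slice-by-slice.

Rays that leave the reconstruction grid simply integrate over whatever
support they cross; no circular field-of-view mask is imposed (edge
artifacts are instead cropped after reconstruction).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .io import TiltGeometry, TiltSeries, Volume

__all__ = ["ProjectionOperator", "forward_project", "back_project", "operator_norm"]


def _build_matrix(angles_deg, nz, nx, n_u):
    """Sparse (n_angles * n_u, nz * nx) Joseph-style sampling matrix.

    Detector bin k sits at u = k - (n_u - 1)/2 from the projection of the
    volume center.  Positive theta rotates the specimen so +x moves toward
    +z; equivalently the ray for (theta, u) passes through the specimen
    points  p(t) = c + u * (-sin t, cos t) + t * (cos t, sin t)  in (z, x).
    """
    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    u = np.arange(n_u) - (n_u - 1) / 2.0
    half_diag = 0.5 * float(np.hypot(nz, nx))
    t = np.arange(-np.ceil(half_diag) - 1, np.ceil(half_diag) + 2)

    rows_all, cols_all, vals_all = [], [], []
    for ia, ang in enumerate(np.deg2rad(angles_deg)):
        s, c = np.sin(ang), np.cos(ang)
        # sample positions, shape (n_u, n_t)
        pz = cz + u[:, None] * (-s) + t[None, :] * c
        px = cx + u[:, None] * c + t[None, :] * s
        z0 = np.floor(pz).astype(np.int64)
        x0 = np.floor(px).astype(np.int64)
        fz = pz - z0
        fx = px - x0
        row = np.broadcast_to(
            ia * n_u + np.arange(n_u)[:, None], pz.shape
        )
        for dz, dx, w in (
            (0, 0, (1 - fz) * (1 - fx)),
            (0, 1, (1 - fz) * fx),
            (1, 0, fz * (1 - fx)),
            (1, 1, fz * fx),
        ):
            zi, xi = z0 + dz, x0 + dx
            ok = (zi >= 0) & (zi < nz) & (xi >= 0) & (xi < nx) & (w > 0)
            rows_all.append(row[ok])
            cols_all.append((zi * nx + xi)[ok])
            vals_all.append(w[ok])

    mat = sparse.coo_matrix(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(len(angles_deg) * n_u, nz * nx),
    )
    return mat.tocsr()


class ProjectionOperator:
    """Forward/adjoint projection for one geometry and grid.

    Parameters
    ----------
    geometry : TiltGeometry
    volume_shape : tuple
        ``(nz, nx)`` or ``(nz, ny, nx)``.
    n_u : int, optional
        Detector bins per projection row; defaults to ``nx``.
    """

    def __init__(self, geometry: TiltGeometry, volume_shape, n_u=None):
        if len(volume_shape) not in (2, 3):
            raise ValueError("volume_shape must be 2D or 3D")
        self.geometry = geometry
        self.volume_shape = tuple(volume_shape)
        nz = volume_shape[0]
        nx = volume_shape[-1]
        self.n_u = int(n_u) if n_u is not None else nx
        self._ny = volume_shape[1] if len(volume_shape) == 3 else None
        if self._ny is None:
            self.projection_shape = (self.n_u,)
        else:
            self.projection_shape = (self._ny, self.n_u)
        self.data_shape = (geometry.n_angles,) + self.projection_shape
        self.matrix = _build_matrix(geometry.angles, nz, nx, self.n_u)

    # -- raw array interface (used by the solver) ---------------------------

    def apply(self, vol_data):
        vol_data = np.asarray(vol_data, dtype=np.float64)
        if vol_data.shape != self.volume_shape:
            raise ValueError(
                f"volume shape {vol_data.shape} != operator grid {self.volume_shape}"
            )
        nz = self.volume_shape[0]
        nx = self.volume_shape[-1]
        if self._ny is None:
            out = self.matrix @ vol_data.ravel()
            return out.reshape(self.geometry.n_angles, self.n_u)
        # (z, y, x) -> columns of y-slices
        v = vol_data.transpose(0, 2, 1).reshape(nz * nx, self._ny)
        out = self.matrix @ v  # (n_angles * n_u, ny)
        return out.reshape(self.geometry.n_angles, self.n_u, self._ny).transpose(
            0, 2, 1
        )

    def adjoint(self, proj_data):
        proj_data = np.asarray(proj_data, dtype=np.float64)
        if proj_data.shape != self.data_shape:
            raise ValueError(
                f"projection shape {proj_data.shape} != expected {self.data_shape}"
            )
        nz = self.volume_shape[0]
        nx = self.volume_shape[-1]
        if self._ny is None:
            out = self.matrix.T @ proj_data.ravel()
            return out.reshape(nz, nx)
        p = proj_data.transpose(0, 2, 1).reshape(
            self.geometry.n_angles * self.n_u, self._ny
        )
        out = self.matrix.T @ p  # (nz * nx, ny)
        return out.reshape(nz, nx, self._ny).transpose(0, 2, 1)


def forward_project(vol: Volume, geom: TiltGeometry, n_u=None) -> TiltSeries:
    """Project a volume: line integrals along the beam after tilting.

    Returns one projection per angle; linear in the volume.
    """
    op = ProjectionOperator(geom, vol.data.shape, n_u=n_u)
    return TiltSeries(
        images=op.apply(vol.data), angles=geom.angles, pixel_size=vol.pixel_size
    )


def back_project(ts: TiltSeries, geom: TiltGeometry, volume_shape=None) -> Volume:
    """Exact adjoint of :func:`forward_project` (transposed sampling weights)."""
    if ts.n_angles != geom.n_angles or not np.allclose(ts.angles, geom.angles):
        raise ValueError("tilt series angles do not match geometry")
    if volume_shape is None:
        volume_shape = _default_volume_shape(ts)
    op = ProjectionOperator(geom, volume_shape, n_u=ts.images.shape[-1])
    return Volume(data=op.adjoint(ts.images), pixel_size=ts.pixel_size)


def _default_volume_shape(ts: TiltSeries):
    n_u = ts.images.shape[-1]
    if ts.images.ndim == 2:
        return (n_u, n_u)
    return (n_u, ts.images.shape[1], n_u)


def operator_norm(forward, adjoint, domain_shape, iterations=50, seed=0) -> float:
    """Largest singular value of a linear operator by power iteration.

    ``forward``/``adjoint`` are callables on raw arrays.  Deterministic for
    a given seed; returns 0.0 for the zero operator.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(domain_shape)
    nv = np.linalg.norm(v)
    if nv == 0:
        return 0.0
    v /= nv
    sigma = 0.0
    for _ in range(int(iterations)):
        w = adjoint(forward(v))
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        sigma = np.sqrt(nw)  # ||K^T K v|| -> sigma^2 for unit v
        v = w / nw
    return float(sigma)
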