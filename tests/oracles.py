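"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use explicit Python loops and elementary formulas so
they share no code path with the package.
"""

import numpy as np


def loop_projector_matrix(angles_deg, nz, nx, n_u):
    """Dense projection matrix built by explicitly walking each ray at unit
    steps and accumulating bilinear interpolation weights."""
    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    half_diag = 0.5 * np.hypot(nz, nx)
    t_lo, t_hi = -int(np.ceil(half_diag)) - 1, int(np.ceil(half_diag)) + 1
    mat = np.zeros((len(angles_deg) * n_u, nz * nx))
    for ia, ang in enumerate(angles_deg):
        th = np.deg2rad(ang)
        s, c = np.sin(th), np.cos(th)
        for k in range(n_u):
            u = k - (n_u - 1) / 2.0
            row = ia * n_u + k
            for t in range(t_lo, t_hi + 1):
                pz = cz - u * s + t * c
                px = cx + u * c + t * s
                z0, x0 = int(np.floor(pz)), int(np.floor(px))
                fz, fx = pz - z0, px - x0
                for dz in (0, 1):
                    for dx in (0, 1):
                        zi, xi = z0 + dz, x0 + dx
                        if 0 <= zi < nz and 0 <= xi < nx:
                            w = (fz if dz else 1 - fz) * (fx if dx else 1 - fx)
                            mat[row, zi * nx + xi] += w
    return mat


def materialize(apply_fn, in_shape, out_size):
    """Dense matrix of a linear operator by applying it to basis vectors."""
    n = int(np.prod(in_shape))
    mat = np.zeros((out_size, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        mat[:, j] = np.asarray(apply_fn(e.reshape(in_shape))).ravel()
    return mat


def brute_radial_average(data, center):
    """Per-voxel loop binning by rounded Euclidean radius."""
    sums, counts = {}, {}
    for idx in np.ndindex(data.shape):
        r = int(round(np.sqrt(sum((i - c) ** 2 for i, c in zip(idx, center)))))
        sums[r] = sums.get(r, 0.0) + float(data[idx])
        counts[r] = counts.get(r, 0) + 1
    nmax = max(sums) + 1
    mean = np.zeros(nmax)
    cnt = np.zeros(nmax, dtype=int)
    for r in sums:
        mean[r] = sums[r] / counts[r]
        cnt[r] = counts[r]
    return mean, cnt
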