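"""Second-order total variation: finite-difference Hessian operator, its
exact adjoint, the TV^2 functional, and the proximal operators used by the
primal-dual solver.  First-order TV (gradient/divergence) is provided with
the same contracts as a negative control.

Stencils and boundary rule
--------------------------
Pure second differences use the central stencil [1, -2, 1]; mixed second
differences use the forward-of-forward stencil on each axis pair.  Every
stencil is evaluated only where it is fully supported inside the grid and
the remaining edge samples carry zeros (a Neumann-type rule): constants and
affine trends are therefore never penalized, anywhere — H(affine) == 0
exactly, interior and boundary — and the volume's overall intensity offset
is free.  Zero padding would instead penalize the volume boundary heavily
and create halo artifacts.

Grouping
--------
``aniso``: l1 over all components, off-diagonal terms counted twice (the
symmetric Hessian has each unordered pair once).  ``iso`` (default): sum
over voxels of the Frobenius norm of the per-voxel Hessian, off-diagonal
terms weighted sqrt(2) inside the norm — a rotation-invariant penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HessianField",
    "HessianOperator",
    "GradientOperator",
    "hessian_apply",
    "hessian_adjoint",
    "tv2_norm",
    "tv1_norm",
    "prox_l1_dual",
    "prox_data_dual",
]


def _sl(ndim, axis, s):
    """Index tuple selecting slice ``s`` along ``axis``."""
    out = [slice(None)] * ndim
    out[axis] = s
    return tuple(out)


def _second_diff(f, axis):
    out = np.zeros_like(f)
    nd = f.ndim
    out[_sl(nd, axis, slice(1, -1))] = (
        f[_sl(nd, axis, slice(2, None))]
        - 2.0 * f[_sl(nd, axis, slice(1, -1))]
        + f[_sl(nd, axis, slice(None, -2))]
    )
    return out


def _second_diff_adj(g, axis):
    out = np.zeros_like(g)
    nd = g.ndim
    gi = g[_sl(nd, axis, slice(1, -1))]
    out[_sl(nd, axis, slice(None, -2))] += gi
    out[_sl(nd, axis, slice(1, -1))] -= 2.0 * gi
    out[_sl(nd, axis, slice(2, None))] += gi
    return out


def _mixed_diff(f, ax_a, ax_b):
    out = np.zeros_like(f)
    nd = f.ndim
    a0, a1 = slice(None, -1), slice(1, None)

    # valid region: all but the last sample along both axes
    def s(sa, sb):
        idx = [slice(None)] * nd
        idx[ax_a], idx[ax_b] = sa, sb
        return tuple(idx)

    out[s(a0, a0)] = f[s(a1, a1)] - f[s(a1, a0)] - f[s(a0, a1)] + f[s(a0, a0)]
    return out


def _mixed_diff_adj(g, ax_a, ax_b):
    out = np.zeros_like(g)
    nd = g.ndim
    a0, a1 = slice(None, -1), slice(1, None)

    def s(sa, sb):
        idx = [slice(None)] * nd
        idx[ax_a], idx[ax_b] = sa, sb
        return tuple(idx)

    gi = g[s(a0, a0)]
    out[s(a1, a1)] += gi
    out[s(a1, a0)] -= gi
    out[s(a0, a1)] -= gi
    out[s(a0, a0)] += gi
    return out


def _component_pairs(ndim):
    pairs = [(i, i) for i in range(ndim)]
    pairs += [(i, j) for i in range(ndim) for j in range(i + 1, ndim)]
    return pairs


@dataclass
class HessianField:
    """Stacked unique second-difference images of a d-dimensional volume.

    ``components[k]`` corresponds to ``index_pairs[k]`` ((i, i) pure terms
    first, then (i, j) mixed terms, i < j).  ``off_diagonal_multiplicity``
    records how mixed terms are counted in the anisotropic norm.
    """

    components: np.ndarray
    index_pairs: list
    off_diagonal_multiplicity: float = 2.0

    @property
    def volume_shape(self):
        return self.components.shape[1:]

    def _is_diag(self):
        return np.array([i == j for i, j in self.index_pairs])


class HessianOperator:
    """Linear operator stacking all unique second differences.

    With ``weighted=True`` (what the solver uses), each component is scaled
    so that the plain l1 / per-voxel l2 norm of the output equals the
    anisotropic / isotropic TV^2 value: off-diagonal weight 2 for
    anisotropic grouping, sqrt(2) for isotropic.
    """

    def __init__(self, shape, grouping="iso", weighted=True):
        if any(n < 3 for n in shape):
            raise ValueError(f"need >= 3 samples per dimension, got {shape}")
        if grouping not in ("iso", "aniso"):
            raise ValueError(f"unknown grouping {grouping!r}")
        self.shape = tuple(shape)
        self.grouping = grouping
        self.pairs = _component_pairs(len(shape))
        off_w = (np.sqrt(2.0) if grouping == "iso" else 2.0) if weighted else 1.0
        self.weights = np.array([1.0 if i == j else off_w for i, j in self.pairs])

    @property
    def n_components(self):
        return len(self.pairs)

    def apply(self, vol_data):
        f = np.asarray(vol_data, dtype=np.float64)
        if f.shape != self.shape:
            raise ValueError(f"volume shape {f.shape} != operator grid {self.shape}")
        out = np.empty((self.n_components,) + self.shape)
        for k, (i, j) in enumerate(self.pairs):
            comp = _second_diff(f, i) if i == j else _mixed_diff(f, i, j)
            out[k] = self.weights[k] * comp
        return out

    def adjoint(self, field):
        q = np.asarray(field, dtype=np.float64)
        if q.shape != (self.n_components,) + self.shape:
            raise ValueError(
                f"field shape {q.shape} != {(self.n_components,) + self.shape}"
            )
        out = np.zeros(self.shape)
        for k, (i, j) in enumerate(self.pairs):
            adj = _second_diff_adj(q[k], i) if i == j else _mixed_diff_adj(q[k], i, j)
            out += self.weights[k] * adj
        return out


class GradientOperator:
    """Forward-difference gradient with zero at the trailing edge; the
    adjoint is the matching negative divergence (first-order TV building
    block)."""

    def __init__(self, shape):
        if any(n < 2 for n in shape):
            raise ValueError(f"need >= 2 samples per dimension, got {shape}")
        self.shape = tuple(shape)
        self.n_components = len(shape)

    def apply(self, vol_data):
        f = np.asarray(vol_data, dtype=np.float64)
        if f.shape != self.shape:
            raise ValueError(f"volume shape {f.shape} != operator grid {self.shape}")
        nd = f.ndim
        out = np.zeros((nd,) + f.shape)
        for ax in range(nd):
            out[ax][_sl(nd, ax, slice(None, -1))] = (
                f[_sl(nd, ax, slice(1, None))] - f[_sl(nd, ax, slice(None, -1))]
            )
        return out

    def adjoint(self, field):
        q = np.asarray(field, dtype=np.float64)
        if q.shape != (self.n_components,) + self.shape:
            raise ValueError("gradient field shape mismatch")
        nd = len(self.shape)
        out = np.zeros(self.shape)
        for ax in range(nd):
            gi = q[ax][_sl(nd, ax, slice(None, -1))]
            out[_sl(nd, ax, slice(1, None))] += gi
            out[_sl(nd, ax, slice(None, -1))] -= gi
        return out


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def hessian_apply(vol_data) -> HessianField:
    """All unique second differences of a volume (unweighted components)."""
    op = HessianOperator(np.shape(vol_data), weighted=False)
    return HessianField(components=op.apply(vol_data), index_pairs=op.pairs)


def hessian_adjoint(field: HessianField) -> np.ndarray:
    """Exact transpose of :func:`hessian_apply` (same boundary handling)."""
    op = HessianOperator(field.volume_shape, weighted=False)
    return op.adjoint(field.components)


def tv2_norm(vol_data, grouping="iso") -> float:
    """TV^2 of a volume: 0 iff the volume is affine.

    ``aniso``: sum of |components| with off-diagonal multiplicity 2.
    ``iso``: sum over voxels of the Frobenius norm of the per-voxel
    Hessian (off-diagonal terms weighted sqrt(2) inside the norm).
    """
    op = HessianOperator(np.shape(vol_data), grouping=grouping, weighted=True)
    q = op.apply(vol_data)
    if grouping == "aniso":
        return float(np.abs(q).sum())
    return float(np.sqrt((q**2).sum(axis=0)).sum())


def tv1_norm(vol_data) -> float:
    """Anisotropic first-order total variation (l1 of forward differences)."""
    op = GradientOperator(np.shape(vol_data))
    return float(np.abs(op.apply(vol_data)).sum())


def prox_l1_dual(field, lam, grouping="iso"):
    """Project a dual field onto the constraint set of the TV term's
    convex conjugate: componentwise clamp to [-lam, lam] (anisotropic) or
    per-voxel rescaling to Frobenius norm <= lam (isotropic).  Idempotent.

    ``field`` is a stacked component array (component axis first), already
    carrying any grouping weights; a :class:`HessianField` is accepted and
    returned as the same type.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    as_field = isinstance(field, HessianField)
    q = np.asarray(field.components if as_field else field, dtype=np.float64)
    if grouping == "aniso":
        out = np.clip(q, -lam, lam)
    elif grouping == "iso":
        mag = np.sqrt((q**2).sum(axis=0))
        scale = np.ones_like(mag)
        over = mag > lam
        if lam == 0:
            scale[:] = 0.0
        else:
            scale[over] = lam / mag[over]
        out = q * scale
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if as_field:
        return HessianField(components=out, index_pairs=field.index_pairs)
    return out


def prox_data_dual(p, g, sigma):
    """Resolvent of the data-fidelity term's conjugate:
    ``(p - sigma * g) / (1 + sigma)`` elementwise."""
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return (np.asarray(p, dtype=np.float64) - sigma * np.asarray(g)) / (1.0 + sigma)
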