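"""Primal-dual hybrid gradient (Chambolle-Pock) solver for the
compressed-sensing tomography problem

    min_{f >= 0}  || P f - g ||_2^2  +  lambda * TV2(f)

where P is the matched real-space projector and TV2 the second-order
total-variation penalty.  The saddle-point reformulation introduces a dual
variable for the data term and one for the regularizer; each iteration
applies the closed-form resolvents (``prox_data_dual``, ``prox_l1_dual``),
a gradient step on the primal with projection onto the non-negative
orthant, and over-relaxation f_bar = f + theta (f - f_prev).

Step sizes default to tau = sigma = 0.99 / ||K||, with ||K|| of the stacked
operator K = [P; H] estimated by seeded power iteration, which satisfies
the convergence condition tau * sigma * ||K||^2 <= 1 with margin.  The
iteration count is fixed (no tolerance-based early exit): runs are
bit-reproducible given the same configuration.

lambda is applied against the data term exactly as written, with no
internal normalization by data size, so useful values scale with image
size and intensity.  Note the solver's resolvents correspond to a data
term (1/2)||P f - g||^2; quoting lambda against the un-halved objective
reported by :func:`objective` doubles it.

First-order TV (``cstv1_reconstruct``) is provided as a negative control:
on smoothly varying specimens it is known to staircase or flatten, which
is the behavior the second-order penalty exists to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .io import TiltGeometry, TiltSeries, Volume
from .projector import ProjectionOperator, operator_norm
from .tv2 import (
    GradientOperator,
    HessianOperator,
    prox_data_dual,
    prox_l1_dual,
    tv2_norm,
)

__all__ = [
    "SolverConfig",
    "SolverState",
    "cstv2_reconstruct",
    "cstv1_reconstruct",
    "objective",
    "select_lambda_by_halfmap_fsc",
]


@dataclass
class SolverConfig:
    """Settings for one CS reconstruction.

    lam is the regularization weight (>= 0, unitless); iterations the fixed
    PDHG step count; tau/sigma the primal/dual step sizes (derived from the
    operator norm when left unset); theta the over-relaxation parameter in
    [0, 1]; nonneg enforces f >= 0; grouping selects the TV^2 dual ball
    ("iso" Frobenius / "aniso" componentwise); seed drives the power
    iteration; warm_start may be "wbp".
    """

    lam: float = 0.05
    iterations: int = 200
    tau: float | None = None
    sigma: float | None = None
    theta: float = 1.0
    nonneg: bool = True
    grouping: str = "iso"
    seed: int = 0
    norm_iterations: int = 50
    record_objective: bool = False
    warm_start: str | None = None

    def validate(self):
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if self.grouping not in ("iso", "aniso"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class SolverState:
    """Final iterates of a PDHG run."""

    primal: np.ndarray
    primal_bar: np.ndarray
    dual_data: np.ndarray
    dual_reg: np.ndarray
    iteration: int
    objective_trace: list = dataclass_field(default_factory=list)
    tau: float = 0.0
    sigma: float = 0.0
    op_norm: float = 0.0


def _default_volume_shape(ts: TiltSeries):
    n_u = ts.images.shape[-1]
    if ts.images.ndim == 2:
        return (n_u, n_u)
    return (n_u, ts.images.shape[1], n_u)


def _run_pdhg(ts, geom, cfg, reg_op, reg_grouping, volume_shape):
    cfg.validate()
    if ts.n_angles != geom.n_angles or not np.allclose(ts.angles, geom.angles):
        raise ValueError("tilt series angles do not match geometry")
    proj = ProjectionOperator(geom, volume_shape, n_u=ts.images.shape[-1])
    g = np.asarray(ts.images, dtype=np.float64)

    def k_fwd(f):
        return proj.apply(f), reg_op.apply(f)

    def k_adj(pq):
        return proj.adjoint(pq[0]) + reg_op.adjoint(pq[1])

    field_shape = (reg_op.n_components,) + tuple(volume_shape)
    norm_k = operator_norm(
        lambda f: _stack(k_fwd(f)),
        lambda w: k_adj(_unstack(w, proj.data_shape, field_shape)),
        volume_shape,
        iterations=cfg.norm_iterations,
        seed=cfg.seed,
    )
    if norm_k == 0:
        raise ValueError("stacked operator has zero norm")
    tau = cfg.tau if cfg.tau is not None else 0.99 / norm_k
    sigma = cfg.sigma if cfg.sigma is not None else 0.99 / norm_k
    if tau * sigma * norm_k**2 > 1.0 + 1e-9:
        raise ValueError(
            f"step sizes violate tau*sigma*||K||^2 <= 1 "
            f"(got {tau * sigma * norm_k**2:.4f})"
        )

    if cfg.warm_start == "wbp":
        from .wbp import wbp_reconstruct

        f = wbp_reconstruct(ts, geom, volume_shape=volume_shape).data
        if cfg.nonneg:
            f = np.maximum(f, 0.0)
    elif cfg.warm_start is None:
        f = np.zeros(volume_shape)
    else:
        raise ValueError(f"unknown warm start {cfg.warm_start!r}")
    f_bar = f.copy()
    p = np.zeros(proj.data_shape)
    q = np.zeros((reg_op.n_components,) + tuple(volume_shape))

    trace = []
    for it in range(1, cfg.iterations + 1):
        p = prox_data_dual(p + sigma * proj.apply(f_bar), g, sigma)
        q = prox_l1_dual(q + sigma * reg_op.apply(f_bar), cfg.lam, reg_grouping)
        f_new = f - tau * (proj.adjoint(p) + reg_op.adjoint(q))
        if cfg.nonneg:
            np.maximum(f_new, 0.0, out=f_new)
        f_bar = f_new + cfg.theta * (f_new - f)
        f = f_new
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"non-finite iterate at iteration {it}")
        if cfg.record_objective:
            resid = proj.apply(f) - g
            reg_val = _penalty_value(reg_op.apply(f), reg_grouping)
            trace.append(float((resid**2).sum() + cfg.lam * reg_val))

    state = SolverState(
        primal=f,
        primal_bar=f_bar,
        dual_data=p,
        dual_reg=q,
        iteration=cfg.iterations,
        objective_trace=trace,
        tau=tau,
        sigma=sigma,
        op_norm=norm_k,
    )
    return Volume(data=f, pixel_size=ts.pixel_size), state


def _stack(pq):
    return np.concatenate([pq[0].ravel(), pq[1].ravel()])

def _unstack(w, data_shape, field_shape):
    n = int(np.prod(data_shape))
    return w[:n].reshape(data_shape), w[n:].reshape(field_shape)


def _penalty_value(field, grouping):
    if grouping == "aniso":
        return float(np.abs(field).sum())
    return float(np.sqrt((np.asarray(field) ** 2).sum(axis=0)).sum())


def cstv2_reconstruct(ts, geom, cfg: SolverConfig, volume_shape=None):
    """CS-TV^2 reconstruction by PDHG; returns (Volume, SolverState)."""
    if volume_shape is None:
        volume_shape = _default_volume_shape(ts)
    reg = HessianOperator(volume_shape, grouping=cfg.grouping, weighted=True)
    return _run_pdhg(ts, geom, cfg, reg, cfg.grouping, volume_shape)


def cstv1_reconstruct(ts, geom, cfg: SolverConfig, volume_shape=None):
    """First-order TV reconstruction (negative control): same solver with
    the forward-difference gradient and the l-infinity dual ball."""
    if volume_shape is None:
        volume_shape = _default_volume_shape(ts)
    reg = GradientOperator(volume_shape)
    state = _run_pdhg(ts, geom, cfg, reg, "aniso", volume_shape)
    return state


def objective(f, ts: TiltSeries, geom: TiltGeometry, cfg: SolverConfig) -> float:
    """|| P f - g ||^2 + lambda * TV2(f) for a candidate volume."""
    data = f.data if isinstance(f, Volume) else np.asarray(f)
    proj = ProjectionOperator(geom, data.shape, n_u=ts.images.shape[-1])
    resid = proj.apply(data) - np.asarray(ts.images, dtype=np.float64)
    return float((resid**2).sum() + cfg.lam * tv2_norm(data, cfg.grouping))


def select_lambda_by_halfmap_fsc(ts_a, ts_b, geom, lambdas, cfg: SolverConfig,
                                 volume_shape=None):
    """Pick lambda by self-consistency of two half-set reconstructions.

    Reconstructs both tilt series (independent noise realizations of the
    same object) at each candidate lambda and scores the area under the
    FSC/FRC between the two half-reconstructions; returns
    ``(best_lambda, {lambda: area})``.  This mirrors the practice of
    choosing the weight that maximizes gold-standard half-map agreement.
    """
    from .metrics import fsc

    areas = {}
    for lam in lambdas:
        run_cfg = SolverConfig(**{**cfg.__dict__, "lam": float(lam)})
        va, _ = cstv2_reconstruct(ts_a, geom, run_cfg, volume_shape=volume_shape)
        vb, _ = cstv2_reconstruct(ts_b, geom, run_cfg, volume_shape=volume_shape)
        curve = fsc(va, vb)
        areas[float(lam)] = float(np.trapezoid(curve.correlation))
    best = max(areas, key=areas.get)
    return best, areas
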