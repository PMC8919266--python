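"""Chunked reconstruction along the tilt axis with overlap-removed
stitching.

Under single-axis parallel-beam geometry the projector is block-separable
across tilt-axis rows, so a volume too large for one solve can be
reconstructed chunk by chunk along ``y``: each chunk sees only its own
rows of the tilt series.  The TV^2 penalty couples rows within a chunk but
not across chunks, so adjacent chunk ranges share ``2 * overlap`` rows and
each chunk discards ``overlap`` rows at every edge shared with a
neighbor; the first and last chunk keep their outer rows.  The retained
sub-ranges tile the axis exactly once — stitching writes each output row
from exactly one chunk and never averages.

Chunking along ``u`` or ``z`` is disallowed: it would change the inverse
problem, not just its partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TiltGeometry, TiltSeries, Volume
from .pdhg import SolverConfig, cstv2_reconstruct
from .wbp import wbp_reconstruct

__all__ = ["ChunkPlan", "plan_chunks", "reconstruct_chunked"]


@dataclass
class ChunkPlan:
    """Half-open chunk ranges plus the retained sub-range of each."""

    axis_length: int
    chunk_extent: int
    overlap: int
    chunks: list  # of (start, stop)
    retained: list  # of (start, stop), tiling [0, axis_length)

    def validate(self):
        covered = np.zeros(self.axis_length, dtype=int)
        for (c0, c1), (r0, r1) in zip(self.chunks, self.retained):
            if not (0 <= c0 < c1 <= self.axis_length):
                raise ValueError(f"chunk ({c0}, {c1}) outside axis")
            if not (c0 <= r0 < r1 <= c1):
                raise ValueError(f"retained ({r0}, {r1}) outside chunk ({c0}, {c1})")
            covered[r0:r1] += 1
        if not np.all(covered == 1):
            raise ValueError("retained ranges do not tile the axis exactly once")


def plan_chunks(axis_length, chunk_extent, overlap) -> ChunkPlan:
    """Deterministic chunk plan along the tilt axis.

    Consecutive chunk starts advance by ``chunk_extent - 2 * overlap``;
    the last chunk is shifted left to end exactly at ``axis_length`` (all
    chunks have equal size, for predictable memory) and the retained
    ranges are adjusted to preserve the exact tiling.
    """
    axis_length, chunk_extent, overlap = (
        int(axis_length), int(chunk_extent), int(overlap)
    )
    if not (0 <= 2 * overlap < chunk_extent <= axis_length):
        raise ValueError(
            f"need 0 <= 2*overlap < chunk_extent <= axis_length, got "
            f"overlap={overlap}, chunk_extent={chunk_extent}, "
            f"axis_length={axis_length}"
        )
    step = chunk_extent - 2 * overlap
    starts = list(range(0, max(axis_length - chunk_extent, 0) + 1, step))
    if starts[-1] + chunk_extent < axis_length:
        starts.append(axis_length - chunk_extent)
    chunks = [(s, s + chunk_extent) for s in starts]

    retained = []
    prev_stop = 0
    for i, (c0, c1) in enumerate(chunks):
        r0 = prev_stop
        r1 = axis_length if i == len(chunks) - 1 else c1 - overlap
        retained.append((r0, r1))
        prev_stop = r1
    plan = ChunkPlan(axis_length, chunk_extent, overlap, chunks, retained)
    plan.validate()
    return plan


def reconstruct_chunked(ts: TiltSeries, geom: TiltGeometry, plan: ChunkPlan,
                        algorithm="cstv2", cfg: SolverConfig | None = None,
                        window="none", volume_shape=None) -> Volume:
    """Reconstruct chunk by chunk along the tilt axis and stitch.

    Each chunk is reconstructed from its own tilt-series rows (the
    projector is row-separable) and only its retained sub-range is written
    to the output; a write-count map asserts that every output voxel is
    produced by exactly one chunk.
    """
    if ts.images.ndim != 3:
        raise ValueError("chunked reconstruction needs a 3D tilt series")
    ny = ts.images.shape[1]
    if plan.axis_length != ny:
        raise ValueError(
            f"plan covers {plan.axis_length} rows but tilt series has {ny}"
        )
    if volume_shape is None:
        n_u = ts.images.shape[-1]
        volume_shape = (n_u, ny, n_u)
    if volume_shape[1] != ny:
        raise ValueError("volume tilt-axis extent must match the tilt series")

    out = np.zeros(volume_shape)
    writes = np.zeros(ny, dtype=int)
    for (c0, c1), (r0, r1) in zip(plan.chunks, plan.retained):
        sub = TiltSeries(images=ts.images[:, c0:c1, :], angles=ts.angles,
                         pixel_size=ts.pixel_size)
        sub_shape = (volume_shape[0], c1 - c0, volume_shape[2])
        if algorithm == "wbp":
            vol = wbp_reconstruct(sub, geom, window=window,
                                  volume_shape=sub_shape)
        elif algorithm == "cstv2":
            vol, _ = cstv2_reconstruct(sub, geom, cfg or SolverConfig(),
                                       volume_shape=sub_shape)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        out[:, r0:r1, :] = vol.data[:, r0 - c0 : r1 - c0, :]
        writes[r0:r1] += 1
    if not np.all(writes == 1):
        raise AssertionError("stitching wrote some rows zero or multiple times")
    return Volume(data=out, pixel_size=ts.pixel_size)
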