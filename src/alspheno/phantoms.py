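"""Deterministic geometric phantoms of known fractal dimension.

These volumes validate the box-counting estimator: a straight line has
dimension 1, a filled plane 2, a solid cube or ball 3, a tube ~1 at
coarse scales, and the level-``l`` Menger sponge has Hausdorff dimension
log 20 / log 3 ~ 2.727.
"""

from __future__ import annotations

import numpy as np

from .volume import BinaryVolume

PHANTOM_KINDS = ("line", "plane", "cube", "ball", "tube", "menger_sponge")


def _menger_mask(level: int) -> np.ndarray:
    """Level-``level`` Menger sponge on a 3**level-per-side boolean grid."""
    mask = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        n = mask.shape[0]
        out = np.zeros((3 * n, 3 * n, 3 * n), dtype=bool)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    # A subcube is kept unless two or more indices are central.
                    if (i == 1) + (j == 1) + (k == 1) >= 2:
                        continue
                    out[i * n:(i + 1) * n, j * n:(j + 1) * n, k * n:(k + 1) * n] = mask
        mask = out
    return mask


def generate_phantom(kind: str, size: int = 64, level: int | None = None) -> BinaryVolume:
    """Build a named geometric phantom.

    Parameters
    ----------
    kind:
        One of ``line``, ``plane``, ``cube``, ``ball``, ``tube``,
        ``menger_sponge``.
    size:
        Edge length of the cubic grid (>= 8).  Ignored for the Menger
        sponge, whose grid is ``3**level`` per side.
    level:
        Recursion depth; required for (and only valid for) the sponge.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}")
    if kind == "menger_sponge":
        if level is None or level < 1:
            raise ValueError("menger_sponge requires level >= 1")
        return BinaryVolume(_menger_mask(level))
    if level is not None:
        raise ValueError(f"level is only valid for menger_sponge, not {kind!r}")
    if size < 8:
        raise ValueError("size must be >= 8")

    grid = np.zeros((size, size, size), dtype=bool)
    c = size // 2
    if kind == "line":
        grid[:, c, c] = True
    elif kind == "plane":
        grid[:, :, c] = True
    elif kind == "cube":
        grid[:, :, :] = True
    elif kind == "ball":
        ax = np.arange(size) - (size - 1) / 2.0
        r2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        grid = r2 <= ((size - 1) / 2.0) ** 2
    elif kind == "tube":
        ax = np.arange(size) - (size - 1) / 2.0
        r2 = ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        grid = np.broadcast_to(r2 <= 2.0 ** 2, (size, size, size)).copy()
    return BinaryVolume(grid)
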