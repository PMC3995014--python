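"""Self-contained dense free-form registration engine.

A demons-style fixed-point iteration estimates a dense voxel-unit
displacement field on the fixed grid: at each step the intensity residual
drives an optical-flow force along the warped moving-image gradient, the
update is smoothed (fluid-like regularization) and the accumulated field is
smoothed again (elastic regularization).  A coarse-to-fine schedule of image
smoothing and regularization widths gives the capture range needed for the
large local shape changes (e.g. hippocampal atrophy) the pipeline must
absorb.

To make the intensity residual meaningful under smooth multiplicative bias
and global gain differences, both images can be locally standardized first
(subtract a Gaussian local mean, divide by the local standard deviation) —
the residual then behaves like a local-correlation mismatch rather than raw
SSD.

Coordinates: the field ``u`` lives in fixed-grid index units; a constant
4x4 map ``fixed_to_moving_index`` (absorbing both grids' affines and any
initial affine transform) sends displaced fixed indices into moving-grid
index coordinates.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = ["optimize_demons", "local_standardize"]


def local_standardize(img: np.ndarray, sigma: float = 4.0) -> np.ndarray:
    """Locally center and scale intensities under a Gaussian window."""
    x = np.asarray(img, dtype=np.float64)
    mean = gaussian_filter(x, sigma)
    var = gaussian_filter(x * x, sigma) - mean * mean
    floor = 1e-3 * float(np.var(x)) + 1e-12
    return (x - mean) / np.sqrt(np.maximum(var, floor))


def _sample(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return map_coordinates(img, coords, order=1, mode="nearest")


def optimize_demons(
    moving: np.ndarray,
    fixed: np.ndarray,
    fixed_to_moving_index: np.ndarray,
    levels=((3.0, 2.0), (1.5, 1.5), (0.7, 1.0)),
    iterations: int = 60,
    step_scale: float = 2.0,
    normalize_sigma: float | None = 4.0,
    tol: float = 2e-2,
    max_displacement: float | None = 8.0,
) -> np.ndarray:
    """Estimate a voxel-unit displacement field ``u`` on the fixed grid.

    ``levels`` is a schedule of (image smoothing sigma, elastic smoothing
    sigma) in voxels; up to ``iterations`` fixed-point steps run per level
    (a scalar or one budget per level), stopping early once the largest
    update magnitude falls below ``tol`` voxels.
    ``step_scale`` is the demons normalization constant K bounding the step
    length.  Returns ``u`` with shape ``fixed.shape + (3,)``.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    B = np.asarray(fixed_to_moving_index, dtype=np.float64)
    Bl, bt = B[:3, :3], B[:3, 3].reshape(3, 1, 1, 1)
    if normalize_sigma:
        fixed = local_standardize(fixed, normalize_sigma)
        moving = local_standardize(moving, normalize_sigma)
    shape = fixed.shape
    base = np.indices(shape, dtype=np.float64)
    u = np.zeros((3,) + shape)
    K2 = step_scale * step_scale
    if np.isscalar(iterations):
        iterations = (int(iterations),) * len(levels)
    for (sigma_img, sigma_elastic), level_iters in zip(levels, iterations):
        f_s = gaussian_filter(fixed, sigma_img) if sigma_img > 0 else fixed
        m_s = gaussian_filter(moving, sigma_img) if sigma_img > 0 else moving
        grad_m = np.gradient(m_s)
        for _ in range(level_iters):
            coords = np.tensordot(Bl, base + u, axes=(1, 0)) + bt
            w = _sample(m_s, coords)
            gm = np.stack([_sample(g, coords) for g in grad_m])
            # chain through the constant index map: d w / d u = Bl^T grad_m
            g = np.einsum("dc,cxyz->dxyz", Bl.T, gm)
            diff = w - f_s
            denom = (g * g).sum(axis=0) + diff * diff / K2
            step = np.where(denom > 1e-12, -diff / (denom + 1e-12), 0.0)
            du = step[None] * g
            du = np.stack([gaussian_filter(du[c], 1.0) for c in range(3)])
            u = u + du
            if sigma_elastic > 0:
                u = np.stack([gaussian_filter(u[c], sigma_elastic) for c in range(3)])
            if max_displacement is not None:
                # cap the displacement magnitude: an unmatched structure must
                # not be "solved" by dragging anatomy in from far away
                mag = np.sqrt((u * u).sum(axis=0))
                excess = mag > max_displacement
                if excess.any():
                    scale = np.where(excess, max_displacement / np.maximum(mag, 1e-9), 1.0)
                    u = u * scale[None]
            if float(np.abs(du).max()) < tol:
                break
    return np.moveaxis(u, 0, -1)
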