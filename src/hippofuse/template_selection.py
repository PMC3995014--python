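"""Region-of-interest extraction and similarity-ranked template selection.

A hippocampal ROI is cut around the propagated prior's 0.5-level set plus a
margin.  Every template is brought near the ROI through the composed
groupwise transforms, refined with a coarse affine registration, and ranked
by global normalized cross-correlation over the ROI brain mask; the top
``k_coarse`` templates then receive a fine nonrigid registration whose
transform also propagates their manual labels onto the ROI grid as
probability maps.  Left and right hippocampi are processed as independent
ROIs.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, PipelineError
from .image_io import Grid, LabelVolume, Volume3D
from .registration import (
    FINE_NONRIGID,
    AffineConfig,
    NonrigidConfig,
    Transform,
    apply_transform,
    compose,
    register_affine,
    register_nonrigid,
)
from .synthetic_data import TemplateDatabase, TemplateEntry

log = logging.getLogger(__name__)

#: default extra voxels sampled around the ROI when warping templates, so a
#: subsequent affine adjustment does not run off the sampled patch
ROI_PAD = 5


@dataclass(frozen=True)
class ROI:
    """An axis-aligned voxel-index box on the subject grid."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # exclusive
    margin: int
    side: int

    def __post_init__(self):
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise DomainError(f"empty ROI box {self.lo}..{self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def grid(self, parent: Grid, pad: int = 0) -> Grid:
        lo = np.asarray(self.lo) - pad
        shape = np.asarray(self.shape) + 2 * pad
        affine = parent.affine.copy()
        affine[:3, 3] = parent.index_to_world([lo])[0]
        return Grid(tuple(int(s) for s in shape), affine)

    def extract(self, vol: Volume3D | LabelVolume):
        sl = tuple(slice(l, h) for l, h in zip(self.lo, self.hi))
        grid = self.grid(vol.grid)
        if isinstance(vol, LabelVolume):
            return LabelVolume(vol.data[sl].copy(), grid.affine, vol.labels)
        return Volume3D(vol.data[sl].copy(), grid.affine)

    def embed(self, mask: LabelVolume, parent: Grid) -> LabelVolume:
        """Place an ROI-sized mask back into a full-size zero volume."""
        out = np.zeros(parent.shape, dtype=mask.data.dtype)
        sl = tuple(slice(l, h) for l, h in zip(self.lo, self.hi))
        out[sl] = mask.data
        return LabelVolume(out, parent.affine.copy(), mask.labels)


def extract_roi(prior: Volume3D, margin_voxels: int = 4, side: int = 0) -> ROI:
    """Bounding box of the prior's 0.5-level set dilated by a margin,
    clipped to the grid.  An empty prior signals an upstream registration
    failure and raises a domain error."""
    support = np.argwhere(prior.data >= 0.5)
    if support.size == 0:
        raise DomainError("prior has no support at the 0.5 level "
                          "(upstream registration likely failed)")
    lo = np.maximum(support.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(support.max(axis=0) + 1 + margin_voxels, prior.data.shape)
    return ROI(tuple(int(v) for v in lo), tuple(int(v) for v in hi),
               margin_voxels, side)


def global_ncc(a: Volume3D | np.ndarray, b: Volume3D | np.ndarray,
               mask: np.ndarray | None = None) -> float:
    """Pearson correlation of intensities over masked voxels, in [-1, 1].

    A constant image within the mask makes the correlation undefined; it is
    reported as 0 (uninformative) with a warning, so a single degenerate
    template cannot abort selection.
    """
    x = (a.data if isinstance(a, Volume3D) else np.asarray(a)).astype(np.float64)
    y = (b.data if isinstance(b, Volume3D) else np.asarray(b)).astype(np.float64)
    if x.shape != y.shape:
        raise DomainError("global NCC requires identical shapes")
    if mask is not None:
        if not np.asarray(mask).any():
            raise DomainError("empty NCC mask")
        x, y = x[mask], y[mask]
    x = x.ravel() - x.mean()
    y = y.ravel() - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        warnings.warn("constant image within NCC mask; returning 0")
        return 0.0
    return float(np.clip((x * y).sum() / denom, -1.0, 1.0))


def roi_brain_mask(subject_roi: Volume3D) -> np.ndarray:
    """Voxels with appreciable intensity (brain/CSF), excluding background."""
    return subject_roi.data > 0.05 * float(subject_roi.data.max())


@dataclass
class RankedTemplate:
    """A template after coarse ranking (and optionally fine refinement).

    After refinement, ``image_roi``/``label_roi`` are produced by warping the
    coarse-aligned padded patch through the fine deformation (the exact
    correspondence the fine registration optimized); ``transform`` holds the
    composed total map for serialization and audit.
    """

    entry: TemplateEntry
    coarse_ncc: float
    transform: Transform          # ROI-world -> entry-world (total map)
    image_roi: Volume3D           # entry anatomy warped onto the ROI grid
    image_pad: Volume3D | None = None  # coarse-aligned anatomy, padded grid
    label_roi: Volume3D | None = None  # propagated label probability map
    fine_ncc: float | None = None

    @property
    def id(self) -> str:
        return self.entry.id


def select_templates(
    subject_roi: Volume3D,
    db: TemplateDatabase,
    entry_transforms: dict[str, Transform],
    subject_to_template: Transform,
    k_coarse: int = 75,
    side: int = 1,
    affine_config: AffineConfig | None = None,
    pad: int = ROI_PAD,
) -> list[RankedTemplate]:
    """Coarsely register every template to the ROI and keep the ``k_coarse``
    best by global NCC (descending; ties by ascending template id)."""
    affine_config = affine_config or AffineConfig(init="identity", sampling=0.25,
                                                 iterations=60)
    if len(db) < k_coarse:
        warnings.warn(
            f"database has {len(db)} templates < k_coarse={k_coarse}; using all"
        )
    roi_grid = subject_roi.grid
    pad_grid = Grid(
        tuple(s + 2 * pad for s in roi_grid.shape),
        _shift_affine(roi_grid, -pad),
    )
    mask = roi_brain_mask(subject_roi)
    ranked: list[RankedTemplate] = []
    for e in db:
        try:
            t_init = compose(entry_transforms[e.id], subject_to_template, grid=pad_grid)
            warped = apply_transform(e.image, t_init, pad_grid, mode="linear")
            res = register_affine(warped, subject_roi, affine_config)
            # keep the composed map on the padded grid: sampling it on the
            # tight ROI would extrapolate at the borders after refinement
            total = compose(t_init, res.transform, grid=pad_grid)
            image_pad = apply_transform(e.image, total, pad_grid, mode="linear")
            image_roi = apply_transform(e.image, total, roi_grid, mode="linear")
            score = global_ncc(subject_roi.data, image_roi.data, mask)
        except (DomainError, RuntimeError) as exc:
            log.warning("template %s excluded during coarse selection: %s", e.id, exc)
            continue
        ranked.append(RankedTemplate(e, score, total, image_roi, image_pad))
    ranked.sort(key=lambda r: (-r.coarse_ncc, r.id))
    return ranked[:k_coarse]


def _shift_affine(grid: Grid, offset_vox: int) -> np.ndarray:
    affine = grid.affine.copy()
    affine[:3, 3] = grid.index_to_world([[offset_vox] * 3])[0]
    return affine


def refine_templates(
    ranked: list[RankedTemplate],
    subject_roi: Volume3D,
    side: int,
    nonrigid_config: NonrigidConfig | None = None,
    min_survivors: int = 15,
    subject_pad: Volume3D | None = None,
) -> list[RankedTemplate]:
    """Fine nonrigid registration of the selected templates to the ROI;
    the same transforms propagate the manual labels as probability maps.

    When a padded subject patch is supplied the registration runs on the
    padded grid for *both* images — smoothing a tight ROI without its
    surroundings manufactures boundary pseudo-structure that drags the
    deformation.  Labels travel the same two-step path the registration
    optimized: the coarse map pulls the (continuous) label indicator onto
    the padded patch, the fine deformation then warps that patch onto the
    ROI.  A single composed map degrades for strongly deformed templates
    because the coarse field must be interpolated at far-displaced points.
    """
    nonrigid_config = nonrigid_config or FINE_NONRIGID
    roi_grid = subject_roi.grid
    mask = roi_brain_mask(subject_roi)
    refined: list[RankedTemplate] = []
    for rt in ranked:
        try:
            moving = rt.image_pad if rt.image_pad is not None else rt.image_roi
            fixed = subject_pad if subject_pad is not None else subject_roi
            res = register_nonrigid(moving, fixed, nonrigid_config)
            pad_grid = moving.grid
            label_pad = apply_transform(rt.entry.labels, rt.transform, pad_grid,
                                        mode="prob", label=side)
            image_roi = apply_transform(moving, res.transform, roi_grid,
                                        mode="linear")
            label_warp = apply_transform(label_pad, res.transform, roi_grid,
                                         mode="linear")
            label_roi = Volume3D(np.clip(label_warp.data, 0.0, 1.0),
                                 label_warp.affine)
            total = compose(rt.transform, res.transform,
                            grid=rt.transform.grid if hasattr(rt.transform, "grid")
                            else roi_grid)
            fine_ncc = global_ncc(subject_roi.data, image_roi.data, mask)
        except (DomainError, RuntimeError) as exc:
            log.warning("template %s excluded during refinement: %s", rt.id, exc)
            continue
        refined.append(
            RankedTemplate(rt.entry, rt.coarse_ncc, total, image_roi,
                           rt.image_pad, label_roi, fine_ncc)
        )
    if len(refined) < min_survivors:
        raise PipelineError(
            f"only {len(refined)} templates survived refinement; "
            f"{min_survivors} required for fusion"
        )
    return refined
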