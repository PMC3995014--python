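"""Volumetry: contour voxelization, volumes, ICV correction, classification.

Manual-style segmentations arrive as per-slice closed polygons; a voxel is
included in the rasterized mask when the contour encloses at least half of
its in-plane footprint (boundary inclusive).  Volumes are per-slice area
times slice thickness, doubled when only alternate slices were segmented.
Hippocampal volumes are corrected for head size by removing the regression
slope on intracranial volume (ICV) estimated in controls::

    corrected = raw - Grad * (ICV - mean_ICV)

and the normative reference range is the control mean +/- 1.96 SD of the
corrected volumes.  Sides are flagged atrophic below the lower bound.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from matplotlib.path import Path as MplPath

from .errors import DomainError, ValidationError
from .image_io import Grid, LabelVolume, Volume3D
from .synthetic_data import ContourSet, TemplateDatabase, brain_mask_database

#: supersampling factor per in-plane axis for the >= half-coverage rule
SUPERSAMPLE = 16


# ---------------------------------------------------------------------------
# Contours -> voxels
# ---------------------------------------------------------------------------

def _inplane_axes(slice_axis: int) -> tuple[int, int]:
    return tuple(ax for ax in range(3) if ax != slice_axis)  # type: ignore[return-value]


def _polygon_coverage(loops, grid: Grid, slice_axis: int,
                      supersample: int | None = None) -> np.ndarray:
    """Fraction of each in-plane voxel footprint enclosed by the loops
    (even-odd rule across loops), estimated on a supersampled point grid."""
    ax0, ax1 = _inplane_axes(slice_axis)
    spacing = grid.spacing
    origin = grid.affine[:3, 3]
    shape2d = (grid.shape[ax0], grid.shape[ax1])
    cover = np.zeros(shape2d)
    if not loops:
        return cover
    # polygon vertices (world mm) -> in-plane index coordinates
    idx_loops = []
    for loop in loops:
        loop = np.asarray(loop, dtype=float)
        if loop.shape[0] < 4 or not np.allclose(loop[0], loop[-1], atol=1e-9):
            raise ValidationError("contours must be closed polygons "
                                  "(first vertex repeated at the end)")
        u = (loop[:, 0] - origin[ax0]) / spacing[ax0]
        v = (loop[:, 1] - origin[ax1]) / spacing[ax1]
        idx_loops.append(np.stack([u, v], axis=1))
    allv = np.concatenate(idx_loops)
    lo = np.maximum(np.floor(allv.min(axis=0) - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil(allv.max(axis=0) + 0.5).astype(int) + 1,
                    np.asarray(shape2d))
    if np.any(hi <= lo):
        return cover
    n0, n1 = hi - lo
    s = supersample or SUPERSAMPLE
    # sample points strictly interior to each voxel footprint
    offs = (np.arange(s) + 0.5) / s - 0.5
    u = (lo[0] + np.arange(n0))[:, None] + offs[None, :]  # (n0, s)
    v = (lo[1] + np.arange(n1))[:, None] + offs[None, :]
    pts = np.stack(
        [np.repeat(u.ravel(), n1 * s), np.tile(v.ravel(), n0 * s)], axis=1
    )
    parity = np.zeros(len(pts), dtype=np.int64)
    for loop in idx_loops:
        parity += MplPath(loop).contains_points(pts)
    inside = (parity % 2 == 1).reshape(n0, s, n1, s)
    cover[lo[0]:hi[0], lo[1]:hi[1]] = inside.mean(axis=(1, 3))
    return cover


def contours_to_mask(
    contours: ContourSet,
    grid: Grid,
    slice_mode: str = "all",
) -> LabelVolume:
    """Rasterize per-slice polygons: a voxel is included iff the contours
    enclose at least half of its footprint (exactly half counts as inside).

    ``slice_mode='alternate'`` treats the input as alternate-slice manual
    segmentation and duplicates each segmented slice onto its unsegmented
    lower neighbour, emulating the double slice thickness used for such data.
    """
    if slice_mode not in ("all", "alternate"):
        raise ValidationError(f"unknown slice_mode {slice_mode!r}")
    slice_axis = contours.slice_axis
    out = np.zeros(grid.shape, dtype=np.int16)
    for k, loops in sorted(contours.slices.items()):
        if not (0 <= k < grid.shape[slice_axis]):
            raise DomainError(f"contour slice {k} outside grid")
        cover = _polygon_coverage(loops, grid, slice_axis)
        mask2d = cover >= 0.5 - 1e-9
        sl = [slice(None)] * 3
        sl[slice_axis] = k
        out[tuple(sl)] = mask2d.astype(np.int16)
        if slice_mode == "alternate" and k - 1 >= 0:
            sl[slice_axis] = k - 1
            out[tuple(sl)] = np.maximum(out[tuple(sl)], mask2d.astype(np.int16))
    return LabelVolume(out, grid.affine.copy(), (0, 1))


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def mask_volume(mask: LabelVolume, slice_mode: str = "all", slice_axis: int = 2) -> float:
    """Volume in cm^3: sum of per-slice cross-sectional areas times slice
    thickness, doubled when only alternate slices were segmented."""
    if slice_mode not in ("all", "alternate"):
        raise ValidationError(f"unknown slice_mode {slice_mode!r}")
    spacing = mask.spacing
    ax0, ax1 = _inplane_axes(slice_axis)
    area = spacing[ax0] * spacing[ax1]
    thickness = spacing[slice_axis]
    count = int(np.count_nonzero(mask.data))
    vol_mm3 = count * area * thickness
    if slice_mode == "alternate":
        vol_mm3 *= 2.0
    return vol_mm3 / 1000.0


def estimate_icv(
    subject: Volume3D,
    db: TemplateDatabase,
    template,
    config=None,
) -> float:
    """Estimate intracranial volume (cm^3) by running the identical
    selection-and-fusion pipeline with whole-head masks as the labels.

    ``db`` may be a hippocampus database (head masks are derived from its
    phantom specs) or an already-converted brain-mask database.
    """
    from .pipeline import PipelineConfig, segment_subject  # local: avoid cycle

    if config is None:
        config = PipelineConfig()
    brain_db = brain_mask_database(db)
    cfg = PipelineConfig(
        k_coarse=config.k_coarse,
        margin_voxels=config.margin_voxels,
        fusion=config.fusion,
        groupwise=config.groupwise,
        prior_affine=config.prior_affine,
        prior_nonrigid=config.prior_nonrigid,
        coarse_affine=config.coarse_affine,
        # head-scale deformations are smooth; the coarse preset suffices and
        # keeps the near-full-volume registrations tractable
        fine_nonrigid=config.prior_nonrigid,
        sides=(1,),
    )
    from .groupwise_template import build_group_template

    brain_template = build_group_template(brain_db, cfg.groupwise)
    res = segment_subject(subject, brain_db, brain_template, cfg)
    return mask_volume(res.mask)


# ---------------------------------------------------------------------------
# Normative model and correction
# ---------------------------------------------------------------------------

@dataclass
class NormativeModel:
    """OLS relationship of control hippocampal volume to ICV (cm^3 units)."""

    grad: float            # regression slope of volume on ICV
    mean_icv: float
    mean_corrected: float
    sd_corrected: float
    n_controls: int

    @property
    def reference_range(self) -> tuple[float, float]:
        half = 1.96 * self.sd_corrected
        return (self.mean_corrected - half, self.mean_corrected + half)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NormativeModel":
        return cls(**json.loads(text))


def fit_normative(volumes_cm3, icv_cm3) -> NormativeModel:
    """Fit the control regression of hippocampal volume on ICV and the
    reference distribution of corrected volumes."""
    v = np.asarray(volumes_cm3, dtype=float)
    icv = np.asarray(icv_cm3, dtype=float)
    if v.shape != icv.shape or v.ndim != 1:
        raise ValidationError("volumes and ICVs must be 1-D and aligned")
    n = len(v)
    if n < 3:
        raise ValidationError("normative fit needs at least 3 controls")
    if np.var(icv) <= 0:
        raise ValidationError("ICV variance is zero; slope undefined")
    grad = float(np.cov(v, icv, ddof=0)[0, 1] / np.var(icv))
    mean_icv = float(icv.mean())
    corrected = v - grad * (icv - mean_icv)
    sd = float(corrected.std(ddof=1))
    if sd <= 0:
        raise ValidationError("corrected control volumes have zero spread")
    return NormativeModel(grad, mean_icv, float(corrected.mean()), sd, n)


def correct_volume(raw_cm3: float, icv_cm3: float, model: NormativeModel) -> float:
    """ICV-corrected volume: remove the control regression trend,
    re-centred at the control mean ICV."""
    return float(raw_cm3 - model.grad * (icv_cm3 - model.mean_icv))


# ---------------------------------------------------------------------------
# Classification on the sum/difference plane
# ---------------------------------------------------------------------------

@dataclass
class VolumeClassification:
    label: str                     # normal | left | right | bilateral
    sum_cm3: float                 # left + right corrected
    diff_cm3: float                # left - right corrected
    left_atrophic: bool
    right_atrophic: bool


def classify(left_corr: float, right_corr: float, model: NormativeModel) -> VolumeClassification:
    """Flag each side atrophic below the control mean - 1.96 SD and map the
    pair onto the (sum, left-right difference) plane used for group scatter."""
    cutoff = model.reference_range[0]
    left_atrophic = left_corr < cutoff
    right_atrophic = right_corr < cutoff
    if left_atrophic and right_atrophic:
        label = "bilateral"
    elif left_atrophic:
        label = "left"
    elif right_atrophic:
        label = "right"
    else:
        label = "normal"
    return VolumeClassification(
        label, left_corr + right_corr, left_corr - right_corr,
        left_atrophic, right_atrophic,
    )


@dataclass
class VolumeReport:
    subject_id: str
    side: str                      # "left" | "right"
    raw_cm3: float
    corrected_cm3: float | None
    icv_cm3: float | None
    method: str                    # "manual" | "automated"
    slice_mode: str                # "all" | "alternate"
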