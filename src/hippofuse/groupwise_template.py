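"""Groupwise average template construction (iterative register-and-average).

The first iteration picks one individual as the reference (first database
entry by sorted id, for reproducibility), affinely registers every other
entry to it and computes the voxelwise mean.  Subsequent iterations register
*all* entries — including the original reference — nonrigidly to the current
average and re-average, until the mean absolute change of the average image
falls below a fraction of the brain-mean intensity or the iteration cap is
reached.  The same transforms are applied to the label maps to build the
per-side probabilistic prior.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import Grid, Volume3D
from .registration import (
    COARSE_NONRIGID,
    AffineConfig,
    AffineTransform,
    NonrigidConfig,
    RegistrationResult,
    Transform,
    apply_transform,
    register_affine,
    register_nonrigid,
)
from .synthetic_data import LEFT, RIGHT, TemplateDatabase


@dataclass(frozen=True)
class GroupwiseConfig:
    max_iter: int = 4
    #: stop when mean |change| of the average < tol_frac * mean brain intensity
    tol_frac: float = 0.01
    reference_id: str | None = None
    affine: AffineConfig = AffineConfig(sampling=0.25)
    nonrigid: NonrigidConfig = COARSE_NONRIGID


@dataclass
class GroupTemplate:
    """The average anatomy, per-side label priors in [0, 1], and the
    per-entry transforms mapping template-space points into each entry."""

    mean_image: Volume3D
    priors: dict[int, Volume3D]
    transforms: dict[str, Transform]
    iterations: int
    trace: list[float]
    converged: bool


def _average(db: TemplateDatabase, transforms: dict[str, Transform], grid: Grid):
    imgs = []
    prior_acc = {side: np.zeros(grid.shape) for side in (LEFT, RIGHT)}
    for e in db:
        t = transforms[e.id]
        imgs.append(apply_transform(e.image, t, grid, mode="linear").data.astype(np.float64))
        for side in (LEFT, RIGHT):
            prior_acc[side] += apply_transform(e.labels, t, grid, mode="prob", label=side).data
    mean_img = Volume3D(np.mean(imgs, axis=0).astype(np.float32), grid.affine.copy())
    priors = {
        side: Volume3D(
            np.clip(prior_acc[side] / len(db), 0.0, 1.0).astype(np.float32),
            grid.affine.copy(),
        )
        for side in (LEFT, RIGHT)
    }
    return mean_img, priors


def build_group_template(db: TemplateDatabase, config: GroupwiseConfig | None = None) -> GroupTemplate:
    """Iterative register-and-average over a template database."""
    config = config or GroupwiseConfig()
    if len(db) < 2:
        raise ValidationError("groupwise template needs at least 2 database entries")
    ref_id = config.reference_id or sorted(db.ids)[0]
    ref = db[ref_id]
    grid = ref.image.grid

    # iteration 1: affine to the arbitrary reference, then voxelwise mean
    affine_init: dict[str, AffineTransform] = {}
    for e in db:
        if e.id == ref_id:
            affine_init[e.id] = AffineTransform.identity()
        else:
            affine_init[e.id] = register_affine(e.image, ref.image, config.affine).transform
    transforms: dict[str, Transform] = dict(affine_init)
    mean_img, priors = _average(db, transforms, grid)

    trace: list[float] = []
    converged = False
    iterations = 1
    for iteration in range(2, config.max_iter + 1):
        iterations = iteration
        new_transforms: dict[str, Transform] = {}
        for e in db:
            res = register_nonrigid(e.image, mean_img, config.nonrigid,
                                    initial=affine_init[e.id])
            new_transforms[e.id] = res.transform
        transforms = new_transforms
        prev = mean_img
        mean_img, priors = _average(db, transforms, grid)
        brain = prev.data > 0.1 * prev.data.max()
        scale = float(prev.data[brain].mean()) if brain.any() else 1.0
        change = float(np.mean(np.abs(mean_img.data - prev.data))) / max(scale, 1e-9)
        trace.append(change)
        if change < config.tol_frac:
            converged = True
            break
    return GroupTemplate(mean_img, priors, transforms, iterations, trace, converged)


def save_group_template(template: GroupTemplate, directory) -> None:
    """Persist a template as NIfTI (mean image, per-side priors), per-entry
    transform files and a JSON provenance record."""
    import json
    from pathlib import Path

    from .image_io import write_volume
    from .registration import save_transform

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(template.mean_image, directory / "mean.nii.gz")
    for side, prior in template.priors.items():
        write_volume(prior, directory / f"prior_{side}.nii.gz")
    tdir = directory / "transforms"
    tdir.mkdir(exist_ok=True)
    kinds = {}
    for eid, t in template.transforms.items():
        if isinstance(t, AffineTransform):
            save_transform(t, tdir / f"{eid}.txt")
            kinds[eid] = "affine"
        else:
            save_transform(t, tdir / f"{eid}.nii.gz")
            kinds[eid] = "field"
    (directory / "template.json").write_text(
        json.dumps(
            {
                "entries": sorted(template.transforms),
                "transform_kinds": kinds,
                "iterations": template.iterations,
                "trace": template.trace,
                "converged": template.converged,
            },
            indent=1,
        )
    )


def load_group_template(directory) -> GroupTemplate:
    import json
    from pathlib import Path

    from .image_io import read_volume
    from .registration import load_transform

    directory = Path(directory)
    prov = json.loads((directory / "template.json").read_text())
    mean_image = read_volume(directory / "mean.nii.gz")
    priors = {
        side: read_volume(directory / f"prior_{side}.nii.gz") for side in (LEFT, RIGHT)
    }
    transforms = {}
    for eid in prov["entries"]:
        suffix = ".txt" if prov["transform_kinds"][eid] == "affine" else ".nii.gz"
        transforms[eid] = load_transform(directory / "transforms" / f"{eid}{suffix}")
    return GroupTemplate(mean_image, priors, transforms,
                         prov["iterations"], prov["trace"], prov["converged"])


@dataclass
class SubjectPrior:
    """Groupwise prior propagated onto a subject grid."""

    priors: dict[int, Volume3D]       # per-side probability maps, subject grid
    transform: Transform              # subject-world -> template-world map
    registration: RegistrationResult


def propagate_prior(
    template: GroupTemplate,
    subject: Volume3D,
    affine_config: AffineConfig | None = None,
    nonrigid_config: NonrigidConfig | None = None,
) -> SubjectPrior:
    """Register the template to the subject and pull the label priors onto
    the subject grid (values clipped to [0, 1]); this gives the approximate
    hippocampus location that the region-of-interest is cut from."""
    affine_config = affine_config or AffineConfig(sampling=0.25)
    nonrigid_config = nonrigid_config or COARSE_NONRIGID
    aff = register_affine(template.mean_image, subject, affine_config)
    res = register_nonrigid(template.mean_image, subject, nonrigid_config,
                            initial=aff.transform)
    priors = {}
    for side, prior in template.priors.items():
        mapped = apply_transform(prior, res.transform, subject.grid, mode="linear")
        priors[side] = Volume3D(
            np.clip(mapped.data, 0.0, 1.0).astype(np.float32), subject.affine.copy()
        )
    return SubjectPrior(priors, res.transform, res)
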