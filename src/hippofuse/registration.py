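"""Affine and dense free-form registration with label propagation.

The module exposes a backend-agnostic contract — ``register_affine``,
``register_nonrigid``, ``apply_transform``, ``compose``.  The affine stage
runs on SimpleITK's registration framework configured for determinism
(correlation metric, seeded regular sampling, center-of-mass or identity
initialization, regular-step gradient descent); the nonrigid stage is the
package's own demons-style dense engine (:mod:`hippofuse.ffd`).  Results
are accepted only when they improve normalized cross-correlation over
their initialization, so a failed optimization degrades gracefully to its
starting transform.

Transform convention (resampling convention, as in ITK): a transform maps
points from the *fixed/target* world frame to the *moving* world frame, so
``apply_transform(moving, t, fixed_grid)`` pulls the moving image onto the
fixed grid.  ``compose(t1, t2)(x) == t1(t2(x))``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import DomainError
from .ffd import optimize_demons
from .image_io import Grid, LabelVolume, Volume3D, sample_volume

# ---------------------------------------------------------------------------
# Transform types
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """A 4x4 world-to-world map (fixed world -> moving world)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]


@dataclass
class DeformationField:
    """Dense per-voxel displacements (mm) on a stated grid.

    The total point map is ``T(x) = x + u(x)`` with ``u`` trilinearly
    interpolated between voxels (edge values extended outside the grid).
    """

    displacement: np.ndarray  # (nx, ny, nz, 3), world-mm components
    grid: Grid
    control_spacing_vox: float | None = None

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=np.float32)
        if self.displacement.shape != tuple(self.grid.shape) + (3,):
            raise ValueError(
                f"displacement shape {self.displacement.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains NaN/Inf")

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        idx = self.grid.world_to_index(pts).T  # (3, N)
        u = np.stack(
            [
                ndimage.map_coordinates(
                    self.displacement[..., c], idx, order=1, mode="nearest"
                )
                for c in range(3)
            ],
            axis=1,
        )
        return pts + u

    def mean_magnitude_mm(self) -> float:
        return float(np.mean(np.linalg.norm(self.displacement, axis=-1)))


Transform = AffineTransform | DeformationField


@dataclass
class RegistrationResult:
    transform: Transform
    similarity: float          # NCC of the accepted transform
    initial_similarity: float  # NCC at initialization
    iterations: int
    converged: bool
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Configuration presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffineConfig:
    iterations: int = 100
    shrink_factors: tuple[int, ...] = (2, 1)
    smoothing_sigmas: tuple[float, ...] = (1.0, 0.0)
    learning_rate: float = 1.0
    min_step: float = 1e-3
    #: fraction of voxels entering the metric (None = dense); regular grid
    #: subsampling, so the choice is deterministic
    sampling: float | None = None
    #: "moments" = center-of-mass alignment, "identity" = trust current pose
    init: str = "moments"


@dataclass(frozen=True)
class NonrigidConfig:
    """Dense free-form refinement on top of an affine initialization.

    ``levels`` is a coarse-to-fine schedule of (image smoothing sigma,
    elastic regularization sigma) in voxels for the demons-style engine;
    ``normalize_sigma`` locally standardizes intensities first so the
    residual force is insensitive to smooth bias and global gain.
    ``passes`` restarts the whole schedule from the warped position and
    composes the fields — large local shape changes (severe atrophy) exceed
    a single additive pass's capture range.
    """

    levels: tuple[tuple[float, float], ...] = (
        (4.0, 2.0), (2.0, 1.5), (1.0, 1.0), (0.5, 0.8)
    )
    #: fixed-point steps per level (scalar = same budget at every level);
    #: heavily smoothed levels drift if run long, so they get less
    iterations: int | tuple[int, ...] = (6, 10, 16, 16)
    step_scale: float = 2.0
    normalize_sigma: float | None = 4.0
    passes: int = 2
    #: stop restarting once this similarity is reached (well-matched pairs
    #: gain nothing from another pass)
    stop_similarity: float = 0.995
    #: per-pass displacement magnitude cap in voxels of the fixed grid
    max_displacement_vox: float | None = 8.0
    folding_guard: float = 0.99


#: heavily smoothed single level, single pass, for template-to-average and
#: whole-volume localization steps where only smooth shape differences matter
COARSE_NONRIGID = NonrigidConfig(levels=((3.0, 2.5),), iterations=30, passes=1)

#: full coarse-to-fine schedule with a restart pass, intended for
#: region-of-interest volumes
FINE_NONRIGID = NonrigidConfig()


# ---------------------------------------------------------------------------
# SimpleITK bridging
# ---------------------------------------------------------------------------


def _to_sitk(vol: Volume3D | LabelVolume) -> sitk.Image:
    """View a volume as a SimpleITK image in the NIfTI world frame.

    The nibabel affine is used directly as origin/spacing/direction, so the
    "physical space" ITK operates in is the same world frame for every image
    and transforms come back in that frame.
    """
    arr = np.asarray(vol.data, dtype=np.float32).transpose(2, 1, 0)
    img = sitk.GetImageFromArray(arr)
    spacing = vol.spacing
    direction = vol.affine[:3, :3] / spacing
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in vol.affine[:3, 3]))
    img.SetDirection(tuple(float(d) for d in direction.flatten()))
    return img


def _sitk_affine(t: AffineTransform) -> sitk.AffineTransform:
    out = sitk.AffineTransform(3)
    out.SetMatrix(tuple(float(v) for v in t.matrix[:3, :3].flatten()))
    out.SetTranslation(tuple(float(v) for v in t.matrix[:3, 3]))
    out.SetCenter((0.0, 0.0, 0.0))
    return out


def _affine_from_sitk(tx) -> AffineTransform:
    params = np.asarray(tx.GetParameters(), dtype=float)
    center = np.asarray(tx.GetFixedParameters(), dtype=float)[:3]
    A = params[:9].reshape(3, 3)
    t = params[9:12]
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = t + center - A @ center
    return AffineTransform(m)


def _set_sampling(reg: sitk.ImageRegistrationMethod, sampling: float | None) -> None:
    if sampling is None or sampling >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        # REGULAR sampling still jitters sample positions; a fixed seed
        # (instead of the wall-clock default) makes runs reproducible
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(float(sampling), 12345)


def _check_overlap(moving: Volume3D, fixed: Volume3D) -> None:
    mlo, mhi = moving.grid.world_bounds()
    flo, fhi = fixed.grid.world_bounds()
    if np.any(mhi < flo) or np.any(mlo > fhi):
        raise DomainError("moving and fixed volumes have disjoint world extents")


def _levels(cfg_shrink, cfg_smooth, fixed_shape) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Drop shrink levels that would make a small ROI degenerate."""
    shrink, smooth = [], []
    for s, g in zip(cfg_shrink, cfg_smooth):
        if min(fixed_shape) // s >= 8:
            shrink.append(s)
            smooth.append(g)
    if not shrink:
        shrink, smooth = [1], [0.0]
    return tuple(shrink), tuple(smooth)


def _ncc_arrays(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def similarity_ncc(moving: Volume3D, fixed: Volume3D, t: Transform) -> float:
    """NCC between fixed and the moving image resampled through ``t``.

    Sampling is edge-extended (no zero fill) so the score matches what the
    optimizers see and is not dominated by field-of-view clipping when the
    moving image is only a patch.
    """
    idx = np.indices(fixed.grid.shape, dtype=float).reshape(3, -1).T
    world = fixed.grid.index_to_world(idx)
    moved = t.apply_points(world)
    src_idx = moving.grid.world_to_index(moved).T
    warped = ndimage.map_coordinates(
        moving.data.astype(np.float64), src_idx, order=1, mode="nearest"
    )
    return _ncc_arrays(warped, fixed.data)


def _inside_fraction(moving: Volume3D, fixed: Volume3D, t: Transform) -> float:
    """Fraction of fixed voxels mapping inside the moving image domain."""
    idx = np.indices(fixed.grid.shape, dtype=float).reshape(3, -1).T
    world = fixed.grid.index_to_world(idx)
    src_idx = moving.grid.world_to_index(t.apply_points(world)).T
    inside = np.ones(src_idx.shape[1], dtype=bool)
    for ax, n in enumerate(moving.data.shape):
        inside &= (src_idx[ax] >= -0.5) & (src_idx[ax] <= n - 0.5)
    return float(inside.mean())


# ---------------------------------------------------------------------------
# Registration operations
# ---------------------------------------------------------------------------


def register_affine(
    moving: Volume3D, fixed: Volume3D, config: AffineConfig | None = None,
    initial: AffineTransform | None = None,
) -> RegistrationResult:
    """Affine registration maximizing NCC; deterministic (dense sampling,
    center-of-mass initialization, fixed optimizer schedule)."""
    config = config or AffineConfig()
    _check_overlap(moving, fixed)
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)

    if initial is not None:
        init_tx = _sitk_affine(initial)
    elif config.init == "identity":
        init_tx = sitk.AffineTransform(3)
    else:
        init_tx = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.AffineTransform(3),
            sitk.CenteredTransformInitializerFilter.MOMENTS,
        )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    _set_sampling(reg, config.sampling)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=config.learning_rate,
        minStep=config.min_step,
        numberOfIterations=config.iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink, smooth = _levels(config.shrink_factors, config.smoothing_sigmas, fixed.data.shape)
    reg.SetShrinkFactorsPerLevel(list(shrink))
    reg.SetSmoothingSigmasPerLevel(list(smooth))
    reg.SetInitialTransform(init_tx, inPlace=False)

    initial_tf = _affine_from_sitk(init_tx)
    init_sim = similarity_ncc(moving, fixed, initial_tf)
    try:
        final = reg.Execute(f_img, m_img)
        iterations = int(reg.GetOptimizerIteration())
    except RuntimeError as exc:
        return RegistrationResult(initial_tf, init_sim, init_sim, 0, False,
                                  warnings=[f"optimizer failure: {exc}"])
    final_tf = _affine_from_sitk(final)
    final_sim = similarity_ncc(moving, fixed, final_tf)
    if final_sim < init_sim:
        # monotone acceptance: never return a transform worse than the start
        return RegistrationResult(initial_tf, init_sim, init_sim, iterations, False,
                                  warnings=["optimization did not improve NCC"])
    return RegistrationResult(final_tf, final_sim, init_sim, iterations, True)


def register_nonrigid(
    moving: Volume3D, fixed: Volume3D, config: NonrigidConfig | None = None,
    initial: AffineTransform | None = None,
) -> RegistrationResult:
    """Free-form refinement of an affine initialization.

    The total map is ``T(x) = A(F(i + u))`` — the optimized voxel-unit
    displacement ``u`` on the fixed grid composed with the initial affine —
    returned as a :class:`DeformationField` sampled on the fixed grid.
    """
    config = config or FINE_NONRIGID
    _check_overlap(moving, fixed)
    initial = initial or AffineTransform.identity()

    F = fixed.affine                       # fixed index -> world
    M_inv = np.linalg.inv(moving.affine)   # world -> moving index
    shape = fixed.data.shape
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1).T
    world = idx @ F[:3, :3].T + F[:3, 3]

    init_sim = similarity_ncc(moving, fixed, initial)
    best: Transform = initial
    best_sim = init_sim
    for p in range(max(1, config.passes)):
        if p == 0:
            # optimize directly against the original moving image through
            # the initial affine
            B = M_inv @ initial.matrix @ F
            moving_data = moving.data
            AF = initial.matrix @ F
        else:
            # restart: warp the moving image through the current total map
            # (edge-extended so patch borders do not leave zero seams)
            moved = best.apply_points(world)
            src = moving.grid.world_to_index(moved).T
            moving_data = ndimage.map_coordinates(
                moving.data.astype(np.float64), src, order=1, mode="nearest"
            ).reshape(shape)
            B = np.eye(4)
            AF = F
        u = optimize_demons(
            moving_data, fixed.data, B,
            levels=config.levels,
            iterations=config.iterations,
            step_scale=config.step_scale,
            normalize_sigma=config.normalize_sigma,
            max_displacement=config.max_displacement_vox,
        )
        target = (idx + u.reshape(-1, 3)) @ AF[:3, :3].T + AF[:3, 3]
        disp = (target - world).reshape(shape + (3,)).astype(np.float32)
        pass_field = DeformationField(disp, fixed.grid, config.levels[-1][1])
        candidate = pass_field if p == 0 else compose(best, pass_field, grid=fixed.grid)
        sim = similarity_ncc(moving, fixed, candidate)
        # coverage guard: a warp must not "improve" similarity by pulling
        # most of the target from outside the moving image domain
        coverage = _inside_fraction(moving, fixed, candidate)
        base_cov = _inside_fraction(moving, fixed, initial)
        if sim <= best_sim or coverage < min(0.75, base_cov - 0.10):
            break
        best, best_sim = candidate, sim
        if best_sim >= config.stop_similarity:
            break

    if isinstance(best, AffineTransform):  # no pass improved on the start
        return RegistrationResult(_affine_as_field(initial, fixed.grid), init_sim,
                                  init_sim, config.iterations, False,
                                  warnings=["optimization did not improve NCC"])
    warn: list[str] = []
    frac_pos = _positive_jacobian_fraction(best)
    if frac_pos < config.folding_guard:
        warn.append(f"Jacobian positive on only {frac_pos:.3f} of voxels")
    return RegistrationResult(best, best_sim, init_sim, config.iterations, True,
                              warnings=warn)


def _affine_as_field(t: AffineTransform, grid: Grid) -> DeformationField:
    idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
    world = grid.index_to_world(idx)
    disp = (t.apply_points(world) - world).reshape(tuple(grid.shape) + (3,))
    return DeformationField(disp.astype(np.float32), grid)


def _positive_jacobian_fraction(field: DeformationField) -> float:
    """Fraction of voxels where the total map is locally orientation-preserving."""
    spacing = field.grid.spacing
    disp_vox = field.displacement @ np.linalg.inv(field.grid.affine[:3, :3]).T
    jac = np.zeros(tuple(field.grid.shape) + (3, 3))
    for c in range(3):
        grads = np.gradient(disp_vox[..., c], axis=(0, 1, 2))
        for ax in range(3):
            jac[..., c, ax] = grads[ax]
    jac += np.eye(3)
    det = np.linalg.det(jac)
    return float(np.mean(det > 0))


# ---------------------------------------------------------------------------
# Transform application and composition
# ---------------------------------------------------------------------------


def apply_transform(
    vol: Volume3D | LabelVolume,
    t: Transform,
    target_grid: Grid,
    mode: str = "linear",
    label: int | None = None,
):
    """Resample ``vol`` through ``t`` onto ``target_grid``.

    Modes: ``linear`` for intensities, ``nearest`` for hard labels, ``prob``
    for a label indicator interpolated linearly into a [0, 1] probability map
    (a :class:`Volume3D`), which is what fusion consumes.
    """
    if isinstance(t, AffineTransform) and np.allclose(t.matrix, np.eye(4)) \
            and vol.grid.matches(target_grid) and mode != "prob":
        return vol.copy()
    idx = np.indices(target_grid.shape, dtype=float).reshape(3, -1).T
    world = target_grid.index_to_world(idx)
    moved = t.apply_points(world)
    src_idx = vol.grid.world_to_index(moved).T.reshape((3,) + tuple(target_grid.shape))

    if mode == "prob":
        if not isinstance(vol, LabelVolume):
            raise DomainError("prob mode requires a LabelVolume")
        data = (vol.binary(label)).astype(np.float32)
        out = sample_volume(data, src_idx, order=1)
        return Volume3D(np.clip(out, 0.0, 1.0).astype(np.float32), target_grid.affine.copy())
    if isinstance(vol, LabelVolume) or mode == "nearest":
        out = sample_volume(vol.data, src_idx, order=0)
        if isinstance(vol, LabelVolume):
            return LabelVolume(out.astype(vol.data.dtype), target_grid.affine.copy(), vol.labels)
        return Volume3D(out.astype(np.float32), target_grid.affine.copy())
    out = sample_volume(vol.data.astype(np.float32), src_idx, order=1)
    return Volume3D(out.astype(np.float32), target_grid.affine.copy())


def compose(t1: Transform, t2: Transform, grid: Grid | None = None) -> Transform:
    """The transform ``x -> t1(t2(x))`` (apply ``t2`` first, then ``t1``).

    Two affines compose exactly; any combination involving a deformation
    field is sampled densely on ``grid`` (default: the grid of the first
    deformation field encountered, scanning t2 then t1).
    """
    if isinstance(t1, AffineTransform) and isinstance(t2, AffineTransform):
        return AffineTransform(t1.matrix @ t2.matrix)
    if grid is None:
        grid = t2.grid if isinstance(t2, DeformationField) else t1.grid
    idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
    world = grid.index_to_world(idx)
    out = t1.apply_points(t2.apply_points(world))
    disp = (out - world).reshape(tuple(grid.shape) + (3,))
    return DeformationField(disp.astype(np.float32), grid)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_transform(t: Transform, path) -> None:
    """Affine -> 4x4 text matrix; deformation -> NIfTI 3-component mm field."""
    path = Path(path)
    if isinstance(t, AffineTransform):
        np.savetxt(path, t.matrix)
    else:
        img = nib.Nifti1Image(t.displacement.astype(np.float32), t.grid.affine)
        nib.save(img, str(path))


def load_transform(path) -> Transform:
    path = Path(path)
    if path.suffix in (".txt", ".mat"):
        return AffineTransform(np.loadtxt(path))
    img = nib.load(str(path))
    disp = np.asarray(img.dataobj, dtype=np.float32)
    grid = Grid(disp.shape[:3], np.asarray(img.affine, dtype=float))
    return DeformationField(disp, grid)
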