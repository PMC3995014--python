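"""Reproducible 3-D brain phantoms with ground-truth hippocampus labels.

The generator emulates the statistical structure a multi-atlas hippocampal
pipeline has to cope with: anatomical variability (pose jitter, global size),
unilateral/bilateral hippocampal atrophy with signal change toward CSF,
smooth multiplicative intensity bias, and additive Gaussian noise.  Each
phantom is a large "head" ellipsoid (the intracranial-volume proxy) with a
CSF rim, two ventricle-like CSF ellipsoids, and two curved hippocampus-like
structures, each built as a union of three overlapping ellipsoids so the
shape is banana-like rather than trivially convex.

Intensity images get partial-volume (soft) edges so registration sees
sub-voxel gradients, as real MRI does; label volumes are hard rasterizations
(voxel center inside the analytic surface).

All randomness flows from integer seeds through ``numpy.random.SeedSequence``
child streams with fixed offsets, so a spec fully determines its phantom.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .image_io import Grid, LabelVolume, Volume3D, read_label_volume, read_volume, write_volume

LEFT, RIGHT = 1, 2

# child-stream offsets fanned out from a phantom's seed
_NOISE_STREAM = 1
_BIAS_STREAM = 2


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; the seed determines it bit-exactly.

    Geometry is given in world millimetres with the world origin at the grid
    center.  ``atrophy_left/right`` scale the hippocampal structures
    isotropically about their own centroids (radius factor, so volume scales
    with the cube); values toward the low end emulate severe sclerosis.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head_radii: tuple[float, float, float] = (44.0, 50.0, 36.0)
    hippo_base_radii: tuple[float, float, float] = (5.8, 7.6, 6.7)
    atrophy_left: float = 1.0
    atrophy_right: float = 1.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size_scale: float = 1.0
    intensity_background: float = 0.0
    intensity_brain: float = 100.0
    intensity_hippo: float = 150.0
    intensity_csf: float = 40.0
    signal_change: bool = True
    bias_amplitude: float = 0.1
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        for name, f in (("atrophy_left", self.atrophy_left), ("atrophy_right", self.atrophy_right)):
            if not (0.3 < f <= 1.0):
                raise ValidationError(f"{name} must lie in (0.3, 1], got {f}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.bias_amplitude < 0:
            raise ValidationError("bias_amplitude must be >= 0")
        if not (0.5 <= self.size_scale <= 1.5):
            raise ValidationError("size_scale must lie in [0.5, 1.5]")

    @property
    def grid(self) -> Grid:
        shape = np.asarray(self.shape)
        spacing = np.asarray(self.spacing, dtype=float)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = -(shape - 1) / 2.0 * spacing
        return Grid(tuple(self.shape), affine)


@dataclass(frozen=True)
class RaterSpec:
    """A simulated segmenter with fixed sensitivity/specificity."""

    sensitivity: float = 0.9
    specificity: float = 0.98
    seed: int = 0

    def __post_init__(self):
        for name, v in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in the open unit interval, got {v}")


def _rotation_matrix(rotation_deg) -> np.ndarray:
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _hippo_lobes(spec: PhantomSpec, side: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """(center, radii) of the three overlapping lobes of one hippocampus.

    Atrophy scales both lobe radii and lobe offsets about the structure
    centroid, i.e. an isotropic shrink of the whole curved shape.
    """
    s = spec.size_scale
    sign = -1.0 if side == LEFT else +1.0
    f = spec.atrophy_left if side == LEFT else spec.atrophy_right
    hx, hy, hz = spec.head_radii
    center = np.array([sign * 0.52 * hx, 0.0, -0.105 * hz]) * s
    radii = np.asarray(spec.hippo_base_radii, dtype=float) * s * f
    rx, ry, rz = spec.hippo_base_radii
    lobes = []
    for t in (-1.0, 0.0, 1.0):
        # curved arc: the head and tail bend medially and upward; offsets are
        # proportional to the base radii so the lobes always overlap
        offset = np.array([-sign * 0.43 * rx * t * t, 1.45 * ry * t, 0.37 * rz * t * t]) * s * f
        lobes.append((center + offset, radii))
    return lobes


def _ventricles(spec: PhantomSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    s = spec.size_scale
    hx, hy, hz = spec.head_radii
    out = []
    for sign in (-1.0, +1.0):
        out.append(
            (
                np.array([sign * 0.196 * hx, 0.074 * hy, 0.21 * hz]) * s,
                np.array([0.13 * hx, 0.26 * hy, 0.21 * hz]) * s,
            )
        )
    return out


def _check_inside(center, radii, R, translation, bounds_lo, bounds_hi, what: str):
    # exact bounding box of a rotated ellipsoid: row norms of R @ diag(radii)
    half = np.sqrt(((R * np.asarray(radii)) ** 2).sum(axis=1))
    c = R @ np.asarray(center) + np.asarray(translation)
    if np.any(c - half < bounds_lo) or np.any(c + half > bounds_hi):
        raise DomainError(f"{what} exceeds the phantom grid (center {c}, half-extent {half})")


class _Rasterizer:
    """Evaluates ellipsoid memberships on the phantom grid, pose applied."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.grid = spec.grid
        idx = np.indices(spec.shape, dtype=float).reshape(3, -1).T
        world = self.grid.index_to_world(idx)
        R = _rotation_matrix(spec.rotation_deg)
        t = np.asarray(spec.translation, dtype=float)
        # local coordinates: undo pose before testing analytic shapes
        self.local = (world - t) @ R  # == R.T applied to each row
        self.R, self.t = R, t
        self.lo, self.hi = self.grid.world_bounds()
        self.edge_mm = float(min(spec.spacing))  # soft-edge width ~ 1 voxel

    def quad(self, center, radii) -> np.ndarray:
        d = (self.local - np.asarray(center)) / np.asarray(radii)
        return (d * d).sum(axis=1)

    def hard(self, center, radii) -> np.ndarray:
        return self.quad(center, radii) <= 1.0

    def soft(self, center, radii) -> np.ndarray:
        q = self.quad(center, radii)
        # approximate signed distance in mm from the ellipsoid surface
        dist = (np.sqrt(q) - 1.0) * float(min(radii))
        return np.clip(0.5 - dist / self.edge_mm, 0.0, 1.0)

    def check(self, center, radii, what):
        _check_inside(center, radii, self.R, self.t, self.lo, self.hi, what)


def _bias_field(spec: PhantomSpec) -> np.ndarray:
    if spec.bias_amplitude == 0:
        return np.ones(spec.shape, dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), _BIAS_STREAM]))
    u = [np.linspace(0.0, 1.0, n) for n in spec.shape]
    U = np.stack(np.meshgrid(*u, indexing="ij"), axis=-1)
    g = np.zeros(spec.shape)
    for _ in range(3):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        g += amp * np.cos(np.pi * (U @ direction) + phase)
    g /= np.max(np.abs(g))
    return (1.0 + spec.bias_amplitude * g).astype(np.float32)


def _rasterize(spec: PhantomSpec) -> dict:
    r = _Rasterizer(spec)
    s = spec.size_scale
    head_radii = np.asarray(spec.head_radii) * s
    r.check((0.0, 0.0, 0.0), head_radii, "head ellipsoid")

    intensity = np.full(np.prod(spec.shape), spec.intensity_background, dtype=np.float64)

    def paint(mask, level):
        nonlocal intensity
        intensity = intensity * (1.0 - mask) + level * mask

    head_soft = r.soft((0, 0, 0), head_radii)
    inner_soft = r.soft((0, 0, 0), head_radii * 0.93)
    paint(head_soft, spec.intensity_csf)   # CSF rim fills the head first
    paint(inner_soft, spec.intensity_brain)
    for c, rad in _ventricles(spec):
        paint(r.soft(c, rad), spec.intensity_csf)

    labels = np.zeros(np.prod(spec.shape), dtype=np.int16)
    for side in (LEFT, RIGHT):
        f = spec.atrophy_left if side == LEFT else spec.atrophy_right
        level = spec.intensity_hippo
        if spec.signal_change:
            level = level + (1.0 - f) * 0.5 * (spec.intensity_csf - spec.intensity_hippo)
        soft = np.zeros(np.prod(spec.shape))
        hard = np.zeros(np.prod(spec.shape), dtype=bool)
        for c, rad in _hippo_lobes(spec, side):
            r.check(c, rad, f"hippocampus side {side}")
            soft = np.maximum(soft, r.soft(c, rad))
            hard |= r.hard(c, rad)
        paint(soft, level)
        labels[hard] = side

    head_hard = r.hard((0, 0, 0), head_radii)
    shape = tuple(spec.shape)
    return {
        "intensity": intensity.reshape(shape),
        "labels": labels.reshape(shape),
        "head_mask": head_hard.reshape(shape),
    }


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, LabelVolume]:
    """Generate one phantom: anatomical volume plus ground-truth labels."""
    vol, lab, _ = make_phantom_with_meta(spec)
    return vol, lab


def make_phantom_with_meta(spec: PhantomSpec) -> tuple[Volume3D, LabelVolume, dict]:
    parts = _rasterize(spec)
    img = parts["intensity"] * _bias_field(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), _NOISE_STREAM]))
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    grid = spec.grid
    vol = Volume3D(img.astype(np.float32), grid.affine)
    lab = LabelVolume(parts["labels"], grid.affine, (0, LEFT, RIGHT))
    voxvol = grid.voxel_volume_mm3
    meta = {
        "true_vol_left_mm3": float((parts["labels"] == LEFT).sum() * voxvol),
        "true_vol_right_mm3": float((parts["labels"] == RIGHT).sum() * voxvol),
        "icv_mm3": float(parts["head_mask"].sum() * voxvol),
    }
    return vol, lab, meta


def head_mask(spec: PhantomSpec) -> LabelVolume:
    """Hard intracranial (head-ellipsoid) mask for a spec — the ICV ground truth."""
    parts = _rasterize(spec)
    return LabelVolume(parts["head_mask"].astype(np.int16), spec.grid.affine, (0, 1))


# ---------------------------------------------------------------------------
# Template database
# ---------------------------------------------------------------------------

ATROPHY_CLASSES = ("normal", "left", "right", "bilateral")


@dataclass(frozen=True)
class DatabaseVariability:
    """Anatomical variability of the simulated template population."""

    translation_sd_mm: float = 3.0
    rotation_sd_deg: float = 3.0
    size_sd: float = 0.05
    atrophy_range: tuple[float, float] = (0.55, 0.8)


@dataclass
class TemplateEntry:
    id: str
    image: Volume3D
    labels: LabelVolume
    spec: PhantomSpec
    meta: dict


@dataclass
class TemplateDatabase:
    entries: list[TemplateEntry]

    def __post_init__(self):
        self.entries = sorted(self.entries, key=lambda e: e.id)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, key):
        if isinstance(key, str):
            for e in self.entries:
                if e.id == key:
                    return e
            raise KeyError(key)
        return self.entries[key]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"id": e.id, "seed": e.spec.seed}
            row.update(e.meta)
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        specs = {}
        for e in self.entries:
            write_volume(e.image, directory / f"{e.id}_image.nii.gz")
            write_volume(e.labels, directory / f"{e.id}_labels.nii.gz")
            specs[e.id] = {"spec": asdict(e.spec), "meta": e.meta}
        (directory / "specs.json").write_text(json.dumps(specs, indent=1))
        self.manifest().to_csv(directory / "manifest.csv", index=False)

    @classmethod
    def load(cls, directory) -> "TemplateDatabase":
        directory = Path(directory)
        specs = json.loads((directory / "specs.json").read_text())
        entries = []
        for eid, rec in specs.items():
            spec_kw = rec["spec"]
            for key in ("shape", "spacing", "head_radii", "hippo_base_radii",
                        "translation", "rotation_deg", "atrophy_range"):
                if key in spec_kw and isinstance(spec_kw[key], list):
                    spec_kw[key] = tuple(spec_kw[key])
            spec = PhantomSpec(**spec_kw)
            entries.append(
                TemplateEntry(
                    id=eid,
                    image=read_volume(directory / f"{eid}_image.nii.gz"),
                    labels=read_label_volume(directory / f"{eid}_labels.nii.gz", (0, LEFT, RIGHT)),
                    spec=spec,
                    meta=rec["meta"],
                )
            )
        return cls(entries)


def sample_jitter(rng, sd: float, n: int = 3) -> np.ndarray:
    """Gaussian pose jitter truncated at 2 sigma so sampled anatomy always
    stays inside the default grid."""
    return np.clip(rng.normal(0.0, sd, n), -2.0 * sd, 2.0 * sd)


def sample_size_scale(rng, sd: float) -> float:
    return float(np.clip(1.0 + rng.normal(0.0, sd), 1.0 - 2.0 * sd, 1.0 + 2.0 * sd))


def _largest_remainder_counts(n: int, fractions: Iterable[float]) -> list[int]:
    fractions = np.asarray(list(fractions), dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions < 0):
        raise ValidationError(f"class fractions must be >= 0 and sum to 1, got {fractions}")
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    # distribute the leftover to the largest fractional parts; ties by class order
    order = np.argsort(-remainder, kind="stable")
    for i in range(n - counts.sum()):
        counts[order[i % len(counts)]] += 1
    return counts.tolist()


def make_template_database(
    n: int,
    base_spec: PhantomSpec | None = None,
    variability: DatabaseVariability | None = None,
    atrophy_mix: dict | tuple = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> TemplateDatabase:
    """Generate ``n`` phantoms with jittered anatomy and a fixed atrophy-class mix.

    ``atrophy_mix`` gives fractions for (normal, left, right, bilateral)
    either as a 4-tuple in that order or as a dict keyed by class name.
    Class counts follow largest-remainder rounding, so the realized mix is
    exact up to integer arithmetic.
    """
    if n < 2:
        raise ValidationError("a template database needs at least 2 entries")
    base_spec = base_spec or PhantomSpec()
    variability = variability or DatabaseVariability()
    if isinstance(atrophy_mix, dict):
        fractions = [atrophy_mix.get(c, 0.0) for c in ATROPHY_CLASSES]
    else:
        fractions = list(atrophy_mix)
    counts = _largest_remainder_counts(n, fractions)
    classes = [c for c, k in zip(ATROPHY_CLASSES, counts) for _ in range(k)]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    classes = [classes[i] for i in rng.permutation(n)]

    entries = []
    for i, cls_name in enumerate(classes):
        child_seed = int(np.random.SeedSequence([int(seed), i + 1]).generate_state(1)[0] % (2**31))
        atrophy_left = atrophy_right = 1.0
        if cls_name in ("left", "bilateral"):
            atrophy_left = float(rng.uniform(*variability.atrophy_range))
        if cls_name in ("right", "bilateral"):
            atrophy_right = float(rng.uniform(*variability.atrophy_range))
        spec = replace(
            base_spec,
            translation=tuple(sample_jitter(rng, variability.translation_sd_mm)),
            rotation_deg=tuple(sample_jitter(rng, variability.rotation_sd_deg)),
            size_scale=sample_size_scale(rng, variability.size_sd),
            atrophy_left=atrophy_left,
            atrophy_right=atrophy_right,
            seed=child_seed,
        )
        image, labels, meta = make_phantom_with_meta(spec)
        meta = dict(meta, atrophy_class=cls_name,
                    atrophy_left=atrophy_left, atrophy_right=atrophy_right)
        entries.append(TemplateEntry(id=f"t{i:03d}", image=image, labels=labels,
                                     spec=spec, meta=meta))
    return TemplateDatabase(entries)


def brain_mask_database(db: TemplateDatabase) -> TemplateDatabase:
    """The same anatomies with whole-head (intracranial) masks as labels.

    This is the template database the ICV estimator runs the pipeline with.
    """
    entries = []
    for e in db:
        entries.append(
            TemplateEntry(
                id=e.id,
                image=e.image,
                labels=head_mask(e.spec),
                spec=e.spec,
                meta=dict(e.meta),
            )
        )
    return TemplateDatabase(entries)


# ---------------------------------------------------------------------------
# Simulated raters
# ---------------------------------------------------------------------------

def simulate_rater(truth: LabelVolume, rater: RaterSpec) -> LabelVolume:
    """Corrupt a binary truth mask with a Bernoulli sensitivity/specificity model.

    Each true-foreground voxel is kept with probability ``sensitivity``; each
    background voxel is flipped on with probability ``1 - specificity``,
    independently.
    """
    truth_bin = truth.binary()
    rng = np.random.default_rng(np.random.SeedSequence([int(rater.seed), 3]))
    u = rng.random(truth_bin.shape)
    out = np.where(truth_bin, u < rater.sensitivity, u >= rater.specificity)
    return LabelVolume(out.astype(np.int16), truth.affine.copy(), (0, 1))


# ---------------------------------------------------------------------------
# Contours (emulating per-slice manual outlining)
# ---------------------------------------------------------------------------

@dataclass
class ContourSet:
    """Per-slice closed polygons in world mm (in-plane axes of ``slice_axis``).

    ``slices`` maps slice index -> list of closed (N, 2) vertex arrays with
    the first vertex repeated at the end.  Polygons follow voxel edges, so a
    voxel footprint is either fully inside or fully outside a loop.
    """

    slice_axis: int
    slices: dict[int, list[np.ndarray]]

    def to_json(self) -> str:
        payload = {
            "slice_axis": self.slice_axis,
            "slices": {str(k): [loop.tolist() for loop in loops]
                       for k, loops in self.slices.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ContourSet":
        payload = json.loads(text)
        slices = {int(k): [np.asarray(loop, dtype=float) for loop in loops]
                  for k, loops in payload["slices"].items()}
        return cls(slice_axis=int(payload["slice_axis"]), slices=slices)


def _inplane_axes(slice_axis: int) -> tuple[int, int]:
    return tuple(ax for ax in range(3) if ax != slice_axis)  # type: ignore[return-value]


def _require_axis_aligned(affine: np.ndarray) -> None:
    lin = np.asarray(affine)[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-9):
        raise ValidationError("contour operations require an axis-aligned affine")


def _trace_boundaries(mask2d: np.ndarray) -> list[np.ndarray]:
    """Closed rectilinear boundary loops (corner-lattice coords) of a 2-D mask.

    Corners live on an (nx+1, ny+1) lattice where corner (a, b) is the voxel
    corner at index coordinates (a - 0.5, b - 0.5).  Edges are oriented with
    foreground on the left; at diagonal contacts the sharpest left turn is
    taken so touching components stay separate loops.
    """
    fg = mask2d.astype(bool)
    padded = np.zeros((fg.shape[0] + 2, fg.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = fg
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a, b):
        edges.setdefault(a, []).append(b)

    ii, jj = np.nonzero(fg)
    for i, j in zip(ii.tolist(), jj.tolist()):
        pi, pj = i + 1, j + 1
        if not padded[pi, pj - 1]:
            add((i, j), (i + 1, j))
        if not padded[pi + 1, pj]:
            add((i + 1, j), (i + 1, j + 1))
        if not padded[pi, pj + 1]:
            add((i + 1, j + 1), (i, j + 1))
        if not padded[pi - 1, pj]:
            add((i, j + 1), (i, j))

    loops = []
    while edges:
        start = min(edges)
        cur = start
        nxt = edges[start].pop(0)
        if not edges[start]:
            del edges[start]
        loop = [start, nxt]
        prev_dir = (nxt[0] - start[0], nxt[1] - start[1])
        while nxt != start:
            candidates = edges.get(nxt, [])
            if not candidates:
                raise RuntimeError("open contour encountered during tracing")
            if len(candidates) == 1:
                chosen = candidates[0]
            else:
                # sharpest left turn: maximize cross(prev_dir, out_dir)
                def cross(c):
                    d = (c[0] - nxt[0], c[1] - nxt[1])
                    return prev_dir[0] * d[1] - prev_dir[1] * d[0]
                chosen = max(candidates, key=cross)
            candidates.remove(chosen)
            if not candidates:
                del edges[nxt]
            prev_dir = (chosen[0] - nxt[0], chosen[1] - nxt[1])
            loop.append(chosen)
            nxt = chosen
        loops.append(np.asarray(loop, dtype=float))
    return loops


def make_contours(label: LabelVolume, slice_axis: int = 2, alternate: bool = False) -> ContourSet:
    """Trace per-slice closed polygons around a binary mask's voxel footprint.

    With ``alternate=True`` only odd-indexed slices are retained, emulating
    manual outlining on alternate slices.  Vertices are in world mm.
    """
    _require_axis_aligned(label.affine)
    ax0, ax1 = _inplane_axes(slice_axis)
    spacing = label.spacing
    origin = label.affine[:3, 3]
    data = label.binary()
    slices: dict[int, list[np.ndarray]] = {}
    for k in range(label.data.shape[slice_axis]):
        if alternate and k % 2 == 0:
            continue
        sl = [slice(None)] * 3
        sl[slice_axis] = k
        mask2d = data[tuple(sl)]  # indexing drops the slice axis, in-plane axes keep order
        if not mask2d.any():
            continue
        loops = _trace_boundaries(mask2d)
        world_loops = []
        for loop in loops:
            idx = loop - 0.5  # corner lattice -> index coordinates
            w0 = origin[ax0] + spacing[ax0] * idx[:, 0]
            w1 = origin[ax1] + spacing[ax1] * idx[:, 1]
            world_loops.append(np.stack([w0, w1], axis=1))
        slices[k] = world_loops
    return ContourSet(slice_axis=slice_axis, slices=slices)
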