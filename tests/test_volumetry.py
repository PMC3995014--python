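import numpy as np
import pytest

from hippofuse.errors import ValidationError
from hippofuse.image_io import Grid, LabelVolume
from hippofuse.synthetic_data import (
    PhantomSpec,
    make_contours,
    make_phantom,
    make_template_database,
)
from hippofuse.volumetry import (
    NormativeModel,
    _polygon_coverage,
    classify,
    contours_to_mask,
    correct_volume,
    estimate_icv,
    fit_normative,
    mask_volume,
)


def _grid(shape, spacing, origin=(0.0, 0.0, 0.0)):
    a = np.eye(4)
    a[:3, :3] = np.diag(spacing)
    a[:3, 3] = origin
    return Grid(shape, a)


def _loop(vertices):
    v = np.asarray(vertices, dtype=float)
    return np.vstack([v, v[:1]])


class TestContoursToMask:
    def test_rectangle_covering_9_voxels(self):
        from hippofuse.synthetic_data import ContourSet

        grid = _grid((10, 10, 3), (1, 1, 1))
        # voxel footprints of (2..4, 3..5): world box [1.5, 4.5] x [2.5, 5.5]
        loop = _loop([(1.5, 2.5), (4.5, 2.5), (4.5, 5.5), (1.5, 5.5)])
        contours = ContourSet(2, {1: [loop]})
        mask = contours_to_mask(contours, grid)
        assert mask.data.sum() == 9
        assert mask.data[2:5, 3:6, 1].all()

    def test_exact_half_coverage_is_inside(self):
        from hippofuse.synthetic_data import ContourSet

        grid = _grid((6, 6, 1), (1, 1, 1))
        # covers the left half of voxel (2, 2) exactly: x in [1.5, 2.0]
        loop = _loop([(1.5, 1.5), (2.0, 1.5), (2.0, 2.5), (1.5, 2.5)])
        contours = ContourSet(2, {0: [loop]})
        mask = contours_to_mask(contours, grid)
        assert mask.data[2, 2, 0] == 1
        assert mask.data.sum() == 1

    def test_supersampling_resolution_sufficient(self):
        # a random star-shaped polygon: the default 16x supersampling must
        # agree voxel-for-voxel with a 256x oracle
        rng = np.random.default_rng(8)
        grid = _grid((32, 32, 1), (1, 1, 1))
        angles = np.sort(rng.uniform(0, 2 * np.pi, 11))
        radii = rng.uniform(4, 13, 11)
        pts = np.stack([15 + radii * np.cos(angles), 15 + radii * np.sin(angles)], 1)
        loop = _loop(pts)
        cov16 = _polygon_coverage([loop], grid, 2, supersample=16)
        cov256 = _polygon_coverage([loop], grid, 2, supersample=256)
        np.testing.assert_array_equal(cov16 >= 0.5 - 1e-9, cov256 >= 0.5 - 1e-9)

    def test_open_polygon_rejected(self):
        from hippofuse.synthetic_data import ContourSet

        grid = _grid((6, 6, 1), (1, 1, 1))
        open_loop = np.array([(0.0, 0.0), (3.0, 0.0), (3.0, 3.0)])
        with pytest.raises(ValidationError):
            contours_to_mask(ContourSet(2, {0: [open_loop]}), grid)

    def test_alternate_mode_duplicates_onto_lower_neighbor(self):
        data = np.zeros((8, 8, 6), np.int16)
        data[2:5, 2:5, 1] = 1
        data[2:5, 2:5, 3] = 1
        lab = LabelVolume(data, np.eye(4), (0, 1))
        contours = make_contours(lab, alternate=True)
        mask = contours_to_mask(contours, lab.grid, slice_mode="alternate")
        for k in (0, 1, 2, 3):
            np.testing.assert_array_equal(mask.data[:, :, k], data[:, :, k | 1])

    def test_roundtrip_with_traced_contours(self, default_phantom):
        _, lab = default_phantom
        mask = LabelVolume((lab.data == 1).astype(np.int16), lab.affine, (0, 1))
        contours = make_contours(mask)
        recon = contours_to_mask(contours, mask.grid)
        np.testing.assert_array_equal(recon.data, mask.data)


class TestMaskVolume:
    def test_unit_voxels(self):
        data = np.zeros((12, 12, 12), np.int16)
        data.ravel()[:1000] = 1
        lab = LabelVolume(data, np.eye(4), (0, 1))
        assert mask_volume(lab) == pytest.approx(1.0)

    def test_alternate_doubles(self):
        data = np.zeros((12, 12, 12), np.int16)
        data.ravel()[:1000] = 1
        lab = LabelVolume(data, np.eye(4), (0, 1))
        assert mask_volume(lab, "alternate") == pytest.approx(2.0)

    def test_anisotropic_clinical_voxels(self):
        a = np.eye(4)
        a[:3, :3] = np.diag((0.9375, 0.9375, 1.1))
        data = np.zeros((16, 16, 16), np.int16)
        data.ravel()[:1000] = 1
        lab = LabelVolume(data, a, (0, 1))
        expected = 0.9375**2 * 1.1 * 1000 / 1000.0
        assert mask_volume(lab) == pytest.approx(expected, abs=1e-9)

    def test_alternate_equals_double_on_uniform_slab(self):
        full = np.zeros((10, 10, 8), np.int16)
        full[3:6, 3:6, :] = 1  # uniform along the slice axis
        alternate = full.copy()
        alternate[:, :, ::2] = 0
        vol_all = mask_volume(LabelVolume(full, np.eye(4), (0, 1)), "all")
        vol_alt = mask_volume(LabelVolume(alternate, np.eye(4), (0, 1)), "alternate")
        assert vol_alt == pytest.approx(vol_all)


SMALL_SPEC = PhantomSpec(shape=(48, 48, 36), spacing=(2.0, 2.0, 2.0),
                         head_radii=(33.0, 37.0, 27.0),
                         hippo_base_radii=(5.0, 6.5, 5.8))


class TestEstimateICV:
    @pytest.fixture(scope="class")
    def icv_setup(self):
        from hippofuse.groupwise_template import GroupwiseConfig
        from hippofuse.label_fusion import FusionConfig
        from hippofuse.pipeline import PipelineConfig

        db = make_template_database(4, base_spec=SMALL_SPEC, seed=61)
        config = PipelineConfig(
            fusion=FusionConfig(k_local=4),
            groupwise=GroupwiseConfig(max_iter=2),
        )
        return db, config

    def test_within_5pct_of_analytic_head_volume(self, icv_setup):
        db, config = icv_setup
        from hippofuse.synthetic_data import make_phantom_with_meta
        import dataclasses

        spec = dataclasses.replace(SMALL_SPEC, seed=404, translation=(2.0, -1.0, 1.0))
        subject, _, meta = make_phantom_with_meta(spec)
        est = estimate_icv(subject, db, None, config)
        true = meta["icv_mm3"] / 1000.0
        assert abs(est - true) / true < 0.05

    def test_larger_head_gives_larger_icv(self, icv_setup):
        db, config = icv_setup
        import dataclasses

        small = dataclasses.replace(SMALL_SPEC, seed=405, size_scale=0.92)
        large = dataclasses.replace(SMALL_SPEC, seed=405, size_scale=1.08)
        icv_small = estimate_icv(make_phantom(small)[0], db, None, config)
        icv_large = estimate_icv(make_phantom(large)[0], db, None, config)
        assert icv_large > icv_small


class TestNormativeModel:
    def test_recovers_constructed_slope(self):
        rng = np.random.default_rng(0)
        icv = rng.uniform(1300, 1700, 50)
        vol = 0.002 * icv + rng.normal(0, 1e-6, 50)
        model = fit_normative(vol, icv)
        assert model.grad == pytest.approx(0.002, abs=1e-5)

    def test_null_slope_when_independent(self):
        rng = np.random.default_rng(1)
        icv = rng.uniform(1300, 1700, 200)
        vol = rng.normal(2.8, 0.2, 200)
        model = fit_normative(vol, icv)
        se = 0.2 / (np.std(icv) * np.sqrt(len(icv)))
        assert abs(model.grad) < 2 * se

    def test_reference_range_width(self):
        rng = np.random.default_rng(2)
        icv = rng.uniform(1300, 1700, 40)
        vol = 0.001 * icv + rng.normal(0, 0.2, 40)
        model = fit_normative(vol, icv)
        lo, hi = model.reference_range
        assert hi - lo == pytest.approx(2 * 1.96 * model.sd_corrected)

    def test_zero_icv_variance_rejected(self):
        with pytest.raises(ValidationError):
            fit_normative([2.0, 2.5, 3.0], [1500.0, 1500.0, 1500.0])

    def test_json_roundtrip(self):
        model = NormativeModel(0.002, 1500.0, 2.85, 0.22, 50)
        back = NormativeModel.from_json(model.to_json())
        assert back == model


class TestCorrectionAndClassification:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(3)
        icv = rng.uniform(1300, 1700, 60)
        vol = 0.0018 * icv + rng.normal(0, 0.15, 60)
        return fit_normative(vol, icv), vol, icv

    def test_zero_grad_identity(self):
        m = NormativeModel(0.0, 1500.0, 2.8, 0.2, 10)
        assert correct_volume(2.5, 1650.0, m) == 2.5

    def test_mean_icv_identity(self, model):
        m, _, _ = model
        assert correct_volume(2.5, m.mean_icv, m) == pytest.approx(2.5)

    def test_corrected_controls_orthogonal_to_icv(self, model):
        m, vol, icv = model
        corrected = np.array([correct_volume(v, i, m) for v, i in zip(vol, icv)])
        slope = np.cov(corrected, icv, ddof=0)[0, 1] / np.var(icv)
        assert abs(slope) < 1e-10

    def test_classification_thresholds(self, model):
        m, _, _ = model
        lo, _ = m.reference_range
        mean = m.mean_corrected
        assert classify(mean, mean, m).label == "normal"
        assert classify(mean, mean, m).diff_cm3 == 0.0
        low = mean - 3 * m.sd_corrected
        assert classify(low, mean, m).label == "left"
        assert classify(mean, low, m).label == "right"
        assert classify(low, low, m).label == "bilateral"

    def test_classification_invariant_to_icv_shift(self, model):
        _, vol, icv = model
        m1 = fit_normative(vol, icv)
        m2 = fit_normative(vol, icv + 250.0)
        for v, i in zip(vol[:10], icv[:10]):
            c1 = classify(correct_volume(v, i, m1), m1.mean_corrected, m1)
            c2 = classify(correct_volume(v, i + 250.0, m2), m2.mean_corrected, m2)
            assert c1.label == c2.label
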