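import numpy as np
import pytest

from hippofuse.errors import DomainError, PipelineError
from hippofuse.image_io import Volume3D
from hippofuse.registration import AffineTransform
from hippofuse.synthetic_data import (
    LEFT,
    PhantomSpec,
    TemplateDatabase,
    TemplateEntry,
    make_phantom_with_meta,
)
from hippofuse.template_selection import (
    extract_roi,
    global_ncc,
    refine_templates,
    select_templates,
)


def _prior(data, spacing=1.0):
    a = np.eye(4) * spacing
    a[3, 3] = 1.0
    return Volume3D(np.asarray(data, np.float32), a)


class TestExtractROI:
    def test_single_voxel_with_margin(self):
        data = np.zeros((40, 40, 40), np.float32)
        data[20, 20, 20] = 1.0
        roi = extract_roi(_prior(data), margin_voxels=10)
        assert roi.shape == (21, 21, 21)
        assert roi.lo == (10, 10, 10)

    def test_zero_margin_is_tight_bbox(self):
        data = np.zeros((20, 20, 20), np.float32)
        data[4:7, 5:9, 6:8] = 1.0
        roi = extract_roi(_prior(data), margin_voxels=0)
        assert roi.lo == (4, 5, 6) and roi.hi == (7, 9, 8)

    def test_clipped_at_grid_edges(self):
        data = np.zeros((12, 12, 12), np.float32)
        data[0, 0, 0] = 1.0
        roi = extract_roi(_prior(data), margin_voxels=5)
        assert roi.lo == (0, 0, 0) and roi.hi == (6, 6, 6)

    def test_empty_prior_raises(self):
        with pytest.raises(DomainError):
            extract_roi(_prior(np.zeros((8, 8, 8))))

    def test_embed_restores_full_grid(self):
        from hippofuse.image_io import LabelVolume

        data = np.zeros((16, 16, 16), np.float32)
        data[5:8, 5:8, 5:8] = 1.0
        prior = _prior(data)
        roi = extract_roi(prior, margin_voxels=1)
        mask = LabelVolume(np.ones(roi.shape, np.int16),
                           roi.grid(prior.grid).affine, (0, 1))
        full = roi.embed(mask, prior.grid)
        assert full.data.shape == (16, 16, 16)
        assert full.data.sum() == np.prod(roi.shape)


class TestGlobalNCC:
    def test_identical_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 8, 8))
        assert global_ncc(a, a) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 8, 8))
        assert global_ncc(a, -a) == pytest.approx(-1.0)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 8, 8))
        assert global_ncc(a, 2.0 * a + 7.0) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 8, 8, 8))
        assert global_ncc(a, b) == pytest.approx(global_ncc(b, a))

    def test_constant_image_warns_and_returns_zero(self):
        a = np.zeros((6, 6, 6))
        with pytest.warns(UserWarning):
            assert global_ncc(a, a) == 0.0

    def test_empty_mask_rejected(self):
        a = np.ones((4, 4, 4))
        with pytest.raises(DomainError):
            global_ncc(a, a, mask=np.zeros((4, 4, 4), bool))


@pytest.fixture(scope="module")
def toy_selection():
    """A 4-entry database in a common space (identity transforms), with the
    subject identical to one entry."""
    specs = [PhantomSpec(seed=s, noise_sd=3.0) for s in (50, 51, 52, 53)]
    entries = []
    for i, spec in enumerate(specs):
        img, lab, meta = make_phantom_with_meta(spec)
        entries.append(TemplateEntry(f"t{i:03d}", img, lab, spec, meta))
    db = TemplateDatabase(entries)
    subject = db["t002"]
    prior = Volume3D((subject.labels.data == LEFT).astype(np.float32),
                     subject.labels.affine)
    roi = extract_roi(prior, margin_voxels=4, side=LEFT)
    subject_roi = roi.extract(subject.image)
    ident = {e.id: AffineTransform.identity() for e in db}
    return db, subject, subject_roi, roi, ident


class TestSelectTemplates:
    def test_exact_copy_ranked_first(self, toy_selection):
        db, subject, subject_roi, roi, ident = toy_selection
        with pytest.warns(UserWarning):
            ranked = select_templates(subject_roi, db, ident,
                                      AffineTransform.identity(), k_coarse=75,
                                      side=LEFT)
        assert ranked[0].id == "t002"
        assert ranked[0].coarse_ncc > 0.99

    def test_small_db_returns_all_with_warning(self, toy_selection):
        db, _, subject_roi, _, ident = toy_selection
        with pytest.warns(UserWarning):
            ranked = select_templates(subject_roi, db, ident,
                                      AffineTransform.identity(), k_coarse=75,
                                      side=LEFT)
        assert len(ranked) == len(db)

    def test_ranking_invariant_to_intensity_scaling(self, toy_selection):
        db, _, subject_roi, _, ident = toy_selection
        scaled_entries = []
        for i, e in enumerate(db):
            img = Volume3D(e.image.data * (1.0 + 0.5 * i) + 10.0, e.image.affine)
            scaled_entries.append(TemplateEntry(e.id, img, e.labels, e.spec, e.meta))
        scaled = TemplateDatabase(scaled_entries)
        with pytest.warns(UserWarning):
            r1 = select_templates(subject_roi, db, ident,
                                  AffineTransform.identity(), 75, LEFT)
        with pytest.warns(UserWarning):
            r2 = select_templates(subject_roi, scaled, ident,
                                  AffineTransform.identity(), 75, LEFT)
        assert [r.id for r in r1] == [r.id for r in r2]

    def test_topk_prefix_property(self, toy_selection):
        db, _, subject_roi, _, ident = toy_selection
        r4 = select_templates(subject_roi, db, ident,
                              AffineTransform.identity(), 4, LEFT)
        r2 = select_templates(subject_roi, db, ident,
                              AffineTransform.identity(), 2, LEFT)
        assert [r.id for r in r2] == [r.id for r in r4[:2]]

    def test_selection_is_deterministic(self, toy_selection):
        db, _, subject_roi, _, ident = toy_selection
        runs = []
        for _ in range(2):
            with pytest.warns(UserWarning):
                r = select_templates(subject_roi, db, ident,
                                     AffineTransform.identity(), 75, LEFT)
            runs.append([(t.id, t.coarse_ncc) for t in r])
        assert runs[0] == runs[1]


class TestRefineTemplates:
    def test_identical_template_reaches_high_dice(self, toy_selection):
        db, subject, subject_roi, roi, ident = toy_selection
        with pytest.warns(UserWarning):
            ranked = select_templates(subject_roi, db, ident,
                                      AffineTransform.identity(), 75, LEFT)
        refined = refine_templates(ranked, subject_roi, LEFT, min_survivors=4)
        best = next(r for r in refined if r.id == "t002")
        truth = roi.extract(subject.labels).data == LEFT
        m = best.label_roi.data >= 0.5
        dice = 2 * (m & truth).sum() / (m.sum() + truth.sum())
        assert dice >= 0.95
        for r in refined:
            assert r.label_roi.data.min() >= 0.0
            assert r.label_roi.data.max() <= 1.0
            assert r.fine_ncc is not None

    def test_too_few_survivors_raise(self, toy_selection):
        db, _, subject_roi, _, ident = toy_selection
        with pytest.warns(UserWarning):
            ranked = select_templates(subject_roi, db, ident,
                                      AffineTransform.identity(), 75, LEFT)
        with pytest.raises(PipelineError):
            refine_templates(ranked[:2], subject_roi, LEFT, min_survivors=5)


def test_fine_ncc_improves_on_coarse(fusion_table):
    # across the study runs, fine registration should not degrade similarity
    # for the large majority of templates
    frac = fusion_table["fine_ge_coarse_frac"].mean()
    assert frac >= 0.9
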