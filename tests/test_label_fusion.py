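import numpy as np
import pytest

from hippofuse.errors import DomainError, PipelineError
from hippofuse.image_io import LabelVolume, Volume3D
from hippofuse.label_fusion import (
    FusionConfig,
    fuse,
    lncc,
    local_rank_select,
    majority_vote,
    mrf_regularize,
    staple_em,
)
from hippofuse.synthetic_data import PhantomSpec, RaterSpec, make_phantom, simulate_rater


def _vol(data, spacing=1.0):
    a = np.eye(4) * spacing
    a[3, 3] = 1.0
    return Volume3D(np.asarray(data, np.float32), a)


class TestLNCC:
    def test_identical_images_give_one(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.normal(100, 20, (16, 16, 16)))
        out = lncc(v, v, sigma=2.0)
        assert np.all(out.data[out.data != 0] > 0.999)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(1)
        a = _vol(rng.normal(100, 20, (16, 16, 16)))
        b = _vol(2.0 * a.data + 7.0)
        out = lncc(a, b, sigma=2.0)
        assert np.all(out.data[np.abs(out.data) > 1e-6] > 0.999)

    def test_independent_noise_decorrelated(self):
        rng = np.random.default_rng(2)
        a = _vol(rng.normal(0, 1, (64, 64, 64)))
        b = _vol(rng.normal(0, 1, (64, 64, 64)))
        out = lncc(a, b, sigma=2.0)
        assert np.mean(np.abs(out.data)) < 0.15

    def test_grid_mismatch_rejected(self):
        a = _vol(np.zeros((8, 8, 8)))
        b = _vol(np.zeros((8, 8, 8)), spacing=2.0)
        with pytest.raises(DomainError):
            lncc(a, b)

    def test_values_bounded(self):
        rng = np.random.default_rng(3)
        a = _vol(rng.normal(0, 1, (12, 12, 12)))
        b = _vol(a.data + rng.normal(0, 0.5, (12, 12, 12)))
        out = lncc(a, b)
        assert out.data.min() >= -1.0 and out.data.max() <= 1.0


class TestLocalRankSelect:
    def test_all_selected_when_k_equals_n(self):
        stack = np.random.default_rng(0).normal(size=(3, 8, 8, 8))
        sel = local_rank_select(stack, 3)
        assert sel.all()

    def test_dominant_template_always_selected(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(-0.5, 0.5, (5, 6, 6, 6))
        stack[2] = 0.99
        sel = local_rank_select(stack, 2)
        assert sel[2].all()

    def test_exact_count_everywhere(self):
        stack = np.random.default_rng(2).normal(size=(8, 16, 16, 16))
        sel = local_rank_select(stack, 5)
        np.testing.assert_array_equal(sel.sum(axis=0), 5)

    def test_ties_broken_by_template_order(self):
        stack = np.zeros((4, 2, 2, 2))
        sel = local_rank_select(stack, 2)
        assert sel[:2].all() and not sel[2:].any()

    def test_too_few_templates_raise(self):
        with pytest.raises(PipelineError):
            local_rank_select(np.zeros((2, 4, 4, 4)), 3)


class TestStapleEM:
    def test_unanimous_templates_binarize(self):
        rng = np.random.default_rng(0)
        m = (rng.random((10, 10, 10)) < 0.2).astype(float)
        d = np.stack([m] * 4)
        state = staple_em(d, None, 0.5, FusionConfig(k_local=1, beta=0.0))
        np.testing.assert_array_equal(state.consensus >= 0.5, m.astype(bool))
        hi = FusionConfig().pq_clamp[1]
        assert np.all(state.sensitivity >= hi - 1e-9)
        assert np.all(state.specificity >= hi - 1e-9)

    def test_degenerate_all_background_warns(self):
        d = np.zeros((3, 4, 4, 4))
        state = staple_em(d, None, None, FusionConfig(k_local=1, beta=0.0))
        assert state.warnings
        assert not (state.consensus >= 0.5).any()

    def test_single_iteration_monotone_in_vote_count(self):
        # equal-performance raters + flat prior: after one EM iteration the
        # consensus must be a monotone function of the per-voxel vote count
        # (majority-vote equivalence), checked by brute-force enumeration
        n_raters, shape = 5, (4, 4, 1)
        votes = np.arange(16).reshape(shape) % (n_raters + 1)
        d = np.stack([(votes > j).astype(float) for j in range(n_raters)])
        cfg = FusionConfig(k_local=1, beta=0.0, max_iter=1, init_pq=0.9)
        state = staple_em(d, None, 0.5, cfg)
        w_of_count = {}
        for c in range(n_raters + 1):
            vals = state.consensus[votes == c]
            assert np.ptp(vals) < 1e-12  # same count -> same consensus
            w_of_count[c] = vals[0]
        counts = sorted(w_of_count)
        assert all(w_of_count[a] < w_of_count[b]
                   for a, b in zip(counts, counts[1:]))

    def test_log_likelihood_monotone_without_mrf(self):
        rng = np.random.default_rng(4)
        truth = (rng.random((12, 12, 12)) < 0.1)
        d = np.stack([
            np.where(truth, rng.random((12, 12, 12)) < 0.85,
                     rng.random((12, 12, 12)) < 0.03).astype(float)
            for _ in range(4)
        ])
        state = staple_em(d, None, None, FusionConfig(k_local=1, beta=0.0))
        ll = state.log_likelihood
        assert all(b >= a - 1e-8 for a, b in zip(ll, ll[1:]))

    def test_invalid_label_maps_rejected(self):
        with pytest.raises(DomainError):
            staple_em(np.full((2, 3, 3, 3), 1.5), None, 0.5)


class TestMRF:
    def test_beta_zero_gives_flat_half(self):
        rng = np.random.default_rng(0)
        W = rng.random((6, 6, 6))
        np.testing.assert_allclose(mrf_regularize(W, 0.0), 0.5)

    def test_uniform_agreement_pulls_above_half(self):
        pi = mrf_regularize(np.ones((6, 6, 6)), 0.5)
        assert np.all(pi[1:-1, 1:-1, 1:-1] > 0.5)

    def test_speck_pulled_toward_neighbors(self):
        # an isolated foreground vote surrounded by background: MRF smoothing
        # must lower its posterior relative to the beta=0 run
        rng = np.random.default_rng(5)
        d = (rng.random((5, 8, 8, 8)) < 0.02).astype(float)
        d[:3, 4, 4, 4] = 1.0  # 3 of 5 raters mark the speck
        cfg0 = FusionConfig(k_local=1, beta=0.0, max_iter=5)
        cfg1 = FusionConfig(k_local=1, beta=0.5, max_iter=5)
        w0 = staple_em(d, None, 0.5, cfg0).consensus[4, 4, 4]
        w1 = staple_em(d, None, 0.5, cfg1).consensus[4, 4, 4]
        assert w1 < w0


@pytest.fixture(scope="module")
def rater_stack():
    img, lab = make_phantom(PhantomSpec(seed=31))
    truth = LabelVolume((lab.data == 1).astype(np.int16), lab.affine, (0, 1))
    sl = (slice(8, 28), slice(16, 46), slice(10, 34))
    aff = img.affine.copy()
    aff[:3, 3] = img.grid.index_to_world([[8, 16, 10]])[0]
    subject_roi = Volume3D(img.data[sl], aff)
    images, labels = [], []
    rng = np.random.default_rng(7)
    for j in range(6):
        r = simulate_rater(truth, RaterSpec(0.9, 0.995, seed=100 + j))
        labels.append(Volume3D(r.data[sl].astype(np.float32), aff))
        # distinct anatomies (no LNCC ties): subject plus small noise
        images.append(Volume3D(
            subject_roi.data + rng.normal(0, 1.0, subject_roi.data.shape)
            .astype(np.float32), aff))
    truth_roi = truth.data[sl] > 0
    return subject_roi, images, labels, truth_roi


class TestFuse:
    def test_fusion_beats_individual_raters(self, rater_stack):
        subject_roi, images, labels, truth = rater_stack
        cfg = FusionConfig(k_local=6, beta=0.5)
        mask, state = fuse(subject_roi, images, labels, None, cfg)
        def dice(m):
            return 2 * (m & truth).sum() / (m.sum() + truth.sum())
        fused = dice(mask.data > 0)
        singles = [dice(l.data >= 0.5) for l in labels]
        assert fused > max(singles)

    def test_output_invariant_to_template_order(self, rater_stack):
        subject_roi, images, labels, _ = rater_stack
        cfg = FusionConfig(k_local=4, beta=0.5)
        mask1, _ = fuse(subject_roi, images, labels, None, cfg)
        perm = [3, 0, 5, 1, 4, 2]
        mask2, _ = fuse(subject_roi, [images[i] for i in perm],
                        [labels[i] for i in perm], None, cfg)
        np.testing.assert_array_equal(mask1.data, mask2.data)

    def test_single_template_identity_limit(self, rater_stack):
        subject_roi, images, labels, _ = rater_stack
        cfg = FusionConfig(k_local=1, beta=0.0)
        mask, _ = fuse(subject_roi, images[:1], labels[:1], None, cfg)
        expected = labels[0].data >= 0.5
        from hippofuse.label_fusion import _largest_component
        np.testing.assert_array_equal(mask.data > 0, _largest_component(expected))

    def test_too_few_templates_raise(self, rater_stack):
        subject_roi, images, labels, _ = rater_stack
        with pytest.raises(PipelineError):
            fuse(subject_roi, images[:2], labels[:2], None, FusionConfig(k_local=5))

    def test_majority_vote_baseline(self, rater_stack):
        _, _, labels, truth = rater_stack
        mv = majority_vote(np.stack([l.data for l in labels]))
        d = 2 * (mv & truth).sum() / (mv.sum() + truth.sum())
        assert d > 0.8
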