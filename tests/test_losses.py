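"""Loss functions: closed-form identities, oracles, gradients, composition."""

import numpy as np
import pytest

from cinestrain.losses import (
    LossWeights,
    anatomical_loss,
    motion_total_loss,
    cce_loss,
    intensity_loss,
    mdc_loss,
    mse_loss,
    smoothness_loss,
)
from cinestrain.nn.engine import Tensor


def _onehot(labels, n=4):
    out = np.zeros((n,) + labels.shape)
    for k in range(n):
        out[k] = labels == k
    return out


class TestMSE:
    def test_identity_is_zero(self):
        a = np.random.default_rng(0).uniform(size=(6, 6, 3))
        assert mse_loss(a, a) == 0.0

    def test_constant_offset_closed_form(self):
        a = np.zeros((5, 5))
        assert mse_loss(a, a + 0.5) == pytest.approx(0.25)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(size=(4, 4, 2)), rng.uniform(size=(4, 4, 2))
        loop = np.mean([(x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())])
        assert mse_loss(a, b) == pytest.approx(loop, abs=1e-10)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((3, 3)), np.zeros((3, 4)))


class TestMDC:
    def test_identical_one_hot_masks_score_minus_one(self):
        m = _onehot(np.random.default_rng(0).integers(0, 4, (6, 6)))
        assert mdc_loss(m, m) == pytest.approx(-1.0, abs=1e-6)

    def test_hand_counted_toy_grid(self):
        # 4x4 grid: masks agree on 8 background pixels; classes 1..3 disjoint
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[:2, :] = 0
        b[:2, :] = 0
        a[2, :] = 1
        b[2, :] = 2          # disagree
        a[3, :] = 3
        b[3, :] = 1          # disagree
        ma, mb = _onehot(a), _onehot(b)
        # per class: bg overlap 8, sizes 8+8 -> dice 1
        # class1: overlap 0, sizes 4+4 -> 0; class2: 0/(0+4) -> ~0;
        # class3: 0/(4+0) -> ~0
        expected = -(1 / 4) * (1 + 0 + 0 + 0)
        assert mdc_loss(ma, mb) == pytest.approx(expected, abs=1e-6)

    def test_all_background_against_itself_is_perfect(self):
        m = _onehot(np.zeros((5, 5), dtype=int))
        assert mdc_loss(m, m) == pytest.approx(-1.0, abs=1e-6)

    def test_bounded_and_monotone_on_nested_masks(self):
        base = np.zeros((8, 8), dtype=int)
        prev = None
        for size in (2, 4, 6):
            other = base.copy()
            other[:size, :size] = 2
            ref = base.copy()
            ref[:6, :6] = 2
            val = mdc_loss(_onehot(ref), _onehot(other))
            assert -1.0 <= val <= 0.0
            if prev is not None:
                assert val <= prev       # growing overlap cannot worsen
            prev = val

    def test_wrong_channel_count_raises(self):
        with pytest.raises(ValueError):
            mdc_loss(np.zeros((3, 5, 5)), np.zeros((3, 5, 5)))


class TestCCE:
    def test_perfect_prediction_is_almost_zero(self):
        m = _onehot(np.random.default_rng(0).integers(0, 4, (5, 5)))
        assert cce_loss(m, m.astype(float)) < 1e-6

    def test_uniform_prediction_gives_log4(self):
        m = _onehot(np.zeros((5, 5), dtype=int))
        p = np.full((4, 5, 5), 0.25)
        assert cce_loss(m, p) == pytest.approx(np.log(4.0), abs=1e-9)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 4, (4, 4))
        m = _onehot(labels)
        p = rng.dirichlet(np.ones(4), size=(4, 4)).transpose(2, 0, 1)
        loop = np.mean([-np.log(p[labels[i, j], i, j])
                        for i in range(4) for j in range(4)])
        assert cce_loss(m, p) == pytest.approx(loop, abs=1e-8)


class TestIntensity:
    def test_identity_pair_zero_field_is_zero(self):
        v = np.random.default_rng(0).uniform(size=(6, 6, 4))
        assert intensity_loss(v, v, np.zeros((3, 6, 6, 4))) == 0.0

    def test_constant_offset(self):
        v = np.random.default_rng(0).uniform(size=(6, 6, 4))
        assert intensity_loss(v, v + 0.2, np.zeros((3, 6, 6, 4))) == \
            pytest.approx(0.2, abs=1e-12)

    def test_truth_field_beats_zero_field_on_phantom(self, desk_phantom):
        from cinestrain.grids import normalize_intensity

        _, seq, truth = desk_phantom
        es = truth.es_index
        v0 = normalize_intensity(seq.frames[0].values)
        ves = normalize_intensity(seq.frames[es].values)
        u_gt = truth.displacements[es].components
        assert intensity_loss(v0, ves, u_gt) < intensity_loss(
            v0, ves, np.zeros_like(u_gt))


class TestAnatomical:
    def test_identity_masks_zero_field_mdc(self):
        m = _onehot(np.random.default_rng(0).integers(0, 4, (6, 6, 4)))
        assert anatomical_loss(m, m, np.zeros((3, 6, 6, 4))) == \
            pytest.approx(-1.0, abs=1e-6)

    def test_identity_masks_zero_field_cce_near_zero(self):
        m = _onehot(np.random.default_rng(0).integers(0, 4, (6, 6, 4)))
        assert anatomical_loss(m, m, np.zeros((3, 6, 6, 4)), mode="cce") < 1e-5

    def test_truth_field_beats_zero_field_on_phantom_masks(self, desk_phantom):
        _, _, truth = desk_phantom
        es = truth.es_index
        m0 = truth.masks[0].one_hot()
        mt = truth.masks[es].one_hot()
        u_gt = truth.displacements[es].components
        assert anatomical_loss(m0, mt, u_gt) < anatomical_loss(
            m0, mt, np.zeros_like(u_gt))

    def test_unknown_mode_raises(self):
        m = _onehot(np.zeros((4, 4, 2), dtype=int))
        with pytest.raises(ValueError):
            anatomical_loss(m, m, np.zeros((3, 4, 4, 2)), mode="dice")


class TestSmoothness:
    def test_constant_field_is_zero(self):
        assert smoothness_loss(np.ones((3, 5, 5, 4))) == 0.0

    def test_linear_field_matches_gradient_loop_oracle(self):
        # u_x = g*x (voxel units): interior derivative g, spacing 1.25
        g = 0.3
        u = np.zeros((3, 8, 8, 4))
        u[0] = np.broadcast_to(g * np.arange(8)[:, None, None], (8, 8, 4))
        dr = (1.25, 1.25, 7.0)
        val = smoothness_loss(u, dr=dr, reduction="sum")
        # loop oracle with one-sided borders (all derivatives equal g here)
        oracle = 8 * 8 * 4 * (g * 1.25) ** 2
        assert val == pytest.approx(oracle, rel=1e-12)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((3, 6, 6, 4))
        assert smoothness_loss(2 * u) == pytest.approx(
            4 * smoothness_loss(u), rel=1e-10)

    def test_random_field_matches_brute_force(self):
        rng = np.random.default_rng(5)
        u = rng.standard_normal((3, 5, 6, 4))
        dr = np.array([1.25, 1.25, 7.0])
        total = 0.0
        for c in range(3):
            for ax in range(3):
                d = np.gradient(u[c], axis=ax)
                total += np.sum((d * dr[ax]) ** 2)
        assert smoothness_loss(u, dr=dr, reduction="sum") == \
            pytest.approx(total, rel=1e-10)


class TestComposition:
    def test_zero_weights_give_zero(self, desk_phantom):
        _, seq, truth = desk_phantom
        v = seq.frames[0].values
        m = truth.masks[0].one_hot()
        u = np.zeros((3,) + v.shape)
        assert motion_total_loss(v, v, m, m, u, LossWeights(0, 0, 0)) == 0.0

    def test_intensity_only_weighting_decomposes(self, desk_phantom):
        _, seq, truth = desk_phantom
        es = truth.es_index
        v0, vt = seq.frames[0].values, seq.frames[es].values
        m = truth.masks[0].one_hot()
        u = truth.displacements[es].components
        assert motion_total_loss(v0, vt, m, m, u, LossWeights(1, 0, 0)) == \
            pytest.approx(intensity_loss(v0, vt, u), rel=1e-12)

    def test_default_weights_recompose_manual_sum(self, desk_phantom):
        p, seq, truth = desk_phantom
        es = truth.es_index
        v0, vt = seq.frames[0].values, seq.frames[es].values
        m0 = truth.masks[0].one_hot()
        mt = truth.masks[es].one_hot()
        u = truth.displacements[es].components
        w = LossWeights()          # (0.01, 0.5, 0.1)
        assert (w.lambda_i, w.lambda_a, w.lambda_s) == (0.01, 0.5, 0.1)
        dr = p.grid.spacing
        manual = (w.lambda_i * intensity_loss(v0, vt, u)
                  + w.lambda_a * anatomical_loss(m0, mt, u)
                  + w.lambda_s * smoothness_loss(u, dr=dr))
        assert motion_total_loss(v0, vt, m0, mt, u, w, dr=dr) == \
            pytest.approx(manual, abs=1e-10)

    def test_fused_training_loss_equals_decomposed(self, desk_phantom):
        from cinestrain.training import _motion_fused_loss

        p, seq, truth = desk_phantom
        es = truth.es_index
        v0 = seq.frames[0].values[None, None]
        vt = seq.frames[es].values[None, None]
        m0 = truth.masks[0].one_hot()[None]
        mt = truth.masks[es].one_hot()[None]
        u = Tensor(truth.displacements[es].components[None], requires_grad=True)
        dr = p.grid.spacing
        fused = _motion_fused_loss(v0, vt, m0, mt, u, LossWeights(), dr, "mdc")
        direct = motion_total_loss(v0[0, 0], vt[0, 0], m0[0], mt[0],
                                   u.data[0], LossWeights(), dr=dr)
        assert fused.item() == pytest.approx(direct, rel=1e-10)


class TestGradients:
    @pytest.mark.parametrize("loss_name", ["intensity", "anatomical", "smooth"])
    def test_loss_gradients_wrt_field_match_finite_differences(self, loss_name):
        rng = np.random.default_rng(0)
        v0 = rng.uniform(size=(5, 5, 4))
        vt = rng.uniform(size=(5, 5, 4))
        m = _onehot(rng.integers(0, 4, (5, 5, 4)))
        u = rng.uniform(-0.5, 0.5, (3, 5, 5, 4))

        def evaluate(field) -> float:
            if loss_name == "intensity":
                out = intensity_loss(v0, vt, field)
            elif loss_name == "anatomical":
                out = anatomical_loss(m, m, field)
            else:
                out = smoothness_loss(field, dr=(1.25, 1.25, 7.0))
            return out.item() if isinstance(out, Tensor) else out

        t = Tensor(u.copy(), requires_grad=True)
        if loss_name == "intensity":
            intensity_loss(v0, vt, t).backward()
        elif loss_name == "anatomical":
            anatomical_loss(m, m, t).backward()
        else:
            smoothness_loss(t, dr=(1.25, 1.25, 7.0)).backward()
        grad = t.grad.reshape(3, 5, 5, 4)

        eps = 1e-6
        num = np.zeros_like(u)
        it = np.nditer(u, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            u[i] += eps
            fp = evaluate(u)
            u[i] -= 2 * eps
            fm = evaluate(u)
            u[i] += eps
            num[i] = (fp - fm) / (2 * eps)
        scale = max(np.abs(num).max(), 1e-8)
        assert np.abs(grad - num).max() / scale < 1e-3
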