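"""Architecture contracts: shapes, normalization, head identities."""

import numpy as np
import pytest

from mammodense.errors import ShapeMismatch
from mammodense.models import (DenseTissueNet, NetworkConfig, apply_confusion,
                               build_model, load_checkpoint, predict,
                               save_checkpoint)
from mammodense.nn import Tensor

CFG_SMALL = dict(input_size=32, encoder_channels=(8, 16, 32))


@pytest.fixture(scope="module")
def x32():
    return np.random.default_rng(7).random((2, 1, 32, 32))


class TestForwardContracts:
    def test_unet_probs_normalized_and_shaped(self, x32):
        model = build_model("unet", **CFG_SMALL, seed=0)
        probs = model(Tensor(x32))["probs"].data
        assert probs.shape == (2, 2, 32, 32)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_ynet_params_inside_boxes(self, x32):
        model = build_model("ynet", **CFG_SMALL, seed=0)
        out = model(Tensor(x32))
        a, t = out["params"].data[:, 0], out["params"].data[:, 1]
        assert np.all((a > 0) & (a <= 4.0))
        assert np.all((t >= 0) & (t <= 1.0))
        assert out["probs"].shape == (2, 2, 32, 32)

    def test_ecnn_params_only(self, x32):
        model = build_model("ecnn", **CFG_SMALL, seed=0)
        out = model(Tensor(x32))
        assert set(out) == {"params"}

    def test_cm_heads_column_stochastic_one_per_annotator(self, x32):
        model = build_model("unet", **CFG_SMALL, n_annotators=2, cm=True, seed=0)
        out = model(Tensor(x32))
        assert len(out["cms"]) == 2
        for cm in out["cms"]:
            assert cm.shape == (2, 2, 2, 32, 32)
            np.testing.assert_allclose(cm.data.sum(axis=1), 1.0, atol=1e-5)

    def test_deterministic_forward(self, x32):
        model = build_model("ynet", **CFG_SMALL, seed=3)
        a = model(Tensor(x32))["params"].data
        b = model(Tensor(x32))["params"].data
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        model = build_model("unet", **CFG_SMALL, seed=0)
        with pytest.raises(ShapeMismatch):
            model(Tensor(np.zeros((1, 1, 30, 30))))
        with pytest.raises(ShapeMismatch):
            model(Tensor(np.zeros((1, 3, 32, 32))))


class TestBranchSharing:
    def test_ecnn_equals_ynet_param_branch_with_shared_weights(self, x32):
        """The parameter branch is the same network whether or not a decoder
        is mounted next to it."""
        ynet = build_model("ynet", **CFG_SMALL, seed=0)
        ecnn = build_model("ecnn", **CFG_SMALL, seed=1)
        ystate = ynet.state_dict()
        estate = {k: v for k, v in ystate.items()
                  if not any(k.startswith(p) for p in
                             ("dec", "up", "head_mask"))}
        ecnn.load_state_dict(estate)
        pa = ynet(Tensor(x32))["params"].data
        pb = ecnn(Tensor(x32))["params"].data
        np.testing.assert_array_equal(pa, pb)

    def test_unet_mask_identical_to_ynet_mask_with_shared_weights(self, x32):
        ynet = build_model("ynet", **CFG_SMALL, seed=0)
        unet = build_model("unet", **CFG_SMALL, seed=1)
        ystate = ynet.state_dict()
        ustate = {k: v for k, v in ystate.items()
                  if not k.startswith("param_branch")}
        unet.load_state_dict(ustate)
        pa = ynet(Tensor(x32))["probs"].data
        pb = unet(Tensor(x32))["probs"].data
        np.testing.assert_array_equal(pa, pb)


class TestApplyConfusion:
    def test_identity_preserves(self, rng):
        y = rng.random((1, 2, 4, 4))
        y /= y.sum(axis=1, keepdims=True)
        eye = np.broadcast_to(np.eye(2)[None, :, :, None, None],
                              (1, 2, 2, 4, 4)).copy()
        np.testing.assert_allclose(apply_confusion(y, eye).data, y, atol=1e-6)

    def test_permutation_swaps_channels(self):
        y = np.zeros((1, 2, 1, 1)); y[0, 0] = 0.3; y[0, 1] = 0.7
        flip = np.array([[0.0, 1.0], [1.0, 0.0]])
        field = np.broadcast_to(flip[None, :, :, None, None],
                                (1, 2, 2, 1, 1)).copy()
        out = apply_confusion(y, field).data
        assert out[0, 0, 0, 0] == pytest.approx(0.7, abs=1e-6)
        assert out[0, 1, 0, 0] == pytest.approx(0.3, abs=1e-6)

    def test_stochastic_closure(self, rng):
        y = rng.random((2, 2, 5, 5))
        y /= y.sum(axis=1, keepdims=True)
        raw = rng.random((2, 2, 2, 5, 5))
        cm = raw / raw.sum(axis=1, keepdims=True)
        out = apply_confusion(y, cm).data
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-5)
        assert out.min() >= 0

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatch):
            apply_confusion(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 2, 3, 3)))


class TestPredict:
    def test_extreme_probabilities(self, monkeypatch, x32):
        model = build_model("unet", **CFG_SMALL, seed=0)
        breast = np.ones((32, 32), bool)

        class Stub:
            cfg = model.cfg
            def __call__(self, t):
                B = t.shape[0]
                return {"probs": Tensor(np.full((B, 2, 32, 32), self.p))}
        stub = Stub()
        stub.p = 0.9
        mask, _ = predict(x32[0, 0], stub, breast)
        assert mask.mask.all()
        stub.p = 0.1
        mask, _ = predict(x32[0, 0], stub, breast)
        assert not mask.mask.any()

    def test_mixed_map_matches_pixel_oracle(self, rng):
        model = build_model("unet", **CFG_SMALL, seed=0)
        breast = rng.random((32, 32)) > 0.2
        img = rng.random((32, 32))
        mask, _ = predict(img, model, breast, binarize_at=0.5)
        probs = model(Tensor(img[None, None]))["probs"].data[0, 1]
        exp = np.zeros((32, 32), bool)
        for r in range(32):
            for c in range(32):
                exp[r, c] = probs[r, c] >= 0.5 and breast[r, c]
        np.testing.assert_array_equal(mask.mask, exp)

    def test_ecnn_predicts_via_reconstruction(self, rng):
        model = build_model("ecnn", **CFG_SMALL, seed=0)
        img = rng.random((32, 32))
        breast = np.ones((32, 32), bool)
        mask, params = predict(img, model, breast)
        corrected = np.clip(params.alpha_bright * img, 0, 1)
        np.testing.assert_array_equal(mask.mask, corrected >= params.th_f)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, x32):
        model = build_model("ynet", **CFG_SMALL, n_annotators=2, cm=True, seed=0)
        ref = model(Tensor(x32))["probs"].data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, variation="cm")
        loaded, variation = load_checkpoint(path)
        assert variation == "cm"
        assert loaded.cfg == model.cfg
        np.testing.assert_array_equal(loaded(Tensor(x32))["probs"].data, ref)


def test_network_config_validation():
    with pytest.raises(ShapeMismatch):
        NetworkConfig(input_size=100)     # not divisible by 8
    with pytest.raises(ValueError):
        NetworkConfig(encoder_channels=(8, 20, 40))
    with pytest.raises(ValueError):
        NetworkConfig(heads=("cm",), n_annotators=2)   # cm needs mask
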