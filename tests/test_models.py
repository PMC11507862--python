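"""Predictors: masked loss, determinism, persistence, recovery basics."""

import numpy as np
import pytest

from diaforge.chem import Peptidoform, parse_modified_sequence
from diaforge.models import (
    FragmentIntensityPredictor,
    RetentionTimePredictor,
    encode_peptidoform,
    masked_l1_loss,
)
from diaforge.nn import Tensor, masked_mean_abs
from diaforge.synthetic import make_fragment_examples, make_rt_examples


class TestMaskedLoss:
    def test_single_unmasked_cell(self):
        pred = np.array([[0.5, 0.2]])
        target = np.array([[1.0, 0.0]])
        mask = np.array([[False, True]])
        assert masked_l1_loss(pred, target, mask) == pytest.approx(0.5)

    def test_zero_when_equal(self, rng):
        x = rng.random((4, 5))
        mask = rng.random((4, 5)) > 0.5
        mask[0, 0] = False
        assert masked_l1_loss(x, x, mask) == 0.0

    def test_matches_brute_force_on_random_grids(self, rng):
        for _ in range(200):
            shape = (int(rng.integers(1, 8)), int(rng.integers(1, 6)))
            pred = rng.normal(size=shape)
            target = rng.normal(size=shape)
            mask = rng.random(shape) > 0.4
            if mask.all():
                mask.flat[0] = False
            expect = 0.0
            n = 0
            for i in range(shape[0]):
                for j in range(shape[1]):
                    if not mask[i, j]:
                        expect += abs(pred[i, j] - target[i, j])
                        n += 1
            expect /= n
            assert masked_l1_loss(pred, target, mask) == pytest.approx(expect, abs=1e-12)

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            masked_l1_loss(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2), bool))

    def test_gradient_exactly_zero_at_masked_cells(self, rng):
        pred = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        target = rng.normal(size=(3, 4))
        keep = rng.random((3, 4)) > 0.5
        keep[1, 1] = True
        loss = masked_mean_abs(pred, target, keep)
        loss.backward()
        assert (pred.grad[~keep] == 0.0).all()
        assert (pred.grad[keep] != 0.0).any()


class TestEncoding:
    def test_deterministic(self):
        p = parse_modified_sequence("AS(UniMod:21)TK")
        a = encode_peptidoform(p, 2, 27.0, "Lumos")
        b = encode_peptidoform(p, 2, 27.0, "Lumos")
        assert np.array_equal(a["aa_idx"], b["aa_idx"])
        assert np.array_equal(a["mod_idx"], b["mod_idx"])

    def test_phospho_position_shifts_mod_channel_only(self):
        a = encode_peptidoform(parse_modified_sequence("AS(UniMod:21)TK"), 2, 27.0, "Lumos")
        b = encode_peptidoform(parse_modified_sequence("AST(UniMod:21)K"), 2, 27.0, "Lumos")
        assert np.array_equal(a["aa_idx"], b["aa_idx"])
        diff = np.nonzero(a["mod_idx"] != b["mod_idx"])[0]
        assert set(diff) == {1, 2}

    def test_charge_changes_metadata_only(self):
        p = Peptidoform("PEPTIDEK")
        a = encode_peptidoform(p, 2, 27.0, "Lumos")
        b = encode_peptidoform(p, 3, 27.0, "Lumos")
        assert np.array_equal(a["aa_idx"], b["aa_idx"])
        assert a["charge"] != b["charge"]

    def test_length_limit(self):
        with pytest.raises(ValueError):
            encode_peptidoform(Peptidoform("A" * 40 + "K"), 2, 27.0, "Lumos")


@pytest.fixture(scope="module")
def tiny_examples():
    return make_fragment_examples(40, seed=3)


@pytest.fixture(scope="module")
def tiny_model(tiny_examples):
    return FragmentIntensityPredictor(
        n_layers=1, d_model=32, n_heads=2, d_ff=64,
        epochs=3, warmup_epochs=1, lr=1e-3, batch_size=16, seed=0,
    ).fit(tiny_examples)


class TestFragmentPredictor:
    def test_zero_epochs_returns_init(self, tiny_examples):
        a = FragmentIntensityPredictor(epochs=0, seed=5).fit(tiny_examples)
        b = FragmentIntensityPredictor(epochs=0, seed=5).fit(tiny_examples)
        ex = tiny_examples[0]
        pa = a.predict_single(ex.peptidoform, ex.charge, 27.0, "Lumos")
        pb = b.predict_single(ex.peptidoform, ex.charge, 27.0, "Lumos")
        assert np.array_equal(pa, pb)
        assert a.history_ == []

    def test_same_seed_same_final_loss(self, tiny_examples):
        kw = dict(n_layers=1, d_model=32, n_heads=2, d_ff=64,
                  epochs=2, warmup_epochs=1, lr=1e-3, batch_size=16, seed=11)
        a = FragmentIntensityPredictor(**kw).fit(tiny_examples)
        b = FragmentIntensityPredictor(**kw).fit(tiny_examples)
        assert a.history_ == b.history_

    def test_prediction_shape_and_normalization(self, tiny_model):
        p = Peptidoform("LVNELTEFAK")  # 9 cleavage sites
        grid = tiny_model.predict_single(p, 2, 27.0, "Lumos")
        assert grid.shape == (9, tiny_model.layout_.n_columns)
        assert grid.min() >= 0.0
        assert grid.max() == pytest.approx(1.0)

    def test_deterministic_prediction(self, tiny_model):
        p = Peptidoform("PEPTIDEK")
        a = tiny_model.predict_single(p, 2, 27.0, "Lumos")
        b = tiny_model.predict_single(p, 2, 27.0, "Lumos")
        assert np.array_equal(a, b)

    def test_batch_equals_single_call(self, tiny_model):
        peps = [Peptidoform("PEPTIDEK"), Peptidoform("LVNELTEFAK"), Peptidoform("ACDEFGK")]
        batch = tiny_model.predict(peps, [2, 2, 3], 27.0, "Lumos")
        for p, z, grid in zip(peps, [2, 2, 3], batch):
            np.testing.assert_allclose(
                grid, tiny_model.predict_single(p, z, 27.0, "Lumos"), atol=1e-12
            )

    def test_save_load_round_trip_bit_identical(self, tiny_model, tmp_path):
        path = str(tmp_path / "m.npz")
        tiny_model.save(path)
        back = FragmentIntensityPredictor.load(path)
        p = Peptidoform("PEPTIDEK")
        assert np.array_equal(
            tiny_model.predict_single(p, 2, 27.0, "Lumos"),
            back.predict_single(p, 2, 27.0, "Lumos"),
        )
        assert back.history_ == tiny_model.history_

    def test_training_reduces_loss(self, tiny_model):
        assert tiny_model.history_[-1] < tiny_model.history_[0]

    def test_sklearn_params_round_trip(self):
        m = FragmentIntensityPredictor(epochs=7, lr=5e-4)
        params = m.get_params()
        assert params["epochs"] == 7
        clone = FragmentIntensityPredictor(**params)
        assert clone.get_params() == params


class TestRTPredictor:
    def test_constant_target_recovered(self):
        ex = make_rt_examples(60, seed=2)
        for e in ex:
            e.rt_norm = 0.4
        m = RetentionTimePredictor(conv_channels=16, hidden=16, epochs=12,
                                   warmup_epochs=2, lr=3e-3, batch_size=32, seed=0).fit(ex)
        pred = m.predict([e.peptidoform for e in ex[:10]])
        assert np.allclose(pred, 0.4, atol=0.08)

    def test_same_seed_identical_parameters(self):
        ex = make_rt_examples(30, seed=4)
        kw = dict(conv_channels=8, hidden=8, epochs=2, warmup_epochs=1,
                  lr=1e-3, batch_size=16, seed=3)
        a = RetentionTimePredictor(**kw).fit(ex)
        b = RetentionTimePredictor(**kw).fit(ex)
        for pa, pb in zip(a.net_.state_arrays(), b.net_.state_arrays()):
            assert np.array_equal(pa, pb)

    def test_batch_equals_single_and_bounded(self):
        ex = make_rt_examples(30, seed=6)
        m = RetentionTimePredictor(conv_channels=8, hidden=8, epochs=1,
                                   warmup_epochs=1, lr=1e-3, batch_size=16, seed=0).fit(ex)
        peps = [e.peptidoform for e in ex[:7]]  # mixed lengths -> padding
        batch = m.predict(peps)
        assert ((batch >= 0) & (batch <= 1)).all()
        for p, v in zip(peps, batch):
            assert m.predict_single(p) == pytest.approx(v, abs=1e-10)

    def test_save_load_round_trip(self, tmp_path):
        ex = make_rt_examples(30, seed=8)
        m = RetentionTimePredictor(conv_channels=8, hidden=8, epochs=1,
                                   warmup_epochs=1, lr=1e-3, batch_size=16, seed=0)
        m.fit(ex, rt_norm_max=45.0)
        path = str(tmp_path / "rt.npz")
        m.save(path)
        back = RetentionTimePredictor.load(path)
        assert back.rt_norm_max_ == 45.0
        peps = [e.peptidoform for e in ex[:5]]
        np.testing.assert_array_equal(m.predict(peps), back.predict(peps))
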