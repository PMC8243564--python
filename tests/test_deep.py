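"""Multi-encoder 1D-CNN: architecture contract, training behaviour, guards."""

import numpy as np
import pytest

from beamtune import nn
from beamtune.deep import (
    DeepModelSpec,
    MultiEncoderNet,
    build_model,
    encoder_depth,
    load_deep,
    predict_deep,
    save_deep,
    train_deep,
)
from beamtune.profiles import DoseProfile, ProfileSet, ProfileSpec


class TestEncoderDepth:
    @pytest.mark.parametrize("n,expected", [(512, 3), (495, 2), (248, 2), (8, 1), (64, 2)])
    def test_depth_formula(self, n, expected):
        assert encoder_depth(n) == expected

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            encoder_depth(7)


class TestArchitecture:
    def test_introspection_matches_spec(self):
        spec = DeepModelSpec(input_lengths=(64, 128), profile_labels=("a", "b"))
        assert spec.encoder_depths == (2, 2)
        assert spec.filter_counts(0) == (16, 32)
        assert spec.encoder_output_lengths == (16, 32)
        assert spec.concat_length == 48
        net = build_model(spec, seed=0)
        # per encoder: L blocks of (conv, relu, conv, relu, pool) + 1x1 conv + flatten
        for enc, depth in zip(net.encoders, spec.encoder_depths):
            convs = [l for l in enc if isinstance(l, nn.Conv1D)]
            assert len(convs) == 2 * depth + 1
            assert [c.c_out for c in convs[:-1]] == [16, 16, 32, 32]
            assert convs[-1].c_out == 1 and convs[-1].kernel == 1
        head_dense = [l for l in net.head if isinstance(l, nn.Dense)]
        assert [d.W.value.shape for d in head_dense] == [
            (48, 100),
            (100, 100),
            (100, 4),
        ]

    def test_forward_output_shape_is_four(self, rng):
        spec = DeepModelSpec(input_lengths=(32, 16), profile_labels=("a", "b"))
        net = build_model(spec, seed=1)
        out = net.forward(
            [rng.normal(size=(5, 32)).astype(np.float32),
             rng.normal(size=(5, 16)).astype(np.float32)]
        )
        assert out.shape == (5, 4)

    def test_encoder_output_never_below_three(self):
        spec = DeepModelSpec(input_lengths=(8,), profile_labels=("a",))
        assert spec.encoder_output_lengths == (4,)
        net = build_model(spec)
        assert net is not None

    def test_wrong_input_count_rejected(self, rng):
        net = build_model(DeepModelSpec(input_lengths=(16, 16), profile_labels=("a", "b")))
        with pytest.raises(ValueError, match="profile inputs"):
            net.forward([rng.normal(size=(2, 16)).astype(np.float32)])


def _tiny_training_data(n_samples=12, n_points=16, seed=0):
    rng = np.random.default_rng(seed)
    specs = [
        ProfileSpec(field_size=10.0, kind="depth", range_cm=(0.0, (n_points - 1) * 0.1)),
        ProfileSpec(
            field_size=10.0, kind="lateral", depth=10.0,
            range_cm=(0.0, (n_points - 1) * 0.1),
        ),
    ]
    targets = np.column_stack(
        [
            rng.uniform(5.6, 6.4, n_samples),
            rng.uniform(0.0, 1.0, n_samples),
            rng.uniform(0.0, 0.4, n_samples),
            rng.uniform(0.0, 3.0, n_samples),
        ]
    )
    sets = []
    for row in targets:
        profs = []
        for k, spec in enumerate(specs):
            t = np.linspace(0, 1, n_points)
            doses = 50 + 20 * row[0] * t + 10 * row[2] * np.sin(6 * t) + k
            profs.append(DoseProfile(spec=spec, doses=doses))
        sets.append(ProfileSet(profs))
    box = np.array([[5.6, 6.4], [0.0, 1.0], [0.0, 0.4], [0.0, 3.0]])
    return sets, targets, box


class TestTraining:
    def test_best_checkpoint_no_worse_than_first_epoch(self):
        sets, targets, box = _tiny_training_data()
        model = train_deep(sets, targets, box, seed=0, epochs=5)
        first = model.history[0]["val_loss"]
        best = min(h["val_loss"] for h in model.history)
        assert best <= first
        assert model.best_epoch >= 1

    def test_seeded_determinism(self):
        sets, targets, box = _tiny_training_data()
        a = train_deep(sets, targets, box, seed=3, epochs=3)
        b = train_deep(sets, targets, box, seed=3, epochs=3)
        assert a.net.weights_hash() == b.net.weights_hash()

    def test_different_seeds_differ(self):
        sets, targets, box = _tiny_training_data()
        a = train_deep(sets, targets, box, seed=3, epochs=2)
        b = train_deep(sets, targets, box, seed=4, epochs=2)
        assert a.net.weights_hash() != b.net.weights_hash()

    def test_too_few_rows_rejected(self):
        sets, targets, box = _tiny_training_data(n_samples=5)
        with pytest.raises(ValueError, match="10 training rows"):
            train_deep(sets, targets, box, seed=0, epochs=1)


@pytest.fixture(scope="module")
def trained():
    sets, targets, box = _tiny_training_data()
    model = train_deep(sets, targets, box, seed=0, epochs=3)
    return model, sets


class TestPredictGuards:
    def test_prediction_inside_hypercube(self, trained):
        model, sets = trained
        pred = predict_deep(model, sets[0])
        arr = pred.params.as_array()
        box = model.hypercube
        assert np.all(arr >= box[:, 0]) and np.all(arr <= box[:, 1])

    def test_permuted_profile_order_rejected(self, trained):
        model, sets = trained
        with pytest.raises(ValueError, match="selection"):
            predict_deep(model, ProfileSet(list(sets[0])[::-1]))

    def test_lattice_mismatch_rejected(self, trained):
        model, sets = trained
        spec = sets[0][0].spec
        shorter = ProfileSpec(
            field_size=spec.field_size, kind=spec.kind,
            range_cm=(0.0, 0.8), step=spec.step,
        )
        bad = ProfileSet(
            [DoseProfile(spec=shorter, doses=np.ones(shorter.n_points)), sets[0][1]]
        )
        with pytest.raises(ValueError, match="selection|lattice"):
            predict_deep(model, bad)


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        sets, targets, box = _tiny_training_data()
        model = train_deep(sets, targets, box, seed=0, epochs=3)
        path = tmp_path / "model.npz"
        save_deep(model, path)
        back = load_deep(path)
        a = predict_deep(model, sets[1]).params
        b = predict_deep(back, sets[1]).params
        assert np.allclose(a.as_array(), b.as_array(), atol=1e-7)

    def test_foreign_file_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, meta="{}", x=np.zeros(3))
        with pytest.raises(ValueError, match="deep-model"):
            load_deep(path)


class TestGradients:
    def test_backprop_matches_numeric_gradient(self, rng):
        """Float64 finite-difference check of the full network gradient."""
        spec = DeepModelSpec(input_lengths=(16, 12), profile_labels=("a", "b"))
        net = MultiEncoderNet(spec, seed=3)
        for p in net.params():
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        X = [rng.standard_normal((3, n)) for n in (16, 12)]
        Y = rng.standard_normal((3, 4))
        pred = net.forward(X)
        _, dl = nn.mse_loss(pred, Y)
        net.backward(dl)
        for p in net.params()[::4]:
            flat, g = p.value.reshape(-1), p.grad.reshape(-1)
            for i in rng.choice(flat.size, size=3, replace=False):
                h, orig = 1e-6, flat[i]
                flat[i] = orig + h
                lp = nn.mse_loss(net.forward(X), Y)[0]
                flat[i] = orig - h
                lm = nn.mse_loss(net.forward(X), Y)[0]
                flat[i] = orig
                num = (lp - lm) / (2 * h)
                assert num == pytest.approx(g[i], rel=1e-4, abs=1e-9)
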