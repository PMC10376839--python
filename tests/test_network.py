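"""Unrolled CRNN: layer equations, scalar oracle, DC invariants, training."""

import numpy as np
import pytest

from crnn_dwi import autodiff as ad
from crnn_dwi.autodiff import Tensor
from crnn_dwi.kspace import (
    SamplingMask,
    image_to_kspace,
    kspace_to_image,
    make_vd_mask,
    series_to_kspace,
    undersample,
    zero_fill_recon,
)
from crnn_dwi.network import (
    CRNNModel,
    NetworkConfig,
    TrainConfig,
    _crnn_block_stacked,
    crnn_b_i_step,
    crnn_block,
    crnn_i_step,
    reconstruct,
    train,
    unrolled_forward,
)
from crnn_dwi.phantom import make_phantom_maps, simulate_dwi
from crnn_dwi.scheme import BValueScheme


def relu(v: float) -> float:
    return max(0.0, v)


def small_scheme() -> BValueScheme:
    return BValueScheme(bvalues=(0, 1000, 2000), directions=((1.0, 0.0, 0.0),))


def randomize(model: CRNNModel, rng) -> None:
    """Random weights with live biases so ReLU units stay active."""
    for name, t in model.parameters():
        if ".B" in name:
            t.data[...] = rng.uniform(0.02, 0.3, t.data.shape).astype(np.float32)
        else:
            t.data[...] = rng.uniform(-0.6, 0.6, t.data.shape).astype(np.float32)


class TestCrnnIStep:
    def test_zero_inputs_zero_bias_give_zero(self):
        z = Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32))
        wc = Tensor(np.zeros((2, 2, 3, 3), dtype=np.float32))
        wr = Tensor(np.zeros((2, 2, 3, 3), dtype=np.float32))
        b = Tensor(np.zeros(2, dtype=np.float32))
        assert not crnn_i_step(z, z, wc, wr, b).data.any()

    def test_large_negative_bias_clamps_to_zero(self, rng):
        x = Tensor(rng.random((1, 2, 4, 4)).astype(np.float32))
        wc = Tensor(rng.normal(size=(2, 2, 3, 3)).astype(np.float32))
        wr = Tensor(rng.normal(size=(2, 2, 3, 3)).astype(np.float32))
        b = Tensor(np.full(2, -1e3, dtype=np.float32))
        assert not crnn_i_step(x, x, wc, wr, b).data.any()

    def test_scalar_formula_with_1x1_kernels(self, rng):
        x = rng.normal(size=(1, 1, 2, 2)).astype(np.float32)
        h = rng.normal(size=(1, 1, 2, 2)).astype(np.float32)
        wc, wr, b = 0.7, -0.4, 0.1
        out = crnn_i_step(
            Tensor(x),
            Tensor(h),
            Tensor(np.full((1, 1, 1, 1), wc, dtype=np.float32)),
            Tensor(np.full((1, 1, 1, 1), wr, dtype=np.float32)),
            Tensor(np.array([b], dtype=np.float32)),
        ).data
        expect = np.maximum(0.0, wc * x + wr * h + b)
        assert np.abs(out - expect).max() < 1e-6


class TestCrnnBIStep:
    def _weights(self, rng, h=2, tie_biases=False):
        wc = Tensor(rng.normal(size=(h, h, 3, 3)).astype(np.float32) * 0.4)
        wb = Tensor(rng.normal(size=(h, h, 3, 3)).astype(np.float32) * 0.4)
        wr = Tensor(rng.normal(size=(h, h, 3, 3)).astype(np.float32) * 0.4)
        bf = Tensor(rng.uniform(0, 0.2, h).astype(np.float32))
        bb = bf if tie_biases else Tensor(rng.uniform(0, 0.2, h).astype(np.float32))
        return wc, wb, wr, bf, bb

    def test_single_frame_forward_backward_coincide(self, rng):
        wc, wb, wr, bf, _ = self._weights(rng)
        zero_b = Tensor(np.zeros(2, dtype=np.float32))
        x = [Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))]
        hprev = [Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))]
        out = crnn_b_i_step(x, hprev, wc, wb, wr, zero_b, zero_b, (1, 2, 4, 4))
        single = ad.relu(ad.conv2d(x[0], wc) + ad.conv2d(hprev[0], wr))
        assert np.abs(out[0].data - 2.0 * single.data).max() < 1e-6

    def test_reversing_frames_reverses_output_under_tied_biases(self, rng):
        wc, wb, wr, bf, bb = self._weights(rng, tie_biases=True)
        T = 4
        xs = [Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32)) for _ in range(T)]
        hp = [Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32)) for _ in range(T)]
        fwd = crnn_b_i_step(xs, hp, wc, wb, wr, bf, bb, (1, 2, 4, 4))
        rev = crnn_b_i_step(xs[::-1], hp[::-1], wc, wb, wr, bf, bb, (1, 2, 4, 4))
        for t in range(T):
            assert np.abs(fwd[t].data - rev[T - 1 - t].data).max() < 1e-6

    def test_scalar_recursion_oracle(self, rng):
        """T=3 frames, 1x1 kernels, 1x1 images vs a hand-unrolled recursion."""
        T = 3
        wc, wb, wr = 0.5, -0.3, 0.8
        bf, bb = 0.05, 0.15
        mk = lambda v: Tensor(np.full((1, 1, 1, 1), v, dtype=np.float32))
        x_vals = rng.normal(size=T)
        h_vals = rng.normal(size=T)
        xs = [Tensor(np.full((1, 1, 1, 1), v, dtype=np.float32)) for v in x_vals]
        hp = [Tensor(np.full((1, 1, 1, 1), v, dtype=np.float32)) for v in h_vals]
        out = crnn_b_i_step(
            xs, hp, mk(wc), mk(wb), mk(wr),
            Tensor(np.array([bf], dtype=np.float32)),
            Tensor(np.array([bb], dtype=np.float32)),
            (1, 1, 1, 1),
        )
        hf, h = [], 0.0
        for t in range(T):
            h = relu(wc * x_vals[t] + wb * h + wr * h_vals[t] + bf)
            hf.append(h)
        hbk, h = [0.0] * T, 0.0
        for t in reversed(range(T)):
            h = relu(wc * x_vals[t] + wb * h + wr * h_vals[t] + bb)
            hbk[t] = h
        for t in range(T):
            assert out[t].data[0, 0, 0, 0] == pytest.approx(hf[t] + hbk[t], abs=1e-6)

    def test_empty_sequence_rejected(self, rng):
        wc, wb, wr, bf, bb = self._weights(rng)
        with pytest.raises(ValueError):
            crnn_b_i_step([], [], wc, wb, wr, bf, bb, (1, 2, 4, 4))


class TestCrnnBlock:
    def test_zero_weights_identity(self, rng):
        model = CRNNModel.initialize(NetworkConfig(n_iterations=1, n_hidden=3, seed=0))
        model.zero_like_()
        xs = [Tensor(rng.normal(size=(2, 2, 6, 6)).astype(np.float32)) for _ in range(3)]
        out, _ = crnn_block(xs, None, model.stacks[0], 3)
        for t in range(3):
            assert np.array_equal(out[t].data, xs[t].data)

    @pytest.mark.parametrize("kernel_size", [1, 3, 5])
    def test_spatial_shape_preserved(self, rng, kernel_size):
        model = CRNNModel.initialize(
            NetworkConfig(n_iterations=1, n_hidden=2, kernel_size=kernel_size, seed=1)
        )
        xs = [Tensor(rng.normal(size=(1, 2, 7, 9)).astype(np.float32))]
        out, hidden = crnn_block(xs, None, model.stacks[0], 2)
        assert out[0].data.shape == (1, 2, 7, 9)
        assert all(h[0].data.shape == (1, 2, 7, 9) for h in hidden)

    def test_stacked_path_matches_per_frame_composition(self, rng):
        """The batched implementation equals composing the layer ops frame by
        frame, across two chained iterations (hidden-state carry included)."""
        model = CRNNModel.initialize(NetworkConfig(n_iterations=2, n_hidden=3, seed=2))
        randomize(model, rng)
        st = model.stacks[0]
        B, T = 2, 4
        x = rng.normal(size=(B, T, 2, 8, 8)).astype(np.float32)
        seq = [Tensor(x[:, t]) for t in range(T)]
        o1, h1 = crnn_block(seq, None, st, 3)
        o1b, _ = crnn_block(o1, h1, st, 3)
        x_st = Tensor(np.concatenate([x[:, t] for t in range(T)], axis=0))
        o2, h2 = _crnn_block_stacked(x_st, None, st, 3, T)
        o2b, _ = _crnn_block_stacked(o2, h2, st, 3, T)
        parts = ad.split0(o2b, T)
        for t in range(T):
            scale = max(np.abs(o1b[t].data).max(), 1.0)
            assert np.abs(o1b[t].data - parts[t].data).max() / scale < 1e-6


class TestUnrolledNetwork:
    @pytest.mark.parametrize("n_iter,T", [(1, 1), (2, 3), (3, 4)])
    def test_scalar_oracle_equivalence(self, rng, n_iter, T):
        """1x1 kernels on 1x1 images: the whole unrolled network (residual
        block + DC) equals a hand-written scalar recursion over both the
        real and imaginary channels."""
        cfg = NetworkConfig(n_iterations=n_iter, n_hidden=1, kernel_size=1, seed=0)
        model = CRNNModel.initialize(cfg)
        randomize(model, rng)
        W = {k: t.data.ravel().astype(float) for k, t in model.stacks[0].items()}
        x0 = rng.normal(size=(T, 2))  # (frame, channel)
        xu = np.zeros((1, T, 2, 1, 1), dtype=np.float32)
        xu[0, :, 0, 0, 0] = x0[:, 0]
        xu[0, :, 1, 0, 0] = x0[:, 1]
        yk = np.zeros((1, T, 1, 1), dtype=np.complex128)
        mask = SamplingMask(
            line_pattern=np.zeros(1, dtype=bool), R=1.0, n_center=0, seed=0
        )
        out = unrolled_forward(model, xu, yk, mask.line_pattern)
        got = np.stack([o.data[0, :, 0, 0] for o in out])

        x = [list(map(float, v)) for v in x0]
        hprev = [[0.0] * T for _ in range(4)]
        for _ in range(n_iter):
            stat = [
                W["bcrnn.Wc"][0] * x[t][0]
                + W["bcrnn.Wc"][1] * x[t][1]
                + W["bcrnn.Wr"][0] * hprev[0][t]
                for t in range(T)
            ]
            hf, h = [], 0.0
            for t in range(T):
                h = relu(stat[t] + W["bcrnn.Wb"][0] * h + W["bcrnn.Bf"][0])
                hf.append(h)
            hbk, h = [0.0] * T, 0.0
            for t in reversed(range(T)):
                h = relu(stat[t] + W["bcrnn.Wb"][0] * h + W["bcrnn.Bb"][0])
                hbk[t] = h
            cur = [hf[t] + hbk[t] for t in range(T)]
            hprev[0] = cur
            for l in range(3):
                cur = [
                    relu(
                        W[f"crnn{l}.Wc"][0] * cur[t]
                        + W[f"crnn{l}.Wr"][0] * hprev[1 + l][t]
                        + W[f"crnn{l}.B"][0]
                    )
                    for t in range(T)
                ]
                hprev[1 + l] = cur
            for t in range(T):
                x[t][0] += W["cnn.W"][0] * cur[t] + W["cnn.B"][0]
                x[t][1] += W["cnn.W"][1] * cur[t] + W["cnn.B"][1]
            # DC with an empty mask leaves the image untouched
        want = np.array(x)
        assert np.abs(got - want).max() < 1e-6

    def test_full_mask_reconstruct_returns_truth_for_any_weights(self, rng):
        scheme = small_scheme()
        maps = make_phantom_maps(32, 32, 1, seed=4)
        series = simulate_dwi(maps, scheme, 0.0, seed=0)
        mask = make_vd_mask(32, 1, n_center=4, seed=0)
        frames = undersample(series_to_kspace(series), mask, scheme)
        model = CRNNModel.initialize(NetworkConfig(n_iterations=2, n_hidden=4, seed=9))
        randomize(model, rng)
        rec = reconstruct(frames, model)
        assert np.abs(rec.series.magnitude() - series.magnitude()).max() < 1e-5

    def test_zero_weight_model_reproduces_zero_fill(self, rng):
        scheme = small_scheme()
        maps = make_phantom_maps(32, 32, 1, seed=4)
        series = simulate_dwi(maps, scheme, 0.0, seed=0)
        mask = make_vd_mask(32, 4, n_center=4, seed=0)
        frames = undersample(series_to_kspace(series), mask, scheme)
        model = CRNNModel.initialize(NetworkConfig(n_iterations=3, n_hidden=4, seed=9))
        model.zero_like_()
        rec = reconstruct(frames, model)
        zf = zero_fill_recon(frames)
        assert np.abs(rec.series.data - zf.data).max() < 1e-5

    def test_hard_dc_invariant_on_reconstruction(self, rng):
        scheme = small_scheme()
        maps = make_phantom_maps(32, 32, 2, seed=6)
        series = simulate_dwi(maps, scheme, 0.01, seed=3)
        mask = make_vd_mask(32, 4, n_center=4, seed=1)
        frames = undersample(series_to_kspace(series), mask, scheme)
        model = CRNNModel.initialize(NetworkConfig(n_iterations=2, n_hidden=4, seed=2))
        randomize(model, rng)
        rec = reconstruct(frames, model)
        k_rec = image_to_kspace(rec.series.data)
        on_lines = k_rec[..., mask.line_pattern, :]
        y_lines = frames.kdata[..., mask.line_pattern, :]
        denom = np.abs(y_lines).max()
        assert np.abs(on_lines - y_lines).max() / denom < 1e-5


class TestCheckpoint:
    def test_save_load_reproduces_reconstruction_bitwise(self, rng, tmp_path):
        scheme = small_scheme()
        maps = make_phantom_maps(32, 32, 1, seed=8)
        series = simulate_dwi(maps, scheme, 0.0, seed=0)
        mask = make_vd_mask(32, 4, n_center=4, seed=0)
        frames = undersample(series_to_kspace(series), mask, scheme)
        model = CRNNModel.initialize(NetworkConfig(n_iterations=2, n_hidden=4, seed=3))
        randomize(model, rng)
        rec1 = reconstruct(frames, model)
        model.save(tmp_path / "ckpt", manifest={"note": "test"})
        model2 = CRNNModel.load(tmp_path / "ckpt")
        rec2 = reconstruct(frames, model2)
        assert np.array_equal(rec1.series.data, rec2.series.data)

    def test_per_iteration_weights_mode(self, rng):
        cfg = NetworkConfig(
            n_iterations=3, n_hidden=2, seed=0, share_across_iterations=False
        )
        model = CRNNModel.initialize(cfg)
        assert len(model.stacks) == 3
        names = [n for n, _ in model.parameters()]
        assert any(n.startswith("stack2.") for n in names)


class TestTraining:
    def _tiny_data(self, n_subjects=2):
        scheme = small_scheme()
        out = []
        for i in range(n_subjects):
            maps = make_phantom_maps(32, 32, 1, seed=10 + i)
            out.append(simulate_dwi(maps, scheme, 0.01, seed=i, subject_id=f"s{i}"))
        return out

    def test_one_epoch_smoke_and_best_checkpoint_contract(self):
        subjects = self._tiny_data(2)
        mask = make_vd_mask(32, 4, n_center=4, seed=0)
        model = CRNNModel.initialize(NetworkConfig(n_iterations=2, n_hidden=4, seed=0))
        hist = train(
            model, subjects[:1], subjects[1:], mask,
            TrainConfig(epochs=1, lr=1e-3, batch_size=2, seed=0),
        )
        assert np.isfinite(hist.train_loss[1]) and np.isfinite(hist.val_loss[1])
        assert hist.best_val_loss <= hist.val_loss[0]

    def test_training_is_reproducible_per_seed(self):
        subjects = self._tiny_data(2)
        mask = make_vd_mask(32, 4, n_center=4, seed=0)
        hists = []
        for _ in range(2):
            model = CRNNModel.initialize(NetworkConfig(n_iterations=1, n_hidden=3, seed=5))
            hists.append(
                train(
                    model, subjects[:1], subjects[1:], mask,
                    TrainConfig(epochs=1, lr=1e-3, batch_size=2, seed=7),
                )
            )
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_loss == hists[1].val_loss
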