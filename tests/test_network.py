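"""U-Net construction, shape contract, schedule, determinism, prediction."""

import numpy as np
import pytest

from tawssnet._nn import Adam, Param
from tawssnet.geometry import SurfacePointCloud
from tawssnet.network import (
    NetworkConfigError,
    TrainingData,
    UNetConfig,
    build_unet,
    load_model,
    predict,
    save_model,
    train,
)
from tawssnet.ordering import pca_order


def _tiny_cfg(**kw):
    base = dict(points=256, grid_rows=16, grid_cols=16, levels=2, channels=4,
                stem_width=4, bottleneck_convs=2, seed=0)
    base.update(kw)
    return UNetConfig(**base)


class TestArchitecture:
    @pytest.mark.parametrize(
        "rows,cols,levels,expected",
        [
            (16, 16, 2, [16, 8, 4]),
            (32, 32, 3, [32, 16, 8, 4]),
            (64, 64, 4, [64, 32, 16, 8, 4]),
        ],
    )
    def test_shape_contract_across_configs(self, rows, cols, levels, expected):
        cfg = UNetConfig(points=rows * cols, grid_rows=rows, grid_cols=cols, levels=levels)
        m = build_unet(cfg)
        out = m.net.forward(np.zeros((1, rows * cols, 3)), train=False)
        assert out.shape == (1, rows * cols, 1)
        assert m.net.encoder_sizes == expected

    def test_default_io_shape_is_4096(self):
        m = build_unet(UNetConfig())
        out = m.net.forward(np.zeros((2, 4096, 3)), train=False)
        assert out.shape == (2, 4096, 1)

    def test_parameter_count_logged_and_positive(self):
        m = build_unet(UNetConfig())
        assert m.parameter_count == sum(p.size for p in m.net.params())
        assert m.parameter_count > 10_000

    def test_skipless_network_has_fewer_parameters(self):
        with_skips = build_unet(_tiny_cfg(skip_connections=True))
        without = build_unet(_tiny_cfg(skip_connections=False))
        assert without.parameter_count < with_skips.parameter_count

    def test_indivisible_grid_rejected(self):
        with pytest.raises(NetworkConfigError):
            UNetConfig(points=36 * 36, grid_rows=36, grid_cols=36, levels=4)

    def test_grid_points_mismatch_rejected(self):
        with pytest.raises(NetworkConfigError):
            UNetConfig(points=100, grid_rows=16, grid_cols=16)


class TestSchedule:
    def test_staircase_decay_closed_form(self):
        opt = Adam([Param(np.zeros(1))], lr0=1e-3, decay_rate=0.9, decay_every=2000)
        opt.step_count = 1999
        assert opt.lr == pytest.approx(1e-3)
        opt.step_count = 4000
        assert opt.lr == pytest.approx(1e-3 * 0.9**2)


def _random_training_data(rng, n_models=6, points=256):
    x = rng.normal(size=(n_models, points, 3))
    # smooth deterministic target so a few epochs make progress
    y = 5.0 + np.abs(x[..., 0]) + 0.5 * x[..., 1] ** 2
    return TrainingData(
        train_x=x[:4], train_y=y[:4], val_x=x[4:], val_y=y[4:],
        tawss_global_max=float(y.max()), tawss_global_min=float(y.min()),
    )


class TestTraining:
    def test_identical_seeds_identical_losses(self):
        rng = np.random.default_rng(0)
        data = _random_training_data(rng)
        runs = []
        for _ in range(2):
            m = build_unet(_tiny_cfg(seed=11))
            train(m, data, epochs=3, batch_size=2)
            runs.append(m.history["train_mse"])
        assert runs[0] == runs[1]

    def test_loss_decreases(self):
        data = _random_training_data(np.random.default_rng(1))
        m = build_unet(_tiny_cfg())
        train(m, data, epochs=15, batch_size=2)
        h = m.history["train_mse"]
        assert h[-1] < h[0]
        assert len(m.history["val_name"]) == len(h)

    def test_checkpoint_round_trip(self, tmp_path):
        data = _random_training_data(np.random.default_rng(2))
        m = build_unet(_tiny_cfg())
        train(m, data, epochs=2, batch_size=2)
        x = data.val_x[:1]
        before = m.net.forward(x, train=False)
        save_model(m, tmp_path / "ckpt.npz")
        m2 = load_model(tmp_path / "ckpt.npz")
        after = m2.net.forward(x, train=False)
        assert np.array_equal(before, after)
        assert m2.config == m.config
        assert m2.tawss_global_max == m.tawss_global_max


class TestPredict:
    def test_unordering_consistency_under_input_permutation(self, labeled_small):
        """Permuting input points (with a recomputed ordering) leaves
        per-point-id predictions unchanged."""
        cloud, _ = labeled_small
        m = build_unet(_tiny_cfg(seed=5))
        m.tawss_global_max, m.tawss_global_min = 20.0, 1.0
        o = pca_order(cloud.coords)
        base = predict(m, cloud, o)
        rng = np.random.default_rng(0)
        shuffle = rng.permutation(cloud.n_points)
        shuffled = SurfacePointCloud(
            coords=cloud.coords[shuffle],
            vessel_label=cloud.vessel_label[shuffle],
            station_index=cloud.station_index[shuffle],
            circ_angle=cloud.circ_angle[shuffle],
            model_id=cloud.model_id,
            rows=cloud.rows,
            cols=cloud.cols,
        )
        o2 = pca_order(shuffled.coords)
        out = predict(m, shuffled, o2)
        assert np.allclose(out, base[shuffle], atol=1e-12)

    def test_point_count_mismatch_rejected(self, labeled_small):
        cloud, _ = labeled_small
        m = build_unet(_tiny_cfg(points=1024, grid_rows=32, grid_cols=32))
        m.tawss_global_max, m.tawss_global_min = 20.0, 1.0
        with pytest.raises(NetworkConfigError):
            predict(m, cloud, pca_order(cloud.coords))

    def test_output_length_matches_default_budget(self):
        m = build_unet(UNetConfig())
        out = m.net.forward(np.zeros((1, 4096, 3)), train=False)
        assert out.shape[1] == 4096
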