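import numpy as np
import pytest

from binloc._network import MLP
from binloc.embedding import (ContrastiveEmbedding, NetworkSpec, TrainConfig,
                              contrastive_loss, contrastive_loss_grad,
                              load_model)
from binloc.neighborhoods import (PairLabel, ThresholdConfig,
                                  batch_pair_arrays)


def _toy_model(ds, task="azimuth_deg", seed=0, **net_kwargs):
    spec = NetworkSpec(input_dim=ds.train_features.shape[1], **net_kwargs)
    return ContrastiveEmbedding(
        ds.train_features, ds.train_labels[task].to_numpy(),
        network=spec, thresholds=ThresholdConfig(5.0),
        val_features=ds.val_features,
        val_labels=ds.val_labels[task].to_numpy())


class TestLoss:
    def test_coincident_similar_pair_costs_nothing(self):
        z = np.zeros(3)
        loss = contrastive_loss([(z, z)], [PairLabel(1, 0.0, 0.5)])
        assert loss.total == 0.0

    def test_separated_dissimilar_pair_costs_nothing(self):
        a, b = np.zeros(3), np.array([2.0, 0, 0])
        loss = contrastive_loss([(a, b)], [PairLabel(0, 10.0, 0.5)])
        assert loss.total == 0.0

    def test_coincident_dissimilar_pair_hinge(self):
        z = np.ones(3)
        loss = contrastive_loss([(z, z)], [PairLabel(0, 10.0, 0.5)])
        assert loss.total == pytest.approx(0.25)  # (0.5 - 0)^2

    def test_terms_decompose(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((6, 3))
        labels = np.array([0.0, 2.0, 50.0, 52.0, 120.0, 122.0])
        iu, ju, y, mu, _ = batch_pair_arrays(labels, ThresholdConfig(5.0),
                                             "supervised")
        loss, dz, info = contrastive_loss_grad(z, iu, ju, y, mu)
        assert loss.total == pytest.approx(loss.similar_term
                                           + loss.dissimilar_term)
        assert loss.total >= 0
        assert loss.n_pairs == 15
        assert info["n_similar"] == 3

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError, match="pairs"):
            contrastive_loss([(np.zeros(3), np.zeros(3))], [])

    def test_gradient_matches_finite_differences(self):
        """Analytic network gradient of the pair loss vs central differences
        on a 5-point toy batch (dropout masks and batch statistics fixed)."""
        rng = np.random.default_rng(3)
        net = MLP(6, [8, 8], 3, dropout_rate=0.2, batch_norm=True, rng=rng)
        x = rng.standard_normal((5, 6))
        labels = np.array([0.0, 4.0, 30.0, 31.0, 90.0])
        iu, ju, y, mu, _ = batch_pair_arrays(labels, ThresholdConfig(5.0),
                                             "supervised")
        masks = [rng.random((5, w)) >= 0.2 for w in (8, 8)]
        keys = sorted(net.params)

        def loss_at(flat):
            i = 0
            for k in keys:
                p = net.params[k]
                p.flat[:] = flat[i:i + p.size]
                i += p.size
            z, cache = net.forward(x, training=True, dropout_masks=masks)
            loss, dz, _ = contrastive_loss_grad(z, iu, ju, y, mu)
            return loss.total, dz, cache

        flat0 = np.concatenate([net.params[k].ravel() for k in keys])
        _, dz, cache = loss_at(flat0)
        grads, _ = net.backward(cache, dz)
        g = np.concatenate([grads[k].ravel() for k in keys])
        eps = 1e-6
        idx = np.random.default_rng(0).choice(flat0.size, 60, replace=False)
        for i in idx:
            up, dn = flat0.copy(), flat0.copy()
            up[i] += eps
            dn[i] -= eps
            fd = (loss_at(up)[0] - loss_at(dn)[0]) / (2 * eps)
            assert abs(fd - g[i]) <= 1e-5 * max(1.0, abs(fd), abs(g[i]))


class TestForward:
    def test_zero_weights_embed_to_origin(self):
        net = MLP(4, [5, 5], 3, dropout_rate=0.0, batch_norm=True,
                  rng=np.random.default_rng(0))
        state = {k: np.zeros_like(v) for k, v in net.get_state().items()}
        for k in state:
            if k.endswith("_var"):
                state[k] = np.ones_like(state[k])
        net.set_state(state)
        z, _ = net.forward(np.random.default_rng(1).standard_normal((4, 4)))
        assert np.allclose(z, 0.0)

    def test_batch_matches_single_forward(self):
        net = MLP(4, [6, 6], 3, dropout_rate=0.3, batch_norm=True,
                  rng=np.random.default_rng(2))
        x = np.random.default_rng(3).standard_normal((7, 4))
        zb, _ = net.forward(x, training=False)
        for i in range(7):
            zi, _ = net.forward(x[i], training=False)
            assert np.allclose(zb[i], zi[0])

    def test_dimension_mismatch_raises(self):
        net = MLP(4, [6], 3, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="dimension"):
            net.forward(np.zeros((2, 5)))

    def test_siamese_branches_share_one_parameter_set(self):
        """The pairwise loss is computed on one network's outputs, so the
        parameter count equals that of a single branch."""
        d, h = 90, 90
        net = MLP(d, [h, h], 3, batch_norm=True,
                  rng=np.random.default_rng(0))
        expected = (d * h + h) + (h * h + h) + 2 * h + 2 * h + (h * 3 + 3)
        assert net.n_parameters == expected


class TestTraining:
    def test_loss_decreases_on_toy_grid(self, clean_coarse_ds):
        res = _toy_model(clean_coarse_ds).fit(
            TrainConfig(max_epochs=30, seed=0))
        h = res.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]

    def test_seeded_rerun_is_identical(self, clean_coarse_ds):
        r1 = _toy_model(clean_coarse_ds).fit(TrainConfig(max_epochs=8, seed=4))
        r2 = _toy_model(clean_coarse_ds).fit(TrainConfig(max_epochs=8, seed=4))
        assert np.array_equal(r1.history["train_loss"].to_numpy(),
                              r2.history["train_loss"].to_numpy())
        x = clean_coarse_ds.val_features[:3]
        assert np.array_equal(r1.embed(x), r2.embed(x))

    def test_degenerate_training_flagged(self):
        """If no mini-batch ever contains a similar pair the run is marked."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 10))
        labels = np.arange(8) * 20.0  # pairwise distances all > eps_u
        model = ContrastiveEmbedding(
            x, labels, network=NetworkSpec(input_dim=10, hidden_widths=(8, 8)),
            thresholds=ThresholdConfig(angle_threshold_deg=1.0))
        res = model.fit(TrainConfig(max_epochs=3, seed=0, batch_size=8))
        assert res.degenerate_training

    def test_neighborhood_preservation_beats_raw_space(self, reverb_coarse_ds):
        """Core claim: embedding 5-NN respect source proximity more often
        than raw measurement-space 5-NN under reverberation."""
        from scipy.spatial.distance import cdist

        ds = reverb_coarse_ds
        res = _toy_model(ds).fit(TrainConfig(max_epochs=60, seed=1))
        eps_u = 5.0
        az = ds.train_labels["azimuth_deg"].to_numpy()
        azt = ds.test_labels["azimuth_deg"].to_numpy()

        def neighbor_fraction(space_train, space_test):
            d = cdist(space_test, space_train)
            nn = np.argsort(d, axis=1)[:, :5]
            close = np.abs(az[nn] - azt[:, None]) <= eps_u
            return close.mean()

        frac_raw = neighbor_fraction(ds.train_features, ds.test_features)
        frac_emb = neighbor_fraction(res.train_embeddings,
                                     res.embed(ds.test_features))
        assert frac_emb > frac_raw


class TestCheckpoint:
    def test_roundtrip_preserves_embeddings(self, clean_coarse_ds, tmp_path):
        res = _toy_model(clean_coarse_ds).fit(TrainConfig(max_epochs=5, seed=2))
        path = tmp_path / "model.ckpt"
        res.save(path)
        loaded = load_model(path)
        x = clean_coarse_ds.test_features[:5]
        assert np.array_equal(res.embed(x), loaded.embed(x))
        assert np.array_equal(res.localize(x).ravel(),
                              loaded.localize(x).ravel())

    def test_wrong_input_dim_raises_naming_field(self, clean_coarse_ds,
                                                 tmp_path):
        import json
        import zipfile

        res = _toy_model(clean_coarse_ds).fit(TrainConfig(max_epochs=2, seed=2))
        path = tmp_path / "model.ckpt"
        res.save(path)
        bad = tmp_path / "bad.ckpt"
        with zipfile.ZipFile(path) as zin, zipfile.ZipFile(bad, "w") as zout:
            for name in zin.namelist():
                data = zin.read(name)
                if name == "header.json":
                    header = json.loads(data)
                    header["network"]["input_dim"] = 17
                    header["network"]["hidden_widths"] = [17, 17]
                    data = json.dumps(header).encode()
                zout.writestr(name, data)
        with pytest.raises(ValueError, match="input_dim"):
            load_model(bad)

    def test_corrupted_file_raises(self, tmp_path):
        path = tmp_path / "junk.ckpt"
        path.write_bytes(b"not a checkpoint at all")
        with pytest.raises(ValueError, match="corrupt"):
            load_model(path)
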