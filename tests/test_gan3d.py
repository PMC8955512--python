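"""Generator/discriminator contracts, losses, and training behavior."""

import numpy as np
import pytest

from voxtrans.gan3d import (GeneratorConfig, ModelBundle, ModelEntry, PRESETS,
                            Pix2PixTranslator, build_discriminator,
                            build_generator, cgan_losses, load_entry,
                            predict, save_entry, train_model)
from voxtrans.volume_io import Volume

TINY = GeneratorConfig(kernel_size=4, base_filters=4, depth=2)


class TestGenerator:
    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_preset_forward_shape_and_range(self, preset, rng):
        """Every production preset maps a cube in [-1,1] to a same-shape cube
        in (-1,1); tested at a reduced side, the architecture is size-free."""
        cfg = PRESETS[preset]
        cfg = GeneratorConfig(kernel_size=cfg.kernel_size, base_filters=4,
                              depth=3)
        gen = build_generator(cfg, input_side=16, seed=0)
        x = rng.uniform(-1, 1, size=(1, 16, 16, 16)).astype(np.float32)
        y = gen.forward(x, train=False)
        assert y.shape == x.shape
        assert np.all(y > -1) and np.all(y < 1)

    def test_indivisible_side_rejected(self):
        gen = build_generator(TINY, input_side=8, seed=0)
        with pytest.raises(ValueError):
            gen.forward(np.zeros((1, 10, 10, 10), dtype=np.float32))

    @pytest.mark.parametrize("preset,side", [(p, 128) for p in sorted(PRESETS)])
    def test_production_parameter_count_order(self, preset, side):
        """Full-size presets hold hundreds of millions of trainable weights."""
        n = PRESETS[preset].num_parameters(side)
        assert 1e8 < n < 1e9

    def test_analytic_count_matches_allocation(self):
        gen = build_generator(TINY, input_side=8, seed=0)
        assert gen.num_parameters() == TINY.num_parameters(8)


class TestDiscriminator:
    def test_score_grid_smaller_than_input(self, rng):
        disc = build_discriminator(TINY, seed=0)
        c = rng.uniform(-1, 1, (1, 16, 16, 16)).astype(np.float32)
        s = disc.forward(c, c, train=False)
        assert s.shape == (1, 2, 2, 2)
        assert np.all((s > 0) & (s < 1))

    def test_shape_mismatch_rejected(self, rng):
        disc = build_discriminator(TINY, seed=0)
        with pytest.raises(ValueError):
            disc.forward(np.zeros((1, 16, 16, 16), dtype=np.float32),
                         np.zeros((1, 8, 8, 8), dtype=np.float32))

    def test_receptive_field_locality(self, rng):
        """A voxel outside a score element's receptive field cannot change it
        (finite-difference oracle at opposite corners)."""
        disc = build_discriminator(TINY, seed=1)
        c = rng.uniform(-1, 1, (1, 32, 32, 32)).astype(np.float32)
        y = rng.uniform(-1, 1, (1, 32, 32, 32)).astype(np.float32)
        s0 = disc.forward(c, y, train=False)
        y2 = y.copy()
        y2[0, -1, -1, -1] += 0.5  # far corner: outside score (0,0,0)'s field
        s1 = disc.forward(c, y2, train=False)
        assert s1[0, 0, 0, 0] == pytest.approx(s0[0, 0, 0, 0], abs=1e-12)
        assert s1[0, -1, -1, -1] != pytest.approx(s0[0, -1, -1, -1], abs=1e-12)


class TestLosses:
    def test_equilibrium_closed_form(self):
        """D == 0.5 everywhere with perfect reconstruction gives
        loss_D = 2 log 2 and loss_G = log 2 (the L1 term vanishes)."""
        half = np.full((1, 2, 2, 2), 0.5)
        x = np.zeros((1, 4, 4, 4))
        loss_d, loss_g = cgan_losses(half, half, x, x)
        assert loss_d == pytest.approx(2 * np.log(2), abs=1e-6)
        assert loss_g == pytest.approx(np.log(2), abs=1e-6)

    def test_l1_term_weighting(self):
        """Constant 0.1 error with lambda = 100 contributes exactly 10."""
        half = np.full((1, 2, 2, 2), 0.5)
        x = np.zeros((1, 4, 4, 4))
        _, loss_g = cgan_losses(half, half, x, x + 0.1, lam=100.0)
        assert loss_g == pytest.approx(np.log(2) + 10.0, abs=1e-6)

    def test_lambda_zero_reduces_to_adversarial(self):
        half = np.full((1, 2, 2, 2), 0.5)
        x = np.zeros((1, 4, 4, 4))
        _, loss_g = cgan_losses(half, half, x, x + 0.3, lam=0.0)
        assert loss_g == pytest.approx(np.log(2), abs=1e-6)

    def test_degenerate_scores_clamped(self):
        ones = np.ones((1, 2, 2, 2))
        x = np.zeros((1, 4, 4, 4))
        loss_d, loss_g = cgan_losses(ones, ones, x, x)
        assert np.isfinite(loss_d) and np.isfinite(loss_g)


class TestTraining:
    def test_history_bookkeeping(self, tiny_pairs):
        entry = train_model(tiny_pairs, TINY, iterations=12, schedule=None,
                            eval_every=4, seed=0)
        assert len(entry.history) == 3
        assert [h["iteration"] for h in entry.history] == [4, 8, 12]
        assert entry.output_range[0] < entry.output_range[1]

    def test_training_reduces_l1_on_identity_task(self, rng):
        """CT == MR phantoms: a short run reduces the mean L1 error below the
        random-initialization level."""
        from voxtrans.preprocess import PairedSample
        pairs = []
        for i in range(4):
            d = np.clip(rng.normal(0, 0.4, (8, 8, 8)), -1, 1)
            v = Volume(data=d)
            pairs.append(PairedSample(subject_id=f"i{i}", mr=v, ct=v.copy_with()))

        def mean_l1(gen):
            return float(np.mean([
                np.abs(gen.forward(p.mr.data[None].astype(np.float32),
                                   train=False) - p.ct.data).mean()
                for p in pairs]))

        init = build_generator(TINY, input_side=8, seed=0)
        before = mean_l1(init)
        entry = train_model(pairs, TINY, iterations=60, schedule=None, seed=0)
        assert mean_l1(entry.generator) < before

    def test_reproducible_histories(self, tiny_pairs):
        kw = dict(iterations=10, schedule=None, eval_every=5, seed=11)
        h1 = train_model(tiny_pairs, TINY, **kw).history
        h2 = train_model(tiny_pairs, TINY, **kw).history
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_model([], TINY, iterations=1)


class TestPredict:
    @pytest.fixture
    def trained(self, tiny_pairs):
        return train_model(tiny_pairs, TINY, iterations=20, schedule=None, seed=0)

    def test_shape_preserved_and_deterministic(self, trained, tiny_pairs):
        mr = tiny_pairs[0].mr
        out1 = predict(trained.generator, mr)
        out2 = predict(trained.generator, mr)
        assert out1.shape == mr.shape
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_shape_mismatch_error(self, trained):
        with pytest.raises(ValueError):
            predict(trained.generator, Volume(data=np.zeros((6, 6, 6))))

    def test_checkpoint_round_trip(self, trained, tiny_pairs, tmp_path):
        save_entry(trained, tmp_path / "model.npz")
        back = load_entry(tmp_path / "model.npz")
        np.testing.assert_array_equal(
            predict(back.generator, tiny_pairs[0].mr).data,
            predict(trained.generator, tiny_pairs[0].mr).data)
        assert back.output_range == pytest.approx(trained.output_range)


class TestBundle:
    def test_complete_bundle_holds_15_entries(self, tiny_pairs):
        stub = ModelEntry(generator=build_generator(TINY, 8, seed=0),
                          config=TINY, output_range=(-1.0, 1.0))
        bundle = ModelBundle(n_patches=5, presets=("k4_f80", "k6_f60", "k8_f30"))
        for p in range(1, 6):
            for preset in bundle.presets:
                bundle.add(p, preset, stub)
        assert len(bundle) == 15
        assert bundle.is_complete

    def test_missing_entries_reported(self):
        bundle = ModelBundle(n_patches=5, presets=("k4_f80",))
        assert (3, "k4_f80") in bundle.missing()
        assert not bundle.is_complete

    def test_bad_keys_rejected(self, tiny_pairs):
        stub = ModelEntry(generator=build_generator(TINY, 8, seed=0),
                          config=TINY, output_range=(-1.0, 1.0))
        bundle = ModelBundle()
        with pytest.raises(IndexError):
            bundle.add(0, "k4_f80", stub)
        with pytest.raises(KeyError):
            bundle.add(1, "nope", stub)


class TestEstimator:
    def test_sklearn_params_and_fit_predict(self, tiny_pairs):
        est = Pix2PixTranslator(kernel_size=4, base_filters=4, depth=2,
                                iterations=8, augment=False, seed=0)
        assert est.get_params()["iterations"] == 8
        est.set_params(iterations=6)
        est.fit(tiny_pairs)
        out = est.predict(tiny_pairs[0].mr)
        assert out.shape == tiny_pairs[0].mr.shape
        assert est.n_iter_ == 6

    def test_unfitted_predict_raises(self, tiny_pairs):
        with pytest.raises(RuntimeError):
            Pix2PixTranslator().predict(tiny_pairs[0].mr)
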