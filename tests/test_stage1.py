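import numpy as np
import pytest

from mvct._training import DEFAULT_HU_WINDOW
from mvct.geometry import CTVolume, split_volume
from mvct.networks import tiny_discriminator_spec, tiny_generator_spec
from mvct.stage1 import (
    Stage1Config,
    TranslationModel,
    ViewPredictionTriple,
    _build_model,
    denoise_volume,
    generate_view_complementary_predictions,
    train_view_model,
)
from mvct.synthetic import (
    DoseSpec,
    PhantomSpec,
    build_unpaired_dataset,
    generate_phantom,
    simulate_low_dose,
)

from helpers import stub_model

HU_SPAN_HALF = (DEFAULT_HU_WINDOW[1] - DEFAULT_HU_WINDOW[0]) / 2.0


@pytest.fixture(scope="module")
def tiny_dataset():
    hd = [generate_phantom(PhantomSpec(shape=(8, 24, 24), seed=s)) for s in range(2)]
    ld = [
        simulate_low_dose(v, DoseSpec(noise_mode="image_gaussian", seed=30 + s))
        for s, v in enumerate(hd)
    ]
    return build_unpaired_dataset(ld, hd, "axial", shuffle_seed=0)


def smoke_config(**kw):
    defaults = dict(
        patch_size=16,
        batch_size=2,
        patches_per_slice=1,
        epochs=1,
        steps_per_epoch=4,
        learning_rate=1e-4,
        seed=0,
    )
    defaults.update(kw)
    return Stage1Config(**defaults)


class TestTrainViewModel:
    def test_smoke_finite_losses(self, tiny_dataset):
        m = train_view_model(
            tiny_dataset, smoke_config(), tiny_generator_spec("redcnn"),
            tiny_discriminator_spec(),
        )
        assert len(m.history) == 4
        for rec in m.history:
            assert np.isfinite(rec["total"])
            assert np.isfinite(rec["gan_d"])

    def test_seeded_determinism(self, tiny_dataset):
        cfg = smoke_config(steps_per_epoch=2)
        m1 = train_view_model(tiny_dataset, cfg, tiny_generator_spec("redcnn"),
                              tiny_discriminator_spec())
        m2 = train_view_model(tiny_dataset, cfg, tiny_generator_spec("redcnn"),
                              tiny_discriminator_spec())
        assert m1.history[0] == m2.history[0]
        assert m1.history[-1] == m2.history[-1]

    def test_paired_dataset_rejected(self, tiny_dataset):
        import dataclasses

        paired = dataclasses.replace(tiny_dataset, paired=True)
        with pytest.raises(ValueError, match="unpaired"):
            train_view_model(paired, smoke_config())

    def test_oversized_patch_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="patch_size"):
            train_view_model(tiny_dataset, smoke_config(patch_size=64))

    def test_checkpoint_round_trip(self, tmp_path, tiny_dataset, rng):
        m = train_view_model(
            tiny_dataset, smoke_config(steps_per_epoch=2),
            tiny_generator_spec("redcnn"), tiny_discriminator_spec(),
        )
        path = m.save(tmp_path / "model.npz")
        m2 = TranslationModel.load(path)
        assert m2.view == m.view
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(m.g_xy(x), m2.g_xy(x))
        np.testing.assert_array_equal(m.d_y(x), m2.d_y(x))
        assert m2.history == m.history


class TestDenoiseVolume:
    def test_identity_generator_preserves_volume(self, small_phantom):
        m = stub_model("axial")
        out = denoise_volume(m, small_phantom, "l2h")
        np.testing.assert_allclose(out.intensities, small_phantom.intensities, atol=1e-2)

    def test_constant_shift_propagates(self, small_phantom):
        c = 0.1
        m = stub_model("coronal", add_l2h=c)
        out = denoise_volume(m, small_phantom, "l2h")
        np.testing.assert_allclose(
            out.intensities, small_phantom.intensities + c * HU_SPAN_HALF, atol=1e-2
        )

    @pytest.mark.parametrize("view", ["axial", "sagittal", "coronal"])
    def test_shape_preserved_all_views(self, small_phantom, view):
        m = stub_model(view)
        assert denoise_volume(m, small_phantom, "h2l").shape == small_phantom.shape

    def test_direction_selects_generator(self, small_phantom):
        m = stub_model("axial", add_l2h=0.2, add_h2l=-0.2)
        up = denoise_volume(m, small_phantom, "l2h")
        down = denoise_volume(m, small_phantom, "h2l")
        assert up.intensities.mean() > down.intensities.mean()

    def test_bad_direction_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="direction"):
            denoise_volume(stub_model("axial"), small_phantom, "sideways")


class TestViewComplementaryPredictions:
    @pytest.fixture(scope="class")
    def identity_models(self):
        return {v: stub_model(v) for v in ("axial", "sagittal", "coronal")}

    def test_identity_models_reproduce_axial_slices(self, small_phantom, identity_models):
        triples = generate_view_complementary_predictions(
            identity_models, small_phantom, "l2h"
        )
        axial = split_volume(small_phantom, "axial")
        assert len(triples) == small_phantom.shape[0]
        for i, t in enumerate(triples):
            np.testing.assert_allclose(t.from_axial, axial.slices[i], atol=1e-2)
            np.testing.assert_allclose(t.from_sagittal, axial.slices[i], atol=1e-2)
            np.testing.assert_allclose(t.from_coronal, axial.slices[i], atol=1e-2)

    def test_constant_models_mark_provenance(self, small_phantom):
        models = {
            "axial": stub_model("axial", add_l2h=0.1),
            "sagittal": stub_model("sagittal", add_l2h=0.2),
            "coronal": stub_model("coronal", add_l2h=0.3),
        }
        triples = generate_view_complementary_predictions(models, small_phantom, "l2h")
        axial = split_volume(small_phantom, "axial")
        t = triples[3]
        np.testing.assert_allclose(
            t.from_axial, axial.slices[3] + 0.1 * HU_SPAN_HALF, atol=1e-2
        )
        np.testing.assert_allclose(
            t.from_sagittal, axial.slices[3] + 0.2 * HU_SPAN_HALF, atol=1e-2
        )
        np.testing.assert_allclose(
            t.from_coronal, axial.slices[3] + 0.3 * HU_SPAN_HALF, atol=1e-2
        )

    def test_axial_member_equals_direct_application(self, small_phantom, identity_models):
        # stack/resplit is a no-op for the axial view
        triples = generate_view_complementary_predictions(
            identity_models, small_phantom, "l2h"
        )
        direct = denoise_volume(identity_models["axial"], small_phantom, "l2h")
        for i, t in enumerate(triples):
            np.testing.assert_array_equal(t.from_axial, direct.intensities[i])

    def test_missing_view_rejected(self, small_phantom, identity_models):
        incomplete = {k: v for k, v in identity_models.items() if k != "coronal"}
        with pytest.raises(ValueError, match="missing model"):
            generate_view_complementary_predictions(incomplete, small_phantom, "l2h")

    def test_mislabeled_view_rejected(self, small_phantom, identity_models):
        swapped = dict(identity_models)
        swapped["axial"] = identity_models["coronal"]
        with pytest.raises(ValueError, match="view"):
            generate_view_complementary_predictions(swapped, small_phantom, "l2h")

    def test_triple_invariants(self, small_phantom, identity_models):
        triples = generate_view_complementary_predictions(
            identity_models, small_phantom, "h2l"
        )
        for t in triples:
            assert t.direction == "h2l"
            assert t.from_axial.shape == small_phantom.shape[1:]

    def test_deterministic_given_frozen_models(self, small_phantom, identity_models):
        t1 = generate_view_complementary_predictions(identity_models, small_phantom, "l2h")
        t2 = generate_view_complementary_predictions(identity_models, small_phantom, "l2h")
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.from_sagittal, b.from_sagittal)


class TestViewPredictionTriple:
    def test_shape_consistency_enforced(self, rng):
        with pytest.raises(ValueError, match="shape"):
            ViewPredictionTriple(
                axial_index=("v", 0),
                from_axial=rng.normal(size=(4, 4)),
                from_sagittal=rng.normal(size=(4, 4)),
                from_coronal=rng.normal(size=(5, 5)),
            )

    def test_bad_direction_rejected(self, rng):
        s = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="direction"):
            ViewPredictionTriple(("v", 0), s, s, s, direction="up")
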