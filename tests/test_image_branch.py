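import dataclasses

import numpy as np
import pytest

from scribepd.image_branch import (
    IMG_H,
    IMG_W,
    ROTATION_SET,
    CNNConfig,
    MicrographiaParams,
    build_network,
    embed_images,
    finetune_and_embed,
    make_pretrain_corpus,
    pretrain_cnn,
    render_recording,
    render_strokes,
    scale_sequence,
)
from scribepd._cnn import FREEZING_SCHEMES
from scribepd.synthetic_data import SubjectProfile, synthesize_recording


class TestScaleSequence:
    def test_late_onset_profile(self):
        assert np.allclose(scale_sequence(5),
                           [1, 1, 1, 1, 1, 1.0, 0.875, 0.75, 0.625, 0.5])

    @pytest.mark.parametrize("onset", range(6))
    def test_endpoints_and_monotonicity(self, onset):
        s = scale_sequence(onset)
        assert s[9] == 0.5
        assert s[onset] == 1.0
        assert np.all(np.diff(s) <= 0)

    @pytest.mark.parametrize("onset", [-1, 6, 2.5])
    def test_invalid_onset_rejected(self, onset):
        with pytest.raises(ValueError):
            scale_sequence(onset)

    def test_rotation_outside_the_stated_set_rejected(self):
        with pytest.raises(ValueError, match="rotation"):
            MicrographiaParams(onset_digit=2, rotation=7.0)


class TestRendering:
    def test_output_shape_and_range(self, hc_recording):
        img = render_recording(hc_recording)
        assert img.pixels.shape == (IMG_H, IMG_W)
        assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0
        assert img.pixels.max() > 0.5  # there is ink

    def test_rendering_is_deterministic(self, hc_recording):
        a = render_recording(hc_recording)
        b = render_recording(hc_recording)
        assert np.array_equal(a.pixels, b.pixels)

    def test_horizontal_line_occupies_one_row_band(self):
        pts = np.column_stack([np.linspace(0, 100, 50), np.full(50, 7.0)])
        img = render_strokes([pts])
        rows = np.flatnonzero((img > 0.1).sum(axis=1) > 0)  # solid ink only
        assert rows.size > 0
        assert rows.max() - rows.min() <= 4

    def test_invariance_to_translation_and_uniform_scaling(self, hc_recording):
        base = render_recording(hc_recording).pixels
        moved = dataclasses.replace(
            hc_recording,
            subject_id="moved",
            x=hc_recording.x * 2.0 + 500.0,
            y=hc_recording.y * 2.0 - 300.0,
        )
        other = render_recording(moved).pixels
        assert np.abs(base - other).max() < 0.05

    def test_no_on_surface_samples_rejected(self, make_recording):
        rec = make_recording(np.zeros(6))
        with pytest.raises(ValueError, match="on-surface"):
            render_recording(rec)


class TestPretrainCorpus:
    def test_half_modified_half_not(self):
        corpus = make_pretrain_corpus(14, seed=0)
        assert len(corpus) == 14
        assert corpus.labels.sum() == 7
        assert len(corpus.train_idx) == 12 and len(corpus.test_idx) == 2

    def test_rotations_only_from_the_stated_set(self):
        corpus = make_pretrain_corpus(20, seed=1)
        assert set(np.unique(corpus.rotations)) <= set(ROTATION_SET)

    def test_odd_total_rejected(self):
        with pytest.raises(ValueError, match="even"):
            make_pretrain_corpus(7, seed=0)

    def test_deterministic_under_seed(self):
        a = make_pretrain_corpus(6, seed=3)
        b = make_pretrain_corpus(6, seed=3)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.labels, b.labels)


class TestNetwork:
    def test_embedding_dimension_is_1944(self, pretrained_model):
        model, _, corpus = pretrained_model
        emb = model.embed(corpus.images[:2])
        assert emb.shape == (2, 18 * 27 * 4) == (2, 1944)

    def test_freezing_chain_is_strictly_increasing(self):
        model = build_network(CNNConfig(seed=0))
        counts = [model.trainable_parameter_count(s)
                  for s in ("fully_frozen", "partially_frozen",
                            "semi_frozen", "unfrozen")]
        assert counts == sorted(counts)
        assert len(set(counts)) == 4

    def test_softmax_outputs_sum_to_one(self, pretrained_model):
        model, _, corpus = pretrained_model
        probs = model.predict_proba(corpus.images[:4])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_pretraining_detects_micrographia(self, pretrained_model):
        _, test_acc, _ = pretrained_model
        assert test_acc > 0.9

    def test_training_is_deterministic(self):
        corpus = make_pretrain_corpus(12, seed=2)
        cfg = CNNConfig(seed=9, epochs=1)
        m1, _ = pretrain_cnn(corpus, cfg)
        m2, _ = pretrain_cnn(corpus, cfg)
        for layer in m1.layers:
            assert m1.weight_hash(layer) == m2.weight_hash(layer)

    def test_single_class_corpus_rejected(self):
        corpus = make_pretrain_corpus(8, seed=0)
        corpus.labels[:] = 1
        with pytest.raises(ValueError, match="both labels"):
            pretrain_cnn(corpus, CNNConfig(epochs=1))


@pytest.fixture(scope="module")
def finetuned(pretrained_model):
    model, _, corpus = pretrained_model
    images = corpus.images[:8]
    labels = corpus.labels[:8]
    cfg = CNNConfig(epochs=1, seed=1)
    out = {}
    for scheme in FREEZING_SCHEMES:
        tuned, vecs = finetune_and_embed(model, images, labels, scheme, cfg)
        out[scheme] = (tuned, vecs)
    return model, out


class TestFreezingSchemes:
    def test_fully_frozen_conv_weights_untouched(self, finetuned):
        model, out = finetuned
        tuned, _ = out["fully_frozen"]
        for layer in ("conv1", "conv2", "conv3"):
            assert tuned.weight_hash(layer) == model.weight_hash(layer)

    def test_semi_frozen_updates_conv1_conv2_only(self, finetuned):
        model, out = finetuned
        tuned, _ = out["semi_frozen"]
        assert tuned.weight_hash("conv1") != model.weight_hash("conv1")
        assert tuned.weight_hash("conv2") != model.weight_hash("conv2")
        assert tuned.weight_hash("conv3") == model.weight_hash("conv3")

    def test_unfrozen_updates_all_conv_layers(self, finetuned):
        model, out = finetuned
        tuned, _ = out["unfrozen"]
        for layer in ("conv1", "conv2", "conv3"):
            assert tuned.weight_hash(layer) != model.weight_hash(layer)

    def test_embeddings_are_static_vectors(self, finetuned):
        _, out = finetuned
        _, vecs = out["fully_frozen"]
        assert len(vecs) == 8
        assert all(v.provenance == "cnn_embedding" for v in vecs)
        assert all(len(v) == 1944 for v in vecs)

    def test_unknown_scheme_rejected(self, pretrained_model):
        model, _, corpus = pretrained_model
        with pytest.raises(ValueError, match="scheme"):
            finetune_and_embed(model, corpus.images[:4], corpus.labels[:4],
                               "mostly_frozen")


def test_rendered_recordings_embed_like_corpus_images(pretrained_model,
                                                      glyph_bank):
    """Rendered subject traces pass through the same embedding path."""
    model, _, _ = pretrained_model
    rec = synthesize_recording(SubjectProfile(seed=21), glyph_bank)
    vecs = embed_images(model, [render_recording(rec)])
    assert len(vecs) == 1 and len(vecs[0]) == 1944
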