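import numpy as np
import pytest

import eegcorrcam as ec
from eegcorrcam import nn
from eegcorrcam.gradcam import (Heatmap, explain_subject, gradcam,
                                pair_attribution, render_heatmap)
from eegcorrcam.model import ModelSpec, build_model

MONTAGE12 = ec.io.DEFAULT_MONTAGE


def _block_detector_net(side=96):
    """Hand-built net whose class-0 logit responds only to input values in
    a known region: conv passes the input through (centre-only kernel),
    global max pool, identity-ish dense."""
    conv = nn.Conv2D(1, 3, activation="relu")
    gmp = nn.GlobalMaxPool2D()
    dense = nn.Dense(2, "softmax")
    net = nn.Network([conv, gmp, dense], (side, side, 1), seed=0)
    conv.params["W"][:] = 0.0
    conv.params["W"][1, 1, 0, 0] = 1.0
    conv.params["b"][:] = 0.0
    dense.params["W"][:] = np.array([[1.0, -1.0]], dtype=np.float32)
    dense.params["b"][:] = 0.0
    return net


class TestGradcam:
    def test_constructed_model_concentrates_mass_in_active_block(self):
        # only rows 16:24 x cols 40:48 carry signal; >= 90% of the heatmap
        # mass must land there (gradient field known analytically)
        x = np.zeros((96, 96), dtype=np.float32)
        x[16:24, 40:48] = 5.0
        net = _block_detector_net()
        hm = gradcam(net, x, 0, target="logit")
        assert hm.values[16:24, 40:48].sum() / hm.values.sum() >= 0.9

    def test_probability_target_matches_logit_on_two_class_detector(self):
        x = np.zeros((96, 96), dtype=np.float32)
        x[8:16, 8:16] = 3.0
        net = _block_detector_net()
        a = gradcam(net, x, 0, target="logit").values
        b = gradcam(net, x, 0, target="probability").values
        # min-max normalisation removes the p(1-p) scale factor
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_repeated_calls_are_identical(self, rng):
        spec = ModelSpec.scaled(input_side=24, conv_filters=(2, 3))
        net = build_model(spec, seed=0)
        x = rng.standard_normal((24, 24)).astype(np.float32)
        a = gradcam(net, x, 1)
        b = gradcam(net, x, 1)
        np.testing.assert_array_equal(a.values, b.values)

    def test_output_normalised_to_unit_interval_at_input_shape(self, rng):
        spec = ModelSpec.scaled(input_side=24, conv_filters=(2, 3))
        net = build_model(spec, seed=2)
        hm = gradcam(net, rng.standard_normal((24, 24)).astype(np.float32), 0)
        assert hm.values.shape == (24, 24)
        assert hm.values.min() >= 0.0
        assert hm.values.max() == pytest.approx(1.0) or hm.values.max() == 0.0

    def test_dead_feature_maps_give_zero_heatmap_with_warning(self):
        net = _block_detector_net(side=24)
        net.layers[0].params["W"][:] = 0.0  # no activation anywhere
        with pytest.warns(UserWarning, match="all zero"):
            hm = gradcam(net, np.ones((24, 24), dtype=np.float32), 0)
        assert np.all(hm.values == 0)

    def test_invalid_target_class_rejected(self):
        net = _block_detector_net(side=24)
        with pytest.raises(ValueError, match="target_class"):
            gradcam(net, np.zeros((24, 24), dtype=np.float32), 5)

    def test_model_without_conv_layer_rejected(self):
        net = nn.Network([nn.Dense(3, "softmax")], (4,), seed=0)
        with pytest.raises(ValueError, match="conv"):
            net.last_conv_index()


class TestPairAttribution:
    def test_uniform_heatmap_ranks_by_tie_break_order(self):
        hm = np.ones((4 * 3, 4 * 3))
        attr = pair_attribution(hm, ["a", "b", "c", "d"], 3)
        assert all(v == pytest.approx(1.0) for v in attr.scores.values())
        assert attr.ranking[:4] == [("a", "a"), ("a", "b"), ("a", "c"), ("a", "d")]
        assert len(attr.scores) == 4 * 5 // 2

    def test_single_block_support_identifies_fp2_p4(self):
        # support on rows 30-59 x cols 150-179 = channel block (1, 5)
        hm = np.zeros((360, 360))
        hm[30:60, 150:180] = 1.0
        attr = pair_attribution(hm, MONTAGE12, 30)
        assert attr.ranking[0] == ("Fp2", "P4")
        assert attr.scores[("Fp2", "P4")] == pytest.approx(0.5)  # one-sided

    def test_diagonal_support_ranks_self_pairs_first(self, rng):
        c, n = 5, 4
        hm = np.zeros((c * n, c * n))
        for i in range(c):
            hm[i * n : (i + 1) * n, i * n : (i + 1) * n] = rng.uniform(0.5, 1.0)
        attr = pair_attribution(hm, list("abcde"), n)
        top = attr.ranking[:c]
        assert all(p[0] == p[1] for p in top)
        assert attr.cross_ranking[0][0] != attr.cross_ranking[0][1]

    def test_invariant_under_symmetrisation(self, rng):
        hm = rng.uniform(0, 1, (12, 12))
        sym = (hm + hm.T) / 2
        a = pair_attribution(hm, list("abc"), 4)
        b = pair_attribution(sym, list("abc"), 4)
        for pair in a.scores:
            assert a.scores[pair] == pytest.approx(b.scores[pair], abs=1e-12)

    def test_block_means_conserve_total_mass(self, rng):
        c, n = 6, 5
        hm = rng.uniform(0, 1, (c * n, c * n))
        blocks = hm.reshape(c, n, c, n).mean(axis=(1, 3))
        assert blocks.sum() * n * n == pytest.approx(hm.sum(), rel=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            pair_attribution(np.zeros((10, 10)), list("abc"), 4)


class TestExplainSubject:
    @pytest.fixture
    def small_net(self):
        spec = ModelSpec.scaled(input_side=24, conv_filters=(2, 3))
        return build_model(spec, seed=4)

    def test_single_epoch_consensus_equals_its_ranking(self, small_net, rng):
        x = rng.standard_normal((24, 24)).astype(np.float32)
        exp = explain_subject(small_net, [x], 0, list("abcdef"), 4)
        assert exp.ranking == exp.attributions[0].ranking

    def test_identical_epochs_share_the_common_ranking(self, small_net, rng):
        x = rng.standard_normal((24, 24)).astype(np.float32)
        exp = explain_subject(small_net, [x] * 8, 1, list("abcdef"), 4)
        assert exp.ranking == exp.attributions[0].ranking
        assert all(a.ranking == exp.attributions[0].ranking
                   for a in exp.attributions)

    def test_empty_epoch_set_rejected(self, small_net):
        with pytest.raises(ValueError, match="at least one"):
            explain_subject(small_net, [], 0, list("abcdef"), 4)


def test_render_heatmap_writes_png(tmp_path, rng):
    hm = Heatmap(rng.uniform(0, 1, (12, 12)), 0)
    out = tmp_path / "map.png"
    render_heatmap(hm, list("abc"), 4, path=out)
    assert out.exists() and out.stat().st_size > 0
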