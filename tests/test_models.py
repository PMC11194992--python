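"""Architecture construction and shape-inference contracts."""

import numpy as np
import pytest

from wolfscan.models import (
    ArchitectureError,
    HeadSpec,
    LayerSpec,
    ModelSpec,
    build_hybrid,
    build_model,
    build_vgg16_backbone,
    infer_shapes,
    materialize,
)


def _chain(*layers, input_shape=(224, 224, 3)):
    specs = []
    prev = ()
    for i, kw in enumerate(layers):
        name = kw.pop("name", f"l{i}")
        specs.append(LayerSpec(name=name, inputs=prev if isinstance(prev, tuple) else (prev,), **kw))
        prev = name
    return ModelSpec(name="chain", layers=specs, input_shape=input_shape)


class TestShapeArithmetic:
    def test_pointwise_conv_preserves_spatial(self):
        m = _chain({"op": "conv", "kernel": (1, 1), "units": 40}, input_shape=(17, 13, 5))
        assert infer_shapes(m)["l0"] == (17, 13, 40)

    def test_valid_pool_seven_to_three(self):
        m = _chain(
            {"op": "maxpool", "kernel": (3, 3), "stride": (2, 2), "padding": "valid"},
            input_shape=(7, 7, 32),
        )
        assert infer_shapes(m)["l0"] == (3, 3, 32)

    def test_same_padding_preserves_at_stride_one(self):
        m = _chain({"op": "conv", "kernel": (7, 1), "units": 8}, input_shape=(7, 7, 4))
        assert infer_shapes(m)["l0"] == (7, 7, 8)

    def test_concat_sums_channels(self):
        a = LayerSpec(name="a", op="conv", kernel=(1, 1), units=3)
        b = LayerSpec(name="b", op="conv", kernel=(1, 1), units=5)
        cat = LayerSpec(name="cat", op="concat", inputs=("a", "b"))
        m = ModelSpec(name="m", layers=[a, b, cat], input_shape=(4, 4, 2))
        assert infer_shapes(m)["cat"] == (4, 4, 8)

    def test_concat_spatial_mismatch_raises(self):
        a = LayerSpec(name="a", op="maxpool", kernel=(2, 2), stride=(2, 2))
        b = LayerSpec(name="b", op="conv", kernel=(1, 1), units=5)
        cat = LayerSpec(name="cat", op="concat", inputs=("a", "b"))
        m = ModelSpec(name="m", layers=[a, b, cat], input_shape=(4, 4, 2))
        with pytest.raises(ArchitectureError):
            infer_shapes(m)

    def test_nonpositive_dimension_names_layer(self):
        m = _chain(
            {"name": "shrink", "op": "conv", "kernel": (9, 9), "padding": "valid", "units": 4},
            input_shape=(5, 5, 1),
        )
        with pytest.raises(ArchitectureError, match="shrink"):
            infer_shapes(m)

    def test_global_avg_pool_and_dense(self):
        m = _chain(
            {"op": "global_avg_pool"},
            {"op": "dense", "units": 10},
            input_shape=(7, 7, 640),
        )
        shapes = infer_shapes(m)
        assert shapes["l0"] == (1, 1, 640)
        assert shapes["l1"] == (10,)


class TestVGGBackbone:
    def test_thirteen_convs_with_doubling_filters(self):
        layers = build_vgg16_backbone()
        convs = [l for l in layers if l.op == "conv"]
        pools = [l for l in layers if l.op == "maxpool"]
        assert len(convs) == 13
        assert len(pools) == 5
        assert convs[0].units == 64
        assert [c.units for c in convs] == [64, 64, 128, 128, 256, 256, 256,
                                            512, 512, 512, 512, 512, 512]
        assert all(c.kernel == (3, 3) and c.stride == (1, 1) for c in convs)

    def test_backbone_output_shape(self):
        layers = build_vgg16_backbone()
        m = ModelSpec(name="vgg", layers=layers)
        assert infer_shapes(m)[layers[-1].name] == (7, 7, 512)


@pytest.fixture(scope="module")
def hybrid():
    spec = build_hybrid()
    return spec, infer_shapes(spec)


class TestHybrid:
    def test_block_shape_trace(self, hybrid):
        spec, shapes = hybrid
        assert shapes[spec.blocks["block1"]] == (7, 7, 512)
        assert shapes[spec.blocks["block2"]] == (7, 7, 640)
        assert shapes[spec.blocks["block3"]] == (3, 3, 832)
        assert shapes[spec.blocks["block4_gap"]] == (1, 1, 1024)
        assert shapes[spec.blocks["block4_fc"]] == (1024,)
        assert shapes[spec.blocks["output"]] == (1,)

    def test_block2_structure(self, hybrid):
        spec, _ = hybrid
        b2 = [l for l in spec.layers if l.name.startswith("b2")]
        one_by_one = [l for l in b2 if l.op == "conv" and l.kernel == (1, 1)]
        three_by_three = [l for l in b2 if l.op == "conv" and l.kernel == (3, 3)]
        pools = [l for l in b2 if l.op == "maxpool"]
        # inception: four 1x1, three 3x3, one pool; reduction: one 1x1, three 3x3, one pool
        assert len(one_by_one) == 5
        assert len(three_by_three) == 6
        assert len(pools) == 2
        assert all(l.stride == (1, 1) for l in b2 if l.op == "conv")

    def test_block3_uses_factorized_sevens(self, hybrid):
        spec, _ = hybrid
        b3 = [l for l in spec.layers if l.name.startswith("b3")]
        sevens = [l for l in b3 if l.op == "conv" and l.kernel in ((7, 1), (1, 7))]
        assert len(sevens) == 8  # three inception pairs + one reduction pair
        assert not any(l.kernel == (7, 7) for l in b3 if l.op == "conv")
        strided = [l for l in b3 if l.stride == (2, 2)]
        assert strided and all(l.padding == "valid" for l in strided)

    def test_concat_channels_conserved_everywhere(self, hybrid):
        spec, shapes = hybrid
        inputs_of = {l.name: l.inputs for l in spec.layers}
        for l in spec.layers:
            if l.op == "concat":
                total = sum(shapes[n][2] for n in inputs_of[l.name])
                assert shapes[l.name][2] == total


class TestBuildModel:
    @pytest.mark.parametrize("name", ["vgg16", "densenet", "densenet_lstm", "inceptionv3", "hybrid"])
    def test_head_contract(self, name):
        """Every model ends in one sigmoid unit with two dropout(0.2) layers."""
        spec = build_model(name)
        shapes = infer_shapes(spec)
        out = spec.layers[-1]
        assert out.op == "dense" and out.units == 1 and out.activation == "sigmoid"
        assert shapes[out.name] == (1,)
        drops = [l for l in spec.layers if l.op == "dropout"]
        assert len(drops) == 2 and all(l.rate == pytest.approx(0.20) for l in drops)
        denses = [l for l in spec.layers if l.op == "dense" and l.name.startswith("head")]
        assert [d.units for d in denses] == [256, 128]

    def test_inception_stem_filters(self):
        spec = build_model("inceptionv3")
        stem = [l for l in spec.layers if l.name.startswith("inc_stem_conv")]
        assert [l.units for l in stem] == [32, 32, 64]

    def test_densenet_feature_map(self):
        spec = build_model("densenet")
        assert infer_shapes(spec)[spec.blocks["features"]] == (7, 7, 1024)

    def test_densenet_lstm_sequence_head(self):
        spec = build_model("densenet_lstm")
        lstm = spec.layer("lstm")
        assert lstm.op == "lstm" and lstm.units == 128
        assert infer_shapes(spec)["lstm"] == (128,)

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            build_model("resnet")

    def test_dense_units_override_from_hyperparameters(self):
        spec = build_model("vgg16", hp={"dense_units": 384})
        denses = [l for l in spec.layers if l.op == "dense" and l.name.startswith("head")]
        assert [d.units for d in denses] == [384, 192]

    def test_yaml_round_trip(self):
        spec = build_model("vgg16")
        clone = ModelSpec.from_yaml(spec.to_yaml())
        assert infer_shapes(clone) == infer_shapes(spec)
        assert [l.name for l in clone.layers] == [l.name for l in spec.layers]


class TestNumpyAdapter:
    def test_hybrid_shapes_match_inference(self):
        """Observed forward-pass shapes equal the symbolic inference, layer by layer."""
        spec = build_hybrid()
        inferred = infer_shapes(spec)
        observed = materialize(spec, seed=0).observed_shapes()
        assert set(observed) == set(inferred)
        for name in inferred:
            assert tuple(observed[name]) == tuple(inferred[name]), name

    def test_small_lstm_model_shapes(self):
        spec_small = ModelSpec(
            name="lstm_small",
            layers=[
                LayerSpec(name="c", op="conv", kernel=(3, 3), units=6),
                LayerSpec(name="lstm", op="lstm", inputs=("c",), units=11),
                LayerSpec(name="out", op="dense", inputs=("lstm",), units=1,
                          activation="sigmoid"),
            ],
            input_shape=(8, 8, 2),
        )
        observed = materialize(spec_small, seed=1).observed_shapes()
        assert observed == infer_shapes(spec_small)

    def test_dense_parameter_count(self):
        m = _chain({"op": "flatten"}, {"op": "dense", "units": 256}, input_shape=(32, 32, 1))
        nm = materialize(m, seed=0)
        nm.forward(np.zeros((32, 32, 1), dtype=np.float32))
        w = nm._weights["l1/w"]
        b = nm._weights["l1/b"]
        assert w.size + b.size == 1024 * 256 + 256

    def test_sigmoid_output_in_unit_interval(self):
        small = ModelSpec(
            name="tiny",
            layers=[
                LayerSpec(name="gap", op="global_avg_pool"),
                LayerSpec(name="out", op="dense", inputs=("gap",), units=1,
                          activation="sigmoid"),
            ],
            input_shape=(16, 16, 3),
        )
        nm = materialize(small, seed=2)
        out, _ = nm.forward(np.random.default_rng(0).uniform(0, 255, (16, 16, 3)))
        assert 0.0 < out[0] < 1.0

    def test_keras_adapter_unavailable_message(self):
        try:
            import keras  # noqa: F401

            pytest.skip("keras is installed here")
        except ImportError:
            pass
        with pytest.raises(ImportError, match="tensorflow"):
            materialize(build_model("vgg16"), adapter="keras")
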