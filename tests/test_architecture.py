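"""Architecture graphs: parameter accounting, dw rewrite, FLOPs, validation."""

import pytest

from bloomdet.architecture import (
    ArchitectureGraph,
    LayerNode,
    build_architecture,
    count_parameters,
    dw_separable_transform,
    flops_estimate,
    node_param_count,
)
from bloomdet.architecture.params import head_shapes


def conv_node(name, di, do, k=3, groups=1, bias=False, section="panet", **kw):
    return LayerNode(name=name, kind="conv", inputs=kw.pop("inputs", ()),
                     in_channels=di, out_channels=do, kernel=k, groups=groups,
                     bias=bias, section=section, **kw)


class TestNodeParamCount:
    def test_conv_3x3_no_bias(self):
        assert node_param_count(conv_node("c", 32, 64)) == 18_432  # 9*32*64

    def test_depthwise_plus_pointwise(self):
        dw = conv_node("d", 32, 32, k=3, groups=32)
        pw = conv_node("p", 32, 64, k=1)
        assert node_param_count(dw) + node_param_count(pw) == 288 + 2048

    def test_batchnorm_two_per_channel(self):
        bn = LayerNode(name="b", kind="batchnorm", in_channels=64, out_channels=64)
        assert node_param_count(bn) == 128

    def test_bias_and_dense(self):
        assert node_param_count(conv_node("c", 8, 4, k=1, bias=True)) == 36
        d = LayerNode(name="d", kind="dense", in_channels=16, out_channels=4)
        assert node_param_count(d) == 68

    def test_parameter_free_kinds(self):
        for kind in ("activation", "maxpool", "upsample", "concat", "add",
                     "slice", "global_pool", "se_scale"):
            n = LayerNode(name="x", kind=kind, in_channels=8, out_channels=8,
                          groups=2 if kind == "slice" else 1)
            assert node_param_count(n) == 0


class TestVariantCounts:
    """The four ablation configurations and their exact parameter totals."""

    @pytest.mark.parametrize("variant,num_classes,expected", [
        ("yolov4", 2, 63_943_071),
        ("yolov4_dw", 2, 35_690_655),
        ("yolov4_tiny", 20, 5_918_006),
        ("improved", 2, 11_309_039),
    ])
    def test_totals(self, variant, num_classes, expected):
        report = count_parameters(build_architecture(variant, num_classes=num_classes))
        assert report.total == expected

    def test_sections_sum_to_total(self):
        report = count_parameters(build_architecture("yolov4", num_classes=2))
        assert sum(report.by_section.values()) == report.total
        assert report.weight_bytes_fp32 == 4 * report.total

    def test_dw_reduction_ledger_diff(self):
        a = count_parameters(build_architecture("yolov4", num_classes=2))
        b = count_parameters(build_architecture("yolov4_dw", num_classes=2))
        assert a.total - b.total == 28_252_416
        # the backbone is untouched by the rewrite
        assert a.by_section["backbone"] == b.by_section["backbone"]

    def test_weight_sizes_round_to_244_and_136_mib(self):
        a = count_parameters(build_architecture("yolov4", num_classes=2))
        b = count_parameters(build_architecture("yolov4_dw", num_classes=2))
        assert round(a.weight_mib_fp32) == 244
        assert round(b.weight_mib_fp32) == 136
        assert round(100 * (1 - b.total / a.total)) == 44  # 44% reduction

    def test_80_class_reference_count(self):
        # the standard 80-class configuration of the full model
        report = count_parameters(build_architecture("yolov4", num_classes=80))
        assert report.total == 64_363_101

    def test_head_channels(self):
        g = build_architecture("yolov4", num_classes=2, anchors_per_head=3)
        assert g.head_channels() == 21
        for h in g.head_names:
            assert g.node(h).out_channels == 21

    def test_graphs_validate(self):
        for variant in ("yolov4", "yolov4_dw", "yolov4_tiny", "yolov4_tiny_dw",
                        "improved"):
            g = build_architecture(variant, num_classes=2)
            g.validate()
            n_heads = 2 if "tiny" in variant else 3
            assert len(g.head_names) == n_heads


class TestDwTransform:
    def test_strictly_fewer_parameters(self):
        g = build_architecture("yolov4", num_classes=2)
        t = dw_separable_transform(g, {"spp", "panet", "heads"})
        assert count_parameters(t).total < count_parameters(g).total

    def test_closed_form_single_conv(self):
        g = ArchitectureGraph(
            nodes=[conv_node("a", 512, 512, k=3, section="panet")],
            variant="yolov4", num_classes=2, head_names=(),
        )
        t = dw_separable_transform(g, {"panet"}, upsample_reducers=False)
        conv_params = sum(node_param_count(n) for n in t.nodes if n.kind == "conv")
        assert conv_params == 9 * 512 + 512 * 512  # 266,752 excluding BN

    def test_idempotent(self):
        g = build_architecture("yolov4", num_classes=2)
        once = dw_separable_transform(g, {"spp", "panet", "heads"})
        twice = dw_separable_transform(once, {"spp", "panet", "heads"})
        assert count_parameters(twice).total == count_parameters(once).total

    def test_empty_scope_identity(self):
        g = build_architecture("yolov4", num_classes=2)
        assert count_parameters(dw_separable_transform(g, set())).total == \
            count_parameters(g).total

    def test_no_untransformed_3x3_left_in_scope(self):
        for variant in ("yolov4_dw", "improved"):
            g = build_architecture(variant, num_classes=2)
            for n in g.nodes:
                if (n.kind == "conv" and n.section in ("spp", "panet", "heads")
                        and n.kernel == 3):
                    assert n.groups == n.in_channels, n.name

    def test_predictors_untouched(self):
        g = build_architecture("yolov4_dw", num_classes=2)
        preds = [n for n in g.nodes if n.role == "predictor"]
        assert len(preds) == 3
        for p in preds:
            assert p.kernel == 1 and p.bias and p.groups == 1


class TestFlops:
    def test_single_conv_closed_form(self):
        g = ArchitectureGraph(
            nodes=[conv_node("a", 3, 32, k=3, section="backbone")],
            variant="yolov4", num_classes=2, input_size=608, head_names=(),
        )
        assert flops_estimate(g) == 608 * 608 * 3 * 32 * 9  # 319,389,696

    def test_dw_pair_cheaper_and_ratio(self):
        full = ArchitectureGraph(
            nodes=[conv_node("a", 256, 512, k=3, section="panet")],
            variant="yolov4", num_classes=2, input_size=608, head_names=(),
        )
        pair = dw_separable_transform(full, {"panet"})
        f_full = flops_estimate(full)
        f_pair = flops_estimate(pair)
        assert f_pair < f_full
        # large-feature-map limit of the cost ratio: 1/Do + 1/(Hk*Wk)
        assert f_pair / f_full == pytest.approx(1 / 512 + 1 / 9, rel=1e-6)

    def test_head_shapes_stride_arithmetic(self):
        g = build_architecture("yolov4", num_classes=2, input_size=608)
        assert head_shapes(g) == [(76, 76, 21), (38, 38, 21), (19, 19, 21)]
        t = build_architecture("yolov4_tiny_dw", num_classes=2, input_size=608)
        assert head_shapes(t) == [(38, 38, 21), (19, 19, 21)]


class TestGraphJson:
    def test_round_trip(self):
        g = build_architecture("yolov4_tiny", num_classes=2)
        d = g.to_json_dict()
        back = ArchitectureGraph.from_json_dict(d)
        assert count_parameters(back).total == count_parameters(g).total
        assert back.head_names == g.head_names
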