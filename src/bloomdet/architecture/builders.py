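"""Builders for the YOLOv4-family architecture graphs.

Variants
--------
``yolov4``         CSPDarknet53 backbone (Mish), SPP, PANet, 3 heads.
``yolov4_dw``      the same with every 3x3 feature-fusion conv rewritten as a
                   depthwise-separable pair, including the two top-down
                   upsample channel reducers (the convention of common
                   lightweight ports of this family).
``yolov4_tiny``    stock two-head CSPDarknet53-tiny model.
``yolov4_tiny_dw`` the tiny model with the depthwise-separable neck rewrite.
``improved``       MobileNetV3-Large backbone (feature taps at strides
                   8/16/32 = 40/112/160 channels) feeding the
                   depthwise-separable SPP+PANet neck with plain 1x1 upsample
                   reducers, 3 heads.

All convs followed by batch norm carry no bias; head predictors are 1x1
convs with bias and are never rewritten.
"""

from __future__ import annotations

from .graph import ArchitectureGraph, LayerNode
from .transform import dw_separable_transform

VARIANTS = ("yolov4", "yolov4_dw", "yolov4_tiny", "yolov4_tiny_dw", "improved")


class _G:
    """Tiny imperative DSL for assembling graphs."""

    def __init__(self):
        self.nodes: list[LayerNode] = []
        self._i = 0

    def _name(self, prefix: str) -> str:
        self._i += 1
        return f"{prefix}_{self._i:03d}"

    def add_node(self, **kw) -> str:
        node = LayerNode(**kw)
        self.nodes.append(node)
        return node.name

    def conv(self, src, cin, cout, k=1, s=1, groups=1, act="leaky_relu", bn=True,
             bias=None, section="backbone", role="", prefix="conv") -> str:
        """conv [+ BN] [+ activation]; bias defaults to ``not bn``."""
        if bias is None:
            bias = not bn
        name = self._name(prefix)
        self.add_node(
            name=name, kind="conv", inputs=(src,) if src else (),
            in_channels=cin, out_channels=cout, kernel=k, stride=s, groups=groups,
            bias=bias, section=section, role=role,
        )
        out = name
        if bn:
            out = self.add_node(
                name=f"{name}_bn", kind="batchnorm", inputs=(out,),
                in_channels=cout, out_channels=cout, section=section, role=role,
            )
        if act != "linear":
            out = self.add_node(
                name=f"{name}_{act}", kind="activation", inputs=(out,),
                in_channels=cout, out_channels=cout, activation_kind=act,
                section=section, role=role,
            )
        return out

    def maxpool(self, src, ch, k, s, section) -> str:
        return self.add_node(
            name=self._name("pool"), kind="maxpool", inputs=(src,),
            in_channels=ch, out_channels=ch, kernel=k, stride=s, section=section,
        )

    def upsample(self, src, ch, section) -> str:
        return self.add_node(
            name=self._name("up"), kind="upsample", inputs=(src,),
            in_channels=ch, out_channels=ch, section=section,
        )

    def concat(self, srcs, chs, section) -> str:
        return self.add_node(
            name=self._name("cat"), kind="concat", inputs=tuple(srcs),
            in_channels=sum(chs), out_channels=sum(chs), section=section,
        )

    def add(self, a, b, ch, section) -> str:
        return self.add_node(
            name=self._name("add"), kind="add", inputs=(a, b),
            in_channels=ch, out_channels=ch, section=section,
        )

    def slice_half(self, src, ch, section) -> str:
        """Keep the second half of the channels (CSP-tiny route group)."""
        return self.add_node(
            name=self._name("slice"), kind="slice", inputs=(src,),
            in_channels=ch, out_channels=ch // 2, groups=2, group_id=1,
            section=section,
        )


# ---------------------------------------------------------------- backbones

def _csp_stage(g: _G, x: str, cin: int, cout: int, n_blocks: int, first: bool) -> str:
    """One cross-stage-partial stage of CSPDarknet53 (Mish activations)."""
    act = "mish"
    x = g.conv(x, cin, cout, k=3, s=2, act=act)  # downsample
    half = cout if first else cout // 2
    hidden = cout // 2 if first else half
    shortcut = g.conv(x, cout, half, k=1, act=act)
    main = g.conv(x, cout, half, k=1, act=act)
    for _ in range(n_blocks):
        t = g.conv(main, half, hidden, k=1, act=act)
        t = g.conv(t, hidden, half, k=3, act=act)
        main = g.add(main, t, half, "backbone")
    main = g.conv(main, half, half, k=1, act=act)
    cat = g.concat([main, shortcut], [half, half], "backbone")
    return g.conv(cat, 2 * half, cout, k=1, act=act)


def _cspdarknet53(g: _G) -> tuple[str, str, str]:
    """Returns feature taps at strides 8 (256ch), 16 (512ch), 32 (1024ch)."""
    x = g.conv(None, 3, 32, k=3, act="mish")
    x = _csp_stage(g, x, 32, 64, 1, first=True)
    x = _csp_stage(g, x, 64, 128, 2, first=False)
    p3 = _csp_stage(g, x, 128, 256, 8, first=False)
    p4 = _csp_stage(g, p3, 256, 512, 8, first=False)
    p5 = _csp_stage(g, p4, 512, 1024, 4, first=False)
    return p3, p4, p5


def _tiny_block(g: _G, x: str, ch: int) -> tuple[str, str]:
    """CSPDarknet53-tiny block; returns (pooled output 2*ch, inner tap ch)."""
    c0 = g.conv(x, ch, ch, k=3)
    s = g.slice_half(c0, ch, "backbone")
    c1 = g.conv(s, ch // 2, ch // 2, k=3)
    c2 = g.conv(c1, ch // 2, ch // 2, k=3)
    cat1 = g.concat([c2, c1], [ch // 2, ch // 2], "backbone")
    c3 = g.conv(cat1, ch, ch, k=1)
    out = g.concat([c0, c3], [ch, ch], "backbone")
    pooled = g.maxpool(out, 2 * ch, k=2, s=2, section="backbone")
    return pooled, c3


def _cspdarknet_tiny(g: _G) -> tuple[str, str]:
    """Returns taps at stride 16 (256ch) and stride 32 (512ch)."""
    x = g.conv(None, 3, 32, k=3, s=2)
    x = g.conv(x, 32, 64, k=3, s=2)
    x, _ = _tiny_block(g, x, 64)
    x, _ = _tiny_block(g, x, 128)
    x, feat1 = _tiny_block(g, x, 256)
    feat2 = g.conv(x, 512, 512, k=3)
    return feat1, feat2


def _make_divisible(v: float, divisor: int = 8) -> int:
    new = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new < 0.9 * v:
        new += divisor
    return new


# (kernel, in, expansion, out, use_se, activation, stride)
_MNV3_LARGE = (
    (3, 16, 16, 16, False, "relu", 1),
    (3, 16, 64, 24, False, "relu", 2),
    (3, 24, 72, 24, False, "relu", 1),
    (5, 24, 72, 40, True, "relu", 2),
    (5, 40, 120, 40, True, "relu", 1),
    (5, 40, 120, 40, True, "relu", 1),
    (3, 40, 240, 80, False, "h_swish", 2),
    (3, 80, 200, 80, False, "h_swish", 1),
    (3, 80, 184, 80, False, "h_swish", 1),
    (3, 80, 184, 80, False, "h_swish", 1),
    (3, 80, 480, 112, True, "h_swish", 1),
    (3, 112, 672, 112, True, "h_swish", 1),
    (5, 112, 672, 160, True, "h_swish", 2),
    (5, 160, 960, 160, True, "h_swish", 1),
    (5, 160, 960, 160, True, "h_swish", 1),
)


def _se_block(g: _G, x: str, ch: int) -> str:
    """Squeeze-excite: global pool, two biased FC layers, hard-sigmoid gate."""
    sq = _make_divisible(ch // 4)
    p = g.add_node(name=g._name("gap"), kind="global_pool", inputs=(x,),
                   in_channels=ch, out_channels=ch, section="backbone")
    d1 = g.add_node(name=g._name("se_fc"), kind="dense", inputs=(p,),
                    in_channels=ch, out_channels=sq, bias=True, section="backbone")
    a1 = g.add_node(name=f"{d1}_relu", kind="activation", inputs=(d1,),
                    in_channels=sq, out_channels=sq, activation_kind="relu",
                    section="backbone")
    d2 = g.add_node(name=g._name("se_fc"), kind="dense", inputs=(a1,),
                    in_channels=sq, out_channels=ch, bias=True, section="backbone")
    a2 = g.add_node(name=f"{d2}_hsig", kind="activation", inputs=(d2,),
                    in_channels=ch, out_channels=ch, activation_kind="h_sigmoid",
                    section="backbone")
    return g.add_node(name=g._name("se_mul"), kind="se_scale", inputs=(x, a2),
                      in_channels=ch, out_channels=ch, section="backbone")


def _mobilenetv3_large(g: _G) -> tuple[str, str, str]:
    """Feature taps at strides 8/16/32 with 40/112/160 channels."""
    x = g.conv(None, 3, 16, k=3, s=2, act="h_swish")
    taps: dict[int, str] = {}
    stride = 2
    for i, (k, cin, exp, cout, se, act, s) in enumerate(_MNV3_LARGE):
        inp = x
        y = inp
        if exp != cin:
            y = g.conv(y, cin, exp, k=1, act=act)
        y = g.conv(y, exp, exp, k=k, s=s, groups=exp, act=act)
        if se:
            y = _se_block(g, y, exp)
        y = g.conv(y, exp, cout, k=1, act="linear")
        if s == 1 and cin == cout:
            y = g.add(y, inp, cout, "backbone")
        stride *= s
        # tap the last block of each stride level
        nxt_s = _MNV3_LARGE[i + 1][6] if i + 1 < len(_MNV3_LARGE) else None
        if stride in (8, 16) and nxt_s == 2:
            taps[stride] = y
        x = y
    taps[32] = x
    return taps[8], taps[16], taps[32]


# ------------------------------------------------------------------- necks

def _three_conv(g: _G, x, cin, mid, out, section):
    x = g.conv(x, cin, out, k=1, section=section)
    x = g.conv(x, out, mid, k=3, section=section)
    return g.conv(x, mid, out, k=1, section=section)


def _five_conv(g: _G, x, cin, mid, out, section):
    x = g.conv(x, cin, out, k=1, section=section)
    x = g.conv(x, out, mid, k=3, section=section)
    x = g.conv(x, mid, out, k=1, section=section)
    x = g.conv(x, out, mid, k=3, section=section)
    return g.conv(x, mid, out, k=1, section=section)


def _spp(g: _G, x: str, ch: int) -> str:
    p5 = g.maxpool(x, ch, k=5, s=1, section="spp")
    p9 = g.maxpool(x, ch, k=9, s=1, section="spp")
    p13 = g.maxpool(x, ch, k=13, s=1, section="spp")
    return g.concat([p13, p9, p5, x], [ch] * 4, "spp")


def _panet_neck(g: _G, p3, p4, p5, f3, f4, f5, head_ch: int):
    """SPP + PANet + 3 heads on taps (p3, p4, p5) with channels (f3, f4, f5)."""
    x = _three_conv(g, p5, f5, 1024, 512, "spp")
    x = _spp(g, x, 512)
    trunk5 = _three_conv(g, x, 2048, 1024, 512, "spp")

    r4 = g.conv(trunk5, 512, 256, k=1, section="panet", role="upsample_reducer")
    u4 = g.upsample(r4, 256, "panet")
    l4 = g.conv(p4, f4, 256, k=1, section="panet", role="lateral")
    cat4 = g.concat([l4, u4], [256, 256], "panet")
    trunk4 = _five_conv(g, cat4, 512, 512, 256, "panet")

    r3 = g.conv(trunk4, 256, 128, k=1, section="panet", role="upsample_reducer")
    u3 = g.upsample(r3, 128, "panet")
    l3 = g.conv(p3, f3, 128, k=1, section="panet", role="lateral")
    cat3 = g.concat([l3, u3], [128, 128], "panet")
    trunk3 = _five_conv(g, cat3, 256, 256, 128, "panet")

    stem3 = g.conv(trunk3, 128, 256, k=3, section="heads", role="head_stem")
    head3 = g.conv(stem3, 256, head_ch, k=1, bn=False, bias=True, act="linear",
                   section="heads", role="predictor", prefix="pred")

    d4 = g.conv(trunk3, 128, 256, k=3, s=2, section="panet", role="downsample")
    cat4b = g.concat([d4, trunk4], [256, 256], "panet")
    trunk4b = _five_conv(g, cat4b, 512, 512, 256, "panet")
    stem4 = g.conv(trunk4b, 256, 512, k=3, section="heads", role="head_stem")
    head4 = g.conv(stem4, 512, head_ch, k=1, bn=False, bias=True, act="linear",
                   section="heads", role="predictor", prefix="pred")

    d5 = g.conv(trunk4b, 256, 512, k=3, s=2, section="panet", role="downsample")
    cat5b = g.concat([d5, trunk5], [512, 512], "panet")
    trunk5b = _five_conv(g, cat5b, 1024, 1024, 512, "panet")
    stem5 = g.conv(trunk5b, 512, 1024, k=3, section="heads", role="head_stem")
    head5 = g.conv(stem5, 1024, head_ch, k=1, bn=False, bias=True, act="linear",
                   section="heads", role="predictor", prefix="pred")

    return head3, head4, head5


def _tiny_neck(g: _G, feat1, feat2, head_ch: int):
    """Stock YOLOv4-tiny neck: FPN-style, two heads."""
    trunk5 = g.conv(feat2, 512, 256, k=1, section="panet")
    stem5 = g.conv(trunk5, 256, 512, k=3, section="heads", role="head_stem")
    head5 = g.conv(stem5, 512, head_ch, k=1, bn=False, bias=True, act="linear",
                   section="heads", role="predictor", prefix="pred")
    r4 = g.conv(trunk5, 256, 128, k=1, section="panet", role="upsample_reducer")
    u4 = g.upsample(r4, 128, "panet")
    cat4 = g.concat([u4, feat1], [128, 256], "panet")
    stem4 = g.conv(cat4, 384, 256, k=3, section="heads", role="head_stem")
    head4 = g.conv(stem4, 256, head_ch, k=1, bn=False, bias=True, act="linear",
                   section="heads", role="predictor", prefix="pred")
    return head4, head5


# ------------------------------------------------------------------ public

def build_architecture(
    variant: str,
    num_classes: int = 2,
    anchors_per_head: int = 3,
    input_size: int = 608,
) -> ArchitectureGraph:
    """Build one of the supported variants as a validated graph."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    head_ch = anchors_per_head * (5 + num_classes)
    g = _G()

    if variant in ("yolov4", "yolov4_dw"):
        p3, p4, p5 = _cspdarknet53(g)
        heads = _panet_neck(g, p3, p4, p5, 256, 512, 1024, head_ch)
    elif variant == "improved":
        p3, p4, p5 = _mobilenetv3_large(g)
        heads = _panet_neck(g, p3, p4, p5, 40, 112, 160, head_ch)
    else:  # tiny family
        feat1, feat2 = _cspdarknet_tiny(g)
        heads = _tiny_neck(g, feat1, feat2, head_ch)

    graph = ArchitectureGraph(
        nodes=g.nodes,
        variant=variant,
        num_classes=num_classes,
        anchors_per_head=anchors_per_head,
        input_size=input_size,
        head_names=tuple(heads),
    )
    if variant == "yolov4_dw":
        graph = dw_separable_transform(
            graph, scope={"spp", "panet", "heads"}, upsample_reducers=True
        )
        graph.variant = "yolov4_dw"
    elif variant == "yolov4_tiny_dw":
        graph = dw_separable_transform(
            graph, scope={"spp", "panet", "heads"}, upsample_reducers=True
        )
        graph.variant = "yolov4_tiny_dw"
    elif variant == "improved":
        graph = dw_separable_transform(
            graph, scope={"spp", "panet", "heads"}, upsample_reducers=False
        )
        graph.variant = "improved"
    return graph
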