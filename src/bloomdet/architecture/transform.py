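"""Depthwise-separable rewrite pass.

Replaces every ordinary 3x3 convolution inside the requested sections with a
depthwise 3x3 + BN + activation followed by a pointwise 1x1 + BN + activation
pair.  Head predictors are never rewritten; the backbone is out of scope by
construction.  Optionally the 1x1 channel reducers feeding the top-down
upsample path are rewritten to depthwise-separable 3x3 blocks as well — the
convention of common lightweight ports of this architecture family.

The pass is idempotent: depthwise convs (groups == channels) and the
pointwise convs it creates are never split again.
"""

from __future__ import annotations

from dataclasses import replace

from .graph import ArchitectureGraph, LayerNode


def _activation_after(nodes: list[LayerNode], name: str) -> str:
    """Activation kind applied (possibly via BN) to the node called ``name``."""
    following = {n.inputs[0]: n for n in nodes if len(n.inputs) == 1}
    cur = name
    for _ in range(2):  # at most conv -> bn -> act
        nxt = following.get(cur)
        if nxt is None:
            return "linear"
        if nxt.kind == "activation":
            return nxt.activation_kind
        if nxt.kind == "batchnorm":
            cur = nxt.name
            continue
        return "linear"
    return "linear"


def dw_separable_transform(
    graph: ArchitectureGraph,
    scope: set[str] = frozenset({"spp", "panet", "heads"}),
    upsample_reducers: bool = True,
) -> ArchitectureGraph:
    """Return a new graph with the depthwise-separable rewrite applied."""
    bad = set(scope) - {"spp", "panet", "heads"}
    if bad:
        raise ValueError(f"scope may only contain spp/panet/heads, got {bad}")
    if not scope:
        return graph.with_nodes(list(graph.nodes))

    out: list[LayerNode] = []
    for node in graph.nodes:
        is_target_3x3 = (
            node.kind == "conv"
            and node.kernel == 3
            and node.groups == 1
            and node.section in scope
            and node.role != "predictor"
            and not node.role.endswith("_dw")
        )
        is_target_reducer = (
            upsample_reducers
            and node.kind == "conv"
            and node.kernel == 1
            and node.groups == 1
            and node.section in scope
            and node.role == "upsample_reducer"
        )
        if not (is_target_3x3 or is_target_reducer):
            out.append(node)
            continue

        act = _activation_after(graph.nodes, node.name)
        di, do = node.in_channels, node.out_channels
        dw_name = f"{node.name}_dw"
        out.append(
            LayerNode(
                name=dw_name, kind="conv", inputs=node.inputs,
                in_channels=di, out_channels=di, kernel=3, stride=node.stride,
                groups=di, bias=False, section=node.section,
                role=f"{node.role}_dwpart" if node.role else "dwpart",
            )
        )
        out.append(
            LayerNode(
                name=f"{dw_name}_bn", kind="batchnorm", inputs=(dw_name,),
                in_channels=di, out_channels=di, section=node.section,
            )
        )
        prev = f"{dw_name}_bn"
        if act != "linear":
            out.append(
                LayerNode(
                    name=f"{dw_name}_act", kind="activation", inputs=(prev,),
                    in_channels=di, out_channels=di, activation_kind=act,
                    section=node.section,
                )
            )
            prev = f"{dw_name}_act"
        # pointwise conv keeps the original node name so consumers stay wired
        out.append(
            replace(
                node,
                inputs=(prev,),
                kernel=1,
                stride=1,
                role=f"{node.role}_dw" if node.role else "pointwise_dw",
            )
        )
    result = graph.with_nodes(out)
    return result
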