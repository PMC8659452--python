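"""Analytic parameter and multiply-add accounting for architecture graphs.

Conventions (trainable parameters only):

* convolution: ``Hk*Wk*(Di/groups)*Do`` weights, plus ``Do`` if biased —
  a depthwise conv (groups = Di = Do) therefore costs ``Hk*Wk*Di``;
* batch norm: 2 trainable values per channel (scale and shift; running
  statistics are buffers, not parameters);
* dense: ``Di*Do + Do`` (always biased);
* pooling, activations, upsampling, concat, add, slice, SE gating: 0.

Multiply-add counts use the standard closed forms
``Ho*Wo*(Di/groups)*Do*Hk*Wk`` for a convolution, so a depthwise 3x3 plus
pointwise pair costs ``Ho*Wo*Di*9 + Ho*Wo*Di*Do`` and its ratio to the
ordinary conv tends to ``1/Do + 1/(Hk*Wk)`` for large feature maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import ArchitectureGraph, LayerNode, SECTIONS


def node_param_count(node: LayerNode) -> int:
    """Exact trainable-parameter count of one node."""
    if node.kind == "conv":
        p = node.kernel * node.kernel * (node.in_channels // node.groups) * node.out_channels
        if node.bias:
            p += node.out_channels
        return p
    if node.kind == "batchnorm":
        return 2 * node.out_channels
    if node.kind == "dense":
        return node.in_channels * node.out_channels + node.out_channels
    if node.kind in (
        "activation", "maxpool", "upsample", "concat", "add", "slice",
        "global_pool", "se_scale",
    ):
        return 0
    raise ValueError(f"unknown node kind {node.kind!r}")


@dataclass
class ParamReport:
    """Total and per-section parameter ledger of a graph."""

    total: int
    by_section: dict[str, int]
    per_node: list[tuple[str, str, int]] = field(default_factory=list)  # (name, section, count)

    @property
    def weight_bytes_fp32(self) -> int:
        return 4 * self.total

    @property
    def weight_mib_fp32(self) -> float:
        return self.weight_bytes_fp32 / 2**20

    def as_tsv(self) -> str:
        lines = ["node\tsection\tparams"]
        lines += [f"{n}\t{s}\t{c}" for n, s, c in self.per_node]
        for s in SECTIONS:
            if s in self.by_section:
                lines.append(f"[section {s}]\t\t{self.by_section[s]}")
        lines.append(f"[total]\t\t{self.total}")
        return "\n".join(lines)


def count_parameters(graph: ArchitectureGraph) -> ParamReport:
    """Sum :func:`node_param_count` over the graph with a per-node ledger."""
    per_node = []
    by_section = {s: 0 for s in SECTIONS}
    total = 0
    for n in graph.nodes:
        c = node_param_count(n)
        per_node.append((n.name, n.section, c))
        by_section[n.section] += c
        total += c
    by_section = {s: v for s, v in by_section.items() if v}
    return ParamReport(total=total, by_section=by_section, per_node=per_node)


def _spatial_sizes(graph: ArchitectureGraph) -> dict[str, int | None]:
    """Per-node feature-map side length via symbolic stride propagation."""
    size: dict[str, int | None] = {}
    for n in graph.nodes:
        if not n.inputs:
            base = graph.input_size
        else:
            base = size[n.inputs[0]]
        if n.kind in ("conv", "maxpool"):
            size[n.name] = None if base is None else (base + n.stride - 1) // n.stride
        elif n.kind == "upsample":
            size[n.name] = None if base is None else base * 2
        elif n.kind in ("global_pool", "dense"):
            size[n.name] = None  # spatially collapsed
        elif n.kind == "se_scale":
            size[n.name] = size[n.inputs[0]]
        else:
            size[n.name] = base
    return size


def flops_estimate(graph: ArchitectureGraph) -> int:
    """Total multiply-add count at the graph's input size."""
    if graph.input_size <= 0:
        raise ValueError("graph input_size must be set for a FLOP estimate")
    sizes = _spatial_sizes(graph)
    total = 0
    for n in graph.nodes:
        if n.kind == "conv":
            side = sizes[n.name]
            if side is None:
                continue
            total += side * side * (n.in_channels // n.groups) * n.out_channels \
                * n.kernel * n.kernel
        elif n.kind == "dense":
            total += n.in_channels * n.out_channels
    return total


def head_shapes(graph: ArchitectureGraph) -> list[tuple[int, int, int]]:
    """(S, S, C) tensor shape of every detection head at the input size."""
    sizes = _spatial_sizes(graph)
    ch = graph.channels()
    return [(sizes[h], sizes[h], ch[h]) for h in graph.head_names]
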