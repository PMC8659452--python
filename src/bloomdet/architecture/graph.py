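"""Declarative layer graphs.

An :class:`ArchitectureGraph` is an ordered list of :class:`LayerNode`
entries forming a DAG.  The graph alone fully determines the trainable
parameter count of the network and suffices to instantiate a runtime model;
no tensor library is required to build or analyse one.

Node kinds
----------
``conv``         spatial convolution (covers depthwise via ``groups``)
``batchnorm``    per-channel scale and shift (2 trainable values/channel)
``activation``   parameter-free nonlinearity
``maxpool``      max pooling (stride 2 downsampling or SPP stride-1 pools)
``upsample``     nearest-neighbour x2
``concat``       channel concatenation
``add``          elementwise residual addition
``slice``        channel-group split (takes one of ``groups`` channel groups)
``global_pool``  global average pooling to 1x1
``dense``        fully connected layer (used inside squeeze-excite blocks)
``se_scale``     channel-wise multiply of a trunk by SE gate output
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

KINDS = (
    "conv", "batchnorm", "activation", "maxpool", "upsample", "concat",
    "add", "slice", "global_pool", "dense", "se_scale",
)

ACTIVATIONS = ("leaky_relu", "mish", "h_swish", "relu", "relu6", "h_sigmoid", "sigmoid", "linear")

SECTIONS = ("backbone", "spp", "panet", "heads")


@dataclass(frozen=True)
class LayerNode:
    """One layer of an architecture graph."""

    name: str
    kind: str
    inputs: tuple[str, ...] = ()
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 1
    stride: int = 1
    groups: int = 1
    bias: bool = False
    activation_kind: str = "linear"
    section: str = "backbone"
    role: str = ""  # semantic tag: "predictor", "upsample_reducer", "head_stem", ...
    group_id: int = 0  # for slice: which channel group to keep

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == "activation" and self.activation_kind not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation_kind!r}")
        if self.section not in SECTIONS:
            raise ValueError(f"unknown section {self.section!r}")
        if self.kind == "conv":
            if self.in_channels % self.groups or self.out_channels % self.groups:
                raise ValueError(
                    f"{self.name}: groups={self.groups} must divide channels "
                    f"{self.in_channels}->{self.out_channels}"
                )

    @property
    def is_depthwise(self) -> bool:
        return (
            self.kind == "conv"
            and self.groups > 1
            and self.groups == self.in_channels == self.out_channels
        )


@dataclass
class ArchitectureGraph:
    """Ordered DAG of layer nodes plus detector-level configuration."""

    nodes: list[LayerNode]
    variant: str
    num_classes: int
    anchors_per_head: int = 3
    input_size: int = 608
    head_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.validate()

    def node(self, name: str) -> LayerNode:
        return self._by_name[name]

    @property
    def _by_name(self) -> dict[str, LayerNode]:
        return {n.name: n for n in self.nodes}

    def validate(self) -> None:
        """Check DAG ordering, channel consistency and spatial consistency."""
        seen: dict[str, LayerNode] = {}
        for n in self.nodes:
            if n.name in seen:
                raise ValueError(f"duplicate node name {n.name!r}")
            for src in n.inputs:
                if src not in seen:
                    raise ValueError(
                        f"{n.name}: input {src!r} not defined earlier (graph must be "
                        "topologically ordered)"
                    )
            seen[n.name] = n
        # channel consistency
        ch = self._infer_channels()
        for n in self.nodes:
            if n.kind in ("conv", "dense") and n.inputs:
                got = ch[n.inputs[0]]
                if got != n.in_channels:
                    raise ValueError(
                        f"{n.name}: declared in_channels={n.in_channels} but input "
                        f"{n.inputs[0]!r} provides {got}"
                    )
        # spatial consistency (symbolic stride products)
        scale = self._infer_scales()
        for n in self.nodes:
            if n.kind in ("concat", "add", "se_scale") and len(n.inputs) > 1:
                scales = {scale[s] for s in n.inputs if scale[s] is not None}
                if len(scales) > 1:
                    raise ValueError(f"{n.name}: inputs at different strides {scales}")
        for h in self.head_names:
            if h not in seen:
                raise ValueError(f"head {h!r} not in graph")

    def _infer_channels(self) -> dict[str, int]:
        ch: dict[str, int] = {}
        for n in self.nodes:
            if n.kind in ("conv", "dense"):
                ch[n.name] = n.out_channels
            elif n.kind == "concat":
                ch[n.name] = sum(ch[s] for s in n.inputs)
            elif n.kind == "slice":
                ch[n.name] = ch[n.inputs[0]] // n.groups
            elif n.kind in ("add", "se_scale"):
                ch[n.name] = ch[n.inputs[0]]
            elif n.inputs:
                ch[n.name] = ch[n.inputs[0]]
            else:  # graph input
                ch[n.name] = n.out_channels
        return ch

    def channels(self) -> dict[str, int]:
        return self._infer_channels()

    def _infer_scales(self) -> dict[str, Optional[int]]:
        """Downsampling factor of each node relative to the input image.

        ``global_pool`` and SE gate nodes map to None (spatial dims collapsed).
        """
        sc: dict[str, Optional[int]] = {}
        for n in self.nodes:
            if not n.inputs:
                sc[n.name] = 1
                continue
            base = sc[n.inputs[0]]
            if n.kind == "global_pool":
                sc[n.name] = None
            elif n.kind in ("dense",):
                sc[n.name] = None
            elif n.kind == "se_scale":
                sc[n.name] = sc[n.inputs[0]]  # trunk input first
            elif n.kind == "upsample":
                sc[n.name] = None if base is None else base // 2
            elif n.kind in ("conv", "maxpool"):
                sc[n.name] = None if base is None else base * n.stride
            else:
                sc[n.name] = base
        return sc

    def scales(self) -> dict[str, Optional[int]]:
        return self._infer_scales()

    def head_channels(self) -> int:
        """Output channels every head predictor must carry."""
        return self.anchors_per_head * (5 + self.num_classes)

    def with_nodes(self, nodes: Iterable[LayerNode]) -> "ArchitectureGraph":
        return ArchitectureGraph(
            nodes=list(nodes),
            variant=self.variant,
            num_classes=self.num_classes,
            anchors_per_head=self.anchors_per_head,
            input_size=self.input_size,
            head_names=self.head_names,
        )

    def to_json_dict(self) -> dict:
        """JSON-interchange representation of the graph."""
        from dataclasses import asdict

        return {
            "variant": self.variant,
            "num_classes": self.num_classes,
            "anchors_per_head": self.anchors_per_head,
            "input_size": self.input_size,
            "head_names": list(self.head_names),
            "nodes": [asdict(n) for n in self.nodes],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ArchitectureGraph":
        nodes = [LayerNode(**{**nd, "inputs": tuple(nd["inputs"])}) for nd in d["nodes"]]
        return cls(
            nodes=nodes,
            variant=d["variant"],
            num_classes=d["num_classes"],
            anchors_per_head=d["anchors_per_head"],
            input_size=d["input_size"],
            head_names=tuple(d["head_names"]),
        )
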