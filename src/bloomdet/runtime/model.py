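"""Executable models instantiated from architecture graphs.

A :class:`RuntimeModel` allocates one parameter array set per graph node and
executes the DAG with the NumPy ops in :mod:`bloomdet.runtime.ops`.  Its
trainable-parameter total equals the analytic ledger of
:func:`bloomdet.architecture.count_parameters` exactly — the central
cross-check between the declarative graphs and the executable network.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..architecture.graph import ArchitectureGraph, LayerNode
from . import ops


class RuntimeModel:
    """NumPy execution of an architecture graph (forward and backward)."""

    def __init__(self, graph: ArchitectureGraph, seed: int = 0):
        self.graph = graph
        self.params: dict[str, dict[str, np.ndarray]] = {}
        self.buffers: dict[str, list[np.ndarray]] = {}
        rng = np.random.default_rng(seed)
        for node in graph.nodes:
            self._init_node(node, rng)
        self._cache: dict[str, tuple] = {}
        self._acts: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------- setup

    def _init_node(self, node: LayerNode, rng: np.random.Generator) -> None:
        if node.kind == "conv":
            cin_g = node.in_channels // node.groups
            fan_in = node.kernel * node.kernel * cin_g
            std = np.sqrt(2.0 / fan_in)
            if node.is_depthwise:
                w = rng.normal(0, std, (node.in_channels, node.kernel, node.kernel)).astype(np.float32)
            else:
                if node.groups != 1:
                    raise NotImplementedError("only groups in {1, C} are supported")
                w = rng.normal(0, std, (node.out_channels, node.in_channels,
                                        node.kernel, node.kernel)).astype(np.float32)
            p = {"w": w}
            if node.bias:
                b = np.zeros(node.out_channels, dtype=np.float32)
                if node.role == "predictor":
                    # start objectness rare so early training suppresses the
                    # overwhelming negative cells quickly
                    a = self.graph.anchors_per_head
                    per = node.out_channels // a
                    for i in range(a):
                        b[i * per + 4] = -4.0
                p["b"] = b
            self.params[node.name] = p
        elif node.kind == "batchnorm":
            self.params[node.name] = {
                "gamma": np.ones(node.out_channels, dtype=np.float32),
                "beta": np.zeros(node.out_channels, dtype=np.float32),
            }
            self.buffers[node.name] = [
                np.zeros(node.out_channels, dtype=np.float32),
                np.ones(node.out_channels, dtype=np.float32),
            ]
        elif node.kind == "dense":
            std = np.sqrt(2.0 / node.in_channels)
            self.params[node.name] = {
                "w": rng.normal(0, std, (node.out_channels, node.in_channels)).astype(np.float32),
                "b": np.zeros(node.out_channels, dtype=np.float32),
            }

    def parameter_count(self) -> int:
        return sum(int(a.size) for p in self.params.values() for a in p.values())

    def parameter_count_by_section(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for node in self.graph.nodes:
            if node.name in self.params:
                n = sum(int(a.size) for a in self.params[node.name].values())
                out[node.section] = out.get(node.section, 0) + n
        return out

    # ----------------------------------------------------------- forward

    def forward(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        """Run the graph on an NCHW batch; returns the head tensors.

        Head tensors are returned as (N, S, S, C) for decoding convenience.
        """
        acts: dict[str, np.ndarray] = {}
        cache: dict[str, tuple] = {}
        for node in self.graph.nodes:
            inp = acts[node.inputs[0]] if node.inputs else x
            if node.kind == "conv":
                p = self.params[node.name]
                b = p.get("b")
                if node.is_depthwise:
                    out, c = ops.depthwise_forward(inp, p["w"], b, node.stride)
                else:
                    out, c = ops.conv2d_forward(inp, p["w"], b, node.stride)
                cache[node.name] = c
            elif node.kind == "batchnorm":
                p = self.params[node.name]
                out, c = ops.batchnorm_forward(
                    inp, p["gamma"], p["beta"], self.buffers[node.name], train=train
                )
                cache[node.name] = c
            elif node.kind == "activation":
                out, c = ops.activation_forward(inp, node.activation_kind)
                cache[node.name] = c
            elif node.kind == "maxpool":
                out, c = ops.maxpool_forward(inp, node.kernel, node.stride)
                cache[node.name] = c
            elif node.kind == "upsample":
                out, c = ops.upsample_forward(inp)
                cache[node.name] = c
            elif node.kind == "concat":
                parts = [acts[s] for s in node.inputs]
                out = np.concatenate(parts, axis=1)
                cache[node.name] = tuple(p.shape[1] for p in parts)
            elif node.kind == "add":
                out = acts[node.inputs[0]] + acts[node.inputs[1]]
            elif node.kind == "slice":
                csize = inp.shape[1] // node.groups
                start = node.group_id * csize
                out = inp[:, start:start + csize]
                cache[node.name] = (inp.shape[1], start, csize)
            elif node.kind == "global_pool":
                out, c = ops.global_pool_forward(inp)
                cache[node.name] = c
            elif node.kind == "dense":
                p = self.params[node.name]
                out, c = ops.dense_forward(inp, p["w"], p["b"])
                cache[node.name] = c
            elif node.kind == "se_scale":
                trunk = acts[node.inputs[0]]
                gate = acts[node.inputs[1]]
                out, c = ops.se_scale_forward(trunk, gate)
                cache[node.name] = c
            else:  # pragma: no cover
                raise ValueError(node.kind)
            acts[node.name] = out
        self._acts, self._cache = acts, cache
        return [acts[h].transpose(0, 2, 3, 1) for h in self.graph.head_names]

    # ---------------------------------------------------------- backward

    def backward(self, head_grads: Sequence[np.ndarray]) -> dict[str, dict[str, np.ndarray]]:
        """Backpropagate gradients given per-head (N, S, S, C) tensors.

        Returns parameter gradients keyed like :attr:`params`.
        """
        grads: dict[str, np.ndarray] = {}
        pgrads: dict[str, dict[str, np.ndarray]] = {}
        for h, g in zip(self.graph.head_names, head_grads):
            grads[h] = g.transpose(0, 3, 1, 2)

        for node in reversed(self.graph.nodes):
            dy = grads.pop(node.name, None)
            if dy is None:
                continue
            if node.kind == "conv":
                p = self.params[node.name]
                if node.is_depthwise:
                    dx, dw, db = ops.depthwise_backward(
                        dy, p["w"], self._cache[node.name], node.bias
                    )
                else:
                    dx, dw, db = ops.conv2d_backward(
                        dy, p["w"], self._cache[node.name], node.bias
                    )
                pg = {"w": dw}
                if db is not None:
                    pg["b"] = db
                pgrads[node.name] = pg
            elif node.kind == "batchnorm":
                dx, dgamma, dbeta = ops.batchnorm_backward(dy, self._cache[node.name])
                pgrads[node.name] = {"gamma": dgamma, "beta": dbeta}
            elif node.kind == "activation":
                dx = ops.activation_backward(dy, self._cache[node.name],
                                             node.activation_kind)
            elif node.kind == "maxpool":
                dx = ops.maxpool_backward(dy, self._cache[node.name])
            elif node.kind == "upsample":
                dx = ops.upsample_backward(dy, self._cache[node.name])
            elif node.kind == "concat":
                sizes = self._cache[node.name]
                ofs = 0
                for src, cs in zip(node.inputs, sizes):
                    part = dy[:, ofs:ofs + cs]
                    _accumulate(grads, src, part)
                    ofs += cs
                continue
            elif node.kind == "add":
                _accumulate(grads, node.inputs[0], dy)
                _accumulate(grads, node.inputs[1], dy)
                continue
            elif node.kind == "slice":
                total, start, csize = self._cache[node.name]
                dx = np.zeros((dy.shape[0], total) + dy.shape[2:])
                dx[:, start:start + csize] = dy
            elif node.kind == "global_pool":
                dx = ops.global_pool_backward(dy, self._cache[node.name])
            elif node.kind == "dense":
                p = self.params[node.name]
                dx, dw, db = ops.dense_backward(dy, p["w"], self._cache[node.name])
                pgrads[node.name] = {"w": dw, "b": db}
            elif node.kind == "se_scale":
                dx, dgate = ops.se_scale_backward(dy, self._cache[node.name])
                _accumulate(grads, node.inputs[0], dx)
                _accumulate(grads, node.inputs[1], dgate)
                continue
            else:  # pragma: no cover
                raise ValueError(node.kind)
            if node.inputs:
                _accumulate(grads, node.inputs[0], dx)
        return pgrads

    # ------------------------------------------------------------- misc

    def predict(self, x: np.ndarray) -> list[np.ndarray]:
        """Inference forward pass (eval-mode batch norm)."""
        return self.forward(x, train=False)

    def state_dict(self) -> dict:
        return {
            "params": {k: {n: a.copy() for n, a in p.items()}
                       for k, p in self.params.items()},
            "buffers": {k: [a.copy() for a in v] for k, v in self.buffers.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        for k, p in state["params"].items():
            for n, a in p.items():
                self.params[k][n][:] = a
        for k, v in state["buffers"].items():
            for dst, src in zip(self.buffers[k], v):
                dst[:] = src


def _accumulate(grads: dict[str, np.ndarray], key: str, value: np.ndarray) -> None:
    if key in grads:
        grads[key] = grads[key] + value
    else:
        grads[key] = value


def build_runtime_model(graph: ArchitectureGraph, seed: int = 0) -> RuntimeModel:
    """Instantiate a trainable NumPy network from a graph."""
    return RuntimeModel(graph, seed=seed)
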