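"""Minimal directed-acyclic layer graph with reverse-mode differentiation.

Tensors are single samples in channel-first layout ``(C, H, W)`` (the
training regime here uses mini-batches of one image, so no batch axis is
carried).  Layers are applied functionally to :class:`Node` objects, Keras
style::

    x = Input(3)
    y = Conv2D(8, 3)(x)
    model = Model(x, y)

Only channel counts are tracked symbolically; spatial sizes are resolved at
forward time, which keeps parameter shapes independent of image size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Param", "Node", "Layer", "Input", "Model"]


@dataclass
class Param:
    """A weight array with a trainability flag and a gradient slot."""

    name: str
    value: np.ndarray
    trainable: bool = True
    grad: np.ndarray | None = None

    @property
    def size(self) -> int:
        return int(self.value.size)


class Node:
    """Symbolic tensor: output of ``layer`` applied to ``parents``."""

    _counter = 0

    def __init__(self, layer: "Layer | None", parents: list["Node"], channels: int,
                 name: str | None = None):
        self.layer = layer
        self.parents = parents
        self.channels = int(channels)
        Node._counter += 1
        self.name = name or (layer.name if layer is not None else f"node_{Node._counter}")


class Layer:
    """Base class.  Subclasses implement :meth:`build`, :meth:`forward` and
    optionally :meth:`backward`."""

    _counts: dict[str, int] = {}

    def __init__(self, name: str | None = None):
        if name is None:
            key = type(self).__name__.lower()
            Layer._counts[key] = Layer._counts.get(key, 0) + 1
            name = f"{key}_{Layer._counts[key]}"
        self.name = name
        self.params: list[Param] = []
        self.built = False

    # -- graph construction -------------------------------------------------
    def __call__(self, inputs: "Node | list[Node]") -> Node:
        nodes = inputs if isinstance(inputs, list) else [inputs]
        if not self.built:
            self.build([n.channels for n in nodes])
            self.built = True
        return Node(self, nodes, self.out_channels([n.channels for n in nodes]))

    def build(self, in_channels: list[int]) -> None:  # pragma: no cover - default
        pass

    def out_channels(self, in_channels: list[int]) -> int:
        return in_channels[0]

    # -- execution ----------------------------------------------------------
    def forward(self, xs: list[np.ndarray], training: bool, cache: dict) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, cache: dict) -> list[np.ndarray]:
        raise NotImplementedError(f"{type(self).__name__} has no backward pass")

    def add_param(self, name: str, value: np.ndarray, trainable: bool = True) -> Param:
        p = Param(f"{self.name}/{name}", np.ascontiguousarray(value, dtype=np.float32),
                  trainable)
        self.params.append(p)
        return p


class _InputLayer(Layer):
    def forward(self, xs, training, cache):  # pragma: no cover - never called
        raise RuntimeError("Input layer is fed directly")


def Input(channels: int, name: str = "input") -> Node:
    return Node(None, [], channels, name=name)


class Model:
    """Executable DAG from one input node to one output node."""

    def __init__(self, inputs: Node, outputs: Node):
        self.input = inputs
        self.output = outputs
        self.order = self._toposort(outputs)

    def _toposort(self, out: Node) -> list[Node]:
        order: list[Node] = []
        seen: set[int] = set()
        stack: list[tuple[Node, bool]] = [(out, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        return order

    # -- parameters ---------------------------------------------------------
    def layers(self) -> list[Layer]:
        out, seen = [], set()
        for node in self.order:
            if node.layer is not None and id(node.layer) not in seen:
                seen.add(id(node.layer))
                out.append(node.layer)
        return out

    def parameters(self, trainable_only: bool = False) -> list[Param]:
        ps = [p for layer in self.layers() for p in layer.params]
        if trainable_only:
            ps = [p for p in ps if p.trainable]
        return ps

    def count_params(self) -> tuple[int, int, int]:
        """Return ``(trainable, non_trainable, total)`` parameter counts."""
        tr = sum(p.size for p in self.parameters() if p.trainable)
        nt = sum(p.size for p in self.parameters() if not p.trainable)
        return tr, nt, tr + nt

    def get_node(self, name: str) -> Node:
        for node in self.order:
            if node.name == name:
                return node
        raise KeyError(f"no layer/node named {name!r}")

    # -- execution ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                record: bool = False) -> np.ndarray | tuple[np.ndarray, dict]:
        """Run the graph on a ``(C, H, W)`` float array."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[0] != self.input.channels:
            raise ValueError(
                f"expected input of shape ({self.input.channels}, H, W), got {x.shape}")
        values: dict[int, np.ndarray] = {id(self.input): x}
        caches: dict[int, dict] = {}
        for node in self.order:
            if node.layer is None:
                continue
            xs = [values[id(p)] for p in node.parents]
            cache: dict = {}
            values[id(node)] = node.layer.forward(xs, training, cache)
            caches[id(node)] = cache
        out = values[id(self.output)]
        if record:
            return out, {"values": values, "caches": caches}
        return out

    def backward(self, grad_out: np.ndarray, ctx: dict,
                 capture: Node | None = None) -> dict:
        """Back-propagate ``dL/d(output)``; accumulates ``Param.grad``.

        Returns a dict with the gradient w.r.t. the model input and, if
        ``capture`` is given, w.r.t. that node's output.
        """
        grads: dict[int, np.ndarray] = {id(self.output): np.asarray(grad_out, np.float32)}
        captured = None
        for node in reversed(self.order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if capture is not None and id(node) == id(capture):
                captured = g.copy()
            if node.layer is None:
                grads[id(node)] = g  # input node: keep
                continue
            parent_grads = node.layer.backward(g, ctx["caches"][id(node)])
            for parent, pg in zip(node.parents, parent_grads):
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        return {"input": grads.get(id(self.input)), "captured": captured}

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in state dict")
            arr = np.asarray(state[p.name], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name!r}")
            p.value = arr.copy()
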