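"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine covering exactly the operation set the potential
needs: elementwise arithmetic and transcendentals, ``matmul``/``einsum``,
reductions, axis-0 gather/segment-sum (the graph message primitives),
concatenation and slicing.  Every backward rule is itself written in terms
of these primitives, so calling :func:`grad` with ``create_graph=True``
yields gradients that are themselves differentiable.  That property is what
makes force training possible: forces are gradients of the energy with
respect to positions, and the training loss needs gradients of those forces
with respect to the model parameters.

Two performance choices shape the implementation: einsum contraction paths
are cached by (subscripts, shapes), and every backward rule receives a
``needed`` mask so gradients that no requested input depends on are never
computed (during a force evaluation no parameter gradients are formed;
during the parameter backward of the training loss no position gradients
are).

Tensors wrap ``numpy`` arrays of whatever dtype the caller supplies; the
engine itself is precision-agnostic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "no_grad", "is_grad_enabled", "grad",
    "add", "sub", "mul", "div", "neg", "power", "exp", "log", "sin", "cos",
    "sqrt", "sigmoid", "silu", "einsum", "matmul", "rowmm", "swap_last", "tsum",
    "reshape", "broadcast_to", "gather", "segment_sum", "concat", "getslice",
    "where",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph recording."""

    def __enter__(self):
        self.prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self.prev
        return False


class _set_grad:
    def __init__(self, mode: bool):
        self.mode = mode

    def __enter__(self):
        self.prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = self.mode

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self.prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[0]


class Tensor:
    __slots__ = ("data", "requires_grad", "parents", "backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.parents: tuple = ()
        self.backward_fn = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return getslice(self, key)


def astensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None:
        arr = arr.astype(dtype, copy=False)
    return Tensor(arr)


def _node(data, parents, bw_builder) -> Tensor:
    """Create a result tensor; record the backward rule only when needed."""
    out = Tensor(data)
    if _GRAD_ENABLED[0]:
        for p in parents:
            if p.requires_grad:
                out.requires_grad = True
                out.parents = tuple(parents)
                out.backward_fn = bw_builder
                break
    return out


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.data.shape == tuple(shape):
        return g
    gshape = g.data.shape
    ndiff = len(gshape) - len(shape)
    axes = list(range(ndiff))
    for i, s in enumerate(shape):
        if s == 1 and gshape[ndiff + i] != 1:
            axes.append(ndiff + i)
    if axes:
        g = tsum(g, axis=tuple(axes), keepdims=False)
    if g.data.shape != tuple(shape):
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------- arithmetic

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def bw(g, needed):
        return (_unbroadcast(g, a.shape) if needed[0] else None,
                _unbroadcast(g, b.shape) if needed[1] else None)

    return _node(a.data + b.data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def bw(g, needed):
        return (_unbroadcast(g, a.shape) if needed[0] else None,
                _unbroadcast(neg(g), b.shape) if needed[1] else None)

    return _node(a.data - b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def bw(g, needed):
        return (_unbroadcast(mul(g, b), a.shape) if needed[0] else None,
                _unbroadcast(mul(g, a), b.shape) if needed[1] else None)

    return _node(a.data * b.data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def bw(g, needed):
        ga = div(g, b) if (needed[0] or needed[1]) else None
        gb = neg(mul(ga, div(a, b))) if needed[1] else None
        return (_unbroadcast(ga, a.shape) if needed[0] else None,
                _unbroadcast(gb, b.shape) if needed[1] else None)

    return _node(a.data / b.data, (a, b), bw)


def neg(a) -> Tensor:
    a = astensor(a)

    def bw(g, needed):
        return (neg(g),)

    return _node(-a.data, (a,), bw)


def power(a, p: float) -> Tensor:
    """Elementwise a**p for a constant exponent."""
    a = astensor(a)
    p = float(p)

    def bw(g, needed):
        return (mul(g, mul(power(a, p - 1.0), p)),)

    return _node(a.data ** p, (a,), bw)


def exp(a) -> Tensor:
    a = astensor(a)
    out_ref = []  # filled after node creation so bw sees the graph node

    def bw(g, needed):
        return (mul(g, out_ref[0]),)

    out = _node(np.exp(a.data), (a,), bw)
    out_ref.append(out)
    return out


def log(a) -> Tensor:
    a = astensor(a)

    def bw(g, needed):
        return (div(g, a),)

    return _node(np.log(a.data), (a,), bw)


def sin(a) -> Tensor:
    a = astensor(a)

    def bw(g, needed):
        return (mul(g, cos(a)),)

    return _node(np.sin(a.data), (a,), bw)


def cos(a) -> Tensor:
    a = astensor(a)

    def bw(g, needed):
        return (neg(mul(g, sin(a))),)

    return _node(np.cos(a.data), (a,), bw)


def sqrt(a) -> Tensor:
    a = astensor(a)

    def bw(g, needed):
        return (mul(g, mul(power(a, -0.5), 0.5)),)

    return _node(np.sqrt(a.data), (a,), bw)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    return div(1.0, add(1.0, exp(neg(a))))


def silu(a) -> Tensor:
    """x * sigmoid(x), the smooth gated activation of the radial network."""
    a = astensor(a)
    return mul(a, sigmoid(a))


# ---------------------------------------------------------------- structural

def reshape(a, shape) -> Tensor:
    a = astensor(a)
    old = a.data.shape

    def bw(g, needed):
        return (reshape(g, old),)

    return _node(a.data.reshape(shape), (a,), bw)


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    old = a.data.shape

    def bw(g, needed):
        return (_unbroadcast(g, old),)

    return _node(np.broadcast_to(a.data, shape), (a,), bw)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    """Sum reduction (named to avoid clobbering builtin ``sum``)."""
    a = astensor(a)
    in_shape = a.data.shape

    def bw(g, needed):
        if axis is None:
            return (broadcast_to(reshape(g, (1,) * len(in_shape)), in_shape),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % len(in_shape) for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(in_shape))
            gk = reshape(g, kshape)
        else:
            gk = g
        return (broadcast_to(gk, in_shape),)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


_EINSUM_PATHS: dict = {}


def einsum(subscripts: str, *operands) -> Tensor:
    """Differentiable einsum.

    Every index of a tensor operand must also appear in the output or in
    another operand (no implicit marginalisation), no repeated indices within
    a single operand, no ellipsis — sufficient for the contractions the model
    performs and keeps the backward rule a plain einsum.
    """
    if "..." in subscripts:
        raise ValueError("ellipsis not supported")
    lhs, out_sub = subscripts.replace(" ", "").split("->")
    in_subs = lhs.split(",")
    if len(in_subs) != len(operands):
        raise ValueError("operand count mismatch")
    ops = [astensor(o) for o in operands]
    for s in in_subs:
        if len(set(s)) != len(s):
            raise ValueError("repeated index within one operand not supported")
    arrays = [o.data for o in ops]
    key = (subscripts, tuple(a.shape for a in arrays))
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(subscripts, *arrays, optimize="greedy")[0]
        _EINSUM_PATHS[key] = path
    data = np.einsum(subscripts, *arrays, optimize=path)

    def bw(g, needed):
        grads = []
        for i, (s, op) in enumerate(zip(in_subs, ops)):
            if not needed[i]:
                grads.append(None)
                continue
            others = [(in_subs[j], ops[j]) for j in range(len(ops)) if j != i]
            avail = out_sub + "".join(s2 for s2, _ in others)
            missing = [c for c in s if c not in avail]
            if missing:
                raise ValueError(
                    f"cannot differentiate einsum '{subscripts}' w.r.t. operand {i}"
                )
            sub_bw = ",".join([out_sub] + [s2 for s2, _ in others]) + "->" + s
            grads.append(einsum(sub_bw, g, *[t for _, t in others]))
        return tuple(grads)

    return _node(data, tuple(ops), bw)


def swap_last(a) -> Tensor:
    """Transpose the last two axes."""
    a = astensor(a)

    def bw(g, needed):
        return (swap_last(g),)

    return _node(np.swapaxes(a.data, -1, -2), (a,), bw)


def matmul(a, b) -> Tensor:
    """Batched matrix product (numpy ``@`` semantics, both operands >= 2-D);
    leading batch dimensions broadcast."""
    a, b = astensor(a), astensor(b)

    def bw(g, needed):
        ga = _unbroadcast(matmul(g, swap_last(b)), a.shape) if needed[0] else None
        gb = _unbroadcast(matmul(swap_last(a), g), b.shape) if needed[1] else None
        return (ga, gb)

    return _node(a.data @ b.data, (a, b), bw)


def rowmm(a, b) -> Tensor:
    """Row-independent matrix product ``out[..., j] = Σ_i a[..., i] b[i, j]``.

    Evaluated element-by-element (no BLAS cache blocking), so each output row
    is bitwise independent of how many other rows the batch contains.  Used
    for per-atom contractions, where appending atoms with zero features must
    leave existing atoms' energies bitwise unchanged.
    """
    a, b = astensor(a), astensor(b)

    def bw(g, needed):
        ga = rowmm(g, swap_last(b)) if needed[0] else None
        gb = None
        if needed[1]:
            batch = "nmpq"[:a.data.ndim - 1]
            gb = einsum(f"{batch}i,{batch}j->ij", a, g)
        return (ga, gb)

    return _node(np.einsum("...i,ij->...j", a.data, b.data, optimize=False),
                 (a, b), bw)


def gather(a, indices) -> Tensor:
    """Row gather along axis 0: ``out[e] = a[indices[e]]``."""
    a = astensor(a)
    idx = np.asarray(indices, dtype=np.intp)
    n = a.data.shape[0]

    def bw(g, needed):
        return (segment_sum(g, idx, n),)

    return _node(a.data[idx], (a,), bw)


_SCATTER_CACHE: dict = {}


def _scatter_matrix(idx: np.ndarray, num: int):
    """CSR one-hot matrix (num × len(idx)) so scatter-add is a sparse GEMM;
    cached by index content."""
    key = (idx.tobytes(), num)
    S = _SCATTER_CACHE.get(key)
    if S is None:
        from scipy.sparse import csr_matrix
        e = len(idx)
        S = csr_matrix((np.ones(e), (idx, np.arange(e))), shape=(num, e))
        if len(_SCATTER_CACHE) > 256:
            _SCATTER_CACHE.clear()
        _SCATTER_CACHE[key] = S
    return S


def segment_sum(a, indices, num: int) -> Tensor:
    """Scatter-add rows of ``a`` into ``num`` output rows: the message
    aggregation primitive.  ``out[j] = sum over e with indices[e] == j``."""
    a = astensor(a)
    idx = np.asarray(indices, dtype=np.intp)
    tail = a.data.shape[1:]
    if a.data.ndim > 1:
        out_data = (_scatter_matrix(idx, num)
                    @ a.data.reshape(len(idx), -1)).reshape((num,) + tail) \
            .astype(a.data.dtype, copy=False)
    else:
        out_data = np.zeros((num,), dtype=a.data.dtype)
        np.add.at(out_data, idx, a.data)

    def bw(g, needed):
        return (gather(g, idx),)

    return _node(out_data, (a,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g, needed):
        grads = []
        for i, t in enumerate(ts):
            if not needed[i]:
                grads.append(None)
                continue
            key = [slice(None)] * g.data.ndim
            key[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(getslice(g, tuple(key)))
        return tuple(grads)

    return _node(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


def getslice(a, key) -> Tensor:
    """Basic (non-advanced) indexing; backward scatters into zeros."""
    a = astensor(a)
    in_shape = a.data.shape

    def bw(g, needed):
        return (_padslice(g, in_shape, key),)

    return _node(a.data[key], (a,), bw)


def _padslice(g, shape, key) -> Tensor:
    g = astensor(g)
    out_data = np.zeros(shape, dtype=g.data.dtype)
    out_data[key] = g.data

    def bw(gg, needed):
        return (getslice(gg, key),)

    return _node(out_data, (g,), bw)


def where(mask, a, b) -> Tensor:
    """Select by a constant boolean mask (the mask is not differentiated)."""
    m = np.asarray(mask, dtype=bool)
    a, b = astensor(a), astensor(b)

    def bw(g, needed):
        zero = Tensor(np.zeros((), dtype=g.data.dtype))
        ga = _unbroadcast(where(m, g, zero), a.shape) if needed[0] else None
        gb = _unbroadcast(where(m, zero, g), b.shape) if needed[1] else None
        return (ga, gb)

    return _node(np.where(m, a.data, b.data), (a, b), bw)


# ----------------------------------------------------------------- autodiff

def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own tape
    and can be differentiated again.  Inputs unreachable from ``output`` get
    a zero gradient of their own shape.  Gradients are only propagated along
    paths that end in one of ``inputs``.
    """
    inputs = list(inputs)
    if grad_output is None:
        if output.data.ndim != 0:
            raise ValueError("grad_output required for non-scalar output")
        grad_output = Tensor(np.ones((), dtype=output.data.dtype))
    else:
        grad_output = astensor(grad_output)

    # topological order over the requires_grad subgraph (parents first)
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))

    # relevance: nodes through which some requested input is reachable
    input_ids = {id(i) for i in inputs}
    relevant: set[int] = set()
    for node in topo:
        if id(node) in input_ids:
            relevant.add(id(node))
        else:
            for p in node.parents:
                if id(p) in relevant:
                    relevant.add(id(node))
                    break

    grads: dict[int, Tensor] = {id(output): grad_output}
    with _set_grad(create_graph):
        for node in reversed(topo):
            if node.backward_fn is None:
                continue
            g = grads.get(id(node))
            if g is None:
                continue
            needed = tuple(p.requires_grad and id(p) in relevant
                           for p in node.parents)
            if not any(needed):
                continue
            parent_grads = node.backward_fn(g, needed)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None:
                    continue
                prev = grads.get(id(p))
                grads[id(p)] = pg if prev is None else add(prev, pg)
        result = []
        for inp in inputs:
            gi = grads.get(id(inp))
            if gi is None:
                gi = Tensor(np.zeros(inp.data.shape, dtype=inp.data.dtype))
            elif gi.data.shape != inp.data.shape:
                gi = broadcast_to(gi, inp.data.shape)
            result.append(gi)
    return result
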