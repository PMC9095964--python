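"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the primitives the registration
and reconstruction networks need: broadcasting arithmetic, reductions,
matmul, convolutions (via im2col), pooling, transposed convolutions,
bilinear warping and a Fourier data-consistency operator.  Complex images
are represented as real arrays with a real/imaginary channel axis; the
Fourier ops form the complex view internally.

All floating-point work is float32 (complex64 in k-space) unless the caller
supplies float64 data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "no_grad"]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        if np.isscalar(other):
            return self * (1.0 / other)
        return _binary(self, other, np.divide,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))
        if out.requires_grad:
            basic = isinstance(key, (slice, int, type(Ellipsis))) or (
                isinstance(key, tuple) and all(
                    isinstance(k, (slice, int, type(Ellipsis))) for k in key))

            def bwd(g, key=key):
                full = np.zeros_like(self.data)
                if basic:
                    full[key] += g
                else:
                    np.add.at(full, key, g)
                self._accumulate(full)
            out._backward = bwd
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bwd(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), parents=(self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # -- elementwise ----------------------------------------------------
    def square(self):
        return self * self

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * 0.5 / out.data)
        return out

    def leaky_relu(self, slope=0.01):
        mask = self.data >= 0
        out = Tensor(np.where(mask, self.data, slope * self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * np.where(mask, 1.0, slope).astype(g.dtype))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)
            out._backward = bwd
        return out


def as_tensor(x, requires_grad=False):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x), requires_grad=requires_grad)


def _unbroadcast(g, shape):
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a, b, fwd, da, db):
    # keep python scalars at the tensor's dtype (avoid float64 promotion)
    if isinstance(a, Tensor) and not isinstance(b, Tensor) and np.isscalar(b) \
            and a.data.dtype.kind == "f":
        b = np.asarray(b, dtype=a.data.dtype)
    elif isinstance(b, Tensor) and not isinstance(a, Tensor) and np.isscalar(a) \
            and b.data.dtype.kind == "f":
        a = np.asarray(a, dtype=b.data.dtype)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data), parents=(a, b))
    if out.requires_grad:
        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(da(g, a.data, b.data), a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(db(g, a.data, b.data), b.data.shape))
        out._backward = bwd
    return out


def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(idx)])
        out._backward = bwd
    return out


class no_grad:
    """Marker context (the engine only tracks explicit `requires_grad`)."""

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


# ---------------------------------------------------------------------------
# convolution primitives (stride 1, odd kernel, 'same' zero padding)
# ---------------------------------------------------------------------------

# cols layout: (k^nd * C, P) with row index offset_index * C + channel, so
# the im2col writes are contiguous; flat weights use the matching layout
# (Cout, k^nd * C) obtained by moving the input-channel axis last.

def _im2col2d(x, k):
    C, Hp, Wp = x.shape
    Ho, Wo = Hp - k + 1, Wp - k + 1
    cols = np.empty((k * k, C, Ho * Wo), dtype=x.dtype)
    i = 0
    for a in range(k):
        for b in range(k):
            cols[i] = x[:, a:a + Ho, b:b + Wo].reshape(C, -1)
            i += 1
    return cols.reshape(k * k * C, Ho * Wo)


def _raw_conv2d(x, wf, k):
    """x: (Cin, H, W), wf: (Cout, k*k*Cin) -> (Cout, H, W)."""
    C, H, W = x.shape
    p = k // 2
    xp = np.zeros((C, H + 2 * p, W + 2 * p), dtype=x.dtype)
    xp[:, p:p + H, p:p + W] = x
    cols = _im2col2d(xp, k)
    return (wf @ cols).reshape(-1, H, W), cols


def _flat_w(w, nd):
    """(Cout, Cin, *k) -> (Cout, k^nd * Cin)."""
    axes = (0,) + tuple(range(2, 2 + nd)) + (1,)
    return np.ascontiguousarray(w.transpose(axes)).reshape(w.shape[0], -1)


def _unflat_gw(gw, shape, nd):
    """Inverse of :func:`_flat_w` for the weight gradient."""
    cout, cin = shape[0], shape[1]
    interim = gw.reshape((cout,) + shape[2:] + (cin,))
    axes = (0, 1 + nd) + tuple(range(1, 1 + nd))
    return interim.transpose(axes)


def conv2d(x, weight, bias, k=3):
    """2D convolution; x (Cin,H,W), weight (Cout,Cin,k,k), bias (Cout,)."""
    Cout = weight.data.shape[0]
    y, cols = _raw_conv2d(x.data, _flat_w(weight.data, 2), k)
    y += bias.data[:, None, None]
    out = Tensor(y, parents=(x, weight, bias))
    if out.requires_grad:
        def bwd(g):
            gf = g.reshape(Cout, -1)
            if bias.requires_grad:
                bias._accumulate(gf.sum(axis=1))
            if weight.requires_grad:
                weight._accumulate(_unflat_gw(gf @ cols.T,
                                              weight.data.shape, 2))
            if x.requires_grad:
                wr = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                gx, _ = _raw_conv2d(g, _flat_w(wr, 2), k)
                x._accumulate(gx)
        out._backward = bwd
    return out


def _shift_pairs(k, dims):
    """Per kernel offset: (offset index tuple, out-slice, in-slice).

    Contribution of offset (a, b, c): y[out] += (W[..., a, b, c] @ x)[in],
    with the slices implementing the zero-padded 'same' geometry without
    materializing an im2col matrix (the frame/space volumes here make the
    shifted-matmul formulation much cheaper).
    """
    p = k // 2
    pairs = []
    for idx in np.ndindex(*(k,) * len(dims)):
        so, si = [], []
        for o, n in zip(idx, dims):
            s = p - o
            so.append(slice(max(s, 0), n + min(s, 0)))
            si.append(slice(max(-s, 0), n + min(-s, 0)))
        pairs.append((idx, (slice(None),) + tuple(so),
                      (slice(None),) + tuple(si)))
    return pairs


def conv3d(x, weight, bias, k=3):
    """3D convolution, stride 1, 'same' zero padding.

    x (Cin,D,H,W), weight (Cout,Cin,k,k,k), bias (Cout,).  Computed as a
    sum of channel-mixing matmuls over shifted views.
    """
    xd, wd = x.data, weight.data
    Cin, D, H, W = xd.shape
    Cout = wd.shape[0]
    pairs = _shift_pairs(k, (D, H, W))
    xf = xd.reshape(Cin, -1)
    y = np.zeros((Cout, D, H, W), dtype=xd.dtype)
    for idx, so, si in pairs:
        t = (wd[(slice(None), slice(None)) + idx] @ xf).reshape(Cout, D, H, W)
        y[so] += t[si]
    y += bias.data[:, None, None, None]
    out = Tensor(y, parents=(x, weight, bias))
    if out.requires_grad:
        def bwd(g):
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(1, 2, 3)))
            gw = np.zeros_like(wd) if weight.requires_grad else None
            gx = np.zeros_like(xd) if x.requires_grad else None
            for idx, so, si in pairs:
                gs = np.ascontiguousarray(g[so]).reshape(Cout, -1)
                if gw is not None:
                    xs = np.ascontiguousarray(xd[si]).reshape(Cin, -1)
                    gw[(slice(None), slice(None)) + idx] = gs @ xs.T
                if gx is not None:
                    wj = wd[(slice(None), slice(None)) + idx]
                    gx[si] += (wj.T @ gs).reshape(
                        (Cin,) + tuple(s.stop - s.start for s in so[1:]))
            if gw is not None:
                weight._accumulate(gw)
            if gx is not None:
                x._accumulate(gx)
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# pooling / upsampling (window 2, stride 2; odd sizes padded with -inf)
# ---------------------------------------------------------------------------

def _pad_even(x, spatial_axes):
    pads = [(0, 0)] * x.ndim
    padded = False
    for ax in spatial_axes:
        if x.shape[ax] % 2:
            pads[ax] = (0, 1)
            padded = True
    if padded:
        x = np.pad(x, pads, constant_values=-np.inf)
    return x


def maxpool(x, ndim_spatial):
    """Max pooling with window/stride 2 over the trailing `ndim_spatial` axes."""
    xd = _pad_even(x.data, range(x.ndim - ndim_spatial, x.ndim))
    lead = xd.shape[: xd.ndim - ndim_spatial]
    spat = xd.shape[xd.ndim - ndim_spatial:]
    newshape = list(lead)
    for s in spat:
        newshape += [s // 2, 2]
    xr = xd.reshape(newshape)
    # interleave: move the window axes to the end
    nl = len(lead)
    perm = list(range(nl)) + [nl + 2 * i for i in range(ndim_spatial)] \
        + [nl + 2 * i + 1 for i in range(ndim_spatial)]
    xr = xr.transpose(perm)
    flat = xr.reshape(xr.shape[: nl + ndim_spatial] + (2 ** ndim_spatial,))
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))
    if out.requires_grad:
        def bwd(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gr = gflat.reshape(xr.shape).transpose(np.argsort(perm))
            gx = gr.reshape(xd.shape)
            sl = tuple(slice(0, s) for s in x.data.shape)
            x._accumulate(gx[sl])
        out._backward = bwd
    return out


def conv_transpose_up(x, weight, ndim_spatial):
    """Transposed convolution with kernel 2, stride 2 (exact x2 upsampling).

    x: (Cin, *spatial); weight: (Cin, Cout, 2[, 2[, 2]]).
    """
    Cin = x.data.shape[0]
    Cout = weight.data.shape[1]
    spat = x.data.shape[1:]
    P = int(np.prod(spat))
    wf = weight.data.reshape(Cin, -1)          # (Cin, Cout * 2^nd)
    xf = x.data.reshape(Cin, P)
    # (Cout*2^nd, P): for each output channel and window offset, the value
    y = (wf.T @ xf).reshape((Cout,) + (2,) * ndim_spatial + (P,))
    if ndim_spatial == 2:
        H, W = spat
        yr = y.reshape(Cout, 2, 2, H, W).transpose(0, 3, 1, 4, 2)
        out_shape = (Cout, 2 * H, 2 * W)
        inv = (0, 2, 4, 1, 3)
    else:
        D, H, W = spat
        yr = y.reshape(Cout, 2, 2, 2, D, H, W).transpose(0, 4, 1, 5, 2, 6, 3)
        out_shape = (Cout, 2 * D, 2 * H, 2 * W)
        inv = (0, 2, 4, 6, 1, 3, 5)
    out = Tensor(np.ascontiguousarray(yr).reshape(out_shape), parents=(x, weight))
    if out.requires_grad:
        def bwd(g):
            gr = g.reshape(yr.shape).transpose(inv).reshape(-1, P)
            if x.requires_grad:
                x._accumulate((wf @ gr).reshape(x.data.shape))
            if weight.requires_grad:
                weight._accumulate((xf @ gr.T).reshape(weight.data.shape))
        out._backward = bwd
    return out


def crop_to(x, shape):
    """Crop trailing axes of `x` down to `shape` (used after upsampling)."""
    sl = (Ellipsis,) + tuple(slice(0, s) for s in shape)
    return x[sl]


# ---------------------------------------------------------------------------
# bilinear warping (backward mapping, border replication)
# ---------------------------------------------------------------------------

_GRID_CACHE: dict = {}


def _base_grid(H, W, dtype):
    key = (H, W, np.dtype(dtype).str)
    if key not in _GRID_CACHE:
        gr, gc = np.meshgrid(np.arange(H, dtype=dtype),
                             np.arange(W, dtype=dtype), indexing="ij")
        _GRID_CACHE[key] = (gr, gc)
    return _GRID_CACHE[key]


def warp(image, disp):
    """Warp a batch of multi-channel frames by displacement fields.

    image: Tensor (N, C, H, W); disp: Tensor (N, 2, H, W) in pixels,
    component order (row, col).  out(x) = image(x + disp(x)) with bilinear
    interpolation; sampling coordinates are clamped to the image (border
    replication).  Differentiable in both arguments.
    """
    img, d = image.data, disp.data
    N, C, H, W = img.shape
    P = H * W
    gr, gc = _base_grid(H, W, d.dtype)
    rr = gr[None] + d[:, 0]
    cc = gc[None] + d[:, 1]
    in_r = (rr >= 0) & (rr <= H - 1)
    in_c = (cc >= 0) & (cc <= W - 1)
    np.clip(rr, 0.0, H - 1.0, out=rr)
    np.clip(cc, 0.0, W - 1.0, out=cc)
    r0 = np.minimum(rr.astype(np.int64), H - 2)
    c0 = np.minimum(cc.astype(np.int64), W - 2)
    fr = (rr - r0).astype(d.dtype, copy=False)
    fc = (cc - c0).astype(d.dtype, copy=False)

    # one fused gather for the 4 bilinear corners over all channels
    i00 = (r0 * W + c0).reshape(N, 1, P)
    corner_idx = np.concatenate([i00, i00 + 1, i00 + W, i00 + W + 1], axis=1)
    idx = np.ascontiguousarray(
        np.broadcast_to(corner_idx[:, :, None, :], (N, 4, C, P)))
    flat = img.reshape(N, C, P)
    gathered = np.take_along_axis(flat[:, None], idx, axis=3)  # (N, 4, C, P)
    v00, v01, v10, v11 = (gathered[:, i].reshape(N, C, H, W) for i in range(4))
    frb, fcb = fr[:, None], fc[:, None]
    w00 = (1 - frb) * (1 - fcb)
    w01 = (1 - frb) * fcb
    w10 = frb * (1 - fcb)
    w11 = frb * fcb
    y = w00 * v00 + w01 * v01 + w10 * v10 + w11 * v11

    out = Tensor(y, parents=(image, disp))
    if out.requires_grad:
        def bwd(g):
            if image.requires_grad:
                base = (np.arange(N * C, dtype=np.int64) * P)[:, None]
                ib = (idx.swapaxes(1, 2).reshape(N * C, 4, P) + base[:, None])
                wstack = np.stack([w00, w01, w10, w11], axis=1)  # (N,4,1,H,W)
                gw = (wstack * g[:, None]).swapaxes(1, 2).reshape(N * C, 4, P)
                gx = np.bincount(ib.ravel(), weights=gw.ravel().astype(np.float64),
                                 minlength=N * C * P)
                image._accumulate(gx.reshape(N, C, H, W).astype(img.dtype))
            if disp.requires_grad:
                d_dr = ((1 - fcb) * (v10 - v00) + fcb * (v11 - v01))
                d_dc = ((1 - frb) * (v01 - v00) + frb * (v11 - v10))
                gr0 = (g * d_dr).sum(axis=1) * in_r
                gc0 = (g * d_dc).sum(axis=1) * in_c
                disp._accumulate(np.stack([gr0, gc0], axis=1).astype(d.dtype))
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Fourier data consistency (centered orthonormal FFT)
# ---------------------------------------------------------------------------

def _fft2c(x):
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)),
                                       norm="ortho"), axes=(-2, -1))


def _ifft2c(x):
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)),
                                        norm="ortho"), axes=(-2, -1))


def data_consistency_op(x, acquired, mask):
    """Replace sampled k-space coefficients of `x` with acquired data.

    x: Tensor (N, 2, H, W) real/imag channels; acquired: ndarray (N, H, W)
    complex; mask: ndarray (N, H, W) in {0,1}.  Returns (N, 2, H, W).
    The map is real-linear and self-adjoint in its x-dependent part, so the
    gradient passes through the same masked Fourier projection.
    """
    xc = x.data[:, 0] + 1j * x.data[:, 1]
    k = _fft2c(xc)
    mixed = mask * acquired + (1.0 - mask) * k
    y = _ifft2c(mixed)
    out = Tensor(np.stack([y.real, y.imag], axis=1).astype(x.data.dtype),
                 parents=(x,))
    if out.requires_grad:
        def bwd(g):
            gc = g[:, 0] + 1j * g[:, 1]
            gx = _ifft2c((1.0 - mask) * _fft2c(gc))
            x._accumulate(np.stack([gx.real, gx.imag], axis=1).astype(x.data.dtype))
        out._backward = bwd
    return out
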