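"""Trainable capsule network in pure numpy with manual backpropagation.

The engine implements exactly the layer vocabulary of
:mod:`melcaps.architecture` — convolution (im2col), batch normalisation,
ReLU, max-pooling, the primary-capsule reshape/squash, the densely
connected capsule layer with routing-by-agreement, and the length head —
each as a small object with ``forward``/``backward`` methods and explicit
parameter/gradient dictionaries.  Gradients are hand-derived and verified
against finite differences in the test suite.

Within a backward pass the routing coupling coefficients are treated as
constants of the forward pass.  For one routing iteration (the
configuration the published results use) this is exact, because the
coefficients are the fixed uniform softmax of zero logits.

Weights are Glorot/Xavier-uniform initialised from a single integer seed;
building twice with the same seed yields bit-identical parameters.
"""

from __future__ import annotations

import pickle

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architecture import ArchitectureSpec, ShapeError, compute_layer_shapes
from .capsule_core import MarginLossParams, routing_softmax

__all__ = ["Model", "build_model", "forward_capsules", "reconstruction_loss"]

_EPS = 1e-12


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Layer:
    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(_Layer):
    def __init__(self, name, rng, in_ch, filters, kernel, stride, padding):
        super().__init__()
        self.name = name
        kh, kw = kernel
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in, fan_out = kh * kw * in_ch, kh * kw * filters
        self.params["W"] = _glorot(rng, (kh, kw, in_ch, filters), fan_in, fan_out)
        self.params["b"] = np.zeros(filters)

    def _pad(self, x):
        if self.padding == "valid":
            return x, (0, 0), (0, 0)
        h, w = x.shape[1:3]
        kh, kw = self.kernel
        oh = -(-h // self.stride)
        ow = -(-w // self.stride)
        ph = max((oh - 1) * self.stride + kh - h, 0)
        pw = max((ow - 1) * self.stride + kw - w, 0)
        pads = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
        x = np.pad(x, ((0, 0), pads[0], pads[1], (0, 0)))
        return x, pads[0], pads[1]

    def forward(self, x, train):
        xp, self._ph, self._pw = self._pad(x)
        kh, kw = self.kernel
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # B,Ho',Wo',C,kh,kw
        win = win[:, :: self.stride, :: self.stride]
        self._win_x = xp
        self._x_shape = x.shape
        out = np.einsum("bhwckl,klcf->bhwf", win, self.params["W"], optimize=True)
        self._win = win
        return out + self.params["b"]

    def backward(self, g):
        kh, kw = self.kernel
        W = self.params["W"]
        self.grads["W"] = np.einsum("bhwckl,bhwf->klcf", self._win, g, optimize=True)
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(self._win_x)
        s = self.stride
        oh, ow = g.shape[1:3]
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += np.einsum(
                    "bhwf,cf->bhwc", g, W[i, j], optimize=True
                )
        (pt, pb), (pl, pr) = self._ph, self._pw
        h, w = self._x_shape[1:3]
        return dxp[:, pt : pt + h, pl : pl + w, :]


class BatchNorm(_Layer):
    """Per-channel batch normalisation (over batch and spatial axes).

    epsilon 1e-3 and running-average momentum 0.9 are engine defaults, not
    published constants; the momentum is chosen so the inference statistics
    converge within the few hundred update steps of a desk-scale run.
    """

    def __init__(self, name, channels, eps=1e-3, momentum=0.9):
        super().__init__()
        self.name = name
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        axes = tuple(range(g.ndim - 1))
        self.grads["gamma"] = (g * self._xhat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gam = self.params["gamma"]
        if not self._train:
            return g * gam / self._std
        m = self._m
        gx = g * gam
        return (gx - gx.mean(axis=axes) - self._xhat * (gx * self._xhat).mean(axis=axes)) / self._std


class ReLU(_Layer):
    def __init__(self, name):
        super().__init__()
        self.name = name

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2D(_Layer):
    def __init__(self, name, kernel, stride):
        super().__init__()
        self.name = name
        self.kernel, self.stride = kernel, stride

    def forward(self, x, train):
        kh, kw = self.kernel
        s = self.stride
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::s, ::s]  # B,Ho,Wo,C,kh,kw
        b, oh, ow, c = win.shape[:4]
        flat = win.reshape(b, oh, ow, c, kh * kw)
        self._arg = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, g):
        kh, kw = self.kernel
        s = self.stride
        b, oh, ow, c = g.shape
        dx = np.zeros(self._x_shape)
        bi, hi, wi, ci = np.indices((b, oh, ow, c))
        ki, kj = self._arg // kw, self._arg % kw
        np.add.at(dx, (bi, hi * s + ki, wi * s + kj, ci), g)
        return dx


class Reshape(_Layer):
    """Flatten stem feature maps into (num_capsules, dim) groups."""

    def __init__(self, name, dim):
        super().__init__()
        self.name = name
        self.dim = dim

    def forward(self, x, train):
        self._x_shape = x.shape
        b = x.shape[0]
        total = int(np.prod(x.shape[1:]))
        if total % self.dim:
            raise ShapeError(f"{self.name}: {total} values not divisible by dim {self.dim}")
        return x.reshape(b, total // self.dim, self.dim)

    def backward(self, g):
        return g.reshape(self._x_shape)


class Squash(_Layer):
    def __init__(self, name):
        super().__init__()
        self.name = name

    def forward(self, x, train):
        self._x = x
        self._n = np.linalg.norm(x, axis=-1, keepdims=True)
        self._f = self._n / (1.0 + self._n**2 + _EPS)
        return x * self._f

    def backward(self, g):
        n = np.maximum(self._n, _EPS)
        fprime = (1.0 - self._n**2) / (1.0 + self._n**2 + _EPS) ** 2
        gs = (g * self._x).sum(axis=-1, keepdims=True)
        return g * self._f + self._x * (fprime / n) * gs


class CapsuleDense(_Layer):
    """Densely connected capsule layer with routing-by-agreement.

    One independent D_in x D_out transform per (input capsule, output
    capsule) pair; coupling coefficients come from the routing loop and
    are treated as constants in the backward pass (exact for one
    iteration).
    """

    def __init__(self, name, rng, n_in, n_out, d_in, d_out, iterations):
        super().__init__()
        self.name = name
        self.n_in, self.n_out = n_in, n_out
        self.iterations = iterations
        self.params["W"] = _glorot(rng, (n_in, n_out, d_in, d_out), d_in, d_out)
        self._squash = Squash(name + "/squash")

    def forward(self, u, train):
        self._u = u
        votes = np.einsum("ijde,bid->bije", self.params["W"], u, optimize=True)
        self._votes = votes
        b = np.zeros((u.shape[0], self.n_in, self.n_out))
        for r in range(self.iterations):
            c = routing_softmax(b)
            s = np.einsum("bij,bije->bje", c, votes, optimize=True)
            v = self._squash.forward(s, train)
            if r < self.iterations - 1:
                b = b + np.einsum("bije,bje->bij", votes, v, optimize=True)
        self._c = c
        return v

    def backward(self, g):
        ds = self._squash.backward(g)  # B, N_out, D_out
        dvotes = self._c[..., None] * ds[:, None, :, :]
        self.grads["W"] = np.einsum("bije,bid->ijde", dvotes, self._u, optimize=True)
        return np.einsum("bije,ijde->bid", dvotes, self.params["W"], optimize=True)


class Length(_Layer):
    def __init__(self, name):
        super().__init__()
        self.name = name

    def forward(self, v, train):
        self._v = v
        self._n = np.linalg.norm(v, axis=-1)
        return self._n

    def backward(self, g):
        return g[..., None] * self._v / np.maximum(self._n[..., None], _EPS)


class _Dense(_Layer):
    def __init__(self, name, rng, n_in, n_out, activation):
        super().__init__()
        self.name = name
        self.activation = activation
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        if self.activation == "sigmoid":
            self._y = 1.0 / (1.0 + np.exp(-z))
            return self._y
        return z

    def backward(self, g):
        if self.activation == "relu":
            g = g * self._mask
        elif self.activation == "sigmoid":
            g = g * self._y * (1.0 - self._y)
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class Model:
    """A built network: ordered layers plus an optional decoder head.

    ``forward`` maps a batch of images (B, H, W, C) with pixels in [0, 1]
    to per-class capsule lengths in [0, 1).
    """

    def __init__(self, spec: ArchitectureSpec, seed: int):
        self.spec = spec
        self.seed = seed
        shapes = compute_layer_shapes(spec)  # validates the geometry
        rng = np.random.default_rng(seed)
        self.layers: list[_Layer] = []
        cur = spec.input_shape
        for ls, (_, out_shape) in zip(spec.layers, shapes):
            if ls.kind == "conv":
                self.layers.append(
                    Conv2D(ls.name, rng, cur[2], ls.width, ls.kernel, ls.stride, ls.padding)
                )
            elif ls.kind == "batchnorm":
                self.layers.append(BatchNorm(ls.name, cur[2]))
            elif ls.kind == "activation":
                self.layers.append(ReLU(ls.name))
            elif ls.kind == "maxpool":
                self.layers.append(MaxPool2D(ls.name, ls.kernel, ls.stride))
            elif ls.kind == "reshape":
                self.layers.append(Reshape(ls.name, ls.width or spec.primary_caps_dim))
            elif ls.kind == "caps_squash":
                self.layers.append(Squash(ls.name))
            elif ls.kind == "capsule_layer":
                n_in, d_in = cur
                ncls = ls.params.get("num_classes", spec.num_classes)
                self.layers.append(
                    CapsuleDense(
                        ls.name,
                        rng,
                        n_in,
                        ncls,
                        d_in,
                        ls.width or spec.class_caps_features,
                        ls.params.get("routing_iterations", spec.routing_iterations),
                    )
                )
            elif ls.kind == "length":
                self.layers.append(Length(ls.name))
            cur = out_shape
        self.decoder_layers: list[_Layer] = []
        if spec.decoder is not None:
            dec = spec.decoder
            n_in = spec.num_classes * spec.class_caps_features
            widths = list(dec.hidden_widths)
            tgt = int(np.prod(dec.reconstruction_target_size))
            sizes = [n_in] + widths + [tgt]
            for k in range(len(sizes) - 1):
                act = "relu" if k < len(sizes) - 2 else "sigmoid"
                self.decoder_layers.append(_Dense(f"decoder_{k}", rng, sizes[k], sizes[k + 1], act))

    # -- parameter plumbing ------------------------------------------------
    def _all_layers(self):
        return self.layers + self.decoder_layers

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{lyr.name}/{k}": v for lyr in self._all_layers() for k, v in lyr.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{lyr.name}/{k}": v for lyr in self._all_layers() for k, v in lyr.grads.items()}

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def forward_capsules(self, x: np.ndarray, train: bool = False):
        """Return (class lengths, class capsule vectors) for a batch."""
        x = np.asarray(x, dtype=float)
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        out = x
        caps = None
        for lyr in self.layers:
            out = lyr.forward(out, train)
            if isinstance(lyr, CapsuleDense):
                caps = out
        return out, caps

    def backward(self, grad_lengths: np.ndarray) -> None:
        g = grad_lengths
        for lyr in reversed(self.layers):
            g = lyr.backward(g)

    # -- losses ------------------------------------------------------------
    def loss_and_grad(
        self,
        lengths: np.ndarray,
        targets_onehot: np.ndarray,
        loss_mode: str = "margin",
        margin_params: MarginLossParams | None = None,
    ) -> tuple[float, np.ndarray]:
        """Mean per-sample loss over the batch and its gradient w.r.t. lengths."""
        p = margin_params or MarginLossParams()
        T = targets_onehot
        B = lengths.shape[0]
        if loss_mode == "margin":
            up = np.maximum(0.0, p.m_plus - lengths)
            dn = np.maximum(0.0, lengths - p.m_minus)
            loss = (T * up**2 + p.lambda_down * (1 - T) * dn**2).sum() / B
            grad = (-2.0 * T * up + 2.0 * p.lambda_down * (1 - T) * dn) / B
        elif loss_mode == "bce":
            q = np.clip(lengths, 1e-7, 1 - 1e-7)
            loss = -(T * np.log(q) + (1 - T) * np.log(1 - q)).sum() / B
            grad = ((q - T) / (q * (1 - q))) / B
            grad = np.where((lengths > 1e-7) & (lengths < 1 - 1e-7), grad, 0.0)
        else:
            raise ValueError(f"unknown loss mode {loss_mode!r}")
        return float(loss), grad

    # -- decoder -----------------------------------------------------------
    def decode(self, caps: np.ndarray, target_class: np.ndarray, train: bool = False):
        """Reconstruct from class capsules with the non-target class masked out."""
        if not self.decoder_layers:
            raise ValueError("model was built without a decoder")
        mask = np.zeros_like(caps)
        mask[np.arange(caps.shape[0]), target_class] = 1.0
        x = (caps * mask).reshape(caps.shape[0], -1)
        self._dec_mask = mask
        for lyr in self.decoder_layers:
            x = lyr.forward(x, train)
        return x.reshape((caps.shape[0],) + tuple(self.spec.decoder.reconstruction_target_size))

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        state = {
            "spec": self.spec.to_dict(),
            "seed": self.seed,
            "params": self.parameters(),
            "bn_state": {
                lyr.name: (lyr.running_mean, lyr.running_var)
                for lyr in self.layers
                if isinstance(lyr, BatchNorm)
            },
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path) -> "Model":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        model = cls(ArchitectureSpec.from_dict(state["spec"]), state["seed"])
        params = model.parameters()
        for k, v in state["params"].items():
            params[k][...] = v
        for lyr in model.layers:
            if isinstance(lyr, BatchNorm) and lyr.name in state["bn_state"]:
                lyr.running_mean, lyr.running_var = state["bn_state"][lyr.name]
        return model


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Model:
    """Build a trainable model with Xavier-initialised weights.

    The same seed always produces bit-identical initial weights.
    """
    return Model(spec, seed)


def forward_capsules(model: Model, images: np.ndarray):
    """Class capsule lengths and vectors for a batch of images in [0, 1]."""
    return model.forward_capsules(images, train=False)


def reconstruction_loss(decoder_output: np.ndarray, image: np.ndarray, spec) -> float:
    """Weighted sum of squared errors against the downsampled image.

    ``image`` may be at full input resolution; it is resized (local mean /
    skimage) to the decoder target before comparison.
    """
    from skimage.transform import resize

    tgt = spec.reconstruction_target_size
    img = np.asarray(image, dtype=float)
    if img.shape != tuple(tgt):
        img = resize(img, tgt, anti_aliasing=True, preserve_range=True)
    sse = float(((decoder_output - img) ** 2).sum())
    return spec.reconstruction_loss_weight * sse
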