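"""SFDI-net: a compact U-Net-style image-to-image regressor.

Maps an n x n x 6 MTF stack to n x n x 7 normalized parameter maps.  The
contracting path has convolutional blocks of 12, 24 and 48 channels with two
2x2 max-pooling steps; the expansive path mirrors it with 24 and 12 channels,
2x2 transposed-convolution upsampling and skip concatenations; every
activation, including the 7-channel output, is tanh, so predictions live in
(-1, 1) and are mapped to physical units by an affine per-channel
normalization over the physiological parameter box.

The loss is mean squared error plus a per-channel weighted anisotropic total
variation (TV) penalty on the prediction, which suppresses noise and
pixelation at a documented cost in raw accuracy.

The network is implemented directly on numpy arrays (forward and backward
passes are hand-written; the optimizer is Adam).  The default 1x1 kernels
make every convolution a per-pixel linear map, so the whole model is small
and fast on a CPU; a 3x3 kernel option is available for stronger spatial
context.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .demodulation import MTFStack
from .inversion import ParameterMaps
from .optics import InvalidInputError, PARAM_NAMES, param_bounds_arrays

__all__ = ["NetworkConfig", "TrainingConfig", "NormalizationSpec", "SFDINet",
           "build_network", "loss", "total_variation", "train", "predict",
           "r_squared", "assemble_training_set", "kfold_validate"]

#: Per-channel TV weights in (thb, sto2, melanin, musp540, b, alpha, h) order.
DEFAULT_TV_WEIGHTS = (1.0e-7, 2.5e-7, 5.0e-8, 1.0e-8, 1.0e-7, 1.0e-8, 2.0e-6)


@dataclass
class NetworkConfig:
    enc_channels: tuple[int, int, int] = (12, 24, 48)
    dec_channels: tuple[int, int] = (24, 12)
    kernel_size: int = 1          # 1 (default) or any odd size, e.g. 3
    in_channels: int = 6
    out_channels: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.kernel_size % 2 != 1:
            raise InvalidInputError("kernel size must be odd")


@dataclass
class TrainingConfig:
    learning_rate: float = 0.00055
    batch_size: int = 32
    epochs: int = 100
    val_fraction: float = 0.1
    tv_weights: tuple = DEFAULT_TV_WEIGHTS
    seed: int = 0

    def __post_init__(self):
        if any(w < 0 for w in self.tv_weights):
            raise InvalidInputError("TV weights must be non-negative")
        if not 0 < self.val_fraction < 1:
            raise InvalidInputError("validation fraction must be in (0, 1)")


@dataclass
class NormalizationSpec:
    """Affine per-channel map between physical units and [-1, 1]."""

    lower: np.ndarray = field(default_factory=lambda: param_bounds_arrays()[0])
    upper: np.ndarray = field(default_factory=lambda: param_bounds_arrays()[1])

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower >= self.upper):
            raise InvalidInputError("lower bounds must be below upper bounds")

    def normalize(self, phys):
        return 2.0 * (np.asarray(phys) - self.lower) / (self.upper - self.lower) - 1.0

    def denormalize(self, norm):
        return self.lower + (np.asarray(norm) + 1.0) * (self.upper - self.lower) / 2.0


# ---------------------------------------------------------------------------
# layer primitives (NHWC layout)
# ---------------------------------------------------------------------------

def _conv_forward(x, W, b):
    """Same-padded stride-1 convolution; W has shape (k, k, Cin, Cout)."""
    k = W.shape[0]
    if k == 1:
        return x @ W[0, 0] + b
    r = k // 2
    xp = np.pad(x, ((0, 0), (r, r), (r, r), (0, 0)))
    N, H, Wd, _ = x.shape
    y = np.zeros(x.shape[:3] + (W.shape[3],), dtype=x.dtype)
    for u in range(k):
        for v in range(k):
            y += xp[:, u:u + H, v:v + Wd, :] @ W[u, v]
    return y + b


def _conv_backward(x, W, dY):
    k = W.shape[0]
    if k == 1:
        dW = np.zeros_like(W)
        dW[0, 0] = np.tensordot(x, dY, axes=([0, 1, 2], [0, 1, 2]))
        db = dY.sum(axis=(0, 1, 2))
        dX = dY @ W[0, 0].T
        return dX, dW, db
    r = k // 2
    N, H, Wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (r, r), (r, r), (0, 0)))
    dW = np.zeros_like(W)
    dXp = np.zeros_like(xp)
    for u in range(k):
        for v in range(k):
            patch = xp[:, u:u + H, v:v + Wd, :]
            dW[u, v] = np.tensordot(patch, dY, axes=([0, 1, 2], [0, 1, 2]))
            dXp[:, u:u + H, v:v + Wd, :] += dY @ W[u, v].T
    db = dY.sum(axis=(0, 1, 2))
    return dXp[:, r:r + H, r:r + Wd, :], dW, db


def _pool_forward(x):
    """2x2 max pooling with stride 2; returns (y, argmax indices)."""
    N, H, W, C = x.shape
    xr = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(N, H // 2, W // 2, C, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _pool_backward(dY, idx, in_shape):
    N, H, W, C = in_shape
    d = np.zeros((N, H // 2, W // 2, C, 4), dtype=dY.dtype)
    np.put_along_axis(d, idx[..., None], dY[..., None], axis=-1)
    d = d.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return d.reshape(N, H, W, C)


def _upconv_forward(x, W, b):
    """2x2 stride-2 transposed convolution; W has shape (2, 2, Cin, Cout)."""
    N, H, Wd, _ = x.shape
    y = np.empty((N, 2 * H, 2 * Wd, W.shape[3]), dtype=x.dtype)
    for u in range(2):
        for v in range(2):
            y[:, u::2, v::2, :] = x @ W[u, v]
    return y + b


def _upconv_backward(x, W, dY):
    dW = np.zeros_like(W)
    dX = np.zeros(x.shape[:3] + (W.shape[2],), dtype=x.dtype)
    for u in range(2):
        for v in range(2):
            sub = dY[:, u::2, v::2, :]
            dW[u, v] = np.tensordot(x, sub, axes=([0, 1, 2], [0, 1, 2]))
            dX += sub @ W[u, v].T
    db = dY.sum(axis=(0, 1, 2))
    return dX, dW, db


class SFDINet:
    """The U-Net-style regressor with hand-written forward/backward passes."""

    def __init__(self, cfg: NetworkConfig | None = None):
        self.cfg = cfg or NetworkConfig()
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # -- construction -------------------------------------------------------
    def _glorot(self, rng, k, cin, cout):
        lim = np.sqrt(6.0 / (k * k * cin + k * k * cout))
        return rng.uniform(-lim, lim, size=(k, k, cin, cout)).astype(np.float32)

    def _init_params(self):
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        k = cfg.kernel_size
        e1, e2, e3 = cfg.enc_channels
        d1, d2 = cfg.dec_channels

        def conv(name, kk, cin, cout):
            self.params[name + "_W"] = self._glorot(rng, kk, cin, cout)
            self.params[name + "_b"] = np.zeros(cout, dtype=np.float32)

        conv("enc1a", k, cfg.in_channels, e1)
        conv("enc1b", k, e1, e1)
        conv("enc2a", k, e1, e2)
        conv("enc2b", k, e2, e2)
        conv("bota", k, e2, e3)
        conv("botb", k, e3, e3)
        conv("up1", 2, e3, d1)
        conv("dec1a", k, d1 + e2, d1)
        conv("dec1b", k, d1, d1)
        conv("up2", 2, d1, d2)
        conv("dec2a", k, d2 + e1, d2)
        conv("dec2b", k, d2, d2)
        conv("out", 1, d2, cfg.out_channels)

    @property
    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x):
        x = np.asarray(x, dtype=self.params["out_W"].dtype)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[3] != self.cfg.in_channels:
            raise InvalidInputError(
                f"expected (N, n, n, {self.cfg.in_channels}) input, got {x.shape}")
        if x.shape[1] % 4 or x.shape[2] % 4:
            raise InvalidInputError(
                "spatial size must be divisible by 4 (two pooling levels)")
        return x

    def forward(self, x, want_cache: bool = False):
        x = self._check_input(x)
        P = self.params
        cache = {"x": x}

        def block(name, inp):
            z = _conv_forward(inp, P[name + "_W"], P[name + "_b"])
            a = np.tanh(z)
            cache[name + "_in"] = inp
            cache[name + "_a"] = a
            return a

        e1 = block("enc1b", block("enc1a", x))
        p1, cache["idx1"] = _pool_forward(e1)
        e2 = block("enc2b", block("enc2a", p1))
        p2, cache["idx2"] = _pool_forward(e2)
        bt = block("botb", block("bota", p2))

        u1 = _upconv_forward(bt, P["up1_W"], P["up1_b"])
        cache["up1_in"] = bt
        c1 = np.concatenate([u1, e2], axis=-1)
        d1 = block("dec1b", block("dec1a", c1))

        u2 = _upconv_forward(d1, P["up2_W"], P["up2_b"])
        cache["up2_in"] = d1
        c2 = np.concatenate([u2, e1], axis=-1)
        d2 = block("dec2b", block("dec2a", c2))

        y = np.tanh(_conv_forward(d2, P["out_W"], P["out_b"]))
        cache["out_in"] = d2
        cache["y"] = y
        return (y, cache) if want_cache else y

    def backward(self, cache, dY):
        """Gradients of a scalar loss w.r.t. all parameters, given dL/dy."""
        P = self.params
        grads = {}

        def conv_back(name, d_out):
            a = cache[name + "_a"]
            dz = d_out * (1.0 - a * a)
            dX, dW, db = _conv_backward(cache[name + "_in"], P[name + "_W"], dz)
            grads[name + "_W"] = dW
            grads[name + "_b"] = db
            return dX

        y = cache["y"]
        dz = (dY * (1.0 - y * y)).astype(y.dtype)
        d_out_in, grads["out_W"], grads["out_b"] = _conv_backward(
            cache["out_in"], P["out_W"], dz)

        d_c2 = conv_back("dec2a", conv_back("dec2b", d_out_in))
        n_up2 = P["up2_W"].shape[3]
        d_u2, d_e1_skip = d_c2[..., :n_up2], d_c2[..., n_up2:]
        d_d1, grads["up2_W"], grads["up2_b"] = _upconv_backward(
            cache["up2_in"], P["up2_W"], d_u2)

        d_c1 = conv_back("dec1a", conv_back("dec1b", d_d1))
        n_up1 = P["up1_W"].shape[3]
        d_u1, d_e2_skip = d_c1[..., :n_up1], d_c1[..., n_up1:]
        d_bt, grads["up1_W"], grads["up1_b"] = _upconv_backward(
            cache["up1_in"], P["up1_W"], d_u1)

        d_p2 = conv_back("bota", conv_back("botb", d_bt))
        e2_shape = cache["enc2b_a"].shape
        d_e2 = _pool_backward(d_p2, cache["idx2"], e2_shape) + d_e2_skip
        d_p1 = conv_back("enc2a", conv_back("enc2b", d_e2))
        e1_shape = cache["enc1b_a"].shape
        d_e1 = _pool_backward(d_p1, cache["idx1"], e1_shape) + d_e1_skip
        conv_back("enc1a", conv_back("enc1b", d_e1))
        return grads

    # -- persistence --------------------------------------------------------
    def save(self, path_prefix: str, norm: "NormalizationSpec | None" = None,
             extra: dict | None = None):
        """Write weights to ``<prefix>.npz`` and a JSON sidecar
        ``<prefix>.json`` with architecture and normalization bounds."""
        np.savez(path_prefix + ".npz", **self.params)
        meta = {
            "enc_channels": list(self.cfg.enc_channels),
            "dec_channels": list(self.cfg.dec_channels),
            "kernel_size": self.cfg.kernel_size,
            "in_channels": self.cfg.in_channels,
            "out_channels": self.cfg.out_channels,
            "seed": self.cfg.seed,
        }
        if norm is not None:
            meta["norm_lower"] = norm.lower.tolist()
            meta["norm_upper"] = norm.upper.tolist()
        if extra:
            meta.update(extra)
        with open(path_prefix + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str):
        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        cfg = NetworkConfig(
            enc_channels=tuple(meta["enc_channels"]),
            dec_channels=tuple(meta["dec_channels"]),
            kernel_size=meta["kernel_size"],
            in_channels=meta["in_channels"],
            out_channels=meta["out_channels"],
            seed=meta.get("seed", 0),
        )
        net = cls(cfg)
        with np.load(path_prefix + ".npz") as npz:
            for k in net.params:
                net.params[k] = npz[k]
        norm = None
        if "norm_lower" in meta:
            norm = NormalizationSpec(np.array(meta["norm_lower"]),
                                     np.array(meta["norm_upper"]))
        return net, norm


def build_network(cfg: NetworkConfig | None = None, n: int | None = None
                  ) -> SFDINet:
    """Construct an initialized network; ``n`` (if given) is validated for
    divisibility by 4."""
    if n is not None and n % 4:
        raise InvalidInputError("image size must be divisible by 4")
    return SFDINet(cfg)


# ---------------------------------------------------------------------------
# loss and metrics
# ---------------------------------------------------------------------------

def total_variation(yhat, weights) -> float:
    """Per-channel weighted anisotropic TV, averaged as in the loss:
    (1/(7 n^2)) * sum_k w_k * sum_ij (|horizontal diff| + |vertical diff|),
    averaged over the batch axis if present."""
    yhat = np.asarray(yhat, dtype=float)
    if yhat.ndim == 3:
        yhat = yhat[None]
    w = np.asarray(weights, dtype=float)
    n2 = yhat.shape[1] * yhat.shape[2]
    dh = np.abs(np.diff(yhat, axis=2))
    dv = np.abs(np.diff(yhat, axis=1))
    tv = (dh.sum(axis=(1, 2)) + dv.sum(axis=(1, 2))) @ w  # (N,)
    return float(tv.mean() / (yhat.shape[3] * n2))


def loss(yhat, y, weights=None) -> float:
    """MSE + weighted TV loss, both normalized by 7 n^2 (and batch size)."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise InvalidInputError("prediction and target shapes differ")
    if yhat.ndim == 3:
        yhat, y = yhat[None], y[None]
    n2 = yhat.shape[1] * yhat.shape[2]
    nch = yhat.shape[3]
    mse = float(((yhat - y) ** 2).sum() / (yhat.shape[0] * nch * n2))
    if weights is None:
        return mse
    return mse + total_variation(yhat, weights)


def _loss_grad(yhat, y, weights):
    """dL/dyhat for the MSE + TV loss (batch mean)."""
    N, H, W, C = yhat.shape
    scale = 1.0 / (N * C * H * W)
    g = 2.0 * (yhat - y) * scale
    if weights is not None:
        w = np.asarray(weights, dtype=yhat.dtype) * scale
        dh = np.sign(np.diff(yhat, axis=2)) * w
        g[:, :, 1:, :] += dh
        g[:, :, :-1, :] -= dh
        dv = np.sign(np.diff(yhat, axis=1)) * w
        g[:, 1:, :, :] += dv
        g[:, :-1, :, :] -= dv
    return g


def r_squared(y, yhat) -> float:
    """Coefficient of determination pooled over all channels and pixels,
    with per-channel means as the baseline."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise InvalidInputError("shapes differ")
    yc = y.reshape(-1, y.shape[-1])
    yhc = yhat.reshape(-1, y.shape[-1])
    ss_res = float(((yc - yhc) ** 2).sum())
    ss_tot = float(((yc - yc.mean(axis=0)) ** 2).sum())
    if ss_tot == 0:
        raise InvalidInputError("R^2 undefined for constant ground truth")
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# dataset assembly and training
# ---------------------------------------------------------------------------

def assemble_training_set(pairs, k: int = 15, per_cluster: int = 15,
                          seed: int = 0):
    """Cluster-balanced sampling of (MTFStack, ParameterMaps) pairs.

    Pairs are clustered by k-means on their flattened MTF stacks and
    ``per_cluster`` pairs are drawn from each cluster (with replacement,
    flagged, when a cluster is smaller).  Returns
    (X (N,n,n,6), Y (N,n,n,7), source indices, replacement flags).
    """
    from sklearn.cluster import KMeans

    if len(pairs) < k:
        raise InvalidInputError("need at least k pairs")
    mtfs = [m.data if isinstance(m, MTFStack) else np.asarray(m, float)
            for m, _ in pairs]
    maps = [p.data if isinstance(p, ParameterMaps) else np.asarray(p, float)
            for _, p in pairs]
    feats = np.stack([m.reshape(-1) for m in mtfs])
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(feats)
    rng = np.random.default_rng(seed)
    indices, flags = [], []
    for ci in range(k):
        members = np.flatnonzero(labels == ci)
        if members.size == 0:
            continue
        replace = members.size < per_cluster
        pick = rng.choice(members, size=per_cluster, replace=replace)
        indices.extend(int(i) for i in pick)
        flags.extend([replace] * per_cluster)
    X = np.stack([mtfs[i] for i in indices])
    Y = np.stack([maps[i] for i in indices])
    return X, Y, np.array(indices), np.array(flags)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _normalize_inputs(X):
    """MTF values live in (0, 1.5); map to tanh-friendly range via 2x - 1."""
    return (2.0 * np.asarray(X, dtype=np.float32) - 1.0)


def train(net: SFDINet, dataset, tcfg: TrainingConfig | None = None,
          norm: NormalizationSpec | None = None):
    """Train on a dataset of (X (N,n,n,6) MTF, Y (N,n,n,7) physical maps).

    Targets are normalized to [-1, 1] via ``norm``.  Runs the configured
    epochs with a seeded random train/validation split and batch shuffling,
    records per-epoch training and validation loss, and restores the weights
    of the best validation epoch before returning.

    Returns a history dict with ``train_loss``, ``val_loss`` and
    ``best_epoch``.
    """
    tcfg = tcfg or TrainingConfig()
    norm = norm or NormalizationSpec()
    X, Y = dataset
    X = _normalize_inputs(X)
    Yn = norm.normalize(np.asarray(Y, dtype=float)).astype(np.float32)
    N = X.shape[0]
    if N == 0:
        raise InvalidInputError("dataset is empty")
    rng = np.random.default_rng(tcfg.seed)
    perm = rng.permutation(N)
    n_val = max(1, int(round(tcfg.val_fraction * N))) if N > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0 or val_idx.size == 0:
        # degenerate split (tiny dataset): validate on the training set
        tr_idx = val_idx = perm
    Xtr, Ytr = X[tr_idx], Yn[tr_idx]
    Xva, Yva = X[val_idx], Yn[val_idx]
    w = np.asarray(tcfg.tv_weights, dtype=np.float32)
    use_tv = bool(np.any(w > 0))
    opt = _Adam(net.params, tcfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None, -1)
    ntr = Xtr.shape[0]
    for epoch in range(tcfg.epochs):
        order = rng.permutation(ntr)
        ep_loss, nb = 0.0, 0
        for s in range(0, ntr, tcfg.batch_size):
            idx = order[s:s + tcfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            yhat, cache = net.forward(xb, want_cache=True)
            lval = loss(yhat, yb, w if use_tv else None)
            if not np.isfinite(lval):
                raise RuntimeError("training diverged (non-finite loss)")
            dY = _loss_grad(yhat, yb, w if use_tv else None)
            grads = net.backward(cache, dY)
            opt.step(net.params, grads)
            ep_loss += lval
            nb += 1
        history["train_loss"].append(ep_loss / nb)
        yva = net.forward(Xva)
        vloss = loss(yva, Yva, w if use_tv else None)
        history["val_loss"].append(vloss)
        if vloss < best[0]:
            best = (vloss, {k: v.copy() for k, v in net.params.items()}, epoch)
    if best[1] is not None:
        net.params = best[1]
    history["best_epoch"] = best[2]
    return net, history


def kfold_validate(dataset, k: int = 5, net_cfg: NetworkConfig | None = None,
                   tcfg: TrainingConfig | None = None,
                   norm: NormalizationSpec | None = None) -> list[float]:
    """Seeded k-fold cross-validation over the training pool.

    Trains a fresh network on each fold's complement and returns the pooled
    held-out R^2 (in normalized units) per fold.
    """
    tcfg = tcfg or TrainingConfig()
    norm = norm or NormalizationSpec()
    X, Y = dataset
    N = X.shape[0]
    if not 2 <= k <= N:
        raise InvalidInputError("k must be in [2, n_pairs]")
    rng = np.random.default_rng(tcfg.seed)
    perm = rng.permutation(N)
    folds = np.array_split(perm, k)
    scores = []
    for i, hold in enumerate(folds):
        tr = np.concatenate([f for j, f in enumerate(folds) if j != i])
        net = SFDINet(net_cfg or NetworkConfig(seed=tcfg.seed + i))
        net, _ = train(net, (X[tr], Y[tr]), tcfg, norm)
        yh = net.forward(_normalize_inputs(X[hold]))
        scores.append(r_squared(norm.normalize(np.asarray(Y[hold], float)),
                                yh))
    return scores


def predict(net: SFDINet, mtf, norm: NormalizationSpec | None = None
            ) -> ParameterMaps:
    """Forward pass + denormalization to physical units."""
    norm = norm or NormalizationSpec()
    data = mtf.data if isinstance(mtf, MTFStack) else np.asarray(mtf, float)
    squeeze = data.ndim == 3
    yhat = net.forward(_normalize_inputs(data))
    phys = norm.denormalize(yhat.astype(float))
    if squeeze:
        phys = phys[0]
    return ParameterMaps(phys)
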