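"""The spatial-temporal transformer network: forward pass and analytic gradients.

Stages, applied to a CSP feature epoch ``S`` (6 feature channels x 500
samples at 250 Hz):

1. **Spatial self-attention** over the six feature-channel time vectors
   ``a_i``: ``q_i = Wq a_i``, ``k_i = Wk a_i``, ``v_i = Wv a_i`` with square
   ``d x d`` projections (d = 500), scaled dot-product scores
   ``q_i . k_j / sqrt(d)`` normalized row-wise by softmax, and output rows
   ``b_i = sum_j alpha_ij v_j``.  Dropout (default 0.3) on the output in
   training mode.
2. **Patch embedding** by two convolutions: a 1-D layer (2 filters, kernel
   51, applied along time to each feature channel independently) and a 2-D
   layer (10 filters, kernel 6 x 5 spanning all feature channels, time
   stride 5), yielding 10 patches x 90 samples.  Each convolution is
   followed by an ELU nonlinearity (configurable; ``"linear"`` disables it).
3. **Temporal multi-head attention**: the 10 patches are split in order
   into h = 5 consecutive pairs ``E_i`` (2 x 90); each head applies scaled
   dot-product attention with 2 x 2 projections (key length 90); head
   outputs are concatenated row-wise and mixed by ``Wo`` (10 x 10),
   ``F = Wo . Concat``.  Dropout (default 0.5) on ``F`` in training mode.
4. **Classifier head**: average pooling over the 90-sample axis, a log
   transform of the pooled 10-vector (the standard compression for
   band-power-like features; values are floored at a small positive
   constant), feature-wise normalization against training-set statistics
   (``bn_mean`` / ``bn_var``, data constants rather than optimized
   parameters) with a learned scale/shift, and an affine map to 3 class
   logits; softmax gives class probabilities, trained with cross-entropy.
   Normalizing per feature rather than per sample keeps the pooled
   vector's overall level and contrast — the statistics that separate
   rest (all channels loud) from imagery (specific channels quiet).

Everything is implemented as pure functions over a parameter dict so that
the backward pass can be verified against finite differences.  With dropout
off the forward pass is a deterministic pure function.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

from .io import ConfigurationError, DataError

_LN_EPS = 1e-5
_POOL_EPS = 1e-6  # floor before the log transform of pooled features


@dataclasses.dataclass(frozen=True)
class NetConfig:
    """Shape and regularization hyperparameters of the network."""

    n_feat: int = 6          # CSP feature channels
    d: int = 500             # samples per epoch (2 s at 250 Hz)
    k1: int = 51             # 1-D conv kernel length
    n_f1: int = 2            # 1-D conv filters
    k2: int = 5              # 2-D conv kernel width (time); height = n_feat
    stride: int = 5          # 2-D conv time stride
    n_patch: int = 10        # 2-D conv filters = embedded patches
    heads: int = 5           # attention heads; n_patch = 2 * heads
    n_classes: int = 3
    dropout_spatial: float = 0.3
    dropout_temporal: float = 0.5
    activation: str = "elu"  # "elu" or "linear"
    # 1-D kernels start as quadrature Gabor atoms at this frequency
    # (cycles/sample; 0.042 = 10.5 Hz at 250 Hz, the mu-band centre).
    # None falls back to uniform fan-in initialization.
    conv1_init_freq: float | None = 10.5 / 250.0
    # initial layer-norm gain; >1 lets the zero-initialized final affine
    # map reach decision-relevant logit scale in fewer Adam steps
    gamma_init: float = 4.0
    # "log" compresses the pooled features before normalization (band-power
    # statistics are multiplicative; log makes them additive, the standard
    # treatment of variance-like EEG features); "linear" disables it
    pool_transform: str = "log"

    def __post_init__(self) -> None:
        if self.n_patch != 2 * self.heads:
            raise ConfigurationError("n_patch must equal 2 * heads")
        if self.d <= self.k1:
            raise ConfigurationError("epoch shorter than the 1-D kernel")
        if self.conv1_len < self.k2:
            raise ConfigurationError("conv1 output shorter than the 2-D kernel")
        if self.activation not in ("elu", "linear"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.pool_transform not in ("log", "linear"):
            raise ConfigurationError(
                f"unknown pool transform {self.pool_transform!r}"
            )
        for p in (self.dropout_spatial, self.dropout_temporal):
            if not 0.0 <= p < 1.0:
                raise ConfigurationError("dropout rates must lie in [0, 1)")

    @property
    def conv1_len(self) -> int:
        return self.d - self.k1 + 1

    @property
    def patch_len(self) -> int:
        return (self.conv1_len - self.k2) // self.stride + 1


def init_params(cfg: NetConfig, rng: np.random.Generator,
                dtype=np.float32) -> dict[str, np.ndarray]:
    """Seeded initialization.

    Attention projections start near identity (identity plus small uniform
    noise) so the untrained network is close to a pass-through; convolution
    kernels use uniform fan-in scaling; the final affine map starts at zero
    so initial class probabilities are uniform.
    """
    def u(*shape, scale):
        return (rng.uniform(-1.0, 1.0, size=shape) * scale).astype(dtype)

    if cfg.conv1_init_freq is not None:
        # quadrature pair of Gabor atoms: band-pass filters whose rectified
        # outputs transduce oscillatory amplitude from the first epoch on
        t = np.arange(cfg.k1) - (cfg.k1 - 1) / 2.0
        envelope = np.exp(-0.5 * (t / (cfg.k1 / 4.0)) ** 2)
        phases = 2 * np.pi * cfg.conv1_init_freq * t
        atoms = [envelope * np.cos(phases + f * np.pi / 2)
                 for f in range(cfg.n_f1)]
        w1 = np.stack([a / np.linalg.norm(a) for a in atoms]).astype(dtype)
    else:
        w1 = (rng.uniform(-1, 1, (cfg.n_f1, cfg.k1))
              * np.sqrt(6.0 / cfg.k1)).astype(dtype)

    eye_d = np.eye(cfg.d, dtype=dtype)
    eye_2 = np.eye(2, dtype=dtype)
    p = {
        "Wq": eye_d + u(cfg.d, cfg.d, scale=0.01),
        "Wk": eye_d + u(cfg.d, cfg.d, scale=0.01),
        "Wv": eye_d + u(cfg.d, cfg.d, scale=0.01),
        "w1": w1,
        "b1": np.zeros(cfg.n_f1, dtype=dtype),
        "w2": _init_conv2(cfg, rng, dtype),
        "b2": np.zeros(cfg.n_patch, dtype=dtype),
        "WQ": np.stack([eye_2] * cfg.heads) + u(cfg.heads, 2, 2, scale=0.01),
        "WK": np.stack([eye_2] * cfg.heads) + u(cfg.heads, 2, 2, scale=0.01),
        "WV": np.stack([eye_2] * cfg.heads) + u(cfg.heads, 2, 2, scale=0.01),
        "Wo": np.eye(cfg.n_patch, dtype=dtype)
        + u(cfg.n_patch, cfg.n_patch, scale=0.01),
        "gamma": np.full(cfg.n_patch, cfg.gamma_init, dtype=dtype),
        "beta": np.zeros(cfg.n_patch, dtype=dtype),
        "Wfc": np.zeros((cfg.n_patch, cfg.n_classes), dtype=dtype),
        "bfc": np.zeros(cfg.n_classes, dtype=dtype),
        # normalization statistics of the pooled features; estimated from
        # training data by the estimator, never gradient-optimized
        "bn_mean": np.zeros(cfg.n_patch, dtype=dtype),
        "bn_var": np.ones(cfg.n_patch, dtype=dtype),
    }
    return p


#: Parameter-dict entries that are data statistics, not trainable weights.
BUFFER_PARAMS = ("bn_mean", "bn_var")


def _init_conv2(cfg: NetConfig, rng: np.random.Generator, dtype) -> np.ndarray:
    """Channel-selective patch-filter initialization.

    Each of the ``n_patch`` filters starts reading one (depth, feature
    channel) pair with a flat positive time window, plus small uniform
    noise everywhere.  Together with the band-pass 1-D kernels this makes
    the initial pooled patch vector approximate the per-feature-channel
    rectified band amplitudes, so the head sees the oscillatory-power
    pattern from the first gradient step; training is free to reshape the
    filters from there.
    """
    scale = np.sqrt(6.0 / (cfg.n_f1 * cfg.n_feat * cfg.k2))
    w2 = rng.uniform(-1, 1, (cfg.n_patch, cfg.n_f1, cfg.n_feat, cfg.k2)) * (
        0.05 * scale
    )
    for q in range(cfg.n_patch):
        chan = q % cfg.n_feat
        depth = (q // cfg.n_feat) % cfg.n_f1
        w2[q, depth, chan, :] += scale
    return w2.astype(dtype)


def count_params(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return x
    out = x.copy()
    neg = x < 0
    out[neg] = np.expm1(x[neg])
    return out


def _act_grad(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return np.ones_like(x)
    out = np.ones_like(x)
    neg = x < 0
    out[neg] = np.exp(x[neg])
    return out


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax_backward(alpha: np.ndarray, dalpha: np.ndarray) -> np.ndarray:
    return alpha * (dalpha - np.sum(dalpha * alpha, axis=-1, keepdims=True))


def spatial_attention(S: np.ndarray, params: dict, cfg: NetConfig,
                      return_weights: bool = False):
    """Enhanced feature channels ``B`` (and optionally the attention weights)."""
    out = forward(np.asarray(S)[None] if S.ndim == 2 else S, params, cfg,
                  upto="spatial", cache=True)
    B, alpha = out["B"], out["alpha"]
    if S.ndim == 2:
        B, alpha = B[0], alpha[0]
    return (B, alpha) if return_weights else B


def embed_patches(B: np.ndarray, params: dict, cfg: NetConfig) -> np.ndarray:
    """Patch set (10 x 90 by default) from enhanced feature channels."""
    single = B.ndim == 2
    out = forward(np.asarray(B)[None] if single else B, params, cfg,
                  upto="embed", cache=True, skip_spatial=True)
    A2 = out["A2"]
    return A2[0] if single else A2


def temporal_mha(patches: np.ndarray, params: dict, cfg: NetConfig) -> np.ndarray:
    """Multi-head attention output ``F`` from embedded patches."""
    single = patches.ndim == 2
    P = np.asarray(patches)[None] if single else np.asarray(patches)
    if P.shape[-2] != cfg.n_patch:
        raise DataError(f"expected {cfg.n_patch} patches, got {P.shape[-2]}")
    F = _mha_forward(P, params, cfg, cache=False)
    return F[0] if single else F


def classify(F: np.ndarray, params: dict, cfg: NetConfig) -> np.ndarray:
    """Class probabilities from the attention output ``F``."""
    single = F.ndim == 2
    Fb = np.asarray(F)[None] if single else np.asarray(F)
    pool = Fb.mean(axis=2)
    pool_t = _pool_transform(pool, cfg)
    y, _, _ = _headnorm_forward(pool_t, params)
    logits = y @ params["Wfc"] + params["bfc"]
    probs = _softmax(logits)
    return probs[0] if single else probs


def _pool_transform(pool: np.ndarray, cfg: NetConfig) -> np.ndarray:
    if cfg.pool_transform == "linear":
        return pool
    return np.log(np.maximum(pool, _POOL_EPS))


def _headnorm_forward(pool_t, params):
    """Feature-wise standardization against stored statistics + affine."""
    inv_std = 1.0 / np.sqrt(params["bn_var"] + _LN_EPS)
    xhat = (pool_t - params["bn_mean"]) * inv_std
    y = params["gamma"] * xhat + params["beta"]
    return y, xhat, inv_std


def pooled_features(S, params, cfg: NetConfig) -> np.ndarray:
    """Pooled (and log-compressed) head features for a batch; used by the
    estimator to set the normalization statistics."""
    c = forward(S, params, cfg, cache=True)
    return c["pool_t"]


def _mha_forward(A2, params, cfg, cache):
    N = A2.shape[0]
    E = A2.reshape(N, cfg.heads, 2, cfg.patch_len)
    Qh = np.einsum("hij,nhjt->nhit", params["WQ"], E)
    Kh = np.einsum("hij,nhjt->nhit", params["WK"], E)
    Vh = np.einsum("hij,nhjt->nhit", params["WV"], E)
    sc = np.einsum("nhit,nhjt->nhij", Qh, Kh) / np.sqrt(cfg.patch_len)
    al = _softmax(sc)
    H = np.einsum("nhij,nhjt->nhit", al, Vh)
    Cc = H.reshape(N, cfg.n_patch, cfg.patch_len)
    F = np.einsum("pq,nqt->npt", params["Wo"], Cc)
    if cache:
        return F, dict(E=E, Qh=Qh, Kh=Kh, Vh=Vh, al=al, Cc=Cc)
    return F


def forward(S: np.ndarray, params: dict, cfg: NetConfig, *,
            train: bool = False, rng: np.random.Generator | None = None,
            cache: bool = False, upto: str = "probs",
            skip_spatial: bool = False):
    """Batched forward pass.

    ``S`` is (N, n_feat, d).  In training mode dropout masks are drawn from
    ``rng``; in evaluation mode the pass is deterministic.  With ``cache``
    a dict of intermediates is returned (used by :func:`backward` and the
    stage-level helpers); otherwise the class probabilities.
    """
    S = np.asarray(S)
    if S.ndim != 3 or S.shape[1] != cfg.n_feat or S.shape[2] != cfg.d:
        raise DataError(
            f"expected input (N, {cfg.n_feat}, {cfg.d}), got {S.shape}"
        )
    S = S.astype(params["Wq"].dtype, copy=False)
    c: dict = {"S": S}
    if train and rng is None:
        raise ValueError("training-mode forward needs an rng for dropout")

    if skip_spatial:
        B = S
        c["alpha"] = None
    else:
        # q_i = Wq a_i over the row vectors of S; BLAS-shaped as S @ Wq'.
        S2 = S.reshape(-1, cfg.d)
        Q = (S2 @ params["Wq"].T).reshape(S.shape)
        K = (S2 @ params["Wk"].T).reshape(S.shape)
        V = (S2 @ params["Wv"].T).reshape(S.shape)
        sc = np.matmul(Q, K.transpose(0, 2, 1)) / np.sqrt(cfg.d)
        alpha = _softmax(sc)
        B = np.matmul(alpha, V)
        c.update(Q=Q, K=K, V=V, alpha=alpha)
    if train and cfg.dropout_spatial > 0:
        keep = 1.0 - cfg.dropout_spatial
        mask = (rng.random(B.shape) < keep) / keep
        B = B * mask.astype(B.dtype)
        c["mask_s"] = mask
    c["B"] = B
    if upto == "spatial":
        return c

    N = B.shape[0]
    L1, P = cfg.conv1_len, cfg.patch_len
    # valid cross-correlation along time == convolution with reversed kernel
    C1 = fftconvolve(
        B[:, None, :, :], params["w1"][None, :, None, ::-1],
        mode="valid", axes=3,
    ).astype(B.dtype)                                      # (N, f1, c, L1)
    C1 += params["b1"][None, :, None, None]
    A1 = _act(C1, cfg.activation)
    win2 = np.ascontiguousarray(
        sliding_window_view(A1, cfg.k2, axis=3)[:, :, :, ::cfg.stride, :]
        .transpose(0, 3, 1, 2, 4)
    )                                                      # (N, P, f1, c, k2)
    C2 = (
        win2.reshape(N * P, -1) @ params["w2"].reshape(cfg.n_patch, -1).T
    ).reshape(N, P, cfg.n_patch).transpose(0, 2, 1)        # (N, patches, P)
    C2 += params["b2"][None, :, None]
    A2 = _act(C2, cfg.activation)
    c.update(C1=C1, A1=A1, C2=C2, A2=A2, win2=win2)
    if upto == "embed":
        return c

    F, mha_cache = _mha_forward(A2, params, cfg, cache=True)
    c.update(mha_cache)
    if train and cfg.dropout_temporal > 0:
        keep = 1.0 - cfg.dropout_temporal
        mask = (rng.random(F.shape) < keep) / keep
        F = F * mask.astype(F.dtype)
        c["mask_t"] = mask
    c["F"] = F

    pool = F.mean(axis=2)
    pool_t = _pool_transform(pool, cfg)
    y, xhat, inv_std = _headnorm_forward(pool_t, params)
    logits = y @ params["Wfc"] + params["bfc"]
    probs = _softmax(logits)
    c.update(pool=pool, pool_t=pool_t, y=y, xhat=xhat, inv_std=inv_std,
             logits=logits, probs=probs)
    return c if cache else probs


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


def backward(c: dict, labels: np.ndarray, params: dict, cfg: NetConfig):
    """Analytic gradients of mean cross-entropy; returns (loss, grads)."""
    N = c["S"].shape[0]
    probs = c["probs"]
    loss = cross_entropy(probs, labels)

    dlogits = probs.copy()
    dlogits[np.arange(N), labels] -= 1.0
    dlogits /= N

    g = {}
    g["Wfc"] = c["y"].T @ dlogits
    g["bfc"] = dlogits.sum(axis=0)
    dy = dlogits @ params["Wfc"].T

    xhat = c["xhat"]
    g["gamma"] = (dy * xhat).sum(axis=0)
    g["beta"] = dy.sum(axis=0)
    dxhat = dy * params["gamma"]
    dpool_t = dxhat * c["inv_std"]  # stats are constants, no mean/var terms
    if cfg.pool_transform == "log":
        pool = c["pool"]
        dpool = np.where(pool > _POOL_EPS, dpool_t / np.maximum(pool, _POOL_EPS),
                         0.0)
    else:
        dpool = dpool_t

    dF = np.repeat(dpool[:, :, None], cfg.patch_len, axis=2) / cfg.patch_len
    if "mask_t" in c:
        dF = dF * c["mask_t"].astype(dF.dtype)

    # temporal MHA
    g["Wo"] = np.tensordot(dF, c["Cc"], axes=([0, 2], [0, 2]))
    dCc = np.matmul(params["Wo"].T, dF)
    dH = dCc.reshape(N, cfg.heads, 2, cfg.patch_len)
    al, Qh, Kh, Vh, E = c["al"], c["Qh"], c["Kh"], c["Vh"], c["E"]
    dal = np.einsum("nhit,nhjt->nhij", dH, Vh)
    dVh = np.einsum("nhij,nhit->nhjt", al, dH)
    dsc = _softmax_backward(al, dal) / np.sqrt(cfg.patch_len)
    dQh = np.einsum("nhij,nhjt->nhit", dsc, Kh)
    dKh = np.einsum("nhij,nhit->nhjt", dsc, Qh)
    g["WQ"] = np.einsum("nhit,nhjt->hij", dQh, E)
    g["WK"] = np.einsum("nhit,nhjt->hij", dKh, E)
    g["WV"] = np.einsum("nhit,nhjt->hij", dVh, E)
    dE = (
        np.einsum("hij,nhit->nhjt", params["WQ"], dQh)
        + np.einsum("hij,nhit->nhjt", params["WK"], dKh)
        + np.einsum("hij,nhit->nhjt", params["WV"], dVh)
    )
    dA2 = dE.reshape(N, cfg.n_patch, cfg.patch_len)

    # conv2
    P, L1 = cfg.patch_len, cfg.conv1_len
    dC2 = dA2 * _act_grad(c["C2"], cfg.activation)
    g["b2"] = dC2.sum(axis=(0, 2))
    win2 = c["win2"]                                       # (N, P, f1, c, k2)
    dC2_flat = dC2.transpose(1, 0, 2).reshape(cfg.n_patch, -1)  # (q, N*P)
    g["w2"] = (dC2_flat @ win2.reshape(N * P, -1)).reshape(params["w2"].shape)
    dwin2 = (
        dC2.transpose(0, 2, 1).reshape(N * P, cfg.n_patch)
        @ params["w2"].reshape(cfg.n_patch, -1)
    ).reshape(win2.shape)
    dA1 = np.zeros_like(c["A1"])
    for k in range(cfg.k2):
        sl = slice(k, k + cfg.stride * (P - 1) + 1, cfg.stride)
        dA1[:, :, :, sl] += dwin2[:, :, :, :, k].transpose(0, 2, 3, 1)

    # conv1 gradients as FFT convolutions (kernel and input correlograms)
    dC1 = dA1 * _act_grad(c["C1"], cfg.activation)
    g["b1"] = dC1.sum(axis=(0, 2, 3))
    g["w1"] = fftconvolve(
        c["B"][:, None, :, :], dC1[:, :, :, ::-1], mode="valid", axes=3
    ).sum(axis=(0, 2)).astype(params["w1"].dtype)
    dB = fftconvolve(
        dC1, params["w1"][None, :, None, :], mode="full", axes=3
    ).sum(axis=1).astype(c["B"].dtype)

    if "mask_s" in c:
        dB = dB * c["mask_s"].astype(dB.dtype)

    # spatial attention
    S, alpha, Q, K, V = c["S"], c["alpha"], c["Q"], c["K"], c["V"]
    dalpha = np.matmul(dB, V.transpose(0, 2, 1))
    dV = np.matmul(alpha.transpose(0, 2, 1), dB)
    dsc = _softmax_backward(alpha, dalpha) / np.sqrt(cfg.d)
    dQ = np.matmul(dsc, K)
    dK = np.matmul(dsc.transpose(0, 2, 1), Q)
    S2 = S.reshape(-1, cfg.d)
    g["Wq"] = dQ.reshape(-1, cfg.d).T @ S2
    g["Wk"] = dK.reshape(-1, cfg.d).T @ S2
    g["Wv"] = dV.reshape(-1, cfg.d).T @ S2

    return loss, g


def loss_and_grads(params: dict, cfg: NetConfig, S: np.ndarray,
                   labels: np.ndarray, *, train: bool = True,
                   rng: np.random.Generator | None = None):
    """Convenience wrapper: forward with cache, then backward."""
    c = forward(S, params, cfg, train=train, rng=rng, cache=True)
    return backward(c, np.asarray(labels), params, cfg)


#: Parameter-name groups for layer-wise learning-rate multipliers.
ATTENTION_PARAMS = ("Wq", "Wk", "Wv", "WQ", "WK", "WV", "Wo")
EMBED_PARAMS = ("w1", "b1", "w2", "b2")
HEAD_PARAMS = ("gamma", "beta", "Wfc", "bfc")


class Adam:
    """Adam over a parameter dict (standard bias-corrected form).

    ``multipliers`` maps parameter names to per-layer learning-rate
    factors; unlisted parameters use the base rate.  Adam's per-parameter
    step is ~lr regardless of layer size, so without the reduced factor on
    the square d x d attention projections those ~750k parameters overrun
    (memorize) a single session's few hundred trials long before the rest
    of the network has learned the band-power rule.
    """

    def __init__(self, params: dict, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 multipliers: dict[str, float] | None = None):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.multipliers = multipliers or {}
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, gk in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gk * gk
            lr = self.lr * self.multipliers.get(k, 1.0)
            params[k] -= (
                lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            )


def group_multipliers(attention: float, embed: float, head: float) -> dict[str, float]:
    """Expand per-group factors into the per-parameter multiplier dict."""
    out: dict[str, float] = {}
    out.update({k: attention for k in ATTENTION_PARAMS})
    out.update({k: embed for k in EMBED_PARAMS})
    out.update({k: head for k in HEAD_PARAMS})
    return out
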