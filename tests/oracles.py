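"""Independent reference implementations used only by the tests.

These deliberately re-derive each quantity with a different method than the
production code: explicit per-vector loops following the attention and
convolution equations, a whitening-based simultaneous diagonalization for
CSP, and a direct counting rule for epoch assembly.
"""

import numpy as np


def elu(x):
    return x if x > 0 else np.expm1(x)


def loop_forward(S, params, cfg, upto="probs"):
    """Straight-line, loop-based forward pass for a single epoch (n_feat x d)."""
    n_feat, d = S.shape
    Wq, Wk, Wv = params["Wq"], params["Wk"], params["Wv"]
    act = elu if cfg.activation == "elu" else (lambda x: x)

    # spatial self-attention over the feature-channel time vectors
    q = [Wq @ S[i] for i in range(n_feat)]
    k = [Wk @ S[i] for i in range(n_feat)]
    v = [Wv @ S[i] for i in range(n_feat)]
    B = np.zeros_like(S)
    for i in range(n_feat):
        scores = np.array([np.dot(q[i], k[j]) / np.sqrt(d) for j in range(n_feat)])
        e = np.exp(scores - scores.max())
        alpha = e / e.sum()
        for j in range(n_feat):
            B[i] += alpha[j] * v[j]
    if upto == "spatial":
        return B

    # 1-D convolution per feature channel (valid, stride 1) + ELU
    L1 = d - cfg.k1 + 1
    A1 = np.zeros((cfg.n_f1, n_feat, L1))
    for f in range(cfg.n_f1):
        for c in range(n_feat):
            for t in range(L1):
                A1[f, c, t] = act(
                    np.dot(B[c, t : t + cfg.k1], params["w1"][f]) + params["b1"][f]
                )

    # 2-D convolution spanning all channels, time stride, + ELU
    P = (L1 - cfg.k2) // cfg.stride + 1
    patches = np.zeros((cfg.n_patch, P))
    for qf in range(cfg.n_patch):
        for p in range(P):
            acc = params["b2"][qf]
            for f in range(cfg.n_f1):
                for c in range(n_feat):
                    t0 = cfg.stride * p
                    acc += np.dot(
                        A1[f, c, t0 : t0 + cfg.k2], params["w2"][qf, f, c]
                    )
            patches[qf, p] = act(acc)
    if upto == "embed":
        return patches

    # temporal multi-head attention over consecutive patch pairs
    concat = np.zeros_like(patches)
    for h in range(cfg.heads):
        E = patches[2 * h : 2 * h + 2]
        Qh = params["WQ"][h] @ E
        Kh = params["WK"][h] @ E
        Vh = params["WV"][h] @ E
        for i in range(2):
            scores = np.array(
                [np.dot(Qh[i], Kh[j]) / np.sqrt(P) for j in range(2)]
            )
            e = np.exp(scores - scores.max())
            alpha = e / e.sum()
            for j in range(2):
                concat[2 * h + i] += alpha[j] * Vh[j]
    F = np.zeros_like(concat)
    for p in range(cfg.n_patch):
        for qf in range(cfg.n_patch):
            F[p] += params["Wo"][p, qf] * concat[qf]
    if upto == "mha":
        return F

    # head: average pooling, log compression, feature norm, affine, softmax
    pooled = np.array([F[p].mean() for p in range(cfg.n_patch)])
    if cfg.pool_transform == "log":
        pooled = np.array([np.log(max(v, 1e-6)) for v in pooled])
    xhat = (pooled - params["bn_mean"]) / np.sqrt(params["bn_var"] + 1e-5)
    y = params["gamma"] * xhat + params["beta"]
    logits = np.array(
        [np.dot(y, params["Wfc"][:, j]) + params["bfc"][j] for j in range(3)]
    )
    e = np.exp(logits - logits.max())
    return e / e.sum()


def whitened_csp(R1, R2):
    """Simultaneous diagonalization via explicit whitening of R2."""
    w2, V2 = np.linalg.eigh(R2)
    W = V2 @ np.diag(1.0 / np.sqrt(w2)) @ V2.T
    M = W @ R1 @ W
    M = (M + M.T) / 2
    w, U = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    P = W @ U[:, order]
    idx = np.argmax(np.abs(P), axis=0)
    signs = np.sign(P[idx, np.arange(P.shape[1])])
    signs[signs == 0] = 1
    return P * signs, w[order]


def count_expected_epochs(timeline, epoch_len_s, is_ao_mi):
    """Direct counting rule for epoch assembly (train count, MI count)."""
    from tstn_bci.synth import BLOCK_REST

    blocks = timeline.blocks
    train = mi = 0
    if is_ao_mi:
        for i in range(0, len(blocks) - 5, 6):
            group = blocks[i : i + 6]
            tasks = group[1::2]
            if any(b.duration + 1e-9 < epoch_len_s for b in tasks):
                continue
            train += 2  # the two AO+MI epochs
            mi += 1
            if group[0].kind == BLOCK_REST and group[0].duration + 1e-9 >= epoch_len_s:
                train += 1
    else:
        for i in range(0, len(blocks) - 1, 2):
            if blocks[i + 1].duration + 1e-9 >= epoch_len_s:
                train += 1
    return train, mi
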