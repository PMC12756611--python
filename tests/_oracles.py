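"""Straight-line NumPy transcriptions of the attention equations.

These are deliberately naive (explicit loops, per-pixel dot products, direct
formula evaluation in float64) and share no code with the package's layers;
they exist so the vectorized implementation can be checked against an
independent reading of the same equations.
"""

import math

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def gelu(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    flat_in, flat_out = x.ravel(), out.ravel()
    for i in range(flat_in.size):
        flat_out[i] = 0.5 * flat_in[i] * (1.0 + math.erf(flat_in[i] / math.sqrt(2.0)))
    return out


def softmax_vec(v):
    v = np.asarray(v, dtype=np.float64)
    e = np.exp(v - v.max())
    return e / e.sum()


def axial_pool(xg):
    """Per-height and per-width mean descriptors by explicit double loop."""
    xg = np.asarray(xg, dtype=np.float64)
    n, c, h, w = xg.shape
    x_h = np.zeros((n, c, h, 1))
    x_w = np.zeros((n, c, 1, w))
    for b in range(n):
        for ch in range(c):
            for i in range(h):
                x_h[b, ch, i, 0] = sum(xg[b, ch, i, j] for j in range(w)) / w
            for j in range(w):
                x_w[b, ch, 0, j] = sum(xg[b, ch, i, j] for i in range(h)) / h
    return x_h, x_w


def conv2d(x, weight, bias, stride=(1, 1), padding=(0, 0)):
    """Per-output-pixel sliding-window cross-correlation."""
    x = np.asarray(x, dtype=np.float64)
    weight = np.asarray(weight, dtype=np.float64)
    n, ci, h, w = x.shape
    co, _, kh, kw = weight.shape
    sh, sw = stride
    ph, pw = padding
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    out = np.zeros((n, co, ho, wo))
    for b in range(n):
        for o in range(co):
            for i in range(ho):
                for j in range(wo):
                    window = xp[b, :, i * sh:i * sh + kh, j * sw:j * sw + kw]
                    out[b, o, i, j] = np.sum(window * weight[o])
            if bias is not None:
                out[b, o] += float(bias[o])
    return out


def conv1x1_strip(strip, weight, bias, stride=1):
    """1x1 convolution along a (n, c, L, 1) strip as explicit matrix products."""
    strip = np.asarray(strip, dtype=np.float64)
    n, c, length, _ = strip.shape
    wmat = np.asarray(weight, dtype=np.float64).reshape(weight.shape[0], c)
    out_len = (length - 1) // stride + 1
    out = np.zeros((n, wmat.shape[0], out_len, 1))
    for b in range(n):
        for t in range(out_len):
            out[b, :, t, 0] = wmat @ strip[b, :, t * stride, 0]
            if bias is not None:
                out[b, :, t, 0] += np.asarray(bias, dtype=np.float64)
    return out


def upsample_strip(z, length, mode="nearest"):
    """Restore a (n, c, L', 1) strip to `length` samples."""
    z = np.asarray(z, dtype=np.float64)
    src = z.shape[2]
    out = np.zeros((z.shape[0], z.shape[1], length, 1))
    if mode == "nearest":
        for j in range(length):
            out[:, :, j, 0] = z[:, :, min((j * src) // length, src - 1), 0]
        return out
    raise NotImplementedError(mode)


def star_structure(x_h, x_w, weights, upsample="nearest"):
    """Strip concat -> stride-2 1x1 conv -> star product -> sigmoid -> upsample."""
    x_h = np.asarray(x_h, dtype=np.float64)
    x_w = np.asarray(x_w, dtype=np.float64)
    h, w = x_h.shape[2], x_w.shape[3]
    x_w_t = np.transpose(x_w, (0, 1, 3, 2))
    strip = np.concatenate([x_h, x_w_t], axis=2)           # (n, c, H+W, 1)
    z = conv1x1_strip(strip, weights["star.down.weight"],
                      weights["star.down.bias"], stride=2)
    a = conv1x1_strip(z, weights["star.proj_a.weight"], weights["star.proj_a.bias"])
    b = gelu(conv1x1_strip(z, weights["star.proj_b.weight"],
                           weights["star.proj_b.bias"]))
    gate = sigmoid(a * b)
    gate = upsample_strip(gate, h + w, upsample)
    gate_h = gate[:, :, :h, :]
    gate_w = np.transpose(gate[:, :, h:, :], (0, 1, 3, 2))
    return gate_h, gate_w


def ccib(xg, weights, use_sss=True, upsample="nearest"):
    """x1 = x_group * sig(x_h) * sig(x_w) * gate_h * gate_w, by explicit loops."""
    xg = np.asarray(xg, dtype=np.float64)
    n, c, h, w = xg.shape
    x_h, x_w = axial_pool(xg)
    if use_sss:
        gate_h, gate_w = star_structure(x_h, x_w, weights, upsample)
    x1 = np.zeros_like(xg)
    for b in range(n):
        for ch in range(c):
            for i in range(h):
                for j in range(w):
                    v = (xg[b, ch, i, j]
                         * sigmoid(x_h[b, ch, i, 0])
                         * sigmoid(x_w[b, ch, 0, j]))
                    if use_sss:
                        v *= gate_h[b, ch, i, 0] * gate_w[b, ch, 0, j]
                    x1[b, ch, i, j] = v
    return x1


def scb(xg, weights, kernels=(1, 5, 7)):
    x = np.asarray(xg, dtype=np.float64)
    for idx, k in enumerate(kernels):
        x = conv2d(x, weights[f"scb.convs.{idx}.weight"],
                   weights[f"scb.convs.{idx}.bias"], padding=(k // 2, k // 2))
    return gelu(x)


def group_norm_per_channel(x, gamma, beta, eps=1e-5):
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    out = np.zeros_like(x)
    for b in range(n):
        for ch in range(c):
            mu = x[b, ch].mean()
            var = ((x[b, ch] - mu) ** 2).mean()
            out[b, ch] = ((x[b, ch] - mu) / np.sqrt(var + eps)
                          * float(gamma[ch]) + float(beta[ch]))
    return out


def csfa(x1, x2, xg, weights, eps=1e-5):
    """Line-by-line scale fusion: softmax channel descriptors, two matrix
    products, sum, sigmoid gate on the grouped input."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    xg = np.asarray(xg, dtype=np.float64)
    n, c, h, w = x1.shape
    gn_x1 = group_norm_per_channel(x1, weights["gn.weight"], weights["gn.bias"], eps)
    out = np.zeros_like(xg)
    for b in range(n):
        pooled1 = np.array([gn_x1[b, ch].mean() for ch in range(c)])
        pooled2 = np.array([x2[b, ch].mean() for ch in range(c)])
        x11 = softmax_vec(pooled1)
        x22 = softmax_vec(pooled2)
        x12 = np.zeros((h, w))
        x21 = np.zeros((h, w))
        for i in range(h):
            for j in range(w):
                x12[i, j] = sum(x11[ch] * x2[b, ch, i, j] for ch in range(c))
                x21[i, j] = sum(x22[ch] * x1[b, ch, i, j] for ch in range(c))
        weight = x12 + x21
        for ch in range(c):
            out[b, ch] = sigmoid(weight) * xg[b, ch]
    return out


def starma(module, x):
    """End-to-end oracle for a StarMA block, driven by the module's weights."""
    x = np.asarray(x, dtype=np.float64)
    weights = {k: np.asarray(v, dtype=np.float64)
               for k, v in module.state_dict().items()}
    g = module.cfg.groups
    b, c, h, w = x.shape
    xg = x.reshape(b * g, c // g, h, w)
    x1 = ccib(xg, weights, use_sss=module.use_sss,
              upsample=module.cfg.star_upsample) if module.use_ccib else None
    x2 = scb(xg, weights, module.cfg.scb_kernels) if module.use_scb else None
    if module.use_csfa:
        out = csfa(x1, x2, xg, weights)
    elif x1 is not None and x2 is not None:
        out = sigmoid(x1 + x2) * xg
    elif x1 is not None:
        out = sigmoid(x1) * xg
    else:
        n, cp = x2.shape[0], x2.shape[1]
        out = np.zeros_like(xg)
        for bb in range(n):
            x22 = softmax_vec([x2[bb, ch].mean() for ch in range(cp)])
            wmap = sum(x22[ch] * x2[bb, ch] for ch in range(cp))
            for ch in range(cp):
                out[bb, ch] = sigmoid(wmap) * xg[bb, ch]
    return out.reshape(b, c, h, w)
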