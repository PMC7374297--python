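"""Independent loop-based reference implementations used as test oracles.

Deliberately naive (explicit scalar loops, no vectorization) and kept
separate from the package so they cannot share bugs with it.
"""

import numpy as np


def pool_mean_of_pairs(channel):
    """Average pooling with kernel 2, stride 2 on one channel."""
    out = []
    for i in range(0, len(channel) - 1, 2):
        out.append((channel[i] + channel[i + 1]) / 2.0)
    return np.array(out)


def upsample_repeat(channel):
    """Nearest-neighbour doubling: out[t] = in[t // 2]."""
    return np.array([channel[t // 2] for t in range(2 * len(channel))])


def conv1d_loops(x, weights, bias=None):
    """Triple-loop stride-1 same-length cross-correlation.

    x: (c_in, l); weights: (c_out, c_in, k); zero padding (k//2-1, k//2)
    for even k, symmetric for odd k.
    """
    c_out, c_in, k = weights.shape
    _, l = x.shape
    pl = k // 2 - 1 if k % 2 == 0 else k // 2
    y = np.zeros((c_out, l))
    for o in range(c_out):
        for t in range(l):
            acc = 0.0
            for c in range(c_in):
                for j in range(k):
                    src = t + j - pl
                    if 0 <= src < l:
                        acc += weights[o, c, j] * x[c, src]
            y[o, t] = acc + (bias[o] if bias is not None else 0.0)
    return y


def octconv_loops(x_high, x_low, layer):
    """Direct transcription of the octave-convolution update built from the
    loop-based conv/pool/upsample oracles.

    Y_high = conv(X_high; W_hh) + upsample(conv(X_low; W_lh))
    Y_low  = conv(X_low; W_ll) + conv(pool(X_high); W_hl)
    """
    y_high = y_low = None
    if layer.w_hh.shape[0] > 0:  # high output exists
        terms = []
        if x_high is not None and layer.w_hh.size:
            terms.append(conv1d_loops(x_high, layer.w_hh))
        if x_low is not None and layer.w_lh.size:
            conv_low = conv1d_loops(x_low, layer.w_lh)
            terms.append(np.stack([upsample_repeat(ch) for ch in conv_low]))
        y_high = sum(terms) + layer.bias_high[:, None]
    if layer.w_ll.shape[0] > 0:  # low output exists
        terms = []
        if x_low is not None and layer.w_ll.size:
            terms.append(conv1d_loops(x_low, layer.w_ll))
        if x_high is not None and layer.w_hl.size:
            pooled = np.stack([pool_mean_of_pairs(ch) for ch in x_high])
            terms.append(conv1d_loops(pooled, layer.w_hl))
        y_low = sum(terms) + layer.bias_low[:, None]
    return y_high, y_low


def conv_mac_count(x, weights):
    """Count multiply-accumulates actually executed by the loop oracle,
    including multiplications against zero padding (the analytic
    convention counts l*k*c_in*c_out)."""
    c_out, c_in, k = weights.shape
    _, l = x.shape
    return l * k * c_in * c_out


def gru_step_scalar(x_t, h_prev, w_x, w_h, bias):
    """Scalar-loop GRU update with reset/update gates and the reset gate
    applied inside the recurrent candidate term."""
    hd = len(h_prev)
    d = len(x_t)

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    def mat_vec(m, v, col0, col1):
        out = np.zeros(col1 - col0)
        for i in range(m.shape[0]):
            for j in range(col0, col1):
                out[j - col0] += m[i, j] * v[i]
        return out

    a = np.zeros(3 * hd)
    for j in range(3 * hd):
        for i in range(d):
            a[j] += w_x[i, j] * x_t[i]
        a[j] += bias[j]
    r = sig(a[:hd] + mat_vec(w_h, h_prev, 0, hd))
    z = sig(a[hd : 2 * hd] + mat_vec(w_h, h_prev, hd, 2 * hd))
    cand = np.tanh(a[2 * hd :] + mat_vec(w_h, r * h_prev, 2 * hd, 3 * hd))
    h = np.zeros(hd)
    for i in range(hd):
        h[i] = (1.0 - z[i]) * h_prev[i] + z[i] * cand[i]
    return h


def weighted_bce_loops(probs, labels, beta):
    """Double-loop weighted binary cross entropy: mean over samples of the
    summed per-frame terms -(beta*y*log(p) + (1-y)*log(1-p))."""
    m, t = probs.shape
    total = 0.0
    for i in range(m):
        for j in range(t):
            p = min(max(probs[i, j], 1e-7), 1 - 1e-7)
            y = labels[i, j]
            total += -(beta * y * np.log(p) + (1 - y) * np.log(1 - p))
    return total / m


def segment_means_loops(features, n_segments):
    """Loop-based per-segment time mean; features (c, l) -> (n, c)."""
    c, l = features.shape
    m = l // n_segments
    out = np.zeros((n_segments, c))
    for s in range(n_segments):
        for ch in range(c):
            acc = 0.0
            for t in range(s * m, (s + 1) * m):
                acc += features[ch, t]
            out[s, ch] = acc / m
    return out
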