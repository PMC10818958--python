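"""Independent brute-force reference implementations for the estimators.

Everything here is written as direct loops over the defining sums (GC via
explicitly assembled normal equations), deliberately ignoring the
vectorized formulations in the package, so the two routes can be compared
numerically.
"""

import math

import numpy as np


def plv_brute(x1, x2):
    n = len(x1)
    acc = 0j
    for k in range(n):
        acc += np.exp(1j * (np.angle(x1[k]) - np.angle(x2[k])))
    return abs(acc / n)


def wpli_brute(x1, x2):
    num = 0.0
    den = 0.0
    for k in range(len(x1)):
        im = (x1[k] * np.conj(x2[k])).imag
        num += im
        den += abs(im)
    return abs(num) / den if den > 0 else 0.0


def cpcc_brute(x1, x2):
    num = 0j
    e1 = e2 = 0.0
    for k in range(len(x1)):
        num += x1[k] * np.conj(x2[k])
        e1 += abs(x1[k]) ** 2
        e2 += abs(x2[k]) ** 2
    return num / math.sqrt(e1 * e2)


def entropy_brute(counts):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def mi_brute(a1, a2):
    """Plug-in histogram MI on amplitudes, bins = ceil(sqrt(N/5))."""
    n = len(a1)
    nb = math.ceil(math.sqrt(n / 5))
    joint, _, _ = np.histogram2d(a1, a2, bins=nb)
    hx = entropy_brute(joint.sum(axis=1))
    hy = entropy_brute(joint.sum(axis=0))
    hxy = entropy_brute(joint.ravel())
    return max(hx + hy - hxy, 0.0)


def _ar_rss(design_rows, y):
    """OLS residual sum of squares via explicit normal equations."""
    d = np.asarray(design_rows)
    g = d @ d.T
    b = d @ y
    beta = np.linalg.solve(g, b)
    resid = y - d.T @ beta
    return float(resid @ resid)


def gc_brute(x, y, order):
    """(gc_xy, gc_yx) from explicitly assembled lag matrices."""
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    n = len(x)

    def lags(sig):
        return [sig[order - l : n - l] for l in range(1, order + 1)]

    out = []
    for src, tgt in ((x, y), (y, x)):
        tgt_future = tgt[order:]
        rss_uni = _ar_rss(lags(tgt), tgt_future)
        rss_biv = _ar_rss(lags(tgt) + lags(src), tgt_future)
        out.append(max(math.log(rss_uni / rss_biv), 0.0))
    return tuple(out)
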