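"""Independent reference implementations used as test oracles.

These are deliberately written with explicit element-wise loops, straight
from the printed update rules, and share no code with the package.
"""

import math

import numpy as np


def pma_brute(X, y, a):
    """Loop-level transcription of the supervised principal-motion fit.

    Returns (scores k x a, loadings a x m, coeffs a, y_mean).
    """
    X = [list(map(float, row)) for row in X]
    y = [float(v) for v in y]
    k, m = len(X), len(X[0])
    y_mean = sum(y) / k
    yc = [v - y_mean for v in y]

    Xn = [row[:] for row in X]
    yn = yc[:]
    scores, loadings, coeffs = [], [], []
    for _ in range(a):
        # w = Xn^T yn, normalised
        w = [sum(Xn[i][j] * yn[i] for i in range(k)) for j in range(m)]
        nw = math.sqrt(sum(v * v for v in w))
        w = [v / nw for v in w]
        # s = Xn w
        s = [sum(Xn[i][j] * w[j] for j in range(m)) for i in range(k)]
        ss = sum(v * v for v in s)
        # p = Xn^T s / (s^T s)
        p = [sum(Xn[i][j] * s[i] for i in range(k)) / ss for j in range(m)]
        # q from the *undeflated* (centred) target
        q = sum(yc[i] * s[i] for i in range(k)) / ss
        scores.append(s)
        loadings.append(p)
        coeffs.append(q)
        # deflation
        for i in range(k):
            for j in range(m):
                Xn[i][j] -= s[i] * p[j]
            yn[i] -= q * s[i]
    return (np.array(scores).T, np.array(loadings), np.array(coeffs), y_mean)


def pma_brute_predict(loadings, coeffs, y_mean, X_new):
    """Single projection of undeflated rows onto the loadings."""
    X_new = np.asarray(X_new, dtype=float)
    out = []
    for row in X_new:
        yhat = y_mean
        for p, q in zip(loadings, coeffs):
            yhat += q * float(row @ p)
        out.append(yhat)
    return np.array(out)


def pearson_brute(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm @ ym) / math.sqrt((xm @ xm) * (ym @ ym)))


def butterworth_filtfilt_gain(f, cutoff, order):
    """Analytic amplitude gain of a forward-backward Butterworth filter."""
    return 1.0 / (1.0 + (f / cutoff) ** (2 * order))
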