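"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the library's own code paths: the Wiener oracle
evaluates the local-statistics filter pixel by pixel with explicit
windows, and the structure-tensor oracle performs the literal weighted
sums of squared Gaussian-derivative responses against a sampled 2-D
Gaussian window.
"""

import numpy as np


def wiener_oracle(img: np.ndarray, wh: int, wv: int, a2: float) -> np.ndarray:
    """Per-pixel local mean/variance (symmetric padding) and adaptive gain."""
    ph, pw = wv // 2, wh // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.empty_like(img, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            win = padded[r: r + wv, c: c + wh]
            m = win.mean()
            s2 = (win ** 2).mean() - m ** 2
            if s2 <= 0:
                out[r, c] = m
            else:
                out[r, c] = m + max(s2 - a2, 0.0) / s2 * (img[r, c] - m)
    return out


def gauss1d(sigma: float, order: int = 0, truncate: float = 4.0):
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    g = np.exp(-0.5 * x ** 2 / sigma ** 2)
    g /= g.sum()
    if order == 0:
        return g, r
    return (x / sigma ** 2) * g, r  # correlation convention


def correlate2d_separable(img, krow, kcol, rr, rc):
    pad = np.pad(img, ((rr, rr), (rc, rc)), mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            acc = 0.0
            for u in range(-rr, rr + 1):
                for v in range(-rc, rc + 1):
                    acc += krow[u + rr] * kcol[v + rc] * pad[i + rr + u, j + rc + v]
            out[i, j] = acc
    return out


def structure_tensor_oracle(img, sigma_d, sigma_w):
    """Literal evaluation: derivative responses, then windowed double sums."""
    g0d, rd = gauss1d(sigma_d, 0)
    g1d, _ = gauss1d(sigma_d, 1)
    phi_x = correlate2d_separable(img, g0d, g1d, rd, rd)
    phi_y = correlate2d_separable(img, g1d, g0d, rd, rd)
    g0w, rw = gauss1d(sigma_w, 0)
    txx = correlate2d_separable(phi_x * phi_x, g0w, g0w, rw, rw)
    tyy = correlate2d_separable(phi_y * phi_y, g0w, g0w, rw, rw)
    txy = correlate2d_separable(phi_x * phi_y, g0w, g0w, rw, rw)
    return txx, tyy, txy


def naive_bayes_posterior_oracle(model, query: np.ndarray) -> np.ndarray:
    """Direct Bayes rule with per-feature Gaussian likelihoods."""
    def gauss(v, mu, var):
        return np.exp(-((v - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)

    out = np.empty((len(query), model.priors.size))
    for i, q in enumerate(query):
        joint = []
        for k in range(model.priors.size):
            lik = np.prod([gauss(q[j], model.means[k, j], model.variances[k, j])
                           for j in range(q.size)])
            joint.append(model.priors[k] * lik)
        joint = np.asarray(joint)
        out[i] = joint / joint.sum()
    return out
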