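"""Brute-force reference implementations used to validate the fast paths.

Every oracle is written as direct per-pixel loops from the operation's
definition and stays independent of the package's vectorized code.
"""

from __future__ import annotations

import numpy as np


def brute_mean(img: np.ndarray, w: int) -> np.ndarray:
    r = w // 2
    pad = np.pad(img, r, mode="symmetric")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = pad[i : i + w, j : j + w].mean()
    return out


def brute_median(img: np.ndarray, w: int) -> np.ndarray:
    r = w // 2
    pad = np.pad(img, r, mode="symmetric")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(pad[i : i + w, j : j + w])
    return out


def brute_lee(img: np.ndarray, w: int) -> np.ndarray:
    r = w // 2
    pad = np.pad(img, r, mode="symmetric")
    m = np.empty_like(img, dtype=float)
    v = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = pad[i : i + w, j : j + w]
            m[i, j] = win.mean()
            v[i, j] = max((win * win).mean() - win.mean() ** 2, 0.0)
    sigma2 = v.mean()
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            k = max(0.0, v[i, j] - sigma2) / v[i, j] if v[i, j] > 0 else 0.0
            out[i, j] = m[i, j] + k * (img[i, j] - m[i, j])
    return out


def brute_nlm(img: np.ndarray, patch: int, search: int, h: float) -> np.ndarray:
    ps, ss = patch // 2, search // 2
    pad = np.pad(img, ss + ps, mode="symmetric")
    off = ss + ps
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            num = 0.0
            den = 0.0
            for di in range(-ss, ss + 1):
                for dj in range(-ss, ss + 1):
                    d2 = 0.0
                    for u in range(-ps, ps + 1):
                        for v in range(-ps, ps + 1):
                            a = pad[off + i + u, off + j + v]
                            b = pad[off + i + di + u, off + j + dj + v]
                            d2 += (a - b) ** 2
                    wgt = np.exp(-d2 / (h * h))
                    num += wgt * pad[off + i + di, off + j + dj]
                    den += wgt
            out[i, j] = num / den
    return out


def brute_lbp(img: np.ndarray, P: int, R: int, variant: str = "ri") -> np.ndarray:
    """Per-pixel LBP labels with -1 on the width-R border.

    Circle sampling at angles 2*pi*k/P (dr = -R sin, dc = R cos, rounded
    to 1e-5), bilinear interpolation, ties (neighbor == center) count 1.
    riu2: uniform codes -> popcount, others -> P+1.  u2: all-zeros -> 0,
    all-ones -> 1, run of n ones starting at k -> 2 + (n-1)P + k,
    non-uniform -> P(P-1)+2.
    """
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    out = np.full((rows, cols), -1, dtype=np.int64)
    for i in range(R, rows - R):
        for j in range(R, cols - R):
            bits = []
            for k in range(P):
                dr = round(-R * np.sin(2 * np.pi * k / P), 5)
                dc = round(R * np.cos(2 * np.pi * k / P), 5)
                r0, c0 = int(np.floor(dr)), int(np.floor(dc))
                fr, fc = dr - r0, dc - c0
                if abs(fr) < 1e-8 and abs(fc) < 1e-8:
                    val = img[i + r0, j + c0]
                else:
                    val = (
                        (1 - fr) * (1 - fc) * img[i + r0, j + c0]
                        + (1 - fr) * fc * img[i + r0, j + c0 + 1]
                        + fr * (1 - fc) * img[i + r0 + 1, j + c0]
                        + fr * fc * img[i + r0 + 1, j + c0 + 1]
                    )
                bits.append(1 if val >= img[i, j] else 0)
            trans = sum(bits[k] != bits[(k + 1) % P] for k in range(P))
            ones = sum(bits)
            if variant == "ri":
                out[i, j] = ones if trans <= 2 else P + 1
            else:
                if trans > 2:
                    out[i, j] = P * (P - 1) + 2
                elif ones == 0:
                    out[i, j] = 0
                elif ones == P:
                    out[i, j] = 1
                else:
                    start = next(k for k in range(P) if bits[k] == 1 and bits[k - 1] == 0)
                    out[i, j] = 2 + (ones - 1) * P + start
    return out


def pca_eig_oracle(X: np.ndarray, n_components: int):
    """Principal axes/variances from the covariance eigendecomposition."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    return vals[order], vecs[:, order].T
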