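"""Speckle-reduction filters, a plug-in denoiser interface and PSNR evaluation.

Implemented filters: mean, median, Lee (local-statistics), wavelet
hard/soft thresholding, and non-local means (NLM).  All filters are
shape-preserving and use reflect (half-sample symmetric) border
handling.  External denoisers plug in as callables through
:class:`DenoiserSpec`; NLM is the pipeline default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt
from scipy import ndimage


def _check_window(w: int) -> None:
    if w < 3 or w % 2 == 0:
        raise ValueError(f"window size must be odd and >= 3, got {w}")


def mean_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """w x w sliding-window mean, reflect-padded borders."""
    _check_window(window)
    return ndimage.uniform_filter(np.asarray(img, dtype=float), size=window, mode="reflect")


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """w x w sliding-window median, reflect-padded borders."""
    _check_window(window)
    return ndimage.median_filter(np.asarray(img, dtype=float), size=window, mode="reflect")


def lee_filter(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Lee local-statistics filter.

    out = m + k (img - m) with local mean m and variance v over the
    w x w window; the noise variance sigma^2 is estimated as the image
    mean of the local variances and the gain is
    k = max(0, v - sigma^2) / v (k = 0 where v = 0), so flat regions
    collapse to their local mean while strong edges are preserved.
    """
    _check_window(window)
    img = np.asarray(img, dtype=float)
    m = ndimage.uniform_filter(img, size=window, mode="reflect")
    m2 = ndimage.uniform_filter(img * img, size=window, mode="reflect")
    v = np.maximum(m2 - m * m, 0.0)
    sigma2 = v.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(v > 0, np.maximum(v - sigma2, 0.0) / v, 0.0)
    return m + k * (img - m)


def wavelet_threshold(
    img: np.ndarray,
    mode: str = "soft",
    t: float | None = None,
    levels: int = 2,
    wavelet: str = "db2",
) -> np.ndarray:
    """Orthogonal wavelet shrinkage of the detail subbands.

    HARD: c -> c * 1[|c| > t]; SOFT: c -> sign(c) * max(|c| - t, 0).
    The approximation band is untouched.  When ``t`` is None the
    universal threshold sigma * sqrt(2 ln N) is used, with sigma from
    the median absolute deviation of the finest diagonal subband.
    """
    mode = mode.lower()
    if mode not in ("hard", "soft"):
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")
    if t is not None and t < 0:
        raise ValueError("threshold t must be >= 0")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    img = np.asarray(img, dtype=float)
    coeffs = pywt.wavedec2(img, wavelet, mode="symmetric", level=levels)
    if t is None:
        sigma = np.median(np.abs(coeffs[-1][2])) / 0.6745
        t = sigma * np.sqrt(2.0 * np.log(img.size))
    def _shrink(d: np.ndarray) -> np.ndarray:
        if mode == "hard":
            return d * (np.abs(d) > t)
        return np.sign(d) * np.maximum(np.abs(d) - t, 0.0)

    out = [coeffs[0]]
    for detail in coeffs[1:]:
        out.append(tuple(_shrink(d) for d in detail))
    rec = pywt.waverec2(out, wavelet, mode="symmetric")
    return rec[: img.shape[0], : img.shape[1]]


def _nlm_pad(img: np.ndarray, patch: int, search: int) -> np.ndarray:
    pad = search // 2 + patch // 2
    return np.pad(img, pad, mode="symmetric")


def nlm_filter(
    img: np.ndarray, patch: int = 5, search: int = 11, h: float = 0.6
) -> np.ndarray:
    """Non-local means with Gaussian-of-distance weights.

    out(i) = sum_j w(i,j) img(j) / sum_j w(i,j) over the s x s search
    window around i, with w(i,j) = exp(-||patch_i - patch_j||^2 / h^2),
    patch distances being plain sums of squared differences over p x p
    patches on the reflect-padded image.  Vectorized over search offsets
    with box filters, so cost is O(s^2) filter passes.
    """
    if patch % 2 == 0 or search % 2 == 0:
        raise ValueError("patch and search sizes must be odd")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    ps, ss = patch // 2, search // 2
    padded = _nlm_pad(img, patch, search)
    base = padded[ss : ss + rows + 2 * ps, ss : ss + cols + 2 * ps]  # patch-padded center
    num = np.zeros((rows, cols))
    den = np.zeros((rows, cols))
    p2 = patch * patch
    for dr in range(-ss, ss + 1):
        for dc in range(-ss, ss + 1):
            shifted = padded[
                ss + dr : ss + dr + rows + 2 * ps, ss + dc : ss + dc + cols + 2 * ps
            ]
            diff2 = (base - shifted) ** 2
            # sum over the p x p patch = p^2 * box mean
            d = p2 * ndimage.uniform_filter(diff2, size=patch, mode="constant")[
                ps : ps + rows, ps : ps + cols
            ]
            w = np.exp(-d / (h * h))
            num += w * shifted[ps : ps + rows, ps : ps + cols]
            den += w
    return num / den


def psnr(ref: np.ndarray, test: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE) in dB; +inf when identical."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {test.shape}")
    if peak is None:
        peak = 255.0 if ref.max() > 1.0 else 1.0
    mse = np.mean((ref - test) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / mse))


@dataclass
class DenoiserSpec:
    """Named denoiser plus parameters; ``plugin`` accepts any image->image callable."""

    name: str = "nlm"
    params: dict = field(default_factory=dict)
    plugin: Callable[[np.ndarray], np.ndarray] | None = None

    def build(self) -> Callable[[np.ndarray], np.ndarray]:
        return get_denoiser(self.name, plugin=self.plugin, **self.params)


_REGISTRY: dict[str, Callable] = {
    "mean": mean_filter,
    "median": median_filter,
    "lee": lee_filter,
    "wavelet_hard": lambda img, **kw: wavelet_threshold(img, mode="hard", **kw),
    "wavelet_soft": lambda img, **kw: wavelet_threshold(img, mode="soft", **kw),
    "nlm": nlm_filter,
    "identity": lambda img, **kw: np.asarray(img, dtype=float),
}


def get_denoiser(
    name: str, plugin: Callable[[np.ndarray], np.ndarray] | None = None, **params
) -> Callable[[np.ndarray], np.ndarray]:
    """Resolve a denoiser name to an image -> image callable with bound parameters."""
    name = name.lower()
    if name == "plugin":
        if plugin is None:
            raise ValueError("plugin denoiser requires a callable")
        return plugin
    if name not in _REGISTRY:
        raise ValueError(f"unknown denoiser {name!r}; choose from {sorted(_REGISTRY)} or 'plugin'")
    fn = _REGISTRY[name]
    return lambda img: fn(img, **params)


def benchmark_denoisers(
    clean_images: list[np.ndarray],
    looks: float,
    specs: list[DenoiserSpec],
    seeds: list[int],
    peak: float = 1.0,
):
    """Mean PSNR per denoiser over speckled realizations of the clean images.

    Adds L-look gamma speckle to every clean image for every seed,
    denoises, and averages PSNR against the clean reference; a ``noisy``
    row records the un-denoised baseline.  Deterministic given seeds.
    """
    import pandas as pd

    from .phantom import add_speckle

    if not clean_images or not seeds:
        raise ValueError("need at least one image and one seed")
    rows = []
    noisy_psnrs = []
    realizations = []
    for img in clean_images:
        for seed in seeds:
            noisy = add_speckle(np.asarray(img, dtype=float), looks, seed=seed)
            realizations.append((img, noisy))
            noisy_psnrs.append(psnr(img, noisy, peak))
    rows.append({"denoiser": "noisy", "mean_psnr_db": float(np.mean(noisy_psnrs))})
    for spec in specs:
        fn = spec.build()
        vals = [psnr(img, fn(noisy), peak) for img, noisy in realizations]
        rows.append({"denoiser": spec.name, "mean_psnr_db": float(np.mean(vals))})
    return pd.DataFrame(rows)
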