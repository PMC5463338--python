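"""RPE localization, RANSAC quadratic fitting, flattening and cropping.

The retinal pigment epithelium (RPE) is the brightest deep band in a
denoised B-scan.  Each column's candidate RPE row is the argmax of a
depth-smoothed intensity profile; a quadratic is fitted to the
candidates with RANSAC to reject columns where vessels or lesions
displace the maximum.  Columns are then shifted by integer amounts so
the RPE lies on one common row (the deepest predicted row), and a fixed
anatomical window is cut around it: 325 px above, 30 px below and a
340 px centered lateral strip by default, giving 356 x 340 B-scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import CropGeometry, PipelineConfig
from .denoise import get_denoiser
from .io import OCTVolume

logger = logging.getLogger(__name__)


class DetectionError(RuntimeError):
    """No usable RPE candidates could be extracted."""


@dataclass
class RPEModel:
    """Quadratic RPE row model: row(x) = a x^2 + b x + c."""

    coeffs: tuple[float, float, float]
    inlier_mask: np.ndarray | None = None
    inlier_fraction: float = 1.0

    def predict(self, x: np.ndarray | float) -> np.ndarray:
        a, b, c = self.coeffs
        xx = np.asarray(x, dtype=float)
        return a * xx**2 + b * xx + c

    def __call__(self, x):
        return self.predict(x)


def detect_rpe_candidates(
    img: np.ndarray, smooth_sigma: float = 3.0, min_rel: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (x, row) RPE candidates.

    Each column's profile is Gaussian-smoothed along depth
    (sigma = 3 px) and the argmax row taken; columns whose maximum
    falls below ``min_rel`` of the image maximum are dropped as missing.
    """
    img = np.asarray(img, dtype=float)
    smoothed = ndimage.gaussian_filter1d(img, sigma=smooth_sigma, axis=0, mode="reflect")
    rows = np.argmax(smoothed, axis=0)
    peak = smoothed[rows, np.arange(img.shape[1])]
    valid = peak >= min_rel * smoothed.max() if smoothed.max() > 0 else np.zeros(img.shape[1], bool)
    if not valid.any():
        raise DetectionError("no RPE candidates: all column maxima below threshold")
    x = np.nonzero(valid)[0]
    return x, rows[valid]


def ransac_quadratic(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int = 500,
    inlier_tol: float = 3.0,
    seed: int | None = 0,
) -> RPEModel:
    """Robust quadratic fit y = a x^2 + b x + c by random sample consensus.

    Repeats ``n_iter`` times: draw 3 points, fit the interpolating
    quadratic, count points within ``inlier_tol`` rows.  The consensus
    set with the most inliers wins (ties broken by lower inlier squared
    error); the returned model is the least-squares quadratic on that
    set.  Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"RANSAC needs >= 3 points, got {n}")
    rng = np.random.default_rng(seed)

    if n == 3:
        coeffs = np.polyfit(x, y, 2)
        return RPEModel(tuple(coeffs), np.ones(3, bool), 1.0)

    # 3 distinct indices per iteration, vectorized
    idx = np.argpartition(rng.random((n_iter, n)), 3, axis=1)[:, :3]
    xs = x[idx]  # (n_iter, 3)
    ys = y[idx]
    # discard degenerate samples (duplicate x) by zeroing their inlier count
    ok = (xs[:, 0] != xs[:, 1]) & (xs[:, 0] != xs[:, 2]) & (xs[:, 1] != xs[:, 2])
    vander = np.stack([xs**2, xs, np.ones_like(xs)], axis=-1)  # (n_iter, 3, 3)
    vander[~ok] = np.eye(3)  # placeholder, masked out below
    coeffs = np.linalg.solve(vander, ys[:, :, None])[:, :, 0]  # (n_iter, 3)
    pred = coeffs @ np.stack([x**2, x, np.ones_like(x)])  # (n_iter, n)
    resid2 = (pred - y) ** 2
    inliers = resid2 <= inlier_tol**2
    counts = inliers.sum(axis=1)
    counts[~ok] = -1
    best_count = counts.max()
    if best_count < 3:
        raise ValueError("RANSAC failed: no sample produced a consensus set")
    tied = np.nonzero(counts == best_count)[0]
    errs = np.where(inliers[tied], resid2[tied], 0.0).sum(axis=1)
    best = tied[np.argmin(errs)]
    mask = inliers[best]
    final = np.polyfit(x[mask], y[mask], 2)
    return RPEModel(tuple(final), mask, float(mask.mean()))


def flatten(img: np.ndarray, model: RPEModel) -> np.ndarray:
    """Shift each column by an integer so the RPE lies on one common row.

    The reference row is the deepest (largest) predicted RPE row;
    columns move down by ``round(max model) - round(model(x))`` and
    vacated pixels are filled with 0.  Shape is preserved.
    """
    img = np.asarray(img)
    rows, cols = img.shape
    x = np.arange(cols)
    pred = model.predict(x)
    outside = (pred < 0) | (pred >= rows)
    if outside.mean() > 0.5:
        raise ValueError("RPE model predicts outside the image for most columns")
    ref = int(np.round(pred.max()))
    shifts = ref - np.round(pred).astype(int)  # >= 0
    out = np.zeros_like(img)
    for s in np.unique(shifts):
        cols_s = np.nonzero(shifts == s)[0]
        if s == 0:
            out[:, cols_s] = img[:, cols_s]
        elif 0 < s < rows:
            out[s:, cols_s] = img[: rows - s, cols_s]
    return out


def crop(img: np.ndarray, rpe_row: int, geom: CropGeometry | None = None) -> np.ndarray:
    """Cut the anatomical window around the flattened RPE row.

    Output rows span ``rpe_row - rows_above .. rpe_row + rows_below``
    inclusive; the lateral strip of ``lateral_width`` columns is
    centered (left edge floor((cols - width) / 2)).  Rows outside the
    source image are zero-padded (logged).
    """
    if geom is None:
        geom = CropGeometry()
    img = np.asarray(img)
    rows, cols = img.shape
    if geom.lateral_width > cols:
        raise ValueError(f"lateral_width {geom.lateral_width} exceeds image width {cols}")
    left = (cols - geom.lateral_width) // 2
    top = rpe_row - geom.rows_above
    bottom = rpe_row + geom.rows_below + 1
    out = np.zeros((geom.out_rows, geom.lateral_width), dtype=img.dtype)
    src_top = max(top, 0)
    src_bottom = min(bottom, rows)
    if src_top >= src_bottom:
        raise ValueError("crop window lies entirely outside the image")
    if top < 0 or bottom > rows:
        logger.info("crop window exceeds image: rows [%d, %d) of %d, zero-padding", top, bottom, rows)
    out[src_top - top : src_bottom - top] = img[src_top:src_bottom, left : left + geom.lateral_width]
    return out


def preprocess_bscan(
    img: np.ndarray,
    denoiser=None,
    geom: CropGeometry | None = None,
    n_iter: int = 500,
    inlier_tol: float = 3.0,
    seed: int | None = 0,
    return_stages: bool = False,
):
    """Denoise -> RPE detection -> RANSAC fit -> flatten -> crop for one B-scan."""
    img = np.asarray(img, dtype=float)
    den = denoiser(img) if denoiser is not None else img
    x, rows = detect_rpe_candidates(den)
    model = ransac_quadratic(x, rows, n_iter=n_iter, inlier_tol=inlier_tol, seed=seed)
    flat = flatten(den, model)
    rpe_row = int(np.round(model.predict(np.arange(img.shape[1])).max()))
    cropped = crop(flat, rpe_row, geom)
    if return_stages:
        return cropped, {"denoised": den, "model": model, "flattened": flat, "rpe_row": rpe_row}
    return cropped


def preprocess_volume(vol: OCTVolume, config: PipelineConfig | None = None) -> OCTVolume:
    """Apply the full preprocessing chain to every B-scan of a volume."""
    if config is None:
        config = PipelineConfig()
    denoiser = get_denoiser(config.denoiser, **config.denoiser_params)
    scans = np.asarray(vol.scans, dtype=float)
    if scans.max() > 1.0:  # 8/16-bit input -> [0, 1]
        scans = scans / float(vol.intensity_range[1])
    out = np.empty((vol.n_scans, config.crop.out_rows, config.crop.lateral_width), dtype=np.float32)
    for i in range(vol.n_scans):
        out[i] = np.clip(preprocess_bscan(
            scans[i],
            denoiser=denoiser,
            geom=config.crop,
            n_iter=config.ransac_iters,
            inlier_tol=config.ransac_tol,
            seed=config.seed + i,
        ), 0.0, 1.0)
    return OCTVolume(
        scans=out,
        patient_id=vol.patient_id,
        label=vol.label,
        intensity_range=(0.0, 1.0),
    )
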