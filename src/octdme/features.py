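"""Multiresolution LBP and HoG descriptors.

A 4-level Gaussian pyramid (5-tap binomial smoothing, floor-halving
decimation) feeds two texture descriptors:

* Rotation-invariant uniform (riu2) and uniform (u2) local binary
  patterns at (P, R) in {(8,1), (16,2), (24,3)}, histogrammed over a
  per-level grid of non-overlapping patches (default 3x3 / 2x2 / 2x2 /
  1x1 = 18 patches) and L1-normalized per patch.  On the default
  356 x 340 cropped geometry this yields per-B-scan vectors of length
  180 / 324 / 468 for riu2 at P = 8 / 16 / 24.
* Histogram of oriented gradients with 4 x 4 px cells, 2 x 2-cell
  blocks at 1-cell stride, 9 unsigned orientation bins and per-block L2
  normalization, for a 347,940-long 4-level vector on 356 x 340 input.

Descriptor lengths are available in closed form via
:func:`descriptor_length` and checked against the extracted vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_PARTITION = ((3, 3), (2, 2), (2, 2), (1, 1))
_VALID_PR = ((8, 1), (16, 2), (24, 3))


@dataclass
class DescriptorConfig:
    """Descriptor choice and geometry for per-B-scan feature extraction."""

    kind: str = "lbp-ri"  # lbp-ri | lbp-nri | hog
    points: int = 16
    radius: int = 2
    levels: int = 4
    partition: tuple[tuple[int, int], ...] = DEFAULT_PARTITION
    patch_mode: str = "grid"  # grid | tiles32 (literal 32 px tiling)
    hog_cell: int = 4
    hog_block: int = 2
    hog_bins: int = 9

    def __post_init__(self) -> None:
        if self.kind not in ("lbp-ri", "lbp-nri", "hog"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.kind != "hog" and (self.points, self.radius) not in _VALID_PR:
            raise ValueError(f"(P, R) must be one of {_VALID_PR}")
        if self.patch_mode not in ("grid", "tiles32"):
            raise ValueError("patch_mode must be 'grid' or 'tiles32'")
        if self.kind != "hog" and self.patch_mode == "grid" and len(self.partition) != self.levels:
            raise ValueError("partition must list one grid per pyramid level")
        if any(g[0] < 1 or g[1] < 1 for g in self.partition):
            raise ValueError("patch grids must be positive")


# ---------------------------------------------------------------------------
# Gaussian pyramid

_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def gaussian_pyramid(img: np.ndarray, levels: int = 4) -> list[np.ndarray]:
    """Multiresolution pyramid; level k has dims floor(r / 2^(k-1)).

    Level 1 is the input; each next level smooths with the separable
    5-tap binomial kernel [1,4,6,4,1]/16 (reflect borders) and keeps
    even-indexed rows/columns, truncated to floor-halved dimensions.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    img = np.asarray(img, dtype=float)
    out = [img]
    for _ in range(levels - 1):
        cur = out[-1]
        if cur.shape[0] < 16 or cur.shape[1] < 16:
            raise ValueError(
                f"image too small for {levels}-level pyramid (level shape {cur.shape})"
            )
        sm = ndimage.correlate1d(cur, _BINOMIAL5, axis=0, mode="reflect")
        sm = ndimage.correlate1d(sm, _BINOMIAL5, axis=1, mode="reflect")
        nr, nc = cur.shape[0] // 2, cur.shape[1] // 2
        out.append(sm[::2, ::2][:nr, :nc])
    if out[-1].shape[0] < 8 or out[-1].shape[1] < 8:
        raise ValueError("coarsest pyramid level is smaller than 8 x 8")
    return out


def pyramid_dims(shape: tuple[int, int], levels: int = 4) -> list[tuple[int, int]]:
    """Closed-form pyramid dimensions by successive floor-halving."""
    dims = [tuple(shape)]
    for _ in range(levels - 1):
        r, c = dims[-1]
        dims.append((r // 2, c // 2))
    return dims


# ---------------------------------------------------------------------------
# Local binary patterns

def lbp_pattern_count(P: int, variant: str = "ri") -> int:
    """Number of LBP labels: riu2 -> P + 2; u2 -> P(P-1) + 3."""
    if P < 4:
        raise ValueError("P must be >= 4")
    variant = _norm_variant(variant)
    return P + 2 if variant == "ri" else P * (P - 1) + 3


def _norm_variant(variant: str) -> str:
    v = variant.lower().replace("lbp-", "")
    if v in ("ri", "riu2"):
        return "ri"
    if v in ("nri", "u2"):
        return "nri"
    raise ValueError(f"unknown LBP variant {variant!r}")


def _circle_offsets(P: int, R: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampling offsets (dr, dc) at angles 2 pi k / P, rounded to 1e-5."""
    k = np.arange(P)
    dr = -R * np.sin(2.0 * np.pi * k / P)
    dc = R * np.cos(2.0 * np.pi * k / P)
    return np.round(dr, 5), np.round(dc, 5)


def _sample_ring(img: np.ndarray, P: int, R: int) -> np.ndarray:
    """Bilinear samples of the P circle neighbors for every interior pixel.

    Returns (P, H, W) for the interior region [R, rows-R) x [R, cols-R).
    Integral offsets (within rounding) use exact grid values.
    """
    rows, cols = img.shape
    h, w = rows - 2 * R, cols - 2 * R
    out = np.empty((P, h, w), dtype=float)
    dr, dc = _circle_offsets(P, R)
    for k in range(P):
        r, c = dr[k], dc[k]
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        fr, fc = r - r0, c - c0
        if abs(fr) < 1e-8 and abs(fc) < 1e-8:
            out[k] = img[R + r0 : R + r0 + h, R + c0 : R + c0 + w]
            continue
        w00 = (1 - fr) * (1 - fc)
        w01 = (1 - fr) * fc
        w10 = fr * (1 - fc)
        w11 = fr * fc
        a = img[R + r0 : R + r0 + h, R + c0 : R + c0 + w]
        b = img[R + r0 : R + r0 + h, R + c0 + 1 : R + c0 + 1 + w]
        c_ = img[R + r0 + 1 : R + r0 + 1 + h, R + c0 : R + c0 + w]
        d = img[R + r0 + 1 : R + r0 + 1 + h, R + c0 + 1 : R + c0 + 1 + w]
        out[k] = w00 * a + w01 * b + w10 * c_ + w11 * d
    return out


def lbp_code_image(img: np.ndarray, P: int, R: int, variant: str = "ri") -> np.ndarray:
    """Per-pixel LBP labels; border of width R is marked -1 (excluded downstream).

    Neighbors on the radius-R circle are compared to the center with >=
    (ties count as 1).  riu2 maps uniform codes (at most 2 circular 0/1
    transitions) to their number of set bits and all non-uniform codes
    to label P+1.  u2 keeps uniform codes distinct: label 0 = all
    zeros, 1 = all ones, then 2 + (ones-1) * P + start for a run of
    ``ones`` ones starting at neighbor index ``start``; non-uniform
    codes map to P(P-1) + 2.
    """
    variant = _norm_variant(variant)
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape
    if rows < 2 * R + 1 or cols < 2 * R + 1:
        raise ValueError(f"image must be at least {2*R+1} x {2*R+1} for R={R}")
    center = img[R : rows - R, R : cols - R]
    ring = _sample_ring(img, P, R)
    bits = ring >= center[None]
    trans = (bits != np.roll(bits, -1, axis=0)).sum(axis=0)
    ones = bits.sum(axis=0)
    if variant == "ri":
        labels = np.where(trans <= 2, ones, P + 1)
    else:
        start = np.argmax(bits & ~np.roll(bits, 1, axis=0), axis=0)
        labels = 2 + (ones - 1) * P + start
        labels = np.where(ones == 0, 0, labels)
        labels = np.where(ones == P, 1, labels)
        labels = np.where(trans <= 2, labels, P * (P - 1) + 2)
    out = np.full((rows, cols), -1, dtype=np.int32)
    out[R : rows - R, R : cols - R] = labels
    return out


def _grid_edges(size: int, n: int) -> list[int]:
    """Floor-divided split points; leftover pixels go to the last cell."""
    step = size // n
    edges = [i * step for i in range(n)] + [size]
    return edges


def _iter_patches(shape: tuple[int, int], grid: tuple[int, int] | None, mode: str):
    """Yield (r0, r1, c0, c1) patch windows in row-major order."""
    rows, cols = shape
    if mode == "grid":
        gr, gc = grid
        re = _grid_edges(rows, gr)
        ce = _grid_edges(cols, gc)
        for i in range(gr):
            for j in range(gc):
                yield re[i], re[i + 1], ce[j], ce[j + 1]
    else:  # literal 32 px non-overlapping tiling, leftovers dropped
        for i in range(rows // 32):
            for j in range(cols // 32):
                yield 32 * i, 32 * (i + 1), 32 * j, 32 * (j + 1)


def lbp_descriptor(
    pyramid: list[np.ndarray],
    P: int = 16,
    R: int = 2,
    variant: str = "ri",
    partition: tuple[tuple[int, int], ...] = DEFAULT_PARTITION,
    patch_mode: str = "grid",
) -> np.ndarray:
    """Concatenated L1-normalized per-patch LBP histograms over all levels.

    Length = total patches x lbp_pattern_count(P, variant); patches are
    traversed level by level in row-major order.
    """
    variant = _norm_variant(variant)
    n_labels = lbp_pattern_count(P, variant)
    pieces = []
    for lvl, img in enumerate(pyramid):
        codes = lbp_code_image(img, P, R, variant)
        grid = partition[lvl] if patch_mode == "grid" else None
        for r0, r1, c0, c1 in _iter_patches(img.shape, grid, patch_mode):
            if r1 - r0 < 2 * R + 1 or c1 - c0 < 2 * R + 1:
                raise ValueError(
                    f"patch {r1-r0} x {c1-c0} at level {lvl+1} smaller than 2R+1={2*R+1}"
                )
            patch = codes[r0:r1, c0:c1]
            valid = patch[patch >= 0]
            if valid.size == 0:
                raise ValueError(f"patch at level {lvl+1} has no interior pixels")
            hist = np.bincount(valid, minlength=n_labels).astype(float)
            pieces.append(hist / hist.sum())
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# Histogram of oriented gradients

def _hog_single_level(img: np.ndarray, cell: int, block: int, bins: int) -> np.ndarray:
    if block != 2:
        raise ValueError("only 2 x 2-cell blocks are supported")
    rows, cols = img.shape
    cr, cc = rows // cell, cols // cell
    if cr < block or cc < block:
        raise ValueError(f"level {rows} x {cols} has fewer than {block} cells per dimension")
    # central differences with reflect (edge-repeat) borders
    pr = np.pad(img, ((1, 1), (0, 0)), mode="edge")
    pc = np.pad(img, ((0, 0), (1, 1)), mode="edge")
    gr = (pr[2:] - pr[:-2]) / 2.0
    gc = (pc[:, 2:] - pc[:, :-2]) / 2.0
    mag = np.hypot(gr, gc)
    ang = np.mod(np.arctan2(gr, gc), np.pi)  # unsigned orientation in [0, pi)

    # magnitude-weighted linear interpolation between the two adjacent bins
    pos = ang * bins / np.pi - 0.5
    b0 = np.floor(pos).astype(int)
    w1 = pos - b0
    w0 = 1.0 - w1
    b0m = np.mod(b0, bins)
    b1m = np.mod(b0 + 1, bins)

    # accumulate into cells (trailing pixels beyond cr*cell / cc*cell dropped)
    r_lim, c_lim = cr * cell, cc * cell
    cell_r = (np.arange(r_lim) // cell)[:, None]
    cell_c = (np.arange(c_lim) // cell)[None, :]
    flat_cell = (cell_r * cc + cell_c).ravel()
    hist = np.zeros((cr * cc, bins))
    for bsel, wsel in ((b0m, w0), (b1m, w1)):
        np.add.at(
            hist,
            (flat_cell, bsel[:r_lim, :c_lim].ravel()),
            (mag[:r_lim, :c_lim] * wsel[:r_lim, :c_lim]).ravel(),
        )
    hist = hist.reshape(cr, cc, bins)

    # 2x2-cell blocks at 1-cell stride, L2 normalization with eps
    eps = 1e-5
    blocks = np.concatenate(
        [
            hist[:-1, :-1],
            hist[:-1, 1:],
            hist[1:, :-1],
            hist[1:, 1:],
        ],
        axis=-1,
    )  # (cr-1, cc-1, 4*bins)
    norms = np.sqrt((blocks**2).sum(axis=-1, keepdims=True) + eps**2)
    return (blocks / norms).ravel()


def hog_descriptor(
    pyramid: list[np.ndarray], cell: int = 4, block: int = 2, bins: int = 9
) -> np.ndarray:
    """Concatenated HoG over all pyramid levels (levels 1 -> 4)."""
    return np.concatenate([_hog_single_level(img, cell, block, bins) for img in pyramid])


# ---------------------------------------------------------------------------
# Closed-form lengths and sklearn-style transformers

def descriptor_length(config: DescriptorConfig, dims: tuple[int, int]) -> int:
    """Exact feature-vector length for ``config`` on an input of shape ``dims``."""
    shapes = pyramid_dims(dims, config.levels)
    if config.kind == "hog":
        total = 0
        for r, c in shapes:
            cr, cc = r // config.hog_cell, c // config.hog_cell
            if cr < config.hog_block or cc < config.hog_block:
                raise ValueError(f"level {r} x {c} yields no HoG blocks")
            total += (cr - 1) * (cc - 1) * config.hog_block**2 * config.hog_bins
        return total
    n_labels = lbp_pattern_count(config.points, "ri" if config.kind == "lbp-ri" else "nri")
    if config.patch_mode == "grid":
        n_patches = sum(g[0] * g[1] for g in config.partition)
    else:
        n_patches = sum((r // 32) * (c // 32) for r, c in shapes)
    if n_patches == 0:
        raise ValueError("geometry yields zero patches")
    return n_patches * n_labels


def extract_descriptor(img: np.ndarray, config: DescriptorConfig) -> np.ndarray:
    """Per-B-scan feature vector for the configured descriptor."""
    pyr = gaussian_pyramid(img, config.levels)
    if config.kind == "hog":
        return hog_descriptor(pyr, config.hog_cell, config.hog_block, config.hog_bins)
    variant = "ri" if config.kind == "lbp-ri" else "nri"
    return lbp_descriptor(pyr, config.points, config.radius, variant, config.partition, config.patch_mode)


class _BaseDescriptor(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping a stack/list of 2-D images to (n, D)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        return np.stack([extract_descriptor(np.asarray(img), cfg) for img in X])


class LBPDescriptor(_BaseDescriptor):
    """Multiresolution LBP histogram extractor (sklearn transformer)."""

    def __init__(
        self,
        points: int = 16,
        radius: int = 2,
        variant: str = "ri",
        levels: int = 4,
        partition: tuple = DEFAULT_PARTITION,
        patch_mode: str = "grid",
    ):
        self.points = points
        self.radius = radius
        self.variant = variant
        self.levels = levels
        self.partition = partition
        self.patch_mode = patch_mode

    def _config(self) -> DescriptorConfig:
        kind = "lbp-ri" if _norm_variant(self.variant) == "ri" else "lbp-nri"
        return DescriptorConfig(
            kind=kind,
            points=self.points,
            radius=self.radius,
            levels=self.levels,
            partition=tuple(self.partition),
            patch_mode=self.patch_mode,
        )


class HOGDescriptor(_BaseDescriptor):
    """Multiresolution HoG extractor (sklearn transformer)."""

    def __init__(self, cell: int = 4, block: int = 2, bins: int = 9, levels: int = 4):
        self.cell = cell
        self.block = block
        self.bins = bins
        self.levels = levels

    def _config(self) -> DescriptorConfig:
        return DescriptorConfig(
            kind="hog", levels=self.levels, hog_cell=self.cell, hog_block=self.block, hog_bins=self.bins
        )
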