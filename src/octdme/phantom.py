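"""Synthetic SD-OCT phantom volumes.

The generator emulates the statistical structure the pipeline assumes
rather than OCT physics: a dark vitreous, a stack of piecewise-constant
retinal bands sitting above a bright, quadratically curved RPE band, a
dim choroid below it, fully-developed multiplicative speckle, and the
three DME lesion types — intraretinal cystoid spaces (dark ellipses in
the retina), subretinal fluid (dark ellipses under the RPE) and retinal
thickening (a local upward bulge of the inner layers).

Speckle follows the standard L-look model: each pixel is multiplied by
an i.i.d. gamma variate with shape L and mean 1, so the clean image is
preserved in expectation and the noise variance is 1/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import DatasetManifest, Label, OCTVolume, save_manifest, write_volume

CYSTOID = "cystoid"
SUBRETINAL_FLUID = "subretinal_fluid"
THICKENING = "thickening"
_LESION_KINDS = (CYSTOID, SUBRETINAL_FLUID, THICKENING)


@dataclass
class Lesion:
    """One DME lesion: an ellipse (row/col center and semi-axes) with a contrast.

    ``contrast`` in (0, 1] darkens the ellipse interior for CYSTOID and
    SUBRETINAL_FLUID; for THICKENING it scales the bulge amplitude
    (``axes[0]`` px of upward displacement at the bulge center).
    """

    kind: str
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (semi-axis rows, semi-axis cols)
    contrast: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in _LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if not (0 < self.contrast <= 1):
            raise ValueError("lesion contrast must lie in (0, 1]")
        if min(self.axes) <= 0:
            raise ValueError("lesion semi-axes must be positive")


def default_layers(rows: int) -> list[tuple[float, float]]:
    """Retinal bands as (offset above RPE in px, intensity), outermost first."""
    return [
        (0.30 * rows, 0.32),  # NFL/GCL complex
        (0.22 * rows, 0.48),
        (0.14 * rows, 0.38),
        (0.07 * rows, 0.55),  # outer retina, just above the RPE
    ]


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic B-scan."""

    rows: int = 1024
    cols: int = 512
    rpe_coeffs: tuple[float, float, float] | None = None  # row = a x^2 + b x + c
    layer_offsets: list[tuple[float, float]] | None = None
    rpe_intensity: float = 0.95
    rpe_thickness: int | None = None
    choroid_intensity: float = 0.45
    choroid_depth: int | None = None
    background: float = 0.03
    speckle_looks: float = 4.0
    lesions: list[Lesion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rpe_coeffs is None:
            # gentle bowl centered laterally, RPE around 0.55 * rows
            amp = 0.06 * self.rows
            cx = (self.cols - 1) / 2.0
            a = amp / cx**2
            self.rpe_coeffs = (a, -2 * a * cx, 0.55 * self.rows + a * cx**2 - amp)
        if self.layer_offsets is None:
            self.layer_offsets = default_layers(self.rows)
        if self.rpe_thickness is None:
            self.rpe_thickness = max(4, self.rows // 80)
        if self.choroid_depth is None:
            self.choroid_depth = max(8, self.rows // 20)
        if self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be positive")
        self.validate()

    def rpe_row(self, x: np.ndarray | float, x_shift: float = 0.0) -> np.ndarray:
        a, b, c = self.rpe_coeffs
        xx = np.asarray(x, dtype=float) + x_shift
        return a * xx**2 + b * xx + c

    def validate(self) -> None:
        x = np.arange(self.cols)
        r = self.rpe_row(x)
        if r.min() < 0.2 * self.rows or r.max() > 0.9 * self.rows:
            raise ValueError("RPE curve must stay within [0.2, 0.9] of the image height")
        offs = [o for o, _ in self.layer_offsets]
        if sorted(offs, reverse=True) != offs:
            raise ValueError("layer_offsets must be sorted outermost (largest offset) first")
        if any(i >= self.rpe_intensity for _, i in self.layer_offsets):
            raise ValueError("retinal band intensities must stay below the RPE intensity")
        for les in self.lesions:
            cr, cc = les.center
            ar, ac = les.axes
            if not (0 <= cr - ar and cr + ar < self.rows and 0 <= cc - ac and cc + ac < self.cols):
                raise ValueError(f"lesion at {les.center} extends outside the image")
            rpe_c = float(self.rpe_row(cc))
            half = self.rpe_thickness / 2.0
            if les.kind == CYSTOID and cr + ar > rpe_c - half:
                raise ValueError("cystoid lesion must lie above the RPE band")
            if les.kind == SUBRETINAL_FLUID and cr - ar < rpe_c + half:
                raise ValueError("subretinal fluid must lie below the RPE band")


def render_clean_bscan(spec: PhantomSpec, x_shift: float = 0.0) -> np.ndarray:
    """Render the noiseless phantom B-scan (float32 in [0, 1]).

    The RPE band is the brightest structure in every column; retinal
    bands are piecewise constant in depth above the quadratic RPE curve.
    """
    spec.validate()
    rows, cols = spec.rows, spec.cols
    x = np.arange(cols)
    rpe = spec.rpe_row(x, x_shift)  # (cols,)

    # per-column upward displacement of the inner layers from THICKENING lesions
    bulge = np.zeros(cols)
    for les in spec.lesions:
        if les.kind == THICKENING:
            _, cc = les.center
            amp = les.axes[0] * les.contrast
            sigma = les.axes[1] / 2.0
            bulge += amp * np.exp(-((x - cc) ** 2) / (2 * sigma**2))

    r_idx = np.arange(rows)[:, None]  # (rows, 1)
    depth = rpe[None, :] - r_idx  # px above the RPE curve; negative below

    img = np.full((rows, cols), spec.background, dtype=np.float32)
    half = spec.rpe_thickness / 2.0
    # retinal bands, outermost first; band i spans (offset_{i+1}, offset_i] above the band top
    offsets = [o for o, _ in spec.layer_offsets]
    intens = [v for _, v in spec.layer_offsets]
    bounds = offsets + [half]
    for i, val in enumerate(intens):
        hi = bounds[i] + bulge[None, :]
        lo = bounds[i + 1] + (bulge[None, :] if i + 1 < len(bounds) - 1 else 0.0)
        img[(depth <= hi) & (depth > lo)] = val
    # RPE band centered on the curve, brightest exactly on it (slight taper
    # toward the band edges keeps the per-column argmax on the curve)
    band = np.abs(depth) <= half
    taper = 0.1 * spec.rpe_intensity
    img[band] = (spec.rpe_intensity - taper * np.abs(depth) / (half + 1.0))[band]
    img[(depth < -half) & (depth >= -half - spec.choroid_depth)] = spec.choroid_intensity

    # fluid-type lesions darken their ellipse interior
    cgrid = np.arange(cols)[None, :]
    for les in spec.lesions:
        if les.kind == THICKENING:
            continue
        cr, cc = les.center
        ar, ac = les.axes
        mask = ((r_idx - cr) / ar) ** 2 + ((cgrid - cc) / ac) ** 2 <= 1.0
        img[mask] *= 1.0 - les.contrast
    return np.clip(img, 0.0, 1.0)


def add_speckle(
    img: np.ndarray, looks: float, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Multiply by i.i.d. unit-mean gamma speckle with shape ``looks``; clip to [0, 1]."""
    if looks <= 0:
        raise ValueError("looks must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    gain = rng.gamma(shape=looks, scale=1.0 / looks, size=img.shape)
    return np.clip(img * gain, 0.0, 1.0).astype(np.float32)


def _sample_spec(
    rng: np.random.Generator, rows: int, cols: int, looks: float
) -> PhantomSpec:
    """Draw one volume's anatomy: random RPE curvature, depth and band intensities."""
    cx = (cols - 1) / 2.0
    amp = rng.uniform(0.02, 0.07) * rows
    c0 = rng.uniform(0.45, 0.65) * rows
    a = amp / cx**2
    coeffs = (a, -2 * a * cx, c0 + a * cx**2 - amp)
    return PhantomSpec(
        rows=rows,
        cols=cols,
        rpe_coeffs=coeffs,
        speckle_looks=looks,
    )


def _jitter_layers(rng: np.random.Generator, spec: PhantomSpec) -> list[tuple[float, float]]:
    """Per-scan intensity jitter emulating acquisition variability."""
    return [
        (off, float(np.clip(val + rng.uniform(-0.05, 0.05), 0.1, 0.7)))
        for off, val in spec.layer_offsets
    ]


def _sample_lesions(
    rng: np.random.Generator, spec: PhantomSpec, contrast: float
) -> list[Lesion]:
    """One DME lesion complex consistent with the geometry invariants.

    DME B-scans typically show edema (retinal thickening) together with
    several intraretinal cystoid spaces and, in some cases, subretinal
    fluid; each lesioned scan therefore gets one thickening bulge, 2-4
    cysts and a subretinal fluid pocket with 30% probability.
    """
    lesions: list[Lesion] = []
    retina_h = spec.layer_offsets[0][0]

    def _try(les: Lesion) -> None:
        try:
            trial = replace(spec, lesions=lesions + [les])
            trial.validate()
        except ValueError:
            return  # rejected draw (out of bounds); geometry stays valid
        lesions.append(les)

    # edema: local thickening of the inner layers
    cc = float(rng.uniform(0.25, 0.75) * spec.cols)
    amp = float(rng.uniform(0.3, 0.6)) * retina_h  # bulge height in px
    width = float(rng.uniform(0.2, 0.4) * spec.cols)
    cr = float(spec.rpe_row(cc)) - retina_h / 2
    _try(Lesion(THICKENING, (cr, cc), (amp, width), contrast))

    # 2-4 intraretinal cystoid spaces
    for _ in range(int(rng.integers(2, 5))):
        cc = float(rng.uniform(0.1, 0.9) * spec.cols)
        rpe_c = float(spec.rpe_row(cc))
        ar = float(rng.uniform(0.1, 0.3)) * retina_h
        ac = float(rng.uniform(1.0, 2.5)) * ar
        cr = rpe_c - spec.rpe_thickness / 2.0 - ar - float(rng.uniform(0.05, 0.5)) * retina_h
        _try(Lesion(CYSTOID, (cr, cc), (ar, ac), contrast))

    # occasional subretinal fluid pocket under the RPE band
    if rng.uniform() < 0.3:
        cc = float(rng.uniform(0.2, 0.8) * spec.cols)
        rpe_c = float(spec.rpe_row(cc))
        ar = float(rng.uniform(0.01, 0.03) * spec.rows)
        ac = float(rng.uniform(2.0, 4.0)) * ar
        cr = rpe_c + spec.rpe_thickness / 2.0 + ar + 1.0
        _try(Lesion(SUBRETINAL_FLUID, (cr, cc), (ar, ac), contrast))
    return lesions


def sample_volume(
    rng: np.random.Generator,
    dme: bool,
    *,
    rows: int = 256,
    cols: int = 512,
    n_scans: int = 128,
    lesion_contrast: float = 0.5,
    looks: float = 16.0,
    lesion_fraction_range: tuple[float, float] = (0.6, 0.85),
    patient_id: str = "",
) -> OCTVolume:
    """Draw one synthetic volume.

    DME volumes carry lesions on at least 60% of their B-scans so that a
    majority vote over correctly classified B-scans can recover the
    volume label; normal volumes are lesion-free.
    """
    spec = _sample_spec(rng, rows, cols, looks)
    n_lesioned = 0
    lesion_scans: set[int] = set()
    if dme:
        frac = rng.uniform(*lesion_fraction_range)
        n_lesioned = min(n_scans, int(math.ceil(frac * n_scans)))
        lesion_scans = set(rng.choice(n_scans, size=n_lesioned, replace=False).tolist())
    scans = np.empty((n_scans, rows, cols), dtype=np.float32)
    shift_scale = 0.05 * cols
    for i in range(n_scans):
        x_shift = float(rng.uniform(-shift_scale, shift_scale))
        s = replace(spec, layer_offsets=_jitter_layers(rng, spec))
        if i in lesion_scans:
            s = replace(s, lesions=_sample_lesions(rng, s, lesion_contrast))
        clean = render_clean_bscan(s, x_shift=x_shift)
        scans[i] = add_speckle(clean, looks, rng=rng)
    return OCTVolume(
        scans=scans,
        patient_id=patient_id,
        label=Label.DME if dme else Label.NORMAL,
    )


def make_dataset(
    out_dir: str | Path,
    n_dme: int,
    n_normal: int,
    *,
    rows: int = 1024,
    cols: int = 512,
    n_scans: int = 128,
    lesion_contrast: float = 0.5,
    looks: float = 16.0,
    seed: int = 0,
) -> DatasetManifest:
    """Write ``n_dme + n_normal`` phantom volumes as TIFF stacks plus a manifest.csv."""
    if n_dme < 1 or n_normal < 1:
        raise ValueError("need at least one volume per class")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str, Label]] = []
    for dme, count, prefix in ((True, n_dme, "dme"), (False, n_normal, "normal")):
        for i in range(count):
            pid = f"{prefix}{i:02d}"
            vol = sample_volume(
                rng,
                dme,
                rows=rows,
                cols=cols,
                n_scans=n_scans,
                lesion_contrast=lesion_contrast,
                looks=looks,
                patient_id=pid,
            )
            path = out_dir / f"{pid}.tiff"
            write_volume(vol, path)
            entries.append((str(path), pid, vol.label))
    manifest = DatasetManifest(entries=entries)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
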