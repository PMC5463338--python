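"""Pipeline configuration with validated defaults.

Defaults mirror the original protocol: NLM denoising, crop window of
325 px above / 30 px below the RPE and a 340 px centered lateral strip,
a 4-level Gaussian pyramid, LBP16-ri descriptors, Histogram+PCA
representation (20 components for LBP, 40 for HoG) and a linear SVM.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class CropGeometry:
    """Anatomical crop window relative to the flattened RPE row."""

    rows_above: int = 325
    rows_below: int = 30
    lateral_width: int = 340

    def __post_init__(self) -> None:
        if self.rows_above < 0 or self.rows_below < 0:
            raise ValueError("crop extents must be non-negative")
        if self.lateral_width < 1:
            raise ValueError("lateral_width must be positive")

    @property
    def out_rows(self) -> int:
        return self.rows_above + self.rows_below + 1


@dataclass
class PipelineConfig:
    """End-to-end settings for preprocess -> features -> represent -> classify."""

    denoiser: str = "nlm"
    denoiser_params: dict = field(default_factory=dict)
    crop: CropGeometry = field(default_factory=CropGeometry)
    pyramid_levels: int = 4
    descriptor: str = "lbp-ri"  # lbp-ri | lbp-nri | hog
    lbp_points: int = 16
    lbp_radius: int = 2
    representation: str = "hist_pca"  # hist | hist_pca | hist_pca_bow
    pca_components: int | None = None  # None -> 40 for HoG, 20 for LBP
    n_words: int = 30
    classifier: str = "linear_svm"  # linear_svm | rbf_svm | rf
    svm_c: float = 1.0
    svm_gamma: float | str = "auto"
    rf_trees: int = 100
    ransac_iters: int = 500
    ransac_tol: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.crop, dict):
            self.crop = CropGeometry(**self.crop)
        if self.descriptor not in ("lbp-ri", "lbp-nri", "hog"):
            raise ValueError(f"unknown descriptor {self.descriptor!r}")
        if (self.lbp_points, self.lbp_radius) not in ((8, 1), (16, 2), (24, 3)):
            raise ValueError("LBP (P, R) must be one of (8,1), (16,2), (24,3)")
        if self.representation not in ("hist", "hist_pca", "hist_pca_bow"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.classifier not in ("linear_svm", "rbf_svm", "rf"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.n_words < 2:
            raise ValueError("n_words must be >= 2")

    @property
    def default_pca_components(self) -> int:
        if self.pca_components is not None:
            return self.pca_components
        return 40 if self.descriptor == "hog" else 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
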