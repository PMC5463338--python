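"""End-to-end helpers tying preprocessing, features and evaluation together."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .classify import ClassifierSpec, EvalReport, FeatureBlock, evaluate_pipeline
from .config import PipelineConfig
from .features import DescriptorConfig, extract_descriptor
from .flatten import preprocess_volume
from .io import DatasetManifest, OCTVolume, read_volume


def descriptor_config(config: PipelineConfig) -> DescriptorConfig:
    from .features import DEFAULT_PARTITION

    return DescriptorConfig(
        kind=config.descriptor,
        points=config.lbp_points,
        radius=config.lbp_radius,
        levels=config.pyramid_levels,
        partition=DEFAULT_PARTITION[: config.pyramid_levels],
    )


def volume_features(vol: OCTVolume, config: PipelineConfig) -> np.ndarray:
    """Preprocess a raw volume and extract one descriptor vector per B-scan."""
    pre = preprocess_volume(vol, config)
    dcfg = descriptor_config(config)
    return np.stack([extract_descriptor(scan, dcfg) for scan in pre.scans])


def build_feature_store(
    volumes: list[OCTVolume] | None = None,
    manifest: DatasetManifest | None = None,
    config: PipelineConfig | None = None,
    root: str | Path | None = None,
) -> dict[str, np.ndarray]:
    """patient_id -> (n_scans, D) descriptor matrix for a set of volumes.

    Volumes may be given in memory or loaded from the manifest's paths
    (relative paths resolved against ``root``).
    """
    if config is None:
        config = PipelineConfig()
    if volumes is None:
        if manifest is None:
            raise ValueError("need volumes or a manifest")
        volumes = []
        for path, pid, lab in manifest.entries:
            p = Path(path)
            if root is not None and not p.is_absolute():
                p = Path(root) / p
            vol = read_volume(p)
            vol.patient_id, vol.label = pid, lab
            volumes.append(vol)
    return {vol.patient_id: volume_features(vol, config) for vol in volumes}


def run_evaluation(
    manifest: DatasetManifest,
    config: PipelineConfig | None = None,
    volumes: list[OCTVolume] | None = None,
    root: str | Path | None = None,
) -> EvalReport:
    """Full pipeline: preprocess, extract, represent, cross-validate."""
    if config is None:
        config = PipelineConfig()
    store = build_feature_store(volumes=volumes, manifest=manifest, config=config, root=root)
    spec = ClassifierSpec(
        kind=config.classifier,
        C=config.svm_c,
        gamma=config.svm_gamma,
        n_trees=config.rf_trees,
        seed=config.seed,
    )
    block = FeatureBlock(store, config.default_pca_components if config.representation != "hist" else None)
    return evaluate_pipeline(
        [block],
        manifest,
        representation=config.representation,
        classifier=spec,
        n_words=config.n_words,
        seed=config.seed,
    )
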