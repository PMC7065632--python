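"""End-to-end composition: simulate -> reconstruct -> featurize -> classify.

``generate_labeled_dataset`` produces a synthetic study: for each tissue
class a set of C-scans is simulated (each attributed to a synthetic
animal), reconstructed, halved along y into sibling samples and reduced to
feature vectors.  ``run_pipeline`` then assembles the animal-held-out
split, fits the classifier and reports cross-validation and test
performance.  All randomness derives from one top-level seed, split
deterministically per volume and per noise source.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import (
    ClassifierReport,
    assemble_dataset,
    evaluate,
    plot_classification,
    split_cscan,
)
from .features import FeatureConfig, FeatureVector, build_feature_vector
from .phantom import (
    NoiseConfig,
    SweepConfig,
    TISSUE_CLASSES,
    make_tissue_scene,
    simulate_sweep,
)
from .recon import ReconConfig, reconstruct_volume

__all__ = ["RunConfig", "generate_labeled_dataset", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic study run."""

    n_volumes_per_class: int = 12
    animals: tuple[str, ...] = ("A", "B", "C")
    holdout_animals: tuple[str, ...] = ("C",)
    classes: tuple[str, ...] = TISSUE_CLASSES
    sweep: SweepConfig = field(default_factory=SweepConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    recon: ReconConfig = field(default_factory=lambda: ReconConfig(medium_index=1.38))
    features: FeatureConfig = field(default_factory=FeatureConfig)
    cv_folds: int = 10
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = {
            "schema_version": 1,
            "n_volumes_per_class": self.n_volumes_per_class,
            "animals": list(self.animals),
            "holdout_animals": list(self.holdout_animals),
            "classes": list(self.classes),
            "sweep": self.sweep.to_dict(),
            "noise": self.noise.to_dict(),
            "recon": self.recon.to_dict(),
            "features": self.features.to_dict(),
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            n_volumes_per_class=d.get("n_volumes_per_class", 12),
            animals=tuple(d.get("animals", ("A", "B", "C"))),
            holdout_animals=tuple(d.get("holdout_animals", ("C",))),
            classes=tuple(d.get("classes", TISSUE_CLASSES)),
            sweep=SweepConfig.from_dict(d["sweep"]) if "sweep" in d else SweepConfig(),
            noise=NoiseConfig.from_dict(d["noise"]) if "noise" in d else NoiseConfig(),
            recon=ReconConfig.from_dict(d["recon"]) if "recon" in d else ReconConfig(medium_index=1.38),
            features=FeatureConfig.from_dict(d["features"]) if "features" in d else FeatureConfig(),
            cv_folds=d.get("cv_folds", 10),
            seed=d.get("seed", 0),
            output_dir=d.get("output_dir"),
        )


def generate_labeled_dataset(cfg: RunConfig) -> list[FeatureVector]:
    """Simulate, reconstruct and featurize a full labelled dataset.

    Returns two sibling feature vectors (the y-halves) per simulated
    C-scan; volumes are distributed round-robin over the synthetic
    animals.
    """
    root = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_volumes_per_class * len(cfg.classes)
    children = root.spawn(n_total)
    vectors: list[FeatureVector] = []
    idx = 0
    for cls_name in cfg.classes:
        for v in range(cfg.n_volumes_per_class):
            child = children[idx]
            idx += 1
            scene_seed, noise_seed = (
                int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2)
            )
            animal = cfg.animals[v % len(cfg.animals)]
            scene = make_tissue_scene(cls_name, seed=scene_seed)
            scene.scene_id = f"{cls_name}-{v:03d}"
            noise = dataclasses.replace(cfg.noise, seed=noise_seed)
            stack = simulate_sweep(scene, cfg.sweep, noise)
            vol = reconstruct_volume(stack, cfg.recon)
            for half in split_cscan(vol):
                vectors.append(
                    build_feature_vector(
                        half,
                        cfg.features,
                        sample_id=half.source,
                        animal_id=animal,
                        class_label=cls_name,
                    )
                )
    return vectors


def run_pipeline(cfg: RunConfig) -> ClassifierReport:
    """Run the whole synthetic study and return the classification report.

    If ``cfg.output_dir`` is set, the feature table (CSV) and the report
    (JSON) are persisted there alongside the run configuration.
    """
    from . import io as ffio  # local import to avoid a cycle at module load

    vectors = generate_labeled_dataset(cfg)
    split = assemble_dataset(vectors, holdout_animals=set(cfg.holdout_animals))
    report = evaluate(split, k=cfg.cv_folds, seed=cfg.seed)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        ffio.write_feature_table(vectors, out / "features.csv")
        ffio.write_json(report.to_dict(), out / "report.json")
        ffio.write_json(cfg.to_dict(), out / "run_config.json")
        plot_classification(report, split.train, str(out / "pca_scatter.png"))
    return report
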