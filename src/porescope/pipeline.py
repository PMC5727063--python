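"""High-level pipeline helpers: simulate -> detect -> featurize -> classify.

These functions wire the stage modules together for the standard study
conditions — two volume-matched rod classes ("sharp" caps, R = 200 nm,
versus "round" caps, R = 1100 nm, emulating the two rod-shaped species)
recorded in the reference 3 um x 40 nm pore with 13 pA rms noise — and
are shared by the command-line interface, the analysis drivers and the
acceptance script.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import classify, features, pulse_detect, pulse_sim
from .features import FeatureRecord, NormalizedPulse
from .pulse_detect import DetectionConfig
from .pulse_sim import (NoiseModel, PoreGeometry, RoundedRod, SimulatedDataset,
                        Variability)

__all__ = [
    "two_class_specs",
    "simulate_two_class_dataset",
    "featurize_dataset",
    "grid_vectors",
    "REDUCED_GRID_SPECS",
    "REDUCED_GRID_CLASSIFIERS",
    "run_reduced_grid",
    "kde_size_features_cv",
    "FeaturizedDataset",
]

#: reduced (feature vector x classifier) grid: 4 specs x 3 classifiers = 12 cells
REDUCED_GRID_SPECS = (
    "beta_apex_30",
    "beta_apex_30+curr",
    "I_p",
    "beta_apex_50+curr+cross",
)
REDUCED_GRID_CLASSIFIERS = (
    "rotation_forest(tree)",
    "rotation_forest(gaussian_nb)",
    "rotation_forest(knn1)",
)


def two_class_specs(sharp_R: float = 200e-9, round_R: float = 1100e-9,
                    volume_matched: bool = True,
                    variability: Variability = Variability()
                    ) -> list[tuple[str, RoundedRod, Variability]]:
    """The two rod classes of the discrimination study.

    Both classes share the rod body (D = 800 nm, Lb = 2.6 um), size and
    velocity jitter; with ``volume_matched`` their volumes are equalized
    so height/width distributions deliberately overlap and only the cap
    shape differs.
    """
    sharp = RoundedRod(R=sharp_R, volume_matched=volume_matched)
    round_ = RoundedRod(R=round_R, volume_matched=volume_matched)
    return [("sharp_rod", sharp, variability), ("round_rod", round_, variability)]


def simulate_two_class_dataset(n_per_class: int = 179, seed: int = 1,
                               geom: PoreGeometry = PoreGeometry(),
                               noise: NoiseModel = NoiseModel()
                               ) -> SimulatedDataset:
    """Generate the standard two-class dataset (179 traces per class)."""
    return pulse_sim.generate_dataset(two_class_specs(), n_per_class, geom,
                                      noise, seed)


@dataclass
class FeaturizedDataset:
    """Per-pulse features of a dataset, with labels and drop accounting."""

    records: list[tuple[FeatureRecord, NormalizedPulse]]
    labels: np.ndarray
    n_dropped: int = 0
    catalog_hash: str = field(default_factory=lambda: features.catalog_hash(
        features.default_catalog()))

    def __len__(self) -> int:
        return len(self.records)


def featurize_dataset(dataset: SimulatedDataset,
                      config: DetectionConfig = DetectionConfig(),
                      y_th_levels=features.DEFAULT_Y_TH,
                      n_partitions: int = features.DEFAULT_PARTITIONS
                      ) -> FeaturizedDataset:
    """Detect and featurize every trace of a simulated dataset.

    Each trace holds one embedded event; when detection returns several
    candidates (noise artifacts), the deepest is kept.  Traces with no
    accepted pulse are dropped and counted.
    """
    records = []
    labels = []
    dropped = 0
    with warnings.catch_warnings():
        # single-event traces are intentionally shorter than one 0.5 s
        # baseline segment; the whole-trace fallback fit is the designed path
        warnings.simplefilter("ignore", UserWarning)
        for rec in dataset.records:
            pulses = pulse_detect.detect_pulses(rec.trace, config)
            if not pulses:
                dropped += 1
                continue
            best = max(pulses, key=lambda p: p.I_p)
            record, np_pulse = features.compute_features(
                best, y_th_levels, n_partitions, label=rec.label)
            records.append((record, np_pulse))
            labels.append(rec.label)
    return FeaturizedDataset(records, np.asarray(labels), dropped)


def grid_vectors(featurized: FeaturizedDataset,
                 spec_names=None) -> dict[str, np.ndarray]:
    """Stack per-pulse feature vectors into per-spec matrices."""
    catalog = features.default_catalog()
    if spec_names is not None:
        wanted = set(spec_names)
        unknown = wanted - {s.name for s in catalog}
        if unknown:
            raise KeyError(f"unknown feature-vector specs: {sorted(unknown)}")
        catalog = [s for s in catalog if s.name in wanted]
    out: dict[str, list[np.ndarray]] = {s.name: [] for s in catalog}
    for record, np_pulse in featurized.records:
        vectors = features.build_feature_vectors(record, np_pulse, catalog)
        for name, vec in vectors.items():
            out[name].append(vec)
    return {name: np.vstack(rows) for name, rows in out.items()}


def run_reduced_grid(featurized: FeaturizedDataset, k_folds: int = 10,
                     seed: int = 1, spec_names=REDUCED_GRID_SPECS,
                     classifier_ids=REDUCED_GRID_CLASSIFIERS
                     ) -> classify.GridResult:
    """Cross-validate the reduced (>=10 cell) grid on a featurized dataset."""
    vectors = grid_vectors(featurized, spec_names)
    return classify.run_grid(vectors, featurized.labels, list(classifier_ids),
                             k_folds=k_folds, seed=seed,
                             catalog_hash=featurized.catalog_hash)


def kde_size_features_cv(featurized: FeaturizedDataset, k_folds: int = 5,
                         seed: int = 1) -> classify.CVResult:
    """KDE classification restricted to the size features (I_p, t_d)."""
    X = np.array([[rec.I_p, rec.t_d] for rec, _ in featurized.records])
    return classify.cross_validate(X, featurized.labels,
                                   classify.KDEClassifier(), k_folds, seed)
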