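#!/usr/bin/env python
"""Detect pulses in the simulated dataset and extract waveform features.

Reads scratch/dataset/ (from 02_simulate_dataset.py), runs the two-stage
extraction (60/10 pA thresholds, 5-sigma boundaries with 256-sample
margins) and the descriptor set (I_p, t_d, beta_apex at Y_th 15/30/50,
theta, areas, inertia).  Writes results/features.tsv plus the composed
grid feature vectors under scratch/vectors/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from porescope import features, pipeline, trace_io
from porescope.pulse_sim import SimulatedDataset, SimulatedPulseRecord

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "scratch" / "dataset"
VECTORS = ROOT / "scratch" / "vectors"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = trace_io.read_manifest(DATASET / "manifest.tsv")
    records = [
        SimulatedPulseRecord(row["label"],
                             trace_io.read_trace(DATASET / row["file"]),
                             {"t0": row["t0"]})
        for _, row in manifest.iterrows()
    ]
    featurized = pipeline.featurize_dataset(SimulatedDataset(records))
    RESULTS.mkdir(exist_ok=True)
    matrix = features.feature_matrix(featurized.records)
    trace_io.write_feature_matrix(matrix, RESULTS / "features.tsv")
    print(f"featurized {len(featurized)} pulses "
          f"({featurized.n_dropped} traces dropped)")
    print(matrix.groupby("label")[["I_p", "t_d", "beta_apex_30"]].mean()
          .rename(columns={"I_p": "I_p (A)", "t_d": "t_d (s)"}))

    VECTORS.mkdir(parents=True, exist_ok=True)
    vectors = pipeline.grid_vectors(featurized, pipeline.REDUCED_GRID_SPECS)
    for name, X in vectors.items():
        frame = pd.DataFrame(X)
        frame.insert(0, "label", featurized.labels)
        frame.to_csv(VECTORS / f"{name.replace('+', '_')}.tsv", sep="\t",
                     index=False)
    print(f"wrote {len(vectors)} feature-vector matrices to {VECTORS} "
          f"(catalog hash {featurized.catalog_hash})")


if __name__ == "__main__":
    main()
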