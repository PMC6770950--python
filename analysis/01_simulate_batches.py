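"""Simulate the full renneting study and write every batch to disk.

Generates 12 normal-operating-condition batches spanning the kinetic
range, 3 center-point replicates, and 3 fault batches (half rennet,
heating off, half CaCl2, severity 0.5), each a 30 x 2202 absorbance
matrix over the instrument's full 12,500-4,000 cm^-1 grid, plus the
paired rheology curing curves and the simulator's ground-truth profiles.

Outputs under results/study/: batches/*.csv (+ JSON metadata sidecars),
rheology/*.csv, truth/*.csv.

Usage: python analysis/01_simulate_batches.py [--seed N]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rennetmon import pipeline
from rennetmon.preprocess import write_batch

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

out = Path("results/study")
for sub in ("batches", "rheology", "truth"):
    (out / sub).mkdir(parents=True, exist_ok=True)

study = pipeline.simulate_study(args.seed)

all_batches = study.noc_batches + study.replicate_batches + study.fault_batches
all_truths = study.noc_truths + study.replicate_truths + study.fault_truths
for batch, truth in zip(all_batches, all_truths):
    bid = batch.meta["batch_id"]
    write_batch(batch, out / "batches" / f"{bid}.csv")
    np.savetxt(out / "truth" / f"{bid}_C_true.csv", truth.C_true, delimiter=",")

curves = list(zip(study.noc_batches, study.rheology)) + list(
    zip(study.replicate_batches, study.replicate_rheology)
)
for batch, curve in curves:
    bid = batch.meta["batch_id"]
    pd.DataFrame(
        {
            "time": curve.times,
            "G_prime": curve.G_prime,
            "G_double_prime": curve.G_double_prime,
        }
    ).to_csv(out / "rheology" / f"{bid}.csv", index=False)

print(f"seed {args.seed}: wrote {len(all_batches)} batches "
      f"({len(study.noc_batches)} NOC, {len(study.replicate_batches)} "
      f"replicates, {len(study.fault_batches)} faults) to {out}")
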