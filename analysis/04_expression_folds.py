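#!/usr/bin/env python
"""Relative-expression arithmetic on a synthetic derepression experiment.

Generates triplicate CT tables for a 30-fold derepression design with
0.2-cycle CT noise, quantifies each replicate against the reference gene
and summarizes per condition.  Writes results/qpcr_summary.csv.
"""

import argparse
from pathlib import Path

from adpa_circuit.expression import prevalence, qpcr_table
from adpa_circuit.synthetic import gen_qpcr

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

table = gen_qpcr(true_fold=30.0, ct_noise_sd=0.2, n_rep=3, seed=args.seed)
summary = qpcr_table(table, target="target", ref="hrdB", control="control")
summary.to_csv(OUT / "qpcr_summary.csv", index=False)
print(summary.to_string(index=False))
fold = float(summary.loc[summary.condition == "test", "fold"].iloc[0])
print(f"estimated derepression: {fold:.1f}-fold (design truth: 30-fold)")
print(f"genus prevalence check: {prevalence(2752, 3033):.2f}% "
      "of 3,033 surveyed strains carry the regulator")
print(f"wrote {OUT / 'qpcr_summary.csv'}")
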