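#!/usr/bin/env python
"""Amino-acid homopolymer analysis: composition-based run-length thresholds,
per-amino-acid repeat densities and their cross-species correlation, and
repeat homology within global alignments of ortholog pairs.

Writes thresholds, run lists, densities and homology calls under
results/homopolymers/.
"""
import argparse
from pathlib import Path

from dictycomp.config import RunConfig
from dictycomp.pipeline import stage_homopolymers
from dictycomp.simulate import DatasetPaths

ap = argparse.ArgumentParser()
ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
ap.add_argument("--out", type=Path, default=Path("results/homopolymers"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

paths = DatasetPaths.in_dir(args.dataset)
r = stage_homopolymers(RunConfig(seed=args.seed), paths.proteins_a,
                       paths.cds_a, paths.proteins_b, paths.cds_b,
                       paths.orthologs, args.out)
thr = {aa: v for aa, v in r["thresholds_a"].min_len.items() if v is not None}
print(f"thresholds (genome A proteome): {min(thr.values())}-"
      f"{max(thr.values())} residues depending on the amino acid")
print(f"significant runs: {r['n_significant_a']} in A, "
      f"{r['n_significant_b']} in B")
print(f"repeat density correlation between species: "
      f"r = {r['density_correlation_r']:.3f} (P = {r['density_correlation_p']:.2g})")
h = r["homology"]
print(f"homologous repeats: {100 * h.fraction_homologous_a:.0f}% of "
      f"{h.n_runs_with_ortholog_a} A-runs in ortholog-bearing genes")
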