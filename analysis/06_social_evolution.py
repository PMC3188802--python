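#!/usr/bin/env python
"""Social-gene molecular evolution: Nei-Gojobori dN and conservation score
per ortholog pair (homopolymer codons excluded), social expression indices
from the stage-structured counts, and the regression / Mann-Whitney battery
relating expression to divergence.

Writes per-pair evolution, per-gene indices and test results under
results/social/.
"""
import argparse
from pathlib import Path

from dictycomp.config import RunConfig
from dictycomp.pipeline import stage_social
from dictycomp.simulate import DatasetPaths

ap = argparse.ArgumentParser()
ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
ap.add_argument("--out", type=Path, default=Path("results/social"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

paths = DatasetPaths.in_dir(args.dataset)
r = stage_social(RunConfig(seed=args.seed), paths.proteins_a,
                 paths.proteins_b, paths.cds_a, paths.cds_b, paths.orthologs,
                 paths.expression_a, args.out)
dn, cs = r["regression_dn"], r["regression_cs"]
print(f"dN ~ social index: slope {dn.slope:.3f}, R2 {dn.r2:.3f}, "
      f"P {dn.p:.2g} (n = {dn.n})")
print(f"CS ~ social index: slope {cs.slope:.3f}, R2 {cs.r2:.3f}, "
      f"P {cs.p:.2g}")
pres = r["presence_test"]
print(f"social index, genes with vs without orthologs: medians "
      f"{pres.median_with:.2f} vs {pres.median_without:.2f}, "
      f"Mann-Whitney P {pres.p:.2g} (n = {pres.n_with}, {pres.n_without})")
if r["repeat_comparison"]:
    rc = r["repeat_comparison"]
    print(f"dN by homopolymer status: {rc.mean_with:.3f} (with) vs "
          f"{rc.mean_without:.3f} (without), t-test P {rc.p:.2g}")
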