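# dictycomp

Comparative genomics of AT-rich social amoeba genome pairs, built for the
kind of two-genome comparison done between *Dictyostelium purpureum* and
*D. discoideum*: the genomes of two species from one clade are compared for
repeat content, conserved gene order, shared non-coding RNA architecture,
and the molecular evolution of socially expressed genes.

The package implements five analyses as a library with numbered driver
scripts, exercised end-to-end on synthetic paired genomes with planted
ground truth:

1. **Simple sequence repeats** — maximal tandem repeats of 1–20 bp units
   with unit-length-specific minimum copies (10/7/5/4/3 for mono- through
   penta-and-longer nucleotide units), coding/non-coding classification and
   genome-fraction summaries.
2. **Amino-acid homopolymers** — maximal runs called non-random when longer
   than the composition-based chance threshold (smallest *L* with
   *N·f^L ≤ 0.01*; 6–9 residues on a dictyostelid-like proteome), repeat
   densities per 1,000 residues, cross-species density correlation, and
   repeat homology inside BLOSUM62 global alignments of ortholog pairs.
3. **Synteny** — blocks of conserved gene order by single-linkage
   clustering of 1:1 ortholog pairs with at most *w* intervening
   ortholog-bearing genes in both genomes, compared to permutation nulls
   with scrambled gene orders; window selection and a gene-wise false
   positive rate (null / real participation).
4. **ncRNA screen** — 8-mers ranked by enrichment of an upstream DUSE
   element (`[AT]CCCA[AT]AA`, ~63 bp upstream), filtered for the class I/II
   small-RNA architecture: a 5-bp 5' stem, the conserved bulge
   `CCTTACAGCCAA` immediately 3' of it, and a complementary 3' stem
   40–70 bp downstream.
5. **Social genes** — Nei–Gojobori dN (repeat codons excluded), a
   conservation score penalizing mismatches and unaligned sequence, the
   social expression index S/(S+V) from stage-structured RNA-seq
   percentage representation, and the regression / Mann–Whitney battery
   relating expression to divergence.

The synthetic-data generator (`dictycomp.simulate`) is first-class, tested
code: it plants SSR tracts, homopolymer runs, rearrangements, ncRNA loci,
class-targeted dN and class-structured expression counts, records
everything in a truth bundle, and verifies the truth against the emitted
files by independent re-parsing.

## Worked example

```
python analysis/01_simulate.py --seed 1
python analysis/04_synteny.py
python analysis/06_social_evolution.py
```

prints (seed 1):

```
dataset: 681 genes over two species, 83 planted SSR tracts, 635 homopolymer runs, 16 ncRNA loci
truth check: PASS (1428 entries verified)

w=0: 25 blocks, mean size 12.0 genes (max 42); 99.7% of 300 ortholog pairs participate
permutation null: 3.9 ± 1.6% over 100 permutations; gene-wise FPR 3.9%
selected window w = 0

dN ~ social index: slope 0.576, R2 0.841, P 2.4e-98 (n = 243)
CS ~ social index: slope -0.989, R2 0.791, P 7e-84
social index, genes with vs without orthologs: medians 0.40 vs 0.60, Mann-Whitney P 0.019 (n = 243, 28)
```

Reading this: the truth check confirms every planted feature is present in
the emitted FASTA/GFF3/TSV files.  With 8 planted rearrangements the 300
ortholog pairs fall into 25 blocks of perfectly conserved order, while
scrambled control genomes put only ~4% of pairs into blocks, so roughly 4%
of the genes called syntenic would be expected by chance.  Social genes are
generated with higher nonsynonymous divergence (dN 0.30 vs 0.10), and the
regression of per-pair dN on the social expression index recovers a strong
positive slope (and the mirror-image negative slope for the conservation
score); genes without an ortholog in the other species have a markedly
higher social index, as planted.

The remaining stages:

```
python analysis/02_repeats.py        # SSR tracts, genome fraction, long tracts
python analysis/03_homopolymers.py   # thresholds, densities, homology
python analysis/05_ncrna.py          # DUSE enrichment + stem filter
```

A `dictycomp` console command exposes the same stages
(`dictycomp simulate|ssr|homopolymers|synteny|ncrna|social|all`), e.g.

```
dictycomp simulate --out ds --seed 7 --n-genes 60
dictycomp all --dataset ds --out results_ds --seed 7
```

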