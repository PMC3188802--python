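# Methods

`dictycomp` re-implements the bespoke computations of a two-genome
comparative analysis of social amoebae (a *Dictyostelium purpureum* /
*D. discoideum*-style pair): simple-sequence-repeat statistics, amino-acid
homopolymer analysis, synteny-block detection with permutation nulls, a
DUSE-anchored ncRNA screen, and social-gene molecular evolution.  All stages
are exercised end-to-end on synthetic paired genomes with planted, recorded
ground truth, so every detector can be scored for exact recovery and every
estimator for parameter recovery.

## Coordinate and masking conventions

All intervals are 0-based half-open internally; GFF3 (1-based inclusive) and
BED conversion happen at the file boundary.  Soft-masked (lowercase) FASTA is
the masking interface; a `hard_mask` flag additionally treats `N` as masked.
How a "masked genome" was produced (repeat library vs SSR masking) is an
input choice, not something the package guesses.

## Simple sequence repeats

A tract is a maximal perfect tandem repeat of a 1–20 bp unit.  Minimum
whole-copy numbers are unit-length specific: 10 (mono), 7 (di), 5 (tri),
4 (tetra) and 3 for units of 5–20 bp.  Fractional trailing units extend the
reported span and copy number but qualification uses the whole-copy count —
this keeps maximality compatible with a crisp threshold.  Detection scans the
forward strand only (a unit and its reverse complement are distinct; the
aggregate statistics are strand-symmetric), masked positions terminate
tracts so they never cross assembly gaps, units are reported in canonical
phase (lexicographically least rotation), and tracts whose unit repeats a
shorter unit are reported only at the primitive unit length.  The genome
fraction covered is computed as union bp by default (`summed` available),
because the source statistic does not say which was used.

## Amino-acid homopolymers

A run of amino acid *a* with proteome frequency *f* in a proteome of *N*
residues is called longer than expected by chance when its length reaches
the smallest *L* with *N·f^L ≤ α* (α = 0.01): *N·f^L* bounds the expected
number of run starts of length ≥ *L*, so the thresholds self-calibrate to
about α expected false calls per proteome.  On a Dictyostelium-like
composition at the scale of a full proteome (~6.4 × 10⁶ residues) the
thresholds fall in the 6–9 residue band.  The composition used in tests
keeps the dictyostelid ranking (N > I ≈ S > K …) but floors rare residues
near 1.8%; with truly rare residues (W < 1%) the same rule gives thresholds
of 5, which is a property of the formula, not a defect.

Only significant runs enter densities (summed run residues per 1,000
proteome residues) and homology calls.  Ortholog pairs are globally aligned
with BLOSUM62 and affine gaps (open 11, extend 1, in score units; the first
gap residue costs the opening penalty).  Two runs are homologous when they
share the amino acid and overlap in ≥ 1 aligned column (a configurable
minimum-overlap is provided; the minimal rule is the strictest reading of
positional conservation).  Fractions of runs without orthologs are reported
over all significant runs, alongside the within-ortholog homologous
fractions.

## Synteny

Gene orders are restricted to genes with a 1:1 ortholog; genes without one
are invisible when counting intervening genes.  Two ortholog pairs are
linked at window *w* when the genes are on one scaffold of genome A with at
most *w* intervening (ortholog-bearing) genes and their partners are on one
chromosome of genome B with at most *w* intervening genes.  Blocks are
connected components (≥ 2 members) under single linkage.  Linkage is
orientation-free — a fully reversed scaffold still clusters — with a
strict-order mode behind a flag.

The null scrambles gene order uniformly and independently within each
scaffold (whole-genome shuffling is available), preserving pairings and
scaffold sizes; participation (fraction of pairs in any block) is summarized
over `n_perm = 100` permutations with a recorded seed.  For n = 4 genes on
one scaffold per genome at w = 0, exhaustive enumeration of all 24 orders
gives mean participation exactly 2/3, and preserved-adjacency fractions
follow the analytic 2/n — both are regression-tested.  Window selection
takes the largest *w* whose participation growth over *w − 1* is positive
and exceeds the null growth mean by ≥ 2 null SDs (the significance rule
behind "grows faster than the null" is otherwise unspecified; the strict
inequality prevents saturated maps from selecting arbitrarily large *w*).
The gene-wise false positive rate is null participation divided by real
participation.

## ncRNA screen

The DUSE promoter element is the degenerate motif `[AT]CCCA[AT]AA`.
Candidate anchors come from ranking 8-mers by upstream-DUSE enrichment: an
occurrence counts as DUSE-positive when a motif match starts 40–90 bp
upstream (a window around the canonical ~63 bp spacing), and each k-mer is
scored by a one-sided binomial test against the genome-wide probability that
a uniformly placed window contains a DUSE start.  Counts are pooled over all
scaffolds — per-scaffold ranking lets locally repeated background k-mers
outrank genuine anchors.  The structural filter then requires a 5-bp 5' stem
starting within 15 bp upstream of (or at) the anchor whose exact reverse
complement lies 40–70 bp downstream of the stem end; the conserved 12-bp
bulge `CCTTACAGCCAA` immediately 3' of the 5' stem is recorded, and classes
are assigned from the 5' stem (GTTGA → class I, GCTCG → class II, otherwise
putative).  All qualifying stem placements are emitted; the pipeline
de-duplicates identical placements reached from different anchor 8-mers.
The stem rule alone is weak — near a random anchor with an upstream DUSE
the expected number of qualifying placements is `16 × 31 × q⁵` (q the
base-complement match probability, ≈ 0.48 for uniform composition), which
the tests verify by simulation — so the DUSE + anchor + bulge combination
carries the specificity.

## Molecular evolution and social genes

dN/dS uses Nei–Gojobori proportional counting: per-codon synonymous site
fractions (changes producing stops count as nonsynonymous), averaged over
the two sequences; observed differences classified by enumerating minimal
substitution paths between codons, excluding paths through stops (falling
back to all paths when every path is blocked); Jukes–Cantor correction
d = −3/4 ln(1 − 4p/3), with p ≥ 3/4 flagged saturated/undefined.  The
implementation is verified against an independent path-enumeration oracle
over all 61 × 61 sense-codon pairs.  Codons backing significant homopolymer
runs are masked before estimation (repeat exclusion), since slippage-driven
repeats would otherwise inflate apparent divergence.

The conservation score is identical aligned residue pairs divided by the
length of the longer unaligned protein — an explicit stand-in, stated in
outputs, for a score defined only qualitatively (declining with both point
differences and unaligned sequence).

The social expression index is S/(S+V): mean percentage representation over
the six social-stage libraries (4–24 h after starvation) over that mean plus
the vegetative percentage.  QC requires ≥ 20 reads summed over libraries and
replicate correlation ≥ 0.8 across stages where replicates exist (the
source's exact thresholds live in unavailable supplementary material; these
defaults are stated, not inferred).  Regressions are OLS with two-sided
slope tests; group comparisons use Student's t or Mann–Whitney U (asymptotic
with tie correction).  Gamete-stage indices reuse the same functional form.

## Synthetic data generator

The generator's defaults are the study conditions: 300 ortholog pairs, 6/4
scaffolds, AT fraction 0.76 (the canonical ~77% AT of dictyostelid genomes,
not printed in the source's summary table), 8 rearrangement operations
(inversions applied before translocations, breakpoints uniform over gene
adjacencies), 12% gene turnover per species, 3% inparalogs, slippage tracts
at 0.5/kb of intergenic sequence with geometric extra copies (p = 0.5),
0.8 homopolymer runs per protein (10–15 residues of N/Q/S/T), dN targets
0.10 (vegetative) and 0.30 (social) with 30% social genes, a social-index
separation of 0.30, negative-binomial counts with dispersion 0.08, and 8
ncRNA loci per species (class I/II stems in genome A, the GAATT stem in
genome B).  Mean protein length is 180 codons and mean intergenic spacing
260 bp, giving ~300 kb genomes — large enough for the ±2-point AT-content
guarantee while keeping a full pipeline run under a minute.

Divergence is applied as single nonsynonymous substitutions at distinct
codons chosen to hit the class dN target through the inverse Jukes–Cantor
map, computed over the repeat-excluded codons so the estimator's
repeat-exclusion convention matches the target definition.  Synonymous
changes are not simulated (dS ≈ 0): the analyses require controlled dN, not
realistic dS.  Substitutions avoid homopolymer runs and their flanking
codons so planted runs survive divergence exactly.

Expression counts give each gene a lognormal (σ = 1.2) stage profile across
the six social time points — emulating developmental regulation, and
necessary for the replicate-correlation QC to be meaningful — normalized so
the mean social expression hits the class index target.  Species-unique
genes are social with probability 0.6, reproducing the association between
social expression and ortholog absence.

By default the background is rejection-sampled so that no unplanted
qualifying SSR tract and no bulge-internal anchor 8-mer occurs anywhere
(CDSs are repaired codon-by-codon; assembled scaffolds are re-screened and
offending background segments regenerated at fixed length, so coordinates
never shift).  This makes recall and precision against truth exactly 1 the
correct expectation.  With `suppress_background_repeats=False` the
background is plain iid sequence whose tract content follows the analytic
expectation `n · Σ_w (1 − p[w₋₁]) · Π_b p_b^(m·c_b(w))` over primitive
units w — verified by simulation.  Planted ncRNA loci are validated in
isolation across all five bulge anchor frames to yield exactly one stem
placement, so "recovered exactly once" is well-defined.

What the generator does **not** emulate: realistic intergenic composition
beyond AT fraction, indels within CDS (alignment behaviour on gaps is tested
with constructed cases instead), transposons, dS, and assembly gaps.
Passing tests therefore demonstrate correctness of the computations under
controlled conditions, not robustness to every artefact of real assemblies.

## Problem sizes and determinism

The test suite uses a 60-pair dataset for structural checks and the 300-pair
default dataset for parameter recovery; slope-sign recovery runs 100
replicates of a reduced 36-pair configuration (proteins of 120 codons, no
ncRNA loci), sizes chosen so the full suite and the acceptance script each
complete in minutes on one CPU.  All stochastic stages draw from a single
seeded `numpy` generator; the same seed reproduces byte-identical outputs,
and every run emits a provenance block with parameters, seed and input
checksums.

## Known limitations

- The conservation score and the QC thresholds are declared stand-ins for
  quantities the source defines only loosely; absolute values are not
  comparable to the original figures, though directions and test outcomes
  are.
- dN is Nei–Gojobori, not maximum likelihood; on real data it will differ
  numerically from codeml-style estimates, particularly at high divergence.
- The ncRNA screen is sequence-pattern based; it does not fold RNA or score
  stem covariation.
- Synteny participation denominators count 1:1 pairs (genes and pairs
  coincide for 1:1 maps); inparalogs are excluded from the ordered map.
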