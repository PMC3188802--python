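"""Amino-acid homopolymer detection and the statistics built on it.

A homopolymer is a maximal run of one amino acid in a protein.  A run is
called non-random ("significant") when it is longer than expected by chance
given the proteome composition: with total proteome length N and amino-acid
frequency f, the expected number of runs of length >= L is bounded by
``N * f**L``, and the threshold is the smallest L with ``N * f**L <= alpha``
(alpha = 0.01 by default).  Only significant runs enter density and homology
statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: standard-table codons per amino acid (uppercase DNA)
CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    CODONS_FOR_AA.setdefault(aa, []).append(codon)


@dataclass
class AAThresholdTable:
    """Per-amino-acid proteome frequency and minimum non-random run length."""

    frequency: dict[str, float]
    min_len: dict[str, int | None]  # None where the amino acid is absent
    total_residues: int
    alpha: float


@dataclass
class AAHomopolymer:
    protein_id: str
    amino_acid: str
    start: int  # 0-based residue offset
    length: int
    significant: bool
    codons: list[str] | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


def thresholds_from_composition(frequency: Mapping[str, float],
                                total_residues: int,
                                alpha: float = 0.01,
                                max_len: int = 1000) -> dict[str, int | None]:
    """Smallest L >= 2 with ``total_residues * f**L <= alpha`` per amino acid."""
    out: dict[str, int | None] = {}
    for aa in AMINO_ACIDS:
        f = frequency.get(aa, 0.0)
        if f <= 0:
            out[aa] = None
            continue
        if f >= 1:
            out[aa] = max_len
            continue
        # N * f^L <= alpha  <=>  L >= log(N/alpha) / log(1/f)
        exact = math.log(total_residues / alpha) / math.log(1.0 / f)
        L = max(2, math.ceil(exact))
        if total_residues * f ** L > alpha:  # guard against fp rounding
            L += 1
        out[aa] = min(L, max_len)
    return out


def aa_run_thresholds(proteome: Mapping[str, str] | Iterable[str],
                      alpha: float = 0.01) -> AAThresholdTable:
    """Composition-based run-length thresholds computed from a proteome."""
    seqs = list(proteome.values()) if isinstance(proteome, Mapping) else list(proteome)
    total = sum(len(s) for s in seqs)
    if total < 1000:
        raise ValueError(f"proteome too small ({total} residues; need >= 1000)")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for s in seqs:
        for aa in s:
            if aa in counts:
                counts[aa] += 1
    freq = {aa: counts[aa] / total for aa in AMINO_ACIDS}
    absent = [aa for aa in AMINO_ACIDS if counts[aa] == 0]
    if absent:
        warnings.warn(f"amino acids absent from proteome: {absent}; "
                      "runs of them are never significant")
    return AAThresholdTable(
        frequency=freq,
        min_len=thresholds_from_composition(freq, total, alpha),
        total_residues=total,
        alpha=alpha,
    )


def find_homopolymers(protein_id: str, protein: str,
                      thresholds: AAThresholdTable,
                      cds: str | None = None) -> list[AAHomopolymer]:
    """All maximal runs of length >= 2, flagged significant per thresholds.

    When a CDS is supplied it must translate to the protein (a trailing stop
    codon is allowed) and each run carries its backing codons.
    """
    if cds is not None:
        if len(cds) % 3:
            raise ValueError(f"{protein_id}: CDS length not divisible by 3")
        translated = str(Seq(cds).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
        if translated != protein:
            for i, (x, y) in enumerate(zip(translated, protein)):
                if x != y:
                    raise ValueError(
                        f"{protein_id}: CDS translation mismatch at residue "
                        f"{i}: {x!r} != {y!r}")
            raise ValueError(f"{protein_id}: CDS/protein length mismatch "
                             f"({len(translated)} vs {len(protein)})")
    runs: list[AAHomopolymer] = []
    i, n = 0, len(protein)
    while i < n:
        j = i + 1
        while j < n and protein[j] == protein[i]:
            j += 1
        if j - i >= 2:
            aa = protein[i]
            min_len = thresholds.min_len.get(aa)
            runs.append(AAHomopolymer(
                protein_id=protein_id,
                amino_acid=aa,
                start=i,
                length=j - i,
                significant=min_len is not None and (j - i) >= min_len,
                codons=[cds[3 * k:3 * k + 3] for k in range(i, j)]
                if cds is not None else None,
            ))
        i = j
    return runs


def repeat_density(runs: Iterable[AAHomopolymer],
                   total_residues: int) -> dict[str, float]:
    """Significant-run residues per amino acid, per 1,000 residues of proteome."""
    if total_residues <= 0:
        raise ValueError("total_residues must be positive")
    dens = {aa: 0.0 for aa in AMINO_ACIDS}
    for run in runs:
        if run.significant:
            dens[run.amino_acid] += run.length
    return {aa: v / total_residues * 1000.0 for aa, v in dens.items()}


@dataclass
class CorrelationResult:
    r: float
    p: float
    defined: bool


def density_correlation(dens_a: Mapping[str, float],
                        dens_b: Mapping[str, float]) -> CorrelationResult:
    """Pearson correlation of the 20 paired per-amino-acid densities."""
    x = np.array([dens_a[aa] for aa in AMINO_ACIDS])
    y = np.array([dens_b[aa] for aa in AMINO_ACIDS])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in a density vector; correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), True)


def codon_diversity(run: AAHomopolymer) -> tuple[int, float]:
    """Distinct backing codons and a [0,1] diversity normalized by the lesser
    of run length and the amino acid's codon repertoire."""
    if run.codons is None:
        raise ValueError("run has no attached codons")
    distinct = len(set(run.codons))
    available = len(CODONS_FOR_AA.get(run.amino_acid, []))
    denom = min(run.length, available) - 1
    return distinct, (distinct - 1) / denom if denom > 0 else 0.0


@dataclass
class ProteinAlignment:
    """A pairwise global alignment as a residue-to-residue map."""

    id_a: str
    id_b: str
    len_a: int
    len_b: int
    score: float
    pairs: list[tuple[int, int]]  # aligned residue index pairs (a, b)
    identities: int

    @property
    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)


def global_align(protein_a: str, protein_b: str,
                 id_a: str = "a", id_b: str = "b",
                 open_gap: float = 11.0,
                 extend_gap: float = 1.0,
                 matrix_name: str = "BLOSUM62") -> ProteinAlignment:
    """Optimal global alignment (BLOSUM62, affine gaps) with a deterministic
    choice among co-optimal alignments (Biopython's first enumeration order,
    which prefers aligned columns over gaps)."""
    if not protein_a or not protein_b:
        raise ValueError("cannot align an empty sequence")
    matrix = substitution_matrices.load(matrix_name)
    allowed = set(str(matrix.alphabet))
    for name, seq in ((id_a, protein_a), (id_b, protein_b)):
        bad = set(seq) - allowed
        if bad:
            raise ValueError(f"{name}: non-amino-acid symbols {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.mode = "global"
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    aln = aligner.align(protein_a, protein_b)[0]
    pairs: list[tuple[int, int]] = []
    identities = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            i, j = a_start + off, b_start + off
            pairs.append((i, j))
            if protein_a[i] == protein_b[j]:
                identities += 1
    return ProteinAlignment(id_a, id_b, len(protein_a), len(protein_b),
                            float(aln.score), pairs, identities)


@dataclass
class RepeatHomologyCall:
    gene_a: str
    gene_b: str
    run_a: AAHomopolymer
    run_b: AAHomopolymer
    homologous: bool
    overlap_columns: int


@dataclass
class RepeatHomologySummary:
    calls: list[RepeatHomologyCall]
    fraction_homologous_a: float
    fraction_homologous_b: float
    n_runs_with_ortholog_a: int
    n_runs_with_ortholog_b: int
    #: fraction of all significant runs lying in genes without an ortholog
    fraction_no_ortholog_a: float
    fraction_no_ortholog_b: float


def call_repeat_homology(pairs: list[tuple[str, str]],
                         runs_a: Mapping[str, list[AAHomopolymer]],
                         runs_b: Mapping[str, list[AAHomopolymer]],
                         alignments: Mapping[tuple[str, str], ProteinAlignment],
                         min_overlap: int = 1) -> RepeatHomologySummary:
    """Call run pairs homologous when they share the amino acid and overlap by
    at least ``min_overlap`` aligned columns within the pair's global
    alignment.  Only significant runs are considered."""
    calls: list[RepeatHomologyCall] = []
    hom_a: set[tuple[str, int]] = set()
    hom_b: set[tuple[str, int]] = set()
    n_with_a = n_with_b = 0
    for ga, gb in pairs:
        if (ga, gb) not in alignments:
            raise KeyError(f"no alignment for ortholog pair ({ga}, {gb})")
        aln = alignments[(ga, gb)]
        a_to_b = aln.a_to_b
        sig_a = [r for r in runs_a.get(ga, []) if r.significant]
        sig_b = [r for r in runs_b.get(gb, []) if r.significant]
        n_with_a += len(sig_a)
        n_with_b += len(sig_b)
        for ra in sig_a:
            for rb in sig_b:
                overlap = sum(
                    1 for i in range(ra.start, ra.end)
                    if rb.start <= a_to_b.get(i, -1) < rb.end)
                hom = (ra.amino_acid == rb.amino_acid
                       and overlap >= min_overlap)
                calls.append(RepeatHomologyCall(ga, gb, ra, rb, hom, overlap))
                if hom:
                    hom_a.add((ga, ra.start))
                    hom_b.add((gb, rb.start))
    total_sig_a = sum(sum(r.significant for r in v) for v in runs_a.values())
    total_sig_b = sum(sum(r.significant for r in v) for v in runs_b.values())
    return RepeatHomologySummary(
        calls=calls,
        fraction_homologous_a=len(hom_a) / n_with_a if n_with_a else 0.0,
        fraction_homologous_b=len(hom_b) / n_with_b if n_with_b else 0.0,
        n_runs_with_ortholog_a=n_with_a,
        n_runs_with_ortholog_b=n_with_b,
        fraction_no_ortholog_a=(total_sig_a - n_with_a) / total_sig_a
        if total_sig_a else 0.0,
        fraction_no_ortholog_b=(total_sig_b - n_with_b) / total_sig_b
        if total_sig_b else 0.0,
    )


@dataclass
class GroupComparison:
    test: str
    n_with: int
    n_without: int
    mean_with: float
    mean_without: float
    median_with: float
    median_without: float
    statistic: float
    p: float
    direction: str  # "with>without", "with<without" or "equal"
    degenerate: bool = False


def compare_by_repeat_status(values: np.ndarray, has_repeat: np.ndarray,
                             test: str = "t") -> GroupComparison:
    """Two-sided comparison of a per-gene statistic between genes with and
    without (significant) repeats: Student's t or Mann-Whitney U."""
    values = np.asarray(values, dtype=float)
    has_repeat = np.asarray(has_repeat, dtype=bool)
    with_ = values[has_repeat]
    without = values[~has_repeat]
    if len(with_) < 2 or len(without) < 2:
        raise ValueError("each group needs at least 2 observations")
    degenerate = np.ptp(values) == 0
    if degenerate:
        warnings.warn("identical constant groups; comparison degenerate")
        stat, p = float("nan"), float("nan")
    elif test == "t":
        stat, p = stats.ttest_ind(with_, without, equal_var=True)
    elif test == "mannwhitney":
        stat, p = stats.mannwhitneyu(with_, without, alternative="two-sided",
                                     method="asymptotic")
    else:
        raise ValueError(f"unknown test {test!r}")
    mw, mo = float(with_.mean()), float(without.mean())
    direction = ("with>without" if mw > mo
                 else "with<without" if mw < mo else "equal")
    return GroupComparison(
        test=test, n_with=len(with_), n_without=len(without),
        mean_with=mw, mean_without=mo,
        median_with=float(np.median(with_)),
        median_without=float(np.median(without)),
        statistic=float(stat), p=float(p),
        direction=direction, degenerate=degenerate)
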