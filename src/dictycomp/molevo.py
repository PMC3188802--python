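"""Per-ortholog-pair divergence and social-expression statistics.

dN/dS follow Nei-Gojobori proportional counting: each codon's positions are
apportioned into synonymous and nonsynonymous site fractions (changes to stop
codons count as nonsynonymous); observed differences between codon pairs are
classified by enumerating the minimal substitution paths between them,
averaging over paths and excluding paths that pass through stop codons; and
the raw proportions are corrected for multiple hits with the one-parameter
(Jukes-Cantor) formula d = -3/4 ln(1 - 4p/3).  Proportions at or beyond the
p = 3/4 saturation bound are flagged undefined.

The conservation score is identical aligned residue pairs divided by the
length of the longer unaligned protein, so both mismatches and unaligned
(gapped) sequence reduce it.  The social expression index of a gene is
S / (S + V), the mean percentage representation across the six social-stage
libraries over that mean plus the vegetative percentage representation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .homopolymers import ProteinAlignment

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TO_AA)
BASES = "ACGT"

SOCIAL_TIMEPOINTS = ("h04", "h08", "h12", "h16", "h20", "h24")
VEGETATIVE_STAGE = "veg"


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each position contributes the fraction of its three single-base changes
    that are synonymous; changes creating stop codons are nonsynonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two sense
    codons, averaged over minimal substitution paths.

    Paths passing through stop codons are excluded; if every path is blocked,
    the average falls back to all paths (stops allowed as intermediates).
    """
    for c in (c1, c2):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        syn = nonsyn = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            aa_cur = CODON_TO_AA.get(cur)
            aa_nxt = CODON_TO_AA.get(nxt)
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    orders = list(itertools.permutations(diff_pos))
    results = [r for o in orders if (r := walk(o, allow_stops=False))]
    if not results:
        results = [walk(o, allow_stops=True) for o in orders]
    syn = float(np.mean([r[0] for r in results]))
    nonsyn = float(np.mean([r[1] for r in results]))
    return syn, nonsyn


@dataclass
class DnDsResult:
    dN: float           # nan when undefined/saturated
    dS: float
    pN: float
    pS: float
    N: float
    S: float
    Nd: float
    Sd: float
    n_codons: int
    dN_defined: bool
    dS_defined: bool
    saturated_N: bool = False
    saturated_S: bool = False


def jukes_cantor(p: float) -> float:
    """One-parameter multiple-hit correction; nan at or beyond saturation."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * float(np.log(1 - 4 * p / 3))


def codon_align(cds_a: str, cds_b: str, alignment: ProteinAlignment,
                masked_a: set[int] | frozenset[int] = frozenset(),
                masked_b: set[int] | frozenset[int] = frozenset(),
                ) -> list[tuple[str, str]]:
    """Back-translate a protein alignment to aligned codon pairs.

    Gap columns are dropped (they carry no substitution information) and
    columns where either residue index is masked (e.g. significant
    homopolymer codons, per the repeat-exclusion rule) are excluded.
    """
    for name, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) % 3:
            raise ValueError(f"cds_{name} length not divisible by 3")
    n_a, n_b = len(cds_a) // 3, len(cds_b) // 3
    pairs = []
    for i, j in alignment.pairs:
        if i in masked_a or j in masked_b:
            continue
        if i >= n_a or j >= n_b:
            raise ValueError("protein alignment extends beyond CDS")
        ca, cb = cds_a[3 * i:3 * i + 3], cds_b[3 * j:3 * j + 3]
        pairs.append((ca, cb))
    return pairs


def estimate_dn(codon_pairs: Sequence[tuple[str, str]],
                min_codons: int = 10) -> DnDsResult:
    """Nei-Gojobori dN and dS over aligned codon pairs."""
    for a, b in codon_pairs:
        if a in STOP_CODONS or b in STOP_CODONS:
            raise ValueError(f"stop codon mid-sequence: {a}/{b}")
    usable = list(codon_pairs)
    if len(usable) < min_codons:
        raise ValueError(
            f"need >= {min_codons} comparable codon pairs, got {len(usable)}")
    S = N = Sd = Nd = 0.0
    for ca, cb in usable:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds_, dn_ = codon_path_differences(ca, cb)
        Sd += ds_
        Nd += dn_
    # zero observed differences define a rate of 0 even with no sites of
    # that class (e.g. identical Met/Trp-only sequences have S = 0)
    pN = Nd / N if N > 0 else (0.0 if Nd == 0 else float("nan"))
    pS = Sd / S if S > 0 else (0.0 if Sd == 0 else float("nan"))
    dN = jukes_cantor(pN) + 0.0 if not np.isnan(pN) else float("nan")
    dS = jukes_cantor(pS) + 0.0 if not np.isnan(pS) else float("nan")
    return DnDsResult(
        dN=dN, dS=dS, pN=pN, pS=pS, N=N, S=S, Nd=Nd, Sd=Sd,
        n_codons=len(usable),
        dN_defined=bool(np.isfinite(dN)),
        dS_defined=bool(np.isfinite(dS)),
        saturated_N=N > 0 and pN >= 0.75,
        saturated_S=S > 0 and pS >= 0.75,
    )


def conservation_score(alignment: ProteinAlignment) -> float:
    """Identities over the longer unaligned length: in [0,1], declining with
    both point differences and non-aligned sequence."""
    longer = max(alignment.len_a, alignment.len_b)
    if longer == 0:
        raise ValueError("empty alignment")
    return alignment.identities / longer


@dataclass
class ExpressionProfile:
    gene_id: str
    vegetative_pct: float
    social_pct: dict[str, float]  # timepoint -> percentage representation
    qc_pass: bool = True

    @property
    def mean_social(self) -> float:
        return float(np.mean([self.social_pct[t] for t in SOCIAL_TIMEPOINTS]))


@dataclass
class SocialIndex:
    gene_id: str
    index: float


def social_index(profile: ExpressionProfile) -> SocialIndex | None:
    """S / (S + V); None (excluded) when both terms are zero or QC failed."""
    if not profile.qc_pass:
        return None
    s = profile.mean_social
    v = profile.vegetative_pct
    if s + v == 0:
        warnings.warn(f"{profile.gene_id}: zero expression everywhere; "
                      "social index undefined")
        return None
    return SocialIndex(profile.gene_id, s / (s + v))


def gamete_index(gamete_count: float, vegetative_count: float) -> float | None:
    """Gamete-stage analogue of the social index; None when both are zero."""
    if gamete_count < 0 or vegetative_count < 0:
        raise ValueError("counts must be >= 0")
    total = gamete_count + vegetative_count
    if total == 0:
        return None
    return gamete_count / total


def percentage_representation(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-library percentage representation from a long count table with
    columns gene_id, stage, replicate, count."""
    out = counts.copy()
    out["library"] = out["stage"].astype(str) + "." + out["replicate"].astype(str)
    totals = out.groupby("library")["count"].transform("sum")
    out["pct"] = out["count"] / totals * 100.0
    return out


def qc_filter(counts: pd.DataFrame, min_total: int = 20,
              min_reproducibility: float = 0.8) -> list[ExpressionProfile]:
    """Build QC-filtered expression profiles from a long count table.

    A gene passes when its reads summed over all libraries reach ``min_total``
    and, where replicates exist, the Pearson correlation of replicate count
    vectors across stages reaches ``min_reproducibility``.
    """
    pct = percentage_representation(counts)
    profiles = []
    for gene_id, sub in pct.groupby("gene_id", sort=True):
        total = sub["count"].sum()
        qc = total >= min_total
        wide = sub.pivot_table(index="stage", columns="replicate",
                               values="count", aggfunc="sum")
        if qc and wide.shape[1] >= 2:
            reps = wide.iloc[:, :2]
            x, y = reps.iloc[:, 0].to_numpy(float), reps.iloc[:, 1].to_numpy(float)
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                r, _ = stats.pearsonr(x, y)
                qc = r >= min_reproducibility
        stage_pct = sub.groupby("stage")["pct"].mean()
        social = {t: float(stage_pct.get(t, 0.0)) for t in SOCIAL_TIMEPOINTS}
        profiles.append(ExpressionProfile(
            gene_id=gene_id,
            vegetative_pct=float(stage_pct.get(VEGETATIVE_STAGE, 0.0)),
            social_pct=social,
            qc_pass=bool(qc),
        ))
    return [p for p in profiles if p.qc_pass]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def regress_on_index(values: Sequence[float],
                     indices: Sequence[float]) -> RegressionResult:
    """OLS of a per-gene statistic (dN or conservation score) on the social
    index, with the two-sided slope p-value."""
    x = np.asarray(indices, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y):
        raise ValueError("values and indices differ in length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError(f"need >= 10 paired observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in indices")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2),
                            p=float(res.pvalue), n=len(x))


@dataclass
class PresenceComparison:
    median_with: float
    median_without: float
    n_with: int
    n_without: int
    statistic: float
    p: float


def ortholog_presence_vs_index(indices: Sequence[float],
                               has_ortholog: Sequence[bool]) -> PresenceComparison:
    """Mann-Whitney U (two-sided, normal approximation with tie correction)
    comparing social indices of genes with vs without orthologs."""
    x = np.asarray(indices, dtype=float)
    flag = np.asarray(has_ortholog, dtype=bool)
    with_, without = x[flag], x[~flag]
    if len(with_) == 0 or len(without) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(with_, without, alternative="two-sided",
                                 method="asymptotic")
    return PresenceComparison(
        median_with=float(np.median(with_)),
        median_without=float(np.median(without)),
        n_with=len(with_), n_without=len(without),
        statistic=float(stat), p=float(p))


@dataclass
class GenePairEvolution:
    gene_a: str
    gene_b: str
    dN: float
    dS: float
    conservation: float
    repeat_excluded: bool


def evolution_table(rows: list[GenePairEvolution]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_a, r.gene_b, r.dN, r.dS, r.conservation, r.repeat_excluded)
         for r in rows],
        columns=["gene_a", "gene_b", "dN", "dS", "conservation_score",
                 "repeat_excluded"])
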