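"""Synthetic paired-genome generator with planted, recorded ground truth.

Emulates the statistical structure of an AT-rich dictyostelid genome pair:
two genomes with a planted 1:1 ortholog map, gene-order rearrangements
(inversions then translocations), species-specific gene turnover, slippage
style simple-sequence-repeat tracts, amino-acid homopolymer runs backed by
real codons, DUSE+stem ncRNA loci, per-ortholog-pair nonsynonymous divergence
driven to class-specific dN targets, and negative-binomial stage-structured
expression counts with class-dependent social/vegetative means.

Every planted feature is recorded in a :class:`TruthRecord` whose coordinates
refer to the emitted files, so each analysis stage can be scored for exact
recovery.  By default background sequence is rejection-sampled so that no
unplanted SSR tract or ncRNA anchor occurs (``suppress_background_repeats``);
switching the flag off yields plain iid background whose incidental repeat
content follows the composition's analytic expectation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .homopolymers import CODONS_FOR_AA
from .io import (GeneModel, GenomeSequence, OrthologTable, revcomp,
                 write_fasta, write_gff3, write_ortholog_table,
                 write_plain_fasta)
from .molevo import CODON_TO_AA, SOCIAL_TIMEPOINTS, STOP_CODONS, VEGETATIVE_STAGE, codon_sites
from .ncrna import DUSE, MotifPattern, scan_motif, stem_filter
from .ssr import canonical_rotation, find_ssr_tracts, is_primitive, DEFAULT_MIN_COPIES

#: Dictyostelium-like amino-acid composition: asparagine/isoleucine/lysine/
#: serine-rich, as in AT-rich amoebozoan proteomes.  Rare residues are kept
#: at >= ~1.8% so composition-based run thresholds stay in the 6-9 band.
DICTY_AA_FREQ: dict[str, float] = {
    "N": 0.100, "I": 0.088, "K": 0.080, "S": 0.085, "L": 0.077,
    "E": 0.059, "D": 0.055, "T": 0.052, "Q": 0.048, "V": 0.046,
    "F": 0.044, "G": 0.043, "Y": 0.034, "P": 0.035, "A": 0.034,
    "R": 0.032, "H": 0.020, "M": 0.018, "C": 0.018, "W": 0.032,
}
_total = sum(DICTY_AA_FREQ.values())
DICTY_AA_FREQ = {k: v / _total for k, v in DICTY_AA_FREQ.items()}

RUN_PRONE_AAS = "NQST"  # dominant homopolymer residues in dictyostelids

BULGE = "CCTTACAGCCAA"
ANCHOR_8MERS = ("CCTTACAG", "CTTACAGC")
_STEM5_SET = ("GTTGA", "GCTCG", "GAATT")
#: every 8-mer of a stem5+bulge junction is invariant across planted loci,
#: hence equally DUSE-enriched and a possible scan anchor; all of them (and
#: their reverse complements, for minus-strand gene bodies) are kept out of
#: background sequence and validated at locus construction
_JUNCTION_8MERS = tuple(dict.fromkeys(
    (s + BULGE)[j:j + 8]
    for s in _STEM5_SET for j in range(len(s) + len(BULGE) - 7)))
_FORBIDDEN_KMERS = tuple(dict.fromkeys(
    _JUNCTION_8MERS + tuple(revcomp(a) for a in _JUNCTION_8MERS)))
CLASS_STEMS_A = {"GTTGA": "classI", "GCTCG": "classII"}
STEM_B = "GAATT"


class SimConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome pair."""

    n_genes: int = 300
    n_scaffolds_a: int = 6
    n_scaffolds_b: int = 4
    at_fraction: float = 0.76
    rearrangement_ops: int = 8
    gene_turnover: float = 0.12
    slippage_rate: float = 0.5          # expected tracts per kb intergenic
    slippage_geometric_p: float = 0.5   # extra-copy distribution
    homopolymer_rate: float = 0.8       # expected planted runs per protein
    dn_low: float = 0.10
    dn_high: float = 0.30
    social_fraction: float = 0.30
    social_effect: float = 0.30         # difference in expected social index
    nb_dispersion: float = 0.08
    n_ncrna_loci: int = 8               # per species
    inparalog_fraction: float = 0.03
    mean_protein_len: int = 180         # codons
    mean_intergenic: int = 260          # bp
    intron_fraction: float = 0.3
    suppress_background_repeats: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gene_turnover", "social_fraction", "social_effect",
                     "slippage_geometric_p", "at_fraction",
                     "inparalog_fraction", "intron_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name}={v} outside [0,1]")
        for name in ("n_genes", "n_scaffolds_a", "n_scaffolds_b",
                     "mean_protein_len", "mean_intergenic"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.n_genes < 2 * max(self.n_scaffolds_a, self.n_scaffolds_b):
            raise SimConfigError("too few genes for the scaffold counts")
        max_adjacencies = self.n_genes - self.n_scaffolds_b
        if self.rearrangement_ops > max_adjacencies:
            raise SimConfigError(
                f"rearrangement_ops={self.rearrangement_ops} exceeds the "
                f"{max_adjacencies} gene adjacencies of genome B")


@dataclass
class TruthRecord:
    """Planted ground truth, with coordinates valid for the emitted files."""

    genes: pd.DataFrame
    repeats: pd.DataFrame
    homopolymers: pd.DataFrame
    ncrna: pd.DataFrame
    rearrangements: pd.DataFrame
    config: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("genes", "repeats", "homopolymers", "ncrna",
                     "rearrangements"):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t",
                                       index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump({"config": self.config,
                       "n_genes": len(self.genes),
                       "n_repeats": len(self.repeats),
                       "n_homopolymers": len(self.homopolymers),
                       "n_ncrna": len(self.ncrna)}, fh, indent=2)

    @classmethod
    def load(cls, outdir: str | Path) -> "TruthRecord":
        outdir = Path(outdir)
        frames = {name: pd.read_csv(outdir / f"{name}.tsv", sep="\t")
                  for name in ("genes", "repeats", "homopolymers", "ncrna",
                               "rearrangements")}
        with open(outdir / "summary.json") as fh:
            config = json.load(fh)["config"]
        return cls(config=config, **frames)


@dataclass
class DatasetPaths:
    outdir: Path
    genome_a: Path
    genome_b: Path
    gff_a: Path
    gff_b: Path
    proteins_a: Path
    proteins_b: Path
    cds_a: Path
    cds_b: Path
    orthologs: Path
    expression_a: Path
    expression_b: Path
    truth_dir: Path

    @classmethod
    def in_dir(cls, outdir: str | Path) -> "DatasetPaths":
        d = Path(outdir)
        return cls(outdir=d,
                   genome_a=d / "genome_a.fasta", genome_b=d / "genome_b.fasta",
                   gff_a=d / "genes_a.gff3", gff_b=d / "genes_b.gff3",
                   proteins_a=d / "proteins_a.fasta",
                   proteins_b=d / "proteins_b.fasta",
                   cds_a=d / "cds_a.fasta", cds_b=d / "cds_b.fasta",
                   orthologs=d / "orthologs.tsv",
                   expression_a=d / "expression_a.tsv",
                   expression_b=d / "expression_b.tsv",
                   truth_dir=d / "truth")


# ---------------------------------------------------------------------------
# low-level sequence builders

def _codon_weights(at: float) -> dict[str, np.ndarray]:
    pb = {"A": at / 2, "T": at / 2, "C": (1 - at) / 2, "G": (1 - at) / 2}
    out = {}
    for aa, codons in CODONS_FOR_AA.items():
        w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


def _contains_forbidden_kmer(seq: str) -> bool:
    return any(k in seq for k in _FORBIDDEN_KMERS)


def _has_ssr(seq: str) -> bool:
    g = GenomeSequence("x", seq, np.zeros(len(seq), bool))
    return bool(find_ssr_tracts(g))


def _screened(draw, check, max_tries: int = 300, what: str = "sequence") -> str:
    for _ in range(max_tries):
        s = draw()
        if check(s):
            return s
    raise SimConfigError(f"could not generate clean {what} in {max_tries} tries")


class _SeqSampler:
    """iid DNA with a given AT fraction, optionally repeat/anchor-screened."""

    def __init__(self, rng: np.random.Generator, at: float, screen: bool):
        self.rng = rng
        self.p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
        self.screen = screen
        self.bases = np.array(list("ACGT"))

    def raw(self, n: int) -> str:
        return "".join(self.rng.choice(self.bases, size=n, p=self.p))

    def clean(self, n: int) -> str:
        if not self.screen:
            return self.raw(n)
        return _screened(
            lambda: self.raw(n),
            lambda s: not _has_ssr(s) and not _contains_forbidden_kmer(s),
            what="background")


# ---------------------------------------------------------------------------
# proteins, codons, divergence

def _make_protein(rng: np.random.Generator, cfg: SimConfig,
                  aas: np.ndarray, freqs: np.ndarray
                  ) -> tuple[str, list[tuple[str, int, int]]]:
    """A protein with planted homopolymer runs; returns (sequence, runs) with
    runs as (amino_acid, start, length)."""
    length = max(60, int(rng.normal(cfg.mean_protein_len,
                                    cfg.mean_protein_len / 3)))
    n_runs = int(rng.poisson(cfg.homopolymer_rate))
    run_specs = [(RUN_PRONE_AAS[rng.integers(len(RUN_PRONE_AAS))],
                  int(rng.integers(10, 16))) for _ in range(n_runs)]
    n_seg = n_runs + 1
    seg_lens = [max(5, x) for x in
                rng.multinomial(length, np.ones(n_seg) / n_seg)]
    parts: list[str] = []
    runs: list[tuple[str, int, int]] = []
    pos = 0
    for k in range(n_seg):
        seg = list(rng.choice(aas, size=seg_lens[k], p=freqs))
        left_aa = run_specs[k - 1][0] if k > 0 else None
        right_aa = run_specs[k][0] if k < n_runs else None
        if left_aa is not None:
            while seg[0] == left_aa:
                seg[0] = str(rng.choice(aas, p=freqs))
        if right_aa is not None:
            while seg[-1] == right_aa:
                seg[-1] = str(rng.choice(aas, p=freqs))
        parts.append("".join(seg))
        pos += len(seg)
        if k < n_runs:
            aa, rl = run_specs[k]
            runs.append((aa, pos, rl))
            parts.append(aa * rl)
            pos += rl
    return "".join(parts), runs


def _codons_for_protein(rng: np.random.Generator, protein: str,
                        weights: dict[str, np.ndarray]) -> list[str]:
    return [CODONS_FOR_AA[aa][rng.choice(len(CODONS_FOR_AA[aa]),
                                         p=weights[aa])]
            for aa in protein]


def _bad_spans(seq: str) -> list[tuple[int, int]]:
    """Qualifying SSR tracts plus forbidden anchor 8-mers in a sequence."""
    g = GenomeSequence("x", seq, np.zeros(len(seq), bool))
    spans = [t.span for t in find_ssr_tracts(g)]
    for k in _FORBIDDEN_KMERS:
        spans.extend((i, i + 8) for i in _find_all(seq, k))
    return spans


def _clean_cds(rng, protein, weights, screen: bool) -> list[str]:
    """AT-weighted codon choice with targeted repair: codons overlapping an
    accidental repeat tract or anchor 8-mer are resampled (uniformly over the
    amino acid's codons, which breaks the AT bias locally) until clean."""
    codons = _codons_for_protein(rng, protein, weights)
    if not screen:
        return codons
    for _ in range(1000):
        spans = _bad_spans("".join(codons) + "TAA")  # include the stop codon
        if not spans:
            return codons
        a, b = spans[0]
        for ci in range(a // 3, min((b + 2) // 3 + 1, len(codons))):
            options = CODONS_FOR_AA[protein[ci]]
            codons[ci] = options[rng.integers(len(options))]
    raise SimConfigError("could not generate a repeat-free CDS")


def _nonsyn_alternatives(codon: str) -> list[str]:
    aa = CODON_TO_AA[codon]
    alts = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] != aa:
                alts.append(alt)
    return alts


def _target_pn(dn: float) -> float:
    """Invert the one-parameter correction: p = 3/4 (1 - exp(-4 d / 3))."""
    return 0.75 * (1.0 - math.exp(-4.0 * dn / 3.0))


def _diverge(rng: np.random.Generator, codons: list[str],
             eligible: list[int], dn_target: float,
             screen: bool) -> list[str]:
    """Apply nonsynonymous single-base substitutions at distinct eligible
    codons so that Nei-Gojobori dN over the eligible codons hits the target."""
    n_sites = sum(codon_sites(codons[i])[1] for i in eligible)
    nd = min(len(eligible), round(_target_pn(dn_target) * n_sites))

    def draw():
        out = list(codons)
        for i in rng.choice(len(eligible), size=nd, replace=False):
            alts = _nonsyn_alternatives(codons[eligible[i]])
            out[eligible[i]] = alts[rng.integers(len(alts))]
        return out

    def ok(out):
        if not screen:
            return True
        s = "".join(out) + "TAA"  # include the stop codon
        return not _has_ssr(s) and not _contains_forbidden_kmer(s)

    for _ in range(100):
        c = draw()
        if ok(c):
            return c
    raise SimConfigError("could not place divergence without creating repeats")


# ---------------------------------------------------------------------------
# planted feature cores

def _repeat_core(rng: np.random.Generator, sampler: _SeqSampler,
                 cfg: SimConfig) -> tuple[str, int, int, str, float]:
    """A guarded SSR tract: returns (text, tract_start_rel, tract_end_rel,
    canonical_unit, copies)."""
    p = sampler.p

    def draw_unit(u: int) -> str:
        return "".join(rng.choice(sampler.bases, size=u, p=p))

    for _ in range(500):
        u = int(rng.integers(1, 7))
        unit = draw_unit(u)
        if not is_primitive(unit):
            continue
        copies = DEFAULT_MIN_COPIES[u] + int(rng.geometric(
            cfg.slippage_geometric_p)) - 1
        copies = min(copies, max(DEFAULT_MIN_COPIES[u], 120 // u))
        tract = unit * copies
        guard_l = str(rng.choice([b for b in "ACGT" if b != unit[-1]]))
        guard_r = str(rng.choice([b for b in "ACGT" if b != unit[0]]))
        core = guard_l + tract + guard_r
        g = GenomeSequence("x", core, np.zeros(len(core), bool))
        found = find_ssr_tracts(g)
        if (len(found) == 1 and found[0].span == (1, 1 + len(tract))
                and found[0].unit == canonical_rotation(unit)
                and not _contains_forbidden_kmer(core)):
            return core, 1, 1 + len(tract), canonical_rotation(unit), float(copies)
    raise SimConfigError("could not construct a clean repeat tract")


#: distinct 2-bp flanks given to each locus on both sides of the
#: stem5+bulge junction, so 8-mers crossing the junction boundary are never
#: shared between loci and cannot rank as enriched anchors
_FLANK_PAIRS = tuple("".join(p) for p in __import__("itertools")
                     .product("ACGT", repeat=2))


def _ncrna_core(rng: np.random.Generator, sampler: _SeqSampler,
                stem5: str, locus_index: int = 0) -> tuple[str, dict]:
    """A guarded ncRNA locus: DUSE .. gap .. stem5 + bulge + spacer + stem3,
    plus an 80-bp screened tail so the stem search window is self-contained.

    In AT-rich sequence accidental 5-bp stem pairs near the anchor are
    common (several are expected per locus), so after drawing the random
    gap/spacer/tail the construction repairs collisions in place: any
    non-planted stem placement reachable from any junction anchor frame is
    broken by mutating one background base inside it.

    Returns (text, meta) with meta holding locus geometry relative to the
    core start.
    """
    stem3 = revcomp(stem5)

    def flank_ok(f: str) -> bool:
        # the flanked junction may contain anchor 8-mers only at its frames
        s = f + stem5 + BULGE + f
        hits = sorted({i for k in _FORBIDDEN_KMERS for i in _find_all(s, k)})
        return hits == [2 + j for j in range(len(stem5) + len(BULGE) - 7)]

    flanks = [f for f in _FLANK_PAIRS if flank_ok(f)]
    flank = flanks[locus_index % len(flanks)]
    for _ in range(200):
        duse = ("A" if rng.random() < 0.5 else "T") + "CCCA" + \
               ("A" if rng.random() < 0.5 else "T") + "AA"
        gap = int(rng.integers(43, 64))        # DUSE start to stem5: 8+gap+2
        spacer_len = int(rng.integers(28, 57))  # separation = 12+2+spacer
        text = list(duse + sampler.raw(gap) + flank + stem5 + BULGE + flank
                    + sampler.raw(spacer_len) + stem3 + sampler.raw(80))
        stem5_start = 8 + gap + 2
        anchor = stem5_start + 5               # bulge start (CCTTACAG)
        stem3_start = anchor + len(BULGE) + 2 + spacer_len
        n_frames = len(stem5) + len(BULGE) - 7
        expected_pos = [stem5_start + j for j in range(n_frames)]
        # background = everything outside DUSE, flanks, stems and bulge
        fixed = set(range(8)) | set(range(stem5_start - 2,
                                          anchor + len(BULGE) + 2))
        fixed |= set(range(stem3_start, stem3_start + len(stem5)))

        def placements() -> set[tuple[int, int]]:
            g = GenomeSequence("x", "".join(text), np.zeros(len(text), bool))
            keys = set()
            for pos in expected_pos:
                for c in stem_filter(g, [pos]):
                    keys.add((c.stem5_start, c.stem3_start))
            return keys

        ok = False
        for _ in range(60):
            extras = placements() - {(stem5_start, stem3_start)}
            if not extras:
                ok = True
                break
            s5, s3 = sorted(extras)[0]
            span = [p for p in list(range(s5, s5 + len(stem5)))
                    + list(range(s3, s3 + len(stem5))) if p not in fixed]
            if not span:
                break  # collision entirely inside fixed elements: redraw
            p = span[rng.integers(len(span))]
            text[p] = str(rng.choice([b for b in "ACGT" if b != text[p]]))
        if not ok:
            continue
        text = "".join(text)
        # junction 8-mers must occur exactly at the locus frames, nowhere else
        anchor_hits = sorted({i for k in _FORBIDDEN_KMERS
                              for i in _find_all(text, k)})
        if anchor_hits != expected_pos:
            continue
        if _has_ssr(text):
            continue
        g = GenomeSequence("x", text, np.zeros(len(text), bool))
        (c,) = stem_filter(g, [anchor])
        if c.duse_start != 0 or not c.bulge_present:
            continue
        meta = {"anchor": anchor, "duse_start": 0, "stem5_start": stem5_start,
                "stem5": stem5, "stem3_start": stem3_start,
                "separation": stem3_start - (stem5_start + 5)}
        return text, meta
    raise SimConfigError("could not construct a clean ncRNA locus")


def _find_all(text: str, sub: str) -> list[int]:
    out, i = [], text.find(sub)
    while i != -1:
        out.append(i)
        i = text.find(sub, i + 1)
    return out


# ---------------------------------------------------------------------------
# gene order and rearrangements

def _apply_rearrangements(rng: np.random.Generator,
                          scaffolds: dict[str, list[str]],
                          n_ops: int) -> pd.DataFrame:
    """Inversions first, then translocations; breakpoints uniform over gene
    adjacencies.  Mutates ``scaffolds`` in place and returns the op log."""
    n_inv = (n_ops + 1) // 2
    rows = []
    names = list(scaffolds)
    for k in range(n_ops):
        op = "inversion" if k < n_inv else "translocation"
        sizes = np.array([len(scaffolds[s]) for s in names], dtype=float)
        if op == "inversion":
            elig = sizes >= 2
            s = names[rng.choice(np.flatnonzero(elig),
                                 p=sizes[elig] / sizes[elig].sum())]
            order = scaffolds[s]
            i = int(rng.integers(0, len(order) - 1))
            j = int(rng.integers(i + 2, len(order) + 1))
            order[i:j] = order[i:j][::-1]
            rows.append((k, op, s, i, j, "", -1))
        else:
            elig = sizes >= 2
            src = names[rng.choice(np.flatnonzero(elig),
                                   p=sizes[elig] / sizes[elig].sum())]
            order = scaffolds[src]
            seg_len = min(len(order) - 1, 1 + int(rng.geometric(0.4)) - 1 + 1)
            i = int(rng.integers(0, len(order) - seg_len + 1))
            seg = order[i:i + seg_len]
            del order[i:i + seg_len]
            dest_choices = [s for s in names if s != src] or [src]
            dest = dest_choices[rng.integers(len(dest_choices))]
            at = int(rng.integers(0, len(scaffolds[dest]) + 1))
            scaffolds[dest][at:at] = seg
            rows.append((k, op, src, i, i + seg_len, dest, at))
    return pd.DataFrame(rows, columns=["op_index", "op_type", "scaffold",
                                       "start", "end", "dest_scaffold",
                                       "dest_pos"])


def _partition(items: list, n_parts: int, rng: np.random.Generator
               ) -> list[list]:
    """Contiguous partition into n_parts non-empty chunks of similar size."""
    n = len(items)
    base = n // n_parts
    sizes = [base] * n_parts
    for k in rng.choice(n_parts, size=n - base * n_parts, replace=False):
        sizes[k] += 1
    out, pos = [], 0
    for s in sizes:
        out.append(items[pos:pos + s])
        pos += s
    return out


# ---------------------------------------------------------------------------
# scaffold assembly with planted features

@dataclass
class _Segment:
    text: str
    regen_len: int = 0  # > 0 when the segment is regenerable background
    gene_id: str | None = None
    feature: tuple | None = None  # ("repeat"/"ncrna", meta)


def _gene_body(rng: np.random.Generator, cds: str, cfg: SimConfig,
               sampler: _SeqSampler
               ) -> tuple[str, str, list[tuple[int, int]]]:
    """Gene body text with optional intron; returns (body, strand, cds_parts)
    with parts in genomic coordinates relative to the body start."""
    strand = "+" if rng.random() < 0.5 else "-"
    if rng.random() < cfg.intron_fraction and len(cds) >= 120:
        split = int(rng.integers(30, len(cds) - 30))
        intron = _screened(
            lambda: sampler.raw(int(rng.integers(60, 121))),
            lambda s: (not cfg.suppress_background_repeats)
            or (not _has_ssr(cds[:split] + s)
                and not _has_ssr(s + cds[split:])
                and not _contains_forbidden_kmer(cds[:split] + s + cds[split:])),
            what="intron")
        plus = cds[:split] + intron + cds[split:]
        parts_plus = [(0, split), (split + len(intron), len(plus))]
    else:
        plus = cds
        parts_plus = [(0, len(cds))]
    if strand == "+":
        return plus, strand, parts_plus
    body = revcomp(plus)
    n = len(body)
    parts = sorted((n - b, n - a) for a, b in parts_plus)
    return body, strand, parts


def _assemble_scaffold(rng: np.random.Generator, sid: str,
                       segments: list[_Segment], cfg: SimConfig,
                       sampler: _SeqSampler, max_rounds: int = 40) -> str:
    """Concatenate segments, then verify that the only SSR tracts and ncRNA
    anchors present are the planted ones, regenerating background segments
    that host accidents.  Segment lengths never change, so coordinates
    computed from them stay valid."""
    offsets = np.cumsum([0] + [len(s.text) for s in segments])

    def expected_tracts() -> set[tuple[int, int, str]]:
        out = set()
        for seg, off in zip(segments, offsets):
            if seg.feature and seg.feature[0] == "repeat":
                m = seg.feature[1]
                out.add((off + m["rel_start"], off + m["rel_end"], m["unit"]))
        return out

    def expected_anchors() -> set[int]:
        out = set()
        for seg, off in zip(segments, offsets):
            if seg.feature and seg.feature[0] == "ncrna":
                m = seg.feature[1]
                s5 = off + m["stem5_start"]
                n_frames = len(m["stem5"]) + len(BULGE) - 7
                out.update(s5 + k for k in range(n_frames))
        return out

    if not cfg.suppress_background_repeats:
        return "".join(s.text for s in segments)

    exp_tracts = expected_tracts()
    exp_anchors = expected_anchors()
    for _ in range(max_rounds):
        seq = "".join(s.text for s in segments)
        g = GenomeSequence(sid, seq, np.zeros(len(seq), bool))
        found = {(t.span[0], t.span[1], t.unit) for t in find_ssr_tracts(g)}
        bad_spans = [(a, b) for a, b, _ in found ^ exp_tracts]
        anchors = {i for k in _FORBIDDEN_KMERS for i in _find_all(seq, k)}
        bad_spans += [(i, i + 8) for i in anchors ^ exp_anchors]
        if not bad_spans:
            return seq
        fixed_any = False
        for a, b in bad_spans:
            for k, seg in enumerate(segments):
                if seg.regen_len and offsets[k] < b and a < offsets[k + 1]:
                    seg.text = sampler.clean(seg.regen_len)
                    fixed_any = True
        if not fixed_any:
            raise SimConfigError(
                f"{sid}: accident at {bad_spans[0]} overlaps no regenerable "
                "background")
    raise SimConfigError(f"{sid}: could not clean scaffold in {max_rounds} rounds")


# ---------------------------------------------------------------------------
# expression counts

def _nb_draw(rng: np.random.Generator, mu: float, dispersion: float) -> int:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    if dispersion <= 0:
        return int(rng.poisson(mu))
    n = 1.0 / dispersion
    return int(rng.negative_binomial(n, n / (n + mu)))


def _expression_counts(rng: np.random.Generator, cfg: SimConfig,
                       gene_ids: list[str],
                       social_flags: list[bool]) -> pd.DataFrame:
    """Stage-structured counts: class-dependent social/vegetative means with a
    per-gene lognormal developmental profile across the six social stages."""
    rows = []
    mu_veg = 200.0
    for gid, social in zip(gene_ids, social_flags):
        idx = 0.5 + (cfg.social_effect / 2 if social else -cfg.social_effect / 2)
        mu_soc = mu_veg * idx / (1 - idx)
        profile = rng.lognormal(0.0, 1.2, size=len(SOCIAL_TIMEPOINTS))
        profile *= len(SOCIAL_TIMEPOINTS) / profile.sum()
        for rep in (1, 2):
            rows.append((gid, VEGETATIVE_STAGE, rep,
                         _nb_draw(rng, mu_veg, cfg.nb_dispersion)))
        for tp, m in zip(SOCIAL_TIMEPOINTS, profile):
            for rep in (1, 2):
                rows.append((gid, tp, rep,
                             _nb_draw(rng, mu_soc * m, cfg.nb_dispersion)))
    return pd.DataFrame(rows, columns=["gene_id", "stage", "replicate",
                                       "count"])


# ---------------------------------------------------------------------------
# whole-dataset generation

@dataclass
class _Gene:
    gene_id: str
    species: str
    protein: str
    codons: list[str]
    runs: list[tuple[str, int, int]]
    social: bool
    dn_class: str          # "low"/"high"/"" (non-ortholog)
    partner: str           # "" when none
    relation: str          # ortholog / inparalog / unique

    @property
    def cds(self) -> str:
        return "".join(self.codons) + "TAA"


def generate_dataset(cfg: SimConfig, outdir: str | Path
                     ) -> tuple[DatasetPaths, TruthRecord]:
    """Generate the full paired dataset into ``outdir`` and return its paths
    plus the planted truth."""
    rng = np.random.default_rng(cfg.seed)
    paths = DatasetPaths.in_dir(outdir)
    paths.outdir.mkdir(parents=True, exist_ok=True)
    screen = cfg.suppress_background_repeats

    aas = np.array(list(DICTY_AA_FREQ))
    freqs = np.array([DICTY_AA_FREQ[a] for a in aas])
    weights = _codon_weights(cfg.at_fraction)

    genes: dict[str, _Gene] = {}

    def excluded_codons(runs):
        out = set()
        for _, start, length in runs:
            out.update(range(max(0, start - 1), start + length + 1))
        return out

    # ancestral ortholog pairs
    for i in range(cfg.n_genes):
        ga, gb = f"ga{i:05d}", f"gb{i:05d}"
        prot, runs = _make_protein(rng, cfg, aas, freqs)
        codons = _clean_cds(rng, prot, weights, screen)
        social = bool(rng.random() < cfg.social_fraction)
        dn_class = "high" if social else "low"
        dn_target = cfg.dn_high if social else cfg.dn_low
        eligible = [k for k in range(len(prot))
                    if k not in excluded_codons(runs)]
        codons_b = _diverge(rng, codons, eligible, dn_target, screen)
        prot_b = "".join(CODON_TO_AA[c] for c in codons_b)
        genes[ga] = _Gene(ga, "a", prot, codons, runs, social, dn_class,
                          gb, "ortholog")
        genes[gb] = _Gene(gb, "b", prot_b, codons_b, runs, social, dn_class,
                          ga, "ortholog")

    # inparalogs in genome A
    n_inpar = round(cfg.inparalog_fraction * cfg.n_genes)
    inpar_parents = rng.choice(cfg.n_genes, size=n_inpar, replace=False)
    for i in sorted(int(x) for x in inpar_parents):
        parent = genes[f"ga{i:05d}"]
        dup_id = f"ga{i:05d}p"
        eligible = [k for k in range(len(parent.protein))
                    if k not in excluded_codons(parent.runs)]
        codons_d = _diverge(rng, parent.codons, eligible, 0.03, screen)
        prot_d = "".join(CODON_TO_AA[c] for c in codons_d)
        genes[dup_id] = _Gene(dup_id, "a", prot_d, codons_d, parent.runs,
                              parent.social, "", parent.partner, "inparalog")

    # species-specific turnover genes
    n_unique = round(cfg.gene_turnover * cfg.n_genes)
    for sp in ("a", "b"):
        for i in range(n_unique):
            gid = f"g{sp}_u{i:04d}"
            prot, runs = _make_protein(rng, cfg, aas, freqs)
            codons = _clean_cds(rng, prot, weights, screen)
            social = bool(rng.random() < 0.6)
            genes[gid] = _Gene(gid, sp, prot, codons, runs, social, "", "",
                               "unique")

    # gene orders
    order_a = [f"ga{i:05d}" for i in range(cfg.n_genes)]
    for gid in [g.gene_id for g in genes.values()
                if g.species == "a" and g.relation != "ortholog"]:
        order_a.insert(int(rng.integers(0, len(order_a) + 1)), gid)
    scaffolds_a = {f"sa{k:02d}": part for k, part in
                   enumerate(_partition(order_a, cfg.n_scaffolds_a, rng))}

    order_b = [f"gb{i:05d}" for i in range(cfg.n_genes)]
    scaffolds_b = {f"sb{k:02d}": part for k, part in
                   enumerate(_partition(order_b, cfg.n_scaffolds_b, rng))}
    rearrangements = _apply_rearrangements(rng, scaffolds_b,
                                           cfg.rearrangement_ops)
    uniques_b = [g.gene_id for g in genes.values()
                 if g.species == "b" and g.relation == "unique"]
    names_b = list(scaffolds_b)
    for gid in uniques_b:
        sid = names_b[rng.integers(len(names_b))]
        scaffolds_b[sid].insert(
            int(rng.integers(0, len(scaffolds_b[sid]) + 1)), gid)

    # build both species' sequences
    result = {}
    for sp, scaffold_orders in (("a", scaffolds_a), ("b", scaffolds_b)):
        result[sp] = _build_species(rng, cfg, sp, scaffold_orders, genes)

    # write files
    write_fasta(result["a"]["genome"], paths.genome_a)
    write_fasta(result["b"]["genome"], paths.genome_b)
    write_gff3(result["a"]["models"], paths.gff_a)
    write_gff3(result["b"]["models"], paths.gff_b)
    write_plain_fasta({g.gene_id: g.protein for g in genes.values()
                       if g.species == "a"}, paths.proteins_a)
    write_plain_fasta({g.gene_id: g.protein for g in genes.values()
                       if g.species == "b"}, paths.proteins_b)
    write_plain_fasta({g.gene_id: g.cds for g in genes.values()
                       if g.species == "a"}, paths.cds_a)
    write_plain_fasta({g.gene_id: g.cds for g in genes.values()
                       if g.species == "b"}, paths.cds_b)

    orth_rows = [(f"ga{i:05d}", f"gb{i:05d}", "one_to_one")
                 for i in range(cfg.n_genes)]
    orth_rows += [(g.gene_id, g.partner, "inparalog_group_member")
                  for g in genes.values() if g.relation == "inparalog"]
    table = OrthologTable(pd.DataFrame(
        orth_rows, columns=["gene_a", "gene_b", "relation"]))
    write_ortholog_table(table, paths.orthologs)

    for sp, path in (("a", paths.expression_a), ("b", paths.expression_b)):
        ids = sorted(g.gene_id for g in genes.values() if g.species == sp)
        flags = [genes[g].social for g in ids]
        counts = _expression_counts(rng, cfg, ids, flags)
        counts.to_csv(path, sep="\t", index=False)
        from .molevo import percentage_representation
        pct = percentage_representation(counts)
        pct.to_csv(path.with_name(path.stem + "_pct.tsv"), sep="\t",
                   index=False)

    # truth tables
    gene_rows = []
    for sp in ("a", "b"):
        for row in result[sp]["gene_rows"]:
            gene_rows.append(row)
    genes_df = pd.DataFrame(gene_rows, columns=[
        "gene_id", "species", "scaffold", "order_index", "strand",
        "start", "end", "social", "dn_class", "partner", "relation"])
    truth = TruthRecord(
        genes=genes_df,
        repeats=pd.DataFrame(
            result["a"]["repeat_rows"] + result["b"]["repeat_rows"],
            columns=["species", "scaffold", "start", "end", "unit", "copies"]),
        homopolymers=pd.DataFrame(
            [(g.species, g.gene_id, aa, start, length)
             for g in genes.values() for aa, start, length in g.runs],
            columns=["species", "gene_id", "amino_acid", "start", "length"]),
        ncrna=pd.DataFrame(
            result["a"]["ncrna_rows"] + result["b"]["ncrna_rows"],
            columns=["species", "scaffold", "anchor_start", "duse_start",
                     "stem5_start", "stem5", "stem3_start", "separation",
                     "ncrna_class"]),
        rearrangements=rearrangements,
        config=dataclasses.asdict(cfg),
    )
    truth.save(paths.truth_dir)
    return paths, truth


def _build_species(rng: np.random.Generator, cfg: SimConfig, sp: str,
                   scaffold_orders: dict[str, list[str]],
                   genes: dict[str, "_Gene"]) -> dict:
    """Assemble one species' scaffolds with planted intergenic features."""
    screen = cfg.suppress_background_repeats

    # composition solve: choose intergenic AT so the whole genome hits target
    cds_bp = sum(len(genes[g].cds) for order in scaffold_orders.values()
                 for g in order)
    cds_at = sum(genes[g].cds.count(x)
                 for order in scaffold_orders.values()
                 for g in order for x in "AT")
    # plan intergenic slot lengths and intron presence up front
    slot_lens: dict[str, list[int]] = {}
    total_bg = 0
    for sid, order in scaffold_orders.items():
        lens = [60 + int(rng.exponential(cfg.mean_intergenic - 60))
                for _ in range(len(order) + 1)]
        slot_lens[sid] = lens
        total_bg += sum(lens)
    at_cds_frac = cds_at / cds_bp
    total_bp = cds_bp + total_bg
    at_i = (cfg.at_fraction * total_bp - at_cds_frac * cds_bp) / total_bg
    at_i = float(np.clip(at_i, 0.25, 0.97))
    sampler = _SeqSampler(rng, at_i, screen)

    # assign planted features to intergenic slots
    all_slots = [(sid, k) for sid, lens in slot_lens.items()
                 for k in range(len(lens))]
    n_repeats = {slot: int(rng.poisson(
        cfg.slippage_rate * slot_lens[slot[0]][slot[1]] / 1000.0))
        for slot in all_slots}
    if cfg.n_ncrna_loci > len(all_slots):
        raise SimConfigError("more ncRNA loci than intergenic slots")
    ncrna_slot_idx = rng.choice(len(all_slots), size=cfg.n_ncrna_loci,
                                replace=False)
    ncrna_slots: dict[tuple[str, int], list[str]] = {}
    stems_a = list(CLASS_STEMS_A)
    for j, si in enumerate(sorted(int(x) for x in ncrna_slot_idx)):
        stem5 = stems_a[j % len(stems_a)] if sp == "a" else STEM_B
        ncrna_slots.setdefault(all_slots[si], []).append((j, stem5))

    genome: list[GenomeSequence] = []
    models: list[GeneModel] = []
    gene_rows, repeat_rows, ncrna_rows = [], [], []

    for sid, order in scaffold_orders.items():
        segments: list[_Segment] = []

        def add_slot(slot_key, length):
            cores: list[_Segment] = []
            for _ in range(n_repeats.get(slot_key, 0) if cfg.slippage_rate > 0
                           else 0):
                text, rs, re_, unit, copies = _repeat_core(rng, sampler, cfg)
                cores.append(_Segment(text, feature=(
                    "repeat", {"rel_start": rs, "rel_end": re_,
                               "unit": unit, "copies": copies})))
            for locus_index, stem5 in ncrna_slots.get(slot_key, []):
                text, meta = _ncrna_core(rng, sampler, stem5, locus_index)
                meta = dict(meta)
                meta["class"] = CLASS_STEMS_A.get(stem5, "putative")
                cores.append(_Segment(text, feature=("ncrna", meta)))
            bg_len = max(30, length // (len(cores) + 1))
            segments.append(_Segment(sampler.clean(bg_len), regen_len=bg_len))
            for core in cores:
                segments.append(core)
                segments.append(_Segment(sampler.clean(bg_len),
                                         regen_len=bg_len))

        for k, gid in enumerate(order):
            add_slot((sid, k), slot_lens[sid][k])
            body, strand, parts = _gene_body(rng, genes[gid].cds, cfg, sampler)
            segments.append(_Segment(body, gene_id=gid,
                                     feature=("gene", {"strand": strand,
                                                       "parts": parts})))
        add_slot((sid, len(order)), slot_lens[sid][len(order)])

        seq = _assemble_scaffold(rng, sid, segments, cfg, sampler)
        genome.append(GenomeSequence(sid, seq, np.zeros(len(seq), bool)))

        # coordinates from segment lengths
        offset = 0
        gene_index = 0
        for seg in segments:
            if seg.gene_id is not None:
                meta = seg.feature[1]
                g = genes[seg.gene_id]
                parts_abs = [(offset + a, offset + b)
                             for a, b in meta["parts"]]
                models.append(GeneModel(
                    gene_id=seg.gene_id, scaffold_id=sid,
                    span=(offset, offset + len(seg.text)),
                    strand=meta["strand"], cds_parts=parts_abs))
                gene_rows.append((
                    seg.gene_id, sp, sid, gene_index, meta["strand"],
                    offset, offset + len(seg.text), g.social, g.dn_class,
                    g.partner, g.relation))
                gene_index += 1
            elif seg.feature and seg.feature[0] == "repeat":
                m = seg.feature[1]
                repeat_rows.append((sp, sid, offset + m["rel_start"],
                                    offset + m["rel_end"], m["unit"],
                                    m["copies"]))
            elif seg.feature and seg.feature[0] == "ncrna":
                m = seg.feature[1]
                ncrna_rows.append((sp, sid, offset + m["anchor"],
                                   offset + m["duse_start"],
                                   offset + m["stem5_start"], m["stem5"],
                                   offset + m["stem3_start"],
                                   m["separation"], m["class"]))
            offset += len(seg.text)

    return {"genome": genome, "models": models, "gene_rows": gene_rows,
            "repeat_rows": repeat_rows, "ncrna_rows": ncrna_rows}


# ---------------------------------------------------------------------------
# truth verification

@dataclass
class CheckReport:
    ok: bool
    n_checked: int
    first_discrepancy: str = ""


def truth_check(paths: DatasetPaths, truth: TruthRecord) -> CheckReport:
    """Re-parse every emitted file independently and verify each truth entry.

    Fails with the first discrepancy found.
    """
    from Bio.Seq import Seq

    from .io import read_fasta, read_gff3, read_ortholog_table, read_protein_fasta

    n = 0

    def fail(msg: str) -> CheckReport:
        return CheckReport(False, n, msg)

    genomes = {"a": {g.scaffold_id: g for g in read_fasta(paths.genome_a)},
               "b": {g.scaffold_id: g for g in read_fasta(paths.genome_b)}}
    proteins = {"a": read_protein_fasta(paths.proteins_a),
                "b": read_protein_fasta(paths.proteins_b)}
    cds = {"a": read_protein_fasta(paths.cds_a),
           "b": read_protein_fasta(paths.cds_b)}
    models = {"a": {m.gene_id: m for m in read_gff3(
                    paths.gff_a, list(genomes["a"].values()))},
              "b": {m.gene_id: m for m in read_gff3(
                    paths.gff_b, list(genomes["b"].values()))}}

    # planted repeats: exact text at the stated coordinates
    for row in truth.repeats.itertuples():
        seq = genomes[row.species][row.scaffold].residues[row.start:row.end]
        u = len(row.unit)
        if len(seq) != row.end - row.start:
            return fail(f"repeat at {row.scaffold}:{row.start} out of bounds")
        if seq != (seq[:u] * (len(seq) // u + 1))[:len(seq)]:
            return fail(f"repeat at {row.scaffold}:{row.start} not periodic")
        if canonical_rotation(seq[:u]) != row.unit:
            return fail(f"repeat at {row.scaffold}:{row.start} unit mismatch")
        if abs(len(seq) / u - row.copies) > 1e-9:
            return fail(f"repeat at {row.scaffold}:{row.start} copy mismatch")
        n += 1

    # planted ncRNA loci: DUSE, bulge, stem complementarity, separation
    duse_rx = DUSE.to_regex()
    for row in truth.ncrna.itertuples():
        seq = genomes[row.species][row.scaffold].residues
        if not duse_rx.match(seq, row.duse_start):
            return fail(f"ncRNA at {row.scaffold}:{row.anchor_start}: no DUSE")
        if seq[row.anchor_start:row.anchor_start + len(BULGE)] != BULGE:
            return fail(f"ncRNA at {row.scaffold}:{row.anchor_start}: no bulge")
        stem5 = seq[row.stem5_start:row.stem5_start + 5]
        stem3 = seq[row.stem3_start:row.stem3_start + 5]
        if stem5 != row.stem5 or stem3 != revcomp(stem5):
            return fail(f"ncRNA at {row.scaffold}:{row.anchor_start}: stems")
        sep = row.stem3_start - (row.stem5_start + 5)
        if sep != row.separation or not 40 <= sep <= 70:
            return fail(f"ncRNA at {row.scaffold}:{row.anchor_start}: "
                        f"separation {sep}")
        n += 1

    # planted homopolymers: exact maximal runs in the protein FASTA
    for row in truth.homopolymers.itertuples():
        p = proteins[row.species].get(row.gene_id)
        if p is None:
            return fail(f"protein {row.gene_id} missing")
        run = p[row.start:row.start + row.length]
        if run != row.amino_acid * row.length:
            return fail(f"homopolymer {row.gene_id}:{row.start} text mismatch")
        if row.start > 0 and p[row.start - 1] == row.amino_acid:
            return fail(f"homopolymer {row.gene_id}:{row.start} not maximal (left)")
        end = row.start + row.length
        if end < len(p) and p[end] == row.amino_acid:
            return fail(f"homopolymer {row.gene_id}:{row.start} not maximal (right)")
        n += 1

    # gene models: coordinates, strand, CDS consistency with protein
    for row in truth.genes.itertuples():
        m = models[row.species].get(row.gene_id)
        if m is None:
            return fail(f"gene {row.gene_id} missing from GFF3")
        if m.span != (row.start, row.end) or m.strand != row.strand:
            return fail(f"gene {row.gene_id} coordinates/strand mismatch")
        genomic_cds = m.cds_sequence(genomes[row.species][row.scaffold])
        if genomic_cds != cds[row.species][row.gene_id]:
            return fail(f"gene {row.gene_id} CDS mismatch with genome")
        translated = str(Seq(genomic_cds).translate())
        if translated.rstrip("*") != proteins[row.species][row.gene_id]:
            return fail(f"gene {row.gene_id} CDS does not translate to protein")
        n += 1

    # gene order per scaffold matches truth order_index
    for (spc, sid), sub in truth.genes.groupby(["species", "scaffold"]):
        expected = list(sub.sort_values("order_index")["gene_id"])
        observed = [m.gene_id for m in sorted(
            (mm for mm in models[spc].values() if mm.scaffold_id == sid),
            key=lambda mm: mm.span)]
        if expected != observed:
            return fail(f"gene order mismatch on {spc}/{sid}")
        n += 1

    # ortholog table matches truth pairings
    table = read_ortholog_table(paths.orthologs)
    truth_pairs = {(r.gene_id, r.partner)
                   for r in truth.genes.itertuples()
                   if r.species == "a" and r.relation == "ortholog"}
    file_pairs = {(r.gene_a, r.gene_b)
                  for r in table.one_to_one.itertuples()}
    if truth_pairs != file_pairs:
        return fail("ortholog table does not match truth pairings")
    n += 1

    # expression: every gene of each species, all stages, both replicates
    for sp, path in (("a", paths.expression_a), ("b", paths.expression_b)):
        expr = pd.read_csv(path, sep="\t")
        ids = set(truth.genes[truth.genes["species"] == sp]["gene_id"])
        stages = set(SOCIAL_TIMEPOINTS) | {VEGETATIVE_STAGE}
        got = expr.groupby("gene_id").size().to_dict()
        want = len(stages) * 2
        missing = [g for g in ids if got.get(g, 0) != want]
        if missing:
            return fail(f"expression rows missing for {missing[0]}")
        n += 1

    return CheckReport(True, n)
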