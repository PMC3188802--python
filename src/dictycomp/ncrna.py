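"""DUSE-anchored ncRNA screening.

The screen looks for loci with the architecture of the dictyostelid class I/II
small ncRNAs: an upstream DUSE promoter element ([AT]CCCA[AT]AA, sitting
roughly 63 bp upstream), a 5-bp 5' stem, the conserved 12-bp non-self-binding
bulge CCTTACAGCCAA immediately 3' of the 5' stem, and a 3' stem that is the
exact reverse complement of the 5' stem lying 40-70 bp downstream.  Candidate
anchors come from a k-mer scan ranked by upstream-DUSE enrichment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from scipy import stats

from .io import GenomeSequence, revcomp


@dataclass
class MotifPattern:
    """IUPAC-degenerate DNA motif."""

    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"invalid IUPAC codes {sorted(bad)} in pattern")
        self.pattern = self.pattern.upper()

    def __len__(self) -> int:
        return len(self.pattern)

    def to_regex(self) -> re.Pattern:
        parts = []
        for c in self.pattern:
            opts = ambiguous_dna_values[c]
            parts.append(opts if len(opts) == 1 else f"[{opts}]")
        return re.compile("".join(parts))


DUSE = MotifPattern("WCCCAWAA")  # [AT]CCCA[AT]AA


@dataclass
class NcRnaCandidate:
    scaffold_id: str
    anchor_start: int
    duse_start: int
    duse_offset: int        # bp between DUSE end and 5' stem start
    stem5_start: int
    stem5: str
    stem3_start: int
    stem_separation: int    # bp between stem5 end and stem3 start
    bulge_present: bool
    assigned_class: str = "putative"

    @property
    def stem3(self) -> str:
        return revcomp(self.stem5)


def scan_motif(genome: GenomeSequence, pattern: MotifPattern | str,
               respect_mask: bool = True) -> list[int]:
    """Forward-strand match start positions, overlapping matches included."""
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    if len(pattern) > 50:
        raise ValueError("pattern longer than 50 bp")
    rx = pattern.to_regex()
    positions = []
    m = len(pattern)
    for p in _iter_overlapping(rx, genome.residues):
        if respect_mask and genome.masked[p:p + m].any():
            continue
        positions.append(p)
    return positions


def _iter_overlapping(rx: re.Pattern, text: str):
    pos = 0
    while True:
        m = rx.search(text, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1


def kmer_duse_enrichment(genomes: GenomeSequence | Sequence[GenomeSequence],
                         k: int = 8,
                         duse_window: tuple[int, int] = (40, 90),
                         respect_mask: bool = True,
                         duse: MotifPattern | str = DUSE,
                         min_occurrences: int = 1) -> pd.DataFrame:
    """Rank k-mers by enrichment of an upstream DUSE among their occurrences.

    Counts are pooled across all supplied scaffolds.  For each occurrence at
    position p, a DUSE is counted when a match starts within
    [p - far, p - near] (``duse_window = (near, far)``).  The null is a
    binomial with the genome-wide probability that a uniformly placed window
    of that size contains a DUSE start; the score is -log10 of the one-sided
    (greater) binomial p-value.  Ties rank lexicographically.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    near, far = duse_window
    if not 0 < near < far:
        raise ValueError(f"malformed duse_window {duse_window}")
    total_bp = sum(len(g) for g in genomes)
    if total_bp < 10_000:
        warnings.warn("genome < 10 kb; enrichment ranking may be meaningless")
    if all(len(g) <= far for g in genomes):
        raise ValueError("genome shorter than the DUSE window")

    counts: dict[str, int] = {}
    hits: dict[str, int] = {}
    n_window_positions = 0
    n_window_with_duse = 0
    for genome in genomes:
        seq = genome.residues
        n = len(seq)
        duse_positions = scan_motif(genome, duse, respect_mask=respect_mask)
        has_duse_start = np.zeros(n, dtype=np.int64)
        if duse_positions:
            has_duse_start[np.asarray(duse_positions)] = 1
        cum = np.concatenate([[0], np.cumsum(has_duse_start)])
        positions = np.arange(n)
        lo = np.maximum(0, positions - far)
        hi = np.maximum(0, positions - near + 1)  # starts counted in [lo, hi)
        window_has_duse = (cum[hi] - cum[lo]) > 0
        if n > far:
            n_window_positions += n - far
            n_window_with_duse += int(window_has_duse[far:].sum())
        masked = genome.masked
        for p in range(n - k + 1):
            kmer = seq[p:p + k]
            if "N" in kmer:
                continue
            if respect_mask and masked[p:p + k].any():
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
            if window_has_duse[p]:
                hits[kmer] = hits.get(kmer, 0) + 1

    p0 = n_window_with_duse / n_window_positions if n_window_positions else 0.0
    rows = []
    for kmer, nocc in counts.items():
        if nocc < min_occurrences:
            continue
        x = hits.get(kmer, 0)
        if p0 in (0.0, 1.0):
            pval = 1.0
        else:
            pval = stats.binomtest(x, nocc, p0, alternative="greater").pvalue
        score = -np.log10(max(pval, 1e-300))
        rows.append((kmer, nocc, x, x / nocc, score, pval))
    table = pd.DataFrame(rows, columns=[
        "kmer", "occurrences", "with_duse", "fraction_with_duse",
        "enrichment_score", "p_value"])
    table["null_probability"] = p0
    return table.sort_values(["enrichment_score", "kmer"],
                             ascending=[False, True]).reset_index(drop=True)


def stem_filter(genome: GenomeSequence, anchor_positions: Sequence[int],
                stem_len: int = 5,
                separation: tuple[int, int] = (40, 70),
                duse_window: tuple[int, int] = (40, 90),
                stem5_offset: int = 15,
                bulge: str = "CCTTACAGCCAA",
                duse: MotifPattern | str = DUSE,
                require_duse: bool = True) -> list[NcRnaCandidate]:
    """Structural filter around anchor k-mers.

    A candidate requires (i) a DUSE start within ``duse_window`` upstream of
    the anchor, and (ii) a ``stem_len``-bp 5' stem starting within
    ``stem5_offset`` bp upstream of (or at) the anchor whose exact reverse
    complement lies ``separation`` bp downstream of the stem's end.  All
    qualifying (stem5, stem3) placements are emitted; the conserved bulge is
    recorded when it immediately follows the 5' stem.
    """
    seq = genome.residues
    n = len(seq)
    sep_lo, sep_hi = separation
    near, far = duse_window
    duse = MotifPattern(duse) if isinstance(duse, str) else duse
    duse_positions = set(scan_motif(genome, duse, respect_mask=False))
    duse_len = len(duse)
    out: list[NcRnaCandidate] = []
    for p in anchor_positions:
        if not 0 <= p < n:
            warnings.warn(f"anchor {p} out of bounds; skipped")
            continue
        upstream = [d for d in range(max(0, p - far), max(0, p - near + 1))
                    if d in duse_positions]
        if require_duse and not upstream:
            continue
        duse_start = max(upstream) if upstream else -1
        for s5 in range(max(0, p - stem5_offset), p + 1):
            stem5 = seq[s5:s5 + stem_len]
            if len(stem5) < stem_len or "N" in stem5:
                continue
            target = revcomp(stem5)
            s5_end = s5 + stem_len
            for sep in range(sep_lo, sep_hi + 1):
                s3 = s5_end + sep
                if s3 + stem_len > n:
                    break
                if seq[s3:s3 + stem_len] == target:
                    out.append(NcRnaCandidate(
                        scaffold_id=genome.scaffold_id,
                        anchor_start=p,
                        duse_start=duse_start,
                        duse_offset=s5 - (duse_start + duse_len)
                        if duse_start >= 0 else -1,
                        stem5_start=s5,
                        stem5=stem5,
                        stem3_start=s3,
                        stem_separation=sep,
                        bulge_present=seq[s5_end:s5_end + len(bulge)] == bulge,
                    ))
    return out


def assign_class(candidate: NcRnaCandidate,
                 class_stems: Mapping[str, str]) -> NcRnaCandidate:
    """Class from the 5' stem lookup (e.g. GTTGA -> classI, GCTCG -> classII);
    anything else stays putative."""
    return replace(candidate,
                   assigned_class=class_stems.get(candidate.stem5, "putative"))


def candidates_to_frame(cands: list[NcRnaCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.scaffold_id, c.anchor_start, c.duse_start, c.duse_offset,
          c.stem5_start, c.stem5, c.stem3_start, c.stem3, c.stem_separation,
          c.bulge_present, c.assigned_class) for c in cands],
        columns=["scaffold", "anchor_start", "duse_start", "duse_offset",
                 "stem5_start", "stem5", "stem3_start", "stem3",
                 "stem_separation", "bulge_present", "assigned_class"])


def candidates_to_gff3(cands: list[NcRnaCandidate], path) -> None:
    """Export candidates as GFF3 ncRNA features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(cands):
            start = min(c.stem5_start, c.duse_start if c.duse_start >= 0
                        else c.stem5_start)
            end = c.stem3_start + len(c.stem5)
            attrs = (f"ID=ncrna{i};stem5={c.stem5};stem3={c.stem3};"
                     f"bulge={'yes' if c.bulge_present else 'no'};"
                     f"class={c.assigned_class}")
            fh.write(f"{c.scaffold_id}\tdictycomp\tncRNA\t{start + 1}\t{end}"
                     f"\t.\t+\t.\t{attrs}\n")
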