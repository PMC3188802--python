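"""Simple-sequence-repeat (microsatellite) detection and summaries.

A repeat tract is a maximal perfect tandem repetition of a 1-20 bp unit.  A
tract qualifies when its whole-copy count reaches the unit-length-specific
minimum: 10 copies for mononucleotide units, 7 for dinucleotides, 5 for
trinucleotides, 4 for tetranucleotides and 3 for units of 5-20 bp.  Fractional
trailing units extend the tract span but do not count toward qualification.

Detection is forward-strand only (a motif and its reverse complement are
distinct units) and masked positions terminate tracts so that tracts never
cross assembly gaps.  Tracts whose unit is itself a repetition of a shorter
unit are reported only at the shortest (primitive) unit length; the reported
unit is the lexicographically least rotation of itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, GenomeSequence, ReferenceMismatchError

#: minimum whole copies required per unit length (1..20)
DEFAULT_MIN_COPIES: dict[int, int] = {1: 10, 2: 7, 3: 5, 4: 4,
                                      **{u: 3 for u in range(5, 21)}}


@dataclass
class RepeatTract:
    scaffold_id: str
    span: tuple[int, int]
    unit: str
    copies: float
    coding: bool = False

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


def canonical_rotation(unit: str) -> str:
    """Lexicographically least rotation (canonical phase) of a repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def is_primitive(unit: str) -> bool:
    """True unless the unit is a whole-number repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_ssr_tracts(genome: GenomeSequence,
                    min_copies: dict[int, int] | None = None,
                    max_unit: int = 20) -> list[RepeatTract]:
    """All maximal qualifying tracts on the forward strand, sorted by position.

    For each unit length u the scan marks positions j where
    ``seq[j] == seq[j-u]`` (both unmasked, both A/C/G/T); maximal runs of such
    matches delimit maximal tracts, which qualify when
    ``floor(length/u) >= min_copies[u]`` and the unit is primitive.
    """
    if min_copies is None:
        min_copies = DEFAULT_MIN_COPIES
    seq = genome.residues
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    valid = ~genome.masked & (arr != b"N")

    tracts: list[RepeatTract] = []
    for u in range(1, max_unit + 1):
        if u not in min_copies:
            continue
        min_len = min_copies[u] * u
        if n < min_len:
            continue
        match = (arr[u:] == arr[:-u]) & valid[u:] & valid[:-u]
        if not match.any():
            continue
        # maximal runs of consecutive True in `match`
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for a, b in zip(edges[::2], edges[1::2]):
            # matches at j in [a, b) (offsets into `match`, i.e. position j+u)
            start, end = int(a), int(b) + u  # tract span [start, end)
            length = end - start
            if length // u < min_copies[u]:
                continue
            unit = seq[start:start + u]
            if not is_primitive(unit):
                continue
            tracts.append(RepeatTract(
                scaffold_id=genome.scaffold_id,
                span=(start, end),
                unit=canonical_rotation(unit),
                copies=length / u,
            ))
    tracts.sort(key=lambda t: (t.span, len(t.unit)))
    return tracts


def classify_coding(tracts: list[RepeatTract],
                    genes: list[GeneModel] | None) -> list[RepeatTract]:
    """Set ``coding`` True iff a tract overlaps any CDS part by >= 1 bp."""
    if not genes:
        warnings.warn("no gene models supplied; all tracts non-coding")
        return [replace(t, coding=False) for t in tracts]
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.scaffold_id, IntervalTree())
        for a, b in g.cds_parts:
            tree.addi(a, b)
    known = set(trees)
    out = []
    for t in tracts:
        if t.scaffold_id not in known:
            raise ReferenceMismatchError(
                f"tract scaffold {t.scaffold_id!r} absent from gene models")
        out.append(replace(t, coding=bool(trees[t.scaffold_id]
                                          .overlap(*t.span))))
    return out


@dataclass
class SsrSummary:
    counts_by_unit_length: pd.DataFrame  # unit_length, coding, n
    length_histogram: pd.DataFrame       # bin_start, bin_end, n
    genome_fraction: float
    n_long: int
    n_tracts: int


def ssr_summary(tracts: list[RepeatTract], genome_bp: int,
                fraction_mode: str = "union",
                hist_bin: int = 10, long_threshold: int = 100) -> SsrSummary:
    """Per-unit-length counts, tract-length histogram, genome fraction and the
    count of long tracts (span strictly greater than ``long_threshold`` bp).

    ``fraction_mode='union'`` counts overlapping tract bp once (default);
    ``'summed'`` adds tract lengths.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    rows = [(len(t.unit), t.coding) for t in tracts]
    counts = (pd.DataFrame(rows, columns=["unit_length", "coding"])
              .value_counts().rename("n").reset_index()
              if rows else
              pd.DataFrame(columns=["unit_length", "coding", "n"]))
    counts["is_multiple_of_3"] = counts["unit_length"] % 3 == 0 \
        if len(counts) else pd.Series(dtype=bool)

    lengths = np.array([t.length for t in tracts], dtype=int)
    if len(lengths):
        top = (lengths.max() // hist_bin + 1) * hist_bin
        bins = np.arange(0, top + hist_bin, hist_bin)
        hist, _ = np.histogram(lengths, bins=bins)
        histogram = pd.DataFrame({"bin_start": bins[:-1], "bin_end": bins[1:],
                                  "n": hist})
    else:
        histogram = pd.DataFrame(columns=["bin_start", "bin_end", "n"])

    if fraction_mode == "summed":
        covered = int(lengths.sum())
    elif fraction_mode == "union":
        covered = 0
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for t in tracts:
            by_scaffold.setdefault(t.scaffold_id, []).append(t.span)
        for spans in by_scaffold.values():
            spans.sort()
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s > cur_e:
                    covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            covered += cur_e - cur_s
    else:
        raise ValueError(f"unknown fraction_mode {fraction_mode!r}")

    return SsrSummary(
        counts_by_unit_length=counts,
        length_histogram=histogram,
        genome_fraction=covered / genome_bp,
        n_long=int((lengths > long_threshold).sum()),
        n_tracts=len(tracts),
    )


def tracts_to_frame(tracts: list[RepeatTract]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.scaffold_id, t.span[0], t.span[1], t.unit, t.copies, t.coding)
         for t in tracts],
        columns=["scaffold", "start", "end", "unit", "copies", "coding"])
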