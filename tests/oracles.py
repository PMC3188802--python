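"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's data structures and algorithms: the
SSR oracle extends every start position by string comparison, the synteny
oracle materializes the full pairwise link matrix and walks components, the
dN oracle enumerates substitution paths with Biopython translation, and the
alignment oracle enumerates every global alignment of tiny sequences.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq


# --- SSR ------------------------------------------------------------------

def _canonical(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _primitive(unit: str) -> bool:
    return all(unit != unit[:d] * (len(unit) // d)
               for d in range(1, len(unit)) if len(unit) % d == 0)


def brute_ssr(seq: str, min_copies: dict[int, int],
              max_unit: int = 20) -> set[tuple[int, int, str]]:
    """All maximal qualifying tracts as (start, end, canonical_unit)."""
    n = len(seq)
    out = set()
    for u in range(1, max_unit + 1):
        for i in range(n - u):
            if i > 0 and i - 1 + u < n and seq[i - 1] == seq[i - 1 + u]:
                continue  # not left-maximal
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            if (j - i) // u >= min_copies[u] and _primitive(seq[i:i + u]):
                out.add((i, j, _canonical(seq[i:i + u])))
    return out


def brute_aa_runs(protein: str) -> list[tuple[str, int, int]]:
    """Maximal single-amino-acid runs of length >= 2 via regex-free scan."""
    out = []
    i = 0
    while i < len(protein):
        j = i
        while j < len(protein) and protein[j] == protein[i]:
            j += 1
        if j - i >= 2:
            out.append((protein[i], i, j - i))
        i = j
    return out


# --- synteny --------------------------------------------------------------

def brute_synteny_components(order_a: dict[str, list[str]],
                             order_b: dict[str, list[str]],
                             partner: dict[str, str],
                             w: int) -> list[frozenset[str]]:
    """Connected components (>= 2 members) from an explicit link matrix."""
    pos_a = {g: (s, i) for s, gs in order_a.items() for i, g in enumerate(gs)}
    pos_b = {g: (s, i) for s, gs in order_b.items() for i, g in enumerate(gs)}
    genes = sorted(pos_a)
    links = {g: set() for g in genes}
    for g1, g2 in itertools.combinations(genes, 2):
        sa1, ia1 = pos_a[g1]
        sa2, ia2 = pos_a[g2]
        sb1, ib1 = pos_b[partner[g1]]
        sb2, ib2 = pos_b[partner[g2]]
        if (sa1 == sa2 and abs(ia1 - ia2) - 1 <= w
                and sb1 == sb2 and abs(ib1 - ib2) - 1 <= w):
            links[g1].add(g2)
            links[g2].add(g1)
    seen: set[str] = set()
    comps = []
    for g in genes:
        if g in seen or not links[g]:
            continue
        comp, stack = set(), [g]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(links[x] - comp)
        seen |= comp
        if len(comp) >= 2:
            comps.append(frozenset(comp))
    return comps


def chain_blocks_w0(order_a: list[str], pos_b: dict[str, tuple[str, int]],
                    partner: dict[str, str]) -> list[list[str]]:
    """Blocks at w=0 by breakpoint walking: maximal runs of consecutive
    genome-A genes whose partners are adjacent on one genome-B scaffold."""
    blocks = []
    current = [order_a[0]] if order_a else []
    for g1, g2 in zip(order_a, order_a[1:]):
        s1, i1 = pos_b[partner[g1]]
        s2, i2 = pos_b[partner[g2]]
        if s1 == s2 and abs(i1 - i2) == 1:
            current.append(g2)
        else:
            if len(current) >= 2:
                blocks.append(current)
            current = [g2]
    if len(current) >= 2:
        blocks.append(current)
    return blocks


# --- dN/dS ----------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_codon_sites(codon: str) -> tuple[float, float]:
    syn = 0.0
    for pos, base in enumerate(codon):
        for alt in "ACGT":
            if alt == base:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1:]
            if mutated not in _STOPS and _aa(mutated) == _aa(codon):
                syn += 1 / 3
    return syn, 3 - syn


def brute_path_counts(c1: str, c2: str) -> tuple[float, float]:
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if not diffs:
        return 0.0, 0.0

    def score(path, allow_stops):
        cur, s, nsy = c1, 0.0, 0.0
        for k in path:
            nxt = cur[:k] + c2[k] + cur[k + 1:]
            if nxt in _STOPS and not allow_stops:
                return None
            if cur not in _STOPS and nxt not in _STOPS and _aa(cur) == _aa(nxt):
                s += 1
            else:
                nsy += 1
            cur = nxt
        return s, nsy

    paths = [score(p, False) for p in itertools.permutations(diffs)]
    paths = [p for p in paths if p is not None]
    if not paths:
        paths = [score(p, True) for p in itertools.permutations(diffs)]
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


# --- global alignment -----------------------------------------------------

def brute_best_alignment_score(a: str, b: str, matrix, open_gap: float,
                               extend_gap: float) -> float:
    """Optimal global alignment score by exhaustive enumeration of all
    alignments (lengths <= ~7).  Gap scoring matches Biopython's
    PairwiseAligner: the first residue of a gap run costs ``open_gap`` and
    each further residue ``extend_gap``."""
    best = -float("inf")

    def rec(i, j, score, prev_gap):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], None)
        if i < len(a):
            cost = extend_gap if prev_gap == "a" else open_gap
            rec(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = extend_gap if prev_gap == "b" else open_gap
            rec(i, j + 1, score - cost, "b")

    rec(0, 0, 0.0, None)
    return best
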