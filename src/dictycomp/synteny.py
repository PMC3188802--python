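"""Conserved gene order: w-linkage synteny blocks with permutation nulls.

Two ortholog pairs are linked when their genes lie on the same scaffold in
genome A with at most w intervening ortholog-bearing genes, and their partners
lie on one chromosome of genome B, again with at most w intervening
ortholog-bearing genes.  Intervening genes are counted in the
ortholog-restricted order: genes without a 1:1 ortholog are invisible.
Blocks are the connected components (>= 2 members) of the link graph under
single-linkage clustering.  Linkage is orientation-free by default, so a fully
reversed scaffold still clusters; a strict-order mode restricts links to pairs
that preserve relative orientation.

The permutation null scrambles gene order independently within each scaffold
(or across the whole genome), preserving scaffold membership and pairings, and
summarizes block participation over permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, OrthologTable


@dataclass
class OrderedOrthologMap:
    """Ortholog-restricted gene orders for both genomes.

    ``order_a``/``order_b`` map scaffold -> ordered gene ids (1:1 genes only);
    ``partner`` maps gene_a -> gene_b.
    """

    order_a: dict[str, list[str]]
    order_b: dict[str, list[str]]
    partner: dict[str, str]

    pos_a: dict[str, tuple[str, int]] = field(init=False)
    pos_b: dict[str, tuple[str, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.pos_a = {g: (s, i) for s, genes in self.order_a.items()
                      for i, g in enumerate(genes)}
        self.pos_b = {g: (s, i) for s, genes in self.order_b.items()
                      for i, g in enumerate(genes)}
        for g in self.pos_a:
            if g not in self.partner:
                raise ValueError(f"gene {g!r} in genome A order lacks a partner")
        for gb in self.pos_b:
            if gb not in set(self.partner.values()):
                raise ValueError(f"gene {gb!r} in genome B order lacks a partner")

    @property
    def n_pairs(self) -> int:
        return len(self.pos_a)

    @classmethod
    def from_inputs(cls, table: OrthologTable,
                    genes_a: list[GeneModel],
                    genes_b: list[GeneModel]) -> "OrderedOrthologMap":
        """Build the map from an ortholog table and positioned gene models."""
        ones = table.one_to_one
        partner = dict(zip(ones["gene_a"], ones["gene_b"]))
        partners_b = set(partner.values())

        def ordered(models: list[GeneModel], keep: set[str]) -> dict[str, list[str]]:
            out: dict[str, list[str]] = {}
            for g in sorted(models, key=lambda m: (m.scaffold_id, m.span)):
                if g.gene_id in keep:
                    out.setdefault(g.scaffold_id, []).append(g.gene_id)
            return out

        return cls(order_a=ordered(genes_a, set(partner)),
                   order_b=ordered(genes_b, partners_b),
                   partner=partner)


@dataclass
class SyntenyBlock:
    member_pairs: list[tuple[str, str]]
    scaffold_a: str
    chromosome_b: str
    w: int

    @property
    def size(self) -> int:
        return len(self.member_pairs)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_blocks(omap: OrderedOrthologMap, w: int,
                 strict_order: bool = False) -> list[SyntenyBlock]:
    """Single-linkage blocks under window w (connected components >= 2)."""
    if w < 0:
        raise ValueError("w must be >= 0")
    genes = sorted(omap.pos_a)
    index = {g: k for k, g in enumerate(genes)}
    uf = _UnionFind(len(genes))
    linked = np.zeros(len(genes), dtype=bool)
    for scaf, order in omap.order_a.items():
        for i, ga in enumerate(order):
            sb1, ib1 = omap.pos_b[omap.partner[ga]]
            # candidates within w intervening genes in A: offsets 1..w+1
            for off in range(1, min(w + 1, len(order) - 1 - i) + 1):
                gc = order[i + off]
                sb2, ib2 = omap.pos_b[omap.partner[gc]]
                if sb1 != sb2 or abs(ib1 - ib2) - 1 > w:
                    continue
                if strict_order and ib2 <= ib1:
                    continue
                uf.union(index[ga], index[gc])
                linked[index[ga]] = linked[index[gc]] = True
    components: dict[int, list[str]] = {}
    for g in genes:
        k = index[g]
        if linked[k]:
            components.setdefault(uf.find(k), []).append(g)
    blocks = []
    for members in components.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda g: omap.pos_a[g])
        blocks.append(SyntenyBlock(
            member_pairs=[(g, omap.partner[g]) for g in members],
            scaffold_a=omap.pos_a[members[0]][0],
            chromosome_b=omap.pos_b[omap.partner[members[0]]][0],
            w=w,
        ))
    blocks.sort(key=lambda b: (b.scaffold_a,
                               omap.pos_a[b.member_pairs[0][0]][1]))
    return blocks


@dataclass
class BlockStats:
    participation: float
    mean_size: float
    max_size: int
    n_blocks: int
    n_genes_in_blocks: int
    n_pairs_total: int
    defined: bool  # False when there are no blocks


def block_stats(blocks: list[SyntenyBlock],
                omap: OrderedOrthologMap) -> BlockStats:
    sizes = [b.size for b in blocks]
    n_in = sum(sizes)
    total = omap.n_pairs
    if not blocks:
        return BlockStats(0.0, 0.0, 0, 0, 0, total, defined=False)
    return BlockStats(
        participation=n_in / total if total else 0.0,
        mean_size=float(np.mean(sizes)),
        max_size=max(sizes),
        n_blocks=len(blocks),
        n_genes_in_blocks=n_in,
        n_pairs_total=total,
        defined=True,
    )


def permute_map(omap: OrderedOrthologMap,
                rng: np.random.Generator | int,
                mode: str = "within_scaffold") -> OrderedOrthologMap:
    """Uniformly scramble gene order; scaffold membership and pairings kept.

    ``within_scaffold`` permutes each scaffold/chromosome independently;
    ``whole_genome`` reassigns genes across scaffolds while keeping each
    scaffold's gene count.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    def scramble(order: dict[str, list[str]]) -> dict[str, list[str]]:
        if mode == "within_scaffold":
            return {s: [genes[i] for i in rng.permutation(len(genes))]
                    for s, genes in order.items()}
        if mode == "whole_genome":
            all_genes = [g for genes in order.values() for g in genes]
            shuffled = [all_genes[i] for i in rng.permutation(len(all_genes))]
            out, k = {}, 0
            for s, genes in order.items():
                out[s] = shuffled[k:k + len(genes)]
                k += len(genes)
            return out
        raise ValueError(f"unknown shuffle mode {mode!r}")

    return OrderedOrthologMap(order_a=scramble(omap.order_a),
                              order_b=scramble(omap.order_b),
                              partner=dict(omap.partner))


@dataclass
class NullSummary:
    n_permutations: int
    participation_mean: float
    participation_sd: float
    seed: int


def null_distribution(omap: OrderedOrthologMap, w: int, n_perm: int,
                      seed: int, mode: str = "within_scaffold") -> NullSummary:
    """Participation over permuted maps: mean and SD across permutations."""
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_perm):
        pm = permute_map(omap, rng, mode=mode)
        parts.append(block_stats(build_blocks(pm, w), pm).participation)
    return NullSummary(n_perm, float(np.mean(parts)),
                       float(np.std(parts, ddof=1)), seed)


@dataclass
class WSelection:
    chosen_w: int | None  # None when no w shows significant growth
    table: pd.DataFrame   # w, participation, null_mean, null_sd, growth, null_growth_mean, null_growth_sd, significant


def select_w(omap: OrderedOrthologMap, w_max: int, n_perm: int, seed: int,
             k_sd: float = 2.0, mode: str = "within_scaffold") -> WSelection:
    """Largest w whose participation growth over w-1 exceeds the null growth
    by at least ``k_sd`` null SDs.  Growth at w=0 is measured from 0.

    Emits the full real-vs-null growth table.
    """
    if w_max < 1:
        raise ValueError("w_max must be >= 1")
    ws = list(range(w_max + 1))
    real = [block_stats(build_blocks(omap, w), omap).participation for w in ws]
    rng = np.random.default_rng(seed)
    null_parts = np.empty((n_perm, len(ws)))
    for p in range(n_perm):
        pm = permute_map(omap, rng, mode=mode)
        for j, w in enumerate(ws):
            null_parts[p, j] = block_stats(build_blocks(pm, w), pm).participation
    null_growth = np.diff(np.concatenate(
        [np.zeros((n_perm, 1)), null_parts], axis=1), axis=1)
    real_growth = np.diff(np.concatenate([[0.0], real]))
    g_mean = null_growth.mean(axis=0)
    g_sd = null_growth.std(axis=0, ddof=1)
    significant = (real_growth > 0) & (real_growth > g_mean + k_sd * g_sd)
    chosen = max((w for w, s in zip(ws, significant) if s), default=None)
    table = pd.DataFrame({
        "w": ws,
        "participation": real,
        "null_mean": null_parts.mean(axis=0),
        "null_sd": null_parts.std(axis=0, ddof=1),
        "growth": real_growth,
        "null_growth_mean": g_mean,
        "null_growth_sd": g_sd,
        "significant": significant,
    })
    return WSelection(chosen_w=chosen, table=table)


def fpr_estimate(real_participation: float, null: NullSummary) -> float:
    """Gene-wise false positive rate: null participation / real participation."""
    if real_participation <= 0:
        raise ValueError("real participation must be positive")
    return null.participation_mean / real_participation


def blocks_to_frame(blocks: list[SyntenyBlock],
                    omap: OrderedOrthologMap) -> pd.DataFrame:
    rows = []
    for k, b in enumerate(blocks):
        for ga, gb in b.member_pairs:
            rows.append((k, b.scaffold_a, b.chromosome_b, b.w, ga, gb,
                         omap.pos_a[ga][1], omap.pos_b[gb][1]))
    return pd.DataFrame(rows, columns=[
        "block", "scaffold_a", "chromosome_b", "w",
        "gene_a", "gene_b", "index_a", "index_b"])
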