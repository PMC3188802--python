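import itertools

import numpy as np
import pytest

from oracles import brute_synteny_components, chain_blocks_w0

from dictycomp.synteny import (NullSummary, OrderedOrthologMap, block_stats,
                               build_blocks, fpr_estimate, null_distribution,
                               permute_map, select_w)


def make_map(order_a, order_b):
    """Single-scaffold-per-genome map; genes named by integers."""
    partner = {f"a{i}": f"b{i}" for i in order_a}
    return OrderedOrthologMap({"sa": [f"a{i}" for i in order_a]},
                              {"sb": [f"b{i}" for i in order_b]},
                              partner)


def random_map(rng, n, n_scaf_a=1, n_scaf_b=1):
    genes = list(range(n))
    order_b = [genes[i] for i in rng.permutation(n)]
    partner = {f"a{i}": f"b{i}" for i in genes}

    def split(order, n_scaf, scaf_prefix, gene_prefix):
        cuts = sorted(rng.choice(np.arange(1, n), size=n_scaf - 1,
                                 replace=False)) if n_scaf > 1 else []
        out, prev = {}, 0
        for k, c in enumerate(list(cuts) + [n]):
            out[f"{scaf_prefix}{k}"] = [f"{gene_prefix}{i}"
                                        for i in order[prev:c]]
            prev = c
        return out

    return OrderedOrthologMap(split(genes, n_scaf_a, "sa", "a"),
                              split(order_b, n_scaf_b, "sb", "b"), partner)


def test_identical_orders_form_one_block_at_w0():
    m = make_map(range(10), range(10))
    blocks = build_blocks(m, 0)
    assert len(blocks) == 1 and blocks[0].size == 10
    s = block_stats(blocks, m)
    assert s.participation == 1.0 and s.mean_size == 10 and s.max_size == 10


def test_reversed_order_still_one_block_adjacency_is_orientation_free():
    m = make_map(range(10), reversed(range(10)))
    blocks = build_blocks(m, 0)
    assert len(blocks) == 1 and blocks[0].size == 10
    # strict-order mode, by contrast, sees no forward-conserved pairs
    assert build_blocks(m, 0, strict_order=True) == []


def test_adjacent_swaps_split_into_pairwise_blocks():
    m = make_map([1, 2, 3, 4], [2, 1, 4, 3])
    blocks = build_blocks(m, 0)
    members = sorted(frozenset(g for g, _ in b.member_pairs) for b in blocks)
    assert members == [frozenset({"a1", "a2"}), frozenset({"a3", "a4"})]


def test_gene_without_partner_rejected():
    with pytest.raises(ValueError):
        OrderedOrthologMap({"sa": ["a1", "a2"]}, {"sb": ["b1"]},
                           {"a1": "b1"})


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("w", [0, 1, 3])
def test_blocks_match_connected_components_oracle(seed, w):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        n = int(rng.integers(2, 13))
        m = random_map(rng, n, n_scaf_a=int(rng.integers(1, 3)),
                       n_scaf_b=int(rng.integers(1, 3)))
        blocks = build_blocks(m, w)
        got = {frozenset(g for g, _ in b.member_pairs) for b in blocks}
        expected = set(brute_synteny_components(
            m.order_a, m.order_b, m.partner, w))
        assert got == expected


def test_participation_nondecreasing_in_w():
    rng = np.random.default_rng(3)
    for _ in range(10):
        m = random_map(rng, 30)
        parts = [block_stats(build_blocks(m, w), m).participation
                 for w in range(6)]
        assert parts == sorted(parts)


def test_blocks_invariant_to_reversing_scaffold_orders():
    rng = np.random.default_rng(4)
    m = random_map(rng, 20)
    rev = OrderedOrthologMap({k: v[::-1] for k, v in m.order_a.items()},
                             {k: v[::-1] for k, v in m.order_b.items()},
                             dict(m.partner))
    for w in (0, 2):
        got = {frozenset(g for g, _ in b.member_pairs)
               for b in build_blocks(m, w)}
        got_rev = {frozenset(g for g, _ in b.member_pairs)
                   for b in build_blocks(rev, w)}
        assert got == got_rev


def test_block_stats_examples():
    m = make_map(range(10), range(10))
    no_blocks = block_stats([], m)
    assert no_blocks.participation == 0.0 and not no_blocks.defined
    blocks = build_blocks(make_map(range(10), [1, 0, 3, 2, 5, 4, 9, 6, 7, 8]), 0)
    # three blocks {0,1},{2,3},{4,5} and one {6,7,8} -> sizes 2,2,2,3
    s = block_stats(blocks, m)
    assert s.n_genes_in_blocks == 9
    assert s.participation == pytest.approx(0.9)


def test_permute_map_determinism_and_single_gene_scaffold():
    m = OrderedOrthologMap({"sa": ["a1"], "sa2": ["a2", "a3"]},
                           {"sb": ["b1", "b2", "b3"]},
                           {"a1": "b1", "a2": "b2", "a3": "b3"})
    p1 = permute_map(m, 42)
    p2 = permute_map(m, 42)
    assert p1.order_a == p2.order_a and p1.order_b == p2.order_b
    assert p1.order_a["sa"] == ["a1"]  # single-gene scaffold unchanged
    assert sorted(p1.order_b["sb"]) == ["b1", "b2", "b3"]


def test_permuted_adjacency_fraction_matches_2_over_n():
    n = 4000
    m = make_map(range(n), range(n))
    rng = np.random.default_rng(9)
    preserved = []
    for _ in range(20):
        pm = permute_map(m, rng)
        pos = {g: i for i, g in enumerate(pm.order_b["sb"])}
        count = sum(abs(pos[f"b{i}"] - pos[f"b{i + 1}"]) == 1
                    for i in range(n - 1))
        preserved.append(count / (n - 1))
    p_hat = np.mean(preserved)
    expect = 2 / n
    mc_sd = np.std(preserved, ddof=1) / np.sqrt(len(preserved))
    assert abs(p_hat - expect) <= 3 * max(mc_sd, 1e-6)


def test_null_distribution_n4_exhaustive_mean_two_thirds():
    # brute enumeration over all 24 genome-B orders
    parts = []
    for perm in itertools.permutations(range(4)):
        m = make_map(range(4), perm)
        parts.append(block_stats(build_blocks(m, 0), m).participation)
    assert np.mean(parts) == pytest.approx(2 / 3)
    # sampled null agrees within Monte-Carlo error
    null = null_distribution(make_map(range(4), range(4)), 0, 400, seed=0)
    assert abs(null.participation_mean - 2 / 3) <= \
        3 * null.participation_sd / np.sqrt(400)


def test_null_distribution_requires_two_permutations():
    with pytest.raises(ValueError):
        null_distribution(make_map(range(4), range(4)), 0, 1, seed=0)


def test_select_w_saturated_map_chooses_zero():
    m = make_map(range(40), range(40))
    sel = select_w(m, 5, 30, seed=1)
    assert sel.chosen_w == 0


def test_select_w_flags_random_map_as_no_synteny():
    rng = np.random.default_rng(8)
    m = random_map(rng, 60)
    sel = select_w(m, 4, 40, seed=2)
    # a scrambled genome should not beat its own null anywhere
    assert sel.chosen_w is None or sel.chosen_w == 0


@pytest.mark.parametrize("spacing", [2, 5, 8])
def test_select_w_tracks_planted_interleaving_spacing(spacing):
    # genome B interleaves `spacing` unrelated genes between each pair of
    # genome-A neighbours, so linkage first appears at w == spacing
    n_real, n_noise = 30, 30 * spacing
    real = [f"r{i}" for i in range(n_real)]
    noise = [f"x{i}" for i in range(n_noise)]
    order_b = []
    k = 0
    for g in real:
        order_b.append(g)
        order_b.extend(noise[k:k + spacing])
        k += spacing
    # noise genes scrambled on their genome-A scaffold so only the real
    # genes carry synteny signal
    rng = np.random.default_rng(0)
    noise_a = [noise[i] for i in rng.permutation(n_noise)]
    partner = {g: g for g in real + noise}
    m = OrderedOrthologMap({"sa": real, "sx": noise_a},
                           {"sb": order_b}, partner)
    sel = select_w(m, spacing + 3, 40, seed=3)
    assert sel.chosen_w == spacing


def test_fpr_examples():
    null = NullSummary(100, 0.058, 0.004, 0)
    assert fpr_estimate(0.76, null) == pytest.approx(0.0763, abs=1e-4)
    assert fpr_estimate(0.5, NullSummary(100, 0.0, 0.0, 0)) == 0.0
    assert fpr_estimate(0.5, NullSummary(100, 0.5, 0.0, 0)) == 1.0
    with pytest.raises(ValueError):
        fpr_estimate(0.0, null)


def test_blocks_at_w0_match_breakpoint_walk_on_dataset(small_dataset):
    paths, truth, cfg = small_dataset
    genes = truth.genes
    orth = genes[genes["relation"] == "ortholog"]
    partner = dict(zip(orth[orth.species == "a"]["gene_id"],
                       orth[orth.species == "a"]["partner"]))

    def orders(sp):
        sub = genes[(genes.species == sp)].sort_values(["scaffold",
                                                        "order_index"])
        keep = set(partner) if sp == "a" else set(partner.values())
        return {sid: [g for g in grp["gene_id"] if g in keep]
                for sid, grp in sub.groupby("scaffold")}

    order_a, order_b = orders("a"), orders("b")
    m = OrderedOrthologMap(order_a, order_b, partner)
    blocks = build_blocks(m, 0)
    pos_b = {g: (s, i) for s, gs in order_b.items()
             for i, g in enumerate(gs)}
    expected = [blk for sid, gs in order_a.items()
                for blk in chain_blocks_w0(gs, pos_b, partner)]
    got = {frozenset(g for g, _ in b.member_pairs) for b in blocks}
    assert got == {frozenset(b) for b in expected}
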