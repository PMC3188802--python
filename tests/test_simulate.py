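import numpy as np
import pandas as pd
import pytest

from conftest import SMALL_CONFIG

from dictycomp.homopolymers import aa_run_thresholds, find_homopolymers
from dictycomp.io import read_fasta, read_protein_fasta
from dictycomp.simulate import (SimConfig, SimConfigError, _SeqSampler,
                                generate_dataset, truth_check)
from dictycomp.ssr import DEFAULT_MIN_COPIES, find_ssr_tracts


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(n_genes=24, n_scaffolds_a=2, n_scaffolds_b=2,
                    rearrangement_ops=2, n_ncrna_loci=2, seed=5)
    p1, _ = generate_dataset(cfg, tmp_path / "run1")
    p2, _ = generate_dataset(cfg, tmp_path / "run2")
    for name in ("genome_a", "genome_b", "gff_a", "gff_b", "proteins_a",
                 "cds_b", "orthologs", "expression_a"):
        assert getattr(p1, name).read_bytes() == getattr(p2, name).read_bytes()


def test_truth_check_passes_on_fresh_dataset(small_dataset):
    paths, truth, _ = small_dataset
    report = truth_check(paths, truth)
    assert report.ok, report.first_discrepancy
    assert report.n_checked > 100


def test_truth_check_catches_perturbations(small_dataset):
    paths, truth, _ = small_dataset
    import copy

    bad = copy.deepcopy(truth)
    bad.repeats.loc[bad.repeats.index[0], "start"] += 1
    report = truth_check(paths, bad)
    assert not report.ok and "repeat" in report.first_discrepancy

    bad2 = copy.deepcopy(truth)
    extra = bad2.genes.iloc[[0]].assign(gene_id="ghost")
    bad2.genes = pd.concat([bad2.genes, extra], ignore_index=True)
    report2 = truth_check(paths, bad2)
    assert not report2.ok


def test_realized_at_content_within_two_points(default_dataset):
    paths, truth, cfg = default_dataset
    for path in (paths.genome_a, paths.genome_b):
        seqs = read_fasta(path)
        total = sum(len(g) for g in seqs)
        assert total >= 100_000
        at = sum(g.residues.count(b) for g in seqs for b in "AT") / total
        assert abs(at - cfg.at_fraction) <= 0.02


def test_no_rearrangements_no_turnover_preserves_gene_order(tmp_path):
    cfg = SimConfig(n_genes=24, n_scaffolds_a=2, n_scaffolds_b=2,
                    rearrangement_ops=0, gene_turnover=0.0,
                    inparalog_fraction=0.0, n_ncrna_loci=0, seed=3)
    _, truth = generate_dataset(cfg, tmp_path)
    g = truth.genes
    order_a = list(g[g.species == "a"].sort_values(["scaffold",
                                                    "order_index"])["gene_id"])
    order_b = list(g[g.species == "b"].sort_values(["scaffold",
                                                    "order_index"])["gene_id"])
    assert [x.replace("ga", "gb") for x in order_a] == order_b


def test_infeasible_rearrangement_count_rejected():
    with pytest.raises(SimConfigError):
        SimConfig(n_genes=20, n_scaffolds_a=2, n_scaffolds_b=2,
                  rearrangement_ops=50)


def test_invalid_proportions_rejected():
    with pytest.raises(SimConfigError):
        SimConfig(gene_turnover=1.5)


def test_planted_ssr_tracts_recovered_exactly(small_dataset):
    paths, truth, _ = small_dataset
    for sp, path in (("a", paths.genome_a), ("b", paths.genome_b)):
        found = {(g.scaffold_id, t.span[0], t.span[1], t.unit)
                 for g in read_fasta(path) for t in find_ssr_tracts(g)}
        planted = {(r.scaffold, r.start, r.end, r.unit)
                   for r in truth.repeats.itertuples() if r.species == sp}
        assert found == planted  # recall and precision both 1


def test_planted_homopolymers_recovered_as_significant(small_dataset):
    paths, truth, _ = small_dataset
    for sp, path in (("a", paths.proteins_a), ("b", paths.proteins_b)):
        proteins = read_protein_fasta(path)
        thresholds = aa_run_thresholds(proteins)
        found = {(gid, r.amino_acid, r.start, r.length)
                 for gid, seq in proteins.items()
                 for r in find_homopolymers(gid, seq, thresholds)
                 if r.significant}
        planted = {(r.gene_id, r.amino_acid, r.start, r.length)
                   for r in truth.homopolymers.itertuples()
                   if r.species == sp}
        assert planted <= found  # every planted run is recovered exactly


def test_planted_ncrna_loci_recovered_exactly_once(small_dataset):
    from dictycomp.config import RunConfig
    from dictycomp.pipeline import stage_ncrna

    paths, truth, _ = small_dataset
    for sp, path in (("a", paths.genome_a), ("b", paths.genome_b)):
        res = stage_ncrna(RunConfig(), path, paths.outdir / "ncx", sp)
        found = {(c.scaffold_id, c.stem5_start, c.stem3_start)
                 for c in res["candidates"]}
        assert len(found) == len(res["candidates"])  # no duplicates
        planted = {(r.scaffold, r.stem5_start, r.stem3_start)
                   for r in truth.ncrna.itertuples() if r.species == sp}
        assert found == planted


def test_suppressed_background_plus_zero_rates_yields_clean_genome(tmp_path):
    cfg = SimConfig(n_genes=24, n_scaffolds_a=2, n_scaffolds_b=2,
                    rearrangement_ops=2, slippage_rate=0.0,
                    homopolymer_rate=0.0, n_ncrna_loci=0, seed=9)
    paths, truth = generate_dataset(cfg, tmp_path)
    assert len(truth.repeats) == 0 and len(truth.homopolymers) == 0
    for g in read_fasta(paths.genome_a):
        assert find_ssr_tracts(g) == []


def test_unsuppressed_background_matches_analytic_tract_expectation():
    """On iid sequence, the expected number of qualifying tracts with
    (primitive) unit w of length u and minimum copies m is, per position,
    (1 - p[w[-1]]) * prod_b p_b^(m * count_b(w)): the minimal span repeats
    w exactly m times and the left flank must break the period.  Summing
    over all primitive units of length 1-6 (longer units contribute
    negligibly) gives the analytic expectation; the count is Poisson."""
    import itertools

    from conftest import genome_of

    rng = np.random.default_rng(13)
    at = 0.76
    n = 400_000
    seq = _SeqSampler(rng, at, screen=False).raw(n)
    found = find_ssr_tracts(genome_of(seq))

    p = {"A": at / 2, "T": at / 2, "C": (1 - at) / 2, "G": (1 - at) / 2}
    from dictycomp.ssr import is_primitive

    expected = 0.0
    for u in range(1, 7):
        m = DEFAULT_MIN_COPIES[u]
        for w in itertools.product("ACGT", repeat=u):
            w = "".join(w)
            if not is_primitive(w):
                continue
            content = np.prod([p[b] ** (m * w.count(b)) for b in "ACGT"])
            expected += n * (1 - p[w[-1]]) * content
    assert abs(len(found) - expected) <= 3 * np.sqrt(expected) + 1


def test_dn_class_means_recovered_within_15pct(default_dataset):
    from dictycomp.config import RunConfig
    from dictycomp.pipeline import stage_homopolymers, pair_evolution

    paths, truth, cfg = default_dataset
    hp = stage_homopolymers(RunConfig(), paths.proteins_a, paths.cds_a,
                            paths.proteins_b, paths.cds_b, paths.orthologs,
                            paths.outdir / "hp")
    prot_a = read_protein_fasta(paths.proteins_a)
    prot_b = read_protein_fasta(paths.proteins_b)
    cds_a = read_protein_fasta(paths.cds_a)
    cds_b = read_protein_fasta(paths.cds_b)
    evo = pair_evolution(RunConfig(), prot_a, prot_b, cds_a, cds_b,
                         hp["pairs"], hp["runs_a"], hp["runs_b"],
                         hp["alignments"])
    classes = truth.genes.set_index("gene_id")["dn_class"]
    evo = evo.assign(dn_class=[classes.get(g) for g in evo["gene_a"]])
    means = evo.groupby("dn_class")["dN"].mean()
    assert len(evo) >= 200
    assert abs(means["low"] - cfg.dn_low) / cfg.dn_low <= 0.15
    assert abs(means["high"] - cfg.dn_high) / cfg.dn_high <= 0.15


def test_expression_counts_cover_all_genes_and_stages(small_dataset):
    paths, truth, _ = small_dataset
    counts = pd.read_csv(paths.expression_a, sep="\t")
    ids = set(truth.genes[truth.genes.species == "a"]["gene_id"])
    assert set(counts["gene_id"]) == ids
    assert counts.groupby("gene_id").size().eq(14).all()  # 7 stages x 2 reps


def test_turnover_and_inparalog_bookkeeping(small_dataset):
    _, truth, cfg = small_dataset
    g = truth.genes
    n_unique = round(cfg.gene_turnover * cfg.n_genes)
    for sp in ("a", "b"):
        assert (g[(g.species == sp) & (g.relation == "unique")]
                .shape[0]) == n_unique
    n_inpar = round(cfg.inparalog_fraction * cfg.n_genes)
    assert (g.relation == "inparalog").sum() == n_inpar
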