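import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oracles import brute_aa_runs, brute_best_alignment_score

from dictycomp.homopolymers import (AAHomopolymer, AAThresholdTable,
                                    aa_run_thresholds, call_repeat_homology,
                                    codon_diversity, compare_by_repeat_status,
                                    density_correlation, find_homopolymers,
                                    global_align, repeat_density,
                                    thresholds_from_composition)
from dictycomp.simulate import DICTY_AA_FREQ


# --- chance-model thresholds ----------------------------------------------

@pytest.mark.parametrize("f,expected", [
    # smallest L with 6.4e6 * f**L <= 0.01, checked by direct evaluation
    (0.1, 9),
    (0.02, 6),
])
def test_threshold_matches_direct_evaluation(f, expected):
    direct = next(L for L in range(2, 31) if 6.4e6 * f ** L <= 0.01)
    assert direct == expected
    got = thresholds_from_composition({"N": f}, 6_400_000)["N"]
    assert got == expected


def test_thresholds_on_dicty_like_composition_span_6_to_9():
    # at the scale of a full dictyostelid proteome (~6.4e6 residues)
    t = thresholds_from_composition(DICTY_AA_FREQ, 6_400_000)
    values = {v for v in t.values() if v is not None}
    assert min(values) == 6 and max(values) == 9


def test_threshold_monotone_in_frequency():
    rng = np.random.default_rng(0)
    freqs = sorted(rng.uniform(0.001, 0.2, size=30))
    t = thresholds_from_composition({"N": f for f in [0.5]}, 10_000)
    thresholds = [thresholds_from_composition({"N": f}, 1_000_000)["N"]
                  for f in freqs]
    assert thresholds == sorted(thresholds)


def test_aa_run_thresholds_from_proteome_counts_and_flags_absent():
    proteome = {"p1": "N" * 500 + "Q" * 500}  # no other residues
    with pytest.warns(UserWarning):
        t = aa_run_thresholds(proteome)
    assert t.total_residues == 1000
    assert t.frequency["N"] == pytest.approx(0.5)
    assert t.min_len["W"] is None
    # absent residues can never yield significant runs
    runs = find_homopolymers("x", "MWWWWWWWWWWM".replace("M", "A"), t)
    assert all(not r.significant for r in runs)


def test_aa_run_thresholds_tiny_proteome_rejected():
    with pytest.raises(ValueError):
        aa_run_thresholds({"p": "NNNN"})


# --- run detection --------------------------------------------------------

def _thresholds(min_n=9):
    return AAThresholdTable(frequency={"N": 0.1}, min_len={"N": min_n},
                            total_residues=1000, alpha=0.01)


def test_find_runs_significance_boundary_and_codons():
    runs = find_homopolymers("p", "MNNNNNNNNNNK", _thresholds(9))
    assert [(r.amino_acid, r.start, r.length, r.significant)
            for r in runs] == [("N", 1, 10, True)]
    runs = find_homopolymers("p", "MNNNNNNNNK", _thresholds(9))
    assert [(r.length, r.significant) for r in runs] == [(8, False)]
    runs = find_homopolymers("p", "MQQQK", _thresholds(),
                             cds="ATGCAACAGCAAAAA")
    (q,) = [r for r in runs if r.amino_acid == "Q"]
    assert q.codons == ["CAA", "CAG", "CAA"]


def test_find_runs_translation_mismatch_reports_position():
    with pytest.raises(ValueError, match="residue 1"):
        find_homopolymers("p", "MKK", _thresholds(), cds="ATGCAAAAA")


@pytest.mark.parametrize("seed", range(3))
def test_run_detector_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    aas = np.array(list(DICTY_AA_FREQ))
    p = np.array(list(DICTY_AA_FREQ.values()))
    protein = "".join(rng.choice(aas, size=800, p=p))
    runs = find_homopolymers("p", protein, _thresholds())
    assert [(r.amino_acid, r.start, r.length) for r in runs] == \
        brute_aa_runs(protein)


# --- densities ------------------------------------------------------------

def test_repeat_density_formula_and_total_conservation():
    runs = [AAHomopolymer("p", "N", 0, 10, True),
            AAHomopolymer("p", "S", 20, 10, True),
            AAHomopolymer("p", "S", 40, 15, True),
            AAHomopolymer("p", "Q", 60, 4, False)]  # not significant
    dens = repeat_density(runs, 5000)
    assert dens["N"] == pytest.approx(2.0)
    assert dens["S"] == pytest.approx(5.0)
    assert dens["Q"] == 0.0
    total = sum(dens.values()) * 5000 / 1000
    assert total == pytest.approx(35)  # sum of significant run lengths
    with pytest.raises(ValueError):
        repeat_density(runs, 0)


def test_density_correlation_identity_scale_and_sign():
    rng = np.random.default_rng(1)
    x = {aa: float(v) for aa, v in zip(DICTY_AA_FREQ,
                                       rng.uniform(0, 5, size=20))}
    assert density_correlation(x, x).r == pytest.approx(1.0)
    doubled = {aa: 2 * v for aa, v in x.items()}
    assert density_correlation(x, doubled).r == pytest.approx(1.0)
    ordered = {aa: float(i) for i, aa in enumerate(DICTY_AA_FREQ)}
    reverse = {aa: -float(i) for i, aa in enumerate(DICTY_AA_FREQ)}
    assert density_correlation(ordered, reverse).r < 0
    flat = {aa: 1.0 for aa in DICTY_AA_FREQ}
    with pytest.warns(UserWarning):
        assert not density_correlation(flat, x).defined


def test_codon_diversity_cases():
    run = AAHomopolymer("p", "N", 0, 3, True, codons=["AAT", "AAT", "AAT"])
    assert codon_diversity(run) == (1, 0.0)
    run = AAHomopolymer("p", "N", 0, 4, True,
                        codons=["AAT", "AAC", "AAT", "AAC"])
    assert codon_diversity(run)[0] == 2
    met = AAHomopolymer("p", "M", 0, 3, True, codons=["ATG"] * 3)
    assert codon_diversity(met) == (1, 0.0)  # single-codon amino acid
    with pytest.raises(ValueError):
        codon_diversity(AAHomopolymer("p", "N", 0, 3, True, codons=None))


# --- alignment ------------------------------------------------------------

def test_global_align_identity_and_errors():
    a = global_align("MKNQ", "MKNQ")
    assert a.pairs == [(0, 0), (1, 1), (2, 2), (3, 3)]
    assert a.identities == 4
    with pytest.raises(ValueError):
        global_align("", "MK")
    with pytest.raises(ValueError):
        global_align("MK1", "MK")


@pytest.mark.parametrize("a,b", [
    ("ACDEF", "ACEF"),
    ("MKNQS", "MKQS"),
    ("WWP", "WP"),
    ("ACDEF", "ACDEF"),
])
def test_global_align_score_matches_exhaustive_enumeration(a, b):
    matrix = substitution_matrices.load("BLOSUM62")
    best = brute_best_alignment_score(a, b, matrix, 11.0, 1.0)
    aln = global_align(a, b)
    assert aln.score == pytest.approx(best)


def test_global_align_acdef_gap_falls_on_unmatched_residue():
    aln = global_align("ACDEF", "ACEF")
    # one residue of the longer sequence is unaligned; all others pair up
    assert len(aln.pairs) == 4
    unaligned = set(range(5)) - {i for i, _ in aln.pairs}
    assert len(unaligned) == 1


# --- repeat homology ------------------------------------------------------

def _runs(gene, aa, start, length):
    return {gene: [AAHomopolymer(gene, aa, start, length, True)]}


def test_repeat_homology_same_run_in_identical_orthologs():
    prot = "MK" + "N" * 10 + "KR"
    aln = {("a1", "b1"): global_align(prot, prot, "a1", "b1")}
    res = call_repeat_homology([("a1", "b1")], _runs("a1", "N", 2, 10),
                               _runs("b1", "N", 2, 10), aln)
    assert res.calls[0].homologous
    assert res.fraction_homologous_a == 1.0
    assert res.fraction_homologous_b == 1.0


def test_repeat_homology_requires_same_amino_acid():
    prot_a = "MK" + "N" * 10 + "KR"
    prot_b = "MK" + "Q" * 10 + "KR"
    aln = {("a1", "b1"): global_align(prot_a, prot_b, "a1", "b1")}
    res = call_repeat_homology([("a1", "b1")], _runs("a1", "N", 2, 10),
                               _runs("b1", "Q", 2, 10), aln)
    assert not res.calls[0].homologous


def test_repeat_homology_run_aligned_to_gap_not_called():
    # the run exists only in species A; species B has nothing at that spot
    prot_a = "MKWC" + "N" * 10 + "WCRY" * 3
    prot_b = "MKWC" + "WCRY" * 3
    aln = {("a1", "b1"): global_align(prot_a, prot_b, "a1", "b1")}
    res = call_repeat_homology([("a1", "b1")], _runs("a1", "N", 4, 10),
                               {"b1": []}, aln)
    assert res.calls == []  # no candidate partner run at all
    assert res.fraction_homologous_a == 0.0


def test_repeat_homology_fractions_swap_under_species_relabel():
    prot_a = "MK" + "N" * 10 + "KR"
    prot_b = "MK" + "N" * 8 + "KR"
    runs_a = _runs("a1", "N", 2, 10)
    runs_a["a2"] = [AAHomopolymer("a2", "S", 0, 9, True)]
    runs_b = _runs("b1", "N", 2, 8)
    aln_ab = {("a1", "b1"): global_align(prot_a, prot_b, "a1", "b1")}
    aln_ba = {("b1", "a1"): global_align(prot_b, prot_a, "b1", "a1")}
    fwd = call_repeat_homology([("a1", "b1")], runs_a, runs_b, aln_ab)
    rev = call_repeat_homology([("b1", "a1")], runs_b, runs_a, aln_ba)
    assert fwd.fraction_homologous_a == rev.fraction_homologous_b
    assert fwd.fraction_homologous_b == rev.fraction_homologous_a
    assert fwd.fraction_no_ortholog_a == rev.fraction_no_ortholog_b


def test_repeat_homology_missing_alignment_raises():
    with pytest.raises(KeyError):
        call_repeat_homology([("a1", "b1")], {}, {}, {})


# --- group comparisons ----------------------------------------------------

@pytest.mark.parametrize("test", ["t", "mannwhitney"])
def test_group_comparison_detects_three_sd_shift(test):
    rng = np.random.default_rng(2)
    with_ = rng.normal(3.0, 1.0, size=50)
    without = rng.normal(0.0, 1.0, size=50)
    values = np.concatenate([with_, without])
    flags = np.array([True] * 50 + [False] * 50)
    res = compare_by_repeat_status(values, flags, test=test)
    assert res.p < 1e-3
    assert res.direction == "with>without"


def test_group_comparison_degenerate_and_small_groups():
    with pytest.warns(UserWarning):
        res = compare_by_repeat_status(np.ones(10),
                                       np.array([True] * 5 + [False] * 5))
    assert res.degenerate and np.isnan(res.p)
    with pytest.raises(ValueError):
        compare_by_repeat_status(np.arange(4.0),
                                 np.array([True, False, False, False]))


from hypothesis import given, settings, strategies as st


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.text(alphabet="NQSK", min_size=2, max_size=200))
def test_run_scanner_total_length_and_maximality_properties(protein):
    runs = find_homopolymers("p", protein, _thresholds())
    assert [(r.amino_acid, r.start, r.length) for r in runs] == \
        brute_aa_runs(protein)
    for r in runs:
        assert r.length >= 2
        if r.start > 0:
            assert protein[r.start - 1] != r.amino_acid
        if r.end < len(protein):
            assert protein[r.end] != r.amino_acid
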