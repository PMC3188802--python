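"""Stage drivers chaining the library modules over files on disk.

Each ``stage_*`` function reads the standard-format inputs, runs one analysis
stage, writes its tabular outputs under ``outdir`` and returns a summary
dict.  ``run_all`` chains every stage the way the command-line interface and
the analysis scripts do.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import homopolymers as hp
from . import molevo, ncrna, ssr, synteny
from .config import RunConfig, write_provenance
from .io import (read_fasta, read_gff3, read_ortholog_table,
                 read_protein_fasta, write_bed)
from .simulate import CLASS_STEMS_A


def _outdir(path: str | Path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_ssr(cfg: RunConfig, genome_path: str | Path,
              gff_path: str | Path | None, outdir: str | Path,
              label: str = "a") -> dict:
    """Detect SSR tracts, classify coding overlap and summarize."""
    out = _outdir(outdir)
    genomes = read_fasta(genome_path)
    genes = read_gff3(gff_path, genomes) if gff_path else None
    tracts = []
    for g in genomes:
        tracts.extend(ssr.find_ssr_tracts(g, max_unit=cfg.ssr_max_unit))
    tracts = ssr.classify_coding(tracts, genes) if genes else tracts
    genome_bp = sum(len(g) for g in genomes)
    summary = ssr.ssr_summary(tracts, genome_bp,
                              fraction_mode=cfg.ssr_fraction_mode)
    ssr.tracts_to_frame(tracts).to_csv(out / f"ssr_tracts_{label}.tsv",
                                       sep="\t", index=False)
    summary.counts_by_unit_length.to_csv(
        out / f"ssr_counts_{label}.tsv", sep="\t", index=False)
    summary.length_histogram.to_csv(
        out / f"ssr_histogram_{label}.tsv", sep="\t", index=False)
    write_bed([(t.scaffold_id, t.span[0], t.span[1], t.unit) for t in tracts],
              out / f"ssr_tracts_{label}.bed")
    return {"label": label, "n_tracts": summary.n_tracts,
            "genome_bp": genome_bp,
            "genome_fraction": summary.genome_fraction,
            "n_long": summary.n_long,
            "tracts": tracts}


def _significant_runs(proteins: dict[str, str], cds: dict[str, str],
                      alpha: float) -> tuple[dict, hp.AAThresholdTable]:
    thresholds = hp.aa_run_thresholds(proteins, alpha=alpha)
    runs = {gid: hp.find_homopolymers(gid, seq, thresholds, cds.get(gid))
            for gid, seq in proteins.items()}
    return runs, thresholds


def stage_homopolymers(cfg: RunConfig, proteins_a_path, cds_a_path,
                       proteins_b_path, cds_b_path, orthologs_path,
                       outdir: str | Path) -> dict:
    """Homopolymer runs, thresholds, densities, correlation and homology."""
    out = _outdir(outdir)
    prot_a = read_protein_fasta(proteins_a_path)
    prot_b = read_protein_fasta(proteins_b_path)
    cds_a = read_protein_fasta(cds_a_path)
    cds_b = read_protein_fasta(cds_b_path)
    runs_a, thr_a = _significant_runs(prot_a, cds_a, cfg.aa_alpha)
    runs_b, thr_b = _significant_runs(prot_b, cds_b, cfg.aa_alpha)

    for label, thr in (("a", thr_a), ("b", thr_b)):
        pd.DataFrame({"amino_acid": list(thr.frequency),
                      "frequency": list(thr.frequency.values()),
                      "min_len": [thr.min_len[aa] for aa in thr.frequency]}
                     ).to_csv(out / f"aa_thresholds_{label}.tsv",
                              sep="\t", index=False)
    for label, runs in (("a", runs_a), ("b", runs_b)):
        pd.DataFrame(
            [(r.protein_id, r.amino_acid, r.start, r.length, r.significant)
             for rs in runs.values() for r in rs],
            columns=["protein_id", "amino_acid", "start", "length",
                     "significant"]
        ).to_csv(out / f"homopolymer_runs_{label}.tsv", sep="\t", index=False)

    dens_a = hp.repeat_density([r for rs in runs_a.values() for r in rs],
                               thr_a.total_residues)
    dens_b = hp.repeat_density([r for rs in runs_b.values() for r in rs],
                               thr_b.total_residues)
    corr = hp.density_correlation(dens_a, dens_b)
    pd.DataFrame({"amino_acid": list(dens_a),
                  "density_a": list(dens_a.values()),
                  "density_b": [dens_b[aa] for aa in dens_a]}
                 ).to_csv(out / "repeat_densities.tsv", sep="\t", index=False)

    table = read_ortholog_table(orthologs_path)
    pairs = [(r.gene_a, r.gene_b) for r in table.one_to_one.itertuples()
             if r.gene_a in prot_a and r.gene_b in prot_b]
    alignments = {(ga, gb): hp.global_align(
        prot_a[ga], prot_b[gb], ga, gb,
        open_gap=cfg.align_open_gap, extend_gap=cfg.align_extend_gap)
        for ga, gb in pairs}
    homology = hp.call_repeat_homology(pairs, runs_a, runs_b, alignments,
                                       min_overlap=cfg.homology_min_overlap)
    pd.DataFrame(
        [(c.gene_a, c.gene_b, c.run_a.amino_acid, c.run_a.start,
          c.run_b.start, c.homologous, c.overlap_columns)
         for c in homology.calls],
        columns=["gene_a", "gene_b", "amino_acid", "start_a", "start_b",
                 "homologous", "overlap_columns"]
    ).to_csv(out / "repeat_homology.tsv", sep="\t", index=False)

    n_sig_a = sum(sum(r.significant for r in rs) for rs in runs_a.values())
    n_sig_b = sum(sum(r.significant for r in rs) for rs in runs_b.values())
    return {"thresholds_a": thr_a, "thresholds_b": thr_b,
            "runs_a": runs_a, "runs_b": runs_b,
            "n_significant_a": n_sig_a, "n_significant_b": n_sig_b,
            "densities_a": dens_a, "densities_b": dens_b,
            "density_correlation_r": corr.r, "density_correlation_p": corr.p,
            "homology": homology, "alignments": alignments, "pairs": pairs}


def stage_synteny(cfg: RunConfig, orthologs_path, gff_a_path, gff_b_path,
                  genome_a_path, genome_b_path, outdir: str | Path) -> dict:
    """Synteny blocks at w, permutation null, w selection and FPR."""
    out = _outdir(outdir)
    genomes_a = read_fasta(genome_a_path)
    genomes_b = read_fasta(genome_b_path)
    table = read_ortholog_table(orthologs_path)
    omap = synteny.OrderedOrthologMap.from_inputs(
        table, read_gff3(gff_a_path, genomes_a),
        read_gff3(gff_b_path, genomes_b))
    blocks = synteny.build_blocks(omap, cfg.synteny_w,
                                  strict_order=cfg.synteny_strict_order)
    stats = synteny.block_stats(blocks, omap)
    null = synteny.null_distribution(omap, cfg.synteny_w, cfg.synteny_n_perm,
                                     cfg.seed, mode=cfg.synteny_shuffle_mode)
    selection = synteny.select_w(omap, cfg.synteny_w_max,
                                 max(10, cfg.synteny_n_perm // 4),
                                 cfg.seed + 1, k_sd=cfg.synteny_k_sd,
                                 mode=cfg.synteny_shuffle_mode)
    fpr = (synteny.fpr_estimate(stats.participation, null)
           if stats.participation > 0 else float("nan"))
    synteny.blocks_to_frame(blocks, omap).to_csv(
        out / "synteny_blocks.tsv", sep="\t", index=False)
    selection.table.to_csv(out / "synteny_w_selection.tsv", sep="\t",
                           index=False)
    return {"omap": omap, "blocks": blocks, "stats": stats, "null": null,
            "fpr": fpr, "selection": selection}


def stage_ncrna(cfg: RunConfig, genome_path, outdir: str | Path,
                label: str = "a",
                class_stems: dict[str, str] | None = None) -> dict:
    """k-mer DUSE enrichment, stem/bulge filtering and class assignment."""
    out = _outdir(outdir)
    if class_stems is None:
        class_stems = dict(CLASS_STEMS_A)
    genomes = read_fasta(genome_path)
    candidates = []
    enrichment = ncrna.kmer_duse_enrichment(
        genomes, k=cfg.ncrna_k, duse_window=cfg.ncrna_duse_window,
        respect_mask=cfg.ncrna_respect_mask, duse=cfg.ncrna_duse_pattern)
    top_kmers = list(enrichment[enrichment["with_duse"] > 0].head(3)["kmer"])
    for g in genomes:
        for kmer in top_kmers:
            anchors = [i for i in range(len(g.residues) - len(kmer) + 1)
                       if g.residues[i:i + len(kmer)] == kmer]
            for c in ncrna.stem_filter(
                    g, anchors, stem_len=cfg.ncrna_stem_len,
                    separation=cfg.ncrna_separation,
                    duse_window=cfg.ncrna_duse_window,
                    stem5_offset=cfg.ncrna_stem5_offset,
                    bulge=cfg.ncrna_bulge,
                    duse=cfg.ncrna_duse_pattern):
                candidates.append(ncrna.assign_class(c, class_stems))
    # an anchor can qualify through several ranked k-mers; keep one record
    seen = set()
    unique = []
    for c in candidates:
        key = (c.scaffold_id, c.stem5_start, c.stem3_start)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    enrichment.head(200).to_csv(out / f"ncrna_enrichment_{label}.tsv",
                                sep="\t", index=False)
    ncrna.candidates_to_frame(unique).to_csv(
        out / f"ncrna_candidates_{label}.tsv", sep="\t", index=False)
    ncrna.candidates_to_gff3(unique, out / f"ncrna_candidates_{label}.gff3")
    return {"label": label, "enrichment": enrichment,
            "top_kmers": top_kmers, "candidates": unique}


def pair_evolution(cfg: RunConfig, prot_a, prot_b, cds_a, cds_b,
                   pairs, runs_a, runs_b, alignments,
                   repeat_excluded: bool = True) -> pd.DataFrame:
    """dN/dS and conservation score for each ortholog pair."""
    rows = []
    for ga, gb in pairs:
        aln = alignments[(ga, gb)]
        mask_a = {i for r in runs_a.get(ga, []) if r.significant
                  for i in range(r.start, r.end)} if repeat_excluded else set()
        mask_b = {i for r in runs_b.get(gb, []) if r.significant
                  for i in range(r.start, r.end)} if repeat_excluded else set()
        codon_pairs = molevo.codon_align(cds_a[ga], cds_b[gb], aln,
                                         mask_a, mask_b)
        try:
            res = molevo.estimate_dn(codon_pairs)
            dn, ds = res.dN, res.dS
        except ValueError:
            dn = ds = float("nan")
        rows.append((ga, gb, dn, ds, molevo.conservation_score(aln),
                     repeat_excluded))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "dN", "dS",
                                       "conservation_score",
                                       "repeat_excluded"])


def stage_social(cfg: RunConfig, proteins_a_path, proteins_b_path,
                 cds_a_path, cds_b_path, orthologs_path,
                 expression_a_path, outdir: str | Path,
                 hp_result: dict | None = None) -> dict:
    """Per-pair evolution, social indices and the regression/U-test battery."""
    out = _outdir(outdir)
    prot_a = read_protein_fasta(proteins_a_path)
    prot_b = read_protein_fasta(proteins_b_path)
    cds_a = read_protein_fasta(cds_a_path)
    cds_b = read_protein_fasta(cds_b_path)
    if hp_result is None:
        hp_result = stage_homopolymers(cfg, proteins_a_path, cds_a_path,
                                       proteins_b_path, cds_b_path,
                                       orthologs_path, outdir)
    evo = pair_evolution(cfg, prot_a, prot_b, cds_a, cds_b,
                         hp_result["pairs"], hp_result["runs_a"],
                         hp_result["runs_b"], hp_result["alignments"])
    evo.to_csv(out / "pair_evolution.tsv", sep="\t", index=False)

    counts = pd.read_csv(expression_a_path, sep="\t")
    profiles = molevo.qc_filter(counts, min_total=cfg.qc_min_total,
                                min_reproducibility=cfg.qc_min_reproducibility)
    indices = {}
    for p in profiles:
        si = molevo.social_index(p)
        if si is not None:
            indices[si.gene_id] = si.index
    pd.DataFrame({"gene_id": list(indices),
                  "social_index": list(indices.values())}
                 ).to_csv(out / "social_index.tsv", sep="\t", index=False)

    evo_idx = evo.assign(index=[indices.get(g, np.nan) for g in evo["gene_a"]])
    sub = evo_idx.dropna(subset=["index", "dN", "conservation_score"])
    reg_dn = molevo.regress_on_index(sub["dN"], sub["index"])
    reg_cs = molevo.regress_on_index(sub["conservation_score"], sub["index"])

    with_orth = {g for g, _ in hp_result["pairs"]}
    idx_genes = [g for g in indices if not g.endswith("p")]  # exclude inparalogs
    presence = molevo.ortholog_presence_vs_index(
        [indices[g] for g in idx_genes],
        [g in with_orth for g in idx_genes])

    # dN by repeat status (repeat = gene carries a significant homopolymer)
    has_rep = {ga: any(r.significant for r in hp_result["runs_a"].get(ga, []))
               for ga, _ in hp_result["pairs"]}
    evo_ok = evo.dropna(subset=["dN"])
    repeat_cmp = None
    flags = np.array([has_rep[g] for g in evo_ok["gene_a"]])
    if 2 <= flags.sum() and 2 <= (~flags).sum():
        repeat_cmp = hp.compare_by_repeat_status(
            evo_ok["dN"].to_numpy(), flags, test="t")

    results = {
        "evolution": evo, "indices": indices,
        "regression_dn": reg_dn, "regression_cs": reg_cs,
        "presence_test": presence, "repeat_comparison": repeat_cmp,
        "n_profiles": len(profiles),
    }
    flat = {
        "regression_dn": vars(reg_dn), "regression_cs": vars(reg_cs),
        "presence_test": vars(presence),
        "repeat_comparison": vars(repeat_cmp) if repeat_cmp else None,
        "n_profiles": len(profiles),
    }
    with open(out / "social_stats.json", "w") as fh:
        json.dump(flat, fh, indent=2, default=float)
    return results


def run_all(cfg: RunConfig, paths, outdir: str | Path) -> dict:
    """Run every analysis stage on a dataset laid out like DatasetPaths."""
    out = _outdir(outdir)
    results = {}
    results["ssr_a"] = stage_ssr(cfg, paths.genome_a, paths.gff_a, out, "a")
    results["ssr_b"] = stage_ssr(cfg, paths.genome_b, paths.gff_b, out, "b")
    results["homopolymers"] = stage_homopolymers(
        cfg, paths.proteins_a, paths.cds_a, paths.proteins_b, paths.cds_b,
        paths.orthologs, out)
    results["synteny"] = stage_synteny(
        cfg, paths.orthologs, paths.gff_a, paths.gff_b,
        paths.genome_a, paths.genome_b, out)
    results["ncrna_a"] = stage_ncrna(cfg, paths.genome_a, out, "a")
    results["ncrna_b"] = stage_ncrna(cfg, paths.genome_b, out, "b")
    results["social"] = stage_social(
        cfg, paths.proteins_a, paths.proteins_b, paths.cds_a, paths.cds_b,
        paths.orthologs, paths.expression_a, out,
        hp_result=results["homopolymers"])
    write_provenance(cfg, {
        "genome_a": paths.genome_a, "genome_b": paths.genome_b,
        "gff_a": paths.gff_a, "gff_b": paths.gff_b,
        "orthologs": paths.orthologs,
        "expression_a": paths.expression_a,
    }, out / "provenance.yml")
    return results
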