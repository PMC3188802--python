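"""Readers and writers for the standard formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``(start, end)``
tuples in base pairs; GFF3 and BED conversion happens only at the file
boundary.  Soft-masked (lowercase) FASTA is the masking interface; an optional
flag additionally treats hard-masked ``N`` runs as masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("dictycomp")

DNA_ALPHABET = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file (bad record, bad alphabet, duplicate id)."""


class CoordinateError(ValueError):
    """A feature lies outside its scaffold or violates interval invariants."""


class ReferenceMismatchError(KeyError):
    """An identifier does not resolve against the supplied sequences/models."""


@dataclass
class GenomeSequence:
    """One scaffold: uppercase residues plus per-position mask flags."""

    scaffold_id: str
    residues: str
    masked: np.ndarray  # bool, same length as residues

    def __post_init__(self) -> None:
        self.masked = np.asarray(self.masked, dtype=bool)
        if len(self.masked) != len(self.residues):
            raise CoordinateError(
                f"{self.scaffold_id}: mask length {len(self.masked)} != "
                f"sequence length {len(self.residues)}"
            )
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{self.scaffold_id}: non-DNA symbols {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A gene with its CDS parts, 0-based half-open, parts ordered 5'->3'."""

    gene_id: str
    scaffold_id: str
    span: tuple[int, int]
    strand: str
    cds_parts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        s, e = self.span
        if not 0 <= s < e:
            raise CoordinateError(f"{self.gene_id}: bad span {self.span}")
        parts = sorted(self.cds_parts)
        for (a1, b1), (a2, b2) in zip(parts, parts[1:]):
            if b1 > a2:
                raise CoordinateError(f"{self.gene_id}: overlapping CDS parts")
        for a, b in parts:
            if a < s or b > e:
                raise CoordinateError(f"{self.gene_id}: CDS outside gene span")
        # 5'->3' on the coding strand: genomic order for +, reversed for -
        self.cds_parts = parts if self.strand == "+" else parts[::-1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_parts)

    def cds_sequence(self, genome: GenomeSequence) -> str:
        """Spliced CDS, 5'->3' on the coding strand."""
        if genome.scaffold_id != self.scaffold_id:
            raise ReferenceMismatchError(
                f"{self.gene_id} is on {self.scaffold_id}, not {genome.scaffold_id}"
            )
        if self.strand == "+":
            return "".join(genome.residues[a:b] for a, b in self.cds_parts)
        return "".join(revcomp(genome.residues[a:b]) for a, b in self.cds_parts)


@dataclass
class OrthologTable:
    """Pair table with relations one_to_one / inparalog_group_member."""

    pairs: pd.DataFrame  # columns gene_a, gene_b, relation

    RELATIONS = {"one_to_one", "inparalog_group_member"}

    def __post_init__(self) -> None:
        required = {"gene_a", "gene_b", "relation"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise FormatError(f"ortholog table missing columns {sorted(missing)}")
        bad = set(self.pairs["relation"]) - self.RELATIONS
        if bad:
            raise FormatError(f"unknown relations {sorted(bad)}")
        ones = self.pairs[self.pairs["relation"] == "one_to_one"]
        for col in ("gene_a", "gene_b"):
            dup = ones[col][ones[col].duplicated()]
            if len(dup):
                raise FormatError(
                    f"one_to_one column {col} has duplicate genes: "
                    f"{sorted(set(dup))[:5]}"
                )

    @property
    def one_to_one(self) -> pd.DataFrame:
        return self.pairs[self.pairs["relation"] == "one_to_one"]

    def __len__(self) -> int:
        return len(self.pairs)


def read_fasta(path: str | Path, hard_mask: bool = False) -> list[GenomeSequence]:
    """Read FASTA; lowercase (and optionally N) positions set the mask flags."""
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if not raw:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate scaffold id {rec.id!r}")
        seen.add(rec.id)
        arr = np.frombuffer(raw.encode(), dtype="S1")
        masked = (arr >= b"a") & (arr <= b"z")
        upper = raw.upper()
        if hard_mask:
            masked = masked | (np.frombuffer(upper.encode(), dtype="S1") == b"N")
        records.append(GenomeSequence(rec.id, upper, masked))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    logger.info("read %d sequences, %d bp from %s",
                len(records), sum(len(r) for r in records), path)
    return records


def write_fasta(seqs: Iterable[GenomeSequence] | dict[str, str],
                path: str | Path, width: int = 70) -> None:
    """Write FASTA, re-applying soft masking where mask flags are set."""
    recs = []
    if isinstance(seqs, dict):
        items: Iterable = (GenomeSequence(k, v, np.zeros(len(v), bool))
                           for k, v in seqs.items())
    else:
        items = seqs
    for g in items:
        res = g.residues
        if g.masked.any():
            chars = np.frombuffer(res.encode(), dtype="S1").copy()
            lower = np.frombuffer(res.lower().encode(), dtype="S1")
            chars[g.masked] = lower[g.masked]
            res = chars.tobytes().decode()
        recs.append(SeqRecord(Seq(res), id=g.scaffold_id, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Plain id -> sequence mapping for protein or CDS FASTA."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_plain_fasta(seqs: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()),
        str(path), "fasta")


def read_gff3(path: str | Path,
              genomes: Sequence[GenomeSequence]) -> list[GeneModel]:
    """Read gene/mRNA/CDS models; converts 1-based inclusive to 0-based half-open."""
    import gffutils

    by_id = {g.scaffold_id: g for g in genomes}
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in by_id:
            raise ReferenceMismatchError(
                f"{gene.id}: unknown scaffold {gene.seqid!r}")
        scaf = by_id[gene.seqid]
        cds = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")]
        for a, b in cds:
            if a < 0 or b > len(scaf):
                raise CoordinateError(
                    f"{gene.id}: CDS [{a},{b}) outside scaffold "
                    f"{gene.seqid} of length {len(scaf)}")
        models.append(GeneModel(
            gene_id=gene.id,
            scaffold_id=gene.seqid,
            span=(gene.start - 1, gene.end),
            strand=gene.strand,
            cds_parts=cds,
        ))
    logger.info("read %d gene models from %s", len(models), path)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path,
               source: str = "dictycomp") -> None:
    """Write gene/mRNA/CDS features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s, e = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.scaffold_id}\t{source}\tgene\t{s + 1}\t{e}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.scaffold_id}\t{source}\tmRNA\t{s + 1}\t{e}\t.\t"
                     f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            for i, (a, b) in enumerate(sorted(g.cds_parts)):
                fh.write(f"{g.scaffold_id}\t{source}\tCDS\t{a + 1}\t{b}\t.\t"
                         f"{g.strand}\t0\tID={mrna}.cds{i};Parent={mrna}\n")


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read the gene_a/gene_b/relation TSV consumed by the synteny and
    molecular-evolution stages.  An empty file yields an empty table with a
    warning rather than an error."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["gene_a", "gene_b", "relation"])
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=["gene_a", "gene_b", "relation"])
    table = OrthologTable(df)
    if not len(table):
        logger.warning("%s: empty ortholog table", path)
    else:
        logger.info("ortholog table %s: %s", path,
                    df["relation"].value_counts().to_dict())
    return table


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def write_bed(intervals: Iterable[tuple[str, int, int, str]],
              path: str | Path) -> None:
    """BED4 export; intervals are already 0-based half-open so no conversion."""
    with open(path, "w") as fh:
        for scaf, start, end, name in intervals:
            fh.write(f"{scaf}\t{start}\t{end}\t{name}\n")
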