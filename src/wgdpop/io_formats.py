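"""Readers/writers for the standard formats the pipeline touches.

Conventions
-----------
* FASTA, GFF3 and VCF are 1-based inclusive on disk; every internal
  interval is 0-based half-open.  Conversion happens only here.
* Gene models keep their CDS parts in *transcription* order (for a
  minus-strand gene the part with the largest genomic coordinate comes
  first), so downstream splicing is a plain concatenation.
* All writers emit deterministic ordering and formatting, so identical
  inputs give byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

#: column names of the 12-column BLAST tabular ("outfmt 6") convention
HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]


class SequenceSet(dict):
    """Mapping of sequence name -> uppercase nucleotide string over {A,C,G,T,N}."""

    def __setitem__(self, name: str, seq: str) -> None:
        if not seq:
            raise ValueError(f"empty sequence for record {name!r}")
        seq = seq.upper().replace("U", "T")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"record {name!r} contains non-ACGTN symbols: {sorted(bad)}")
        super().__setitem__(name, seq)

    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.items()}


@dataclass
class GeneModel:
    """One representative transcript of a gene.

    ``cds_parts`` are 0-based half-open genomic intervals in transcription
    order.  ``rank`` is the dense order index of the gene along its
    chromosome (assigned by the catalog).  ``valid_codon`` is False when the
    summed CDS length is not a multiple of 3; such genes are kept in the
    catalog but excluded from codon analyses.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_parts: list[tuple[int, int]]
    rank: int = -1
    transcript_id: str = ""
    valid_codon: bool = True

    @property
    def start(self) -> int:
        return min(s for s, _ in self.cds_parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.cds_parts)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_parts)


@dataclass
class GeneCatalog:
    """Per-chromosome ordered gene models plus a gene_id index."""

    chromosomes: dict[str, list[GeneModel]] = field(default_factory=dict)
    by_id: dict[str, GeneModel] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, genes: Iterable[GeneModel]) -> "GeneCatalog":
        cat = cls()
        for g in genes:
            cat.chromosomes.setdefault(g.chromosome, []).append(g)
        for chrom, gs in cat.chromosomes.items():
            gs.sort(key=lambda g: (g.start, g.gene_id))
            for rank, g in enumerate(gs):
                g.rank = rank
                if g.gene_id in cat.by_id:
                    raise ValueError(f"duplicate gene id {g.gene_id!r}")
                cat.by_id[g.gene_id] = g
        return cat

    def __len__(self) -> int:
        return len(self.by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.by_id[gene_id]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP-loci genotype matrix with per-genotype depth.

    ``g[i, l]`` is the alt-allele count in {0,1,2} or ``-1`` for missing;
    ``d[i, l]`` is the read depth or ``-1`` where absent.  ``loci`` is a
    DataFrame with columns chromosome, position (1-based), ref, alt.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    g: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.int16)
        self.d = np.asarray(self.d, dtype=np.int32)
        n, m = len(self.sample_ids), len(self.loci)
        if self.g.shape != (n, m) or self.d.shape != (n, m):
            raise ValueError("genotype/depth shapes do not match samples x loci")
        for chrom, sub in self.loci.groupby("chromosome", sort=False):
            pos = sub["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=self.loci.iloc[keep].reset_index(drop=True)
            if keep.dtype != bool
            else self.loci.loc[keep].reset_index(drop=True),
            g=self.g[:, keep].copy(),
            d=self.d[:, keep].copy(),
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a multi-record FASTA into a :class:`SequenceSet`.

    Lowercase input is uppercased and U mapped to T.  A duplicate header or
    an empty sequence is a hard error.
    """
    seqs = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _gff_attributes(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.strip().rstrip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, genome: SequenceSet) -> GeneCatalog:
    """Build a :class:`GeneCatalog` from a GFF3 file with gene/mRNA/CDS rows.

    One representative transcript is chosen per gene: the one with the
    longest summed CDS, ties broken by lexicographically smallest transcript
    id.  Genes on chromosomes absent from ``genome`` are dropped with a
    warning; genes whose CDS length is not divisible by 3 are flagged
    invalid for codon analyses but retained for gene order.
    """
    gene_chrom: dict[str, tuple[str, str]] = {}  # gene -> (chrom, strand)
    mrna_gene: dict[str, str] = {}
    mrna_cds: dict[str, list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "mRNA", "CDS"):
                continue
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gene_chrom[a["ID"]] = (chrom, strand)
            elif ftype == "mRNA":
                parent = a.get("Parent")
                if parent is None or parent not in gene_chrom:
                    log.warning("%s:%d: mRNA with unknown parent gene; skipped", path, lineno)
                    continue
                mrna_gene[a["ID"]] = parent
                mrna_cds.setdefault(a["ID"], [])
            else:  # CDS
                parent = a.get("Parent")
                if parent is None or parent not in mrna_gene:
                    log.warning("%s:%d: CDS referencing unknown parent %r; skipped", path, lineno, parent)
                    continue
                mrna_cds[parent].append((int(start) - 1, int(end)))

    genes: list[GeneModel] = []
    gene_mrnas: dict[str, list[str]] = {}
    for mrna_id, gene_id in mrna_gene.items():
        gene_mrnas.setdefault(gene_id, []).append(mrna_id)

    for gene_id in sorted(gene_mrnas):
        chrom, strand = gene_chrom[gene_id]
        if chrom not in genome:
            log.warning("gene %s on chromosome %s absent from genome; dropped", gene_id, chrom)
            continue
        candidates = [m for m in gene_mrnas[gene_id] if mrna_cds.get(m)]
        if not candidates:
            log.warning("gene %s has no CDS; dropped", gene_id)
            continue
        rep = max(candidates, key=lambda m: (sum(e - s for s, e in mrna_cds[m]), _neg_lex(m)))
        parts = sorted(mrna_cds[rep])
        for (s1, e1), (s2, _) in zip(parts, parts[1:]):
            if s2 < e1:
                raise ValueError(f"gene {gene_id}: overlapping CDS parts")
        if strand == "-":
            parts = parts[::-1]
        total = sum(e - s for s, e in parts)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                cds_parts=parts,
                transcript_id=rep,
                valid_codon=(total % 3 == 0),
            )
        )
        if total % 3 != 0:
            log.warning("gene %s: CDS length %d not divisible by 3; excluded from codon analyses", gene_id, total)

    return GeneCatalog.from_genes(genes)


class _neg_lex(str):
    """Inverts lexicographic comparison, so max() prefers the smallest id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


def extract_cds(catalog: GeneCatalog, genome: SequenceSet) -> SequenceSet:
    """Spliced CDS per gene; minus-strand sequences reverse-complemented."""
    out = SequenceSet()
    for gene_id in sorted(catalog.by_id):
        gene = catalog[gene_id]
        chrom_seq = genome[gene.chromosome]
        pieces = []
        for s, e in gene.cds_parts:
            if s < 0 or e > len(chrom_seq):
                raise ValueError(
                    f"gene {gene_id}: CDS part ({s},{e}) out of bounds for "
                    f"{gene.chromosome} (len {len(chrom_seq)})"
                )
            part = chrom_seq[s:e]
            if gene.strand == "-":
                part = str(Seq(part).reverse_complement())
            pieces.append(part)
        out[gene_id] = "".join(pieces)
    return out


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required) into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (counted in the log);
    half-calls are treated as missing.  If FORMAT/DP is absent the depth is
    recorded as -1 and the genotype kept, with one global warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows, gs, ds = [], [], []
    n_skipped = 0
    dp_warned = False
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        geno = np.array([gt[:2] for gt in v.genotypes], dtype=np.int16)
        g = geno.sum(axis=1)
        g[(geno < 0).any(axis=1)] = -1
        dp = v.format("DP")
        if dp is None:
            if not dp_warned:
                log.warning("%s: FORMAT/DP absent; depths recorded as -1", path)
                dp_warned = True
            d = np.full(len(samples), -1, dtype=np.int32)
        else:
            d = dp[:, 0].astype(np.int32)
            d[d < 0] = -1
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        gs.append(g)
        ds.append(d)
    if n_skipped:
        log.info("%s: skipped %d multiallelic/non-SNP records", path, n_skipped)
    loci = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt"])
    g = np.array(gs, dtype=np.int16).T if gs else np.zeros((len(samples), 0), np.int16)
    d = np.array(ds, dtype=np.int32).T if ds else np.zeros((len(samples), 0), np.int32)
    return GenotypeMatrix(sample_ids=samples, loci=loci, g=g, d=d)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Emit a minimal deterministic VCF v4.2 with GT and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(gm.loci["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for l in range(gm.n_loci):
            row = gm.loci.iloc[l]
            fields = [
                str(row["chromosome"]), str(row["position"]), ".",
                row["ref"], row["alt"], ".", ".", ".", "GT:DP",
            ]
            for i in range(gm.n_samples):
                dp = gm.d[i, l]
                fields.append(f"{gt_str[int(gm.g[i, l])]}:{dp if dp >= 0 else '.'}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Homology hits (BLAST outfmt 6)


def read_homology_table(path: str | Path, max_evalue: float = 1e-10) -> pd.DataFrame:
    """Read a 12-column tabular homology table, filter by e-value, drop self-hits.

    Rows with ``e_value > max_evalue`` are excluded (the cutoff is
    inclusive).  An unparsable row raises with its line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(cols)}")
            try:
                rows.append(
                    (
                        cols[0], cols[1], float(cols[2]), int(cols[3]),
                        int(cols[4]), int(cols[5]), int(cols[6]), int(cols[7]),
                        int(cols[8]), int(cols[9]), float(cols[10]), float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable row ({exc})") from None
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(hits):
        if (hits["e_value"] < 0).any():
            raise ValueError(f"{path}: negative e-value encountered")
        hits = hits[(hits["e_value"] <= max_evalue) & (hits["query_id"] != hits["subject_id"])]
    return hits.reset_index(drop=True)


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, float_format="%g")
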