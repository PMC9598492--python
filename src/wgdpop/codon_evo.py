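"""Protein-guided pairwise codon alignment and the 4DTv divergence statistic.

The 4DTv statistic measures divergence between two coding sequences as the
transversion rate at fourfold-degenerate third codon positions.  Because any
base at such a position encodes the same amino acid, these changes are
synonymous and their accumulation tracks neutral divergence time; a peak in
the 4DTv distribution over many paralog pairs marks a burst of duplication
(e.g. a whole-genome duplication).

A site is counted as fourfold-degenerate ("4D") only when *both* codons of
the aligned column belong to a fourfold-degenerate codon family of the
standard genetic code and their first two positions are identical — the
strictest common convention, which avoids counting sites whose degeneracy
class differs between the two sequences.

The raw transversion proportion ``p = n_tv / n_4d`` saturates at 1/2 under
symmetric substitution models, so the multiple-hit-corrected distance is

    d = -(1/2) * ln(1 - 2 p),       undefined for p >= 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

#: fourfold-degenerate codon families of the standard code (first two bases)
FOURFOLD_PREFIXES = frozenset(["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"])

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")  # X from N-containing codons


@dataclass
class AlignmentScoring:
    """Protein alignment scoring: substitution matrix name + affine gaps."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


@dataclass
class ProteinAlignment:
    seq_a: str  # aligned, with '-' gaps
    seq_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned rows differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.seq_a, self.seq_b)):
            raise ValueError("column with gap in both rows")


@dataclass
class CodonAlignment:
    """Gap-free paired codon columns from a protein-guided alignment."""

    gene_a: str
    gene_b: str
    columns: list[tuple[str, str]]
    n_dropped_n: int = 0  # columns dropped because a codon contained N


@dataclass
class FourDTvResult:
    pair_id: str
    n_4d: int
    n_tv: int
    p_raw: float | None
    d_corr: float | None
    status: str  # "ok" | "saturated" | "too_few_4d_sites"


def align_proteins_global(
    seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None
) -> ProteinAlignment:
    """Optimal global alignment of two amino-acid strings (affine gaps).

    Deterministic: a single traceback is taken in Biopython's fixed internal
    order, so repeated calls give identical alignments.
    """
    scoring = scoring or AlignmentScoring()
    for name, s in (("a", seq_a), ("b", seq_b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        bad = set(s) - _AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name} has non-amino-acid symbols: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    return ProteinAlignment(seq_a=aln[0], seq_b=aln[1], score=aln.score)


def translate_cds(cds: str) -> str:
    """Translate a CDS, trimming a single terminal stop if present."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon in CDS")
    return prot


def backtranslate(
    protein_aln: ProteinAlignment,
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CodonAlignment:
    """Map a protein alignment back onto the source codons.

    Gap columns are dropped; columns where either codon contains N are
    dropped and counted.  Raises if a CDS does not translate to its aligned
    (ungapped) protein row.
    """
    for gene, row, cds in ((gene_a, protein_aln.seq_a, cds_a), (gene_b, protein_aln.seq_b, cds_b)):
        prot = translate_cds(cds)
        ungapped = row.replace("-", "")
        if prot != ungapped:
            idx = next((i for i, (x, y) in enumerate(zip(prot, ungapped)) if x != y), min(len(prot), len(ungapped)))
            raise ValueError(f"translation mismatch for {gene} at residue {idx}")
    columns: list[tuple[str, str]] = []
    n_dropped = 0
    ia = ib = 0
    for ca, cb in zip(protein_aln.seq_a, protein_aln.seq_b):
        if ca != "-" and cb != "-":
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            if "N" in codon_a or "N" in codon_b:
                n_dropped += 1
            else:
                columns.append((codon_a, codon_b))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return CodonAlignment(gene_a=gene_a, gene_b=gene_b, columns=columns, n_dropped_n=n_dropped)


def classify_fourfold_column(codon_a: str, codon_b: str) -> bool:
    """True iff both codons are in 4D families and share their first two bases."""
    return (
        codon_a[:2] == codon_b[:2]
        and codon_a[:2] in FOURFOLD_PREFIXES
        and codon_b[:2] in FOURFOLD_PREFIXES
    )


def is_transversion(base_a: str, base_b: str) -> bool:
    """Purine <-> pyrimidine change (A/G vs C/T)."""
    return (base_a in PURINES) != (base_b in PURINES)


def correct_saturation(p_raw: float) -> float | None:
    """Multiple-substitution correction d = -(1/2) ln(1 - 2p); None at saturation."""
    if p_raw >= 0.5:
        return None
    return -0.5 * math.log1p(-2.0 * p_raw)


def fourdtv(
    codon_aln: CodonAlignment, min_4d: int = 10, pair_id: str | None = None
) -> FourDTvResult:
    """4DTv statistic over the 4D columns of a codon alignment."""
    pair_id = pair_id or f"{codon_aln.gene_a}|{codon_aln.gene_b}"
    n_4d = n_tv = 0
    for codon_a, codon_b in codon_aln.columns:
        if classify_fourfold_column(codon_a, codon_b):
            n_4d += 1
            if is_transversion(codon_a[2], codon_b[2]):
                n_tv += 1
    if n_4d < min_4d:
        return FourDTvResult(pair_id, n_4d, n_tv, None, None, "too_few_4d_sites")
    p_raw = n_tv / n_4d
    d_corr = correct_saturation(p_raw)
    status = "ok" if d_corr is not None else "saturated"
    return FourDTvResult(pair_id, n_4d, n_tv, p_raw, d_corr, status)


def fourdtv_for_pair(
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    scoring: AlignmentScoring | None = None,
    min_4d: int = 10,
) -> FourDTvResult:
    """Convenience: align proteins, backtranslate, compute 4DTv for one CDS pair."""
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    aln = align_proteins_global(prot_a, prot_b, scoring)
    codon_aln = backtranslate(aln, cds_a, cds_b, gene_a, gene_b)
    return fourdtv(codon_aln, min_4d=min_4d, pair_id=f"{gene_a}|{gene_b}")
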