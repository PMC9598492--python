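"""Synthetic inputs with the statistical structure the analyses assume.

Two generators cover the pipeline's two tracks:

* :func:`simulate_wgd_genome` builds a genome that carries a whole-genome
  duplication of known age: every chromosome is duplicated with conserved
  gene order, and each homeolog pair's fourfold-degenerate third codon
  positions are mutated so that a 4D column differs by a transversion with
  a known probability p*.  Gene loss and local order shuffling add the
  noise real duplicated genomes show.  A truth table records every pair's
  realized transversion count, so downstream estimates are testable as
  parameter recovery.

* :func:`simulate_admixed_genotypes` draws an admixed genotype panel under
  the Balding-Nichols model: population allele frequencies are Beta-drawn
  around an ancestral frequency with variance p(1-p)*Fst, individuals carry
  Dirichlet ancestry proportions, and genotypes are Binomial(2, q·p) with
  negative-binomial read depths and random missingness — so the depth /
  missingness / MAF filter cascade is exercisable end to end.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_evo import FOURFOLD_PREFIXES, PURINES
from .io_formats import GeneCatalog, GenotypeMatrix, SequenceSet, write_vcf

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}
_4D_PREFIXES = sorted(FOURFOLD_PREFIXES)
_NON4D_CODONS = sorted(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b not in FOURFOLD_PREFIXES and a + b + c not in _STOPS
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {b: sorted(set("CT" if b in PURINES else "AG")) for b in _BASES}


# ---------------------------------------------------------------------------
# WGD genome simulation


@dataclass
class WGDSimSpec:
    """Conditions for the duplicated-genome simulation.

    ``transversion_target`` (p*) is the probability that a 4D third codon
    position differs by a transversion between the two homeologs; the
    corrected 4DTv distance implied is -(1/2) ln(1 - 2 p*).  Transitions
    occur with probability p* * ts_tv_ratio at the same positions (they are
    synonymous there and do not affect the transversion count).
    """

    n_chromosomes: int = 20
    genes_per_chromosome: int = 60
    codons_per_gene: int = 200
    transversion_target: float = 0.12
    ts_tv_ratio: float = 2.0
    gene_loss_rate: float = 0.1
    local_shuffle_rate: float = 0.02
    fourfold_fraction: float = 0.6
    intergenic_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transversion_target < 0.5:
            raise ValueError("transversion_target must be in [0, 0.5)")
        for name in ("gene_loss_rate", "local_shuffle_rate", "fourfold_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.transversion_target * (1.0 + self.ts_tv_ratio) > 1.0:
            raise ValueError("p* (1 + ts_tv_ratio) must not exceed 1")


@dataclass
class WGDSim:
    genome: SequenceSet
    gff_text: str
    hits: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .io_formats import write_fasta, write_hits

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "hits": outdir / "hits.tsv",
            "truth": outdir / "truth_pairs.tsv",
        }
        write_fasta(self.genome, paths["fasta"])
        paths["gff3"].write_text(self.gff_text)
        write_hits(self.hits, paths["hits"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _sample_gene_codons(rng: np.random.Generator, spec: WGDSimSpec) -> list[str]:
    codons = ["ATG"]
    is_4d = rng.random(spec.codons_per_gene - 1) < spec.fourfold_fraction
    prefixes = rng.integers(0, len(_4D_PREFIXES), size=spec.codons_per_gene - 1)
    thirds = rng.integers(0, 4, size=spec.codons_per_gene - 1)
    others = rng.integers(0, len(_NON4D_CODONS), size=spec.codons_per_gene - 1)
    for j in range(spec.codons_per_gene - 1):
        if is_4d[j]:
            codons.append(_4D_PREFIXES[prefixes[j]] + _BASES[thirds[j]])
        else:
            codons.append(_NON4D_CODONS[others[j]])
    return codons


def _mutate_duplicate(
    rng: np.random.Generator, codons: list[str], spec: WGDSimSpec
) -> tuple[list[str], int, int]:
    """Mutate 4D third positions; returns (codons', n_tv, n_ts) realized."""
    out = list(codons)
    n_tv = n_ts = 0
    p = spec.transversion_target
    pt = p * spec.ts_tv_ratio
    u = rng.random(len(codons))
    pick = rng.integers(0, 2, size=len(codons))
    for j, codon in enumerate(codons):
        if codon[:2] not in FOURFOLD_PREFIXES:
            continue
        if u[j] < p:
            out[j] = codon[:2] + _TRANSVERSIONS[codon[2]][pick[j]]
            n_tv += 1
        elif u[j] < p + pt:
            out[j] = codon[:2] + _TRANSITION[codon[2]]
            n_ts += 1
    return out, n_tv, n_ts


def simulate_wgd_genome(spec: WGDSimSpec) -> WGDSim:
    """Simulate a genome with a duplication of known 4DTv age.

    Each ancestral chromosome ``chrNN`` gets a duplicate ``chrNNd`` whose
    genes carry third-position mutations; a fraction ``gene_loss_rate`` of
    duplicated genes is deleted and ``local_shuffle_rate`` adjacent swaps
    perturb the duplicate's gene order.  The hits table lists true homeolog
    pairs in 12-column tabular form; the truth table records each pair's
    fourfold site and realized substitution counts.
    """
    rng = np.random.default_rng(spec.seed)
    genome = SequenceSet()
    gff_lines = ["##gff-version 3"]
    hit_rows = []
    truth_rows = []

    min_block_warning = spec.genes_per_chromosome * (1.0 - spec.gene_loss_rate) < 10
    if min_block_warning:
        import logging

        logging.getLogger(__name__).warning(
            "expected surviving genes per chromosome < 10; blocks may be undetectable"
        )

    for c in range(1, spec.n_chromosomes + 1):
        chrom_a, chrom_b = f"chr{c:02d}", f"chr{c:02d}d"
        gene_codons = [_sample_gene_codons(rng, spec) for _ in range(spec.genes_per_chromosome)]
        strands = rng.choice(["+", "-"], size=spec.genes_per_chromosome)

        dup_entries = []  # (orig_index, codons_b)
        for j, codons in enumerate(gene_codons):
            codons_b, n_tv, n_ts = _mutate_duplicate(rng, codons, spec)
            n_4d = sum(1 for cd in codons if cd[:2] in FOURFOLD_PREFIXES)
            lost = rng.random() < spec.gene_loss_rate
            if not lost:
                dup_entries.append((j, codons_b))
                gene_a = f"ms{c:02d}g{j + 1:03d}"
                gene_b = gene_a + "d"
                truth_rows.append((gene_a, gene_b, chrom_a, chrom_b, n_4d, n_tv, n_ts))

        # adjacent swaps on the duplicate's gene order
        order = list(range(len(dup_entries)))
        for j in range(len(order) - 1):
            if rng.random() < spec.local_shuffle_rate:
                order[j], order[j + 1] = order[j + 1], order[j]
        dup_entries = [dup_entries[j] for j in order]

        genome[chrom_a] = _emit_chromosome(
            gff_lines, chrom_a,
            [(f"ms{c:02d}g{j + 1:03d}", codons, strands[j]) for j, codons in enumerate(gene_codons)],
            spec.intergenic_length, rng,
        )
        genome[chrom_b] = _emit_chromosome(
            gff_lines, chrom_b,
            [(f"ms{c:02d}g{j + 1:03d}d", codons_b, strands[j]) for j, codons_b in dup_entries],
            spec.intergenic_length, rng,
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_a", "gene_b", "chrom_a", "chrom_b", "n_4d", "n_tv", "n_ts"],
    )
    length = spec.codons_per_gene * 3
    for row in truth.itertuples():
        mismatches = row.n_tv + row.n_ts
        identity = 100.0 * (1.0 - mismatches / length)
        bit = 2.0 * length - 4.0 * mismatches
        hit_rows.append(
            (row.gene_a, row.gene_b, round(identity, 2), length, mismatches, 0,
             1, length, 1, length, 1e-180, round(bit, 1))
        )
    from .io_formats import HIT_COLUMNS

    hits = pd.DataFrame(hit_rows, columns=HIT_COLUMNS)
    return WGDSim(genome=genome, gff_text="\n".join(gff_lines) + "\n", hits=hits, truth=truth)


def _emit_chromosome(
    gff_lines: list[str],
    chrom: str,
    genes: list[tuple[str, list[str], str]],
    spacer: int,
    rng: np.random.Generator,
) -> str:
    """Append gene/mRNA/CDS rows for one chromosome; return its sequence."""
    pieces = []
    cursor = 0
    for gene_id, codons, strand in genes:
        inter = "".join(_BASES[i] for i in rng.integers(0, 4, size=spacer))
        pieces.append(inter)
        cursor += spacer
        cds = "".join(codons)
        segment = cds if strand == "+" else cds.translate(_COMPLEMENT)[::-1]
        start, end = cursor + 1, cursor + len(cds)  # 1-based inclusive
        pieces.append(segment)
        cursor += len(cds)
        gff_lines.append(f"{chrom}\twgdpop_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}")
        gff_lines.append(
            f"{chrom}\twgdpop_sim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}.t1;Parent={gene_id}"
        )
        gff_lines.append(
            f"{chrom}\twgdpop_sim\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={gene_id}.t1.cds;Parent={gene_id}.t1"
        )
    pieces.append("".join(_BASES[i] for i in rng.integers(0, 4, size=spacer)))
    return "".join(pieces)


# ---------------------------------------------------------------------------
# Admixed genotype simulation


@dataclass
class PopSimSpec:
    """Conditions for the admixed genotype panel.

    Defaults mirror the scale of the study system: 85 accessions from two
    source populations (40 + 45), ~2500 biallelic loci, moderate divergence
    (Fst 0.1).  ``admixture_alpha_main``/``_other`` parameterize the
    Dirichlet law for individual ancestry: alpha (9, 1) gives individuals
    mostly assigned to their home population with minor admixture.
    """

    n_populations: int = 2
    n_individuals: tuple[int, ...] = (40, 45)
    n_loci: int = 2500
    fst: float = 0.1
    admixture_alpha_main: float = 9.0
    admixture_alpha_other: float = 1.0
    depth_mean: float = 60.0
    depth_dispersion: float = 10.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("Fst must be in (0, 1)")
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if len(self.n_individuals) != self.n_populations:
            raise ValueError("n_individuals must have one entry per population")


@dataclass
class PopSim:
    gm: GenotypeMatrix
    Q_true: np.ndarray
    P_true: np.ndarray
    population_of: np.ndarray  # home population index per individual
    loci_annotations: pd.DataFrame = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"vcf": outdir / "genotypes.vcf", "q_true": outdir / "truth_Q.tsv", "p_true": outdir / "truth_P.tsv"}
        write_vcf(self.gm, paths["vcf"])
        pd.DataFrame(self.Q_true).to_csv(paths["q_true"], sep="\t", index=False, float_format="%.6f")
        pd.DataFrame(self.P_true).to_csv(paths["p_true"], sep="\t", index=False, float_format="%.6f")
        return paths


def simulate_admixed_genotypes(
    spec: PopSimSpec,
    catalog: GeneCatalog | None = None,
    genome: SequenceSet | None = None,
    fourfold_locus_fraction: float = 1.0,
) -> PopSim:
    """Balding-Nichols admixture simulation with depths and missingness.

    Ancestral frequencies ~ Uniform(0.1, 0.9); population k's frequency at
    each locus ~ Beta(p (1-F)/F, (1-p)(1-F)/F) so that its variance is
    p(1-p) Fst.  Individual alt counts ~ Binomial(2, sum_k q_ik p_kl);
    depths ~ NegativeBinomial(mean, dispersion); genotypes are masked
    missing at ``missing_rate``.

    When ``catalog`` and ``genome`` are given, a fraction
    ``fourfold_locus_fraction`` of loci is placed at true fourfold-
    degenerate third codon positions and the rest at other CDS positions,
    so the 4D-site restriction can be tested against the returned
    annotation.
    """
    rng = np.random.default_rng(spec.seed)
    K, L = spec.n_populations, spec.n_loci
    n = int(sum(spec.n_individuals))

    p_anc = rng.uniform(0.1, 0.9, size=L)
    F = spec.fst
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    P = np.stack([rng.beta(a, b) for _ in range(K)])  # K x L

    pop_of = np.concatenate([np.full(m, k) for k, m in enumerate(spec.n_individuals)])
    alphas = np.full((n, K), spec.admixture_alpha_other)
    alphas[np.arange(n), pop_of] = spec.admixture_alpha_main
    Q = np.vstack([rng.dirichlet(alpha) for alpha in alphas])

    f = Q @ P
    g = rng.binomial(2, f).astype(np.int16)

    p_nb = spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean)
    d = rng.negative_binomial(spec.depth_dispersion, p_nb, size=(n, L)).astype(np.int32)
    miss = rng.random((n, L)) < spec.missing_rate
    g[miss] = -1

    loci, annotations = _locus_table(rng, L, catalog, genome, fourfold_locus_fraction)
    sample_ids = [f"acc{j + 1:03d}" for j in range(n)]
    gm = GenotypeMatrix(sample_ids=sample_ids, loci=loci, g=g, d=d)
    return PopSim(gm=gm, Q_true=Q, P_true=P, population_of=pop_of, loci_annotations=annotations)


def _locus_table(rng, L, catalog, genome, fourfold_fraction):
    if catalog is None or genome is None:
        positions = np.sort(rng.choice(np.arange(1, L * 100 + 1), size=L, replace=False))
        refs = rng.integers(0, 4, size=L)
        alt_off = rng.integers(1, 4, size=L)
        loci = pd.DataFrame(
            {
                "chromosome": "chr01",
                "position": positions,
                "ref": [_BASES[i] for i in refs],
                "alt": [_BASES[(i + o) % 4] for i, o in zip(refs, alt_off)],
            }
        )
        ann = pd.DataFrame({"is_4d": np.zeros(L, dtype=bool)})
        return loci, ann

    from .popgen import fourfold_positions

    sites = fourfold_positions(catalog, genome)
    all_4d = sorted((c, p) for c, ps in sites.items() for p in ps)
    fourfold_set = set(all_4d)
    all_cds = sorted(
        {
            (g.chromosome, p)
            for g in catalog.by_id.values()
            for s, e in g.cds_parts
            for p in range(s + 1, e + 1)
        }
        - fourfold_set
    )
    n_4d = min(int(round(L * fourfold_fraction)), len(all_4d))
    n_other = L - n_4d
    if n_other > len(all_cds):
        raise ValueError("not enough non-4D CDS positions for the requested locus count")
    idx_4d = rng.choice(len(all_4d), size=n_4d, replace=False)
    idx_ot = rng.choice(len(all_cds), size=n_other, replace=False)
    chosen = [all_4d[i] for i in idx_4d] + [all_cds[i] for i in idx_ot]
    flags = [True] * n_4d + [False] * n_other
    order = sorted(range(len(chosen)), key=lambda i: chosen[i])
    chosen = [chosen[i] for i in order]
    flags = [flags[i] for i in order]
    refs = []
    alts = []
    for chrom, pos in chosen:
        ref = genome[chrom][pos - 1]
        ref = ref if ref in _BASES else "A"
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        refs.append(ref)
        alts.append(alt)
    loci = pd.DataFrame(
        {
            "chromosome": [c for c, _ in chosen],
            "position": [p for _, p in chosen],
            "ref": refs,
            "alt": alts,
        }
    )
    return loci, pd.DataFrame({"is_4d": flags})


# ---------------------------------------------------------------------------
# Toy fixtures


def make_toy_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the deterministic toy fixtures used by the documented examples.

    * ``chain_toy``: a 12-gene chromosome pair whose hits chain into exactly
      one colinear block.
    * ``splice_toy``: a two-part minus-strand gene whose spliced CDS is
      hand-checkable.
    * ``filter_toy``: a 10-sample x 5-locus VCF exercising each stage of
      the depth / missingness / MAF cascade.

    Repeated invocation produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- chaining toy: 12 genes on chrA, 12 on chrB, one-to-one hits
    gene_len = 30  # 10 codons
    cds = "ATG" + "GCA" * 9
    lines = ["##gff-version 3"]
    seqs = SequenceSet()
    for chrom, prefix in (("chrA", "ta"), ("chrB", "tb")):
        pieces, cursor = [], 0
        for j in range(1, 13):
            pieces.append("A" * 10)
            cursor += 10
            start, end = cursor + 1, cursor + gene_len
            pieces.append(cds)
            cursor += gene_len
            gid = f"{prefix}{j:02d}"
            lines.append(f"{chrom}\ttoy\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
            lines.append(f"{chrom}\ttoy\tmRNA\t{start}\t{end}\t.\t+\t.\tID={gid}.t;Parent={gid}")
            lines.append(f"{chrom}\ttoy\tCDS\t{start}\t{end}\t.\t+\t0\tID={gid}.c;Parent={gid}.t")
        seqs[chrom] = "".join(pieces) + "A" * 10
    hit_lines = [
        f"ta{j:02d}\ttb{j:02d}\t100.00\t{gene_len}\t0\t0\t1\t{gene_len}\t1\t{gene_len}\t1e-50\t60.0"
        for j in range(1, 13)
    ]
    paths["chain_fasta"] = outdir / "chain_toy.fa"
    paths["chain_gff3"] = outdir / "chain_toy.gff3"
    paths["chain_hits"] = outdir / "chain_toy_hits.tsv"
    from .io_formats import write_fasta

    write_fasta(seqs, paths["chain_fasta"])
    paths["chain_gff3"].write_text("\n".join(lines) + "\n")
    paths["chain_hits"].write_text("\n".join(hit_lines) + "\n")

    # --- minus-strand splice toy: CDS parts at genomic 31-39 then 11-19 in
    # transcription order; spliced+revcomp CDS is ATGGCTGCAGCCGGTTAA
    chrom_seq = "ACGTACGTAC" + "TTAACCGGC" + "ACGTACGTACG" + "TGCAGCCAT" + "ACGTACGTACG"
    splice = SequenceSet()
    splice["chrS"] = chrom_seq
    gff = [
        "##gff-version 3",
        "chrS\ttoy\tgene\t11\t39\t.\t-\t.\tID=gm1",
        "chrS\ttoy\tmRNA\t11\t39\t.\t-\t.\tID=gm1.t;Parent=gm1",
        "chrS\ttoy\tCDS\t31\t39\t.\t-\t0\tID=gm1.c1;Parent=gm1.t",
        "chrS\ttoy\tCDS\t11\t19\t.\t-\t0\tID=gm1.c2;Parent=gm1.t",
    ]
    paths["splice_fasta"] = outdir / "splice_toy.fa"
    paths["splice_gff3"] = outdir / "splice_toy.gff3"
    write_fasta(splice, paths["splice_fasta"])
    paths["splice_gff3"].write_text("\n".join(gff) + "\n")

    # --- 5-locus filter toy: 10 samples; sample 1 has depths 10/30/250/100/60
    n, L = 10, 5
    g = np.ones((n, L), dtype=np.int16)  # start all heterozygous
    d = np.full((n, L), 50, dtype=np.int32)
    d[0] = [10, 30, 250, 100, 60]
    # locus 4 (index 3): exactly one alt allele among 10 diploids -> MAF 0.05
    g[:, 3] = 0
    g[1, 3] = 1
    # locus 5 (index 4): two samples already missing -> 20% missing
    g[1, 4] = -1
    g[2, 4] = -1
    loci = pd.DataFrame(
        {
            "chromosome": "chrP",
            "position": [100, 200, 300, 400, 500],
            "ref": ["A", "C", "G", "T", "A"],
            "alt": ["G", "T", "A", "C", "T"],
        }
    )
    gm = GenotypeMatrix(
        sample_ids=[f"s{j + 1:02d}" for j in range(n)], loci=loci, g=g, d=d
    )
    paths["filter_vcf"] = outdir / "filter_toy.vcf"
    write_vcf(gm, paths["filter_vcf"])
    return paths
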