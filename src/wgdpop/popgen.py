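"""SNP filter cascade, diversity statistics, covariance PCA and admixture.

The filter cascade mirrors standard RAD-seq practice: per-genotype depth
masking (calls outside [dp_min, dp_max] become missing), then a per-locus
missingness filter, then a minor-allele-frequency filter computed on the
surviving calls.  An optional restriction keeps only SNPs at
fourfold-degenerate third codon positions, where both alleles are
synonymous by construction.

Diversity statistics per biallelic locus with allele frequencies p, q=1-p:

    GD  = 1 - p^2 - q^2              (gene diversity / expected heterozygosity)
    PIC = GD - 2 p^2 q^2             (polymorphism information content)
    Ho  = fraction heterozygous among non-missing genotypes
    MAF = min(p, q)

Population structure is fit with the maximum-likelihood admixture model:
individual i's genotype at locus l is Binomial(2, sum_k q_ik p_kl), with
ancestry proportions Q and cluster allele frequencies P estimated by EM.
The number of clusters is selected with the Evanno delta-K criterion over
replicate fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_evo import FOURFOLD_PREFIXES
from .io_formats import GeneCatalog, GenotypeMatrix, SequenceSet

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# Filters


@dataclass
class FilterReport:
    n_input: int
    n_genotypes_depth_masked: int
    n_after_missingness: int
    n_after_maf: int

    def as_dict(self) -> dict:
        return {
            "loci_in": self.n_input,
            "genotypes_depth_masked": self.n_genotypes_depth_masked,
            "loci_after_missingness": self.n_after_missingness,
            "loci_after_maf": self.n_after_maf,
        }


def apply_filters(
    gm: GenotypeMatrix,
    dp_min: int = 20,
    dp_max: int = 200,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Depth mask -> missingness filter -> MAF filter, with attrition report.

    Genotypes whose depth lies outside [dp_min, dp_max] (or is absent) are
    set missing; loci with a missing fraction >= ``max_missing`` are
    dropped; loci with MAF <= ``maf_min`` (strict > required to keep,
    computed on the remaining calls) are dropped.
    """
    g = gm.g.copy()
    depth_bad = (gm.d < dp_min) | (gm.d > dp_max)
    n_masked = int((depth_bad & (g >= 0)).sum())
    g[depth_bad] = -1

    missing_frac = (g < 0).mean(axis=0)
    keep_missing = missing_frac < max_missing

    called = (g >= 0).sum(axis=0)
    alt = np.where(g >= 0, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(called > 0, alt / (2.0 * called), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep_maf = keep_missing & (maf > maf_min)

    report = FilterReport(
        n_input=gm.n_loci,
        n_genotypes_depth_masked=n_masked,
        n_after_missingness=int(keep_missing.sum()),
        n_after_maf=int(keep_maf.sum()),
    )
    if report.n_after_maf == 0:
        raise ValueError(f"all loci removed by filters; attrition: {report.as_dict()}")
    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        loci=gm.loci.loc[keep_maf].reset_index(drop=True),
        g=g[:, keep_maf],
        d=gm.d[:, keep_maf].copy(),
    )
    log.info("filter attrition: %s", report.as_dict())
    return out, report


# ---------------------------------------------------------------------------
# Fourfold-degenerate site restriction


def fourfold_positions(catalog: GeneCatalog, genome: SequenceSet) -> dict[str, set[int]]:
    """Genomic 1-based positions that are 4D third codon positions.

    Positions covered by the CDS of more than one gene are excluded (their
    codon context is ambiguous); the count of such exclusions is logged.
    Strand-aware: for a minus-strand gene the codon is read off the reverse
    complement in transcription order.
    """
    claimed: dict[tuple[str, int], int] = {}
    fourfold: dict[str, set[int]] = {}
    per_gene: list[tuple[str, list[int]]] = []

    for gene_id in sorted(catalog.by_id):
        gene = catalog[gene_id]
        if not gene.valid_codon:
            continue
        # genomic position (1-based) of each CDS base, transcription order
        gpos: list[int] = []
        for s, e in gene.cds_parts:
            block = range(s + 1, e + 1)
            gpos.extend(reversed(block) if gene.strand == "-" else block)
        seq = genome[gene.chromosome]
        hits: list[int] = []
        for c in range(len(gpos) // 3):
            p1, p2, p3 = gpos[3 * c : 3 * c + 3]
            b1, b2 = seq[p1 - 1], seq[p2 - 1]
            if gene.strand == "-":
                b1, b2 = b1.translate(_COMPLEMENT), b2.translate(_COMPLEMENT)
            if "N" in (b1, b2) or "N" == seq[p3 - 1]:
                continue
            if b1 + b2 in FOURFOLD_PREFIXES:
                hits.append(p3)
        per_gene.append((gene.chromosome, hits))
        for p in gpos:
            claimed[(gene.chromosome, p)] = claimed.get((gene.chromosome, p), 0) + 1

    n_ambiguous = 0
    for chrom, hits in per_gene:
        for p in hits:
            if claimed[(chrom, p)] > 1:
                n_ambiguous += 1
            else:
                fourfold.setdefault(chrom, set()).add(p)
    if n_ambiguous:
        log.info("excluded %d 4D positions inside overlapping genes", n_ambiguous)
    return fourfold


def restrict_to_4d_sites(
    gm: GenotypeMatrix, catalog: GeneCatalog, genome: SequenceSet
) -> GenotypeMatrix:
    """Keep loci at fourfold-degenerate third codon positions of the catalog."""
    sites = fourfold_positions(catalog, genome)
    keep = np.array(
        [
            row.position in sites.get(row.chromosome, ())
            for row in gm.loci.itertuples()
        ],
        dtype=bool,
    )
    return gm.subset_loci(keep)


# ---------------------------------------------------------------------------
# Diversity statistics


def locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus GD, PIC, Ho, MAF over non-missing calls.

    Loci with zero called genotypes get NaN stats and flagged=True.
    """
    g = gm.g
    called = (g >= 0).sum(axis=0)
    alt = np.where(g >= 0, g, 0).sum(axis=0)
    het = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / (2.0 * called), np.nan)
    q = 1.0 - p
    gd = 1.0 - p**2 - q**2
    pic = gd - 2.0 * p**2 * q**2
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called > 0, het / called, np.nan)
    maf = np.minimum(p, q)
    out = gm.loci.copy()
    out["GD"] = gd
    out["PIC"] = pic
    out["Ho"] = ho
    out["MAF"] = maf
    out["n_called"] = called
    out["flagged"] = called == 0
    return out


def stats_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Across-locus mean/min/max of GD, PIC, Ho, MAF (flagged loci excluded)."""
    ok = stats[~stats["flagged"]]
    return ok[["GD", "PIC", "Ho", "MAF"]].agg(["mean", "min", "max"])


# ---------------------------------------------------------------------------
# PCA (covariance method)


def pca_covariance(gm: GenotypeMatrix) -> dict:
    """PCA of the sample covariance matrix of locus-mean-centered genotypes.

    Missing genotypes are imputed to the locus mean.  Returns scores
    (samples x components), eigenvalues (descending) and the proportion of
    variance each component explains.  Sign convention: each component's
    largest-magnitude loading is positive.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    g = gm.g.astype(float)
    mask = g < 0
    col_mean = np.where(
        (~mask).sum(axis=0) > 0,
        np.where(mask, 0, g).sum(axis=0) / np.maximum((~mask).sum(axis=0), 1),
        0.0,
    )
    x = np.where(mask, col_mean, g) - col_mean
    cov = x @ x.T / max(gm.n_loci - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for k in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] *= -1
    total = eigvals.sum()
    proportions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    scores = eigvecs * np.sqrt(eigvals)
    return {
        "scores": scores,
        "eigenvalues": eigvals,
        "proportions": proportions,
        "components": eigvecs,
    }


# ---------------------------------------------------------------------------
# Allele-sharing distance


def distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing distance: mean over co-called loci of |g_i - g_j| / 2.

    NaN where a pair shares no co-called locus.
    """
    g = gm.g.astype(float)
    miss = g < 0
    g = np.where(miss, np.nan, g)
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g - g[i]) / 2.0
        co = (~np.isnan(diff)).sum(axis=1)
        sums = np.nansum(diff, axis=1)
        d[i] = np.where(co > 0, sums / np.maximum(co, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Admixture EM


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # samples x K
    P: np.ndarray  # K x loci
    loglik: float
    loglik_trace: list[float]
    iterations: int
    seed: int
    converged: bool


def admixture_loglik(g: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial admixture log-likelihood; missing genotypes contribute nothing."""
    f = Q @ P  # samples x loci mixture alt frequency
    miss = g < 0
    gg = np.where(miss, 0, g).astype(float)
    ll = gg * np.log(f) + (2.0 - gg) * np.log1p(-f)
    ll[miss] = 0.0
    return float(ll.sum())


def admixture_em(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """EM for the K-cluster binomial admixture model.

    E-step computes per-allele-copy cluster responsibilities; M-step
    renormalizes Q rows and updates P as responsibility-weighted allele
    fractions.  Stops when |delta loglik| < tol or at ``max_iter``.  The
    log-likelihood trace is non-decreasing (an EM guarantee).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError(f"K={K} exceeds the number of samples ({gm.n_samples})")
    g = gm.g.astype(float)
    miss = gm.g < 0
    galt = np.where(miss, 0.0, g)  # alt allele copies
    gref = np.where(miss, 0.0, 2.0 - g)  # ref allele copies
    n, L = g.shape
    n_called = (~miss).sum(axis=1) * 2.0  # allele copies per individual

    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(
            (~miss).sum(axis=0) > 0,
            galt.sum(axis=0) / np.maximum((~miss).sum(axis=0) * 2.0, 1.0),
            0.5,
        )
    P = np.clip(freq[None, :] + rng.uniform(-0.1, 0.1, size=(K, L)), 1e-6, 1 - 1e-6)
    Q = rng.dirichlet(np.ones(K), size=n)
    Q = np.clip(Q, 1e-9, None)
    Q /= Q.sum(axis=1, keepdims=True)

    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step responsibilities (implicit): r_alt[i,l,k] ∝ Q[i,k] P[k,l]
        fa = Q @ P  # P(alt copy)  n x L
        fr = 1.0 - fa
        # log-likelihood at the *current* params, reusing fa
        ll = float((galt * np.log(fa) + gref * np.log(fr)).sum())
        trace.append(ll)
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
        # M-step sufficient statistics without materialising n x L x K:
        #   A[i,k] = sum_l galt[i,l] Q[i,k] P[k,l] / fa[i,l]
        #   B[i,k] = sum_l gref[i,l] Q[i,k] (1-P[k,l]) / fr[i,l]
        wa = galt / fa  # n x L
        wr = gref / fr
        A = Q * (wa @ P.T)  # n x K
        B = Q * (wr @ (1.0 - P).T)
        #   Calt[k,l] = sum_i galt[i,l] Q[i,k] P[k,l] / fa[i,l]
        Calt = P * (Q.T @ wa)  # K x L
        Cref = (1.0 - P) * (Q.T @ wr)
        Q = (A + B) / n_called[:, None]
        Q = np.clip(Q, 1e-9, None)
        Q /= Q.sum(axis=1, keepdims=True)
        denom = Calt + Cref
        P = np.where(denom > 0, Calt / np.maximum(denom, 1e-300), P)
        P = np.clip(P, 1e-6, 1 - 1e-6)
    else:
        # max_iter reached: record the likelihood of the final params
        trace.append(admixture_loglik(gm.g, Q, P))

    return AdmixtureFit(
        K=K, Q=Q, P=P, loglik=trace[-1], loglik_trace=trace,
        iterations=it, seed=seed, converged=converged,
    )


def align_cluster_labels(Q_hat: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute Q_hat's columns to best match Q_true (minimum mean |diff|)."""
    from itertools import permutations

    K = Q_hat.shape[1]
    best_perm = min(
        permutations(range(K)),
        key=lambda perm: np.abs(Q_hat[:, list(perm)] - Q_true).mean(),
    )
    return Q_hat[:, list(best_perm)]


# ---------------------------------------------------------------------------
# Evanno delta-K


@dataclass
class DeltaKReport:
    ks: list[int]
    mean_loglik: dict[int, float]
    sd_loglik: dict[int, float]
    delta_k: dict[int, float | None]
    selected_k: int | None
    reliable: bool


def evanno_delta_k(fits_by_k: dict[int, list[AdmixtureFit]], flat_tol: float = 1e-3) -> DeltaKReport:
    """Evanno's delta-K over replicate log-likelihoods.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined for interior K with sd > 0.  The selected K maximizes delta-K;
    selection is flagged unreliable when the mean log-likelihood is flat
    across K (relative spread below ``flat_tol``).
    """
    ks = sorted(fits_by_k)
    if len(ks) < 3 or any(len(fits_by_k[k]) < 3 for k in ks):
        raise ValueError("delta-K needs >=3 consecutive K values with >=3 replicates each")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    mean_l = {k: float(np.mean([f.loglik for f in fits_by_k[k]])) for k in ks}
    sd_l = {k: float(np.std([f.loglik for f in fits_by_k[k]], ddof=1)) for k in ks}
    delta: dict[int, float | None] = {}
    for k in ks[1:-1]:
        if sd_l[k] == 0.0:
            delta[k] = None
        else:
            delta[k] = abs(mean_l[k + 1] - 2.0 * mean_l[k] + mean_l[k - 1]) / sd_l[k]
    defined = {k: v for k, v in delta.items() if v is not None}
    selected = max(defined, key=lambda k: (defined[k], -k)) if defined else None
    spread = max(mean_l.values()) - min(mean_l.values())
    scale = max(abs(v) for v in mean_l.values()) or 1.0
    reliable = bool(defined) and spread / scale > flat_tol
    return DeltaKReport(
        ks=ks, mean_loglik=mean_l, sd_loglik=sd_l,
        delta_k=delta, selected_k=selected, reliable=reliable,
    )


def fit_k_range(
    gm: GenotypeMatrix,
    k_values: list[int],
    n_replicates: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> dict[int, list[AdmixtureFit]]:
    """Replicated admixture fits per K with deterministic derived seeds."""
    fits: dict[int, list[AdmixtureFit]] = {}
    for k in k_values:
        fits[k] = [
            admixture_em(gm, k, seed=(seed * 1000 + k * 100 + r) % (2**31 - 1),
                         max_iter=max_iter, tol=tol)
            for r in range(n_replicates)
        ]
    return fits
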