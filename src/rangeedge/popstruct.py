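"""Population-structure and diversity statistics on genotype matrices.

Implements the desk-scale structure toolkit for RADseq SNP matrices:
Weir & Cockerham (1984) FST with the weighted (ratio-of-sums) multi-locus
estimator, nucleotide diversity π, minimum cross-population pairwise
distance, KING-robust kinship with relationship-degree classification,
genotype PCA with per-site mean imputation, and DAPC (linear discriminant
analysis on retained principal components).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


# ======================================================================
# Weir & Cockerham FST
# ======================================================================

def weir_cockerham_components(G: GenotypeMatrix, pops=None):
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    ``a`` is the among-population, ``b`` the among-individual-within-
    population and ``c`` the within-individual component of allele-
    frequency variance; the per-site FST is a/(a+b+c) and the weighted
    multi-locus estimate is Σa / Σ(a+b+c). Missing genotypes are excluded
    per site; sites where fewer than two populations retain at least one
    genotyped individual yield NaN components.
    """
    if pops is None:
        pops = [p for p in dict.fromkeys(G.populations.tolist())]
    if len(pops) < 2:
        raise ValueError("need at least two populations for FST")
    geno = G.genotypes
    n_sites = G.n_sites
    r = len(pops)
    # per-pop per-site sample sizes (individuals), allele freqs, het freqs
    n_mat = np.zeros((r, n_sites))
    p_mat = np.zeros((r, n_sites))
    h_mat = np.zeros((r, n_sites))
    for pi, pop in enumerate(pops):
        rows = G.population_index(pop)
        sub = geno[rows]
        called = sub >= 0
        n_i = called.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(sub > 0, sub, 0).sum(axis=0) / (2.0 * n_i)
            h_i = (sub == 1).sum(axis=0) / n_i
        n_mat[pi] = n_i
        p_mat[pi] = p_i
        h_mat[pi] = h_i
    valid = (n_mat > 0).sum(axis=0) >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r_eff = (n_mat > 0).sum(axis=0).astype(float)
        nbar = n_mat.sum(axis=0) / r_eff
        nc = (n_mat.sum(axis=0) - (n_mat**2).sum(axis=0) / n_mat.sum(axis=0)) / (
            r_eff - 1.0
        )
        w = np.where(n_mat > 0, n_mat, 0.0)
        pbar = (w * np.nan_to_num(p_mat)).sum(axis=0) / n_mat.sum(axis=0)
        s2 = (w * (np.nan_to_num(p_mat) - pbar) ** 2).sum(axis=0) / (
            (r_eff - 1.0) * nbar
        )
        hbar = (w * np.nan_to_num(h_mat)).sum(axis=0) / n_mat.sum(axis=0)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - ((r_eff - 1.0) / r_eff) * s2 - hbar / 4.0)
            / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r_eff - 1.0) / r_eff) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def weir_cockerham_fst(G: GenotypeMatrix, pops=None) -> pd.DataFrame:
    """Pairwise weighted Weir–Cockerham FST matrix.

    For each population pair the multi-locus estimate is the ratio of
    sums Σa / Σ(a+b+c) over all sites with defined components; negative
    estimates are reported as computed. Returns a symmetric DataFrame
    with NaN diagonal; per-site components for the audit trail are
    available from :func:`weir_cockerham_components`.
    """
    if pops is None:
        pops = [p for p in dict.fromkeys(G.populations.tolist())]
    if len(pops) < 2:
        raise ValueError("need at least two populations for FST")
    if G.n_sites < 1:
        raise ValueError("need at least one site")
    out = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for pa, pb in combinations(pops, 2):
        idx = np.concatenate([G.population_index(pa), G.population_index(pb)])
        sub = G.subset_individuals(idx)
        a, b, c = weir_cockerham_components(sub, pops=[pa, pb])
        denom = a + b + c
        ok = np.isfinite(denom) & (np.abs(denom) > 0)
        if not ok.any():
            raise ValueError(f"no informative sites for pair ({pa}, {pb})")
        fst = float(np.nansum(a[ok]) / np.nansum(denom[ok]))
        out.loc[pa, pb] = fst
        out.loc[pb, pa] = fst
    return out


def global_weir_cockerham_fst(G: GenotypeMatrix, pops=None) -> float:
    """Single weighted FST across all populations."""
    a, b, c = weir_cockerham_components(G, pops=pops)
    denom = a + b + c
    ok = np.isfinite(denom) & (np.abs(denom) > 0)
    return float(np.nansum(a[ok]) / np.nansum(denom[ok]))


# ======================================================================
# Diversity and distances
# ======================================================================

def nucleotide_diversity(G: GenotypeMatrix, pop: str | None = None, L: float | None = None) -> float:
    """Nucleotide diversity π per assayed site.

    Per polymorphic site the unbiased heterozygosity is
    (n/(n−1))·2p(1−p) for n observed allele copies; the per-site values
    are summed and divided by the assayed sequence length ``L`` (default
    ``G.L``), so monomorphic assayed sites dilute the average exactly as
    in sequence-based π.
    """
    if pop is not None:
        G = G.subset_individuals(G.population_index(pop))
    L = float(L if L is not None else G.L)
    if L <= 0:
        raise ValueError("L must be positive")
    if L < G.n_sites:
        raise ValueError("L is smaller than the number of sites")
    geno = G.genotypes
    called = geno >= 0
    n = 2.0 * called.sum(axis=0)
    alt = np.where(geno > 0, geno, 0).sum(axis=0)
    ok = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n
        per_site = (n / (n - 1.0)) * 2.0 * p * (1.0 - p)
    return float(per_site[ok].sum() / L)


def min_pairwise_distance(
    G: GenotypeMatrix, popA: str, popB: str, L: float | None = None
) -> float:
    """Lowest cross-population individual pairwise distance.

    Per pair the distance is the summed absolute dosage difference / 2
    over shared non-missing sites, divided by ``L`` (default ``G.L``);
    pairs with no shared sites are skipped.
    """
    L = float(L if L is not None else G.L)
    ia = G.population_index(popA)
    ib = G.population_index(popB)
    geno = G.genotypes
    best = np.inf
    any_pair = False
    for i in ia:
        for j in ib:
            shared = (geno[i] >= 0) & (geno[j] >= 0)
            if not shared.any():
                continue
            any_pair = True
            d = np.abs(geno[i, shared].astype(float) - geno[j, shared]).sum() / 2.0 / L
            best = min(best, d)
    if not any_pair:
        raise ValueError(f"no pair between {popA} and {popB} shares a genotyped site")
    return float(best)


# ======================================================================
# KING-robust kinship
# ======================================================================

KINSHIP_DEGREE_THRESHOLDS = (
    ("duplicate", 0.354),
    ("1st", 0.177),
    ("2nd", 0.0884),
    ("3rd", 0.0442),
)


def classify_kinship(phi: float) -> str:
    """Degree class from the powers-of-two midpoint thresholds."""
    for label, thr in KINSHIP_DEGREE_THRESHOLDS:
        if phi >= thr:
            return label
    return "unrelated"


def king_kinship(G: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise KING-robust kinship coefficients with degree classes.

    For individuals i, j over their shared non-missing sites:
    φ = (N_het,het − 2·N_opp-hom) / (N_het(i) + N_het(j)), the
    allele-frequency-free estimator of Manichaikul et al. (2010); φ is
    0.5 for duplicates, ≈0.25 for parent–offspring, ≈0 for unrelated
    pairs. Degree classes use the standard midpoint thresholds.
    """
    if G.n_individuals < 2:
        raise ValueError("need at least two individuals")
    geno = G.genotypes
    rows = []
    for i, j in combinations(range(G.n_individuals), 2):
        gi, gj = geno[i], geno[j]
        shared = (gi >= 0) & (gj >= 0)
        if not shared.any():
            raise ValueError(
                f"pair ({G.samples[i]}, {G.samples[j]}) has zero informative sites"
            )
        a, b = gi[shared], gj[shared]
        n_het_het = int(np.sum((a == 1) & (b == 1)))
        n_opp = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
        n_het_i = int(np.sum(a == 1))
        n_het_j = int(np.sum(b == 1))
        denom = n_het_i + n_het_j
        if denom == 0:
            phi = np.nan
        else:
            phi = (n_het_het - 2.0 * n_opp) / denom
        rows.append(
            {
                "sample_a": G.samples[i],
                "sample_b": G.samples[j],
                "phi": phi,
                "degree": classify_kinship(phi) if np.isfinite(phi) else "undetermined",
                "n_shared_sites": int(shared.sum()),
            }
        )
    return pd.DataFrame(rows)


# ======================================================================
# PCA and DAPC
# ======================================================================

@dataclass
class PCAResult:
    scores: np.ndarray  # (n_individuals, n_components)
    loadings: np.ndarray  # (n_sites, n_components)
    explained_variance_fraction: np.ndarray


def _impute_center(G: GenotypeMatrix, scale: bool = False) -> np.ndarray:
    X = G.genotypes.astype(float)
    X[X < 0] = np.nan
    means = np.nanmean(X, axis=0)
    means = np.where(np.isfinite(means), means, 0.0)
    inds = np.where(np.isnan(X))
    X[inds] = means[inds[1]]
    X -= means
    if scale:
        p = means / 2.0
        sd = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        X /= sd
    return X


def pca_genotypes(
    G: GenotypeMatrix, n_components: int = 10, scale: bool = False
) -> PCAResult:
    """Genotype PCA with per-site mean imputation of missing dosages.

    Sites are centred (and optionally scaled by the binomial SD of the
    imputed allele frequency); the individual covariance matrix is
    eigendecomposed via SVD. Explained-variance fractions are relative
    to the total variance over all axes; each component's sign is fixed
    so its largest-magnitude site loading is positive.
    """
    X = _impute_center(G, scale=scale)
    poly = np.ptp(X, axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, S.size)
    total_var = float((S**2).sum())
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    for c in range(n_components):
        top = np.argmax(np.abs(loadings[:, c]))
        if loadings[top, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    frac = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(scores, loadings, frac)


@dataclass
class DAPCResult:
    scores: np.ndarray  # discriminant-axis coordinates per individual
    posteriors: pd.DataFrame  # row-stochastic assignment probabilities
    assignments: np.ndarray
    accuracy: float
    confusion: pd.DataFrame


def dapc(G: GenotypeMatrix, groups=None, n_pcs: int = 10) -> DAPCResult:
    """Discriminant analysis of principal components.

    Linear discriminant analysis on the first ``n_pcs`` genotype PC
    scores; reports per-individual posterior group membership, the
    maximum-posterior assignment, the confusion matrix against the given
    labels, and the overall correct-assignment rate.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(groups if groups is not None else G.populations, dtype=object)
    uniq, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        bad = uniq[counts < 2][0]
        raise ValueError(f"group {bad!r} has a single member; cannot estimate scatter")
    if n_pcs >= G.n_individuals - len(uniq):
        raise ValueError("n_pcs must be < n_individuals - n_groups")
    pca = pca_genotypes(G, n_components=n_pcs)
    lda = LinearDiscriminantAnalysis()
    lda.fit(pca.scores, labels)
    post = lda.predict_proba(pca.scores)
    pred = lda.predict(pca.scores)
    acc = float(np.mean(pred == labels))
    confusion = pd.crosstab(
        pd.Series(labels, name="true"), pd.Series(pred, name="assigned"), dropna=False
    ).reindex(index=uniq, columns=uniq, fill_value=0)
    posteriors = pd.DataFrame(post, columns=lda.classes_, index=G.samples)
    return DAPCResult(lda.transform(pca.scores), posteriors, pred, acc, confusion)
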