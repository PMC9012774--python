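"""Site-frequency-spectrum construction, folding, thinning and projection.

The SFS is the workhorse summary for single-population demographic
inference: entry ``k`` counts the SNPs whose alternate (or minor, if
folded) allele appears ``k`` times among the ``n`` sampled allele copies.
Monomorphic classes (0 and n) are excluded throughout.

RADseq matrices with missing calls are handled by hypergeometric
down-projection: each site is projected from its observed allele-copy
count down to a common target ``m``, which keeps (in expectation) every
segregating site genotyped in at least ``m`` copies instead of discarding
incomplete sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .genotypes import GenotypeMatrix


@dataclass
class SiteFrequencySpectrum:
    """SFS for ``n`` sampled allele copies.

    ``values`` has length ``n-1`` (classes 1..n−1) when unfolded and
    ``⌊n/2⌋`` (classes 1..⌊n/2⌋) when folded. ``kind`` distinguishes
    observed SNP counts (``"counts"``) from the expected density per unit
    θ produced by the demographic solver (``"density"``).
    """

    n: int
    values: np.ndarray
    folded: bool = False
    kind: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        expected = self.n // 2 if self.folded else self.n - 1
        if self.values.shape != (expected,):
            raise ValueError(
                f"SFS length {self.values.shape} does not match n={self.n}, folded={self.folded}"
            )
        if np.any(self.values < -1e-9):
            raise ValueError("SFS entries must be nonnegative")

    @property
    def classes(self) -> np.ndarray:
        """Allele-count class labels matching ``values``."""
        return np.arange(1, len(self.values) + 1)

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "SiteFrequencySpectrum":
        return SiteFrequencySpectrum(self.n, self.values.copy(), self.folded, self.kind)

    # ----------------------------------------------------------------- text IO
    def write(self, path) -> None:
        """Single header line ``n=<int> folded=<0|1>`` then the values."""
        with open(path, "w") as fh:
            fh.write(f"n={self.n} folded={int(self.folded)} kind={self.kind}\n")
            fh.write(" ".join(repr(float(v)) for v in self.values) + "\n")

    @classmethod
    def read(cls, path) -> "SiteFrequencySpectrum":
        with open(path) as fh:
            header = fh.readline().split()
            fields = dict(tok.split("=", 1) for tok in header)
            values = np.array([float(v) for v in fh.readline().split()])
        return cls(
            n=int(fields["n"]),
            values=values,
            folded=bool(int(fields["folded"])),
            kind=fields.get("kind", "counts"),
        )


def _site_allele_counts(G: GenotypeMatrix):
    """Per-site (alt copies, observed copies) ignoring missing calls."""
    geno = G.genotypes
    observed = 2 * (geno >= 0).sum(axis=0)
    alt = np.where(geno > 0, geno, 0).sum(axis=0)
    return alt.astype(int), observed.astype(int)


def sfs_from_genotypes(
    G: GenotypeMatrix,
    fold: bool = False,
    project_to: int | None = None,
) -> SiteFrequencySpectrum:
    """Tally the SFS of a biallelic genotype matrix.

    Without missing data every polymorphic site increments one integer
    class. With ``project_to=m`` each site is down-projected from its
    observed allele-copy count to ``m`` copies via the hypergeometric
    weights (sites observed in fewer than ``m`` copies are dropped, and
    mass landing on the monomorphic classes is discarded), which is the
    standard way to keep incomplete RADseq sites. Set ``fold=True`` for
    the minor-allele spectrum.
    """
    if G.n_sites == 0:
        raise ValueError("empty genotype matrix")
    alt, observed = _site_allele_counts(G)
    n_full = 2 * G.n_individuals
    if project_to is None:
        if np.any(observed < n_full):
            raise ValueError(
                "matrix has missing genotypes; pass project_to=m to project per site"
            )
        m = n_full
        sfs = np.zeros(m - 1)
        poly = (alt > 0) & (alt < m)
        np.add.at(sfs, alt[poly] - 1, 1.0)
    else:
        m = int(project_to)
        if m < 2 or m > n_full:
            raise ValueError("projection target must be in [2, 2*n_individuals]")
        sfs = np.zeros(m - 1)
        keep = observed >= m
        j = np.arange(m + 1)
        for k, n_obs in zip(alt[keep], observed[keep]):
            if k == 0 or k == n_obs:
                continue
            weights = hypergeom.pmf(j, n_obs, k, m)
            sfs += weights[1:m]
    out = SiteFrequencySpectrum(n=m, values=sfs, folded=False, kind="counts")
    return fold_sfs(out) if fold else out


def fold_sfs(S: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Fold an unfolded SFS onto minor-allele classes.

    Class ``j`` (j < n/2) receives ``unfolded[j] + unfolded[n−j]``; for
    even ``n`` the central class ``n/2`` is carried through unchanged.
    The total number of sites is conserved.
    """
    if S.folded:
        raise ValueError("SFS is already folded")
    n = S.n
    half = n // 2
    folded = np.zeros(half)
    for j in range(1, half + 1):
        if j < n - j:
            folded[j - 1] = S.values[j - 1] + S.values[n - j - 1]
        else:  # central class of an even-n spectrum
            folded[j - 1] = S.values[j - 1]
    return SiteFrequencySpectrum(n=n, values=folded, folded=True, kind=S.kind)


def project(S: SiteFrequencySpectrum, m: int) -> SiteFrequencySpectrum:
    """Hypergeometric down-projection of an unfolded SFS to ``m`` copies.

    Each class ``k`` of ``n`` contributes to class ``j`` of ``m`` with
    weight ``C(k,j)·C(n−k, m−j)/C(n,m)`` — the distribution of the allele
    count in a random subsample without replacement. Linear and
    expectation-preserving; mass projected onto the monomorphic classes
    (0 and m) is dropped, so the total can only shrink.
    """
    if S.folded:
        raise ValueError("project operates on unfolded spectra; fold afterwards")
    if not 2 <= m <= S.n:
        raise ValueError(f"projection target m={m} must satisfy 2 <= m <= n={S.n}")
    if m == S.n:
        return S.copy()
    n = S.n
    j = np.arange(m + 1)
    out = np.zeros(m - 1)
    for k in range(1, n):
        if S.values[k - 1] == 0:
            continue
        weights = hypergeom.pmf(j, n, k, m)
        out += S.values[k - 1] * weights[1:m]
    return SiteFrequencySpectrum(n=m, values=out, folded=False, kind=S.kind)


def thin_one_snp_per_locus(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Keep one uniformly chosen SNP per locus (linkage thinning).

    RAD loci are short enough that SNPs within a locus are tightly linked;
    sampling one SNP per locus restores the independence the Poisson
    random-field likelihood assumes. Only sites polymorphic among the
    non-missing calls count as SNPs; loci without any SNP contribute
    nothing. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    alt, observed = _site_allele_counts(G)
    is_snp = (alt > 0) & (alt < observed)
    chosen = []
    by_locus: dict = {}
    for s in range(G.n_sites):
        if is_snp[s]:
            by_locus.setdefault(G.site_loci[s], []).append(s)
    for locus in sorted(by_locus):
        sites = by_locus[locus]
        chosen.append(sites[rng.integers(len(sites))])
    chosen = np.array(sorted(chosen), dtype=int)
    return G.subset_sites(chosen)
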