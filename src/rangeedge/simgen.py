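"""Synthetic-data generators: coalescent SFS, multi-deme genotypes, relative
pairs, and allometric morphology tables.

All simulators work in the diffusion time convention used throughout the
package: time is measured backwards from the present in units of 2·Nref
generations, population sizes are ratios ν relative to the ancestral
reference size Nref, and the scaled mutation rate is θ = 4·Nref·μ (per
locus or per site as stated). Under this convention two lineages in a
population of ratio ν coalesce at rate 1/ν, and mutations fall on a branch
of length t at rate θ·t/2, so the expected pairwise difference count in a
constant-size population is exactly θ.

The single-population simulator (:func:`simulate_coalescent_sfs`) is exact
for piecewise constant/exponential size histories: coalescence waiting
times are drawn by closed-form inversion of the cumulative coalescent rate
through the epochs, with no discretisation. It serves as the independent
Monte-Carlo oracle for the deterministic expected-SFS solver in
:mod:`rangeedge.demography`.

The multi-deme simulator emulates a RADseq study design at a postglacial
range edge: ~78 diploids in 5 demes, ~1000 unlinked 51-bp loci, very low
per-site diversity (θ ≈ 1e−3), recent nested splits and no post-split gene
flow, plus uniformly random missing genotype calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .genotypes import MISSING, GenotypeMatrix


# ======================================================================
# Size histories
# ======================================================================

@dataclass(frozen=True)
class Epoch:
    """One epoch of a piecewise size history, ordered present → past.

    ``duration`` is in units of 2·Nref generations (``inf`` for the most
    ancient epoch). ``nu_start`` is the size ratio at the epoch's recent
    boundary and ``nu_end`` at its ancient boundary; equal values give a
    constant epoch, unequal values an exponential ramp between them.
    """

    duration: float
    nu_start: float
    nu_end: float

    @property
    def is_constant(self) -> bool:
        return self.nu_start == self.nu_end


@dataclass(frozen=True)
class SizeHistory:
    """Piecewise population-size history, epochs ordered present → past.

    The most ancient epoch must be constant (by convention at ratio 1, the
    reference size); all ratios are positive and durations nonnegative.
    """

    epochs: tuple
    Nref: float = 1.0

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("a size history needs at least one epoch")
        for ep in self.epochs:
            if ep.duration < 0:
                raise ValueError("epoch durations must be >= 0")
            if ep.nu_start <= 0 or ep.nu_end <= 0:
                raise ValueError("population size ratios must be > 0")
        last = self.epochs[-1]
        if not last.is_constant:
            raise ValueError("the most ancient epoch must have constant size")
        if not math.isinf(last.duration):
            object.__setattr__(
                self, "epochs", self.epochs[:-1] + (replace(last, duration=math.inf),)
            )

    # -- canonical single-population model constructors -------------------
    @classmethod
    def constant(cls, nu: float = 1.0) -> "SizeHistory":
        return cls((Epoch(math.inf, nu, nu),))

    @classmethod
    def two_epoch(cls, nu: float, T: float) -> "SizeHistory":
        """Instantaneous change to ratio ν at time T before present."""
        return cls((Epoch(T, nu, nu), Epoch(math.inf, 1.0, 1.0)))

    @classmethod
    def growth(cls, nu: float, T: float) -> "SizeHistory":
        """Exponential change from 1 to ν over the last T time units."""
        return cls((Epoch(T, nu, 1.0), Epoch(math.inf, 1.0, 1.0)))

    @classmethod
    def bottlegrowth(cls, nuB: float, nu: float, T: float) -> "SizeHistory":
        """Instantaneous change to νB at T, then exponential νB → ν to present."""
        return cls((Epoch(T, nu, nuB), Epoch(math.inf, 1.0, 1.0)))

    @classmethod
    def three_epoch(cls, nuB: float, nu: float, TB: float, TF: float) -> "SizeHistory":
        """Ancient size 1, then νB for duration TB, then ν for the last TF."""
        return cls(
            (Epoch(TF, nu, nu), Epoch(TB, nuB, nuB), Epoch(math.inf, 1.0, 1.0))
        )

    def nu_at(self, t: float) -> float:
        """Size ratio at backwards time t."""
        start = 0.0
        for ep in self.epochs:
            end = start + ep.duration
            if t <= end or math.isinf(end):
                if ep.is_constant:
                    return ep.nu_start
                lam = math.log(ep.nu_end / ep.nu_start) / ep.duration
                return ep.nu_start * math.exp(lam * (t - start))
            start = end
        return self.epochs[-1].nu_end

    def _arrays(self):
        """Flat arrays (t0, t1, nu0, lam) for the numba kernel."""
        t0, t1, nu0, lam = [], [], [], []
        start = 0.0
        for ep in self.epochs:
            end = start + ep.duration
            t0.append(start)
            t1.append(end)
            nu0.append(ep.nu_start)
            if ep.is_constant or ep.duration == 0:
                lam.append(0.0)
            else:
                lam.append(math.log(ep.nu_end / ep.nu_start) / ep.duration)
            start = end
        return (
            np.array(t0),
            np.array(t1),
            np.array(nu0),
            np.array(lam),
        )


# ======================================================================
# Single-population coalescent SFS simulator (Monte-Carlo oracle)
# ======================================================================

@njit(cache=False)
def _sim_sfs_kernel(t0, t1, nu0, lam, n, theta, n_reps, seed):  # pragma: no cover
    np.random.seed(seed)
    out = np.zeros((n_reps, n - 1), dtype=np.int64)
    counts = np.empty(n, dtype=np.int64)
    class_len = np.empty(n - 1, dtype=np.float64)
    for rep in range(n_reps):
        for i in range(n):
            counts[i] = 1
        for i in range(n - 1):
            class_len[i] = 0.0
        t = 0.0
        e = 0
        k = n
        while k > 1:
            E = np.random.exponential(1.0)
            C = 0.5 * k * (k - 1)
            tw = t  # walking time pointer through epochs
            ew = e
            while True:
                if lam[ew] == 0.0:
                    if t1[ew] == np.inf:
                        cap = np.inf
                    else:
                        cap = C * (t1[ew] - tw) / nu0[ew]
                else:
                    a = tw - t0[ew]
                    b = t1[ew] - t0[ew]
                    cap = (
                        C
                        / (lam[ew] * nu0[ew])
                        * (math.exp(-lam[ew] * a) - math.exp(-lam[ew] * b))
                    )
                if E <= cap:
                    if lam[ew] == 0.0:
                        tnew = tw + E * nu0[ew] / C
                    else:
                        a = tw - t0[ew]
                        val = math.exp(-lam[ew] * a) - E * lam[ew] * nu0[ew] / C
                        tnew = t0[ew] - math.log(val) / lam[ew]
                    break
                E -= cap
                tw = t1[ew]
                ew += 1
            dt = tnew - t
            for i in range(k):
                class_len[counts[i] - 1] += dt
            # merge a uniformly chosen pair
            i = np.random.randint(0, k)
            j = np.random.randint(0, k - 1)
            if j >= i:
                j += 1
            counts[i] += counts[j]
            counts[j] = counts[k - 1]
            t = tnew
            e = ew
            k -= 1
        for i in range(n - 1):
            if class_len[i] > 0.0:
                out[rep, i] = np.random.poisson(0.5 * theta * class_len[i])
    return out


def simulate_coalescent_sfs(
    history: SizeHistory,
    n_alleles: int,
    theta: float,
    n_reps: int,
    seed: int,
    per_rep: bool = False,
):
    """Simulate the unfolded SFS under a piecewise size history.

    Runs ``n_reps`` independent time-rescaled coalescent genealogies of
    ``n_alleles`` allele copies, places mutations on branches as a Poisson
    process at rate θ/2 per unit of branch length (time in 2·Nref
    generations), and tallies derived-allele counts.

    Returns the summed :class:`~rangeedge.sfs_ops.SiteFrequencySpectrum`
    over replicates, or with ``per_rep=True`` the raw
    ``(n_reps, n_alleles-1)`` integer matrix of per-replicate spectra
    (useful for Monte-Carlo standard errors). Bit-reproducible for a
    fixed seed.
    """
    from .sfs_ops import SiteFrequencySpectrum

    if n_alleles < 2:
        raise ValueError("need at least 2 allele copies")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    t0, t1, nu0, lam = history._arrays()
    mat = _sim_sfs_kernel(
        t0, t1, nu0, lam, int(n_alleles), float(theta), int(n_reps), int(seed) % (2**32)
    )
    if per_rep:
        return mat
    return SiteFrequencySpectrum(
        n=int(n_alleles),
        values=mat.sum(axis=0).astype(float),
        folded=False,
        kind="counts",
    )


@njit(cache=False)
def _sim_tmrca_tbl_kernel(t0, t1, nu0, lam, n, n_reps, seed):  # pragma: no cover
    """Per-replicate (T_MRCA, total branch length); shares the epoch walk."""
    np.random.seed(seed)
    out = np.zeros((n_reps, 2))
    for rep in range(n_reps):
        t = 0.0
        e = 0
        k = n
        tbl = 0.0
        while k > 1:
            E = np.random.exponential(1.0)
            C = 0.5 * k * (k - 1)
            tw = t
            ew = e
            while True:
                if lam[ew] == 0.0:
                    if t1[ew] == np.inf:
                        cap = np.inf
                    else:
                        cap = C * (t1[ew] - tw) / nu0[ew]
                else:
                    a = tw - t0[ew]
                    b = t1[ew] - t0[ew]
                    cap = (
                        C
                        / (lam[ew] * nu0[ew])
                        * (math.exp(-lam[ew] * a) - math.exp(-lam[ew] * b))
                    )
                if E <= cap:
                    if lam[ew] == 0.0:
                        tnew = tw + E * nu0[ew] / C
                    else:
                        a = tw - t0[ew]
                        val = math.exp(-lam[ew] * a) - E * lam[ew] * nu0[ew] / C
                        tnew = t0[ew] - math.log(val) / lam[ew]
                    break
                E -= cap
                tw = t1[ew]
                ew += 1
            tbl += k * (tnew - t)
            t = tnew
            e = ew
            k -= 1
        out[rep, 0] = t
        out[rep, 1] = tbl
    return out


def simulate_tree_heights(
    history: SizeHistory, n_alleles: int, n_reps: int, seed: int
) -> np.ndarray:
    """Per-replicate ``(T_MRCA, total branch length)`` pairs, coalescent units."""
    t0, t1, nu0, lam = history._arrays()
    return _sim_tmrca_tbl_kernel(
        t0, t1, nu0, lam, int(n_alleles), int(n_reps), int(seed) % (2**32)
    )


# ======================================================================
# Multi-deme split-model genotype simulator
# ======================================================================

@dataclass(frozen=True)
class SplitModelConfig:
    """Configuration for the multi-deme split genotype simulator.

    Defaults emulate the study design the package targets: 78 diploids in
    five demes, 1000 unlinked 51-bp RAD loci, per-site θ = 4·Nref·μ with
    μ = 7.7e−10 and Nref = 3.25e5 (θ ≈ 1e−3, i.e. the very low diversity
    of a recently founded range-edge population), nested splits between
    0.05 and 0.14 coalescent time units chosen so that pairwise
    Weir–Cockerham FST falls in the moderate range observed for such
    populations, and 25% missing genotype calls.

    ``merges`` lists backwards-time events ``(time, into, source)``: at
    ``time`` (units of 2·Nref generations) deme ``source`` merges into
    deme ``into``. Times must be positive and the referenced demes alive
    at that time; after the last merge a single ancestral deme of ratio
    ``ancestral_size`` remains.
    """

    deme_names: tuple = ("OLY", "PUGn", "KITs", "PUGs", "KITw")
    sample_sizes: tuple = (16, 16, 16, 15, 15)
    deme_sizes: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    merges: tuple = (
        (0.05, "PUGs", "KITw"),
        (0.07, "PUGn", "KITs"),
        (0.10, "PUGs", "OLY"),
        (0.14, "PUGs", "PUGn"),
    )
    ancestral_size: float = 1.0
    n_loci: int = 1000
    locus_length: int = 51
    mu: float = 7.7e-10
    Nref: float = 3.25e5
    missing_fraction: float = 0.25
    seed: int = 0

    @property
    def theta_site(self) -> float:
        return 4.0 * self.Nref * self.mu

    def validate(self) -> None:
        if len(self.sample_sizes) != len(self.deme_names):
            raise ValueError("one sample size per deme required")
        if len(self.deme_sizes) != len(self.deme_names):
            raise ValueError("one size ratio per deme required")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if any(v <= 0 for v in self.deme_sizes):
            raise ValueError("deme size ratios must be > 0")
        if not 0 <= self.missing_fraction <= 0.5:
            raise ValueError("missing_fraction must be in [0, 0.5]")
        alive = set(self.deme_names)
        last_t = 0.0
        for t, into, src in self.merges:
            if t <= 0:
                raise ValueError("split times must be positive")
            if t < last_t:
                raise ValueError("merge events must be ordered by time")
            if into not in alive or src not in alive:
                raise ValueError(
                    f"merge at t={t} references a deme that no longer exists"
                )
            alive.discard(src)
            last_t = t
        if len(alive) != 1:
            raise ValueError(
                f"merge schedule must reduce the tree to one ancestral deme, got {sorted(alive)}"
            )


def _simulate_locus_tree(rng, deme_of_leaf, nu, merges, n_leaves):
    """One genealogy under the structured coalescent without migration.

    Returns a list of (descendant boolean mask, branch lifetime) pairs,
    one per non-root lineage.
    """
    desc = [None] * n_leaves
    for i in range(n_leaves):
        m = np.zeros(n_leaves, dtype=bool)
        m[i] = True
        desc[i] = m
    deme = list(deme_of_leaf)
    born = [0.0] * n_leaves
    alive = list(range(n_leaves))
    segments = []  # (mask, lifetime)
    t = 0.0
    merge_idx = 0
    n_demes = len(nu)
    while len(alive) > 1:
        k_per = [0] * n_demes
        for lin in alive:
            k_per[deme[lin]] += 1
        rates = [k_per[d] * (k_per[d] - 1) / 2.0 / nu[d] for d in range(n_demes)]
        total = sum(rates)
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = math.inf
        if merge_idx < len(merges) and t + wait > merges[merge_idx][0]:
            t_merge, into, src = merges[merge_idx]
            for lin in alive:
                if deme[lin] == src:
                    deme[lin] = into
            t = t_merge
            merge_idx += 1
            continue
        t += wait
        # choose deme proportional to its coalescence rate
        u = rng.uniform(0.0, total)
        acc = 0.0
        d_sel = n_demes - 1
        for d in range(n_demes):
            acc += rates[d]
            if u <= acc:
                d_sel = d
                break
        members = [lin for lin in alive if deme[lin] == d_sel]
        i, j = rng.choice(len(members), size=2, replace=False)
        a, b = members[i], members[j]
        segments.append((desc[a], t - born[a]))
        segments.append((desc[b], t - born[b]))
        new = len(desc)
        desc.append(desc[a] | desc[b])
        deme.append(d_sel)
        born.append(t)
        alive.remove(a)
        alive.remove(b)
        alive.append(new)
    return segments


def simulate_split_genotypes(config: SplitModelConfig) -> GenotypeMatrix:
    """Simulate a multi-deme RADseq genotype matrix under a split model.

    Each locus gets an independent structured-coalescent genealogy
    (lineages coalesce only within their deme; demes merge backwards in
    time at the configured split times; no migration). Mutations fall on
    branches as a Poisson process with per-locus rate θ_site·locus_length,
    each creating one biallelic segregating site; allele copies are paired
    into diploid individuals and missing calls injected uniformly at
    random. Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    deme_index = {name: i for i, name in enumerate(config.deme_names)}
    n_demes = len(config.deme_names)
    merges = [
        (t, deme_index[into], deme_index[src]) for t, into, src in config.merges
    ]
    nu = list(config.deme_sizes)
    root = merges[-1][1] if merges else 0

    deme_of_leaf = []
    pops = []
    samples = []
    for name, n_dip in zip(config.deme_names, config.sample_sizes):
        d = deme_index[name]
        deme_of_leaf.extend([d] * (2 * n_dip))
        pops.extend([name] * n_dip)
        samples.extend(f"{name}_{i:02d}" for i in range(n_dip))
    n_leaves = len(deme_of_leaf)
    n_ind = n_leaves // 2

    # After the final merge the surviving deme represents the ancestral
    # population; model that by giving the root deme the ancestral ratio
    # for times past the last merge. Implemented by appending a pseudo
    # merge of root into a fresh ancestral deme.
    nu_full = nu + [config.ancestral_size]
    if merges:
        t_last = merges[-1][0]
        merges = merges + [(t_last, n_demes, root)]
    else:
        # single deme: lineage deme switch to ancestral at time 0 is a no-op
        nu_full[0] = config.deme_sizes[0]

    theta_locus = config.theta_site * config.locus_length

    dosage_cols = []
    loci_ids = []
    pos_ids = []
    for locus in range(config.n_loci):
        segments = _simulate_locus_tree(rng, deme_of_leaf, nu_full, merges, n_leaves)
        total_len = sum(seg[1] for seg in segments)
        n_mut = rng.poisson(0.5 * theta_locus * total_len)
        if n_mut == 0:
            continue
        n_mut = min(n_mut, config.locus_length)
        weights = np.array([seg[1] for seg in segments])
        weights /= weights.sum()
        which = rng.choice(len(segments), size=n_mut, p=weights)
        positions = 1 + rng.choice(config.locus_length, size=n_mut, replace=False)
        for m_i, seg_i in enumerate(which):
            carriers = segments[seg_i][0]
            dos = carriers[0::2].astype(np.int8) + carriers[1::2].astype(np.int8)
            dosage_cols.append(dos)
            loci_ids.append(f"locus{locus:05d}")
            pos_ids.append(int(positions[m_i]))

    if dosage_cols:
        geno = np.column_stack(dosage_cols).astype(np.int8)
    else:
        geno = np.zeros((n_ind, 0), dtype=np.int8)
    if config.missing_fraction > 0 and geno.size:
        mask = rng.random(geno.shape) < config.missing_fraction
        geno[mask] = MISSING
    return GenotypeMatrix(
        geno,
        samples,
        np.array(pops, dtype=object),
        np.array(loci_ids, dtype=object),
        np.array(pos_ids, dtype=int),
        locus_length=config.locus_length,
        n_loci_assayed=config.n_loci,
        metadata={"seed": config.seed, "theta_site": config.theta_site},
    )


def _invert_waiting(t, E, C, t0, t1, nu0, lam):
    """Closed-form inversion of the cumulative coalescent rate.

    From backwards time ``t`` with pair-rate ``C`` and unit-exponential
    draw ``E``, returns the coalescence time under the piecewise history
    described by the `SizeHistory._arrays` tuples.
    """
    e = int(np.searchsorted(t1, t, side="right"))
    tw = t
    while True:
        if lam[e] == 0.0:
            cap = math.inf if math.isinf(t1[e]) else C * (t1[e] - tw) / nu0[e]
        else:
            a = tw - t0[e]
            b = t1[e] - t0[e]
            cap = C / (lam[e] * nu0[e]) * (math.exp(-lam[e] * a) - math.exp(-lam[e] * b))
        if E <= cap:
            if lam[e] == 0.0:
                return tw + E * nu0[e] / C
            a = tw - t0[e]
            val = math.exp(-lam[e] * a) - E * lam[e] * nu0[e] / C
            return t0[e] - math.log(val) / lam[e]
        E -= cap
        tw = t1[e]
        e += 1


def simulate_history_genotypes(
    history: SizeHistory,
    n_diploids: int,
    n_loci: int,
    locus_length: int = 51,
    theta_site: float = 1e-3,
    missing_fraction: float = 0.0,
    seed: int = 0,
    pop_label: str = "pop1",
) -> GenotypeMatrix:
    """Single-population genotype matrix under a piecewise size history.

    Per-locus genealogies use the same exact epoch-walk inversion as the
    SFS simulator but track descendant leaf sets, so mutations become
    genotyped segregating sites suitable for the full thin → project →
    fit pipeline (including locus-bootstrap resampling). ``theta_site``
    is the per-site scaled mutation rate 4·Nref·μ.
    """
    if n_diploids < 1 or n_loci < 1:
        raise ValueError("need at least one individual and one locus")
    rng = np.random.default_rng(seed)
    t0, t1, nu0, lam = history._arrays()
    n_leaves = 2 * n_diploids
    theta_locus = theta_site * locus_length
    dosage_cols, loci_ids, pos_ids = [], [], []
    for locus in range(n_loci):
        desc = [None] * n_leaves
        for i in range(n_leaves):
            m = np.zeros(n_leaves, dtype=bool)
            m[i] = True
            desc[i] = m
        born = [0.0] * n_leaves
        alive = list(range(n_leaves))
        segments = []
        t = 0.0
        k = n_leaves
        while k > 1:
            E = rng.exponential(1.0)
            C = 0.5 * k * (k - 1)
            tnew = _invert_waiting(t, E, C, t0, t1, nu0, lam)
            i, j = rng.choice(k, size=2, replace=False)
            a, b = alive[i], alive[j]
            segments.append((desc[a], tnew - born[a]))
            segments.append((desc[b], tnew - born[b]))
            new = len(desc)
            desc.append(desc[a] | desc[b])
            born.append(tnew)
            alive.remove(a)
            alive.remove(b)
            alive.append(new)
            t = tnew
            k -= 1
        total_len = sum(seg[1] for seg in segments)
        n_mut = rng.poisson(0.5 * theta_locus * total_len)
        if n_mut == 0:
            continue
        n_mut = min(n_mut, locus_length)
        weights = np.array([seg[1] for seg in segments])
        weights /= weights.sum()
        which = rng.choice(len(segments), size=n_mut, p=weights)
        positions = 1 + rng.choice(locus_length, size=n_mut, replace=False)
        for m_i, seg_i in enumerate(which):
            carriers = segments[seg_i][0]
            dos = carriers[0::2].astype(np.int8) + carriers[1::2].astype(np.int8)
            dosage_cols.append(dos)
            loci_ids.append(f"locus{locus:05d}")
            pos_ids.append(int(positions[m_i]))
    if dosage_cols:
        geno = np.column_stack(dosage_cols).astype(np.int8)
    else:
        geno = np.zeros((n_diploids, 0), dtype=np.int8)
    if missing_fraction > 0 and geno.size:
        mask = rng.random(geno.shape) < missing_fraction
        geno[mask] = MISSING
    samples = [f"{pop_label}_{i:02d}" for i in range(n_diploids)]
    return GenotypeMatrix(
        geno,
        samples,
        np.array([pop_label] * n_diploids, dtype=object),
        np.array(loci_ids, dtype=object),
        np.array(pos_ids, dtype=int),
        locus_length=locus_length,
        n_loci_assayed=n_loci,
        metadata={"seed": seed, "theta_site": theta_site},
    )


# ======================================================================
# Relative pairs
# ======================================================================

def simulate_relative_pair(
    allele_freqs: np.ndarray,
    relationship: str,
    seed: int,
) -> GenotypeMatrix:
    """Two-individual genotype matrix with a known relationship.

    ``duplicate`` repeats one Hardy–Weinberg draw; ``parent-offspring``
    transmits one allele Mendelianly from a simulated parent and draws
    the other from the population frequency; ``unrelated`` draws both
    individuals independently from Hardy–Weinberg proportions.
    """
    p = np.asarray(allele_freqs, dtype=float)
    if p.size == 0:
        raise ValueError("allele frequency vector is empty")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    n_sites = p.size

    def hwe_draw():
        return (rng.random(n_sites) < p).astype(np.int8) + (
            rng.random(n_sites) < p
        ).astype(np.int8)

    if relationship == "duplicate":
        a = hwe_draw()
        b = a.copy()
    elif relationship == "parent-offspring":
        parent_allele1 = (rng.random(n_sites) < p).astype(np.int8)
        parent_allele2 = (rng.random(n_sites) < p).astype(np.int8)
        a = parent_allele1 + parent_allele2
        pick_first = rng.random(n_sites) < 0.5
        transmitted = np.where(pick_first, parent_allele1, parent_allele2)
        other = (rng.random(n_sites) < p).astype(np.int8)
        b = (transmitted + other).astype(np.int8)
    elif relationship == "unrelated":
        a = hwe_draw()
        b = hwe_draw()
    else:
        raise ValueError(f"unknown relationship {relationship!r}")
    geno = np.vstack([a, b]).astype(np.int8)
    loci = np.array([f"site{i:05d}" for i in range(n_sites)], dtype=object)
    return GenotypeMatrix(
        geno,
        ["ind_a", "ind_b"],
        np.array(["pair", "pair"], dtype=object),
        loci,
        np.ones(n_sites, dtype=int),
        locus_length=1,
        n_loci_assayed=n_sites,
    )


# ======================================================================
# Morphology
# ======================================================================

MORPHOMETRIC_TRAITS = ("TL", "HL", "HW", "RLL", "LLL", "RFL", "LFL")
MERISTIC_TRAITS = ("LFP", "RFP", "LTL", "RTL", "MS", "DS")

# baseline ln-scale intercepts / allometric slopes on ln SVL, and meristic
# count means, loosely matching adult Sceloporus proportions
_DEFAULT_INTERCEPTS = {
    "TL": 0.30, "HL": -1.45, "HW": -1.60,
    "RLL": -1.90, "LLL": -1.90, "RFL": -1.35, "LFL": -1.35,
}
_DEFAULT_MERISTIC_MEANS = {
    "LFP": 15.0, "RFP": 15.0, "LTL": 24.0, "RTL": 24.0, "MS": 46.0, "DS": 36.0,
}


def simulate_morphology(
    n_per_group,
    allometry_slope=1.0,
    group_effects=None,
    noise_sd=0.05,
    seed: int = 0,
    group_names=None,
    meristic_group_shift=0.0,
):
    """Simulate a morphometric/meristic table with allometric growth.

    Snout–vent length (SVL) is drawn log-normally per individual; each of
    the seven morphometric traits is generated as
    ``exp(intercept + slope·ln SVL + group_effect + N(0, noise_sd))`` so
    that regressing ln trait on ln SVL recovers the allometry exactly in
    the noise-free case. Meristic counts are Poisson with group-shifted
    means. ``group_effects`` may be a scalar spacing (groups get effects
    ``0, e, 2e, ...`` on every trait), a per-group vector, or a
    ``(n_groups, n_traits)`` matrix.

    Returns a :class:`pandas.DataFrame` with the package's standard
    morphology columns (SVL, the traits, sex, population).
    """
    import pandas as pd

    n_per_group = list(np.atleast_1d(n_per_group))
    n_groups = len(n_per_group)
    if n_groups < 1:
        raise ValueError("need at least one group")
    if np.any(np.asarray(noise_sd, dtype=float) < 0):
        raise ValueError("noise SD must be >= 0")
    if group_names is None:
        group_names = [f"grp{i+1}" for i in range(n_groups)]
    slopes = np.broadcast_to(
        np.asarray(allometry_slope, dtype=float), (len(MORPHOMETRIC_TRAITS),)
    )
    sds = np.broadcast_to(np.asarray(noise_sd, dtype=float), (len(MORPHOMETRIC_TRAITS),))
    if group_effects is None:
        eff = np.zeros((n_groups, len(MORPHOMETRIC_TRAITS)))
    else:
        ge = np.asarray(group_effects, dtype=float)
        if ge.ndim == 0:
            eff = np.outer(np.arange(n_groups), np.full(len(MORPHOMETRIC_TRAITS), ge))
        elif ge.ndim == 1:
            eff = np.repeat(ge[:, None], len(MORPHOMETRIC_TRAITS), axis=1)
        else:
            eff = ge
        if eff.shape != (n_groups, len(MORPHOMETRIC_TRAITS)):
            raise ValueError("group_effects shape mismatch")

    rng = np.random.default_rng(seed)
    rows = []
    for g, (name, n) in enumerate(zip(group_names, n_per_group)):
        ln_svl = rng.normal(math.log(65.0), 0.10, size=n)
        svl = np.exp(ln_svl)
        sex = rng.choice(["M", "F"], size=n)
        for i in range(n):
            row = {"SVL": svl[i]}
            for t_i, trait in enumerate(MORPHOMETRIC_TRAITS):
                noise = rng.normal(0.0, sds[t_i]) if sds[t_i] > 0 else 0.0
                row[trait] = math.exp(
                    _DEFAULT_INTERCEPTS[trait]
                    + slopes[t_i] * ln_svl[i]
                    + eff[g, t_i]
                    + noise
                )
            for trait in MERISTIC_TRAITS:
                mean = _DEFAULT_MERISTIC_MEANS[trait] + g * meristic_group_shift
                row[trait] = int(rng.poisson(mean))
            row["sex"] = sex[i]
            row["population"] = name
            rows.append(row)
    cols = ["SVL", *MORPHOMETRIC_TRAITS, *MERISTIC_TRAITS, "sex", "population"]
    return pd.DataFrame(rows, columns=cols)
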