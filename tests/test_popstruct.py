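"""Structure statistics against brute-force and dual-implementation oracles."""

from itertools import combinations

import numpy as np
import pytest

from rangeedge import (
    SplitModelConfig,
    dapc,
    king_kinship,
    min_pairwise_distance,
    nucleotide_diversity,
    pca_genotypes,
    simulate_relative_pair,
    simulate_split_genotypes,
    weir_cockerham_fst,
)
from rangeedge.popstruct import classify_kinship, global_weir_cockerham_fst
from tests.conftest import make_matrix


# ----------------------------------------------------------------------
# independent scalar transcription of the Weir & Cockerham (1984)
# variance components, looped site by site and population by population
# ----------------------------------------------------------------------
def wc84_oracle(geno_by_pop):
    """geno_by_pop: list of (n_i x S) arrays, -1 missing. Returns Σa/Σ(a+b+c)."""
    S = geno_by_pop[0].shape[1]
    num, den = 0.0, 0.0
    for s in range(S):
        ns, ps, hs = [], [], []
        for sub in geno_by_pop:
            col = sub[:, s]
            col = col[col >= 0]
            if len(col) == 0:
                continue
            ns.append(len(col))
            ps.append(col.sum() / (2.0 * len(col)))
            hs.append(np.mean(col == 1))
        r = len(ns)
        if r < 2 or min(ns) < 1:
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (sum(ns) - sum(n**2 for n in ns) / sum(ns)) / (r - 1)
        if nc == 0:
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


class TestWeirCockerhamFst:
    def test_reciprocally_fixed_populations(self):
        geno = np.vstack([np.zeros((4, 20)), np.full((4, 20), 2)])
        G = make_matrix(geno, pops=["A"] * 4 + ["B"] * 4)
        assert weir_cockerham_fst(G).loc["A", "B"] == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self, rng):
        block = rng.integers(0, 3, size=(6, 30))
        G = make_matrix(np.vstack([block, block]), pops=["A"] * 6 + ["B"] * 6)
        assert weir_cockerham_fst(G).loc["A", "B"] <= 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_independent_transcription(self, trial):
        rng = np.random.default_rng(1000 + trial)
        geno = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        miss = rng.random(geno.shape) < 0.1
        geno[miss] = -1
        pops = ["A"] * 7 + ["B"] * 6 + ["C"] * 7
        G = make_matrix(geno, pops=pops)
        mine = global_weir_cockerham_fst(G)
        oracle = wc84_oracle([geno[:7], geno[7:13], geno[13:]])
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_fst_increases_with_split_time(self):
        # monotone trend over a split-time ladder (Spearman rho)
        from scipy.stats import spearmanr

        times = [0.02, 0.05, 0.1, 0.2, 0.5]
        fsts = []
        for i, t in enumerate(times):
            cfg = SplitModelConfig(
                deme_names=("A", "B"),
                sample_sizes=(10, 10),
                deme_sizes=(1.0, 1.0),
                merges=((t, "A", "B"),),
                n_loci=400,
                missing_fraction=0.0,
                seed=77,
            )
            fsts.append(weir_cockerham_fst(simulate_split_genotypes(cfg)).loc["A", "B"])
        rho, _ = spearmanr(times, fsts)
        assert rho > 0.9

    def test_single_population_rejected(self, rng):
        G = make_matrix(rng.integers(0, 3, (5, 10)))
        with pytest.raises(ValueError):
            weir_cockerham_fst(G)


class TestNucleotideDiversity:
    def test_two_sequences_one_difference(self):
        # one heterozygote-free difference between two haploid-equivalent rows
        geno = np.array([[0], [2]])
        G = make_matrix(geno, locus_length=50, n_loci=2)  # L = 100
        # n=4 copies, p=0.5: pi_site = (4/3)*2*0.25 = 2/3... use direct pairwise:
        # mean pairwise difference over pairs of allele copies = 2*2/(4*3/2... )
        # assert against the brute-force oracle instead of a hand constant
        assert nucleotide_diversity(G) == pytest.approx(self.pairwise_oracle(geno, 100))

    @staticmethod
    def pairwise_oracle(geno, L):
        # expand each diploid into two allele copies per site, then take the
        # mean pairwise difference over all pairs of copies
        n_ind, S = geno.shape
        total = 0.0
        for s in range(S):
            col = geno[:, s]
            col = col[col >= 0]
            alleles = []
            for g in col:
                alleles.extend([1] * g + [0] * (2 - g))
            diffs = sum(a != b for a, b in combinations(alleles, 2))
            n_pairs = len(alleles) * (len(alleles) - 1) / 2
            if n_pairs:
                total += diffs / n_pairs
        return total / L

    def test_monomorphic_population_zero(self):
        G = make_matrix(np.full((5, 10), 2))
        assert nucleotide_diversity(G) == 0.0

    def test_matches_pairwise_oracle_random(self, rng):
        geno = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.15] = -1
        G = make_matrix(geno, locus_length=51)
        L = G.L
        assert nucleotide_diversity(G) == pytest.approx(
            self.pairwise_oracle(geno, L), rel=1e-12
        )

    def test_invariant_to_individual_order(self, rng):
        geno = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        G = make_matrix(geno)
        perm = rng.permutation(10)
        assert nucleotide_diversity(G) == pytest.approx(
            nucleotide_diversity(G.subset_individuals(perm))
        )

    def test_l_smaller_than_sites_rejected(self, rng):
        G = make_matrix(rng.integers(0, 3, (4, 30)))
        with pytest.raises(ValueError):
            nucleotide_diversity(G, L=10)


class TestMinPairwiseDistance:
    def test_identical_individuals_zero(self, rng):
        row = rng.integers(0, 3, 20)
        G = make_matrix(np.vstack([row, row]), pops=["A", "B"])
        assert min_pairwise_distance(G, "A", "B") == 0.0

    def test_opposite_homozygotes(self):
        geno = np.vstack([np.zeros((1, 10)), np.full((1, 10), 2)])
        G = make_matrix(geno, pops=["A", "B"], locus_length=10, n_loci=5)  # L=50
        assert min_pairwise_distance(G, "A", "B") == pytest.approx(10 / 50)

    def test_matches_exhaustive_enumeration(self, rng):
        geno = rng.integers(0, 3, size=(9, 25)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.1] = -1
        pops = ["A"] * 4 + ["B"] * 5
        G = make_matrix(geno, pops=pops)
        L = G.L
        best = np.inf
        for i in range(4):
            for j in range(4, 9):
                shared = (geno[i] >= 0) & (geno[j] >= 0)
                if shared.any():
                    d = np.abs(
                        geno[i, shared].astype(float) - geno[j, shared]
                    ).sum() / 2 / L
                    best = min(best, d)
        assert min_pairwise_distance(G, "A", "B") == pytest.approx(best)


class TestKingKinship:
    def test_duplicate_rows_phi_exactly_half(self, rng):
        row = rng.integers(0, 3, 500)
        row[0] = 1  # ensure at least one heterozygote
        G = make_matrix(np.vstack([row, row]))
        assert king_kinship(G)["phi"].iloc[0] == 0.5

    def test_parent_offspring_quarter(self, rng):
        p = rng.uniform(0.2, 0.8, 10_000)
        G = simulate_relative_pair(p, "parent-offspring", seed=6)
        phi = king_kinship(G)["phi"].iloc[0]
        assert phi == pytest.approx(0.25, abs=0.03)

    def test_unrelated_zero(self, rng):
        p = rng.uniform(0.2, 0.8, 10_000)
        G = simulate_relative_pair(p, "unrelated", seed=7)
        assert king_kinship(G)["phi"].iloc[0] == pytest.approx(0.0, abs=0.03)

    def test_symmetry_and_degree_classes(self, rng):
        geno = rng.integers(0, 3, size=(4, 300)).astype(np.int8)
        G = make_matrix(geno)
        kin = king_kinship(G)
        # phi computed on (i,j) equals phi on (j,i): rerun on reversed order
        kin_rev = king_kinship(G.subset_individuals(np.array([3, 2, 1, 0])))
        merged = {
            frozenset((r.sample_a, r.sample_b)): r.phi for r in kin.itertuples()
        }
        merged_rev = {
            frozenset((r.sample_a, r.sample_b)): r.phi for r in kin_rev.itertuples()
        }
        assert merged == merged_rev
        assert classify_kinship(0.4) == "duplicate"
        assert classify_kinship(0.25) == "1st"
        assert classify_kinship(0.125) == "2nd"
        assert classify_kinship(0.06) == "3rd"
        assert classify_kinship(0.01) == "unrelated"


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        geno = np.vstack([np.zeros((5, 40)), np.full((5, 40), 2)])
        G = make_matrix(geno)
        res = pca_genotypes(G, n_components=3)
        pc1 = res.scores[:, 0]
        assert np.ptp(pc1[:5]) == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(pc1[5:]) == pytest.approx(0.0, abs=1e-9)
        assert abs(pc1[:5].mean() - pc1[5:].mean()) > 1.0

    def test_variance_fractions_valid(self, rng):
        G = make_matrix(rng.integers(0, 3, (12, 60)))
        res = pca_genotypes(G, n_components=5)
        frac = res.explained_variance_fraction
        assert frac.sum() <= 1.0 + 1e-9
        assert (np.diff(frac) <= 1e-12).all()

    def test_matches_dense_eigendecomposition(self, rng):
        geno = rng.integers(0, 3, (10, 50)).astype(float)
        G = make_matrix(geno.astype(np.int8))
        res = pca_genotypes(G, n_components=4)
        X = geno - geno.mean(axis=0)
        C = X @ X.T
        w, V = np.linalg.eigh(C)
        w, V = w[::-1], V[:, ::-1]
        for c in range(4):
            ref = V[:, c] * np.sqrt(w[c])
            got = res.scores[:, c]
            err = min(np.abs(got - ref).max(), np.abs(got + ref).max())
            assert err < 1e-8

    def test_monomorphic_matrix_rejected(self):
        G = make_matrix(np.ones((4, 10)) * 2)
        with pytest.raises(ValueError):
            pca_genotypes(G)


class TestDapc:
    def test_perfectly_separated_demes(self):
        geno = np.vstack(
            [np.zeros((6, 40)), np.full((6, 40), 2), np.tile([0, 2], (6, 20))]
        )
        G = make_matrix(geno, pops=["A"] * 6 + ["B"] * 6 + ["C"] * 6)
        res = dapc(G, n_pcs=5)
        assert res.accuracy == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        geno = rng.integers(0, 3, (60, 80)).astype(np.int8)
        labels = np.array(["g%d" % (i % 5) for i in rng.permutation(60)], dtype=object)
        G = make_matrix(geno, pops=list(labels))
        res = dapc(G, n_pcs=5)
        # chance = 0.2; allow ~3 binomial SD (sqrt(.2*.8/60) ~ 0.05) + optimism
        assert res.accuracy < 0.2 + 0.25

    def test_posteriors_row_stochastic(self, rng):
        geno = rng.integers(0, 3, (20, 40)).astype(np.int8)
        G = make_matrix(geno, pops=["A"] * 10 + ["B"] * 10)
        res = dapc(G, n_pcs=4)
        assert np.allclose(res.posteriors.sum(axis=1), 1.0)

    def test_singleton_group_rejected(self, rng):
        geno = rng.integers(0, 3, (5, 20)).astype(np.int8)
        G = make_matrix(geno, pops=["A", "A", "A", "A", "B"])
        with pytest.raises(ValueError, match="B"):
            dapc(G, n_pcs=2)
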