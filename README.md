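# rangeedge

Desk-scale population genomics for small, recently founded populations at
a species' range edge — the kind of system sampled with ddRADseq: a few
dozen diploids from a handful of subpopulations, thousands of short
unlinked loci, very low nucleotide diversity, and a demographic history
dominated by postglacial colonisation and expansion.

The package has four pillars, each usable on its own:

1. **Demographic inference from the site frequency spectrum (SFS).**
   The expected SFS of a sample of *n* allele copies under a
   piecewise population-size history ν(t) is computed by integrating the
   closed moment system of the Wright–Fisher diffusion,

   dF/dt = D F / ν(t) + (n/2)·θ·e₁,  (DF)ᵢ = ½[(i−1)(n−i+1)F₍ᵢ₋₁₎ − 2i(n−i)Fᵢ + (i+1)(n−i−1)F₍ᵢ₊₁₎],

   whose constant-size equilibrium is the classical ξᵢ = θ/i. Each SFS
   class is treated as an independent Poisson count with mean θ·ξᵢ
   (the Poisson random-field composite likelihood), so
   θ̂ = Σ obsᵢ / Σ ξᵢ is profiled analytically. Four size-history models
   are fitted by multi-round randomised bounded optimisation —
   `two_epoch`, `growth`, `bottlegrowth`, `three_epoch` — and ranked by
   AIC = 2k − 2·logL with Akaike weights. Uncertainty comes from a
   parametric goodness-of-fit bootstrap and a non-parametric bootstrap
   over RAD loci; scaled estimates convert to demographic units via
   Nref = θ̂/(4 μ L) and years = T · 2 Nref · g.
2. **SFS construction.** One-SNP-per-locus thinning, hypergeometric
   down-projection (the standard treatment of missing RADseq calls),
   folding, and a plain-text SFS format.
3. **Population structure.** Weir–Cockerham (1984) FST (weighted
   ratio-of-sums estimator with per-site components for audit),
   nucleotide diversity π per assayed site, minimum cross-population
   pairwise distance, KING-robust kinship with relationship-degree
   classes, genotype PCA, and DAPC.
4. **Morphometrics.** ln-transformation, allometric size-correction by
   regressing each ln trait on ln snout–vent length, Mann–Whitney sex
   screen, PCA, and linear discriminant classification with a confusion
   matrix and leave-one-out accuracy.

A coalescent **synthetic-data generator** (exact time-rescaled
simulation under piecewise constant/exponential histories, a structured
multi-deme split model, Mendelian relative pairs, and allometric
morphology tables) gives every stage a download-free input — and serves
as the independent Monte-Carlo oracle for the deterministic SFS solver.

## Worked example

`python examples/demographic_inference.py` simulates a population that
expanded 25× at T = 0.1 (units of 2·Nref generations), thins to one SNP
per locus, fits all four models and prints:

```
simulated 1418 SNPs on 3491 loci; 1171 SNPs in the spectrum after thinning

       model  k  loglik    AIC  dAIC  rel_lik  wAIC  cum_wAIC
      growth  2 -161.74 327.48  0.00     1.00  0.44      0.44
   two_epoch  2 -161.95 327.90  0.42     0.81  0.35      0.79
bottlegrowth  3 -161.74 329.48  2.00     0.37  0.16      0.95
 three_epoch  4 -161.90 331.80  4.32     0.12  0.05      1.00

  growth     expansion    142.2x   T = 0.133 (138,189 years ...)   wAIC = 0.44
  two_epoch  expansion     25.3x   T = 0.106 (111,388 years ...)   wAIC = 0.35
```

Instantaneous and exponential expansions produce nearly identical
spectra, so the top two models share ~80% of the cumulative Akaike
weight — the honest statistical situation for this class of data. The
correctly specified `two_epoch` fit recovers the generating parameters
(25.3× vs 25, T = 0.106 vs 0.1).

The other examples cover structure statistics on the default synthetic
5-deme dataset (`population_structure.py`: pairwise FST ≈ 0.04–0.15,
π ≈ 1.1e−3/site, kinship screen, 100% DAPC assignment), SFS building and
projection, morphometric discrimination, and the solver-vs-coalescent
cross-check.

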