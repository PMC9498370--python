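# Methods

## Fight networks and trait definitions

Input records are aggregated reciprocal-fight durations for unordered pairs
of penmates. Aggregation sums all records for the same dyad, so the pen
graph has at most one edge per pair, weighted by total seconds of fighting.
Every roster member is a node: animals that never fought are isolated nodes
and legitimately score zero on all six traits (the zeros carry information —
they are the non-fighters).

Per animal we compute:

* **degree** — opponents / (n − 1), in [0, 1];
* **weighted degree (strength)** — summed incident edge weight, seconds;
* **betweenness** — Brandes betweenness with edge weights as *path costs*
  (a long joint fight means a "long" path), fractional credit over tied
  shortest paths, normalised by (n − 1)(n − 2)/2;
* **closeness** — (r − 1)/Σd within the node's component, scaled by
  (r − 1)/(n − 1) (the Wasserman–Faust correction), where r is the number of
  reachable nodes; 0 for isolates;
* **eigenvector centrality** — the leading eigenvector of the weighted
  adjacency matrix, rescaled so the maximum node scores 1; computed by power
  iteration with a positive diagonal shift (0.05 × max row sum). The shift
  changes no eigenvector but breaks the ±λ symmetry of bipartite components
  (stars, paths), on which unshifted iteration oscillates forever. Stopping
  tolerance 1e-12 on the iterate change, hard failure after 10,000 steps.
  On disconnected graphs mass concentrates on the spectrally dominant
  component; other components score ~0 (values below 1e-10 are snapped to
  zero). An edgeless pen scores 0 everywhere.
* **clustering coefficient** — unweighted local proportion of closed
  neighbour pairs by default; 0 when a node has fewer than two neighbours.
  The Barrat weighted variant (triangle credit (w_ij + w_ih)/2 relative to
  strength) is available via `clustering_mode="barrat"`.

Treating durations as costs (rather than inverting them to affinities) is a
modelling choice exposed as `weight_mode`; the default follows the common
default of graph libraries, under which betweenness/closeness read as
"bridging/being close in terms of accumulated fighting". All six scores are
square-root transformed (they are non-negative and strongly right-skewed);
the transformed values are the responses of the genetic analysis.

## Kinship

Inbreeding coefficients use the Meuwissen–Luo ancestor-walk recursion
(exactly equal to the tabular diagonal, which is also implemented and
cross-checked). The A-inverse is assembled directly by Henderson's rules
with inbreeding-adjusted Mendelian-sampling variances d_i (0.5 − 0.25(F_s +
F_d) with both parents known, 0.75 − 0.25 F_p with one, 1 for founders);
each animal contributes α_i · u u' with u = (1, −½, −½) over (animal, sire,
dam). Dense A by the tabular method exists for tests and small pedigrees;
the sampler only ever touches the sparse inverse.

## The Gibbs sampler

Location effects (fixed-effect columns, each animal's breeding value over
the *whole* pedigree, each pen effect) are drawn single-site from their
Gaussian full conditionals given current G0, C0, R0; the t × t (t ≤ 2)
linear algebra is hand-written inside a numba kernel so the per-animal inner
loop makes no LAPACK calls. Variance matrices are drawn from their
inverse-Wishart full conditionals, e.g. G0 | a ~ IW(S_g + a'A⁻¹a, ν_g + q)
with q the pedigree size. A full chain is one jitted call; all randomness
flows from one seed, so chains are bit-reproducible.

**Priors.** Fixed effects: flat. Covariances: flat by default
(ν = −(t + 1), S = 0), matching standard practice for pedigree Gibbs
samplers; the conditionals stay proper whenever effect counts exceed t + 1.
A proper weakly-informative alternative (ν = t + 1, S = 1e-6·I) is
available, but beware: its univariate marginal is InvGamma(1, 5e-7), which
puts most prior mass below 1e-6 and diverges like σ⁻² at the origin. That
spike acts as a quasi-absorbing state — once a weakly-identified component
(e.g. the pen variance, with only 50 pens) wanders near zero, the chain can
stay there for astronomically long times. We observed exactly this on
moderate-size problems, with the trapped component depending on the
trajectory; the flat prior has no such spike (the likelihood vanishes at
zero variance) and recovered truth wherever the proper-weak prior collapsed.

**Identification and mixing.** The sampler was validated three ways:
(i) with location effects frozen, variance draws match their analytic
inverse-Wishart conditionals (Kolmogorov–Smirnov); (ii) posterior means
agree with an independent dense-block Gibbs sampler (joint multivariate
draws of a, b, c via dense Cholesky) to ~0.01 on a 300-record problem;
(iii) on balanced half-sib designs the posterior mean h² matches the ANOVA
sire-variance estimator within Monte Carlo error.

**Missing data.** Bivariate records missing one trait are kept and the
missing component is drawn each sweep from its residual conditional (data
augmentation); records missing every requested trait are dropped at design
assembly. Fixed factors use corner (reference-level) constraints — variance
components are invariant to this parameterisation — and covariates are
centred.

**Chain lengths.** Production preset: 1,000,000 iterations, 100,000
burn-in, thinning 20 (45,000 saved draws). The development/test preset is
20,000 / 2,000 / 10 (1,800 saved draws); at the emulated study scale this
gives effective sample sizes of a few hundred for h² and runs in ~15 s per
univariate model, which is what the test suite and the acceptance script
use throughout.

## Posterior summaries

h², c², Vp, and rg are computed *per draw* and then summarised, so the
posterior uncertainty of ratios is exact rather than a delta-method
approximation. HPD95% intervals use the shortest-sorted-window method
(exact for unimodal empirical posteriors; leftmost window on ties); a
correlation is flagged significant when its HPD95% excludes zero (boundary
= inclusion). Convergence is screened with a Geweke-type z (mean of first
10% vs last 50%, Bartlett-windowed long-run variances) plus bulk effective
sample size via arviz. Phenotypic correlations are pairwise-complete
Spearman rank correlations with average ranks for ties; rank correlations
are unchanged by the square-root transform, which the tests assert.

## Synthetic-study generator

The generator reproduces the design features that matter for identification:

* **Pedigree** — three generations: a founder pool, 116 sires + 391 dams
  (each with two founder parents drawn at random), and 900 focal offspring
  assigned to dams nearly evenly (litters ≈ 2.3) with one sire per dam. The
  founder pool is sized so the pedigree totals 4,104; founders without
  descendants stand in for the collateral ancestors a real herd-book drags
  in. Labels are F*/S*/D*/P*.
* **Housing** — 50 single-sex pens of 18 (25 female, 25 castrate pens),
  batches as contiguous pen groups (sexes interleaved so every batch has
  both), line following the sire (9 lines round-robin), mixing weight
  ~ N(30, 4²) kg truncated positive.
* **Fights** — an explicit generative stand-in (real studies observe fights,
  they do not model them): latent aggressiveness u_i = a_i + ε_i with
  additive-genetic and environmental variances 1 + 1 (latent heritability
  0.5); each dyad fights with probability logistic(α + λ(u_i + u_j)) and a
  realised fight lasts LogNormal(μ + κ(u_i + u_j), σ) seconds, floored at
  1 s. Defaults α = −3.7, λ = 0.5, μ = 1.8, κ = 0.35, σ = 1.5 were fixed
  once to reproduce the descriptive character of observed post-mixing
  networks (transformed weighted degree mean ≈ 2.6, SD ≈ 4.4; ~55%
  non-fighters; strongly right-skewed durations). The trait-level
  heritability this induces is *emergent* (~0.05–0.3 for weighted degree),
  not a dial.
* **Phenotypes** — y = Xb + Za + Wc + e assembled exactly, univariate per
  trait or jointly with full G0/C0/R0 for correlated-trait scenarios;
  breeding values by gene-dropping (founders ~ N(0, G0), offspring = parent
  mean + Mendelian deviation with inbreeding-adjusted variance). Fixed
  effects are drawn once per trait at SD 0.25 × phenotypic SD. Performance
  traits default to realistic means/SDs (g/d, kg, mm scales) with h² 0.30 to
  0.45, c² 0.05; feed efficiency is derived as TDG/DFI on a g/d-per-g/d
  basis, not simulated independently.

What the generator does **not** emulate: dominance hierarchies and
winner/loser dynamics, temporal bout structure, attacker/receiver asymmetry,
litter environmental effects (litters enter only through dam structure),
and genotype-by-pen interaction. Passing tests therefore show the estimation
machinery is correct under the stated generative model, not that real fight
networks satisfy that model.

## Numerical and design notes

* Validation is fail-loud: every malformed input row raises an error naming
  the file, row and offence; nothing is silently dropped.
* Pedigrees are topologically sorted with a deterministic stable sort (ties
  by file order), so matrix indices — and therefore chains — are
  reproducible across runs.
* The sampler raises (with the iteration index) on non-positive-definite
  conditional scale matrices or non-finite draws rather than continuing.
* Per-model seeds in batch runs are derived from one master seed via a
  dedicated RNG stream, so adding models does not perturb existing chains.
* HPD intervals require ≥ 100 draws; Geweke ≥ 1,000. Spearman entries with
  fewer than 3 complete pairs or a constant column are reported missing.
* The full 6-trait pipeline (6 univariate + 15 + 48 bivariate chains) at the
  test preset completes in roughly 10–15 minutes on one CPU; tests use
  2-trait subsets and the batch-seed machinery to keep runtimes in seconds.

## Known limitations

* Single-site location sampling mixes slowly for strongly confounded
  effects; at the emulated design the h² posterior is intrinsically broad
  (posterior SD ≈ 0.08–0.15), and posterior means scatter around truth with
  SD ≈ 0.10 across replicates — a property of the design, not the sampler.
* Only one or two traits per model (the analysis is a series of univariate
  and bivariate fits, not one multi-trait model).
* No maternal, litter or genetic-group effects; unknown parents are
  unrelated phantom founders.
* Bivariate posteriors under the flat prior are proper only when the data
  identify both genetic variances; a collapsed (rg → ±1) chain on
  weakly-informative data is detectable via the reported HPD widths.
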