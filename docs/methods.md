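# Methods

## Problem and model

A forensic mtDNA mixture is a haploid analogue of an unphased genotype:
each of K contributors donates one complete mitotype, in unknown
proportions, and massively parallel sequencing reports per-site counts of
reference and alternative alleles.  `mitophase` recovers the contributor
proportions and full haplotypes by continuous statistical phasing — the
multi-strain deconvolution strategy developed for *Plasmodium falciparum*
infections — specialized to the non-recombining mitochondrial genome.

The model has three parts.

**Read counts.**  At site *j* with depth *n_j*, the alternative count is
binomial,

    a_j ~ Binomial(n_j, pi_j),   pi_j = q_j (1 - e) + (1 - q_j) e,

where `q_j = Σ_k w_k h_kj` is the proportion-weighted (within-sample)
alternative-allele fraction and *e* is a symmetric per-read error rate.
Zero-depth sites are carried but contribute nothing to the likelihood.  A
beta-binomial alternative (parameter `overdispersion`, the concentration
of the mixing Beta) is exposed for over-dispersed count data; it is off by
default because the simulator produces exactly binomial-consistent counts.

**Proportions.**  `w = softmax(t)` with Gaussian titres
`t_k ~ Normal(0, sigma_t^2)`, giving an unconstrained random walk on the
simplex.  Titres are updated jointly by Metropolis–Hastings with an
isotropic Normal(0, delta^2) proposal.

**Haplotypes.**  Each contributor's haplotype is an imperfect copy of a
single reference-panel member, the Li–Stephens mosaic with recombination
rate fixed at 0 (mtDNA does not recombine): the donor `z_k` is uniform
over the panel and each site matches the donor's allele with probability
`1 - mu` (mis-copying rate `mu`), letting estimated mitotypes deviate from
every panel sequence.

## Sampling scheme

Because each strain copies exactly one donor, the conditional
`p(z_k, h_k | rest)` factorizes over sites and can be sampled exactly:
donor weights integrate the two possible alleles at every site
(emission-weighted binomial site likelihoods, accumulated in log space),
the donor is drawn from those weights, and alleles are then drawn
independently per site.

Single-strain updates alone are not ergodic in practice.  At near-equal
proportions the two strains' likelihood roles are symmetric, and moving a
heterozygous site's alternative allele from one strain to the other
requires both alleles to change in the same sweep; the He-site partition
freezes in whatever configuration the chain first finds (observed: a 4:1
mixture pinned at w ≈ 0.5 with a log likelihood ~150 units below the
optimum).  The sweep therefore uses an exact joint pair update: for a
strain pair, donor-*pair* weights integrate all four allele combinations
at every site (one N_p×N_p log-weight matrix assembled from a single
matrix product plus rank-one terms), the donor pair is drawn, and allele
pairs are drawn per site.  For K = 2 this redraws the entire haplotype
configuration from its exact conditional every sweep; for odd K the
leftover strain gets the single-strain update.

A sweep is one MH titre update followed by one haplotype pass over a
random strain ordering.  In one sweep in ten (in expectation) an
*independence* titre update is interleaved, proposing fresh titres from
their prior; its acceptance ratio reduces to the likelihood ratio, so it
is nearly always rejected when the proportions are identified but mixes
freely in the label-degenerate regime of extreme ratios (both strains
carrying the same haplotype leaves the likelihood flat in `w`, and a
random walk alone can take arbitrarily long to traverse back to the
identified mode).  Chains start at uniform proportions with random
panel rows as haplotypes.  All randomness flows from one
`numpy.random.Generator` seed; identical seeds give bit-identical runs.

## Summaries and label alignment

After discarding burn-in (default: first half), strains are relabelled per
sample by decreasing proportion.  When the top two proportions are within
0.05 — label-switching territory, e.g. 1:1 mixtures — the sampled pair is
aligned to the running modal haplotypes by minimal Hamming matching before
accumulation.  Per-site alternative-allele posteriors are thresholded at
0.5 to give modal haplotypes.

Reported proportions are the per-slot posterior **median** of the aligned
samples, renormalized (the per-sweep samples remain available in
`proportion_trace`).  The median rather than the mean is deliberate: in
highly imbalanced mixtures (50:1) the chain occasionally visits a
label-degenerate mode in which the minor haplotype collapses onto the
major, the likelihood becomes flat in `w`, and the minor proportion
wanders over its prior.  These excursions inflate a posterior mean
non-monotonically across ratios, while the median stays on the identified
mode and keeps the expected-versus-observed relation affine (the read
error *e* shrinks all estimates by the affine map `(pi - e)/(1 - 2e)`,
which regression absorbs).

## Convergence diagnostic

The `diagnostics` statistic compares the mean log posterior of the first
10% of the retained trace against the last 50%, standardized by the
trace's marginal standard deviation, flagging |z| > 2.  The
standardization is by the marginal spread rather than a standard error of
the means because the titre random walk gives the log posterior
long-memory fluctuations: an iid (or short-lag spectral) standard error
flagged 30–40% of demonstrably stationary 3000-sweep chains in
calibration runs.  As implemented, the flag reads "the early level sits
more than two trace-widths from the late level" — the quantitative form
of a trace plot failing the fuzzy-caterpillar inspection.  A constant
trace scores 0; linear drifts and burn-in steps score |z| ≈ 2.4–2.8 and
are flagged; stationary chains were flagged in 0 of 20 calibration runs.

## Reference panels

The production builder filters a haplotype database by *graph edit
distance* to the mixture: the number of allele changes a candidate needs
to be compatible with the observed genotypes, where heterozygous sites
accept either allele and zero-depth sites are free.  Candidates within
distance *d* are kept, capped at the `max_panel` nearest (default 25),
ties broken by sample ID; if the filter empties, the single nearest
haplotype is returned with a warning, since the engine requires a
non-empty panel.  Four experimental designs probe panel-composition
effects: both contributors included; hold-two-out; a one-SNP "derived"
contributor in the mixture with its ancestor in the panel; and the
converse, a one-SNP-mutated copy in the panel.

## Minor interpolation and error taxonomy

In a two-person mixture, a trusted major haplotype determines the minor:
complement at heterozygous sites, copy the single observed allele at
homozygous sites, no call at zero-depth sites (missing sites yield no
default allele — partial mitotypes are acceptable output).  If the major
carries an allele with zero supporting reads the premise fails and an
error is raised; the automated pipeline catches it and keeps the raw
minor call.  Phasing errors are classified as He→Ho coercion, Ho→He
coercion, or point switches (both strains wrong in complementary fashion
at a heterozygous site).

## Synthetic databases

The generator emulates a population mitogenome database with haplogroup
structure as a star phylogeny: each of 8 haplogroups receives
Poisson(lambda_branch = 17) defining substitutions at fresh rCRS
positions, and each of 4 samples per group adds Poisson(lambda_private
= 4) private substitutions; alternative bases are uniform over the three
non-reference bases.  These defaults put the mean pairwise Hamming
distance near `2*lambda_p + 0.9 * 2*lambda_b ≈ 38.7` with pairs spanning
roughly 4–59 — the distance regime of real population panels (closest
pairs a few SNPs apart, divergent haplogroups in the 50s).  Since no
reference genome ships with the package, the reference base at each
position is a deterministic synthetic assignment (`reference_base`); a
real rCRS FASTA can be supplied instead.  What the simulator does *not*
model — sequencing noise, strand bias, point heteroplasmies, allele
drop-out, NUMT contamination, recurrent mutation within a lineage, nested
subclade structure — bounds what passing tests show: they validate the
inference machinery on exact genotypes, not robustness to instrument
artefacts, which the error taxonomy and missing-site handling merely
surface rather than repair.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 2 | number of contributors (1–5) |
| `n_steps` | 3000 | MCMC sweeps (800-step runs were not reliably stationary; 3000 is the study setting) |
| `burn_in_fraction` | 0.5 | discarded prefix of the chain |
| `read_error` | 0.01 | per-read miscall probability, folded symmetrically into pi |
| `miscopy_rate` | 0.01 | copying-emission mismatch probability |
| `recombination_rate` | 0.0 | fixed; non-zero values are rejected |
| `titre_sd` | 3.0 | prior scale of the Gaussian titres |
| `proposal_sd` | 0.1 | MH random-walk scale on titres |
| `proportion_floor` | 0.01 | detection threshold for `effective_contributors` |
| depth | 100 | per-site total reads; mixture ratios are normalized into exact counts (grid also runs 50 and 75) |

Numerical guards: allele fractions are clipped away from {0, 1} before
logs, each log-pmf term is floored at −745 so `read_error = 0` cannot
produce −inf, and all products over sites are log-space sums.

## Problem sizes used in the shipped studies

The idealized-panel study deconvolves all 45 source pairs of a
32-haplotype database (10 sources, 22 background) at one ratio with the
full database as panel; the tuned study runs 20 seeded pairs per ratio
for the five imbalanced ratios against edit-distance-4 panels capped at
25.  Both use depth 100 and 3000 sweeps, the study's reference
configuration.  The full 7290-run grid (45 pairs × 6 ratios × 3 depths ×
3 step counts × 3 edit distances) is exposed through `run_grid` /
`mitophase grid` and is a pure function of its master seed; the shipped
tests exercise a reduced grid and single cells.

## Known limitations

* Point heteroplasmy is not modelled; a PHP site will be forced toward
  one allele per contributor.
* Multi-allelic positions and indels are filtered out before inference,
  discarding potentially diagnostic variation.
* Interpolation is defined for two-person mixtures only.
* With `max_panel` = 25, subequal (1:1) mixtures remain the hard case:
  quantitative signal vanishes and accuracy depends entirely on the panel
  containing near-exact matches.
* The proportion estimates inherit a small deterministic shrinkage from
  the read-error fold-in; comparisons across ratios are affine-faithful
  but absolute minor proportions at extreme ratios are biased toward
  `(expected - e)/(1 - 2e)`.
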