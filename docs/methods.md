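# Methods

This note documents the models behind `norinherit`, the choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Genome and pedigree model

Chromosomes are linear intervals with a physical length (bp), a genetic
length (cM) and a fixed 100-kb window grid (last window truncated; all
coordinates 0-based, half-open).  The preset `GenomeModel.arabidopsis()`
uses TAIR10-scale physical lengths (30.4 / 19.7 / 23.5 / 18.6 / 26.9 Mb)
and consensus-scale genetic lengths (120 / 90 / 100 / 105 / 120 cM); a
`compact()` preset with ~20 windows per chromosome keeps repeated
whole-pipeline studies cheap while preserving the topology (NOR2 and NOR4
at the tops of chromosomes 2 and 4, depth baseline on chromosome 3).

Meiosis places crossovers under a no-interference model: the crossover
count is Poisson with mean L/100 per chromosome of genetic length L cM,
positions uniform on the genetic map, consistent with the Haldane map
function used everywhere downstream.  Each NOR is a single locus pinned to
window 0 of its chromosome.  Its copy count always travels with the
top-window allele of the transmitted haplotype — homologous NORs do not
exchange material, matching the observed absence of inter-homolog NOR
recombination in this species.  Intra-array structure (repeat variants,
partial-unit exchange) is not modelled.

Copy-number instability is summarised as a per-meiosis jump process: with
probability `mu` per NOR the transmitted count is perturbed by a rounded
draw from N(0, `jump_scale`²), floored at zero.  No rate for this process
is established empirically; the defaults `mu = 0.02`, `jump_scale = 100`
were chosen once so that excursions of one hundred to a few hundred copies
become visible within ten to thirty generations of single-seed descent —
the magnitude observed in inbred-line panels — and are not tuned further.
Under `mu = 0` copy number is conserved exactly through any pedigree, which
the test-suite uses as an invariant.

Designs: F2 = two inbred founders → F1 → n selfed offspring; RIL = each F2
advanced by single-seed descent to `n_generations` total selfing
generations (residual heterozygosity 0.5^g); MA = independent single-seed
lineages from one founder with every generation retained.  The MA stability
design additionally splits each line into sibling replicate plants one
generation before the first measured one, so the replicate random effect in
the mixed model has a biological interpretation (each sibling passes
through its own meiosis).

## Measurement layers

**Coverage.**  Per-base depth is negative binomial with variance
m + d·m² (dispersion `d`; `d = 0` returns exact expectations).  Because
regional sums of i.i.d. negative binomials are themselves negative
binomial, regional means are drawn in aggregate — one draw for the 1808-bp
18S interval, one for the 10-Mb baseline — which makes population-scale
simulation essentially free.  The 18S mean has expectation
depth × C_diploid/2, so the depth ratio estimates copies per haploid genome
directly; at depth 20 and d = 0.1 the ratio's relative bias over 200
replicates is below 0.1% (the Jensen bias from the noisy denominator is
negligible because the baseline averages 10⁷ bases).

**Window SNP calls.**  Segregating-site counts are Poisson per window
(default mean 300) and shared across samples, since parental divergence is
a property of the cross; a configurable fraction of windows is
low-diversity (<100 sites) to exercise the discard rule.  Each site is
called with probability `call_rate` (default 0.5, low-coverage scale); a
called site reports the class of the true window diplotype and flips to one
of the two wrong classes, equiprobably, with probability `error_rate`
(default 0.01).  Real GBS artefacts not emulated: read-depth-dependent
allelic dropout at heterozygous windows, reference bias, and correlated
errors along reads — so passing tests demonstrate correctness of the rule
logic and estimator calibration, not robustness to those artefacts.

**qPCR.**  True cycles satisfy 2^(Ct_ACT2 − Ct_18S) = copies per haploid.
Observed cycles add a per-plate offset shared by both targets (which
cancels in the delta), an optional target-specific plate offset (which does
not cancel and is what standardization corrects), and Gaussian replicate
noise (default sd 0.04 cycles, the scale of reported technical-replicate
errors).  The common control sample is placed on every plate.

## Copy-number estimation

The 18S mean uses the annotated subunit interval 2195–4002 of the 45S
repeat unit with a fixed denominator (zero-depth bases included); when
depth tables come from real alignments they should be computed before
duplicate removal, since duplicate removal is known to weaken the
depth/qPCR correlation for rDNA.  Plate standardization offers two modes:
*control* divides each plate by its control reading relative to the grand
mean of the control, making the control identical across plates; and
*regression*, which fits per-plate multiplicative factors by least squares
on the log scale using samples measured on more than one plate as links.
The log-additive (multiplicative) form was chosen because plate effects in
2^ΔCt space are multiplicative by construction; factors are only
identifiable up to one global scale, fixed by normalising to geometric mean
one, and the plate-sharing graph must be connected.

FISH signal-area ratios are truncated (rounded toward zero) to two
decimals: of the two printed reference ratios, 1.4964 → 1.49 is reproduced
only by truncation, and 2.3920 → 2.39 is consistent with it.

## Window genotyping and the genetic map

The caller applies the published thresholds with *strict* inequalities
exactly as printed (>90%, <100, <40, >25%, <30%), evaluates every fraction
against the called-site count (heterozygous calls included in the
denominator), and checks rules in the listed order: discard, A, B, H, else
NA.  Precedence is a choice — the source lists the rules without an
explicit order — and the homozygote rule is checked first because it is the
stricter claim.  Comparisons are computed in exact rational arithmetic so
boundary cases never depend on floating-point rounding; an exhaustive
brute-force oracle over ~1.7×10⁵ count vectors straddling every boundary
confirms equivalence.

Adjacent-window recombination fractions are estimated by maximum
likelihood: F2 pairs use the full two-meiosis 3×3 joint genotype likelihood
maximised on a dense r grid; RIL pairs use the observed discordance
fraction mapped back through the selfing relation R = 2r/(1+2r) with H
treated as missing (residual heterozygosity is rare).  Distances follow
d = −50·ln(1−2r); r is capped at 0.49 with a warning.  Windows called in
fewer than half the samples are dropped as uninformative.  No breakpoint
smoothing or imputation is applied — a documented extension point.

## QTL scans

Interval mapping is realised as Haley–Knott regression rather than
EM-based normal-mixture interval mapping: deterministic, fast, and
equivalent at fully observed markers, where the closed-form ANOVA oracle
(n/2)·log10(RSS0/RSS1) applies.  Genotype probabilities at markers and
2-cM pseudomarkers condition on the nearest non-missing flanking markers
under Haldane recombination (F2: 3-state chain; RIL: 2-state chain with
R = 2r/(1+2r)); positions with one flank use that flank's transition
against the design prior, positions with none fall back to the prior.  F2
models fit additive + dominance dosages, RIL additive only; individuals
with missing phenotype are dropped.  A perfect fit (RSS1 → 0) is floored
at RSS0·10⁻¹², capping the LOD at 6n rather than producing infinities.

Permutation thresholds are the empirical (1−α) quantile (linear, "type 7")
of the genome-wide maximum LOD over seeded label permutations, computed by
reusing each position's QR factorisation across all permutations.  The
cofactor scan conditions both the null and full model on significant-peak
dosages, excluding cofactors within 10 cM of the test position on the same
chromosome; it is a CIM-style approximation of multiple-QTL mapping, not a
reimplementation of backward-elimination MQM, but honours the 2-cM step
and 10-cM window.  Whether that window is in cM or marker count is not
documented for the original analysis; cM is assumed.

## Mixed models and CV trajectories

The stability model is value ~ line + generation (categorical fixed
effects) with a random intercept per line:replicate and i.i.d. error,
fitted by maximum likelihood — not REML, because REML likelihoods are not
comparable across different fixed structures and the whole point is a
likelihood-ratio test between them.  For fixed variance ratio
λ = σ²_rep/σ²_e the GLS coefficients and σ²_e have closed forms via the
Woodbury identity on per-group sums, leaving a one-dimensional profiled
likelihood; it is maximised on λ ∈ {0} ∪ 10^[−8,8] (81 points) and refined
by golden-section search on log λ to 10⁻⁸, with the λ = 0 boundary (OLS)
checked explicitly.  The fit matches a dense GLS grid oracle to <10⁻⁶
log-likelihood and statsmodels' ML MixedLM to ~10⁻⁴.

LRT degrees of freedom are computed from the actual fixed-parameter-count
difference: omitting "line" with 10 lines costs 9 parameters, omitting
"generation" with two levels costs 1.  Published df labels for this design
(1 and 2 respectively) cannot be reconciled with any parameterisation of
the described model, so the package reports its own computed df and treats
the reference statistics as qualitative direction only (line effect
overwhelming, generation effect marginal) — which the power simulations
reproduce.

CV trajectories group individuals sharing founder genotypes at *both* NOR
loci and report sd/mean (sample sd, n−1) per generation since divergence.
Under `mu = 0` with no measurement noise the CV is identically zero; with
`mu > 0` the across-lineage variance accumulates roughly linearly in
generations, so the mean CV rises monotonically — the validation study
checks a positive Spearman correlation (p < 0.01 over 100 seeded runs).

## Problem sizes and numerics

Validation studies use: 100 seeded F2 mapping runs (n = 93, full-scale
genome, 1000 permutations each), 500 null scans with 200-permutation
thresholds on the compact genome, 200 coverage replicates, 1000 null LRT
simulations (10 lines × 5 replicates × 2 generations) and 100
mutation-accumulation runs (30 lineages × 33 generations).  These sizes
give binomial standard errors comfortably inside the asserted bands while
keeping the full suite to a few minutes on one CPU.  Degenerate inputs are
handled explicitly: zero phenotypic variance yields an all-zero scan with a
warning, zero baseline depth and zero group means raise flagged errors, and
capped quantities (r ≥ 0.5 intervals, perfect-fit LODs) warn rather than
propagate infinities.

## Known limitations

* The unequal-crossover jump process is phenomenological; rates are
  calibration choices, not measured quantities.
* Multiparent (MAGIC) founder-haplotype mapping, read-level simulation,
  amplification-efficiency modelling and wet-lab QC are out of scope.
* The cofactor scan approximates, but is not, R/qtl's MQM; on data with a
  single strong QTL the two agree in peak location by construction of the
  exclusion window.
* Genetic maps estimated from n ≈ 100 individuals at 0.4-cM marker spacing
  are locally noisy; cumulative positions are accurate but interval-level
  distances carry large relative error, which the scan tolerates because
  probabilities depend only on nearby informative markers.
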