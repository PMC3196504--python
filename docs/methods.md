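# Methods

## Demographic model

All simulators and tests use a haploid continuous-time Kingman coalescent.
The standard history is piecewise constant with a single instantaneous size
change: population size N(t) = `ne_present` for t < T and
`ne_present × ratio_ancestral` for t ≥ T, with T = 13,000 years by default,
converted to generations via `generations_per_year` (1 for the moths,
1/30 for the Joshua tree). Sizes are haploid effective sizes used directly
as the coalescent's N — inheritance scaling is already folded into the
per-locus Θ from which the sizes are derived (Ne = Θ/2µ), so no extra ploidy
factors are applied. The four built-in scenario labels map to
ancestral:present ratios derived from palaeodistribution cell counts:
doubling = 240/432, slight growth = 434/509, decline = 641/566, and
constant = 1 exactly. (The reconstruction the original study labels
"constant" actually implies a ratio of ≈1.13; we assign that ratio to the
decline label and keep a literal ratio-1 constant scenario, because the
constant history serves as the null in every significance computation and
must be a true null.)

The growth simulator and estimator use the LAMARC parameterization:
Θ(u) = Θ_present·e^(−gu) with time u in mutational units (1/µ generations),
so the total coalescence hazard with k lineages is k(k−1)e^(gu)/Θ. The
simulator inverts the integrated hazard analytically and supports g ≥ 0
only: for g < 0 the integrated hazard is finite and the process fails to
reach an MRCA with positive probability, so a literal simulation is
improper. The estimator accepts any g.

The stepping-stone variant places demes on a 1-D chain with symmetric
nearest-neighbour migration at rate m per lineage per generation and
within-deme pairwise coalescence at rate 1/N_deme; it exists to generate
data with strong structure and isolation by distance, as seen in the
chloroplast data. What matters is the scaled rate N_deme·m: the default
community configuration uses N_deme·m ≈ 0.06, which produces global
Φ_ST ≈ 0.8–0.9 and a significant Mantel correlation, matching the study
system's chloroplast pattern.

## Sequence evolution

Rate matrices are reversible (q_ij = r_ij·π_j with symmetric
exchangeabilities) and normalized to one expected substitution per site per
unit time at stationarity, so branch length × µ is expected substitutions.
Families: HKY (κ on both transitions), TrN (separate A↔G and C↔T rates),
K81 (a single printed κ interpreted as the transition rate against two equal
transversion classes, with an optional second class parameter). Base
frequencies are not printed for the real loci; the default is equal
frequencies, configurable. Among-site rate variation uses a discrete Gamma
with 4 equal-probability categories whose values are the conditional
category means (mean-preserving, renormalized to average exactly 1); site
categories are drawn once per alignment and shared across branches.
Transition matrices come from a symmetrized eigendecomposition of Q
(exact for reversible models, validated against a Taylor-series oracle).

## Statistics

**Fu's Fs.** θ̂ = π (mean pairwise differences per locus);
S′ = P(K ≥ k_obs) under the Ewens sampling distribution,
P(K = k) = |s(n,k)|θ^k / (θ)_n, computed from exact integer Stirling numbers
of the first kind (bigint recurrence) with the tail sum in log space, so
n = 80 is exact and overflow-free. S′ saturating numerically returns ±∞ with
a warning rather than raising. Distinct haplotypes are counted on full
strings including ambiguity characters (a documented tie-break).

**Gap handling.** Sites with a gap or N are excluded per pair of sequences
(complete-case per site pair), not listwise; the generator itself never
emits gaps or N, but the readers accept them.

**Tajima's D** uses the canonical coefficients; at n = 3 both variance
coefficients vanish and the statistic is reported as undefined.

**Mismatch τ.** The observed pairwise-difference histogram is fitted by
least squares to the sudden-expansion expected curve
F_j = Ĝ_j(θ1) + e^(−τ(θ1+1)/θ1) Σ_{i≤j} (τ^i/i!)(Ĝ_{j−i}(θ0) − Ĝ_{j−i}(θ1)),
Ĝ the equilibrium geometric, over (τ, θ0) with θ1 pinned at 10³·max(θ0, 1)
— the exact estimator of the original desktop software is unspecified, so
the package's reference is a brute-force grid oracle, and the production fit
(coarse grid + Nelder–Mead polish) is tested never to do worse than the
grid. τ converts to years as t = τ/µ_locus (`paper_table`, default, which
reproduces the published dates) or t = τ/(2µ_locus) (`classical`); the two
conventions differ by exactly 2 and are deliberately both exposed rather
than silently reconciled, because the source tables and the textbook
definition disagree.

**Power analysis.** Each replicate runs the full chain genealogy → sequences
→ Fs; the reported proportion uses strict "<" (ties are not extreme).
Monomorphic replicates (S = 0) are uninformative for a lower-tail test and
are redrawn and logged. The constant-size null p-value is the ratio-1
special case and shares the replicate stream seed-for-seed with the power
engine.

**Growth fit.** Single-genealogy maximum likelihood: Θ̂(g) has a closed form
given the intercoalescent intervals, and g is profiled by bounded scalar
search, with a Δlog L = 1.92 profile interval. Sequence mode builds a UPGMA
tree from pairwise p-distances (heights halved to mutational time) — a
deliberate, declared single-genealogy approximation of MCMC genealogy
samplers. Single-locus ĝ is upward-biased; recovery tests therefore check
medians and signs, and downstream interpretation should treat g as a sign
and magnitude class.

**AMOVA.** Two-level nested Excoffier-style decomposition using the number
of pairwise nucleotide differences directly as the squared distance
(standard haplotypic format, no model correction), with unequal-sample-size
coefficients. Negative variance components are retained. Permutation schemes
follow the statistic: haplotypes among all populations (Φ_ST), haplotypes
among populations within regions (Φ_SC), whole populations among regions
(Φ_CT); p-values use (extreme+1)/(perms+1) so they are never exactly zero
(a documented deviation from the naive fraction). Region schemes are
metadata-driven. Global F_ST is exposed both as the AMOVA Φ_ST (default,
used by the structure gate) and as the mean of pairwise values, since either
reading fits a printed "global F_ST".

**Structure gate.** True iff global F_ST > 0.2 and the Mantel p < 0.05 —
the rule used to decide whether a dataset warrants spatially explicit
phylogeographic analysis.

**McDonald–Kreitman.** Codons are classified fixed/polymorphic ×
synonymous/nonsynonymous; codons requiring more than one nucleotide step, or
that are simultaneously polymorphic and fixed against the outgroup, are
excluded and counted (a conservative choice where the source is silent).
Internal stop codons are an error. Significance is two-tailed Fisher exact.

**SDM evaluation.** Presence at a threshold is strict exceedance
(score > t); candidate thresholds are midpoints between adjacent sorted
unique scores plus the boundary values, which makes the selection exactly
reproducible without an arbitrary grid. NODATA cells are excluded from
min/max and counts, never imputed. Non-analog masking flags a past cell when
any variable leaves the closed global [min, max] of the current stack.

## Synthetic community generator

The default configuration reproduces the study design: 4 moth species with
an ~1800 bp mitochondrial locus (n = 24–32) and a 490 bp nuclear locus
(n = 43–58 phased haplotypes), plus the plant with a 2000 bp chloroplast
locus (n = 79; the real total cpDNA length is unpublished, 2000 bp is the
package default). Substitution models and Γ shapes follow the fitted values
(e.g. TrN 65.95/24.28 with α = 0.04 for *P. sordidus* mtDNA; K81 κ = 2.81,
α = 1.55 for cpDNA), mutation rates are 1.5×10⁻⁸ (mtDNA), 2.2×10⁻⁹ (EF1α)
and 2.42×10⁻⁸ (cpDNA, per generation at 30 yr/generation), and present-day
sizes are Ne = Θ/2µ from the published Θ estimates. The moths are panmictic
across five sampling sites; the plant is a 12-deme stepping-stone chain
whose coordinates increase along the chain, producing isolation by distance.
All randomness flows from one master seed; identical seeds give byte-identical
FASTA output.

What the generator does **not** emulate: indel evolution, sequencing error,
PHASE-style haplotype ambiguity, recombination, selection, and real spatial
geometry beyond the 1-D chain. Tests passing on these data therefore
demonstrate correctness of the estimators under the stated generative model,
not robustness to those real-data complications.

Note that the published cpDNA Θ = 1.1 per site implies extremely high
simulated diversity (near-saturated alignments); the package takes the
printed values at face value.

## Numerical and scale choices

Monte-Carlo test sizes follow the checks' stated designs where a published
quantity is at stake (1000 replicates for the power cell, 5000 for the
coalescent cross-validation, 200 for growth recovery and Mantel
calibration, 100 exact-oracle Fs cases); purely illustrative distributional
comparisons use 60–300 replicates, chosen so the full suite runs in a few
minutes on one CPU. Scenario-ordering checks (doubling vs constant) are run
where the change time is on the order of Ne generations, since an
instantaneous change much more recent than Ne leaves no detectable
signature — the study's own conclusion about its simulated scenarios.

## Known limitations

- The mismatch τ estimator pins θ1 rather than fitting it; for gently grown
  populations τ̂ absorbs some of the unmodelled post-expansion diversity.
- The single-genealogy growth fit understates uncertainty relative to a
  genealogy-sampling estimator; its profile CI is conditional on the tree.
- The published simulation-based power proportions for the constant history
  are not reproducible by a standard coalescent at the stated parameters
  (the same publication's θ-matched null gives p two orders of magnitude
  smaller, in line with this package's output); the power engine here is
  validated instead against exact oracles and an independent coalescent
  implementation.
- AMOVA permutation p-values for Φ_CT are unstable when a region holds a
  single population; the result is flagged degenerate rather than suppressed.
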