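# Methods

This note documents the models behind `ladkit`, the parameters that matter,
what the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Coordinates and binning

All genomic coordinates are 0-based half-open (BED convention) internally
and on disk; 1-based "GTF-lite" input is converted at the reader boundary.
Strand is ignored throughout: every analysis here (domain coverage, gene
overlap, TE signal) is strandless. A chromosome of length L at bin size b
has ⌈L/b⌉ bins; only the final bin may be short, and RPKM uses each bin's
actual length. Binned tracks serialize as bedGraph text (one record per
valid bin, float `repr` for bit-exact round trips); bigWig is not required
for correctness and is not used by the tests.

## Spike-in normalization

CUT&RUN releases antibody-targeted fragments; a fixed exogenous spike-in
lets samples be compared on one quantitative scale. The scale factor for a
sample is `s = C / n_spikein` with an arbitrary per-antibody constant C
(H3K9me2: 3,000; H3K9me3: 7,000; LAP2β/LB1: 8,000) and n_spikein the
properly paired spike-in read count; `n_spikein = 0` is a hard error rather
than a pseudo-count. RPKM in a bin is
`c / ((L_bin/1000) · (M/10⁶))` with M the total mapped fragment count.

Numerical choices:

- **Fragments are assigned to bins by midpoint**, once each, rather than by
  per-base coverage. This conserves the total fragment count exactly
  (tested) and the downstream segmentation is insensitive to the coverage
  dialect. M counts fragments (read pairs), not reads.
- **Blacklist masking is any-overlap**: a bin partially covered by a
  blacklist interval is fully masked. Masked bins are treated as missing —
  excluded from normalization, averaging and HMM input — not zeroed, since
  zeros would bias the background state.
- Replicate averaging is the per-bin arithmetic mean over bins valid in
  *all* replicates; a bin invalid anywhere is invalid in the average.

## HMM segmentation

Emissions are univariate Gaussians on the normalized RPKM values directly
(an optional `log2(x+1)` transform flag exists because RPKM is
heavy-tailed, but the default is the plain Normal). Each chromosome — and
each maximal valid-bin run within it — is an independent sequence: blacklist
gaps carry no adjacency information, so no transition is modeled across
them.

Fitting is Baum–Welch (via hmmlearn) with deterministic initialization
given a seed: state means at the quantile midpoints of the pooled data
(25th/75th percentile for K = 2), all standard deviations at the sample SD,
transition matrix diagonal 0.95, uniform start. Convergence at
|ΔlnL| < 1e-4 or 500 iterations; the per-iteration log-likelihood trace is
retained and checked to be non-decreasing (EM guarantee) at every
iteration. Standard deviations are floored at 1e-3 of the sample SD. A fit
in which a state's expected occupancy drops below one observation is
restarted with jittered means (up to 5 restarts) and is an error after
that. States are relabeled by ascending mean on return; state K−1 is "high
signal".

Model selection fits K ∈ {2,3,4,5} and reports
`AIC = 2p − 2lnL` and `BIC = p·ln n − 2lnL` with `p = K² + 2K − 1` free
parameters (K(K−1) transitions, K−1 start, 2K emission) and n the total
number of valid bins. On data generated from a two-state Gaussian HMM at
d′ = (μ₁−μ₀)/σ ≥ 3, BIC recovers K = 2 essentially always (acceptance
suite: 20/20 seeded runs at 10,000 bins). On the negative-binomial
synthetic counts the criteria prefer more states — extra Gaussian
components absorb the count skew — which mirrors why two states are
*imposed* for domain calling rather than chosen per run; `analysis/02`
prints both outcomes.

Domains are maximal runs of the high state in the Viterbi path, decoded per
valid-bin run; invalid bins therefore break domains. One model per mark is
trained jointly on all wild-type replicates (each replicate's runs as
separate sequences) and then decodes every replicate. The consensus is the
base-pair intersection across all replicates with bookended fragments
merged (distance 0) — associative, commutative, and verified against a
per-base boolean-AND oracle. No minimum domain length filter is applied by
default.

## Domain taxonomy, genes and expression

Gene membership in a mark's domain set uses the fraction of the gene body
covered by the **union** of that mark's domains, with ≥ 0.90 semantics
(coverage exactly 0.90 is a member). In mES cells the three-mark pattern
space partitions into LAD (LB1 ∧ LAP2β ∧ H3K9me2), LB1+LAP2β (lamina marks
without H3K9me2), KOD (H3K9me2 only), non-LAD (none), and systematically
named residual patterns. The EpiLC scheme uses two marks only (LB1,
H3K9me2) because LAP2β is not a reliable lamina fiducial in that state;
transition labels between the two tables are cLAD, cKOD, newKOD (non-LAD →
KOD), LAD→LB1, non-LAD, with everything else retained as "other" rather
than forced into a named path.

Expression thresholds are strict: expressed means TPM > 5 (a `tpm_ge` flag
switches to ≥ for the boundary; the default is strict). DEG calls are
strict on both axes: up means log2FC > 1 (at the default 2-fold threshold)
*and* p_adj < 0.05. An empty class yields NaN (flagged), never a silent 0.

DEG enrichment per class is a two-sided Fisher's exact test on the 2×2
table (DEG vs not) × (in class vs not) over the full annotated gene
universe. The p-value is computed by direct fixed-margin hypergeometric
enumeration — the sum of probabilities of all tables no more probable than
the observed one, with a 1e-12 relative slack for floating-point ties — and
is verified in the tests against an independent exact-rational enumeration
and against scipy. The odds ratio is the sample odds ratio ad/bc, with 0
and ∞ permitted on zero cells; a zero margin gives p = 1 by convention.

Overlap accounting partitions the genome covered by any mark into the 2^m
membership patterns via a boundary sweep; pattern masses sum exactly to the
union coverage (tested against an independent interval-union oracle).

## TE-family enrichment

Family signal is the mean RPKM across replicates per copy, then the
unweighted mean across copies per family (a length-weighted flag exists).
The modified z-score is `0.6745 · (x − median) / MAD` where MAD is the
**raw** median of absolute deviations — the 0.6745 consistency constant is
applied explicitly in the formula, so a pre-scaled MAD would
double-correct. MAD = 0 is an explicit degenerate-distribution error, never
a silent division. A family is enriched when z strictly exceeds 2 for at
least one queried mark (and/or semantics across marks). Median ties for
even n use the conventional mean of the central order statistics.

## Imaging

Radial position inside a nucleus mask is measured with the Euclidean
distance transform to the mask complement: normalized depth
`r = 1 − EDT/max(EDT)` is 0 at the most interior pixel and approaches 1 at
the envelope, and is cut into n_shells = 25 equal-depth shells
(shell 1 = center, shell 25 = periphery;
`k = min(⌈r·n_shells⌉, n_shells)`, r = 0 → shell 1). Per shell the profile
reports the intensity fraction, area fraction and area-normalized mean —
both fraction-of-total and area-normalized views are exported since either
can be the quantity of interest. Analyses are strictly 2-D (one central
z-slice per nucleus) and no background subtraction is applied. Masks must
be a single connected component; a mask one pixel thick has no interior and
is an error.

The TEM-style quantification centers a square of side
`round(0.2 µm / pixel_size)` px (minimum 1) at each of 40 coordinates per
region, sums pixel values (integrated density), and reports
mean(envelope) / mean(nucleoplasm). Automated point sampling draws envelope
points from depth r > 0.9 and nucleoplasm points from r < 0.6, uniformly
without replacement, deterministically per seed (manual selection is the
lab reality; sampling makes the quantification testable).

## Synthetic data: what it emulates and what it does not

Defaults are desk-scale and chosen once: 2 chromosomes × 50 Mb at 10 kb
bins (10,000 bins), 3 replicates, spike-in expectation 3,000 reads.

- **Domain landscape**: a first-order Markov chain over
  {background, domain} with stay-probabilities 0.995/0.995 (geometric mean
  domain length 200 bins = 2 Mb) defines LADs carrying LB1, LAP2β and
  H3K9me2 together; an independent sparser chain adds H3K9me2-only (KOD)
  regions. Genes (2–200 kb, log-uniform, uniformly placed) get truth
  classes by the same 90% rule applied to the truth domains.
- **Counts**: negative binomial per bin with background mean 20, domain
  mean 80, dispersion (size) 10 — giving d′ ≈ 3 between states — with
  Poisson spike-ins. These emission levels are free parameters of the
  simulation, not measured values. The genotype contact-loss factor f has
  two scopes: `domain` interpolates the domain mean toward background
  (`bg + f·(dom − bg)`, so f = 0 makes domains statistically background),
  and `genome` multiplies every bin's mean by f, emulating global loss of
  recovered material against a fixed spike-in (f = 0.5 halves the
  target:spike-in yield ratio, which the tests confirm).
- **Expression**: genes are expressed (TPM drawn strictly above 5) with
  class probabilities non-LAD 0.6, KOD 0.35, LAD 0.1 (free parameters); a
  configurable fraction (default 0.2) of repressed domain genes is
  derepressed in the mutant with log2FC > 1 and p_adj < 0.05.
- **TE table**: 1,200 families with one latent gamma-distributed abundance
  per family shared across marks (shape 50, mean 10) plus 2% mark-specific
  noise; 40 designated families are shifted upward by 10×MAD in every mark.
  The shared abundance reflects that family copy number drives RPKM under
  every antibody; with independent per-mark nulls the and/or flag rule
  would inflate false positives well beyond what replicate-averaged real
  data shows.
- **Nuclei**: elliptical masks (default radii 60 × 45 px at 0.1 µm/px) with
  a marker that is a boundary ring (peripheral, the wild-type-like
  pattern), interior Gaussian foci (internal, the tether-loss-like
  pattern), or uniform; additive Gaussian noise clipped at 0.

Not emulated: read-level artifacts (fragment lengths, mappability,
duplicates), chromosome-scale heterogeneity, correlated replicate noise,
partial-domain boundaries at sub-bin resolution, 3-D nuclear geometry, and
real antibody efficiency differences. Passing tests therefore demonstrate
the correctness of the computations and the recoverability of truth under
the stated statistical structure — not performance on any particular real
dataset.

## Problem sizes used by the test and acceptance runs

Segmentation and recovery checks run on the default 10,000-bin genome with
3 replicates; model selection runs 20 seeded two-state Gaussian tracks of
10,000 bins each; enumeration oracles use sequences of T ≤ 8 (forward,
K ≤ 3) and T ≤ 12 (Viterbi, K = 2), 100 instances each; imaging checks use
200×200 px images with 40 squares per region and 100 noisy trials. These
sizes give stable estimates while keeping a full run to a few minutes on
one CPU.

## Known limitations

- The Gaussian emission model is misspecified for raw counts; on strongly
  skewed signal the two-state fit can place the high-state mean below the
  visual domain level. The log-transform flag mitigates this.
- Consensus by strict all-replicate intersection is conservative; a
  majority-vote consensus is not implemented.
- The Fisher test enumerates the hypergeometric support, which is exact but
  O(min margin); for gene universes in the millions a normal approximation
  would be preferable (irrelevant at realistic scales).
- Duration-explicit (hidden semi-Markov) models are out of scope; domain
  length is implicitly geometric.
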