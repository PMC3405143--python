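# Methods

This note documents the models, the numerical choices and the synthetic
data-generating process behind `bloodmeth`, including the reasoning for
every default that matters.

## 1. Preprocessing

Raw data are per-probe methylated/unmethylated fluorescence intensities
(probes × samples) with a per-probe color-channel label (Grn / Red for
single-channel chemistries, Both for two-channel probes). Stages, in order:

1. **Background subtraction.** Per sample and per signal channel, the
   `background_quantile` (default 0.05) quantile of the channel's
   intensities is subtracted; results are clipped at a floor of 1 intensity
   unit. A quantile of 0 disables subtraction. This is a deliberately
   simple order-statistic estimator: it assumes the dimmest probes are
   background-dominated and, by construction, floors exactly that fraction
   of each column.
2. **Color-bias adjustment.** Within each sample, the pooled
   (meth + unmeth) intensities of Red-channel probes are quantile-mapped
   onto a reference distribution — the Grn pool (default), the Red pool
   (no-op), or the arithmetic midpoint of the two sets of order statistics.
   Rank order within a channel is preserved; channels with fewer than two
   probes are skipped with a warning.
3. **Quantile normalization.** The stacked (meth over unmeth) matrix is
   normalized so every column shares the mean-of-order-statistics target;
   ties within a column receive the average target over the tied ranks.
   Stacking both channels gives them one common target distribution, which
   keeps the meth/unmeth ratio comparable across samples.
4. **M computation.** `M = log2((meth + c)/(unmeth + c))`.

**The offset `c` defaults to 100, not 1.** The floor in stage 1 sends the
bottom `background_quantile` fraction of each channel to intensity 1; with
`c = 1` those probes reach `|M| ≈ log2(total intensity) ≈ 13` and pile up
in heavy spikes at the extremes of the M distribution. Real array M-value
distributions are bounded near ±7; more importantly, the boundary spikes
sit right against the data-driven mixture anchors (§3) and make the
two-gamma fit collapse into two overlapping broad components whose
posterior is ≈0.5 everywhere. An offset of 100 — the same constant
conventionally used to stabilize beta values — bounds the dynamic range at
`log2(T/100)` ≈ 6–7 for typical total intensity T ≈ 10⁴ and restores a
cleanly bimodal geometry. The elementwise `compute_m` keeps the offset as
an explicit argument for callers who need the raw log-ratio.

**Scaling invariance is asymptotic, not exact.** Multiplying one sample's
intensities by `c > 0` leaves its ranks unchanged, but shifts the shared
mean-of-order-statistics target by `(c−1)/N` times that sample's share of
each rank (N = number of samples). The residual effect on M is bounded by
`log2(1 + (c−1)·r/N)` with `r` the sample's maximal ratio to the target —
a few hundredths of an M unit at N = 18, shrinking as 1/N — and the tests
assert exactly that bound rather than a fixed small tolerance.

Beta/M conversions are exact logistic transforms; `beta_to_m` clamps
`beta ∈ {0, 1}` to ±15 (beyond any array's dynamic range) and flags the
clamped entries.

## 2. Differential methylation

Probe-wise one-way layout of M on population: group means and the pooled
residual variance s² with `d = N − G` degrees of freedom (every group needs
≥2 samples). The empirical-Bayes prior (d₀, s₀²) is estimated from all
probe variances by the method of moments on `z = log s²`, using the exact
relations `E z = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)` and
`Var z = ψ′(d/2) + ψ′(d₀/2)`; ψ′ is inverted by Newton iteration. When the
observed variance of z does not exceed ψ′(d/2) there is no evidence of
variance heterogeneity and d₀ = ∞ (complete shrinkage to s₀²) is returned;
exactly identical variances skip the finite-d bias correction, since
zero scatter is inconsistent with any finite d.

The moderated t for contrast A−B uses
`s²_post = (d₀s₀² + d s²)/(d₀ + d)` and a t reference distribution with
`d₀ + d` df (normal when d₀ = ∞). Edge cases: zero posterior variance gives
t = ±∞ (p = 0) unless the difference is also zero, in which case t = 0,
p = 1. d₀ = 0 reduces exactly to the classical pooled-variance t, which the
tests verify at 1e−10.

Benjamini–Hochberg adjustment is applied **within each pairwise contrast
separately** (a global option exists); probes with q < 0.01 are significant.
The one-way model carries no donor term by default; donor effects in the
generator are shared across a donor's samples and therefore cancel in
expectation from between-population contrasts.

## 3. Three-state methylation calling

Per sample, M-values are modeled as a two-component mixture of reflected
gammas anchored just outside the data range (anchors `max+ε` / `min−ε`,
ε = 0.1):

    f(m) = π_u · Γ(a_u − m; k_u, θ_u) + (1 − π_u) · Γ(m − a_m; k_m, θ_m)

EM: posterior responsibilities in the E-step; weighted gamma maximum
likelihood in the M-step (Newton on the shape via the digamma equation,
closed-form scale, Minka's closed-form start). The log-likelihood is
non-decreasing by construction and asserted at 1e−8 in the tests.
Convergence: relative log-likelihood change < 1e−6 (max 500 iterations;
non-convergence returns the best fit flagged). Mixing proportions are
pinned to [1e−6, 1−1e−6] so one-sided data cannot produce degenerate fits.

**Label switching and orientation.** The likelihood surface has two
near-mirror basins: each component can either *reach across* to the far
mode (the state-consistent geometry, in which the top-anchored component
describes the low-M/unmethylated mode) or *hug its own anchor*. Which basin
has higher likelihood depends on the data shape, and in the hugging basin
the posterior band is far too diffuse for three-state calling. The fit
therefore starts from a responsibility split at the data midrange (not a
fixed M = 0, so that the whole procedure — anchors included — is exactly
equivariant under adding a constant to all M-values) and pins the
state-consistent basin by default; `init={"orientation": "high"|"auto"}`
exposes the other basin for simulation studies whose generating truth hugs
the anchors. A fitted `inverted` flag records which component captured the
high-M mass, and `p_methylated` maps component posteriors to the methylated
state accordingly, so calls are correct in either basin. Randomized
restarts (3, seeded) perturb the initialization within the chosen basin and
the best log-likelihood wins.

Anchor estimation from the sample extremes biases fitted shapes slightly
downward (the sample minimum overestimates the true anchor by the expected
minimum gap, ≈ θ·(Γ(k+1)/n)^{1/k}); at n = 5,000 recovery errors stay
within a few percent for π_u and ~10–15% for shapes.

**Calls.** `P(methylated) ≥ τ` → Methylated, `≤ 1 − τ` → Unmethylated,
otherwise Marginal; τ defaults to 0.9. Population calls are the strict
majority over that population's donors, any plurality tie → Marginal.
The discordance filter keeps a significant probe only when the two compared
populations' consensus calls differ; it is idempotent and always a subset
of the significant set.

## 4. Genomic context and enrichment

RefGene group tokens collapse to region classes (TSS200/TSS1500 → TSS,
5′UTR/1st exon → 5′ region, Body → intragenic, 3′UTR → 3′ region, no gene →
intergenic); probes annotated to several groups resolve by the precedence
TSS > 5′ > 3′ > body, so a promoter association always wins. CpG context
uses the manifest's island-relation column when present, otherwise island
intervals (BED, 0-based half-open; manifest positions are 1-based, with one
central conversion function): inside → island, ≤2 kb from an edge → shore,
2–4 kb → shelf, else open sea.

Enrichment is a DAVID-style upper-tail hypergeometric test of a gene list
against each term of a user-supplied term map over an explicit universe;
terms with p < 0.05 are reported, sorted ascending, top 10. Raw p drives
the cut (a BH column is included for reference). The canonical input list
is the genes with ≥1 filtered probe called unmethylated in the cell
population and methylated in whole blood; this list may legitimately be
empty.

## 5. The synthetic cell-mixture generator

The generator emulates a blood methylation study: 7 purified populations
(CD4T, CD8T, CD56NK, CD19B, CD14Mono, Neutrophils, Eosinophils), 3
composites (whole blood, PBMC, granulocytes), 6 donors, 20,000 probes.

**Base profiles.** Per-probe base beta from three archetypes —
constitutively unmethylated Beta(2,18) (40%), constitutively methylated
Beta(18,2) (40%), intermediate Beta(3,3) (20%). The intermediate archetype
is deliberately broad: intermediate CpGs on real arrays spread over the
unit interval rather than piling at exactly 0.5, and a tight bump at
β = 0.5 would create an artifactual third M mode that no real sample shows
(and that structurally miscalibrates any two-component fit).

**Planted effects.** Default 250 probes per pure population with
|Δβ| ~ U(0.45, 0.75) (direction: 85% hypomethylating in myeloid
populations, 30% in lymphoid, mirroring the observed myeloid demethylation
skew). The lower bound 0.45 is chosen so that a planted effect still
crosses call states after mixture dilution at the largest composite weight
(neutrophils, 0.60): the whole-blood profile moves w·Δβ alongside the cell,
leaving an effective separation (1−w)·Δβ ≥ 0.18 that the τ = 0.9 posterior
band resolves. A further 500-probe lineage block is hypomethylated
(Δβ = 0.4) in all three myeloid populations, giving the dendrogram its
myeloid/lymphoid bipartition.

**Mixing is linear in beta space.** Cell fractions mix methylated-molecule
proportions physically: `β_composite = Σ w_c β_c` (whole-blood weights
default to {Neutrophils 0.60, CD4T 0.12, CD8T 0.08, CD56NK 0.06, CD19B
0.04, CD14Mono 0.07, Eosinophils 0.03}; PBMC and granulocytes renormalize
over their member populations). Because the logistic transform is
nonlinear, the composite M-value is *not* the weighted mean of pure
M-values — a common modeling error the tests assert against explicitly.

**Noise model.** Donor effects N(0, 0.10) on the logit scale per
(donor, probe), shared between a donor's pure and composite samples (the
within-donor design); per-sample measurement noise N(0, 0.08) in M units
folded in through the logit; total intensity T ~ Gamma(8, 1250) per
probe-sample (mean 10⁴); a per-sample red-channel bias U(1, 1.2) applied to
Red probes; additive background Gamma(4, 12.5) (mean 50) per value.

*Calibration.* The noise defaults satisfy, by construction, the stated
generator property that the 6-donor mean empirical beta tracks truth within
±0.02 for ≥95% of probes: the combined logit-scale SD is
√(0.10² + (0.08·ln2)²) = 0.114, so the donor-mean SD is 0.114/√6 = 0.047,
worth ≤0.012 in beta at the steepest point (β = 0.5, slope 1/4) and ~0.004
at the archetype extremes (slope ≈ 0.09); the raw-ratio estimator bias from
additive background, (B − 2Bβ)/T ≲ 0.005 at B = 50, stays inside the
remaining budget. A background of 200 would already exhaust the ±0.02
budget on its own at extreme betas — the default models
scanner-software-corrected intensities whose residual offsets are small.

**Annotation and terms.** Probes are placed on 22 chromosomes with island
intervals every 40 kb, and the written relation column is generated from
the same geometry the classifier uses (self-consistent). Planted probes
draw their region class with a 60% gene-body share (the tissue-DMR
pattern); background probes 36%. The term map holds 40 random terms plus
one planted term covering exactly the genes that carry hypomethylating
planted effects (base β ≥ 0.7) in the designated enrichment population
(default CD14Mono) — the population's unmethylated-in-cell /
methylated-in-whole-blood gene list should recover it as the top hit.

**What the generator does not emulate:** Infinium I/II chemistry
differences, chip/batch effects, SNP-affected or cross-reactive probes,
detection failures (missing values), and correlated probes within CpG
islands. Passing tests therefore demonstrate the statistical machinery and
the mixture logic, not robustness to those artifacts.

## 6. Structure analyses

Population profiles are per-probe medians across the population's samples
(even counts: mean of the two middle values). Hierarchical clustering uses
euclidean distance and average linkage (both configurable; labels are
sorted before linkage so ties break deterministically) and exports newick.
PCA runs on probe-wise mean-centered, unscaled M-values via SVD, with a
deterministic sign convention; explained-variance fractions are
non-increasing and sum to ≤1. The lineage-vs-individual contrast is
summarized as mean pairwise distance within populations (across donors)
versus within donors (across populations).

## 7. Problem sizes used by the tests and the acceptance script

The shipped analyses run the full emulated design — 20,000 probes ×
60 samples — for the end-to-end recovery checks (≈20 s on one CPU), with
smaller dedicated configurations for scenario tests: 6,000 probes for the
mixture-weight dilution series ({0.05, 0.2, 0.6} × 3 replicates) and the
hypomethylated-population scenario, 10,000 probes for the global-null
control, n = 5,000 × 20 seeds for gamma-mixture parameter recovery. All
randomness is seeded; the acceptance script derives every seed from its
`--seed` argument.

## 8. Known limitations

* The background estimator floors a fixed fraction of each channel; very
  aggressive `background_quantile` settings distort the M tails (mitigated
  by the offset, §1).
* The two-component mixture cannot represent a genuine third mode; heavily
  intermediate samples widen the marginal band rather than forming a third
  state.
* Per-contrast BH matches the per-pair reporting convention but does not
  control the FDR across the full contrast family; use the global option
  when a family-wide guarantee is needed.
* The moderated model assumes exchangeable probe variances; variance trends
  along intensity (as on real arrays) are not modeled.
* Consensus calling by majority discards the posterior magnitudes; a
  probabilistic consensus would retain more information but has no
  counterpart in the emulated procedure.
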