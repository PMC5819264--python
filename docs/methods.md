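# Methods

## The statistical model

The analysis treats a morphological screen as a one-sample testing problem
per trait, calibrated entirely by wild-type replicates, followed by a
dimension-reduced distance statistic for the overall (holistic) defect.

**Per-trait nulls.** Each trait's wild-type distribution is fitted by
maximum likelihood with one of four families, assigned by trait type and
support:

| trait type                        | family        | parameters |
|-----------------------------------|---------------|------------|
| non-negative summary ("mean")     | gamma         | shape, rate |
| noise residual (real line)        | Gaussian      | μ, σ (divisor n) |
| proportion with cell counts       | beta-binomial | π, ρ |
| proportion without counts         | beta          | α, β |

The assignment is overridable per trait. Zero-variance traits are dropped
with a warning rather than fitted. The beta-binomial is parameterized by
the mean proportion π and overdispersion ρ (beta concentration
(1−ρ)/ρ) and maximized numerically on the logit scale (L-BFGS-B,
gradient tolerance 1e-8); gamma and beta use scipy's constrained MLE with
the location pinned at 0 (and scale at 1 for beta).

**Noise traits.** CV traits are replaced by residuals of log CV on
log mean of the paired mean trait, fitted by least squares across all
strains. This removes the strong mean–CV dependence so that the residual
("noise") traits can be treated as Gaussian real-line traits. The pairing
follows the `*_cv` ↔ `*_mean` naming convention or an explicit map;
orphan CV traits are an error.

**Normalization.** Values are mapped to a common scale by the
probability-integral transform through the fitted null,
`Z = Φ⁻¹(F̂(x))`, clipped at ±8. For the Gaussian family this is exactly
the classical `(x−μ̂)/σ̂`; realizing the Wald-type normalization as a PIT
puts all four families, including the discrete beta-binomial, on one
standard-normal scale. Missing measurements map to Z = 0 and p = 1 (the
null-neutral value); strains missing more than 10% of traits are dropped
with a warning.

**Two-sided p-values.** `p = min(1, 2·min(F̂(x), 1−F̂(x)))`. For the
discrete beta-binomial both tails include the observed count (no mid-p).
The smallest p over traits defines the *specific abnormality*
`−log₁₀(min p)`; altered traits are those with Storey q ≤ the FDR level,
with q-values pooled over the whole mutant × trait p-matrix (a single
multiplicity family; per-trait FDR is available via a flag).

**PCA and the holistic distance.** PCA is fitted on the mutant Z matrix
(centered on the mutant mean, no rescaling — Z is already
variance-calibrated), components retained up to CCR ≥ 0.80, wild-type
rows projected onto the mutant axes. Retained PC scores are standardized
by the wild-type mean and sd (divisor n), and the holistic abnormality is
the Euclidean distance from the wild-type center. Column signs are fixed
(largest-magnitude loading positive) for reproducible score files;
distances are sign- and rotation-invariant.

**Gamma null and calls.** A two-parameter gamma is fitted to the
wild-type replicate distances and mutants are tested in the upper tail
only (the distance is non-negative and abnormality one-directional).
Wild-type distances are computed with **leave-one-out standardization**:
each replicate is standardized against the mean/sd of the other
replicates. Standardizing a replicate against moments that include itself
shrinks its own distance (the studentized-residual effect, a ≈3% bias in
d² at 109 replicates) and makes the null anti-conservative; the jackknife
removes exactly this term. Plain self-inclusive centering remains
available (`HolisticDetector(wt_centering="plain")`).

**Classification and associations.** Holistic call (q ≤ FDR) takes
precedence; otherwise ≥1 altered trait makes a mutant *specific*, else
*other* — the three classes partition the strains. Crossed with a
one-tailed normal test of the fitness coefficient against its stated null
(slow vs normal growth at the same FDR), genes fall into groups I–VI.
Enrichment uses one-sided Fisher exact tests per (term, group) over the
background of all classified genes (configurable), testing terms with ≥3
annotated background genes, with q-values over all tested pairs.
Morphological similarity is the Pearson correlation of two mutants'
retained-PC score vectors in a *wild-type-fitted* PCA space at CCR 0.99;
edges are binned by |r| (weak (0.2, 0.4], moderate (0.4, 0.6], strong
> 0.6 — correlations above 0.8 are kept in the strong bin rather than
dropped). Feature correlations support Pearson/Spearman with partial
correlation by double residualization on the controls and Fisher-z 95%
CIs; group comparisons use two-sided Mann–Whitney U tests with Bonferroni
correction.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with known
ground truth:

* **Latent Gaussian field.** Every trait value derives from a standard
  normal latent variable; traits share `n_latent_factors = 57` factors at
  communality `factor_strength = 0.8` (each trait: 80% shared, 20% unique
  variance). These defaults emulate the compressibility of real CalMorph
  data, where roughly 57 PCs carry 80% of the variance of the 501-trait
  panel (the synthetic pure-null screen reaches 60/70/80/90% CCR at
  34/43/55/173 PCs).
* **Families.** Mean traits are gamma (shape U(2,10), scale U(0.5,20));
  CV traits obey `log CV = a + b·log(mean) + ε` with the global slope
  `cv_mean_slope = −0.3`, trait intercepts U(−1.5,−0.5) and residual sd
  0.2 (the residual channel carries the factor correlation); ratio traits
  are beta-binomial with denominator 200 cells and overdispersion
  ρ = 0.05, drawn as beta-distributed per-strain proportions followed by
  binomial counts.
* **Planted effects** are additive shifts of the latent variable, i.e.
  effect sizes are in wild-type sd units on the normalized scale.
  *Specific* mutants shift 1–5 random traits independently. *Holistic*
  mutants draw from a dictionary of `n_effect_modes = 20` shared
  **abnormality modes**: each mode is a fixed ±`holistic_effect_sd`
  pattern over a random 30% subset of traits, its sign pattern following a
  random factor-space direction so that correlated traits deviate
  coherently; each holistic mutant applies one mode with a random overall
  sign. Low-rank, module-aligned effects reflect how grossly abnormal
  mutants behave in real screens (they form tight similarity clusters);
  they are also what makes a PCA-reduced distance an appropriate statistic
  at all. With independent per-mutant random shift patterns instead, the
  planted effects act as high-rank isotropic noise: the 80%-CCR cut then
  retains a long tail of sample-noise PCs whose in-sample eigenvalues
  exceed any out-of-sample variance, and the planted-null false-call rate
  rises above 90% — a property of in-sample PCA, not of the detector.

**What the generator does not emulate.** Real screens have heterogeneous
per-trait measurement error, heavy-tailed traits outside the four
families, strain-level batch effects, and effect sizes spanning a
continuum rather than three classes. Passing tests therefore demonstrate
the statistical machinery (calibration, recovery, ordering) under the
stated generative assumptions, not performance on any particular real
dataset.

## Calibration behavior and known limitations

Under planted-null conditions the procedure is slightly anti-conservative,
for a structural reason worth stating plainly: **mutants are scored in the
same PCA they were fitted on, while the wild type is projected
out-of-sample.** At p/n = 501/2500 the in-sample score variance along a
retained PC of strength ℓ exceeds the out-of-sample variance by roughly a
factor 1 + γ·(bulk)/ℓ (γ = p/n); summed over ~60 retained PCs this puts
planted-null distances ≈4–6% above the wild-type-calibrated gamma null in
d², independent of the number of wild-type replicates. At the q ≤ 0.01
call threshold (null tail probability ≈ 0.002, gamma shape ≈ 90–115)
this inflates the realized false-discovery proportion among calls to
≈0.015–0.06 by seed (mean ≈ 0.03), with sensitivity ≈ 1.0 for 3-sd
effects on 30% of traits. The leave-one-out wild-type distances remove
the separate self-standardization bias (without them the mean FDP is
≈0.044); the residual in-sample inflation is intrinsic to the published
procedure and would vanish only if all retained components were far
stronger than the noise bulk. Users who need strict FDP control at the
nominal level should interpret q ≤ 0.01 calls as controlling FDR at
roughly the few-percent level, or score mutants through a PCA fitted on
an independent split.

Other numerical choices: gamma/beta/beta-binomial fits converge to
gradient tolerance 1e-8 and are cross-checked against generic optimizers;
q-values use Storey's smoother (cubic-polynomial fit of π0(λ) on
λ ∈ {0.05,…,0.95}, read off at λ = 0.95, clipped to (0,1], falling back
to π0 = 1 with a warning when the smoother degenerates); CCR retention
uses a ≥ comparison (a CCR exactly on target retains that PC); p-values
are floored at 1e-300 so `−log₁₀ p` stays finite; values outside a
family's support are evaluated at the boundary with a warning.

**Problem sizes.** The test suite exercises the full 501-trait panel with
up to 2500 mutants (the calibration audits) and smaller screens
(~120–1000 mutants) for mechanics; the acceptance script runs five
2609-strain screens. These sizes give the calibration estimates a
Monte-Carlo error of about ±0.004 on a false-discovery proportion near
0.01.

**CLI layout.** Model fitting, normalization, embedding and calling share
all intermediate state and are exposed as the single `detect` stage
(subcommands: `simulate`, `detect`, `classify`, `similarity`, `enrich`,
`report`, `run`); each stage writes a manifest with a configuration hash,
and reruns regenerate only stages whose manifest no longer matches.
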