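# Methods

## Model

`selblup` implements genomic BLUP with a *selection-adjusted* genomic
relationship matrix (GRM). The mixed model is

    y = 1·mu + a + e,      a ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

with phenotypes assumed pre-adjusted for fixed effects (an intercept is
projected out regardless). The GRM encodes an assumed relationship between
minor allele frequency (MAF) and marker effect variance through the
exponent S:

    m_ij = (x_ij - 2 p_i) · [2 p_i (1 - p_i)]^(S/2)
    G    = M M' / sum_i [2 p_i (1 - p_i)]^(S+1)

where `x_ij` is the 0/1/2 dosage of individual j at SNP i and `p_i` the
frequency of the counted allele. S = 0 recovers the VanRaden GRM (all
markers share one effect-variance scale), S = -1 recovers the GCTA matrix
(per-SNP standardization, equal expected heritability per marker); negative
S gives rare alleles larger effect variance, as under negative
(purifying/directional) selection, positive S the reverse.

The MAF-stratified variant (five-component model) partitions QC-passing
SNPs into the five MAF bins [0.01, 0.1], (0.1, 0.2], (0.2, 0.3],
(0.3, 0.4], (0.4, 0.5], builds one GRM per bin with the same S, and fits

    y = 1·mu + sum_t a_t + e,    a_t ~ N(0, G_t sigma_t^2).

Bins are right-closed so the conventional interval labels are unambiguous;
a boundary MAF belongs to the lower-labeled bin. Each bin GRM carries its
own normalizing denominator — the per-bin variance component absorbs any
scale — and the denominator-weighted sum of the bin GRMs reconstructs the
single GRM exactly (checked as an algebraic identity in the tests).

Centering uses the counted-allele frequency (not the folded MAF) so that
`x - 2p` is mean-zero; the bin assignment and the simulator's effect law
use the folded MAF, where `2p(1-p)` is the same either way. Missing
genotypes that survive QC are mean-imputed with `2p` at GRM construction
only, which makes their centered contribution exactly zero; the raw panel
keeps its missing entries.

## Quality control

Per-SNP filters run sequentially — missing call rate > 0.05, exact
Hardy-Weinberg test p < 1e-5, folded MAF < 0.01 — with each SNP attributed
to the first filter it fails. The HWE test is the exact conditional test
(enumeration of heterozygote counts given allele counts, no mid-p),
matching common SNP-chip practice; a chi-square approximation is not used.
The HWE threshold default is 1e-5; users preferring the stricter 1e-6
convention can pass it. Missingness is per-SNP only; per-individual call
rates are not filtered.

## REML estimation

* **Single GRM.** G is eigendecomposed once; in the rotated basis the
  restricted likelihood profiles analytically over the total variance,
  leaving a 1-D problem in the heritability ratio h² = sigma_a²/(sigma_a²+
  sigma_e²). A 101-point coarse grid guards against local optima, followed
  by bounded scalar minimization. The h² = 0 boundary is checked
  explicitly.
* **Several GRMs.** Average-information (AI) REML on the variance vector
  (sigma_1², …, sigma_k², sigma_e²), initialized at an equal split of the
  phenotypic variance. Components driven negative are projected to a small
  floor (1e-8 of the phenotypic variance); a component pinned at the floor
  with an inward-pointing gradient is frozen out of the AI system
  (active-set treatment). If a projected AI step still decreases the
  restricted likelihood it is halved up to ten times, then replaced by an
  EM-REML step. Convergence requires both |Δ loglik| < 1e-8 and a maximum
  damped relative parameter change < 1e-6; the iteration cap is 200. The
  tolerances are deliberately tight so that the single- and multi-component
  code paths agree to 1e-6 in h² when given the same one-component problem.
  Plain EM is never used as the main engine: near the zero boundary its
  per-step likelihood gain falls below any tolerance long before the
  parameters reach the boundary, which produces spurious "converged"
  results; the projected AI step does not have this failure mode.

Reported log-likelihoods always come from one dense evaluator (including
the REML constants), so values from different paths and from the
residual-only null fit are directly comparable. The LRT is
2·(loglik_full − loglik_null) floored at zero and reported as a raw fit
statistic; an optional boundary-mixture p-value (0.5·chi²₀ + 0.5·chi²₁) is
available for the single-component case only, since the five-component
boundary null is a heavier mixture.

## Prediction

BLUP of candidate genetic values uses the conditional-expectation form

    a_t(cand) = sigma_t² G_t[cand, train] P y_train

with P the REML projection (V⁻¹ minus its intercept correction) built on
the training block; the GEBV is the sum over components. This equals the
mixed-model-equations solution extended by the genomic covariance (verified
against a dense MME solve in the tests). Prediction accuracy is the plain
Pearson correlation of GEBV with the simulated true breeding values (or
with phenotypes for real data), with no division by sqrt(h²).

For train/candidate splits, allele frequencies should be taken from the
full QC'd panel so both sets are centered on a common scale; the
`GBLUPRegressor` estimator exposes this as its `allele_freq` parameter and
falls back to training-set frequencies when it is not supplied.

## Trait simulator

Traits are simulated on a genotype panel (real or synthetic) as follows:
`n_cv` causal variants (default 1000) are drawn uniformly without
replacement from the polymorphic SNPs; each effect is
g = [2p(1-p)]^(S/2)·g* with g* ~ N(0,1), so the effect variance follows
[2p(1-p)]^S; the true breeding value is the dosage-weighted effect sum;
the residual SD is sqrt(sigma_a²(1-h²)/h²) with sigma_a² the *empirical*
variance of the TBV vector, computed per replicate after the effect draws.
The empirical calibration keeps the realized heritability var(TBV)/var(y)
tightly concentrated at the target (default h² = 0.1, the reference study
condition). Causal variants stay inside the analysis SNP set; users who
want to study imperfect tagging can exclude them manually. Replicates
redraw causal-variant positions independently.

The per-CV heritability diagnostic is h_i² = 2p_i(1-p_i)·g_i², whose
expectation is proportional to [2p(1-p)]^(S+1): constant in MAF at S = -1,
concentrated in rare variants for S < -1, in common variants for S > -1.

Synthetic panels draw allele frequencies uniformly on [0.01, 0.5] and
genotypes as two Bernoulli(p) allele draws (Hardy-Weinberg, linkage
equilibrium); in-sample monomorphic columns are redrawn. Because the
models under study ignore linkage disequilibrium, the default generator is
LD-free; this means passing tests demonstrate correctness of the
estimation machinery under the models' own assumptions, not robustness to
the LD structure, ascertainment bias, or family structure of real SNP-chip
data. Sample MAFs can fall slightly below the nominal lower bound, so
panels are passed through QC before MAF binning, exactly as real data
would be.

One integer master seed drives everything; per-stage child generators
(panel, causal-variant choice, effects, residuals, fold assignment) are
spawned from it with fixed stream keys, so stages are independently
reproducible and the full pipeline is bit-reproducible under a fixed seed.

## Enrichment diagnostic for choosing S

For a five-component fit, bin t's observed heritability share is
sigma_t² / sum(sigma²); its expected share under the model's S is

    E_t = sum_{j in bin t} [2p_j(1-p_j)]^(S+1) / (grand total)

(at S = -1 this reduces to the bin's SNP-count fraction). The per-bin
enrichment is observed/expected, and

    chi² = sum_t (O_t - E_t)² / E_t

summarizes the departure from the ideal 1:1:1:1:1 pattern, with O and E
the observed and expected *proportions* (each summing to one, so the
statistic is dimensionless and comparable across traits). Expected shares
are computed with the same S being evaluated, so the statistic measures
the internal consistency of that S; scanning a grid of S values and taking
the argmin selects the best-calibrated exponent. The observed-proportion
convention makes the statistic a pure calibration measure; it is not a
formal test by default (4 degrees of freedom apply if a p-value is
wanted).

## Cross-validation

Two schemes: a single 9:1 holdout (candidate fold of round(0.1·n)
individuals), used for simulation replicates, and 10-fold CV with fold
sizes differing by at most one, used for real-data evaluation. In the
S-grid driver the heritability, LRT and enrichment columns come by default
from one full-data fit per S (prediction still uses per-fold training
fits), mirroring the separate reporting of accuracy distributions and
point heritability estimates; per-fold fitting is available via a flag.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script Monte-Carlos run at reduced scale,
chosen so each check retains clear statistical power: heritability
recovery uses a 1500 x 8000 panel at h² = 0.3 (20 replicates); simulator
calibration a 1000 x 5000 panel at the reference h² = 0.1 (50 replicates);
the enrichment-argmin and accuracy-contrast Monte-Carlos an 800 x 3000
panel with 500 causal variants at h² = 0.4 (10 replicates). The higher h²
in the calibration and contrast checks compensates for the smaller sample
sizes — the sampling SD of a single-GRM h² estimate scales roughly like
sqrt(2m)/n for an LD-free panel, so effects that are obvious at
n ≈ 5000, h² = 0.1 would be noise at n ≈ 800 without it.

## Known limitations

* No LD-aware SNP weighting, dominance/epistatic relationship matrices, or
  sparse GRMs.
* Fixed effects beyond the intercept must be pre-adjusted out of the
  phenotype.
* No pedigree information, single-step H-matrix, or Bayesian estimation of
  S; S is chosen by grid search over the chi-square diagnostic.
* Heritability estimates from breeding populations with strong family
  structure conflate genetic and shared-environment variance; the
  simulator does not emulate that structure, so the calibration shown here
  is for the idealized unrelated-individual setting.
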