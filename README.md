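# selblup — selection-adjusted genomic prediction

Tools for genomic BLUP (GBLUP) and SNP-heritability estimation in breeding
populations when natural or artificial selection has shaped the
relationship between minor allele frequency (MAF) and marker effect sizes.
Intended for quantitative geneticists working with SNP-chip genotypes
(PLINK binary format) and pre-adjusted phenotypes or pseudo-phenotypes.

## The model

Classic GBLUP assumes every marker effect is drawn from one Gaussian
distribution. Under negative selection, rare alleles tend to carry larger
effects; under positive selection the reverse. `selblup` encodes this in
the genomic relationship matrix (GRM) through a selection exponent S:

```
m_ij = (x_ij − 2p_i) · [2p_i(1−p_i)]^(S/2)
G    = M M′ / Σ_i [2p_i(1−p_i)]^(S+1)
```

so that the implied marker effect variance scales as `[2p(1−p)]^S`.
S = 0 is the VanRaden GRM (classic GBLUP), S = −1 the GCTA matrix.
Two estimators are provided:

* **GBLUP-S** — one GRM built at a chosen S, one genetic variance
  component, fitted by REML (eigendecomposition + profile likelihood).
* **GBLUP-SMS** — five GRMs, one per MAF bin (0.01–0.1, 0.1–0.2, 0.2–0.3,
  0.3–0.4, 0.4–0.5), five variance components, fitted by AI-REML. The
  per-bin heritability shares, compared with the shares expected under the
  model's S, give a heritability *enrichment* per bin; the chi-square
  statistic `Σ (O_i − E_i)²/E_i` over the five bins measures calibration,
  and scanning S for its minimum selects the exponent best matched to the
  trait's genetic architecture.

A trait simulator with MAF-dependent effect variances, a PLINK bed/bim/fam
reader-writer with QC (missingness, exact Hardy–Weinberg, MAF), GCTA-format
GRM serialization, cross-validation and accuracy scoring, and a CLI round
out the toolkit. See `docs/methods.md` for the full model description and
numerical choices.

## Worked example

```python
import numpy as np
import selblup as sb
from selblup import GBLUPRegressor

# 1. synthetic panel: 400 individuals x 2000 SNPs, HWE, MAF ~ U(0.01, 0.5)
panel = sb.generate_panel(sb.SyntheticPanelConfig(n_individuals=400, n_snps=2000, seed=7))
panel, report = sb.apply_qc(panel)
print(report)

# 2. simulate a trait under negative selection (S = -1), h2 = 0.4
trait = sb.simulate_trait(panel, sb.SimulationConfig(n_cv=300, s_true=-1.0, h2=0.4, seed=7))
print(f"realized h2 = {trait.realized_h2:.3f}")

# 3. fit GBLUP-S at the matched S on 360 training individuals
train, cand = np.arange(360), np.arange(360, 400)
model = GBLUPRegressor(s_value=-1.0, allele_freq=panel.freq_a)
model.fit(panel.dosages[train], trait.phenotypes[train])
print(f"h2 estimate = {model.h2_:.3f}   LRT = {model.lrt_:.2f}")

# 4. predict candidates and score against the simulated breeding values
gebv = model.gebv(panel.dosages[cand])
print(f"prediction accuracy r(TBV, GEBV) = {np.corrcoef(gebv, trait.tbv[cand])[0,1]:.3f}")

# 5. choose S by the enrichment chi-square (five MAF-bin model)
from selblup.evaluation import select_s_by_chi_square
best_s, table = select_s_by_chi_square(panel, trait.phenotypes, s_grid=(-2.0, -1.0, 0.0, 1.0))
print(table.to_string(index=False))
print(f"chi-square selects S = {best_s}")
```

Output:

```
QC: 2000 SNPs in; removed 0 (missingness), 0 (HWE), 6 (MAF); 1994 retained
realized h2 = 0.382
h2 estimate = 0.342   LRT = 3.38
prediction accuracy r(TBV, GEBV) = 0.446
 s_model     chi2       h2  converged
    -2.0 1.281743 0.428031       True
    -1.0 0.167833 0.473011       True
     0.0 0.483481 0.460991       True
     1.0 1.362198 0.417025       True
chi-square selects S = -1.0
```

The simulator drew 300 causal variants whose effect variances scale as
`[2p(1−p)]^{-1}` and calibrated residual noise for a 0.4 heritability
(0.382 realized in this replicate). The single-GRM fit at the matched S
estimates h² = 0.34 on the 360 training individuals and predicts the 40
candidates' breeding values with accuracy 0.45. The five-bin chi-square
is smallest at the true S = −1: the fitted per-bin heritability shares sit
closest to the shares that S implies, which is exactly the calibration
signal used to pick S for real traits.

`GBLUPRegressor` follows the scikit-learn estimator contract
(`get_params`/`set_params`, `fit`/`predict`, fitted attributes
`h2_`, `sigma_a2_`, `sigma_e2_`, `loglik_`, `lrt_`), so it composes with
`sklearn.model_selection` tooling; pass `maf_stratified=True` for the
five-component model. The functional layer (`build_grm`, `fit_reml`,
`predict_gebv`, `run_s_grid`, …) exposes the same machinery for
kinship-matrix workflows.

## Command line

```
selblup qc        --bfile data --out data_qc
selblup grm       --bfile data_qc --s-value -0.5 [--maf-stratify] --out kin
selblup simulate  --synthetic 1000,5000 --n-cv 1000 --s-true -1 --h2 0.1 --reps 10 --seed 1 --out sim/
selblup fit       --pheno sim/pheno_rep0.txt --grm kin --out fit.tsv
selblup evaluate  --bfile data_qc --pheno pheno.txt --model gblup-sms --cv kfold10 --out eval/
selblup reproduce-sim --config run.yaml --seed 1 --out study/
```

`reproduce-sim` runs the full simulation study (synthetic panel → traits
across an S grid → both models → accuracy / heritability / LRT /
enrichment table) and writes its resolved configuration and provenance
next to the results, so any run can be re-executed exactly.

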