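"""Synthetic genotype panels and quantitative traits under selection.

Traits are built from randomly chosen causal variants (CVs) whose effect
variances scale with allele frequency as ``[2p(1-p)]^S``: negative S gives
rare alleles larger effects (negative selection), S = 0 gives every CV the
same effect variance, positive S mimics positive selection. Residual
variance is calibrated from the realized genetic variance so that the
realized heritability concentrates at the target h2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypePanel, SNPRecord, compute_freqs

#: S grid used throughout the simulation study.
S_GRID = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0)

# stream-separation offsets for deriving per-stage child seeds from one
# master seed (documented contract: panel, cv choice, effects, residuals,
# fold assignment each get an independent bit-mixed stream)
_STAGE = {"panel": 0, "cv": 1, "effects": 2, "residuals": 3, "folds": 4}


def stage_rng(seed: int, stage: str, replicate: int = 0) -> np.random.Generator:
    """Deterministic per-stage random generator derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE[stage], replicate))
    )


@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Shape and allele-frequency law of a synthetic genotype panel.

    Allele frequencies are drawn uniformly on [maf_low, maf_high] and
    genotypes as two independent Bernoulli(p) draws per individual
    (Hardy-Weinberg, linkage equilibrium).
    """

    n_individuals: int
    n_snps: int
    maf_low: float = 0.01
    maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 < self.maf_low < self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low < maf_high <= 0.5")


@dataclass(frozen=True)
class SimulationConfig:
    """Trait-simulation settings.

    Defaults follow the reference study conditions: 1000 causal variants,
    h2 = 0.1, 10 replicates, S drawn from {-2, -1.5, -1, -0.5, 0, 0.5, 1}.
    """

    n_cv: int = 1000
    s_true: float = -1.0
    h2: float = 0.1
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2 must be in (0, 1), got {self.h2}")
        if self.n_cv <= 0:
            raise ValueError("n_cv must be positive")


@dataclass
class SimulatedTrait:
    """One simulated trait: causal variants, effects, TBV and phenotypes."""

    cv_indices: np.ndarray
    effects: np.ndarray
    tbv: np.ndarray
    residuals: np.ndarray
    phenotypes: np.ndarray
    sigma_a2: float
    s_true: float
    h2: float
    seed: int

    @property
    def realized_h2(self) -> float:
        """var(TBV) / var(y) actually achieved in this replicate."""
        return float(np.var(self.tbv) / np.var(self.phenotypes))


def generate_panel(config: SyntheticPanelConfig) -> GenotypePanel:
    """Simulate an HWE, linkage-equilibrium genotype panel.

    Monomorphic draws (possible at small n and low MAF) are resampled so
    that every SNP is polymorphic in-sample. Deterministic under the seed.
    """
    rng = stage_rng(config.seed, "panel")
    n, m = config.n_individuals, config.n_snps
    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    dosages = rng.binomial(1, p, size=(n, m)) + rng.binomial(1, p, size=(n, m))
    dosages = dosages.astype(float)
    # resample columns that came out monomorphic
    for _ in range(100):
        mono = np.flatnonzero(np.ptp(dosages, axis=0) == 0)
        if mono.size == 0:
            break
        p[mono] = rng.uniform(config.maf_low, config.maf_high, size=mono.size)
        redraw = rng.binomial(1, p[mono], size=(n, mono.size)) + rng.binomial(
            1, p[mono], size=(n, mono.size)
        )
        dosages[:, mono] = redraw

    snps = [
        SNPRecord(chromosome="1", snp_id=f"snp{i}", position=i + 1,
                  allele_a1="A", allele_a2="B")
        for i in range(m)
    ]
    individuals = [("0", f"ind{j}") for j in range(n)]
    return compute_freqs(
        GenotypePanel(individuals=individuals, snps=snps, dosages=dosages)
    )


def simulate_trait(
    panel: GenotypePanel, config: SimulationConfig, replicate: int = 0
) -> SimulatedTrait:
    """Simulate one trait replicate on ``panel``.

    CVs are sampled uniformly without replacement from the panel's SNPs.
    Each CV effect is g = [2p(1-p)]^(S/2) * g*, g* ~ N(0,1), so the effect
    variance is [2p(1-p)]^S. TBV_j = sum_i x_ij g_i (missing dosages are
    mean-imputed). The residual SD is sqrt(sigma_a2 (1-h2)/h2) with
    sigma_a2 the empirical variance of the TBV vector, so the realized
    heritability var(tbv)/var(y) concentrates near the target h2.
    """
    if panel.freq_a is None:
        panel = compute_freqs(panel)
    if config.n_cv > panel.n_snps:
        raise ValueError("n_cv exceeds the panel SNP count")

    rng_cv = stage_rng(config.seed, "cv", replicate)
    poly = np.flatnonzero((panel.freq_a > 0.0) & (panel.freq_a < 1.0))
    if poly.size < config.n_cv:
        raise ValueError("not enough polymorphic SNPs for the requested CV count")
    cv = np.sort(rng_cv.choice(poly, size=config.n_cv, replace=False))

    p = panel.maf[cv]
    het = 2.0 * p * (1.0 - p)
    rng_eff = stage_rng(config.seed, "effects", replicate)
    g_star = rng_eff.standard_normal(config.n_cv)
    effects = np.exp(0.5 * config.s_true * np.log(het)) * g_star

    x = panel.dosages[:, cv]
    x = np.where(np.isnan(x), 2.0 * panel.freq_a[cv][None, :], x)
    tbv = x @ effects
    sigma_a2 = float(np.var(tbv))

    rng_res = stage_rng(config.seed, "residuals", replicate)
    resid_sd = np.sqrt(sigma_a2 * (1.0 - config.h2) / config.h2)
    residuals = rng_res.normal(0.0, resid_sd, size=panel.n_individuals)
    phenotypes = tbv + residuals
    return SimulatedTrait(
        cv_indices=cv,
        effects=effects,
        tbv=tbv,
        residuals=residuals,
        phenotypes=phenotypes,
        sigma_a2=sigma_a2,
        s_true=config.s_true,
        h2=config.h2,
        seed=config.seed,
    )


def per_cv_heritability(
    trait: SimulatedTrait, panel: GenotypePanel
) -> np.ndarray:
    """Heritability contributed by each causal variant: 2p(1-p) g^2.

    This is the realized single-draw version; its expectation is
    proportional to [2p(1-p)]^(S+1), constant in MAF at S = -1, decreasing
    in MAF for S < -1 and increasing for S > -1.
    """
    if panel.freq_a is None:
        panel = compute_freqs(panel)
    p = panel.maf[trait.cv_indices]
    return 2.0 * p * (1.0 - p) * trait.effects**2
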