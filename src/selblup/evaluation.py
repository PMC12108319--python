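"""Cross-validation, prediction accuracy, and heritability-enrichment
diagnostics for choosing the selection exponent S.

For a five-component MAF-stratified fit, each bin's share of the total
estimated heritability is compared with the share expected under the
model's S (proportional to ``sum_{j in bin} [2p_j(1-p_j)]^(S+1)``); their
ratio is the bin's heritability enrichment, and a chi-square statistic over
the five bins summarizes departure from the ideal 1:1:1:1:1 pattern. The
model S minimizing the statistic is the best-calibrated choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel, compute_freqs
from .kinship import (
    MAF_BIN_EDGES,
    KinshipMatrix,
    MAFBinning,
    assign_bins,
    build_grm,
    build_stratified_grms,
)
from .mixedmodel import FitResult, fit_reml, lrt, predict_gebv
from .simulator import (
    S_GRID,
    SimulationConfig,
    simulate_trait,
    stage_rng,
)


@dataclass
class CVScheme:
    """Assignment of individuals to validation folds.

    mode "holdout91" puts ~10% of individuals in a single candidate fold
    (fold 1, the rest fold 0); mode "kfold10" partitions into ten folds of
    near-equal size.
    """

    mode: str = "holdout91"
    seed: int = 0
    fold_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("holdout91", "kfold10"):
            raise ValueError(f"unknown CV mode {self.mode!r}")

    @property
    def n_folds(self) -> int:
        return 10 if self.mode == "kfold10" else 2

    def candidate_folds(self) -> list[int]:
        """Fold indices that serve as candidate (validation) sets."""
        return list(range(10)) if self.mode == "kfold10" else [1]


def make_folds(ids: list, scheme: CVScheme) -> CVScheme:
    """Random fold assignment, deterministic under the scheme's seed."""
    n = len(ids)
    if n < 20:
        raise ValueError("need at least 20 individuals for cross-validation")
    rng = stage_rng(scheme.seed, "folds")
    perm = rng.permutation(n)
    assignment = np.zeros(n, dtype=int)
    if scheme.mode == "holdout91":
        n_cand = int(round(0.1 * n))
        assignment[perm[:n_cand]] = 1
    else:
        # spread the remainder so fold sizes differ by at most one
        assignment[perm] = np.arange(n) % 10
    return CVScheme(mode=scheme.mode, seed=scheme.seed, fold_assignment=assignment)


def accuracy(truth: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between (true or observed) values and GEBVs."""
    truth = np.asarray(truth, dtype=float).ravel()
    gebv = np.asarray(gebv, dtype=float).ravel()
    if len(truth) != len(gebv):
        raise ValueError("length mismatch")
    if len(truth) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(truth) == 0.0 or np.std(gebv) == 0.0:
        raise ValueError("zero-variance input; correlation undefined")
    return float(np.corrcoef(truth, gebv)[0, 1])


@dataclass
class EnrichmentResult:
    """Observed vs expected per-bin heritability shares and their fit."""

    observed_h2: np.ndarray
    observed_prop: np.ndarray
    expected_prop: np.ndarray
    enrichment: np.ndarray
    chi_square: float
    s_value: float


def expected_bin_props(
    panel: GenotypePanel,
    binning: MAFBinning,
    s_value: float,
) -> np.ndarray:
    """Expected per-bin heritability share under the model's S.

    Bin i's share is sum_{j in bin i} [2p_j(1-p_j)]^(S+1) over the grand
    total; at S = -1 every term is 1 and shares reduce to SNP-count
    fractions. Shares sum to one.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    if panel.maf is None:
        panel = compute_freqs(panel)
    het = 2.0 * panel.maf * (1.0 - panel.maf)
    terms = het ** (s_value + 1.0)
    n_bins = len(binning.edges) - 1
    sums = np.array(
        [terms[binning.assignment == t].sum() for t in range(n_bins)]
    )
    return sums / sums.sum()


def enrichment(fit: FitResult, expected: np.ndarray) -> EnrichmentResult:
    """Per-bin observed/expected heritability-share ratios.

    ``fit`` must be a MAF-stratified fit with one component per bin of
    ``expected``. Ratios of 1 in every bin indicate a well-calibrated S.
    """
    expected = np.asarray(expected, dtype=float)
    if fit.n_components != len(expected):
        raise ValueError(
            f"fit has {fit.n_components} components but expected shares "
            f"cover {len(expected)} bins"
        )
    observed_h2 = fit.h2_per_component
    total = observed_h2.sum()
    if total <= 0.0:
        raise ValueError("total estimated heritability is zero")
    observed_prop = observed_h2 / total
    with np.errstate(divide="ignore"):
        ratio = np.where(
            expected > 0.0, observed_prop / expected, np.inf
        )
    result = EnrichmentResult(
        observed_h2=observed_h2,
        observed_prop=observed_prop,
        expected_prop=expected,
        enrichment=ratio,
        chi_square=np.nan,
        s_value=np.nan,
    )
    result.chi_square = (
        float("inf") if np.any(expected <= 0.0) else chi_square_uniformity(result)
    )
    return result


def chi_square_uniformity(result: EnrichmentResult) -> float:
    """Goodness-of-fit statistic sum_i (O_i - E_i)^2 / E_i over the bins.

    O and E are the observed and expected heritability proportions (each
    summing to one); smaller values indicate a better-calibrated S.
    """
    o = np.asarray(result.observed_prop, dtype=float)
    e = np.asarray(result.expected_prop, dtype=float)
    if np.any(e <= 0.0):
        raise ValueError("expected proportion of zero; statistic undefined")
    return float(np.sum((o - e) ** 2 / e))


def _fit_and_predict(
    y: np.ndarray,
    grms: list[KinshipMatrix],
    train_idx: np.ndarray,
    cand_idx: np.ndarray,
):
    """Fit on the training block, BLUP the candidates, return (fit, gebv)."""
    sub = [
        KinshipMatrix(
            values=g.values[np.ix_(train_idx, train_idx)],
            individuals=[g.individuals[i] for i in train_idx],
            s_value=g.s_value,
            snp_ids=g.snp_ids,
            denominator=g.denominator,
        )
        for g in grms
    ]
    fit = fit_reml(y[train_idx], sub)
    pred = predict_gebv(fit, grms, y[train_idx], train_idx, cand_idx)
    return fit, pred.gebv


def run_s_grid(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    s_grid=S_GRID,
    model: str = "gblup-s",
    scheme: CVScheme | None = None,
    truth: np.ndarray | None = None,
    full_data_fit: bool = True,
) -> pd.DataFrame:
    """Accuracy, heritability, LRT (and enrichment for the stratified
    model) for each model S on each validation fold.

    ``truth`` is the accuracy reference for candidates (simulated TBVs);
    when omitted the phenotype itself is used, as for real data. The
    heritability / LRT / enrichment columns come from a single full-data
    fit per S when ``full_data_fit`` (the per-fold training fits are still
    used for prediction); set it False to report per-fold training-fit
    values instead.

    Returns a tidy DataFrame with one row per (S, fold).
    """
    if panel.freq_a is None:
        panel = compute_freqs(panel)
    phenotype = np.asarray(phenotype, dtype=float).ravel()
    if len(phenotype) != panel.n_individuals:
        raise ValueError("phenotype length does not match panel")
    if model not in ("gblup-s", "gblup-sms"):
        raise ValueError(f"unknown model {model!r}")
    if scheme is None:
        scheme = CVScheme(mode="holdout91", seed=0)
    if scheme.fold_assignment is None:
        scheme = make_folds(panel.individuals, scheme)
    ref = phenotype if truth is None else np.asarray(truth, dtype=float)

    binning = assign_bins(panel) if model == "gblup-sms" else None
    rows = []
    for s in s_grid:
        if model == "gblup-s":
            grms = [build_grm(panel, s)]
        else:
            grms = build_stratified_grms(panel, s, binning)
        if full_data_fit:
            fit_full = fit_reml(phenotype, grms)
            null_full = fit_reml(phenotype, [])
            stat = lrt(fit_full, null_full)
            enr = (
                enrichment(fit_full, expected_bin_props(panel, binning, s))
                if model == "gblup-sms" and fit_full.n_components == 5
                else None
            )
        for fold in scheme.candidate_folds():
            cand = np.flatnonzero(scheme.fold_assignment == fold)
            train = np.flatnonzero(scheme.fold_assignment != fold)
            fit, gebv = _fit_and_predict(phenotype, grms, train, cand)
            if not full_data_fit:
                null = fit_reml(phenotype[train], [])
                stat = lrt(fit, null)
                enr = (
                    enrichment(fit, expected_bin_props(panel, binning, s))
                    if model == "gblup-sms" and fit.n_components == 5
                    else None
                )
            h2_src = fit_full if full_data_fit else fit
            row = {
                "model": model,
                "s_model": float(s),
                "fold": int(fold),
                "n_candidates": len(cand),
                # a boundary fit (all genetic variances 0) yields constant
                # GEBVs whose correlation is undefined; report nan
                "accuracy": (
                    accuracy(ref[cand], gebv) if np.std(gebv) > 0 else np.nan
                ),
                "h2": h2_src.h2_total,
                "lrt": stat,
                "converged": h2_src.converged,
            }
            if model == "gblup-sms" and enr is not None:
                row["chi2"] = enr.chi_square
                for t in range(5):
                    row[f"enrichment_bin{t + 1}"] = enr.enrichment[t]
            rows.append(row)
    return pd.DataFrame(rows)


def select_s_by_chi_square(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    s_grid=S_GRID,
) -> tuple[float, pd.DataFrame]:
    """Pick the model S whose stratified fit minimizes the chi-square.

    Fits the five-component model once per grid S on the full data and
    returns (best S, per-S table of chi-square / h2 / enrichment).
    """
    if panel.freq_a is None:
        panel = compute_freqs(panel)
    binning = assign_bins(panel)
    rows = []
    for s in s_grid:
        grms = build_stratified_grms(panel, s, binning)
        fit = fit_reml(np.asarray(phenotype, dtype=float), grms)
        enr = enrichment(fit, expected_bin_props(panel, binning, s))
        rows.append(
            {"s_model": float(s), "chi2": enr.chi_square,
             "h2": fit.h2_total, "converged": fit.converged}
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["chi2"].idxmin(), "s_model"])
    return best, table
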