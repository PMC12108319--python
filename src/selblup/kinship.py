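"""Selection-adjusted genomic relationship matrices.

The GRM element scaling encodes an assumed MAF/effect-size relationship via
the exponent S: each centered dosage column is multiplied by
``[2p(1-p)]^(S/2)`` and the Gram matrix is divided by
``sum_i [2p_i(1-p_i)]^(S+1)``. S = 0 recovers the VanRaden matrix; S = -1
recovers the GCTA (per-SNP standardized) matrix. SNPs can be partitioned
into five MAF bins, each contributing its own GRM and variance component.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype_io import GenotypePanel, compute_freqs

logger = logging.getLogger(__name__)

#: Bin edges of the five-way MAF partition (bin 1 is [0.01, 0.1], the rest
#: are left-open, right-closed).
MAF_BIN_EDGES = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5)

N_BINS = len(MAF_BIN_EDGES) - 1


@dataclass
class KinshipMatrix:
    """A symmetric relatedness matrix tagged with its S and SNP set."""

    values: np.ndarray
    individuals: list[tuple[str, str]]
    s_value: float
    snp_ids: list[str]
    denominator: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match individual list")
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def check_symmetry(self, tol: float = 1e-10) -> None:
        if np.abs(self.values - self.values.T).max() > tol:
            raise ValueError("kinship matrix is not symmetric")

    def min_max_eigenvalues(self) -> tuple[float, float]:
        w = np.linalg.eigvalsh(self.values)
        return float(w[0]), float(w[-1])


@dataclass
class MAFBinning:
    """Per-SNP assignment to the five MAF bins (indices 0..4)."""

    edges: tuple[float, ...]
    assignment: np.ndarray

    def indices(self, bin_index: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == bin_index)

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=len(self.edges) - 1)


def _scaling_weights(freq_a: np.ndarray, s_value: float) -> np.ndarray:
    """[2p(1-p)]^(S/2) per SNP, computed in log space for stability."""
    het = 2.0 * freq_a * (1.0 - freq_a)
    return np.exp(0.5 * s_value * np.log(het))


def _scaled_centered_matrix(
    dosages: np.ndarray, freq_a: np.ndarray, s_value: float
) -> tuple[np.ndarray, float]:
    """Return M (scaled centered dosages) and the Eq-2-style denominator.

    Missing dosages are mean-imputed with 2p, which makes their centered
    contribution exactly zero.
    """
    het = 2.0 * freq_a * (1.0 - freq_a)
    centered = dosages - 2.0 * freq_a[None, :]
    centered = np.where(np.isnan(centered), 0.0, centered)
    m = centered * _scaling_weights(freq_a, s_value)[None, :]
    denominator = float(np.sum(het ** (s_value + 1.0)))
    return m, denominator


def build_grm(
    panel: GenotypePanel,
    s_value: float,
    snp_subset: np.ndarray | None = None,
) -> KinshipMatrix:
    """Construct the selection-adjusted GRM G = M M' / sum [2p(1-p)]^(S+1).

    ``snp_subset`` restricts the construction to the given SNP column
    indices. Every contributing SNP must be polymorphic (0 < p < 1): with
    negative S a monomorphic SNP has an undefined (infinite) weight.
    """
    if panel.freq_a is None:
        panel = compute_freqs(panel)
    if snp_subset is None:
        idx = np.arange(panel.n_snps)
    else:
        idx = np.asarray(snp_subset)
        if idx.size == 0:
            raise ValueError("empty SNP subset")
    freq = panel.freq_a[idx]
    if np.any(np.isnan(freq)) or np.any((freq <= 0.0) | (freq >= 1.0)):
        raise ValueError(
            "monomorphic or all-missing SNP in GRM subset; "
            "zero-variance scaling is undefined"
        )
    m, denom = _scaled_centered_matrix(panel.dosages[:, idx], freq, s_value)
    g = (m @ m.T) / denom
    g = 0.5 * (g + g.T)
    return KinshipMatrix(
        values=g,
        individuals=list(panel.individuals),
        s_value=float(s_value),
        snp_ids=[panel.snps[i].snp_id for i in idx],
        denominator=denom,
    )


def assign_bins(panel: GenotypePanel) -> MAFBinning:
    """Assign each SNP to one of the five MAF bins.

    Bin 1 covers [0.01, 0.1]; the remaining bins are (lower, upper], so a
    boundary MAF belongs to the lower-labeled bin.
    """
    if panel.maf is None:
        panel = compute_freqs(panel)
    maf = panel.maf
    lo, hi = MAF_BIN_EDGES[0], MAF_BIN_EDGES[-1]
    if np.any(np.isnan(maf)) or np.any((maf < lo) | (maf > hi)):
        raise ValueError(
            f"MAF outside [{lo}, {hi}]; apply QC before binning"
        )
    inner = np.array(MAF_BIN_EDGES[1:-1])
    assignment = np.digitize(maf, inner, right=True)
    return MAFBinning(edges=MAF_BIN_EDGES, assignment=assignment)


def build_stratified_grms(
    panel: GenotypePanel,
    s_value: float,
    binning: MAFBinning | None = None,
) -> list[KinshipMatrix]:
    """One selection-adjusted GRM per non-empty MAF bin.

    Empty bins are dropped with a logged warning; each returned GRM keeps
    its own denominator (the per-bin variance component absorbs the scale).
    """
    if panel.freq_a is None:
        panel = compute_freqs(panel)
    if binning is None:
        binning = assign_bins(panel)
    grms: list[KinshipMatrix] = []
    for t in range(N_BINS):
        idx = binning.indices(t)
        if idx.size == 0:
            lo, hi = binning.edges[t], binning.edges[t + 1]
            msg = f"MAF bin {t + 1} ({lo}-{hi}) is empty; component dropped"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        grms.append(build_grm(panel, s_value, snp_subset=idx))
    if not grms:
        raise ValueError("all MAF bins are empty")
    return grms


def write_grm(matrix: KinshipMatrix, prefix: str | Path) -> None:
    """Write GCTA text format: prefix.grm.gz, prefix.grm.id, JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = matrix.n
    n_snps = len(matrix.snp_ids)
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_snps}\t"
                         f"{matrix.values[i, j]:.12g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for fid, iid in matrix.individuals:
            fh.write(f"{fid}\t{iid}\n")
    meta = {
        "s_value": matrix.s_value,
        "denominator": matrix.denominator,
        "snp_ids": matrix.snp_ids,
    }
    with open(f"{prefix}.grm.meta.json", "w") as fh:
        json.dump(meta, fh)


def read_grm(prefix: str | Path) -> KinshipMatrix:
    """Read a GRM written by :func:`write_grm` (lossless round-trip)."""
    prefix = Path(prefix)
    id_path = Path(f"{prefix}.grm.id")
    if not id_path.exists():
        raise FileNotFoundError(id_path)
    individuals = []
    with open(id_path) as fh:
        for line in fh:
            parts = line.split()
            individuals.append((parts[0], parts[1]))
    n = len(individuals)

    values = np.full((n, n), np.nan)
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for line in fh:
            i_s, j_s, _, v = line.split()
            i, j = int(i_s) - 1, int(j_s) - 1
            if i >= n or j >= n:
                raise ValueError("GRM index exceeds the .grm.id individual count")
            values[i, j] = values[j, i] = float(v)
    if np.isnan(values).any():
        raise ValueError("truncated GRM file: missing lower-triangle entries")

    meta_path = Path(f"{prefix}.grm.meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        s_value = meta["s_value"]
        denominator = meta["denominator"]
        snp_ids = meta["snp_ids"]
    else:
        s_value, denominator, snp_ids = float("nan"), 1.0, []
    return KinshipMatrix(
        values=values,
        individuals=individuals,
        s_value=s_value,
        snp_ids=snp_ids,
        denominator=denominator,
    )
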