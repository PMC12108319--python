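"""PLINK binary genotype I/O, allele frequencies, and SNP quality control.

Genotypes are held as an individuals x SNPs dosage matrix counting copies of
the A1 allele of the ``.bim`` file, with ``numpy.nan`` marking missing calls.
QC mirrors common practice for SNP-chip data: per-SNP missing-rate, exact
Hardy-Weinberg, and minor-allele-frequency filters applied in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = np.nan

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# PLINK 2-bit codes (per individual, low bits first within each byte):
# 00 -> hom A1 (dosage 2), 01 -> missing, 10 -> het (1), 11 -> hom A2 (0)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

# 256 x 4 lookup: byte value -> dosages of the four individuals it packs
_BYTE_LUT = np.empty((256, 4))
for _b in range(256):
    for _i in range(4):
        _BYTE_LUT[_b, _i] = _CODE_TO_DOSAGE[(_b >> (2 * _i)) & 0b11]

_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


@dataclass(frozen=True)
class SNPRecord:
    """Identity of one biallelic marker."""

    chromosome: str
    snp_id: str
    position: int
    allele_a1: str
    allele_a2: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position for SNP {self.snp_id}")


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with marker metadata.

    ``dosages[j, i]`` counts copies of allele A1 of SNP ``i`` carried by
    individual ``j`` (0, 1, 2, or nan for missing). ``freq_a`` is the
    frequency of the counted (A1) allele; ``maf`` is the folded minor-allele
    frequency, ``min(freq_a, 1 - freq_a)``.
    """

    individuals: list[tuple[str, str]]
    snps: list[SNPRecord]
    dosages: np.ndarray
    freq_a: np.ndarray | None = None
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the SNP columns in ``index`` (order kept)."""
        index = np.asarray(index)
        return GenotypePanel(
            individuals=list(self.individuals),
            snps=[self.snps[i] for i in index],
            dosages=self.dosages[:, index],
            freq_a=None if self.freq_a is None else self.freq_a[index],
            maf=None if self.maf is None else self.maf[index],
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            individuals=[self.individuals[i] for i in index],
            snps=list(self.snps),
            dosages=self.dosages[index, :],
            freq_a=self.freq_a,
            maf=self.maf,
        )


@dataclass(frozen=True)
class QCParams:
    """Thresholds for sequential SNP filtering.

    ``hwe_p_threshold`` defaults to 1e-5; users following the stricter
    PLINK-tutorial convention can pass 1e-6.
    """

    max_missing_rate: float = 0.05
    hwe_p_threshold: float = 1e-5
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "hwe_p_threshold", "min_maf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_hwe: int
    n_removed_maf: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_removed_missing + self.n_removed_hwe + self.n_removed_maf
        if self.n_retained != self.n_input - removed:
            raise ValueError("QC report totals inconsistent")

    def __str__(self) -> str:
        return (
            f"QC: {self.n_input} SNPs in; removed {self.n_removed_missing} "
            f"(missingness), {self.n_removed_hwe} (HWE), "
            f"{self.n_removed_maf} (MAF); {self.n_retained} retained"
        )


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1.9 binary trio ``prefix``.bed/.bim/.fam.

    The .bed must be SNP-major. The counted allele is A1 of the .bim;
    individual and SNP order follow the .fam and .bim.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    individuals = list(zip(fam[0], fam[1]))
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    snps = [
        SNPRecord(
            chromosome=row[0], snp_id=row[1], position=int(row[3]),
            allele_a1=row[4], allele_a2=row[5],
        )
        for row in bim.itertuples(index=False)
    ]

    n, m = len(individuals), len(snps)
    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK .bed file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{bed_path}: only SNP-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ValueError(
            f"{bed_path}: file length {len(raw)} inconsistent with "
            f"{n} individuals x {m} SNPs (expected {expected})"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # decode: each byte expands to 4 dosages; trim the padding individuals
    dosages = _BYTE_LUT[body].reshape(m, bytes_per_snp * 4)[:, :n].T.copy()
    return GenotypePanel(individuals=individuals, snps=snps, dosages=dosages)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK 1.9 SNP-major binary trio."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.n_individuals, panel.n_snps

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for fid, iid in panel.individuals:
            fh.write(f"{fid} {iid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in panel.snps:
            fh.write(
                f"{s.chromosome} {s.snp_id} 0 {s.position} "
                f"{s.allele_a1} {s.allele_a2}\n"
            )

    bytes_per_snp = (n + 3) // 4
    out = bytearray(_BED_MAGIC + bytes([_SNP_MAJOR]))
    for i in range(m):
        col = panel.dosages[:, i]
        buf = bytearray(bytes_per_snp)
        for j in range(n):
            x = col[j]
            code = 0b01 if np.isnan(x) else _DOSAGE_TO_CODE[float(x)]
            buf[j // 4] |= code << (2 * (j % 4))
        out += buf
    prefix.with_suffix(".bed").write_bytes(bytes(out))


def round_dosages(panel: GenotypePanel) -> GenotypePanel:
    """Round fractional (imputed) dosages to the nearest integer code.

    Ties at .5 round half away from zero (0.5 -> 1, 1.5 -> 2); missing
    entries pass through unchanged.
    """
    x = panel.dosages
    finite = x[~np.isnan(x)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosages outside [0, 2]")
    # entries are nonnegative, so floor(x + 0.5) is round-half-away-from-zero
    rounded = np.floor(x + 0.5)
    rounded = np.where(np.isnan(x), np.nan, np.clip(rounded, 0, 2))
    return replace(panel, dosages=rounded, freq_a=None, maf=None)


def compute_freqs(panel: GenotypePanel) -> GenotypePanel:
    """Fill per-SNP counted-allele frequency and folded MAF.

    freq_a = (sum of non-missing dosages) / (2 x non-missing call count);
    an all-missing SNP gets nan frequencies.
    """
    x = panel.dosages
    n_called = np.sum(~np.isnan(x), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_a = np.nansum(x, axis=0) / (2.0 * n_called)
    freq_a = np.where(n_called == 0, np.nan, freq_a)
    maf = np.minimum(freq_a, 1.0 - freq_a)
    return replace(panel, freq_a=freq_a, maf=maf)


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Exact Hardy-Weinberg test p-value for one SNP.

    Enumerates heterozygote counts conditional on the observed allele counts
    and sums the probabilities of all configurations no more probable than
    the observed one (two-sided exact conditional test, no mid-p).
    Monomorphic SNPs return 1.
    """
    n_hom_a, n_het, n_hom_b = genotype_counts
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("no genotype calls")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    # valid het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * math.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, n_het)]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    called = col[~np.isnan(col)]
    return (
        int(np.sum(called == 2)),
        int(np.sum(called == 1)),
        int(np.sum(called == 0)),
    )


def apply_qc(
    panel: GenotypePanel, params: QCParams | None = None
) -> tuple[GenotypePanel, QCReport]:
    """Sequential SNP filtering: missing rate, then HWE, then MAF.

    A SNP failing several filters is counted once, at the first filter it
    fails. Frequencies of the retained panel are recomputed. Raises if no
    SNP survives.
    """
    if params is None:
        params = QCParams()
    if panel.freq_a is None:
        panel = compute_freqs(panel)

    x = panel.dosages
    n = panel.n_individuals
    missing_rate = np.isnan(x).sum(axis=0) / n
    fail_missing = missing_rate > params.max_missing_rate

    fail_hwe = np.zeros(panel.n_snps, dtype=bool)
    for i in np.flatnonzero(~fail_missing):
        if hwe_test(_genotype_counts(x[:, i])) < params.hwe_p_threshold:
            fail_hwe[i] = True

    maf = panel.maf
    fail_maf = ~fail_missing & ~fail_hwe & (np.isnan(maf) | (maf < params.min_maf))

    keep = ~(fail_missing | fail_hwe | fail_maf)
    report = QCReport(
        n_input=panel.n_snps,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise ValueError("QC removed every SNP; nothing retained")
    return compute_freqs(panel.subset_snps(np.flatnonzero(keep))), report


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited FID IID VALUE phenotype file.

    A header line is detected by a non-numeric third field; the missing
    code is "NA". Returns a DataFrame with columns fid, iid, value.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().split()
    if len(first) < 3:
        raise ValueError(f"{path}: expected at least 3 columns")
    try:
        float(first[2])
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(
        path, sep=r"\s+", header=header, usecols=[0, 1, 2], na_values=["NA"]
    )
    df.columns = ["fid", "iid", "value"]
    df["fid"] = df["fid"].astype(str)
    df["iid"] = df["iid"].astype(str)
    df["value"] = df["value"].astype(float)
    return df


def write_phenotypes(
    df: pd.DataFrame | None,
    path: str | Path,
    *,
    individuals: list[tuple[str, str]] | None = None,
    values: np.ndarray | None = None,
) -> None:
    """Write FID IID VALUE, "NA" for missing."""
    if df is None:
        df = pd.DataFrame(
            {"fid": [f for f, _ in individuals],
             "iid": [i for _, i in individuals],
             "value": np.asarray(values, dtype=float)}
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            v = "NA" if pd.isna(row.value) else repr(float(row.value))
            fh.write(f"{row.fid} {row.iid} {v}\n")
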