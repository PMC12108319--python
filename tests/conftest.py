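import numpy as np
import pytest

from selblup.genotype_io import GenotypePanel, SNPRecord, compute_freqs


def make_panel(dosages, freqs=True) -> GenotypePanel:
    """Build a panel from a raw dosage array with generated metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    panel = GenotypePanel(
        individuals=[("f", f"i{j}") for j in range(n)],
        snps=[
            SNPRecord(chromosome="1", snp_id=f"s{i}", position=i + 1,
                      allele_a1="A", allele_a2="B")
            for i in range(m)
        ],
        dosages=dosages,
    )
    return compute_freqs(panel) if freqs else panel


@pytest.fixture
def panel_factory():
    return make_panel


@pytest.fixture(scope="session")
def qc_panel():
    """A QC-clean synthetic panel shared across read-only tests."""
    import selblup as sb

    panel = sb.generate_panel(
        sb.SyntheticPanelConfig(n_individuals=200, n_snps=600, seed=42)
    )
    panel, _ = sb.apply_qc(panel)
    return panel
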