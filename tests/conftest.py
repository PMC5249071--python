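import numpy as np
import pytest

from snpreclass import SnpPanel, SnpRecord, generate_reference_panel


@pytest.fixture(scope="session")
def reference_panel() -> SnpPanel:
    """The default calibrated 70-SNP synthetic reference panel."""
    return generate_reference_panel(seed=1)


@pytest.fixture
def single_snp() -> SnpRecord:
    return SnpRecord("rs_demo", risk_allele_freq=0.3, odds_ratio=1.2)


@pytest.fixture
def null_panel() -> SnpPanel:
    """Three SNPs with no effect (odds ratio 1)."""
    return SnpPanel(
        SnpRecord(f"null{i}", risk_allele_freq=p, odds_ratio=1.0)
        for i, p in enumerate((0.1, 0.3, 0.5))
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
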