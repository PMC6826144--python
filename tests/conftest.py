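import numpy as np
import pytest

from telomr.panel import SNPPanel, SNPRecord, default_panel


@pytest.fixture(scope="session")
def panel() -> SNPPanel:
    return default_panel()


def make_panel(eaf, beta, se=None, r2=None) -> SNPPanel:
    """Build a small ad-hoc panel for simulation tests."""
    eaf = np.atleast_1d(np.asarray(eaf, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    se = np.full_like(beta, 0.01) if se is None else np.atleast_1d(np.asarray(se, float))
    snps = [
        SNPRecord(
            rsid=f"rs{i + 1}", chrom="1", pos=1000 * (i + 1),
            effect_allele="A", other_allele="G",
            eaf=float(p), beta_sd=float(b), se_sd=float(s),
        )
        for i, (p, b, s) in enumerate(zip(eaf, beta, se))
    ]
    r2_m = np.eye(len(snps)) if r2 is None else np.asarray(r2, dtype=float)
    return SNPPanel(snps=snps, r2=r2_m)


@pytest.fixture(scope="session")
def tiny_panel() -> SNPPanel:
    return make_panel([0.3, 0.6], [0.08, 0.05])
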