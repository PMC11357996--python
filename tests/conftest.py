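import numpy as np
import pytest

from mutlink import genotype, simulate


@pytest.fixture(scope="session")
def reference():
    """One 1.2-kb random transcript standing in for a captured CHIP gene."""
    return simulate.random_reference(["DNMT3A"], length=1200, seed=7)


@pytest.fixture(scope="session")
def snv_site(reference):
    base = reference["DNMT3A"][599]
    alt = "T" if base != "T" else "C"
    return genotype.VariantSite("DNMT3A", 600, base, alt, "R882H")


@pytest.fixture(scope="session")
def clean_dataset(reference, snv_site):
    """Error-free simulation: every stage should be exact on it."""
    cfg = simulate.SimConfig(
        n_cells=30, clone_fraction=0.3, sites=(snv_site,),
        sub_rate=0.0, ins_rate=0.0, del_rate=0.0, seed=11,
    )
    return simulate.simulate_dataset(cfg, reference)


@pytest.fixture(scope="session")
def noisy_dataset(reference, snv_site):
    """Default Nanopore-like error rates."""
    cfg = simulate.SimConfig(
        n_cells=30, clone_fraction=0.3, sites=(snv_site,), seed=13,
    )
    return simulate.simulate_dataset(cfg, reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
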