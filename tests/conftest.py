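import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import popdrift as pk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_panel(calls, populations=None, chrom=None, pos_bp=None, pos_cm=None,
                ref="A", alt="G"):
    """Tiny GenotypePanel from a nested list of dosage rows (samples x variants)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_variants = calls.shape
    if populations is None:
        populations = ["pop1"] * n_samples
    if chrom is None:
        chrom = ["1"] * n_variants
    if pos_bp is None:
        pos_bp = [1000 * (j + 1) for j in range(n_variants)]
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos_bp": np.asarray(pos_bp, dtype=np.int64),
        "id": [f"v{j+1}" for j in range(n_variants)],
        "ref_allele": ref,
        "alt_allele": alt,
        "pos_cM": np.nan if pos_cm is None else np.asarray(pos_cm, dtype=float),
    })
    samples = pd.DataFrame({
        "id": [f"s{i+1}" for i in range(n_samples)],
        "population": populations,
        "group_tags": "",
    })
    return pk.GenotypePanel(variants, samples, calls)


@pytest.fixture(scope="session")
def wf_run():
    """One seeded Wright-Fisher run shared by the LD/Ne tests."""
    panel, gmap = pk.wright_fisher_forward(seed=1)
    return panel, gmap


@pytest.fixture(scope="session")
def wf_binned(wf_run):
    panel, _ = wf_run
    return pk.r2_by_distance(panel, "pop1", pk.make_bins())
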