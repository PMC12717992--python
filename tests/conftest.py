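import numpy as np
import pandas as pd
import pytest

from landrace_popgen.panel import GenotypePanel


def make_sites(n, chrom="1", spacing=100, quality="PolyHighResolution",
               ancestral=None):
    """Site table with ref A / alt G and an explicit ancestral column."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 1 + spacing * np.arange(n),
            "ref": "A",
            "alt": "G",
            "ancestral": ancestral if ancestral is not None else "A",
            "quality_class": quality,
        }
    )


def make_panel(dosage, pops=None, coding="alt", **site_kwargs):
    """Panel from a raw dosage array; samples s0.. mapped to populations."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    sample_ids = [f"s{i}" for i in range(n_samples)]
    if pops is None:
        pops = ["pop1"] * n_samples
    return GenotypePanel(
        sample_ids=sample_ids,
        pop_of_sample=dict(zip(sample_ids, pops)),
        sites=make_sites(n_sites, **site_kwargs),
        dosage=dosage,
        coding=coding,
    )


def random_panel(rng, n_samples=5, n_sites=20, missing_rate=0.0, pops=None):
    dosage = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = -1
    anc = rng.choice(["A", "G"], size=n_sites)
    panel = make_panel(dosage, pops=pops)
    panel.sites["ancestral"] = anc
    return panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def write_popmap(path, samples, pops):
    pd.DataFrame({"sample": samples, "population": pops}).to_csv(
        path, sep="\t", index=False
    )
    return path
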