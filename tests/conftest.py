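import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from epiarray import build_profile, filter_by_flags
from epiarray.arrayio import RawArraySet
from epiarray.simdata import SimConfig, simulate_dataset

settings.register_profile("det", derandomize=True, max_examples=100)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed-class dataset with planted effects and its ground truth."""
    cfg = SimConfig(
        n_transcripts={"mRNA": 300, "lncRNA": 80, "snoRNA": 20},
        frac_dm_up=0.1,
        frac_dm_down=0.1,
        frac_de_up=0.05,
        frac_de_down=0.05,
        seed=7,
    )
    raw, truth = simulate_dataset(cfg)
    return cfg, raw, truth


@pytest.fixture(scope="session")
def small_profile(small_sim):
    _, raw, _ = small_sim
    return build_profile(filter_by_flags(raw))


def make_raw(cy5, cy3, flags=None, spikein=None, groups=("g1", "g1", "g2", "g2")):
    """Hand-build a RawArraySet from per-probe intensity rows."""
    cy5 = np.asarray(cy5, dtype=float)
    cy3 = np.asarray(cy3, dtype=float)
    n_probes, n_samples = cy5.shape
    probe_ids = [f"probe{i}" for i in range(n_probes)]
    samples = [f"s{i}" for i in range(n_samples)]
    if flags is None:
        flags = np.full((n_probes, n_samples), "P", dtype=object)
    if spikein is None:
        spikein = ["none"] * n_probes
    probes = pd.DataFrame(
        {
            "transcript_id": [f"tx{i}" for i in range(n_probes)],
            "gene_symbol": [f"g{i}" for i in range(n_probes)],
            "rna_class": ["mRNA"] * n_probes,
            "spikein": spikein,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    sheet = pd.DataFrame(
        {"group": list(groups)}, index=pd.Index(samples, name="sample_id")
    )
    return RawArraySet(
        probes=probes,
        samples=sheet,
        cy5=pd.DataFrame(np.where(cy5 > 0, cy5, np.nan), index=probes.index, columns=samples),
        cy3=pd.DataFrame(np.where(cy3 > 0, cy3, np.nan), index=probes.index, columns=samples),
        flags=pd.DataFrame(flags, index=probes.index, columns=samples),
    )
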