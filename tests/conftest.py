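import numpy as np
import pandas as pd
import pytest

from tandem5hmc import SimConfig, simulate_dataset
from tandem5hmc.datatypes import CytosineProportions, SampleFrame


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_cpg=600,
        n_tumor=10,
        n_nontumor=3,
        n_genes=40,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """One small synthetic dataset shared across read-only tests."""
    return simulate_dataset(small_cfg)


def props_from_5hmc(h: np.ndarray, locus_ids=None, sample_ids=None) -> CytosineProportions:
    """Wrap a 5hmC matrix into a valid proportions container (pC absorbs
    the remainder, 5mC set to zero)."""
    h = np.asarray(h, dtype=float)
    idx = pd.Index(locus_ids if locus_ids is not None else [f"cg{i:06d}" for i in range(h.shape[0])])
    cols = pd.Index(sample_ids if sample_ids is not None else [f"S{j}" for j in range(h.shape[1])])
    zeros = np.zeros_like(h)
    return CytosineProportions(
        pd.DataFrame(1.0 - h, index=idx, columns=cols),
        pd.DataFrame(zeros, index=idx, columns=cols),
        pd.DataFrame(h, index=idx, columns=cols),
    )


def sample_frame(
    groups,
    subtypes=None,
    ages=None,
    sexes=None,
    times=None,
    events=None,
    ids=None,
) -> SampleFrame:
    n = len(groups)
    ids = ids if ids is not None else [f"S{j}" for j in range(n)]
    tab = pd.DataFrame(
        {
            "group": groups,
            "subtype": subtypes if subtypes is not None else ["glioma" if g == "tumor" else "nontumor" for g in groups],
            "age": ages if ages is not None else [10.0] * n,
            "sex": sexes if sexes is not None else ["F"] * n,
            "death_time": times if times is not None else [np.nan] * n,
            "death_event": events if events is not None else [np.nan] * n,
            "recurrence_time": times if times is not None else [np.nan] * n,
            "recurrence_event": events if events is not None else [np.nan] * n,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return SampleFrame(tab)
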