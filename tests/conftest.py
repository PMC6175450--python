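import numpy as np
import pytest

from homeodiv import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def cohort_arrays(families):
    """Flatten a cohort into (gene_ids, F, SD, within-family index pairs)."""
    genes, F, SD = [], [], []
    for fam in families:
        for m in fam.members:
            genes.append(m.gene_id)
            F.append(m.fpkm)
            SD.append(m.fpkm_sd)
    F, SD = np.asarray(F), np.asarray(SD)
    gi = {g: i for i, g in enumerate(genes)}
    pairs = [
        (gi[a], gi[b])
        for fam in families
        for i, a in enumerate(fam.gene_ids)
        for b in fam.gene_ids[i + 1 :]
    ]
    return genes, F, SD, pairs


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate_cohort(n_per_pattern=3, noise_sd=0.1, seed=5)
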